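# Methods

This note documents the modelling choices behind `disann`: what each
component assumes, which parameters matter, what the synthetic data does and
does not emulate, and the numerical conventions.

## Task and data model

The task is single-class named-entity recognition: find every *disability
mention* in an abstract.  A mention is a contiguous token span inside one
sentence; nested and discontinuous mentions are out of scope (the reference
corpora for this task contain none).  Internally spans are encoded as BIO2
for the tagger (`B-DIS` opens every mention) and decoded back to spans before
scoring; the encoding is invisible to evaluation, which is span-based and
strict.  Ill-formed tagger output (an `I-` with no open mention of the same
label) is repaired by promoting the tag to `B-` — the standard CoNLL
convention that keeps evaluation total.

Character offsets are 0-based half-open; token spans are inclusive indices.
The tokenizer is rule-based: maximal runs of word characters, single
punctuation characters otherwise.  Parentheses are therefore always
standalone tokens, which the acronym rules require.  There is no
language-specific morphology; the same tokenizer serves English and Spanish
text.  The inline-annotation dialect (`<dis>…</dis>` by default) is
configurable because the on-disk format of distributed corpora varies.

## Embeddings

A *stack* is an ordered list of per-token embedding providers whose outputs
are concatenated.  Components are frozen during tagger training: the tagger
adapts to the representation, never the reverse.  Static tables use exact,
case-sensitive lookup by default (capitalization distinguishes acronyms from
words), with an optional lowercase fallback; out-of-vocabulary words map to
the zero vector by default, optionally the table mean.  Components are not
normalized before concatenation — scale differences are absorbed by the
encoder's input weights.

### Contextual character embeddings

The forward model is a one-layer LSTM over the character stream trained to
predict the next character; the backward model is the same machinery on the
reversed stream.  A word's embedding is `[forward state after its last
character ‖ backward state after (having just consumed) its first
character]`, so each half summarizes one full side of the sentence.  The
backward-extraction position follows the published construction of
contextual string embeddings that this component re-implements.  Sentences
are rendered with single spaces between tokens; the hidden state resets at
document/window boundaries.  Training uses truncated backpropagation over
fixed-length windows (`chars_per_batch`, default 128), Adam with gradient
clipping, and a held-out tail slice whose per-character cross-entropy is
logged.  Defaults (hidden 64, character dimension 16) are desk-scale; the
sizes used for full-scale pretraining in the literature are far larger and
are not claimed here.

## Tagger

One bidirectional LSTM layer (default 128 units per direction; the reference
benchmarks use 48) over the stack output, a linear projection to tag scores,
and a linear-chain CRF with learned transitions.  Transitions are initialized
at zero with forbidden entries (into START, out of STOP) at −10⁴; no hard
BIO mask is applied by default — the CRF learns tag grammar from data — but a
`strict_bio` flag masks invalid `I-` transitions at decode time.  Training
minimizes the exact CRF negative log-likelihood (forward recursion in log
space) by Adam with per-epoch learning-rate decay (default 0.95) and
global-norm gradient clipping at 5.  Sentences are processed individually;
gradients accumulate over a batch (default 8) before each update.

Model selection: 10–15% of training documents (seeded choice) are held out
as a development split; the snapshot with the best strict dev F1 is returned,
preferring the most recent snapshot on ties (later epochs are better trained;
with a small dev set ties are common).  All randomness — initialization,
shuffling, the dev split — flows from one seed, and computation is float64 on
one thread, so runs are bit-reproducible.  Viterbi ties break toward the
lowest tag index, making decoding deterministic even for degenerate scores.

## Acronym module

Two rules, applied per abstract to *predicted* mentions only (gold is never
read):

1. **Detection.** A candidate is a token of ≥ 2 characters, uppercase letters
   only (digits and punctuation disqualify), enclosed in parenthesis tokens,
   whose opening parenthesis is at most one word after the end of a predicted
   mention.  Only the post-mention position is searched: the worked examples
   in the literature all show the acronym after the term (a pre-mention
   search exists behind a flag, default off).
2. **Propagation.** The linked mention is extended to cover `( ACRO )` as one
   mention, and every other exact, case-sensitive occurrence of the acronym
   in the same document becomes a single-token predicted mention, skipping
   positions already inside a prediction.

The module is monotone (never removes a span) and idempotent.  A propagated
standalone acronym counts as its own mention, consistent with the worked
example that counts the definition and a later bare occurrence as two
detected instances.  Propagation never crosses abstract boundaries.

## Evaluation

Strict matching: a predicted span is correct only on exact boundary and
label equality; partial overlaps count as both a false positive and a false
negative.  Counts are pooled over the whole corpus before computing P/R/F
(micro-averaging), 0/0 conventions give 0, and tables print metrics ×100
with two decimals.  Multi-seed runs aggregate per-metric mean and sample
standard deviation (n−1); aggregation refuses to mix A− and A+ reports.

## Crosslingual transfer

Supervised alignment maps the *source* space into the *target* space (not
both into a third space): `W = UVᵀ` from the SVD of `XᵀY` over
lexicon-paired rows, the closed-form orthogonal Procrustes solution.  Lexicon
pairs with an out-of-vocabulary side are skipped and counted; duplicate
source words keep all pairs (least squares handles multiplicity); fewer
usable pairs than dimensions triggers a warning.  Zero-shot runs train the
tagger on source text embedded through `W` and predict target text with the
target table unchanged.  Contextual character embeddings are excluded from
the crosslingual stack: no alignment is defined for them here, so the
zero-shot protocol is static-only — an approximation of full-scale
multilingual contextual systems, which are out of scope.

## Synthetic data: what it emulates, what it does not

The generator emulates the structural properties the pipeline depends on:

- **Long, compositional mentions.** Entity phrases are built from a seeded
  inventory of heads ("perdida", "trastornos", …) and modifiers ("visual",
  "del movimiento", …), averaging ~2.3 tokens — matching the observation
  that disability mentions run long — and giving a diverse phrase set whose
  unseen combinations test boundary generalization.
- **Acronym ecology.** A configurable fraction of mentions (default 0.3) is
  defined as `phrase ( ACRO )` with the acronym derived from the phrase
  initials; the gold annotation covers the whole definition, and the bare
  acronym is guaranteed to re-occur later in the same abstract as its own
  gold mention.  Because the compositional lexicon makes most acronyms rare,
  a learned tagger reliably misses some of them — the regime the rule module
  exists for.  Background sentences and post-mention positions also carry
  lowercase parenthetical asides, so an opening parenthesis alone never
  implies extension.
- **A shared language.** The background vocabulary is a property of the
  language (its own seed), not of the split, so train and test corpora share
  it — as real corpora do.
- **Distributional structure.** Generated embeddings are unit-norm random
  vectors, optionally with group structure: words of one semantic group
  (here, the disability terms) share a centroid with cohesion 0.7.  This
  emulates the clustering of real embedding spaces — that semantically
  related words lie near each other is precisely the property that makes
  pre-trained vectors useful to a tagger, and without it word-class
  membership in low dimensions is not linearly separable at all.
- **A parallel pseudo-language.** Deterministic vowel rotation with
  consonants and acronyms preserved, so the two "languages" share subword
  skeletons; target embeddings are the source vectors under a seeded random
  orthogonal rotation, perturbed by Gaussian noise (default 0.1) and
  renormalized — real bilingual spaces are never exact rotations, and the
  noise is what separates monolingual from zero-shot performance.

It does **not** emulate: real lexical statistics or syntax, annotation noise,
sentence-length and document-length distributions of scientific abstracts,
polysemy, or genuinely out-of-vocabulary test words.  Passing the synthetic
benchmarks therefore shows that the machinery is correct and that the
qualitative orderings (stacked ≥ best single representation; monolingual >
noisy zero-shot; A+ ≥ A− in recall) emerge under controlled conditions — not
that the specific scores transfer to real corpora, whose headline numbers
additionally require large pretrained embeddings and in-domain language
models.

## Reference study conditions

`disann.benchmarks` freezes the desk-scale problem sizes: ~180 training and
~50–60 test sentences (40/11 documents), embedding dimensions 32–48, one
BiLSTM layer of 48 units per direction, 20–35 epochs; character LMs with
hidden size 24 trained for 250 windows of 96 characters on ~20k characters
of generated text.  These sizes were chosen so a full acceptance run
completes in minutes on one CPU while leaving each benchmark comfortably
solvable; the corpora and tables are fixed resources of the tasks, and the
training seed is the quantity varied across runs.

## Numerical conventions and edge cases

- Float64 throughout; forbidden CRF transitions use −10⁴ rather than −∞ to
  keep arithmetic NaN-free; log-sum-exp is max-shifted.
- Empty sentences decode to no spans; the empty corpus, an all-OOV lexicon,
  zero usable alignment pairs, and a corpus shorter than one LM window are
  errors, not silent degenerate results.
- JSON checkpoints round-trip float64 exactly (shortest-repr serialization),
  so save → load → predict is bit-identical to predict.
- Duplicate words in a vector file keep the first row (warned); a dimension
  change mid-file is an error naming the line.

## Limitations

- Single entity class; no nested or discontinuous mentions.
- Static-only zero-shot stack (see above); no subword inventories.
- The autodiff engine is deliberately minimal (no batching across sentences,
  no GPU); it is sized for corpora of hundreds of sentences, not hundreds of
  thousands.
- Static-embedding fine-tuning is not implemented; components are always
  frozen.
- The acronym rules are literal: lowercase, digit-bearing, or hyphenated
  abbreviations ("cp", "CP2", "C-P") are never detected, by design.
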