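"""Synthetic corpora, embedding tables, and bilingual lexica for the pipeline.

The generator emulates the structural properties the pipeline depends on in
biomedical abstracts annotated with disabilities: multi-word mentions (the
phrase inventory averages ~2.3 tokens, matching the observation that
disability mentions run long), parenthesized acronym definitions whose bare
acronym re-occurs later in the same abstract, and — in bilingual mode — a
parallel pseudo-language built by a deterministic character rewrite so the
two "languages" share consonant skeletons, plus embedding tables related by
a planted orthogonal rotation so alignment recovery is exactly testable.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass, field

import numpy as np

from .corpus import AnnotatedDocument, Corpus, EntitySpan, Token
from .embeddings import StaticEmbeddingTable

__all__ = [
    "DEFAULT_LEXICON",
    "GeneratorConfig",
    "generate_corpus",
    "generate_embeddings",
    "generate_bilingual_tables",
    "generate_raw_text",
    "corpus_vocabulary",
    "translate_word",
    "translate_corpus",
    "random_orthogonal",
    "lexicon_oracle_predict",
]

# Disability mentions are built compositionally from a head ("perdida",
# "trastorno", ...) plus one or two modifiers, the way they occur in
# abstracts; generated phrases average ~2.3 tokens and their initial-letter
# acronyms are diverse, so most acronyms are rare — the regime the rule
# module exists for.
_HEADS = ["deficiencia", "perdida", "trastornos", "alteracion", "retraso",
          "deterioro", "disfuncion", "paralisis", "sordera", "ceguera",
          "hipoacusia", "afectacion", "limitacion"]
_MODIFIERS = ["visual", "auditiva", "cognitivo", "motora", "sensorial",
              "bilateral", "progresiva", "congenita", "severa", "leve",
              "global", "brusca", "neurosensorial", "sensoriomotora",
              "del movimiento", "del desarrollo", "de vision", "de audicion",
              "de memoria", "del lenguaje"]

_SYLLABLES = ["ba", "co", "du", "fe", "gi", "lo", "mu", "na", "pe", "ri",
              "sa", "te", "vi", "zo", "car", "men", "tal", "dor", "lis", "qui"]


def build_entity_lexicon(n_phrases: int = 40, seed: int = 97) -> list[str]:
    """Seeded compositional inventory of disability-like phrases."""
    rng = np.random.default_rng(seed)
    phrases: list[str] = []
    seen = set()
    while len(phrases) < n_phrases:
        head = _HEADS[int(rng.integers(len(_HEADS)))]
        k = 1 + int(rng.random() < 0.4)
        mods = rng.choice(len(_MODIFIERS), size=k, replace=False)
        phrase = " ".join([head] + [_MODIFIERS[int(m)] for m in mods])
        if phrase not in seen:
            seen.add(phrase)
            phrases.append(phrase)
    return phrases


DEFAULT_LEXICON = build_entity_lexicon()


@dataclass
class GeneratorConfig:
    seed: int = 0
    n_documents: int = 50
    sentences_per_doc: tuple[int, int] = (3, 6)
    entity_lexicon: list[str] = field(default_factory=lambda: list(DEFAULT_LEXICON))
    acronym_rate: float = 0.3  # fraction of mentions defined with "( ACRO )"
    paren_rate: float = 0.15  # background sentences with a "( word )" aside,
    # so parentheses alone are not an entity cue
    vocab_size: int = 120  # background vocabulary size
    vocab_seed: int = 97  # background vocabulary is a property of the language,
    # not of the split: train/test corpora with the same vocab_seed share it
    entity_rate: float = 0.6  # fraction of sentences bearing a mention
    bilingual: bool = False
    language: str = "es"
    split: str = "train"

    def validate(self) -> None:
        if not self.entity_lexicon:
            raise ValueError("entity lexicon must be non-empty")
        if not 0.0 <= self.acronym_rate <= 1.0:
            raise ValueError(f"acronym_rate {self.acronym_rate} outside [0,1]")
        if self.n_documents < 1 or self.vocab_size < 10:
            raise ValueError("need n_documents >= 1 and vocab_size >= 10")
        lo, hi = self.sentences_per_doc
        if not 1 <= lo <= hi:
            raise ValueError(f"bad sentences_per_doc range {self.sentences_per_doc}")


def _background_vocab(rng: np.random.Generator, size: int) -> list[str]:
    words: list[str] = []
    seen = set()
    while len(words) < size:
        n_syl = int(rng.integers(2, 4))
        w = "".join(rng.choice(_SYLLABLES) for _ in range(n_syl))
        if w not in seen:
            seen.add(w)
            words.append(w)
    return words


def _looks_like_acronym(token: str) -> bool:
    return len(token) >= 2 and token.isalpha() and token == token.upper()


def _acronym_of(phrase: str) -> str | None:
    """Uppercased ASCII initials of the phrase words; None if shorter than 2."""
    initials = []
    for w in phrase.split():
        c = unicodedata.normalize("NFKD", w[0]).encode("ascii", "ignore").decode()
        if c.isalpha():
            initials.append(c.upper())
    acro = "".join(initials)
    return acro if len(acro) >= 2 else None


def _sentence_tokens(words: list[str]) -> list[Token]:
    toks, pos = [], 0
    for w in words:
        toks.append(Token(w, pos, pos + len(w)))
        pos += len(w) + 1
    return toks


def generate_corpus(cfg: GeneratorConfig) -> Corpus | tuple[Corpus, Corpus]:
    """Generate an annotated corpus (a parallel pair in bilingual mode).

    Every acronym-defined mention is annotated over the full "phrase ( ACRO )"
    stretch and is guaranteed a later bare-acronym mention in the same
    document, so the acronym module has real recall headroom to recover.
    Output is byte-identical for a fixed config.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    background = _background_vocab(np.random.default_rng(cfg.vocab_seed), cfg.vocab_size)
    docs: list[AnnotatedDocument] = []
    for d in range(cfg.n_documents):
        sentences: list[list[str]] = []
        gold: list[set[EntitySpan]] = []
        pending_acros: list[str] = []
        lo, hi = cfg.sentences_per_doc
        n_sent = int(rng.integers(lo, hi + 1))
        for _ in range(n_sent):
            words = list(rng.choice(background, size=int(rng.integers(4, 9))))
            if rng.random() < cfg.paren_rate:
                aside = str(rng.choice(background))
                pos = int(rng.integers(0, len(words) + 1))
                words = words[:pos] + ["(", aside, ")"] + words[pos:]
            spans: set[EntitySpan] = set()
            if rng.random() < cfg.entity_rate:
                phrase = cfg.entity_lexicon[int(rng.integers(len(cfg.entity_lexicon)))]
                ptoks = phrase.split()
                insert = int(rng.integers(0, len(words) + 1))
                acro = _acronym_of(phrase) if rng.random() < cfg.acronym_rate else None
                if acro is not None:
                    mention = ptoks + ["(", acro, ")"]
                    pending_acros.append(acro)
                    tail: list[str] = []
                elif rng.random() < cfg.paren_rate:
                    # non-acronym parenthetical right after a mention (a count,
                    # a reference, ...) — not part of the annotation, so an
                    # opening parenthesis alone never implies extension
                    mention = ptoks
                    tail = ["(", str(rng.choice(background)), ")"]
                else:
                    mention = ptoks
                    tail = []
                words = words[:insert] + mention + tail + words[insert:]
                spans.add(EntitySpan(insert, insert + len(mention) - 1))
            sentences.append(words)
            gold.append(spans)
        for acro in pending_acros:  # guaranteed later bare occurrence
            words = list(rng.choice(background, size=int(rng.integers(3, 7))))
            pos = int(rng.integers(0, len(words) + 1))
            words = words[:pos] + [acro] + words[pos:]
            sentences.append(words)
            gold.append({EntitySpan(pos, pos)})
        docs.append(AnnotatedDocument(
            doc_id=f"{cfg.language}_{cfg.split}_{d:04d}",
            sentences=[_sentence_tokens(s) for s in sentences],
            gold_spans=gold,
        ))
    source = Corpus(documents=docs, language=cfg.language, split=cfg.split)
    if not cfg.bilingual:
        return source
    return source, translate_corpus(source)


_VOWEL_MAP = str.maketrans("aeiou", "eioua")


def translate_word(word: str) -> str:
    """Deterministic pseudo-translation: vowel rotation, consonants kept.

    Uppercase tokens (acronyms) and punctuation are left unchanged — acronyms
    are shared across the language pair, as they commonly are in practice.
    """
    if word == word.upper():
        return word
    return word.translate(_VOWEL_MAP)


def translate_corpus(corpus: Corpus, language: str | None = None) -> Corpus:
    """Word-by-word pseudo-translation preserving spans and structure."""
    docs = []
    for doc in corpus:
        sentences = [_sentence_tokens([translate_word(t.text) for t in sent])
                     for sent in doc.sentences]
        docs.append(AnnotatedDocument(
            doc_id=doc.doc_id.replace(corpus.language, language or "xx", 1),
            sentences=sentences,
            gold_spans=[set(s) for s in doc.gold_spans],
        ))
    return Corpus(documents=docs, language=language or "xx", split=corpus.split)


def corpus_vocabulary(*corpora: Corpus) -> list[str]:
    vocab = sorted({t.text for c in corpora for d in c for s in d.sentences for t in s})
    return vocab


def random_orthogonal(d: int, rng: np.random.Generator) -> np.ndarray:
    """Haar-ish random orthogonal matrix via QR with sign fixing."""
    A = rng.normal(size=(d, d))
    Q, R = np.linalg.qr(A)
    return Q * np.sign(np.diag(R))


def generate_embeddings(vocab: list[str], d: int, seed: int = 0,
                        rotation: np.ndarray | None = None,
                        groups: dict[str, str] | None = None,
                        cohesion: float = 0.7) -> StaticEmbeddingTable:
    """Unit-norm random vectors for ``vocab``; optionally rotated by ``rotation``.

    With ``groups``, words mapped to the same group name share a unit
    centroid and each word vector is ``sqrt(1-c^2) * noise + c * centroid``
    (renormalized), with ``c = cohesion``.  This emulates the distributional
    clustering of real embedding spaces — semantically related words (here,
    the disability terms) lie near each other — which is precisely the
    property static word vectors contribute to a tagger.  Without ``groups``
    the table is isotropically random.
    """
    if d < 2:
        raise ValueError("need d >= 2")
    rng = np.random.default_rng(seed)
    M = rng.normal(size=(len(vocab), d))
    M /= np.linalg.norm(M, axis=1, keepdims=True)
    if groups:
        names = sorted(set(groups.values()))
        centroids = rng.normal(size=(len(names), d))
        centroids /= np.linalg.norm(centroids, axis=1, keepdims=True)
        cidx = {g: i for i, g in enumerate(names)}
        c = float(cohesion)
        for row, w in enumerate(vocab):
            g = groups.get(w)
            if g is not None:
                M[row] = np.sqrt(1 - c * c) * M[row] + c * centroids[cidx[g]]
        M /= np.linalg.norm(M, axis=1, keepdims=True)
    if rotation is not None:
        M = M @ rotation
    return StaticEmbeddingTable({w: i for i, w in enumerate(vocab)}, M)


def entity_word_groups(lexicon: list[str], group: str = "disability") -> dict[str, str]:
    """Group map putting every entity-phrase word in one semantic cluster."""
    return {w: group for phrase in lexicon for w in phrase.split()}


def generate_bilingual_tables(
    vocab_src: list[str], d: int, seed: int = 0, noise: float = 0.1,
    groups: dict[str, str] | None = None, cohesion: float = 0.7,
) -> tuple[StaticEmbeddingTable, StaticEmbeddingTable, list[tuple[str, str]], np.ndarray]:
    """Source/target tables with a planted rotation, plus the word-pair lexicon.

    The target vector of ``translate_word(w)`` is the source vector of ``w``
    rotated by a seeded random orthogonal matrix Q, perturbed by Gaussian
    noise of scale ``noise`` and renormalized — real bilingual spaces are
    never exact rotations of each other, and the perturbation is what makes
    zero-shot transfer degrade relative to the monolingual run, as it does in
    practice.  Returns (src_table, tgt_table, lexicon, Q).
    """
    rng = np.random.default_rng(seed)
    src = generate_embeddings(vocab_src, d, seed=seed, groups=groups, cohesion=cohesion)
    Q = random_orthogonal(d, rng)
    tgt_vocab = [translate_word(w) for w in vocab_src]
    M = src.matrix @ Q
    if noise > 0:
        M = M + rng.normal(scale=noise, size=M.shape)
        M /= np.linalg.norm(M, axis=1, keepdims=True)
    # translation may collide (e.g. shared acronyms map to themselves): keep first
    tgt_index: dict[str, int] = {}
    rows = []
    for w, row in zip(tgt_vocab, M):
        if w not in tgt_index:
            tgt_index[w] = len(rows)
            rows.append(row)
    tgt = StaticEmbeddingTable(tgt_index, np.stack(rows))
    lexicon = list(dict.fromkeys(zip(vocab_src, tgt_vocab)))
    return src, tgt, lexicon, Q


def generate_raw_text(cfg: GeneratorConfig, min_chars: int = 20000) -> str:
    """Raw character stream for LM pretraining, from generated sentences."""
    corpus = generate_corpus(GeneratorConfig(**{**cfg.__dict__, "bilingual": False}))
    parts: list[str] = []
    total = 0
    while total < min_chars:
        for doc in corpus:
            for text in doc.sentence_texts:
                parts.append(text)
                total += len(text) + 1
                if total >= min_chars:
                    break
            if total >= min_chars:
                break
    return "\n".join(parts)


def lexicon_oracle_predict(corpus: Corpus, lexicon: list[str]) -> Corpus:
    """Frequency-oracle baseline: label every lexicon-phrase occurrence.

    On generated data (where mentions are exactly the lexicon phrases plus
    their acronym extensions) this oracle attains F1 = 1, an upper bound for
    any tagger trained on the same corpus.
    """
    phrase_tokens = [p.split() for p in lexicon]
    out_docs = []
    for doc in corpus:
        new = doc.copy()
        for s_idx, sent in enumerate(new.sentences):
            words = [t.text for t in sent]
            preds: set[EntitySpan] = set()
            acros: list[str] = []
            for ptoks in phrase_tokens:
                for i in range(len(words) - len(ptoks) + 1):
                    if words[i : i + len(ptoks)] == ptoks:
                        last = i + len(ptoks) - 1
                        # extend over a parenthesized acronym definition
                        if (last + 3 < len(words) and words[last + 1] == "("
                                and words[last + 3] == ")"
                                and _looks_like_acronym(words[last + 2])):
                            acros.append(words[last + 2])
                            last += 3
                        preds.add(EntitySpan(i, last))
            # longest-match semantics: a phrase strictly contained in another
            # match (shared-prefix lexicon entries) is not its own mention
            preds = {sp for sp in preds
                     if not any(o != sp and o.first_token <= sp.first_token
                                and sp.last_token <= o.last_token for o in preds)}
            new.pred_spans[s_idx] = preds
        # second pass: bare acronym mentions anywhere in the document
        seen_acros = {a for p in lexicon if (a := _acronym_of(p)) is not None}
        for s_idx, sent in enumerate(new.sentences):
            covered = {i for sp in new.pred_spans[s_idx] for i in sp.tokens()}
            for t_idx, tok in enumerate(sent):
                if tok.text in seen_acros and t_idx not in covered:
                    new.pred_spans[s_idx].add(EntitySpan(t_idx, t_idx))
        out_docs.append(new)
    return Corpus(documents=out_docs, language=corpus.language, split=corpus.split)
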