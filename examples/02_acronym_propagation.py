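"""Rule-based acronym detection and document-wide propagation.

A sequence tagger typically finds "cerebral palsy" but not the acronym
defined next to it.  The rules link a parenthesized all-caps token (at most
one word after a predicted mention) to that mention, extend the mention over
the parentheses, and label every other occurrence of the acronym in the
document — here turning one detected mention into two.
"""

from disann import AnnotatedDocument, EntitySpan, apply_acronym_module, tokenize

SENTENCES = (
    "There are many instruments designed to evaluate motor function "
    "in children with cerebral palsy (CP)",
    "motor function over time in children with CP",
)

doc = AnnotatedDocument(doc_id="abstract",
                        sentences=[tokenize(s) for s in SENTENCES],
                        sentence_texts=list(SENTENCES))
words = [t.text for t in doc.sentences[0]]
start = words.index("cerebral")
doc.pred_spans[0] = {EntitySpan(start, start + 1)}  # what the tagger found

result = apply_acronym_module(doc)
print("extended:", [(s, f"{a.first_token}-{a.last_token} -> {b.first_token}-{b.last_token}")
                    for s, a, b in result.extended])
print("added:", [(s, (sp.first_token, sp.last_token)) for s, sp in result.added])
for s_idx, spans in enumerate(result.doc.pred_spans):
    w = [t.text for t in result.doc.sentences[s_idx]]
    for sp in sorted(spans):
        print(f"mention (sentence {s_idx}):", " ".join(w[sp.first_token:sp.last_token + 1]))
# Two CP-bearing mentions come out: the extended definition and the bare
# acronym later in the abstract.
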