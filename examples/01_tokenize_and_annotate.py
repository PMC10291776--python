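"""Tokenization and inline-annotated abstracts.

Parses a tagged abstract into token spans, converts the gold spans to BIO
tags, and shows that re-serialization is lossless.
"""

from disann import parse_inline_annotations, render_inline, spans_to_bio

RAW = ("children with <dis>cerebral palsy</dis> (CP) were assessed\n"
       "se observa <dis>pérdida brusca de visión</dis> en el paciente")

doc = parse_inline_annotations(RAW, doc_id="example")
for sent, spans, text in zip(doc.sentences, doc.gold_spans, doc.sentence_texts):
    words = [t.text for t in sent]
    print("sentence:", words)
    for sp in sorted(spans):
        print("  gold mention:", " ".join(words[sp.first_token:sp.last_token + 1]),
              f"(tokens {sp.first_token}-{sp.last_token})")
    print("  BIO tags:", spans_to_bio(len(sent), spans))

print("round trip identical:", render_inline(doc) == RAW)
# The mention spans are inclusive token indices; BIO is only the tagger-side
# encoding — scoring always compares spans with exact boundaries.
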