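"""Rule-based acronym detection and document-wide propagation.

Sequence taggers routinely miss disability acronyms ("CP" for cerebral
palsy): the acronym token carries little lexical signal.  This post-processor
recovers them with two rules.  A candidate acronym is a parenthesized token
of two or more uppercase letters at most one word after a predicted
disability mention.  Once linked, (1) the mention is extended to cover the
parenthesized acronym, and (2) every other occurrence of the acronym in the
same document is labelled as a disability mention of its own.  The module
reads only predicted spans; gold annotations are never touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .corpus import AnnotatedDocument, EntitySpan

__all__ = ["AcronymCandidate", "PropagationResult", "find_acronym_candidates",
           "propagate", "apply_acronym_module"]


@dataclass(frozen=True)
class AcronymCandidate:
    sentence: int  # sentence index in the document
    token: int  # index of the acronym token (inside the parentheses)
    surface: str
    linked_span: EntitySpan  # the predicted mention the acronym abbreviates


@dataclass
class PropagationResult:
    doc: AnnotatedDocument
    added: list[tuple[int, EntitySpan]] = field(default_factory=list)
    extended: list[tuple[int, EntitySpan, EntitySpan]] = field(default_factory=list)


def _is_acronym_token(text: str) -> bool:
    # Two or more characters, uppercase letters only: digits and internal
    # punctuation disqualify ("CP2", "C-P" are rejected; the latter never
    # reaches here as one token because the tokenizer detaches punctuation).
    return len(text) >= 2 and text.isalpha() and text == text.upper()


def find_acronym_candidates(doc: AnnotatedDocument,
                            max_gap: int = 1) -> list[AcronymCandidate]:
    """Parenthesized all-caps acronyms within ``max_gap`` words after a predicted mention."""
    candidates = []
    for s_idx, (sent, preds) in enumerate(zip(doc.sentences, doc.pred_spans)):
        for i in range(1, len(sent) - 1):
            if (sent[i - 1].text == "(" and sent[i + 1].text == ")"
                    and _is_acronym_token(sent[i].text)):
                # "(" at token i-1; gap counts the words between the mention's
                # last token and the "(": 0 = adjacent, 1 = one word between.
                linked = None
                for sp in sorted(preds):
                    gap = (i - 1) - sp.last_token - 1
                    if 0 <= gap <= max_gap:
                        linked = sp
                if linked is not None:
                    candidates.append(AcronymCandidate(s_idx, i, sent[i].text, linked))
    return candidates


def propagate(doc: AnnotatedDocument,
              candidates: list[AcronymCandidate]) -> PropagationResult:
    """Extend linked mentions over their acronym and label all other occurrences.

    Never removes a predicted span; applying the result to itself is a no-op
    (idempotence), because an extended mention no longer has a parenthesized
    acronym *after* it and propagated occurrences are already covered.
    The input document is left untouched; a modified copy is returned.
    """
    doc = doc.copy()
    result = PropagationResult(doc=doc)
    covered: list[set[int]] = [set() for _ in doc.sentences]
    for s_idx, preds in enumerate(doc.pred_spans):
        for sp in preds:
            covered[s_idx].update(sp.tokens())

    for cand in candidates:
        preds = doc.pred_spans[cand.sentence]
        if cand.linked_span not in preds:
            continue  # replaced by an earlier extension over the same tokens
        extended = EntitySpan(cand.linked_span.first_token, cand.token + 1,
                              cand.linked_span.label)
        preds.discard(cand.linked_span)
        preds.add(extended)
        covered[cand.sentence].update(extended.tokens())
        result.extended.append((cand.sentence, cand.linked_span, extended))

    acronyms = {c.surface: c.linked_span.label for c in candidates}
    for s_idx, sent in enumerate(doc.sentences):
        for t_idx, tok in enumerate(sent):
            label = acronyms.get(tok.text)  # exact, case-sensitive match
            if label is None or t_idx in covered[s_idx]:
                continue
            new_span = EntitySpan(t_idx, t_idx, label)
            doc.pred_spans[s_idx].add(new_span)
            covered[s_idx].add(t_idx)
            result.added.append((s_idx, new_span))
    return result


def apply_acronym_module(doc: AnnotatedDocument, max_gap: int = 1) -> PropagationResult:
    """Detection followed by propagation (the A+ condition) on one document."""
    return propagate(doc, find_acronym_candidates(doc, max_gap=max_gap))
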