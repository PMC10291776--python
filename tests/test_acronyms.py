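"""Acronym candidate detection rules and document-wide propagation."""

import pytest

from disann.acronyms import apply_acronym_module, find_acronym_candidates, propagate
from disann.corpus import AnnotatedDocument, EntitySpan, tokenize
from disann.synthetic import GeneratorConfig, generate_corpus, lexicon_oracle_predict


def make_doc(*sentences: str, preds=None) -> AnnotatedDocument:
    doc = AnnotatedDocument(doc_id="d", sentences=[tokenize(s) for s in sentences],
                            sentence_texts=list(sentences))
    if preds:
        for s_idx, spans in preds.items():
            doc.pred_spans[s_idx] = {EntitySpan(a, b) for a, b in spans}
    return doc


class TestCandidateRules:
    def test_adjacent_acronym_is_linked(self):
        doc = make_doc("children with cerebral palsy ( CP )",
                       preds={0: [(2, 3)]})
        (cand,) = find_acronym_candidates(doc)
        assert cand.surface == "CP"
        assert cand.linked_span == EntitySpan(2, 3)

    def test_one_word_gap_accepted_two_rejected(self):
        near = make_doc("cerebral palsy seen ( CP )", preds={0: [(0, 1)]})
        far = make_doc("cerebral palsy was seen ( CP )", preds={0: [(0, 1)]})
        assert len(find_acronym_candidates(near)) == 1
        assert find_acronym_candidates(far) == []

    @pytest.mark.parametrize("inner", ["cp", "C", "CP2"])
    def test_rule_violations_rejected(self, inner):
        doc = make_doc(f"cerebral palsy ( {inner} )", preds={0: [(0, 1)]})
        assert find_acronym_candidates(doc) == []

    def test_hyphenated_caps_never_one_token(self):
        doc = make_doc("cerebral palsy ( C-P )", preds={0: [(0, 1)]})
        assert find_acronym_candidates(doc) == []

    def test_no_predicted_mention_no_candidate(self):
        doc = make_doc("we saw ( CP ) here")
        assert find_acronym_candidates(doc) == []


class TestPropagation:
    def test_extends_definition_and_labels_later_occurrence(self):
        doc = make_doc("children with cerebral palsy ( CP )",
                       "function over time in children with CP",
                       preds={0: [(2, 3)]})
        result = apply_acronym_module(doc)
        assert result.doc.pred_spans[0] == {EntitySpan(2, 6)}  # ... ( CP )
        assert result.doc.pred_spans[1] == {EntitySpan(6, 6)}
        assert len(result.extended) == 1 and len(result.added) == 1

    def test_no_other_occurrence_only_extension(self):
        doc = make_doc("children with cerebral palsy ( CP )", preds={0: [(2, 3)]})
        result = apply_acronym_module(doc)
        assert result.doc.pred_spans[0] == {EntitySpan(2, 6)}
        assert result.added == []

    def test_occurrence_inside_existing_span_not_duplicated(self):
        doc = make_doc("cerebral palsy ( CP )", "severe CP palsy",
                       preds={0: [(0, 1)], 1: [(0, 2)]})
        result = apply_acronym_module(doc)
        assert result.doc.pred_spans[1] == {EntitySpan(0, 2)}

    def test_propagation_is_case_sensitive(self):
        doc = make_doc("cerebral palsy ( CP )", "the word cp appears",
                       preds={0: [(0, 1)]})
        result = apply_acronym_module(doc)
        assert result.doc.pred_spans[1] == set()

    def test_monotone_and_idempotent(self):
        doc = make_doc("palsy motor disorder ( MD ) here", "later MD again MD",
                       preds={0: [(1, 2)]})
        once = apply_acronym_module(doc)
        twice = apply_acronym_module(once.doc)
        assert twice.doc.pred_spans == once.doc.pred_spans
        assert twice.added == [] and twice.extended == []
        n_in = sum(len(s) for s in doc.pred_spans)
        n_out = sum(len(s) for s in once.doc.pred_spans)
        assert n_out >= n_in

    def test_input_doc_and_gold_never_modified(self):
        doc = make_doc("cerebral palsy ( CP )", "with CP", preds={0: [(0, 1)]})
        doc.gold_spans[0] = {EntitySpan(0, 4)}
        before_gold = [set(s) for s in doc.gold_spans]
        before_pred = [set(s) for s in doc.pred_spans]
        result = apply_acronym_module(doc)
        assert doc.gold_spans == before_gold
        assert doc.pred_spans == before_pred
        assert result.doc.gold_spans == before_gold

    def test_propagate_requires_candidates_from_same_doc(self):
        doc = make_doc("nothing here")
        result = propagate(doc, [])
        assert result.doc.pred_spans == [set()]


def test_module_recovers_all_acronym_mentions_on_generated_data():
    """A tagger that finds bare phrases but never acronyms is completed to gold."""
    corpus = generate_corpus(GeneratorConfig(seed=40, n_documents=15, acronym_rate=1.0))
    lexicon = GeneratorConfig().entity_lexicon
    oracle = lexicon_oracle_predict(corpus, lexicon)
    for doc in oracle:
        # strip everything the rules should recover: un-extend definitions,
        # drop bare acronym mentions
        for s_idx, spans in enumerate(doc.pred_spans):
            stripped = set()
            for sp in spans:
                words = [t.text for t in doc.sentences[s_idx]]
                if words[sp.last_token] == ")":
                    stripped.add(EntitySpan(sp.first_token, sp.last_token - 3))
                elif not (sp.first_token == sp.last_token
                          and words[sp.first_token].isupper()):
                    stripped.add(sp)
            doc.pred_spans[s_idx] = stripped
    from disann.evaluation import evaluate_corpus
    repaired = [apply_acronym_module(d).doc for d in oracle]
    assert evaluate_corpus(repaired).f1 == 1.0
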