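"""Tokenization, inline-annotation parsing, BIO conversion, CoNLL round trips."""

import pytest
from hypothesis import given, settings, strategies as st

from disann.corpus import (
    AnnotatedDocument,
    Corpus,
    EntitySpan,
    Token,
    bio_to_spans,
    parse_inline_annotations,
    read_conll,
    render_inline,
    spans_to_bio,
    tokenize,
    write_conll,
)


class TestTokenize:
    def test_parentheses_are_standalone_tokens(self):
        assert [t.text for t in tokenize("cerebral palsy (CP)")] == [
            "cerebral", "palsy", "(", "CP", ")"]

    def test_empty_text(self):
        assert tokenize("") == []

    def test_accented_offsets(self):
        toks = tokenize("Pérdida brusca de visión")
        assert [(t.start, t.end) for t in toks] == [(0, 7), (8, 14), (15, 17), (18, 24)]

    @given(st.text(max_size=80))
    @settings(max_examples=100, deadline=None)
    def test_offsets_slice_back_to_token_text(self, text):
        for tok in tokenize(text):
            assert text[tok.start:tok.end] == tok.text

    @given(st.text(alphabet="ab (-)é.", max_size=60))
    @settings(max_examples=100, deadline=None)
    def test_tokens_sorted_and_nonoverlapping(self, text):
        toks = tokenize(text)
        for a, b in zip(toks, toks[1:]):
            assert a.end <= b.start


class TestInlineAnnotations:
    def test_single_span_over_tagged_tokens(self):
        doc = parse_inline_annotations("children with <dis>cerebral palsy</dis>")
        (spans,) = doc.gold_spans
        (span,) = spans
        words = [t.text for t in doc.sentences[0]]
        assert words[span.first_token:span.last_token + 1] == ["cerebral", "palsy"]

    def test_untagged_text_has_no_spans(self):
        doc = parse_inline_annotations("no tags here")
        assert doc.gold_spans == [set()]

    def test_unclosed_tag_reports_offset(self):
        with pytest.raises(ValueError, match="unclosed .* offset"):
            parse_inline_annotations("<dis>a</dis> <dis>b")

    def test_nested_tags_rejected(self):
        with pytest.raises(ValueError, match="nested"):
            parse_inline_annotations("<dis>a <dis>b</dis></dis>")

    def test_unmatched_close_rejected(self):
        with pytest.raises(ValueError, match="unmatched"):
            parse_inline_annotations("a</dis> b")

    def test_parse_then_render_reproduces_raw(self):
        raw = ("children with <dis>cerebral palsy</dis> (CP)\n"
               "se observa <dis>pérdida brusca de visión</dis> y <dis>sordera</dis>")
        doc = parse_inline_annotations(raw)
        assert render_inline(doc) == raw


class TestBioConversion:
    @pytest.mark.parametrize("n,spans,expected", [
        (5, {EntitySpan(2, 3)}, ["O", "O", "B-DIS", "I-DIS", "O"]),
        (3, set(), ["O", "O", "O"]),
        (4, {EntitySpan(0, 0), EntitySpan(1, 2)}, ["B-DIS", "B-DIS", "I-DIS", "O"]),
    ])
    def test_spans_to_bio2(self, n, spans, expected):
        assert spans_to_bio(n, spans) == expected

    def test_overlapping_spans_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            spans_to_bio(4, {EntitySpan(0, 2), EntitySpan(2, 3)})

    @pytest.mark.parametrize("tags,expected", [
        (["O", "B-DIS", "I-DIS"], {EntitySpan(1, 2)}),
        (["I-DIS", "O"], {EntitySpan(0, 0)}),  # leading I- promoted to B-
        (["O", "I-DIS", "I-DIS"], {EntitySpan(1, 2)}),  # I after O repaired
    ])
    def test_bio_to_spans_with_repair(self, tags, expected):
        assert bio_to_spans(tags) == expected

    def test_unknown_tag_rejected(self):
        with pytest.raises(ValueError, match="X-DIS"):
            bio_to_spans(["O", "X-DIS"])

    @given(st.integers(1, 12), st.data())
    @settings(max_examples=200, deadline=None)
    def test_roundtrip_is_identity_on_wellformed(self, n, data):
        # random non-overlapping span set
        spans, pos = set(), 0
        while pos < n:
            if data.draw(st.booleans()):
                end = data.draw(st.integers(pos, n - 1))
                spans.add(EntitySpan(pos, end))
                pos = end + 1
            else:
                pos += 1
        assert bio_to_spans(spans_to_bio(n, spans)) == spans


class TestConll:
    def _corpus(self):
        doc = AnnotatedDocument(
            doc_id="d0",
            sentences=[[Token("la", 0, 2), Token("sordera", 3, 10)],
                       [Token("ok", 0, 2)]],
            gold_spans=[{EntitySpan(1, 1)}, set()],
        )
        return Corpus(documents=[doc])

    def test_write_read_write_is_byte_identical(self, tmp_path):
        p1, p2 = tmp_path / "a.conll", tmp_path / "b.conll"
        write_conll(self._corpus(), p1)
        write_conll(read_conll(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_read_write_preserves_data_model(self, tmp_path):
        p = tmp_path / "c.conll"
        write_conll(self._corpus(), p)
        corpus = read_conll(p)
        assert corpus.n_sentences() == 2
        assert corpus.documents[0].gold_spans[0] == {EntitySpan(1, 1)}

    def test_blank_file_is_an_error(self, tmp_path):
        p = tmp_path / "empty.conll"
        p.write_text("\n\n")
        with pytest.raises(ValueError, match="empty corpus"):
            read_conll(p)

    def test_unknown_tag_names_the_tag(self, tmp_path):
        p = tmp_path / "bad.conll"
        p.write_text("word\tB-XYZ\n")
        with pytest.raises(ValueError, match="B-XYZ"):
            read_conll(p)

    def test_ragged_line_names_the_line(self, tmp_path):
        p = tmp_path / "ragged.conll"
        p.write_text("word\tO\nword\tO\textra\n")
        with pytest.raises(ValueError, match=":2"):
            read_conll(p)


def test_document_validates_span_bounds():
    with pytest.raises(ValueError, match="exceeds sentence length"):
        AnnotatedDocument(doc_id="d", sentences=[[Token("a", 0, 1)]],
                          gold_spans=[{EntitySpan(0, 4)}])


def test_duplicate_doc_ids_rejected():
    doc = AnnotatedDocument(doc_id="d", sentences=[[Token("a", 0, 1)]])
    with pytest.raises(ValueError, match="duplicate"):
        Corpus(documents=[doc, doc.copy()])
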