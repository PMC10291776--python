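"""Corpus handling: tokenization, inline-annotated abstracts, BIO tags, CoNLL files.

The data model is span-based: a disability mention is a contiguous run of
tokens inside one sentence, stored as inclusive token indices.  BIO tags are
only an interchange encoding used at the tagger boundary; evaluation is always
on spans.  Character offsets are 0-based and half-open.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "Token",
    "EntitySpan",
    "AnnotatedDocument",
    "Corpus",
    "tokenize",
    "parse_inline_annotations",
    "render_inline",
    "spans_to_bio",
    "bio_to_spans",
    "read_conll",
    "write_conll",
]

# A token is either a maximal run of word characters (letters, digits,
# underscore; Unicode-aware, so accented characters stay inside words) or a
# single punctuation character.  Parentheses therefore always come out as
# standalone tokens, which the acronym detector relies on.
_TOKEN_RE = re.compile(r"\w+|[^\w\s]", re.UNICODE)

DEFAULT_LABEL = "DIS"


@dataclass(frozen=True)
class Token:
    """A surface token with its character offsets into the sentence text."""

    text: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty token at offset {self.start}")


@dataclass(frozen=True, order=True)
class EntitySpan:
    """Inclusive token-index span carrying an entity label."""

    first_token: int
    last_token: int
    label: str = DEFAULT_LABEL

    def __post_init__(self) -> None:
        if self.first_token < 0 or self.last_token < self.first_token:
            raise ValueError(f"invalid span ({self.first_token},{self.last_token})")

    def overlaps(self, other: "EntitySpan") -> bool:
        return not (self.last_token < other.first_token or other.last_token < self.first_token)

    def tokens(self) -> range:
        return range(self.first_token, self.last_token + 1)


@dataclass
class AnnotatedDocument:
    """A tokenized document with gold and (optionally) predicted entity spans.

    ``sentence_texts`` keeps the raw sentence strings so that inline
    re-serialization is lossless; when a document is built from token lists
    only, the texts are reconstructed with single spaces.
    """

    doc_id: str
    sentences: list[list[Token]]
    gold_spans: list[set[EntitySpan]] = field(default_factory=list)
    pred_spans: list[set[EntitySpan]] = field(default_factory=list)
    sentence_texts: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.sentences)
        if not self.gold_spans:
            self.gold_spans = [set() for _ in range(n)]
        if not self.pred_spans:
            self.pred_spans = [set() for _ in range(n)]
        if not self.sentence_texts:
            self.sentence_texts = [" ".join(t.text for t in s) for s in self.sentences]
        self.validate()

    def validate(self) -> None:
        n = len(self.sentences)
        if not (len(self.gold_spans) == len(self.pred_spans) == len(self.sentence_texts) == n):
            raise ValueError(f"document {self.doc_id}: ragged sentence-parallel lists")
        for s_idx, (sent, text) in enumerate(zip(self.sentences, self.sentence_texts)):
            for tok in sent:
                if text[tok.start : tok.end] != tok.text:
                    raise ValueError(
                        f"document {self.doc_id}, sentence {s_idx}: token offsets "
                        f"({tok.start},{tok.end}) do not slice to {tok.text!r}"
                    )
            for spans in (self.gold_spans[s_idx], self.pred_spans[s_idx]):
                for sp in spans:
                    if sp.last_token >= len(sent):
                        raise ValueError(
                            f"document {self.doc_id}, sentence {s_idx}: span {sp} "
                            f"exceeds sentence length {len(sent)}"
                        )
            _check_no_overlap(self.gold_spans[s_idx], where=f"{self.doc_id}[{s_idx}] gold")

    def n_tokens(self) -> int:
        return sum(len(s) for s in self.sentences)

    def copy(self) -> "AnnotatedDocument":
        """Copy with independent span sets (tokens are immutable and shared)."""
        return AnnotatedDocument(
            doc_id=self.doc_id,
            sentences=[list(s) for s in self.sentences],
            gold_spans=[set(s) for s in self.gold_spans],
            pred_spans=[set(s) for s in self.pred_spans],
            sentence_texts=list(self.sentence_texts),
        )


@dataclass
class Corpus:
    """An ordered collection of annotated documents for one language/split."""

    documents: list[AnnotatedDocument]
    language: str = "es"
    split: str = "train"

    def __post_init__(self) -> None:
        ids = [d.doc_id for d in self.documents]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate doc_id in corpus")

    def __len__(self) -> int:
        return len(self.documents)

    def __iter__(self):
        return iter(self.documents)

    def n_sentences(self) -> int:
        return sum(len(d.sentences) for d in self.documents)

    def n_tokens(self) -> int:
        return sum(d.n_tokens() for d in self.documents)

    def n_gold_entities(self) -> int:
        return sum(len(sp) for d in self.documents for sp in d.gold_spans)

    def statistics(self) -> dict:
        """Corpus summary counts (documents, tokens, annotated disabilities)."""
        return {
            "documents": len(self),
            "tokens": self.n_tokens(),
            "entities": self.n_gold_entities(),
        }


def _check_no_overlap(spans: Iterable[EntitySpan], where: str = "") -> None:
    ordered = sorted(spans)
    for a, b in zip(ordered, ordered[1:]):
        if a.overlaps(b):
            raise ValueError(f"overlapping spans {a} and {b}" + (f" in {where}" if where else ""))


def tokenize(text: str) -> list[Token]:
    """Split ``text`` into tokens, detaching punctuation (incl. parentheses).

    Concatenating token texts with the original inter-token gaps reconstructs
    the input; offsets always slice back to the token text.
    """
    return [Token(m.group(), m.start(), m.end()) for m in _TOKEN_RE.finditer(text)]


def parse_inline_annotations(
    raw: str,
    open_tag: str = "<dis>",
    close_tag: str = "</dis>",
    doc_id: str = "doc",
    label: str = DEFAULT_LABEL,
) -> AnnotatedDocument:
    """Parse text with inline entity tags into an :class:`AnnotatedDocument`.

    Each non-empty line of ``raw`` becomes one sentence.  Tags must be
    balanced and non-nested; violations raise :class:`ValueError` naming the
    character offset in ``raw``.
    """
    sentences: list[list[Token]] = []
    texts: list[str] = []
    gold: list[set[EntitySpan]] = []
    line_start = 0
    for line in raw.split("\n"):
        if line.strip():
            toks, text, spans = _parse_inline_line(line, open_tag, close_tag, line_start, label)
            sentences.append(toks)
            texts.append(text)
            gold.append(spans)
        line_start += len(line) + 1
    return AnnotatedDocument(doc_id=doc_id, sentences=sentences, gold_spans=gold, sentence_texts=texts)


def _parse_inline_line(
    line: str, open_tag: str, close_tag: str, offset0: int, label: str
) -> tuple[list[Token], str, set[EntitySpan]]:
    clean_parts: list[str] = []
    clean_len = 0
    char_ranges: list[tuple[int, int]] = []
    open_at: int | None = None  # clean-text offset of the pending open tag
    pos = 0
    tag_re = re.compile("|".join(re.escape(t) for t in (open_tag, close_tag)))
    for m in tag_re.finditer(line):
        clean_parts.append(line[pos : m.start()])
        clean_len += m.start() - pos
        if m.group() == open_tag:
            if open_at is not None:
                raise ValueError(f"nested {open_tag} at character offset {offset0 + m.start()}")
            open_at = clean_len
        else:
            if open_at is None:
                raise ValueError(f"unmatched {close_tag} at character offset {offset0 + m.start()}")
            char_ranges.append((open_at, clean_len))
            open_at = None
        pos = m.end()
    if open_at is not None:
        raise ValueError(f"unclosed {open_tag} before character offset {offset0 + len(line)}")
    clean_parts.append(line[pos:])
    text = "".join(clean_parts)
    toks = tokenize(text)
    spans: set[EntitySpan] = set()
    for cs, ce in char_ranges:
        inside = [i for i, t in enumerate(toks) if t.end > cs and t.start < ce]
        if not inside:
            raise ValueError(f"annotation covers no tokens at clean offset {cs}")
        spans.add(EntitySpan(inside[0], inside[-1], label))
    return toks, text, spans


def render_inline(
    doc: AnnotatedDocument,
    open_tag: str = "<dis>",
    close_tag: str = "</dis>",
    spans: str = "gold",
) -> str:
    """Serialize a document back to inline-tagged text (inverse of parsing)."""
    span_lists = doc.gold_spans if spans == "gold" else doc.pred_spans
    lines = []
    for sent, text, sp in zip(doc.sentences, doc.sentence_texts, span_lists):
        inserts: list[tuple[int, int, str]] = []  # (char pos, order, text)
        for span in sp:
            inserts.append((sent[span.first_token].start, 0, open_tag))
            inserts.append((sent[span.last_token].end, 1, close_tag))
        out, prev = [], 0
        for cpos, _, tag in sorted(inserts):
            out.append(text[prev:cpos])
            out.append(tag)
            prev = cpos
        out.append(text[prev:])
        lines.append("".join(out))
    return "\n".join(lines)


def spans_to_bio(sentence_len: int, spans: Iterable[EntitySpan]) -> list[str]:
    """Encode a span set as BIO2 tags (every entity starts with ``B-``)."""
    spans = list(spans)
    _check_no_overlap(spans)
    tags = ["O"] * sentence_len
    for sp in spans:
        if sp.last_token >= sentence_len:
            raise ValueError(f"span {sp} exceeds sentence length {sentence_len}")
        tags[sp.first_token] = f"B-{sp.label}"
        for i in range(sp.first_token + 1, sp.last_token + 1):
            tags[i] = f"I-{sp.label}"
    return tags


_TAG_RE = re.compile(r"^(O|[BI]-[A-Za-z][\w-]*)$")


def bio_to_spans(tags: Sequence[str]) -> set[EntitySpan]:
    """Decode BIO tags to spans, repairing ill-formed tagger output.

    Repair rule: an ``I-`` tag with no live entity of the same label (sentence
    start, after ``O``, or after a different label) is promoted to ``B-``.
    Unknown tag strings raise :class:`ValueError`.
    """
    spans: set[EntitySpan] = set()
    cur_start: int | None = None
    cur_label: str | None = None

    def flush(end: int) -> None:
        nonlocal cur_start, cur_label
        if cur_start is not None:
            spans.add(EntitySpan(cur_start, end, cur_label))
        cur_start = cur_label = None

    for i, tag in enumerate(tags):
        if not _TAG_RE.match(tag):
            raise ValueError(f"unknown tag {tag!r} at position {i}")
        if tag == "O":
            flush(i - 1)
        elif tag.startswith("B-"):
            flush(i - 1)
            cur_start, cur_label = i, tag[2:]
        else:  # I-
            if cur_label != tag[2:]:
                flush(i - 1)  # repair: promote to B-
                cur_start, cur_label = i, tag[2:]
    flush(len(tags) - 1)
    return spans


_DOCSTART = "-DOCSTART-"


def read_conll(path: str | Path, tag_set: set[str] | None = None,
               language: str = "es", split: str = "train") -> Corpus:
    """Read a two-column (token TAB tag) CoNLL file into a :class:`Corpus`.

    Blank lines separate sentences; ``-DOCSTART-`` lines separate documents.
    Gold spans are decoded from the BIO tags.  Ragged lines and unknown tags
    raise :class:`ValueError` with the offending line number.
    """
    if tag_set is None:
        tag_set = {"O", "B-DIS", "I-DIS"}
    path = Path(path)
    docs: list[AnnotatedDocument] = []
    cur_sents: list[tuple[list[str], list[str]]] = []
    cur_tokens: list[str] = []
    cur_tags: list[str] = []
    saw_content = False

    def flush_sentence() -> None:
        nonlocal cur_tokens, cur_tags
        if cur_tokens:
            cur_sents.append((cur_tokens, cur_tags))
            cur_tokens, cur_tags = [], []

    def flush_document() -> None:
        nonlocal cur_sents
        flush_sentence()
        if cur_sents:
            docs.append(_doc_from_tagged(f"doc_{len(docs):04d}", cur_sents))
            cur_sents = []

    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                flush_sentence()
                continue
            fields = line.split("\t")
            if fields[0] == _DOCSTART:
                flush_document()
                continue
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'token<TAB>tag', got {line!r}")
            tok, tag = fields
            if tag not in tag_set:
                raise ValueError(f"{path}:{lineno}: tag {tag!r} not in tag set {sorted(tag_set)}")
            saw_content = True
            cur_tokens.append(tok)
            cur_tags.append(tag)
    flush_document()
    if not saw_content:
        raise ValueError(f"{path}: empty corpus")
    return Corpus(documents=docs, language=language, split=split)


def _doc_from_tagged(doc_id: str, sents: list[tuple[list[str], list[str]]]) -> AnnotatedDocument:
    sentences, gold = [], []
    for words, tags in sents:
        toks, pos = [], 0
        for w in words:
            toks.append(Token(w, pos, pos + len(w)))
            pos += len(w) + 1
        sentences.append(toks)
        gold.append(bio_to_spans(tags))
    return AnnotatedDocument(doc_id=doc_id, sentences=sentences, gold_spans=gold)


def write_conll(corpus: Corpus, path: str | Path, spans: str = "gold") -> None:
    """Write a corpus in canonical two-column CoNLL form (inverse of read)."""
    path = Path(path)
    lines: list[str] = []
    for doc in corpus:
        lines.append(f"{_DOCSTART}\tO")
        lines.append("")
        span_lists = doc.gold_spans if spans == "gold" else doc.pred_spans
        for sent, sp in zip(doc.sentences, span_lists):
            tags = spans_to_bio(len(sent), sp)
            lines.extend(f"{t.text}\t{tag}" for t, tag in zip(sent, tags))
            lines.append("")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
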