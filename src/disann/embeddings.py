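"""Static word-vector tables and stacked per-token representations.

A *stack* is an ordered list of embedding providers whose outputs are
concatenated per token, mirroring the practice of feeding a sequence tagger
the concatenation of heterogeneous embedding sources (static word vectors,
contextual character-LM vectors, ...).  Any object with a ``dim`` attribute
and an ``embed(tokens) -> (n, dim)`` method can be a component.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path
from typing import Sequence

import numpy as np

from .corpus import Token

__all__ = ["StaticEmbeddingTable", "EmbeddingStack", "load_word_vectors",
           "write_word_vectors", "embed_tokens"]

logger = logging.getLogger(__name__)


class StaticEmbeddingTable:
    """Word -> fixed vector lookup with a configurable OOV policy.

    oov_policy "zero" maps unknown words to the zero vector; "mean" maps them
    to the mean of all table rows.  Lookup is case-sensitive by default
    (capitalization is meaningful for acronyms); ``lowercase_fallback`` retries
    the lowercased form on a miss.
    """

    def __init__(self, vocab: dict[str, int], matrix: np.ndarray,
                 oov_policy: str = "zero", lowercase_fallback: bool = False):
        matrix = np.asarray(matrix, dtype=np.float64)
        if matrix.ndim != 2 or matrix.shape[1] < 1:
            raise ValueError("matrix must be (|V|, d) with d > 0")
        if len(vocab) != matrix.shape[0]:
            raise ValueError("vocab size does not match matrix rows")
        if not np.isfinite(matrix).all():
            raise ValueError("non-finite embedding values")
        if oov_policy not in ("zero", "mean"):
            raise ValueError(f"unknown oov_policy {oov_policy!r}")
        self.vocab = dict(vocab)
        self.matrix = matrix
        self.oov_policy = oov_policy
        self.lowercase_fallback = lowercase_fallback
        self._oov = (matrix.mean(axis=0) if (oov_policy == "mean" and len(vocab))
                     else np.zeros(matrix.shape[1]))

    @classmethod
    def from_pairs(cls, pairs: Sequence[tuple[str, np.ndarray]], **kwargs) -> "StaticEmbeddingTable":
        vocab = {w: i for i, (w, _) in enumerate(pairs)}
        return cls(vocab, np.stack([v for _, v in pairs]), **kwargs)

    @property
    def dim(self) -> int:
        return self.matrix.shape[1]

    def __len__(self) -> int:
        return len(self.vocab)

    def __contains__(self, word: str) -> bool:
        return word in self.vocab

    def vector(self, word: str) -> np.ndarray:
        idx = self.vocab.get(word)
        if idx is None and self.lowercase_fallback:
            idx = self.vocab.get(word.lower())
        return self.matrix[idx] if idx is not None else self._oov

    def embed(self, tokens: Sequence[Token]) -> np.ndarray:
        if not tokens:
            return np.zeros((0, self.dim))
        return np.stack([self.vector(t.text) for t in tokens])

    def mapped(self, W: np.ndarray) -> "StaticEmbeddingTable":
        """A new table with every row mapped through ``W`` (d x d)."""
        return StaticEmbeddingTable(self.vocab, self.matrix @ W,
                                    oov_policy=self.oov_policy,
                                    lowercase_fallback=self.lowercase_fallback)

    def fingerprint(self) -> str:
        h = hashlib.sha256()
        for w in sorted(self.vocab):
            h.update(w.encode("utf-8"))
        h.update(np.ascontiguousarray(self.matrix).tobytes())
        return h.hexdigest()[:16]


class EmbeddingStack:
    """Ordered concatenation of embedding components."""

    def __init__(self, components: Sequence):
        if not components:
            raise ValueError("stack must have at least one component")
        self.components = list(components)

    @property
    def total_dim(self) -> int:
        return sum(c.dim for c in self.components)

    def embed(self, tokens: Sequence[Token]) -> np.ndarray:
        return embed_tokens(self, tokens)


def embed_tokens(stack: EmbeddingStack, sentence: Sequence[Token]) -> np.ndarray:
    """(n, total_dim) matrix: per-token concatenation in component order."""
    n = len(sentence)
    blocks = []
    for comp in stack.components:
        block = np.asarray(comp.embed(sentence), dtype=np.float64)
        if block.shape != (n, comp.dim):
            raise ValueError(f"component {comp!r} returned shape {block.shape}, "
                             f"expected ({n},{comp.dim})")
        blocks.append(block)
    if n == 0:
        return np.zeros((0, stack.total_dim))
    return np.concatenate(blocks, axis=1)


def load_word_vectors(path: str | Path, limit: int | None = None,
                      oov_policy: str = "zero",
                      lowercase_fallback: bool = False) -> StaticEmbeddingTable:
    """Read a whitespace-separated text vector file (the common ``.vec`` dialect).

    The first line may be a ``vocab_size dim`` header; its absence is
    auto-detected.  Duplicate words keep the first occurrence (warned);
    inconsistent dimensionality raises with the line number.
    """
    path = Path(path)
    vocab: dict[str, int] = {}
    rows: list[np.ndarray] = []
    dim: int | None = None
    with path.open(encoding="utf-8") as fh:
        first = fh.readline()
        lines = []
        parts = first.split()
        if len(parts) == 2 and all(p.lstrip("-").isdigit() for p in parts):
            dim = int(parts[1])  # header line
        elif first.strip():
            lines.append((1, first))
        for lineno, line in enumerate(fh, start=2):
            if line.strip():
                lines.append((lineno, line))
    for lineno, line in lines:
        if limit is not None and len(rows) >= limit:
            break
        parts = line.rstrip("\n").split(" ")
        word, values = parts[0], parts[1:]
        if dim is None:
            dim = len(values)
        if len(values) != dim:
            raise ValueError(f"{path}:{lineno}: expected {dim} values, got {len(values)}")
        if word in vocab:
            logger.warning("%s:%d: duplicate word %r kept first occurrence", path, lineno, word)
            continue
        vocab[word] = len(rows)
        rows.append(np.array([float(v) for v in values]))
    if not rows:
        raise ValueError(f"{path}: no vectors read")
    return StaticEmbeddingTable(vocab, np.stack(rows), oov_policy=oov_policy,
                                lowercase_fallback=lowercase_fallback)


def write_word_vectors(table: StaticEmbeddingTable, path: str | Path) -> None:
    """Write a table in the headered text ``.vec`` dialect (inverse of load)."""
    words = sorted(table.vocab, key=table.vocab.get)
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write(f"{len(words)} {table.dim}\n")
        for w in words:
            vals = " ".join(repr(float(x)) for x in table.matrix[table.vocab[w]])
            fh.write(f"{w} {vals}\n")
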