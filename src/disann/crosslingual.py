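"""Supervised embedding-space alignment and zero-shot crosslingual transfer.

A bilingual lexicon pairs source-language words with target-language words.
The closed-form orthogonal Procrustes solution maps the source embedding
space into the target space: W = argmin_{W orthogonal} ||X W - Y||_F over the
lexicon-paired row matrices, obtained from the SVD of X^T Y.  A tagger
trained on source-language text embedded through W can then be applied
unchanged to target-language text embedded with the target table — the
zero-shot setting, in which no target-language annotations exist.

Contextual character embeddings have no alignment defined here, so the
zero-shot stack is static-only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .acronyms import apply_acronym_module
from .corpus import Corpus
from .embeddings import EmbeddingStack, StaticEmbeddingTable
from .evaluation import EvalReport, evaluate_corpus
from .tagger import TaggerModel, TrainingConfig, predict_corpus, train_tagger

__all__ = ["BilingualLexicon", "OrthogonalMap", "read_lexicon",
           "procrustes_align", "zero_shot_run"]

logger = logging.getLogger(__name__)


@dataclass
class BilingualLexicon:
    pairs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.pairs:
            raise ValueError("empty lexicon")

    def __len__(self) -> int:
        return len(self.pairs)


def read_lexicon(path: str | Path) -> BilingualLexicon:
    """Two whitespace-separated columns, one (source, target) pair per line."""
    pairs = []
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip():
            continue
        fields = line.split()
        if len(fields) != 2:
            raise ValueError(f"{path}:{lineno}: expected two columns, got {len(fields)}")
        pairs.append((fields[0], fields[1]))
    return BilingualLexicon(pairs)


@dataclass
class OrthogonalMap:
    W: np.ndarray  # (d, d), maps source vectors into the target space
    src_fingerprint: str
    tgt_fingerprint: str
    n_pairs_used: int

    def __post_init__(self) -> None:
        d = self.W.shape[0]
        if self.W.shape != (d, d):
            raise ValueError("map must be square")
        if not np.allclose(self.W.T @ self.W, np.eye(d), atol=1e-6):
            raise ValueError("map is not orthogonal within 1e-6")


def procrustes_align(src: StaticEmbeddingTable, tgt: StaticEmbeddingTable,
                     lex: BilingualLexicon) -> OrthogonalMap:
    """Closed-form orthogonal map from source to target space.

    Lexicon pairs with either side out of vocabulary are skipped (count
    logged); duplicated source words keep all their pairs.  Raises if no pair
    is usable; warns when fewer usable pairs than dimensions remain.
    """
    if src.dim != tgt.dim:
        raise ValueError(f"dimension mismatch: source {src.dim} vs target {tgt.dim}")
    X_rows, Y_rows, skipped = [], [], 0
    for s, t in lex.pairs:
        if s in src and t in tgt:
            X_rows.append(src.vector(s))
            Y_rows.append(tgt.vector(t))
        else:
            skipped += 1
    if skipped:
        logger.info("procrustes: skipped %d lexicon pairs with OOV words", skipped)
    if not X_rows:
        raise ValueError("no usable lexicon pairs (all out of vocabulary)")
    if len(X_rows) < src.dim:
        logger.warning("procrustes: only %d usable pairs for dimension %d",
                       len(X_rows), src.dim)
    X = np.stack(X_rows)
    Y = np.stack(Y_rows)
    U, _, Vt = np.linalg.svd(X.T @ Y)
    W = U @ Vt
    return OrthogonalMap(W=W, src_fingerprint=src.fingerprint(),
                         tgt_fingerprint=tgt.fingerprint(),
                         n_pairs_used=len(X_rows))


def zero_shot_run(train_corpus_src: Corpus, test_corpus_tgt: Corpus,
                  src_table: StaticEmbeddingTable, tgt_table: StaticEmbeddingTable,
                  lex: BilingualLexicon,
                  cfg: TrainingConfig | None = None) -> tuple[EvalReport, EvalReport]:
    """Train on source, evaluate on target with no target annotations.

    The tagger is trained on the source corpus with source embeddings mapped
    into the target space; at test time the same model reads target
    embeddings (unmapped).  Returns the (A-, A+) report pair — without and
    with the acronym module.
    """
    mapping = procrustes_align(src_table, tgt_table, lex)
    mapped_src = src_table.mapped(mapping.W)
    train_stack = EmbeddingStack([mapped_src])
    model = train_tagger(train_corpus_src, train_stack, cfg)
    tgt_stack = EmbeddingStack([tgt_table])
    predicted = predict_corpus(model, test_corpus_tgt, stack=tgt_stack)
    report_plain = evaluate_corpus(predicted, condition="A-")
    propagated = Corpus(documents=[apply_acronym_module(d).doc for d in predicted],
                        language=predicted.language, split=predicted.split)
    report_acro = evaluate_corpus(propagated, condition="A+")
    return report_plain, report_acro
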