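"""Strict entity-level evaluation and multi-seed aggregation.

A predicted mention counts only on exact (first_token, last_token, label)
equality with a gold mention — the shared-task convention for disability
annotation; partial overlaps are errors.  Counts are micro-averaged (pooled
over all sentences and documents before computing P/R/F).  The 0/0 cases use
the standard CoNLL-scorer convention P=R=F=0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .corpus import AnnotatedDocument, Corpus, EntitySpan

__all__ = [
    "EvalCounts",
    "EvalReport",
    "MultiSeedReport",
    "strict_match",
    "prf",
    "evaluate_corpus",
    "aggregate_seeds",
]


@dataclass
class EvalCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    def __add__(self, other: "EvalCounts") -> "EvalCounts":
        return EvalCounts(self.tp + other.tp, self.fp + other.fp, self.fn + other.fn)


@dataclass
class EvalReport:
    precision: float
    recall: float
    f1: float
    counts: EvalCounts
    condition: str = "A-"  # "A-" without / "A+" with the acronym module

    def formatted(self) -> str:
        """Metrics x100 with two decimals, the conventional table format."""
        return (f"[{self.condition}] P={self.precision * 100:.2f} "
                f"R={self.recall * 100:.2f} F={self.f1 * 100:.2f} "
                f"(tp={self.counts.tp} fp={self.counts.fp} fn={self.counts.fn})")


@dataclass
class MultiSeedReport:
    reports: list[EvalReport]
    mean: dict[str, float] = field(init=False)
    stdev: dict[str, float] | None = field(init=False)

    def __post_init__(self) -> None:
        if not self.reports:
            raise ValueError("need at least one report")
        conditions = {r.condition for r in self.reports}
        if len(conditions) > 1:
            raise ValueError(f"mixed conditions {sorted(conditions)} cannot be aggregated")
        self.mean = {m: _mean([getattr(r, m) for r in self.reports])
                     for m in ("precision", "recall", "f1")}
        if len(self.reports) >= 2:
            self.stdev = {m: _sample_stdev([getattr(r, m) for r in self.reports])
                          for m in ("precision", "recall", "f1")}
        else:
            self.stdev = None

    @property
    def condition(self) -> str:
        return self.reports[0].condition

    def formatted(self) -> str:
        parts = []
        for m in ("precision", "recall", "f1"):
            s = f"{m[0].upper()}={self.mean[m] * 100:.2f}"
            if self.stdev is not None:
                s += f" (±{self.stdev[m] * 100:.2f})"
            parts.append(s)
        return f"[{self.condition}] n={len(self.reports)} " + " ".join(parts)


def _mean(xs: Sequence[float]) -> float:
    return sum(xs) / len(xs)


def _sample_stdev(xs: Sequence[float]) -> float:
    mu = _mean(xs)
    return math.sqrt(sum((x - mu) ** 2 for x in xs) / (len(xs) - 1))


def strict_match(gold: Iterable[EntitySpan], pred: Iterable[EntitySpan]) -> EvalCounts:
    """Exact-boundary, exact-label matching of two span sets."""
    gold, pred = set(gold), set(pred)
    tp = len(gold & pred)
    return EvalCounts(tp=tp, fp=len(pred) - tp, fn=len(gold) - tp)


def prf(counts: EvalCounts, condition: str = "A-") -> EvalReport:
    """Precision/recall/F1 from counts, with 0/0 -> 0."""
    p = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else 0.0
    r = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else 0.0
    f = 2 * p * r / (p + r) if p + r else 0.0
    return EvalReport(precision=p, recall=r, f1=f, counts=counts, condition=condition)


def evaluate_corpus(corpus: Corpus | Iterable[AnnotatedDocument],
                    condition: str = "A-") -> EvalReport:
    """Micro-averaged strict evaluation of pred_spans against gold_spans."""
    total = EvalCounts()
    for doc in corpus:
        for gold, pred in zip(doc.gold_spans, doc.pred_spans):
            total = total + strict_match(gold, pred)
    return prf(total, condition=condition)


def aggregate_seeds(reports: list[EvalReport]) -> MultiSeedReport:
    """Mean and sample stdev (n-1) of each metric across seed runs."""
    return MultiSeedReport(reports=list(reports))
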