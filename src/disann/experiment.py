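"""End-to-end experiment orchestration: multi-seed A-/A+ runs.

One experiment trains the tagger once per seed, scores the test predictions
without the acronym module (A-), applies the module and scores again (A+),
and aggregates both conditions as mean ± sample stdev across seeds.  When an
output directory is given, every artifact (config snapshot, per-seed models,
predictions, reports) is written under it so a run is replayable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from .acronyms import apply_acronym_module
from .corpus import Corpus, write_conll
from .embeddings import EmbeddingStack
from .evaluation import EvalReport, MultiSeedReport, aggregate_seeds, evaluate_corpus
from .tagger import TrainingConfig, predict_corpus, train_tagger

__all__ = ["ExperimentConfig", "run_experiment"]

logger = logging.getLogger(__name__)


@dataclass
class ExperimentConfig:
    seeds: list[int] = field(default_factory=lambda: [1, 2, 3])
    training: TrainingConfig = field(default_factory=TrainingConfig)
    acronyms: bool = True  # also produce the A+ condition
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if not self.seeds:
            raise ValueError("seeds list must be non-empty")

    def snapshot(self) -> dict:
        d = dataclasses.asdict(self)
        d["config_hash"] = hashlib.sha256(
            json.dumps(d, sort_keys=True).encode()).hexdigest()[:12]
        return d


def run_experiment(train_corpus: Corpus, test_corpus: Corpus,
                   stack: EmbeddingStack, cfg: ExperimentConfig,
                   ) -> tuple[MultiSeedReport, MultiSeedReport | None]:
    """Multi-seed train/predict/score; returns (A- report, A+ report or None)."""
    out = Path(cfg.output_dir) if cfg.output_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
        (out / "config.json").write_text(json.dumps(cfg.snapshot(), indent=2))
    plain_reports: list[EvalReport] = []
    acro_reports: list[EvalReport] = []
    for seed in cfg.seeds:
        tcfg = dataclasses.replace(cfg.training, seed=seed)
        logger.info("experiment: training seed %d", seed)
        model = train_tagger(train_corpus, stack, tcfg)
        predicted = predict_corpus(model, test_corpus)
        plain_reports.append(evaluate_corpus(predicted, condition="A-"))
        if cfg.acronyms:
            propagated = Corpus(
                documents=[apply_acronym_module(d).doc for d in predicted],
                language=predicted.language, split=predicted.split)
            acro_reports.append(evaluate_corpus(propagated, condition="A+"))
        if out:
            model.save(out / f"model_seed{seed}.json")
            write_conll(predicted, out / f"pred_seed{seed}.conll", spans="pred")
            if cfg.acronyms:
                write_conll(propagated, out / f"pred_acro_seed{seed}.conll", spans="pred")
    agg_plain = aggregate_seeds(plain_reports)
    agg_acro = aggregate_seeds(acro_reports) if cfg.acronyms else None
    if out:
        payload = {
            "config": cfg.snapshot(),
            "A-": _report_payload(agg_plain),
        }
        if agg_acro is not None:
            payload["A+"] = _report_payload(agg_acro)
        (out / "report.json").write_text(json.dumps(payload, indent=2))
    return agg_plain, agg_acro


def _report_payload(agg: MultiSeedReport) -> dict:
    return {
        "per_seed": [
            {"precision": r.precision, "recall": r.recall, "f1": r.f1,
             "tp": r.counts.tp, "fp": r.counts.fp, "fn": r.counts.fn}
            for r in agg.reports
        ],
        "mean": agg.mean,
        "stdev": agg.stdev,
    }
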