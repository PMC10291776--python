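"""BiLSTM-CRF sequence tagger over stacked embeddings.

The encoder is one bidirectional LSTM layer over the frozen per-token stack
output; a linear projection gives per-tag emission scores and a linear-chain
CRF models tag-transition structure.  Training minimizes the CRF negative
log-likelihood with Adam; model selection is by strict entity F1 on a
held-out development split.  All randomness flows from the seed in
:class:`TrainingConfig`, so runs are bit-reproducible on one thread.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import crf
from .corpus import AnnotatedDocument, Corpus, EntitySpan, bio_to_spans, spans_to_bio
from .embeddings import EmbeddingStack
from .evaluation import EvalCounts, prf, strict_match
from .nn import Adam, LSTM, Parameter, Tensor, concat

__all__ = ["TAGS", "TrainingConfig", "TaggerModel", "train_tagger",
           "predict_spans", "predict_corpus"]

logger = logging.getLogger(__name__)

TAGS = ("O", "B-DIS", "I-DIS")


@dataclass
class TrainingConfig:
    seed: int = 0
    epochs: int = 20
    batch_size: int = 8
    lr: float = 1e-2
    lr_decay: float = 0.95  # per-epoch multiplicative decay
    hidden_size: int = 128  # per direction
    dev_fraction: float = 0.1  # carved from the train split, by document
    clip_norm: float = 5.0
    strict_bio: bool = False  # mask I-after-O transitions at decode time


class TaggerModel:
    """BiLSTM encoder + CRF parameters, bound to an embedding stack."""

    def __init__(self, stack: EmbeddingStack, config: TrainingConfig,
                 tags: tuple[str, ...] = TAGS):
        self.stack = stack
        self.config = config
        self.tags = tuple(tags)
        k = len(self.tags)
        rng = np.random.default_rng(config.seed)
        d, h = stack.total_dim, config.hidden_size
        self.lstm_f = LSTM(d, h, rng)
        self.lstm_b = LSTM(d, h, rng)
        scale = 1.0 / np.sqrt(2 * h)
        self.Wp = Parameter(rng.uniform(-scale, scale, size=(2 * h, k)))
        self.bp = Parameter(np.zeros(k))
        self.T = Parameter(crf.init_transitions(k))
        self.loss_history: list[float] = []
        self.dev_f1_history: list[float] = []

    @property
    def n_tags(self) -> int:
        return len(self.tags)

    def parameters(self):
        return [*self.lstm_f.parameters(), *self.lstm_b.parameters(),
                self.Wp, self.bp, self.T]

    def emissions(self, emb: np.ndarray) -> Tensor:
        """(n, K) emission scores for one sentence's embedding matrix."""
        X = Tensor(np.asarray(emb, dtype=np.float64))
        H = concat([self.lstm_f.run(X), self.lstm_b.run(X, reverse=True)], axis=1)
        return H @ self.Wp + self.bp

    def sentence_nll(self, emb: np.ndarray, tag_indices: np.ndarray) -> Tensor:
        return crf.crf_nll(self.emissions(emb), tag_indices, self.T)

    def _decode_transitions(self) -> np.ndarray:
        T = self.T.data
        if self.config.strict_bio:
            T = T.copy()
            for j, tag in enumerate(self.tags):
                if tag.startswith("I-"):
                    # I-X reachable only from B-X / I-X
                    for i, prev in enumerate(self.tags):
                        if prev[2:] != tag[2:]:
                            T[i, j] = crf.NEG_INF
                    T[crf.start_index(self.n_tags), j] = crf.NEG_INF
        return T

    def decode(self, emb: np.ndarray) -> list[str]:
        """Viterbi tag strings for one sentence (empty sentence -> [])."""
        if len(emb) == 0:
            return []
        path, _ = crf.viterbi_decode(self.emissions(emb).data, self._decode_transitions())
        return [self.tags[i] for i in path]

    # -- persistence -----------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        return {
            "lstm_f_W": self.lstm_f.W.data, "lstm_f_b": self.lstm_f.b.data,
            "lstm_b_W": self.lstm_b.W.data, "lstm_b_b": self.lstm_b.b.data,
            "Wp": self.Wp.data, "bp": self.bp.data, "T": self.T.data,
        }

    def load_state(self, arrays: dict[str, np.ndarray]) -> None:
        self.lstm_f.W.data = np.array(arrays["lstm_f_W"])
        self.lstm_f.b.data = np.array(arrays["lstm_f_b"])
        self.lstm_b.W.data = np.array(arrays["lstm_b_W"])
        self.lstm_b.b.data = np.array(arrays["lstm_b_b"])
        self.Wp.data = np.array(arrays["Wp"])
        self.bp.data = np.array(arrays["bp"])
        self.T.data = np.array(arrays["T"])

    def save(self, path: str | Path) -> None:
        payload = {
            "config": asdict(self.config),
            "tags": list(self.tags),
            "stack_dim": self.stack.total_dim,
            "params": {k: v.tolist() for k, v in self.state_arrays().items()},
        }
        Path(path).write_text(json.dumps(payload), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path, stack: EmbeddingStack) -> "TaggerModel":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        if stack.total_dim != payload["stack_dim"]:
            raise ValueError(f"stack dim {stack.total_dim} != saved "
                             f"{payload['stack_dim']}")
        model = cls(stack, TrainingConfig(**payload["config"]),
                    tags=tuple(payload["tags"]))
        model.load_state({k: np.array(v) for k, v in payload["params"].items()})
        return model


def _prepare(corpus_docs: list[AnnotatedDocument], stack: EmbeddingStack,
             tags: tuple[str, ...]) -> list[tuple[np.ndarray, np.ndarray]]:
    tag_index = {t: i for i, t in enumerate(tags)}
    items = []
    for doc in corpus_docs:
        for sent, gold in zip(doc.sentences, doc.gold_spans):
            if not sent:
                continue
            emb = stack.embed(sent)
            idx = np.array([tag_index[t] for t in spans_to_bio(len(sent), gold)],
                           dtype=np.intp)
            items.append((emb, idx))
    return items


def _dev_counts(model: TaggerModel, docs: list[AnnotatedDocument]) -> EvalCounts:
    total = EvalCounts()
    for doc in docs:
        for sent, gold in zip(doc.sentences, doc.gold_spans):
            pred = bio_to_spans(model.decode(model.stack.embed(sent))) if sent else set()
            total = total + strict_match(gold, pred)
    return total


def train_tagger(corpus: Corpus, stack: EmbeddingStack,
                 cfg: TrainingConfig | None = None,
                 dev_corpus: Corpus | None = None) -> TaggerModel:
    """Train a BiLSTM-CRF on ``corpus``; returns the best-on-dev snapshot.

    If no explicit ``dev_corpus`` is given, ``cfg.dev_fraction`` of the
    training documents (seeded choice) are held out for model selection.
    With no dev data at all, the final epoch's parameters are returned.
    """
    cfg = cfg or TrainingConfig()
    docs = list(corpus.documents)
    if not docs or all(not d.sentences for d in docs):
        raise ValueError("empty training split")
    rng = np.random.default_rng(cfg.seed)
    if dev_corpus is not None:
        train_docs, dev_docs = docs, list(dev_corpus.documents)
    else:
        n_dev = int(round(len(docs) * cfg.dev_fraction))
        dev_ids = set(rng.choice(len(docs), size=n_dev, replace=False)) if n_dev else set()
        train_docs = [d for i, d in enumerate(docs) if i not in dev_ids]
        dev_docs = [d for i, d in enumerate(docs) if i in dev_ids]
    items = _prepare(train_docs, stack, TAGS)
    if not items:
        raise ValueError("empty training split")

    model = TaggerModel(stack, cfg)
    opt = Adam(model.parameters(), lr=cfg.lr, clip_norm=cfg.clip_norm)
    best_f1, best_state = -1.0, None
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(items))
        epoch_loss = 0.0
        for start in range(0, len(order), cfg.batch_size):
            batch = order[start : start + cfg.batch_size]
            opt.zero_grad()
            for j in batch:
                emb, idx = items[j]
                loss = model.sentence_nll(emb, idx) / len(batch)
                loss.backward()
                epoch_loss += float(loss.data) * len(batch)
            opt.step()
        model.loss_history.append(epoch_loss / len(items))
        opt.lr *= cfg.lr_decay
        if dev_docs:
            f1 = prf(_dev_counts(model, dev_docs)).f1
            model.dev_f1_history.append(f1)
            if f1 >= best_f1:  # on ties keep the most-trained snapshot
                best_f1 = f1
                best_state = {k: v.copy() for k, v in model.state_arrays().items()}
            logger.info("epoch %d: loss %.4f dev F1 %.4f", epoch, model.loss_history[-1], f1)
        else:
            logger.info("epoch %d: loss %.4f", epoch, model.loss_history[-1])
    if best_state is not None:
        model.load_state(best_state)
    return model


def predict_spans(model: TaggerModel, doc: AnnotatedDocument,
                  stack: EmbeddingStack | None = None) -> AnnotatedDocument:
    """Copy of ``doc`` with pred_spans filled by Viterbi decoding.

    ``stack`` overrides the model's embedding stack (used for zero-shot
    prediction with target-language embeddings of matching dimensionality).
    """
    use = stack or model.stack
    if use.total_dim != model.stack.total_dim:
        raise ValueError("override stack dimensionality mismatch")
    out = doc.copy()
    swap = model.stack
    model.stack = use
    try:
        for s_idx, sent in enumerate(out.sentences):
            out.pred_spans[s_idx] = bio_to_spans(model.decode(use.embed(sent))) if sent else set()
    finally:
        model.stack = swap
    return out


def predict_corpus(model: TaggerModel, corpus: Corpus,
                   stack: EmbeddingStack | None = None) -> Corpus:
    return Corpus(documents=[predict_spans(model, d, stack) for d in corpus],
                  language=corpus.language, split=corpus.split)
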