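"""Character-level language models and contextual word embeddings.

A forward LM predicts each character from its left context; a backward LM
reads the stream right-to-left and predicts each character from its right
context.  A word's contextual embedding is the concatenation of the forward
hidden state after the word's last character and the backward hidden state
after (i.e. having just consumed) the word's first character, so each half
summarizes one full side of the sentence and the same word gets different
vectors in different contexts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .corpus import Token
from .nn import Adam, LSTM, Parameter, Tensor, concat, logsumexp

__all__ = [
    "CharVocabulary",
    "CharLMConfig",
    "CharLanguageModel",
    "train_char_lm",
    "extract_word_embeddings",
    "CharLMEmbedder",
]

logger = logging.getLogger(__name__)

UNK, BOS, EOS = "<unk>", "<bos>", "<eos>"


class CharVocabulary:
    """Dense char->index map with reserved unknown / begin / end markers."""

    def __init__(self, chars: Sequence[str]):
        reserved = [UNK, BOS, EOS]
        real = sorted(set(chars) - set(reserved))
        self._index = {c: i for i, c in enumerate(reserved + real)}

    @classmethod
    def from_text(cls, text: str) -> "CharVocabulary":
        return cls(sorted(set(text)))

    def __len__(self) -> int:
        return len(self._index)

    def __eq__(self, other) -> bool:
        return isinstance(other, CharVocabulary) and self._index == other._index

    def index(self, ch: str) -> int:
        return self._index.get(ch, self._index[UNK])

    def encode(self, text: str) -> np.ndarray:
        return np.array([self.index(c) for c in text], dtype=np.intp)

    def to_list(self) -> list[str]:
        return [c for c, _ in sorted(self._index.items(), key=lambda kv: kv[1])]

    @classmethod
    def from_list(cls, chars: list[str]) -> "CharVocabulary":
        v = cls.__new__(cls)
        v._index = {c: i for i, c in enumerate(chars)}
        return v


@dataclass
class CharLMConfig:
    direction: str = "forward"  # or "backward"
    char_dim: int = 16
    hidden_dim: int = 64
    chars_per_batch: int = 128  # window length = truncated-BPTT horizon
    steps: int = 300
    lr: float = 5e-3
    seed: int = 0
    val_fraction: float = 0.05


class CharLanguageModel:
    """One-layer recurrent next-character predictor.

    A backward model is trained and run on the reversed character stream, so
    internally both directions share the same left-to-right machinery.
    """

    def __init__(self, vocab: CharVocabulary, config: CharLMConfig,
                 rng: np.random.Generator | None = None):
        if config.direction not in ("forward", "backward"):
            raise ValueError(f"unknown direction {config.direction!r}")
        self.vocab = vocab
        self.config = config
        rng = rng if rng is not None else np.random.default_rng(config.seed)
        V, dc, h = len(vocab), config.char_dim, config.hidden_dim
        self.E = Parameter(rng.normal(scale=0.1, size=(V, dc)))
        self.lstm = LSTM(dc, h, rng)
        self.Wo = Parameter(rng.normal(scale=1.0 / np.sqrt(h), size=(h, V)))
        self.bo = Parameter(np.zeros(V))

    @property
    def direction(self) -> str:
        return self.config.direction

    @property
    def hidden_dim(self) -> int:
        return self.config.hidden_dim

    def parameters(self):
        return [self.E, *self.lstm.parameters(), self.Wo, self.bo]

    # -- training-graph loss --------------------------------------------
    def window_loss(self, char_indices: np.ndarray) -> Tensor:
        """Mean next-character cross-entropy (nats) over one window.

        The window is given in *reading* order (already reversed for a
        backward model); the hidden state starts at zero (document/window
        boundaries reset it).
        """
        targets = np.asarray(char_indices, dtype=np.intp)
        inputs = np.concatenate(([self.vocab.index(BOS)], targets[:-1]))
        X = self.E.take_rows(inputs)
        H = self.lstm.run(X)
        logits = H @ self.Wo + self.bo
        n = len(targets)
        ce = logsumexp(logits, axis=1).sum() - logits.gather(np.arange(n), targets).sum()
        return ce / n

    # -- inference (numpy only) -----------------------------------------
    def _np_states(self, inputs: np.ndarray) -> np.ndarray:
        """Hidden states after each consumed character, pure numpy forward."""
        W, b = self.lstm.W.data, self.lstm.b.data
        Hd = self.config.hidden_dim
        h = np.zeros(Hd)
        c = np.zeros(Hd)
        out = np.empty((len(inputs), Hd))
        E = self.E.data
        for t, idx in enumerate(inputs):
            z = np.concatenate((E[idx], h)) @ W + b
            i = _sig(z[:Hd]); f = _sig(z[Hd:2 * Hd])
            g = np.tanh(z[2 * Hd:3 * Hd]); o = _sig(z[3 * Hd:])
            c = f * c + i * g
            h = o * np.tanh(c)
            out[t] = h
        return out

    def hidden_states(self, text: str) -> np.ndarray:
        """(len(text), h) matrix; row i is the state after consuming char i.

        For a backward model the stream is consumed right-to-left but rows are
        returned in original string order.
        """
        idx = self.vocab.encode(text)
        if self.direction == "backward":
            return self._np_states(idx[::-1])[::-1].copy()
        return self._np_states(idx)

    def cross_entropy(self, text: str) -> float:
        """Average per-character cross-entropy (nats) on ``text``, numpy only."""
        targets = self.vocab.encode(text)
        if self.direction == "backward":
            targets = targets[::-1]
        inputs = np.concatenate(([self.vocab.index(BOS)], targets[:-1]))
        H = self._np_states(inputs)
        logits = H @ self.Wo.data + self.bo.data
        m = logits.max(axis=1, keepdims=True)
        logz = (m[:, 0] + np.log(np.exp(logits - m).sum(axis=1)))
        return float((logz - logits[np.arange(len(targets)), targets]).mean())

    # -- persistence -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "config": asdict(self.config),
            "vocab": self.vocab.to_list(),
            "params": {
                "E": self.E.data.tolist(),
                "lstm_W": self.lstm.W.data.tolist(),
                "lstm_b": self.lstm.b.data.tolist(),
                "Wo": self.Wo.data.tolist(),
                "bo": self.bo.data.tolist(),
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CharLanguageModel":
        model = cls(CharVocabulary.from_list(d["vocab"]), CharLMConfig(**d["config"]))
        p = d["params"]
        model.E.data = np.array(p["E"])
        model.lstm.W.data = np.array(p["lstm_W"])
        model.lstm.b.data = np.array(p["lstm_b"])
        model.Wo.data = np.array(p["Wo"])
        model.bo.data = np.array(p["bo"])
        return model

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "CharLanguageModel":
        return cls.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))


def _sig(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def train_char_lm(raw_text_corpus: str, config: CharLMConfig) -> CharLanguageModel:
    """Train a character LM on raw text with truncated BPTT windows.

    A held-out tail slice (``val_fraction``) is excluded from training; its
    per-character cross-entropy is logged at the end.  Training is
    deterministic given the seed.
    """
    if not raw_text_corpus:
        raise ValueError("empty training corpus")
    n_val = max(int(len(raw_text_corpus) * config.val_fraction), 0)
    train_text = raw_text_corpus[: len(raw_text_corpus) - n_val] if n_val else raw_text_corpus
    val_text = raw_text_corpus[len(raw_text_corpus) - n_val:] if n_val else ""
    if len(train_text) < config.chars_per_batch + 1:
        raise ValueError(
            f"training text has {len(train_text)} chars, shorter than one "
            f"window of {config.chars_per_batch}")
    vocab = CharVocabulary.from_text(raw_text_corpus)
    rng = np.random.default_rng(config.seed)
    model = CharLanguageModel(vocab, config, rng)
    stream = vocab.encode(train_text)
    if config.direction == "backward":
        stream = stream[::-1]
    opt = Adam(model.parameters(), lr=config.lr)
    w = config.chars_per_batch
    for step in range(config.steps):
        start = int(rng.integers(0, len(stream) - w))
        loss = model.window_loss(stream[start : start + w])
        opt.zero_grad()
        loss.backward()
        opt.step()
    if val_text:
        logger.info("%s char LM held-out cross-entropy: %.4f nats/char",
                    config.direction, model.cross_entropy(val_text))
    return model


def extract_word_embeddings(fwd: CharLanguageModel, bwd: CharLanguageModel,
                            sentence: Sequence[Token]) -> np.ndarray:
    """(n, 2h) contextual word embeddings from a forward/backward LM pair.

    The sentence is rendered as its token texts joined by single spaces.  Row
    i is [forward state at token i's last character || backward state at
    token i's first character].
    """
    if fwd.direction != "forward" or bwd.direction != "backward":
        raise ValueError(f"need a (forward, backward) pair, got "
                         f"({fwd.direction}, {bwd.direction})")
    if fwd.vocab != bwd.vocab:
        raise ValueError("forward and backward models must share the character vocabulary")
    if not sentence:
        return np.zeros((0, fwd.hidden_dim + bwd.hidden_dim))
    stream = " ".join(t.text for t in sentence)
    fwd_states = fwd.hidden_states(stream)
    bwd_states = bwd.hidden_states(stream)
    rows = []
    pos = 0
    for tok in sentence:
        first, last = pos, pos + len(tok.text) - 1
        rows.append(np.concatenate((fwd_states[last], bwd_states[first])))
        pos += len(tok.text) + 1
    return np.stack(rows)


class CharLMEmbedder:
    """Embedding-stack component wrapping a forward/backward LM pair."""

    def __init__(self, fwd: CharLanguageModel, bwd: CharLanguageModel):
        if fwd.direction != "forward" or bwd.direction != "backward":
            raise ValueError("CharLMEmbedder needs a (forward, backward) pair")
        self.fwd = fwd
        self.bwd = bwd

    @property
    def dim(self) -> int:
        return self.fwd.hidden_dim + self.bwd.hidden_dim

    def embed(self, tokens: Sequence[Token]) -> np.ndarray:
        return extract_word_embeddings(self.fwd, self.bwd, tokens)
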