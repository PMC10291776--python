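"""Linear-chain CRF: path scoring, forward algorithm, Viterbi decoding.

The transition matrix is (K+2)x(K+2) over the K real tags plus virtual START
and STOP states (indices K and K+1).  Transitions into START and out of STOP
are forbidden and held at a large negative constant.  A tag path's potential
is the sum of its emission scores and the transitions it crosses, including
START->first and last->STOP.

The numpy functions here are the inference path (used at decode time and as
the reference semantics); :func:`crf_nll` builds the same quantities on the
autodiff tape for training.
"""

from __future__ import annotations

import itertools

import numpy as np

from .nn import Tensor, logsumexp

__all__ = [
    "NEG_INF",
    "start_index",
    "stop_index",
    "init_transitions",
    "crf_score_sequence",
    "crf_log_partition",
    "viterbi_decode",
    "brute_force_log_partition",
    "brute_force_decode",
    "crf_nll",
]

NEG_INF = -1e4  # forbidden-transition score; finite to keep arithmetic NaN-free


def start_index(k: int) -> int:
    return k


def stop_index(k: int) -> int:
    return k + 1


def init_transitions(k: int) -> np.ndarray:
    """Zero-initialized transitions with forbidden entries at ``NEG_INF``."""
    T = np.zeros((k + 2, k + 2))
    T[:, start_index(k)] = NEG_INF  # nothing enters START
    T[stop_index(k), :] = NEG_INF  # nothing leaves STOP
    return T


def _check(emissions: np.ndarray, T: np.ndarray) -> int:
    emissions = np.asarray(emissions)
    if emissions.ndim != 2 or emissions.shape[0] < 1:
        raise ValueError("emissions must be a non-empty (n, K) matrix")
    if np.isnan(emissions).any() or np.isnan(T).any():
        raise ValueError("NaN in CRF scores")
    k = emissions.shape[1]
    if T.shape != (k + 2, k + 2):
        raise ValueError(f"transition matrix must be ({k+2},{k+2}), got {T.shape}")
    return k


def crf_score_sequence(emissions: np.ndarray, tags, T: np.ndarray) -> float:
    """Potential of one tag path: emissions + crossed transitions."""
    k = _check(emissions, T)
    tags = np.asarray(tags, dtype=np.intp)
    if tags.ndim != 1 or tags.shape[0] != emissions.shape[0]:
        raise ValueError("tags must be one index per emission row")
    if (tags < 0).any() or (tags >= k).any():
        raise ValueError(f"tag index out of range [0,{k})")
    score = float(emissions[np.arange(len(tags)), tags].sum())
    score += float(T[start_index(k), tags[0]])
    score += float(T[tags[:-1], tags[1:]].sum())
    score += float(T[tags[-1], stop_index(k)])
    return score


def crf_log_partition(emissions: np.ndarray, T: np.ndarray) -> float:
    """log sum over all K^n paths of exp(path score), by the forward recursion."""
    k = _check(emissions, T)
    alpha = T[start_index(k), :k] + emissions[0]
    for t in range(1, emissions.shape[0]):
        alpha = _lse(alpha[:, None] + T[:k, :k], axis=0) + emissions[t]
    return float(_lse(alpha + T[:k, stop_index(k)], axis=0))


def _lse(a: np.ndarray, axis: int) -> np.ndarray:
    m = a.max(axis=axis, keepdims=True)
    return np.squeeze(m + np.log(np.exp(a - m).sum(axis=axis, keepdims=True)), axis=axis)


def viterbi_decode(emissions: np.ndarray, T: np.ndarray) -> tuple[list[int], float]:
    """Global argmax tag path and its score.

    Ties break toward the lowest tag index at every backpointer (argmax takes
    the first maximum), so decoding is fully deterministic.
    """
    k = _check(emissions, T)
    n = emissions.shape[0]
    delta = T[start_index(k), :k] + emissions[0]
    back = np.zeros((n, k), dtype=np.intp)
    for t in range(1, n):
        scores = delta[:, None] + T[:k, :k]
        back[t] = scores.argmax(axis=0)
        delta = scores.max(axis=0) + emissions[t]
    final = delta + T[:k, stop_index(k)]
    last = int(final.argmax())
    best_score = float(final[last])
    path = [last]
    for t in range(n - 1, 0, -1):
        path.append(int(back[t, path[-1]]))
    path.reverse()
    return path, best_score


def brute_force_log_partition(emissions: np.ndarray, T: np.ndarray) -> float:
    """Independent oracle: enumerate all K^n paths (tiny n only)."""
    n, k = np.asarray(emissions).shape
    scores = [crf_score_sequence(emissions, path, T)
              for path in itertools.product(range(k), repeat=n)]
    return float(_lse(np.array(scores), axis=0))


def brute_force_decode(emissions: np.ndarray, T: np.ndarray) -> tuple[list[int], float]:
    """Independent oracle: exhaustive argmax with lowest-path tie-break."""
    n, k = np.asarray(emissions).shape
    best_path, best_score = None, -np.inf
    for path in itertools.product(range(k), repeat=n):
        s = crf_score_sequence(emissions, path, T)
        if s > best_score:  # strict improvement keeps the first (lexicographically lowest) tie
            best_path, best_score = list(path), s
    return best_path, best_score


def crf_nll(emissions: Tensor, tags: np.ndarray, T: Tensor) -> Tensor:
    """Negative log-likelihood (log Z minus gold score) on the autodiff tape."""
    n, k = emissions.data.shape
    tags = np.asarray(tags, dtype=np.intp)
    rows = np.arange(n)
    gold = emissions.gather(rows, tags).sum()
    start_pairs_r = np.concatenate(([start_index(k)], tags))
    start_pairs_c = np.concatenate((tags, [stop_index(k)]))
    gold = gold + T.gather(start_pairs_r, start_pairs_c).sum()

    alpha = T[start_index(k), :k] + emissions[0, :]
    for t in range(1, n):
        prev = alpha.reshape(k, 1)
        alpha = logsumexp(prev + T[:k, :k], axis=0) + emissions[t, :]
    log_z = logsumexp(alpha + T[:k, stop_index(k)], axis=0)
    return log_z - gold
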