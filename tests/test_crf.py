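"""Linear-chain CRF scoring, forward algorithm, and Viterbi against oracles."""

import itertools

import numpy as np
import pytest

from disann import crf
from disann.nn import Parameter


def random_instance(rng, n, k):
    emissions = rng.normal(size=(n, k))
    T = crf.init_transitions(k)
    T[:k, :] += rng.normal(size=(k, k + 2)) * (T[:k, :] > crf.NEG_INF / 2)
    T[crf.start_index(k), :k] = rng.normal(size=k)
    return emissions, T


class TestScoreSequence:
    def test_single_token_all_zeros(self):
        T = np.zeros((5, 5))
        assert crf.crf_score_sequence(np.zeros((1, 3)), [0], T) == 0.0

    def test_hand_sum_two_tokens(self):
        emissions = np.array([[1.0, 2.0], [3.0, 4.0]])
        T = np.zeros((4, 4))
        T[2, 0] = 0.5   # START -> tag0
        T[0, 1] = 0.25  # tag0 -> tag1
        T[1, 3] = 0.125  # tag1 -> STOP
        got = crf.crf_score_sequence(emissions, [0, 1], T)
        assert got == pytest.approx(1.0 + 4.0 + 0.5 + 0.25 + 0.125)

    def test_linearity_in_emissions(self, rng):
        emissions, T = random_instance(rng, 4, 3)
        tags = [0, 2, 1, 0]
        base = crf.crf_score_sequence(emissions, tags, T)
        shifted = emissions.copy()
        shifted[np.arange(4), tags] += 1.5
        assert crf.crf_score_sequence(shifted, tags, T) == pytest.approx(base + 4 * 1.5)

    def test_tag_out_of_range(self, rng):
        emissions, T = random_instance(rng, 2, 3)
        with pytest.raises(ValueError, match="out of range"):
            crf.crf_score_sequence(emissions, [0, 3], T)


class TestLogPartition:
    def test_single_step_uniform_is_log_k(self):
        k = 3
        T = np.zeros((k + 2, k + 2))
        got = crf.crf_log_partition(np.zeros((1, k)), T)
        assert got == pytest.approx(np.log(3), abs=1e-12)

    def test_matches_brute_force(self, rng):
        for _ in range(30):
            n, k = int(rng.integers(1, 4)), int(rng.integers(2, 4))
            emissions, T = random_instance(rng, n, k)
            assert crf.crf_log_partition(emissions, T) == pytest.approx(
                crf.brute_force_log_partition(emissions, T), abs=1e-8)

    def test_upper_bounds_any_path(self, rng):
        emissions, T = random_instance(rng, 3, 3)
        logz = crf.crf_log_partition(emissions, T)
        for path in itertools.product(range(3), repeat=3):
            assert logz >= crf.crf_score_sequence(emissions, path, T)

    def test_path_probabilities_sum_to_one(self, rng):
        emissions, T = random_instance(rng, 3, 3)
        logz = crf.crf_log_partition(emissions, T)
        total = sum(np.exp(crf.crf_score_sequence(emissions, p, T) - logz)
                    for p in itertools.product(range(3), repeat=3))
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_nan_rejected(self):
        emissions = np.full((2, 3), np.nan)
        with pytest.raises(ValueError, match="NaN"):
            crf.crf_log_partition(emissions, crf.init_transitions(3))


class TestViterbi:
    def test_matches_brute_force(self, rng):
        for _ in range(50):
            n, k = int(rng.integers(1, 5)), int(rng.integers(2, 6))
            emissions, T = random_instance(rng, n, k)
            path, score = crf.viterbi_decode(emissions, T)
            bpath, bscore = crf.brute_force_decode(emissions, T)
            assert path == bpath
            assert score == pytest.approx(bscore, abs=1e-10)
            assert score == pytest.approx(
                crf.crf_score_sequence(emissions, path, T), abs=1e-10)

    def test_dominant_emission_wins(self):
        k = 3
        emissions = np.zeros((4, k))
        emissions[:, 1] = 100.0
        path, _ = crf.viterbi_decode(emissions, crf.init_transitions(k))
        assert path == [1, 1, 1, 1]

    def test_all_zero_ties_break_to_lowest_index(self):
        path, score = crf.viterbi_decode(np.zeros((3, 4)), np.zeros((6, 6)))
        assert path == [0, 0, 0]
        assert score == 0.0


class TestAutodiffNll:
    def test_value_matches_numpy_parts(self, rng):
        emissions, T = random_instance(rng, 4, 3)
        tags = [0, 1, 2, 1]
        nll = crf.crf_nll(Parameter(emissions), np.array(tags), Parameter(T))
        expected = (crf.crf_log_partition(emissions, T)
                    - crf.crf_score_sequence(emissions, tags, T))
        assert float(nll.data) == pytest.approx(expected, abs=1e-10)

    def test_gradient_matches_finite_differences(self, rng):
        emissions, T = random_instance(rng, 3, 3)
        tags = np.array([0, 2, 1])
        p = Parameter(emissions)
        crf.crf_nll(p, tags, Parameter(T)).backward()
        eps = 1e-6
        for i, j in [(0, 0), (1, 2), (2, 1)]:
            up, down = emissions.copy(), emissions.copy()
            up[i, j] += eps
            down[i, j] -= eps
            num = ((crf.crf_log_partition(up, T) - crf.crf_score_sequence(up, tags, T))
                   - (crf.crf_log_partition(down, T)
                      - crf.crf_score_sequence(down, tags, T))) / (2 * eps)
            assert p.grad[i, j] == pytest.approx(num, abs=1e-6)
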