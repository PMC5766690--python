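"""Metrics: L2 coefficient distance, Otsu threshold, MCC, coherence."""

import itertools

import numpy as np
import pytest

from phasebayes.evaluate import (
    DegenerateValuesError,
    coherence,
    infer_connections,
    l2_distance,
    mcc,
    otsu_threshold,
    summed_power,
)
from phasebayes.model_core import FourierInteraction
from phasebayes.synthesize import SpikeDataset

from conftest import random_interaction


class TestL2Distance:
    def test_identical_zero(self):
        f = FourierInteraction(a=[0.3, 0.1], b=[-0.2, 0.4])
        assert l2_distance(f, f) == 0.0

    def test_against_all_zero(self):
        f = FourierInteraction(a=[1.0], b=[0.0])
        z = FourierInteraction(a=[0.0], b=[0.0])
        assert l2_distance(f, z, n_pad=5) == pytest.approx(1.0)

    def test_unmodeled_harmonic_penalized(self):
        truth = FourierInteraction(a=[0.0, 0.0], b=[0.3, 0.5])
        est = FourierInteraction(a=[0.0], b=[0.3])  # matches b1, misses b2
        assert l2_distance(truth, est) == pytest.approx(0.5)

    def test_no_sqrt_option(self):
        truth = FourierInteraction(a=[1.0], b=[0.0])
        z = FourierInteraction(a=[0.0], b=[0.0])
        assert l2_distance(truth, z, sqrt=False) == pytest.approx(1.0)
        truth2 = FourierInteraction(a=[2.0], b=[0.0])
        assert l2_distance(truth2, z, sqrt=False) == pytest.approx(4.0)

    def test_pad_must_cover(self):
        f = FourierInteraction(a=[0, 0, 0], b=[0, 0, 1])
        with pytest.raises(ValueError):
            l2_distance(f, f, n_pad=2)

    @pytest.mark.parametrize("seed", range(10))
    def test_metric_properties(self, seed):
        rng = np.random.default_rng(seed)
        f, g, h = (random_interaction(rng) for _ in range(3))
        dfg = l2_distance(f, g)
        assert dfg == pytest.approx(l2_distance(g, f))  # symmetry
        assert l2_distance(f, f) == 0.0  # identity
        assert dfg <= l2_distance(f, h) + l2_distance(h, g) + 1e-12  # triangle


class TestSummedPower:
    def test_zero(self):
        assert summed_power(FourierInteraction(a=[0.0], b=[0.0])) == 0.0

    def test_pythagorean(self):
        assert summed_power(FourierInteraction(a=[3.0], b=[4.0])) == pytest.approx(25.0)

    def test_sign_flip_invariant(self):
        f = FourierInteraction(a=[0.3, -0.2], b=[0.1, 0.7])
        g = FourierInteraction(a=[-0.3, 0.2], b=[-0.1, -0.7])
        assert summed_power(f) == pytest.approx(summed_power(g))


def brute_force_otsu(values):
    """Independent exhaustive oracle: try every split of the sorted values."""
    v = np.sort(np.asarray(values, float))
    n = v.size
    best_t, best_score = None, -1.0
    uniq = np.unique(v)
    for t in 0.5 * (uniq[:-1] + uniq[1:]):
        lo = [x for x in v if x <= t]
        hi = [x for x in v if x > t]
        score = (len(lo) / n) * (len(hi) / n) * (np.mean(lo) - np.mean(hi)) ** 2
        if score > best_score + 1e-15:
            best_t, best_score = t, score
    return best_t


class TestOtsu:
    def test_two_clusters(self):
        assert otsu_threshold([0.0, 0.0, 1.0, 1.0]) == pytest.approx(0.5)

    def test_isolates_outlier(self):
        t = otsu_threshold([0.1, 0.1, 0.1, 0.9])
        assert 0.1 < t < 0.9
        assert t == pytest.approx(0.5)

    def test_identical_values_error(self):
        with pytest.raises(DegenerateValuesError):
            otsu_threshold([0.5, 0.5])

    @pytest.mark.parametrize("seed", range(100))
    def test_against_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 30))
        vals = np.round(rng.uniform(0, 1, n), 3)
        if np.unique(vals).size < 2:
            vals[0] += 0.5
        assert otsu_threshold(vals) == pytest.approx(brute_force_otsu(vals))


class TestMCC:
    def _mats(self, e, a):
        return np.array(e), np.array(a)

    def test_perfect_agreement(self):
        w = np.array([[0, 1, 0], [0, 0, 1], [1, 0, 0]])
        assert mcc(w, w) == pytest.approx(1.0)

    def test_balanced_random_zero(self):
        e = np.array([1] * 5 + [1] * 5 + [0] * 5 + [0] * 5)
        a = np.array([1] * 5 + [0] * 5 + [1] * 5 + [0] * 5)
        assert mcc(e, a) == pytest.approx(0.0)

    def test_inverted_minus_one(self):
        a = np.array([[0, 1], [0, 0]])
        e = 1 - a
        e[np.diag_indices(2)] = 0
        # off-diagonal entries fully inverted
        assert mcc(e, a) == pytest.approx(-1.0)

    def test_label_swap_invariance(self):
        rng = np.random.default_rng(2)
        e = rng.integers(0, 2, 30)
        a = rng.integers(0, 2, 30)
        assert mcc(e, a) == pytest.approx(mcc(1 - e, 1 - a))

    def test_zero_denominator_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            assert mcc(np.ones(6, dtype=int), np.array([1, 0, 1, 0, 1, 0])) == 0.0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            mcc(np.zeros((2, 2)), np.zeros((3, 3)))

    def test_diagonal_excluded(self):
        e = np.eye(3, dtype=int)  # diagonal entries must not count
        a = np.zeros((3, 3), dtype=int)
        with pytest.warns(UserWarning):
            assert mcc(e, a) == 0.0  # off-diagonal all TN -> one-class


class TestInferConnections:
    def _est(self, power):
        return FourierInteraction(a=[np.sqrt(power)], b=[0.0])

    def test_clean_separation_mcc_one(self):
        ests = {
            (0, 1): self._est(0.01), (0, 2): self._est(0.02),
            (1, 0): self._est(0.90), (1, 2): self._est(1.00),
        }
        truth = np.zeros((3, 3), dtype=int)
        truth[1, 0] = truth[1, 2] = 1
        inf = infer_connections(ests, truth=truth)
        assert inf.mcc == pytest.approx(1.0)
        assert inf.w_est[(1, 0)] == 1 and inf.w_est[(0, 1)] == 0
        assert inf.normalized_powers.max() == pytest.approx(1.0)

    def test_all_equal_powers_degenerate(self):
        ests = {(0, 1): self._est(0.5), (1, 0): self._est(0.5)}
        with pytest.raises(DegenerateValuesError):
            infer_connections(ests)

    def test_pair_permutation_consistent(self):
        rng = np.random.default_rng(3)
        pairs = [(i, j) for i, j in itertools.permutations(range(4), 2)]
        powers = rng.uniform(0, 1, len(pairs))
        ests1 = {p: self._est(w) for p, w in zip(pairs, powers)}
        ests2 = {p: ests1[p] for p in reversed(pairs)}
        i1 = infer_connections(ests1)
        i2 = infer_connections(ests2)
        assert i1.threshold == pytest.approx(i2.threshold)
        assert i1.w_est == i2.w_est


class TestCoherence:
    def test_identical_trains_kappa_one(self):
        s = np.arange(1.0, 100.0, 7.0)
        ds = SpikeDataset(spikes=[s, s.copy()], t_start=0, t_end=100)
        for b in (1.0, 5.0, 20.0):
            res = coherence(ds, b)
            assert res.kappa_mean[b] == pytest.approx(1.0)

    def test_disjoint_trains_zero_at_fine_bins(self):
        ds = SpikeDataset(
            spikes=[np.arange(1.0, 50.0, 4.0), np.arange(3.0, 50.0, 4.0)],
            t_start=0, t_end=50,
        )
        res = coherence(ds, 1.0)
        assert res.kappa_mean[1.0] == 0.0

    def test_independent_trains_grow_with_bin_size(self):
        rng = np.random.default_rng(0)
        spikes = [np.sort(rng.uniform(0, 1000, 300)) for _ in range(4)]
        ds = SpikeDataset(spikes=spikes, t_start=0, t_end=1000)
        bins = [1.0, 2.0, 4.0]
        res = coherence(ds, bins)
        k = [res.kappa_mean[b] for b in bins]
        assert k[0] < k[1] < k[2]
        # roughly linear growth before saturation
        assert k[2] / k[0] == pytest.approx(4.0, rel=0.5)

    def test_kappa_bounds(self):
        rng = np.random.default_rng(1)
        ds = SpikeDataset(
            spikes=[np.sort(rng.uniform(0, 100, 30)) for _ in range(3)],
            t_start=0, t_end=100,
        )
        res = coherence(ds, [2.0, 10.0])
        for kp in res.kappa_per_pair.values():
            for v in kp.values():
                assert 0.0 <= v <= 1.0

    def test_empty_dataset_rejected(self):
        ds = SpikeDataset(spikes=[np.array([]), np.array([])], t_start=0, t_end=10)
        with pytest.raises(ValueError):
            coherence(ds, 1.0)
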