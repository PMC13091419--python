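import numpy as np
import pytest

from hiephys.synchrony import (CrossCorrMatrix, binned_rate, cluster_order,
                               correlogram, matrix_similarity,
                               pairwise_r2_matrix, spike_spike_coherence)
from hiephys.synthetic import simulate_spike_train

from conftest import make_train


class TestCorrelogram:
    def test_autocorrelogram_of_periodic_train(self, periodic_train):
        # 3 ms bins keep the +/-100 and +/-200 ms peaks off bin edges
        cg = correlogram(periodic_train, periodic_train, bin_ms=3.0,
                         max_lag_ms=250.0)
        # peaks at +/-100 ms and +/-200 ms, nothing at 0 (self-pairs removed)
        zero = np.argmin(np.abs(cg.lags_ms))
        assert cg.counts[zero] == 0
        for lag in (-200, -100, 100, 200):
            k = np.argmin(np.abs(cg.lags_ms - lag))
            assert cg.counts[k] > 900

    def test_shifted_copy_peaks_at_shift(self, rng):
        a = make_train(np.sort(rng.uniform(0, 100, 500)), 100.0)
        b = make_train(a.times[a.times < 99.9] + 0.02, 100.0, unit_id="b")
        cg = correlogram(a, b, bin_ms=2.0, max_lag_ms=50.0)
        assert cg.lags_ms[np.argmax(cg.counts)] == pytest.approx(21.0, abs=2.0)

    def test_reversal_symmetry(self, rng):
        a = make_train(np.sort(rng.uniform(0, 50, 300)), 50.0)
        b = make_train(np.sort(rng.uniform(0, 50, 260)), 50.0, unit_id="b")
        ab = correlogram(a, b, 5.0, 100.0)
        ba = correlogram(b, a, 5.0, 100.0)
        np.testing.assert_array_equal(ab.counts, ba.counts[::-1])

    def test_independent_poisson_flat(self):
        a = simulate_spike_train(10.0, 1000.0, seed=1)
        b = simulate_spike_train(10.0, 1000.0, seed=2, unit_id="b")
        cg = correlogram(a, b, 5.0, 100.0)
        assert cg.counts.max() / cg.counts.mean() < 1.5


class TestBinnedRate:
    def test_count_to_rate_arithmetic(self):
        train = make_train([0.001, 0.004, 0.008, 0.0124], 1.0)
        _, rate = binned_rate(train, bin_ms=12.5, smooth_sigma_ms=0.0)
        assert rate[0] == pytest.approx(4 / 0.0125)
        assert rate[1:].sum() == 0.0

    def test_empty_train_zero_series(self):
        _, rate = binned_rate(make_train([], 10.0))
        assert np.all(rate == 0.0)

    def test_zero_sigma_is_identity_and_preserves_count(self, rng):
        train = make_train(np.sort(rng.uniform(0, 60, 500)), 60.0)
        _, r0 = binned_rate(train, 12.5, 0.0)
        assert r0.sum() * 0.0125 == pytest.approx(500)

    def test_smoothing_preserves_total_rate(self, rng):
        train = make_train(np.sort(rng.uniform(0, 60, 500)), 60.0)
        _, r = binned_rate(train, 12.5, 25.0)
        assert r.sum() * 0.0125 == pytest.approx(500, rel=0.01)


class TestSpikeSpikeCoherence:
    def test_identical_trains_fully_coherent(self):
        a = simulate_spike_train(20.0, 100.0, seed=3)
        _, coh, mean_c = spike_spike_coherence(a, a)
        assert np.all(coh > 0.999)
        assert mean_c > 0.999

    def test_independent_trains_low(self):
        a = simulate_spike_train(8.0, 1000.0, seed=4)
        b = simulate_spike_train(8.0, 1000.0, seed=5, unit_id="b")
        _, _, mean_c = spike_spike_coherence(a, b)
        assert mean_c < 0.1

    def test_shared_modulation_peaks_in_theta(self, rng):
        # common 6 Hz rate modulation on two otherwise independent trains
        dur, f0 = 600.0, 6.0

        def modulated(seed):
            r = np.random.default_rng(seed)
            n = r.poisson(10.0 * dur * 2)
            cand = np.sort(r.uniform(0, dur, n))
            keep = r.uniform(size=n) < 0.5 * (1 + 0.8 * np.cos(2 * np.pi * f0 * cand))
            return make_train(cand[keep], dur)

        f, coh, _ = spike_spike_coherence(modulated(6), modulated(7))
        band = (f >= 4) & (f <= 8)
        out = (f > 12) & (f <= 100)
        assert coh[band].max() > 5 * coh[out].mean()

    def test_too_short_rejected(self):
        a = simulate_spike_train(20.0, 0.1, seed=8)
        with pytest.raises(ValueError):
            spike_spike_coherence(a, a)


class TestR2Matrix:
    def test_duplicated_series_perfectly_correlated(self, rng):
        x = rng.normal(size=1000) + 5
        m = pairwise_r2_matrix({"a": x, "b": x.copy(), "c": rng.normal(size=1000)})
        assert m.r2[0, 1] == pytest.approx(1.0)
        assert m.r2[0, 2] < 0.1

    def test_independent_units_low_median(self):
        rates = {}
        for k in range(6):
            tr = simulate_spike_train(5.0, 600.0, seed=20 + k, unit_id=f"u{k}")
            rates[f"u{k}"] = binned_rate(tr)[1]
        m = pairwise_r2_matrix(rates)
        iu = np.triu_indices(6, k=1)
        assert np.median(m.r2[iu]) < 0.05

    def test_zero_variance_warns_and_zeroes(self, rng):
        with pytest.warns(UserWarning, match="zero-variance"):
            m = pairwise_r2_matrix({"a": np.ones(100), "b": rng.normal(size=100)})
        assert m.r2[0, 1] == 0.0

    def test_permutation_equivariance(self, rng):
        series = {f"u{k}": rng.normal(size=500) for k in range(4)}
        m1 = pairwise_r2_matrix(series)
        rev = {k: series[k] for k in reversed(list(series))}
        m2 = pairwise_r2_matrix(rev)
        np.testing.assert_allclose(m2.r2, m1.r2[::-1, ::-1], atol=1e-12)


class TestClusterOrder:
    def test_blocks_stay_contiguous(self, rng):
        ids = tuple("abcdef")
        m = np.eye(6)
        for i in range(3):
            for j in range(3):
                m[i, j] = m[i + 3, j + 3] = 0.9 if i != j else 1.0
        m += rng.normal(0, 0.01, (6, 6))
        m = np.clip((m + m.T) / 2, 0, 1)
        np.fill_diagonal(m, 1.0)
        order = cluster_order(CrossCorrMatrix(ids, m))
        pos = [order.index(u) for u in "abc"]
        assert max(pos) - min(pos) == 2
        pos = [order.index(u) for u in "def"]
        assert max(pos) - min(pos) == 2

    def test_identity_matrix_preserves_input_order(self):
        ids = tuple("abcde")
        order = cluster_order(CrossCorrMatrix(ids, np.eye(5)))
        assert order == list(ids)

    def test_two_cluster_recovery(self, rng):
        n = 12
        truth = np.array([0] * 6 + [1] * 6)
        m = np.where(truth[:, None] == truth[None, :], 0.7, 0.05)
        m = np.clip(m + rng.normal(0, 0.03, (n, n)), 0, 1)
        m = (m + m.T) / 2
        np.fill_diagonal(m, 1.0)
        ids = tuple(f"u{k}" for k in range(n))
        order = cluster_order(CrossCorrMatrix(ids, m))
        # Rand index of the leaf-order split vs ground truth
        first = {u for u in order[:6]}
        pred = np.array([0 if f"u{k}" in first else 1 for k in range(n)])
        same_pred = pred[:, None] == pred[None, :]
        same_true = truth[:, None] == truth[None, :]
        iu = np.triu_indices(n, 1)
        rand = np.mean(same_pred[iu] == same_true[iu])
        assert rand > 0.9


class TestMatrixSimilarity:
    def _mat(self, rng, n=6):
        m = np.clip(rng.uniform(0, 1, (n, n)), 0, 1)
        m = (m + m.T) / 2
        np.fill_diagonal(m, 1.0)
        return CrossCorrMatrix(tuple(f"u{k}" for k in range(n)), m)

    def test_self_similarity_is_one(self, rng):
        m = self._mat(rng)
        assert matrix_similarity(m, m) == pytest.approx(1.0)

    def test_complement_anticorrelated(self, rng):
        m = self._mat(rng)
        inv = 1.0 - m.r2
        np.fill_diagonal(inv, 1.0)
        m2 = CrossCorrMatrix(m.unit_ids, inv)
        assert matrix_similarity(m, m2) == pytest.approx(-1.0)

    def test_mismatched_units_rejected(self, rng):
        m = self._mat(rng)
        other = CrossCorrMatrix(tuple(f"v{k}" for k in range(6)), m.r2)
        with pytest.raises(ValueError):
            matrix_similarity(m, other)
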