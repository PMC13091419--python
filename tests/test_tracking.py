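import numpy as np
import pytest
from scipy import stats

from hiephys.synthetic import (simulate_learning_series, simulate_spike_train,
                               simulate_waveform_set)
from hiephys.tracking import (ISIH_EDGES_MS, amplitude_change,
                              assess_stability, classify_learning_response,
                              kl_divergence, learning_response_features,
                              log_histograms, score_pair, waveform_similarity)

from conftest import make_train


class TestWaveformSimilarity:
    def test_identical_waveforms(self):
        w = simulate_waveform_set(0.5, 0.25, 100.0, 1, 0.0)[0, 0]
        r, z = waveform_similarity(w, w)
        assert r == pytest.approx(1.0)
        assert z == pytest.approx(np.arctanh(0.9999))

    def test_shifted_copy_recovered(self):
        w = simulate_waveform_set(0.5, 0.25, 100.0, 1, 0.0)[0, 0]
        r, _ = waveform_similarity(w, np.roll(w, 2), max_shift_samples=4)
        assert r == pytest.approx(1.0, abs=1e-6)

    def test_independent_noise_matches_permutation_null(self, rng):
        # empirical max-r distribution must sit within the null band obtained
        # by shuffling one waveform of each pair
        obs, null = [], []
        for _ in range(100):
            a, b = rng.normal(size=40), rng.normal(size=40)
            obs.append(waveform_similarity(a, b, 8)[0])
            null.append(waveform_similarity(a, rng.permutation(b), 8)[0])
        assert abs(np.median(obs) - np.median(null)) < 0.1
        assert stats.ks_2samp(obs, null).pvalue > 0.01

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            waveform_similarity(np.zeros(40), np.ones(40))


class TestAmplitudeChange:
    def test_cases(self):
        w = simulate_waveform_set(0.5, 0.25, 100.0, 1, 0.0)[0, 0]
        assert amplitude_change(w, w) == 0.0
        assert amplitude_change(w, 1.5 * w) == pytest.approx(0.5)
        assert amplitude_change(w, 0.5 * w) == pytest.approx(0.5)

    def test_zero_amplitude_rejected(self):
        with pytest.raises(ValueError):
            amplitude_change(np.zeros(40), np.ones(40))


class TestLogHistograms:
    def test_periodic_isi_mass_in_hundred_ms_bin(self, periodic_train):
        h = log_histograms(periodic_train)
        k = np.searchsorted(ISIH_EDGES_MS, 100.0) - 1
        assert h["isih"][k] > 0.99

    def test_histograms_normalized(self):
        tr = simulate_spike_train(5.0, 300.0, seed=1)
        h = log_histograms(tr)
        assert h["isih"].sum() == pytest.approx(1.0)
        assert h["acorr"].sum() == pytest.approx(1.0)
        assert np.all(h["isih"] > 0)

    def test_poisson_isih_matches_exponential(self):
        tr = simulate_spike_train(5.0, 2000.0, seed=2)
        h = log_histograms(tr, eps=0.0)
        mu_ms = 1000.0 / tr.mean_rate_hz
        cdf = 1.0 - np.exp(-ISIH_EDGES_MS / mu_ms)
        expected = np.diff(cdf)
        expected /= expected.sum()
        n = tr.n_spikes - 1
        keep = expected * n >= 5
        chi2 = np.sum((h["isih"][keep] * n - expected[keep] * n) ** 2
                      / (expected[keep] * n))
        p = stats.chi2.sf(chi2, keep.sum() - 1)
        assert p > 0.01

    def test_too_few_spikes_rejected(self):
        with pytest.raises(ValueError):
            log_histograms(make_train([1.0], 10.0))


class TestKLDivergence:
    def test_identity(self):
        p = np.array([0.25, 0.25, 0.5])
        assert kl_divergence(p, p)[0] == 0.0

    def test_two_bin_closed_form(self):
        p = np.array([0.9, 0.1])
        q = np.array([0.1, 0.9])
        kl, log_kl = kl_divergence(p, q)
        assert kl == pytest.approx(0.8 * np.log(9.0))
        assert log_kl == pytest.approx(np.log(kl + 1e-10))

    def test_asymmetry(self):
        p = np.array([0.9, 0.1])
        q = np.array([0.5, 0.5])
        assert kl_divergence(p, q)[0] != pytest.approx(kl_divergence(q, p)[0])

    def test_binning_mismatch_rejected(self):
        with pytest.raises(ValueError):
            kl_divergence(np.ones(3) / 3, np.ones(4) / 4)


def _unit_params(rng, n):
    return [dict(ttp=rng.uniform(0.4, 0.7), hw=rng.uniform(0.22, 0.32),
                 amp=rng.uniform(80, 150), rate=rng.uniform(2, 10),
                 br=rng.uniform(0, 6)) for _ in range(n)]


def _unit_data(p, seed):
    w = simulate_waveform_set(p["ttp"], p["hw"], p["amp"], 60, 10.0,
                              seed=seed).mean(axis=0)[0]
    tr = simulate_spike_train(p["rate"], 600.0, p["br"], 8.0, 5.0, seed=seed + 1)
    return w, tr


@pytest.fixture(scope="module")
def experiment():
    rng = np.random.default_rng(7)
    params = _unit_params(rng, 25)
    day1 = [_unit_data(p, 1000 + 3 * i) for i, p in enumerate(params)]
    within = [_unit_data(p, 2000 + 3 * i) for i, p in enumerate(params)]
    day7 = [_unit_data(p, 3000 + 3 * i) for i, p in enumerate(params)]
    cal = [score_pair(day1[i][0], within[i][0], day1[i][1], within[i][1])
           for i in range(25)]
    return params, day1, day7, cal


class TestStability:
    def test_persisting_units_mostly_stable(self, experiment):
        _, day1, day7, cal = experiment
        persist = [score_pair(day1[i][0], day7[i][0], day1[i][1], day7[i][1])
                   for i in range(25)]
        labeled, report = assess_stability(persist, cal)
        assert np.mean([s.stable for s in labeled]) > 0.5
        assert 0.0 <= report["false_negative_rate"] <= 0.3

    def test_swapped_units_detected(self, experiment):
        _, day1, day7, cal = experiment
        swap = [score_pair(day1[i][0], day7[(i + 7) % 25][0],
                           day1[i][1], day7[(i + 7) % 25][1])
                for i in range(25)]
        labeled, _ = assess_stability(swap, cal)
        sensitivity = np.mean([not s.stable for s in labeled])
        assert sensitivity > 0.8

    def test_small_calibration_rejected(self, experiment):
        _, day1, day7, cal = experiment
        with pytest.raises(ValueError):
            assess_stability(cal[:5], cal[:5])


class TestLearningResponse:
    def test_generated_labels_recovered(self):
        for seed in range(10):
            series = simulate_learning_series(seed=seed)
            labels = classify_learning_response(series)
            acc = np.mean([lab == s.true_label
                           for lab, s in zip(labels, series)])
            assert acc >= 0.9

    def test_feature_contrast_between_classes(self):
        series = simulate_learning_series(seed=3)
        feats = {s.true_label: learning_response_features(s) for s in series}
        assert feats["reactive"][0] > feats["affected"][0]      # R^2 contrast
        assert feats["affected"][1] > feats["non_reactive"][1]  # coherence

    def test_quadrant_rule_with_explicit_thresholds(self):
        series = simulate_learning_series(n_reactive=2, n_nonreactive=2,
                                          n_affected=2, seed=4)
        labels = classify_learning_response(series, r2_threshold=0.5,
                                            coherence_threshold=0.35)
        assert labels == [s.true_label for s in series]
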