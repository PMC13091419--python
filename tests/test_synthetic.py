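import numpy as np
import pytest
from scipy import special

from hiephys.bursts import burst_summary, detect_bursts
from hiephys.phase import band_phase, plv, spike_phases
from hiephys.synthetic import (CohortSpec, simulate_cohort,
                               simulate_learning_series, simulate_lfp,
                               simulate_phase_locked_train,
                               simulate_spike_train, simulate_waveform_set)


class TestSimulateLfp:
    def test_pure_theta_is_six_hz_tone(self):
        lfp = simulate_lfp({"theta": 10.0}, 500.0, 20.0, 0.0, seed=1)
        x = lfp.samples
        assert np.abs(x).max() == pytest.approx(10.0, rel=1e-3)
        # zero crossings of a 6 Hz tone: 12 per second
        crossings = np.sum(np.diff(np.signbit(x)))
        assert crossings == pytest.approx(12 * 20, abs=2)

    def test_white_noise_sd_recovered(self):
        lfp = simulate_lfp({}, 500.0, 200.0, 1.0, seed=2)
        assert lfp.samples.std() == pytest.approx(1.0, rel=0.05)

    def test_deterministic_given_seed(self):
        a = simulate_lfp({"theta": 5.0}, 500.0, 10.0, 1.0, seed=3)
        b = simulate_lfp({"theta": 5.0}, 500.0, 10.0, 1.0, seed=3)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_low_rate_rejected(self):
        with pytest.raises(ValueError):
            simulate_lfp({"gamma": 1.0}, 100.0, 10.0, 0.0, seed=4)


class TestSimulateSpikeTrain:
    def test_rate_recovered(self):
        tr = simulate_spike_train(5.0, 1000.0, seed=5)
        assert tr.mean_rate_hz == pytest.approx(5.0, rel=0.05)

    def test_zero_rate_empty(self):
        assert simulate_spike_train(0.0, 100.0, seed=6).n_spikes == 0

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            simulate_spike_train(-1.0, 10.0)

    def test_burst_count_recovered_by_detector(self):
        counts = []
        for seed in range(5):
            tr = simulate_spike_train(1.0, 600.0, 6.0, 8.0, 5.0, seed=seed)
            counts.append(len(detect_bursts(tr, 5.0)))
        assert abs(np.mean(counts) - 60.0) / 60.0 < 0.2

    def test_strictly_increasing_times(self):
        tr = simulate_spike_train(10.0, 100.0, 10.0, 8.0, 5.0, seed=7)
        assert np.all(np.diff(tr.times) > 0)


@pytest.fixture(scope="module")
def theta_lfp():
    return simulate_lfp({"theta": 10.0}, 500.0, 2000.0, 0.0, seed=8)


class TestPhaseLockedTrain:
    def _phases(self, lfp, train):
        phase, _ = band_phase(lfp, (4.0, 12.0))
        return spike_phases(train, phase, lfp.fs)

    def test_kappa_zero_is_homogeneous(self, theta_lfp):
        tr = simulate_phase_locked_train(theta_lfp, (4, 12), 10.0, 0.0, seed=9)
        r, _ = plv(self._phases(theta_lfp, tr))
        assert tr.n_spikes > 10000
        assert r < 0.05

    def test_preferred_phase_recovered(self, theta_lfp):
        tr = simulate_phase_locked_train(theta_lfp, (4, 12), 20.0, 5.0,
                                         np.pi / 3, seed=10)
        _, mu = plv(self._phases(theta_lfp, tr))
        assert np.degrees(np.angle(np.exp(1j * (mu - np.pi / 3)))) == pytest.approx(
            0.0, abs=10.0)

    def test_plv_matches_bessel_ratio(self, theta_lfp):
        tr = simulate_phase_locked_train(theta_lfp, (4, 12), 50.0, 2.0, seed=11)
        r, _ = plv(self._phases(theta_lfp, tr))
        assert tr.n_spikes > 90000
        assert r == pytest.approx(special.i1(2.0) / special.i0(2.0), abs=0.02)

    def test_band_outside_nyquist_rejected(self, theta_lfp):
        with pytest.raises(ValueError):
            simulate_phase_locked_train(theta_lfp, (4, 400), 10.0, 1.0)


class TestWaveformSet:
    def test_deterministic(self):
        a = simulate_waveform_set(0.5, 0.25, 100.0, 10, 5.0, seed=12)
        b = simulate_waveform_set(0.5, 0.25, 100.0, 10, 5.0, seed=12)
        np.testing.assert_array_equal(a, b)

    def test_four_channels_with_gains(self):
        w = simulate_waveform_set(0.5, 0.25, 100.0, 3, 0.0)
        assert w.shape == (3, 4, 40)
        np.testing.assert_allclose(w[0, 1], 0.8 * w[0, 0], atol=1e-9)

    def test_ttp_exceeding_window_rejected(self):
        with pytest.raises(ValueError):
            simulate_waveform_set(1.5, 0.25, 100.0)

    def test_averaging_stabilizes_features(self):
        from hiephys.waveforms import waveform_features
        vals = []
        for seed in range(10):
            w = simulate_waveform_set(0.5, 0.25, 100.0, 100, 20.0, seed=seed)
            f = waveform_features(w.mean(axis=0), 30000.0)
            vals.append(f.trough_to_peak_ms)
        assert np.std(vals) / np.mean(vals) < 0.1


@pytest.fixture(scope="module")
def small_cohort():
    spec = CohortSpec(
        units_per_group={"sham_left": 4, "sham_right": 4,
                         "hi_contra": 4, "hi_ipsi": 2},
        duration_s=120.0, seed=13)
    return simulate_cohort(spec)


class TestCohort:
    def test_ipsilateral_unit_deficit_as_configured(self, small_cohort):
        per_group = {}
        for tr in small_cohort.trains:
            if small_cohort.cell_types[tr.unit_id] == "PN":
                per_group[tr.group] = per_group.get(tr.group, 0) + 1
        assert per_group["hi_ipsi"] / per_group["sham_left"] == pytest.approx(0.5)

    def test_ipsilateral_burst_excess(self, small_cohort):
        loads = {"hi_ipsi": [], "sham_left": []}
        for tr in small_cohort.trains:
            if tr.group in loads and small_cohort.cell_types[tr.unit_id] == "PN":
                loads[tr.group].append(
                    burst_summary(detect_bursts(tr))["pct_spikes_in_bursts"])
        assert np.mean(loads["hi_ipsi"]) > np.mean(loads["sham_left"])

    def test_every_group_region_has_lfp(self, small_cohort):
        assert set(small_cohort.lfps) == {
            (g, r) for g in ("sham_left", "sham_right", "hi_contra", "hi_ipsi")
            for r in ("RSC", "HPC")}

    def test_deterministic_given_seed(self):
        spec = dict(units_per_group={"sham_left": 2, "sham_right": 2,
                                     "hi_contra": 2, "hi_ipsi": 1},
                    duration_s=60.0, seed=14)
        a = simulate_cohort(CohortSpec(**spec))
        b = simulate_cohort(CohortSpec(**spec))
        for ta, tb in zip(a.trains, b.trains):
            np.testing.assert_array_equal(ta.times, tb.times)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(shared_modulation={"hi_ipsi": 1.5})
        with pytest.raises(ValueError):
            CohortSpec(kappa={"hi_ipsi": -1.0})


class TestLearningSeries:
    def test_reactive_units_ramp(self):
        series = simulate_learning_series(n_reactive=3, n_nonreactive=0,
                                          n_affected=0, seed=15)
        assert len(series) == 3
        for s in series:
            assert s.coherence.size == 21
            slope = np.polyfit(np.arange(21), s.coherence, 1)[0]
            assert slope > 0.01

    def test_deterministic(self):
        a = simulate_learning_series(seed=16)
        b = simulate_learning_series(seed=16)
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.coherence, sb.coherence)

    def test_sham_latency_improves_hi_does_not(self):
        series = simulate_learning_series(seed=17)
        sham = [s for s in series if s.group == "sham_left"]
        hi = [s for s in series if s.group == "hi_ipsi"]
        sham_gain = np.mean([s.latency_s[-3:].mean() - s.latency_s[:3].mean()
                             for s in sham])
        hi_gain = np.mean([s.latency_s[-3:].mean() - s.latency_s[:3].mean()
                           for s in hi])
        assert sham_gain > 100.0
        assert abs(hi_gain) < 30.0
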