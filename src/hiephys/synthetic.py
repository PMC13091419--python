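"""Synthetic cohorts with the statistical structure of the HI phenotype.

The generator emulates four hemisphere-groups (two sham hemispheres, the HI
contralateral and the HI ipsilateral hemisphere) by two regions (RSC,
hippocampal CA1).  Relative to sham baseline, the ipsilateral group carries:
about half as many units, reduced pyramidal firing rates, an elevated burst
load, elevated pairwise synchrony through a shared slow log-rate modulation,
theta-band LFP excess, and von Mises concentration of spike phases in the
4-12 Hz band.  A separate generator produces the 7-day x 3-trial rotarod
learning series with reactive, non-reactive and HI-affected units.

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal, special

from .io import DEFAULT_BANDS, GROUPS, LFPSignal, SpikeTrain
from .phase import band_phase
from .tracking import N_SESSIONS, SessionSeries

__all__ = [
    "CohortSpec", "Cohort", "simulate_lfp", "simulate_spike_train",
    "simulate_phase_locked_train", "simulate_waveform_set", "simulate_cohort",
    "simulate_learning_series",
]


def _band_centre(band: tuple[float, float]) -> float:
    return (band[0] + band[1]) / 2.0


def simulate_lfp(band_amplitudes: dict[str, float], fs: float, duration: float,
                 noise_sd: float = 0.0, seed: int = 0,
                 region: str = "RSC", group: str = "sham_left") -> LFPSignal:
    """One sinusoid per nonzero band (at the band centre frequency, random
    phase from the seed) plus white noise of the stated sd, in microvolts."""
    highest = max((DEFAULT_BANDS[b][1] for b, a in band_amplitudes.items() if a),
                  default=0.0)
    if fs < 4.0 * highest:
        raise ValueError(f"fs={fs} Hz below 4x the highest band edge {highest} Hz")
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    x = np.zeros(n)
    for name, amp in band_amplitudes.items():
        if name not in DEFAULT_BANDS:
            raise ValueError(f"unknown band {name!r}")
        phi = rng.uniform(0.0, 2.0 * np.pi)
        if amp:
            x += amp * np.cos(2.0 * np.pi * _band_centre(DEFAULT_BANDS[name]) * t + phi)
    if noise_sd:
        x += rng.normal(0.0, noise_sd, n)
    if not x.any():
        x += 1e-12  # LFPSignal rejects empty; keep an all-zero request representable
    return LFPSignal(x, fs, region, group)


def _homogeneous_poisson(rate: float, duration: float,
                         rng: np.random.Generator) -> np.ndarray:
    n = rng.poisson(rate * duration)
    return np.sort(rng.uniform(0.0, duration, n))


def simulate_spike_train(rate: float, duration: float,
                         burst_rate_per_min: float = 0.0,
                         burst_size_mean: float = 8.0,
                         intraburst_isi_ms: float = 5.0, seed: int = 0,
                         unit_id: str = "u0", region: str = "RSC",
                         group: str = "sham_left") -> SpikeTrain:
    """Homogeneous Poisson background plus injected burst events.

    Burst onsets are Poisson at ``burst_rate_per_min``; each burst holds a
    Poisson(``burst_size_mean``) spike count at a fixed intra-burst ISI (a
    fixed ISI keeps the Poisson-surprise of an injected burst analytically
    predictable).  Times are sorted and deduplicated.
    """
    if rate < 0 or burst_rate_per_min < 0:
        raise ValueError("rates must be >= 0")
    rng = np.random.default_rng(seed)
    t = _homogeneous_poisson(rate, duration, rng)
    if burst_rate_per_min > 0:
        onsets = _homogeneous_poisson(burst_rate_per_min / 60.0, duration, rng)
        isi = intraburst_isi_ms / 1000.0
        extra = [on + np.arange(rng.poisson(burst_size_mean)) * isi for on in onsets]
        if extra:
            t = np.concatenate([t] + extra)
    t = np.unique(t)
    t = t[(t >= 0) & (t <= duration)]
    return SpikeTrain(unit_id, region, group, t, duration)


def _thinned_train(rate: float, duration: float, log_modulation, max_log: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Inhomogeneous Poisson sampling by thinning a max-rate candidate stream.

    ``log_modulation(times) - max_log`` is the log acceptance probability;
    thinning is exact, with no time discretization of the event times.
    """
    lam_max = rate * np.exp(max_log)
    cand = _homogeneous_poisson(lam_max, duration, rng)
    if cand.size == 0:
        return cand
    accept = rng.uniform(size=cand.size) < np.exp(log_modulation(cand) - max_log)
    return cand[accept]


def simulate_phase_locked_train(lfp: LFPSignal, band: tuple[float, float],
                                rate: float, kappa: float,
                                preferred_phase: float = 0.0, seed: int = 0,
                                unit_id: str = "u0") -> SpikeTrain:
    """Inhomogeneous Poisson train locked to the band-filtered LFP phase.

    The intensity is ``rate * exp(kappa * cos(phi(t) - mu)) / I0(kappa)``:
    a von Mises density of the instantaneous band phase, normalized so the
    mean rate over a uniform phase distribution stays ``rate``.  ``kappa=0``
    reduces exactly to a homogeneous Poisson process; the stationary spike
    phase distribution is von Mises(mu, kappa), so the expected
    phase-locking value is ``I1(kappa)/I0(kappa)``.
    """
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    rng = np.random.default_rng(seed)
    duration = lfp.duration
    if kappa == 0:
        t = _homogeneous_poisson(rate, duration, rng)
        return SpikeTrain(unit_id, lfp.region, lfp.group, np.unique(t), duration)
    phase, _ = band_phase(lfp, band)

    def log_mod(times: np.ndarray) -> np.ndarray:
        idx = np.clip(np.rint(times * lfp.fs).astype(int), 0, phase.size - 1)
        return kappa * np.cos(phase[idx] - preferred_phase) - np.log(special.i0(kappa))

    max_log = kappa - np.log(special.i0(kappa))
    t = _thinned_train(rate, duration, log_mod, max_log, rng)
    return SpikeTrain(unit_id, lfp.region, lfp.group, np.unique(t), duration)


CHANNEL_GAINS = np.array([1.0, 0.8, 0.6, 0.4])


def simulate_waveform_set(ttp_ms: float, half_width_ms: float,
                          amplitude_uv: float, n_events: int = 100,
                          noise_sd: float = 0.0, fs: float = 30000.0,
                          seed: int = 0, window: int = 40,
                          alignment_sample: int = 10) -> np.ndarray:
    """Biphasic extracellular spike templates with additive noise.

    The template is a negative Gaussian trough at the alignment sample (sd
    chosen so the measured half-width equals ``half_width_ms``) followed by a
    positive Gaussian peak ``ttp_ms`` later at 40 % of the trough depth,
    replicated over 4 channels with fixed gains.  Returns an array of shape
    (n_events, 4, window) in microvolts.
    """
    ttp_samples = ttp_ms / 1000.0 * fs
    if alignment_sample + ttp_samples >= window:
        raise ValueError("trough-to-peak exceeds the cut window")
    s = np.arange(window, dtype=float)
    from .waveforms import waveform_features

    def build(sigma: float, peak_pos: float) -> np.ndarray:
        trough = -amplitude_uv * np.exp(-((s - alignment_sample) ** 2) / (2 * sigma ** 2))
        peak = 0.4 * amplitude_uv * np.exp(-((s - peak_pos) ** 2) / (2 * (2 * sigma) ** 2))
        return trough + peak

    # the two Gaussian lobes overlap, so the closed-form width/peak placement
    # drifts; calibrate (sigma, peak position) to the *measured* features by
    # alternating a secant step on the width with a shift of the peak centre
    sigma = half_width_ms / 1000.0 * fs / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    peak_pos = alignment_sample + ttp_samples
    for _ in range(8):
        s0, s1 = sigma, sigma * 1.05
        f0 = waveform_features(build(s0, peak_pos), fs).half_width_ms - half_width_ms
        for _ in range(20):
            f1 = waveform_features(build(s1, peak_pos), fs).half_width_ms - half_width_ms
            if abs(f1) < 1e-9 or f1 == f0:
                break
            s0, s1, f0 = s1, s1 - f1 * (s1 - s0) / (f1 - f0), f1
        sigma = s1
        meas_ttp = waveform_features(build(sigma, peak_pos), fs).trough_to_peak_ms
        err = meas_ttp - ttp_ms
        if abs(err) <= 0.5 / fs * 1000.0 + 1e-12:
            break  # measured ttp is quantized to the sample grid

        peak_pos -= err / 1000.0 * fs
        if not alignment_sample < peak_pos < window:
            raise ValueError("trough-to-peak exceeds the cut window")
    template = build(sigma, peak_pos)
    rng = np.random.default_rng(seed)
    out = np.empty((n_events, CHANNEL_GAINS.size, window))
    for ch, gain in enumerate(CHANNEL_GAINS):
        out[:, ch, :] = gain * template
    if noise_sd:
        out += rng.normal(0.0, noise_sd, out.shape)
    return out


@dataclass
class CohortSpec:
    """Study conditions of the simulated cohort.

    Per-group values map hemisphere-group name to the parameter; groups
    absent from a mapping fall back to the ``*_default``.  The defaults put
    the HI-ipsilateral phenotype on top of a sham baseline: half the units,
    3 vs 5 Hz pyramidal rates, a burst load near 20 % of spikes, shared-
    modulation strength 0.8, theta LFP excess, and kappa 4 phase coupling.
    """

    units_per_group: dict = field(default_factory=lambda: {
        "sham_left": 8, "sham_right": 8, "hi_contra": 8, "hi_ipsi": 4})
    pyramidal_rate_hz: dict = field(default_factory=lambda: {
        "sham_left": 5.0, "sham_right": 5.0, "hi_contra": 5.0, "hi_ipsi": 3.0})
    burst_rate_per_min: dict = field(default_factory=lambda: {
        "sham_left": 0.5, "sham_right": 0.5, "hi_contra": 0.5, "hi_ipsi": 6.0})
    burst_size_mean: float = 8.0
    intraburst_isi_ms: float = 5.0
    shared_modulation: dict = field(default_factory=lambda: {
        "sham_left": 0.0, "sham_right": 0.0, "hi_contra": 0.0, "hi_ipsi": 0.8})
    kappa: dict = field(default_factory=lambda: {
        "sham_left": 0.0, "sham_right": 0.0, "hi_contra": 0.0, "hi_ipsi": 4.0})
    preferred_phase: float = np.pi / 3.0
    band_amplitudes: dict = field(default_factory=lambda: {
        "sham_left": {"delta": 8.0, "theta": 5.0, "alpha": 4.0, "beta": 3.0, "gamma": 2.0},
        "sham_right": {"delta": 8.0, "theta": 5.0, "alpha": 4.0, "beta": 3.0, "gamma": 2.0},
        "hi_contra": {"delta": 9.0, "theta": 5.0, "alpha": 4.0, "beta": 3.0, "gamma": 2.0},
        "hi_ipsi": {"delta": 9.0, "theta": 15.0, "alpha": 5.0, "beta": 2.0, "gamma": 1.5}})
    lfp_noise_sd_uv: float = 5.0
    in_per_cell: int = 1          # narrow fast-spiking units per group/region
    in_rate_hz: float = 20.0
    duration_s: float = 300.0
    lfp_fs: float = 500.0
    coupling_band: tuple = (4.0, 12.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for g in GROUPS:
            if self.units_per_group.get(g, 0) < 0:
                raise ValueError("unit counts must be >= 0")
        if any(k < 0 for k in self.kappa.values()):
            raise ValueError("kappa must be >= 0")
        if any(not 0 <= m <= 1 for m in self.shared_modulation.values()):
            raise ValueError("shared modulation strength must lie in [0, 1]")
        for table in self.band_amplitudes.values():
            if any(a < 0 for a in table.values()):
                raise ValueError("band amplitudes must be >= 0")


@dataclass
class Cohort:
    """A simulated recording session: trains, LFPs and waveforms by cell."""

    spec: CohortSpec
    trains: list                 # SpikeTrain
    lfps: dict                   # (group, region) -> LFPSignal
    waveforms: dict              # unit_id -> (n_events, 4, window) array
    cell_types: dict             # unit_id -> generating type ("PN" | "IN")


def _shared_log_modulation(duration: float, fs: float, strength: float,
                           rng: np.random.Generator) -> np.ndarray:
    """Slow (~1 Hz bandwidth) common log-rate signal, clipped at 3 sd."""
    n = int(round(duration * fs))
    white = rng.normal(size=n)
    sos = signal.butter(2, 1.0, btype="lowpass", fs=fs, output="sos")
    slow = signal.sosfiltfilt(sos, white)
    slow = slow / slow.std()
    return strength * np.clip(slow, -3.0, 3.0)


def simulate_cohort(spec: CohortSpec | None = None) -> Cohort:
    """Generate the full four-group, two-region session described by ``spec``."""
    spec = spec or CohortSpec()
    rng = np.random.default_rng(spec.seed)
    trains: list[SpikeTrain] = []
    lfps: dict = {}
    waveforms: dict = {}
    cell_types: dict = {}
    fs = spec.lfp_fs
    duration = spec.duration_s

    for region in ("RSC", "HPC"):
        for group in GROUPS:
            sub = rng.integers(0, 2**31 - 1)
            lfp = simulate_lfp(spec.band_amplitudes[group], fs, duration,
                               spec.lfp_noise_sd_uv, seed=int(sub),
                               region=region, group=group)
            lfps[(group, region)] = lfp

            kappa = spec.kappa.get(group, 0.0)
            mod_strength = spec.shared_modulation.get(group, 0.0)
            shared = (_shared_log_modulation(duration, fs, mod_strength, rng)
                      if mod_strength > 0 else None)
            if kappa > 0:
                phase, _ = band_phase(lfp, spec.coupling_band)
            else:
                phase = None

            n_pn = spec.units_per_group.get(group, 0)
            for u in range(n_pn + spec.in_per_cell):
                is_in = u >= n_pn
                unit_id = f"{group}_{region}_{'in' if is_in else 'pn'}{u}"
                rate = spec.in_rate_hz if is_in else spec.pyramidal_rate_hz[group]

                def log_mod(times: np.ndarray) -> np.ndarray:
                    idx = np.clip(np.rint(times * fs).astype(int), 0,
                                  int(duration * fs) - 1)
                    lm = np.zeros(times.size)
                    if phase is not None and not is_in:
                        lm += (kappa * np.cos(phase[idx] - spec.preferred_phase)
                               - np.log(special.i0(kappa)))
                    if shared is not None and not is_in:
                        # centre the lognormal so the mean rate stays ~rate
                        lm += shared[idx] - mod_strength ** 2 / 2.0
                    return lm

                max_log = 0.0
                if phase is not None and not is_in:
                    max_log += kappa - np.log(special.i0(kappa))
                if shared is not None and not is_in:
                    max_log += mod_strength * 3.0 - mod_strength ** 2 / 2.0
                t = _thinned_train(rate, duration, log_mod, max_log,
                                   np.random.default_rng(int(rng.integers(0, 2**31 - 1))))

                if not is_in:
                    br = spec.burst_rate_per_min[group]
                    if br > 0:
                        burst_train = simulate_spike_train(
                            0.0, duration, br, spec.burst_size_mean,
                            spec.intraburst_isi_ms,
                            seed=int(rng.integers(0, 2**31 - 1)),
                            unit_id=unit_id, region=region, group=group)
                        t = np.concatenate([t, burst_train.times])
                t = np.unique(t)
                t = t[(t >= 0) & (t <= duration)]
                trains.append(SpikeTrain(unit_id, region, group, t, duration))
                cell_types[unit_id] = "IN" if is_in else "PN"

                thr = 0.25 if region == "HPC" else 0.4
                ttp = (thr * 0.6) if is_in else (thr + 0.3)
                hw = 0.45 * ttp if is_in else 0.35
                waveforms[unit_id] = simulate_waveform_set(
                    ttp, hw, 120.0, n_events=50,
                    noise_sd=8.0, seed=int(rng.integers(0, 2**31 - 1)))
    return Cohort(spec, trains, lfps, waveforms, cell_types)


def simulate_learning_series(n_days: int = 7, trials_per_day: int = 3,
                             n_reactive: int = 5, n_nonreactive: int = 5,
                             n_affected: int = 5, seed: int = 0,
                             noise_sd: float = 0.04) -> list[SessionSeries]:
    """Per-unit, per-session coherence series over the rotarod protocol.

    Reactive units ramp coherence linearly from 0.10 to 0.70 across the 21
    sessions; non-reactive units stay at 0.10; HI-affected units stay at
    0.60 with no training trend.  Latencies ramp toward the 300 s cap for
    sham/contralateral units and stay flat for ipsilateral (HI) units.
    """
    n_sessions = n_days * trials_per_day
    if n_sessions != N_SESSIONS:
        raise ValueError("learning series is defined for 7 days x 3 trials")
    rng = np.random.default_rng(seed)
    x = np.arange(n_sessions) / (n_sessions - 1)
    out: list[SessionSeries] = []

    def make(label: str, group: str, base: np.ndarray, latency: np.ndarray,
             k: int) -> SessionSeries:
        c = np.clip(base + rng.normal(0.0, noise_sd, n_sessions), 0.0, 1.0)
        lat = np.clip(latency + rng.normal(0.0, 10.0, n_sessions), 1.0, 300.0)
        task_on = np.minimum(lat, 300.0) / 300.0
        return SessionSeries(f"{label}{k}", group, c, task_on, lat, label)

    sham_lat = 60.0 + 240.0 * x          # ramp toward the cap
    hi_lat = np.full(n_sessions, 60.0)
    for k in range(n_reactive):
        out.append(make("reactive", "sham_left", 0.10 + 0.60 * x, sham_lat, k))
    for k in range(n_nonreactive):
        out.append(make("non_reactive", "sham_left", np.full(n_sessions, 0.10),
                        sham_lat, k))
    for k in range(n_affected):
        out.append(make("affected", "hi_ipsi", np.full(n_sessions, 0.60),
                        hi_lat, k))
    return out
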