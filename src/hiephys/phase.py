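"""Spike-phase statistics in the theta-alpha band.

Extracts instantaneous phase and amplitude of the band-filtered LFP via the
analytic signal (phase 0 at the oscillation peak, pi at the trough), samples
the phase at spike times, and quantifies locking by the phase-locking value
(mean resultant length), the Rayleigh uniformity test, and the entropy-based
phase-amplitude modulation index.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .io import LFPSignal, SpikeTrain

__all__ = [
    "PhaseStats", "band_phase", "spike_phases", "plv", "rayleigh_test",
    "phase_histogram", "modulation_index", "phase_stats",
]

TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class PhaseStats:
    """Summary of one unit's spike-phase sample in a band."""

    angles: np.ndarray        # radians, wrapped to [0, 2pi)
    plv: float
    mean_angle: float         # radians in [0, 2pi)
    rayleigh_z: float
    rayleigh_p: float
    modulation_index: float
    n: int


def _bandpass_sos(band: tuple[float, float], fs: float, order: int = 4):
    lo, hi = band
    nyq = fs / 2.0
    if not 0 < lo < hi < nyq:
        raise ValueError(f"band {band} outside (0, Nyquist={nyq}) Hz")
    return signal.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")

def band_phase(lfp: LFPSignal, band: tuple[float, float] = (4.0, 12.0)
               ) -> tuple[np.ndarray, np.ndarray]:
    """Instantaneous phase and amplitude envelope of the band-filtered LFP.

    Zero-phase (forward-backward) Butterworth band-pass followed by the
    Hilbert analytic signal.  Phase convention: 0 at an oscillation peak,
    pi at a trough; returned wrapped to [0, 2pi).

    Returns
    -------
    phase : ndarray
    envelope : ndarray
    """
    sos = _bandpass_sos(band, lfp.fs)
    x = signal.sosfiltfilt(sos, lfp.samples)
    if np.allclose(x, 0.0):
        raise ValueError("band-filtered signal is identically zero: phase undefined")
    analytic = signal.hilbert(x)
    phase = np.mod(np.angle(analytic), TWO_PI)
    return phase, np.abs(analytic)


def spike_phases(train: SpikeTrain, phase: np.ndarray, fs: float) -> np.ndarray:
    """Band phase at each spike, read from the nearest LFP sample."""
    if train.n_spikes == 0:
        return np.empty(0)
    idx = np.rint(train.times * fs).astype(int)
    bad = np.flatnonzero((idx < 0) | (idx > phase.size))
    if bad.size:
        raise ValueError(f"spike(s) outside the LFP interval at indices {bad[:5].tolist()}")
    # a spike exactly at the end of the interval reads the last sample
    return phase[np.minimum(idx, phase.size - 1)]


def plv(angles: np.ndarray) -> tuple[float, float]:
    """Phase-locking value and mean resultant angle of a circular sample.

    ``PLV = |mean(exp(i*theta))|``; the mean angle is the argument of that
    resultant, wrapped to [0, 2pi).
    """
    a = np.asarray(angles, dtype=float)
    if a.size == 0:
        raise ValueError("empty phase sample")
    z = np.exp(1j * a).mean()
    return float(np.abs(z)), float(np.mod(np.angle(z), TWO_PI))


def rayleigh_test(angles: np.ndarray) -> tuple[float, float]:
    """Rayleigh test of circular uniformity.

    ``Z = n * PLV**2``; p-value with the standard small-sample correction
    ``p = exp(sqrt(1 + 4n + 4(n^2 - R^2)) - (1 + 2n))`` where ``R = n*PLV``,
    clipped to [0, 1].
    """
    a = np.asarray(angles, dtype=float)
    n = a.size
    if n < 10:
        warnings.warn(f"Rayleigh approximation unreliable for n={n} < 10", stacklevel=2)
    r, _ = plv(a)
    big_r = n * r
    z = n * r * r
    arg = 1.0 + 4.0 * n + 4.0 * (n * n - big_r * big_r)
    p = math.exp(min(math.sqrt(max(arg, 0.0)) - (1.0 + 2.0 * n), 0.0))
    return float(z), float(min(max(p, 0.0), 1.0))


def phase_histogram(angles: np.ndarray, n_bins: int = 18
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Counts of phases over [0, 2pi) in equal bins.

    Returns (bin_centres, counts); counts sum to the sample size.
    """
    if n_bins < 4:
        raise ValueError("n_bins must be >= 4")
    a = np.mod(np.asarray(angles, dtype=float), TWO_PI)
    edges = np.linspace(0.0, TWO_PI, n_bins + 1)
    counts, _ = np.histogram(a, bins=edges)
    centres = (edges[:-1] + edges[1:]) / 2.0
    return centres, counts


def modulation_index(phase: np.ndarray, envelope: np.ndarray,
                     n_bins: int = 18) -> float:
    """Entropy-based phase-amplitude modulation index in [0, 1].

    Mean envelope amplitude per phase bin, normalized to a distribution
    ``p``; ``MI = (ln N - H(p)) / ln N`` with ``H`` the Shannon entropy.
    0 means the envelope is independent of phase; 1 means all amplitude
    concentrates in a single phase bin.  Invariant to positive rescaling
    of the envelope.
    """
    ph = np.mod(np.asarray(phase, dtype=float), TWO_PI)
    env = np.asarray(envelope, dtype=float)
    if ph.shape != env.shape:
        raise ValueError("phase and envelope must be aligned, same length")
    if not np.any(env > 0):
        raise ValueError("all-zero envelope: modulation index undefined")
    edges = np.linspace(0.0, TWO_PI, n_bins + 1)
    which = np.clip(np.digitize(ph, edges) - 1, 0, n_bins - 1)
    sums = np.bincount(which, weights=env, minlength=n_bins)
    counts = np.bincount(which, minlength=n_bins)
    empty = counts == 0
    if empty.any():
        warnings.warn(f"{int(empty.sum())} empty phase bin(s) in MI", stacklevel=2)
    means = np.where(empty, 0.0, sums / np.maximum(counts, 1))
    p = means / means.sum()
    nz = p[p > 0]
    entropy = float(-(nz * np.log(nz)).sum())
    mi = (math.log(n_bins) - entropy) / math.log(n_bins)
    return float(min(max(mi, 0.0), 1.0))


def phase_stats(train: SpikeTrain, lfp: LFPSignal,
                band: tuple[float, float] = (4.0, 12.0),
                n_bins_mi: int = 18) -> PhaseStats:
    """Full spike-phase summary of one unit against one LFP.

    The modulation index is the entropy-based index applied to the unit's
    spike-phase histogram (spiking activity as the amplitude distribution
    over phase bins), so it quantifies spike-LFP coupling: an unlocked unit
    fills all bins evenly (MI near 0) while a unit firing in a narrow phase
    range concentrates the distribution (MI toward 1).
    """
    phase, env = band_phase(lfp, band)
    angles = spike_phases(train, phase, lfp.fs)
    if angles.size == 0:
        raise ValueError(f"unit {train.unit_id}: no spikes, phase stats undefined")
    r, mu = plv(angles)
    z, p = rayleigh_test(angles)
    _, counts = phase_histogram(angles, n_bins_mi)
    pj = counts[counts > 0] / counts.sum()
    entropy = float(-(pj * np.log(pj)).sum())
    mi = float(min(max((math.log(n_bins_mi) - entropy) / math.log(n_bins_mi),
                       0.0), 1.0))
    return PhaseStats(np.mod(angles, TWO_PI), r, mu, z, p, mi, angles.size)
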