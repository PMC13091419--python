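"""Spike detection on filtered wideband traces and waveform feature extraction.

Wideband traces are zero-phase band-passed 600-6000 Hz; spikes are negative
threshold crossings (extracellular trough first) cut into 40-sample windows
with the crossing aligned at a fixed sample.  Features are the trough-to-peak
time, the trough half-width, the peak amplitude, and the unit's mean rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

__all__ = [
    "WaveformSet", "UnitFeatures", "bandpass_spike_filter", "detect_spikes",
    "average_waveform", "waveform_features", "pc_projection",
]


@dataclass(frozen=True)
class WaveformSet:
    """Detected spike waveforms: events x channels x window samples (uV)."""

    waveforms: np.ndarray
    fs: float
    alignment_sample: int
    event_times: np.ndarray     # seconds of the threshold crossings

    def __post_init__(self) -> None:
        w = np.asarray(self.waveforms, dtype=float)
        if w.ndim == 2:            # single channel convenience
            w = w[:, None, :]
        object.__setattr__(self, "waveforms", w)
        if w.ndim != 3:
            raise ValueError("waveforms must be events x channels x samples")
        if not 0 <= self.alignment_sample < w.shape[2]:
            raise ValueError("alignment sample outside window")

    @property
    def n_events(self) -> int:
        return self.waveforms.shape[0]

    @property
    def window(self) -> int:
        return self.waveforms.shape[2]


@dataclass(frozen=True)
class UnitFeatures:
    trough_to_peak_ms: float
    half_width_ms: float
    peak_amplitude_uv: float
    mean_rate_hz: float


def bandpass_spike_filter(raw: np.ndarray, fs: float,
                          band: tuple[float, float] = (600.0, 6000.0),
                          order: int = 3) -> np.ndarray:
    """Zero-phase Butterworth band-pass in the spike band; length preserved."""
    lo, hi = band
    if fs <= 2 * hi:
        raise ValueError(f"fs={fs} Hz too low for a {hi} Hz band edge")
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(raw, dtype=float))


def detect_spikes(filtered: np.ndarray, fs: float, threshold_uv: float = 50.0,
                  window: int = 40, alignment_sample: int = 10) -> WaveformSet:
    """Cut waveforms at negative-going threshold crossings.

    One event per crossing of ``-threshold_uv`` with a refractory lockout of
    one full window; the crossing sample sits at ``alignment_sample`` within
    the cut.  Crossings too close to either trace edge to cut a full window
    are dropped.  Accepts a single channel (1-D) or channels x samples (2-D)
    input; detection runs on the first channel, cutting applies to all.
    """
    x = np.asarray(filtered, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    n = x.shape[1]
    if n <= window:
        raise ValueError("trace shorter than one spike window")
    det = x[0]
    below = det < -threshold_uv
    crossings = np.flatnonzero(below[1:] & ~below[:-1]) + 1
    events = []
    times = []
    last = -window
    for c in crossings:
        if c - last < window:
            continue
        start = c - alignment_sample
        if start < 0 or start + window > n:
            continue
        events.append(x[:, start:start + window].copy())
        times.append(c / fs)
        last = c
    w = np.array(events) if events else np.empty((0, x.shape[0], window))
    return WaveformSet(w, fs, alignment_sample, np.array(times))


def average_waveform(ws: WaveformSet) -> np.ndarray:
    """Arithmetic mean waveform per channel (channels x samples)."""
    if ws.n_events == 0:
        raise ValueError("cannot average an empty waveform set")
    return ws.waveforms.mean(axis=0)


def waveform_features(mean_wf: np.ndarray, fs: float,
                      spike_times: np.ndarray | None = None,
                      duration: float | None = None) -> UnitFeatures:
    """Trough-to-peak time, trough half-width, peak amplitude, mean rate.

    Operates on the channel with the deepest trough.  Trough-to-peak is the
    time from the global trough to the subsequent global maximum (ties go to
    the earlier sample); half-width is the width of the trough at half its
    depth, with sub-sample linear interpolation at both flanks.
    """
    w = np.asarray(mean_wf, dtype=float)
    if w.ndim == 1:
        w = w[None, :]
    ch = int(np.argmin(w.min(axis=1)))
    v = w[ch]
    trough = int(np.argmin(v))
    if v[trough] >= 0:
        raise ValueError("no negative trough: cannot extract spike features")
    after = v[trough + 1:]
    if after.size == 0:
        raise ValueError("trough at window end: no subsequent peak")
    peak = trough + 1 + int(np.argmax(after))
    ttp_ms = (peak - trough) / fs * 1000.0

    half = v[trough] / 2.0
    i = trough
    while i > 0 and v[i] <= half:
        i -= 1
    if v[i] <= half:          # trough shoulder off the window edge
        left = float(i)
    else:
        left = i + (half - v[i]) / (v[i + 1] - v[i])
    j = trough
    while j < v.size - 1 and v[j] <= half:
        j += 1
    if v[j] <= half:
        right = float(j)
    else:
        right = j - (half - v[j]) / (v[j - 1] - v[j])
    half_width_ms = (right - left) / fs * 1000.0

    amp = float(v[peak] - v[trough])
    rate = 0.0
    if spike_times is not None and duration:
        rate = float(np.asarray(spike_times).size / duration)
    return UnitFeatures(ttp_ms, half_width_ms, amp, rate)


def pc_projection(ws: WaveformSet, n_components: int = 2) -> np.ndarray:
    """Principal-component projection of event waveforms (visualization aid).

    Components are ordered by explained variance with the sign fixed so each
    component's largest-magnitude loading is positive.
    """
    if ws.n_events < 2:
        raise ValueError("need at least two events for a PC projection")
    x = ws.waveforms.reshape(ws.n_events, -1)
    x = x - x.mean(axis=0)
    _, s, vt = np.linalg.svd(x, full_matrices=False)
    comps = vt[:n_components]
    for k in range(comps.shape[0]):
        i = np.argmax(np.abs(comps[k]))
        if comps[k, i] < 0:
            comps[k] = -comps[k]
    return x @ comps.T
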