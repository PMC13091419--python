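"""Longitudinal unit tracking across the 7-day rotarod protocol.

Identity of a unit across days is scored by four measures: the maximum
time-shifted correlation of averaged waveforms (Fisher-transformed), the
normalized trough-to-peak amplitude change, and Kullback-Leibler divergences
between log-binned inter-spike-interval histograms and between
autocorrelograms.  Thresholds come from within-day split-half calibration:
two back-to-back sessions of the same unit are assumed stable, and the
fraction of calibration units failing the conjunctive criterion estimates
the false-negative rate.

Tracked units are then classified by their learning response over the
7 day x 3 trial series: reactive units ramp their spike-field coherence with
training (high regression R^2, high coherence), non-reactive units stay low,
and HI-affected units keep pathologically high coherence without a training
trend (low R^2, high coherence).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import SpikeTrain

__all__ = [
    "TrackingScore", "SessionSeries", "waveform_similarity", "amplitude_change",
    "log_histograms", "kl_divergence", "score_pair", "assess_stability",
    "learning_response_features", "classify_learning_response",
]

N_SESSIONS = 21  # 7 days x 3 trials


@dataclass(frozen=True)
class TrackingScore:
    max_r: float
    fisher_z: float
    delta_p_amp: float
    kl_isih: float
    kl_acorr: float
    stable: bool | None = None


@dataclass(frozen=True)
class SessionSeries:
    """Per-session spike-field coherence of one tracked unit over training."""

    unit_id: str
    group: str
    coherence: np.ndarray     # length 21
    task_on: np.ndarray       # per-session fraction of time on the rotarod
    latency_s: np.ndarray     # latency to fall per trial, in (0, 300]
    true_label: str | None = None   # generator ground truth, if synthetic

    def __post_init__(self) -> None:
        for name in ("coherence", "task_on", "latency_s"):
            v = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, v)
            if v.size != N_SESSIONS:
                raise ValueError(f"{name} must have {N_SESSIONS} sessions, got {v.size}")
        if np.any(self.latency_s <= 0) or np.any(self.latency_s > 300):
            raise ValueError("latencies must lie in (0, 300] s")


def waveform_similarity(w_day1: np.ndarray, w_dayk: np.ndarray,
                        max_shift_samples: int = 8) -> tuple[float, float]:
    """Maximum time-shifted linear correlation of two averaged waveforms.

    The later waveform slides over integer shifts in
    [-max_shift, +max_shift]; the correlation of the overlapping parts is
    maximized.  Returns (max_r, fisher_z) with r clipped to +/-0.9999 before
    the Fisher transform ``atanh``.
    """
    a = np.asarray(w_day1, dtype=float).ravel()
    b = np.asarray(w_dayk, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError("waveforms must have equal length")
    if max_shift_samples >= a.size // 2:
        raise ValueError("max shift too large for the window")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero-variance waveform")
    best = -1.0
    for s in range(-max_shift_samples, max_shift_samples + 1):
        if s >= 0:
            x, y = a[s:], b[:b.size - s]
        else:
            x, y = a[:a.size + s], b[-s:]
        if x.std() == 0 or y.std() == 0:
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        best = max(best, r)
    r = min(max(best, -0.9999), 0.9999)
    return best, float(math.atanh(r))


def amplitude_change(w_day1: np.ndarray, w_dayk: np.ndarray) -> float:
    """Normalized trough-to-peak amplitude difference |A_k - A_1| / A_1."""
    def _amp(w: np.ndarray) -> float:
        v = np.asarray(w, dtype=float).ravel()
        trough = int(np.argmin(v))
        after = v[trough:]
        return float(after.max() - v[trough])
    a1, ak = _amp(w_day1), _amp(w_dayk)
    if a1 <= 0:
        raise ValueError("day-1 amplitude is zero")
    return abs(ak - a1) / a1


ISIH_EDGES_MS = np.logspace(np.log10(0.5), 5.0, 101)   # 0.5 .. 1e5 ms, 100 log bins
ACORR_EDGES_MS = np.linspace(-100.0, 100.0, 101)       # +/-100 ms, 100 bins


def log_histograms(train: SpikeTrain, eps: float = 1e-6
                   ) -> dict[str, np.ndarray]:
    """Normalized log-ISI histogram and autocorrelogram densities.

    ISIH: 100 log-spaced bins over 0.5-1e5 ms.  Autocorrelogram: 100 bins
    over +/-100 ms, self-pairs excluded.  Both receive additive smoothing
    ``eps`` before normalization, so every bin is strictly positive and KL
    divergences stay finite.
    """
    if train.n_spikes < 2:
        raise ValueError("need at least 2 spikes")
    isi_ms = np.diff(train.times) * 1000.0
    isih, _ = np.histogram(isi_ms, bins=ISIH_EDGES_MS)

    t = train.times
    lags = []
    lo = 0
    for i, ti in enumerate(t):
        while t[lo] < ti - 0.1:
            lo += 1
        hi = i
        while hi < t.size and t[hi] <= ti + 0.1:
            hi += 1
        d = (t[lo:hi] - ti) * 1000.0
        lags.append(np.delete(d, i - lo))
    acorr, _ = np.histogram(np.concatenate(lags), bins=ACORR_EDGES_MS)

    out = {}
    for name, h in (("isih", isih), ("acorr", acorr)):
        p = h.astype(float) + eps
        out[name] = p / p.sum()
    return out


def kl_divergence(p: np.ndarray, q: np.ndarray, eps: float = 1e-10
                  ) -> tuple[float, float]:
    """Kullback-Leibler divergence of two normalized histograms.

    Returns ``(kl, log_kl)`` where ``kl = sum p * ln(p/q)`` and
    ``log_kl = ln(kl + eps)`` (the log transform used to normalize the
    score distribution for thresholding).
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("histograms have mismatched binning")
    if np.any(p < 0) or np.any(q <= 0):
        raise ValueError("histograms must be smoothed and positive")
    nz = p > 0
    kl = float(np.sum(p[nz] * np.log(p[nz] / q[nz])))
    kl = max(kl, 0.0)
    return kl, float(math.log(kl + eps))


def score_pair(w1: np.ndarray, wk: np.ndarray, train1: SpikeTrain,
               traink: SpikeTrain, max_shift_samples: int = 8) -> TrackingScore:
    """All four identity measures for a candidate day-1/day-k unit pair."""
    max_r, z = waveform_similarity(w1, wk, max_shift_samples)
    damp = amplitude_change(w1, wk)
    h1, hk = log_histograms(train1), log_histograms(traink)
    kl_i, _ = kl_divergence(h1["isih"], hk["isih"])
    kl_a, _ = kl_divergence(h1["acorr"], hk["acorr"])
    return TrackingScore(max_r, z, damp, kl_i, kl_a)


def assess_stability(pair_scores: list[TrackingScore],
                     calibration: list[TrackingScore]
                     ) -> tuple[list[TrackingScore], dict[str, float]]:
    """Label day-pair scores stable/unstable against within-day calibration.

    Thresholds: 99th percentile of within-day ``kl_isih``, ``kl_acorr`` and
    ``delta_p_amp``; 1st percentile of within-day ``fisher_z``.  A pair is
    stable only if all four measures fall on the stable side (conjunctive
    rule).  The calibration false-negative rate is the fraction of
    within-day pairs that fail their own criterion.
    """
    if len(calibration) < 10:
        raise ValueError("need a calibration set of >= 10 within-day units")

    def col(scores, attr):
        return np.array([getattr(s, attr) for s in scores])

    thr = {
        "kl_isih": float(np.percentile(col(calibration, "kl_isih"), 99)),
        "kl_acorr": float(np.percentile(col(calibration, "kl_acorr"), 99)),
        "delta_p_amp": float(np.percentile(col(calibration, "delta_p_amp"), 99)),
        "fisher_z": float(np.percentile(col(calibration, "fisher_z"), 1)),
    }

    def is_stable(s: TrackingScore) -> bool:
        return (s.kl_isih <= thr["kl_isih"] and s.kl_acorr <= thr["kl_acorr"]
                and s.delta_p_amp <= thr["delta_p_amp"]
                and s.fisher_z >= thr["fisher_z"])

    labeled = [TrackingScore(s.max_r, s.fisher_z, s.delta_p_amp, s.kl_isih,
                             s.kl_acorr, is_stable(s)) for s in pair_scores]
    fn_rate = float(np.mean([not is_stable(s) for s in calibration]))
    report = dict(thr, false_negative_rate=fn_rate)
    return labeled, report


def learning_response_features(series: SessionSeries) -> tuple[float, float]:
    """(regression R^2, mean coherence) of one unit over its 21 sessions.

    Linear regression of per-session coherence on session index, weighted to
    sessions with task-on time (off-task sessions carry no learning signal
    and are dropped).
    """
    c = series.coherence
    on = series.task_on > 0
    if on.sum() < 3:
        raise ValueError(f"unit {series.unit_id}: too few task-on sessions")
    x = np.arange(N_SESSIONS, dtype=float)[on]
    res = stats.linregress(x, c[on])
    return float(res.rvalue ** 2), float(c[on].mean())


def classify_learning_response(series_list: list[SessionSeries],
                               r2_threshold: float | None = None,
                               coherence_threshold: float | None = None,
                               threshold_rule: str = "midrange"
                               ) -> list[str]:
    """Quadrant classification into reactive / non_reactive / affected.

    High-R^2 & high-coherence units are reactive, low/low non-reactive, and
    low-R^2 & high-coherence units HI-affected (pathologically elevated
    coherence without a training trend).  Default thresholds are the cohort
    midrange (midpoint of min and max) per feature, which splits a bimodal
    cohort regardless of class balance; ``threshold_rule="median"`` uses
    cohort medians instead, and explicit thresholds override either.
    """
    feats = np.array([learning_response_features(s) for s in series_list])
    r2, coh = feats[:, 0], feats[:, 1]

    def default_thr(v: np.ndarray) -> float:
        if threshold_rule == "median":
            return float(np.median(v))
        if threshold_rule == "midrange":
            return float((v.min() + v.max()) / 2.0)
        raise ValueError(f"unknown threshold rule {threshold_rule!r}")

    thr_r2 = default_thr(r2) if r2_threshold is None else r2_threshold
    thr_coh = default_thr(coh) if coherence_threshold is None else coherence_threshold
    labels = []
    for r, c in zip(r2, coh):
        if c > thr_coh:
            labels.append("reactive" if r > thr_r2 else "affected")
        else:
            labels.append("non_reactive")
    return labels
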