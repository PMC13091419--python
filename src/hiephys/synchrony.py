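"""Pairwise synchrony: correlograms, spike-spike coherence, and R^2 matrices.

Instantaneous firing rates are 12.5 ms binned counts smoothed with a
Gaussian kernel; pairwise synchrony over a task window is the squared linear
correlation of those smoothed rates, assembled into a symmetric matrix whose
rows are ordered by hierarchical clustering for display, and compared across
sessions by correlating off-diagonal entries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.cluster import hierarchy
from scipy.ndimage import gaussian_filter1d
from scipy.spatial.distance import squareform

from .io import SpikeTrain

__all__ = [
    "Correlogram", "CrossCorrMatrix", "correlogram", "binned_rate",
    "spike_spike_coherence", "pairwise_r2_matrix", "cluster_order",
    "matrix_similarity",
]


@dataclass(frozen=True)
class Correlogram:
    lags_ms: np.ndarray     # bin centres
    counts: np.ndarray
    bin_ms: float
    max_lag_ms: float


@dataclass(frozen=True)
class CrossCorrMatrix:
    unit_ids: tuple
    r2: np.ndarray          # symmetric, diagonal 1, entries in [0, 1]
    session: str = ""

    def __post_init__(self) -> None:
        m = np.asarray(self.r2, dtype=float)
        object.__setattr__(self, "r2", m)
        if m.shape != (len(self.unit_ids),) * 2:
            raise ValueError("matrix shape does not match unit list")
        if not np.allclose(m, m.T):
            raise ValueError("R^2 matrix must be symmetric")
        if m.min() < -1e-9 or m.max() > 1 + 1e-9:
            raise ValueError("R^2 entries must lie in [0, 1]")


def correlogram(a: SpikeTrain, b: SpikeTrain, bin_ms: float = 1.0,
                max_lag_ms: float = 100.0) -> Correlogram:
    """Histogram of pairwise spike-time differences ``t_b - t_a``.

    With ``a is b`` (or equal times) this is the autocorrelogram and
    self-pairs (zero differences of a spike with itself) are excluded.
    """
    max_lag = max_lag_ms / 1000.0
    n_bins = int(np.ceil(max_lag_ms / bin_ms))
    edges = np.arange(-n_bins, n_bins + 1) * (bin_ms / 1000.0)
    ta, tb = a.times, b.times
    counts = np.zeros(edges.size - 1)
    auto = ta.size == tb.size and np.array_equal(ta, tb)
    # sliding-window over sorted times: O(n * spikes-per-window)
    lo = 0
    for i, t in enumerate(ta):
        while lo < tb.size and tb[lo] < t - max_lag:
            lo += 1
        hi = lo
        while hi < tb.size and tb[hi] <= t + max_lag:
            hi += 1
        d = tb[lo:hi] - t
        if auto:
            d = np.delete(d, i - lo)
        counts += np.histogram(d, bins=edges)[0]
    centres = (edges[:-1] + edges[1:]) / 2.0 * 1000.0
    return Correlogram(centres, counts, bin_ms, n_bins * bin_ms)


def binned_rate(train: SpikeTrain, bin_ms: float = 12.5,
                smooth_sigma_ms: float = 25.0) -> tuple[np.ndarray, np.ndarray]:
    """Instantaneous firing rate: binned counts / bin width, Gaussian smoothed.

    Returns (bin_centres_s, rate_hz).  Total spike count is preserved before
    smoothing; ``smooth_sigma_ms = 0`` leaves the series untouched.
    """
    if bin_ms <= 0:
        raise ValueError("bin_ms must be > 0")
    bin_s = bin_ms / 1000.0
    n_bins = max(int(np.ceil(train.duration / bin_s)), 1)
    edges = np.arange(n_bins + 1) * bin_s
    counts, _ = np.histogram(train.times, bins=edges)
    rate = counts / bin_s
    if smooth_sigma_ms > 0:
        rate = gaussian_filter1d(rate, smooth_sigma_ms / bin_ms, mode="reflect")
    centres = (edges[:-1] + edges[1:]) / 2.0
    return centres, rate


def spike_spike_coherence(a: SpikeTrain, b: SpikeTrain,
                          bin_rate_hz: float = 1000.0, nfft: int = 256,
                          overlap_fraction: float = 0.05
                          ) -> tuple[np.ndarray, np.ndarray, float]:
    """Welch magnitude-squared coherence between two binned spike trains.

    Both trains are binned into counts at ``bin_rate_hz`` and mean-subtracted;
    Hann-tapered blocks of ``nfft`` samples with 5 % overlap.  The scalar
    summary is the mean coherence over 0.5-100 Hz.

    Returns (frequencies, coherence, mean_coherence_0p5_100hz).
    """
    duration = min(a.duration, b.duration)
    n = int(np.floor(duration * bin_rate_hz))
    if n < nfft:
        raise ValueError("recording shorter than one Welch block")
    edges = np.arange(n + 1) / bin_rate_hz
    xa = np.histogram(a.times, bins=edges)[0].astype(float)
    xb = np.histogram(b.times, bins=edges)[0].astype(float)
    xa -= xa.mean()
    xb -= xb.mean()
    f, c = signal.coherence(xa, xb, fs=bin_rate_hz, window="hann", nperseg=nfft,
                            noverlap=int(round(nfft * overlap_fraction)))
    m = (f >= 0.5) & (f <= 100.0)
    return f, np.clip(c, 0.0, 1.0), float(c[m].mean())


def pairwise_r2_matrix(rates: dict[str, np.ndarray],
                       window: tuple[int, int] | None = None,
                       session: str = "") -> CrossCorrMatrix:
    """Squared linear correlation of smoothed rate series over a bin window.

    ``rates`` maps unit id to an aligned rate series; ``window`` is a
    half-open (start_bin, end_bin) restriction, e.g. a rotarod start/fall-off
    interval expressed in rate bins.  Zero-variance series yield 0 entries
    with a warning.
    """
    ids = tuple(rates)
    if len(ids) < 2:
        raise ValueError("need at least two units")
    series = [np.asarray(rates[u], dtype=float) for u in ids]
    n = min(s.size for s in series)
    lo, hi = (0, n) if window is None else window
    x = np.stack([s[lo:hi] for s in series])
    sd = x.std(axis=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        warnings.warn(
            f"zero-variance rate series for unit(s) {[ids[i] for i in dead]}; "
            "their correlations are set to 0", stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x)
    r[~np.isfinite(r)] = 0.0
    m = np.clip(r * r, 0.0, 1.0)
    np.fill_diagonal(m, 1.0)
    return CrossCorrMatrix(ids, (m + m.T) / 2.0, session)


def cluster_order(m: CrossCorrMatrix) -> list:
    """Dendrogram leaf order from average-linkage clustering on 1 - R^2.

    Deterministic: equal distances resolve by the input (unit id) order, so
    an identity matrix returns the units unpermuted.
    """
    n = len(m.unit_ids)
    if n < 3:
        return list(m.unit_ids)
    d = 1.0 - m.r2
    np.fill_diagonal(d, 0.0)
    cond = squareform(d, checks=False)
    # index-ordered epsilon so equal distances merge in input order
    cond = cond + np.arange(cond.size) * 1e-12
    z = hierarchy.linkage(cond, method="average")
    # orient every node so the subtree holding the earliest input unit comes
    # first: ties then reproduce the input order exactly
    root = hierarchy.to_tree(z)
    order: list[int] = []
    stack = [root]
    while stack:
        node = stack.pop()
        if node.is_leaf():
            order.append(node.id)
            continue
        left, right = node.left, node.right
        if (min(left.pre_order(lambda n: n.id))
                > min(right.pre_order(lambda n: n.id))):
            left, right = right, left
        stack.extend([right, left])
    return [m.unit_ids[i] for i in order]


def matrix_similarity(m1: CrossCorrMatrix, m2: CrossCorrMatrix) -> float:
    """Linear correlation of the strict upper triangles of two R^2 matrices."""
    if m1.unit_ids != m2.unit_ids:
        raise ValueError("matrices cover different unit sets or orders")
    iu = np.triu_indices(len(m1.unit_ids), k=1)
    v1, v2 = m1.r2[iu], m2.r2[iu]
    if v1.std() == 0 or v2.std() == 0:
        raise ValueError("degenerate (constant) off-diagonal entries")
    return float(np.corrcoef(v1, v2)[0, 1])
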