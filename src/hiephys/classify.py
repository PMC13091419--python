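"""Putative cell-type and discharge-pattern classification.

Cell type follows the region-specific quadrant rule on the waveform/rate
plane: narrow spikes (trough-to-peak below 0.4 ms in cortex, 0.25 ms in
hippocampus) firing above 15 Hz are putative interneurons; wide spikes firing
at or below 15 Hz are putative pyramidal neurons; the two off-diagonal
quadrants stay unclassified and are excluded from group statistics.

Discharge pattern compares the unit's inter-spike-interval histogram against
three analytic templates by chi-square goodness of fit: a narrow Gaussian at
the mean ISI (regular firing, symmetric ISI mass), an exponential at the
train's mean rate (irregular/Poisson firing), and an early-peaked
quasi-normal (bursting, ISI mass concentrated at short intra-burst lags).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import AnalysisConfig, SpikeTrain
from .waveforms import UnitFeatures

__all__ = ["UnitLabel", "classify_cell_type", "classify_discharge_pattern",
           "discharge_chi2"]

CELL_TYPES = ("PN", "IN", "unclassified")
DISCHARGE_CLASSES = ("bursting", "irregular", "regular_PN", "regular_IN",
                     "unclassified")


@dataclass(frozen=True)
class UnitLabel:
    cell_type: str
    discharge_class: str

    def __post_init__(self) -> None:
        if self.cell_type not in CELL_TYPES:
            raise ValueError(f"unknown cell type {self.cell_type!r}")
        if self.discharge_class not in DISCHARGE_CLASSES:
            raise ValueError(f"unknown discharge class {self.discharge_class!r}")
        if self.discharge_class == "regular_IN" and self.cell_type != "IN":
            raise ValueError("regular_IN requires cell_type IN")


def classify_cell_type(features: UnitFeatures, region: str,
                       config: AnalysisConfig | None = None) -> str:
    """Region-thresholded quadrant rule on (trough-to-peak, mean rate).

    Boundary points (trough-to-peak exactly at the threshold, or rate exactly
    15 Hz) fall on the wide/slow side and are therefore PN candidates.
    """
    cfg = config or AnalysisConfig()
    if region not in cfg.in_threshold_ttp_ms:
        raise ValueError(f"unknown region {region!r}")
    thr = cfg.in_threshold_ttp_ms[region]
    narrow = features.trough_to_peak_ms < thr
    fast = features.mean_rate_hz > cfg.rate_threshold_hz
    if narrow and fast:
        return "IN"
    if not narrow and not fast:
        return "PN"
    return "unclassified"


def _isi_histogram(isi: np.ndarray, n_bins: int = 50
                   ) -> tuple[np.ndarray, np.ndarray]:
    upper = np.quantile(isi, 0.99)
    if upper <= 0:
        upper = isi.max() if isi.max() > 0 else 1.0
    edges = np.linspace(0.0, upper, n_bins + 1)
    counts, _ = np.histogram(isi[isi <= upper], bins=edges)
    return counts.astype(float), edges


def _template_probs(dist, edges: np.ndarray) -> np.ndarray:
    cdf = dist.cdf(edges)
    p = np.diff(cdf)
    total = p.sum()
    if total <= 0:
        return np.full(edges.size - 1, 1.0 / (edges.size - 1))
    return p / total


def discharge_chi2(train: SpikeTrain, n_bins: int = 50) -> dict[str, float]:
    """Chi-square statistic of the ISI histogram against the three discharge
    templates (smaller = better fit).

    Template parameters are estimated from the train: mean ISI for the
    regular Gaussian (sd = max(ISI sd restricted to symmetric spread, a bin
    width, 10 % of the mean)), mean rate for the exponential, and the median
    and spread of the short-ISI subset (below half the mean) for the
    bursting template.
    """
    if train.n_spikes < 2:
        raise ValueError("need at least 2 spikes")
    isi = np.diff(train.times)
    counts, edges = _isi_histogram(isi, n_bins)
    n = counts.sum()
    width = edges[1] - edges[0]
    mu = float(isi.mean())

    sd_reg = max(0.1 * mu, width)
    short = isi[isi < mu / 2.0]
    long_ = isi[isi >= mu / 2.0]
    if short.size:
        w = short.size / isi.size
        mu_b = float(np.median(short))
        sd_b = max(float(short.std()), width / 2.0, 0.1 * mu_b)
    else:
        w, mu_b, sd_b = 0.0, mu / 4.0, max(mu / 8.0, width)
    mu_long = float(long_.mean()) if long_.size else mu

    probs = {
        "regular": _template_probs(stats.norm(loc=mu, scale=sd_reg), edges),
        "irregular": _template_probs(stats.expon(scale=mu), edges),
        # early quasi-normal intra-burst peak + exponential inter-burst tail
        "bursting": (w * _template_probs(stats.norm(loc=mu_b, scale=sd_b), edges)
                     + (1.0 - w) * _template_probs(stats.expon(scale=mu_long), edges)),
    }
    out = {}
    floor = 1e-6
    for name, p in probs.items():
        p = np.maximum(p, floor)
        p = p / p.sum()
        e = n * p
        out[name] = float(((counts - e) ** 2 / e).sum())
    return out


def classify_discharge_pattern(train: SpikeTrain, cell_type: str = "PN",
                               n_bins: int = 50, min_spikes: int = 50) -> str:
    """Assign bursting / irregular / regular_(PN|IN) by smallest chi-square.

    Trains with fewer than ``min_spikes`` spikes stay unclassified.  The
    statistic depends only on inter-spike intervals, so the label is
    invariant to translating the whole train in time.
    """
    if train.n_spikes < min_spikes:
        return "unclassified"
    chi2 = discharge_chi2(train, n_bins)
    best = min(chi2, key=chi2.get)
    if best == "regular":
        return "regular_IN" if cell_type == "IN" else "regular_PN"
    return best
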