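"""Poisson-surprise (Legendy-Salcman) burst detection and burst-load summaries.

A burst is a contiguous run of spikes whose count is improbably high for a
homogeneous Poisson process at the unit's whole-session mean rate.  The
surprise of a window holding ``n`` spikes over ``T`` seconds at baseline rate
``r`` is ``S = -ln Pr[N >= n]`` with ``N ~ Poisson(rT)``; bursts are accepted
at ``S >= 5`` (i.e. tail probability below ``e**-5``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io import SpikeTrain

__all__ = ["Burst", "BurstSet", "poisson_surprise", "detect_bursts", "burst_summary"]


@dataclass(frozen=True)
class Burst:
    start: float          # time of first spike, s
    end: float            # time of last spike, s
    n_spikes: int
    surprise: float
    first_index: int      # index of first spike within the source train
    last_index: int       # inclusive

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class BurstSet:
    """Ordered, non-overlapping accepted bursts of one spike train."""

    train: SpikeTrain
    bursts: list[Burst] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.bursts)

    def __iter__(self):
        return iter(self.bursts)


def poisson_surprise(n: int, T: float, r: float) -> float:
    """Surprise ``S = -ln Pr[N >= n]`` for ``N ~ Poisson(r*T)``.

    Uses the regularized upper incomplete gamma function through the Poisson
    survival function, so the deep tail (S of hundreds) is computed without
    underflow.  ``n = 0`` has tail probability 1, hence S = 0.
    """
    if T <= 0 or r <= 0:
        raise ValueError(f"require T > 0 and r > 0, got T={T}, r={r}")
    if n < 0:
        raise ValueError(f"spike count must be >= 0, got {n}")
    if n == 0:
        return 0.0
    # Pr[N >= n] = sf(n - 1)
    s = -stats.poisson.logsf(n - 1, r * T)
    return float(max(s, 0.0))


def _window_surprise(times: np.ndarray, i: int, j: int, r: float) -> float:
    """Surprise of the spike window ``times[i..j]`` inclusive."""
    T = times[j] - times[i]
    if T <= 0:
        return 0.0
    return poisson_surprise(j - i + 1, T, r)


def detect_bursts(train: SpikeTrain, surprise_threshold: float = 5.0,
                  rate: float | None = None, min_spikes: int = 3,
                  lookahead: int = 15) -> BurstSet:
    """Legendy-Salcman search for high-surprise spike runs.

    Candidate bursts are seeded wherever firing locally outpaces the
    baseline: at any inter-spike interval below half the mean ISI, or any
    two adjacent intervals summing below the mean (three spikes inside one
    mean interval); adjacent marks coalesce into maximal seed runs.  Around
    each seed run the surprise is maximized exhaustively over every window
    that intersects the run, with boundaries allowed up to ``lookahead``
    spikes past either end of the run (spikes outside a seed carry long
    intervals, so the maximal window never strays far from one).
    Candidates reaching ``surprise_threshold`` are accepted; overlapping
    accepted bursts merge when merging does not lose surprise, otherwise
    the higher-surprise window is kept.

    The baseline ``rate`` defaults to the whole-train mean rate.
    """
    t = train.times
    n = t.size
    out = BurstSet(train)
    if n < min_spikes:
        return out
    r = train.mean_rate_hz if rate is None else float(rate)
    if r <= 0:
        return out
    isi = np.diff(t)
    mu = isi.mean()
    mark = isi < mu / 2.0
    pair = isi[:-1] + isi[1:] < mu
    mark[:-1] |= pair
    mark[1:] |= pair

    # maximal runs of consecutive marked ISIs -> seed spike windows
    seeds: list[tuple[int, int]] = []
    k = 0
    while k < mark.size:
        if mark[k]:
            j = k
            while j + 1 < mark.size and mark[j + 1]:
                j += 1
            seeds.append((k, j + 1))  # spike indices [k, j+1]
            k = j + 1
        k += 1

    accepted: list[tuple[int, int, float]] = []
    for s0, e0 in seeds:
        lo = max(0, s0 - lookahead)
        hi = min(n - 1, e0 + lookahead)
        ii, jj = np.meshgrid(np.arange(lo, e0 + 1), np.arange(s0, hi + 1),
                             indexing="ij")
        ok = jj - ii >= min_spikes - 1            # window must intersect the run
        ii, jj = ii[ok], jj[ok]
        T = t[jj] - t[ii]
        valid = T > 0
        ii, jj, T = ii[valid], jj[valid], T[valid]
        if ii.size == 0:
            continue
        with np.errstate(divide="ignore"):
            s_all = -stats.poisson.logsf(jj - ii, r * T)
        k = int(np.argmax(s_all))
        s = float(s_all[k])
        if s >= surprise_threshold:
            accepted.append((int(ii[k]), int(jj[k]), s))

    # merge overlapping windows; a merge must not lose surprise, otherwise
    # the better of the two windows wins
    accepted.sort()
    merged: list[tuple[int, int, float]] = []
    for i, j, s in accepted:
        if merged and i <= merged[-1][1]:
            pi, pj, ps = merged[-1]
            mi, mj = pi, max(pj, j)
            ms = _window_surprise(t, mi, mj, r)
            if ms >= max(ps, s):
                merged[-1] = (mi, mj, ms)
            elif s > ps:
                merged[-1] = (i, j, s)
        else:
            merged.append((i, j, s))

    out.bursts = [Burst(t[i], t[j], j - i + 1, s, i, j) for i, j, s in merged]
    return out


def burst_summary(bursts: BurstSet) -> dict[str, float]:
    """Percent of spikes occurring in bursts and percent of time spent bursting.

    Burst duration is last-spike minus first-spike time (no padding).
    """
    train = bursts.train
    total = train.n_spikes
    in_bursts = sum(b.n_spikes for b in bursts)
    t_bursts = sum(b.duration for b in bursts)
    return {
        "pct_spikes_in_bursts": 100.0 * in_bursts / total if total else 0.0,
        "pct_time_in_bursts": 100.0 * t_bursts / train.duration,
        "n_bursts": float(len(bursts)),
    }
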