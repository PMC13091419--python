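"""Canonical data model, file readers/writers, and shared analysis configuration.

All spike times are absolute seconds (double precision); every binning
operation downstream uses half-open bins ``[start, end)`` so a spike on an
edge is counted exactly once.  Tabular interchange is plain CSV with a header
row; continuous signals are single-column text or raw little-endian float32.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

REGIONS = ("RSC", "HPC")
GROUPS = ("sham_left", "sham_right", "hi_contra", "hi_ipsi")

#: Frequency bands (Hz) used for LFP power and spike-field coherence grouping:
#: delta, theta, alpha, beta, gamma.
DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 30.0),
    "gamma": (30.0, 50.0),
}


class FormatError(ValueError):
    """Malformed input file (missing column, unparseable value, unknown key)."""


class ValidationError(ValueError):
    """Input parsed but violates a domain invariant."""


@dataclass(frozen=True)
class SpikeTrain:
    """Ordered spike times of one sorted single unit.

    Parameters
    ----------
    unit_id : str
        Unique unit label within a session.
    region : {"RSC", "HPC"}
        Recording site: retrosplenial cortex or hippocampal CA1.
    group : {"sham_left", "sham_right", "hi_contra", "hi_ipsi"}
        Hemisphere-group of the animal (sham hemispheres, or the hemisphere
        contralateral/ipsilateral to the carotid ligation in HI animals).
    times : ndarray
        Strictly increasing spike times in seconds, within [0, duration].
    duration : float
        Recording duration in seconds (> 0).
    """

    unit_id: str
    region: str
    group: str
    times: np.ndarray
    duration: float

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValidationError(f"unknown region {self.region!r}; expected one of {REGIONS}")
        if self.group not in GROUPS:
            raise ValidationError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        if not self.duration > 0:
            raise ValidationError(f"duration must be > 0, got {self.duration}")
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if t.ndim != 1:
            raise ValidationError("times must be one-dimensional")
        if t.size:
            if not np.all(np.isfinite(t)):
                raise ValidationError("non-finite spike time")
            if t[0] < 0 or t[-1] > self.duration:
                raise ValidationError(
                    f"unit {self.unit_id}: spike times outside [0, {self.duration}]"
                )
            if np.any(np.diff(t) <= 0):
                raise ValidationError(f"unit {self.unit_id}: times not strictly increasing")

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    @property
    def mean_rate_hz(self) -> float:
        return self.n_spikes / self.duration

    def shifted(self, dt: float) -> "SpikeTrain":
        """Translate all spike times by ``dt`` >= 0, extending the window."""
        return dataclasses.replace(self, times=self.times + dt,
                                   duration=self.duration + dt)


@dataclass(frozen=True)
class LFPSignal:
    """Uniformly sampled local field potential trace in microvolts."""

    samples: np.ndarray
    fs: float
    region: str = "RSC"
    group: str = "sham_left"

    def __post_init__(self) -> None:
        if not self.fs > 0:
            raise ValidationError(f"sampling rate must be > 0, got {self.fs}")
        if self.region not in REGIONS or self.group not in GROUPS:
            raise ValidationError(f"bad labels ({self.region}, {self.group})")
        x = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", x)
        if x.ndim != 1 or x.size == 0:
            raise ValidationError("samples must be a non-empty 1-D array")
        bad = np.flatnonzero(~np.isfinite(x))
        if bad.size:
            raise ValidationError(f"non-finite LFP sample at index {bad[0]}")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)


@dataclass
class AnalysisConfig:
    """All tunable analysis parameters with their standard defaults.

    Defaults follow the recording/analysis conventions for tetrode data:
    region-specific interneuron trough-to-peak cutoffs (0.4 ms cortex,
    0.25 ms hippocampus) with a 15 Hz rate cutoff, Poisson-surprise burst
    threshold 5, 256-point Welch blocks with 5 % overlap, 12.5 ms rate bins,
    600-6000 Hz spike band with a 50 uV threshold over 40-sample windows,
    and the 4-12 Hz theta-alpha coupling band with 18 phase bins for the
    modulation index.
    """

    in_threshold_ttp_ms: dict = field(default_factory=lambda: {"RSC": 0.4, "HPC": 0.25})
    rate_threshold_hz: float = 15.0
    surprise_threshold: float = 5.0
    bands: dict = field(default_factory=lambda: dict(DEFAULT_BANDS))
    coupling_band: tuple = (4.0, 12.0)
    nfft: int = 256
    overlap_fraction: float = 0.05
    rate_bin_ms: float = 12.5
    smooth_sigma_ms: float = 25.0
    spike_filter_hz: tuple = (600.0, 6000.0)
    spike_threshold_uv: float = 50.0
    spike_window_samples: int = 40
    spike_alignment_sample: int = 10
    phase_bins_mi: int = 18
    lfp_fs: float = 500.0
    coherence_bin_hz: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if set(self.in_threshold_ttp_ms) != set(REGIONS):
            raise ValidationError("in_threshold_ttp_ms must map exactly RSC and HPC")
        for thr in (self.rate_threshold_hz, self.surprise_threshold,
                    self.spike_threshold_uv, self.lfp_fs, self.coherence_bin_hz,
                    self.rate_bin_ms):
            if not thr > 0:
                raise ValidationError(f"threshold/rate must be > 0, got {thr}")
        if not 0 <= self.overlap_fraction < 1:
            raise ValidationError("overlap_fraction must be in [0, 1)")
        if self.nfft < 2 or self.phase_bins_mi < 2 or self.spike_window_samples < 4:
            raise ValidationError("nfft, phase_bins_mi, spike_window_samples too small")
        if not 0 <= self.spike_alignment_sample < self.spike_window_samples:
            raise ValidationError("alignment sample outside spike window")
        lo, hi = self.spike_filter_hz
        if not 0 < lo < hi:
            raise ValidationError("spike_filter_hz must be an increasing positive pair")
        edges = sorted(self.bands.values())
        for (a0, a1), (b0, b1) in zip(edges, edges[1:]):
            if a1 > b0:
                raise ValidationError("bands must be non-overlapping and ordered")
        for name, (b0, b1) in self.bands.items():
            if not b0 < b1:
                raise ValidationError(f"band {name} edges not increasing")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["coupling_band"] = list(self.coupling_band)
        d["spike_filter_hz"] = list(self.spike_filter_hz)
        d["bands"] = {k: list(v) for k, v in self.bands.items()}
        return d


_TUPLE_KEYS = {"coupling_band", "spike_filter_hz"}


def load_config(path: str | Path | None = None) -> AnalysisConfig:
    """Load an :class:`AnalysisConfig` from a flat key-value (YAML) file.

    Absent keys take their defaults; unknown keys are rejected by name so a
    typo never silently falls back to a default.
    """
    if path is None:
        return AnalysisConfig()
    raw = Path(path).read_text()
    data = yaml.safe_load(raw) if raw.strip() else {}
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise FormatError(f"config {path} is not a key-value mapping")
    known = {f.name for f in dataclasses.fields(AnalysisConfig)}
    unknown = set(data) - known
    if unknown:
        raise FormatError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    kwargs = {}
    for k, v in data.items():
        if k in _TUPLE_KEYS:
            v = tuple(v)
        elif k == "bands":
            v = {name: tuple(edges) for name, edges in v.items()}
        kwargs[k] = v
    return AnalysisConfig(**kwargs)


SPIKE_COLUMNS = ["unit_id", "region", "group", "time_s", "duration_s"]


def read_spike_table(path: str | Path) -> list[SpikeTrain]:
    """Read a spike-event CSV into one :class:`SpikeTrain` per unit.

    Times are sorted; duplicate timestamps within a unit (refractory
    violations from upstream sorting) collapse to one spike with a warning.
    """
    df = pd.read_csv(path, dtype={"unit_id": str}, float_precision="round_trip")
    missing = [c for c in SPIKE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    bad = df.index[(df["time_s"] < 0) | (df["time_s"] > df["duration_s"])]
    if len(bad):
        raise ValidationError(
            f"{path}: row {bad[0] + 2} has time_s outside [0, duration_s]")
    trains = []
    for unit_id, sub in df.groupby("unit_id", sort=True):
        region = sub["region"].iloc[0]
        group = sub["group"].iloc[0]
        duration = float(sub["duration_s"].iloc[0])
        t = np.sort(sub["time_s"].to_numpy(dtype=float))
        uniq = np.unique(t)
        if uniq.size < t.size:
            warnings.warn(
                f"unit {unit_id}: collapsed {t.size - uniq.size} duplicate "
                "spike timestamp(s)", stacklevel=2)
        trains.append(SpikeTrain(str(unit_id), region, group, uniq, duration))
    return trains


def write_spike_table(trains: Iterable[SpikeTrain], path: str | Path) -> None:
    """Write spike trains as CSV; float formatting round-trips bit-exactly."""
    rows = []
    for tr in trains:
        for t in tr.times:
            rows.append((tr.unit_id, tr.region, tr.group, repr(float(t)),
                         repr(float(tr.duration))))
    df = pd.DataFrame(rows, columns=SPIKE_COLUMNS)
    df.to_csv(path, index=False)


def read_continuous(path: str | Path, fs: float, region: str = "RSC",
                    group: str = "sham_left") -> LFPSignal:
    """Read a continuous trace: single-column text (*.csv/*.txt) or raw
    little-endian float32 (any other suffix)."""
    if not fs > 0:
        raise ValidationError(f"fs must be > 0, got {fs}")
    p = Path(path)
    if p.suffix.lower() in {".csv", ".txt"}:
        x = np.loadtxt(p, dtype=float, ndmin=1)
    else:
        x = np.fromfile(p, dtype="<f4").astype(float)
    if x.size == 0:
        raise FormatError(f"{path}: zero-length stream")
    return LFPSignal(x, fs, region, group)


def write_continuous(lfp: LFPSignal, path: str | Path) -> None:
    p = Path(path)
    if p.suffix.lower() in {".csv", ".txt"}:
        np.savetxt(p, lfp.samples)
    else:
        lfp.samples.astype("<f4").tofile(p)


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()[:16]


def write_results(tables: Mapping[str, pd.DataFrame], out_dir: str | Path,
                  config: AnalysisConfig | None = None, seed: int | None = None,
                  inputs: Sequence[str | Path] = ()) -> dict:
    """Write result tables as CSV plus a machine-readable run summary.

    The summary (``run_summary.json``) records every analysis parameter, the
    seed, and SHA-256 digests of the inputs: enough to re-execute the same
    run and obtain identical outputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = {}
    for name, df in tables.items():
        p = out / f"{name}.csv"
        df.to_csv(p, index=False)
        written[name] = p.name
    summary = {
        "parameters": (config or AnalysisConfig()).to_dict(),
        "seed": seed,
        "inputs": {str(p): _digest(Path(p)) for p in inputs},
        "tables": written,
    }
    (out / "run_summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
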