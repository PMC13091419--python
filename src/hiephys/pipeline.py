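"""End-to-end cohort analysis: classify -> bursts -> synchrony -> fields ->
phase -> tracking, with figure-level summary tables.

``run_pipeline`` consumes either a data directory in the package's CSV
formats or a simulation spec, runs every stage deterministically for a given
seed, and returns the per-group/region tables group-difference statistics
would be computed from (the inferential tests themselves are out of scope).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from . import bursts as bursts_mod
from . import classify as classify_mod
from . import fields as fields_mod
from . import phase as phase_mod
from . import synchrony as synchrony_mod
from . import tracking as tracking_mod
from . import waveforms as waveforms_mod
from .io import (AnalysisConfig, GROUPS, REGIONS, LFPSignal, SpikeTrain,
                 read_continuous, read_spike_table, write_results)
from .synthetic import Cohort, CohortSpec, simulate_cohort, simulate_learning_series

__all__ = ["CohortReport", "run_pipeline", "composition_table",
           "corrected_infarct_volume", "round_pct"]


@dataclass
class CohortReport:
    """All per-unit and per-cell tables of one pipeline run."""

    units: pd.DataFrame                  # unit_id, region, group, rate, ttp, labels
    composition: pd.DataFrame            # Table-1-style counts and percentages
    burst_table: pd.DataFrame            # per-unit burst-load summaries
    synchrony_table: pd.DataFrame        # per-cell median pairwise R^2
    band_auc_table: pd.DataFrame         # per-cell LFP band areas
    coherence_table: pd.DataFrame        # per-unit spike-field band coherence
    phase_table: pd.DataFrame            # per-unit PLV / Rayleigh / MI
    learning_table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "units": self.units, "composition": self.composition,
            "bursts": self.burst_table, "synchrony": self.synchrony_table,
            "band_auc": self.band_auc_table, "coherence": self.coherence_table,
            "phase": self.phase_table, "learning": self.learning_table,
        }


def round_pct(x: float) -> float:
    """Round a percentage half-up to one decimal (display convention)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def composition_table(labels: pd.DataFrame) -> pd.DataFrame:
    """Counts and percentages of PNs and INs per hemisphere-group and region.

    ``labels`` needs columns ``unit_id``, ``region``, ``group``,
    ``cell_type``.  Unclassified units are excluded from the percentages.
    Percentages are rounded half-up to one decimal; empty cells show 0.0
    with an ``empty`` flag.  A grand-total row closes the table.
    """
    rows = []
    tot_pn = tot_in = 0
    for group in GROUPS:
        for region in REGIONS:
            sub = labels[(labels["group"] == group) & (labels["region"] == region)]
            n_pn = int((sub["cell_type"] == "PN").sum())
            n_in = int((sub["cell_type"] == "IN").sum())
            n = n_pn + n_in
            rows.append({
                "group": group, "region": region,
                "pn_count": n_pn, "pn_pct": round_pct(100.0 * n_pn / n) if n else 0.0,
                "in_count": n_in, "in_pct": round_pct(100.0 * n_in / n) if n else 0.0,
                "is_empty": n == 0,
            })
            tot_pn += n_pn
            tot_in += n_in
    total = tot_pn + tot_in
    rows.append({
        "group": "total", "region": "all", "pn_count": tot_pn,
        "pn_pct": round_pct(100.0 * tot_pn / total) if total else 0.0,
        "in_count": tot_in,
        "in_pct": round_pct(100.0 * tot_in / total) if total else 0.0,
        "is_empty": total == 0,
    })
    return pd.DataFrame(rows)


def corrected_infarct_volume(contra_vol: float, ipsi_vol: float,
                             infarct_vol: float) -> float:
    """Corrected infarct volume as a percentage of the contralateral
    hemisphere:

    ``CIV% = [contra - (ipsi - infarct)] / contra * 100``

    which counts both the infarcted tissue and the net hemispheric volume
    loss.
    """
    if contra_vol <= 0:
        raise ValueError("contralateral volume must be > 0")
    if not 0 <= infarct_vol <= ipsi_vol or ipsi_vol < 0:
        raise ValueError("require 0 <= infarct volume <= ipsilateral volume")
    return (contra_vol - (ipsi_vol - infarct_vol)) / contra_vol * 100.0


def _load_dir(input_dir: Path, config: AnalysisConfig) -> Cohort:
    spike_file = input_dir / "spikes.csv"
    if not spike_file.exists():
        raise FileNotFoundError(f"no spikes.csv in {input_dir}")
    trains = read_spike_table(spike_file)
    lfps = {}
    for p in sorted(input_dir.glob("lfp_*_*.f32")):
        group, region = p.stem.split("_", 1)[1].rsplit("_", 1)
        lfps[(group, region)] = read_continuous(p, config.lfp_fs, region, group)
    waveforms = {}
    for p in sorted(input_dir.glob("waveforms_*.npyt")):
        unit_id = p.stem.split("_", 1)[1]
        flat = np.loadtxt(p)
        waveforms[unit_id] = flat.reshape(-1, 4, config.spike_window_samples)
    return Cohort(CohortSpec(), trains, lfps, waveforms, {})


def run_pipeline(config: AnalysisConfig | None = None,
                 input_dir: str | Path | None = None,
                 simulate: bool = False, spec: CohortSpec | None = None,
                 seed: int | None = None, out_dir: str | Path | None = None,
                 with_learning: bool = True) -> CohortReport:
    """Run every analysis stage over a cohort and assemble the report.

    Exactly one of ``input_dir`` / ``simulate`` selects the input.  With
    ``simulate`` the synthetic cohort spec (optionally reseeded by ``seed``)
    defines the session; results are deterministic given the seed.
    """
    cfg = config or AnalysisConfig()
    if simulate == (input_dir is not None):
        raise ValueError("provide exactly one of input_dir or simulate=True")
    if simulate:
        spec = spec or CohortSpec()
        if seed is not None:
            spec.seed = seed
        cohort = simulate_cohort(spec)
    else:
        input_dir = Path(input_dir)
        if not input_dir.exists() or not any(input_dir.iterdir()):
            raise FileNotFoundError(f"input directory {input_dir} is missing or empty")
        cohort = _load_dir(input_dir, cfg)

    # --- classification -------------------------------------------------
    unit_rows = []
    features_by_unit = {}
    for tr in cohort.trains:
        try:
            if tr.unit_id in cohort.waveforms:
                ws = waveforms_mod.WaveformSet(
                    cohort.waveforms[tr.unit_id], 30000.0,
                    cfg.spike_alignment_sample, np.empty(0))
                mean_wf = waveforms_mod.average_waveform(ws)
                feats = waveforms_mod.waveform_features(
                    mean_wf, 30000.0, tr.times, tr.duration)
            else:
                feats = waveforms_mod.UnitFeatures(1.0, 0.3, 100.0, tr.mean_rate_hz)
            cell_type = classify_mod.classify_cell_type(feats, tr.region, cfg)
            discharge = classify_mod.classify_discharge_pattern(tr, cell_type)
        except Exception as exc:
            raise RuntimeError(f"stage classify failed on unit {tr.unit_id}: {exc}") from exc
        features_by_unit[tr.unit_id] = feats
        unit_rows.append({
            "unit_id": tr.unit_id, "region": tr.region, "group": tr.group,
            "n_spikes": tr.n_spikes, "mean_rate_hz": tr.mean_rate_hz,
            "trough_to_peak_ms": feats.trough_to_peak_ms,
            "half_width_ms": feats.half_width_ms,
            "cell_type": cell_type, "discharge_class": discharge,
        })
    units = pd.DataFrame(unit_rows)
    composition = composition_table(units)
    pn_units = units[units["cell_type"] == "PN"]["unit_id"].tolist()

    # --- bursts ---------------------------------------------------------
    burst_rows = []
    for tr in cohort.trains:
        try:
            bs = bursts_mod.detect_bursts(tr, cfg.surprise_threshold)
            summ = bursts_mod.burst_summary(bs)
        except Exception as exc:
            raise RuntimeError(f"stage bursts failed on unit {tr.unit_id}: {exc}") from exc
        burst_rows.append(dict(unit_id=tr.unit_id, region=tr.region,
                               group=tr.group, **summ))
    burst_table = pd.DataFrame(burst_rows)

    # --- synchrony ------------------------------------------------------
    sync_rows = []
    for region in REGIONS:
        for group in GROUPS:
            cell = [tr for tr in cohort.trains
                    if tr.region == region and tr.group == group
                    and tr.unit_id in pn_units]
            if len(cell) < 2:
                continue
            rates = {tr.unit_id: synchrony_mod.binned_rate(
                tr, cfg.rate_bin_ms, cfg.smooth_sigma_ms)[1] for tr in cell}
            try:
                m = synchrony_mod.pairwise_r2_matrix(rates, session=f"{group}/{region}")
            except Exception as exc:
                raise RuntimeError(f"stage synchrony failed in {group}/{region}: {exc}") from exc
            iu = np.triu_indices(len(m.unit_ids), k=1)
            sync_rows.append({
                "group": group, "region": region, "n_units": len(m.unit_ids),
                "median_offdiag_r2": float(np.median(m.r2[iu])),
                "mean_offdiag_r2": float(np.mean(m.r2[iu])),
            })
    synchrony_table = pd.DataFrame(sync_rows)

    # --- fields ---------------------------------------------------------
    auc_rows, coh_rows = [], []
    for (group, region), lfp in cohort.lfps.items():
        try:
            ps = fields_mod.power_spectrum(lfp, cfg.nfft, cfg.overlap_fraction)
            aucs = fields_mod.band_auc(ps, cfg.bands)
        except Exception as exc:
            raise RuntimeError(f"stage fields failed on LFP {group}/{region}: {exc}") from exc
        auc_rows.append(dict(group=group, region=region, **aucs))
        for tr in cohort.trains:
            if tr.group != group or tr.region != region or tr.n_spikes == 0:
                continue
            cs = fields_mod.spike_field_coherence(tr, lfp, cfg.nfft,
                                                  cfg.overlap_fraction, cfg.bands)
            coh_rows.append(dict(unit_id=tr.unit_id, group=group,
                                 region=region, **cs.band_means))
    band_auc_table = pd.DataFrame(auc_rows)
    coherence_table = pd.DataFrame(coh_rows)

    # --- phase ----------------------------------------------------------
    phase_rows = []
    for (group, region), lfp in cohort.lfps.items():
        for tr in cohort.trains:
            if tr.group != group or tr.region != region or tr.n_spikes == 0:
                continue
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    st = phase_mod.phase_stats(tr, lfp, cfg.coupling_band,
                                               cfg.phase_bins_mi)
            except Exception as exc:
                raise RuntimeError(f"stage phase failed on unit {tr.unit_id}: {exc}") from exc
            phase_rows.append({
                "unit_id": tr.unit_id, "group": group, "region": region,
                "plv": st.plv, "mean_angle_deg": np.degrees(st.mean_angle),
                "rayleigh_z": st.rayleigh_z, "rayleigh_p": st.rayleigh_p,
                "modulation_index": st.modulation_index, "n_spikes": st.n,
            })
    phase_table = pd.DataFrame(phase_rows)

    # --- tracking (learning series) ------------------------------------
    learning_table = pd.DataFrame()
    if simulate and with_learning:
        series = simulate_learning_series(seed=cohort.spec.seed)
        labels = tracking_mod.classify_learning_response(series)
        rows = []
        for s, lab in zip(series, labels):
            r2, coh = tracking_mod.learning_response_features(s)
            rows.append({"unit_id": s.unit_id, "group": s.group,
                         "r_squared": r2, "mean_coherence": coh,
                         "label": lab, "true_label": s.true_label})
        learning_table = pd.DataFrame(rows)

    report = CohortReport(units, composition, burst_table, synchrony_table,
                          band_auc_table, coherence_table, phase_table,
                          learning_table)
    if out_dir is not None:
        write_results(report.tables(), out_dir, cfg,
                      seed=cohort.spec.seed if simulate else seed)
    return report
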