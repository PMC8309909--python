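"""Study orchestration: model study, synthetic cohort, and comparisons.

Three analyses mirror the structure of the electrode-displacement
investigation:

* :func:`run_model_study` runs the voxel heart/torso forward model,
  extracts the leads at all seven electrode configurations on front and
  back, computes ensemble-average segment coefficients at the reference
  position and the DTW distance of every displaced position to it.

* :func:`run_synthetic_cohort` generates the synthetic volunteer
  cohort, processes every subject's rest records into coefficient
  statistics and DTW-by-position tables, and the walking records into
  SNR and DTW-variation tables.

* :func:`compare_tables` reduces two coefficient tables to headline
  scalars: per-lead/side similarity percentages (difference/similarity
  applied per coefficient, averaged over the eight coefficients) and
  the front-versus-back mean percentage difference over all 24
  coefficient x lead pairs.

Every quantity in an emitted table is reproducible by calling the
underlying module functions; cohort outputs are a pure function of the
configuration and master seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from torsoecg.records import ECGRecord, COEFFICIENT_NAMES, LEADS, SIDES
from torsoecg import cohort_tables
from torsoecg.morphology import (dtw_distance, snr_db, percent_difference,
                                 percent_similarity, variation_percent)
from torsoecg.ensemble_average import (detect_r_peaks, remove_baseline,
                                       compute_ensemble_average,
                                       extract_coefficients)

LEAD_SIDE = [(lead, side) for lead in LEADS for side in SIDES]
_COLUMNS = [f"{lead}{side}" for lead, side in LEAD_SIDE]
_POS_COLS = [f"position_{k}" for k in range(1, 7)]


@dataclass
class StudyReport:
    """Tables and headline scalars of one study run."""

    coefficients: pd.DataFrame | None = None       # 8 x 6, mean
    coefficients_sd: pd.DataFrame | None = None    # 8 x 6, cohort only
    dtw_by_position: pd.DataFrame | None = None    # 6 x 6, uV
    dtw_by_position_sd: pd.DataFrame | None = None
    snr_by_position: pd.DataFrame | None = None    # leads x 6, dB
    snr_by_position_sd: pd.DataFrame | None = None
    variation_by_position: pd.DataFrame | None = None  # leads x 6, %
    variation_by_position_sd: pd.DataFrame | None = None
    headline: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)

    def to_csv(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in ("coefficients", "coefficients_sd", "dtw_by_position",
                     "dtw_by_position_sd", "snr_by_position",
                     "snr_by_position_sd", "variation_by_position",
                     "variation_by_position_sd"):
            df = getattr(self, name)
            if df is not None:
                df.to_csv(out / f"{name}.csv")
        (out / "manifest.json").write_text(json.dumps(
            {"headline": self.headline, "config": self.config}, indent=1,
            default=str))


# ---------------------------------------------------------------------------
# shared processing

def record_coefficients(records: dict, norm: float | None = None):
    """EA coefficients for a dict ``lead -> ECGRecord`` of one side.

    R peaks are detected on lead D2 (largest, cleanest R) and shared by
    the other leads of the simultaneously recorded set.  ``norm``
    defaults to each record's stored normalization amplitude, falling
    back to the cross-lead maximum EA amplitude.
    """
    clean = {lead: remove_baseline(rec) for lead, rec in records.items()}
    peaks = detect_r_peaks(clean["D2"])
    eas = {lead: compute_ensemble_average(rec, peaks)
           for lead, rec in clean.items()}
    if norm is None:
        norm = records["D2"].meta.get("max_amplitude_mv")
    if norm is None:
        norm = max(np.abs(ea.mean).max() for ea in eas.values())
    return {lead: extract_coefficients(ea, norm=norm)
            for lead, ea in eas.items()}, eas


def _ea_beat(record: ECGRecord, peaks=None) -> np.ndarray:
    rec = remove_baseline(record)
    ea = compute_ensemble_average(rec, peaks)
    return ea.mean


# ---------------------------------------------------------------------------
# model study

def run_model_study(geometry=None, duration: float = 3.5,
                    dt: float = 1e-4, fs: float = 250.0,
                    simulation=None) -> StudyReport:
    """Forward-model analysis: coefficients and DTW-by-position tables.

    ``simulation`` may carry a pre-computed :class:`SimulationResult`
    to avoid re-running the solver.  The output is deterministic: the
    forward model has no random elements.
    """
    from torsoecg.cardiac_sim import run_simulation
    from torsoecg.geometry import build_torso_geometry, place_electrodes

    if simulation is None:
        geometry = geometry or build_torso_geometry()
        layout = place_electrodes(geometry)
        simulation = run_simulation(geometry, duration=duration, dt=dt,
                                    fs=fs, layout=layout,
                                    store_surface=False)
    leads = simulation.leads

    coeffs = {}
    beats = {}
    for side in SIDES:
        for pos in range(7):
            records = {lead: leads.record(lead, side, pos)
                       for lead in LEADS}
            clean = {lead: remove_baseline(rec)
                     for lead, rec in records.items()}
            peaks = detect_r_peaks(clean["D2"])
            eas = {lead: compute_ensemble_average(rec, peaks)
                   for lead, rec in clean.items()}
            for lead in LEADS:
                beats[(lead, side, pos)] = eas[lead].mean
            if pos == 0:
                norm = max(np.abs(ea.mean).max() for ea in eas.values())
                for lead in LEADS:
                    coeffs[(lead, side)] = extract_coefficients(
                        eas[lead], norm=norm)

    coeff_tbl = pd.DataFrame(
        {f"{lead}{side}": coeffs[(lead, side)].as_array()
         for lead, side in LEAD_SIDE}, index=COEFFICIENT_NAMES)

    dtw_tbl = pd.DataFrame(index=_COLUMNS, columns=_POS_COLS, dtype=float)
    for lead, side in LEAD_SIDE:
        ref = beats[(lead, side, 0)] * 1000.0   # uV
        for k in range(1, 7):
            cmp_beat = beats[(lead, side, k)] * 1000.0
            dtw_tbl.loc[f"{lead}{side}", f"position_{k}"] = dtw_distance(
                ref, cmp_beat)

    report = StudyReport(
        coefficients=coeff_tbl, dtw_by_position=dtw_tbl,
        config={"kind": "model", "duration": duration, "dt": dt, "fs": fs,
                "diagnostics": simulation.diagnostics})
    report.headline["position_distance_spearman"] = {
        col: float(_spearman(np.arange(1, 7),
                             dtw_tbl.loc[col].to_numpy(float)))
        for col in _COLUMNS}
    return report


def _spearman(x, y) -> float:
    from scipy.stats import spearmanr

    return spearmanr(x, y).statistic


# ---------------------------------------------------------------------------
# synthetic cohort study

def run_synthetic_cohort(cfg=None, seed: int | None = None,
                         positions=range(7),
                         include_walking: bool = True) -> StudyReport:
    """Generate and analyze the synthetic cohort end to end.

    Emits the cohort coefficient table (mean and SD at the reference
    position), the DTW-by-position table of the rest records, and - if
    ``include_walking`` - the SNR and DTW-variation tables of the
    walking records (displaced position versus reference, both
    contaminated).  With a fixed seed the report is identical across
    runs.
    """
    from torsoecg.synthetic_ecg import (CohortConfig, generate_cohort,
                                        subject_record)

    cfg = cfg or CohortConfig()
    if seed is not None:
        cfg.seed = seed
    subjects = generate_cohort(cfg)
    positions = [k for k in positions]

    coeff_rows = {col: [] for col in _COLUMNS}
    dtw_rows = {(col, k): [] for col in _COLUMNS for k in positions if k}
    snr_rows = {(lead, k): [] for lead in LEADS for k in positions if k}
    var_rows = {(lead, k): [] for lead in LEADS for k in positions if k}

    for spec in subjects:
        for side in SIDES:
            recs0 = {lead: subject_record(spec, cfg, lead, side, 0)
                     for lead in LEADS}
            co, eas0 = record_coefficients(recs0)
            for lead in LEADS:
                coeff_rows[f"{lead}{side}"].append(co[lead].as_array())
            for lead in LEADS:
                ref_uv = eas0[lead].mean * 1000.0
                for k in positions:
                    if k == 0:
                        continue
                    rec_k = subject_record(spec, cfg, lead, side, k)
                    beat_k = _ea_beat(rec_k, rec_k.meta["r_peaks"]) * 1000.0
                    dtw_rows[(f"{lead}{side}", k)].append(
                        dtw_distance(ref_uv, beat_k))
            if side == "front" and include_walking:
                for lead in LEADS:
                    ref_walk = subject_record(spec, cfg, lead, side, 0,
                                              "walking")
                    ref_beat = _ea_beat(ref_walk,
                                        ref_walk.meta["r_peaks"])
                    for k in positions:
                        if k == 0:
                            continue
                        walk_k = subject_record(spec, cfg, lead, side, k,
                                                "walking")
                        snr_rows[(lead, k)].append(
                            snr_db(ref_walk.samples, walk_k.samples))
                        beat_k = _ea_beat(walk_k, walk_k.meta["r_peaks"])
                        var_rows[(lead, k)].append(
                            variation_percent(ref_beat * 1000.0,
                                              beat_k * 1000.0))

    coeff_mean = pd.DataFrame(
        {col: np.nanmean(np.vstack(rows), axis=0)
         for col, rows in coeff_rows.items()}, index=COEFFICIENT_NAMES)
    coeff_sd = pd.DataFrame(
        {col: np.nanstd(np.vstack(rows), axis=0)
         for col, rows in coeff_rows.items()}, index=COEFFICIENT_NAMES)

    def table(rows_dict, index):
        mean = pd.DataFrame(index=index, columns=_POS_COLS, dtype=float)
        sd = pd.DataFrame(index=index, columns=_POS_COLS, dtype=float)
        for (row, k), vals in rows_dict.items():
            if vals:
                mean.loc[row, f"position_{k}"] = float(np.mean(vals))
                sd.loc[row, f"position_{k}"] = float(np.std(vals))
        return mean, sd

    dtw_mean, dtw_sd = table(dtw_rows, _COLUMNS)
    report = StudyReport(
        coefficients=coeff_mean, coefficients_sd=coeff_sd,
        dtw_by_position=dtw_mean, dtw_by_position_sd=dtw_sd,
        config={"kind": "synthetic_cohort", "seed": cfg.seed,
                "n_subjects": cfg.n_subjects,
                "rest_duration": cfg.rest_duration,
                "walking_duration": cfg.walking_duration})
    if include_walking:
        snr_mean, snr_sd = table(snr_rows, list(LEADS))
        var_mean, var_sd = table(var_rows, list(LEADS))
        report.snr_by_position = snr_mean
        report.snr_by_position_sd = snr_sd
        report.variation_by_position = var_mean
        report.variation_by_position_sd = var_sd
    report.headline["position_distance_spearman"] = {
        col: float(_spearman(
            np.arange(1, report.dtw_by_position.shape[1] + 1),
            report.dtw_by_position.loc[col].to_numpy(float)))
        for col in _COLUMNS
        if report.dtw_by_position.loc[col].notna().all()}
    return report


# ---------------------------------------------------------------------------
# table comparisons

def similarity_by_column(table_a: pd.DataFrame,
                         table_b: pd.DataFrame) -> pd.Series:
    """Mean similarity (%) per lead x side column: the percentage
    difference/similarity applied per coefficient, averaged over the
    eight coefficients."""
    if not table_a.index.equals(table_b.index) or \
            list(table_a.columns) != list(table_b.columns):
        raise ValueError("coefficient tables must share layout")
    out = {}
    for col in table_a.columns:
        sims = []
        for i in table_a.index:
            e1 = float(table_a.loc[i, col])
            e2 = float(table_b.loc[i, col])
            if not (np.isfinite(e1) and np.isfinite(e2)) or e1 + e2 == 0:
                continue   # missing or degenerate pair: excluded
            sims.append(percent_similarity(e1, e2))
        out[col] = float(np.mean(sims)) if sims else np.nan
    return pd.Series(out)


def front_back_difference(table: pd.DataFrame) -> float:
    """Mean percentage difference between front and back coefficients.

    The percentage difference is applied to each of the 24
    (coefficient, lead) front/back mean pairs and averaged.
    """
    diffs = []
    for lead in LEADS:
        for name in table.index:
            e1 = float(table.loc[name, f"{lead}front"])
            e2 = float(table.loc[name, f"{lead}back"])
            if not (np.isfinite(e1) and np.isfinite(e2)) or e1 + e2 == 0:
                continue   # missing or degenerate pair: excluded
            diffs.append(percent_difference(e1, e2))
    return float(np.mean(diffs))


def compare_tables(model: pd.DataFrame, cohort: pd.DataFrame) -> dict:
    """Headline scalars comparing a model and a cohort coefficient table."""
    sims = similarity_by_column(model, cohort)
    return {
        "similarity_by_column": sims.to_dict(),
        "mean_similarity": float(sims.mean()),
        "front_back_difference_model": front_back_difference(model),
        "front_back_difference_cohort": front_back_difference(cohort),
    }


def reference_mean_similarity() -> float:
    """Mean of the published per-lead model-versus-volunteer
    similarities at the reference position."""
    return float(
        cohort_tables.MODEL_VOLUNTEER_SIMILARITY["similarity"].mean())


def reference_front_back_difference() -> float:
    """Front/back mean percentage difference of the published volunteer
    coefficient table."""
    return front_back_difference(cohort_tables.VOLUNTEER_COEFFS_MEAN)
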