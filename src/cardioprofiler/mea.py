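"""Multi-electrode-array (MEA) electrophysiology parameters and QC flags.

Implements the five standard field-potential parameters for beating
cardiomyocyte monolayers, computed from event-level beat/FPD tables:

    BPM     = 60 / mean beat period (s)
    BRI     = 100 × SD(per-electrode mean beat period) / well mean period
    BRV CV  = 100 × SD(per-well BPM) / plate mean BPM
    FPDc    = FPD (ms) / beat period (s) ^ 0.192
    FPD CV  = 100 × SD(per-well FPD) / plate mean FPD

plus active-electrode and FPD-detection-success percentages, and the media-QC
flags used to exclude unstable wells/plates (active electrodes < 50%,
BRI > 5%, BPM outside 20–45, BRV CV > 20%, FPD CV > 20% or FPD detection
success < 50%). All standard deviations are sample SDs (n−1). Undefined
quantities (quiescent wells, < 2 active electrodes) propagate as NaN and are
excluded from plate-level CVs rather than imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FPDC_EXPONENT",
    "QcThresholds",
    "WellParameters",
    "PlateParameters",
    "active_electrode_pct",
    "analyze_recordings",
    "compute_bpm",
    "compute_bri",
    "compute_brv_cv",
    "compute_fpd_cv",
    "compute_fpdc",
    "qc_evaluate",
    "well_parameters",
]

#: Rate-correction exponent applied to the beat period (in seconds).
FPDC_EXPONENT = 0.192

#: Spike amplitude (µV) below which an electrode is not detecting beats.
DETECTION_THRESHOLD_UV = 300.0

#: Minimum detected beats for an electrode to count as active.
MIN_BEATS = 2


@dataclass(frozen=True)
class QcThresholds:
    """QC cut-offs; defaults are the assay's standard acceptance windows."""

    min_active_pct: float = 50.0
    max_bri_pct: float = 5.0
    bpm_window: tuple[float, float] = (20.0, 45.0)
    max_brv_cv_pct: float = 20.0
    max_fpd_cv_pct: float = 20.0
    min_fpd_success_pct: float = 50.0
    detection_threshold_uV: float = DETECTION_THRESHOLD_UV


@dataclass
class WellParameters:
    """Electrophysiology parameters of one well (NaN where undefined)."""

    well: str
    n_electrodes: int
    active_pct: float
    bpm: float
    bri: float
    fpd: float
    fpdc: float
    fpd_success_pct: float
    mean_beat_period_s: float
    flags: set[str] = field(default_factory=set)


@dataclass
class PlateParameters:
    """Across-well variability parameters of one plate."""

    plate: str
    n_wells: int
    n_wells_used: int
    brv_cv: float
    fpd_cv: float
    flags: set[str] = field(default_factory=set)


def _sd(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1))


def compute_bpm(mean_beat_period_s: float) -> float:
    """Beats per minute from a mean beat period in seconds; NaN if not > 0."""
    if not np.isfinite(mean_beat_period_s) or mean_beat_period_s <= 0:
        return float("nan")
    return 60.0 / mean_beat_period_s


def compute_bri(per_electrode_mean_periods_s, well_mean_period_s: float | None = None) -> float:
    """Beat-rate irregularity: CV% of per-electrode mean periods within a well.

    NaN when fewer than two active electrodes contribute.
    """
    x = np.asarray(per_electrode_mean_periods_s, float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        return float("nan")
    mean = float(np.mean(x)) if well_mean_period_s is None else float(well_mean_period_s)
    return 100.0 * _sd(x) / mean


def compute_brv_cv(per_well_bpm) -> float:
    """Beat-rate variability: CV% of per-well BPM across a plate."""
    x = np.asarray(per_well_bpm, float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        return float("nan")
    return 100.0 * _sd(x) / float(np.mean(x))


def compute_fpdc(fpd_ms: float, beat_period_s: float) -> float:
    """Rate-corrected FPD: FPD (ms) divided by period (s) to the 0.192 power.

    The printed formula divides milliseconds by a dimensionless power of the
    period in seconds and is followed literally; at a 1 s period the
    correction is the identity.
    """
    if not (np.isfinite(fpd_ms) and np.isfinite(beat_period_s)):
        return float("nan")
    if fpd_ms <= 0 or beat_period_s <= 0:
        return float("nan")
    return fpd_ms / beat_period_s ** FPDC_EXPONENT


def compute_fpd_cv(per_well_fpd_ms) -> float:
    """FPD variability: CV% of per-well FPD across a plate."""
    x = np.asarray(per_well_fpd_ms, float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        return float("nan")
    return 100.0 * _sd(x) / float(np.mean(x))


def _electrode_summary(
    well_df: pd.DataFrame, detection_threshold_uV: float
) -> pd.DataFrame:
    """Per electrode: amplitude, beat count, mean period, mean FPD."""
    beats = well_df[well_df["beat_index"] >= 0]
    grouped = beats.groupby("electrode", sort=True)
    summary = pd.DataFrame(
        {
            "n_beats": grouped.size(),
            "mean_period_s": grouped["beat_period_s"].mean(),
            "mean_fpd_ms": grouped["fpd_ms"].mean(),
        }
    )
    amp = well_df.groupby("electrode", sort=True)["amplitude_uV"].first()
    summary = summary.reindex(amp.index)
    summary["n_beats"] = summary["n_beats"].fillna(0).astype(int)
    summary["amplitude_uV"] = amp
    summary["active"] = (summary["amplitude_uV"] >= detection_threshold_uV) & (
        summary["n_beats"] >= MIN_BEATS
    )
    return summary


def active_electrode_pct(
    well_df: pd.DataFrame, detection_threshold_uV: float = DETECTION_THRESHOLD_UV
) -> float:
    """Percent of a well's electrodes detecting ≥2 beats at ≥ threshold µV."""
    if well_df.empty or well_df["electrode"].nunique() == 0:
        raise ValueError("empty well: no electrodes")
    s = _electrode_summary(well_df, detection_threshold_uV)
    return 100.0 * float(s["active"].sum()) / len(s)


def well_parameters(
    well_df: pd.DataFrame,
    detection_threshold_uV: float = DETECTION_THRESHOLD_UV,
) -> WellParameters:
    """All per-well parameters from one well's event table.

    The well FPD is the mean over active electrodes' per-electrode mean FPD;
    FPDc combines it with the well mean beat period.
    """
    if well_df.empty:
        raise ValueError("empty well: no electrodes")
    s = _electrode_summary(well_df, detection_threshold_uV)
    active = s[s["active"]]
    active_pct = 100.0 * len(active) / len(s)
    periods = active["mean_period_s"].to_numpy(float)
    mean_period = float(np.mean(periods)) if len(active) else float("nan")
    bpm = compute_bpm(mean_period)
    bri = compute_bri(periods, mean_period) if len(active) >= 2 else float("nan")
    with_fpd = active["mean_fpd_ms"].dropna()
    fpd = float(with_fpd.mean()) if len(with_fpd) else float("nan")
    fpd_success = 100.0 * len(with_fpd) / len(active) if len(active) else float("nan")
    fpdc = compute_fpdc(fpd, mean_period)
    return WellParameters(
        well=str(well_df["well"].iloc[0]),
        n_electrodes=len(s),
        active_pct=active_pct,
        bpm=bpm,
        bri=bri,
        fpd=fpd,
        fpdc=fpdc,
        fpd_success_pct=fpd_success,
        mean_beat_period_s=mean_period,
    )


def qc_evaluate(
    well: WellParameters,
    plate: PlateParameters | None = None,
    thresholds: QcThresholds = QcThresholds(),
) -> tuple[set[str], set[str]]:
    """Flag a well (and optionally its plate) against the QC windows.

    Well flags: ``excluded_low_activity`` (active < 50%), ``arrhythmic``
    (BRI strictly > 5%), ``bpm_out_of_window`` (BPM outside [20, 45]).
    Plate flags: ``brv_unstable`` (BRV CV > 20%), ``fpd_unstable``
    (FPD CV > 20% or FPD detection success < 50%). Undefined inputs yield no
    flag (they are reported as NaN, not as failures).
    """
    wf: set[str] = set()
    if np.isfinite(well.active_pct) and well.active_pct < thresholds.min_active_pct:
        wf.add("excluded_low_activity")
    if np.isfinite(well.bri) and well.bri > thresholds.max_bri_pct:
        wf.add("arrhythmic")
    lo, hi = thresholds.bpm_window
    if np.isfinite(well.bpm) and not (lo <= well.bpm <= hi):
        wf.add("bpm_out_of_window")
    if np.isfinite(well.fpd_success_pct) and well.fpd_success_pct < thresholds.min_fpd_success_pct:
        wf.add("fpd_detection_low")
    well.flags = wf

    pf: set[str] = set()
    if plate is not None:
        if np.isfinite(plate.brv_cv) and plate.brv_cv > thresholds.max_brv_cv_pct:
            pf.add("brv_unstable")
        if (np.isfinite(plate.fpd_cv) and plate.fpd_cv > thresholds.max_fpd_cv_pct) or (
            np.isfinite(well.fpd_success_pct)
            and well.fpd_success_pct < thresholds.min_fpd_success_pct
        ):
            pf.add("fpd_unstable")
        plate.flags |= pf
    return wf, pf


def analyze_recordings(
    df: pd.DataFrame,
    thresholds: QcThresholds = QcThresholds(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Compute per-well and per-plate parameter tables from a long event table.

    Expects the long format written by the generator (one row per beat;
    beatless electrodes carried with ``beat_index = -1``). Plate CVs are
    computed over wells that pass the activity exclusion; quiescent wells
    contribute NaN parameters and are left out of the CVs.
    """
    required = {"plate", "well", "electrode", "beat_index", "beat_period_s", "amplitude_uV"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"MEA table missing columns: {sorted(missing)}")

    meta_cols = [c for c in ["line", "compound", "concentration_uM", "replicate"] if c in df.columns]
    well_rows = []
    for (plate, well), wdf in df.groupby(["plate", "well"], sort=True):
        wp = well_parameters(wdf, thresholds.detection_threshold_uV)
        qc_evaluate(wp, None, thresholds)
        row = {
            "plate": plate,
            "well": well,
            **{m: wdf[m].iloc[0] for m in meta_cols},
            "n_electrodes": wp.n_electrodes,
            "active_pct": wp.active_pct,
            "bpm": wp.bpm,
            "bri": wp.bri,
            "fpd_ms": wp.fpd,
            "fpdc_ms": wp.fpdc,
            "fpd_success_pct": wp.fpd_success_pct,
            "mean_beat_period_s": wp.mean_beat_period_s,
            "flags": ";".join(sorted(wp.flags)),
        }
        well_rows.append(row)
    wells = pd.DataFrame(well_rows)

    plate_rows = []
    for plate, pdf in wells.groupby("plate", sort=True):
        used = pdf[~pdf["flags"].str.contains("excluded_low_activity")]
        pp = PlateParameters(
            plate=plate,
            n_wells=len(pdf),
            n_wells_used=len(used),
            brv_cv=compute_brv_cv(used["bpm"]),
            fpd_cv=compute_fpd_cv(used["fpd_ms"]),
        )
        dummy = WellParameters(plate, 0, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan)
        qc_evaluate(dummy, pp, thresholds)
        plate_rows.append(
            {
                "plate": plate,
                "n_wells": pp.n_wells,
                "n_wells_used": pp.n_wells_used,
                "brv_cv": pp.brv_cv,
                "fpd_cv": pp.fpd_cv,
                "flags": ";".join(sorted(pp.flags)),
            }
        )
    plates = pd.DataFrame(plate_rows)
    return wells, plates
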