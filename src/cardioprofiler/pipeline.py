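"""End-to-end orchestration: simulate → MEA metrics → profiles → fingerprints
→ supervised classification, with validated configuration and auditable
intermediate artifacts.

Every stage writes its outputs as CSV/TSV/JSON under the run directory, and
the run report contains only numbers recomputable from those files.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict

from . import fingerprints as fp
from . import mea as mea_mod
from . import profiles as prof
from .design import default_study_design
from .simulate import META_COLUMNS, VEHICLE, generate_study
from .splsda import SparsePLSDA, block_combine

__all__ = [
    "RunConfig",
    "build_supervised_inputs",
    "read_feature_table",
    "run_pipeline",
]

EPHYS_FEATURES = ["bpm", "bri", "fpd_ms", "fpdc_ms", "active_pct", "fpd_success_pct"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class QcConfig(_Strict):
    mad_threshold: float = 3.0
    nzv_freq_ratio: float = 19.0
    nzv_unique_fraction: float = 0.10
    min_active_pct: float = 50.0
    max_bri_pct: float = 5.0
    bpm_window: tuple[float, float] = (20.0, 45.0)
    max_brv_cv_pct: float = 20.0
    max_fpd_cv_pct: float = 20.0
    min_fpd_success_pct: float = 50.0
    detection_threshold_uV: float = 300.0


class DesignConfig(_Strict):
    cells_per_well: int = 2000
    n_replicates: int = 6
    lines: tuple[str, ...] = ("NcyteCM1", "NcyteCM2", "NCRM5")
    n_electrodes: int = 8
    outlier_fraction: float = 0.01
    noise_sigma: float = 0.25


class ClassifyConfig(_Strict):
    n_components: int = 2
    keep_x: int = 50
    block_weights: tuple[float, float] = (1.0, 1.0)
    line: str | None = None  # default: first line of the design


class RunConfig(_Strict):
    """Validated pipeline configuration; unknown keys are rejected."""

    seed: int = 0
    out_dir: str = "cardioprofiler_run"
    vehicle_label: str = VEHICLE
    stages: tuple[str, ...] = ("simulate", "mea", "profiles", "fingerprint", "classify")
    k_clusters: int | None = None  # None → silhouette-selected
    write_artifacts: bool = True
    column_map: dict[str, str] = {}
    cells_path: str | None = None  # external inputs when simulate is disabled
    mea_path: str | None = None
    design: DesignConfig = DesignConfig()
    qc: QcConfig = QcConfig()
    classify: ClassifyConfig = ClassifyConfig()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.model_validate(raw)


def read_feature_table(path: str | Path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a delimited per-cell feature table into the canonical dialect.

    `column_map` renames third-party export columns onto the mandatory
    metadata names (line, plate, well, compound, concentration_uM,
    replicate). Unparseable feature values become missing values.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep)
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"feature table missing mandatory column(s): {missing}")
    feature_cols = [c for c in df.columns if c not in META_COLUMNS]
    df[feature_cols] = df[feature_cols].apply(pd.to_numeric, errors="coerce")
    df["concentration_uM"] = pd.to_numeric(df["concentration_uM"])
    df["replicate"] = df["replicate"].astype(int)
    return df


def build_supervised_inputs(
    normalized: pd.DataFrame,
    mea_wells: pd.DataFrame,
    selected_concentration: dict[str, float],
    kept_features: list[str],
    line: str,
    vehicle_label: str = VEHICLE,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Assemble matched morphology/ephys blocks at each compound's exposure dose.

    One row per compound × replicate well of the chosen line, morphology =
    vehicle-normalized replicate profile, ephys = the matching MEA well's
    parameter vector; residual missing ephys entries (e.g. FPD undetected in
    a whole well) are filled with the column median.
    """
    sel = pd.Series(selected_concentration, name="sel")
    m = normalized[
        (normalized["line"] == line) & (normalized["compound"] != vehicle_label)
    ].copy()
    m = m[m["concentration_uM"].to_numpy() == m["compound"].map(sel).to_numpy()]
    morph = m.set_index(["compound", "replicate"])[kept_features].sort_index()

    e = mea_wells[
        (mea_wells["line"] == line) & (mea_wells["compound"] != vehicle_label)
    ].copy()
    e = e[e["concentration_uM"].to_numpy() == e["compound"].map(sel).to_numpy()]
    ephys = e.set_index(["compound", "replicate"])[EPHYS_FEATURES].sort_index()

    idx = morph.index.intersection(ephys.index)
    if idx.empty:
        raise ValueError("no matched morphology/ephys samples at the selected doses")
    morph, ephys = morph.loc[idx], ephys.loc[idx]
    ephys = ephys.fillna(ephys.median())
    compounds = pd.Series(idx.get_level_values("compound"), index=range(len(idx)))
    morph.index = ephys.index = pd.RangeIndex(len(idx))
    return morph, ephys, compounds


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in fixed order; return the run report."""
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config_seed": config.seed, "stages": {}, "timings_s": {}}

    def stage_time(name, start):
        report["timings_s"][name] = round(time.time() - start, 3)

    qc = config.qc
    thresholds = mea_mod.QcThresholds(
        min_active_pct=qc.min_active_pct,
        max_bri_pct=qc.max_bri_pct,
        bpm_window=qc.bpm_window,
        max_brv_cv_pct=qc.max_brv_cv_pct,
        max_fpd_cv_pct=qc.max_fpd_cv_pct,
        min_fpd_success_pct=qc.min_fpd_success_pct,
        detection_threshold_uV=qc.detection_threshold_uV,
    )

    cells = mea_df = truth = None
    if "simulate" in config.stages:
        t = time.time()
        design = default_study_design(seed=config.seed).with_(
            cells_per_well=config.design.cells_per_well,
            n_replicates=config.design.n_replicates,
            lines=tuple(config.design.lines),
            n_electrodes=config.design.n_electrodes,
            outlier_fraction=config.design.outlier_fraction,
            noise_sigma=config.design.noise_sigma,
        )
        cells, mea_df, truth = generate_study(design)
        if config.write_artifacts:
            cells.to_csv(out / "cell_features.tsv", sep="\t", index=False)
            mea_df.to_csv(out / "mea_events.csv", index=False)
            with open(out / "ground_truth.json", "w") as fh:
                json.dump(truth.to_dict(), fh)
        report["stages"]["simulate"] = {
            "n_cells": int(len(cells)),
            "n_mea_beats": int((mea_df["beat_index"] >= 0).sum()),
            "n_compounds": len(design.compounds),
        }
        stage_time("simulate", t)
    else:
        if config.cells_path:
            cells = read_feature_table(config.cells_path, config.column_map)
        if config.mea_path:
            mea_df = pd.read_csv(config.mea_path)

    wells = None
    if "mea" in config.stages:
        if mea_df is None:
            raise RuntimeError("mea stage: no MEA events available (enable simulate or set mea_path)")
        t = time.time()
        wells, plates = mea_mod.analyze_recordings(mea_df, thresholds)
        if config.write_artifacts:
            wells.to_csv(out / "mea_well_parameters.csv", index=False)
            plates.to_csv(out / "mea_plate_parameters.csv", index=False)
        report["stages"]["mea"] = {
            "n_wells": int(len(wells)),
            "n_excluded_low_activity": int(wells["flags"].str.contains("excluded_low_activity").sum()),
            "n_arrhythmic": int(wells["flags"].str.contains("arrhythmic").sum()),
        }
        stage_time("mea", t)

    normalized = kept = None
    if "profiles" in config.stages:
        if cells is None:
            raise RuntimeError("profiles stage: no cell table available")
        t = time.time()
        flags = prof.flag_area_outliers(cells, threshold=qc.mad_threshold)
        replicate_profiles, undetectable = prof.aggregate_replicates(cells, flags)
        normalized, zero_vehicle = prof.normalize_to_vehicle(
            replicate_profiles, vehicle_label=config.vehicle_label
        )
        feature_cols = [
            c for c in replicate_profiles.columns
            if c not in prof.PROFILE_KEYS + ["n_cells"]
        ]
        candidates = [f for f in feature_cols if f not in set(undetectable) | set(zero_vehicle)]
        nzv = prof.filter_near_zero_variance(
            normalized[candidates], qc.nzv_freq_ratio, qc.nzv_unique_fraction
        )
        mask = prof.build_feature_mask(feature_cols, nzv, undetectable, zero_vehicle)
        kept = mask.kept
        viability = prof.viability_summary(cells, config.vehicle_label)
        if config.write_artifacts:
            replicate_profiles.to_csv(out / "replicate_profiles.csv", index=False)
            normalized.to_csv(out / "normalized_profiles.csv", index=False)
            mask.status.rename("status").to_csv(out / "feature_mask.csv")
            viability.to_csv(out / "viability.csv", index=False)
        report["stages"]["profiles"] = {
            "n_cells_read": int(len(cells)),
            "n_cells_flagged_outlier": int(flags.sum()),
            "n_replicate_profiles": int(len(replicate_profiles)),
            "features_dropped_by_reason": {
                r: int(n)
                for r, n in mask.status[mask.status != "kept"].value_counts().items()
            },
            "n_features_kept": len(kept),
        }
        stage_time("profiles", t)

    if "fingerprint" in config.stages:
        if normalized is None:
            raise RuntimeError("fingerprint stage requires the profiles stage")
        t = time.time()
        fps, evr = fp.compound_fingerprints(normalized, kept, config.vehicle_label)
        if config.k_clusters is None:
            assignment = fp.select_k_silhouette(fps, seed=config.seed)
        else:
            assignment = fp.cluster_fingerprints(fps, k=config.k_clusters, seed=config.seed)
        if config.write_artifacts:
            fps.to_csv(out / "fingerprints.csv")
            assignment.as_series().rename_axis("compound").to_csv(out / "clusters.csv")
            evr.to_csv(out / "pc1_explained_variance.csv", index=False)
        report["stages"]["fingerprint"] = {
            "k": assignment.k,
            "inertia": assignment.inertia,
            "clusters": assignment.labels,
            "silhouette_by_k": assignment.silhouette_by_k,
        }
        stage_time("fingerprint", t)

    if "classify" in config.stages:
        if normalized is None or wells is None:
            raise RuntimeError("classify stage requires the profiles and mea stages")
        if truth is None:
            raise RuntimeError("classify stage needs compound annotations (simulated ground truth)")
        t = time.time()
        lines_present = list(dict.fromkeys(normalized["line"]))
        line = config.classify.line or (
            "NcyteCM1" if "NcyteCM1" in lines_present else lines_present[0]
        )
        morph, ephys, compounds = build_supervised_inputs(
            normalized, wells, truth.selected_concentration, kept, line, config.vehicle_label
        )
        X = block_combine(morph, ephys, config.classify.block_weights)
        labels = compounds.map(truth.group_labels)
        # block_combine already standardized and block-weighted the columns;
        # re-scaling inside the fit would undo the datatype weighting
        model = SparsePLSDA(
            X,
            labels,
            n_components=config.classify.n_components,
            keep_x=config.classify.keep_x,
            scale=False,
        )
        res = model.fit()
        pred = res.predict(X, compounds=compounds, true_labels=truth.group_labels)
        scores = pd.DataFrame(
            res.scores, columns=[f"comp{h+1}" for h in range(res.n_components_)]
        )
        scores.insert(0, "compound", compounds.to_numpy())
        scores.insert(1, "group", labels.to_numpy())
        if config.write_artifacts:
            scores.to_csv(out / "splsda_scores.csv", index=False)
            pred.confusion.to_csv(out / "confusion.csv")
            with open(out / "model_summary.json", "w") as fh:
                json.dump(
                {
                    "classes": res.classes,
                    "keep_x": model.keep_x,
                    "n_components": res.n_components_,
                    "sample_accuracy_pct": pred.accuracy_pct,
                    "compound_accuracy_pct": pred.compound_accuracy_pct,
                        "compound_predictions": dict(pred.compound_labels),
                    },
                    fh,
                )
        report["stages"]["classify"] = {
            "line": line,
            "n_samples": int(len(X)),
            "sample_accuracy_pct": pred.accuracy_pct,
            "compound_accuracy_pct": pred.compound_accuracy_pct,
        }
        stage_time("classify", t)

    report["timings_s"]["total"] = round(time.time() - t0, 3)
    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    return report
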