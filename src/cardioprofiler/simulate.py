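"""Synthetic screen generator.

Draws per-cell imaging feature tables and MEA beat/FPD event streams with the
hierarchical structure the analysis chain assumes: line-specific feature
baselines, Hill-type dose responses acting on organelle blocks, multiplicative
lognormal cell-to-cell noise, Poisson cell counts with sigmoidal viability
loss, planted cytoplasm-area outliers, exactly-constant acquisition columns,
an undetectable-signal condition, and 8-electrode wells covering normal,
irregular (high BRI) and quiescent beating regimes.

Every generated quantity is recorded in a :class:`GroundTruth` object so that
recovery experiments can compare estimates against planted values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import (
    CONSTANT_FEATURES,
    CYTOPLASM_AREA,
    CompoundSpec,
    StudyDesign,
    build_feature_space,
)

__all__ = [
    "GroundTruth",
    "generate_cell_features",
    "generate_mea_recordings",
    "generate_study",
    "hill",
    "select_exposure",
    "viability_multiplier",
]

#: Vehicle control label (0.1% DMSO condition).
VEHICLE = "DMSO"

#: Metadata columns of the per-cell feature table, in export order.
META_COLUMNS = ["line", "plate", "well", "compound", "concentration_uM", "replicate"]

#: Condition in which one feature's signal is simulated as undetectable:
#: (compound, index of the concentration within its series, feature name).
UNDETECTABLE_CONDITION = ("amiodarone", -1, "peroxisomes_intensity_17")

_OUTLIER_AREA_FACTOR = 6.0  # places planted outliers far beyond 3 raw MADs
_MAX_VIABILITY_LOSS = 0.2  # exposure selection: tolerated fractional cell loss


def hill(conc, ec50: float, n: float = 2.0):
    """Hill response in [0, 1): conc^n / (conc^n + ec50^n); 0 at conc = 0."""
    c = np.asarray(conc, dtype=float)
    out = np.zeros_like(c)
    pos = c > 0
    out[pos] = c[pos] ** n / (c[pos] ** n + ec50 ** n)
    return out if out.ndim else float(out)


def viability_multiplier(compound: CompoundSpec, conc: float) -> float:
    """Expected fraction of cells surviving at `conc` (1 for vehicle)."""
    ec50 = compound.viability_ec50 if compound.viability_ec50 is not None else 3.0 * compound.ec50
    return 1.0 - compound.viability_effect * hill(conc, ec50, compound.hill)


def _ephys_magnitude(compound: CompoundSpec, conc: float) -> float:
    e = compound.ephys
    return (abs(e.bpm_shift) + e.bri_inflation + abs(e.fpd_shift)) * hill(
        conc, compound.ec50, compound.hill
    )


def select_exposure(design: StudyDesign) -> dict[str, float]:
    """Per compound, the concentration entering the supervised analysis.

    Chosen as the dose with the most pronounced electrophysiological effect
    among doses that neither silence the well nor lose more than 20% of the
    cells; compounds without electrophysiological activity default to the
    highest tolerated dose.
    """
    out: dict[str, float] = {}
    for c in design.compounds:
        q = c.ephys.quiescence_dose
        ok = [
            x
            for x in c.concentrations
            if viability_multiplier(c, x) >= 1.0 - _MAX_VIABILITY_LOSS
            and (q is None or x < q)
        ]
        if not ok:
            ok = [c.concentrations[0]]
        mags = [_ephys_magnitude(c, x) for x in ok]
        out[c.name] = ok[int(np.argmax(mags))] if max(mags) > 0 else ok[-1]
    return out


@dataclass
class GroundTruth:
    """Planted quantities of one simulated screen."""

    group_labels: dict[str, str]
    planted_cluster: dict[str, int]
    selected_concentration: dict[str, float]
    effect_log_fc: pd.DataFrame | None = None  # (line, compound, conc) × features
    well_cell_counts: pd.DataFrame | None = None
    mea_wells: pd.DataFrame | None = None
    n_planted_outliers: int = 0
    constant_features: tuple[str, ...] = CONSTANT_FEATURES
    undetectable: tuple = field(default_factory=tuple)

    def to_dict(self) -> dict:
        def df(x):
            return None if x is None else x.reset_index().to_dict(orient="list")

        return {
            "group_labels": self.group_labels,
            "planted_cluster": self.planted_cluster,
            "selected_concentration": self.selected_concentration,
            "effect_log_fc": df(self.effect_log_fc),
            "well_cell_counts": df(self.well_cell_counts),
            "mea_wells": df(self.mea_wells),
            "n_planted_outliers": self.n_planted_outliers,
            "constant_features": list(self.constant_features),
            "undetectable": list(self.undetectable),
        }


def _labels(design: StudyDesign) -> tuple[dict[str, str], dict[str, int]]:
    return (
        {c.name: c.toxicity_group for c in design.compounds},
        {c.name: c.mechanism_cluster for c in design.compounds},
    )


def _feature_scale(name: str) -> float:
    if name == CYTOPLASM_AREA:
        return 2500.0  # µm²
    if name in CONSTANT_FEATURES:
        return 1.0
    if "intensity" in name:
        return 1000.0
    if "area" in name:
        return 300.0
    if "count" in name:
        return 12.0
    return 1.0  # texture-like, dimensionless


def _conditions(design: StudyDesign) -> list[tuple[str, float]]:
    conds = [(c.name, x) for c in design.compounds for x in c.concentrations]
    conds += [(VEHICLE, 0.0)] * design.n_vehicle_wells
    return conds


def generate_cell_features(
    design: StudyDesign, seed: int | None = None
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate the per-cell imaging feature table of one screen.

    Returns the table (metadata columns first, then `design.n_features`
    feature columns) and the matching ground truth. Identical design + seed
    reproduce the table exactly.
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    features, blocks = build_feature_space(design.organelle_blocks)
    p = len(features)
    const_idx = np.array([features.index(f) for f in CONSTANT_FEATURES if f in features], int)
    area_idx = features.index(CYTOPLASM_AREA)
    scale = np.array([_feature_scale(f) for f in features])

    baselines = {
        line: scale * np.exp(rng.normal(0.0, design.line_baseline_sigma, p))
        for line in design.lines
    }
    for line in design.lines:
        baselines[line][const_idx] = 1.0

    stress = np.zeros(p)
    for block, mag in design.nonspecific_stress.items():
        idx = np.array(blocks[block], int)
        stress[idx] = mag * rng.uniform(0.8, 1.0, idx.size)
    stress[const_idx] = 0.0

    # fixed loading pattern of the well-level global nuisance factor
    factor_w = rng.uniform(0.2, 1.0, p)
    factor_w[const_idx] = 0.0

    emax: dict[str, np.ndarray] = {}
    for c in design.compounds:
        v = np.zeros(p)
        for block, mag in c.mechanism_profile.items():
            idx = np.array(blocks[block], int)
            v[idx] = mag * rng.uniform(0.5, 1.0, idx.size)
        v[const_idx] = 0.0
        emax[c.name] = v + stress  # specific mechanism on top of shared stress
    emax[VEHICLE] = np.zeros(p)

    ec50_shift = {
        (line, c.name): 10.0 ** rng.uniform(-design.line_ec50_shift, design.line_ec50_shift)
        for line in design.lines
        for c in design.compounds
    }

    by_name = {c.name: c for c in design.compounds}
    undet_name, undet_conc_i, undet_feature = UNDETECTABLE_CONDITION
    undet_conc = (
        by_name[undet_name].concentrations[undet_conc_i] if undet_name in by_name else None
    )
    undet_idx = features.index(undet_feature) if undet_feature in features else None

    meta_rows: list[tuple] = []
    mats: list[np.ndarray] = []
    count_rows: list[tuple] = []
    effect_truth: dict[tuple, np.ndarray] = {}
    n_outliers_total = 0
    undetectable_hits = []

    for line in design.lines:
        for rep in range(1, design.n_replicates + 1):
            plate = f"{line}_R{rep}"
            for w, (comp, conc) in enumerate(_conditions(design)):
                well = f"{plate}_W{w + 1:03d}"
                if comp == VEHICLE:
                    mult, eff = 1.0, np.zeros(p)
                else:
                    spec = by_name[comp]
                    mult = viability_multiplier(spec, conc)
                    eff = emax[comp] * hill(
                        conc, spec.ec50 * ec50_shift[(line, comp)], spec.hill
                    )
                effect_truth.setdefault((line, comp, conc), eff)
                n = int(rng.poisson(design.cells_per_well * mult))
                n_out = int(round(design.outlier_fraction * n))
                count_rows.append(
                    (line, plate, well, comp, conc, rep, design.cells_per_well * mult, n, n_out)
                )
                if n == 0:
                    continue
                g = rng.normal(0.0, design.well_factor_sigma)
                logv = (
                    np.log(baselines[line])[None, :]
                    + eff[None, :]
                    + g * factor_w[None, :]
                    + rng.normal(0.0, design.noise_sigma, (n, p))
                )
                values = np.exp(logv)
                values[:, const_idx] = 1.0
                if n_out:
                    which = rng.choice(n, n_out, replace=False)
                    values[which, area_idx] *= _OUTLIER_AREA_FACTOR
                    n_outliers_total += n_out
                if (
                    undet_idx is not None
                    and comp == undet_name
                    and conc == undet_conc
                ):
                    values[:, undet_idx] = np.nan
                    undetectable_hits.append((comp, conc, undet_feature))
                meta_rows.append((line, plate, well, comp, conc, rep, n))
                mats.append(values)

    meta = pd.DataFrame(
        meta_rows, columns=META_COLUMNS + ["_n"]
    )
    cells = pd.DataFrame(
        np.vstack(mats), columns=features
    )
    meta_rep = meta.loc[meta.index.repeat(meta["_n"])].drop(columns="_n").reset_index(drop=True)
    table = pd.concat([meta_rep, cells], axis=1)

    eff_index = pd.MultiIndex.from_tuples(
        list(effect_truth), names=["line", "compound", "concentration_uM"]
    )
    effect_df = pd.DataFrame(
        np.vstack([effect_truth[k] for k in effect_truth]), index=eff_index, columns=features
    )
    counts = pd.DataFrame(
        count_rows,
        columns=META_COLUMNS + ["expected_cells", "n_cells", "n_planted_outliers"],
    )
    groups, clusters = _labels(design)
    truth = GroundTruth(
        group_labels=groups,
        planted_cluster=clusters,
        selected_concentration=select_exposure(design),
        effect_log_fc=effect_df,
        well_cell_counts=counts,
        n_planted_outliers=n_outliers_total,
        undetectable=tuple(sorted(set(undetectable_hits))),
    )
    return table, truth


def generate_mea_recordings(
    design: StudyDesign, seed: int | None = None
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate long-format MEA event tables for one screen.

    One row per detected beat (plate, well, electrode, beat_index,
    beat_period_s, fpd_ms, amplitude_uV plus condition metadata); electrodes
    without detected beats (quiescent wells, sub-threshold amplitudes) appear
    once with beat_index -1 so electrode totals remain recoverable.
    """
    rng = np.random.default_rng((design.seed if seed is None else seed) + 10_007)
    by_name = {c.name: c for c in design.compounds}

    cols: dict[str, list] = {k: [] for k in [
        "line", "plate", "well", "compound", "concentration_uM", "replicate",
        "electrode", "beat_index", "beat_period_s", "fpd_ms", "amplitude_uV",
    ]}
    truth_rows = []

    base_period = 60.0 / design.base_bpm

    def emit(meta, electrode, beat_idx, periods, fpds, amp):
        k = len(beat_idx)
        cols["line"].append(np.repeat(meta[0], k))
        cols["plate"].append(np.repeat(meta[1], k))
        cols["well"].append(np.repeat(meta[2], k))
        cols["compound"].append(np.repeat(meta[3], k))
        cols["concentration_uM"].append(np.repeat(meta[4], k))
        cols["replicate"].append(np.repeat(meta[5], k))
        cols["electrode"].append(np.repeat(electrode, k))
        cols["beat_index"].append(np.asarray(beat_idx))
        cols["beat_period_s"].append(np.asarray(periods, float))
        cols["fpd_ms"].append(np.asarray(fpds, float))
        cols["amplitude_uV"].append(np.repeat(float(amp), k))

    for line in design.lines:
        for rep in range(1, design.n_replicates + 1):
            plate = f"MEA_{line}_R{rep}"
            for w, (comp, conc) in enumerate(_conditions(design)):
                well = f"{plate}_W{w + 1:03d}"
                meta = (line, plate, well, comp, conc, rep)
                if comp == VEHICLE:
                    h, eph, quiescent = 0.0, None, False
                else:
                    spec = by_name[comp]
                    h = hill(conc, spec.ec50, spec.hill)
                    eph = spec.ephys
                    quiescent = (
                        eph.quiescence_dose is not None
                        and conc >= eph.quiescence_dose * (1 - 1e-12)
                    )
                bpm_shift = eph.bpm_shift * h if eph else 0.0
                cv = design.base_electrode_cv + (eph.bri_inflation * h if eph else 0.0)
                well_period = base_period * np.exp(rng.normal(0, 0.05)) / (1.0 + bpm_shift)
                fpd_mean = (
                    design.base_fpd_ms
                    * (1.0 + (eph.fpd_shift * h if eph else 0.0))
                    * np.exp(rng.normal(0, 0.03))
                )
                truth_rows.append(
                    meta + (cv, 60.0 / well_period, fpd_mean, quiescent)
                )
                for e in range(1, design.n_electrodes + 1):
                    low = rng.random() < design.low_amplitude_fraction
                    amp = (
                        rng.uniform(50, 250)
                        if low
                        else 300.0 + abs(rng.normal(500.0, 150.0))
                    )
                    if quiescent or low:
                        emit(meta, e, [-1], [np.nan], [np.nan], amp)
                        continue
                    e_period = well_period * max(0.2, 1.0 + rng.normal(0.0, cv))
                    nb = max(2, int(design.recording_s / e_period))
                    periods = e_period * (
                        1.0 + rng.normal(0.0, design.beat_noise_cv, nb)
                    )
                    periods = np.clip(periods, 0.05, None)
                    if rng.random() < design.fpd_detect_prob:
                        fpd_e = fpd_mean * (1.0 + rng.normal(0.0, 0.02))
                        fpds = fpd_e * (1.0 + rng.normal(0.0, 0.01, nb))
                    else:
                        fpds = np.full(nb, np.nan)
                    emit(meta, e, np.arange(nb), periods, fpds, amp)

    df = pd.DataFrame({k: np.concatenate(v) for k, v in cols.items()})
    df["beat_index"] = df["beat_index"].astype(int)
    df["replicate"] = df["replicate"].astype(int)
    df["electrode"] = df["electrode"].astype(int)
    df["concentration_uM"] = df["concentration_uM"].astype(float)

    mea_truth = pd.DataFrame(
        truth_rows,
        columns=META_COLUMNS
        + ["planted_electrode_cv", "expected_bpm", "expected_fpd_ms", "quiescent"],
    )
    groups, clusters = _labels(design)
    truth = GroundTruth(
        group_labels=groups,
        planted_cluster=clusters,
        selected_concentration=select_exposure(design),
        mea_wells=mea_truth,
    )
    return df, truth


def generate_study(
    design: StudyDesign,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate imaging and MEA tables for one screen with shared ground truth."""
    cells, truth = generate_cell_features(design)
    mea, mea_truth = generate_mea_recordings(design)
    truth.mea_wells = mea_truth.mea_wells
    return cells, mea, truth
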