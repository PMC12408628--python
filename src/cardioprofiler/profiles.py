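"""Imaging-feature QC chain.

Order of operations (fixed, idempotent on re-run):

1. cytoplasm-area outlier masking per dataset (raw-MAD rule, threshold 3);
2. replicate-level aggregation (feature-wise median over retained cells);
3. vehicle normalization (ratio to the feature-wise median of the matched
   vehicle-control replicate profiles);
4. near-zero-variance feature filtering (frequency ratio > 19 AND unique
   fraction < 10%), applied across the whole normalized dataset;

plus nuclei-count viability summaries (percent change vs vehicle).

The MAD here is the raw median absolute deviation, without the 1.4826
normal-consistency constant: the threshold of 3 is calibrated to the raw MAD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import CYTOPLASM_AREA
from .simulate import META_COLUMNS, VEHICLE

__all__ = [
    "FeatureMask",
    "OutlierMask",
    "aggregate_replicates",
    "build_feature_mask",
    "filter_near_zero_variance",
    "flag_area_outliers",
    "flag_outliers",
    "normalize_to_vehicle",
    "viability_percent_change",
    "viability_summary",
]

MAD_THRESHOLD = 3.0
NZV_FREQ_RATIO = 19.0
NZV_UNIQUE_FRACTION = 0.10

#: Replicate-profile key columns (one profile per replicate well).
PROFILE_KEYS = ["line", "plate", "well", "compound", "concentration_uM", "replicate"]


@dataclass
class OutlierMask:
    """Per-cell outlier flags with the diagnostics that produced them."""

    flags: np.ndarray  # boolean, aligned to the input values
    median: float
    mad: float
    n_flagged: int


@dataclass
class FeatureMask:
    """Per-feature keep/drop status; each feature has exactly one reason."""

    status: pd.Series  # feature → reason in {kept, near_zero_variance, undetectable, zero_vehicle}

    @property
    def kept(self) -> list[str]:
        return list(self.status.index[self.status == "kept"])

    @property
    def dropped(self) -> dict[str, str]:
        bad = self.status[self.status != "kept"]
        return dict(bad)


def flag_outliers(values, threshold: float = MAD_THRESHOLD) -> OutlierMask:
    """Raw-MAD outlier rule on one dataset's cytoplasm areas.

    A value x is flagged iff |x − median(X)| / MAD(X) > threshold, with
    MAD(X) = median(|x − median(X)|). When MAD = 0 nothing is flagged (cells
    are assumed morphologically uniform), and any mathematically undefined
    ratio (0/0) is treated as a non-outlier. NaN values are never flagged.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("flag_outliers: empty value vector")
    finite = np.isfinite(x)
    med = float(np.median(x[finite])) if finite.any() else float("nan")
    dev = np.abs(x - med)
    mad = float(np.median(dev[finite])) if finite.any() else float("nan")
    if not np.isfinite(mad) or mad == 0.0:
        flags = np.zeros_like(x, dtype=bool)
    else:
        with np.errstate(invalid="ignore"):
            flags = (dev / mad) > threshold
        flags &= finite
    return OutlierMask(flags=flags, median=med, mad=mad, n_flagged=int(flags.sum()))


def flag_area_outliers(
    cells: pd.DataFrame,
    area_column: str = CYTOPLASM_AREA,
    dataset_columns: tuple[str, ...] = ("line",),
    threshold: float = MAD_THRESHOLD,
) -> pd.Series:
    """Apply the MAD rule per dataset (cell line/batch) on cytoplasmic area."""
    if area_column not in cells.columns:
        raise ValueError(f"missing area column {area_column!r}")
    out = pd.Series(False, index=cells.index)
    for _, idx in cells.groupby(list(dataset_columns), sort=False).groups.items():
        mask = flag_outliers(cells.loc[idx, area_column], threshold)
        out.loc[idx] = mask.flags
    return out


def aggregate_replicates(
    cells: pd.DataFrame,
    outlier_flags: pd.Series | None = None,
    feature_columns: list[str] | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Median-aggregate retained cells to one profile per replicate well.

    Missing (undetectable) values are ignored within each median; features
    that are missing in *all* cells of some condition are returned as
    undetectable. Replicate wells with zero retained cells are dropped.
    Returns (profiles, undetectable_features); profiles carry the replicate
    keys plus an ``n_cells`` column, then one median per feature.
    """
    if feature_columns is None:
        feature_columns = [c for c in cells.columns if c not in META_COLUMNS]
    kept = cells if outlier_flags is None else cells.loc[~outlier_flags.astype(bool)]
    if kept.empty:
        raise ValueError("no cells retained after outlier filtering")
    n_wells_in = cells.groupby(PROFILE_KEYS, sort=False).ngroups
    grouped = kept.groupby(PROFILE_KEYS, sort=True)
    if grouped.ngroups < n_wells_in:
        warnings.warn(
            f"{n_wells_in - grouped.ngroups} replicate well(s) dropped: "
            "no cells retained after outlier filtering",
            stacklevel=2,
        )
    medians = grouped[feature_columns].median()
    n_cells = grouped.size().rename("n_cells")

    # a feature undetectable in at least one condition (all-NaN there)
    cond = kept.groupby(["compound", "concentration_uM"], sort=True)[feature_columns]
    all_missing = cond.count() == 0
    undetectable = sorted(all_missing.columns[all_missing.any(axis=0)])

    profiles = pd.concat([n_cells, medians], axis=1).reset_index()
    return profiles, undetectable


def normalize_to_vehicle(
    profiles: pd.DataFrame,
    stratum: tuple[str, ...] = ("line", "plate"),
    vehicle_label: str = VEHICLE,
    feature_columns: list[str] | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Express each replicate profile as fold change over its vehicle control.

    The reference is the feature-wise median across the vehicle-control
    replicate profiles of the same stratum (default: same line and plate).
    Features whose vehicle reference is 0 in any stratum are reported as
    zero_vehicle (their normalized values are set to NaN, not infinity).
    Returns (normalized profiles, zero_vehicle_features).
    """
    if feature_columns is None:
        feature_columns = [
            c for c in profiles.columns if c not in PROFILE_KEYS + ["n_cells"]
        ]
    is_vehicle = profiles["compound"] == vehicle_label
    out = profiles.copy()
    zero_vehicle: set[str] = set()
    for key, idx in profiles.groupby(list(stratum), sort=False).groups.items():
        sub = profiles.loc[idx]
        veh = sub[sub["compound"] == vehicle_label]
        if veh.empty:
            raise ValueError(f"stratum {dict(zip(stratum, np.atleast_1d(key)))} has no vehicle control")
        ref = veh[feature_columns].median(axis=0)
        zero = ref.index[(ref == 0) | ~np.isfinite(ref)]
        zero_vehicle.update(zero)
        ref = ref.replace(0, np.nan)
        out.loc[idx, feature_columns] = sub[feature_columns].div(ref, axis=1).to_numpy()
    out.loc[:, "is_vehicle"] = is_vehicle
    return out, sorted(zero_vehicle)


def _round_sig(x: np.ndarray, digits: int = 8) -> np.ndarray:
    """Round to `digits` significant digits (continuous-value uniqueness)."""
    x = np.asarray(x, dtype=float)
    out = x.copy()
    nz = np.isfinite(x) & (x != 0)
    mag = np.floor(np.log10(np.abs(x[nz])))
    out[nz] = np.round(x[nz] / 10.0 ** mag, digits - 1) * 10.0 ** mag
    return out


def filter_near_zero_variance(
    matrix: pd.DataFrame,
    freq_ratio: float = NZV_FREQ_RATIO,
    unique_fraction: float = NZV_UNIQUE_FRACTION,
) -> pd.Series:
    """Near-zero-variance decision per feature over the whole dataset.

    A feature is dropped iff (count of most common value / count of second
    most common value) > freq_ratio AND (number of distinct values / number
    of rows) < unique_fraction; constant features (no second value) are
    always dropped. Values are compared after rounding to 8 significant
    digits. Returns a boolean Series (True = drop).
    """
    if len(matrix) < 2:
        raise ValueError("need at least two rows to assess variance")
    drop = {}
    n = len(matrix)
    for col in matrix.columns:
        vals = _round_sig(matrix[col].to_numpy(float))
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            drop[col] = True
            continue
        _, counts = np.unique(vals, return_counts=True)
        counts = np.sort(counts)[::-1]
        if counts.size == 1:
            drop[col] = True
            continue
        ratio = counts[0] / counts[1]
        uniq = counts.size / n
        drop[col] = bool(ratio > freq_ratio and uniq < unique_fraction)
    return pd.Series(drop, name="near_zero_variance")


def build_feature_mask(
    features: list[str],
    nzv_drop: pd.Series | None = None,
    undetectable: list[str] | None = None,
    zero_vehicle: list[str] | None = None,
) -> FeatureMask:
    """Combine QC outcomes into one status per feature.

    Precedence when several reasons apply: undetectable > zero_vehicle >
    near_zero_variance > kept.
    """
    status = pd.Series("kept", index=pd.Index(features, name="feature"))
    if nzv_drop is not None:
        status[nzv_drop.index[nzv_drop.astype(bool)]] = "near_zero_variance"
    for f in zero_vehicle or []:
        status[f] = "zero_vehicle"
    for f in undetectable or []:
        status[f] = "undetectable"
    return FeatureMask(status=status)


def viability_percent_change(treated_counts, vehicle_counts) -> float:
    """Percent change in nuclei count: 100 × (mean treated − mean vehicle)/mean vehicle."""
    t = np.asarray(treated_counts, float)
    v = np.asarray(vehicle_counts, float)
    if t.size == 0 or v.size == 0:
        raise ValueError("need at least one well per arm")
    mv = float(np.mean(v))
    if mv == 0:
        raise ValueError("vehicle mean nuclei count is zero")
    return 100.0 * (float(np.mean(t)) - mv) / mv


def viability_summary(
    cells: pd.DataFrame, vehicle_label: str = VEHICLE
) -> pd.DataFrame:
    """Nuclei-count viability per condition: percent change vs vehicle wells.

    Uses per-well cell counts as the nuclei-count proxy, compared within the
    same cell line against that line's vehicle wells.
    """
    counts = (
        cells.groupby(["line", "compound", "concentration_uM", "plate", "well"], sort=True)
        .size()
        .rename("n_cells")
        .reset_index()
    )
    rows = []
    for line, ldf in counts.groupby("line", sort=True):
        veh = ldf.loc[ldf["compound"] == vehicle_label, "n_cells"]
        if veh.empty:
            raise ValueError(f"line {line!r} has no vehicle wells")
        for (comp, conc), cdf in ldf.groupby(["compound", "concentration_uM"], sort=True):
            if comp == vehicle_label:
                continue
            rows.append(
                {
                    "line": line,
                    "compound": comp,
                    "concentration_uM": conc,
                    "n_wells": len(cdf),
                    "pct_change": viability_percent_change(cdf["n_cells"], veh),
                }
            )
    return pd.DataFrame(rows)
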