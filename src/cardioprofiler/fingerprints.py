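"""Compound morphological fingerprints and unsupervised clustering.

For each compound and cell line, a PCA is run on the line-level aggregated,
vehicle-normalized profiles of that compound's pooled concentration series
plus the vehicle condition. The elementwise absolute values of the unit-norm
PC1 loading vector summarize which features drive the compound's primary axis
of variation; averaging these |loading| vectors across lines gives the
compound's fingerprint. Fingerprints are clustered by k-means (k = 4 by
default, or silhouette-selected over a range).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .simulate import VEHICLE

__all__ = [
    "ClusterAssignment",
    "cluster_fingerprints",
    "compound_fingerprints",
    "line_level_profiles",
    "pc1_loadings",
    "select_k_silhouette",
]

DEFAULT_K = 4
KMEANS_RESTARTS = 50


def pc1_loadings(X, scale: bool = False) -> tuple[np.ndarray, float]:
    """Absolute PC1 loadings and PC1 explained-variance fraction.

    Columns are centered and the first principal axis is taken from the
    singular value decomposition of the centered matrix — numerically stable
    when observations are far fewer than features. Vehicle-normalized fold
    changes are already commensurate across features, so no per-feature
    standardization is applied by default: unit-variance scaling would erase
    the effect-size contrast that distinguishes a compound's affected
    organelles from incidentally dose-correlated noise (set ``scale=True``
    to standardize anyway). Requires ≥ 2 observations, and with ``scale``
    no zero-variance column (near-zero-variance filtering must precede).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("pc1_loadings: need a 2-D matrix with ≥ 2 observations")
    if not np.all(np.isfinite(X)):
        raise ValueError("pc1_loadings: non-finite values in input")
    Xc = X - X.mean(axis=0)
    if scale:
        sd = Xc.std(axis=0, ddof=1)
        if np.any(sd == 0):
            bad = int(np.sum(sd == 0))
            raise ValueError(
                f"pc1_loadings: {bad} zero-variance feature(s) remain; "
                "apply the near-zero-variance filter first"
            )
        Xc = Xc / sd
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    loadings = vt[0]
    evr = float(s[0] ** 2 / np.sum(s ** 2))
    return np.abs(loadings / np.linalg.norm(loadings)), evr


def line_level_profiles(
    normalized: pd.DataFrame, feature_columns: list[str]
) -> pd.DataFrame:
    """One profile per line × condition: median across replicate wells."""
    return (
        normalized.groupby(["line", "compound", "concentration_uM"], sort=True)[
            feature_columns
        ]
        .median()
        .reset_index()
    )


def compound_fingerprints(
    normalized: pd.DataFrame,
    feature_columns: list[str],
    vehicle_label: str = VEHICLE,
    scale: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean |PC1 loading| fingerprints across lines, per compound.

    All concentrations of a compound are pooled with the vehicle condition
    into a single PCA input per line (capturing perturbation patterns at any
    exposure level), and per-line |loading| vectors are averaged elementwise.
    Returns (fingerprints: compounds × features, evr: per compound × line).
    """
    site = line_level_profiles(normalized, feature_columns)
    compounds = sorted(c for c in site["compound"].unique() if c != vehicle_label)
    lines = sorted(site["line"].unique())
    fp_rows, evr_rows = [], []
    for comp in compounds:
        per_line = []
        for line in lines:
            sub = site[
                (site["line"] == line)
                & site["compound"].isin([comp, vehicle_label])
            ]
            if len(sub) < 3:
                raise ValueError(
                    f"{comp}/{line}: need ≥ 3 pooled observations, got {len(sub)}"
                )
            loadings, evr = pc1_loadings(sub[feature_columns].to_numpy(), scale=scale)
            per_line.append(loadings)
            evr_rows.append({"compound": comp, "line": line, "explained_variance_pc1": evr})
        fp_rows.append(np.mean(per_line, axis=0))
    fingerprints = pd.DataFrame(
        fp_rows, index=pd.Index(compounds, name="compound"), columns=feature_columns
    )
    return fingerprints, pd.DataFrame(evr_rows)


@dataclass
class ClusterAssignment:
    """K-means result on the fingerprint matrix."""

    labels: dict[str, int]  # compound → cluster id in 1..k
    k: int
    inertia: float
    seed: int
    n_restarts: int
    silhouette_by_k: dict[int, float] = field(default_factory=dict)

    def as_series(self) -> pd.Series:
        return pd.Series(self.labels, name="cluster")


def cluster_fingerprints(
    fingerprints: pd.DataFrame,
    k: int = DEFAULT_K,
    seed: int = 0,
    n_restarts: int = KMEANS_RESTARTS,
) -> ClusterAssignment:
    """Euclidean k-means (k-means++ init, `n_restarts` restarts) on fingerprints."""
    n = len(fingerprints)
    if not 2 <= k <= n:
        raise ValueError(f"k must lie in [2, {n}], got {k}")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(fingerprints.to_numpy())
    return ClusterAssignment(
        labels={c: int(l) + 1 for c, l in zip(fingerprints.index, labels)},
        k=k,
        inertia=float(km.inertia_),
        seed=seed,
        n_restarts=n_restarts,
    )


def select_k_silhouette(
    fingerprints: pd.DataFrame,
    k_range=range(2, 9),
    seed: int = 0,
    n_restarts: int = KMEANS_RESTARTS,
) -> ClusterAssignment:
    """Pick k maximizing the mean silhouette, then cluster at that k."""
    X = fingerprints.to_numpy()
    scores: dict[int, float] = {}
    for k in k_range:
        if k >= len(fingerprints):
            continue
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
        labels = km.fit_predict(X)
        scores[k] = float(silhouette_score(X, labels))
    best_k = max(scores, key=scores.get)
    out = cluster_fingerprints(fingerprints, k=best_k, seed=seed, n_restarts=n_restarts)
    out.silhouette_by_k = scores
    return out


def plot_fingerprint_heatmap(fingerprints: pd.DataFrame, assignment=None, path=None):
    """Basic fingerprint heatmap (compounds × features); optional file export."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = fingerprints.index
    if assignment is not None:
        order = sorted(fingerprints.index, key=lambda c: assignment.labels.get(c, 0))
    fig, ax = plt.subplots(figsize=(10, 4))
    im = ax.imshow(fingerprints.loc[order].to_numpy(), aspect="auto", cmap="viridis")
    ax.set_yticks(range(len(order)), order, fontsize=6)
    ax.set_xlabel("feature")
    fig.colorbar(im, ax=ax, label="|PC1 loading| (mean over lines)")
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
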