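"""Sparse partial least squares discriminant analysis (sPLS-DA) with
block-weighted fusion of morphology and electrophysiology features.

Model
-----
Given centered/scaled predictors X (n × p) and the centered one-hot class
indicator Y (n × G), each component h extracts

    w_h = dominant left singular vector of X_hᵀ Y_h   (cross-covariance)
    u_h = soft_threshold_select(w_h, keepX_h)          (lasso-like sparsity)
    t_h = X_h u_h                                      (score)

followed by regression-mode deflation of both X_h and Y_h on t_h, which makes
the scores mutually orthogonal. Samples are assigned to the nearest class
centroid (Euclidean) in score space; compounds by majority vote over their
replicate wells.

Usage follows the Model → fit() → Results convention::

    model = SparsePLSDA(X, labels, n_components=2, keep_x=50)
    res = model.fit()
    print(res.summary())
    pred = res.predict(X_new)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ClassificationResult",
    "SparsePLSDA",
    "SparsePLSDAResults",
    "block_combine",
    "one_hot",
    "soft_threshold_select",
]


def one_hot(labels) -> tuple[np.ndarray, list[str]]:
    """Class indicator matrix (one 1 per row; columns = sorted class names)."""
    labels = list(labels)
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValueError("discrimination undefined with a single class")
    Y = np.zeros((len(labels), len(classes)))
    pos = {c: j for j, c in enumerate(classes)}
    for i, lab in enumerate(labels):
        Y[i, pos[lab]] = 1.0
    return Y, classes


def soft_threshold_select(w, keep: int) -> np.ndarray:
    """Soft-threshold w to at most `keep` nonzeros, then renormalize.

    λ is the (keep+1)-th largest |w| (0 when keep = len(w)); entries shrink
    by λ toward zero and vanish at or below it. Ties at λ are broken by
    first-index priority so that exactly ≤ keep entries survive.
    """
    w = np.asarray(w, dtype=float)
    if w.ndim != 1:
        raise ValueError("w must be a vector")
    if not 1 <= keep <= w.size:
        raise ValueError(f"keep must lie in [1, {w.size}]")
    if not np.any(w != 0):
        raise ValueError("all-zero weight vector")
    a = np.abs(w)
    lam = 0.0 if keep == w.size else float(np.sort(a)[::-1][keep])
    u = np.sign(w) * np.maximum(a - lam, 0.0)
    nnz = np.flatnonzero(u)
    if nnz.size > keep:  # ties exactly at λ: keep the first `keep` by index
        u[nnz[keep:]] = 0.0
    norm = np.linalg.norm(u)
    if norm == 0.0:
        # degenerate tie pattern: fall back to the single largest entry
        u = np.zeros_like(w)
        j = int(np.argmax(a))
        u[j] = np.sign(w[j])
        norm = 1.0
    return u / norm


def block_combine(
    morph: pd.DataFrame | np.ndarray,
    ephys: pd.DataFrame | np.ndarray,
    weights: tuple[float, float] = (1.0, 1.0),
) -> pd.DataFrame:
    """Concatenate two feature blocks with per-datatype weighting.

    Each block is standardized column-wise, then scaled by w_b / √p_b where
    p_b is the block's feature count, so that at equal weights each block
    contributes equal total variance regardless of dimensionality.
    """
    m = pd.DataFrame(morph)
    e = pd.DataFrame(ephys)
    if len(m) != len(e):
        raise ValueError(f"row mismatch between blocks: {len(m)} vs {len(e)}")

    def prep(df: pd.DataFrame, w: float, tag: str) -> pd.DataFrame:
        X = df.to_numpy(float)
        mu = np.nanmean(X, axis=0)
        sd = np.nanstd(X, axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Z = (X - mu) / sd * (w / np.sqrt(X.shape[1]))
        return pd.DataFrame(Z, index=df.index, columns=[f"{tag}:{c}" for c in df.columns])

    return pd.concat(
        [prep(m, weights[0], "morph"), prep(e.set_index(m.index), weights[1], "ephys")],
        axis=1,
    )


@dataclass
class ClassificationResult:
    """Predictions of an sPLS-DA model on one sample set."""

    sample_labels: pd.Series  # per-sample predicted group
    compound_labels: pd.Series | None  # per-compound majority vote
    confusion: pd.DataFrame | None
    accuracy_pct: float | None  # per-sample accuracy
    compound_accuracy_pct: float | None


class SparsePLSDA:
    """Sparse PLS-DA model specification.

    Parameters
    ----------
    X : array-like or DataFrame, samples × features
    labels : per-sample class labels (≥ 2 classes)
    n_components : number of latent components (default 2)
    keep_x : features retained per component; an int applies to all
        components, a sequence gives one value per component. Defaults to
        min(50, p).
    scale : center/scale X columns to unit variance before fitting.
    """

    def __init__(self, X, labels, n_components: int = 2, keep_x=None, scale: bool = True):
        self.X = pd.DataFrame(X)
        self.labels = pd.Series(list(labels), index=self.X.index, name="group")
        if len(self.X) != len(self.labels):
            raise ValueError("X and labels length mismatch")
        if len(self.X) < n_components + 1:
            raise ValueError("need at least n_components + 1 samples")
        if not np.all(np.isfinite(self.X.to_numpy(float))):
            raise ValueError("X contains non-finite values")
        self.n_components = n_components
        p = self.X.shape[1]
        if keep_x is None:
            keep_x = min(50, p)
        if np.isscalar(keep_x):
            keep_x = [int(keep_x)] * n_components
        self.keep_x = [min(int(k), p) for k in keep_x]
        if len(self.keep_x) != n_components:
            raise ValueError("keep_x must give one value per component")
        self.scale = scale

    @classmethod
    def from_dataframe(
        cls, data: pd.DataFrame, label_column: str, feature_columns=None, **kwargs
    ) -> "SparsePLSDA":
        if feature_columns is None:
            feature_columns = [
                c for c in data.columns
                if c != label_column and pd.api.types.is_numeric_dtype(data[c])
            ]
        return cls(data[feature_columns], data[label_column], **kwargs)

    def fit(self) -> "SparsePLSDAResults":
        X = self.X.to_numpy(float)
        self._x_mean = X.mean(axis=0)
        self._x_scale = X.std(axis=0, ddof=1) if self.scale else np.ones(X.shape[1])
        self._x_scale[self._x_scale == 0] = 1.0
        Xh = (X - self._x_mean) / self._x_scale
        Y, classes = one_hot(self.labels)
        Yh = Y - Y.mean(axis=0)

        U, T, P = [], [], []
        for h in range(self.n_components):
            M = Xh.T @ Yh
            if np.linalg.norm(M) < 1e-12:
                break  # zero cross-covariance: no further discriminative direction
            left, _, _ = np.linalg.svd(M, full_matrices=False)
            w = left[:, 0]
            u = soft_threshold_select(w, self.keep_x[h])
            t = Xh @ u
            tt = float(t @ t)
            if tt < 1e-12:
                break
            p_load = Xh.T @ t / tt
            q_load = Yh.T @ t / tt
            Xh = Xh - np.outer(t, p_load)
            Yh = Yh - np.outer(t, q_load)
            U.append(u)
            T.append(t)
            P.append(p_load)

        if not U:
            raise ValueError("degenerate problem: no component could be extracted")
        scores = np.column_stack(T)
        centroids = {
            c: scores[np.asarray(self.labels) == c].mean(axis=0) for c in classes
        }
        return SparsePLSDAResults(
            model=self,
            classes=classes,
            x_weights=np.column_stack(U),
            x_loadings=np.column_stack(P),
            scores=scores,
            centroids=centroids,
        )


@dataclass
class SparsePLSDAResults:
    """Fitted sPLS-DA: weights, scores, centroids, prediction and summary."""

    model: SparsePLSDA
    classes: list[str]
    x_weights: np.ndarray  # p × H sparse unit-norm weight vectors
    x_loadings: np.ndarray  # p × H deflation loadings
    scores: np.ndarray  # n × H training scores
    centroids: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_components_(self) -> int:
        return self.x_weights.shape[1]

    def transform(self, X_new) -> np.ndarray:
        """Project new samples into score space with matching deflation."""
        Xn = pd.DataFrame(X_new)
        if list(Xn.columns) != list(self.model.X.columns):
            if set(Xn.columns) == set(self.model.X.columns):
                Xn = Xn[self.model.X.columns]
            else:
                raise ValueError("feature mismatch with the training feature set")
        Xh = (Xn.to_numpy(float) - self.model._x_mean) / self.model._x_scale
        T = []
        for h in range(self.n_components_):
            t = Xh @ self.x_weights[:, h]
            Xh = Xh - np.outer(t, self.x_loadings[:, h])
            T.append(t)
        return np.column_stack(T)

    def predict(
        self,
        X_new,
        compounds=None,
        true_labels: pd.Series | dict | None = None,
    ) -> ClassificationResult:
        """Nearest-centroid assignment; optional per-compound majority vote.

        `compounds` gives each sample's compound identity; `true_labels`
        (compound → group, or per-sample Series) enables accuracy and the
        confusion table.
        """
        Xn = pd.DataFrame(X_new)
        if Xn.empty:
            raise ValueError("empty test set")
        T = self.transform(Xn)
        cmat = np.vstack([self.centroids[c] for c in self.classes])
        d2 = ((T[:, None, :] - cmat[None, :, :]) ** 2).sum(axis=2)
        sample_pred = pd.Series(
            [self.classes[j] for j in np.argmin(d2, axis=1)],
            index=Xn.index,
            name="predicted",
        )

        compound_pred = None
        if compounds is not None:
            comp = pd.Series(list(compounds), index=Xn.index, name="compound")
            compound_pred = sample_pred.groupby(comp).agg(
                lambda s: s.value_counts().sort_index().idxmax()
            )

        confusion = acc = comp_acc = None
        if true_labels is not None:
            if isinstance(true_labels, dict):
                truth_by_compound = pd.Series(true_labels)
                if compounds is None:
                    raise ValueError("compound identities required with a compound→group map")
                sample_truth = pd.Series(list(compounds), index=Xn.index).map(truth_by_compound)
            else:
                sample_truth = pd.Series(list(true_labels), index=Xn.index)
                truth_by_compound = None
            acc = 100.0 * float((sample_pred == sample_truth).mean())
            confusion = pd.crosstab(
                sample_truth.rename("true"), sample_pred.rename("predicted"), dropna=False
            )
            if compound_pred is not None:
                if truth_by_compound is None:
                    truth_by_compound = sample_truth.groupby(
                        pd.Series(list(compounds), index=Xn.index)
                    ).first()
                aligned = truth_by_compound.reindex(compound_pred.index)
                comp_acc = 100.0 * float((compound_pred == aligned).mean())
        return ClassificationResult(
            sample_labels=sample_pred,
            compound_labels=compound_pred,
            confusion=confusion,
            accuracy_pct=acc,
            compound_accuracy_pct=comp_acc,
        )

    def summary(self) -> str:
        """Plain-text model summary."""
        lines = [
            "Sparse PLS-DA Results",
            "=" * 54,
            f"samples: {len(self.model.X):>5}    features: {self.model.X.shape[1]}",
            f"components: {self.n_components_}    keepX: {self.model.keep_x}",
            f"classes: {', '.join(self.classes)}",
            "-" * 54,
        ]
        for h in range(self.n_components_):
            nnz = int(np.sum(self.x_weights[:, h] != 0))
            var = float(np.var(self.scores[:, h], ddof=1))
            lines.append(f"comp {h + 1}: {nnz:>4} active features, score variance {var:9.4f}")
        lines.append("-" * 54)
        for c in self.classes:
            coord = ", ".join(f"{v: .3f}" for v in self.centroids[c])
            lines.append(f"centroid[{c}]: ({coord})")
        return "\n".join(lines)
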