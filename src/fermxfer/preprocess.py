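"""Data augmentation and dimensionality reduction.

Two standard preparation steps for scarce batch-process data:

* linear-interpolation augmentation — insert ``g`` equally spaced points on
  the straight segment between every pair of adjacent samples, per column,
  growing a series of ``n`` rows to ``n + (n - 1) * g`` rows;
* principal component analysis with component selection by cumulative
  explained variance.

PCA is computed from the eigen-decomposition of the sample covariance
matrix (unbiased ``n - 1`` divisor).  Features are expected to be z-scored
before the fit when their units are heterogeneous; :class:`FeatureReducer`
bundles the standardizer, the PCA and the retained-component choice so the
projection fitted on source batches can be reused verbatim on target data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from sklearn.preprocessing import StandardScaler

from .synthetic import Batch

__all__ = [
    "interpolate_augment",
    "augment_batch",
    "PCAModel",
    "fit_pca",
    "transform_pca",
    "inverse_transform_pca",
    "select_components",
    "FeatureReducer",
]


def interpolate_augment(series: np.ndarray, points_per_gap: int) -> np.ndarray:
    """Insert ``points_per_gap`` linearly interpolated rows in every gap.

    Inserted rows sit at equal fractions of each gap (1/3 and 2/3 for the
    default two points per gap); original rows are preserved unchanged at
    their ordered positions.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim == 1:
        series = series[:, None]
    n = series.shape[0]
    if n < 2:
        raise ValueError("need at least 2 rows to interpolate")
    g = int(points_per_gap)
    if g < 1:
        raise ValueError("points_per_gap must be >= 1")
    if not np.all(np.isfinite(series)):
        raise ValueError("series contains non-finite values")

    step = g + 1
    out = np.empty(((n - 1) * step + 1, series.shape[1]), dtype=float)
    out[::step] = series
    a = series[:-1]
    b = series[1:]
    for j in range(1, step):
        frac = j / step
        out[j::step][: n - 1] = a + (b - a) * frac
    return out


def augment_batch(batch: Batch, points_per_gap: int) -> Batch:
    """Augment every column of a batch (time, auxiliaries and targets alike).

    Inserted samples take the phase label of their left-hand original
    neighbour (labels are generator ground truth, kept only for diagnostics).
    """
    stacked = np.column_stack([batch.time_h, batch.X_aux, batch.Y_target])
    aug = interpolate_augment(stacked, points_per_gap)
    n_aux = batch.X_aux.shape[1]
    phase = None
    if batch.phase_label is not None:
        reps = np.repeat(batch.phase_label[:-1], points_per_gap + 1)
        phase = np.concatenate([reps, batch.phase_label[-1:]])
    return Batch(
        batch_id=f"{batch.batch_id}_aug",
        time_h=aug[:, 0],
        X_aux=aug[:, 1:1 + n_aux],
        Y_target=aug[:, 1 + n_aux:],
        phase_label=phase,
    )


@dataclass
class PCAModel:
    """Eigen-decomposition of a sample covariance matrix.

    ``components`` holds all ``p`` eigenvectors as columns, sorted by
    descending eigenvalue; ``explained_variance_ratio`` sums to one over
    the full decomposition (all-zero for rank-0 input).
    """

    mean_vector: np.ndarray
    components: np.ndarray
    eigenvalues: np.ndarray
    explained_variance_ratio: np.ndarray
    n_components_retained: int

    @property
    def n_features(self) -> int:
        return self.components.shape[0]

    def to_json(self) -> str:
        return json.dumps({
            "mean_vector": self.mean_vector.tolist(),
            "components": self.components.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "explained_variance_ratio": self.explained_variance_ratio.tolist(),
            "n_components_retained": self.n_components_retained,
        })

    @classmethod
    def from_json(cls, text: str) -> "PCAModel":
        d = json.loads(text)
        return cls(
            mean_vector=np.array(d["mean_vector"]),
            components=np.array(d["components"]),
            eigenvalues=np.array(d["eigenvalues"]),
            explained_variance_ratio=np.array(d["explained_variance_ratio"]),
            n_components_retained=int(d["n_components_retained"]),
        )


def fit_pca(X: np.ndarray) -> PCAModel:
    """Fit PCA by eigen-decomposing the (unbiased) sample covariance."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 1:
        raise ValueError("X must be a 2-D matrix with >= 2 samples")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite values")
    mean = X.mean(axis=0)
    Xc = X - mean
    cov = Xc.T @ Xc / (X.shape[0] - 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    # deterministic sign: largest-magnitude loading of each component positive
    for j in range(eigvecs.shape[1]):
        k = np.argmax(np.abs(eigvecs[:, j]))
        if eigvecs[k, j] < 0:
            eigvecs[:, j] = -eigvecs[:, j]
    total = eigvals.sum()
    ratio = eigvals / total if total > 0 else np.zeros_like(eigvals)
    return PCAModel(
        mean_vector=mean,
        components=eigvecs,
        eigenvalues=eigvals,
        explained_variance_ratio=ratio,
        n_components_retained=X.shape[1],
    )


def transform_pca(model: PCAModel, X: np.ndarray, k: int | None = None
                  ) -> np.ndarray:
    """Project centered ``X`` onto the first ``k`` principal components."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    p = model.n_features
    if X.shape[1] != p:
        raise ValueError(f"X has {X.shape[1]} features, model expects {p}")
    k = model.n_components_retained if k is None else int(k)
    if not 1 <= k <= p:
        raise ValueError(f"k must be in [1, {p}]")
    return (X - model.mean_vector) @ model.components[:, :k]


def inverse_transform_pca(model: PCAModel, scores: np.ndarray) -> np.ndarray:
    scores = np.asarray(scores, dtype=float)
    k = scores.shape[1]
    return scores @ model.components[:, :k].T + model.mean_vector


def select_components(model: PCAModel, cum_var_threshold: float) -> int:
    """Smallest component count whose cumulative variance ratio meets the threshold."""
    if not 0 < cum_var_threshold <= 1:
        raise ValueError("cum_var_threshold must be in (0, 1]")
    cum = np.cumsum(model.explained_variance_ratio)
    if cum[-1] <= 0:  # rank-0 model: no variance anywhere
        return 1
    hits = np.nonzero(cum >= cum_var_threshold - 1e-12)[0]
    return int(hits[0]) + 1


class FeatureReducer:
    """Standardize-then-PCA front end fitted on source data, reused on targets.

    Parameters
    ----------
    cum_var_threshold : float
        Cumulative explained-variance level used to pick the number of
        retained components (default 0.99).
    """

    def __init__(self, cum_var_threshold: float = 0.99):
        self.cum_var_threshold = cum_var_threshold
        self.scaler: StandardScaler | None = None
        self.pca: PCAModel | None = None
        self.n_components: int | None = None

    def fit(self, X: np.ndarray) -> "FeatureReducer":
        self.scaler = StandardScaler().fit(X)
        Z = self.scaler.transform(X)
        self.pca = fit_pca(Z)
        self.n_components = select_components(self.pca, self.cum_var_threshold)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.pca is None:
            raise RuntimeError("FeatureReducer is not fitted")
        return transform_pca(self.pca, self.scaler.transform(X), self.n_components)

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)

    def to_json(self) -> str:
        return json.dumps({
            "cum_var_threshold": self.cum_var_threshold,
            "scaler_mean": self.scaler.mean_.tolist(),
            "scaler_scale": self.scaler.scale_.tolist(),
            "pca": json.loads(self.pca.to_json()),
            "n_components": self.n_components,
        })

    @classmethod
    def from_json(cls, text: str) -> "FeatureReducer":
        d = json.loads(text)
        r = cls(d["cum_var_threshold"])
        r.scaler = StandardScaler()
        r.scaler.mean_ = np.array(d["scaler_mean"])
        r.scaler.scale_ = np.array(d["scaler_scale"])
        r.scaler.var_ = r.scaler.scale_ ** 2
        r.scaler.n_features_in_ = len(r.scaler.mean_)
        r.pca = PCAModel.from_json(json.dumps(d["pca"]))
        r.n_components = d["n_components"]
        return r
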