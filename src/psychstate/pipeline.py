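"""Feature normalization, selection and dimension reduction.

The pipeline mirrors the preprocessing chain of the prediction method:

1. min-max normalization of every feature to [0, 1];
2. mRMR feature selection (greedy maximal-relevance, minimal-redundancy on
   binned mutual information; zero-MI features are discarded outright);
3. PCA for variance-based dimension reduction;
4. generalized discriminant analysis (kernel Fisher discriminant) to
   concentrate same-state observations in a low-dimensional space.

:class:`PipelineModel` bundles the fitted stages so the identical
transform can be replayed on held-out data and serialized to JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.spatial.distance import pdist, cdist
from sklearn.decomposition import PCA

__all__ = [
    "minmax_normalize",
    "mutual_information",
    "mrmr_select",
    "pca_fit_transform",
    "GDAModel",
    "gda_fit",
    "gda_fit_transform",
    "fisher_ratio",
    "PipelineModel",
]

DEFAULT_N_BINS = 10
DEFAULT_GDA_EPS = 1e-6


# ---------------------------------------------------------------------------
# normalization


def minmax_normalize(
    matrix: pd.DataFrame, bounds: dict[str, tuple[float, float]] | None = None
) -> tuple[pd.DataFrame, dict[str, tuple[float, float]]]:
    """Map each column to [0, 1] by (x - min) / (max - min).

    Constant columns map to 0.  When ``bounds`` (from a previous fit) are
    supplied they are applied instead of the data's own extremes and the
    result is clipped into [0, 1].  A column with no observed value at
    all is an error, named explicitly.
    """
    if len(matrix) < 1:
        raise ValueError("need at least one row")
    out = {}
    fitted: dict[str, tuple[float, float]] = {}
    for col in matrix.columns:
        x = matrix[col].to_numpy(dtype=float)
        if bounds is None:
            finite = x[np.isfinite(x)]
            if finite.size == 0:
                raise ValueError(f"column {col!r} has no observed values")
            lo, hi = float(finite.min()), float(finite.max())
        else:
            lo, hi = bounds[col]
        fitted[col] = (lo, hi)
        if hi > lo:
            out[col] = np.clip((x - lo) / (hi - lo), 0.0, 1.0)
        else:
            out[col] = np.zeros_like(x)
    return pd.DataFrame(out, index=matrix.index), fitted


# ---------------------------------------------------------------------------
# mutual information and mRMR


def _discretize(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-width bins over [0, 1] (values clipped); assumes normalized input."""
    return np.clip((np.clip(x, 0.0, 1.0) * n_bins).astype(int), 0, n_bins - 1)


def _mi_discrete(a: np.ndarray, b: np.ndarray) -> float:
    """MI in bits between two integer-coded variables."""
    joint = pd.crosstab(pd.Series(a), pd.Series(b)).to_numpy(dtype=float)
    joint /= joint.sum()
    pa = joint.sum(axis=1, keepdims=True)
    pb = joint.sum(axis=0, keepdims=True)
    mask = joint > 0
    return float(np.sum(joint[mask] * np.log2(joint[mask] / (pa @ pb)[mask])))


def mutual_information(
    feature: np.ndarray, labels: np.ndarray, n_bins: int = DEFAULT_N_BINS
) -> float:
    """Mutual information (bits) between a binned feature and class labels."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least two distinct labels")
    x = np.asarray(feature, dtype=float)
    keep = np.isfinite(x)
    codes = pd.factorize(labels[keep])[0]
    return _mi_discrete(_discretize(x[keep], n_bins), codes)


def mrmr_select(
    matrix: pd.DataFrame,
    labels: np.ndarray,
    k: int,
    n_bins: int = DEFAULT_N_BINS,
) -> list[tuple[str, float]]:
    """Greedy mRMR (difference criterion) over normalized features.

    Features with zero mutual information with the label are discarded
    before selection.  At each step the feature maximizing
    ``relevance - mean redundancy`` against the already selected set is
    added; exact ties resolve by feature name order.  Returns the ordered
    list of (name, relevance) pairs.
    """
    names = sorted(matrix.columns)
    relevance = {
        n: mutual_information(matrix[n].to_numpy(), labels, n_bins) for n in names
    }
    candidates = [n for n in names if relevance[n] > 0]
    if k > len(candidates):
        raise ValueError(
            f"k={k} exceeds the {len(candidates)} features with nonzero MI"
        )
    binned = {
        n: _discretize(np.nan_to_num(matrix[n].to_numpy(dtype=float)), n_bins)
        for n in candidates
    }
    pair_cache: dict[tuple[str, str], float] = {}

    def redundancy(a: str, b: str) -> float:
        key = (a, b) if a < b else (b, a)
        if key not in pair_cache:
            pair_cache[key] = _mi_discrete(binned[a], binned[b])
        return pair_cache[key]

    selected: list[tuple[str, float]] = []
    remaining = list(candidates)
    while len(selected) < k:
        best_name, best_score = None, -np.inf
        for n in remaining:  # name order = deterministic tie-break
            if selected:
                red = np.mean([redundancy(n, s) for s, _ in selected])
            else:
                red = 0.0
            score = relevance[n] - red
            if score > best_score + 1e-12:
                best_name, best_score = n, score
        selected.append((best_name, relevance[best_name]))
        remaining.remove(best_name)
    return selected


# ---------------------------------------------------------------------------
# PCA


def pca_fit_transform(
    matrix: np.ndarray, n_components: int | float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Centered PCA with a deterministic sign convention.

    Each component is flipped so its largest-magnitude loading is
    positive.  Returns (scores, components, explained-variance ratios).
    """
    X = np.asarray(matrix, dtype=float)
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    comps = pca.components_.copy()
    for i in range(comps.shape[0]):
        j = int(np.argmax(np.abs(comps[i])))
        if comps[i, j] < 0:
            comps[i] *= -1
            scores[:, i] *= -1
    return scores, comps, pca.explained_variance_ratio_.copy()


# ---------------------------------------------------------------------------
# generalized discriminant analysis (kernel Fisher discriminant)


def _kernel(
    X: np.ndarray, Y: np.ndarray, kind: str, gamma: float | None
) -> np.ndarray:
    if kind == "linear":
        return X @ Y.T
    if kind == "rbf":
        return np.exp(-gamma * cdist(X, Y, "sqeuclidean"))
    raise ValueError(f"unknown kernel {kind!r}")


def _median_heuristic_gamma(X: np.ndarray) -> float:
    n = len(X)
    if n > 1500:  # subsample pairwise distances; the median is stable
        rng = np.random.default_rng(0)
        X = X[rng.choice(n, 1500, replace=False)]
    d = pdist(X)
    med = np.median(d[d > 0]) if np.any(d > 0) else 1.0
    return 1.0 / (2.0 * med**2)


@dataclass
class GDAModel:
    """Fitted kernel discriminant projection."""

    kernel: str
    gamma: float | None
    X_train: np.ndarray
    alphas: np.ndarray  # (n_train, n_components) dual coefficients
    classes: list
    eigvals: np.ndarray = field(default_factory=lambda: np.array([]))

    def transform(self, X: np.ndarray) -> np.ndarray:
        K = _kernel(np.asarray(X, dtype=float), self.X_train, self.kernel, self.gamma)
        return K @ self.alphas


def _stratified_basis(labels: np.ndarray, basis_size: int) -> np.ndarray:
    """Deterministic class-proportional subset of sample indices."""
    n = len(labels)
    if n <= basis_size:
        return np.arange(n)
    picked: list[int] = []
    for c in sorted(pd.unique(labels).tolist()):
        idx = np.flatnonzero(labels == c)
        take = max(2, int(round(basis_size * len(idx) / n)))
        sel = np.linspace(0, len(idx) - 1, min(take, len(idx))).astype(int)
        picked.extend(idx[sel].tolist())
    return np.array(sorted(set(picked)), dtype=int)


def gda_fit(
    X: np.ndarray,
    labels: np.ndarray,
    kernel: str = "rbf",
    gamma: float | None = None,
    n_components: int | None = None,
    eps: float = DEFAULT_GDA_EPS,
    basis_size: int = 512,
) -> GDAModel:
    """Fit a kernel Fisher discriminant.

    Every sample is represented by its kernel similarities to a basis of
    training points (all of them up to ``basis_size``, else a
    deterministic class-proportional subset), and Fisher's between- over
    within-class scatter criterion is maximized in that representation by
    the generalized eigenproblem ``Sb a = lambda (Sw + eps I) a``.  With
    the full basis this is exactly the dual kernel discriminant; with a
    linear kernel the projection spans the classical LDA directions.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    classes = sorted(pd.unique(labels).tolist())
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    max_comp = len(classes) - 1
    n_components = max_comp if n_components is None else min(n_components, max_comp)
    if eps <= 0:
        raise ValueError("regularization eps must be > 0")
    if kernel == "rbf" and gamma is None:
        gamma = _median_heuristic_gamma(X)
    basis = _stratified_basis(labels, basis_size)
    X_basis = X[basis]
    Phi = _kernel(X, X_basis, kernel, gamma)  # (n, b)
    b = Phi.shape[1]
    mean = Phi.mean(axis=0)
    Sb = np.zeros((b, b))
    Sw = np.zeros((b, b))
    for c in classes:
        Pc = Phi[labels == c]
        mc = Pc.mean(axis=0)
        diff = mc - mean
        Sb += len(Pc) * np.outer(diff, diff)
        centered = Pc - mc
        Sw += centered.T @ centered
    try:
        w, v = linalg.eigh(Sb, Sw + eps * np.eye(b))
    except linalg.LinAlgError as exc:
        raise ValueError(
            "within-class scatter is singular; raise the regularization eps"
        ) from exc
    order = np.argsort(w)[::-1][:n_components]
    alphas = v[:, order]
    eigvals = w[order]
    # unit within-class normalization + deterministic sign
    for i in range(alphas.shape[1]):
        a = alphas[:, i]
        scale = np.sqrt(a @ (Sw + eps * np.eye(b)) @ a)
        if scale > 0:
            a = a / scale
        if a[np.argmax(np.abs(a))] < 0:
            a = -a
        alphas[:, i] = a
    return GDAModel(kernel, gamma, X_basis.copy(), alphas, classes, eigvals)


def gda_fit_transform(
    X: np.ndarray,
    labels: np.ndarray,
    kernel: str = "rbf",
    gamma: float | None = None,
    n_components: int | None = None,
    eps: float = DEFAULT_GDA_EPS,
) -> tuple[np.ndarray, GDAModel]:
    model = gda_fit(X, labels, kernel, gamma, n_components, eps)
    return model.transform(X), model


def fisher_ratio(X: np.ndarray, labels: np.ndarray) -> float:
    """trace(between-class scatter) / trace(within-class scatter)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1:
        X = X.T
    labels = np.asarray(labels)
    mean = X.mean(axis=0)
    sb = sw = 0.0
    for c in pd.unique(labels):
        Xc = X[labels == c]
        mc = Xc.mean(axis=0)
        sb += len(Xc) * float(np.sum((mc - mean) ** 2))
        sw += float(np.sum((Xc - mc) ** 2))
    return sb / sw if sw > 0 else np.inf


# ---------------------------------------------------------------------------
# end-to-end pipeline model


@dataclass
class PipelineModel:
    """Fitted normalize -> mRMR -> PCA -> GDA chain."""

    bounds: dict[str, tuple[float, float]]
    medians: dict[str, float]
    selected_features: list[tuple[str, float]]
    pca_mean: np.ndarray
    pca_components: np.ndarray
    explained_variance: np.ndarray
    gda: GDAModel

    @property
    def feature_names(self) -> list[str]:
        return [n for n, _ in self.selected_features]

    @classmethod
    def fit(
        cls,
        matrix: pd.DataFrame,
        labels: np.ndarray,
        k_features: int | None = None,
        pca_variance: float = 0.95,
        kernel: str = "rbf",
        gda_eps: float = DEFAULT_GDA_EPS,
        n_bins: int = DEFAULT_N_BINS,
    ) -> "PipelineModel":
        """Fit all stages on a training feature table.

        Missing entries are imputed with the training median of their
        column before normalization; the medians are stored so held-out
        data receives the identical treatment.
        """
        medians = {
            c: float(np.nanmedian(matrix[c].to_numpy(dtype=float)))
            for c in matrix.columns
        }
        filled = matrix.fillna(medians)
        normalized, fitted_bounds = minmax_normalize(filled)
        n_nonzero = sum(
            1
            for c in normalized.columns
            if mutual_information(normalized[c].to_numpy(), labels, n_bins) > 0
        )
        if n_nonzero == 0:
            raise ValueError("no feature carries mutual information with the labels")
        k = n_nonzero if k_features is None else min(k_features, n_nonzero)
        selected = mrmr_select(normalized, labels, k, n_bins)
        X = normalized[[n for n, _ in selected]].to_numpy(dtype=float)
        n_comp = min(X.shape[0], X.shape[1])
        if n_comp > 1:
            scores, comps, evr = pca_fit_transform(X, pca_variance)
        else:
            scores, comps, evr = pca_fit_transform(X, 1)
        gda_scores, gda = gda_fit_transform(scores, labels, kernel=kernel, eps=gda_eps)
        return cls(
            bounds=fitted_bounds,
            medians=medians,
            selected_features=selected,
            pca_mean=X.mean(axis=0),
            pca_components=comps,
            explained_variance=evr,
            gda=gda,
        )

    def transform(self, matrix: pd.DataFrame) -> np.ndarray:
        """Apply the fitted chain to a feature table; returns GDA scores."""
        filled = matrix.fillna(self.medians)
        normalized, _ = minmax_normalize(filled[list(self.bounds)], self.bounds)
        X = normalized[self.feature_names].to_numpy(dtype=float)
        pc = (X - self.pca_mean) @ self.pca_components.T
        return self.gda.transform(pc)

    # -- JSON round trip ----------------------------------------------------
    def to_json(self, path: str) -> None:
        payload = {
            "bounds": self.bounds,
            "medians": self.medians,
            "selected_features": self.selected_features,
            "pca_mean": self.pca_mean.tolist(),
            "pca_components": self.pca_components.tolist(),
            "explained_variance": self.explained_variance.tolist(),
            "gda": {
                "kernel": self.gda.kernel,
                "gamma": self.gda.gamma,
                "X_train": self.gda.X_train.tolist(),
                "alphas": self.gda.alphas.tolist(),
                "classes": self.gda.classes,
                "eigvals": self.gda.eigvals.tolist(),
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path: str) -> "PipelineModel":
        with open(path) as fh:
            d = json.load(fh)
        gda = GDAModel(
            kernel=d["gda"]["kernel"],
            gamma=d["gda"]["gamma"],
            X_train=np.array(d["gda"]["X_train"]),
            alphas=np.array(d["gda"]["alphas"]),
            classes=d["gda"]["classes"],
            eigvals=np.array(d["gda"]["eigvals"]),
        )
        return cls(
            bounds={k: tuple(v) for k, v in d["bounds"].items()},
            medians=d["medians"],
            selected_features=[(n, s) for n, s in d["selected_features"]],
            pca_mean=np.array(d["pca_mean"]),
            pca_components=np.array(d["pca_components"]),
            explained_variance=np.array(d["explained_variance"]),
            gda=gda,
        )
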