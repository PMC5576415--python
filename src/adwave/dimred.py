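"""Dimensionality reduction: PCA followed by Fisher linear discriminant analysis.

PCA is computed by singular-value decomposition of the mean-centered data
matrix — numerically equivalent to eigendecomposition of the sample
covariance but stable in the n_features >> n_samples regime this pipeline
lives in (at most n_samples - 1 components carry variance).

Fisher LDA then maximizes the generalized Rayleigh quotient
J(w) = (w' S_B w) / (w' S_w w), with the between-class scatter S_B averaged
over the c classes and the within-class scatter S_w left unnormalized (any
consistent rescaling leaves the eigenvectors unchanged).  The discriminant
axes solve the generalized eigenproblem S_B W = lambda S_w W; running LDA
after PCA plus a small ridge on S_w keeps the problem well posed in the
small-sample regime.  For two classes there is a single discriminant axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

__all__ = [
    "PCAModel",
    "LDAModel",
    "ProjectedFeatures",
    "max_components",
    "pca_fit",
    "pca_transform",
    "pca_inverse_transform",
    "lda_fit",
    "lda_transform",
    "fisher_ratio",
]


def _data(X) -> np.ndarray:
    """Accept a FeatureMatrix or a plain 2-D array."""
    X = getattr(X, "X", X)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a 2-D samples x features matrix")
    return X


def max_components(n_samples: int, n_features: int) -> int:
    """Upper bound on components carrying variance after mean-centering."""
    return min(n_samples - 1, n_features)


@dataclass
class PCAModel:
    mean: np.ndarray
    components: np.ndarray  # (n_components, n_features), orthonormal rows
    eigenvalues: np.ndarray  # nonincreasing, variances along components
    n_components: int


def pca_fit(X, n_components: int | None = None) -> PCAModel:
    """Fit PCA via SVD of the centered data.

    ``n_components=None`` keeps every component up to the
    ``min(n_samples - 1, n_features)`` bound.
    """
    X = _data(X)
    n, p = X.shape
    if n < 2:
        raise ValueError("PCA requires at least 2 samples")
    bound = max_components(n, p)
    if n_components is None:
        n_components = bound
    if not 1 <= n_components <= bound:
        raise ValueError(
            f"n_components={n_components} out of range [1, {bound}] "
            f"(min(n_samples - 1, n_features) for n={n}, p={p})"
        )
    mean = X.mean(axis=0)
    _, s, Vt = np.linalg.svd(X - mean, full_matrices=False)
    eigenvalues = s ** 2 / (n - 1)
    # sign convention: largest-magnitude entry of each component positive
    comps = Vt[:bound]
    flip = np.sign(comps[np.arange(len(comps)), np.argmax(np.abs(comps), axis=1)])
    flip[flip == 0] = 1.0
    comps = comps * flip[:, None]
    return PCAModel(mean, comps[:n_components], eigenvalues[:n_components], n_components)


def pca_transform(model: PCAModel, X) -> np.ndarray:
    X = _data(X)
    if X.shape[1] != model.mean.shape[0]:
        raise ValueError(
            f"feature count {X.shape[1]} does not match model ({model.mean.shape[0]})"
        )
    return (X - model.mean) @ model.components.T


def pca_inverse_transform(model: PCAModel, Xp) -> np.ndarray:
    Xp = np.asarray(Xp, dtype=float)
    return Xp @ model.components + model.mean


@dataclass
class LDAModel:
    S_B: np.ndarray
    S_w: np.ndarray
    class_means: np.ndarray  # (c, p)
    grand_mean: np.ndarray
    classes: np.ndarray
    W: np.ndarray  # (p, l) retained discriminant axes
    eigenvalues: np.ndarray
    l: int


def _scatter(X: np.ndarray, y: np.ndarray):
    classes = np.unique(y)
    c = len(classes)
    m = X.mean(axis=0)
    means = np.stack([X[y == cls].mean(axis=0) for cls in classes])
    S_B = sum(np.outer(mj - m, mj - m) for mj in means) / c
    S_w = np.zeros((X.shape[1], X.shape[1]))
    for cls, mj in zip(classes, means):
        D = X[y == cls] - mj
        S_w += D.T @ D
    return classes, m, means, S_B, S_w


def lda_fit(Xp, labels, l: int | None = None, ridge_rel: float = 1e-6) -> LDAModel:
    """Fisher discriminant axes from (PCA-projected) features.

    Solves the symmetric-definite generalized eigenproblem
    ``S_B w = lambda (S_w + eps I) w`` with ``eps = ridge_rel * tr(S_w) / p``
    and keeps the ``l <= c - 1`` axes of largest eigenvalue.  Every class
    needs at least 2 samples.
    """
    X = _data(Xp)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("LDA requires at least 2 classes")
    if counts.min() < 2:
        raise ValueError("every class needs at least 2 samples")
    l_max = len(classes) - 1
    if l is None:
        l = l_max
    if not 1 <= l <= l_max:
        raise ValueError(f"l={l} out of range [1, {l_max}]")

    classes, m, means, S_B, S_w = _scatter(X, y)
    p = X.shape[1]
    eps = ridge_rel * (np.trace(S_w) / p if np.trace(S_w) > 0 else 1.0)
    S_w_reg = S_w + eps * np.eye(p)
    try:
        vals, vecs = scipy.linalg.eigh(S_B, S_w_reg)
    except scipy.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise ValueError("within-class scatter numerically singular after ridge") from exc
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    W = vecs[:, :l].copy()
    for j in range(l):  # reproducible sign: largest-magnitude entry positive
        i = np.argmax(np.abs(W[:, j]))
        if W[i, j] < 0:
            W[:, j] = -W[:, j]
    return LDAModel(S_B, S_w, means, m, classes, W, vals[:l], l)


@dataclass
class ProjectedFeatures:
    """Final features F = W' ᵀ ψ(x_pc): one row per subject, l columns."""

    F: np.ndarray
    provenance: dict


def lda_transform(model: LDAModel, Xp) -> ProjectedFeatures:
    X = _data(Xp)
    if X.shape[1] != model.W.shape[0]:
        raise ValueError(
            f"feature count {X.shape[1]} does not match model ({model.W.shape[0]})"
        )
    return ProjectedFeatures(X @ model.W, {"lda_l": model.l, "input_dim": X.shape[1]})


def fisher_ratio(w: np.ndarray, S_B: np.ndarray, S_w: np.ndarray) -> float:
    """Generalized Rayleigh quotient J(w) = (w'S_B w)/(w'S_w w)."""
    w = np.asarray(w, dtype=float)
    denom = float(w @ S_w @ w)
    if denom == 0.0:
        return np.inf if float(w @ S_B @ w) > 0 else 0.0
    return float(w @ S_B @ w) / denom
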