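"""PCA and Fisher linear discriminant analysis for high-dimensional spectra.

With ~1500 channels and a few hundred spectra per class the within-class
scatter matrix is singular in channel space, so LDA is fitted in a PCA
subspace retaining a target fraction of variance (default 99%) and the
discriminant directions are mapped back to channel space for interpretation.
Both models expose deterministic outputs: every direction is oriented so its
largest-magnitude loading is positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg


def _orient(directions: np.ndarray) -> np.ndarray:
    """Flip each row so its largest-|.| entry is positive (sign convention)."""
    out = directions.copy()
    for i, row in enumerate(out):
        j = int(np.argmax(np.abs(row)))
        if row[j] < 0:
            out[i] = -row
    return out


@dataclass
class PCAModel:
    """Centered principal components: mean, orthonormal loadings, variances."""

    mean_: np.ndarray
    components_: np.ndarray  # (k, channels), orthonormal rows
    explained_variance_: np.ndarray  # eigenvalues of the covariance, retained k
    explained_variance_ratio_: np.ndarray  # fractions of TOTAL variance
    k: int

    @property
    def n_channels(self) -> int:
        return self.mean_.size


def fit_pca(matrix: np.ndarray, k: int | None = None,
            variance_target: float | None = None) -> PCAModel:
    """Centered SVD principal components.

    Exactly one of ``k`` / ``variance_target`` may be given; with
    ``variance_target`` the smallest k whose cumulative explained variance
    reaches the target is retained; with neither, all ``min(n-1, channels)``
    components are kept.
    """
    X = np.asarray(matrix, dtype=float)
    n, p = X.shape
    if n < 2:
        raise ValueError("PCA needs at least 2 spectra")
    max_k = min(n - 1, p)
    if k is not None and variance_target is not None:
        raise ValueError("give either k or variance_target, not both")
    if k is not None and k > max_k:
        raise ValueError(f"k={k} exceeds min(n-1, channels)={max_k}")

    mean = X.mean(axis=0)
    Xc = X - mean
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    ev = s**2 / (n - 1)
    total = ev.sum()
    ratio = ev / total if total > 0 else np.zeros_like(ev)

    if k is None:
        if variance_target is not None:
            if not 0 < variance_target <= 1:
                raise ValueError("variance_target must lie in (0, 1]")
            cum = np.cumsum(ratio)
            k = int(np.searchsorted(cum, variance_target - 1e-12) + 1)
            k = min(k, max_k)
        else:
            k = max_k
    return PCAModel(
        mean_=mean,
        components_=_orient(Vt[:k]),
        explained_variance_=ev[:k],
        explained_variance_ratio_=ratio[:k],
        k=k,
    )


@dataclass
class LDAModel:
    """Fisher discriminant axes fitted in a PCA subspace.

    ``directions_`` are unit-norm discriminant directions in channel space
    (axes x channels, at most n_classes - 1 rows); ``class_means_ld_`` are the
    training class means projected into discriminant space; ``ridge_``
    records the regularization added to the within-class scatter (0 when
    none was needed).
    """

    pca: PCAModel
    directions_: np.ndarray
    class_means_ld_: np.ndarray  # (n_classes, n_axes)
    classes_: np.ndarray
    eigenvalues_: np.ndarray = field(default_factory=lambda: np.array([]))
    ridge_: float = 0.0

    @property
    def n_axes(self) -> int:
        return self.directions_.shape[0]


def _scatter_matrices(Z: np.ndarray, y: np.ndarray, classes: np.ndarray):
    d = Z.shape[1]
    grand = Z.mean(axis=0)
    Sw = np.zeros((d, d))
    Sb = np.zeros((d, d))
    for c in classes:
        Zc = Z[y == c]
        mu = Zc.mean(axis=0)
        dev = Zc - mu
        Sw += dev.T @ dev
        dm = (mu - grand)[:, None]
        Sb += Zc.shape[0] * (dm @ dm.T)
    return Sw, Sb


def fit_lda(matrix: np.ndarray, labels, pca_variance_target: float = 0.99) -> LDAModel:
    """PCA reduction then Fisher LDA via the generalized eigenproblem.

    Maximizes between-class over within-class scatter; keeps at most
    ``n_classes - 1`` axes.  A singular within-class scatter after PCA is
    ridge-regularized with eps = 1e-8 * trace(Sw) / dim (recorded on the
    model).
    """
    X = np.asarray(matrix, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("LDA needs at least 2 classes")
    for c in classes:
        if (y == c).sum() < 2:
            raise ValueError(f"class {c!r} has fewer than 2 spectra")

    pca = fit_pca(X, variance_target=pca_variance_target)
    Z = (X - pca.mean_) @ pca.components_.T
    Sw, Sb = _scatter_matrices(Z, y, classes)

    ridge = 0.0
    d = Z.shape[1]
    try:
        evals, evecs = scipy.linalg.eigh(Sb, Sw)
    except (np.linalg.LinAlgError, scipy.linalg.LinAlgError):
        ridge = 1e-8 * np.trace(Sw) / d
        evals, evecs = scipy.linalg.eigh(Sb, Sw + ridge * np.eye(d))

    n_axes = min(classes.size - 1, d)
    order = np.argsort(evals)[::-1][:n_axes]
    W = evecs[:, order].T  # (axes, pca-dim)

    directions = W @ pca.components_  # back to channel space
    norms = np.linalg.norm(directions, axis=1, keepdims=True)
    directions = _orient(directions / norms)

    # class means in discriminant space, consistent with project()
    scores = (X - pca.mean_) @ directions.T
    class_means = np.vstack([scores[y == c].mean(axis=0) for c in classes])
    return LDAModel(
        pca=pca,
        directions_=directions,
        class_means_ld_=class_means,
        classes_=classes,
        eigenvalues_=evals[order],
        ridge_=ridge,
    )


def project(model: PCAModel | LDAModel, matrix: np.ndarray) -> np.ndarray:
    """Scores per spectrum per axis (PCA components or LD1, LD2, ...)."""
    X = np.atleast_2d(np.asarray(matrix, dtype=float))
    if isinstance(model, PCAModel):
        if X.shape[1] != model.n_channels:
            raise ValueError(
                f"matrix has {X.shape[1]} channels, model expects {model.n_channels}"
            )
        return (X - model.mean_) @ model.components_.T
    if isinstance(model, LDAModel):
        if X.shape[1] != model.pca.n_channels:
            raise ValueError(
                f"matrix has {X.shape[1]} channels, model expects {model.pca.n_channels}"
            )
        return (X - model.pca.mean_) @ model.directions_.T
    raise TypeError(f"unsupported model type {type(model).__name__}")


def nearest_class_mean_predict(model: LDAModel, matrix: np.ndarray) -> np.ndarray:
    """Classify by nearest class mean in discriminant space."""
    scores = project(model, matrix)
    d2 = ((scores[:, None, :] - model.class_means_ld_[None, :, :]) ** 2).sum(axis=2)
    return model.classes_[np.argmin(d2, axis=1)]


def top_loading_wavenumbers(
    model: LDAModel, wavenumbers: np.ndarray, axis: str = "LD1", fraction: float = 0.10
) -> np.ndarray:
    """Wavenumbers of the ceil(fraction * channels) largest-|loading| channels
    on one discriminant axis, sorted by descending magnitude (ties broken by
    lower wavenumber)."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    try:
        idx = int(axis.upper().removeprefix("LD")) - 1
    except ValueError:
        raise ValueError(f"axis must look like 'LD1', got {axis!r}") from None
    if not 0 <= idx < model.n_axes:
        raise ValueError(f"axis {axis} not available (model has {model.n_axes} axes)")
    wavenumbers = np.asarray(wavenumbers, dtype=float)
    loading = np.abs(model.directions_[idx])
    m = int(np.ceil(fraction * loading.size))
    order = np.lexsort((wavenumbers, -loading))
    return wavenumbers[order[:m]]
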