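"""Principal-component model of preprocessed fragment spectra.

The model is fitted on normalised, mean-centred reference and
representative spectra by eigendecomposition of the sample covariance
(divisor ``n - 1``).  Components are sign-fixed (largest-magnitude
loading entry positive) so fits are reproducible.  New spectra are
projected by subtracting the training mean and multiplying by the
loadings.

Two components matter downstream and are identified from the training
labels rather than assumed by index: a *coverage* component separating
bare substrate from protein-covered surfaces, and an *orientation*
component separating Fc-fragment from F(ab')2-fragment reference layers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .spectra_io import PeakTable

__all__ = [
    "PCAModel",
    "PCSelection",
    "fit_pca",
    "project",
    "select_pcs",
    "confidence_ellipse",
    "save_model",
    "load_model",
]


@dataclass
class PCAModel:
    """Fitted PCA: training mean, orthonormal loadings, eigenvalues, scores."""

    mean_vector: np.ndarray          # (p,)
    loadings: np.ndarray             # (p, k), orthonormal columns
    eigenvalues: np.ndarray          # (k,), descending
    variance_fractions: np.ndarray   # (k,), eigenvalue / total variance
    training_scores: np.ndarray      # (n, k)
    training_labels: list[str]
    peaks: list[str]

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


@dataclass(frozen=True)
class PCSelection:
    """Indices (0-based) of the coverage and orientation components.

    ``orientation_sign`` is the convention factor that makes the mean
    Fc-reference score positive on the orientation axis.
    """

    coverage_pc: int
    orientation_pc: int
    orientation_sign: int

    def __post_init__(self) -> None:
        if self.coverage_pc == self.orientation_pc:
            raise ValueError("coverage and orientation components must differ")
        if self.orientation_sign not in (-1, 1):
            raise ValueError("orientation_sign must be +1 or -1")


def fit_pca(
    centered: np.ndarray,
    n_components: int,
    *,
    labels: list[str] | None = None,
    peaks: list[str] | None = None,
) -> PCAModel:
    """Fit a PCA by covariance eigendecomposition of a centred matrix.

    ``centered`` must already be column-centred (the caller keeps the mean
    vector; :func:`igg_orient.spectra_io.mean_center` returns both).
    """
    X = np.asarray(centered, dtype=float)
    n, p = X.shape
    if n < 2:
        raise ValueError("need at least 2 spectra to fit a PCA")
    rank_bound = min(n - 1, p)
    if n_components > rank_bound:
        raise ValueError(
            f"n_components={n_components} exceeds rank bound {rank_bound} "
            f"for a {n}x{p} matrix"
        )
    col_means = X.mean(axis=0)
    if np.max(np.abs(col_means)) > 1e-8 * max(1.0, np.max(np.abs(X))):
        raise ValueError("input matrix is not mean-centred")

    cov = (X.T @ X) / (n - 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]

    # deterministic sign: largest-|entry| loading element is positive
    for j in range(eigvecs.shape[1]):
        i = int(np.argmax(np.abs(eigvecs[:, j])))
        if eigvecs[i, j] < 0:
            eigvecs[:, j] = -eigvecs[:, j]

    total_var = float(np.trace(cov))
    loadings = eigvecs[:, :n_components]
    eigenvalues = eigvals[:n_components]
    variance_fractions = (
        eigenvalues / total_var if total_var > 0 else np.zeros_like(eigenvalues)
    )
    return PCAModel(
        mean_vector=np.zeros(p),  # model space is the centred space; see project()
        loadings=loadings,
        eigenvalues=eigenvalues,
        variance_fractions=variance_fractions,
        training_scores=X @ loadings,
        training_labels=list(labels) if labels is not None else [""] * n,
        peaks=list(peaks) if peaks is not None else [f"peak{i}" for i in range(p)],
    )


def fit_pca_on_table(table: PeakTable, n_components: int) -> PCAModel:
    """Convenience: mean-centre a normalised table and fit, storing the mean."""
    if not table.normalized:
        raise ValueError("table must be normalised before fitting")
    from .spectra_io import mean_center

    centered, mean = mean_center(table.intensities)
    model = fit_pca(
        centered,
        n_components,
        labels=list(table.meta["group"]),
        peaks=table.peaks,
    )
    model.mean_vector = mean
    return model


def project(model: PCAModel, table: PeakTable) -> np.ndarray:
    """Project normalised spectra onto the model: (X - mean) @ loadings."""
    if list(table.peaks) != list(model.peaks):
        missing = set(model.peaks) ^ set(table.peaks)
        raise ValueError(
            f"peak set/order mismatch between table and model; symmetric "
            f"difference: {sorted(missing) if missing else 'same set, different order'}"
        )
    return (table.intensities - model.mean_vector) @ model.loadings


def _standardized_separation(a: np.ndarray, b: np.ndarray) -> float:
    """|mean(a) - mean(b)| / pooled SD; +inf when both groups are constant."""
    na, nb = len(a), len(b)
    diff = abs(float(np.mean(a)) - float(np.mean(b)))
    if na < 2 or nb < 2:
        pooled = float(np.std(np.concatenate([a, b]), ddof=1))
    else:
        va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
        pooled = float(np.sqrt(((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)))
    if pooled == 0.0:
        return np.inf if diff > 0 else 0.0
    return diff / pooled


def select_pcs(model: PCAModel) -> PCSelection:
    """Identify the coverage and orientation components from training labels.

    Coverage: component with the largest standardized separation between
    bare-substrate spectra and all protein-bearing spectra.  Orientation:
    the remaining component best separating the Fc and F(ab')2 reference
    layers, with its sign chosen so the Fc-reference mean score is
    positive.  Ties break toward the lower component index.
    """
    labels = np.asarray(model.training_labels)
    for required in ("bare", "fc_ref", "fab2_ref"):
        if required not in labels:
            raise ValueError(f"training set lacks required reference class {required!r}")
    scores = model.training_scores
    bare = labels == "bare"
    protein = ~bare

    cov_sep = [
        _standardized_separation(scores[bare, j], scores[protein, j])
        for j in range(model.n_components)
    ]
    coverage_pc = int(np.argmax(cov_sep))

    fc = labels == "fc_ref"
    fab = labels == "fab2_ref"
    ori_sep = np.array(
        [
            -np.inf
            if j == coverage_pc
            else _standardized_separation(scores[fc, j], scores[fab, j])
            for j in range(model.n_components)
        ]
    )
    orientation_pc = int(np.argmax(ori_sep))
    sign = 1 if float(np.mean(scores[fc, orientation_pc])) >= 0 else -1
    return PCSelection(
        coverage_pc=coverage_pc, orientation_pc=orientation_pc, orientation_sign=sign
    )


def confidence_ellipse(
    scores_2d: np.ndarray, level: float = 0.95
) -> tuple[np.ndarray, np.ndarray, float]:
    """Chi-square confidence ellipse of a 2-D score cloud.

    Returns (center, semi-axis lengths, rotation angle in radians).  The
    contour encloses ``level`` probability of the fitted bivariate normal:
    semi-axes are sqrt(chi2_2(level) * eigenvalue) of the sample
    covariance.
    """
    X = np.asarray(scores_2d, dtype=float)
    if X.ndim != 2 or X.shape[1] != 2:
        raise ValueError("scores_2d must be n x 2")
    if X.shape[0] < 3:
        raise ValueError("need at least 3 points for a confidence ellipse")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    center = X.mean(axis=0)
    cov = np.cov(X, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(cov)
    if np.min(eigvals) <= 0:
        raise ValueError("degenerate (zero-variance) scores: ellipse undefined")
    q = stats.chi2.ppf(level, df=2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    axes = np.sqrt(q * eigvals)
    angle = float(np.arctan2(eigvecs[1, 0], eigvecs[0, 0]))
    return center, axes, angle


def save_model(model: PCAModel, path) -> None:
    payload = {
        "schema_version": 1,
        "peaks": model.peaks,
        "mean_vector": model.mean_vector.tolist(),
        "loadings": model.loadings.tolist(),
        "eigenvalues": model.eigenvalues.tolist(),
        "variance_fractions": model.variance_fractions.tolist(),
        "training_scores": model.training_scores.tolist(),
        "training_labels": model.training_labels,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path) -> PCAModel:
    with open(path) as fh:
        payload = json.load(fh)
    return PCAModel(
        mean_vector=np.array(payload["mean_vector"], dtype=float),
        loadings=np.array(payload["loadings"], dtype=float),
        eigenvalues=np.array(payload["eigenvalues"], dtype=float),
        variance_fractions=np.array(payload["variance_fractions"], dtype=float),
        training_scores=np.array(payload["training_scores"], dtype=float),
        training_labels=list(payload["training_labels"]),
        peaks=list(payload["peaks"]),
    )
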