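"""Feature extraction and wavelength selection for seed spectra.

Two dimensionality reductions:

* PCA — mean-centred (no variance scaling) principal components of the
  preprocessed spectra; with these data the first two components carry
  almost all variance and serve as the classification features.
* SFS — greedy sequential forward selection of individual wavebands: at
  each step the band that maximises the estimator's mean cross-validated
  accuracy on the current subset is added.  Selecting k of n bands
  eliminates 100*(1 - k/n) percent of the features, the figure of merit for
  reducing a hyperspectral instrument to a cheap multispectral one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import clone
from sklearn.decomposition import PCA
from sklearn.model_selection import StratifiedKFold, cross_val_score

from .segmentation import SpectraTable

__all__ = [
    "PCAResult",
    "SFSResult",
    "fit_pca",
    "transform_pca",
    "sfs_select",
    "elimination_percent",
]


@dataclass
class PCAResult:
    """Fitted principal-component model.

    ``loadings`` is (n_bands, k) with orthonormal columns, sign-fixed so the
    largest-magnitude element of each loading is positive; ``scores`` are the
    training-row projections; ``center`` the per-band mean removed before
    projection.
    """

    loadings: np.ndarray
    scores: np.ndarray
    explained_variance_ratio: np.ndarray
    center: np.ndarray

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


def _as_matrix(table) -> np.ndarray:
    if isinstance(table, SpectraTable):
        return table.spectra
    return np.asarray(table, dtype=float)


def fit_pca(table, k: int = 2) -> PCAResult:
    """Mean-centred PCA with ``k`` components.

    Components are the covariance eigenvectors in decreasing eigenvalue
    order; each loading's sign is chosen so its largest-magnitude element is
    positive, making the decomposition fully deterministic.
    """
    x = _as_matrix(table)
    n_rows, n_bands = x.shape
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= min(n_rows, n_bands) + 1 or n_rows <= k:
        raise ValueError(f"k={k} too large for a {n_rows}x{n_bands} matrix")

    model = PCA(n_components=k, svd_solver="full")
    model.fit(x)
    loadings = model.components_.T.copy()
    for j in range(k):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] = -loadings[:, j]
    center = model.mean_
    scores = (x - center) @ loadings
    return PCAResult(
        loadings=loadings,
        scores=scores,
        explained_variance_ratio=model.explained_variance_ratio_.copy(),
        center=center,
    )


def transform_pca(model: PCAResult, table) -> np.ndarray:
    """Project rows onto the fitted components: ``(x - center) @ loadings``."""
    x = _as_matrix(table)
    if x.ndim == 1:
        x = x[None, :]
    if x.shape[1] != model.center.size:
        raise ValueError(
            f"band mismatch: data has {x.shape[1]} bands, model was fitted on {model.center.size}"
        )
    return (x - model.center) @ model.loadings


@dataclass
class SFSResult:
    """Outcome of greedy forward waveband selection."""

    selected_band_indices: list
    selected_wavelengths_nm: list
    cv_score_trace: list
    estimator_spec: object = None
    elimination_percent: float = 0.0
    n_total_bands: int = 0

    def format_wavelengths(self) -> str:
        return ", ".join(f"{w:.2f}" for w in self.selected_wavelengths_nm)


def sfs_select(
    table,
    labels=None,
    k: int = 5,
    estimator=None,
    cv_folds: int = 5,
    rng_seed: int = 0,
) -> SFSResult:
    """Greedy sequential forward selection of ``k`` wavebands.

    At each step every unselected band is tried in union with the current
    subset; the band with the highest mean stratified ``cv_folds``-fold CV
    accuracy is added (ties go to the lowest band index).  The score trace
    records the achieved CV accuracy after each addition.  ``estimator`` is
    an (unfitted) classifier or a :class:`~milletspec.classify.ClassifierSpec`;
    default is the gradient-tree-boosting configuration.  Deterministic in
    ``rng_seed``.
    """
    from .classify import ClassifierSpec, build_classifier  # local import avoids cycle

    if isinstance(table, SpectraTable):
        x = table.spectra
        wavelengths = table.wavelengths
        if labels is None:
            labels = table.labels
    else:
        x = np.asarray(table, dtype=float)
        wavelengths = None
    y = np.asarray(labels)
    n_bands = x.shape[1]
    if not (1 <= k <= n_bands):
        raise ValueError(f"k must be in 1..{n_bands}, got {k}")

    if estimator is None:
        estimator = ClassifierSpec.default("GTB")
    if isinstance(estimator, ClassifierSpec):
        base = build_classifier(estimator, rng_seed=rng_seed)
        spec = estimator
    else:
        base = estimator
        spec = None
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=rng_seed)

    selected: list[int] = []
    trace: list[float] = []
    remaining = list(range(n_bands))
    for _ in range(k):
        best_score, best_band = -np.inf, None
        for band in remaining:
            cols = selected + [band]
            score = float(
                np.mean(cross_val_score(clone(base), x[:, cols], y, cv=cv, scoring="accuracy"))
            )
            if score > best_score:  # strict: ties keep the lowest index
                best_score, best_band = score, band
        selected.append(best_band)
        remaining.remove(best_band)
        trace.append(best_score)

    return SFSResult(
        selected_band_indices=selected,
        selected_wavelengths_nm=(
            [float(wavelengths[i]) for i in selected] if wavelengths is not None else []
        ),
        cv_score_trace=trace,
        estimator_spec=spec,
        elimination_percent=elimination_percent(k, n_bands),
        n_total_bands=n_bands,
    )


def elimination_percent(k_selected: int, n_total: int = 254) -> float:
    """Percentage of features eliminated by keeping ``k_selected`` of ``n_total``."""
    if not (0 <= k_selected <= n_total):
        raise ValueError(f"k_selected must be in 0..{n_total}, got {k_selected}")
    return round(100.0 * (1.0 - k_selected / n_total), 2)
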