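"""Band selection: correlation pruning, PCA summarisation and recursive
feature elimination (RFE).

RFE implements the one-band-per-iteration elimination loop: starting from
all bands, fit an importance-scoring model, drop the single band with the
lowest importance, and repeat until ``k`` bands survive.  Importance ties
are broken by dropping the longer wavelength, which makes the selection a
function of the wavelengths rather than of column order.  Two importance
scorers are provided, matching the models named for the elimination loop:
an impurity-based random-forest scorer (default) and a linear one-vs-rest
margin scorer (|weight| aggregated over classes).

PCA is exposed for exploration and as an optional classifier input mode;
it is not part of the default training path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import LinearSVC

from .errors import ContractError, InsufficientDataError, ParameterError
from .spectra_io import SpectralLibrary


# ---------------------------------------------------------------- correlation
@dataclass
class CorrelationMatrix:
    wavelengths: np.ndarray
    r: np.ndarray  # (n_bands, n_bands), symmetric, unit diagonal


def correlation_matrix(library: SpectralLibrary) -> CorrelationMatrix:
    """Pairwise Pearson correlation between bands across samples.

    Zero-variance bands are excluded with a warning (their correlation is
    undefined).  Requires at least two samples.
    """
    if library.n_samples < 2:
        raise InsufficientDataError("correlation requires at least 2 samples")
    sd = library.reflectance.std(axis=0)
    keep = sd > 0
    if not keep.all():
        warnings.warn(
            f"excluding {int((~keep).sum())} zero-variance band(s) from the correlation matrix",
            stacklevel=2,
        )
    x = library.reflectance[:, keep]
    r = np.corrcoef(x, rowvar=False)
    r = np.atleast_2d(r)
    return CorrelationMatrix(wavelengths=library.wavelengths[keep].copy(), r=r)


def prune_redundant(matrix: CorrelationMatrix, threshold: float = 0.95) -> list:
    """Greedy scan in wavelength order; drop bands with |r| > threshold
    against any already-retained band.  Returns retained wavelengths."""
    if not 0 < threshold <= 1:
        raise ParameterError("threshold must lie in (0, 1]")
    retained: list = []
    retained_idx: list = []
    for j, wl in enumerate(matrix.wavelengths):
        if all(abs(matrix.r[j, i]) <= threshold for i in retained_idx):
            retained.append(float(wl))
            retained_idx.append(j)
    return retained


# ----------------------------------------------------------------------- PCA
@dataclass
class PCAModel:
    wavelengths: np.ndarray
    loadings: np.ndarray                 # (n_bands, k), orthonormal columns
    explained_variance_ratio: np.ndarray
    mean: np.ndarray
    k: int


def pca_fit(library: SpectralLibrary, k: int = 30) -> PCAModel:
    """Principal components of the band-mean-centred reflectance, Z = X_c W."""
    if k < 1 or k > min(library.n_samples, library.n_bands):
        raise ParameterError("k must satisfy 1 <= k <= min(n_samples, n_bands)")
    p = PCA(n_components=k, svd_solver="full").fit(library.reflectance)
    return PCAModel(
        wavelengths=library.wavelengths.copy(),
        loadings=p.components_.T.copy(),
        explained_variance_ratio=p.explained_variance_ratio_.copy(),
        mean=p.mean_.copy(),
        k=k,
    )


def pca_transform(model: PCAModel, library: SpectralLibrary) -> np.ndarray:
    """Component scores Z = (X - mean) W."""
    if library.n_bands != model.loadings.shape[0]:
        raise ParameterError("library band count does not match the PCA model")
    return (library.reflectance - model.mean) @ model.loadings


# ----------------------------------------------------------------------- RFE
class ForestImportance:
    """Impurity-based random-forest importance scorer."""

    def __init__(self, n_estimators: int = 100, seed: int = 0):
        self.n_estimators = n_estimators
        self.seed = seed
        self._model = None

    def fit(self, features: np.ndarray, labels: np.ndarray) -> None:
        self._model = RandomForestClassifier(
            n_estimators=self.n_estimators, random_state=self.seed, n_jobs=1
        ).fit(features, labels)

    def importances(self) -> np.ndarray:
        if self._model is None:
            raise ContractError("importances requested before fit")
        return self._model.feature_importances_


class LinearMarginImportance:
    """Linear one-vs-rest margin scorer: sum of |weight| over classes."""

    def __init__(self, C: float = 1.0, seed: int = 0):
        self.C = C
        self.seed = seed
        self._model = None

    def fit(self, features: np.ndarray, labels: np.ndarray) -> None:
        self._model = LinearSVC(
            C=self.C, dual=False, random_state=self.seed, max_iter=5000
        ).fit(features, labels)

    def importances(self) -> np.ndarray:
        if self._model is None:
            raise ContractError("importances requested before fit")
        coef = np.atleast_2d(self._model.coef_)
        return np.abs(coef).sum(axis=0)


_ESTIMATORS = {"forest": ForestImportance, "linear": LinearMarginImportance}


@dataclass
class BandRanking:
    """RFE outcome: surviving bands ordered by final-fit importance."""

    wavelengths: np.ndarray             # k survivors, descending importance
    scores: np.ndarray                  # final-fit importance per survivor
    k: int
    elimination_order: list = field(default_factory=list)  # wavelengths, first dropped first

    def top(self, n: int) -> np.ndarray:
        return self.wavelengths[:n]


def rfe_select(
    library: SpectralLibrary,
    labels: Optional[np.ndarray] = None,
    estimator: Union[str, object] = "forest",
    k: int = 10,
    seed: int = 0,
) -> BandRanking:
    """Recursive feature elimination down to ``k`` stress-sensitive bands.

    One band is removed per iteration (the lowest-importance one; ties drop
    the longest wavelength).  The full elimination order is recorded; the
    surviving bands are ranked by a final fit on the survivors.
    """
    y = library.labels if labels is None else np.asarray(labels)
    if y is None:
        raise ContractError("rfe_select requires a labeled library")
    if k < 1 or k > library.n_bands:
        raise ParameterError("k must satisfy 1 <= k <= n_bands")
    if isinstance(estimator, str):
        try:
            estimator = _ESTIMATORS[estimator](seed=seed)
        except KeyError:
            raise ParameterError(f"unknown estimator {estimator!r}") from None
    if not (hasattr(estimator, "fit") and hasattr(estimator, "importances")):
        raise ContractError("estimator must provide fit(X, y) and importances()")

    active = list(range(library.n_bands))
    eliminated: list = []
    x = library.reflectance
    wl = library.wavelengths
    while len(active) > k:
        estimator.fit(x[:, active], y)
        imp = np.asarray(estimator.importances(), dtype=float)
        if imp.shape != (len(active),):
            raise ContractError("estimator returned a wrong-length importance vector")
        low = np.flatnonzero(imp == imp.min())
        # tie-break: drop the longest wavelength among the minima
        drop_pos = low[np.argmax(wl[[active[i] for i in low]])]
        eliminated.append(float(wl[active[drop_pos]]))
        del active[drop_pos]

    estimator.fit(x[:, active], y)
    final_imp = np.asarray(estimator.importances(), dtype=float)
    # rank survivors by descending importance; equal scores keep wavelength order
    order = np.lexsort((wl[active], -final_imp))
    survivors = np.array([wl[active[i]] for i in order])
    return BandRanking(
        wavelengths=survivors,
        scores=final_imp[order],
        k=k,
        elimination_order=eliminated,
    )
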