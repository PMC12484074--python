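"""Spectral preprocessing: Savitzky-Golay smoothing and z-score normalization.

Smoothing fits a low-degree polynomial over a moving window along the
wavelength axis (the classic Savitzky-Golay filter, y_hat_i = sum_j c_j
y_{i+j}); the centre-point evaluation weights c_j are computed from the
window design matrix, never from published coefficient tables.

Normalization is the per-band z-score (X - mu) / sigma with the population
(1/n) standard deviation; statistics are fitted on a caller-chosen subset
(normally the training rows) and applied to all rows, so held-out samples
never leak into the statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import InsufficientDataError, ParameterError
from .spectra_io import SpectralLibrary, check_alignment

_EDGE_MODES = {"mirror": "reflect", "reflect": "reflect", "edge": "edge", "wrap": "wrap"}


@dataclass
class SavGolKernel:
    """Centre-point smoothing weights for a (2m+1)-wide polynomial fit."""

    half_width: int
    polyorder: int
    coefficients: np.ndarray  # length 2m+1, sums to 1

    @property
    def window(self) -> int:
        return 2 * self.half_width + 1


def savgol_coefficients(half_width: int, polyorder: int) -> SavGolKernel:
    """Least-squares smoothing kernel for window 2m+1, polynomial degree p.

    Solves the window least-squares projector directly: with the design
    matrix A[j, q] = j^q (j = -m..m, q = 0..p), the centre-point weights are
    the first row of (A^T A)^{-1} A^T.  Requires p < 2m+1.
    """
    m, p = int(half_width), int(polyorder)
    if m < 1:
        raise ParameterError("half_width must be >= 1")
    if p < 0 or p >= 2 * m + 1:
        raise ParameterError("polyorder must satisfy 0 <= p < window length 2m+1")
    offsets = np.arange(-m, m + 1, dtype=float)
    design = np.vander(offsets, p + 1, increasing=True)
    # centre evaluation = value of the fitted polynomial at offset 0 = coeff of j^0
    proj = np.linalg.pinv(design)  # (p+1, 2m+1)
    return SavGolKernel(half_width=m, polyorder=p, coefficients=proj[0])


def smooth_library(
    library: SpectralLibrary,
    half_width: int = 5,
    polyorder: int = 2,
    edge_mode: str = "mirror",
) -> SpectralLibrary:
    """Savitzky-Golay smooth each spectrum along the wavelength axis.

    Edges are produced by padding (default mirror reflection), so the output
    has the same shape as the input.
    """
    kernel = savgol_coefficients(half_width, polyorder)
    if library.n_bands < kernel.window:
        raise ParameterError(
            f"library has {library.n_bands} bands; window {kernel.window} requires at least that"
        )
    if edge_mode not in _EDGE_MODES:
        raise ParameterError(f"unknown edge_mode {edge_mode!r}")
    m = kernel.half_width
    padded = np.pad(library.reflectance, ((0, 0), (m, m)), mode=_EDGE_MODES[edge_mode])
    windows = np.lib.stride_tricks.sliding_window_view(padded, kernel.window, axis=1)
    return library.with_reflectance(windows @ kernel.coefficients)


@dataclass
class NormalizationStats:
    """Per-band mean and population standard deviation from a fit subset."""

    wavelengths: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    zero_variance: np.ndarray   # bool mask of flagged sigma == 0 bands
    ddof: int = 0               # population (1/n) convention, recorded explicitly
    n_fit: int = 0


def zscore_fit(
    library: SpectralLibrary, sample_subset: Optional[Sequence[int]] = None
) -> NormalizationStats:
    """Fit per-band mean/sd over ``sample_subset`` rows (default: all rows)."""
    idx = np.arange(library.n_samples) if sample_subset is None else np.asarray(sample_subset)
    if idx.size == 0:
        raise InsufficientDataError("empty fit subset")
    if idx.size < 2:
        raise InsufficientDataError("standard deviation undefined for a single sample")
    x = library.reflectance[idx]
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    zero = sd == 0.0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} zero-variance band(s) flagged "
            f"(e.g. {library.wavelengths[zero][:3]} nm)",
            stacklevel=2,
        )
    return NormalizationStats(
        wavelengths=library.wavelengths.copy(),
        mean=mean,
        sd=sd,
        zero_variance=zero,
        n_fit=int(idx.size),
    )


def zscore_apply(
    library: SpectralLibrary,
    stats: NormalizationStats,
    zero_variance: str = "drop",
) -> SpectralLibrary:
    """Transform every value to (X - mu) / sigma.

    Zero-variance bands are dropped (default) or passed through as 0
    (``zero_variance="zero"``).
    """
    check_alignment(library.wavelengths, stats.wavelengths, "zscore_apply")
    if zero_variance not in ("drop", "zero"):
        raise ParameterError("zero_variance must be 'drop' or 'zero'")
    keep = ~stats.zero_variance
    if zero_variance == "drop" and not keep.all():
        sub = library.subset_bands(np.flatnonzero(keep))
        z = (sub.reflectance - stats.mean[keep]) / stats.sd[keep]
        return sub.with_reflectance(z)
    safe_sd = np.where(stats.zero_variance, 1.0, stats.sd)
    z = (library.reflectance - stats.mean) / safe_sd
    z[:, stats.zero_variance] = 0.0
    return library.with_reflectance(z)


def zscore_inverse(library: SpectralLibrary, stats: NormalizationStats) -> SpectralLibrary:
    """Undo :func:`zscore_apply` (only valid for the 'zero' policy or no drops)."""
    check_alignment(library.wavelengths, stats.wavelengths, "zscore_inverse")
    return library.with_reflectance(library.reflectance * stats.sd + stats.mean)


def zscore_array(x: np.ndarray, mean: np.ndarray, sd: np.ndarray) -> np.ndarray:
    """Z-score a plain feature array with precomputed statistics (sd floor 1e-12)."""
    return (x - mean) / np.maximum(sd, 1e-12)
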