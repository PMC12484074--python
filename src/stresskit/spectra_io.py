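"""Spectral-library container and CSV I/O.

The on-disk dialect follows the GHISACONUS spectral-library convention:
one row per sample, reflectance columns named ``X<wavelength_nm>`` (integer
nanometres, e.g. ``X661``, ``X854``, ``X1649``, ``X2133``), optional metadata
columns (latitude, longitude, crop type, growth stage, Julian day-of-year)
and an optional integer stress label in {0..5} (0 = healthy, 5 = extreme
stress).  Reflectance is stored as a unitless fraction; files that appear to
carry percent reflectance (values in (1.5, 100]) trigger a warning and can be
rescaled with ``rescale_percent=True``.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    BandNotFoundError,
    SpectralFormatError,
    SpectralParseError,
    SpectralValidationError,
)

logger = logging.getLogger(__name__)

#: canonical band centres (nm) used throughout: red, NIR, SWIR1, SWIR2
RED_NM = 661.0
NIR_NM = 854.0
SWIR1_NM = 1649.0
SWIR2_NM = 2133.0

#: default nearest-band matching tolerance (nm), about one Hyperion band spacing
DEFAULT_BAND_TOLERANCE = 15.0

_SPECTRAL_RE = re.compile(r"^X(\d+)$")
_FRACTIONAL_RE = re.compile(r"^X\d+\.\d+$")

# accepted metadata column spellings (case-insensitive) -> canonical name
_METADATA_SYNONYMS = {
    "lat": "latitude",
    "latitude": "latitude",
    "lon": "longitude",
    "long": "longitude",
    "longitude": "longitude",
    "crop": "crop_type",
    "crop_type": "crop_type",
    "stage": "growth_stage",
    "growth_stage": "growth_stage",
    "doy": "julian_date",
    "julian_date": "julian_date",
    "julian_day": "julian_date",
}

_LABEL_SYNONYMS = {"label", "stress_class", "stress_label"}

METADATA_COLUMNS = ("latitude", "longitude", "crop_type", "growth_stage", "julian_date")

MIN_STRESS_CLASS = 0
MAX_STRESS_CLASS = 5


@dataclass
class SpectralLibrary:
    """A samples x bands reflectance matrix with metadata and optional labels.

    Invariants (checked on construction): wavelengths strictly increasing and
    matching the reflectance column count; all reflectance finite; labels, if
    present, integers in {0..5}.  Negative reflectance is rejected at *load*
    time only, so transformed (e.g. z-scored) libraries remain representable.
    """

    wavelengths: np.ndarray  # (n_bands,) nm, strictly increasing
    reflectance: np.ndarray  # (n_samples, n_bands)
    sample_ids: list = field(default_factory=list)
    metadata: Optional[pd.DataFrame] = None  # n_samples rows
    labels: Optional[np.ndarray] = None  # (n_samples,) ints in {0..5}

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.reflectance = np.atleast_2d(np.asarray(self.reflectance, dtype=float))
        if self.wavelengths.ndim != 1:
            raise SpectralValidationError("wavelengths must be one-dimensional")
        if self.reflectance.shape[1] != self.wavelengths.size:
            raise SpectralValidationError(
                f"reflectance has {self.reflectance.shape[1]} columns but "
                f"{self.wavelengths.size} wavelengths were given"
            )
        if self.wavelengths.size and np.any(np.diff(self.wavelengths) <= 0):
            raise SpectralValidationError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.reflectance)):
            raise SpectralValidationError("reflectance contains non-finite values")
        if not self.sample_ids:
            self.sample_ids = [f"s{i:05d}" for i in range(self.n_samples)]
        if len(self.sample_ids) != self.n_samples:
            raise SpectralValidationError("sample_ids length != number of samples")
        if self.metadata is not None and len(self.metadata) != self.n_samples:
            raise SpectralValidationError("metadata row count != number of samples")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape != (self.n_samples,):
                raise SpectralValidationError("labels length != number of samples")
            as_int = self.labels.astype(int)
            if np.any(as_int != self.labels):
                raise SpectralValidationError("labels must be integers")
            self.labels = as_int
            if self.labels.size and (
                self.labels.min() < MIN_STRESS_CLASS or self.labels.max() > MAX_STRESS_CLASS
            ):
                raise SpectralValidationError(
                    f"labels must lie in {{{MIN_STRESS_CLASS}..{MAX_STRESS_CLASS}}}"
                )

    # -- shape helpers -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.reflectance.shape[0]

    @property
    def n_bands(self) -> int:
        return self.reflectance.shape[1]

    # -- band access ---------------------------------------------------
    def band_index(self, target_nm: float, tolerance: float = DEFAULT_BAND_TOLERANCE) -> int:
        """Index of the band nearest ``target_nm``; error if the gap exceeds tolerance."""
        if self.n_bands == 0:
            raise BandNotFoundError("library has no bands")
        idx = int(np.argmin(np.abs(self.wavelengths - target_nm)))
        gap = abs(self.wavelengths[idx] - target_nm)
        if gap > tolerance:
            raise BandNotFoundError(
                f"no band within {tolerance} nm of {target_nm} nm "
                f"(nearest is {self.wavelengths[idx]:.0f} nm, gap {gap:.0f} nm)"
            )
        return idx

    def subset_samples(self, idx) -> "SpectralLibrary":
        md = self.metadata.iloc[idx].reset_index(drop=True) if self.metadata is not None else None
        labels = self.labels[idx] if self.labels is not None else None
        ids = [self.sample_ids[i] for i in np.atleast_1d(np.arange(self.n_samples)[idx])]
        return SpectralLibrary(
            wavelengths=self.wavelengths.copy(),
            reflectance=self.reflectance[idx].copy(),
            sample_ids=ids,
            metadata=md,
            labels=labels,
        )

    def subset_bands(self, band_idx: Sequence[int]) -> "SpectralLibrary":
        band_idx = np.asarray(band_idx, dtype=int)
        order = np.argsort(self.wavelengths[band_idx])
        band_idx = band_idx[order]
        return replace(
            self,
            wavelengths=self.wavelengths[band_idx].copy(),
            reflectance=self.reflectance[:, band_idx].copy(),
        )

    def with_reflectance(self, reflectance: np.ndarray) -> "SpectralLibrary":
        return replace(self, reflectance=np.asarray(reflectance, dtype=float))


@dataclass
class BandReflectance:
    """Per-sample reflectance at the four canonical stress-diagnostic bands."""

    red: np.ndarray    # nearest band to 661 nm (chlorophyll absorption)
    nir: np.ndarray    # 854 nm (canopy structure)
    swir1: np.ndarray  # 1649 nm (water content)
    swir2: np.ndarray  # 2133 nm (leaf dryness)

    def __post_init__(self) -> None:
        for name in ("red", "nir", "swir1", "swir2"):
            v = np.asarray(getattr(self, name), dtype=float)
            if not np.all(np.isfinite(v)) or np.any(v < 0):
                raise SpectralValidationError(f"{name} reflectance must be finite and >= 0")
            setattr(self, name, v)


def canonical_bands(
    library: SpectralLibrary, tolerance: float = DEFAULT_BAND_TOLERANCE
) -> BandReflectance:
    """Extract the red/NIR/SWIR1/SWIR2 columns (nearest-band rule)."""
    return BandReflectance(
        red=extract_band(library, RED_NM, tolerance),
        nir=extract_band(library, NIR_NM, tolerance),
        swir1=extract_band(library, SWIR1_NM, tolerance),
        swir2=extract_band(library, SWIR2_NM, tolerance),
    )


def extract_band(
    library: SpectralLibrary, target_nm: float, tolerance: float = DEFAULT_BAND_TOLERANCE
) -> np.ndarray:
    """Reflectance column whose wavelength is nearest ``target_nm``.

    Raises :class:`BandNotFoundError` when the nearest gap exceeds ``tolerance``.
    """
    idx = library.band_index(target_nm, tolerance)
    return library.reflectance[:, idx].copy()


def read_spectral_library(path, rescale_percent: bool = False) -> SpectralLibrary:
    """Read a GHISACONUS-style spectral-library CSV.

    Wavelengths are parsed from ``X<nm>`` column names and returned sorted
    ascending regardless of column order in the file.  Metadata columns are
    matched case-insensitively with common synonyms (lat/latitude, lon/longitude,
    doy/julian_date).  A missing label column yields ``labels=None``.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in df.columns:
        if _FRACTIONAL_RE.match(col):
            raise SpectralFormatError(
                f"fractional wavelength in column name {col!r}; integer nm required"
            )
    spectral_cols = [(int(m.group(1)), c) for c in df.columns if (m := _SPECTRAL_RE.match(c))]
    if not spectral_cols:
        raise SpectralFormatError(f"{path}: no spectral columns matching 'X<nm>' found")
    spectral_cols.sort()  # ascending wavelength, independent of file order
    wavelengths = np.array([w for w, _ in spectral_cols], dtype=float)

    n = len(df)
    refl = np.empty((n, len(spectral_cols)), dtype=float)
    for j, (_, col) in enumerate(spectral_cols):
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise SpectralParseError(
                f"non-numeric reflectance at row {row}, column {col!r}: {df[col].iloc[row]!r}"
            )
        refl[:, j] = parsed.to_numpy()
    if np.any(refl < 0):
        i, j = np.argwhere(refl < 0)[0]
        raise SpectralValidationError(
            f"negative reflectance at row {int(i)}, column X{int(wavelengths[j])}"
        )
    if refl.size and np.nanmax(refl) > 1.5:
        if rescale_percent:
            logger.info("reflectance appears to be percent; rescaling to fractions")
            refl = refl / 100.0
        else:
            warnings.warn(
                "reflectance values exceed 1; file may carry percent reflectance "
                "(pass rescale_percent=True to convert)",
                stacklevel=2,
            )

    lower = {c.lower(): c for c in df.columns}
    metadata = {}
    for key, canonical in _METADATA_SYNONYMS.items():
        if key in lower and canonical not in metadata:
            if key != canonical:
                logger.info("metadata column %r read as %r", lower[key], canonical)
            col = df[lower[key]]
            if canonical in ("latitude", "longitude"):
                metadata[canonical] = pd.to_numeric(col, errors="coerce")
            elif canonical == "julian_date":
                metadata[canonical] = pd.to_numeric(col, errors="coerce").astype("Int64")
            else:
                metadata[canonical] = col
    metadata_df = pd.DataFrame(metadata) if metadata else None

    labels = None
    for key in _LABEL_SYNONYMS:
        if key in lower:
            labels = pd.to_numeric(df[lower[key]], errors="raise").to_numpy()
            break

    sample_ids = (
        df[lower["sample_id"]].tolist() if "sample_id" in lower else [f"s{i:05d}" for i in range(n)]
    )
    return SpectralLibrary(
        wavelengths=wavelengths,
        reflectance=refl,
        sample_ids=sample_ids,
        metadata=metadata_df,
        labels=labels,
    )


def write_spectral_library(library: SpectralLibrary, path) -> None:
    """Write a library as CSV with ``X<nm>`` columns in ascending wavelength order.

    The label column is emitted only when labels are present; metadata columns
    are emitted in canonical order.
    """
    out = {"sample_id": library.sample_ids}
    if library.metadata is not None:
        for col in METADATA_COLUMNS:
            if col in library.metadata.columns:
                out[col] = library.metadata[col].to_numpy()
    for j, wl in enumerate(library.wavelengths):
        if float(wl) != int(wl):
            raise SpectralValidationError(
                f"cannot serialise fractional wavelength {wl} nm in the X<nm> dialect"
            )
        out[f"X{int(wl)}"] = library.reflectance[:, j]
    if library.labels is not None:
        out["label"] = library.labels
    pd.DataFrame(out).to_csv(path, index=False, float_format="%.10g")


def check_alignment(a_wavelengths: np.ndarray, b_wavelengths: np.ndarray, what: str) -> None:
    """Raise :class:`AlignmentError` unless the two band grids are identical."""
    a = np.asarray(a_wavelengths, dtype=float)
    b = np.asarray(b_wavelengths, dtype=float)
    if a.shape != b.shape or not np.allclose(a, b):
        raise AlignmentError(f"{what}: band grids differ")
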