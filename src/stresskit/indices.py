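"""Vegetation stress indices.

Traditional and novel indices over the four canonical bands (red 661 nm,
NIR 854 nm, SWIR1 1649 nm, SWIR2 2133 nm):

* ``NDVI  = (NIR - Red)   / (NIR + Red)`` — chlorophyll-driven, responds late;
* ``NDWI  = (NIR - SWIR1) / (NIR + SWIR1)`` — water stress;
* ``H_VSI = (NIR - SWIR1) / (NIR + SWIR1 + SWIR2)`` — early water and
  structural stress;
* ``MLVI  = (R_854 - R_1649) / R_2133`` — the machine-learning-derived ratio
  index; the generic form ``(R_l1 - R_l2) / R_l3`` takes its three bands from
  the top of an RFE ranking, roles assigned by ascending wavelength.

Undefined values (zero denominators) propagate as NaN rather than raising,
so one bad pixel cannot abort a field-scale run.  MLVI severity bands:
>= 0.7 healthy, [0.3, 0.7) mild, [0, 0.3) moderate, < 0 severe.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import ParameterError
from .spectra_io import (
    DEFAULT_BAND_TOLERANCE,
    NIR_NM,
    RED_NM,
    SWIR1_NM,
    SWIR2_NM,
    SpectralLibrary,
    extract_band,
)
from .feature_select import BandRanking

#: category labels in increasing severity
CATEGORIES = ("healthy", "mild", "moderate", "severe")


def _safe_ratio(num, den):
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    return out if out.ndim else float(out)


def ndvi(red, nir):
    """(NIR - Red) / (NIR + Red); NaN where the denominator is not positive."""
    nir = np.asarray(nir, dtype=float)
    red = np.asarray(red, dtype=float)
    return _safe_ratio(nir - red, nir + red)


def ndwi(nir, swir1):
    """(NIR - SWIR1) / (NIR + SWIR1); NaN where undefined."""
    nir = np.asarray(nir, dtype=float)
    swir1 = np.asarray(swir1, dtype=float)
    return _safe_ratio(nir - swir1, nir + swir1)


def h_vsi(nir, swir1, swir2):
    """(NIR - SWIR1) / (NIR + SWIR1 + SWIR2); bounded in (-1, 1) for positive input."""
    nir = np.asarray(nir, dtype=float)
    swir1 = np.asarray(swir1, dtype=float)
    swir2 = np.asarray(swir2, dtype=float)
    return _safe_ratio(nir - swir1, nir + swir1 + swir2)


def mlvi_value(nir, swir1, swir2):
    """(R_854 - R_1649) / R_2133 from already-extracted band values."""
    nir = np.asarray(nir, dtype=float)
    swir1 = np.asarray(swir1, dtype=float)
    return _safe_ratio(nir - swir1, swir2)


@dataclass
class IndexSeries:
    """Per-sample values of one index over a library."""

    name: str
    values: np.ndarray
    library: Optional[SpectralLibrary] = None

    def __post_init__(self) -> None:
        self.values = np.atleast_1d(np.asarray(self.values, dtype=float))


@dataclass
class IndexDefinition:
    """A band-combination formula with resolved wavelength roles.

    kinds: ``normalized_difference`` -> (R_l1 - R_l2)/(R_l1 + R_l2);
    ``h_vsi`` -> (R_l1 - R_l2)/(R_l1 + R_l2 + R_l3);
    ``mlvi_ratio`` -> (R_l1 - R_l2)/R_l3.
    Three-band kinds use the ascending-wavelength role convention l1 < l2 < l3.
    """

    name: str
    kind: str
    lambda1: float
    lambda2: float
    lambda3: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in ("normalized_difference", "h_vsi", "mlvi_ratio"):
            raise ParameterError(f"unknown index kind {self.kind!r}")
        if self.kind != "normalized_difference":
            if self.lambda3 is None:
                raise ParameterError(f"{self.kind} requires three bands")
            if not self.lambda1 < self.lambda2 < self.lambda3:
                raise ParameterError("band roles must be in ascending wavelength order")

    def evaluate(
        self, library: SpectralLibrary, tolerance: float = DEFAULT_BAND_TOLERANCE
    ) -> IndexSeries:
        r1 = extract_band(library, self.lambda1, tolerance)
        r2 = extract_band(library, self.lambda2, tolerance)
        if self.kind == "normalized_difference":
            vals = _safe_ratio(r1 - r2, r1 + r2)
        else:
            r3 = extract_band(library, self.lambda3, tolerance)
            if self.kind == "h_vsi":
                vals = _safe_ratio(r1 - r2, r1 + r2 + r3)
            else:
                vals = _safe_ratio(r1 - r2, r3)
        return IndexSeries(name=self.name, values=vals, library=library)


#: the canonical MLVI instance over the 854/1649/2133 nm bands
MLVI_DEFINITION = IndexDefinition(
    name="mlvi", kind="mlvi_ratio", lambda1=NIR_NM, lambda2=SWIR1_NM, lambda3=SWIR2_NM
)


def mlvi(library: SpectralLibrary, tolerance: float = DEFAULT_BAND_TOLERANCE) -> IndexSeries:
    """MLVI = (R_854 - R_1649) / R_2133 per sample (nearest-band resolution)."""
    return MLVI_DEFINITION.evaluate(library, tolerance)


def hvsi_series(library: SpectralLibrary, tolerance: float = DEFAULT_BAND_TOLERANCE) -> IndexSeries:
    vals = h_vsi(
        extract_band(library, NIR_NM, tolerance),
        extract_band(library, SWIR1_NM, tolerance),
        extract_band(library, SWIR2_NM, tolerance),
    )
    return IndexSeries(name="h_vsi", values=vals, library=library)


def ndvi_series(library: SpectralLibrary, tolerance: float = DEFAULT_BAND_TOLERANCE) -> IndexSeries:
    vals = ndvi(
        extract_band(library, RED_NM, tolerance), extract_band(library, NIR_NM, tolerance)
    )
    return IndexSeries(name="ndvi", values=vals, library=library)


def ndwi_series(library: SpectralLibrary, tolerance: float = DEFAULT_BAND_TOLERANCE) -> IndexSeries:
    vals = ndwi(
        extract_band(library, NIR_NM, tolerance), extract_band(library, SWIR1_NM, tolerance)
    )
    return IndexSeries(name="ndwi", values=vals, library=library)


def formulate_index(ranking: BandRanking, name: str = "mlvi_gen") -> IndexDefinition:
    """Derive the generic ratio index from the top-3 RFE bands.

    Roles l1 < l2 < l3 are assigned by ascending wavelength, yielding
    (R_l1 - R_l2)/R_l3; applied to a ranking whose top three bands are
    {854, 1649, 2133} this reproduces the canonical MLVI exactly.
    """
    if ranking.wavelengths.size < 3:
        raise ParameterError("ranking must contain at least 3 bands")
    l1, l2, l3 = sorted(float(w) for w in ranking.top(3))
    return IndexDefinition(name=name, kind="mlvi_ratio", lambda1=l1, lambda2=l2, lambda3=l3)


def interpret_mlvi(value):
    """Map an MLVI value to a severity category.

    >= 0.7 healthy (high NIR, low SWIR); [0.3, 0.7) mild (SWIR1 rising,
    early water loss); [0, 0.3) moderate (SWIR1 and SWIR2 both rising);
    < 0 severe (dehydration, structural collapse).  NaN maps to "unknown".
    """
    v = np.asarray(value, dtype=float)
    out = np.full(v.shape, "unknown", dtype=object)
    out[v < 0] = "severe"
    out[(v >= 0) & (v < 0.3)] = "moderate"
    out[(v >= 0.3) & (v < 0.7)] = "mild"
    out[v >= 0.7] = "healthy"
    out[np.isnan(v)] = "unknown"
    if out.ndim == 0:
        return out.item()
    return out


def index_label_correlation(series: IndexSeries, labels) -> float:
    """Pearson r between index values and numeric stress labels.

    NaN index values are excluded pairwise; returns NaN when either side has
    zero variance or fewer than two valid pairs remain.
    """
    y = np.asarray(labels, dtype=float)
    x = series.values
    if x.shape != y.shape:
        raise ParameterError("series and labels must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 2:
        return float("nan")
    xc = x - x.mean()
    yc = y - y.mean()
    den = np.sqrt((xc**2).sum() * (yc**2).sum())
    if den == 0:
        return float("nan")
    return float((xc * yc).sum() / den)
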