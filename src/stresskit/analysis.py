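"""Temporal early-detection analysis and geospatial stress mapping.

Early detection compares a stressed index trajectory against a healthy
baseline trajectory on the same Julian-date grid.  The detector declares
stress at the first date where the stressed-minus-baseline difference
exceeds ``z_threshold`` times the null scale for ``run_length`` consecutive
dates of the same sign; the null scale is the standard deviation of the
paired difference over an initial calibration window, which is the correct
scale for a difference of two noisy series.  The lead time of one index
over another is the difference of their detection days.

Mapping converts per-sample index values into a [0, 1] stress score by
min-max normalisation with the sign flipped (low MLVI = high stress) and
exports RFC 7946 GeoJSON Point features in (lon, lat) order.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ParameterError
from .indices import (
    IndexDefinition,
    IndexSeries,
    hvsi_series,
    interpret_mlvi,
    mlvi,
    ndvi_series,
    ndwi_series,
)
from .spectra_io import SpectralLibrary
from .synth import TemporalDataset

logger = logging.getLogger(__name__)

_SERIES_FNS = {"mlvi": mlvi, "ndvi": ndvi_series, "ndwi": ndwi_series, "hvsi": hvsi_series}


@dataclass
class TemporalProfile:
    """Per-date mean index values for a stressed series and a healthy baseline."""

    index_name: str
    dates: np.ndarray
    stressed: np.ndarray
    baseline: np.ndarray

    def __post_init__(self) -> None:
        self.dates = np.asarray(self.dates)
        self.stressed = np.asarray(self.stressed, dtype=float)
        self.baseline = np.asarray(self.baseline, dtype=float)
        if np.any(np.diff(self.dates) <= 0):
            raise ParameterError("dates must be strictly increasing")
        if not self.dates.shape == self.stressed.shape == self.baseline.shape:
            raise ParameterError("dates, stressed and baseline must have equal length")


def temporal_profile(dataset: TemporalDataset, index: str | IndexDefinition) -> TemporalProfile:
    """Evaluate an index day-by-day on a paired temporal dataset (replicate means)."""
    if isinstance(index, IndexDefinition):
        name, fn = index.name, index.evaluate
    else:
        try:
            name, fn = index, _SERIES_FNS[index]
        except KeyError:
            raise ParameterError(f"unknown index {index!r}") from None
    stressed = np.array([np.nanmean(fn(lib).values) for lib in dataset.stressed])
    baseline = np.array([np.nanmean(fn(lib).values) for lib in dataset.baseline])
    return TemporalProfile(index_name=name, dates=dataset.dates, stressed=stressed, baseline=baseline)


def detection_day(
    profile: TemporalProfile,
    z_threshold: float = 2.0,
    run_length: int = 3,
    calibration_days: int = 15,
    floor: float = 1e-9,
) -> Optional[int]:
    """First date with ``run_length`` consecutive same-sign deviations beyond
    ``z_threshold`` times the null scale, or None if never.

    The null scale is the sd of (stressed - baseline) over the first
    ``calibration_days`` dates, clamped from below by its own sampling
    uncertainty (sd / sqrt(2(n-1))) so a lucky-quiet calibration window does
    not produce a hair-trigger threshold; scanning starts after the window.
    A degenerate all-zero difference falls back to the absolute floor.
    Adding the same constant to both series leaves the result unchanged.
    """
    if profile.dates.size < max(5, calibration_days) + run_length:
        raise ParameterError("profile too short for the calibration window")
    diff = profile.stressed - profile.baseline
    cal = diff[:calibration_days]
    scale = float(np.std(cal))
    if scale == 0.0:
        scale = floor / z_threshold if z_threshold > 0 else floor
    else:
        # one-sided guard against underestimating the null sd from few points
        scale = scale * (1.0 + 1.0 / np.sqrt(2.0 * (calibration_days - 1)))
    exceed_pos = diff > z_threshold * scale
    exceed_neg = -diff > z_threshold * scale
    for start in range(calibration_days, diff.size - run_length + 1):
        window_pos = exceed_pos[start : start + run_length]
        window_neg = exceed_neg[start : start + run_length]
        if window_pos.all() or window_neg.all():
            return int(profile.dates[start])
    return None


def earliness_lead(profile_a: TemporalProfile, profile_b: TemporalProfile, **kwargs):
    """Days by which index a detects before index b (positive = a earlier).

    None-propagating: if either index never detects, the lead is None.
    """
    if profile_a.dates.shape != profile_b.dates.shape or np.any(profile_a.dates != profile_b.dates):
        raise ParameterError("profiles must share the same date grid")
    day_a = detection_day(profile_a, **kwargs)
    day_b = detection_day(profile_b, **kwargs)
    if day_a is None or day_b is None:
        return None
    return day_b - day_a


@dataclass
class StressMap:
    """Georeferenced per-sample stress scores (score in [0, 1], 1 = most stressed)."""

    points: pd.DataFrame  # latitude, longitude, index_value, stress_score, severity
    index_name: str


def build_stress_map(library: SpectralLibrary, index_series: IndexSeries) -> StressMap:
    """Min-max normalise index values into stress scores over valid samples.

    score = (v_max - v) / (v_max - v_min), so the lowest index value (most
    stressed, for MLVI-like indices) scores 1.  Samples with missing
    coordinates or undefined index values are skipped (count logged).
    A constant index yields all scores 0.5 with a warning.
    """
    if library.metadata is None or not {"latitude", "longitude"} <= set(library.metadata.columns):
        raise ParameterError("library has no coordinates")
    if index_series.values.size != library.n_samples:
        raise ParameterError("index series does not match the library")
    lat = library.metadata["latitude"].to_numpy(dtype=float)
    lon = library.metadata["longitude"].to_numpy(dtype=float)
    v = index_series.values
    ok = np.isfinite(v) & np.isfinite(lat) & np.isfinite(lon)
    skipped = int((~ok).sum())
    if skipped:
        logger.info("build_stress_map: skipped %d sample(s) with missing data", skipped)
    v, lat, lon = v[ok], lat[ok], lon[ok]
    if v.size < 2 or np.unique(v).size < 2:
        if v.size == 0:
            raise ParameterError("no valid samples to map")
        warnings.warn("constant index; all stress scores set to 0.5", stacklevel=2)
        score = np.full(v.size, 0.5)
    else:
        score = (v.max() - v) / (v.max() - v.min())
    severity = (
        interpret_mlvi(v)
        if index_series.name.startswith("mlvi")
        else np.full(v.size, "", dtype=object)
    )
    points = pd.DataFrame(
        {
            "latitude": lat,
            "longitude": lon,
            "index_value": v,
            "stress_score": score,
            "severity": severity,
        }
    )
    return StressMap(points=points, index_name=index_series.name)


def export_geojson(stress_map: StressMap, path) -> None:
    """Write the map as an RFC 7946 FeatureCollection of Points (lon, lat order)."""
    features = []
    for _, row in stress_map.points.iterrows():
        features.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "Point",
                    "coordinates": [float(row["longitude"]), float(row["latitude"])],
                },
                "properties": {
                    "index": stress_map.index_name,
                    "index_value": float(row["index_value"]),
                    "stress_score": float(row["stress_score"]),
                    "severity": str(row["severity"]),
                },
            }
        )
    collection = {"type": "FeatureCollection", "features": features}
    with open(path, "w") as fh:
        json.dump(collection, fh, indent=1)
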