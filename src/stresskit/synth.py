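"""Seeded synthetic spectral libraries with stress-dependent structure.

The generator emulates a GHISACONUS-style canopy reflectance library over
437-2345 nm and encodes the physiology that the stress indices exploit:

* healthy canopy: green bump near 550 nm, chlorophyll absorption dip near
  661 nm, red-edge rise to a NIR plateau (~0.45 near 854 nm) and reduced
  SWIR shoulders (~0.18 at 1649 nm, ~0.09 at 2133 nm);
* progressive stress (severity ``s`` in [0, 1], class ``c`` mapped as
  ``s = c/5``): NIR reflectance declines (structural degradation), SWIR1
  rises first (early water loss) with SWIR2 following at reduced weight,
  and the red band responds late (chlorophyll breakdown) — only above
  severity 0.4 in the static library, and ``red_lag_days`` after onset in
  the temporal generator.

Bands below 620 nm and in the 700-740 nm red-edge gap carry no stress
signal by construction ("inert" bands), which makes band-selection
recovery testable against a known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .errors import ParameterError
from .spectra_io import SpectralLibrary

# smooth healthy-canopy control points (nm, reflectance fraction)
_BASE_CONTROL_POINTS = (
    (400, 0.050), (490, 0.050), (550, 0.100), (600, 0.065), (661, 0.040),
    (690, 0.050), (720, 0.220), (745, 0.400), (780, 0.440), (854, 0.450),
    (1000, 0.460), (1150, 0.450), (1300, 0.410), (1450, 0.120), (1560, 0.190),
    (1649, 0.180), (1750, 0.200), (1870, 0.070), (1940, 0.050), (2050, 0.100),
    (2133, 0.090), (2230, 0.080), (2345, 0.055), (2500, 0.040),
)

# stress-responsive wavelength regions (nm)
RED_REGION = (620.0, 700.0)
NIR_REGION = (740.0, 1360.0)
SWIR1_REGION = (1400.0, 1850.0)
SWIR2_REGION = (1860.0, 2345.0)


@dataclass
class SynthConfig:
    """Generator settings; defaults define the standard study conditions."""

    n_per_class: int = 100
    n_classes: int = 6                      # stress classes 0 (healthy) .. 5 (extreme)
    band_start: float = 437.0
    band_stop: float = 2345.0
    band_step: float = 10.0
    noise_sd: float = 0.01                  # i.i.d. Gaussian reflectance noise
    nir_drop: float = 0.45                  # fractional NIR decline at class 5
    swir_rise: float = 0.12                 # additive SWIR1 increase at class 5
    swir2_weight: float = 0.7               # SWIR2 responds at this fraction of SWIR1
    red_rise: float = 0.10                  # additive red increase at full red response
    red_onset_severity: float = 0.4         # static red response starts at this severity
    red_lag_days: int = 12                  # chlorophyll response lag (temporal mode)
    ramp_days: int = 30                     # severity 0 -> 1 ramp length (temporal mode)
    nir_structural_exponent: float = 2.0    # temporal NIR decline follows s**exponent
    bbox: tuple = (37.0, 38.0, -98.0, -97.0)  # lat_min, lat_max, lon_min, lon_max
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ParameterError("n_per_class must be >= 1")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if not 0 < self.nir_drop < 1:
            raise ParameterError("nir_drop must lie in (0, 1)")
        if self.red_lag_days < 0:
            raise ParameterError("red_lag_days must be >= 0")
        if self.ramp_days < 1:
            raise ParameterError("ramp_days must be >= 1")
        if self.n_classes < 2 or self.n_classes > 6:
            raise ParameterError("n_classes must lie in 2..6")

    @property
    def band_grid(self) -> np.ndarray:
        return np.arange(self.band_start, self.band_stop + 1e-9, self.band_step)


def base_healthy_spectrum(band_grid: Sequence[float]) -> np.ndarray:
    """Deterministic smooth healthy-canopy reflectance on ``band_grid`` (nm).

    The grid must lie within 400-2500 nm.  Repeated calls are identical.
    """
    grid = np.asarray(band_grid, dtype=float)
    if grid.size == 0 or grid.min() < 400 or grid.max() > 2500:
        raise ParameterError("band grid must lie within 400-2500 nm")
    wl, r = zip(*_BASE_CONTROL_POINTS)
    return PchipInterpolator(np.array(wl, float), np.array(r, float))(grid)


def _region_mask(grid: np.ndarray, region: tuple) -> np.ndarray:
    lo, hi = region
    return (grid >= lo) & (grid <= hi)


def inert_mask(band_grid: Sequence[float]) -> np.ndarray:
    """True for bands that carry no stress signal by construction."""
    grid = np.asarray(band_grid, dtype=float)
    responsive = (
        _region_mask(grid, RED_REGION)
        | _region_mask(grid, NIR_REGION)
        | _region_mask(grid, SWIR1_REGION)
        | _region_mask(grid, SWIR2_REGION)
    )
    return ~responsive


def spectrum_for_severity(
    config: SynthConfig,
    severity: float,
    red_severity: Optional[float] = None,
    nir_severity: Optional[float] = None,
) -> np.ndarray:
    """Noise-free canopy spectrum at a given stress severity in [0, 1].

    ``red_severity`` defaults to the static late-chlorophyll rule
    ``clip((s - red_onset_severity)/(1 - red_onset_severity), 0, 1)``;
    ``nir_severity`` defaults to ``s`` (linear structural decline).  The
    temporal generator overrides both to impose the response ordering
    (SWIR first, NIR structural decline accelerating later, red lagged).
    """
    s = float(severity)
    if red_severity is None:
        denom = 1.0 - config.red_onset_severity
        red_severity = float(np.clip((s - config.red_onset_severity) / denom, 0.0, 1.0))
    if nir_severity is None:
        nir_severity = s
    grid = config.band_grid
    r = base_healthy_spectrum(grid).copy()
    r[_region_mask(grid, NIR_REGION)] *= 1.0 - config.nir_drop * float(nir_severity)
    r[_region_mask(grid, SWIR1_REGION)] += config.swir_rise * s
    r[_region_mask(grid, SWIR2_REGION)] += config.swir2_weight * config.swir_rise * s
    r[_region_mask(grid, RED_REGION)] += config.red_rise * float(red_severity)
    return r


def _sample_block(
    config: SynthConfig,
    clean: np.ndarray,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    noisy = clean[None, :] + rng.normal(0.0, config.noise_sd, size=(n, clean.size))
    # reflectance cannot be negative; clip the rare deep-noise excursions
    return np.clip(noisy, 0.0, None)


def _random_coords(config: SynthConfig, n: int, rng: np.random.Generator):
    lat_min, lat_max, lon_min, lon_max = config.bbox
    return rng.uniform(lat_min, lat_max, n), rng.uniform(lon_min, lon_max, n)


def _metadata(lat, lon, julian_date: int) -> pd.DataFrame:
    n = len(lat)
    return pd.DataFrame(
        {
            "latitude": lat,
            "longitude": lon,
            "crop_type": ["corn"] * n,
            "growth_stage": ["mid"] * n,
            "julian_date": [julian_date] * n,
        }
    )


def generate_library(config: SynthConfig, julian_date: int = 180) -> SpectralLibrary:
    """Labeled library: ``n_per_class`` samples per stress class 0..n_classes-1.

    Severity maps linearly from class, ``s = c/5``, so class means are exactly
    ordered at the NIR/SWIR1/SWIR2 bands when ``noise_sd == 0``.  A fixed seed
    yields bitwise-identical output.
    """
    rng = np.random.default_rng(config.seed)
    blocks, labels = [], []
    for c in range(config.n_classes):
        clean = spectrum_for_severity(config, c / 5.0)
        blocks.append(_sample_block(config, clean, config.n_per_class, rng))
        labels.extend([c] * config.n_per_class)
    refl = np.vstack(blocks)
    lat, lon = _random_coords(config, refl.shape[0], rng)
    return SpectralLibrary(
        wavelengths=config.band_grid,
        reflectance=refl,
        metadata=_metadata(lat, lon, julian_date),
        labels=np.array(labels),
    )


@dataclass
class TemporalDataset:
    """Per-day paired stressed and healthy-baseline libraries."""

    dates: np.ndarray                       # Julian day-of-year, strictly increasing
    stressed: list                          # SpectralLibrary per date
    baseline: list                          # healthy replicate SpectralLibrary per date
    onset_day: int
    config: SynthConfig = field(repr=False, default=None)


def generate_temporal(
    config: SynthConfig,
    onset_day: int = 140,
    n_days: int = 120,
    n_replicates: int = 8,
    start_day: Optional[int] = None,
) -> TemporalDataset:
    """Daily paired series around a stress onset.

    Severity ramps linearly 0 -> 1 over ``config.ramp_days`` starting at
    ``onset_day``.  The SWIR and NIR responses begin at onset — SWIR
    linearly (early water loss), the NIR structural decline as
    ``s ** nir_structural_exponent`` (tissue degradation accelerates late);
    the red band joins ``red_lag_days`` later (tracking the current overall
    severity once the lag has elapsed, i.e. chlorophyll breakdown catches
    up quickly).  A healthy replicate series is generated alongside as the
    baseline.
    """
    if not 1 <= onset_day <= 366:
        raise ParameterError("onset_day must lie in 1..366")
    if start_day is None:
        start_day = max(1, onset_day - 20)
    rng = np.random.default_rng(config.seed)
    healthy_clean = spectrum_for_severity(config, 0.0)
    dates = np.arange(start_day, start_day + n_days)
    stressed, baseline = [], []
    for d in dates:
        s = float(np.clip((d - onset_day) / config.ramp_days, 0.0, 1.0))
        red_s = s if d >= onset_day + config.red_lag_days else 0.0
        nir_s = s**config.nir_structural_exponent
        clean = spectrum_for_severity(config, s, red_severity=red_s, nir_severity=nir_s)
        lat, lon = _random_coords(config, n_replicates, rng)
        stressed.append(
            SpectralLibrary(
                wavelengths=config.band_grid,
                reflectance=_sample_block(config, clean, n_replicates, rng),
                metadata=_metadata(lat, lon, int(d)),
            )
        )
        lat, lon = _random_coords(config, n_replicates, rng)
        baseline.append(
            SpectralLibrary(
                wavelengths=config.band_grid,
                reflectance=_sample_block(config, healthy_clean, n_replicates, rng),
                metadata=_metadata(lat, lon, int(d)),
            )
        )
    return TemporalDataset(
        dates=dates, stressed=stressed, baseline=baseline, onset_day=onset_day, config=config
    )


def generate_field(
    config: SynthConfig,
    hotspot_centers: Sequence[tuple],
    hotspot_radius: float,
    n_points: int = 400,
    julian_date: int = 200,
) -> SpectralLibrary:
    """Library with spatial stress structure: Gaussian hotspots of severity.

    Severity at each point is ``exp(-d^2 / (2 r^2))`` of the distance ``d`` (in
    degrees) to the nearest hotspot centre, so a point at a centre has severity
    ~1 and a far point ~0.  Labels are the nearest stress class ``round(5 s)``.
    """
    lat_min, lat_max, lon_min, lon_max = config.bbox
    centers = np.asarray(hotspot_centers, dtype=float)
    if centers.ndim != 2 or centers.shape[1] != 2:
        raise ParameterError("hotspot_centers must be (lat, lon) pairs")
    for clat, clon in centers:
        if not (lat_min <= clat <= lat_max and lon_min <= clon <= lon_max):
            raise ParameterError("hotspot centres must lie inside the bounding box")
    if hotspot_radius <= 0:
        raise ParameterError("hotspot_radius must be > 0")
    rng = np.random.default_rng(config.seed)
    lat, lon = _random_coords(config, n_points, rng)
    d2 = np.min(
        (lat[:, None] - centers[:, 0]) ** 2 + (lon[:, None] - centers[:, 1]) ** 2, axis=1
    )
    severity = np.exp(-d2 / (2.0 * hotspot_radius**2))
    refl = np.empty((n_points, config.band_grid.size))
    for i, s in enumerate(severity):
        refl[i] = spectrum_for_severity(config, float(s))
    refl = np.clip(refl + rng.normal(0.0, config.noise_sd, refl.shape), 0.0, None)
    return SpectralLibrary(
        wavelengths=config.band_grid,
        reflectance=refl,
        metadata=_metadata(lat, lon, julian_date),
        labels=np.round(severity * 5).astype(int),
    )


def generate_band_recovery_library(
    n_per_class: int = 50,
    n_bands: int = 30,
    noise_sd: float = 0.01,
    seed: int = 0,
    n_classes: int = 6,
):
    """Benchmark library for band-selection recovery tests.

    Exactly three bands — the grid positions nearest the NIR/SWIR1/SWIR2
    analogues (854/1649/2133 nm) — carry class signal with the standard
    stress response; every other band is pure noise around a constant 0.2.
    Returns ``(library, informative_wavelengths)``.
    """
    rng = np.random.default_rng(seed)
    grid = np.round(np.linspace(437, 2345, n_bands)).astype(float)
    targets = {854.0: "nir", 1649.0: "swir1", 2133.0: "swir2"}
    info_idx = {int(np.argmin(np.abs(grid - t))): role for t, role in targets.items()}
    if len(info_idx) != 3:
        raise ParameterError("n_bands too small to place three distinct informative bands")
    base = {"nir": 0.45, "swir1": 0.18, "swir2": 0.09}
    blocks, labels = [], []
    for c in range(n_classes):
        s = c / 5.0
        clean = np.full(n_bands, 0.2)
        for idx, role in info_idx.items():
            if role == "nir":
                clean[idx] = base["nir"] * (1 - 0.45 * s)
            elif role == "swir1":
                clean[idx] = base["swir1"] + 0.12 * s
            else:
                clean[idx] = base["swir2"] + 0.7 * 0.12 * s
        noisy = clean[None, :] + rng.normal(0.0, noise_sd, size=(n_per_class, n_bands))
        blocks.append(np.clip(noisy, 0.0, None))
        labels.extend([c] * n_per_class)
    library = SpectralLibrary(
        wavelengths=grid, reflectance=np.vstack(blocks), labels=np.array(labels)
    )
    informative = sorted(grid[i] for i in info_idx)
    return library, informative
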