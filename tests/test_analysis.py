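"""Early-detection timing and geospatial stress mapping."""

import json

import numpy as np
import pytest

from stresskit import (
    IndexSeries,
    SynthConfig,
    TemporalProfile,
    build_stress_map,
    detection_day,
    earliness_lead,
    export_geojson,
    generate_field,
    mlvi,
    temporal_profile,
)
from stresskit.errors import ParameterError
from stresskit.synth import generate_temporal


def profile_from(diff, sd=1.0, rng=None, n=60):
    """Baseline = noise; stressed = baseline + diff (diff padded to length n)."""
    rng = rng or np.random.default_rng(0)
    base = rng.normal(0, sd, n)
    stressed = base + rng.normal(0, sd, n)
    stressed[: len(diff)] += 0  # placeholder to keep lengths explicit
    full_diff = np.zeros(n)
    full_diff[-len(diff) :] = diff
    return TemporalProfile(
        index_name="x", dates=np.arange(100, 100 + n), stressed=stressed + full_diff, baseline=base
    )


class TestDetectionDay:
    def test_identical_series_never_detects(self):
        dates = np.arange(100, 160)
        p = TemporalProfile("x", dates, np.full(60, 0.4), np.full(60, 0.4))
        assert detection_day(p) is None

    def test_step_change_detected_at_step(self, rng):
        n = 60
        base = rng.normal(0, 0.01, n)
        stressed = base.copy()  # paired series: no pre-step difference
        stressed[40:] += 0.1  # 10x the series sd
        p = TemporalProfile("x", np.arange(100, 100 + n), stressed, base)
        assert detection_day(p, run_length=1) == 140

    def test_shift_invariance(self, rng):
        n = 60
        base = rng.normal(0, 0.01, n)
        stressed = base + rng.normal(0, 0.01, n)
        stressed[35:] += 0.08
        dates = np.arange(100, 100 + n)
        a = detection_day(TemporalProfile("x", dates, stressed, base))
        b = detection_day(TemporalProfile("x", dates, stressed + 5.0, base + 5.0))
        assert a == b

    def test_degenerate_baseline_uses_floor(self):
        dates = np.arange(100, 160)
        stressed = np.full(60, 0.4)
        stressed[30:] += 1e-3
        p = TemporalProfile("x", dates, stressed, np.full(60, 0.4))
        assert detection_day(p) == 130

    def test_too_short_profile_rejected(self):
        p = TemporalProfile("x", np.arange(5), np.ones(5), np.ones(5))
        with pytest.raises(ParameterError):
            detection_day(p)


class TestEarlinessLead:
    def test_identical_profiles_lead_zero(self, rng):
        n = 60
        base = rng.normal(0, 0.01, n)
        stressed = base + rng.normal(0, 0.01, n)
        stressed[40:] += 0.1
        p = TemporalProfile("x", np.arange(100, 100 + n), stressed, base)
        assert earliness_lead(p, p) == 0

    def test_subtraction_and_antisymmetry(self, rng):
        n = 70
        dates = np.arange(100, 100 + n)
        base = rng.normal(0, 0.01, n)
        a_vals = base + rng.normal(0, 0.01, n)
        b_vals = base + rng.normal(0, 0.01, n)
        a_vals[50:] += 0.1  # a detects at 150
        b_vals[62:] += 0.1  # b detects at 162
        pa = TemporalProfile("a", dates, a_vals, base)
        pb = TemporalProfile("b", dates, b_vals, base)
        assert earliness_lead(pa, pb) == 12
        assert earliness_lead(pb, pa) == -12

    def test_missing_detection_propagates_none(self, rng):
        n = 60
        dates = np.arange(100, 100 + n)
        base = rng.normal(0, 0.01, n)
        quiet = TemporalProfile("q", dates, base + rng.normal(0, 0.01, n), base)
        loud_vals = base + rng.normal(0, 0.01, n)
        loud_vals[40:] += 0.2
        loud = TemporalProfile("l", dates, loud_vals, base)
        assert earliness_lead(loud, quiet) is None

    def test_mismatched_grids_rejected(self):
        a = TemporalProfile("a", np.arange(30), np.ones(30), np.ones(30))
        b = TemporalProfile("b", np.arange(1, 31), np.ones(30), np.ones(30))
        with pytest.raises(ParameterError):
            earliness_lead(a, b)


class TestTemporalProfileFromGenerator:
    def test_mlvi_leads_ndvi_single_seed(self):
        cfg = SynthConfig(noise_sd=0.005, red_lag_days=12, seed=0)
        data = generate_temporal(cfg, onset_day=140)
        lead = earliness_lead(temporal_profile(data, "mlvi"), temporal_profile(data, "ndvi"))
        assert lead is not None and 9 <= lead <= 15


class TestStressMap:
    def test_score_endpoints(self):
        cfg = SynthConfig(noise_sd=0.0, seed=0)
        lib = generate_field(cfg, [(37.5, -97.5)], hotspot_radius=0.15, n_points=50)
        series = mlvi(lib)
        smap = build_stress_map(lib, series)
        v = smap.points["index_value"].to_numpy()
        s = smap.points["stress_score"].to_numpy()
        assert s[np.argmin(v)] == pytest.approx(1.0)
        assert s[np.argmax(v)] == pytest.approx(0.0)

    def test_score_monotone_nonincreasing_in_index(self):
        cfg = SynthConfig(noise_sd=0.005, seed=1)
        lib = generate_field(cfg, [(37.5, -97.5)], hotspot_radius=0.15, n_points=80)
        smap = build_stress_map(lib, mlvi(lib))
        df = smap.points.sort_values("index_value")
        assert np.all(np.diff(df["stress_score"].to_numpy()) <= 1e-12)

    def test_hotspot_scores_exceed_background(self):
        cfg = SynthConfig(noise_sd=0.005, seed=2)
        center, radius = (37.5, -97.5), 0.15
        lib = generate_field(cfg, [center], hotspot_radius=radius, n_points=300)
        smap = build_stress_map(lib, mlvi(lib))
        d = np.hypot(
            smap.points["latitude"] - center[0], smap.points["longitude"] - center[1]
        ).to_numpy()
        scores = smap.points["stress_score"].to_numpy()
        assert scores[d < radius].mean() > scores[d >= radius].mean()

    def test_constant_index_half_scores_with_warning(self):
        cfg = SynthConfig(noise_sd=0.005, seed=3)
        lib = generate_field(cfg, [(37.5, -97.5)], hotspot_radius=0.15, n_points=20)
        series = IndexSeries(name="flat", values=np.full(20, 1.5))
        with pytest.warns(UserWarning, match="constant"):
            smap = build_stress_map(lib, series)
        assert np.all(smap.points["stress_score"] == 0.5)

    def test_undefined_values_skipped(self):
        cfg = SynthConfig(noise_sd=0.005, seed=4)
        lib = generate_field(cfg, [(37.5, -97.5)], hotspot_radius=0.15, n_points=20)
        vals = mlvi(lib).values
        vals[3] = np.nan
        smap = build_stress_map(lib, IndexSeries(name="mlvi", values=vals))
        assert len(smap.points) == 19


class TestGeoJSON:
    def test_round_trip_counts_and_coordinate_order(self, tmp_path):
        cfg = SynthConfig(noise_sd=0.005, seed=5)
        lib = generate_field(cfg, [(37.5, -97.5)], hotspot_radius=0.15, n_points=60)
        smap = build_stress_map(lib, mlvi(lib))
        path = tmp_path / "map.geojson"
        export_geojson(smap, path)
        parsed = json.loads(path.read_text())
        assert parsed["type"] == "FeatureCollection"
        assert len(parsed["features"]) == 60
        feat = parsed["features"][0]
        lon, lat = feat["geometry"]["coordinates"]  # RFC 7946: lon first
        assert -98.0 <= lon <= -97.0
        assert 37.0 <= lat <= 38.0
        assert {"index_value", "stress_score", "severity"} <= set(feat["properties"])
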