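"""Geospatial stress mapping: hotspots to GeoJSON.

Simulates a field with two stress hotspots (severity = Gaussian of the
distance to the nearest hotspot centre), computes MLVI per sample, converts
it to a [0, 1] stress score (low MLVI = high stress) and exports an
RFC 7946 GeoJSON FeatureCollection of Points.
"""

import numpy as np

from stresskit import SynthConfig, build_stress_map, export_geojson, generate_field, mlvi

config = SynthConfig(noise_sd=0.005, seed=5)
centers = [(37.3, -97.7), (37.7, -97.2)]
field = generate_field(config, centers, hotspot_radius=0.12, n_points=300)

stress_map = build_stress_map(field, mlvi(field))
points = stress_map.points

d = np.minimum.reduce([
    np.hypot(points["latitude"] - lat, points["longitude"] - lon) for lat, lon in centers
])
inside = points["stress_score"][d < 0.12]
outside = points["stress_score"][d >= 0.12]
print(f"{len(points)} mapped points")
print(f"mean stress score inside hotspots:  {inside.mean():.3f}")
print(f"mean stress score outside hotspots: {outside.mean():.3f}")
print("severity counts:", points["severity"].value_counts().to_dict())

export_geojson(stress_map, "stress_map.geojson")
print("\nwrote stress_map.geojson (Point features, [lon, lat] order, with"
      "\nindex_value / stress_score / severity properties); scores near 1"
      "\nmark the most stressed locations.")
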