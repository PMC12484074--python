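"""Simulate a labeled spectral library and compute stress indices.

Generates a 6-class synthetic canopy-reflectance library (437-2345 nm,
class 0 = healthy .. class 5 = extreme stress), then evaluates NDVI, NDWI,
H_VSI and MLVI per class.  MLVI = (R_854 - R_1649)/R_2133 should fall from
~3 (healthy: high NIR plateau, low SWIR) to below 0 (severe: NIR collapse,
SWIR rise), crossing the severity bands healthy/mild/moderate/severe.
"""

import numpy as np

from stresskit import SynthConfig, generate_library, interpret_mlvi, mlvi
from stresskit.indices import hvsi_series, ndvi_series, ndwi_series

library = generate_library(SynthConfig(n_per_class=50, seed=7))
print(f"library: {library.n_samples} samples x {library.n_bands} bands "
      f"({library.wavelengths[0]:.0f}-{library.wavelengths[-1]:.0f} nm)\n")

series = {
    "NDVI": ndvi_series(library).values,
    "NDWI": ndwi_series(library).values,
    "H_VSI": hvsi_series(library).values,
    "MLVI": mlvi(library).values,
}
print(f"{'class':>5} {'NDVI':>7} {'NDWI':>7} {'H_VSI':>7} {'MLVI':>7}  category")
for c in range(6):
    mask = library.labels == c
    means = {k: np.nanmean(v[mask]) for k, v in series.items()}
    category = interpret_mlvi(means["MLVI"])
    print(f"{c:>5} {means['NDVI']:>7.3f} {means['NDWI']:>7.3f} "
          f"{means['H_VSI']:>7.3f} {means['MLVI']:>7.3f}  {category}")

print("\nMLVI separates the severity levels monotonically and its category"
      "\nbands (>=0.7 healthy, 0.3-0.7 mild, 0-0.3 moderate, <0 severe)"
      "\ntrack the class labels; NDVI barely moves for the first two classes"
      "\nbecause the red band responds late.")
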