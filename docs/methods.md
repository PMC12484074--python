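# Methods

This note documents the models, conventions and design choices behind
stresskit: what the synthetic data emulate, how each stage is defined, the
parameters that matter, and what the package's tests do and do not show
about real spectral libraries.

## Data model

A `SpectralLibrary` is a samples × bands matrix of unitless reflectance
fractions on a strictly increasing wavelength grid (nm), with per-sample
metadata (latitude, longitude, crop type, growth stage, Julian day) and an
optional ordinal stress label 0–5. The CSV dialect uses `X<integer nm>`
column names; fractional wavelengths in names are rejected. Band access is
nearest-neighbour with a 15 nm tolerance (about one spaceborne
hyperspectral band spacing); the four canonical bands are red 661 nm, NIR
854 nm, SWIR1 1649 nm, SWIR2 2133 nm. Values in (1.5, 100] trigger a
percent-scale warning with an opt-in rescale, since library provenance
often leaves units ambiguous. Negative reflectance is rejected at load
time only, so z-scored libraries remain representable in memory.

## Synthetic generator

The generator is the package's study-condition definition, not a
convenience fixture. The healthy base spectrum is a monotone-segment PCHIP
curve through fixed control points: low visible reflectance with a green
bump at 550 nm, a chlorophyll absorption dip at 661 nm (~0.04), a red-edge
rise to a NIR plateau of ~0.45, water-absorption dips at 1450/1940 nm, and
SWIR shoulders of ~0.18 (1649 nm) and ~0.09 (2133 nm).

Stress is a severity s ∈ [0, 1]; class c maps linearly as s = c/5.
Responses by region:

* NIR (740–1360 nm): scaled by (1 − 0.45·s) — structural degradation;
* SWIR1 (1400–1850 nm): + 0.12·s — early water loss;
* SWIR2 (1860–2345 nm): + 0.7·0.12·s — drying, at reduced weight so that
  H_VSI and MLVI differ measurably;
* red (620–700 nm): + 0.10·clip((s − 0.4)/0.6, 0, 1) — chlorophyll
  breakdown, a late response that only starts above severity 0.4.

Bands below 620 nm and in the 700–740 nm gap are inert by construction,
which gives band-selection tests a ground truth. Noise is i.i.d. Gaussian
per band (default sd 0.01) with a clip at zero; no band-correlated noise
model is included. All magnitudes are package conventions chosen once to
match the qualitative physiology above; they are exposed in `SynthConfig`.

**Temporal mode** ramps severity linearly 0 → 1 over `ramp_days`
(default 30) from an onset day. The response *ordering* is imposed
explicitly: SWIR responds from onset; the NIR decline follows
s^2 (exponent configurable) so the structural response accelerates late;
the red band stays at baseline until `red_lag_days` (default 12) after
onset and then tracks the current severity. The s² NIR shape matters: with
a linear NIR decline, NDVI drifts away from baseline through its NIR term
well before the red response, and no parameter choice can hold the
detection lead near the chlorophyll lag. Each day carries `n_replicates`
(default 8) stressed and healthy samples; profiles use replicate means.

**Field mode** places Gaussian severity hotspots: severity =
exp(−d²/2r²) of the distance to the nearest centre, in degrees.

**Recovery benchmark**: a separate generator in which exactly three bands
(the grid positions nearest 854/1649/2133 nm) carry the standard class
signal and all others are pure noise around 0.2 — the setting in which
"did selection find the right bands" is a well-posed question.

## Preprocessing

Savitzky–Golay weights are computed from the window design matrix
A[j, q] = j^q via pseudoinverse; the centre-point row gives the kernel.
Default window 11 bands (m = 5), polynomial order 2 — wide enough to
suppress noise, low enough to preserve narrow absorption features. Edges
are mirror-padded so output length equals input length. The implementation
is cross-checked in tests against an independent per-window polynomial-fit
oracle and against `scipy.signal.savgol_coeffs`.

Z-scoring uses the population (1/n) standard deviation, recorded in the
statistics object to keep round-trips unambiguous. Statistics are fitted
on the training rows only and applied to all rows; this deviates from the
common normalise-then-split ordering deliberately, to prevent test-set
leakage. `pooled_normalization=True` in the pipeline (CLI `--pooled-norm`)
restores whole-dataset fitting for strict reproduction of that ordering. Zero-variance bands are flagged
and either dropped or passed through as 0.

## Band selection

RFE follows the strict one-band-per-iteration loop: fit, score, drop the
single lowest-importance band, repeat to k = 10. Importance ties are
broken by dropping the *longest* wavelength, making selection a function
of wavelengths rather than column order (libraries are always stored
wavelength-sorted, so file column order cannot matter either). Two
importance scorers satisfy the estimator contract: a random-forest
impurity scorer (default) and a linear one-vs-rest margin scorer
(Σ|coef| over classes). The surviving bands are ranked by a final fit.

Correlation pruning (greedy scan in wavelength order, drop at |r| > 0.95
against a retained band) and PCA (k = 30, scikit-learn backed, verified
against an eigendecomposition oracle) are exploration tools. Pruning is
*not* a default pipeline stage: under the generator's single severity
latent, NIR and SWIR regions are anti-correlated beyond the threshold, and
pruning would delete entire informative regions rather than duplicates.

For the same reason the default pipeline computes MLVI from the canonical
854/1649/2133 nm bands rather than from its own RFE ranking
(`use_generated_index=False`): on effectively rank-1 data,
importance-guided elimination concentrates the surviving bands inside the
single strongest region (NIR), because once one region separates the
classes the others add no importance. The ranking-derived index
(`formulate_index`, top-3 bands, roles by ascending wavelength) is
exercised on the recovery benchmark, where it reproduces the canonical
formula exactly.

## Indices

All index arithmetic propagates undefined values (zero denominators) as
NaN rather than raising, so a single bad pixel cannot abort a field run.
MLVI is an unbounded ratio and is reported raw. The severity mapping
closes the gaps the qualitative banding leaves open: boundaries at 0, 0.3
and 0.7, half-open intervals with the lower bound inclusive, so every
finite value maps to exactly one of severe/moderate/mild/healthy.

## Classifiers

The stratified split is 70/15/15 with largest-remainder rounding per
class (deviation ≤ 1 sample from target) and requires ≥ 3 samples per
class. The 1D CNN is implemented in NumPy: valid convolutions (f1 = 32,
f2 = 64, kernel 3) with ReLU, max-pool 2, inverted dropout 0.3, dense
softmax over 6 classes; categorical cross-entropy with a 1e-12 log floor;
Adam (lr 0.001) with reduce-on-plateau (factor 0.5, patience 5) on the
validation loss; best-validation weights retained; 60 epochs, batch 32.
One seed drives initialisation, batch order and dropout masks, so training
is bit-reproducible on CPU, and the backward pass is verified against
finite differences. The default feature sequence is the 10 RFE-selected
band z-scores (ascending wavelength) followed by z-scored [MLVI, H_VSI];
index-pair-only, PCA-score and NDVI-only modes reproduce the alternative
input arms, noting that sequences shorter than the kernel require a
smaller `kernel_size` (the configuration is rejected otherwise).

LDA (pooled within-class covariance, lsqr solver with 0.01 diagonal
shrinkage for near-collinear features) and a linear one-vs-rest SVM with
cross-validated probability calibration consume the identical features and
split. scikit-learn stands behind both baselines and behind the RFE
estimators; the elimination loop, the CNN, the metrics and the indices are
implemented in the package.

## Metrics

Accuracy is trace/total. Precision/recall/F1 come from the one-vs-rest
reduction per class; macro averages exclude undefined (empty-class)
entries with a warning; micro variants are also reported. The headline MCC
is the multiclass Rₖ coefficient — the Pearson correlation between one-hot
truth and prediction — which reduces exactly to the binary formula at
C = 2 (asserted numerically in tests); a zero denominator yields 0 by
convention, and the doubly degenerate case (single true and single
predicted class) is reported missing. AUC uses the Mann–Whitney rank
statistic with midranks for ties, per class one-vs-rest plus a pooled
micro average, verified against a brute-force all-pairs oracle.

## Early detection and mapping

The detector declares stress at the first date where
|stressed − baseline| exceeds z·(null scale) for `run_length` consecutive
same-sign dates (defaults z = 2, run 3). The null scale is the standard
deviation of the *paired difference* over an initial calibration window
(default 15 dates) — the correct scale for a noisy-minus-noisy comparison —
inflated by its own sampling uncertainty (1 + 1/√(2(n−1))) so a
lucky-quiet window cannot produce a hair-trigger threshold; scanning
starts after the window, and an all-zero difference falls back to an
absolute floor. With the default calibration (12-day lag, noise 0.005),
MLVI detects ~2 days after onset and NDVI at the red response, giving
leads of 9–11 days in almost all seeds.

Stress maps min-max normalise index values to scores
(v_max − v)/(v_max − v_min), so the lowest MLVI scores 1 (most stressed);
a constant index yields all 0.5 with a warning. Export is RFC 7946
GeoJSON, coordinates in (lon, lat) order; logs use (lat, lon).

## Pipeline and reproducibility

`run_pipeline` chains simulate → split → smooth → z-score → (optional
prune) → RFE → indices → features → train → evaluate (→ map), writing
metrics JSON, ranking JSON, index CSV, CNN weights + JSON sidecar,
training history CSV and a GeoJSON map, each stamped with a config hash
and the seed. A single global seed fans out per stage via CRC32 of the
stage name, so stages can be re-run in isolation.

Problem sizes in the shipped tests and the acceptance script are
desk-scale by design: 100 samples per class for classification runs,
50 per class on a 30-band grid for selection-recovery, 8 replicates per
day over ~120 days for temporal runs. The acceptance script averages 3
pipeline seeds and 10 selection/temporal seeds.

## What the synthetic results do and do not show

The generator produces cleanly separable classes — a single severity
latent, region-wise deterministic responses, i.i.d. noise — so classifier
scores sit at or near the ceiling and should be read as contract checks
(the pipeline learns what is learnable, the CNN at least matches the
linear baselines, metrics are computed correctly), not as performance
forecasts for field data, which add sensor artefacts, mixed stressors,
atmospheric residuals and label noise. Likewise the early-detection lead
measures the generator's configured chlorophyll lag propagated through
both index formulas and the detector — evidence that the indices respond
in the designed order, not a field-measured lead time. Known limitations:
no radiative-transfer simulation, no band-correlated noise, no derivative
spectra or continuum removal, point maps without raster interpolation.
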