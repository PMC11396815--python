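# Methods

This note records the scientific model behind `smcfusion`, the defaults and
why they are what they are, and the choices made where the underlying
methodology left room for interpretation.

## Problem and pipeline

Gravimetric soil moisture content (SMC, mass fraction) at three depths
(0–20, 20–40, 40–60 cm) is predicted per experimental plot from two
airborne rasters: 6-band canopy reflectance (490, 555, 680, 720, 800,
900 nm) and a thermal image (°C). The chain is

1. canopy masking (per-pixel NDVI > threshold),
2. plot-mean band reflectance → 15 vegetation indices (VIs),
3. per-band GLCM textures → 48 texture values (TF),
4. exhaustive pairing of texture values into 6 texture indices (TIs),
5. thermal calibration → 4 thermal indices (TVIs),
6. Pearson screening at p < 0.01,
7. three regression learners over ten single/fused input combinations,
   scored on a held-out third of the plots.

## Ground measurements

SMC per sample is `W = (M1 − M2)/M1` (wet basis): the water lost on oven
drying divided by the **wet** mass. This is the form the workflow is built
around; note that soil physics more commonly uses the dry-basis form
`(M1 − M2)/M2`, which is available via `basis="dry"`. Five samples per plot
are averaged. Wet-basis W is bounded in [0, 1) and scale-invariant in the
masses.

## Vegetation indices

Formulas follow the published catalog, including two deliberately
non-canonical forms kept for comparability rather than "corrected":

* **OSAVI** uses the green band, `(1+X)(R_NIR − R_G)/(R_NIR + R_G + X)`
  with X = 0.16, where the canonical form uses red;
* **NLI** uses the red edge, `(R_NIR² − R_RE)/(R_NIR² + R_RE)`.

Each index is computed at both candidate NIR bands (800, 900 nm) and the
band with the larger |Pearson r| against SMC **on the training split only**
is kept (ties → 800 nm). Restricting the choice to the training split
avoids selection leakage into validation metrics. A zero denominator makes
the value missing (NaN); nothing is imputed.

Masking uses NDVI > 0.3 by default — a common canopy/soil cut for a dense
flowering canopy; it is a config field (`vi_threshold`) since the right cut
depends on canopy closure.

## GLCM textures

Per band, the raster is min–max quantized to G = 32 gray levels (a standard
remote-sensing default; configurable). A 3×3 window slides over the raster;
for each of the four distance-1 directions a symmetric co-occurrence
distribution is built from the pixel pairs inside the window, the eight
statistics are evaluated, and the four directional values are averaged into
the window's (center-pixel) texture value. Plot values are means over
canopy-masked interior pixels.

Conventions that matter numerically:

* gray levels are the 0-based bins (so `Mea` of a constant plot is 0, not 1);
* entropy is `−Σ P ln P` with `0·ln 0 = 0`. The source table prints the sum
  without the minus sign, which would be ≤ 0 and violate the Ent ≥ 0 bound
  the rest of the methodology assumes; the standard signed form is used.
  Base-e is used throughout — any fixed base only rescales entropy and
  cannot change correlation-based rankings;
* correlation (`Cor`) returns the sentinel 0 when a marginal variance is
  zero (single-gray-level window) instead of NaN, so constant regions do
  not poison plot means; this is a documented degeneracy convention;
* windows are "valid" only — edge pixels with no full 3×3 neighborhood are
  skipped, never padded, so no border statistics are fabricated;
* directional offsets use the (row, col) = (sin θ, cos θ) convention of
  scikit-image; with symmetric counting the sign of the offset is
  irrelevant, and 4-direction averages are convention-free.

The sliding implementation is vectorized (per-window pair lists, multiplicity
counting for Sec/Ent) and is tested pointwise against an independent oracle:
scikit-image `graycomatrix` per window plus direct matrix formulas.

## Texture indices and the exhaustive search

Six forms combine two texture values T1, T2:
NDTI = (T1−T2)/(T1+T2), DTI = T1−T2, RTI = T1/T2,
NTI = (T1²−T2)/(T1²+T2), RDTI = 1/T1 − 1/T2, RATI = 1/T1 + 1/T2.

The search space is **all ordered pairs of the 48 identities, identical
pairs included** (48×48 per form). Identical pairs are deliberately in
scope: RATI(x, x) = 2/x is a legitimate reciprocal transform that can be
the best scorer. Ties break to the first pair in band-major catalog order.
The best pair is chosen by |Pearson r| against each layer's SMC on the full
sample (see the leakage note under Screening). Degenerate candidates
(constant or undefined vectors) are skipped with a warning.

## Thermal features

Thermal rasters are calibrated by OLS (`reference = a·image + b`) against
leaf/water reference targets; ≥2 points with distinct image temperatures
are required and the fit R² is reported. The four indices use °C as given
— CRTD and SRTD are ratios of temperature sums, so their values are
unit-convention dependent; this matches the published definition and is
why they are documented as °C-only.

`TcD = T_canopy,plot-mean − T_air` (canopy minus air: positive = stressed).
NRCT normalizes the plot mean by **field-wide canopy extremes** (over all
plots' canopy pixels, after calibration); soil extremes for SRTD are
within-plot. Because the field extremes are shared, CRTD is constant across
plots of one flight and is screened out by the significance filter — the
implementation keeps it for single-flight completeness rather than
usefulness. An absent soil mask records SRTD as missing, not an error.

## Screening

Each feature is tested per layer with the two-sided t-test
`t = r√(n−2)/√(1−r²)`, df = n−2; selection at α = 0.01. At n = 96 the
implied critical |r| is ≈ 0.262. **No multiple-testing correction** is
applied: the rule is per-feature by design, a liberal choice that mirrors
how such screens are used in this literature, and the type-I rate is
verified by simulation in the acceptance suite. Screening (and the TI pair
search) runs on the full sample rather than the training split — the
conventional but leakage-prone practice in this field; the NIR-band choice
is split-aware, and moving the whole screen inside the split is the obvious
hardening for real use.

## Learners

* **"XGBoost"**: the xgboost library is not available in the supported
  environment, so this working point (100 estimators, learning rate 0.03,
  max depth 5) is backed by scikit-learn's `GradientBoostingRegressor` —
  the same additive-tree model class at the same hyperparameters.
* **RF**: scikit-learn `RandomForestRegressor`, 100 trees.
* **GA-BP** (implemented here from scratch): a feedforward net with one
  hidden layer of 5 sigmoid units and a linear output. A genetic algorithm
  (population 5, 50 generations, crossover 0.4, mutation 0.05, elitism 1,
  fitness-proportional selection, arithmetic crossover, Gaussian mutation)
  chooses the initial weights; fitness is the training MSE after a short
  (20-epoch) backpropagation refinement. The best genome is then trained up
  to 1000 epochs or MSE ≤ 1e-6.

GA-BP details chosen here: inputs and target are min–max scaled to [0, 1]
on the training data (stored with the model; the 1e-6 goal applies to the
scaled MSE, as is conventional for that goal value). Backpropagation is
full-batch gradient descent with an adaptive step (×1.05 on improvement,
×0.7 and reject otherwise) — deterministic, robust across input dimensions,
and the classical adaptive-rate BP variant. The crossover/mutation rates
are read as probabilities 0.4/0.05; the literal "percent" values (0.004,
0.0005) would leave a population of 5 essentially inert. The input layer is
sized to the number of selected features for the combination at hand rather
than fixed at 5, since input dimension varies by combination.

All three learners are seeded; per-cell seeds derive deterministically
(crc32 of the cell label) from the run seed, so a run is reproducible
byte-for-byte.

## Split and metrics

A seeded uniform split puts round(2n/3) plots in training (64/32 at n = 96);
no stratification. Metrics on validation, with SMC expressed in percent:

* `R² = 1 − Σ(ŷ−y)²/Σ(y−ȳ)²`, `RMSE = √(Σ(ŷ−y)²/n)` (% SMC),
  `MRE = mean(|ŷ−y|/y)·100`.
* The source prints R² as `Σ(ŷ−ȳ)²/Σ(y−ȳ)²` and RMSE on deviations from
  the mean; taken literally, that RMSE never looks at the predictions.
  The standard forms above are the defaults; the printed forms remain
  available via `metrics(..., printed_variant=True)` for comparison only.

## The synthetic world

No field data are deposited, so a seeded generator stands in: 96 plots
(16 treatments × 3 replicates × 2 years, treatments kept as labels only),
64-px rasters, soil pixels interspersed at 15%. Planted structure, all
linear in the surface-layer SMC:

* NIR reflectance rises with SMC, red falls slightly (canopy vigour);
* canopy temperature falls with SMC (range 5 °C across the SMC span);
* within-canopy spatial heterogeneity (amplitude of a smoothed Gaussian
  field, zero-meaned over the canopy so plot means stay exactly linear)
  falls with SMC — this is what gives GLCM features real signal;
* deeper layers are Gaussian-copula copies of the surface layer
  (ρ = 0.8 between adjacent layers), so all signals decay with depth;
* soil pixels are hot (+8 °C over air) with a high-red/low-NIR spectrum
  (NDVI ≈ 0.15), making masking and SRTD non-degenerate.

Default magnitudes were fixed once, from first principles: SMC spans
0.09–0.24 (the site description's wilting point ≈ 8.5% and field capacity
≈ 23–25% by mass); pixel noise sd 0.01 reflectance / 0.3 °C. Pixel noise
averages out over ~3.5k canopy pixels, so **plot-level residuals** are what
set realistic correlations — band-relative reflectance sd 10% and thermal
sd 1.5 °C put |r(SMC, plot-mean NIR)| near 0.65–0.7 for the surface layer,
the scale of the strongest correlations such studies report. These are free
parameters of the stated world, not estimates of any real site.

What the generator does **not** emulate: radiative transfer, row/canopy
geometry, registration error, treatment effects (available as an optional
SMC offset but zero by default), spatially correlated sensor noise, or any
SMC-dependence of soil temperature (so SRTD is honest noise). A green
end-to-end test therefore establishes that the pipeline recovers planted
monotone couplings through the full feature chain — not that it would reach
any particular accuracy on real fields.

## Evaluation findings on the synthetic world

With all defaults, fusing VIs+TIs+TVIs improves validation R² over the best
single family for the surface layer in ≥70% of seeds for the
best-performing learner, and mean fused R² decays with depth (≈0.83 / 0.43
/ 0.23 over 20 seeds). The best learner on this world is GA-BP, not the
boosted trees: at n_train = 64 and learning rate 0.03 the gradient-boosted
model degrades as correlated features are added, a known small-sample
behavior of boosting at fixed hyperparameters. The fusion-vs-single
comparison is therefore stated for the empirically best learner (as such
studies state their headline result), determined from the evaluation matrix
itself rather than fixed in advance.

## Known limitations

* Full-sample screening and TI search leak target information into feature
  selection (flagged above); validation R² is optimistic to that extent.
* CRTD is uninformative within a single flight by construction.
* The GA at population 5 is a light global search; it mainly diversifies
  initializations rather than exploring weight space broadly.
* Geo-metadata is a dummy affine: rasters are plain multi-band TIFFs with a
  JSON sidecar, not full GeoTIFFs with CRS.
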