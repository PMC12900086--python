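# Methods

## Pipeline model

The package implements a four-stage diagnostic chain over a single
nadir RGB canopy image:

1. **Per-pixel classification.** The discriminant index
   `I = 128 + 128·(G − R)/(G + R)` is the normalised green–red contrast
   mapped onto a 0–256 scale with gray at 128. It is computed in double
   precision and never rounded or clamped before thresholding; the
   classification rule is the inclusive comparison `I ≥ 134`. The blue
   channel is decoded but excluded from the classifier by design: under
   paddy conditions blue varies strongly with sky reflection on water
   while the green–red contrast tracks leaf tissue.
2. **Cover ratio.** `C = 100 · (vegetation pixels)/(total pixels)`. The
   whole frame is counted — no border exclusion and no automatic
   cropping to the hill grid; framing is a capture-protocol concern.
3. **Tiller estimation.** `T(C) = a·C² + b·C + c` with built-in
   coefficients `a = −0.0548`, `b = 9.13`, `c = 77.7` (cover in
   **percent**, T in tillers m⁻²). The coefficient units make the
   percent convention unambiguous: `c = 77.7 tillers m⁻²` is the
   zero-cover baseline and mid-range covers give realistic field
   values. The built-in model carries its source planting-density
   range (11.0–18.3 hills m⁻², 'Koshihikari') as metadata only — the
   package cannot observe density from an image, so it documents
   rather than enforces applicability.
4. **Threshold diagnosis.** Optimal drainage timing iff
   `T ≥ target(cultivar)`, inclusive at equality, on the unrounded
   estimate. Built-in targets: Fusaotome 400, Fusakogane 360,
   Koshihikari 320 tillers m⁻². Rounding before comparison would
   create a second, undocumented threshold, so display rounding (one
   decimal) is confined to the CLI's human-readable summary line.

## Assumptions and edge cases

- **r + g = 0** (pure black or pure blue pixels): the index is defined
  as the neutral value 128, so such pixels never classify as
  vegetation. Black is never canopy; 128 is the midpoint of the scale.
- **Non-monotone region.** With `a < 0` the quadratic peaks at
  `C = −b/2a` (≈ 83.3 % for the built-in model) and decreases beyond
  it. Estimates past the vertex — or outside a refitted model's
  calibration domain — are returned unclamped with `extrapolated=True`,
  so downstream consumers can see that the model has left the region
  where more cover means more tillers.
- **Refitting** is ordinary least squares on the Vandermonde design
  (`numpy.linalg.lstsq`); at the problem sizes involved (tens to
  hundreds of points, covers in 0–100) no rescaling or regularisation
  is needed. At least three distinct cover values are required; the
  fitted model records `[min cover, max cover]` as its calibration
  domain.
- **JPEG inputs** are accepted, but decoder IDCT rounding differs
  between libraries, so cover values from JPEG may differ at the
  classification margin; bit-exact expectations hold for PNG only.
  Images deeper than 8 bits per channel are rejected rather than
  silently rescaled.

## Agreement statistics

For paired series (estimated `e`, observed `o`), with population (1/n)
moments throughout:

- `rmse = sqrt(mean((e−o)²))`, `mae = mean(|e−o|)`,
  `bias = mean(e−o)` — the sign convention makes systematic
  underestimation by the image method a *negative* bias.
- `R²` is the coefficient of determination of the OLS regression of
  estimated on observed **with intercept**, which for simple OLS equals
  the squared Pearson correlation. Regression through the origin was
  the open alternative; the intercept form was chosen because it is the
  default reading of "linear regression" and is what the squared-r
  identity assumes.
- `CCC = 2·s_eo / (s_e² + s_o² + (ē−ō)²)` — Lin's original
  concordance estimator with 1/n denominators. This choice makes the
  decomposition `rmse² = bias² + var(e−o)` exact (the test suite
  asserts it to 1e−9) and keeps `|CCC| ≤ |r|` with equality exactly
  when means and variances match.
- Degenerate inputs (fewer than two pairs, or zero variance in either
  series) raise rather than returning NaN.
- The CSV reader accepts optional `group`/`replicate` columns and
  averages replicates within each group before pairing, matching field
  protocols that compare means of replicate images and counts per
  date/site.
- `error_in_days(err, rate) = err/rate` translates a tiller-count error
  into days of growth at a daily tillering rate; with the reference
  rates 12.0–24.3 tillers m⁻² day⁻¹ a ~35 tillers m⁻² bias corresponds
  to roughly 1.4–2.9 days of timing error.

## Synthetic-data generator

`render_canopy` constructs images whose segmentation ground truth is
known *exactly*, not statistically:

- The vegetation fraction is realised by pixel count —
  `round(f·N)` pixels are vegetation — rather than i.i.d. sampling, so
  cover round-trips are exact equalities.
- Palettes keep a margin around the decision boundary: vegetation
  colours have index ≥ 140, background colours ≤ 128 (threshold 134).
  Segmenting a rendered scene therefore recovers the construction mask
  pixel for pixel. Boundary behaviour itself is tested separately with
  hand-built pixels such as (61, 67), which lands on 134 exactly.
- Vegetation is clustered into a default 4 × 4 grid of blobs, mirroring
  the 16-hill framing of the capture protocol, with each cell's quota
  apportioned by largest remainder and grown outward from the cell
  centre. The blobs are axis-aligned clusters, not botanically
  realistic leaves: the generator validates plumbing and statistics,
  not agronomy. If the grid cannot fit the image the generator logs a
  notice and falls back to pixel-wise placement.
- `simulate_calibration` draws evenly spaced covers on
  `[cover_min, cover_max]` (defaults 10–70 %, n = 50) and adds i.i.d.
  Gaussian noise (default sd 5 tillers m⁻²) to the true quadratic —
  a noise level small relative to field-scale RMSE, chosen so
  fit-recovery checks are sharp. `simulate_growth` is a linear daily
  series at a fixed rate in the 12–24 tillers m⁻² day⁻¹ reference
  range.
- All generators are deterministic for a fixed seed
  (`numpy.random.default_rng`).

What passing on synthetic scenes does **not** show: robustness to
illumination, colour balance, leaf erectness, occlusion between hills,
water-surface glare, or any real optical effect — the scenes are
constructed to sit away from the classification boundary. The printed
field-accuracy figures of the originating study cannot be reproduced
here because the underlying field images and manual counts are not
available; the test battery instead verifies every printed constant,
rule and identity the method is built from.

## Problem sizes and numerical choices

Verification runs use deliberately small inputs — scenes up to
~120 × 120 px, calibration sets of 200 points, 100 Monte-Carlo
replicates, 1000 randomized metric trials — which keep the full suite
under ten seconds while still exercising every exactness claim (the
oracle-equivalence check covers all 65,536 (R, G) channel pairs
exhaustively). Thresholds in tests are identities (exact equality or
1e−8/1e−9 tolerances) except the Monte-Carlo fit recovery, which uses a
3-standard-error band.

## Design shape

The package exposes scikit-learn-style estimators —
`CanopySegmenter` (transform: image → mask), `TillerRegressor`
(fit/predict over cover), `DrainageDiagnoser` (predict status from
estimates) — because the regression stage is genuinely fit/predict
shaped and this lets the model compose with sklearn model selection
(cross-validation over calibration data works out of the box). The
module-level functions (`segment`, `cover_ratio`, `estimate_tillers`,
`diagnose`, `diagnose_image`, …) are the primary documented surface and
stay thin over the same code paths. The CLI (`canopydx`) wraps the
library one-to-one; its exit code reflects run success, never the
diagnosis outcome.

## Known limitations

- Single-image, single-date diagnosis: no growth tracking or
  forecasting of a future drainage date.
- Cultivar targets are scalars; regional guidelines that vary targets
  by soil type are not modelled.
- No illumination or colour calibration, EXIF-orientation handling
  beyond the decoder's, or automatic cropping of the hill grid.
- The built-in quadratic was calibrated for one cultivar; applying it
  across cultivars inherits that approximation.
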