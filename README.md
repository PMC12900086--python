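# canopydx

Desk-testable pipeline for image-based diagnosis of mid-season drainage
timing in rice paddies: nadir RGB canopy photo → vegetation segmentation
→ canopy cover ratio → tiller-number estimate → cultivar-threshold
decision, plus the agreement statistics used to validate such estimates
and a synthetic-scene generator with exactly known ground truth.

## Who it is for

Agronomists and phenotyping engineers who want the smartphone-style
canopy-cover diagnostic workflow as a reproducible library and CLI:
every stage is a pure function over arrays, testable without field
data.

## The method

**Segmentation.** Each pixel of an 8-bit RGB image is scored with the
red–green discriminant index

```
I = 128 + 128 · (G − R) / (G + R)
```

Gray pixels (R = G) sit at the neutral value 128; pure green maps to
256, pure red to 0. Pixels with **I ≥ 134** (inclusive) are classified
as rice leaf/stem; the blue channel is decoded but ignored. The canopy
cover ratio C (%) is 100 × vegetation pixels / total pixels.

**Estimation.** Tiller number per m² is a quadratic in cover percent:

```
T(C) = −0.0548 · C² + 9.13 · C + 77.7
```

calibrated for 'Koshihikari' at planting densities of 11.0–18.3
hills m⁻². The parabola peaks at C = −b/2a ≈ 83.3 %; estimates beyond
the vertex are flagged `extrapolated` rather than clamped. The model
can be refit from `(cover, tillers)` pairs by ordinary least squares
(`TillerRegressor`, a scikit-learn estimator).

**Diagnosis.** The estimate is compared, unrounded, against a
cultivar-specific target tiller number — built-in targets: 'Fusaotome'
400, 'Fusakogane' 360, 'Koshihikari' 320 tillers m⁻². Estimate ≥ target
diagnoses *optimal drainage timing*; below target, tillering is not yet
sufficient.

**Evaluation.** Paired (estimated, observed) series are summarised by
RMSE, MAE, mean bias (estimated − observed), R² of the OLS line of
estimated on observed, and Lin's concordance correlation coefficient
(population-moment estimator). `error_in_days(err, rate)` converts a
tiller error into days of growth at a daily tillering rate (typical
range near drainage timing: 12.0–24.3 tillers m⁻² day⁻¹).

## Worked example

Render a synthetic scene with exactly 42 % vegetation and diagnose it:

```
$ canopydx simulate --width 400 --height 300 --fraction 0.42 --seed 7 --outdir demo
$ canopydx diagnose demo/scene_400x300_f0.42_s7.png Fusakogane
{
  "cover": {
    "vegetation_pixels": 50400,
    "total_pixels": 120000,
    "cover_percent": 42.0
  },
  "estimate": {
    "cover_percent": 42.0,
    "tillers_per_m2": 364.49280000000005,
    "extrapolated": false
  },
  "diagnosis": {
    "status": "OPTIMAL_DRAINAGE_TIMING",
    "estimated_tillers": 364.49280000000005,
    "target_tillers": 360.0,
    "margin": 4.492800000000045,
    "cultivar": "Fusakogane"
  },
  ...
}
Fusakogane: cover 42.0 %, estimated 364.5 tillers/m2 (target 360.0) -> OPTIMAL_DRAINAGE_TIMING
```

The generator placed exactly 50,400 of 120,000 pixels on the vegetation
side of the classifier, so the measured cover is 42.0 % exactly;
T(42) = −0.0548·42² + 9.13·42 + 77.7 ≈ 364.5 tillers m⁻², which is at
or above the 360 target for 'Fusakogane', hence the optimal-timing
diagnosis. The same pipeline is available in Python:

```python
import canopydx as cx

image = cx.load_image("demo/scene_400x300_f0.42_s7.png")
record = cx.diagnose_image(image, "Fusakogane")
print(record.cover.cover_percent)            # 42.0
print(record.diagnosis.status)               # OPTIMAL_DRAINAGE_TIMING
```

Other subcommands: `segment` (binary mask PNG, vegetation white, plus
cover JSON), `evaluate` (accuracy report from an `estimated,observed`
CSV), `calibrate` (OLS quadratic from a `cover_percent,tillers_per_m2`
CSV).

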