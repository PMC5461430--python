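# Methods

## Geometry: from silhouettes to head volume

A potted plant rotates about a vertical axis; an orthographic camera takes
`n_views` side images at fixed azimuth steps (default 11 × 30°, covering
330°). In each binary silhouette, for every image row h the radial extent
about the known axis column is

  r(h) = max(|left extent|, |right extent|) · pixel_scale.

The max-of-extents convention (rather than half-width) is conservative
against small axis mis-centering on the turntable; `mode="halfwidth"` is
available for sensitivity analyses. The per-view profiles are aggregated
row-wise — `mean` (default), `min` (a revolved visual-hull approximation) or
`max` — and revolved:

  Vh = π · Σ_h r̄(h)² · Δh  (midpoint rule on pixel rows, Δh = pixel_scale).

For true solids of revolution the aggregation policy and the number of views
are immaterial up to the 1-px discretisation: rendered spheres and cylinders
recover their closed-form volumes within 2% at pixel_scale ≤ R/100 (asserted
in the test suite). For a rosette the revolved silhouette encloses inter-leaf
gaps, so Vh overestimates tissue volume by a roughly constant envelope
factor (~2.6 for the default architecture). This factor cancels in the
linear calibration, which is the reason a linear volume→weight model works
at all.

## Calibration model

`VolumeCalibration(fw, volume).fit()` performs OLS of fresh weight on head
volume and reports RMSEC = sqrt(SSR/n) — the calibration-literature
convention with denominator n, not the regression estimate s = sqrt(SSR/(n−2));
the difference is documented and covered by a test against OLS residual
theory (E[RMSEC] ≈ σ·sqrt((n−2)/n)). Predictions outside the calibrated
fresh-weight range are flagged as extrapolation but returned, since growth
monitoring inevitably queries beyond the calibration conditions. Two-point
calibrations are accepted (exact interpolation, RMSEC 0); a design with zero
volume variance raises a singular-fit error.

## Synthetic plants

Each plant is a radial arrangement of 10 solid half-ellipsoid leaves (an
outer whorl at ~55° from vertical, an inner whorl at ~31°, fixed inter-whorl
phase, one random turntable orientation per plant). Ground truth is defined
by voxelisation: head volume = count of grid cells (pitch = min leaf
dimension / 10) whose centres fall in the union of leaf primitives above the
pot rim, times pitch³. Halving the pitch changes this volume by < 1%
(tested).

Fresh weight is drawn first — lognormal around the configured group mean
with CV `fw_cv` — and true volume derived by inverting the generative
density relation FW = a0 + a1·V (defaults a0 = −1.97 g, a1 = 0.013 g cm⁻³).
The canonical rosette is then scaled uniformly, *including its voxel pitch*,
so the voxel ground truth matches the target volume exactly; this makes
calibration-recovery tests exact by construction. The destructively
"measured" weight of calibration plants adds Gaussian balance/handling error
(`fw_measurement_sd`, default 2.2 g).

Default study conditions:

- treatment experiment: 5 groups (control, leaf/flower extract at 1 and
  10 mL L⁻¹) × 9 plants × 3 time points (12/17/22 days after
  transplanting); day-22 group means encode control 55.9 g with
  +4/+15/+13/+18% effects, day-12 means near-equal (~22 g).
- calibration cohort: 6 plants per harvest every fourth day × 13 dates = 78
  plants, date means geometrically spaced so weights span 2.5–155.8 g
  (draws clipped to that range).
- `fw_cv` defaults to 0.05: a uniform single-cultivar greenhouse cohort is
  at the homogeneous end of reported lettuce fresh-weight variability, and
  the architectural jitter of the generator (below) adds its own ~2%
  envelope noise on top.

Rendering splats rotated voxel centres onto the pixel grid (orthographic),
closes 1-px sampling holes with a single 3×3 closing plus hole filling, and
draws the pot as a filled rectangle below the head. A plant that exceeds the
frame raises an error naming the required image size.

What the generator does **not** emulate: leaf curvature and serration,
self-occlusion texture, perspective and lens distortion, cabinet-background
clutter, specular highlights, or growth physiology (each visit is an
independent draw, not a trajectory). Passing tests therefore demonstrate the
correctness and statistical calibration of the *pipeline*, not segmentation
robustness on real imagery.

### Architectural variability

Between-plant jitter (leaf length ±0.25 cm SD, inclination ±2°, azimuth
±3°) is deliberately small: a cultivar cohort is morphologically uniform,
and the silhouette-envelope factor must be near-constant across plants
(CV ≈ 2%) for a linear weight calibration to hold the way it does on real
heads. An irreducible ~1.3% envelope CV remains from the random turntable
orientation because 11 views at 30° cover only 330°.

## Segmentation

Otsu thresholding by default (a uniform raster yields an empty mask;
`fixed:<value>` is available for degenerate synthetic images), 3×3
morphological opening and closing, largest connected component above
`min_component_px`, and all rows at/below the configured `pot_cut_row`
zeroed. The pot-cut rule substitutes for whatever background/pot masking the
physical cabinet used; the rig's geometry is configuration, not estimation,
so the axis column is taken from config rather than fitted per image.

## Assay quantification

Every colorimetric path is linear: tissue value = (A − blank − intercept)/
slope × dilution × extract_volume / tissue_mass × unit_scale. Negative
blank-corrected responses clip to zero with a warning; concentrations
outside the standards' range are flagged, not refused. Specifics:

- **Pigments**: Lichtenthaler coefficients for 100% methanol
  (chl a = 16.72·A665.2 − 9.16·A652.4; chl b = 34.09·A652.4 − 15.28·A665.2;
  carotenoids = (1000·A470 − 1.63·chl a − 104.96·chl b)/221, μg mL⁻¹),
  scaled to mg g⁻¹ FW. The coefficient set is a constant of the module; other
  solvents would need their own set.
- **PAL**: the absorbance increase is normalised to an hourly rate first
  (assays run 30 or 60 min), then 0.01 ΔA290 h⁻¹ = 1 unit = 3.09 nmol
  trans-cinnamic acid h⁻¹; specific activity divides by mg soluble protein
  in the assay.
- **Ethylene**: rate = headspace concentration × jar volume / (plant mass ×
  elapsed time), μL kg⁻¹ h⁻¹; the free headspace is taken as the nominal
  jar volume (no plant-displacement correction).
- Flavonoids are reported as nmol rutin equivalents g⁻¹ FW, antioxidant
  capacity as μmol ascorbic-acid equivalents g⁻¹ FW, phenolics as mg
  gallic-acid equivalents g⁻¹ FW.

The synthetic reading generator back-computes absorbances from configured
tissue levels through the same curves (plus Gaussian read noise, default SD
0.005), so at zero noise quantification inverts generation exactly — the
round-trip is asserted for every assay.

## Statistics

One-way ANOVA uses the classical between/within decomposition (verified
against a hand-coded oracle and a permutation test); two-way ANOVA uses
type-I sums of squares on balanced complete factorials only, and raises on
unbalanced designs rather than silently choosing a SS type. Post-hoc
comparisons are Bonferroni-adjusted pairwise t tests — Welch by default,
pooled-variance selectable — with the family defined as all pairwise
comparisons within one response at one time point. The compact letter
display assigns letters from the maximal cliques of the
"not-significantly-different" graph, so groups share a letter iff no member
pair differs at α; correctness is checked exhaustively against the adjusted-p
matrix rather than against one particular labelling. Time points are treated
as independent samples (each visit an independent plant draw), not repeated
measures — a deliberate simplification.

Fv/Fm stress classification uses a strict inequality at the conventional
0.83 boundary (0.83 itself classifies as stressed).

## Numerical and design choices

- Volume integration: midpoint rule on pixel rows; error is bounded by the
  discretisation tests (sphere/cylinder within 2%).
- Rows where no view saw foreground contribute zero volume.
- Aggregation ordering Vh(min) ≤ Vh(mean) ≤ Vh(max) holds by construction
  and is property-tested.
- Seeds: one named seed per generator call; the CLI fans a single global
  seed out to per-stage substreams keyed by stage name (CRC32), so stages
  reproduce independently of execution order. Identical seed + config gives
  byte-identical tables and rasters.
- Problem sizes in the test suite (e.g. 10 end-to-end replicates of the
  harvest-day experiment, 100 replicates for coverage/type-I checks) were
  chosen to keep the full suite in the low minutes on one CPU while leaving
  the binomial acceptance margins comfortable.

## Known limitations

- The solid-of-revolution model is only as good as the envelope-factor
  constancy; cultivars with irregular architecture would need a per-cultivar
  calibration (as the physical method does).
- Orthographic projection ignores perspective foreshortening of a real
  camera at finite distance.
- Segmentation is a stand-in: real cabinet imagery needs background
  modelling that no synthetic test here exercises.
- The two-way ANOVA is restricted to balanced designs by design.
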