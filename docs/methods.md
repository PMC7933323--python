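# Methods

## Problem and scope

`octme` quantifies middle-ear disease from cross-sectional OCT B-scans of
the tympanic membrane (TM). The pipeline has five analysis stages —
segmentation of the TM plus any adherent biofilm, conversion of boundary
curves into refraction-corrected orthogonal thickness, rule-based
classification of middle-ear effusion (MEE) and biofilm state,
longitudinal polynomial trend testing, and cohort end-state tabulation —
plus a synthetic phantom generator that renders scenes with exact ground
truth so that every stage is testable without animal or patient data.

## Image model and conventions

A B-scan is a 2-D intensity grid: row = axial depth, column = lateral
position, 0-based, depth increasing with row. The axial scale is
**air-calibrated optical path** (the standard spectral-domain convention):
a structure of physical thickness `d` inside tissue of refractive index
`n` occupies `n·d` of axial image distance along the refracted ray.
Intensities are normalised to `[0, 1]`; physical calibration
(`axial_pitch_um`, `lateral_pitch_um`) travels in a YAML/JSON sidecar.

Default optics approximate a handheld spectral-domain scanner: 3 µm axial
pitch and 8 µm lateral pitch on a 1000 × 500 grid (≈3 mm depth, 4 mm
field), axial PSF FWHM 4.5 µm, tissue index n = 1.44. Pixel pitches are
not measurable from the literature we model; they are chosen so the
stated depth/field/resolution fit the grid, and all are configurable.

## Phantom generator

The renderer draws, per column:

* an anterior TM surface as a straight line whose physical tilt is the
  configured incident angle θᵢ (image slope = tan θᵢ · lateral/axial
  pitch);
* a TM band whose *apparent* axial extent is the refraction-distorted
  optical path `n·d/cos θₜ`, with `θₜ = asin(sin θᵢ / n)` — the renderer
  distorts, the corrector undoes it, and the two are independently
  testable against the closed form;
* an optional adherent biofilm band on the posterior surface, brighter
  than the TM, whose thickness is a Gaussian-smoothed random field
  standardised over the imaged columns so its realised coefficient of
  variation matches `biofilm_cv`;
* one of three effusion regimes: `clear` (noise floor), `watery`
  (Poisson-placed 2×2 bright particles at a configured density per mm²
  on a dark background), `dense` (uniform bright tissue-like fill, under
  speckle); a bright 2-row fluid–air meniscus line is drawn when
  0 < fill fraction < 1;
* a thin (21 µm optical) low-scattering film between the posterior
  membrane surface and any effusion content. Biofilm is adherent — no
  film. This keeps the membrane optically distinct from a dense fill, as
  it is in practice, and keeps "thickness includes adherent biofilm"
  well defined.

Noise is multiplicative unit-mean gamma speckle (SD = `speckle_contrast`,
default 0.4 — display-scale OCT speckle after log compression is
sub-unity) followed by an axial Gaussian blur at the PSF FWHM and
additive Gaussian read noise on a background floor (mean 0.05, SD 0.01).
All randomness derives from one integer seed; identical configuration and
seed reproduce identical pixels bit for bit.

Columns where the tilted band would exit the grid are rendered as air and
flagged invalid in the truth record; rendering fails loudly only when
fewer than 32 columns remain. Steep membranes therefore legitimately
occupy only part of the frame — at 55° about half the default grid width.

### Longitudinal scenarios

`render_series` turns a disease course into day-by-day scenes:

* `control` — constant baseline (25 µm), always clear;
* `om_progression` — linear growth, default 31 µm at day 0 rising to
  ≈210 µm at day 21 (slope ≈ 8.52 µm/day); watery effusion from day 1,
  dense from day 7, biofilm onset day 5;
* `treated_nonresponder` — progression that plateaus after a failed
  day-7 treatment;
* `treated_responder` — cubic rise–drop–rise (≈80 µm at day 4, dip
  after day-7 treatment, rise by day 13), effusion clearing at the end;
* `spontaneous_healing` — rise then return to baseline with flags
  cleared.

After biofilm onset the adherent layer accounts for 70 % of the excess
over baseline (the accumulating layer dominates late-stage thickening);
the inflamed membrane proper accounts for the rest. Within-day scans get
independent seeds and a tilt jittered uniformly in 40–52° (steep, as in
the middle ear, while keeping at least half the frame usable on the
default grid). `scans_per_day` defaults to 5 — a desk-scale stand-in for
the several hundred frames a real session collects.

## Segmentation

Median filter → global threshold → morphological closing → connected
components → boundary extraction. Non-obvious choices:

* **Axial (per-A-scan) median filter**, kernel 5×1. A square kernel
  erases a thin layer that is steeply tilted: at 70° the band is only
  1–3 columns wide horizontally and a 5×5 median removes it entirely.
* **Otsu threshold** by default: parameter-free and scale-invariant on
  the bimodal air/tissue histogram; a fixed threshold is available for
  reproducibility runs. If the "foreground" mean is less than 1.5× the
  background mean the image contains no reflective layer and
  `NoMembraneDetected` is raised (blocked or empty view).
* **Vertical-line closing** (5×1): fills speckle dropouts inside the
  band without laterally bridging the thin dark space that separates a
  tilted membrane from effusion below — a disk footprint bridges that
  space because it is only ~3 px wide normal to the band.
* **Component selection**: among components of at least
  `min_component_area_px`, candidates are those spanning at least half
  the widest candidate's column span; the shallowest (smallest mean row)
  wins. The membrane is the first continuous reflective layer under the
  air column; the span rule keeps meniscus lines and effusion bodies out.
* **Sub-pixel boundaries at half maximum**: per column, the anterior and
  posterior edges are located by linear interpolation where the filtered
  profile crosses the level midway between local air background and the
  band's median intensity. With a symmetric axial PSF this estimator is
  unbiased no matter where the global threshold landed on the edge ramp
  (interpolating at the Otsu level itself biased thickness by up to
  5 µm at normal incidence). Boundary curves are then smoothed with an
  11-column moving average.

A quality gate (`mask_quality`) calls a scan usable when at least half
the columns have valid boundaries and the anterior boundary's
first-difference SD is below 3 rows; this mirrors the 50–80 % usable
frame rates reported for real middle-ear imaging.

## Thickness quantification

Per column: the incident angle θᵢ is `arctan |slope|` of a least-squares
line through 21 columns of the *anterior* boundary in physical units
(the posterior surface is refraction-distorted in image space and never
used for angle). The orthogonal image distance `d_img` is measured from
the anterior point along the anterior-surface normal to the interpolated
posterior curve, honouring the 3:8 pixel anisotropy. The physical
thickness is

    d = d_img · cos θₜ / (n · cos θᵢ),      θₜ = asin(sin θᵢ / n)

derived from: (i) air-calibrated axial scale, so the band's apparent
axial extent is `n·d/cos θₜ`; (ii) locally parallel membrane surfaces,
so the measured inter-boundary orthogonal distance is that extent times
`cos θᵢ`. At θᵢ = 0 the correction reduces to `d_img/n`, and at n = 1 it
is the identity. The renderer draws exactly this distortion, so the
generator/corrector pair is self-validating, and both are checked
against the closed form independently in the tests.

If the axial scale of an instrument were calibrated in tissue rather
than air, the `1/n` factor would not apply; the air convention is the
standard one and is assumed throughout.

A scan summary is the mean ± sample SD of the first `n_points`
(default 100, per the consecutive-point averaging convention) of the
longest run of consecutive valid columns. How the original analysis
chose *which* ~100 points is not documented; the longest-run rule is
deterministic and favours the cleanest stretch of membrane. Tests on
narrow high-tilt phantoms use 50–80 points — at 70° with a 210 µm band
only ≈100 valid columns exist on the default grid.

Validated accuracy: for noiseless phantoms over θᵢ ∈ {0…70}°,
n ∈ {1, 1.33, 1.44}, d ∈ {20…210} µm, the full
render → segment → measure → correct chain recovers d with a worst-case
error of ≈0.7 µm, well within one axial pixel (3 µm).

## Middle-ear classification

All thresholds operationalize *visual* reading criteria and are exposed
in `ClassifierParams`; none of the numeric values below comes from the
modelled study — they were chosen to separate the generator's regimes
and are documented as this package's operationalization.

* **ROI**: everything deeper than the posterior boundary plus a 2-px
  guard, restricted to valid columns eroded by 8 columns at each run end
  (boundary smoothing is least reliable there, and a leaking membrane
  tail otherwise mimics a particle).
* **Noise floor**: mean/SD of the air region above the anterior
  boundary.
* **Scatterers**: pixels above mean + 4 SD, grouped 8-connected;
  components of 2–50 px count as particles.
* **Fluid–air boundary**: a supra-threshold component spanning >30 % of
  the valid columns but at most 12 rows tall — a meniscus line, not a
  filled cavity.
* **Effusion rule** (total and deterministic): *dense* if the ROI median
  is ≥3 noise SDs above the floor or the supra-threshold fraction
  exceeds 0.10; else *watery* if any particle or a fluid–air boundary is
  present; else *clear*.
* **Biofilm**: mean corrected thickness ≥ control reference (30 µm)
  + 20 µm excess, AND thickness CV ≥ 0.15 ("inconsistent thickness"),
  AND posterior band half at least 0.8× as bright as the anterior half.
  A uniformly thickened membrane (inflammation without an irregular
  adherent layer) is deliberately negative. A thin residual biofilm
  below the excess threshold goes undetected — detection onset lags
  biological onset, as it does for human readers.

Ear × day aggregation uses the published any-scan OR rule: effusion is
present if seen in *any* usable scan and the class is the most severe
seen; clear requires all scans clear. Zero usable scans mark the
observation blocked. The end state of an ear is taken solely from its
last observation; a blocked last observation excludes the ear from
cohort tables.

Measured on 200 seeded phantoms spanning all regimes at default
thresholds: effusion-label accuracy ≈1.00, biofilm-flag accuracy ≈0.99
(requirements: ≥0.95 and ≥0.90).

## Trend statistics

Per animal (ears averaged first), mean thickness vs. day is fit by OLS
on raw (uncentered) day values with an intercept, degree 1–3; each
coefficient gets a two-sided t test on n−(degree+1) df. For degree 1 a
significant (p < 0.05) positive slope is called an increasing trend,
negative decreasing, otherwise none. No multiple-testing correction is
applied across coefficients or animals — a mirrored limitation of the
modelled procedure. Degree selection ("depending on the distribution of
the data" is otherwise undefined) uses an adjusted-R² parsimony rule:
the smallest degree within 0.02 of the best adjusted R²; a forced degree
is always available. Group curves average animals (not ears) per day and
exclude animals tracked ≤ day 3.

Calibration at n = 8 days, noise SD 8 µm: empirical type-I error 0.050 ±
0.005 over 2000 null replicates; under a 4.4 µm/day alternative the mean
slope estimate is within 0.03 of truth and 95 % CI coverage is 0.95–0.96.

## Cohort tables

Per group: end-state counts over {clear, MEE only, biofilm only,
MEE + biofilm} after dropping excluded (blocked-at-end) ears, with
integer percentages of the post-exclusion denominator computed by
**round-half-up** — the unique rounding consistent with every published
count/percentage pair we reproduce (e.g. 15/16 → 94, 2/16 → 13,
1/8 → 13 under half-up where banker's rounding would give 12). Text
output renders zero counts as "–" per table convention; CSV stores 0.

## Pipeline and reproducibility

`run_pipeline` executes simulate → segment → thickness → classify →
trend → cohort from one `RunConfig`; a single master seed derives all
per-ear scenario seeds via `SeedSequence`, so a rerun with the same
resolved config produces byte-identical CSVs. The demo configuration is
3 animals × 2 ears in each of two arms (control, untreated progression)
over the 10-day imaging schedule (daily to day 5, then every other day
to day 13) with 2 scans per ear-day on a 600 × 300 grid — sized so a
full end-to-end run takes well under a minute on one core. Stage errors
are logged with animal/ear/day identifiers; unusable scans are excluded
and logged, never fatal.

## Known limitations

* The phantom is geometric, not wave-optical: no depth-dependent signal
  roll-off, no shadowing, no multiple scattering, no registration drift
  between days. Passing recovery tests shows the *analysis chain* is
  correct under the stated image model, not that segmentation would be
  this accurate on clinical data.
* The membrane is locally planar (curvature off by default); a single
  incident angle per point is assumed, matching the correction model.
* Blocked ears are injected as flags, not rendered occlusions.
* Frames are treated independently; no cross-day region matching is
  attempted (the original workflow matched regions visually).
* The classifier thresholds separate the generator's regimes; real
  effusions form a continuum and would require re-tuning against
  annotated data.
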