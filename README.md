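# octme — quantitative OCT analysis of the middle ear

`octme` is a Python package for quantifying middle-ear disease from
optical coherence tomography (OCT) B-scans of the tympanic membrane
(TM), the kind of imaging used to track experimental otitis media and
its response to antibiotics. It is aimed at researchers who need a
tested, reproducible implementation of the full analysis chain:

1. **Segmentation** of the TM — including any adherent bacterial
   biofilm — from a cross-sectional B-scan (median filtering, Otsu
   thresholding, morphology, sub-pixel boundary refinement);
2. **Refraction-corrected orthogonal thickness**: the TM is steeply
   angled to the beam (θᵢ ≈ 40–70°) and the axial image scale is optical
   path, so the physical thickness is recovered as

       d = d_img · cos θₜ / (n · cos θᵢ),   θₜ = asin(sin θᵢ / n),  n = 1.44

   where `d_img` is the orthogonal distance between the anterior and
   posterior boundary curves and θᵢ is estimated from the local anterior
   surface slope;
3. **Rule-based middle-ear state classification**: clear vs *watery*
   effusion (particulate scatterers on a dark background, or a visible
   fluid–air boundary) vs *dense* effusion (bright tissue-like fill),
   plus a biofilm flag (thick + irregular + bright adherent layer);
4. **Longitudinal trend statistics**: per-animal OLS polynomial fits of
   thickness vs. day with two-sided t tests on the coefficients
   (significant positive slope ⇒ increasing trend);
5. **Cohort end-state tables**: per-group counts and round-half-up
   integer percentages of {clear, MEE, biofilm, MEE + biofilm} ears,
   with blocked ears excluded.

Because no public middle-ear OCT dataset accompanies the modelled study,
the package ships a first-class **synthetic phantom generator**
(`octme.phantom`) that renders B-scans with exact ground truth —
refraction-distorted membrane geometry, biofilm layers, three effusion
regimes, meniscus boundaries, speckle and PSF blur — and longitudinal
disease-course scenarios. Every analysis stage is validated against
generator truth and closed-form oracles.

See `docs/methods.md` for the full model description, parameter
defaults, and known limitations.

## Worked example

Render a noisy phantom (30 µm membrane at 55° with a watery effusion),
then run the analysis chain:

```python
from octme import (OpticsConfig, SceneConfig, render_bscan, segment_tm,
                   CorrectionParams, compute_profile, classify_scan)

optics = OpticsConfig()                      # 3 um axial / 8 um lateral pitch
scene = SceneConfig(tm_thickness_um=30.0, tilt_deg=55.0, ri=1.44,
                    mee_type="watery", fluid_fill_fraction=1.0, seed=42)
scan, truth = render_bscan(optics, scene)

boundaries = segment_tm(scan)
profile = compute_profile(boundaries, CorrectionParams(ri=1.44, n_points=100))
print(f"incident angle : {profile.theta_i_deg[profile.valid].mean():.1f} deg")
print(f"raw distance   : {profile.d_img_um[profile.valid].mean():.1f} um (optical)")
print(f"corrected      : {profile.mean_um:.1f} +/- {profile.sd_um:.1f} um")

result = classify_scan(scan, boundaries, profile)
print(f"effusion class : {result.mee_class} ({result.scatter.particle_count} particles)")
print(f"biofilm        : {result.biofilm_present}")
```

Output:

```
incident angle : 55.0 deg
raw distance   : 29.9 um (optical)
corrected      : 29.6 +/- 0.3 um
effusion class : watery (149 particles)
biofilm        : False
```

The recovered incident angle matches the configured 55°, and the
corrected thickness recovers the true 30 µm to within a third of an
axial pixel despite speckle; the sparse particles below the membrane are
read as a watery effusion.

End-to-end, the demo cohort (3 animals × 2 ears per arm, control vs.
untreated progression, imaged daily to day 5 then every other day to
day 13):

```bash
octme run --seed 3 --out demo_run/
cat demo_run/cohort.txt
```

```
group  n_animals  ears  clear  mee_only  biofilm_only  mee_and_biofilm
control  n=3  ears=6  6 (100%)  -  -  -
no_treatment  n=3  ears=6  -  1 (17%)  -  5 (83%)
```

All control ears stay clear; the infected ears end with effusion, most
with a detected biofilm as well. `demo_run/fits.csv` holds the
per-animal trend fits — e.g. an untreated animal:

```
om_p_01,no_treatment,1,0.990,10,increasing,30.38,...,8.889,2.7e-09
```

a significantly increasing linear trend (slope ≈ 8.9 µm/day, p ≈ 10⁻⁹,
R² = 0.99) against the simulated growth of ≈8.5 µm/day, while the
control fits call no trend.

Each pipeline stage is also exposed as a CLI subcommand
(`octme simulate bscan|series`, `segment`, `thickness`, `classify`,
`trend`, `cohort`) operating on TIFF images with YAML sidecars and CSV
tables, so stages can be rerun or swapped independently.

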