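"""Synthetic middle-ear OCT B-scan phantoms with exact ground truth.

The generator renders the scene features that matter for downstream
quantification of experimental otitis media:

* a thin, steeply angled tympanic membrane (TM) whose *apparent* axial
  extent in the image is the refraction-distorted optical path
  ``n * d / cos(theta_t)`` (air-calibrated axial scale, Snell refraction
  at tissue index ``n``), while the anterior surface appears at its true
  tilt;
* an optional adherent biofilm band on the posterior TM surface, brighter
  than the TM and with smoothly varying thickness;
* three middle-ear effusion (MEE) regimes — ``clear`` (noise floor),
  ``watery`` (sparse particulate scatterers on a dark background), and
  ``dense`` (bright tissue-like speckle fill) — plus an optional bright
  fluid–air meniscus boundary for partially filled cavities;
* multiplicative speckle (unit-mean gamma), additive read noise, and an
  axial Gaussian point-spread blur at the system resolution.

Every rendered scan carries a :class:`PhantomTruth` record of the exact
pre-noise geometry, which is the oracle for all recovery tests.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .scan_io import BScan, GROUPS

MEE_TYPES = ("clear", "watery", "dense")

SCENARIOS = (
    "control",
    "om_progression",
    "treated_responder",
    "treated_nonresponder",
    "spontaneous_healing",
)

# Pre-noise structure intensities (normalised scale).  The biofilm band is
# rendered at least as bright as the TM, matching its denser, tissue-like
# scattering; dense effusion sits below the TM so thresholding separates
# the membrane from the fill.
TM_INTENSITY = 0.55
BIOFILM_INTENSITY = 0.68
DENSE_FILL_INTENSITY = 0.30
PARTICLE_INTENSITY = 0.60
FLUID_BOUNDARY_INTENSITY = 0.72

# Thin low-scattering film between the posterior membrane surface and any
# effusion content (optical micrometres).  Biofilm is adherent: no gap.
MEMBRANE_FLUID_GAP_UM = 21.0

MIN_VALID_COLUMNS = 32


class PhantomGeometryError(ValueError):
    """The TM band exits the image grid over (nearly) all columns."""


@dataclass
class OpticsConfig:
    """Imaging-system parameters of the simulated OCT scanner.

    Defaults approximate a handheld spectral-domain system with ~3 mm
    imaging depth, ~4 mm lateral field and ~4.5 um axial resolution.
    The axial scale is air-calibrated optical path per pixel row.
    """

    axial_pitch_um: float = 3.0
    lateral_pitch_um: float = 8.0
    axial_resolution_um: float = 4.5
    image_rows: int = 1000
    image_cols: int = 500
    noise_floor_mean: float = 0.05
    noise_floor_sd: float = 0.01
    speckle_contrast: float = 0.4

    def __post_init__(self) -> None:
        if min(self.axial_pitch_um, self.lateral_pitch_um, self.axial_resolution_um) <= 0:
            raise ValueError("pitches and axial resolution must be strictly positive")
        if self.image_rows < 64 or self.image_cols < 64:
            raise ValueError("image grid must be at least 64 x 64")
        if not 0.0 <= self.speckle_contrast <= 1.0:
            raise ValueError("speckle_contrast must lie in [0, 1]")


@dataclass
class SceneConfig:
    """One middle-ear scene: membrane geometry, optics of the tissue, state.

    ``tm_thickness_um`` is the true physical orthogonal thickness of the
    TM proper; ``biofilm_mean_um`` adds an adherent layer of smoothly
    varying thickness (coefficient of variation ``biofilm_cv``).  A zero
    biofilm mean means no biofilm.  ``fluid_fill_fraction`` places the
    fluid meniscus: 0 = no fluid column, 1 = fully filled (no visible
    fluid-air boundary), intermediate values render a bright boundary.
    """

    tm_thickness_um: float = 25.0
    tilt_deg: float = 55.0
    ri: float = 1.44
    biofilm_mean_um: float = 0.0
    biofilm_cv: float = 0.3
    mee_type: str = "clear"
    particle_density_per_mm2: float = 50.0
    fluid_fill_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tm_thickness_um <= 0:
            raise ValueError("tm_thickness_um must be > 0")
        if not 0.0 <= self.tilt_deg < 85.0:
            raise ValueError("tilt_deg must lie in [0, 85)")
        if self.ri < 1.0:
            raise ValueError("refractive index must be >= 1")
        if self.biofilm_mean_um < 0:
            raise ValueError("biofilm_mean_um must be >= 0")
        if not 0.0 <= self.fluid_fill_fraction <= 1.0:
            raise ValueError("fluid_fill_fraction must lie in [0, 1]")
        if self.mee_type not in MEE_TYPES:
            raise ValueError(f"mee_type must be one of {MEE_TYPES}")

    @property
    def biofilm_present(self) -> bool:
        return self.biofilm_mean_um > 0


@dataclass
class PhantomTruth:
    """Exact pre-noise geometry and state of a rendered phantom scene."""

    anterior_row: np.ndarray  # per-column true anterior surface row (NaN = invalid)
    thickness_um: np.ndarray  # per-column true physical TM+biofilm thickness
    valid: np.ndarray  # per-column validity (band fully inside the grid)
    tilt_deg: float
    ri: float
    mee_type: str
    biofilm_present: bool
    fluid_boundary_row: float | None
    seed: int

    def __post_init__(self) -> None:
        self.anterior_row = np.asarray(self.anterior_row, dtype=float)
        self.thickness_um = np.asarray(self.thickness_um, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.valid.any() and np.nanmin(self.thickness_um[self.valid]) < 0:
            raise ValueError("thickness arrays must be non-negative")

    @property
    def mean_thickness_um(self) -> float:
        return float(np.nanmean(self.thickness_um[self.valid]))


def snell_theta_t_deg(theta_i_deg: float, ri: float) -> float:
    """Refracted angle from Snell's law, in degrees."""
    return math.degrees(math.asin(math.sin(math.radians(theta_i_deg)) / ri))


def apparent_axial_extent_um(d_um: float, theta_i_deg: float, ri: float) -> float:
    """Apparent axial band extent ``n*d/cos(theta_t)`` in optical micrometres.

    This is the closed-form oracle for the refraction distortion the
    renderer draws and the correction chain must undo.
    """
    theta_t = math.radians(snell_theta_t_deg(theta_i_deg, ri))
    return ri * d_um / math.cos(theta_t)


def _band_coverage(rows: np.ndarray, top: np.ndarray, bottom: np.ndarray) -> np.ndarray:
    """Fractional pixel coverage of the band [top, bottom) per (row, col)."""
    return np.clip(np.minimum(rows + 1.0, bottom) - np.maximum(rows, top), 0.0, 1.0)


def _smooth_biofilm_field(
    ncols: int, mean_um: float, cv: float, rng, norm_mask: np.ndarray | None = None
) -> np.ndarray:
    """Smooth, non-negative per-column biofilm thickness with target mean/CV.

    The field is a Gaussian-smoothed noise process standardised over
    ``norm_mask`` (the imaged membrane columns) so its realised
    coefficient of variation over the visible membrane matches ``cv``.
    """
    if mean_um <= 0:
        return np.zeros(ncols)
    g = rng.standard_normal(ncols)
    g = gaussian_filter1d(g, sigma=25.0, mode="reflect")
    sel = g[norm_mask] if norm_mask is not None and norm_mask.any() else g
    sd = sel.std()
    if sd > 0:
        g = (g - sel.mean()) / sd
    return np.clip(mean_um * (1.0 + cv * g), 0.0, None)


def render_bscan(optics: OpticsConfig, scene: SceneConfig) -> tuple[BScan, PhantomTruth]:
    """Render one B-scan and its exact ground truth.

    The anterior TM surface is a straight line at the configured tilt,
    anchored mid-image.  Columns where the refraction-distorted band
    would exit the grid are rendered as plain air and flagged invalid in
    the truth record; if fewer than ``MIN_VALID_COLUMNS`` columns remain
    a :class:`PhantomGeometryError` is raised.
    """
    rng = np.random.default_rng(scene.seed)
    nrows, ncols = optics.image_rows, optics.image_cols
    ap, lp = optics.axial_pitch_um, optics.lateral_pitch_um

    cols = np.arange(ncols, dtype=float)
    # image-space slope of the anterior line, rows per column, so that the
    # physical surface makes angle tilt_deg with the horizontal
    slope_rows_per_col = math.tan(math.radians(scene.tilt_deg)) * lp / ap

    theta_t_deg = snell_theta_t_deg(scene.tilt_deg, scene.ri)
    cos_tt = math.cos(math.radians(theta_t_deg))

    # first pass: columns where the membrane alone fits the grid, used to
    # standardise the biofilm field over the imaged part of the membrane
    extent_tm_rows = scene.ri * scene.tm_thickness_um / cos_tt / ap
    c_mid = 0.5 * (ncols - 1)
    a_mid0 = 0.5 * nrows - 0.5 * extent_tm_rows
    anterior0 = a_mid0 + slope_rows_per_col * (cols - c_mid)
    valid0 = (anterior0 >= 1.0) & (anterior0 + extent_tm_rows <= nrows - 1.0)
    biofilm_um = _smooth_biofilm_field(
        ncols, scene.biofilm_mean_um, scene.biofilm_cv, rng, norm_mask=valid0
    )
    total_um = scene.tm_thickness_um + biofilm_um  # physical orthogonal thickness
    extent_total_rows = scene.ri * total_um / cos_tt / ap

    a_mid = 0.5 * nrows - 0.5 * float(np.mean(extent_total_rows))
    anterior = a_mid + slope_rows_per_col * (cols - c_mid)
    bottom = anterior + extent_total_rows

    valid = (anterior >= 1.0) & (bottom <= nrows - 1.0)
    if valid.sum() < MIN_VALID_COLUMNS:
        raise PhantomGeometryError(
            f"TM band exits the image grid in all but {int(valid.sum())} columns: "
            f"tilt_deg={scene.tilt_deg} too steep for image_rows={nrows} at "
            f"axial_pitch_um={ap}"
        )

    rows = np.arange(nrows, dtype=float)[:, None]
    structure = np.zeros((nrows, ncols))

    ant = np.where(valid, anterior, np.nan)
    tm_bot = np.where(valid, anterior + extent_tm_rows, np.nan)
    bio_bot = np.where(valid, bottom, np.nan)
    with np.errstate(invalid="ignore"):
        cov_tm = np.where(valid, _band_coverage(rows, ant, tm_bot), 0.0)
        cov_bio = np.where(valid, _band_coverage(rows, tm_bot, bio_bot), 0.0)
    structure += TM_INTENSITY * np.nan_to_num(cov_tm)
    structure += BIOFILM_INTENSITY * np.nan_to_num(cov_bio)

    gap_rows = MEMBRANE_FLUID_GAP_UM / ap
    fluid_top = np.where(valid, bottom + gap_rows, np.inf)

    fluid_boundary_row: float | None = None
    has_fluid = scene.mee_type != "clear" and scene.fluid_fill_fraction > 0
    if has_fluid:
        # horizontal meniscus: fill fraction of the sub-membrane cavity depth
        cavity_top = float(np.nanmin(fluid_top[valid]))
        level = nrows - scene.fluid_fill_fraction * (nrows - cavity_top)
        fluid_top_eff = np.maximum(fluid_top, level)
        if scene.fluid_fill_fraction < 1.0:
            # bright interface where the horizontal surface is exposed
            exposed = valid & (level > fluid_top + 1.0)
            if exposed.any():
                cov_b = _band_coverage(
                    rows, np.full(ncols, level), np.full(ncols, level + 2.0)
                )
                structure += FLUID_BOUNDARY_INTENSITY * cov_b * exposed[None, :]
                fluid_boundary_row = float(level)
        fluid_mask = (rows >= fluid_top_eff[None, :]) & valid[None, :]
        if scene.mee_type == "dense":
            structure = np.where(fluid_mask, np.maximum(structure, DENSE_FILL_INTENSITY), structure)
        else:  # watery: sparse particulate scatterers on a dark background
            area_mm2 = fluid_mask.sum() * ap * lp * 1e-6
            n_particles = rng.poisson(scene.particle_density_per_mm2 * area_mm2)
            if n_particles > 0:
                flat = np.flatnonzero(fluid_mask.ravel())
                centers = rng.choice(flat, size=min(n_particles, flat.size), replace=False)
                rr, cc = np.unravel_index(centers, fluid_mask.shape)
                for dr in (0, 1):
                    for dc in (0, 1):
                        r2 = np.clip(rr + dr, 0, nrows - 1)
                        c2 = np.clip(cc + dc, 0, ncols - 1)
                        structure[r2, c2] = np.maximum(structure[r2, c2], PARTICLE_INTENSITY)

    # --- noise and resolution ---------------------------------------------
    if optics.speckle_contrast > 0:
        k = 1.0 / optics.speckle_contrast**2
        speckle = rng.gamma(shape=k, scale=1.0 / k, size=structure.shape)
        structure = structure * speckle
    sigma_px = optics.axial_resolution_um / 2.3548 / ap
    blurred = gaussian_filter1d(structure, sigma=sigma_px, axis=0, mode="nearest")
    image = blurred + optics.noise_floor_mean
    if optics.noise_floor_sd > 0:
        image = image + rng.normal(0.0, optics.noise_floor_sd, size=image.shape)
    image = np.clip(image, 0.0, 1.0)

    truth = PhantomTruth(
        anterior_row=np.where(valid, anterior, np.nan),
        thickness_um=np.where(valid, total_um, np.nan),
        valid=valid,
        tilt_deg=scene.tilt_deg,
        ri=scene.ri,
        mee_type=scene.mee_type,
        biofilm_present=scene.biofilm_present,
        fluid_boundary_row=fluid_boundary_row,
        seed=scene.seed,
    )
    scan = BScan(
        pixels=image,
        axial_pitch_um=ap,
        lateral_pitch_um=lp,
    )
    return scan, truth


# ---------------------------------------------------------------------------
# Longitudinal scenarios
# ---------------------------------------------------------------------------

#: Default cubic (ascending coefficients, um/day^k) for the treated responder:
#: rises to ~80 um by day 4, dips after the day-7 treatment, rises by day 13.
RESPONDER_CUBIC = (30.0, 30.858974358974358, -5.666666666666667, 0.2692307692307692)

#: Default untreated progression: ~31 um at day 0 growing to ~210 um by day 21.
OM_BASELINE_UM = 31.0
OM_SLOPE_UM_PER_DAY = (210.0 - 31.0) / 21.0

_SCENARIO_GROUP = {
    "control": "control",
    "om_progression": "no_treatment",
    "spontaneous_healing": "no_treatment",
    "treated_responder": "high_dose",
    "treated_nonresponder": "low_dose",
}


@dataclass
class ScenarioConfig:
    """A longitudinal disease course for one ear.

    ``scans_per_day`` is a desk-scale stand-in for the several hundred
    frames collected per imaging session; it is fully configurable.
    """

    scenario: str = "om_progression"
    days: tuple = (0, 1, 2, 3, 4, 5, 7, 9, 11, 13)
    baseline_um: float = OM_BASELINE_UM
    slope_um_per_day: float = OM_SLOPE_UM_PER_DAY
    cubic_coeffs: tuple = RESPONDER_CUBIC
    scans_per_day: int = 5
    seed: int = 0
    animal: str = "A1"
    ear: str = "L"
    group: str | None = None  # inferred from scenario when None
    tilt_range_deg: tuple = (40.0, 52.0)

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(
                f"unknown scenario {self.scenario!r}; valid scenarios: {SCENARIOS}"
            )
        days = tuple(int(d) for d in self.days)
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError("days must be strictly increasing")
        self.days = days
        if self.scans_per_day < 1:
            raise ValueError("scans_per_day must be >= 1")
        if self.group is None:
            self.group = _SCENARIO_GROUP[self.scenario]
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; valid groups: {GROUPS}")


@dataclass
class DayState:
    """True thickness and middle-ear state on one scenario day."""

    day: int
    total_um: float
    tm_um: float
    biofilm_um: float
    mee_type: str
    biofilm_present: bool
    fluid_fill_fraction: float


def scenario_day_state(cfg: ScenarioConfig, day: int) -> DayState:
    """Evaluate the scenario's disease-course curve and state flags at ``day``."""
    b = cfg.baseline_um
    name = cfg.scenario
    if name == "control":
        total, mee, biofilm_on = b, "clear", False
    elif name == "om_progression":
        total = b + cfg.slope_um_per_day * day
        mee = "clear" if day < 1 else ("watery" if day < 7 else "dense")
        biofilm_on = day >= 5
    elif name == "treated_nonresponder":
        # progression that plateaus after the (failed) day-7 treatment
        total = b + cfg.slope_um_per_day * min(day, 7)
        mee = "clear" if day < 1 else ("watery" if day < 7 else "dense")
        biofilm_on = day >= 5
    elif name == "treated_responder":
        c = cfg.cubic_coeffs
        total = c[0] + c[1] * day + c[2] * day**2 + c[3] * day**3
        if day < 1:
            mee = "clear"
        elif day < 5:
            mee = "watery"
        elif day < 9:
            mee = "dense"
        elif day < 12:
            mee = "watery"
        else:
            mee = "clear"
        biofilm_on = day >= 5  # thin biofilm persists at the end point
    elif name == "spontaneous_healing":
        peak_day, peak_excess, heal_day = 7.0, 60.0, 13.0
        if day <= peak_day:
            total = b + peak_excess * day / peak_day
        else:
            total = b + peak_excess * max(0.0, (heal_day - day) / (heal_day - peak_day))
        mee = "watery" if 1 <= day <= 9 else "clear"
        biofilm_on = 5 <= day <= 9
    else:  # pragma: no cover - guarded by ScenarioConfig
        raise ValueError(name)
    total = max(total, 0.6 * b)
    if biofilm_on:
        # the adherent layer dominates late-stage thickening; the inflamed
        # membrane proper accounts for the rest
        biofilm = max(0.0, 0.7 * (total - b))
        biofilm_on = biofilm > 0
    else:
        biofilm = 0.0
    return DayState(
        day=day,
        total_um=float(total),
        tm_um=float(total - biofilm),
        biofilm_um=float(biofilm),
        mee_type=mee,
        biofilm_present=biofilm_on,
        fluid_fill_fraction=1.0 if mee != "clear" else 0.0,
    )


def render_series(
    optics: OpticsConfig, scenario: ScenarioConfig
) -> list[tuple[int, BScan, PhantomTruth]]:
    """Render a longitudinal series of B-scans following a disease course.

    Per-day true thickness follows the scenario curve; state flags evolve
    with it (biofilm only after its onset day, effusion regime per
    phase).  Every scan carries its own truth record.  Within-day scans
    differ in seed and in a small tilt jitter drawn from
    ``tilt_range_deg``.
    """
    master = np.random.default_rng(scenario.seed)
    out: list[tuple[int, BScan, PhantomTruth]] = []
    for day in scenario.days:
        state = scenario_day_state(scenario, day)
        for _ in range(scenario.scans_per_day):
            tilt = float(master.uniform(*scenario.tilt_range_deg))
            scene = SceneConfig(
                tm_thickness_um=state.tm_um,
                tilt_deg=tilt,
                ri=1.44,
                biofilm_mean_um=state.biofilm_um,
                biofilm_cv=0.3,
                mee_type=state.mee_type,
                fluid_fill_fraction=state.fluid_fill_fraction,
                seed=int(master.integers(0, 2**31 - 1)),
            )
            scan, truth = render_bscan(optics, scene)
            scan.animal = scenario.animal
            scan.ear = scenario.ear
            scan.day = day
            scan.group = scenario.group
            out.append((day, scan, truth))
    return out


# ---------------------------------------------------------------------------
# Truth sidecars
# ---------------------------------------------------------------------------


def write_truth_sidecar(truth: PhantomTruth, path: str | os.PathLike) -> None:
    """Serialise a truth record to JSON (lossless round-trip)."""
    payload = {
        "anterior_row": [None if not np.isfinite(v) else float(v) for v in truth.anterior_row],
        "thickness_um": [None if not np.isfinite(v) else float(v) for v in truth.thickness_um],
        "valid": [bool(v) for v in truth.valid],
        "tilt_deg": truth.tilt_deg,
        "ri": truth.ri,
        "mee_type": truth.mee_type,
        "biofilm_present": truth.biofilm_present,
        "fluid_boundary_row": truth.fluid_boundary_row,
        "seed": truth.seed,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh)


def read_truth_sidecar(path: str | os.PathLike) -> PhantomTruth:
    """Load a truth record written by :func:`write_truth_sidecar`."""
    with open(path, "r", encoding="utf-8") as fh:
        payload = json.load(fh)
    return PhantomTruth(
        anterior_row=np.array(
            [np.nan if v is None else v for v in payload["anterior_row"]], dtype=float
        ),
        thickness_um=np.array(
            [np.nan if v is None else v for v in payload["thickness_um"]], dtype=float
        ),
        valid=np.array(payload["valid"], dtype=bool),
        tilt_deg=payload["tilt_deg"],
        ri=payload["ri"],
        mee_type=payload["mee_type"],
        biofilm_present=payload["biofilm_present"],
        fluid_boundary_row=payload["fluid_boundary_row"],
        seed=payload["seed"],
    )
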