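"""Rule-based middle-ear state classification.

Operationalizes visual reading criteria into a deterministic classifier:

* *watery* effusion — particulate-like scatterers in a dark, low-
  scattering background (or a visible fluid-air boundary);
* *dense* effusion — a brighter, tissue-like fill of the cavity;
* *clear* — no scatterers, no boundary, low background;
* *biofilm* — an additional bright layer adherent to the TM with
  inconsistent thickness, detected from thickness excess, thickness
  variability, and the relative brightness of the posterior half of the
  segmented band.

All numeric thresholds are this package's operationalization of verbal
criteria; they are exposed in :class:`ClassifierParams`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.measure import label, regionprops

from .scan_io import BScan
from .thickness_quant import ThicknessProfile
from .tm_segment import TMBoundaries

MEE_CLASSES = ("clear", "watery", "dense")
END_STATES = ("clear", "mee_only", "biofilm_only", "mee_and_biofilm", "excluded")


@dataclass
class ClassifierParams:
    """Numeric thresholds of the rule-based middle-ear classifier."""

    noise_k: float = 4.0  # scatterer threshold, noise-floor SD units
    particle_min_px: int = 2
    particle_max_px: int = 50
    watery_fraction_max: float = 0.10
    dense_background_z: float = 3.0
    biofilm_min_excess_um: float = 20.0
    biofilm_cv_min: float = 0.15
    biofilm_posterior_brightness_ratio: float = 0.8
    control_reference_um: float = 30.0
    roi_guard_px: int = 2
    roi_edge_trim_cols: int = 8  # drop columns near valid-run ends, where
    # boundary smoothing is least reliable
    boundary_min_span_fraction: float = 0.30
    boundary_max_rows: int = 12

    def __post_init__(self) -> None:
        if not 0.0 < self.watery_fraction_max < 1.0:
            raise ValueError("watery_fraction_max must lie in (0, 1)")
        for name in (
            "noise_k",
            "dense_background_z",
            "biofilm_min_excess_um",
            "biofilm_cv_min",
            "control_reference_um",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class ScatterStats:
    """Scatterer statistics of the middle-ear region of interest."""

    particle_count: int
    foreground_fraction: float
    roi_median_z: float
    noise_mean: float
    noise_sd: float
    roi_pixels: int


@dataclass
class ScanClassification:
    """Per-scan middle-ear reading."""

    mee_class: str
    biofilm_present: bool
    scatter: ScatterStats
    fluid_boundary_present: bool
    fluid_boundary_row: float | None

    @property
    def mee_present(self) -> bool:
        return self.mee_class != "clear" or self.fluid_boundary_present


@dataclass
class EarObservation:
    """One ear x day record aggregated over all usable scans."""

    animal: str
    ear: str
    day: int
    group: str
    thickness_mean_um: float = float("nan")
    thickness_sd_um: float = float("nan")
    mee_class: str = "clear"
    mee_present: bool = False
    biofilm_present: bool = False
    blocked: bool = False
    n_scans_used: int = 0


def middle_ear_roi(scan: BScan, boundaries: TMBoundaries, params: ClassifierParams | None = None) -> np.ndarray:
    """Boolean mask of the middle-ear cavity below the posterior boundary.

    Strictly deeper than the posterior curve with a guard band, restricted
    to columns with valid boundaries; never overlaps the TM segment.
    """
    params = params or ClassifierParams()
    nrows, ncols = scan.pixels.shape
    rows = np.arange(nrows)[:, None]
    cols_ok = boundaries.valid.copy()
    if params.roi_edge_trim_cols > 0 and cols_ok.any():
        from scipy.ndimage import binary_erosion

        cols_ok = binary_erosion(
            cols_ok, structure=np.ones(2 * params.roi_edge_trim_cols + 1, dtype=bool)
        )
    floor = np.where(cols_ok, boundaries.posterior + params.roi_guard_px, np.inf)
    return (rows > floor[None, :]) & cols_ok[None, :]


def estimate_noise_floor(
    scan: BScan, boundaries: TMBoundaries, guard_px: int = 4
) -> tuple[float, float]:
    """Mean and SD of the air region above the anterior boundary."""
    nrows = scan.pixels.shape[0]
    rows = np.arange(nrows)[:, None]
    ceil = np.where(boundaries.valid, boundaries.anterior - guard_px, -np.inf)
    air = (rows < ceil[None, :]) & boundaries.valid[None, :]
    if air.sum() < 100:
        raise ValueError("no air region above the membrane to estimate the noise floor")
    px = scan.pixels[air]
    return float(px.mean()), float(px.std())


def detect_scatterers(
    scan: BScan,
    roi: np.ndarray,
    params: ClassifierParams | None = None,
    noise: tuple[float, float] | None = None,
    boundaries: TMBoundaries | None = None,
) -> ScatterStats:
    """Count particulate scatterers and measure ROI foreground statistics.

    Pixels above ``noise_mean + noise_k * noise_sd`` are grouped by
    connectivity; components within the particle size band count as
    particles.  The foreground fraction is the supra-threshold pixel
    share of the ROI, and the ROI median is expressed in noise-SD units.
    """
    params = params or ClassifierParams()
    if noise is None:
        if boundaries is None:
            raise ValueError("either noise stats or boundaries must be given")
        noise = estimate_noise_floor(scan, boundaries)
    noise_mean, noise_sd = noise
    if roi.sum() == 0:
        return ScatterStats(0, 0.0, 0.0, noise_mean, noise_sd, 0)
    thr = noise_mean + params.noise_k * noise_sd
    fg = (scan.pixels > thr) & roi
    labelled = label(fg, connectivity=2)
    count = sum(
        1
        for p in regionprops(labelled)
        if params.particle_min_px <= p.area <= params.particle_max_px
    )
    fraction = float(fg.sum()) / float(roi.sum())
    median_z = (float(np.median(scan.pixels[roi])) - noise_mean) / max(noise_sd, 1e-9)
    return ScatterStats(count, fraction, median_z, noise_mean, noise_sd, int(roi.sum()))


def detect_fluid_air_boundary(
    scan: BScan,
    roi: np.ndarray,
    boundaries: TMBoundaries,
    params: ClassifierParams | None = None,
    noise: tuple[float, float] | None = None,
) -> tuple[bool, float | None]:
    """Detect a laterally extended bright fluid-air interface in the ROI.

    A qualifying component spans more than ``boundary_min_span_fraction``
    of the valid columns while staying thin axially (at most
    ``boundary_max_rows`` rows) — a meniscus line, not a filled cavity.
    """
    params = params or ClassifierParams()
    if noise is None:
        noise = estimate_noise_floor(scan, boundaries)
    noise_mean, noise_sd = noise
    if roi.sum() == 0:
        return False, None
    thr = noise_mean + params.noise_k * noise_sd
    fg = (scan.pixels > thr) & roi
    labelled = label(fg, connectivity=2)
    min_span = params.boundary_min_span_fraction * max(int(boundaries.valid.sum()), 1)
    for p in regionprops(labelled):
        span = p.bbox[3] - p.bbox[1]
        height = p.bbox[2] - p.bbox[0]
        if span > min_span and height <= params.boundary_max_rows:
            return True, float(p.centroid[0])
    return False, None


def classify_effusion(
    scatter: ScatterStats,
    fluid_boundary_present: bool,
    params: ClassifierParams | None = None,
) -> str:
    """Deterministic, total effusion rule.

    dense — bright tissue-like fill (high ROI median or large foreground
    fraction); watery — any particulate scatterers or a fluid-air
    boundary on a dark background; clear — neither.
    """
    params = params or ClassifierParams()
    if (
        scatter.roi_median_z >= params.dense_background_z
        or scatter.foreground_fraction > params.watery_fraction_max
    ):
        return "dense"
    if scatter.particle_count >= 1 or fluid_boundary_present:
        return "watery"
    return "clear"


def detect_biofilm(
    profile: ThicknessProfile,
    scan: BScan,
    boundaries: TMBoundaries,
    params: ClassifierParams | None = None,
) -> bool:
    """Flag an adherent biofilm layer on the TM.

    Requires simultaneously: mean corrected thickness at least
    ``control_reference_um + biofilm_min_excess_um`` (the band is far
    thicker than a clean TM), thickness coefficient of variation at least
    ``biofilm_cv_min`` ("inconsistent thickness"), and a posterior band
    half at least ``biofilm_posterior_brightness_ratio`` times as bright
    as the anterior half (the extra layer scatters strongly).
    """
    params = params or ClassifierParams()
    if not np.isfinite(profile.mean_um):
        return False
    thick_enough = profile.mean_um >= params.control_reference_um + params.biofilm_min_excess_um
    irregular = np.isfinite(profile.cv) and profile.cv >= params.biofilm_cv_min
    if not (thick_enough and irregular):
        return False

    ant_px, post_px = [], []
    for c in np.flatnonzero(boundaries.valid):
        a, b = boundaries.anterior[c], boundaries.posterior[c]
        mid = 0.5 * (a + b)
        r0, r1, r2 = int(np.ceil(a)), int(round(mid)), int(np.floor(b))
        if r1 > r0:
            ant_px.append(scan.pixels[r0:r1, c])
        if r2 > r1:
            post_px.append(scan.pixels[r1:r2, c])
    if not ant_px or not post_px:
        return False
    ant_mean = float(np.concatenate(ant_px).mean())
    post_mean = float(np.concatenate(post_px).mean())
    return post_mean >= params.biofilm_posterior_brightness_ratio * ant_mean


def classify_scan(
    scan: BScan,
    boundaries: TMBoundaries,
    profile: ThicknessProfile,
    params: ClassifierParams | None = None,
) -> ScanClassification:
    """Full per-scan reading: effusion class + biofilm flag."""
    params = params or ClassifierParams()
    noise = estimate_noise_floor(scan, boundaries)
    roi = middle_ear_roi(scan, boundaries, params)
    scatter = detect_scatterers(scan, roi, params, noise=noise)
    boundary_present, boundary_row = detect_fluid_air_boundary(
        scan, roi, boundaries, params, noise=noise
    )
    mee_class = classify_effusion(scatter, boundary_present, params)
    biofilm = detect_biofilm(profile, scan, boundaries, params)
    return ScanClassification(
        mee_class=mee_class,
        biofilm_present=biofilm,
        scatter=scatter,
        fluid_boundary_present=boundary_present,
        fluid_boundary_row=boundary_row,
    )


def aggregate_ear_day(
    scan_results: list[tuple[ScanClassification | None, ThicknessProfile | None]],
    animal: str,
    ear: str,
    day: int,
    group: str,
) -> EarObservation:
    """Combine per-scan readings into one ear x day observation.

    The effusion rule is an any-scan OR: the effusion is *present* if
    seen in any scan, and *clear* only when every scan is clear; the
    class is the most severe seen (dense > watery > clear).  Unusable
    scans (``None`` entries) are dropped; with zero usable scans the
    observation is marked blocked.
    """
    usable = [
        (c, p)
        for c, p in scan_results
        if c is not None and p is not None and np.isfinite(p.mean_um)
    ]
    if not usable:
        return EarObservation(animal=animal, ear=ear, day=day, group=group, blocked=True)

    classes = [c.mee_class for c, _ in usable]
    if "dense" in classes:
        mee_class = "dense"
    elif "watery" in classes:
        mee_class = "watery"
    else:
        mee_class = "clear"
    mee_present = any(c.mee_present for c, _ in usable)
    biofilm = any(c.biofilm_present for c, _ in usable)

    means = np.array([p.mean_um for _, p in usable])
    sds = np.array([p.sd_um for _, p in usable])
    ns = np.array([p.n_points_used for _, p in usable], dtype=float)
    grand = float(np.average(means, weights=ns))
    # pooled SD combining within-scan and between-scan variance
    total_n = ns.sum()
    pooled_var = (
        np.sum((ns - 1) * sds**2) + np.sum(ns * (means - grand) ** 2)
    ) / max(total_n - 1, 1)
    return EarObservation(
        animal=animal,
        ear=ear,
        day=day,
        group=group,
        thickness_mean_um=grand,
        thickness_sd_um=float(np.sqrt(pooled_var)),
        mee_class=mee_class,
        mee_present=mee_present,
        biofilm_present=biofilm,
        blocked=False,
        n_scans_used=len(usable),
    )


def ear_end_state(observations: list[EarObservation]) -> str:
    """End-time-point category for one ear's longitudinal series.

    Determined solely from the last observation; a blocked last
    observation excludes the ear from cohort tables.
    """
    if not observations:
        raise ValueError("empty observation series")
    last = max(observations, key=lambda o: o.day)
    if last.blocked:
        return "excluded"
    if last.mee_present and last.biofilm_present:
        return "mee_and_biofilm"
    if last.mee_present:
        return "mee_only"
    if last.biofilm_present:
        return "biofilm_only"
    return "clear"
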