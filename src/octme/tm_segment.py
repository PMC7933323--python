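"""Tympanic-membrane (plus adherent biofilm) segmentation.

The membrane is the first continuous reflective layer below the dark air
column of the ear canal.  Segmentation is deliberately classical: median
filtering, global thresholding (Otsu by default), morphological closing,
and connected-component selection, followed by sub-pixel boundary
refinement.  Any biofilm attached to the posterior surface is *included*
in the segment by construction — the downstream thickness is the overall
membrane-plus-biofilm thickness, with no attempt to split sublayers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_closing, median_filter
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from .scan_io import BScan


class NoMembraneDetected(RuntimeError):
    """No qualifying membrane component found (blocked or empty scan)."""


@dataclass
class SegmentationParams:
    """Tunable parameters of the classical segmentation chain."""

    median_kernel: int = 5
    threshold_method: str = "otsu"  # or "fixed"
    fixed_threshold: float = 0.3
    min_component_area_px: int = 200
    closing_radius_px: int = 2
    boundary_smooth_window: int = 11
    min_contrast_ratio: float = 1.5  # foreground/background mean intensity

    def __post_init__(self) -> None:
        for name in ("median_kernel", "boundary_smooth_window"):
            v = getattr(self, name)
            if v < 3 or v % 2 == 0:
                raise ValueError(f"{name} must be odd and >= 3")
        if self.threshold_method not in ("otsu", "fixed"):
            raise ValueError("threshold_method must be 'otsu' or 'fixed'")
        if not 0.0 < self.fixed_threshold < 1.0:
            raise ValueError("fixed_threshold must lie in (0, 1)")


@dataclass
class TMBoundaries:
    """Sub-pixel anterior/posterior membrane surface curves per column."""

    anterior: np.ndarray  # float rows, NaN where invalid
    posterior: np.ndarray
    valid: np.ndarray  # bool per column
    axial_pitch_um: float
    lateral_pitch_um: float
    labels: dict
    threshold: float = float("nan")
    low_valid_warning: bool = False

    def __post_init__(self) -> None:
        ok = self.valid
        if np.any(self.posterior[ok] < self.anterior[ok]):
            raise ValueError("posterior boundary crosses anterior boundary")

    @property
    def n_columns(self) -> int:
        return self.anterior.size

    @property
    def valid_fraction(self) -> float:
        return float(self.valid.mean()) if self.valid.size else 0.0


@dataclass
class QualityReport:
    """Usability verdict for one segmented scan."""

    valid_fraction: float
    roughness_rows: float
    usable: bool


def _nan_moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average ignoring NaNs (window odd)."""
    mask = np.isfinite(x)
    vals = np.where(mask, x, 0.0)
    kernel = np.ones(window)
    num = np.convolve(vals, kernel, mode="same")
    den = np.convolve(mask.astype(float), kernel, mode="same")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[~mask] = np.nan
    return out


def _halfmax_edges(
    col_profile: np.ndarray, rlo: int, rhi: int, margin: int = 4
) -> tuple[float, float]:
    """Sub-pixel anterior/posterior rows at the half-maximum level.

    The edge is located where the (median-filtered) intensity crosses the
    level midway between the local air background and the band's typical
    intensity; with a symmetric axial PSF this estimator is unbiased
    regardless of where the global threshold landed on the edge ramp.
    Pixel ``r`` samples the continuous depth coordinate ``r + 0.5``.
    """
    n = col_profile.size
    bg = col_profile[max(0, rlo - 30) : max(0, rlo - 6)]
    if bg.size >= 5:
        v_bg = float(np.median(bg))
    else:
        v_bg = float(np.percentile(col_profile, 10))
    band = col_profile[rlo : rhi + 1]
    v_peak = float(np.median(band)) if band.size >= 5 else float(band.max())
    t_edge = v_bg + 0.5 * (v_peak - v_bg)

    wlo, whi = max(0, rlo - margin), min(n - 1, rhi + margin)
    win = col_profile[wlo : whi + 1]
    above = np.flatnonzero(win >= t_edge)
    if above.size == 0:
        return float(rlo), float(rhi + 1)

    i = int(above[0])
    anterior = wlo + i + 0.5
    if i > 0 and win[i] > win[i - 1]:
        anterior -= (win[i] - t_edge) / (win[i] - win[i - 1])

    j = int(above[-1])
    posterior = wlo + j + 0.5
    if j < win.size - 1 and win[j] > win[j + 1]:
        posterior += (win[j] - t_edge) / (win[j] - win[j + 1])
    return float(anterior), float(posterior)


def segment_tm(scan: BScan, params: SegmentationParams | None = None) -> TMBoundaries:
    """Segment the TM (+ adherent biofilm) band and extract boundary curves.

    Chain: median filter -> global threshold -> morphological closing ->
    connected components -> component selection -> per-column first/last
    foreground rows with sub-pixel threshold-crossing refinement ->
    centered moving-average smoothing.

    Component selection: among components at least
    ``min_component_area_px`` large, candidates are those whose lateral
    span is at least half the widest candidate's span; of these the
    shallowest (smallest mean row) is the membrane — the first continuous
    reflective layer under the air column.  A steeply tilted membrane may
    legitimately span only part of the image width.
    """
    params = params or SegmentationParams()
    # median filtering along A-scans (axial direction): suppresses speckle
    # while preserving thin layers that are only a column or two wide
    # horizontally at steep tilt
    filtered = median_filter(scan.pixels, size=(params.median_kernel, 1))
    if params.threshold_method == "otsu":
        threshold = float(threshold_otsu(filtered))
    else:
        threshold = params.fixed_threshold
    binary = filtered >= threshold
    # a reflective layer is far brighter than the air background; when the
    # "foreground" is just the upper tail of the noise floor there is no
    # membrane in view
    fg_mean = float(filtered[binary].mean()) if binary.any() else 0.0
    bg_mean = float(filtered[~binary].mean()) if (~binary).any() else 0.0
    if not binary.any() or fg_mean < params.min_contrast_ratio * max(bg_mean, 1e-6):
        raise NoMembraneDetected(
            "no high-contrast reflective layer above the noise floor — "
            "blocked or empty scan"
        )
    if params.closing_radius_px > 0:
        # axial (vertical) closing: fills speckle dropouts inside the band
        # without laterally bridging the thin dark space that separates a
        # steeply tilted membrane from effusion content below it
        structure = np.ones((2 * params.closing_radius_px + 1, 1), dtype=bool)
        binary = binary_closing(binary, structure=structure)

    labelled = label(binary, connectivity=2)
    props = [p for p in regionprops(labelled) if p.area >= params.min_component_area_px]
    if not props:
        raise NoMembraneDetected("no component above the minimum area — blocked or empty scan")

    spans = {p.label: p.bbox[3] - p.bbox[1] for p in props}
    widest = max(spans.values())
    candidates = [p for p in props if spans[p.label] >= 0.5 * widest]
    membrane = min(candidates, key=lambda p: p.centroid[0])
    comp = labelled == membrane.label

    ncols = scan.pixels.shape[1]
    anterior = np.full(ncols, np.nan)
    posterior = np.full(ncols, np.nan)
    any_fg = comp.any(axis=0)
    for c in np.flatnonzero(any_fg):
        rows = np.flatnonzero(comp[:, c])
        anterior[c], posterior[c] = _halfmax_edges(filtered[:, c], rows[0], rows[-1])

    anterior = _nan_moving_average(anterior, params.boundary_smooth_window)
    posterior = _nan_moving_average(posterior, params.boundary_smooth_window)
    valid = np.isfinite(anterior) & np.isfinite(posterior)
    # smoothing cannot make the surfaces cross, but guard numerically
    bad = valid & (posterior < anterior)
    valid[bad] = False
    anterior[~valid] = np.nan
    posterior[~valid] = np.nan

    return TMBoundaries(
        anterior=anterior,
        posterior=posterior,
        valid=valid,
        axial_pitch_um=scan.axial_pitch_um,
        lateral_pitch_um=scan.lateral_pitch_um,
        labels=scan.labels,
        threshold=threshold,
        low_valid_warning=bool(valid.mean() < 0.5),
    )


def mask_quality(
    boundaries: TMBoundaries,
    min_valid_fraction: float = 0.5,
    roughness_cap_rows: float = 3.0,
) -> QualityReport:
    """Judge whether a segmented scan is usable for quantification.

    Roughness is the standard deviation of the first differences of the
    anterior boundary (rows): a straight boundary — horizontal or tilted —
    has roughness zero, while focus loss and artifacts inflate it.
    """
    frac = boundaries.valid_fraction
    ant = boundaries.anterior[boundaries.valid]
    if ant.size >= 3:
        roughness = float(np.std(np.diff(ant)))
    else:
        roughness = float("inf")
    usable = frac >= min_valid_fraction and roughness <= roughness_cap_rows
    return QualityReport(valid_fraction=frac, roughness_rows=roughness, usable=usable)
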