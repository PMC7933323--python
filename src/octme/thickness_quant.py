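"""Refraction-corrected orthogonal membrane thickness.

The OCT axial scale is air-calibrated optical path, so a membrane of
physical orthogonal thickness ``d`` imaged at incident angle ``theta_i``
through tissue of refractive index ``n`` appears with axial extent
``n * d / cos(theta_t)``, where ``theta_t = asin(sin(theta_i)/n)`` is the
refracted in-tissue angle.  The orthogonal distance measured between the
anterior and posterior boundary curves in image space equals that
apparent extent times ``cos(theta_i)`` (locally parallel surfaces), so
the physical thickness is recovered as

    d = d_img * cos(theta_t) / (n * cos(theta_i))

which reduces to ``d_img / n`` at normal incidence and to the identity
when ``n = 1``.  The incident angle is estimated from the *anterior*
surface only — the posterior surface is refraction-distorted in image
space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .tm_segment import TMBoundaries


class ScanUnusable(RuntimeError):
    """No run of enough consecutive valid points for a scan summary."""


@dataclass
class CorrectionParams:
    """Parameters of the angle estimation and refraction correction."""

    ri: float = 1.44
    tangent_window: int = 21
    n_points: int = 100
    max_angle_deg: float = 80.0

    def __post_init__(self) -> None:
        if self.ri < 1.0:
            raise ValueError("refractive index must be >= 1")
        if self.tangent_window < 3 or self.tangent_window % 2 == 0:
            raise ValueError("tangent_window must be odd and >= 3")
        if self.n_points < 10:
            raise ValueError("n_points must be >= 10")


@dataclass
class ThicknessProfile:
    """Per-point angles and thickness, plus the scan-level summary."""

    columns: np.ndarray
    theta_i_deg: np.ndarray
    theta_t_deg: np.ndarray
    d_img_um: np.ndarray  # raw orthogonal image distance (optical um)
    d_um: np.ndarray  # corrected physical thickness
    valid: np.ndarray
    labels: dict
    mean_um: float = float("nan")
    sd_um: float = float("nan")
    run_start: int = -1
    n_points_used: int = 0

    @property
    def cv(self) -> float:
        """Coefficient of variation of corrected thickness over valid points."""
        d = self.d_um[self.valid]
        if d.size < 2 or np.mean(d) == 0:
            return float("nan")
        return float(np.std(d, ddof=1) / np.mean(d))


def snell_refract(theta_i_deg, ri: float):
    """Refracted angle theta_t = asin(sin(theta_i)/n), degrees in and out."""
    theta_i = np.asarray(theta_i_deg, dtype=float)
    if np.any((theta_i < 0) | (theta_i >= 90)):
        raise ValueError("incident angle must lie in [0, 90) degrees")
    if ri < 1.0:
        raise ValueError("refractive index must be >= 1")
    out = np.degrees(np.arcsin(np.sin(np.radians(theta_i)) / ri))
    return float(out) if np.isscalar(theta_i_deg) else out


def correct_thickness(d_img_um, theta_i_deg, ri: float):
    """Convert orthogonal image distance to physical thickness (micrometres).

    ``d = d_img * cos(theta_t) / (n * cos(theta_i))``; at normal incidence
    this is ``d_img / n``, and at ``n = 1`` it is the identity.
    """
    d_img = np.asarray(d_img_um, dtype=float)
    if np.any(d_img <= 0):
        raise ValueError("d_img must be > 0")
    theta_i = np.asarray(theta_i_deg, dtype=float)
    if np.any(theta_i >= 90):
        raise ValueError("incident angle must be < 90 degrees")
    theta_t = np.radians(snell_refract(theta_i, ri))
    out = d_img * np.cos(theta_t) / (ri * np.cos(np.radians(theta_i)))
    return float(out) if np.isscalar(d_img_um) else out


def _local_slopes(boundaries: TMBoundaries, params: CorrectionParams) -> np.ndarray:
    """Least-squares anterior-surface slope (dz/dx, um/um) per column.

    A centered window of ``tangent_window`` columns is fit with a line in
    physical units; columns whose window contains any invalid point get
    NaN.
    """
    n = boundaries.n_columns
    half = params.tangent_window // 2
    x = np.arange(n) * boundaries.lateral_pitch_um
    z = boundaries.anterior * boundaries.axial_pitch_um
    slopes = np.full(n, np.nan)
    ok = boundaries.valid
    for c in range(half, n - half):
        sl = slice(c - half, c + half + 1)
        if not ok[sl].all():
            continue
        xs, zs = x[sl], z[sl]
        xm = xs.mean()
        denom = np.sum((xs - xm) ** 2)
        slopes[c] = np.sum((xs - xm) * (zs - zs.mean())) / denom
    return slopes


def incident_angle(boundaries: TMBoundaries, params: CorrectionParams | None = None) -> np.ndarray:
    """Per-column incident angle theta_i (degrees) from the anterior surface.

    theta_i = arctan(|slope|) is the angle between the vertical beam axis
    and the local surface normal.  Columns at grazing incidence (above
    ``max_angle_deg``) or with incomplete tangent windows are NaN.
    """
    params = params or CorrectionParams()
    if boundaries.valid.sum() < params.tangent_window:
        raise ScanUnusable("fewer valid columns than the tangent window")
    slopes = _local_slopes(boundaries, params)
    theta = np.degrees(np.arctan(np.abs(slopes)))
    theta[theta > params.max_angle_deg] = np.nan
    return theta


def orthogonal_distance(
    boundaries: TMBoundaries,
    column: int,
    params: CorrectionParams | None = None,
    slopes: np.ndarray | None = None,
) -> float:
    """Orthogonal image distance (micrometres) at one column.

    Measured from the anterior point along the anterior-surface normal to
    the intersection with the linearly interpolated posterior curve, in
    physical units honouring the anisotropic pixel pitches.  Returns NaN
    when the normal ray exits the valid posterior domain.
    """
    params = params or CorrectionParams()
    if slopes is None:
        slopes = _local_slopes(boundaries, params)
    m = slopes[column]
    if not np.isfinite(m) or not boundaries.valid[column]:
        return float("nan")
    lp, ap = boundaries.lateral_pitch_um, boundaries.axial_pitch_um
    x0 = column * lp
    z0 = boundaries.anterior[column] * ap

    vcols = np.flatnonzero(boundaries.valid)
    xv = vcols * lp
    zv = boundaries.posterior[vcols] * ap

    norm = math.hypot(m, 1.0)
    ux, uz = -m / norm, 1.0 / norm  # unit normal pointing deeper

    def gap(t: float) -> float:
        x, z = x0 + t * ux, z0 + t * uz
        if x < xv[0] or x > xv[-1]:
            return float("nan")
        return z - float(np.interp(x, xv, zv))

    g0 = gap(0.0)
    if not np.isfinite(g0) or g0 > 0:
        return float("nan")
    # march outward until the ray crosses the posterior curve
    t_hi, step = 0.0, max(ap, 2.0)
    for _ in range(100000):
        t_try = t_hi + step
        g = gap(t_try)
        if not np.isfinite(g):
            return float("nan")
        if g >= 0:
            return float(brentq(gap, t_hi, t_try, xtol=1e-6))
        t_hi = t_try
    return float("nan")


def compute_profile(
    boundaries: TMBoundaries, params: CorrectionParams | None = None
) -> ThicknessProfile:
    """Full per-point chain: angle -> orthogonal distance -> RI correction.

    The scan summary (mean +/- SD over the first ``n_points`` of the
    longest consecutive valid run) is attached when such a run exists;
    otherwise the summary fields stay NaN (use :func:`summarize_scan` to
    get a hard error instead).
    """
    params = params or CorrectionParams()
    theta_i = incident_angle(boundaries, params)
    slopes = _local_slopes(boundaries, params)
    n = boundaries.n_columns
    d_img = np.full(n, np.nan)
    for c in np.flatnonzero(np.isfinite(theta_i)):
        d_img[c] = orthogonal_distance(boundaries, c, params, slopes=slopes)

    valid = np.isfinite(theta_i) & np.isfinite(d_img) & (d_img > 0)
    theta_t = np.full(n, np.nan)
    d = np.full(n, np.nan)
    if valid.any():
        theta_t[valid] = snell_refract(theta_i[valid], params.ri)
        d[valid] = correct_thickness(d_img[valid], theta_i[valid], params.ri)

    profile = ThicknessProfile(
        columns=np.arange(n),
        theta_i_deg=theta_i,
        theta_t_deg=theta_t,
        d_img_um=d_img,
        d_um=d,
        valid=valid,
        labels=boundaries.labels,
    )
    try:
        summarize_scan(profile, params)
    except ScanUnusable:
        pass
    return profile


def _longest_true_run(mask: np.ndarray) -> tuple[int, int]:
    """(start, length) of the longest run of True values."""
    best_start = best_len = 0
    start = None
    for i, v in enumerate(mask):
        if v and start is None:
            start = i
        elif not v and start is not None:
            if i - start > best_len:
                best_start, best_len = start, i - start
            start = None
    if start is not None and mask.size - start > best_len:
        best_start, best_len = start, mask.size - start
    return best_start, best_len


def summarize_scan(
    profile: ThicknessProfile, params: CorrectionParams | None = None
) -> tuple[float, float]:
    """Scan-level thickness: mean and sample SD over ``n_points`` points.

    The points are the first ``n_points`` of the longest run of
    consecutive valid points; requiring a long consecutive run mirrors
    averaging "around 100 consecutive points" along the membrane.
    Mutates the profile's summary fields and returns ``(mean, sd)``.
    """
    params = params or CorrectionParams()
    start, length = _longest_true_run(profile.valid)
    if length < params.n_points:
        raise ScanUnusable(
            f"longest valid run has {length} points; {params.n_points} required"
        )
    sel = profile.d_um[start : start + params.n_points]
    profile.mean_um = float(np.mean(sel))
    profile.sd_um = float(np.std(sel, ddof=1))
    profile.run_start = start
    profile.n_points_used = params.n_points
    return profile.mean_um, profile.sd_um
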