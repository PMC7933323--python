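"""Longitudinal polynomial trend fitting and group summaries.

Per-animal mean thickness versus day is fit with an ordinary
least-squares polynomial (degree 1, 2 or 3) on raw day values, and each
coefficient is tested against zero with a two-sided t test on
``n - (degree + 1)`` degrees of freedom.  For a linear fit, a
significant positive slope (p < 0.05) is called an increasing trend and
a significant negative slope a decreasing one; otherwise no trend.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

ALPHA = 0.05


@dataclass
class TrendFit:
    """A fitted polynomial trend with per-coefficient inference.

    Coefficients are in ascending order (intercept first), in units of
    um/day^k.
    """

    degree: int
    coefficients: np.ndarray
    standard_errors: np.ndarray
    t_statistics: np.ndarray
    p_values: np.ndarray
    r_squared: float
    n: int
    trend_call: str = "none"  # increasing / decreasing / none (degree 1 only)

    @property
    def slope(self) -> float:
        return float(self.coefficients[1])

    def predict(self, days) -> np.ndarray:
        days = np.asarray(days, dtype=float)
        return sum(c * days**k for k, c in enumerate(self.coefficients))


def _design(days: np.ndarray, degree: int) -> np.ndarray:
    return np.column_stack([days**k for k in range(degree + 1)])


def fit_polynomial_trend(days, values, degree: int = 1) -> TrendFit:
    """OLS polynomial fit of thickness over time with coefficient t tests.

    Requires ``n >= degree + 2`` so the residual degrees of freedom allow
    inference.  Days are used raw (uncentered).
    """
    days = np.asarray(days, dtype=float)
    values = np.asarray(values, dtype=float)
    if degree not in (1, 2, 3):
        raise ValueError("degree must be 1, 2 or 3")
    n = days.size
    if n < degree + 2:
        raise ValueError(f"need at least {degree + 2} time points for degree {degree}")
    if np.all(days == days[0]):
        raise ValueError("days must not all be equal")
    X = _design(days, degree)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular design matrix (repeated days?)")
    res = sm.OLS(values, X).fit()

    call = "none"
    if degree == 1:
        slope, p = res.params[1], res.pvalues[1]
        if p < ALPHA:
            call = "increasing" if slope > 0 else "decreasing"
    return TrendFit(
        degree=degree,
        coefficients=np.asarray(res.params),
        standard_errors=np.asarray(res.bse),
        t_statistics=np.asarray(res.tvalues),
        p_values=np.asarray(res.pvalues),
        r_squared=float(res.rsquared),
        n=n,
        trend_call=call,
    )


def select_degree(days, values, candidates=(1, 2, 3)) -> int:
    """Choose the polynomial degree by an adjusted-R-squared parsimony rule.

    Among candidate degrees with enough points, the smallest degree whose
    adjusted R-squared is within 0.02 of the maximum wins; ties break
    toward the smaller degree.  Deterministic.
    """
    days = np.asarray(days, dtype=float)
    values = np.asarray(values, dtype=float)
    if days.size < 5:
        raise ValueError("degree selection needs at least 5 time points")
    adj: dict[int, float] = {}
    for deg in sorted(candidates):
        if days.size >= deg + 2:
            X = _design(days, deg)
            adj[deg] = float(sm.OLS(values, X).fit().rsquared_adj)
    if not adj:
        raise ValueError("no feasible candidate degree")
    best = max(adj.values())
    for deg in sorted(adj):
        if adj[deg] >= best - 0.02:
            return deg
    return max(adj)  # pragma: no cover


def group_summary(observations: pd.DataFrame, group: str, min_tracking_day: int = 3) -> pd.DataFrame:
    """Per-day mean +/- SD of thickness across animals in one group.

    Animals are the averaging unit: both ears of an animal are averaged
    first, then the mean and SD across animals are taken per calendar
    day.  Animals tracked no longer than ``min_tracking_day`` are
    excluded.  Blocked observations are dropped.
    """
    obs = observations[(observations["group"] == group) & (~observations["blocked"])]
    if len(obs) == 0:
        raise ValueError(f"no usable observations for group {group!r}")
    last_day = obs.groupby("animal")["day"].max()
    keep = last_day[last_day > min_tracking_day].index
    obs = obs[obs["animal"].isin(keep)]
    if len(obs) == 0:
        raise ValueError(
            f"group {group!r} empty after excluding animals tracked <= day {min_tracking_day}"
        )
    per_animal = (
        obs.groupby(["animal", "day"])["thickness_mean_um"].mean().reset_index()
    )
    out = (
        per_animal.groupby("day")["thickness_mean_um"]
        .agg(mean_um="mean", sd_um=lambda s: s.std(ddof=1), n_animals="count")
        .reset_index()
    )
    return out


def plot_group_trends(observations: pd.DataFrame, out_path, groups=None) -> None:
    """Plot per-group mean +/- SD thickness curves over time (PNG/SVG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if groups is None:
        groups = sorted(observations.loc[~observations["blocked"], "group"].unique())
    fig, ax = plt.subplots(figsize=(6, 4))
    for group in groups:
        gs = group_summary(observations, group)
        n = int(gs["n_animals"].max())
        ax.errorbar(
            gs["day"], gs["mean_um"], yerr=gs["sd_um"].fillna(0.0),
            marker="o", capsize=3, label=f"{group} (n = {n})",
        )
    ax.set_xlabel("days post-inoculation")
    ax.set_ylabel("TM thickness (um)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
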