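"""ATP-maintenance calibration from measured growth-rate ranges.

The non-growth-associated ATP maintenance (ATPM) flux is the model's free
energy-expenditure parameter.  It is calibrated per temperature by

1. a robustness scan: successively increasing the ATPM flux and maximizing
   biomass at each step;
2. an ordinary-least-squares line through the (ATPM, max biomass) points in
   the linear regime (points with biomass above 1% of the scan maximum —
   the near-zero plateau would bias the fit);
3. projecting the measured growth-rate range (μ_lo, μ_hi) through the
   inverted fit, atpm(μ) = (μ − intercept)/slope, giving the ATPM window
   [atpm(μ_hi), atpm(μ_lo)] (slope is negative, so the faster measured
   growth maps to the lower maintenance bound).

The default grid is 50 evenly spaced points from 0 to the ATPM value at
which biomass first reaches 0, located by bisection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .tmfa import TMFAProblem, TMFASolution, fix_flux, solve

__all__ = [
    "RobustnessCurve",
    "ATPMRange",
    "robustness_scan",
    "fit_linear",
    "project_atpm",
    "default_atpm_grid",
    "calibrate_atpm",
    "plot_robustness",
]

log = logging.getLogger(__name__)

#: Biomass below this fraction of the scan maximum is treated as the
#: infeasible plateau and excluded from the linear fit.
LINEAR_REGIME_FRACTION = 0.01


@dataclass
class RobustnessCurve:
    """Ordered (ATPM flux, max biomass) points from one scan."""

    atpm: np.ndarray
    max_biomass: np.ndarray
    flagged: np.ndarray  # True where the solve was infeasible (biomass set 0)
    temperature_K: float

    def __post_init__(self) -> None:
        self.atpm = np.asarray(self.atpm, dtype=float)
        self.max_biomass = np.asarray(self.max_biomass, dtype=float)
        self.flagged = np.asarray(self.flagged, dtype=bool)
        if not np.all(np.diff(self.atpm) > 0):
            raise ValueError("ATPM grid must be strictly increasing")


@dataclass
class ATPMRange:
    """Calibrated maintenance-flux window for one temperature."""

    lower: float
    upper: float
    fit_slope: float
    fit_intercept: float
    fit_r2: float
    growth_range: tuple[float, float]

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError("ATPM range: lower > upper")


def robustness_scan(
    problem: TMFAProblem, atpm_grid, seed: int = 0
) -> RobustnessCurve:
    """Maximize biomass at each ATPM grid value.

    Infeasible grid points are recorded with max_biomass = 0 and flagged.
    """
    grid = np.asarray(list(atpm_grid), dtype=float)
    if grid.size == 0:
        raise ValueError("empty ATPM grid")
    atpm_id = problem.model.atpm_reaction_id
    biomass_id = problem.model.biomass_reaction_id
    biomass = np.zeros_like(grid)
    flagged = np.zeros(grid.shape, dtype=bool)
    for i, value in enumerate(grid):
        fixed = fix_flux(problem, atpm_id, float(value), tolerance=0.0)
        sol: TMFASolution = solve(fixed, {biomass_id: 1.0}, sense="max", seed=seed)
        if sol.feasible:
            biomass[i] = sol.objective_value
        else:
            flagged[i] = True
            log.info("ATPM=%g infeasible during robustness scan", value)
    return RobustnessCurve(
        atpm=grid,
        max_biomass=biomass,
        flagged=flagged,
        temperature_K=problem.config.temperature_K,
    )


def fit_linear(
    curve: RobustnessCurve, min_fraction: float = LINEAR_REGIME_FRACTION
) -> tuple[float, float, float]:
    """OLS fit (slope, intercept, r²) over the curve's linear regime."""
    mask = ~curve.flagged
    peak = curve.max_biomass[mask].max() if mask.any() else 0.0
    mask &= curve.max_biomass > min_fraction * peak
    if mask.sum() < 2:
        raise ValueError("fewer than 2 usable points for the linear fit")
    x = curve.atpm[mask]
    y = curve.max_biomass[mask]
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 if ss_tot == 0 else 1.0 - np.sum(resid**2) / ss_tot
    return float(slope), float(intercept), float(r2)


def project_atpm(
    fit: tuple[float, float, float], growth_range: tuple[float, float]
) -> ATPMRange:
    """Invert the fit over the measured growth range.

    Requires a negative slope (a real biomass/maintenance trade-off);
    projections below 0 are clipped with a warning.
    """
    slope, intercept, r2 = fit
    if slope >= 0:
        raise ValueError(
            f"non-negative robustness slope {slope}: no ATP trade-off detected"
        )
    mu_lo, mu_hi = growth_range
    if mu_lo > mu_hi:
        raise ValueError("growth range must satisfy mu_lo <= mu_hi")
    lower = (mu_hi - intercept) / slope
    upper = (mu_lo - intercept) / slope
    if lower < 0:
        log.warning("projected ATPM lower bound %.4g < 0; clipping to 0", lower)
        lower = 0.0
    if upper < 0:
        log.warning("projected ATPM upper bound %.4g < 0; clipping to 0", upper)
        upper = 0.0
    return ATPMRange(
        lower=lower,
        upper=upper,
        fit_slope=slope,
        fit_intercept=intercept,
        fit_r2=r2,
        growth_range=(mu_lo, mu_hi),
    )


def default_atpm_grid(
    problem: TMFAProblem, n_points: int = 50, seed: int = 0
) -> np.ndarray:
    """Evenly spaced grid from 0 to the zero-biomass ATPM limit (bisection)."""
    atpm_id = problem.model.atpm_reaction_id
    biomass_id = problem.model.biomass_reaction_id

    def max_biomass(value: float) -> float:
        sol = solve(
            fix_flux(problem, atpm_id, value), {biomass_id: 1.0}, sense="max", seed=seed
        )
        return sol.objective_value if sol.feasible else -1.0

    lo = 0.0
    hi = problem.flux_bounds(atpm_id)[1]
    if max_biomass(lo) <= 0:
        raise ValueError("no growth at zero maintenance; cannot build a grid")
    if max_biomass(hi) > 1e-9:
        return np.linspace(lo, hi, n_points)
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if max_biomass(mid) > 1e-9:
            lo = mid
        else:
            hi = mid
    return np.linspace(0.0, hi, n_points)


def calibrate_atpm(
    problem: TMFAProblem,
    growth_range: tuple[float, float],
    n_points: int = 50,
    seed: int = 0,
) -> tuple[ATPMRange, RobustnessCurve]:
    """Full calibration: scan, fit, project.  Returns (range, curve)."""
    grid = default_atpm_grid(problem, n_points=n_points, seed=seed)
    curve = robustness_scan(problem, grid, seed=seed)
    fit = fit_linear(curve)
    return project_atpm(fit, growth_range), curve


def plot_robustness(
    curve: RobustnessCurve, atpm_range: ATPMRange, path: str | Path
) -> None:
    """Robustness curve with growth-rate and projection guide lines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ok = ~curve.flagged
    ax.plot(curve.atpm[ok], curve.max_biomass[ok], "o-", ms=3, label="max biomass")
    for mu in atpm_range.growth_range:
        ax.axhline(mu, color="gray", lw=0.8)
    for a in (atpm_range.lower, atpm_range.upper):
        ax.axvline(a, color="tab:red", lw=0.8)
    ax.set_xlabel("ATPM flux")
    ax.set_ylabel("optimized biomass flux")
    ax.set_title(f"T = {curve.temperature_K:.2f} K")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
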