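"""Random-simulation ensembles and derived efficiency metrics.

For one temperature condition the ensemble draws, for each of n
simulations, a growth rate μ_k uniformly from the measured range, fixes the
biomass flux to μ_k, and solves the thermodynamically constrained program
under a random linear objective over all reaction fluxes (coefficients
uniform on [−1, 1]).  The random objective explores different vertices of
the μ-constrained feasible set, which is what makes flux variability across
draws informative; the per-draw objective is recorded so any row can be
replayed.  Reaction fluxes, realized ΔrG′, and metabolite
log-concentrations are collected into per-condition matrices.

Per-simulation metrics:

* carbon use efficiency  CUE = (C_in − C_out)/C_in, with exchange fluxes
  partitioned by sign and scaled by each compound's carbon count;
* ATP produced per unit of carbon source, and ATP consumed per gDW of
  biomass — from summing flux × ATP stoichiometry over all ATP-involving
  reactions, with the maintenance reaction excluded so the metrics reflect
  metabolic demands only.

Direction classes over an ensemble (tolerance 1e-6 flux units): a reaction
is obligate in a direction if every simulation carries flux that way,
blocked if no simulation does, optional otherwise — the solid vs. dashed
arrows of a pathway-utilization map.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .calibration import ATPMRange
from .gem import MetabolicModel, carbon_count
from .tmfa import TMFAProblem, fix_flux, solve

__all__ = [
    "ConditionSpec",
    "EnsembleResult",
    "run_ensemble",
    "compute_cue",
    "atp_accounting",
    "efficiency_metrics",
    "concentration_ratio",
    "classify_directions",
    "summarize",
    "save_ensemble",
    "load_ensemble",
    "OXYGEN_SOLUBILITY",
]

log = logging.getLogger(__name__)

#: |flux| below this is "no flux" for direction classification, flux units.
DIRECTION_TOL = 1e-6

#: O2 solubility in seawater-like media, mol/L, by temperature (deg C).
#: Benson-Krause-style values; overridable per condition.
OXYGEN_SOLUBILITY = {4.0: 4.0e-4, 15.0: 3.1e-4, 20.0: 2.8e-4}


@dataclass
class ConditionSpec:
    """One temperature condition of the study design."""

    name: str
    temperature_K: float
    growth_range: tuple[float, float]
    atpm_range: tuple[float, float] | ATPMRange
    n_simulations: int = 1000
    seed: int = 0
    oxygen_conc_hi: float | None = None  # mol/L
    oxygen_exchange_lo: float | None = None  # flux units
    oxygen_metabolite_id: str | None = None
    oxygen_exchange_id: str | None = None

    def __post_init__(self) -> None:
        lo, hi = self.growth_range
        if lo > hi:
            raise ValueError("growth_range must satisfy mu_lo <= mu_hi")
        if self.n_simulations < 1:
            raise ValueError("n_simulations must be >= 1")

    @property
    def atpm_bounds(self) -> tuple[float, float]:
        if isinstance(self.atpm_range, ATPMRange):
            return (self.atpm_range.lower, self.atpm_range.upper)
        return self.atpm_range


@dataclass
class EnsembleResult:
    """Per-simulation matrices for one condition (rows = simulations)."""

    condition: ConditionSpec
    fluxes: pd.DataFrame
    drG: pd.DataFrame
    ln_conc: pd.DataFrame
    mu: np.ndarray
    objective_seeds: list[int] = field(default_factory=list)
    failures: int = 0

    @property
    def n(self) -> int:
        return len(self.fluxes)


def _apply_condition(problem: TMFAProblem, condition: ConditionSpec) -> TMFAProblem:
    p = problem.copy()
    p.flux_bound_overrides[problem.model.atpm_reaction_id] = condition.atpm_bounds
    if condition.oxygen_conc_hi is not None:
        if condition.oxygen_metabolite_id is None:
            raise ValueError("oxygen_conc_hi set but oxygen_metabolite_id missing")
        lo, _ = p.conc_bounds(condition.oxygen_metabolite_id)
        p.conc_bound_overrides[condition.oxygen_metabolite_id] = (
            lo,
            condition.oxygen_conc_hi,
        )
    if condition.oxygen_exchange_lo is not None:
        if condition.oxygen_exchange_id is None:
            raise ValueError("oxygen_exchange_lo set but oxygen_exchange_id missing")
        _, hi = p.flux_bounds(condition.oxygen_exchange_id)
        p.flux_bound_overrides[condition.oxygen_exchange_id] = (
            condition.oxygen_exchange_lo,
            hi,
        )
    return p


def run_ensemble(problem: TMFAProblem, condition: ConditionSpec) -> EnsembleResult:
    """Run the random-simulation ensemble for one condition.

    Deterministic for a fixed (problem, condition): all randomness flows
    from ``condition.seed``.  An infeasible draw is logged and resampled up
    to 3 times; more than 10% failed draws aborts with diagnostics.
    """
    base = _apply_condition(problem, condition)
    rng = np.random.default_rng(condition.seed)
    rxn_ids = list(problem.model.reactions)
    mu_lo, mu_hi = condition.growth_range
    biomass_id = problem.model.biomass_reaction_id

    flux_rows, drg_rows, lnc_rows, mus = [], [], [], []
    failures = 0
    for k in range(condition.n_simulations):
        solved = False
        for attempt in range(4):
            mu = float(rng.uniform(mu_lo, mu_hi))
            coefs = rng.uniform(-1.0, 1.0, size=len(rxn_ids))
            objective = dict(zip(rxn_ids, coefs))
            fixed = fix_flux(base, biomass_id, mu, tolerance=0.0)
            sol = solve(fixed, objective, sense="max", seed=condition.seed)
            if sol.feasible:
                solved = True
                break
            failures += 1
            log.warning(
                "simulation %d attempt %d infeasible at mu=%.6g", k, attempt, mu
            )
        if not solved:
            continue
        flux_rows.append(sol.fluxes)
        drg_rows.append(sol.drG)
        lnc_rows.append(sol.ln_conc)
        mus.append(mu)

    if failures > 0.1 * condition.n_simulations:
        raise RuntimeError(
            f"condition {condition.name}: {failures} infeasible draws out of "
            f"{condition.n_simulations} requested — check ATPM/growth ranges "
            f"(atpm={condition.atpm_bounds}, mu={condition.growth_range})"
        )
    return EnsembleResult(
        condition=condition,
        fluxes=pd.DataFrame(flux_rows).reindex(columns=rxn_ids),
        drG=pd.DataFrame(drg_rows),
        ln_conc=pd.DataFrame(lnc_rows),
        mu=np.array(mus),
        failures=failures,
    )


# ---------------------------------------------------------------------------
# Per-simulation metrics
# ---------------------------------------------------------------------------


def compute_cue(fluxes: Mapping[str, float], model: MetabolicModel) -> float:
    """Carbon use efficiency of one solution.

    Exchange fluxes are split by sign (negative = uptake), each scaled by
    the compound's carbon count; CUE = (C_in − C_out)/C_in.  Returns NaN
    when no carbon is consumed.
    """
    c_in = 0.0
    c_out = 0.0
    for rid in model.exchange_reactions():
        rxn = model.reactions[rid]
        v = fluxes.get(rid, 0.0)
        if abs(v) <= DIRECTION_TOL:
            continue
        (mid,) = [
            m for m in rxn.stoichiometry if not model.metabolites[m].artificial
        ]
        met = model.metabolites[mid]
        if not met.formula:
            continue
        n_c = carbon_count(met.formula)
        if n_c == 0:
            continue
        # exchange convention: coefficient −1 on the boundary metabolite,
        # so negative flux is uptake and positive flux is secretion
        if v < 0:
            c_in += n_c * (-v) * abs(rxn.stoichiometry[mid])
        else:
            c_out += n_c * v * abs(rxn.stoichiometry[mid])
    if c_in <= 0:
        return math.nan
    return (c_in - c_out) / c_in


def atp_accounting(
    fluxes: Mapping[str, float],
    model: MetabolicModel,
    atp_id: str | None = None,
) -> tuple[float, float]:
    """Total ATP produced and consumed across the flux vector.

    Per reaction, term = flux × s_ATP; positive terms sum to production,
    negative terms (absolute) to consumption.  The ATPM reaction is
    excluded so the totals reflect metabolic processes only.
    """
    atp = atp_id or model.atp_metabolite_id
    if atp is None:
        raise ValueError("ATP metabolite id unknown; set model.atp_metabolite_id")
    produced = 0.0
    consumed = 0.0
    for rid, rxn in model.reactions.items():
        if rid == model.atpm_reaction_id:
            continue
        s = rxn.stoichiometry.get(atp)
        if not s:
            continue
        term = fluxes.get(rid, 0.0) * s
        if term > 0:
            produced += term
        else:
            consumed += -term
    return produced, consumed


def efficiency_metrics(
    ensemble: EnsembleResult,
    model: MetabolicModel,
    substrate_exchange_id: str,
    atp_id: str | None = None,
) -> pd.DataFrame:
    """Per-simulation CUE, ATP/substrate, ATP/biomass table.

    ``atp_per_substrate`` divides total ATP production by the magnitude of
    the carbon-source exchange flux; ``atp_per_biomass`` divides total ATP
    consumption by the biomass flux.  Rows with zero substrate uptake get
    NaN metrics.
    """
    biomass_id = model.biomass_reaction_id
    records = []
    for _, row in ensemble.fluxes.iterrows():
        produced, consumed = atp_accounting(row, model, atp_id=atp_id)
        uptake = abs(row[substrate_exchange_id])
        mu = row[biomass_id]
        records.append(
            {
                "cue": compute_cue(row, model),
                "atp_per_substrate": produced / uptake if uptake > DIRECTION_TOL else math.nan,
                "atp_per_biomass": consumed / mu if mu > DIRECTION_TOL else math.nan,
            }
        )
    return pd.DataFrame(records)


def concentration_ratio(
    ln_conc: Mapping[str, float], numerator_id: str, denominator_id: str
) -> float:
    """exp(ln c_num − ln c_den) for one solution's concentration vector."""
    for mid in (numerator_id, denominator_id):
        if mid not in ln_conc:
            raise KeyError(f"metabolite {mid!r} carries no concentration variable")
    return math.exp(ln_conc[numerator_id] - ln_conc[denominator_id])


def classify_directions(
    ensemble: EnsembleResult, tol: float = DIRECTION_TOL
) -> dict[str, str]:
    """Obligate/optional/blocked classes per reaction over the ensemble."""
    if ensemble.n == 0:
        raise ValueError("empty ensemble")
    out: dict[str, str] = {}
    for rid in ensemble.fluxes.columns:
        v = ensemble.fluxes[rid].to_numpy()
        if np.all(v > tol):
            out[rid] = "obligate_forward"
        elif np.all(v < -tol):
            out[rid] = "obligate_reverse"
        elif np.all(np.abs(v) <= tol):
            out[rid] = "blocked"
        else:
            out[rid] = "optional"
    return out


def summarize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Median/min/max/q25/q75 per column (linear-interpolation quantiles)."""
    if matrix.empty:
        raise ValueError("empty ensemble matrix")
    return pd.DataFrame(
        {
            "median": matrix.median(),
            "min": matrix.min(),
            "max": matrix.max(),
            "q25": matrix.quantile(0.25, interpolation="linear"),
            "q75": matrix.quantile(0.75, interpolation="linear"),
        }
    )


# ---------------------------------------------------------------------------
# Persistence: directory of TSV matrices + JSON manifest
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.12g"


def save_ensemble(ensemble: EnsembleResult, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ensemble.fluxes.to_csv(directory / "fluxes.tsv", sep="\t", float_format=_FLOAT_FMT)
    ensemble.drG.to_csv(directory / "drG.tsv", sep="\t", float_format=_FLOAT_FMT)
    ensemble.ln_conc.to_csv(
        directory / "ln_conc.tsv", sep="\t", float_format=_FLOAT_FMT
    )
    cond = ensemble.condition
    manifest = {
        "condition": {
            "name": cond.name,
            "temperature_K": cond.temperature_K,
            "growth_range": list(cond.growth_range),
            "atpm_bounds": list(cond.atpm_bounds),
            "n_simulations": cond.n_simulations,
            "seed": cond.seed,
        },
        "n_rows": ensemble.n,
        "failures": ensemble.failures,
        "mu": [round(float(v), 12) for v in ensemble.mu],
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))


def load_ensemble(directory: str | Path) -> EnsembleResult:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    c = manifest["condition"]
    condition = ConditionSpec(
        name=c["name"],
        temperature_K=c["temperature_K"],
        growth_range=tuple(c["growth_range"]),
        atpm_range=tuple(c["atpm_bounds"]),
        n_simulations=c["n_simulations"],
        seed=c["seed"],
    )
    return EnsembleResult(
        condition=condition,
        fluxes=pd.read_csv(directory / "fluxes.tsv", sep="\t", index_col=0),
        drG=pd.read_csv(directory / "drG.tsv", sep="\t", index_col=0),
        ln_conc=pd.read_csv(directory / "ln_conc.tsv", sep="\t", index_col=0),
        mu=np.array(manifest["mu"]),
        failures=manifest["failures"],
    )
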