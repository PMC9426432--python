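"""Thermodynamics-based metabolic flux analysis as a mixed-integer program.

For each thermodynamically constrained reaction i the flux is decomposed
into nonnegative forward and reverse parts with direction binaries,

    v_i = v_i^f − v_i^r,   0 ≤ v_i^f ≤ cap_f·z_i^f,   0 ≤ v_i^r ≤ cap_r·z_i^r,
    z_i^f + z_i^r ≤ 1,

and the Gibbs energy variable ΔG_i (defined by the affine ΔrG′ expression
from :mod:`thermoflux.thermo`) is coupled to the binaries by big-M rows

    ΔG_i − K_i·(1 − z_i^f) ≤ −ε,      −ΔG_i − K_i·(1 − z_i^r) ≤ −ε,

so that a direction may only carry flux if it is thermodynamically feasible
(ΔrG′ ≤ −ε in that direction; ε = 0 by default).  Excluded reactions get a
plain signed flux variable with bound constraints only.  Metabolite
log-concentrations and the two pH variables are bounded decision variables;
steady state S·v = 0 is enforced for every metabolite.

K_i is computed per reaction as the attainable |ΔrG′| range plus a 1 kJ/mol
margin, which keeps the relaxation tight; a global ``bigM_K`` override is
validated against that range at build time.

The flux split uses nonnegative parts rather than indicator constraints so
the formulation is portable across MILP backends.  The default backend is
HiGHS via :func:`scipy.optimize.milp` (single-threaded and deterministic);
the backend is selected by a config key and unknown keys raise.
"""

from __future__ import annotations

import copy
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp
from scipy.optimize import Bounds, LinearConstraint, milp

from .gem import ConstraintTables, MetabolicModel
from .thermo import DrGExpression, ThermoConfig, ThermoData, drG_expression

__all__ = [
    "TMFAProblem",
    "TMFASolution",
    "build_problem",
    "solve",
    "fix_flux",
    "variability",
    "export_lp",
]

log = logging.getLogger(__name__)

#: Tolerance below which a flux is treated as zero, model flux units.
FLUX_TOL = 1e-9
#: Relative MIP gap required for a solution to be reported optimal.
MIP_REL_GAP = 1e-9

_BACKENDS = ("highs",)


@dataclass
class TMFASolution:
    """One feasible/optimal point of the thermodynamically constrained program."""

    status: str  # optimal | feasible | infeasible
    objective_value: float | None
    fluxes: dict[str, float]
    directions: dict[str, str]  # forward | reverse | off
    ln_conc: dict[str, float]
    drG: dict[str, float]
    ph_in: float | None = None
    ph_out: float | None = None
    solver_gap: float = 0.0

    @property
    def feasible(self) -> bool:
        return self.status in ("optimal", "feasible")


@dataclass
class TMFAProblem:
    """Declarative problem state; compiled to matrices at each solve.

    Holding the high-level description (model, thermo data, config, tables,
    plus override dictionaries) rather than a compiled matrix makes
    copy-on-write operations like :func:`fix_flux` trivial and keeps solves
    reproducible: every solve compiles the same matrices from the same
    state.  Compilation cost is negligible at the problem sizes TMFA big-M
    formulations are practical for.
    """

    model: MetabolicModel
    thermo: ThermoData
    config: ThermoConfig
    tables: ConstraintTables
    flux_bound_overrides: dict[str, tuple[float, float]] = field(default_factory=dict)
    conc_bound_overrides: dict[str, tuple[float, float]] = field(default_factory=dict)
    include_thermo: bool = True
    backend: str = "highs"

    def copy(self) -> "TMFAProblem":
        new = copy.copy(self)
        new.flux_bound_overrides = dict(self.flux_bound_overrides)
        new.conc_bound_overrides = dict(self.conc_bound_overrides)
        return new

    def relaxed(self) -> "TMFAProblem":
        """Copy with all thermodynamic rows removed (plain FBA)."""
        new = self.copy()
        new.include_thermo = False
        return new

    # -- effective bounds ---------------------------------------------------

    def flux_bounds(self, rid: str) -> tuple[float, float]:
        if rid in self.flux_bound_overrides:
            return self.flux_bound_overrides[rid]
        rxn = self.model.reactions[rid]
        if rxn.is_exchange and rid in self.tables.exchange_bounds:
            return self.tables.exchange_bounds[rid]
        return (rxn.lower_bound, rxn.upper_bound)

    def conc_bounds(self, mid: str) -> tuple[float, float]:
        if mid in self.conc_bound_overrides:
            return self.conc_bound_overrides[mid]
        return self.tables.conc_bounds(mid)

    def constrained_reactions(self) -> list[str]:
        if not self.include_thermo:
            return []
        return self.thermo.constrained_ids(self.model)

    def concentration_metabolites(self) -> list[str]:
        from .thermo import is_proton, is_water

        out = []
        for mid, met in self.model.metabolites.items():
            if met.artificial or is_water(met) or is_proton(met):
                continue
            out.append(mid)
        return out

    # -- big-M --------------------------------------------------------------

    def _expr(self, rid: str) -> DrGExpression:
        return drG_expression(
            self.model.reactions[rid], self.model, self.thermo, self.config
        )

    def bigM(self, rid: str) -> float:
        """Per-reaction K covering the attainable |ΔrG′| range plus margin."""
        expr = self._expr(rid)
        span = abs(expr.const)
        for mid, coef in expr.lnc_coefs.items():
            lo, hi = self.conc_bounds(mid)
            span += abs(coef) * max(abs(math.log(lo)), abs(math.log(hi)))
        for coef, (lo, hi) in (
            (expr.ph_in_coef, self.config.pH_in_bounds),
            (expr.ph_out_coef, self.config.pH_out_bounds),
        ):
            span += abs(coef) * max(abs(lo), abs(hi))
        K = span + abs(self.config.feasibility_epsilon) + 1.0
        if self.thermo.bigM_K is not None:
            if self.thermo.bigM_K < K:
                raise ValueError(
                    f"bigM_K={self.thermo.bigM_K} too small for reaction "
                    f"{rid}; safe value is {K:.3f} kJ/mol"
                )
            return self.thermo.bigM_K
        return K


def build_problem(
    model: MetabolicModel,
    thermo: ThermoData,
    config: ThermoConfig,
    tables: ConstraintTables,
    backend: str = "highs",
) -> TMFAProblem:
    """Validate inputs and assemble a TMFA problem."""
    if backend not in _BACKENDS:
        raise ValueError(f"unknown solver backend {backend!r}; known: {_BACKENDS}")
    model.validate()
    problem = TMFAProblem(
        model=model, thermo=thermo, config=config, tables=tables, backend=backend
    )
    # Trigger the big-M safety check at build time for every constrained
    # reaction so that an undersized global K fails early, with the computed
    # safe value in the message.
    for rid in problem.constrained_reactions():
        problem.bigM(rid)
    return problem


# ---------------------------------------------------------------------------
# Compilation to scipy.optimize.milp
# ---------------------------------------------------------------------------


class _Compiled:
    """Variable index maps + sparse constraint matrix for one problem state."""

    def __init__(self, problem: TMFAProblem):
        self.problem = problem
        self.names: list[str] = []
        self.lb: list[float] = []
        self.ub: list[float] = []
        self.integrality: list[int] = []
        self.index: dict[str, int] = {}

        self.rows: list[dict[int, float]] = []
        self.row_lb: list[float] = []
        self.row_ub: list[float] = []

        self._build()

    def _add_var(
        self, name: str, lb: float, ub: float, integer: bool = False
    ) -> int:
        idx = len(self.names)
        self.names.append(name)
        self.lb.append(lb)
        self.ub.append(ub)
        self.integrality.append(1 if integer else 0)
        self.index[name] = idx
        return idx

    def _add_row(self, coefs: dict[int, float], lb: float, ub: float) -> None:
        self.rows.append(coefs)
        self.row_lb.append(lb)
        self.row_ub.append(ub)

    def _build(self) -> None:
        p = self.problem
        model = p.model
        cfg = p.config
        eps = cfg.feasibility_epsilon
        constrained = set(p.constrained_reactions())

        # flux variables
        for rid in model.reactions:
            lb, ub = p.flux_bounds(rid)
            if rid in constrained:
                cap_f = max(0.0, ub)
                cap_r = max(0.0, -lb)
                self._add_var(f"vf::{rid}", max(0.0, lb), cap_f)
                self._add_var(f"vr::{rid}", max(0.0, -ub), cap_r)
                self._add_var(f"zf::{rid}", 0.0, 1.0 if cap_f > 0 else 0.0, True)
                self._add_var(f"zr::{rid}", 0.0, 1.0 if cap_r > 0 else 0.0, True)
                self._add_var(f"dg::{rid}", -np.inf, np.inf)
            else:
                self._add_var(f"v::{rid}", lb, ub)

        if p.include_thermo:
            for mid in p.concentration_metabolites():
                lo, hi = p.conc_bounds(mid)
                self._add_var(f"lnc::{mid}", math.log(lo), math.log(hi))
            self._add_var("ph_in", *cfg.pH_in_bounds)
            self._add_var("ph_out", *cfg.pH_out_bounds)

        # steady state: for each metabolite, sum_i s_ij * v_i = 0
        balance: dict[str, dict[int, float]] = {
            mid: {} for mid in model.metabolites
        }
        for rid, rxn in model.reactions.items():
            if rid in constrained:
                i_f = self.index[f"vf::{rid}"]
                i_r = self.index[f"vr::{rid}"]
                for mid, coef in rxn.stoichiometry.items():
                    balance[mid][i_f] = balance[mid].get(i_f, 0.0) + coef
                    balance[mid][i_r] = balance[mid].get(i_r, 0.0) - coef
            else:
                i_v = self.index[f"v::{rid}"]
                for mid, coef in rxn.stoichiometry.items():
                    balance[mid][i_v] = balance[mid].get(i_v, 0.0) + coef
        for mid, coefs in balance.items():
            if coefs:
                self._add_row(coefs, 0.0, 0.0)

        # direction coupling + thermodynamic rows
        for rid in model.reactions:
            if rid not in constrained:
                continue
            i_f = self.index[f"vf::{rid}"]
            i_r = self.index[f"vr::{rid}"]
            i_zf = self.index[f"zf::{rid}"]
            i_zr = self.index[f"zr::{rid}"]
            i_dg = self.index[f"dg::{rid}"]
            cap_f = self.ub[i_f]
            cap_r = self.ub[i_r]
            if cap_f > 0:
                self._add_row({i_f: 1.0, i_zf: -cap_f}, -np.inf, 0.0)
            if cap_r > 0:
                self._add_row({i_r: 1.0, i_zr: -cap_r}, -np.inf, 0.0)
            self._add_row({i_zf: 1.0, i_zr: 1.0}, -np.inf, 1.0)

            expr = p._expr(rid)
            # dg - RT*sum(s*lnc) - ph terms = const
            row = {i_dg: 1.0}
            for mid, coef in expr.lnc_coefs.items():
                row[self.index[f"lnc::{mid}"]] = -coef
            if expr.ph_in_coef:
                row[self.index["ph_in"]] = row.get(self.index["ph_in"], 0.0) - expr.ph_in_coef
            if expr.ph_out_coef:
                row[self.index["ph_out"]] = (
                    row.get(self.index["ph_out"], 0.0) - expr.ph_out_coef
                )
            self._add_row(row, expr.const, expr.const)

            K = p.bigM(rid)
            # dg + K*zf <= K - eps ;  -dg + K*zr <= K - eps
            self._add_row({i_dg: 1.0, i_zf: K}, -np.inf, K - eps)
            self._add_row({i_dg: -1.0, i_zr: K}, -np.inf, K - eps)

    # -- solving ------------------------------------------------------------

    def objective_vector(self, objective: dict[str, float], sense: str) -> np.ndarray:
        c = np.zeros(len(self.names))
        constrained = set(self.problem.constrained_reactions())
        for rid, coef in objective.items():
            if rid in constrained:
                c[self.index[f"vf::{rid}"]] += coef
                c[self.index[f"vr::{rid}"]] -= coef
            elif f"v::{rid}" in self.index:
                c[self.index[f"v::{rid}"]] += coef
            else:
                raise KeyError(f"objective references unknown reaction {rid!r}")
        if sense == "max":
            c = -c
        elif sense != "min":
            raise ValueError(f"sense must be 'max' or 'min', got {sense!r}")
        return c

    def constraint_matrix(self) -> LinearConstraint:
        n = len(self.names)
        data, ri, ci = [], [], []
        for r, coefs in enumerate(self.rows):
            for cidx, val in coefs.items():
                ri.append(r)
                ci.append(cidx)
                data.append(val)
        A = sp.csr_matrix((data, (ri, ci)), shape=(len(self.rows), n))
        return LinearConstraint(A, np.array(self.row_lb), np.array(self.row_ub))

    def solve(self, objective: dict[str, float], sense: str):
        c = self.objective_vector(objective, sense)
        res = milp(
            c=c,
            constraints=self.constraint_matrix(),
            bounds=Bounds(np.array(self.lb), np.array(self.ub)),
            integrality=np.array(self.integrality),
            options={"mip_rel_gap": MIP_REL_GAP, "presolve": True},
        )
        return res

    def extract(self, res, sense: str) -> TMFASolution:
        p = self.problem
        if res.status != 0 or res.x is None:
            return TMFASolution(
                status="infeasible",
                objective_value=None,
                fluxes={},
                directions={},
                ln_conc={},
                drG={},
            )
        x = res.x
        constrained = set(p.constrained_reactions())
        fluxes: dict[str, float] = {}
        directions: dict[str, str] = {}
        drG: dict[str, float] = {}
        for rid in p.model.reactions:
            if rid in constrained:
                vf = x[self.index[f"vf::{rid}"]]
                vr = x[self.index[f"vr::{rid}"]]
                zf = x[self.index[f"zf::{rid}"]]
                zr = x[self.index[f"zr::{rid}"]]
                fluxes[rid] = vf - vr
                if zf > 0.5:
                    directions[rid] = "forward"
                elif zr > 0.5:
                    directions[rid] = "reverse"
                else:
                    directions[rid] = "off"
                drG[rid] = x[self.index[f"dg::{rid}"]]
            else:
                v = x[self.index[f"v::{rid}"]]
                fluxes[rid] = v
                if v > FLUX_TOL:
                    directions[rid] = "forward"
                elif v < -FLUX_TOL:
                    directions[rid] = "reverse"
                else:
                    directions[rid] = "off"
        ln_conc = {}
        ph_in = ph_out = None
        if p.include_thermo:
            ln_conc = {
                mid: x[self.index[f"lnc::{mid}"]]
                for mid in p.concentration_metabolites()
            }
            ph_in = x[self.index["ph_in"]]
            ph_out = x[self.index["ph_out"]]
        gap = float(getattr(res, "mip_gap", 0.0) or 0.0)
        objective_value = -res.fun if sense == "max" else res.fun
        status = "optimal" if gap <= 1e-6 else "feasible"
        return TMFASolution(
            status=status,
            objective_value=objective_value,
            fluxes=fluxes,
            directions=directions,
            ln_conc=ln_conc,
            drG=drG,
            ph_in=ph_in,
            ph_out=ph_out,
            solver_gap=gap,
        )


def solve(
    problem: TMFAProblem,
    objective: dict[str, float],
    sense: str = "max",
    seed: int = 0,
) -> TMFASolution:
    """Solve the program for a linear objective over reaction fluxes.

    ``seed`` is accepted for interface stability; the HiGHS backend is
    deterministic for a fixed problem, so it is unused there.
    """
    compiled = _Compiled(problem)
    res = compiled.solve(objective, sense)
    return compiled.extract(res, sense)


def fix_flux(
    problem: TMFAProblem,
    reaction_id: str,
    value: float,
    tolerance: float = 0.0,
) -> TMFAProblem:
    """Copy of the problem with a reaction pinned to value ± tolerance.

    The original problem is unmodified (copy-on-write).  ``value`` must lie
    within the reaction's current effective bounds.
    """
    lb, ub = problem.flux_bounds(reaction_id)
    if not (lb - FLUX_TOL <= value <= ub + FLUX_TOL):
        raise ValueError(
            f"cannot fix {reaction_id} at {value}: outside bounds ({lb}, {ub})"
        )
    new = problem.copy()
    new.flux_bound_overrides[reaction_id] = (value - tolerance, value + tolerance)
    return new


def variability(
    problem: TMFAProblem, targets: list[str], seed: int = 0
) -> dict[str, tuple[float, float]]:
    """Per-reaction (min, max) flux over the MILP feasible set.

    Two solves per target.  Raises ``RuntimeError`` if the problem itself is
    infeasible.
    """
    out: dict[str, tuple[float, float]] = {}
    for rid in targets:
        lo = solve(problem, {rid: 1.0}, sense="min", seed=seed)
        hi = solve(problem, {rid: 1.0}, sense="max", seed=seed)
        if not lo.feasible or not hi.feasible:
            raise RuntimeError("variability on an infeasible problem")
        out[rid] = (lo.fluxes[rid], hi.fluxes[rid])
    return out


def export_lp(problem: TMFAProblem, path: str | Path, objective: dict[str, float] | None = None) -> None:
    """Write the compiled program as a CPLEX-LP-format text file for debugging."""
    compiled = _Compiled(problem)
    objective = objective or {problem.model.biomass_reaction_id: 1.0}
    c = compiled.objective_vector(objective, "min")

    def vname(i: int) -> str:
        return compiled.names[i].replace("::", "_").replace("[", "_").replace("]", "")

    obj_terms = " + ".join(f"{c[i]:g} {vname(i)}" for i in range(len(c)) if c[i])
    lines = ["Minimize", f" obj: {obj_terms or '0'}", "Subject To"]
    for r, coefs in enumerate(compiled.rows):
        terms = " + ".join(f"{v:g} {vname(i)}" for i, v in coefs.items())
        lo, hi = compiled.row_lb[r], compiled.row_ub[r]
        if lo == hi:
            lines.append(f" c{r}: {terms} = {lo:g}")
        else:
            if np.isfinite(hi):
                lines.append(f" c{r}u: {terms} <= {hi:g}")
            if np.isfinite(lo):
                lines.append(f" c{r}l: {terms} >= {lo:g}")
    lines.append("Bounds")
    for i in range(len(compiled.names)):
        lines.append(f" {compiled.lb[i]:g} <= {vname(i)} <= {compiled.ub[i]:g}")
    binaries = [vname(i) for i in range(len(compiled.names)) if compiled.integrality[i]]
    if binaries:
        lines.append("Binary")
        lines.extend(f" {b}" for b in binaries)
    lines.append("End")
    Path(path).write_text("\n".join(lines) + "\n")
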