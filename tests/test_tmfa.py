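"""MILP construction and solution properties, checked against LP enumeration."""

import numpy as np
import pytest

from thermoflux.synthetic import ToyNetworkSpec, make_chain_model
from thermoflux.thermo import ThermoConfig, ThermoData
from thermoflux.tmfa import (
    _Compiled,
    build_problem,
    export_lp,
    fix_flux,
    solve,
    variability,
)

from _oracles import enumerate_tmfa

T = 288.15


def _problem(spec=None, temperature=T, **thermo_overrides):
    model, thermo, tables, meta = make_chain_model(spec or ToyNetworkSpec())
    for k, v in thermo_overrides.items():
        setattr(thermo, k, v)
    return (
        build_problem(model, thermo, ThermoConfig(temperature_K=temperature), tables),
        meta,
    )


class TestStructure:
    def test_chain_problem_counts(self, chain_problem):
        """Each constrained reaction contributes one ΔG variable and two binaries."""
        compiled = _Compiled(chain_problem)
        constrained = chain_problem.constrained_reactions()
        # chain: T_sub + R1..R3 constrained
        assert set(constrained) == {"T_sub", "R1", "R2", "R3"}
        dg_vars = [n for n in compiled.names if n.startswith("dg::")]
        binaries = [
            n
            for i, n in enumerate(compiled.names)
            if compiled.integrality[i]
        ]
        assert len(dg_vars) == 4
        assert len(binaries) == 8

    def test_excluded_reaction_gets_plain_bounds(self, chain_problem):
        compiled = _Compiled(chain_problem)
        assert "v::SEC" in compiled.index
        assert "dg::SEC" not in compiled.index
        assert "zf::SEC" not in compiled.index

    def test_undersized_global_bigM_rejected(self):
        model, thermo, tables, _ = make_chain_model(ToyNetworkSpec())
        thermo.bigM_K = 1.0
        with pytest.raises(ValueError, match="safe value"):
            build_problem(model, thermo, ThermoConfig(temperature_K=T), tables)

    def test_unknown_backend_rejected(self):
        model, thermo, tables, _ = make_chain_model(ToyNetworkSpec())
        with pytest.raises(ValueError, match="backend"):
            build_problem(
                model, thermo, ThermoConfig(temperature_K=T), tables, backend="cplex"
            )

    def test_lp_export_writes_program(self, tmp_path, chain_problem):
        path = tmp_path / "problem.lp"
        export_lp(chain_problem, path)
        text = path.read_text()
        assert "Binary" in text and "Subject To" in text


class TestSolve:
    def test_max_biomass_equals_analytic_yield(self, chain_problem, chain):
        _, _, _, meta = chain
        sol = solve(chain_problem, {"BIOMASS": 1.0}, "max")
        assert sol.status == "optimal"
        assert sol.objective_value == pytest.approx(meta["max_biomass"], abs=1e-7)

    def test_no_carbon_source_means_no_growth(self, chain):
        model, thermo, tables, _ = chain
        problem = build_problem(model, thermo, ThermoConfig(temperature_K=T), tables)
        problem.flux_bound_overrides["EX_sub"] = (0.0, 0.0)
        # biomass demanded but unreachable -> infeasible
        forced = fix_flux(problem, "BIOMASS", 1.0)
        assert solve(forced, {"BIOMASS": 1.0}, "max").status == "infeasible"

    def test_steady_state_and_direction_consistency(self, chain_problem, chain):
        model, _, _, _ = chain
        sol = solve(chain_problem, {"BIOMASS": 1.0}, "max")
        S = model.stoichiometric_matrix()
        v = np.array([sol.fluxes[rid] for rid in S.columns])
        assert np.allclose(S.to_numpy() @ v, 0.0, atol=1e-7)
        eps = chain_problem.config.feasibility_epsilon
        for rid in chain_problem.constrained_reactions():
            if sol.fluxes[rid] > 1e-6:
                assert sol.drG[rid] <= eps + 1e-7
            elif sol.fluxes[rid] < -1e-6:
                assert sol.drG[rid] >= -eps - 1e-7

    def test_concentrations_within_bounds(self, chain_problem):
        sol = solve(chain_problem, {"BIOMASS": 1.0}, "max")
        for mid, lnc in sol.ln_conc.items():
            lo, hi = chain_problem.conc_bounds(mid)
            assert np.log(lo) - 1e-9 <= lnc <= np.log(hi) + 1e-9

    def test_fba_relaxation_dominates(self, chain_problem):
        tmfa_opt = solve(chain_problem, {"BIOMASS": 1.0}, "max").objective_value
        fba_opt = solve(chain_problem.relaxed(), {"BIOMASS": 1.0}, "max").objective_value
        assert fba_opt >= tmfa_opt - 1e-9


class TestFixFlux:
    def test_fix_then_solve_returns_value(self, chain_problem):
        fixed = fix_flux(chain_problem, "BIOMASS", 0.25)
        sol = solve(fixed, {"BIOMASS": 1.0}, "max")
        assert sol.fluxes["BIOMASS"] == pytest.approx(0.25, abs=1e-9)

    def test_original_unmodified(self, chain_problem):
        before = dict(chain_problem.flux_bound_overrides)
        fix_flux(chain_problem, "BIOMASS", 0.25)
        assert chain_problem.flux_bound_overrides == before

    def test_fix_beyond_achievable_max_is_infeasible(self, chain_problem):
        mx = solve(chain_problem, {"BIOMASS": 1.0}, "max").objective_value
        fixed = fix_flux(chain_problem, "BIOMASS", mx + 1.0)
        assert solve(fixed, {"BIOMASS": 1.0}, "max").status == "infeasible"

    def test_value_outside_bounds_rejected(self, chain_problem):
        with pytest.raises(ValueError):
            fix_flux(chain_problem, "BIOMASS", 101.0)


class TestVariability:
    def test_blocked_reaction_range_is_zero(self, cycle_problem, cycle):
        _, _, _, meta = cycle
        ranges = variability(cycle_problem, meta["cycle_reactions"])
        for rid in meta["cycle_reactions"]:
            assert ranges[rid] == pytest.approx((0.0, 0.0), abs=1e-9)

    def test_substrate_uptake_strictly_negative_with_biomass_fixed(
        self, chain_problem
    ):
        fixed = fix_flux(chain_problem, "BIOMASS", 1.0)
        ranges = variability(fixed, ["EX_sub"])
        assert ranges["EX_sub"][1] < 0

    def test_variability_matches_enumeration(self, chain_problem):
        ranges = variability(chain_problem, ["R1"])
        lo, _ = enumerate_tmfa(chain_problem, {"R1": 1.0}, "min")
        hi, _ = enumerate_tmfa(chain_problem, {"R1": 1.0}, "max")
        assert ranges["R1"][0] == pytest.approx(lo, abs=1e-7)
        assert ranges["R1"][1] == pytest.approx(hi, abs=1e-7)


class TestEnumerationOracle:
    """MILP feasible set == exhaustive direction enumeration, small nets."""

    @pytest.mark.parametrize(
        "spec",
        [
            ToyNetworkSpec(n_linear_steps=2),
            ToyNetworkSpec(n_linear_steps=3, include_bypass=True),
            ToyNetworkSpec(n_linear_steps=2, include_cycle=True),
            ToyNetworkSpec(n_linear_steps=3, dG0_profile={"R2": 25.0}),
            ToyNetworkSpec(n_linear_steps=2, reversible_step="R2"),
        ],
        ids=["chain2", "bypass", "cycle", "blocked-step", "reversible-step"],
    )
    def test_optimum_matches_enumeration(self, spec):
        problem, _ = _problem(spec)
        objective = {"BIOMASS": 1.0}
        milp_sol = solve(problem, objective, "max")
        oracle_best, patterns = enumerate_tmfa(problem, objective, "max")
        if oracle_best is None:
            assert milp_sol.status == "infeasible"
        else:
            assert milp_sol.objective_value == pytest.approx(oracle_best, abs=1e-6)

    def test_feasible_patterns_match(self):
        """Fixing the binaries reproduces the oracle's per-pattern feasibility."""
        problem, _ = _problem(ToyNetworkSpec(n_linear_steps=2, include_cycle=True))
        _, patterns = enumerate_tmfa(problem, {"BIOMASS": 1.0}, "max")
        compiled = _Compiled(problem)
        state_bits = {"F": (1, 0), "R": (0, 1), "O": (0, 0)}
        for pattern, oracle_value in patterns.items():
            lb = list(compiled.lb)
            ub = list(compiled.ub)
            for rid, state in pattern:
                zf, zr = state_bits[state]
                for name, val in ((f"zf::{rid}", zf), (f"zr::{rid}", zr)):
                    i = compiled.index[name]
                    lb[i] = ub[i] = float(val)
            compiled.lb, compiled.ub = lb, ub
            res = compiled.solve({"BIOMASS": 1.0}, "max")
            milp_feasible = res.status == 0
            assert milp_feasible == (oracle_value is not None), pattern
            if milp_feasible:
                assert -res.fun == pytest.approx(oracle_value, abs=1e-6), pattern
            compiled = _Compiled(problem)  # reset bounds


class TestLoopLaw:
    def test_no_circulation_under_thermo(self, cycle_problem, cycle):
        _, _, _, meta = cycle
        for rid in meta["cycle_reactions"]:
            sol = solve(cycle_problem, {rid: 1.0}, "max")
            assert sol.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_relaxation_circulates(self, cycle_problem, cycle):
        _, _, _, meta = cycle
        rid = meta["cycle_reactions"][0]
        sol = solve(cycle_problem.relaxed(), {rid: 1.0}, "max")
        assert sol.objective_value > 10.0


def test_determinism_same_problem_same_solution(chain_problem):
    a = solve(chain_problem, {"BIOMASS": 1.0, "SEC": -0.1}, "max", seed=1)
    b = solve(chain_problem, {"BIOMASS": 1.0, "SEC": -0.1}, "max", seed=1)
    assert a.fluxes == b.fluxes
    assert a.ln_conc == b.ln_conc
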