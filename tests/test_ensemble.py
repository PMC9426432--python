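"""Ensemble determinism, efficiency metrics, direction classes, summaries."""

import math

import numpy as np
import pandas as pd
import pytest

from thermoflux.ensemble import (
    ConditionSpec,
    atp_accounting,
    classify_directions,
    compute_cue,
    concentration_ratio,
    efficiency_metrics,
    load_ensemble,
    run_ensemble,
    save_ensemble,
    summarize,
)
from thermoflux.synthetic import ToyNetworkSpec, make_chain_model

T = 288.15


@pytest.fixture(scope="module")
def chain_ensemble(chain_problem):
    cond = ConditionSpec(
        name="ref",
        temperature_K=T,
        growth_range=(3.0, 3.4),
        atpm_range=(0.2, 0.6),
        n_simulations=30,
        seed=11,
    )
    return run_ensemble(chain_problem, cond)


class TestRunEnsemble:
    def test_degenerate_range_single_draw(self, chain_problem):
        cond = ConditionSpec(
            name="one", temperature_K=T, growth_range=(2.5, 2.5),
            atpm_range=(0.0, 0.0), n_simulations=1, seed=0,
        )
        ens = run_ensemble(chain_problem, cond)
        assert ens.n == 1
        assert ens.fluxes["BIOMASS"].iloc[0] == pytest.approx(2.5, abs=1e-9)

    def test_same_seed_bit_identical(self, chain_problem):
        cond = ConditionSpec(
            name="det", temperature_K=T, growth_range=(3.0, 3.4),
            atpm_range=(0.2, 0.6), n_simulations=8, seed=5,
        )
        a = run_ensemble(chain_problem, cond)
        b = run_ensemble(chain_problem, cond)
        assert a.fluxes.equals(b.fluxes)
        assert a.drG.equals(b.drG)
        assert a.ln_conc.equals(b.ln_conc)

    def test_biomass_always_inside_growth_range(self, chain_ensemble):
        mu = chain_ensemble.fluxes["BIOMASS"]
        assert ((mu >= 3.0 - 1e-9) & (mu <= 3.4 + 1e-9)).all()

    def test_alternative_path_explored_by_random_objectives(self):
        """With a bypass route, both flux patterns appear across draws."""
        from thermoflux.thermo import ThermoConfig
        from thermoflux.tmfa import build_problem

        model, thermo, tables, _ = make_chain_model(
            ToyNetworkSpec(n_linear_steps=2, include_bypass=True)
        )
        problem = build_problem(model, thermo, ThermoConfig(temperature_K=T), tables)
        cond = ConditionSpec(
            name="paths", temperature_K=T, growth_range=(1.0, 1.2),
            atpm_range=(0.0, 0.0), n_simulations=60, seed=3,
        )
        ens = run_ensemble(problem, cond)
        bypass_used = (ens.fluxes["RB"].abs() > 1e-6).sum()
        assert 0 < bypass_used < ens.n

    def test_impossible_condition_aborts_with_diagnostics(self, chain_problem):
        cond = ConditionSpec(
            name="bad", temperature_K=T, growth_range=(50.0, 60.0),
            atpm_range=(0.0, 0.0), n_simulations=5, seed=0,
        )
        with pytest.raises(RuntimeError, match="infeasible draws"):
            run_ensemble(chain_problem, cond)


class TestCUE:
    def test_arithmetic_example(self, chain):
        model, _, _, _ = chain
        # uptake 1 substrate (6 C), secrete 0.5 waste (6 C) -> (6-3)/6 = 0.5
        fluxes = {"EX_sub": -1.0, "EX_waste": 0.5, "EX_pi": 0.0}
        assert compute_cue(fluxes, model) == pytest.approx(0.5)

    def test_all_carbon_secreted_gives_zero(self, chain):
        model, _, _, _ = chain
        fluxes = {"EX_sub": -2.0, "EX_waste": 2.0}
        assert compute_cue(fluxes, model) == pytest.approx(0.0)

    def test_no_uptake_undefined(self, chain):
        model, _, _, _ = chain
        assert math.isnan(compute_cue({"EX_sub": 0.0}, model))

    def test_cue_within_unit_interval_on_ensemble(self, chain_ensemble, chain):
        model, _, _, _ = chain
        for _, row in chain_ensemble.fluxes.iterrows():
            cue = compute_cue(row, model)
            assert 0.0 - 1e-9 <= cue <= 1.0 + 1e-9


class TestATPAccounting:
    def test_single_producing_reaction(self, chain):
        model, _, _, _ = chain
        fluxes = {rid: 0.0 for rid in model.reactions}
        fluxes["R1"] = 2.0  # R1 produces 1 ATP per unit
        produced, consumed = atp_accounting(fluxes, model)
        assert produced == pytest.approx(2.0)
        assert consumed == pytest.approx(0.0)

    def test_atpm_excluded(self, chain):
        model, _, _, _ = chain
        fluxes = {rid: 0.0 for rid in model.reactions}
        fluxes["ATPM"] = 7.0
        assert atp_accounting(fluxes, model) == (0.0, 0.0)

    def test_changing_atpm_flux_leaves_totals_unchanged(self, chain_ensemble, chain):
        model, _, _, _ = chain
        row = chain_ensemble.fluxes.iloc[0].to_dict()
        base = atp_accounting(row, model)
        row["ATPM"] = row["ATPM"] + 5.0
        assert atp_accounting(row, model) == base

    def test_steady_state_atp_node_balance(self, chain_ensemble, chain):
        """produced = consumed + ATPM term when no ATP crosses the boundary."""
        model, _, _, _ = chain
        s_atpm = abs(model.reactions["ATPM"].stoichiometry["atp_c"])
        for _, row in chain_ensemble.fluxes.iterrows():
            produced, consumed = atp_accounting(row, model)
            assert produced == pytest.approx(
                consumed + row["ATPM"] * s_atpm, abs=1e-6
            )


class TestEfficiencyMetrics:
    def test_ratio_arithmetic(self, chain_ensemble, chain):
        model, _, _, _ = chain
        em = efficiency_metrics(chain_ensemble, model, "EX_sub")
        row = chain_ensemble.fluxes.iloc[0]
        produced, consumed = atp_accounting(row, model)
        assert em["atp_per_substrate"].iloc[0] == pytest.approx(
            produced / abs(row["EX_sub"])
        )
        assert em["atp_per_biomass"].iloc[0] == pytest.approx(
            consumed / row["BIOMASS"]
        )

    def test_toy_chain_analytic_atp_yield(self, chain_ensemble, chain):
        model, _, _, meta = chain
        em = efficiency_metrics(chain_ensemble, model, "EX_sub")
        # every substrate passes the single ATP-generating step exactly once
        assert np.allclose(em["atp_per_substrate"], meta["atp_yield_per_substrate"])


class TestConcentrationRatio:
    def test_equal_concentrations_unity(self):
        assert concentration_ratio({"a": -5.0, "b": -5.0}, "a", "b") == pytest.approx(1.0)

    def test_bound_ratio(self):
        lnc = {"a": math.log(0.02), "b": math.log(1e-5)}
        assert concentration_ratio(lnc, "a", "b") == pytest.approx(2000.0)

    def test_reciprocal_identity(self):
        lnc = {"a": -4.2, "b": -9.7}
        assert concentration_ratio(lnc, "a", "b") * concentration_ratio(
            lnc, "b", "a"
        ) == pytest.approx(1.0)

    def test_missing_variable_is_error(self):
        with pytest.raises(KeyError):
            concentration_ratio({"a": -5.0}, "a", "b")


class TestDirections:
    def test_biomass_obligate_forward(self, chain_ensemble):
        classes = classify_directions(chain_ensemble)
        assert classes["BIOMASS"] == "obligate_forward"
        assert classes["EX_sub"] == "obligate_reverse"  # uptake

    def test_unused_reaction_blocked(self, cycle_problem, cycle):
        _, _, _, meta = cycle
        cond = ConditionSpec(
            name="cyc", temperature_K=T, growth_range=(2.0, 2.2),
            atpm_range=(0.0, 0.0), n_simulations=10, seed=2,
        )
        ens = run_ensemble(cycle_problem, cond)
        classes = classify_directions(ens)
        for rid in meta["cycle_reactions"]:
            assert classes[rid] == "blocked"

    def test_empty_ensemble_rejected(self, chain_ensemble):
        import dataclasses

        empty = dataclasses.replace(
            chain_ensemble, fluxes=chain_ensemble.fluxes.iloc[:0]
        )
        with pytest.raises(ValueError):
            classify_directions(empty)


class TestSummaries:
    def test_constant_column(self):
        df = pd.DataFrame({"x": [3.0] * 10})
        s = summarize(df)
        assert (s.loc["x"] == 3.0).all()

    def test_linear_interpolation_quantiles(self):
        df = pd.DataFrame({"x": np.arange(1.0, 101.0)})
        s = summarize(df)
        assert s.loc["x", "median"] == pytest.approx(50.5)
        assert s.loc["x", "q25"] == pytest.approx(25.75)
        assert s.loc["x", "q75"] == pytest.approx(75.25)

    def test_row_order_invariance(self, chain_ensemble):
        a = summarize(chain_ensemble.fluxes)
        shuffled = chain_ensemble.fluxes.sample(frac=1.0, random_state=0)
        b = summarize(shuffled)
        pd.testing.assert_frame_equal(a, b)

    def test_quantile_ordering_invariant(self, chain_ensemble):
        s = summarize(chain_ensemble.fluxes)
        assert (s["min"] <= s["q25"] + 1e-12).all()
        assert (s["q25"] <= s["median"] + 1e-12).all()
        assert (s["median"] <= s["q75"] + 1e-12).all()
        assert (s["q75"] <= s["max"] + 1e-12).all()


def test_save_load_round_trip(tmp_path, chain_ensemble):
    save_ensemble(chain_ensemble, tmp_path / "ens")
    back = load_ensemble(tmp_path / "ens")
    assert back.n == chain_ensemble.n
    assert np.allclose(back.fluxes.to_numpy(), chain_ensemble.fluxes.to_numpy())
    assert back.condition.seed == chain_ensemble.condition.seed
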