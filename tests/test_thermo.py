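"""Gibbs-energy assembly: formation fallback, transport terms, ΔrG′ expression."""

import math

import numpy as np
import pytest

from thermoflux.gem import MetabolicModel, Metabolite, Reaction
from thermoflux.thermo import (
    F_KJ,
    R_KJ,
    ThermoConfig,
    ThermoData,
    dG0_from_formation,
    drG_expression,
    transport_energy_terms,
)

LN10 = math.log(10.0)


def _toy(stoich_by_rxn, formulas=None, charges=None):
    mets = {}
    for stoich in stoich_by_rxn.values():
        for mid in stoich:
            if mid not in mets:
                mets[mid] = Metabolite(
                    mid,
                    formula=(formulas or {}).get(mid, "C1"),
                    charge=(charges or {}).get(mid, 0),
                    compartment="c",
                )
    rxns = {
        rid: Reaction(rid, stoich, -100, 100) for rid, stoich in stoich_by_rxn.items()
    }
    rxns["BIOMASS"] = Reaction("BIOMASS", {next(iter(mets)): -1.0}, 0, 100)
    rxns["ATPM"] = Reaction("ATPM", {next(iter(mets)): -1.0}, 0, 100)
    return MetabolicModel(mets, rxns, "BIOMASS", "ATPM")


class TestFormationFallback:
    def test_simple_difference(self):
        model = _toy({"R": {"a_c": -1.0, "b_c": 1.0}})
        thermo = dG0_from_formation(model, {"a_c": -10.0, "b_c": -20.0})
        assert thermo.dG0["R"] == pytest.approx(-10.0)

    def test_null_reaction_gives_zero(self):
        model = _toy({"R": {"a_c": -1.0, "b_c": 1.0}, "R2": {"a_c": -1.0, "c_c": 1.0}})
        thermo = dG0_from_formation(model, {"a_c": -7.0, "b_c": -7.0, "c_c": -7.0})
        assert thermo.dG0["R"] == 0.0

    def test_random_reaction_matches_dot_product(self):
        rng = np.random.default_rng(7)
        stoich = {f"m{i}_c": float(c) for i, c in enumerate(rng.integers(-3, 4, 4)) if c}
        model = _toy({"R": stoich})
        dfg = {mid: float(v) for mid, v in zip(stoich, rng.normal(0, 50, len(stoich)))}
        thermo = dG0_from_formation(model, dfg)
        expected = sum(stoich[m] * dfg[m] for m in stoich)
        assert thermo.dG0["R"] == pytest.approx(expected, abs=1e-12)

    def test_missing_formation_energy_excludes(self):
        model = _toy({"R": {"a_c": -1.0, "b_c": 1.0}})
        thermo = dG0_from_formation(model, {"a_c": -10.0})
        assert "R" not in thermo.dG0
        assert "R" in thermo.excluded


class TestTransportTerms:
    def setup_method(self):
        self.model = _toy({"T": {"a_c": -1.0, "b_c": 1.0}})
        self.config = ThermoConfig(temperature_K=298.15)

    def test_no_params_zero_expression(self):
        thermo = ThermoData(dG0={"T": 0.0}, transport={})
        expr = transport_energy_terms(self.model.reactions["T"], thermo, self.config)
        assert expr.const == 0.0 and expr.ph_in_coef == 0.0 and expr.ph_out_coef == 0.0

    def test_zero_h_and_charge_identically_zero(self):
        thermo = ThermoData(dG0={"T": 0.0}, transport={"T": (0.0, 0.0)})
        expr = transport_energy_terms(self.model.reactions["T"], thermo, self.config)
        assert expr.evaluate({}, 6.0, 8.0) == pytest.approx(0.0)

    def test_equal_ph_reduces_to_charge_term(self):
        thermo = ThermoData(dG0={"T": 0.0}, transport={"T": (2.0, 3.0)})
        expr = transport_energy_terms(self.model.reactions["T"], thermo, self.config)
        # dpH = 0 leaves only c*F*b
        expected = 3.0 * F_KJ * self.config.psi_intercept
        assert expr.evaluate({}, 7.0, 7.0) == pytest.approx(expected)

    def test_hand_evaluation_two_term_formula(self):
        h, c = 1.0, 1.0
        thermo = ThermoData(dG0={"T": 0.0}, transport={"T": (h, c)})
        expr = transport_energy_terms(self.model.reactions["T"], thermo, self.config)
        dph = -0.5
        ph_in, ph_out = 7.0, 7.0 + dph
        T = 298.15
        expected = c * F_KJ * (self.config.psi_slope * dph + self.config.psi_intercept)
        expected += h * LN10 * R_KJ * T * dph
        assert expr.evaluate({}, ph_in, ph_out) == pytest.approx(expected, rel=1e-12)


class TestDrGExpression:
    def test_unit_concentrations_recover_standard_energy(self):
        model = _toy({"R": {"a_c": -1.0, "b_c": 1.0}})
        thermo = ThermoData(dG0={"R": -13.7})
        cfg = ThermoConfig(temperature_K=310.0)
        expr = drG_expression(model.reactions["R"], model, thermo, cfg)
        assert expr.evaluate({"a_c": 0.0, "b_c": 0.0}) == pytest.approx(-13.7)

    def test_symmetric_concentrations_cancel(self):
        model = _toy({"R": {"a_c": -1.0, "b_c": 1.0}})
        thermo = ThermoData(dG0={"R": 0.0})
        cfg = ThermoConfig(temperature_K=277.15)
        expr = drG_expression(model.reactions["R"], model, thermo, cfg)
        lnc = {"a_c": math.log(3e-4), "b_c": math.log(3e-4)}
        assert expr.evaluate(lnc) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_value(self):
        # A -> 2B, dG0 = -5, c_A = 0.02, c_B = 1e-5, T = 277.15
        model = _toy({"R": {"a_c": -1.0, "b_c": 2.0}})
        thermo = ThermoData(dG0={"R": -5.0})
        cfg = ThermoConfig(temperature_K=277.15)
        expr = drG_expression(model.reactions["R"], model, thermo, cfg)
        value = expr.evaluate({"a_c": math.log(0.02), "b_c": math.log(1e-5)})
        expected = -5.0 + R_KJ * 277.15 * (2 * math.log(1e-5) - math.log(0.02))
        assert value == pytest.approx(expected, rel=1e-12)

    def test_excluded_reaction_is_contract_violation(self):
        model = _toy({"R": {"a_c": -1.0, "b_c": 1.0}})
        thermo = ThermoData(dG0={"R": -5.0}, excluded={"R"})
        with pytest.raises(ValueError):
            drG_expression(
                model.reactions["R"], model, thermo, ThermoConfig(temperature_K=298.15)
            )

    def test_water_and_protons_carry_no_concentration_terms(self):
        model = _toy(
            {"R": {"a_c": -1.0, "w_c": -1.0, "h_c": 2.0, "b_c": 1.0}},
            formulas={"w_c": "H2O", "h_c": "H", "a_c": "C1H2", "b_c": "C1O1"},
            charges={"h_c": 1},
        )
        thermo = ThermoData(dG0={"R": 1.0})
        expr = drG_expression(
            model.reactions["R"], model, thermo, ThermoConfig(temperature_K=298.15)
        )
        assert set(expr.lnc_coefs) == {"a_c", "b_c"}

    def test_reverse_reaction_negates_expression(self):
        rng = np.random.default_rng(3)
        stoich = {"a_c": -2.0, "b_c": 1.0, "c_c": 3.0}
        model = _toy({"R": stoich, "Rrev": {k: -v for k, v in stoich.items()}})
        thermo = ThermoData(dG0={"R": 8.25, "Rrev": -8.25})
        cfg = ThermoConfig(temperature_K=293.15)
        e1 = drG_expression(model.reactions["R"], model, thermo, cfg)
        e2 = drG_expression(model.reactions["Rrev"], model, thermo, cfg)
        for _ in range(5):
            lnc = {m: float(rng.uniform(-11.5, -3.9)) for m in stoich}
            assert e1.evaluate(lnc) == pytest.approx(-e2.evaluate(lnc), rel=1e-12)

    def test_cycle_sum_is_concentration_independent(self):
        """Loop law at the expression level: conc terms cancel around a cycle."""
        rxns = {
            "R1": {"a_c": -1.0, "b_c": 1.0},
            "R2": {"b_c": -1.0, "c_c": 1.0},
            "R3": {"c_c": -1.0, "a_c": 1.0},
        }
        model = _toy(rxns)
        thermo = ThermoData(dG0={"R1": -2.0, "R2": -2.0, "R3": 4.0})
        cfg = ThermoConfig(temperature_K=288.15)
        rng = np.random.default_rng(11)
        for _ in range(5):
            lnc = {m: float(rng.uniform(-11.5, -3.9)) for m in ("a_c", "b_c", "c_c")}
            total = sum(
                drG_expression(model.reactions[r], model, thermo, cfg).evaluate(lnc)
                for r in rxns
            )
            assert total == pytest.approx(0.0, abs=1e-12)

    def test_temperature_scales_concentration_term(self):
        model = _toy({"R": {"a_c": -1.0, "b_c": 1.0}})
        thermo = ThermoData(dG0={"R": 0.0})
        lnc = {"a_c": math.log(1e-4), "b_c": math.log(1e-2)}
        v1 = drG_expression(
            model.reactions["R"], model, thermo, ThermoConfig(temperature_K=277.15)
        ).evaluate(lnc)
        v2 = drG_expression(
            model.reactions["R"], model, thermo, ThermoConfig(temperature_K=293.15)
        ).evaluate(lnc)
        assert v2 / v1 == pytest.approx(293.15 / 277.15, rel=1e-12)


def test_config_validation():
    with pytest.raises(ValueError):
        ThermoConfig(temperature_K=-1)
    with pytest.raises(ValueError):
        ThermoConfig(temperature_K=298, pH_in_bounds=(-1, 8))
    with pytest.raises(NotImplementedError):
        ThermoConfig(temperature_K=298, gibbs_helmholtz=True)
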