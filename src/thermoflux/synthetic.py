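"""Small, fully specified toy metabolic networks with planted ground truth.

Every generator returns ``(MetabolicModel, ThermoData, ConstraintTables,
metadata)`` where the metadata dictionary records the analytic quantities
the construction guarantees (yields, slopes, admissible intervals).  The
networks are mass- and charge-balanced by construction:

* carbon-carrying metabolites all use the synthetic formula ``C6H12O6`` so
  chain steps A → B balance trivially and carbon accounting is exact;
* the energy currency uses phosphate-only formulas ``P3``/``P2``/``P1``
  (atp/adp/pi analogs) with atp = adp + pi elementally, so ATP-coupled
  steps balance without water or protons.

The chain model plants an exact ATP/biomass trade-off: with substrate
uptake capped at U and a biomass ATP cost of y, the maximum growth rate at
maintenance flux m is μ(m) = (U − m)/y, i.e. a robustness curve with slope
−1/y and intercept U/y.

The temperature-switch model emulates a thermodynamic pathway switch: the
payoff route's key reaction gets a ΔrG′° chosen inside the interval
(R·T_low·Δln, R·T_high·Δln), where Δln = ln(c_hi/c_lo) is the extremal
log-concentration ratio, so its minimum attainable ΔrG′ is positive at
T_low (blocked) and negative at T_high (available) — a toy-scale analog of
a glycolytic payoff-phase reaction that is thermodynamically unfavorable
only at low temperature, with an always-available bypass route of lower ATP
yield standing in for the Entner-Doudoroff pathway.

The cycle model plants a three-reaction internal cycle with no net
transformation whose per-reaction standard energies sum to +1 kJ/mol
(mimicking the small inconsistencies of independently estimated
group-contribution energies).  Because concentration terms cancel around a
closed cycle, the three forward directions can never be simultaneously
feasible, so thermodynamic constraints forbid circulation exactly while the
stoichiometry-only relaxation permits it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .gem import ConstraintTables, MetabolicModel, Metabolite, Reaction
from .thermo import R_KJ, ThermoData

__all__ = [
    "ToyNetworkSpec",
    "make_chain_model",
    "make_temperature_switch_model",
    "make_cycle_model",
]

# Study-condition defaults for the toy networks.
UPTAKE_CAP = 10.0  # substrate uptake bound, flux units
BIOMASS_ATP_COST = 2.0  # mol ATP per biomass flux unit
CARBON_FORMULA = "C6H12O6"


@dataclass
class ToyNetworkSpec:
    """Parameters of the linear-chain generator.

    ``dG0_profile`` overrides per-reaction standard energies (kJ/mol);
    reactions keep their defaults when absent.  ``planted_atpm`` sets the
    lower bound of the maintenance reaction, planting a known ATP drain.
    """

    n_linear_steps: int = 3
    include_bypass: bool = False
    include_cycle: bool = False
    planted_atpm: float = 0.0
    dG0_profile: dict[str, float] = field(default_factory=dict)
    seed: int = 0
    uptake_cap: float = UPTAKE_CAP
    biomass_atp_cost: float = BIOMASS_ATP_COST
    reversible_step: str | None = None  # id of one chain step made reversible

    def __post_init__(self) -> None:
        if self.n_linear_steps < 2:
            raise ValueError("n_linear_steps must be >= 2")


def _carbon_met(mid: str, compartment: str) -> Metabolite:
    return Metabolite(
        id=mid, name=mid, formula=CARBON_FORMULA, charge=0, compartment=compartment
    )


def _currency_mets() -> list[Metabolite]:
    return [
        Metabolite(id="atp_c", name="atp", formula="P3", charge=0, compartment="c"),
        Metabolite(id="adp_c", name="adp", formula="P2", charge=0, compartment="c"),
        Metabolite(id="pi_c", name="pi", formula="P1", charge=0, compartment="c"),
        Metabolite(id="pi_e", name="pi", formula="P1", charge=0, compartment="e"),
    ]


def make_chain_model(
    spec: ToyNetworkSpec | None = None,
) -> tuple[MetabolicModel, ThermoData, ConstraintTables, dict]:
    """Substrate exchange → transport → linear pathway → biomass.

    Layout (n = n_linear_steps chain reactions R1..Rn):

        EX_sub:  sub[e] =>                       (uptake, lb = −U)
        T_sub:   sub[e] => sub[c]                (transport, h=1, c=1)
        R1:      sub[c] + adp + pi => I2 + atp   (substrate-level ATP)
        Rk:      I_k => I_{k+1}                  (k = 2..n)
        SEC:     I_end => waste[e]               (overflow, excluded)
        EX_waste, EX_pi: free boundary exchanges
        BIOMASS: I_end + y atp => y adp + y pi   (flux = growth rate μ)
        ATPM:    atp => adp + pi                 (maintenance, lb = planted)

    Analytic ground truth (in returned metadata): max biomass at maintenance
    m is μ(m) = (U − m)/y; robustness slope −1/y; ATP yield 1 per substrate.
    """
    spec = spec or ToyNetworkSpec()
    n = spec.n_linear_steps
    U = spec.uptake_cap
    y = spec.biomass_atp_cost

    mets: dict[str, Metabolite] = {}
    for m in [
        _carbon_met("sub_e", "e"),
        _carbon_met("sub_c", "c"),
        *[_carbon_met(f"I{k}_c", "c") for k in range(2, n + 2)],
        _carbon_met("waste_e", "e"),
        *_currency_mets(),
    ]:
        mets[m.id] = m

    end = f"I{n + 1}_c"
    rxns: dict[str, Reaction] = {}

    def add(rid: str, stoich, lb, ub, **kw):
        rxns[rid] = Reaction(rid, stoich, lb, ub, **kw)

    add("EX_sub", {"sub_e": -1.0}, -U, 0.0, is_exchange=True)
    add("T_sub", {"sub_e": -1.0, "sub_c": 1.0}, 0.0, 100.0, is_transport=True,
        gene_association="g_tsub")
    first_target = "I2_c"
    add(
        "R1",
        {"sub_c": -1.0, "adp_c": -1.0, "pi_c": -1.0, first_target: 1.0, "atp_c": 1.0},
        0.0,
        100.0,
        gene_association="g1",
    )
    for k in range(2, n + 1):
        add(f"R{k}", {f"I{k}_c": -1.0, f"I{k + 1}_c": 1.0}, 0.0, 100.0,
            gene_association=f"g{k}")
    add("SEC", {end: -1.0, "waste_e": 1.0}, 0.0, 100.0)
    add("EX_waste", {"waste_e": -1.0}, 0.0, 100.0, is_exchange=True)
    add("EX_pi", {"pi_e": -1.0}, -100.0, 100.0, is_exchange=True)
    add("T_pi", {"pi_e": -1.0, "pi_c": 1.0}, -100.0, 100.0, is_transport=True)
    add(
        "BIOMASS",
        {end: -1.0, "atp_c": -y, "adp_c": y, "pi_c": y},
        0.0,
        100.0,
    )
    add("ATPM", {"atp_c": -1.0, "adp_c": 1.0, "pi_c": 1.0}, spec.planted_atpm, 100.0)

    if spec.include_cycle:
        for cid in ("CY1_c", "CY2_c"):
            mets[cid] = _carbon_met(cid, "c")
        anchor = first_target
        add("RC1", {anchor: -1.0, "CY1_c": 1.0}, 0.0, 100.0)
        add("RC2", {"CY1_c": -1.0, "CY2_c": 1.0}, 0.0, 100.0)
        add("RC3", {"CY2_c": -1.0, anchor: 1.0}, 0.0, 100.0)

    if spec.include_bypass:
        # Direct route to the pathway end skipping the ATP-generating step.
        add("RB", {"sub_c": -1.0, end: 1.0}, 0.0, 100.0, gene_association="g_b")

    if spec.reversible_step and spec.reversible_step in rxns:
        rxns[spec.reversible_step].lower_bound = -100.0

    model = MetabolicModel(
        metabolites=mets,
        reactions=rxns,
        biomass_reaction_id="BIOMASS",
        atpm_reaction_id="ATPM",
        atp_metabolite_id="atp_c",
        name=f"toy_chain_{n}",
    )

    dG0 = {"T_sub": -5.0, "R1": -10.0}
    for k in range(2, n + 1):
        dG0[f"R{k}"] = -10.0
    if spec.include_cycle:
        dG0.update({"RC1": -2.0, "RC2": -2.0, "RC3": 5.0})  # sum = +1 kJ/mol
    if spec.include_bypass:
        dG0["RB"] = -8.0
    dG0.update(spec.dG0_profile)

    thermo = ThermoData(
        dG0=dG0,
        excluded={"EX_sub", "EX_waste", "EX_pi", "T_pi", "SEC", "BIOMASS", "ATPM"},
        transport={"T_sub": (1.0, 1.0)},
    )
    tables = ConstraintTables(
        exchange_bounds={"EX_sub": (-U, 0.0), "EX_waste": (0.0, 100.0),
                         "EX_pi": (-100.0, 100.0)},
    )
    meta = {
        "uptake_cap": U,
        "biomass_atp_cost": y,
        "atp_yield_per_substrate": 1.0,
        "max_biomass": (U - spec.planted_atpm) / y,
        "robustness_slope": -1.0 / y,
        "robustness_intercept": U / y,
        "substrate_exchange": "EX_sub",
        "substrate_carbons": 6,
        "cycle_reactions": ["RC1", "RC2", "RC3"] if spec.include_cycle else [],
        "bypass_reaction": "RB" if spec.include_bypass else None,
    }
    model.validate()
    return model, thermo, tables, meta


def make_cycle_model() -> tuple[MetabolicModel, ThermoData, ConstraintTables, dict]:
    """Chain model with a planted 3-reaction internal cycle (loop-law fixture)."""
    return make_chain_model(ToyNetworkSpec(n_linear_steps=3, include_cycle=True))


def make_temperature_switch_model(
    T_low: float,
    T_high: float,
    conc_lo: float = 1e-5,
    conc_hi: float = 0.02,
) -> tuple[MetabolicModel, ThermoData, ConstraintTables, dict]:
    """Two routes to biomass; the payoff route flips feasibility with T.

    Layout:

        EX_sub → T_sub → RU: sub[c] + adp + pi => G + atp
        route P (payoff):  RP1: G => P1 (ΔrG′° = d*, the switch)
                           RP2: P1 + adp + pi => I_end + atp
        route E (bypass):  RE1: G => E1 ;  RE2: E1 => I_end
        BIOMASS: I_end + 2 atp => ... ;  ATPM: atp => adp + pi
        SEC/EX_waste overflow as in the chain model.

    d* is placed at the midpoint of the admissible interval
    (R·T_low·Δln, R·T_high·Δln), Δln = ln(conc_hi/conc_lo); an empty
    interval (T_low ≥ T_high) raises with the interval in the message.

    ATP yields: 2 per substrate through route P, 1 through route E.  Paired
    with per-condition growth ranges in which the T_high demand exceeds what
    route E alone can supply, the switch reaction is obligate at T_high and
    blocked at T_low.
    """
    dln = math.log(conc_hi / conc_lo)
    lo_bound = R_KJ * T_low * dln
    hi_bound = R_KJ * T_high * dln
    if not lo_bound < hi_bound:
        raise ValueError(
            f"no admissible switch energy: interval ({lo_bound:.4f}, "
            f"{hi_bound:.4f}) kJ/mol is empty; need T_low < T_high"
        )
    d_star = 0.5 * (lo_bound + hi_bound)

    U = UPTAKE_CAP
    y = BIOMASS_ATP_COST

    mets: dict[str, Metabolite] = {}
    for m in [
        _carbon_met("sub_e", "e"),
        _carbon_met("sub_c", "c"),
        _carbon_met("G_c", "c"),
        _carbon_met("P1_c", "c"),
        _carbon_met("E1_c", "c"),
        _carbon_met("Iend_c", "c"),
        _carbon_met("waste_e", "e"),
        *_currency_mets(),
    ]:
        mets[m.id] = m

    rxns: dict[str, Reaction] = {}

    def add(rid, stoich, lb, ub, **kw):
        rxns[rid] = Reaction(rid, stoich, lb, ub, **kw)

    add("EX_sub", {"sub_e": -1.0}, -U, 0.0, is_exchange=True)
    add("T_sub", {"sub_e": -1.0, "sub_c": 1.0}, 0.0, 100.0, is_transport=True)
    add("RU", {"sub_c": -1.0, "adp_c": -1.0, "pi_c": -1.0, "G_c": 1.0, "atp_c": 1.0},
        0.0, 100.0, gene_association="g_u")
    add("RP1", {"G_c": -1.0, "P1_c": 1.0}, 0.0, 100.0, gene_association="g_p1")
    add("RP2", {"P1_c": -1.0, "adp_c": -1.0, "pi_c": -1.0, "Iend_c": 1.0,
                "atp_c": 1.0}, 0.0, 100.0, gene_association="g_p2")
    add("RE1", {"G_c": -1.0, "E1_c": 1.0}, 0.0, 100.0, gene_association="g_e1")
    add("RE2", {"E1_c": -1.0, "Iend_c": 1.0}, 0.0, 100.0, gene_association="g_e2")
    add("SEC", {"Iend_c": -1.0, "waste_e": 1.0}, 0.0, 100.0)
    add("EX_waste", {"waste_e": -1.0}, 0.0, 100.0, is_exchange=True)
    add("EX_pi", {"pi_e": -1.0}, -100.0, 100.0, is_exchange=True)
    add("T_pi", {"pi_e": -1.0, "pi_c": 1.0}, -100.0, 100.0, is_transport=True)
    add("BIOMASS", {"Iend_c": -1.0, "atp_c": -y, "adp_c": y, "pi_c": y}, 0.0, 100.0)
    add("ATPM", {"atp_c": -1.0, "adp_c": 1.0, "pi_c": 1.0}, 0.0, 100.0)

    model = MetabolicModel(
        metabolites=mets,
        reactions=rxns,
        biomass_reaction_id="BIOMASS",
        atpm_reaction_id="ATPM",
        atp_metabolite_id="atp_c",
        name="toy_temperature_switch",
    )
    thermo = ThermoData(
        dG0={
            "T_sub": -5.0,
            "RU": -10.0,
            "RP1": d_star,
            "RP2": -10.0,
            "RE1": -10.0,
            "RE2": -10.0,
        },
        excluded={"EX_sub", "EX_waste", "EX_pi", "T_pi", "SEC", "BIOMASS", "ATPM"},
        transport={"T_sub": (1.0, 1.0)},
    )
    tables = ConstraintTables(
        exchange_bounds={"EX_sub": (-U, 0.0), "EX_waste": (0.0, 100.0),
                         "EX_pi": (-100.0, 100.0)},
        default_conc_lo=conc_lo,
        default_conc_hi=conc_hi,
    )
    meta = {
        "switch_reaction": "RP1",
        "switch_dG0": d_star,
        "admissible_interval": (lo_bound, hi_bound),
        "delta_ln": dln,
        "uptake_cap": U,
        "biomass_atp_cost": y,
        "atp_yield_payoff": 2.0,
        "atp_yield_bypass": 1.0,
        "substrate_exchange": "EX_sub",
        # Growth-rate study conditions: T_low draws keep ATP demand within
        # the bypass route's supply; T_high draws exceed it, making the
        # payoff route obligatory (and its key reaction non-blocked).
        "growth_range_low": (2.0, 2.2),
        "growth_range_high": (5.0, 5.5),
        "atpm_range": (1.0, 1.0),
    }
    model.validate()
    return model, thermo, tables, meta
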