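"""Reaction Gibbs energies and the linear ΔrG′ expression.

The transformed Gibbs energy of reaction i at temperature T is

    ΔrG′_i = ΔrG′°_i + R·T · Σ_j s_ij · ln c_j + ΔG_transport,i

where the sum runs over the reaction's non-artificial metabolites excluding
water (activity 1) and protons (handled through pH variables), and for
membrane transport reactions

    ΔG_transport = c·F·ΔΨ + h·ln(10)·R·T·(pH_out − pH_in)

with h the net protons and c the net charge moved outside→inside, and the
membrane potential modeled as an affine function of the pH gradient,
ΔΨ = a·ΔpH + b (defaults from the TMFA literature for a gram-negative
bacterium).  Everything stays affine in the decision variables (ln c, pH_in,
pH_out) so the downstream program remains a linear MILP.

Standard energies ΔrG′° refer to pH 7, ionic strength 0 M, 298.15 K.  They
are *not* re-transformed for temperature (no Gibbs–Helmholtz correction):
temperature enters only through the R·T factors, since reaction enthalpies
are unavailable for most genome-scale reactions.  A config switch reserves
space for such a correction but is off by default and currently
unimplemented.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from .gem import MetabolicModel, Metabolite, Reaction

__all__ = [
    "R_KJ",
    "F_KJ",
    "ThermoData",
    "ThermoConfig",
    "DrGExpression",
    "dG0_from_formation",
    "transport_energy_terms",
    "drG_expression",
    "is_water",
    "is_proton",
    "read_dG0_table",
    "read_exclusion_table",
    "read_transport_table",
    "read_thermo_tables",
    "write_thermo_tables",
]

log = logging.getLogger(__name__)

#: Gas constant, kJ mol^-1 K^-1
R_KJ = 8.314462618e-3
#: Faraday constant, kJ mol^-1 V^-1
F_KJ = 96.485

LN10 = math.log(10.0)


def is_water(met: Metabolite) -> bool:
    return met.formula == "H2O"


def is_proton(met: Metabolite) -> bool:
    return met.formula == "H" and met.charge == 1


@dataclass
class ThermoData:
    """Per-reaction standard energies, exclusions, and transport parameters.

    ``excluded`` wins over ``dG0``: a reaction listed in both carries no
    thermodynamic constraint.  ``transport`` maps reaction id to (h, c) =
    (net protons, net charge) moved outside→inside.
    """

    dG0: dict[str, float] = field(default_factory=dict)
    excluded: set[str] = field(default_factory=set)
    transport: dict[str, tuple[float, float]] = field(default_factory=dict)
    bigM_K: float | None = None  # kJ/mol; None = compute per reaction

    def is_constrained(self, reaction_id: str) -> bool:
        return reaction_id in self.dG0 and reaction_id not in self.excluded

    def constrained_ids(self, model: MetabolicModel) -> list[str]:
        return [rid for rid in model.reactions if self.is_constrained(rid)]


@dataclass
class ThermoConfig:
    """Condition-level thermodynamic settings.

    ``psi_slope``/``psi_intercept`` parameterize ΔΨ(V) = a·ΔpH + b.
    ``feasibility_epsilon`` (kJ/mol) is the strictness of the directionality
    inequality: an active direction must satisfy ΔrG′ ≤ −ε; the canonical
    TMFA inequality uses ε = 0.
    """

    temperature_K: float
    pH_in_bounds: tuple[float, float] = (6.0, 8.0)
    pH_out_bounds: tuple[float, float] = (6.0, 8.0)
    R: float = R_KJ
    F: float = F_KJ
    psi_slope: float = 0.03333  # V per pH unit
    psi_intercept: float = -0.14333  # V
    feasibility_epsilon: float = 0.0
    gibbs_helmholtz: bool = False  # reserved; ΔrH° data unavailable

    def __post_init__(self) -> None:
        if self.temperature_K <= 0:
            raise ValueError("temperature_K must be positive")
        for lo, hi in (self.pH_in_bounds, self.pH_out_bounds):
            if not (0 <= lo <= hi <= 14):
                raise ValueError(f"pH bounds ({lo}, {hi}) outside [0, 14]")
        if self.gibbs_helmholtz:
            raise NotImplementedError(
                "Gibbs-Helmholtz re-transformation requires reaction "
                "enthalpies; not available"
            )

    @property
    def RT(self) -> float:
        return self.R * self.temperature_K


@dataclass
class DrGExpression:
    """Affine expression for ΔrG′ in (ln c_j, pH_in, pH_out), kJ/mol.

    value = const + Σ_j lnc_coefs[j]·ln c_j + ph_in_coef·pH_in
            + ph_out_coef·pH_out
    """

    const: float
    lnc_coefs: dict[str, float]
    ph_in_coef: float = 0.0
    ph_out_coef: float = 0.0

    def evaluate(
        self,
        ln_conc: Mapping[str, float],
        ph_in: float = 7.0,
        ph_out: float = 7.0,
    ) -> float:
        total = self.const + self.ph_in_coef * ph_in + self.ph_out_coef * ph_out
        for mid, coef in self.lnc_coefs.items():
            total += coef * ln_conc[mid]
        return total


def dG0_from_formation(
    model: MetabolicModel, dfG0: Mapping[str, float]
) -> ThermoData:
    """Assemble per-reaction ΔrG′° from metabolite formation energies.

    ΔrG′°_i = Σ_j s_ij · ΔfG′°_j.  A reaction touching any non-artificial
    metabolite without a formation energy is moved to the excluded set
    rather than erroring — exclusion is the fallback, matching how
    genome-scale reconstructions treat structurally complex metabolites.
    """
    dG0: dict[str, float] = {}
    excluded: set[str] = set()
    for rid, rxn in model.reactions.items():
        total = 0.0
        ok = True
        for mid, coef in rxn.stoichiometry.items():
            met = model.metabolites[mid]
            if met.artificial:
                ok = False
                break
            if mid not in dfG0:
                ok = False
                break
            total += coef * dfG0[mid]
        if ok:
            dG0[rid] = total
        else:
            excluded.add(rid)
    return ThermoData(dG0=dG0, excluded=excluded)


def transport_energy_terms(
    reaction: Reaction, thermo: ThermoData, config: ThermoConfig
) -> DrGExpression:
    """Electrochemical + pH-gradient energy of a membrane transport reaction.

    Returns the affine expression
    c·F·(a·ΔpH + b) + h·ln10·R·T·ΔpH  with  ΔpH = pH_out − pH_in,
    i.e. constant c·F·b plus coefficient (c·F·a + h·ln10·R·T) on pH_out and
    its negative on pH_in.  A reaction absent from the transport table
    contributes an identically zero expression (logged at debug level).
    """
    if reaction.id not in thermo.transport:
        log.debug("reaction %s not in transport table; zero transport term", reaction.id)
        return DrGExpression(const=0.0, lnc_coefs={})
    h, c = thermo.transport[reaction.id]
    dph_coef = c * config.F * config.psi_slope + h * LN10 * config.RT
    return DrGExpression(
        const=c * config.F * config.psi_intercept,
        lnc_coefs={},
        ph_in_coef=-dph_coef,
        ph_out_coef=dph_coef,
    )


def drG_expression(
    reaction: Reaction,
    model: MetabolicModel,
    thermo: ThermoData,
    config: ThermoConfig,
) -> DrGExpression:
    """Full affine ΔrG′ expression for a thermodynamically constrained reaction.

    Water, protons, and artificial metabolites carry no ln-concentration
    term (water activity 1; protons enter through the pH variables).
    Raises ``ValueError`` for excluded/unconstrained reactions: callers must
    not request an expression that the program will not constrain.
    """
    if not thermo.is_constrained(reaction.id):
        raise ValueError(
            f"reaction {reaction.id} carries no thermodynamic constraint"
        )
    transport = transport_energy_terms(reaction, thermo, config)
    lnc: dict[str, float] = {}
    for mid, coef in reaction.stoichiometry.items():
        met = model.metabolites[mid]
        if met.artificial or is_water(met) or is_proton(met):
            continue
        lnc[mid] = lnc.get(mid, 0.0) + config.RT * coef
    return DrGExpression(
        const=thermo.dG0[reaction.id] + transport.const,
        lnc_coefs=lnc,
        ph_in_coef=transport.ph_in_coef,
        ph_out_coef=transport.ph_out_coef,
    )


# ---------------------------------------------------------------------------
# Table I/O — per-reaction ΔrG′° / exclusion list / transport parameters
# ---------------------------------------------------------------------------


def read_dG0_table(path: str | Path) -> dict[str, float]:
    """Read a per-reaction standard-energy TSV (columns: id, dG0 in kJ/mol)."""
    df = pd.read_csv(path, sep="\t")
    return {str(r["id"]): float(r["dG0"]) for _, r in df.iterrows()}


def read_exclusion_table(path: str | Path) -> set[str]:
    """Read the thermodynamic-exclusion list (single column: id)."""
    df = pd.read_csv(path, sep="\t")
    return {str(v) for v in df["id"]}


def read_transport_table(path: str | Path) -> dict[str, tuple[float, float]]:
    """Read transport parameters (columns: id, protons, charge)."""
    df = pd.read_csv(path, sep="\t")
    return {
        str(r["id"]): (float(r["protons"]), float(r["charge"]))
        for _, r in df.iterrows()
    }


def write_thermo_tables(thermo: ThermoData, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [{"id": k, "dG0": v} for k, v in thermo.dG0.items()],
        columns=["id", "dG0"],
    ).to_csv(directory / "dG0.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"id": k} for k in sorted(thermo.excluded)], columns=["id"]
    ).to_csv(directory / "excluded.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {"id": k, "protons": h, "charge": c}
            for k, (h, c) in thermo.transport.items()
        ],
        columns=["id", "protons", "charge"],
    ).to_csv(directory / "transport.tsv", sep="\t", index=False)


def read_thermo_tables(
    dG0_path: str | Path,
    exclusion_path: str | Path | None = None,
    transport_path: str | Path | None = None,
) -> ThermoData:
    return ThermoData(
        dG0=read_dG0_table(dG0_path),
        excluded=read_exclusion_table(exclusion_path) if exclusion_path else set(),
        transport=read_transport_table(transport_path) if transport_path else {},
    )
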