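"""Genome-scale metabolic model containers and I/O.

A :class:`MetabolicModel` holds metabolites, reactions, and the identities of
the biomass and ATP-maintenance (ATPM) pseudo-reactions.  Three on-disk
dialects are supported:

* ``tsv`` — a directory with ``metabolites.tsv``, ``reactions.tsv`` and
  ``model_info.tsv``.  Reaction equations use ``coef cpd[compartment]``
  tokens, ``=>`` for irreversible and ``<=>`` for reversible reactions.
* ``yaml`` — the same content in a single YAML file.
* ``sbml`` — SBML Level 3 with the fbc package, read and written through
  cobrapy.

Compartments are restricted to cytosol ``c`` and extracellular ``e``; any
other compartment encountered on load (e.g. a periplasm) is merged into
``c``, because the transport energetics only distinguish outside vs. inside.

Flux sign conventions follow the constraint-based modeling standard: a
negative coefficient consumes, a positive one produces, and exchange
reactions are written with the boundary metabolite on the left so that
negative flux is uptake.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "ConstraintTables",
    "BalanceReport",
    "parse_formula",
    "carbon_count",
    "parse_equation",
    "format_equation",
    "load_model",
    "save_model",
    "validate_balance",
    "read_constraint_tables",
    "write_constraint_tables",
    "ModelFormatError",
    "ModelValidationError",
]

log = logging.getLogger(__name__)

# Default metabolite concentration window, mol/L.
DEFAULT_CONC_LO = 1e-5
DEFAULT_CONC_HI = 0.02

# Global flux caps, model flux units.
FLUX_MAX = 100.0
FLUX_MIN = -100.0


class ModelFormatError(ValueError):
    """Raised when an input file cannot be parsed in the named dialect."""


class ModelValidationError(ValueError):
    """Raised when a loaded model violates a structural invariant."""


# ---------------------------------------------------------------------------
# Formulas
# ---------------------------------------------------------------------------

_ELEMENT_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse an elemental formula string into an element -> count mapping.

    Supports plain Hill-style formulas (``C8H15NO6``).  Raises
    :class:`ModelFormatError` on anything that does not fully tokenize.
    """
    if not formula:
        raise ModelFormatError("empty formula")
    counts: dict[str, int] = {}
    pos = 0
    for m in _ELEMENT_RE.finditer(formula):
        if m.start() != pos:
            raise ModelFormatError(
                f"unparseable formula {formula!r} at position {pos}"
            )
        element, digits = m.groups()
        counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
        pos = m.end()
    if pos != len(formula):
        raise ModelFormatError(f"unparseable formula {formula!r} at position {pos}")
    return counts


def carbon_count(formula: str) -> int:
    """Number of carbon atoms in a formula (0 for carbon-free compounds)."""
    return parse_formula(formula).get("C", 0)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class Metabolite:
    """A model metabolite.

    ``artificial`` marks biomass-class pseudometabolites whose formulas are
    not meaningful; they are skipped by mass balancing and carry no
    concentration variables.  The flag is explicit rather than inferred from
    names so it is testable.
    """

    id: str
    name: str = ""
    formula: str = ""
    charge: int = 0
    compartment: str = "c"
    smiles: str | None = None
    artificial: bool = False

    def elements(self) -> dict[str, int]:
        return parse_formula(self.formula)


@dataclass
class Reaction:
    """A model reaction: signed stoichiometry plus flux bounds.

    Negative stoichiometric coefficients consume, positive produce.
    """

    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = FLUX_MIN
    upper_bound: float = FLUX_MAX
    gene_association: str | None = None
    is_exchange: bool = False
    is_transport: bool = False
    subsystem: str | None = None

    def __post_init__(self) -> None:
        if not self.stoichiometry:
            raise ModelValidationError(f"reaction {self.id}: empty stoichiometry")
        if self.lower_bound > self.upper_bound:
            raise ModelValidationError(
                f"reaction {self.id}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound


@dataclass
class MetabolicModel:
    """A stoichiometric model with designated biomass and ATPM reactions."""

    metabolites: dict[str, Metabolite]
    reactions: dict[str, Reaction]
    biomass_reaction_id: str
    atpm_reaction_id: str
    atp_metabolite_id: str | None = None
    name: str = "model"

    @property
    def compartments(self) -> set[str]:
        return {m.compartment for m in self.metabolites.values()}

    def validate(self) -> None:
        """Check structural invariants; raise ModelValidationError on failure."""
        for rid in (self.biomass_reaction_id, self.atpm_reaction_id):
            if rid not in self.reactions:
                raise ModelValidationError(f"designated reaction {rid!r} not in model")
        for rxn in self.reactions.values():
            for met_id in rxn.stoichiometry:
                if met_id not in self.metabolites:
                    raise ModelValidationError(
                        f"reaction {rxn.id}: unknown metabolite {met_id!r}"
                    )
            if rxn.is_exchange:
                real = [
                    m
                    for m in rxn.stoichiometry
                    if not self.metabolites[m].artificial
                ]
                if len(real) != 1:
                    raise ModelValidationError(
                        f"exchange reaction {rxn.id} must touch exactly one "
                        f"non-artificial metabolite, found {len(real)}"
                    )
        bad = self.compartments - {"c", "e"}
        if bad:
            raise ModelValidationError(f"unexpected compartments {sorted(bad)}")

    def stoichiometric_matrix(self) -> pd.DataFrame:
        """Dense S matrix (metabolites x reactions) as a DataFrame."""
        S = pd.DataFrame(
            0.0,
            index=list(self.metabolites),
            columns=list(self.reactions),
        )
        for rid, rxn in self.reactions.items():
            for mid, coef in rxn.stoichiometry.items():
                S.loc[mid, rid] = coef
        return S

    def exchange_reactions(self) -> list[str]:
        return [rid for rid, r in self.reactions.items() if r.is_exchange]

    def gene_ids(self) -> set[str]:
        genes: set[str] = set()
        for rxn in self.reactions.values():
            if rxn.gene_association:
                genes.update(
                    g
                    for g in re.split(r"[\s()]+|\band\b|\bor\b", rxn.gene_association)
                    if g and g not in ("and", "or")
                )
        return genes


@dataclass
class ConstraintTables:
    """Metabolite concentration windows and exchange flux bounds.

    Defaults apply wherever no override exists: concentrations in
    [1e-5, 0.02] mol/L, exchange fluxes keep the reaction's own bounds.
    """

    concentration_bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    exchange_bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    default_conc_lo: float = DEFAULT_CONC_LO
    default_conc_hi: float = DEFAULT_CONC_HI

    def __post_init__(self) -> None:
        for mid, (lo, hi) in self.concentration_bounds.items():
            if not (0 < lo < hi):
                raise ModelValidationError(
                    f"concentration bounds for {mid}: need 0 < lo < hi, got ({lo}, {hi})"
                )
        if not (0 < self.default_conc_lo < self.default_conc_hi):
            raise ModelValidationError("default concentration bounds invalid")

    def conc_bounds(self, met_id: str) -> tuple[float, float]:
        return self.concentration_bounds.get(
            met_id, (self.default_conc_lo, self.default_conc_hi)
        )

    def with_override(
        self, met_id: str, lo: float, hi: float
    ) -> "ConstraintTables":
        new = dict(self.concentration_bounds)
        new[met_id] = (lo, hi)
        return replace(self, concentration_bounds=new)


# ---------------------------------------------------------------------------
# Equation strings
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"^(?:\(?([\d.eE+-]+)\)?\s+)?(\S+)\[(\w+)\]$")


def parse_equation(equation: str) -> tuple[dict[str, float], bool]:
    """Parse ``a A[c] + b B[e] => c C[c]`` into (stoichiometry, reversible).

    Keys of the returned mapping are the raw ``cpd[compartment]`` tokens;
    callers map them to canonical metabolite ids.
    """
    if "<=>" in equation:
        lhs, rhs = equation.split("<=>")
        reversible = True
    elif "=>" in equation:
        lhs, rhs = equation.split("=>")
        reversible = False
    else:
        raise ModelFormatError(f"equation {equation!r}: no => or <=> arrow")

    stoich: dict[str, float] = {}

    def add_side(side: str, sign: float) -> None:
        side = side.strip()
        if not side:
            return
        for token in side.split(" + "):
            token = token.strip()
            m = _TOKEN_RE.match(token)
            if m is None:
                raise ModelFormatError(
                    f"equation {equation!r}: bad term {token!r}"
                )
            coef_s, cpd, comp = m.groups()
            coef = float(coef_s) if coef_s else 1.0
            key = f"{cpd}[{comp}]"
            stoich[key] = stoich.get(key, 0.0) + sign * coef

    add_side(lhs, -1.0)
    add_side(rhs, +1.0)
    stoich = {k: v for k, v in stoich.items() if v != 0.0}
    if not stoich:
        raise ModelFormatError(f"equation {equation!r}: nets to nothing")
    return stoich, reversible


def _fmt_coef(c: float) -> str:
    return f"{c:g}"


def format_equation(
    stoichiometry: Mapping[str, float],
    metabolites: Mapping[str, Metabolite],
    reversible: bool,
) -> str:
    """Inverse of :func:`parse_equation` given the model's metabolites."""

    def token(mid: str, coef: float) -> str:
        met = metabolites[mid]
        base = mid
        if base.endswith(f"_{met.compartment}"):
            base = base[: -(len(met.compartment) + 1)]
        tok = f"{base}[{met.compartment}]"
        if coef != 1.0:
            tok = f"{_fmt_coef(coef)} {tok}"
        return tok

    lhs = " + ".join(
        token(mid, -c) for mid, c in sorted(stoichiometry.items()) if c < 0
    )
    rhs = " + ".join(
        token(mid, c) for mid, c in sorted(stoichiometry.items()) if c > 0
    )
    arrow = "<=>" if reversible else "=>"
    return f"{lhs} {arrow} {rhs}".strip()


def _met_id(cpd_comp: str) -> str:
    """``cpd[comp]`` token -> canonical metabolite id ``cpd_comp``."""
    m = re.match(r"^(\S+)\[(\w+)\]$", cpd_comp)
    if m is None:
        raise ModelFormatError(f"bad metabolite token {cpd_comp!r}")
    cpd, comp = m.groups()
    if comp not in ("c", "e"):
        comp = "c"  # merge periplasm etc. into the inside compartment
    return f"{cpd}_{comp}"


# ---------------------------------------------------------------------------
# Load / save
# ---------------------------------------------------------------------------


def load_model(path: str | Path, dialect: str = "tsv", **kwargs) -> MetabolicModel:
    """Load a model in the named dialect (``tsv``, ``yaml`` or ``sbml``).

    For SBML, ``biomass_id``/``atpm_id``/``atp_id`` keyword overrides may be
    given; otherwise the fbc objective is taken as the biomass reaction and a
    reaction literally named ``ATPM`` as the maintenance reaction.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "tsv":
        model = _load_tsv(path)
    elif dialect == "yaml":
        model = _load_yaml(path)
    elif dialect == "sbml":
        model = _load_sbml(path, **kwargs)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    model.validate()
    return model


def save_model(model: MetabolicModel, path: str | Path, dialect: str = "tsv") -> None:
    path = Path(path)
    if dialect == "tsv":
        _save_tsv(model, path)
    elif dialect == "yaml":
        _save_yaml(model, path)
    elif dialect == "sbml":
        _save_sbml(model, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def _model_from_records(
    met_records: Iterable[dict],
    rxn_records: Iterable[dict],
    info: Mapping[str, str],
) -> MetabolicModel:
    metabolites: dict[str, Metabolite] = {}
    for rec in met_records:
        met = Metabolite(
            id=str(rec["id"]),
            name=str(rec.get("name", "") or ""),
            formula=str(rec.get("formula", "") or ""),
            charge=int(rec.get("charge", 0) or 0),
            compartment=str(rec.get("compartment", "c")),
            smiles=(rec.get("smiles") or None),
            artificial=_parse_bool(rec.get("artificial", False)),
        )
        if met.compartment not in ("c", "e"):
            met.compartment = "c"
        if met.id in metabolites:
            raise ModelValidationError(f"duplicate metabolite id {met.id}")
        metabolites[met.id] = met

    reactions: dict[str, Reaction] = {}
    for rec in rxn_records:
        rid = str(rec["id"])
        stoich_tokens, reversible = parse_equation(str(rec["equation"]))
        stoich = {_met_id(tok): coef for tok, coef in stoich_tokens.items()}
        lb = float(rec.get("lower", FLUX_MIN if reversible else 0.0))
        ub = float(rec.get("upper", FLUX_MAX))
        rxn = Reaction(
            id=rid,
            stoichiometry=stoich,
            lower_bound=lb,
            upper_bound=ub,
            gene_association=(str(rec["genes"]) if rec.get("genes") else None),
            is_exchange=_parse_bool(rec.get("exchange", False)),
            is_transport=_parse_bool(rec.get("transport", False)),
            subsystem=(str(rec["subsystem"]) if rec.get("subsystem") else None),
        )
        if rid in reactions:
            raise ModelValidationError(f"duplicate reaction id {rid}")
        reactions[rid] = rxn

    if "biomass_reaction" not in info:
        raise ModelValidationError("model info missing biomass_reaction")
    if "atpm_reaction" not in info:
        raise ModelValidationError("model info missing atpm_reaction")
    return MetabolicModel(
        metabolites=metabolites,
        reactions=reactions,
        biomass_reaction_id=str(info["biomass_reaction"]),
        atpm_reaction_id=str(info["atpm_reaction"]),
        atp_metabolite_id=(str(info["atp_metabolite"]) if info.get("atp_metabolite") else None),
        name=str(info.get("name", "model")),
    )


def _parse_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    return str(value).strip().lower() in ("1", "true", "yes")


def _load_tsv(path: Path) -> MetabolicModel:
    if not path.is_dir():
        raise ModelFormatError(f"tsv dialect expects a directory, got {path}")
    try:
        mets = pd.read_csv(path / "metabolites.tsv", sep="\t", dtype=str).fillna("")
        rxns = pd.read_csv(path / "reactions.tsv", sep="\t", dtype=str).fillna("")
        info_df = pd.read_csv(path / "model_info.tsv", sep="\t", dtype=str)
    except FileNotFoundError as exc:
        raise ModelFormatError(f"missing model table: {exc}") from exc
    info = dict(zip(info_df["key"], info_df["value"]))
    return _model_from_records(
        mets.to_dict("records"), rxns.to_dict("records"), info
    )


def _save_tsv(model: MetabolicModel, path: Path) -> None:
    path.mkdir(parents=True, exist_ok=True)
    met_rows = [
        {
            "id": m.id,
            "name": m.name,
            "formula": m.formula,
            "charge": m.charge,
            "compartment": m.compartment,
            "smiles": m.smiles or "",
            "artificial": str(m.artificial).lower(),
        }
        for m in model.metabolites.values()
    ]
    rxn_rows = [
        {
            "id": r.id,
            "equation": format_equation(r.stoichiometry, model.metabolites, r.reversible),
            "lower": f"{r.lower_bound:g}",
            "upper": f"{r.upper_bound:g}",
            "genes": r.gene_association or "",
            "exchange": str(r.is_exchange).lower(),
            "transport": str(r.is_transport).lower(),
            "subsystem": r.subsystem or "",
        }
        for r in model.reactions.values()
    ]
    info_rows = [
        {"key": "name", "value": model.name},
        {"key": "biomass_reaction", "value": model.biomass_reaction_id},
        {"key": "atpm_reaction", "value": model.atpm_reaction_id},
    ]
    if model.atp_metabolite_id:
        info_rows.append({"key": "atp_metabolite", "value": model.atp_metabolite_id})
    pd.DataFrame(met_rows).to_csv(path / "metabolites.tsv", sep="\t", index=False)
    pd.DataFrame(rxn_rows).to_csv(path / "reactions.tsv", sep="\t", index=False)
    pd.DataFrame(info_rows).to_csv(path / "model_info.tsv", sep="\t", index=False)


def _load_yaml(path: Path) -> MetabolicModel:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "reactions" not in doc:
        raise ModelFormatError(f"{path}: not a model YAML document")
    return _model_from_records(
        doc.get("metabolites", []), doc["reactions"], doc.get("info", {})
    )


def _save_yaml(model: MetabolicModel, path: Path) -> None:
    doc = {
        "info": {
            "name": model.name,
            "biomass_reaction": model.biomass_reaction_id,
            "atpm_reaction": model.atpm_reaction_id,
            **(
                {"atp_metabolite": model.atp_metabolite_id}
                if model.atp_metabolite_id
                else {}
            ),
        },
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "formula": m.formula,
                "charge": m.charge,
                "compartment": m.compartment,
                **({"smiles": m.smiles} if m.smiles else {}),
                **({"artificial": True} if m.artificial else {}),
            }
            for m in model.metabolites.values()
        ],
        "reactions": [
            {
                "id": r.id,
                "equation": format_equation(
                    r.stoichiometry, model.metabolites, r.reversible
                ),
                "lower": r.lower_bound,
                "upper": r.upper_bound,
                **({"genes": r.gene_association} if r.gene_association else {}),
                **({"exchange": True} if r.is_exchange else {}),
                **({"transport": True} if r.is_transport else {}),
                **({"subsystem": r.subsystem} if r.subsystem else {}),
            }
            for r in model.reactions.values()
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def _load_sbml(
    path: Path,
    biomass_id: str | None = None,
    atpm_id: str | None = None,
    atp_id: str | None = None,
) -> MetabolicModel:
    import cobra.io

    cm = cobra.io.read_sbml_model(str(path))
    metabolites = {}
    for m in cm.metabolites:
        comp = m.compartment if m.compartment in ("c", "e") else "c"
        metabolites[m.id] = Metabolite(
            id=m.id,
            name=m.name or "",
            formula=m.formula or "",
            charge=int(m.charge or 0),
            compartment=comp,
        )
    reactions = {}
    for r in cm.reactions:
        reactions[r.id] = Reaction(
            id=r.id,
            stoichiometry={m.id: c for m, c in r.metabolites.items()},
            lower_bound=r.lower_bound,
            upper_bound=r.upper_bound,
            gene_association=(r.gene_reaction_rule or None),
            is_exchange=(r in cm.exchanges or r.boundary),
            subsystem=(r.subsystem or None),
        )
    if biomass_id is None:
        objective = [
            r.id for r in cm.reactions if r.objective_coefficient
        ]
        if len(objective) != 1:
            raise ModelValidationError(
                "SBML model has no unique objective; pass biomass_id explicitly"
            )
        biomass_id = objective[0]
    if atpm_id is None:
        candidates = [rid for rid in reactions if rid.upper() == "ATPM"]
        if not candidates:
            raise ModelValidationError(
                "no ATPM reaction found; pass atpm_id explicitly"
            )
        atpm_id = candidates[0]
    return MetabolicModel(
        metabolites=metabolites,
        reactions=reactions,
        biomass_reaction_id=biomass_id,
        atpm_reaction_id=atpm_id,
        atp_metabolite_id=atp_id,
        name=cm.id or "model",
    )


def _save_sbml(model: MetabolicModel, path: Path) -> None:
    import cobra
    import cobra.io

    cm = cobra.Model(model.name)
    cmets = {}
    for m in model.metabolites.values():
        cmet = cobra.Metabolite(
            m.id,
            name=m.name,
            formula=m.formula or None,
            charge=m.charge,
            compartment=m.compartment,
        )
        cmets[m.id] = cmet
    cm.add_metabolites(list(cmets.values()))
    crxns = []
    for r in model.reactions.values():
        cr = cobra.Reaction(r.id, lower_bound=r.lower_bound, upper_bound=r.upper_bound)
        crxns.append(cr)
    cm.add_reactions(crxns)
    for r in model.reactions.values():
        cm.reactions.get_by_id(r.id).add_metabolites(
            {cmets[mid]: c for mid, c in r.stoichiometry.items()}
        )
        if r.gene_association:
            cm.reactions.get_by_id(r.id).gene_reaction_rule = r.gene_association
    cm.objective = model.biomass_reaction_id
    cobra.io.write_sbml_model(cm, str(path))


# ---------------------------------------------------------------------------
# Balance checking
# ---------------------------------------------------------------------------


@dataclass
class BalanceReport:
    """Per-reaction element/charge imbalances; report-only, never raises."""

    element_imbalance: dict[str, dict[str, float]]
    charge_imbalance: dict[str, float]
    skipped: list[str]

    @property
    def balanced(self) -> bool:
        return not self.element_imbalance and not self.charge_imbalance


def validate_balance(model: MetabolicModel) -> BalanceReport:
    """Check elemental and charge balance of every checkable reaction.

    Exchange reactions, the biomass reaction, and any reaction touching an
    artificial metabolite are skipped (and listed as skipped): they move
    matter across the boundary or involve pseudometabolites by design.
    """
    element_imb: dict[str, dict[str, float]] = {}
    charge_imb: dict[str, float] = {}
    skipped: list[str] = []
    for rid, rxn in model.reactions.items():
        if rxn.is_exchange or rid == model.biomass_reaction_id:
            skipped.append(rid)
            continue
        mets = [model.metabolites[mid] for mid in rxn.stoichiometry]
        if any(m.artificial for m in mets):
            skipped.append(rid)
            continue
        try:
            elems = {m.id: m.elements() for m in mets}
        except ModelFormatError:
            skipped.append(rid)
            continue
        totals: dict[str, float] = {}
        charge = 0.0
        for mid, coef in rxn.stoichiometry.items():
            for el, n in elems[mid].items():
                totals[el] = totals.get(el, 0.0) + coef * n
            charge += coef * model.metabolites[mid].charge
        totals = {el: v for el, v in totals.items() if abs(v) > 1e-9}
        if totals:
            element_imb[rid] = totals
        if abs(charge) > 1e-9:
            charge_imb[rid] = charge
    return BalanceReport(element_imb, charge_imb, skipped)


# ---------------------------------------------------------------------------
# Constraint tables (concentration / exchange bounds)
# ---------------------------------------------------------------------------


def read_constraint_tables(
    concentrations_path: str | Path | None = None,
    exchanges_path: str | Path | None = None,
) -> ConstraintTables:
    """Read concentration and exchange bound TSVs (columns id, lower, upper)."""
    conc: dict[str, tuple[float, float]] = {}
    exch: dict[str, tuple[float, float]] = {}
    if concentrations_path is not None:
        df = pd.read_csv(concentrations_path, sep="\t")
        conc = {
            str(r["id"]): (float(r["lower"]), float(r["upper"]))
            for _, r in df.iterrows()
        }
    if exchanges_path is not None:
        df = pd.read_csv(exchanges_path, sep="\t")
        exch = {
            str(r["id"]): (float(r["lower"]), float(r["upper"]))
            for _, r in df.iterrows()
        }
    return ConstraintTables(concentration_bounds=conc, exchange_bounds=exch)


def write_constraint_tables(tables: ConstraintTables, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            {"id": k, "lower": lo, "upper": hi}
            for k, (lo, hi) in tables.concentration_bounds.items()
        ],
        columns=["id", "lower", "upper"],
    ).to_csv(directory / "concentrations.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {"id": k, "lower": lo, "upper": hi}
            for k, (lo, hi) in tables.exchange_bounds.items()
        ],
        columns=["id", "lower", "upper"],
    ).to_csv(directory / "exchanges.tsv", sep="\t", index=False)
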