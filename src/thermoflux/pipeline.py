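"""End-to-end orchestration: load → thermo → calibrate → simulate → compare.

A pipeline run is described by a single YAML config (see
:func:`load_config`) naming the model, the thermodynamic tables, and one
block per temperature condition.  Outputs per condition: a calibration TSV
and robustness plot, an ensemble directory (flux/ΔrG′/ln-concentration
matrices + manifest), an efficiency-metrics TSV, and a summary TSV per
matrix.  Across conditions: a significance-screen report per matrix and a
direction-class table.  A run manifest records seeds, versions, and input
digests; identical configs produce byte-identical numeric outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .calibration import ATPMRange, calibrate_atpm, plot_robustness
from .ensemble import (
    ConditionSpec,
    classify_directions,
    efficiency_metrics,
    run_ensemble,
    save_ensemble,
    summarize,
)
from .gem import load_model, read_constraint_tables, validate_balance
from .stats import compare_conditions
from .thermo import ThermoConfig, read_thermo_tables
from .tmfa import build_problem

__all__ = ["PipelineConfig", "ConditionConfig", "load_config", "run_pipeline"]

log = logging.getLogger(__name__)

_FLOAT_FMT = "%.12g"


@dataclass
class ConditionConfig:
    name: str
    temperature_K: float
    growth_range: tuple[float, float]
    atpm_range: tuple[float, float] | None = None  # None = calibrate
    n_simulations: int = 1000
    oxygen_conc_hi: float | None = None
    oxygen_exchange_lo: float | None = None
    oxygen_metabolite_id: str | None = None
    oxygen_exchange_id: str | None = None


@dataclass
class PipelineConfig:
    model_path: str
    model_dialect: str
    out_dir: str
    conditions: list[ConditionConfig]
    dG0_path: str | None = None
    exclusion_path: str | None = None
    transport_path: str | None = None
    concentrations_path: str | None = None
    exchanges_path: str | None = None
    substrate_exchange_id: str | None = None
    solver: str = "highs"
    seed: int = 0
    calibration_grid_points: int = 50

    def __post_init__(self) -> None:
        if not self.conditions:
            raise ValueError("pipeline config needs at least one condition")


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    conditions = [
        ConditionConfig(
            name=c["name"],
            temperature_K=float(c["temperature_K"]),
            growth_range=tuple(float(v) for v in c["growth_range"]),
            atpm_range=(
                tuple(float(v) for v in c["atpm_range"])
                if c.get("atpm_range")
                else None
            ),
            n_simulations=int(c.get("n_simulations", 1000)),
            oxygen_conc_hi=c.get("oxygen_conc_hi"),
            oxygen_exchange_lo=c.get("oxygen_exchange_lo"),
            oxygen_metabolite_id=c.get("oxygen_metabolite_id"),
            oxygen_exchange_id=c.get("oxygen_exchange_id"),
        )
        for c in doc["conditions"]
    ]
    base = Path(path).parent

    def resolve(p):
        return str(base / p) if p else None

    return PipelineConfig(
        model_path=resolve(doc["model"]),
        model_dialect=doc.get("dialect", "tsv"),
        out_dir=str(base / doc.get("out_dir", "thermoflux_out")),
        conditions=conditions,
        dG0_path=resolve(doc.get("dG0")),
        exclusion_path=resolve(doc.get("excluded")),
        transport_path=resolve(doc.get("transport")),
        concentrations_path=resolve(doc.get("concentrations")),
        exchanges_path=resolve(doc.get("exchanges")),
        substrate_exchange_id=doc.get("substrate_exchange"),
        solver=doc.get("solver", "highs"),
        seed=int(doc.get("seed", 0)),
        calibration_grid_points=int(doc.get("calibration_grid_points", 50)),
    )


def _digest(path: str | None) -> str | None:
    if path is None:
        return None
    h = hashlib.sha256()
    p = Path(path)
    if p.is_dir():
        for f in sorted(p.rglob("*")):
            if f.is_file():
                h.update(f.name.encode())
                h.update(f.read_bytes())
    else:
        h.update(p.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT, index=index)


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage; returns the report directory.

    On a stage failure, partial outputs are retained next to a ``FAILED``
    marker naming the stage, and the exception propagates.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "load"
    try:
        model = load_model(config.model_path, config.model_dialect)
        balance = validate_balance(model)
        if not balance.balanced:
            log.warning(
                "model has %d element and %d charge imbalances",
                len(balance.element_imbalance),
                len(balance.charge_imbalance),
            )
        thermo = read_thermo_tables(
            config.dG0_path, config.exclusion_path, config.transport_path
        )
        tables = read_constraint_tables(
            config.concentrations_path, config.exchanges_path
        )

        ensembles = {}
        calib_rows = []
        stage = "conditions"
        for i, cond_cfg in enumerate(config.conditions):
            stage = f"condition:{cond_cfg.name}"
            cfg = ThermoConfig(temperature_K=cond_cfg.temperature_K)
            problem = build_problem(
                model, thermo, cfg, tables, backend=config.solver
            )
            if cond_cfg.atpm_range is None:
                atpm, curve = calibrate_atpm(
                    problem,
                    cond_cfg.growth_range,
                    n_points=config.calibration_grid_points,
                    seed=config.seed,
                )
                plot_robustness(curve, atpm, out / f"robustness_{cond_cfg.name}.png")
                calib_rows.append(
                    {
                        "condition": cond_cfg.name,
                        "temperature_K": cond_cfg.temperature_K,
                        "slope": atpm.fit_slope,
                        "intercept": atpm.fit_intercept,
                        "r2": atpm.fit_r2,
                        "atpm_lower": atpm.lower,
                        "atpm_upper": atpm.upper,
                    }
                )
                atpm_range: tuple[float, float] | ATPMRange = atpm
            else:
                atpm_range = cond_cfg.atpm_range
            condition = ConditionSpec(
                name=cond_cfg.name,
                temperature_K=cond_cfg.temperature_K,
                growth_range=cond_cfg.growth_range,
                atpm_range=atpm_range,
                n_simulations=cond_cfg.n_simulations,
                seed=config.seed + 1000 * (i + 1),
                oxygen_conc_hi=cond_cfg.oxygen_conc_hi,
                oxygen_exchange_lo=cond_cfg.oxygen_exchange_lo,
                oxygen_metabolite_id=cond_cfg.oxygen_metabolite_id,
                oxygen_exchange_id=cond_cfg.oxygen_exchange_id,
            )
            ens = run_ensemble(problem, condition)
            ensembles[cond_cfg.name] = ens
            ens_dir = out / f"ensemble_{cond_cfg.name}"
            save_ensemble(ens, ens_dir)
            for label, matrix in (
                ("fluxes", ens.fluxes),
                ("drG", ens.drG),
                ("ln_conc", ens.ln_conc),
            ):
                _write_tsv(summarize(matrix), ens_dir / f"summary_{label}.tsv")
            if config.substrate_exchange_id:
                _write_tsv(
                    efficiency_metrics(ens, model, config.substrate_exchange_id),
                    out / f"efficiency_{cond_cfg.name}.tsv",
                )

        if calib_rows:
            _write_tsv(pd.DataFrame(calib_rows), out / "calibration.tsv", index=False)

        stage = "compare"
        direction_rows = []
        for name, ens in ensembles.items():
            classes = classify_directions(ens)
            for rid, cls in classes.items():
                direction_rows.append(
                    {"condition": name, "reaction": rid, "class": cls}
                )
        _write_tsv(
            pd.DataFrame(direction_rows), out / "direction_classes.tsv", index=False
        )
        if len(ensembles) >= 2:
            for label in ("fluxes", "drG", "ln_conc"):
                report = compare_conditions(
                    {n: getattr(e, label) for n, e in ensembles.items()}
                )
                _write_tsv(report, out / f"comparison_{label}.tsv", index=False)

        stage = "manifest"
        manifest = {
            "thermoflux_version": __version__,
            "python": platform.python_version(),
            "solver": config.solver,
            "seed": config.seed,
            "inputs": {
                "model": _digest(config.model_path),
                "dG0": _digest(config.dG0_path),
                "excluded": _digest(config.exclusion_path),
                "transport": _digest(config.transport_path),
                "concentrations": _digest(config.concentrations_path),
                "exchanges": _digest(config.exchanges_path),
            },
            "conditions": [c.name for c in config.conditions],
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise
    return out
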