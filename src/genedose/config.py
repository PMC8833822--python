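"""Structured scenario configuration (YAML) with strict validation.

A scenario document has four sections::

    gene:        {k, rho, f, h}                       # rates in 1/h
    drugs:       [{name, target, lam, r1}, ...]       # r0 is the gene baseline
    agendas:     {drug_name: [{tau, xi}, ...], ...}
    simulation:  {horizon, output_dt, threshold, target_mean, window}

Unknown keys are rejected, every validation failure names the offending key,
and parse -> serialize -> parse is the identity.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any

import yaml

from .dosing import Agenda, DoseEvent, DrugSpec
from .kinetics import GeneKinetics
from .simulate import TreatmentScenario

__all__ = ["load_config", "save_config", "scenario_to_dict", "scenario_from_dict"]

_GENE_KEYS = {"k", "rho", "f", "h"}
_DRUG_KEYS = {"name", "target", "lam", "r1"}
_DOSE_KEYS = {"tau", "xi"}
_SIM_KEYS = {"horizon", "output_dt", "threshold", "target_mean", "window", "name"}
_TOP_KEYS = {"gene", "drugs", "agendas", "simulation"}


def _require_keys(d: dict, allowed: set[str], required: set[str], where: str) -> None:
    if not isinstance(d, dict):
        raise ValueError(f"{where}: expected a mapping, got {type(d).__name__}")
    extra = set(d) - allowed
    if extra:
        raise ValueError(f"{where}: unknown keys {sorted(extra)}")
    missing = required - set(d)
    if missing:
        raise ValueError(f"{where}: missing keys {sorted(missing)}")


def scenario_from_dict(doc: dict[str, Any]) -> TreatmentScenario:
    """Validated TreatmentScenario from a parsed configuration document."""
    _require_keys(doc, _TOP_KEYS, {"gene"}, "scenario")
    g = doc["gene"]
    _require_keys(g, _GENE_KEYS, _GENE_KEYS, "gene")
    try:
        gene = GeneKinetics(k=float(g["k"]), rho=float(g["rho"]),
                            f=float(g["f"]), h=float(g["h"]))
    except ValueError as e:
        raise ValueError(f"gene: {e}") from e
    drugs = []
    agendas = doc.get("agendas", {}) or {}
    if not isinstance(agendas, dict):
        raise ValueError("agendas: expected a mapping of drug name to dose list")
    seen = set()
    for i, d in enumerate(doc.get("drugs", []) or []):
        _require_keys(d, _DRUG_KEYS, _DRUG_KEYS, f"drugs[{i}]")
        name = str(d["name"])
        seen.add(name)
        try:
            spec = DrugSpec(name=name, target=d["target"], lam=float(d["lam"]),
                            r0=float(getattr(gene, d["target"])),
                            r1=float(d["r1"]))
        except (ValueError, AttributeError) as e:
            raise ValueError(f"drugs[{i}] ({name}): {e}") from e
        doses = []
        for j, ev in enumerate(agendas.get(name, []) or []):
            _require_keys(ev, _DOSE_KEYS, _DOSE_KEYS, f"agendas.{name}[{j}]")
            try:
                doses.append(DoseEvent(tau=float(ev["tau"]), xi=float(ev["xi"])))
            except ValueError as e:
                raise ValueError(f"agendas.{name}[{j}]: {e}") from e
        try:
            agenda = Agenda(tuple(doses))
        except ValueError as e:
            raise ValueError(f"agendas.{name}: {e}") from e
        drugs.append((spec, agenda))
    unmatched = set(agendas) - seen
    if unmatched:
        raise ValueError(f"agendas: no drug named {sorted(unmatched)}")
    sim = doc.get("simulation", {}) or {}
    _require_keys(sim, _SIM_KEYS, set(), "simulation")
    window = sim.get("window", (60.0, 80.0))
    if not (isinstance(window, (list, tuple)) and len(window) == 2):
        raise ValueError("simulation.window: expected [start_h, end_h]")
    try:
        return TreatmentScenario(
            baseline=gene,
            drugs=tuple(drugs),
            horizon=float(sim.get("horizon", 150.0)),
            output_dt=float(sim.get("output_dt", 0.05)),
            threshold=float(sim.get("threshold", 80.0)),
            target_mean=float(sim.get("target_mean", 100.0)),
            window=(float(window[0]), float(window[1])),
            name=str(sim.get("name", "")),
        )
    except ValueError as e:
        raise ValueError(f"simulation: {e}") from e


def scenario_to_dict(sc: TreatmentScenario) -> dict[str, Any]:
    """Normalized configuration document for a scenario."""
    return {
        "gene": {"k": sc.baseline.k, "rho": sc.baseline.rho,
                 "f": sc.baseline.f, "h": sc.baseline.h},
        "drugs": [
            {"name": d.name, "target": d.target, "lam": d.lam, "r1": d.r1}
            for d, _ in sc.drugs
        ],
        "agendas": {
            d.name: [{"tau": ev.tau, "xi": ev.xi} for ev in a.doses]
            for d, a in sc.drugs
        },
        "simulation": {
            "horizon": sc.horizon, "output_dt": sc.output_dt,
            "threshold": sc.threshold, "target_mean": sc.target_mean,
            "window": [sc.window[0], sc.window[1]], "name": sc.name,
        },
    }


def load_config(path: str | Path) -> TreatmentScenario:
    """Load and validate a scenario configuration file."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if doc is None:
        raise ValueError(f"{path}: empty configuration")
    return scenario_from_dict(doc)


def save_config(sc: TreatmentScenario, path: str | Path) -> None:
    """Serialize a scenario so that load_config(save_config(sc)) == sc."""
    with open(path, "w") as fh:
        yaml.safe_dump(scenario_to_dict(sc), fh, sort_keys=False)
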