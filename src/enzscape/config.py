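"""YAML round-trip of run configurations and calibrated model parameters."""
from __future__ import annotations

from dataclasses import asdict

import yaml

from .energy import SingleBasinParams
from .integrator import SimulationConfig
from .reaction import ChemistryParams

__all__ = ["dump_run_config", "load_run_config"]


def dump_run_config(
    path,
    sim: SimulationConfig,
    params: SingleBasinParams | None = None,
    chemistry: ChemistryParams | None = None,
    model_extras: dict | None = None,
) -> None:
    """Write a complete run configuration (simulation + model parameters)."""
    doc = {"simulation": asdict(sim)}
    if params is not None:
        doc["potential"] = asdict(params)
    if chemistry is not None:
        doc["chemistry"] = asdict(chemistry)
    if model_extras:
        doc["model"] = dict(model_extras)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_run_config(path):
    """Read a run configuration; returns (SimulationConfig, SingleBasinParams
    or None, ChemistryParams or None, model extras dict)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    sim = SimulationConfig(**doc.get("simulation", {}))
    params = SingleBasinParams(**doc["potential"]) if "potential" in doc else None
    chem = ChemistryParams(**doc["chemistry"]) if "chemistry" in doc else None
    return sim, params, chem, doc.get("model", {})
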