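"""YAML round-tripping for simulation and analysis configurations."""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import yaml

from .pipeline import PipelineParams
from .synthetic import CurvePriors, SimConfig

__all__ = ["save_config", "load_config"]


def save_config(path, sim: SimConfig | None = None,
                params: PipelineParams | None = None) -> None:
    """Write simulation and/or analysis settings as nested YAML."""
    doc = {}
    if sim is not None:
        d = asdict(sim)
        d["years"] = list(sim.years)
        d["corn_fraction_range"] = list(sim.corn_fraction_range)
        d["curve_priors"] = {k: (list(v) if isinstance(v, tuple) else v)
                             for k, v in asdict(sim.curve_priors).items()}
        doc["simulation"] = d
    if params is not None:
        doc["analysis"] = asdict(params)
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_config(path) -> tuple[SimConfig | None, PipelineParams | None]:
    """Read settings written by :func:`save_config`."""
    doc = yaml.safe_load(Path(path).read_text()) or {}
    sim = None
    if "simulation" in doc:
        d = dict(doc["simulation"])
        d["years"] = tuple(d["years"])
        d["corn_fraction_range"] = tuple(d["corn_fraction_range"])
        pri = {k: (tuple(v) if isinstance(v, list) else v)
               for k, v in d.get("curve_priors", {}).items()}
        d["curve_priors"] = CurvePriors(**pri)
        d["yield_betas"] = {k: float(v) for k, v in d["yield_betas"].items()}
        sim = SimConfig(**d)
    params = PipelineParams(**doc["analysis"]) if "analysis" in doc else None
    return sim, params
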