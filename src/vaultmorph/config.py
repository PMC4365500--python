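"""YAML/JSON configuration for full pipeline runs.

A config file carries up to six sections — ``mesh``, ``turing``,
``differentiation``, ``growth``, ``simulation``, ``perturbation`` — each
overriding defaults field by field. Unknown keys are rejected so typos fail
loudly. ``differentiation.Ta_hours`` may be given instead of ``Ta`` (which
is in seconds); ``simulation`` times accept ``*_days`` variants.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import yaml

from .differentiation import HOUR, DifferentiationParams
from .growth import GrowthParams
from .simulate import DAY, PerturbationSpec, SimulationConfig, default_perturbation_points
from .turing import TuringParams


@dataclasses.dataclass
class MeshSpec:
    kind: str = "dome"        # dome | sheet | interval | file
    length: float = 7.0
    width: float = 5.2
    height: float = 2.49
    target_edge: float = 0.15
    n_cells: int = 200        # interval meshes
    periodic: bool = False
    path: str | None = None   # kind == "file"

    def build(self):
        from . import geometry

        if self.kind == "dome":
            return geometry.build_dome_mesh(
                self.length, self.width, self.height, self.target_edge
            )
        if self.kind == "sheet":
            return geometry.build_sheet_mesh(
                self.length, self.width, self.target_edge, self.periodic
            )
        if self.kind == "interval":
            return geometry.build_interval_mesh(
                self.length, self.n_cells, self.periodic
            )
        if self.kind == "file":
            if not self.path:
                raise ValueError("mesh.kind 'file' requires mesh.path")
            return geometry.load_mesh(self.path)
        raise ValueError(f"unknown mesh kind {self.kind!r}")


@dataclasses.dataclass
class RunConfig:
    mesh: MeshSpec
    turing: TuringParams
    differentiation: DifferentiationParams
    growth: GrowthParams
    simulation: SimulationConfig
    perturbation: PerturbationSpec


def _fill(cls, section: dict, name: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - valid
    if unknown:
        raise ValueError(f"unknown keys in {name!r} section: {sorted(unknown)}")
    return cls(**section)


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Load a run configuration from a YAML/JSON file plus optional overrides."""
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        raw = (json.loads(text) if str(path).endswith(".json")
               else yaml.safe_load(text)) or {}
    if overrides:
        for sec, vals in overrides.items():
            raw.setdefault(sec, {}).update(vals)

    diff_sec = dict(raw.get("differentiation", {}))
    if "Ta_hours" in diff_sec:
        diff_sec["Ta"] = diff_sec.pop("Ta_hours") * HOUR
    sim_sec = dict(raw.get("simulation", {}))
    for key in ("t_end", "handoff_time", "output_every"):
        if f"{key}_days" in sim_sec:
            sim_sec[key] = sim_sec.pop(f"{key}_days") * DAY

    mesh = _fill(MeshSpec, dict(raw.get("mesh", {})), "mesh")
    pert_sec = dict(raw.get("perturbation", {}))
    if "points" not in pert_sec:
        pert_sec["points"] = default_perturbation_points(
            mesh.length, mesh.width, mesh.height
        )
    return RunConfig(
        mesh=mesh,
        turing=_fill(TuringParams, dict(raw.get("turing", {})), "turing"),
        differentiation=_fill(DifferentiationParams, diff_sec, "differentiation"),
        growth=_fill(GrowthParams, dict(raw.get("growth", {})), "growth"),
        simulation=_fill(SimulationConfig, sim_sec, "simulation"),
        perturbation=_fill(PerturbationSpec, pert_sec, "perturbation"),
    )
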