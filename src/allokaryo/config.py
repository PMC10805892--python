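"""Run configuration: a strict, flat-ish YAML schema for the CLI.

Unknown keys are rejected so that a typo in a threshold name fails fast
instead of silently running with defaults.  Every threshold in the
config is echoed in the run log, making filter behaviour auditable.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .diversity import DiversityConfig
from .karyotype import KaryotypeConfig
from .simulate import SimulationParams


@dataclasses.dataclass
class RunConfig:
    seed: int = 0
    simulation: SimulationParams = dataclasses.field(default_factory=SimulationParams)
    karyotype: KaryotypeConfig = dataclasses.field(default_factory=KaryotypeConfig)
    diversity: DiversityConfig = dataclasses.field(default_factory=DiversityConfig)
    window_content: int = 100_000
    n_panel_accessions: int = 20

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def log_lines(self) -> list[str]:
        """Every parameter, one per line, for the run log."""
        out = []

        def walk(prefix: str, d: dict) -> None:
            for k, v in sorted(d.items()):
                if isinstance(v, dict):
                    walk(f"{prefix}{k}.", v)
                else:
                    out.append(f"{prefix}{k} = {v}")

        walk("", self.to_dict())
        return out


def _build(cls, data: dict, context: str):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - fields
    if unknown:
        raise ValueError(f"unknown key(s) in {context}: {', '.join(sorted(unknown))}")
    return cls(**data)


def load_config(path: str | Path | None = None, seed: int | None = None) -> RunConfig:
    """Load and validate a YAML run config; `seed` overrides the file."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError("config root must be a mapping")
    known = {"seed", "simulation", "karyotype", "diversity", "window_content",
             "n_panel_accessions"}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown key(s) in config: {', '.join(sorted(unknown))}")
    sim = dict(data.get("simulation") or {})
    if seed is not None:
        data["seed"] = seed
    sim.setdefault("seed", data.get("seed", 0))
    kar = data.get("karyotype") or {}
    div = data.get("diversity") or {}
    for section, val in (("simulation", sim), ("karyotype", kar), ("diversity", div)):
        if not isinstance(val, dict):
            raise ValueError(f"config section {section} must be a mapping")
    # YAML reads tuples as lists
    for key in ("mosaic_band", "catalog_band"):
        if key in kar:
            kar[key] = tuple(kar[key])
    return RunConfig(
        seed=int(data.get("seed", 0)),
        simulation=_build(SimulationParams, sim, "simulation"),
        karyotype=_build(KaryotypeConfig, kar, "karyotype"),
        diversity=_build(DiversityConfig, div, "diversity"),
        window_content=int(data.get("window_content", 100_000)),
        n_panel_accessions=int(data.get("n_panel_accessions", 20)),
    )
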