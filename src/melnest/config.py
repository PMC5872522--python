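"""Run configuration: a YAML file with geometry, parameter, initial,
run and analysis blocks.  Defaults equal the baseline co-culture setup;
the only required field is the run seed.

Example::

    geometry: {nx: 150, ny: 150, nz: 100, delta_um: 20.0}
    parameters: {tau_h: 0.01, Pm_m: 0.075, Pm_s: 0.3,
                 Pp_m: 0.0004, Pp_s: 0.00025, q: 0.7}
    initial: {N_s0: 9549, N_m0: 2706}
    run: {duration_h: 96.0, snapshot_every_steps: 960, seed: 1}
    analysis: {connectivity: 26, min_agents: 4, area_convention: agent_count}

The ``initial`` block may instead give wet-lab cell numbers, which are
converted to density-matched agent counts::

    initial: {skin_cells: 30000, melanoma_cells: 8500, disc_radius_mm: 3.0}
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .lattice import LatticeGeometry
from .params import ModelParameters, density_matched_count

_KNOWN_BLOCKS = {"geometry", "parameters", "initial", "run", "analysis"}
_KNOWN_KEYS = {
    "geometry": {"nx", "ny", "nz", "delta_um"},
    "parameters": {"tau_h", "Pm_m", "Pm_s", "Pp_m", "Pp_s", "q"},
    "initial": {"N_s0", "N_m0", "skin_cells", "melanoma_cells", "disc_radius_mm"},
    "run": {"duration_h", "snapshot_every_steps", "seed"},
    "analysis": {"connectivity", "min_agents", "area_convention"},
}


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration for a single simulation run."""

    geometry: LatticeGeometry = field(default_factory=LatticeGeometry)
    params: ModelParameters = field(default_factory=ModelParameters)
    N_s0: int = 9549
    N_m0: int = 2706
    duration_h: float = 96.0
    snapshot_every_steps: int | None = None
    seed: int = 0
    connectivity: int = 26
    min_agents: int = 4
    area_convention: str = "agent_count"

    def __post_init__(self) -> None:
        if self.N_s0 < 0 or self.N_m0 < 0:
            raise ValueError("initial agent counts must be non-negative")
        if not self.duration_h >= 0:
            raise ValueError("duration_h must be non-negative")
        if self.connectivity not in (6, 26):
            raise ValueError("connectivity must be 6 or 26")
        if self.min_agents < 1:
            raise ValueError("min_agents must be >= 1")
        if self.area_convention not in ("agent_count", "projected"):
            raise ValueError(f"unknown area_convention {self.area_convention!r}")

    def to_mapping(self) -> dict:
        return {
            "geometry": {
                "nx": self.geometry.nx,
                "ny": self.geometry.ny,
                "nz": self.geometry.nz,
                "delta_um": self.geometry.delta,
            },
            "parameters": {
                "tau_h": self.params.tau,
                "Pm_m": self.params.Pm_m,
                "Pm_s": self.params.Pm_s,
                "Pp_m": self.params.Pp_m,
                "Pp_s": self.params.Pp_s,
                "q": self.params.q,
            },
            "initial": {"N_s0": self.N_s0, "N_m0": self.N_m0},
            "run": {
                "duration_h": self.duration_h,
                "snapshot_every_steps": self.snapshot_every_steps,
                "seed": self.seed,
            },
            "analysis": {
                "connectivity": self.connectivity,
                "min_agents": self.min_agents,
                "area_convention": self.area_convention,
            },
        }


def config_from_mapping(doc: dict) -> RunConfig:
    """Build a validated RunConfig from a nested mapping; unknown keys
    warn, a missing seed is an error."""
    if not isinstance(doc, dict):
        raise ValueError("configuration must be a mapping of blocks")
    for block in set(doc) - _KNOWN_BLOCKS:
        warnings.warn(f"ignoring unknown configuration block {block!r}")
    for block, known in _KNOWN_KEYS.items():
        sub = doc.get(block) or {}
        for key in set(sub) - known:
            warnings.warn(f"ignoring unknown key {block}.{key!r}")

    g = doc.get("geometry") or {}
    geometry = LatticeGeometry(
        nx=int(g.get("nx", 150)),
        ny=int(g.get("ny", 150)),
        nz=int(g.get("nz", 100)),
        delta=float(g.get("delta_um", 20.0)),
    )
    p = doc.get("parameters") or {}
    params = ModelParameters(
        tau=float(p.get("tau_h", 0.01)),
        delta=geometry.delta,
        Pm_m=float(p.get("Pm_m", 0.075)),
        Pm_s=float(p.get("Pm_s", 0.3)),
        Pp_m=float(p.get("Pp_m", 0.0004)),
        Pp_s=float(p.get("Pp_s", 0.00025)),
        q=float(p.get("q", 0.7)),
    )
    init = doc.get("initial") or {}
    if "skin_cells" in init or "melanoma_cells" in init:
        r = float(init.get("disc_radius_mm", 3.0))
        side = geometry.nx * geometry.delta / 1000.0
        N_s0 = density_matched_count(int(init.get("skin_cells", 0)), r, side)
        N_m0 = density_matched_count(int(init.get("melanoma_cells", 0)), r, side)
    else:
        N_s0 = int(init.get("N_s0", 9549))
        N_m0 = int(init.get("N_m0", 2706))
    r = doc.get("run") or {}
    if "seed" not in r:
        raise ValueError("run.seed is required")
    sn = r.get("snapshot_every_steps")
    a = doc.get("analysis") or {}
    return RunConfig(
        geometry=geometry,
        params=params,
        N_s0=N_s0,
        N_m0=N_m0,
        duration_h=float(r.get("duration_h", 96.0)),
        snapshot_every_steps=None if sn is None else int(sn),
        seed=int(r["seed"]),
        connectivity=int(a.get("connectivity", 26)),
        min_agents=int(a.get("min_agents", 4)),
        area_convention=str(a.get("area_convention", "agent_count")),
    )


def read_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return config_from_mapping(doc or {})


def write_config(config: RunConfig, path: str | Path) -> None:
    """Write a config that round-trips through :func:`read_config`."""
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_mapping(), fh, sort_keys=False)
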