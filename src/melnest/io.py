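"""Snapshot and result readers/writers, and the run log.

Snapshots are plain CSV, one row per agent, columns
``step, t_hours, agent_id, species, i, j, k`` (header mandatory).
Nest tables and summaries are CSV/JSON.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .engine import SimulationState
from .lattice import SPECIES_CODES, VACANT, LatticeGeometry
from .nests import NestSummary

SNAPSHOT_COLUMNS = ["step", "t_hours", "agent_id", "species", "i", "j", "k"]


def write_snapshot(state_or_df: SimulationState | pd.DataFrame, path) -> None:
    df = (
        state_or_df.to_dataframe()
        if isinstance(state_or_df, SimulationState)
        else state_or_df
    )
    df.to_csv(path, index=False, columns=SNAPSHOT_COLUMNS)


def read_snapshot(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(SNAPSHOT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"snapshot {path} lacks columns {sorted(missing)}")
    return df


def occupancy_from_snapshot(
    df: pd.DataFrame, geom: LatticeGeometry
) -> tuple[np.ndarray, np.ndarray]:
    """Rebuild the (grid, species) arrays from a snapshot table.

    Returns the agent-id grid (VACANT = -1) and the per-agent species-code
    array; raises on out-of-domain sites, duplicate occupancy or unknown
    species labels.
    """
    grid = np.full(geom.shape, VACANT, dtype=np.int32)
    species = np.empty(len(df), dtype=np.int8)
    for row, (aid, sp, i, j, k) in enumerate(
        zip(df["agent_id"], df["species"], df["i"], df["j"], df["k"])
    ):
        if sp not in SPECIES_CODES:
            raise ValueError(f"unknown species label {sp!r}")
        site = (int(i), int(j), int(k))
        if not (0 <= site[0] < geom.nx and 0 <= site[1] < geom.ny and 0 <= site[2] < geom.nz):
            raise ValueError(f"agent {aid} at out-of-domain site {site}")
        if grid[site] != VACANT:
            raise ValueError(f"two agents on site {site}")
        grid[site] = int(aid)
        species[row] = SPECIES_CODES[sp]
    return grid, species


def write_nest_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def write_summary(summary: NestSummary, path) -> None:
    with open(path, "w") as fh:
        json.dump(summary.to_dict(), fh, indent=2)


def config_hash(mapping: dict) -> str:
    """Stable digest of a configuration mapping."""
    canon = yaml.safe_dump(mapping, sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def write_run_log(
    path,
    config_mapping: dict,
    seed: int,
    tallies: dict[str, int],
    extra: dict | None = None,
) -> None:
    """Plain-text run log: config hash, seed, version, event tallies."""
    from . import __version__

    move_attempted = sum(
        v for k, v in tallies.items() if k == "moved" or k.startswith("move_")
    )
    prolif_attempted = sum(
        v
        for k, v in tallies.items()
        if k == "births" or k.startswith("proliferation_")
    )
    lines = [
        f"melnest version: {__version__}",
        f"config hash: {config_hash(config_mapping)}",
        f"seed: {seed}",
        f"motility selections: {move_attempted}",
        f"proliferation selections: {prolif_attempted}",
    ]
    lines += [f"{k}: {v}" for k, v in tallies.items()]
    for k, v in (extra or {}).items():
        lines.append(f"{k}: {v}")
    Path(path).write_text("\n".join(lines) + "\n")
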