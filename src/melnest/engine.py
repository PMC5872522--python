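"""The stochastic simulation engine.

Each discrete time step of duration tau performs two sequential phases of
a random sequential update: a motility phase then a proliferation phase.
In each phase, N agents are selected one at a time *with replacement*,
where N and the selectable agent list are frozen at phase start; daughters
born mid-phase join the registry immediately but become selectable only at
the next step.  There is no cell death.

Melanoma motility is adhesion-modified: a melanoma agent passing its
motility gate moves with additional probability (1 - q)^a, where a is the
number of melanoma agents among its 26 Moore neighbours at its current
site.  Crowded or vertically out-of-domain targets abort the event.
"""

from __future__ import annotations

import enum
import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels
from .lattice import (
    MELANOMA,
    SKIN,
    SPECIES_NAMES,
    VACANT,
    CapacityError,
    LatticeGeometry,
    OccupancyGrid,
    Site,
)
from .params import ModelParameters, derive_rates

TALLY_NAMES = (
    "moved",
    "move_aborted_gate",
    "move_aborted_adhesion",
    "move_aborted_boundary",
    "move_aborted_crowding",
    "births",
    "proliferation_aborted_gate",
    "proliferation_aborted_crowding",
)


class MoveOutcome(enum.IntEnum):
    MOVED = _kernels.MOVED
    ABORTED_GATE = _kernels.MOVE_ABORT_GATE
    ABORTED_ADHESION = _kernels.MOVE_ABORT_ADHESION
    ABORTED_BOUNDARY = _kernels.MOVE_ABORT_BOUNDARY
    ABORTED_CROWDING = _kernels.MOVE_ABORT_CROWDING


class ProliferationOutcome(enum.IntEnum):
    PLACED_DAUGHTER = _kernels.BIRTH
    ABORTED_GATE = _kernels.PROLIF_ABORT_GATE
    ABORTED_CROWDING = _kernels.PROLIF_ABORT_CROWDING


@dataclass
class SimulationState:
    """Mutable state of one realisation.

    Agent ``id`` is the index into the position/species arrays; ids are
    assigned in placement order and daughters take the next free id.
    """

    geometry: LatticeGeometry
    params: ModelParameters
    seed: int
    rng: np.random.Generator
    grid: OccupancyGrid
    n: int = 0
    t: float = 0.0
    step_count: int = 0
    _pos: np.ndarray = field(default=None, repr=False)  # (capacity, 3) int64
    _species: np.ndarray = field(default=None, repr=False)  # (capacity,) int8
    tally_array: np.ndarray = field(
        default_factory=lambda: np.zeros(_kernels.N_TALLIES, dtype=np.int64),
        repr=False,
    )

    # -- registry views ------------------------------------------------
    @property
    def positions(self) -> np.ndarray:
        """(n, 3) view of agent lattice indices."""
        return self._pos[: self.n]

    @property
    def species(self) -> np.ndarray:
        """(n,) view of agent species codes."""
        return self._species[: self.n]

    @property
    def n_melanoma(self) -> int:
        return int(np.count_nonzero(self.species == MELANOMA))

    @property
    def n_skin(self) -> int:
        return self.n - self.n_melanoma

    @property
    def tallies(self) -> dict[str, int]:
        """Cumulative per-outcome event counts since t = 0."""
        return dict(zip(TALLY_NAMES, (int(v) for v in self.tally_array)))

    def agent_site(self, agent_id: int) -> Site:
        i, j, k = self._pos[agent_id]
        return Site(int(i), int(j), int(k))

    # -- internals -----------------------------------------------------
    def _ensure_capacity(self, needed: int) -> None:
        cap = self._pos.shape[0]
        if needed <= cap:
            return
        new = min(max(2 * cap, needed), self.geometry.n_sites)
        pos = np.empty((new, 3), dtype=np.int64)
        pos[: self.n] = self._pos[: self.n]
        spc = np.empty(new, dtype=np.int8)
        spc[: self.n] = self._species[: self.n]
        self._pos = pos
        self._species = spc

    def validate(self) -> None:
        """Assert grid/registry consistency and the exclusion invariant."""
        occupied = np.argwhere(self.grid.array != VACANT)
        if len(occupied) != self.n:
            raise AssertionError(
                f"grid holds {len(occupied)} agents but registry holds {self.n}"
            )
        ids = self.grid.array[tuple(self.positions.T)]
        if not np.array_equal(np.sort(ids), np.arange(self.n)):
            raise AssertionError("grid and agent registry are inconsistent")

    def state_hash(self) -> str:
        """Digest of the full configuration (positions, species, clock)."""
        h = hashlib.sha256()
        h.update(np.int64(self.n).tobytes())
        h.update(np.float64(self.t).tobytes())
        h.update(np.ascontiguousarray(self.positions).tobytes())
        h.update(np.ascontiguousarray(self.species).tobytes())
        return h.hexdigest()

    def to_dataframe(self) -> pd.DataFrame:
        """Snapshot table: one row per agent."""
        return pd.DataFrame(
            {
                "step": self.step_count,
                "t_hours": self.t,
                "agent_id": np.arange(self.n),
                "species": [SPECIES_NAMES[s] for s in self.species],
                "i": self.positions[:, 0],
                "j": self.positions[:, 1],
                "k": self.positions[:, 2],
            }
        )


def seed_surface(
    N_s: int,
    N_m: int,
    geom: LatticeGeometry,
    params: ModelParameters | None = None,
    seed: int = 0,
) -> SimulationState:
    """Place N_s skin and N_m melanoma agents uniformly at random, without
    replacement, on the k = 0 surface layer.

    Mimics seeding cell suspensions onto the top of the skin model.  The
    combined N_s + N_m surface sites are drawn in one pass; skin agents
    take ids 0..N_s-1, melanoma agents the rest.
    """
    if N_s < 0 or N_m < 0:
        raise ValueError("agent counts must be non-negative")
    n = N_s + N_m
    if n > geom.n_surface_sites:
        raise CapacityError(
            f"{n} agents exceed the {geom.n_surface_sites} surface sites"
        )
    params = params if params is not None else ModelParameters()
    rng = np.random.default_rng(seed)
    state = SimulationState(
        geometry=geom,
        params=params,
        seed=seed,
        rng=rng,
        grid=OccupancyGrid(geom),
    )
    cap = min(max(1024, 4 * max(n, 1)), geom.n_sites)
    state._pos = np.empty((cap, 3), dtype=np.int64)
    state._species = np.empty(cap, dtype=np.int8)
    if n > 0:
        flat = rng.choice(geom.n_surface_sites, size=n, replace=False)
        ii, jj = np.divmod(flat, geom.ny)
        state._pos[:n, 0] = ii
        state._pos[:n, 1] = jj
        state._pos[:n, 2] = 0
        state._species[:N_s] = SKIN
        state._species[N_s:n] = MELANOMA
        state.grid.array[ii, jj, 0] = np.arange(n, dtype=np.int32)
    state.n = n
    return state


def state_from_agents(
    positions,
    species,
    geom: LatticeGeometry,
    params: ModelParameters | None = None,
    seed: int = 0,
) -> SimulationState:
    """Build a state from explicit agent sites and species.

    ``species`` entries may be codes (0/1) or names ("skin"/"melanoma").
    Raises on duplicate or out-of-domain sites.
    """
    codes = {v: k for k, v in SPECIES_NAMES.items()}
    spc = [codes[s] if isinstance(s, str) else int(s) for s in species]
    if len(positions) != len(spc):
        raise ValueError("positions and species must have equal length")
    params = params if params is not None else ModelParameters()
    state = SimulationState(
        geometry=geom,
        params=params,
        seed=seed,
        rng=np.random.default_rng(seed),
        grid=OccupancyGrid(geom),
    )
    n = len(spc)
    cap = min(max(1024, 4 * max(n, 1)), geom.n_sites)
    state._pos = np.empty((cap, 3), dtype=np.int64)
    state._species = np.empty(cap, dtype=np.int8)
    for aid, (site, sp) in enumerate(zip(positions, spc)):
        site = Site(*site)
        state.grid.place(aid, site)
        state._pos[aid] = site
        state._species[aid] = sp
    state.n = n
    return state


def attempt_move(state: SimulationState, agent_id: int) -> MoveOutcome:
    """Offer agent ``agent_id`` one motility event (used by the phases and
    directly by tests); updates the state in place."""
    p = state.params
    code = _kernels.try_move(
        state.grid.array,
        state._pos,
        state._species,
        agent_id,
        p.Pm_m,
        p.Pm_s,
        p.q,
        state.rng,
    )
    state.tally_array[code] += 1
    return MoveOutcome(code)


def attempt_proliferation(
    state: SimulationState, agent_id: int
) -> ProliferationOutcome:
    """Offer agent ``agent_id`` one proliferation event; a daughter of the
    same species takes the next free id."""
    state._ensure_capacity(state.n + 1)
    p = state.params
    code, n_total = _kernels.try_proliferate(
        state.grid.array,
        state._pos,
        state._species,
        agent_id,
        state.n,
        p.Pp_m,
        p.Pp_s,
        state.rng,
    )
    state.n = n_total
    state.tally_array[5 + code] += 1
    return ProliferationOutcome(code)


def motility_phase(state: SimulationState) -> SimulationState:
    """N selections with replacement, each offered a move; N frozen at
    phase start."""
    p = state.params
    _kernels.motility_phase(
        state.grid.array,
        state._pos,
        state._species,
        state.n,
        p.Pm_m,
        p.Pm_s,
        p.q,
        state.rng,
        state.tally_array,
    )
    return state


def proliferation_phase(state: SimulationState) -> SimulationState:
    """N selections with replacement, each offered a proliferation event;
    at most N daughters can be born, so capacity is reserved up front."""
    state._ensure_capacity(min(2 * state.n, state.geometry.n_sites))
    p = state.params
    state.n = _kernels.proliferation_phase(
        state.grid.array,
        state._pos,
        state._species,
        state.n,
        p.Pp_m,
        p.Pp_s,
        state.rng,
        state.tally_array,
    )
    return state


def step(state: SimulationState, n_steps: int = 1) -> SimulationState:
    """Advance the simulation by ``n_steps`` time steps of duration tau."""
    for _ in range(n_steps):
        motility_phase(state)
        proliferation_phase(state)
        state.t += state.params.tau
        state.step_count += 1
    return state


def run(
    state: SimulationState,
    duration_h: float,
    snapshot_every_steps: int | None = None,
) -> list[pd.DataFrame]:
    """Run until t = duration_h (rounded to whole steps) and return the
    scheduled snapshots; the final state is always snapshotted."""
    total = int(round(duration_h / state.params.tau))
    snapshots: list[pd.DataFrame] = []
    if snapshot_every_steps is not None and snapshot_every_steps < 1:
        raise ValueError("snapshot_every_steps must be >= 1")
    remaining = total - state.step_count
    for s in range(1, remaining + 1):
        step(state)
        if (
            snapshot_every_steps is not None
            and state.step_count % snapshot_every_steps == 0
            and s != remaining
        ):
            snapshots.append(state.to_dataframe())
    snapshots.append(state.to_dataframe())
    return snapshots


def measure_msd(
    params: ModelParameters,
    t_hours: float = 10.0,
    n_walkers: int = 10_000,
    seed: int = 0,
    geom: LatticeGeometry | None = None,
) -> dict[str, float]:
    """Mean squared displacement of independent single-agent walks.

    Runs ``n_walkers`` lone melanoma agents (a = 0 throughout, so adhesion
    is inert) through the real motility kernel on an empty lattice and
    compares the measured MSD with the isotropic-diffusion prediction
    MSD = 6 D t, D = Pm * delta^2 / (6 tau).
    """
    geom = geom or LatticeGeometry(41, 41, 41, params.delta)
    n_steps = int(round(t_hours / params.tau))
    rng = np.random.default_rng(seed)
    msd_sites = _kernels.msd_single_walkers(
        n_walkers,
        n_steps,
        params.Pm_m,
        params.q,
        geom.nx,
        geom.ny,
        geom.nz,
        geom.nx // 2,
        geom.ny // 2,
        geom.nz // 2,
        rng,
    )
    msd_um2 = msd_sites * params.delta**2
    predicted = 6.0 * derive_rates(params).D_m * t_hours
    return {
        "msd_um2": msd_um2,
        "predicted_um2": predicted,
        "ratio": msd_um2 / predicted if predicted > 0 else float("nan"),
        "n_walkers": n_walkers,
        "t_hours": t_hours,
    }
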