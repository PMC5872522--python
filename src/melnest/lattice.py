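"""3D lattice geometry, neighbourhoods and exclusion-constrained occupancy.

The simulation domain is a regular cubic lattice representing the central
region of a 3D skin-equivalent culture.  Lateral (x, y) boundaries are
periodic; the top (k = 0, the seeding surface) and bottom (k = nz - 1)
boundaries are no-flux.  Each site holds at most one agent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

#: Species codes used throughout the package.
SKIN = 0
MELANOMA = 1
SPECIES_NAMES = {SKIN: "skin", MELANOMA: "melanoma"}
SPECIES_CODES = {v: k for k, v in SPECIES_NAMES.items()}

#: Sentinel for an unoccupied lattice site.
VACANT = -1

#: von Neumann direction table (dx, dy, dz); the order is part of the
#: engine's documented random-draw sequence.
VON_NEUMANN_DIRECTIONS = (
    (1, 0, 0),
    (-1, 0, 0),
    (0, 1, 0),
    (0, -1, 0),
    (0, 0, 1),
    (0, 0, -1),
)

_MOORE_OFFSETS = tuple(
    (di, dj, dk)
    for di in (-1, 0, 1)
    for dj in (-1, 0, 1)
    for dk in (-1, 0, 1)
    if not (di == 0 and dj == 0 and dk == 0)
)


class DomainError(ValueError):
    """A site lies outside the lattice domain."""


class ExclusionError(ValueError):
    """An operation would place two agents on one site."""


class CapacityError(ValueError):
    """More agents requested than the lattice (or surface) can hold."""


class Site(NamedTuple):
    """Integer lattice indices. k = 0 is the top (seeding) surface; k
    increases downward into the tissue."""

    i: int
    j: int
    k: int


@dataclass(frozen=True)
class LatticeGeometry:
    """Dimensions and spacing of the simulation lattice.

    Parameters
    ----------
    nx, ny : int
        Lateral site counts (periodic directions).
    nz : int
        Depth site count (no-flux direction).
    delta : float
        Lattice spacing in micrometres; also the nominal agent diameter.

    The default geometry, 150 x 150 x 100 sites at 20 um spacing, spans
    3 mm x 3 mm laterally and 2 mm in depth.
    """

    nx: int = 150
    ny: int = 150
    nz: int = 100
    delta: float = 20.0

    def __post_init__(self) -> None:
        if self.nx < 1 or self.ny < 1 or self.nz < 1:
            raise ValueError("lattice dimensions must be >= 1")
        if not self.delta > 0:
            raise ValueError("lattice spacing delta must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.nx, self.ny, self.nz)

    @property
    def n_sites(self) -> int:
        return self.nx * self.ny * self.nz

    @property
    def n_surface_sites(self) -> int:
        return self.nx * self.ny

    @property
    def extent_um(self) -> tuple[float, float, float]:
        """Physical extent (x, y, z) in micrometres."""
        return (self.nx * self.delta, self.ny * self.delta, self.nz * self.delta)

    def contains(self, site: Site) -> bool:
        i, j, k = site
        return 0 <= i < self.nx and 0 <= j < self.ny and 0 <= k < self.nz

    def wrap(self, i: int, j: int, k: int) -> Site:
        """Wrap lateral indices periodically; k is left untouched."""
        return Site(i % self.nx, j % self.ny, k)

    def require(self, site: Site) -> None:
        if not self.contains(site):
            raise DomainError(f"site {tuple(site)} outside lattice {self.shape}")


def von_neumann_neighbors(site: Site, geom: LatticeGeometry) -> list[Site]:
    """The <= 6 axis-adjacent in-domain sites of ``site``.

    Lateral neighbours wrap periodically; vertical neighbours beyond the
    top or bottom layer are dropped.  On degenerate lattices (a dimension
    of size 1 or 2) wrapped duplicates and the centre site are removed.
    """
    geom.require(site)
    out: list[Site] = []
    seen = set()
    for di, dj, dk in VON_NEUMANN_DIRECTIONS:
        k = site.k + dk
        if k < 0 or k >= geom.nz:
            continue
        nb = geom.wrap(site.i + di, site.j + dj, k)
        if nb == site or nb in seen:
            continue
        seen.add(nb)
        out.append(nb)
    return out


def moore_neighbors(site: Site, geom: LatticeGeometry) -> list[Site]:
    """The <= 26 surrounding in-domain sites (full 3x3x3 shell minus centre),
    laterally wrapped and vertically clipped, with no duplicates."""
    geom.require(site)
    out: list[Site] = []
    seen = set()
    for di, dj, dk in _MOORE_OFFSETS:
        k = site.k + dk
        if k < 0 or k >= geom.nz:
            continue
        nb = geom.wrap(site.i + di, site.j + dj, k)
        if nb == site or nb in seen:
            continue
        seen.add(nb)
        out.append(nb)
    return out


class OccupancyGrid:
    """Mapping from lattice sites to agent identifiers with volume exclusion.

    Backed by an ``int32`` array storing the agent id at each site
    (``VACANT`` = -1 where empty); this array is shared directly with the
    compiled simulation kernels.
    """

    def __init__(self, geometry: LatticeGeometry):
        self.geometry = geometry
        self.array = np.full(geometry.shape, VACANT, dtype=np.int32)

    def occupant(self, site: Site) -> int | None:
        self.geometry.require(site)
        v = int(self.array[site])
        return None if v == VACANT else v

    def is_vacant(self, site: Site) -> bool:
        return self.occupant(site) is None

    @property
    def n_occupied(self) -> int:
        return int(np.count_nonzero(self.array != VACANT))

    def place(self, agent_id: int, site: Site) -> None:
        """Place ``agent_id`` on a vacant in-domain site."""
        self.geometry.require(site)
        if self.array[site] != VACANT:
            raise ExclusionError(
                f"site {tuple(site)} already holds agent {int(self.array[site])}"
            )
        self.array[site] = agent_id

    def remove(self, site: Site) -> int:
        self.geometry.require(site)
        v = int(self.array[site])
        if v == VACANT:
            raise ValueError(f"site {tuple(site)} is vacant")
        self.array[site] = VACANT
        return v

    def move(self, source: Site, target: Site) -> None:
        """Atomically move the occupant of ``source`` to vacant ``target``."""
        self.geometry.require(source)
        self.geometry.require(target)
        v = int(self.array[source])
        if v == VACANT:
            raise ValueError(f"source {tuple(source)} is vacant")
        if self.array[target] != VACANT:
            raise ExclusionError(f"target {tuple(target)} is occupied")
        self.array[target] = v
        self.array[source] = VACANT


def count_melanoma_neighbors(
    grid: OccupancyGrid, species: np.ndarray, site: Site
) -> int:
    """Number of Moore-neighbour sites occupied by melanoma agents.

    ``species`` maps agent id -> species code; skin occupants never
    contribute.  This is the adhesion contact count *a* in the motility
    modifier (1 - q)^a.
    """
    a = 0
    for nb in moore_neighbors(site, grid.geometry):
        occ = grid.array[nb]
        if occ != VACANT and species[occ] == MELANOMA:
            a += 1
    return a
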