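"""Compiled inner loops of the random sequential update.

All kernels operate on raw arrays shared with the Python-level state:
``grid[i, j, k]`` holds the agent id (-1 vacant), ``pos[id]`` the (i, j, k)
indices, ``species[id]`` the species code (0 skin, 1 melanoma).  Every
random draw comes from the single ``numpy.random.Generator`` owned by the
simulation, in a fixed order (see docstrings), so runs are bit-reproducible
for a given seed.

Boundary conventions: lateral indices wrap periodically; a move drawing a
vertically out-of-domain direction is an aborted event (not a re-draw),
which is required for D = P_m * delta^2 / (6 tau) to hold on an empty
lattice.
"""

import numpy as np
from numba import njit

# Motility outcome codes (= tally indices 0-4).
MOVED = 0
MOVE_ABORT_GATE = 1
MOVE_ABORT_ADHESION = 2
MOVE_ABORT_BOUNDARY = 3
MOVE_ABORT_CROWDING = 4
# Proliferation outcome codes (tally index = 5 + code).
BIRTH = 0
PROLIF_ABORT_GATE = 1
PROLIF_ABORT_CROWDING = 2

N_TALLIES = 8

# von Neumann direction table; order matches lattice.VON_NEUMANN_DIRECTIONS.
_DI = np.array([1, -1, 0, 0, 0, 0], dtype=np.int64)
_DJ = np.array([0, 0, 1, -1, 0, 0], dtype=np.int64)
_DK = np.array([0, 0, 0, 0, 1, -1], dtype=np.int64)


@njit(cache=True)
def moore_melanoma_count(grid, species, i, j, k):
    """Adhesion contact count a: melanoma occupants of the 26-site Moore
    shell, laterally wrapped, vertically clipped."""
    nx, ny, nz = grid.shape
    a = 0
    for di in range(-1, 2):
        ii = (i + di) % nx
        for dj in range(-1, 2):
            jj = (j + dj) % ny
            for dk in range(-1, 2):
                if di == 0 and dj == 0 and dk == 0:
                    continue
                kk = k + dk
                if kk < 0 or kk >= nz:
                    continue
                occ = grid[ii, jj, kk]
                if occ >= 0 and species[occ] == 1:
                    a += 1
    return a


@njit(cache=True)
def try_move(grid, pos, species, idx, Pm_m, Pm_s, q, rng):
    """One motility attempt for agent ``idx``.

    Draw order: motility gate; (melanoma only) adhesion gate against
    (1 - q)^a with a evaluated at the current site; direction uniform
    over the six von Neumann directions.  The move executes only if the
    target is vertically in-domain and vacant.
    """
    i = pos[idx, 0]
    j = pos[idx, 1]
    k = pos[idx, 2]
    mel = species[idx] == 1
    pm = Pm_m if mel else Pm_s
    if rng.random() >= pm:
        return MOVE_ABORT_GATE
    if mel:
        a = moore_melanoma_count(grid, species, i, j, k)
        if a > 0 and rng.random() >= (1.0 - q) ** a:
            return MOVE_ABORT_ADHESION
    d = int(rng.random() * 6.0)
    nx, ny, nz = grid.shape
    kk = k + _DK[d]
    if kk < 0 or kk >= nz:
        return MOVE_ABORT_BOUNDARY
    ii = (i + _DI[d]) % nx
    jj = (j + _DJ[d]) % ny
    if grid[ii, jj, kk] >= 0:
        return MOVE_ABORT_CROWDING
    grid[i, j, k] = -1
    grid[ii, jj, kk] = idx
    pos[idx, 0] = ii
    pos[idx, 1] = jj
    pos[idx, 2] = kk
    return MOVED


@njit(cache=True)
def try_proliferate(grid, pos, species, idx, n_total, Pp_m, Pp_s, rng):
    """One proliferation attempt for agent ``idx``.

    On passing the gate, the daughter (same species, id ``n_total``) is
    placed uniformly at random among the vacant in-domain von Neumann
    sites; the event is aborted only when none is vacant.
    """
    pp = Pp_m if species[idx] == 1 else Pp_s
    if rng.random() >= pp:
        return PROLIF_ABORT_GATE, n_total
    nx, ny, nz = grid.shape
    i = pos[idx, 0]
    j = pos[idx, 1]
    k = pos[idx, 2]
    ti = np.empty(6, dtype=np.int64)
    tj = np.empty(6, dtype=np.int64)
    tk = np.empty(6, dtype=np.int64)
    v = 0
    for d in range(6):
        kk = k + _DK[d]
        if kk < 0 or kk >= nz:
            continue
        ii = (i + _DI[d]) % nx
        jj = (j + _DJ[d]) % ny
        if grid[ii, jj, kk] < 0:
            ti[v] = ii
            tj[v] = jj
            tk[v] = kk
            v += 1
    if v == 0:
        return PROLIF_ABORT_CROWDING, n_total
    c = int(rng.random() * v)
    grid[ti[c], tj[c], tk[c]] = n_total
    pos[n_total, 0] = ti[c]
    pos[n_total, 1] = tj[c]
    pos[n_total, 2] = tk[c]
    species[n_total] = species[idx]
    return BIRTH, n_total + 1


@njit(cache=True)
def motility_phase(grid, pos, species, n, Pm_m, Pm_s, q, rng, tallies):
    """Phase 1: n selections with replacement from the n agents present at
    phase start, each offered a motility event."""
    for _ in range(n):
        idx = int(rng.random() * n)
        code = try_move(grid, pos, species, idx, Pm_m, Pm_s, q, rng)
        tallies[code] += 1


@njit(cache=True)
def proliferation_phase(grid, pos, species, n, Pp_m, Pp_s, rng, tallies):
    """Phase 2: n selections with replacement from the n agents present at
    phase start.  Daughters enter the registry immediately (ids >= n) but
    cannot be selected until the next step.  Returns the new agent count."""
    n_total = n
    for _ in range(n):
        idx = int(rng.random() * n)
        code, n_total = try_proliferate(
            grid, pos, species, idx, n_total, Pp_m, Pp_s, rng
        )
        tallies[5 + code] += 1
    return n_total


@njit(cache=True)
def msd_single_walkers(n_walkers, n_steps, Pm, q, nx, ny, nz, i0, j0, k0, rng):
    """Mean squared displacement (site^2 units) of independent single-agent
    walks through the real motility kernel on an otherwise empty lattice.

    Per-step displacements are unwrapped by minimal image, valid while a
    walk never travels half a lattice width between steps (always true:
    one site per step)."""
    grid = np.full((nx, ny, nz), -1, dtype=np.int32)
    pos = np.empty((1, 3), dtype=np.int64)
    species = np.ones(1, dtype=np.int8)  # melanoma path; a = 0 throughout
    total = 0.0
    for _ in range(n_walkers):
        pos[0, 0] = i0
        pos[0, 1] = j0
        pos[0, 2] = k0
        grid[i0, j0, k0] = 0
        dx = 0
        dy = 0
        dz = 0
        for _s in range(n_steps):
            oi = pos[0, 0]
            oj = pos[0, 1]
            ok = pos[0, 2]
            code = try_move(grid, pos, species, 0, Pm, Pm, q, rng)
            if code == MOVED:
                di = pos[0, 0] - oi
                if di > nx // 2:
                    di -= nx
                elif di < -(nx // 2):
                    di += nx
                dj = pos[0, 1] - oj
                if dj > ny // 2:
                    dj -= ny
                elif dj < -(ny // 2):
                    dj += ny
                dx += di
                dy += dj
                dz += pos[0, 2] - ok
        total += dx * dx + dy * dy + dz * dz
        grid[pos[0, 0], pos[0, 1], pos[0, 2]] = -1
    return total / n_walkers
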