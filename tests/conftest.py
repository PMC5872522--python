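import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def small_geom():
    from melnest import LatticeGeometry

    return LatticeGeometry(20, 20, 15, 20.0)


def flood_fill_components(occupied, shape, connectivity, periodic=True):
    """Brute-force BFS connected components on the (optionally laterally
    periodic) lattice; independent oracle for the labelling pipeline.

    ``occupied`` is a set of (i, j, k) tuples; returns a set of frozensets.
    """
    nx, ny, nz = shape
    if connectivity == 26:
        offs = [
            (a, b, c)
            for a in (-1, 0, 1)
            for b in (-1, 0, 1)
            for c in (-1, 0, 1)
            if (a, b, c) != (0, 0, 0)
        ]
    else:
        offs = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    remaining = set(occupied)
    comps = []
    while remaining:
        seed_site = remaining.pop()
        comp = {seed_site}
        queue = [seed_site]
        while queue:
            i, j, k = queue.pop()
            for a, b, c in offs:
                kk = k + c
                if kk < 0 or kk >= nz:
                    continue
                if periodic:
                    nb = ((i + a) % nx, (j + b) % ny, kk)
                else:
                    ii, jj = i + a, j + b
                    if not (0 <= ii < nx and 0 <= jj < ny):
                        continue
                    nb = (ii, jj, kk)
                if nb in remaining:
                    remaining.remove(nb)
                    comp.add(nb)
                    queue.append(nb)
        comps.append(frozenset(comp))
    return set(comps)


def labels_to_components(labels):
    """Convert a label array to a set of frozensets of site tuples."""
    comps = {}
    for site in np.argwhere(labels > 0):
        comps.setdefault(int(labels[tuple(site)]), set()).add(tuple(site))
    return {frozenset(s) for s in comps.values()}
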