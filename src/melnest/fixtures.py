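"""Deterministic constructed agent configurations for tests and demos.

Each fixture is a small hand-placed arrangement exercising one rule of
the model or the nest pipeline (all synthetic; none derives from data):

- ``two_blocks``          two 2x2x2 melanoma cubes separated by vacant
                          space in every axis -> two 8-agent nests;
- ``diagonal_pair``       two melanoma agents touching only diagonally
                          -> one nest under 26-connectivity, two under 6;
- ``triplet_and_quad``    components of size 3 and 4 for the minimum-size
                          filter;
- ``enclosed_agent``      a melanoma agent with all 26 Moore neighbours
                          melanoma (adhesion count a = 26);
- ``mixed_neighbourhood`` a melanoma agent with 2 melanoma and 3 skin
                          Moore neighbours (a = 2: skin never counts).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .lattice import LatticeGeometry

FIXTURE_NAMES = (
    "two_blocks",
    "diagonal_pair",
    "triplet_and_quad",
    "enclosed_agent",
    "mixed_neighbourhood",
)


@dataclass(frozen=True)
class Fixture:
    name: str
    geometry: LatticeGeometry
    snapshot: pd.DataFrame
    focus: tuple[int, int, int] | None = None  #: the probed site, if any


def _snapshot(melanoma, skin=()):
    rows = []
    for aid, (i, j, k) in enumerate(list(skin) + list(melanoma)):
        rows.append(
            {
                "step": 0,
                "t_hours": 0.0,
                "agent_id": aid,
                "species": "skin" if aid < len(skin) else "melanoma",
                "i": i,
                "j": j,
                "k": k,
            }
        )
    return pd.DataFrame(
        rows, columns=["step", "t_hours", "agent_id", "species", "i", "j", "k"]
    )


def make_fixture(name: str) -> Fixture:
    geom = LatticeGeometry(14, 14, 10, 20.0)
    if name == "two_blocks":
        block = lambda oi, oj, ok: [
            (oi + a, oj + b, ok + c) for a in (0, 1) for b in (0, 1) for c in (0, 1)
        ]
        mel = block(2, 2, 2) + block(8, 8, 5)
        return Fixture(name, geom, _snapshot(mel))
    if name == "diagonal_pair":
        return Fixture(name, geom, _snapshot([(3, 3, 3), (4, 4, 4)]))
    if name == "triplet_and_quad":
        mel = [(2, 2, 2), (3, 2, 2), (4, 2, 2)]  # 3-agent line
        mel += [(9, 9, 5), (10, 9, 5), (9, 10, 5), (9, 9, 6)]  # 4-agent cluster
        return Fixture(name, geom, _snapshot(mel))
    if name == "enclosed_agent":
        c = (6, 6, 5)
        mel = [
            (c[0] + a, c[1] + b, c[2] + d)
            for a in (-1, 0, 1)
            for b in (-1, 0, 1)
            for d in (-1, 0, 1)
        ]
        return Fixture(name, geom, _snapshot(mel), focus=c)
    if name == "mixed_neighbourhood":
        c = (6, 6, 5)
        mel = [c, (7, 6, 5), (5, 5, 4)]
        skin = [(6, 7, 5), (6, 6, 4), (7, 7, 6)]
        return Fixture(name, geom, _snapshot(mel, skin), focus=c)
    raise ValueError(f"unknown fixture {name!r}; known: {FIXTURE_NAMES}")
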