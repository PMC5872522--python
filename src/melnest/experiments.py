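"""Scenario definitions and replicate runners.

The co-culture experiment seeds skin and melanoma cell suspensions onto
the skin surface and cultures for four days.  Four simulated conditions
are predefined:

- ``baseline``            — default co-culture parameters;
- ``no_melanoma_proliferation`` — melanoma proliferation suppressed
  (Pp_m = 0), the in-silico analogue of gamma-irradiated melanoma cells;
- ``half_proliferation``  — melanoma proliferation probability halved;
- ``half_adhesion``       — melanoma adhesion strength halved (q = 0.35).

Initial agent counts are expressed on the reference 3 mm x 3 mm surface
(150 x 150 sites) and scaled with lateral area for reduced geometries, so
the initial surface density is preserved.  The default run geometry is a
density-matched 75 x 75 x 60 lattice that keeps replicate batteries fast;
the full 150 x 150 x 100 reference domain is available by passing it
explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import run, seed_surface
from .lattice import LatticeGeometry
from .nests import NestSummary, find_nests, summarize
from .params import BASELINE_PARAMETERS, ModelParameters, density_matched_count

#: Full-size reference domain: 3 mm x 3 mm x 2 mm at 20 um spacing.
REFERENCE_GEOMETRY = LatticeGeometry(150, 150, 100, 20.0)
#: Default reduced domain for replicate batteries (same density, 1/4 area).
REDUCED_GEOMETRY = LatticeGeometry(75, 75, 60, 20.0)

#: Cells seeded in the wet-lab protocol (inside a 3 mm radius disc).
SKIN_CELLS_SEEDED = 30_000
MELANOMA_CELLS_SEEDED = (1250, 5000, 8500)

#: Density-matched agent counts on the reference surface.
N_S0_REFERENCE = density_matched_count(SKIN_CELLS_SEEDED)  # 9549
N_M0_REFERENCE = tuple(density_matched_count(n) for n in MELANOMA_CELLS_SEEDED)

#: Named parameter overrides relative to the baseline.
SCENARIOS: dict[str, dict[str, float]] = {
    "baseline": {},
    "no_melanoma_proliferation": {"Pp_m": 0.0},
    "half_proliferation": {"Pp_m": BASELINE_PARAMETERS.Pp_m / 2},
    "half_adhesion": {"q": BASELINE_PARAMETERS.q / 2},
}


def scale_count(
    n_reference: int,
    geom: LatticeGeometry,
    reference: LatticeGeometry = REFERENCE_GEOMETRY,
) -> int:
    """Scale a reference-surface agent count to ``geom``'s lateral area so
    the initial surface density is preserved (nearest integer)."""
    frac = (geom.nx * geom.ny) / (reference.nx * reference.ny)
    return int(round(n_reference * frac))


def replicate_seeds(base_seed: int, n: int) -> list[int]:
    """Deterministic per-replicate seeds (< 2^31) derived from one seed."""
    ss = np.random.SeedSequence(base_seed)
    return [int(s >> 1) for s in ss.generate_state(n, dtype=np.uint32)]


@dataclass(frozen=True)
class ScenarioSpec:
    """One simulated condition.

    ``N_m0`` is the initial melanoma count on the *reference* surface
    (398, 1592 or 2706 for the three experimental seeding densities);
    the runner rescales it, together with the skin count, to the actual
    geometry.  Extra ``overrides`` stack on top of the named scenario's.
    """

    name: str = "baseline"
    N_m0: int = 2706
    N_s0: int = N_S0_REFERENCE
    replicates: int = 5
    seeds: tuple[int, ...] | None = None
    duration_h: float = 96.0
    overrides: dict = field(default_factory=dict)
    connectivity: int = 26
    min_agents: int = 4
    area_convention: str = "agent_count"

    def __post_init__(self) -> None:
        if self.name not in SCENARIOS and self.name != "custom":
            raise ValueError(
                f"unknown scenario {self.name!r}; known: {sorted(SCENARIOS)}"
            )
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    def parameters(self) -> ModelParameters:
        ov = dict(SCENARIOS.get(self.name, {}))
        ov.update(self.overrides)
        return BASELINE_PARAMETERS.replace(**ov)


@dataclass
class ExperimentResult:
    """Per-condition output: one nest table and summary per replicate."""

    spec: ScenarioSpec
    geometry: LatticeGeometry
    params: ModelParameters
    seeds: list[int]
    nest_tables: list[pd.DataFrame]
    summaries: list[NestSummary]
    final_counts: list[tuple[int, int]]  # (n_skin, n_melanoma) per replicate
    final_snapshots: list[pd.DataFrame] | None = None  # kept on request

    @property
    def pooled_areas(self) -> np.ndarray:
        """All filtered nest areas (um^2) pooled across replicates."""
        if not self.nest_tables:
            return np.array([])
        return np.concatenate(
            [t["area_um2"].to_numpy() for t in self.nest_tables]
        )

    @property
    def pooled_summary(self) -> NestSummary:
        return summarize(self.pooled_areas)


def run_scenario(
    spec: ScenarioSpec,
    geom: LatticeGeometry = REDUCED_GEOMETRY,
    base_seed: int = 0,
    keep_snapshots: bool = False,
) -> ExperimentResult:
    """Run a scenario's replicates for ``spec.duration_h`` (default four
    days) and quantify nests in the final snapshot of each replicate.

    ``keep_snapshots`` retains the final agent tables so alternative nest
    quantifications can be applied without re-simulating."""
    params = spec.parameters()
    seeds = (
        list(spec.seeds)
        if spec.seeds is not None
        else replicate_seeds(base_seed, spec.replicates)
    )
    n_s0 = scale_count(spec.N_s0, geom)
    n_m0 = scale_count(spec.N_m0, geom)
    tables, summaries, counts = [], [], []
    snapshots: list[pd.DataFrame] | None = [] if keep_snapshots else None
    for sd in seeds:
        state = seed_surface(n_s0, n_m0, geom, params, seed=sd)
        run(state, spec.duration_h)
        table = find_nests(
            state,
            geom,
            connectivity=spec.connectivity,
            min_agents=spec.min_agents,
            area_convention=spec.area_convention,
        )
        tables.append(table)
        summaries.append(summarize(table["area_um2"]))
        counts.append((state.n_skin, state.n_melanoma))
        if snapshots is not None:
            snapshots.append(state.to_dataframe())
    return ExperimentResult(
        spec=spec,
        geometry=geom,
        params=params,
        seeds=seeds,
        nest_tables=tables,
        summaries=summaries,
        final_counts=counts,
        final_snapshots=snapshots,
    )


@dataclass(frozen=True)
class FoldChange:
    """Ratio of pooled median nest areas with a percentile bootstrap CI."""

    fold: float
    ci_low: float
    ci_high: float
    median_a: float
    median_b: float
    n_boot: int


def compare_scenarios(
    result_a: ExperimentResult,
    result_b: ExperimentResult,
    n_boot: int = 1000,
    seed: int = 0,
) -> FoldChange:
    """Fold change median(a) / median(b) of pooled nest areas, with a
    seeded percentile bootstrap (resampling areas within each condition)."""
    a = result_a.pooled_areas
    b = result_b.pooled_areas
    if a.size == 0 or b.size == 0:
        raise ValueError(
            "cannot form a median-area ratio: at least one condition has no "
            "nests after filtering"
        )
    med_a, med_b = float(np.median(a)), float(np.median(b))
    rng = np.random.default_rng(seed)
    folds = np.empty(n_boot)
    for i in range(n_boot):
        ra = np.median(rng.choice(a, size=a.size, replace=True))
        rb = np.median(rng.choice(b, size=b.size, replace=True))
        folds[i] = ra / rb
    lo, hi = np.percentile(folds, [2.5, 97.5])
    return FoldChange(
        fold=med_a / med_b,
        ci_low=float(lo),
        ci_high=float(hi),
        median_a=med_a,
        median_b=med_b,
        n_boot=n_boot,
    )
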