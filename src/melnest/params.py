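"""Model parameters and the probability <-> rate conversions.

The discrete model is parameterised by per-step event probabilities; these
map onto continuum cell-level quantities via

    lambda = P_p / tau          (proliferation rate, per hour)
    D      = P_m * delta^2 / (6 * tau)   (cell diffusivity, um^2 per hour)

where tau is the time-step duration and delta the lattice spacing.  The
default parameter set describes SK-MEL-28 melanoma cells co-cultured with
primary skin (keratinocyte/fibroblast) cells: melanoma agents are slower
and more proliferative than skin agents and adhere to each other with
strength q.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass


@dataclass(frozen=True)
class ModelParameters:
    """Per-step probabilities and discretisation of the lattice model.

    Attributes
    ----------
    tau : float
        Time-step duration, hours.
    delta : float
        Lattice spacing, micrometres.
    Pm_m, Pm_s : float
        Per-selection motility probabilities (melanoma, skin).
    Pp_m, Pp_s : float
        Per-selection proliferation probabilities (melanoma, skin).
    q : float
        Melanoma-melanoma adhesion strength in [0, 1]; a potentially
        motile melanoma agent with ``a`` melanoma Moore neighbours moves
        with additional probability (1 - q)^a.  q = 0 disables adhesion;
        q = 1 immobilises any melanoma agent in contact with another.
    """

    tau: float = 0.01
    delta: float = 20.0
    Pm_m: float = 0.075
    Pm_s: float = 0.3
    Pp_m: float = 0.0004
    Pp_s: float = 0.00025
    q: float = 0.7

    def __post_init__(self) -> None:
        if not self.tau > 0:
            raise ValueError("tau must be positive")
        if not self.delta > 0:
            raise ValueError("delta must be positive")
        for name in ("Pm_m", "Pm_s", "Pp_m", "Pp_s", "q"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")

    def replace(self, **overrides: float) -> "ModelParameters":
        return dataclasses.replace(self, **overrides)


#: The default co-culture parameter set (see module docstring).
BASELINE_PARAMETERS = ModelParameters()


@dataclass(frozen=True)
class DerivedRates:
    """Continuum cell-level rates implied by a :class:`ModelParameters`."""

    lambda_m: float  #: melanoma proliferation rate, 1/h
    lambda_s: float  #: skin proliferation rate, 1/h
    D_m: float  #: melanoma diffusivity, um^2/h
    D_s: float  #: skin diffusivity, um^2/h


def derive_rates(params: ModelParameters) -> DerivedRates:
    """Convert per-step probabilities into proliferation rates and
    diffusivities (exact arithmetic, see module docstring)."""
    f = params.delta**2 / (6.0 * params.tau)
    return DerivedRates(
        lambda_m=params.Pp_m / params.tau,
        lambda_s=params.Pp_s / params.tau,
        D_m=params.Pm_m * f,
        D_s=params.Pm_s * f,
    )


def probs_from_rates(
    rates: DerivedRates, tau: float, delta: float, q: float = 0.7
) -> ModelParameters:
    """Inverse of :func:`derive_rates` at the given discretisation.

    Satisfies ``probs_from_rates(derive_rates(p), p.tau, p.delta, p.q) == p``
    exactly for representable inputs.
    """
    f = delta**2 / (6.0 * tau)
    return ModelParameters(
        tau=tau,
        delta=delta,
        Pm_m=rates.D_m / f,
        Pm_s=rates.D_s / f,
        Pp_m=rates.lambda_m * tau,
        Pp_s=rates.lambda_s * tau,
        q=q,
    )


def adhesion_modifier(q: float, a: int) -> float:
    """The melanoma motility modifier (1 - q)^a.

    ``a`` is the number of melanoma agents among the 26 Moore neighbours.
    Equals 1 when a = 0 regardless of q (0^0 is taken as 1).
    """
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"q must lie in [0, 1], got {q}")
    if not 0 <= a <= 26:
        raise ValueError(f"melanoma neighbour count a must lie in [0, 26], got {a}")
    if a == 0:
        return 1.0
    return (1.0 - q) ** a


def density_matched_count(
    n_cells: int, r_disc_mm: float = 3.0, side_mm: float = 3.0
) -> int:
    """Agent count matching the areal density of ``n_cells`` seeded in a disc.

    Experimentally, cells are pipetted inside a ring of radius ``r_disc_mm``;
    the simulation seeds a square of side ``side_mm``.  The density-matched
    count is ``n_cells * side^2 / (pi * r^2)``, rounded half away from zero.
    With the default 3 mm disc and 3 mm square this is ``n / pi``:
    30000 skin cells -> 9549 agents; 1250/5000/8500 melanoma cells ->
    398/1592/2706 agents.
    """
    if n_cells < 0:
        raise ValueError("n_cells must be non-negative")
    if not (r_disc_mm > 0 and side_mm > 0):
        raise ValueError("disc radius and square side must be positive")
    x = n_cells * side_mm**2 / (math.pi * r_disc_mm**2)
    return int(math.floor(x + 0.5))
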