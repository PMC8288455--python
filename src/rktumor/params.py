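"""Life-history and interaction parameters for two competing cell phenotypes.

The two phenotypes are the classical density-dependent selection strategists:
``r`` cells (high intrinsic growth rate, poor performance in crowded
conditions) and ``K`` cells (slower growth, high carrying capacity and
tolerance of crowding).  All rates are per hour; capacities are cell counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

__all__ = [
    "PhenotypeParams",
    "InteractionParams",
    "PopulationState",
    "Trajectory",
    "default_r_params",
    "default_k_params",
]


@dataclass(frozen=True)
class PhenotypeParams:
    """Per-phenotype life-history parameters.

    Parameters
    ----------
    label :
        ``"r"`` or ``"K"``.
    intrinsic_rate :
        Net per-capita growth rate at vanishing density (per hour); the
        classical ``r_i``.
    carrying_capacity :
        Population size at which net growth is zero (cells); the classical
        ``K_i``.
    baseline_death :
        Density-independent death rate (per hour).  In the deterministic
        model this is part of the turnover hidden inside ``intrinsic_rate``;
        the stochastic and spatial simulators use it explicitly.
    density_death_coef :
        Extra death rate at full local crowding (per hour); used by the
        spatial model only.
    motility :
        Migration attempt rate (per hour); used by the spatial model only.
    """

    label: Literal["r", "K"]
    intrinsic_rate: float
    carrying_capacity: float
    baseline_death: float = 0.0
    density_death_coef: float = 0.0
    motility: float = 0.0

    def __post_init__(self) -> None:
        if self.label not in ("r", "K"):
            raise ValueError(f"label must be 'r' or 'K', got {self.label!r}")
        if not (self.intrinsic_rate > 0 and math.isfinite(self.intrinsic_rate)):
            raise ValueError(f"intrinsic_rate must be positive, got {self.intrinsic_rate}")
        if not (self.carrying_capacity > 0 and math.isfinite(self.carrying_capacity)):
            raise ValueError(f"carrying_capacity must be positive, got {self.carrying_capacity}")
        for name in ("baseline_death", "density_death_coef", "motility"):
            v = getattr(self, name)
            if not (v >= 0 and math.isfinite(v)):
                raise ValueError(f"{name} must be non-negative, got {v}")

    def scaled_capacity(self, factor: float) -> "PhenotypeParams":
        """Return a copy with the carrying capacity multiplied by ``factor``."""
        return replace(self, carrying_capacity=self.carrying_capacity * factor)


@dataclass(frozen=True)
class InteractionParams:
    """Dimensionless competition coefficients.

    ``alpha`` is the effect of K cells on r cells: one K cell crowds an r cell
    as much as ``alpha`` r cells would.  ``beta`` is the reverse effect of r
    cells on K cells.
    """

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        for name in ("alpha", "beta"):
            v = getattr(self, name)
            if not (v >= 0 and math.isfinite(v)):
                raise ValueError(f"{name} must be non-negative and finite, got {v}")


@dataclass(frozen=True)
class PopulationState:
    """Counts of r and K cells at a moment in time (hours).

    Counts are real-valued in the deterministic (ODE) context and integer in
    the stochastic simulators; both must be non-negative and finite.
    """

    n_r: float
    n_K: float
    time: float = 0.0

    def __post_init__(self) -> None:
        for name in ("n_r", "n_K"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        if not (math.isfinite(self.time) and self.time >= 0):
            raise ValueError(f"time must be finite and >= 0, got {self.time}")

    @property
    def total(self) -> float:
        return self.n_r + self.n_K

    @property
    def fraction_r(self) -> float:
        """Fraction of r cells; NaN when the population is empty."""
        tot = self.total
        return self.n_r / tot if tot > 0 else math.nan


@dataclass
class Trajectory:
    """Ordered sequence of population states with strictly increasing times."""

    states: list[PopulationState]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        times = [s.time for s in self.states]
        if any(t1 >= t2 for t1, t2 in zip(times, times[1:])):
            raise ValueError("trajectory times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.states)

    @property
    def times(self):
        import numpy as np

        return np.array([s.time for s in self.states])

    @property
    def n_r(self):
        import numpy as np

        return np.array([s.n_r for s in self.states])

    @property
    def n_K(self):
        import numpy as np

        return np.array([s.n_K for s in self.states])

    def to_frame(self):
        """Tidy table with columns time_h, n_r, n_K."""
        import pandas as pd

        return pd.DataFrame({"time_h": self.times, "n_r": self.n_r, "n_K": self.n_K})


def default_r_params() -> PhenotypeParams:
    """Default r-cell parameters for the well-mixed (passage) simulations.

    Fast grower (doubling time ~14 h at low density, in the range of rapidly
    cycling HeLa subclones) with a carrying capacity half that of the K cells:
    the r strategist trades crowding tolerance for speed.
    """
    return PhenotypeParams(
        label="r",
        intrinsic_rate=0.05,
        carrying_capacity=5e4,
        baseline_death=0.01,
        density_death_coef=0.10,
        motility=0.3,
    )


def default_k_params() -> PhenotypeParams:
    """Default K-cell parameters: slower growth, doubled carrying capacity."""
    return PhenotypeParams(
        label="K",
        intrinsic_rate=0.03,
        carrying_capacity=1e5,
        baseline_death=0.005,
        density_death_coef=0.01,
        motility=0.05,
    )
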