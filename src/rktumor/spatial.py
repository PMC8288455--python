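"""On-lattice agent-based model of r/K co-growth with local density effects.

Cells live on a 2D square lattice with at most one cell per site (volume
exclusion) and interact through their Moore neighborhood (the 8 surrounding
sites).  Each hour, cells are visited in a fresh uniform random order and
attempt mutually exclusive events in the order death -> division ->
migration:

* death with probability ``(baseline_death + density_death_coef * c) * dt``,
  where the local crowding ``c`` of an r cell counts r neighbors plus
  ``alpha`` times K neighbors (divided by 8), and symmetrically with ``beta``
  for K cells — crowding-weighted death is how the competition coefficients
  enter the spatial model;
* division with probability ``intrinsic_rate * dt`` into a uniformly chosen
  empty neighbor site, only if one exists;
* migration with probability ``motility * dt`` to a uniformly chosen empty
  neighbor site, only if division did not fire and an empty site exists.

Cells with no empty neighbor can neither divide nor migrate, so both birth
and movement are gated by free space.  The boundary is reflecting (a culture
well wall): out-of-bounds sites are simply not available, and crowding keeps
a denominator of 8 everywhere.

Daughters born during a sweep act for the first time in the next sweep.
The update loop is compiled with numba; each replicate runs on its own
deterministically derived seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from numba import njit

from .errors import ConfigurationError, InvalidInputError
from .params import InteractionParams, PhenotypeParams

__all__ = [
    "Lattice",
    "SpatialConfig",
    "SpatialResult",
    "default_spatial_r_params",
    "default_spatial_k_params",
    "seed_lattice",
    "local_crowding",
    "step_lattice",
    "run_spatial",
    "segregation_index",
    "growth_rate_series",
    "late_growth_rate",
]

EMPTY, R_CELL, K_CELL = 0, 1, 2


def default_spatial_r_params() -> PhenotypeParams:
    """Spatial-model r-cell parameters.

    Calibration knobs chosen to express the r strategy on the lattice (fast
    division, strong crowding-induced death, high motility); they are not
    empirical measurements.
    """
    return PhenotypeParams(
        label="r",
        intrinsic_rate=0.06,
        carrying_capacity=1e5,  # unused on the lattice; density is local
        baseline_death=0.002,
        density_death_coef=0.10,
        motility=0.3,
    )


def default_spatial_k_params() -> PhenotypeParams:
    """Spatial-model K-cell parameters (slow division, crowding-tolerant)."""
    return PhenotypeParams(
        label="K",
        intrinsic_rate=0.025,
        carrying_capacity=1e5,
        baseline_death=0.002,
        density_death_coef=0.01,
        motility=0.05,
    )


@dataclass
class Lattice:
    """Lattice state: int8 occupancy grid (0 empty, 1 r, 2 K) plus time."""

    occupancy: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy)
        if occ.ndim != 2 or not np.isin(occ, (EMPTY, R_CELL, K_CELL)).all():
            raise InvalidInputError("occupancy must be a 2-D grid of {0, 1, 2}")
        self.occupancy = occ.astype(np.int8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.occupancy.shape

    @property
    def counts(self) -> tuple[int, int]:
        """(n_r, n_K) tallied from the grid."""
        return int((self.occupancy == R_CELL).sum()), int((self.occupancy == K_CELL).sum())

    def to_text(self, path) -> None:
        np.savetxt(path, self.occupancy, fmt="%d")

    @classmethod
    def from_text(cls, path, time: float = 0.0) -> "Lattice":
        return cls(np.loadtxt(path, dtype=np.int8), time=time)


@dataclass(frozen=True)
class SpatialConfig:
    """Spatial experiment settings.

    The default seeds ~2,800 well-mixed cells in a central disc of radius 32
    on a 200x200 lattice — a desk-scale stand-in for the ~10^6 cells seeded
    in the center of a culture well.
    """

    width: int = 200
    height: int = 200
    seeding_radius: float = 32.0
    init_fraction_r: float = 0.5
    total_seeded: int = 2800
    dt: float = 1.0
    horizon: float = 144.0
    snapshot_times: tuple[float, ...] = (72.0, 144.0)
    n_replicates: int = 100
    rng_seed: int = 0
    pr: PhenotypeParams = field(default_factory=default_spatial_r_params)
    pk: PhenotypeParams = field(default_factory=default_spatial_k_params)
    inter: InteractionParams = field(default_factory=lambda: InteractionParams(2.2, 0.0))

    def __post_init__(self) -> None:
        if self.width < 3 or self.height < 3:
            raise ConfigurationError("lattice must be at least 3x3")
        if not 0.0 <= self.init_fraction_r <= 1.0:
            raise ConfigurationError("init_fraction_r must lie in [0, 1]")
        if self.dt <= 0 or self.horizon < 0:
            raise ConfigurationError("dt must be > 0 and horizon >= 0")
        if any(t > self.horizon or t < 0 for t in self.snapshot_times):
            raise ConfigurationError("snapshot times must lie in [0, horizon]")
        if self.total_seeded > self._disc_size():
            raise ConfigurationError(
                f"cannot seed {self.total_seeded} cells in a disc of "
                f"{self._disc_size()} sites; enlarge seeding_radius"
            )
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be >= 1")

    def _disc_sites(self) -> tuple[np.ndarray, np.ndarray]:
        cy, cx = (self.height - 1) / 2.0, (self.width - 1) / 2.0
        ys, xs = np.mgrid[0 : self.height, 0 : self.width]
        inside = (ys - cy) ** 2 + (xs - cx) ** 2 <= self.seeding_radius**2
        return ys[inside], xs[inside]

    def _disc_size(self) -> int:
        return len(self._disc_sites()[0])

    @property
    def n_steps(self) -> int:
        n = self.horizon / self.dt
        if abs(n - round(n)) > 1e-9:
            raise ConfigurationError("dt must divide horizon")
        return int(round(n))

    @property
    def snapshot_steps(self) -> np.ndarray:
        steps = []
        for t in self.snapshot_times:
            s = t / self.dt
            if abs(s - round(s)) > 1e-9:
                raise ConfigurationError(f"snapshot time {t} not a multiple of dt")
            steps.append(int(round(s)))
        return np.array(sorted(steps), dtype=np.int64)


@dataclass
class SpatialResult:
    """Growth curves and snapshots for every replicate.

    ``counts`` has shape ``(n_replicates, n_steps + 1, 2)`` with the r and K
    totals after every step; ``snapshots`` has shape
    ``(n_replicates, n_snapshots, H, W)``.
    """

    counts: np.ndarray
    snapshots: np.ndarray
    snapshot_times: np.ndarray
    config: SpatialConfig

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.counts.shape[1]) * self.config.dt

    @property
    def totals(self) -> np.ndarray:
        return self.counts.sum(axis=2)

    def snapshot_lattice(self, replicate: int, which: int) -> Lattice:
        return Lattice(
            self.snapshots[replicate, which].copy(),
            time=float(self.snapshot_times[which]),
        )


def seed_lattice(config: SpatialConfig, rng: np.random.Generator) -> Lattice:
    """Seed ``total_seeded`` well-mixed cells uniformly in the central disc.

    The r-cell count is exact (``round(total_seeded * init_fraction_r)``);
    type labels are randomly shuffled over the chosen sites.
    """
    ys, xs = config._disc_sites()
    idx = rng.choice(len(ys), size=config.total_seeded, replace=False)
    n_r = int(round(config.total_seeded * config.init_fraction_r))
    types = np.full(config.total_seeded, K_CELL, dtype=np.int8)
    types[:n_r] = R_CELL
    rng.shuffle(types)
    grid = np.zeros((config.height, config.width), dtype=np.int8)
    grid[ys[idx], xs[idx]] = types
    return Lattice(grid, time=0.0)


def local_crowding(
    lattice: Lattice, site: tuple[int, int], inter: InteractionParams
) -> float:
    """Crowding felt by the cell at ``site``: weighted neighbors over 8.

    For an r cell: (r neighbors + alpha * K neighbors) / 8; for a K cell the
    K neighbors count plainly and r neighbors are weighted by beta.  Sites
    beyond the wall contribute nothing but the denominator stays 8.
    """
    y, x = site
    occ = lattice.occupancy
    t = occ[y, x]
    if t == EMPTY:
        raise InvalidInputError(f"site {site} is empty")
    same = other = 0
    h, w = occ.shape
    for dy in (-1, 0, 1):
        for dx in (-1, 0, 1):
            if dy == 0 and dx == 0:
                continue
            ny, nx = y + dy, x + dx
            if 0 <= ny < h and 0 <= nx < w:
                n = occ[ny, nx]
                if n == t:
                    same += 1
                elif n != EMPTY:
                    other += 1
    weight = inter.alpha if t == R_CELL else inter.beta
    return (same + weight * other) / 8.0


@njit(cache=True)
def _sweep(grid, stamp, step_id, dt,
           b_r, d0_r, dd_r, m_r,
           b_k, d0_k, dd_k, m_k,
           alpha, beta):  # pragma: no cover - exercised via wrappers
    h, w = grid.shape
    # collect occupied sites
    n_cells = 0
    ys = np.empty(h * w, dtype=np.int32)
    xs = np.empty(h * w, dtype=np.int32)
    for y in range(h):
        for x in range(w):
            if grid[y, x] != 0:
                ys[n_cells] = y
                xs[n_cells] = x
                n_cells += 1
    if n_cells == 0:
        return
    order = np.random.permutation(n_cells)
    ey = np.empty(8, dtype=np.int32)
    ex = np.empty(8, dtype=np.int32)
    for i in range(n_cells):
        y = ys[order[i]]
        x = xs[order[i]]
        t = grid[y, x]
        if t == 0 or stamp[y, x] == step_id:
            continue  # vacated site or a daughter born this sweep
        same = 0
        other = 0
        n_empty = 0
        for dy in range(-1, 2):
            for dx in range(-1, 2):
                if dy == 0 and dx == 0:
                    continue
                ny = y + dy
                nx = x + dx
                if 0 <= ny < h and 0 <= nx < w:
                    n = grid[ny, nx]
                    if n == 0:
                        ey[n_empty] = ny
                        ex[n_empty] = nx
                        n_empty += 1
                    elif n == t:
                        same += 1
                    else:
                        other += 1
        if t == 1:
            crowd = (same + alpha * other) / 8.0
            p_death = (d0_r + dd_r * crowd) * dt
            p_div = b_r * dt
            p_mig = m_r * dt
        else:
            crowd = (same + beta * other) / 8.0
            p_death = (d0_k + dd_k * crowd) * dt
            p_div = b_k * dt
            p_mig = m_k * dt
        if np.random.random() < min(1.0, p_death):
            grid[y, x] = 0
            continue
        if n_empty == 0:
            continue
        if np.random.random() < min(1.0, p_div):
            j = np.random.randint(n_empty)
            grid[ey[j], ex[j]] = t
            stamp[ey[j], ex[j]] = step_id
        elif np.random.random() < min(1.0, p_mig):
            j = np.random.randint(n_empty)
            grid[y, x] = 0
            grid[ey[j], ex[j]] = t


@njit(cache=True)
def _run(grid, n_steps, dt,
         b_r, d0_r, dd_r, m_r,
         b_k, d0_k, dd_k, m_k,
         alpha, beta,
         snap_steps, snaps, counts, seed):  # pragma: no cover
    np.random.seed(seed)
    h, w = grid.shape
    stamp = np.full((h, w), -1, dtype=np.int64)
    nr = 0
    nk = 0
    for y in range(h):
        for x in range(w):
            if grid[y, x] == 1:
                nr += 1
            elif grid[y, x] == 2:
                nk += 1
    counts[0, 0] = nr
    counts[0, 1] = nk
    si = 0
    while si < len(snap_steps) and snap_steps[si] == 0:
        snaps[si] = grid
        si += 1
    for step in range(1, n_steps + 1):
        _sweep(grid, stamp, step, dt,
               b_r, d0_r, dd_r, m_r,
               b_k, d0_k, dd_k, m_k,
               alpha, beta)
        nr = 0
        nk = 0
        for y in range(h):
            for x in range(w):
                if grid[y, x] == 1:
                    nr += 1
                elif grid[y, x] == 2:
                    nk += 1
        counts[step, 0] = nr
        counts[step, 1] = nk
        while si < len(snap_steps) and snap_steps[si] == step:
            snaps[si] = grid
            si += 1


def _kernel_args(config: SpatialConfig):
    pr, pk, inter = config.pr, config.pk, config.inter
    return (
        config.dt,
        pr.intrinsic_rate, pr.baseline_death, pr.density_death_coef, pr.motility,
        pk.intrinsic_rate, pk.baseline_death, pk.density_death_coef, pk.motility,
        inter.alpha, inter.beta,
    )


def step_lattice(
    lattice: Lattice, config: SpatialConfig, rng: np.random.Generator
) -> Lattice:
    """Advance the lattice by one asynchronous random-order sweep of ``dt``."""
    grid = lattice.occupancy.copy()
    counts = np.zeros((2, 2), dtype=np.int64)
    snaps = np.zeros((0, *grid.shape), dtype=np.int8)
    seed = int(rng.integers(0, 2**31 - 1))
    _run(grid, 1, *_kernel_args(config), np.zeros(0, dtype=np.int64), snaps, counts, seed)
    return Lattice(grid, time=lattice.time + config.dt)


def run_spatial(config: SpatialConfig) -> SpatialResult:
    """Run all replicates, recording growth curves hourly and snapshots.

    Each replicate draws its seeding and its sweep randomness from its own
    stream, spawned as ``SeedSequence(rng_seed).spawn(n_replicates)``.
    """
    n_steps = config.n_steps
    snap_steps = config.snapshot_steps
    counts = np.zeros((config.n_replicates, n_steps + 1, 2), dtype=np.int64)
    snaps = np.zeros(
        (config.n_replicates, len(snap_steps), config.height, config.width),
        dtype=np.int8,
    )
    args = _kernel_args(config)
    for i, ss in enumerate(np.random.SeedSequence(config.rng_seed).spawn(config.n_replicates)):
        rng = np.random.default_rng(ss)
        lattice = seed_lattice(config, rng)
        kernel_seed = int(rng.integers(0, 2**31 - 1))
        _run(lattice.occupancy, n_steps, *args, snap_steps, snaps[i], counts[i], kernel_seed)
    return SpatialResult(counts, snaps, snap_steps * config.dt, config)


def save_snapshot_image(lattice: Lattice, path) -> None:
    """Render a lattice snapshot as a raster image (r green, K red, empty black)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    fig, ax = plt.subplots(figsize=(4, 4), dpi=150)
    ax.imshow(
        lattice.occupancy,
        cmap=ListedColormap(["black", "#2ca02c", "#d62728"]),
        vmin=0,
        vmax=2,
        interpolation="nearest",
    )
    ax.set_axis_off()
    fig.savefig(path, bbox_inches="tight", pad_inches=0)
    plt.close(fig)


def segregation_index(lattice: Lattice) -> float:
    """Normalized radial separation of the two types.

    (mean distance of r cells from the lattice center - mean distance of K
    cells) / (mean distance of all cells); positive when r cells sit at the
    periphery and K cells in the core.  NaN if either type is absent.
    """
    occ = lattice.occupancy
    ys, xs = np.nonzero(occ)
    if len(ys) == 0:
        return math.nan
    types = occ[ys, xs]
    if not (types == R_CELL).any() or not (types == K_CELL).any():
        return math.nan
    cy, cx = (occ.shape[0] - 1) / 2.0, (occ.shape[1] - 1) / 2.0
    dist = np.hypot(ys - cy, xs - cx)
    mean_r = dist[types == R_CELL].mean()
    mean_k = dist[types == K_CELL].mean()
    return float((mean_r - mean_k) / dist.mean())


def growth_rate_series(result: SpatialResult) -> pd.DataFrame:
    """Per-interval per-capita growth rates, averaged over replicates.

    The rate over (t, t + dt) is (N(t+dt) - N(t)) / N(t); intervals with
    N(t) = 0 are excluded from the average (``n_valid`` reports how many
    replicates contributed).
    """
    totals = result.totals.astype(float)
    if totals.shape[0] < 1 or totals.shape[1] < 2:
        raise InvalidInputError("result must contain at least one replicate and one interval")
    with np.errstate(divide="ignore", invalid="ignore"):
        rates = np.diff(totals, axis=1) / totals[:, :-1]
    rates[totals[:, :-1] == 0] = np.nan
    n_valid = np.sum(~np.isnan(rates), axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(rates, axis=0)
        sd = np.nanstd(rates, axis=0, ddof=1)
    return pd.DataFrame(
        {
            "time_h": result.times[:-1],
            "mean_rate": mean,
            "sd_rate": sd,
            "n_valid": n_valid,
        }
    )


def late_growth_rate(result: SpatialResult, window_h: Optional[float] = None) -> np.ndarray:
    """Per-replicate mean per-capita growth rate over the final time window.

    ``window_h`` defaults to the last quarter of the horizon.
    """
    if window_h is None:
        window_h = result.config.horizon / 4.0
    n_int = int(round(window_h / result.config.dt))
    totals = result.totals.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        rates = np.diff(totals, axis=1) / totals[:, :-1]
    rates[totals[:, :-1] == 0] = np.nan
    return np.nanmean(rates[:, -n_int:], axis=1)
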