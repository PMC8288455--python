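"""Synthetic co-culture datasets with flow-cytometry-like counting noise.

Real measurements of the r-cell fraction come from scoring a finite number of
gated cells in a flow cytometer, so the measured fraction of a replicate at a
passage is modelled as ``Binomial(gated_cells, true_fraction) / gated_cells``
applied on top of a stochastic serial-passage simulation.  Binomial gating
noise with 10^4 cells per measurement is typical of routine acquisitions; it
is unbiased, with SD ``sqrt(f (1-f) / gated_cells)``.

A frozen reference dataset (three replicates, thirty high-density passages,
9:1 initial r:K ratio, alpha = 2.2, beta = 0) ships with the package as a
versioned CSV fixture.  It is synthetic — a stand-in with the statistical
shape of the study's measurements, not measured data.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .inference import ObservedDataset
from .params import InteractionParams, PhenotypeParams
from .passage import PassageConfig, simulate_passages

__all__ = [
    "FlowDesign",
    "parse_ratio",
    "gen_flow_fractions",
    "gen_reference_dataset",
    "load_reference_dataset",
    "REFERENCE_SEED",
    "REFERENCE_FIXTURE",
]

#: Documented seed of the shipped reference fixture.
REFERENCE_SEED = 424242

#: Packaged fixture file name (synthetic stand-in, see module docstring).
REFERENCE_FIXTURE = "synthetic_cocult_9to1.csv"


def parse_ratio(ratio: str | float) -> float:
    """Parse an ``"r:K"`` ratio string (e.g. ``"9:1"``) into an r fraction."""
    if isinstance(ratio, (int, float)):
        frac = float(ratio)
    else:
        try:
            r_part, k_part = (float(x) for x in str(ratio).split(":"))
        except ValueError as exc:
            raise InvalidInputError(f"cannot parse ratio {ratio!r}") from exc
        if r_part < 0 or k_part < 0 or r_part + k_part == 0:
            raise InvalidInputError(f"ratio parts must be non-negative, got {ratio!r}")
        frac = r_part / (r_part + k_part)
    if not 0.0 <= frac <= 1.0:
        raise InvalidInputError(f"ratio {ratio!r} is outside [0, 1]")
    return frac


@dataclass(frozen=True)
class FlowDesign:
    """Design of a fraction-measurement experiment.

    Five-passage designs mirror the short fitness assays; thirty-passage
    designs mirror the long high-density co-culture, both with three
    replicate cultures measured by a 10^4-cell gate.
    """

    n_replicates: int = 3
    n_passages: int = 30
    gated_cells: int = 10_000
    initial_ratio: str = "9:1"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.gated_cells < 1:
            raise InvalidInputError("gated_cells must be >= 1")
        if self.n_replicates < 1 or self.n_passages < 0:
            raise InvalidInputError("n_replicates must be >= 1 and n_passages >= 0")
        parse_ratio(self.initial_ratio)  # validate eagerly

    @property
    def init_fraction_r(self) -> float:
        return parse_ratio(self.initial_ratio)


def _derived_seeds(root: int) -> tuple[int, int]:
    sim, gate = np.random.SeedSequence(root).generate_state(2)
    return int(sim) & 0x7FFFFFFF, int(gate) & 0x7FFFFFFF


def gen_flow_fractions(
    design: FlowDesign,
    pr: Optional[PhenotypeParams] = None,
    pk: Optional[PhenotypeParams] = None,
    inter: Optional[InteractionParams] = None,
    config: Optional[PassageConfig] = None,
) -> ObservedDataset:
    """Simulate a passage experiment and measure it through a finite gate.

    The latent truth comes from :func:`rktumor.passage.simulate_passages`;
    each (replicate, passage) fraction is then re-measured as a binomial draw
    of ``gated_cells`` scored cells.  A replicate whose whole population died
    out scores fraction zero.
    """
    sim_seed, gate_seed = _derived_seeds(design.rng_seed)
    # dt = 0.02 h: the binomial tau-leap is first-order in dt, and the latent
    # trajectories must track the continuous-time model to within gating
    # noise for downstream inference to be well-posed (convergence-checked;
    # at coarse steps the discretization bias masquerades as a small beta).
    base = config if config is not None else PassageConfig(dt=0.02)
    cfg = replace(
        base,
        n_passages=design.n_passages,
        init_fraction_r=design.init_fraction_r,
        n_replicates=design.n_replicates,
        rng_seed=sim_seed,
    )
    result = simulate_passages(cfg, pr, pk, inter)
    true_frac = np.nan_to_num(result.fraction_r, nan=0.0)

    gate_rng = np.random.default_rng(gate_seed)
    counts = gate_rng.binomial(design.gated_cells, true_frac)
    measured = counts / design.gated_cells

    reps, passages = np.meshgrid(
        np.arange(design.n_replicates), np.arange(design.n_passages + 1), indexing="ij"
    )
    frame = pd.DataFrame(
        {
            "replicate": reps.ravel(),
            "passage": passages.ravel(),
            "fraction_r": measured.ravel(),
        }
    )
    inter = inter if inter is not None else InteractionParams(2.2, 0.0)
    return ObservedDataset(
        frame,
        metadata={
            "initial_ratio": design.initial_ratio,
            "gated_cells": design.gated_cells,
            "rng_seed": design.rng_seed,
            "true_alpha": inter.alpha,
            "true_beta": inter.beta,
        },
    )


def gen_reference_dataset() -> ObservedDataset:
    """Regenerate the shipped reference co-culture dataset bit-identically.

    Thirty high-density passages from a 9:1 r:K seeding under the
    best-supported interaction (alpha = 2.2, beta = 0), three replicates,
    10^4-cell gate, fixed seed ``REFERENCE_SEED``.
    """
    design = FlowDesign(rng_seed=REFERENCE_SEED)
    return gen_flow_fractions(design, inter=InteractionParams(2.2, 0.0))


def write_reference_fixture(path: str | Path) -> None:
    """Write the reference dataset CSV (used to version the shipped fixture)."""
    gen_reference_dataset().to_csv(path)


def load_reference_dataset() -> ObservedDataset:
    """Load the packaged synthetic reference fixture."""
    with resources.as_file(
        resources.files("rktumor").joinpath("data", REFERENCE_FIXTURE)
    ) as p:
        return ObservedDataset.from_csv(
            p,
            initial_ratio="9:1",
            gated_cells=10_000,
            rng_seed=REFERENCE_SEED,
            synthetic=True,
        )
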