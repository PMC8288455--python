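"""Experiment drivers and summary metrics tying the simulators together.

Four in-silico experiments mirror the study designs the package emulates:

* ``fraction_trajectories`` — r-fraction-versus-passage curves of the
  high-density serial-passage co-culture under the fitted interaction
  (alpha = 2.2, beta = 0) from a 9:1 start, and the no-interaction control
  (alpha = beta = 0) from 9:1, 1:1 and 1:9 starts, overlaid with the shipped
  synthetic reference dataset.
* ``extinction_vs_alpha`` — distribution of the r-cell extinction passage as
  the competition pressure alpha increases at beta = 0.
* ``extinction_vs_init`` — extinction ordering by initial r fraction in a
  micro-culture regime where demographic drift is visible (see
  ``MICRO_CULTURE``).
* ``spatial_niche`` — lattice snapshots and the radial segregation index of
  a 1:1 centrally seeded co-culture.
* ``mixed_fitness`` — per-capita growth-rate comparison of pure r, pure K
  and 1:1 mixed cultures near confluence.

Every experiment writes plain CSV tables plus a JSON manifest (configs,
seeds, package version) sufficient to regenerate its outputs bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidInputError
from .params import InteractionParams, PhenotypeParams
from .passage import (
    PassageConfig,
    extinction_passage,
    median_extinction,
    simulate_passages,
)
from .spatial import (
    SpatialConfig,
    late_growth_rate,
    growth_rate_series,
    run_spatial,
    segregation_index,
)
from .synth import load_reference_dataset

__all__ = [
    "ExperimentSpec",
    "EXPERIMENTS",
    "MICRO_CULTURE",
    "MIXED_FITNESS_SPATIAL",
    "growth_rate_7day",
    "summarize_replicates",
    "run_experiment",
    "extinction_ordering",
    "segregation_with_null",
]

logger = logging.getLogger(__name__)

#: Micro-culture passage regime for drift-driven extinction experiments:
#: 10 cells reseeded into a 100-cell-capacity well every 6 days.  At
#: flow-cytometry scale (10^4-cell reseeds) the no-interaction co-culture is
#: stably coexisting and r extinction essentially never occurs; demographic
#: absorption is observable only with a handful of founders.
MICRO_CULTURE = PassageConfig(
    n_passages=200,
    passage_duration=144.0,
    capacity_total=100.0,
    seed_size=10,
    n_replicates=100,
)

#: Near-confluence spatial setting for the growth-rate comparison: a reduced
#: 128x128 well run for 16 days so the fast r front approaches the wall
#: within the run.  The final 48 h form the "late horizon" window.
MIXED_FITNESS_SPATIAL = SpatialConfig(
    width=128,
    height=128,
    seeding_radius=20.0,
    total_seeded=1100,
    horizon=384.0,
    snapshot_times=(384.0,),
    n_replicates=100,
)

LATE_WINDOW_H = 48.0


def growth_rate_7day(counts: Sequence[float], interval_days: float = 1.0) -> float:
    """Log-linear end-point growth rate per day from daily cell counts.

    ``(ln N_end - ln N_0) / elapsed_days`` — the conventional summary of a
    seven-day growth curve counted every 24 hours.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.size < 2:
        raise InvalidInputError("need at least two daily counts")
    if np.any(counts <= 0) or not np.all(np.isfinite(counts)):
        raise InvalidInputError("counts must be positive and finite")
    elapsed = (counts.size - 1) * interval_days
    return float((math.log(counts[-1]) - math.log(counts[0])) / elapsed)


def summarize_replicates(groups: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Mean, sample SD (n-1 denominator) and n per condition.

    SD is NaN for single-value groups (the undefined-SD sentinel).
    """
    rows = []
    for name, values in groups.items():
        arr = np.asarray(list(values), dtype=float)
        if arr.size == 0:
            raise InvalidInputError(f"group {name!r} is empty")
        rows.append(
            {
                "condition": name,
                "mean": float(arr.mean()),
                "sd": float(arr.std(ddof=1)) if arr.size > 1 else math.nan,
                "n": int(arr.size),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ExperimentSpec:
    """What to run, where to write it, and with which root seed."""

    name: str
    out_dir: str | Path
    seed: int = 0
    n_replicates: Optional[int] = None
    passage_config: Optional[PassageConfig] = None
    spatial_config: Optional[SpatialConfig] = None
    verbose: bool = False

    def __post_init__(self) -> None:
        if self.name not in EXPERIMENTS:
            raise InvalidInputError(
                f"unknown experiment {self.name!r}; choose from {sorted(EXPERIMENTS)}"
            )


def _write_manifest(out: Path, spec: ExperimentSpec, extra: dict) -> None:
    from . import __version__

    def encode(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {"__type__": type(obj).__name__, **dataclasses.asdict(obj)}
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, Path):
            return str(obj)
        raise TypeError(f"cannot serialize {type(obj)}")

    spec_dict = dataclasses.asdict(replace(spec, out_dir=""))
    spec_dict.pop("out_dir")  # parametric, not part of the result identity
    manifest = {
        "package_version": __version__,
        "experiment": spec.name,
        "seed": spec.seed,
        "spec": spec_dict,
        **extra,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=encode, sort_keys=True))


def _fraction_trajectories(spec: ExperimentSpec, out: Path) -> dict:
    base = spec.passage_config or PassageConfig()
    n_reps = spec.n_replicates or base.n_replicates
    conditions = [
        ("fitted_9to1", InteractionParams(2.2, 0.0), 0.9),
        ("null_9to1", InteractionParams(0.0, 0.0), 0.9),
        ("null_1to1", InteractionParams(0.0, 0.0), 0.5),
        ("null_1to9", InteractionParams(0.0, 0.0), 0.1),
    ]
    summaries = []
    medians = {}
    for i, (name, inter, f0) in enumerate(conditions):
        cfg = replace(
            base, init_fraction_r=f0, n_replicates=n_reps, rng_seed=spec.seed * 1000 + i
        )
        res = simulate_passages(cfg, inter=inter)
        summ = res.summary()
        summ.insert(0, "condition", name)
        summaries.append(summ)
        res.to_frame().assign(condition=name).to_csv(out / f"trajectories_{name}.csv", index=False)
        medians[name] = median_extinction(extinction_passage(res))
        logger.info("condition %s: median extinction passage %s", name, medians[name])
    pd.concat(summaries).to_csv(out / "summary.csv", index=False)
    ref = load_reference_dataset()
    ref.data.to_csv(out / "reference_overlay.csv", index=False)
    return {"median_extinction": {k: (v if math.isfinite(v) else None) for k, v in medians.items()}}


def _extinction_vs_alpha(
    spec: ExperimentSpec, out: Path, alphas: Sequence[float] = (0.0, 1.0, 2.0, 3.0)
) -> dict:
    base = spec.passage_config or PassageConfig()
    n_reps = spec.n_replicates or base.n_replicates
    rows = []
    medians = {}
    for i, a in enumerate(alphas):
        cfg = replace(base, n_replicates=n_reps, rng_seed=spec.seed * 1000 + i)
        res = simulate_passages(cfg, inter=InteractionParams(a, 0.0))
        ext = extinction_passage(res)
        for rep, (p, c) in enumerate(zip(ext.passage, ext.censored)):
            rows.append({"alpha": a, "replicate": rep, "extinction_passage": p, "censored": c})
        medians[a] = median_extinction(ext)
        logger.info("alpha=%g: median extinction passage %s", a, medians[a])
    pd.DataFrame(rows).to_csv(out / "extinction_passages.csv", index=False)
    return {"median_extinction": {str(k): (v if math.isfinite(v) else None) for k, v in medians.items()}}


def extinction_ordering(
    seed: int,
    init_fractions: Sequence[float] = (0.1, 0.5, 0.9),
    config: PassageConfig = MICRO_CULTURE,
    inter: InteractionParams = InteractionParams(0.0, 0.0),
) -> dict[float, float]:
    """Median extinction passage per initial r fraction (micro-culture regime)."""
    medians = {}
    for i, f0 in enumerate(init_fractions):
        cfg = replace(config, init_fraction_r=f0, rng_seed=seed * 1000 + i)
        res = simulate_passages(cfg, inter=inter)
        medians[f0] = median_extinction(extinction_passage(res))
    return medians


def _extinction_vs_init(spec: ExperimentSpec, out: Path) -> dict:
    base = spec.passage_config or MICRO_CULTURE
    if spec.n_replicates:
        base = replace(base, n_replicates=spec.n_replicates)
    medians = extinction_ordering(spec.seed, config=base)
    pd.DataFrame(
        [{"init_fraction_r": f, "median_extinction_passage": m} for f, m in medians.items()]
    ).to_csv(out / "extinction_by_init_fraction.csv", index=False)
    return {
        "median_extinction": {str(k): (v if math.isfinite(v) else None) for k, v in medians.items()}
    }


def segregation_with_null(
    lattices, n_permutations: int = 200, rng: Optional[np.random.Generator] = None
) -> dict:
    """Mean segregation index across lattices with a label-permutation null.

    Shuffling type labels among occupied sites destroys any spatial
    organisation while preserving counts; the p-value is the fraction of
    permuted mean indices at least as extreme as the observed mean
    (one-sided, r-peripheral direction, add-one smoothed).
    """
    from .spatial import Lattice

    rng = rng if rng is not None else np.random.default_rng(0)
    observed = np.array([segregation_index(lat) for lat in lattices])
    perm_means = np.empty(n_permutations)
    for p in range(n_permutations):
        vals = []
        for lat in lattices:
            occ = lat.occupancy.copy()
            ys, xs = np.nonzero(occ)
            labels = occ[ys, xs]
            rng.shuffle(labels)
            occ[ys, xs] = labels
            vals.append(segregation_index(Lattice(occ, time=lat.time)))
        perm_means[p] = np.nanmean(vals)
    obs_mean = float(np.nanmean(observed))
    p_value = (1 + np.sum(perm_means >= obs_mean)) / (1 + n_permutations)
    return {
        "observed": observed,
        "mean": obs_mean,
        "perm_means": perm_means,
        "p_value": float(p_value),
    }


def _spatial_niche(spec: ExperimentSpec, out: Path) -> dict:
    cfg = spec.spatial_config or SpatialConfig(n_replicates=20)
    if spec.n_replicates:
        cfg = replace(cfg, n_replicates=spec.n_replicates)
    cfg = replace(cfg, rng_seed=spec.seed)
    result = run_spatial(cfg)
    rows = []
    for w, t in enumerate(result.snapshot_times):
        for rep in range(cfg.n_replicates):
            rows.append(
                {
                    "time_h": t,
                    "replicate": rep,
                    "segregation_index": segregation_index(result.snapshot_lattice(rep, w)),
                }
            )
    pd.DataFrame(rows).to_csv(out / "segregation.csv", index=False)
    final = [result.snapshot_lattice(rep, len(result.snapshot_times) - 1)
             for rep in range(cfg.n_replicates)]
    null = segregation_with_null(final, rng=np.random.default_rng(spec.seed + 1))
    result.snapshot_lattice(0, len(result.snapshot_times) - 1).to_text(
        out / "snapshot_final_rep0.txt"
    )
    logger.info("segregation mean %.4f (perm p=%.4g)", null["mean"], null["p_value"])
    return {"segregation_mean": null["mean"], "permutation_p": null["p_value"]}


def _mixed_fitness(spec: ExperimentSpec, out: Path) -> dict:
    base = spec.spatial_config or MIXED_FITNESS_SPATIAL
    if spec.n_replicates:
        base = replace(base, n_replicates=spec.n_replicates)
    rates = {}
    curves = []
    for i, (name, f0) in enumerate([("pure_K", 0.0), ("mix_1to1", 0.5), ("pure_r", 1.0)]):
        cfg = replace(base, init_fraction_r=f0, rng_seed=spec.seed * 1000 + i)
        result = run_spatial(cfg)
        rates[name] = late_growth_rate(result, LATE_WINDOW_H)
        series = growth_rate_series(result)
        series.insert(0, "condition", name)
        curves.append(series)
        logger.info("%s: late growth rate %.5f", name, float(np.nanmean(rates[name])))
    pd.concat(curves).to_csv(out / "growth_rate_series.csv", index=False)
    summary = summarize_replicates(rates)
    welch = {}
    for other in ("pure_r", "pure_K"):
        t, p = stats.ttest_ind(rates["mix_1to1"], rates[other], equal_var=False)
        welch[f"mix_vs_{other}"] = {"t": float(t), "p": float(p)}
    summary.to_csv(out / "late_growth_summary.csv", index=False)
    return {
        "late_growth_mean": {k: float(np.nanmean(v)) for k, v in rates.items()},
        "welch": welch,
    }


EXPERIMENTS = {
    "fraction_trajectories": _fraction_trajectories,
    "extinction_vs_alpha": _extinction_vs_alpha,
    "extinction_vs_init": _extinction_vs_init,
    "spatial_niche": _spatial_niche,
    "mixed_fitness": _mixed_fitness,
}


def run_experiment(spec: ExperimentSpec) -> Path:
    """Run one named experiment, writing tables and a manifest to its out_dir."""
    out = Path(spec.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if spec.verbose:
        logging.basicConfig(level=logging.INFO)
    try:
        extra = EXPERIMENTS[spec.name](spec, out)
    except Exception:
        logger.exception("experiment %s failed", spec.name)
        raise
    _write_manifest(out, spec, extra)
    return out
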