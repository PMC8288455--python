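"""On-lattice agent-based model: seeding, crowding, sweeps, segregation."""

from dataclasses import replace

import numpy as np
import pytest

from rktumor.errors import ConfigurationError, InvalidInputError
from rktumor.params import InteractionParams, PhenotypeParams
from rktumor.spatial import (
    EMPTY,
    K_CELL,
    R_CELL,
    Lattice,
    SpatialConfig,
    default_spatial_k_params,
    default_spatial_r_params,
    growth_rate_series,
    local_crowding,
    run_spatial,
    seed_lattice,
    segregation_index,
    step_lattice,
)


def small_config(**kwargs) -> SpatialConfig:
    defaults = dict(
        width=40,
        height=40,
        seeding_radius=8.0,
        total_seeded=150,
        horizon=24.0,
        snapshot_times=(24.0,),
        n_replicates=2,
        rng_seed=0,
    )
    defaults.update(kwargs)
    return SpatialConfig(**defaults)


class TestSeeding:
    def test_counts_and_disc_containment(self, rng):
        cfg = small_config(init_fraction_r=0.5)
        lat = seed_lattice(cfg, rng)
        n_r, n_k = lat.counts
        assert n_r == 75 and n_k == 75  # exact-count assignment
        ys, xs = np.nonzero(lat.occupancy)
        dist = np.hypot(ys - 19.5, xs - 19.5)
        assert dist.max() <= cfg.seeding_radius + 1e-9

    def test_zero_fraction_seeds_only_k(self, rng):
        lat = seed_lattice(small_config(init_fraction_r=0.0), rng)
        assert lat.counts == (0, 150)

    def test_full_disc_occupancy(self, rng):
        # odd lattice -> integer center; brute-force count of the disc sites
        cfg = SpatialConfig(
            width=41, height=41, seeding_radius=4.0, total_seeded=1,
            horizon=0.0, snapshot_times=(), n_replicates=1, rng_seed=0,
        )
        expected = sum(
            1
            for y in range(41)
            for x in range(41)
            if (y - 20) ** 2 + (x - 20) ** 2 <= 16
        )
        cfg = replace(cfg, total_seeded=expected)
        lat = seed_lattice(cfg, rng)
        assert sum(lat.counts) == expected
        # disc completely full, exterior empty
        ys, xs = np.nonzero(lat.occupancy)
        assert np.all((ys - 20) ** 2 + (xs - 20) ** 2 <= 16)

    def test_overfull_disc_rejected(self):
        with pytest.raises(ConfigurationError, match="seed"):
            small_config(seeding_radius=2.0, total_seeded=150)


class TestLocalCrowding:
    def build(self, center, ring):
        occ = np.zeros((5, 5), dtype=np.int8)
        occ[2, 2] = center
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if (dy, dx) != (0, 0):
                    occ[2 + dy, 2 + dx] = ring
        return Lattice(occ)

    def test_isolated_cell_feels_nothing(self):
        occ = np.zeros((5, 5), dtype=np.int8)
        occ[2, 2] = R_CELL
        assert local_crowding(Lattice(occ), (2, 2), InteractionParams(2.2, 0.0)) == 0.0

    def test_r_surrounded_by_k_weighs_alpha(self):
        lat = self.build(R_CELL, K_CELL)
        assert local_crowding(lat, (2, 2), InteractionParams(2.2, 0.0)) == pytest.approx(2.2)

    def test_k_surrounded_by_r_with_zero_beta(self):
        lat = self.build(K_CELL, R_CELL)
        assert local_crowding(lat, (2, 2), InteractionParams(2.2, 0.0)) == 0.0

    def test_wall_keeps_denominator_eight(self):
        occ = np.zeros((3, 3), dtype=np.int8)
        occ[0, 0] = R_CELL
        occ[0, 1] = R_CELL
        lat = Lattice(occ)
        assert local_crowding(lat, (0, 0), InteractionParams(0.0, 0.0)) == pytest.approx(1 / 8)

    def test_empty_site_rejected(self):
        occ = np.zeros((3, 3), dtype=np.int8)
        occ[1, 1] = K_CELL
        with pytest.raises(InvalidInputError):
            local_crowding(Lattice(occ), (0, 0), InteractionParams(0.0, 0.0))


class TestStep:
    def test_empty_lattice_stays_empty(self, rng):
        cfg = small_config()
        lat = Lattice(np.zeros((40, 40), dtype=np.int8))
        out = step_lattice(lat, cfg, rng)
        assert out.counts == (0, 0)
        assert out.time == pytest.approx(1.0)

    def test_fully_enclosed_immortal_cell_is_frozen(self, rng):
        """No empty neighbor and no death: the cell can neither divide nor move."""
        frozen = PhenotypeParams(
            label="r", intrinsic_rate=0.9, carrying_capacity=1.0,
            baseline_death=0.0, density_death_coef=0.0, motility=0.9,
        )
        pk = default_spatial_k_params()
        cfg = small_config(
            pr=frozen,
            pk=replace(pk, baseline_death=0.0, density_death_coef=0.0),
            dt=1.0,
        )
        occ = np.zeros((40, 40), dtype=np.int8)
        occ[10:13, 10:13] = K_CELL
        occ[11, 11] = R_CELL
        before = occ.copy()
        out = step_lattice(Lattice(occ), cfg, rng)
        assert out.occupancy[11, 11] == R_CELL
        # the enclosed r cell did not divide: r count unchanged
        assert (out.occupancy == R_CELL).sum() == (before == R_CELL).sum()

    def test_occupancy_exclusion_and_count_conservation(self):
        cfg = small_config(total_seeded=120, horizon=30.0, snapshot_times=(), n_replicates=1)
        rng = np.random.default_rng(8)
        lat = seed_lattice(cfg, rng)
        for _ in range(30):
            new = step_lattice(lat, cfg, rng)
            assert set(np.unique(new.occupancy)) <= {EMPTY, R_CELL, K_CELL}
            lat = new
        assert sum(lat.counts) > 0

    def test_branching_expectation_before_crowding(self):
        """A lone immortal cell divides at rate b: E[N after 10 steps] = 1.1^10."""
        p = PhenotypeParams(
            label="r", intrinsic_rate=0.1, carrying_capacity=1.0,
            baseline_death=0.0, density_death_coef=0.0, motility=0.2,
        )
        cfg = SpatialConfig(
            width=31, height=31, seeding_radius=1.0, total_seeded=1,
            init_fraction_r=1.0, horizon=10.0, snapshot_times=(),
            n_replicates=600, rng_seed=17, pr=p, pk=p, inter=InteractionParams(0, 0),
        )
        res = run_spatial(cfg)
        finals = res.totals[:, -1].astype(float)
        se = finals.std(ddof=1) / np.sqrt(len(finals))
        assert abs(finals.mean() - 1.1**10) < 3 * se

    def test_growth_bounded_geometrically(self):
        """Without density death or motility, growth ratio is at most (1 + b dt)."""
        p = PhenotypeParams(
            label="K", intrinsic_rate=0.5, carrying_capacity=1.0,
            baseline_death=0.0, density_death_coef=0.0, motility=0.0,
        )
        cfg = SpatialConfig(
            width=60, height=60, seeding_radius=3.0, total_seeded=9,
            init_fraction_r=0.0, horizon=20.0, snapshot_times=(),
            n_replicates=20, rng_seed=3, pr=default_spatial_r_params(), pk=p,
            inter=InteractionParams(0, 0),
        )
        res = run_spatial(cfg)
        totals = res.totals.astype(float)
        ratios = totals[:, 1:] / np.maximum(totals[:, :-1], 1)
        # hard bound: each cell leaves at most one daughter per sweep
        assert np.all(ratios <= 2.0)
        # expected bound: mean growth factor at most 1 + b*dt
        mean_ratio = ratios.mean(axis=0)
        se = ratios.std(axis=0, ddof=1) / np.sqrt(ratios.shape[0])
        assert np.all(mean_ratio <= 1.5 + 3 * se + 1e-12)


class TestRunSpatial:
    def test_zero_horizon_returns_seeded_state(self):
        cfg = small_config(horizon=0.0, snapshot_times=(0.0,))
        res = run_spatial(cfg)
        assert res.counts.shape == (2, 1, 2)
        np.testing.assert_array_equal(
            res.counts[:, 0, :].sum(axis=1), [150, 150]
        )
        assert np.array_equal(
            res.counts[0, 0], np.array(Lattice(res.snapshots[0, 0]).counts)
        )

    def test_bit_identical_reruns(self):
        cfg = small_config(n_replicates=3)
        a = run_spatial(cfg)
        b = run_spatial(cfg)
        assert np.array_equal(a.counts, b.counts)
        assert np.array_equal(a.snapshots, b.snapshots)

    def test_counts_match_snapshots(self):
        cfg = small_config(horizon=12.0, snapshot_times=(6.0, 12.0))
        res = run_spatial(cfg)
        for rep in range(2):
            for w, t in enumerate(res.snapshot_times):
                step = int(t)
                lat = res.snapshot_lattice(rep, w)
                assert lat.counts == tuple(res.counts[rep, step])

    def test_text_grid_roundtrip(self, tmp_path):
        cfg = small_config()
        res = run_spatial(cfg)
        lat = res.snapshot_lattice(0, 0)
        path = tmp_path / "snap.txt"
        lat.to_text(path)
        again = Lattice.from_text(path)
        assert np.array_equal(lat.occupancy, again.occupancy)

    def test_raster_snapshot_export(self, tmp_path):
        from rktumor.spatial import save_snapshot_image

        cfg = small_config()
        res = run_spatial(cfg)
        path = tmp_path / "snap.png"
        save_snapshot_image(res.snapshot_lattice(0, 0), path)
        assert path.stat().st_size > 0


class TestSegregation:
    def test_mirror_symmetric_placement_scores_zero(self):
        occ = np.zeros((21, 21), dtype=np.int8)
        occ[10, 2] = R_CELL
        occ[10, 18] = K_CELL
        assert segregation_index(Lattice(occ)) == pytest.approx(0.0)

    def test_rim_r_core_k_is_positive(self):
        occ = np.zeros((21, 21), dtype=np.int8)
        occ[0, :] = R_CELL
        occ[-1, :] = R_CELL
        occ[9:12, 9:12] = K_CELL
        assert segregation_index(Lattice(occ)) > 0.5

    def test_missing_type_is_nan(self):
        occ = np.zeros((5, 5), dtype=np.int8)
        occ[2, 2] = R_CELL
        assert np.isnan(segregation_index(Lattice(occ)))

    def test_random_labelling_has_zero_mean(self, rng):
        """Permutation null: uniform labels on an occupied disc center on 0."""
        ys, xs = np.mgrid[0:41, 0:41]
        inside = (ys - 20) ** 2 + (xs - 20) ** 2 <= 15**2
        vals = []
        for _ in range(500):
            occ = np.zeros((41, 41), dtype=np.int8)
            labels = rng.choice([R_CELL, K_CELL], size=inside.sum())
            occ[inside] = labels
            vals.append(segregation_index(Lattice(occ)))
        vals = np.array(vals)
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean()) < 3 * se

    def test_label_symmetry_under_identical_phenotypes(self):
        """Identical parameters and alpha = beta: no expected segregation."""
        p = default_spatial_r_params()
        cfg = SpatialConfig(
            width=50, height=50, seeding_radius=10.0, total_seeded=200,
            init_fraction_r=0.5, horizon=48.0, snapshot_times=(48.0,),
            n_replicates=40, rng_seed=29, pr=p, pk=replace(p, label="K"),
            inter=InteractionParams(0.5, 0.5),
        )
        res = run_spatial(cfg)
        vals = np.array(
            [segregation_index(res.snapshot_lattice(i, 0)) for i in range(40)]
        )
        vals = vals[~np.isnan(vals)]
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean()) < 3 * se


class TestGrowthRates:
    def test_constant_population_rate_zero(self):
        cfg = small_config()
        res = run_spatial(cfg)
        res.counts = np.tile([[30, 30]], (1, 5, 1))
        out = growth_rate_series(res)
        assert np.allclose(out["mean_rate"], 0.0)

    def test_doubling_population_rate_one(self):
        cfg = small_config()
        res = run_spatial(cfg)
        res.counts = (2 ** np.arange(5))[None, :, None] * np.array([[[1, 1]]])
        out = growth_rate_series(res)
        assert np.allclose(out["mean_rate"], 1.0)

    def test_matches_bruteforce_recomputation(self):
        cfg = small_config(n_replicates=5, horizon=20.0, snapshot_times=())
        res = run_spatial(cfg)
        out = growth_rate_series(res)
        totals = res.totals
        for rep in range(5):
            rates = []
            for t in range(totals.shape[1] - 1):
                n0 = totals[rep, t]
                rates.append((totals[rep, t + 1] - n0) / n0 if n0 else np.nan)
            for t, r in enumerate(rates):
                col = [
                    (totals[j, t + 1] - totals[j, t]) / totals[j, t]
                    for j in range(5)
                    if totals[j, t] > 0
                ]
                assert out["mean_rate"][t] == pytest.approx(np.mean(col))
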