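"""Synthetic-world generators: landscapes, trees, Brownian niches,
occurrence sampling and background pools."""

import numpy as np
import pytest

from nichephylo.errors import DataError
from nichephylo.geodata import CONTINUOUS
from nichephylo.phylo_metrics import patristic_matrix
from nichephylo.synthetic_data import (evolve_niches, make_background_pool_cells,
                                       make_env_stack, make_world,
                                       sample_occurrences, simulate_tree)


class TestEnvStack:
    def test_same_seed_identical(self):
        a = make_env_stack(seed=3)
        b = make_env_stack(seed=3)
        for ga, gb in zip(a.layers, b.layers):
            np.testing.assert_array_equal(ga.values, gb.values)

    def test_high_smoothness_kills_variance(self):
        rough = make_env_stack(n_rows=32, n_cols=32, n_categorical=0,
                               smoothness=1.0, seed=4)
        # raw (pre-scaling) variance shrinks with smoothing; after min-max
        # scaling compare spatial roughness instead: lag-1 increments
        smooth = make_env_stack(n_rows=32, n_cols=32, n_categorical=0,
                                smoothness=8.0, seed=4)
        d_rough = np.abs(np.diff(rough.layers[0].values, axis=1)).mean()
        d_smooth = np.abs(np.diff(smooth.layers[0].values, axis=1)).mean()
        assert d_smooth < d_rough

    def test_spatial_autocorrelation_beats_shuffled_oracle(self):
        """Lag-1 Moran-style autocorrelation of a smooth layer exceeds that
        of the same values spatially shuffled."""
        stack = make_env_stack(n_rows=32, n_cols=32, n_categorical=0, seed=5)
        vals = stack.layers[0].values

        def lag1_corr(v):
            a = v[:, :-1].ravel() - v.mean()
            b = v[:, 1:].ravel() - v.mean()
            return float((a * b).mean() / v.var())

        rng = np.random.default_rng(0)
        shuffled = rng.permutation(vals.ravel()).reshape(vals.shape)
        assert lag1_corr(vals) > lag1_corr(shuffled) + 0.5

    def test_categorical_has_at_least_two_codes(self):
        stack = make_env_stack(seed=6)
        cat = [g for g, k in zip(stack.layers, stack.kinds)
               if k != CONTINUOUS][0]
        assert len(np.unique(cat.values)) >= 2

    def test_too_small_grid_rejected(self):
        with pytest.raises(DataError):
            make_env_stack(n_rows=4, n_cols=4)


class TestSimulateTree:
    def test_two_tips_cherry_depth_one(self):
        tree = simulate_tree(2, seed=0)
        assert len(tree.tip_labels) == 2
        mat = patristic_matrix(tree)
        a, b = sorted(tree.tip_labels)
        assert mat.loc[a, b] == pytest.approx(2.0)

    @pytest.mark.parametrize("n_tips", [2, 5, 16])
    def test_depth_one_ultrametric(self, n_tips):
        tree = simulate_tree(n_tips, seed=1)
        assert tree.ultrametric
        depths = [lf.distance_from_root()
                  for lf in tree.tree.leaf_node_iter()]
        np.testing.assert_allclose(depths, 1.0, atol=1e-9)

    def test_same_seed_identical_newick(self):
        a = simulate_tree(8, seed=2).tree.as_string(schema="newick")
        b = simulate_tree(8, seed=2).tree.as_string(schema="newick")
        assert a == b

    def test_mean_patristic_grows_with_tip_count(self):
        """Denser Yule trees coalesce a larger share of pairs near the
        root, nudging the average pairwise distance up on depth-1 trees.
        The effect is small, so it is averaged over 50 seeded trees."""
        def mean_dist(n, seeds):
            vals = []
            for s in seeds:
                mat = patristic_matrix(simulate_tree(n, seed=s))
                iu = np.triu_indices(len(mat), k=1)
                vals.append(mat.values[iu].mean())
            return np.mean(vals)

        assert mean_dist(64, range(50)) > mean_dist(4, range(50))


class TestEvolveNiches:
    def test_zero_rate_keeps_root_optimum(self):
        tree = simulate_tree(6, seed=3)
        optima = evolve_niches(tree, sigma2=0.0, seed=1)
        for v in optima.values():
            np.testing.assert_allclose(v, 0.5)

    def test_tip_variance_matches_bm_theory(self):
        """On a depth-1 cherry the tip value variance equals sigma2."""
        tree = simulate_tree(2, seed=4)
        sigma2 = 0.3
        tips = sorted(tree.tip_labels)
        draws = [evolve_niches(tree, sigma2=sigma2, n_dims=1, seed=s)[tips[0]][0]
                 for s in range(1000)]
        assert np.var(draws) == pytest.approx(sigma2, rel=0.15)

    def test_sisters_more_similar_than_distant_tips(self):
        """Average niche disparity grows with patristic distance."""
        diffs_close, diffs_far = [], []
        for s in range(30):
            tree = simulate_tree(8, seed=s)
            optima = evolve_niches(tree, sigma2=0.2, n_dims=1, seed=1000 + s)
            mat = patristic_matrix(tree)
            labels = list(mat.index)
            for i, a in enumerate(labels):
                for b in labels[i + 1:]:
                    gap = abs(optima[a][0] - optima[b][0])
                    (diffs_close if mat.loc[a, b] < 1.0 else
                     diffs_far).append(gap)
        assert np.mean(diffs_close) < np.mean(diffs_far)


class TestSampleOccurrences:
    def test_same_seed_identical(self):
        stack = make_env_stack(n_rows=16, n_cols=16, n_categorical=0, seed=7)
        optima = {"sp": np.array([0.5, 0.5])}
        a = sample_occurrences(stack, optima, seed=9)
        b = sample_occurrences(stack, optima, seed=9)
        assert a.records.equals(b.records)

    def test_small_tau_tracks_optimum(self):
        """Mean environment at sampled cells sits closer to the optimum
        than the domain mean does."""
        stack = make_env_stack(n_rows=32, n_cols=32, n_categorical=0, seed=8)
        target = np.array([0.9, 0.9])
        occ = sample_occurrences(stack, {"sp": target}, tau=0.05,
                                 n_per_species=20, seed=10)
        from nichephylo.geodata import assign_cells, deduplicate
        cells = deduplicate(assign_cells(occ, stack.grid)).records
        vals = np.array([[stack.layers[k].values[r, c] for k in range(2)]
                         for r, c in zip(cells.row, cells.col)])
        domain_mean = stack.valid_values()[:, :2].mean(axis=0)
        assert np.linalg.norm(vals.mean(axis=0) - target) < \
            np.linalg.norm(domain_mean - target)

    def test_huge_tau_near_uniform(self):
        """With very broad niches the sampled environmental mean
        approaches the domain mean."""
        stack = make_env_stack(n_rows=32, n_cols=32, n_categorical=0, seed=12)
        occ = sample_occurrences(stack, {"sp": np.array([0.9, 0.9])},
                                 tau=1e4, n_per_species=500, seed=13)
        from nichephylo.geodata import assign_cells
        cells = assign_cells(occ, stack.grid).records
        vals = np.array([stack.layers[0].values[r, c]
                         for r, c in zip(cells.row, cells.col)])
        domain_mean = stack.valid_values()[:, 0].mean()
        assert abs(vals.mean() - domain_mean) < 0.05

    def test_demand_exceeding_cells_rejected(self):
        stack = make_env_stack(n_rows=8, n_cols=8, n_categorical=0, seed=14)
        with pytest.raises(DataError):
            sample_occurrences(stack, {"sp": np.array([0.5, 0.5])},
                               n_per_species=65, seed=0)


class TestBackgroundPool:
    def test_union_of_disjoint_species(self):
        world = make_world(n_rows=32, n_cols=32, n_tips=4,
                           n_per_species=10, seed=20)
        pool = make_background_pool_cells(world, mode="union")
        # pool size equals the number of unique occupied cells
        from nichephylo.geodata import assign_cells, deduplicate
        occ = deduplicate(assign_cells(world.occurrences, world.env.grid))
        unique_cells = occ.records[["row", "col"]].drop_duplicates()
        assert len(pool) == len(unique_cells)

    def test_uniform_full_domain(self):
        world = make_world(n_rows=16, n_cols=16, n_tips=2,
                           n_per_species=5, seed=21)
        pool = make_background_pool_cells(world, mode="uniform",
                                          n_pool=world.env.n_valid_cells,
                                          seed=0)
        assert len(pool) == world.env.n_valid_cells

    def test_pool_has_no_duplicate_cells(self):
        world = make_world(n_rows=16, n_cols=16, n_tips=4,
                           n_per_species=10, seed=22)
        pool = make_background_pool_cells(world, mode="union")
        assert len(np.unique(pool, axis=0)) == len(pool)


class TestMakeWorld:
    def test_same_seed_identical_world(self):
        a = make_world(n_rows=16, n_cols=16, n_tips=4, n_per_species=5, seed=30)
        b = make_world(n_rows=16, n_cols=16, n_tips=4, n_per_species=5, seed=30)
        assert a.occurrences.records.equals(b.occurrences.records)
        assert a.tree.tree.as_string(schema="newick") == \
            b.tree.tree.as_string(schema="newick")

    def test_tips_and_species_agree(self):
        world = make_world(n_rows=16, n_cols=16, n_tips=5, n_per_species=5,
                           seed=31)
        assert sorted(world.tree.tip_labels) == world.occurrences.species

    def test_shuffle_tips_permutes_optima(self):
        plain = make_world(n_rows=16, n_cols=16, n_tips=6, n_per_species=5,
                           seed=32)
        shuffled = make_world(n_rows=16, n_cols=16, n_tips=6, n_per_species=5,
                              seed=32, shuffle_tips=True)
        plain_vals = sorted(map(tuple, plain.optima.values()))
        shuf_vals = sorted(map(tuple, shuffled.optima.values()))
        assert plain_vals == shuf_vals  # same multiset of optima
        assert any(not np.array_equal(plain.optima[k], shuffled.optima[k])
                   for k in plain.optima)
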