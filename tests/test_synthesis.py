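"""Neutral-landscape generator, composition control, and LSI metrics."""

import math

import numpy as np
import pytest

from pollscape.grid import AGRICULTURE, HABITAT, FieldMap, LandscapeGrid
from pollscape.synthesis import (
    ClusteringGradient,
    ConfigurationError,
    GeneratorSettings,
    build_clustering_gradient,
    default_candidates,
    generate_landscape,
    generate_random_field,
    landscape_shape_index,
    log_lsi,
    replicate_landscapes,
    select_equally_spaced,
    threshold_to_composition,
)

from conftest import brute_force_lsi

EXTENT = (2000.0, 2000.0)


class TestRandomField:
    def test_white_noise_has_negligible_spatial_correlation(self):
        s = GeneratorSettings(0.5, 10.0, 0.0, seed=11)
        f = generate_random_field(s, 10.0, EXTENT).values
        r = np.corrcoef(f[:, :-1].ravel(), f[:, 1:].ravel())[0, 1]
        assert abs(r) < 0.02

    def test_nearest_neighbour_upsampling_gives_constant_blocks(self):
        s = GeneratorSettings(0.5, 40.0, 0.0, seed=3)
        f = generate_random_field(s, 10.0, EXTENT).values
        blocks = f.reshape(50, 4, 50, 4)
        assert np.all(blocks == blocks[:, :1, :, :1])

    def test_smoothing_reduces_roughness(self):
        rough = generate_random_field(GeneratorSettings(0.5, 10.0, 0.0, seed=5), 10.0, EXTENT).values
        smooth = generate_random_field(GeneratorSettings(0.5, 10.0, 50.0, seed=5), 10.0, EXTENT).values
        assert np.abs(np.diff(smooth, axis=1)).mean() < np.abs(np.diff(rough, axis=1)).mean()

    def test_deterministic_given_seed(self):
        s = GeneratorSettings(0.3, 40.0, 20.0, seed=42)
        a = generate_random_field(s, 10.0, EXTENT).values
        b = generate_random_field(s, 10.0, EXTENT).values
        assert np.array_equal(a, b)
        c = generate_random_field(GeneratorSettings(0.3, 40.0, 20.0, seed=43), 10.0, EXTENT).values
        assert not np.array_equal(a, c)

    def test_invalid_settings_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_random_field(GeneratorSettings(0.5, 25.0), 10.0, EXTENT)  # not a multiple
        with pytest.raises(ConfigurationError):
            generate_random_field(GeneratorSettings(0.5, 10.0), 10.0, (0.0, 2000.0))
        with pytest.raises(ConfigurationError):
            generate_random_field(GeneratorSettings(0.5, 30.0), 10.0, EXTENT)  # extent not divisible
        with pytest.raises(ConfigurationError):
            GeneratorSettings(1.5, 10.0)


class TestComposition:
    @pytest.mark.parametrize("p,expected", [(0.0, 0), (0.03, 1200), (0.1, 4000), (0.5, 20000), (1.0, 40000)])
    def test_habitat_cell_count_exact(self, p, expected):
        f = generate_random_field(GeneratorSettings(p, 10.0, 0.0, seed=1), 10.0, EXTENT)
        grid = threshold_to_composition(f, p)
        assert int((grid.values == HABITAT).sum()) == expected

    def test_exact_count_despite_constant_blocks(self):
        # coarse blocks create massive ties; the count must still be exact
        f = generate_random_field(GeneratorSettings(0.05, 200.0, 0.0, seed=2), 10.0, EXTENT)
        grid = threshold_to_composition(f, 0.05)
        assert int((grid.values == HABITAT).sum()) == 2000

    def test_habitat_occupies_top_quantile(self):
        rng = np.random.default_rng(0)
        f = FieldMap(rng.normal(size=(30, 30)), "random", cell_size=10.0)
        grid = threshold_to_composition(f, 0.2)
        hab = grid.values == HABITAT
        assert f.values[hab].min() >= f.values[~hab].max()


class TestShapeIndex:
    def test_single_class_square_attains_minimum(self):
        grid = LandscapeGrid(np.full((200, 200), HABITAT, dtype=np.int32), cell_size=10.0)
        assert landscape_shape_index(grid) == pytest.approx(1.0)
        assert log_lsi(grid) == pytest.approx(0.0)

    def test_half_split_analytic_value(self, half_split_grid):
        assert landscape_shape_index(half_split_grid) == pytest.approx(1.25)
        assert log_lsi(half_split_grid) == pytest.approx(math.log(1.25))
        assert log_lsi(half_split_grid) == pytest.approx(0.2231, abs=1e-4)

    def test_checkerboard_analytic_value(self, checkerboard_grid):
        assert landscape_shape_index(checkerboard_grid) == pytest.approx(100.5)
        assert log_lsi(checkerboard_grid) == pytest.approx(4.610, abs=1e-3)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_pair_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 50))
        values = rng.choice([HABITAT, AGRICULTURE], size=(n, n)).astype(np.int32)
        grid = LandscapeGrid(values, cell_size=float(rng.integers(1, 20)))
        assert landscape_shape_index(grid) == pytest.approx(brute_force_lsi(grid), rel=1e-12)
        assert log_lsi(grid) >= 0.0


class TestClusteringGradient:
    def test_log_lsi_decreases_with_coarser_blocks_and_smoothing(self):
        def mean_ll(coarse, acl):
            vals = [
                log_lsi(generate_landscape(GeneratorSettings(0.3, coarse, acl, seed=s), 10.0, EXTENT))
                for s in range(20)
            ]
            return np.mean(vals)

        by_coarse = [mean_ll(c, 0.0) for c in (10.0, 40.0, 100.0)]
        assert by_coarse[0] > by_coarse[1] > by_coarse[2]
        by_acl = [mean_ll(10.0, a) for a in (0.0, 20.0, 80.0)]
        assert by_acl[0] > by_acl[1] > by_acl[2]

    def test_selection_matches_equal_spacing_example(self):
        # brute-force over all 3-subsets of {0.2, 0.5, 1.1, 2.3, 4.6}
        means = [0.2, 0.5, 1.1, 2.3, 4.6]
        idx = select_equally_spaced(means, 3)
        assert [means[i] for i in idx] == [0.2, 2.3, 4.6]

    @pytest.mark.parametrize("seed", range(5))
    def test_selection_matches_brute_force_subsets(self, seed):
        from itertools import combinations

        rng = np.random.default_rng(seed)
        means = np.sort(rng.uniform(0, 5, size=8))
        k = int(rng.integers(2, 7))
        targets = np.linspace(means.min(), means.max(), k)

        def cost(subset):
            return sum(abs(means[i] - t) for i, t in zip(sorted(subset), targets))

        best = min(cost(c) for c in combinations(range(len(means)), k))
        got = select_equally_spaced(means, k)
        assert cost(got) == pytest.approx(best, rel=1e-12)

    def test_all_candidates_selected_when_counts_match(self):
        means = [3.0, 0.4, 1.7]
        assert [means[i] for i in select_equally_spaced(means, 3)] == [0.4, 1.7, 3.0]

    def test_gradient_levels_strictly_increasing(self):
        grad = build_clustering_gradient(
            0.1, default_candidates(0.1), 4, reps_for_estimation=3, base_seed=0
        )
        assert len(grad.levels) == 4
        assert all(b > a for a, b in zip(grad.level_log_lsi, grad.level_log_lsi[1:]))
        assert grad.most_clustered is grad.levels[0]

    def test_degenerate_and_invalid_gradients_rejected(self):
        cands = default_candidates(0.1)
        with pytest.raises(ConfigurationError):
            build_clustering_gradient(0.1, cands[:2], 3, reps_for_estimation=2)
        with pytest.raises(ConfigurationError):
            build_clustering_gradient(0.1, [cands[0], cands[0]], 2, reps_for_estimation=2)


class TestReplicates:
    def test_counts_seeds_and_composition(self):
        grad = ClusteringGradient(
            0.05,
            (GeneratorSettings(0.05, 10.0, 0.0), GeneratorSettings(0.05, 40.0, 20.0),
             GeneratorSettings(0.05, 200.0, 100.0)),
            (0.3, 1.2, 2.3),
        )
        reps = replicate_landscapes(grad, 5, base_seed=9, extent=EXTENT)
        assert len(reps) == 15
        assert len({r.seed for r in reps}) == 15
        for r in reps:
            assert int((r.grid.values == HABITAT).sum()) == 2000

    def test_reproducible_from_base_seed(self):
        grad = ClusteringGradient(0.1, (GeneratorSettings(0.1, 40.0, 20.0),), (1.0,))
        a = replicate_landscapes(grad, 3, base_seed=4, extent=(400.0, 400.0))
        b = replicate_landscapes(grad, 3, base_seed=4, extent=(400.0, 400.0))
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.grid.values, rb.grid.values)
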