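import numpy as np
import pytest
from shapely.geometry import box

from hetspot.grids import GridSpec, Surface
from hetspot.hetkde import KdeSpec
from hetspot.mc_significance import (
    McSpec,
    consensus_overlap,
    deconstruct_restricted,
    mc_pvalue,
    run_mc,
    simulate_null_unrestricted,
)
from hetspot.spatial_prep import build_voronoi


class TestMcPvalue:
    def _surfaces(self, actual_val, null_vals):
        g = GridSpec(0, 0, 2, 2, 1.0)
        actual = Surface.full(g, actual_val)
        nulls = [Surface.full(g, v) for v in null_vals]
        return actual, nulls

    def test_actual_below_every_null(self):
        actual, nulls = self._surfaces(0.1, [0.5] * 9)
        p = mc_pvalue(actual, nulls)
        assert (p.values == 1.0).all()

    def test_actual_above_every_null_k999(self):
        actual, nulls = self._surfaces(9.0, [0.5] * 999)
        p = mc_pvalue(actual, nulls)
        np.testing.assert_allclose(p.values, 0.001)

    def test_half_exceedance(self):
        actual, nulls = self._surfaces(0.5, [1.0] * 499 + [0.0] * 500)
        p = mc_pvalue(actual, nulls)  # ties count toward exceedance
        np.testing.assert_allclose(p.values, 0.5)

    def test_tie_counts_as_exceedance(self):
        actual, nulls = self._surfaces(0.5, [0.5])
        assert (mc_pvalue(actual, nulls).values == 1.0).all()

    def test_monotone_in_null_surfaces(self):
        """Adding a null surface strictly below the actual cannot raise any p."""
        rng = np.random.default_rng(0)
        g = GridSpec(0, 0, 4, 4, 1.0)
        actual = Surface(g, rng.uniform(1, 2, g.shape))
        nulls = [Surface(g, rng.uniform(0, 3, g.shape)) for _ in range(9)]
        p_before = mc_pvalue(actual, nulls)
        low = Surface(g, actual.values - 0.5)
        p_after = mc_pvalue(actual, nulls + [low])
        assert (p_after.values <= p_before.values + 1e-15).all()

    def test_grid_mismatch_rejected(self):
        a = Surface.full(GridSpec(0, 0, 2, 2, 1.0), 1.0)
        b = Surface.full(GridSpec(0, 0, 3, 3, 1.0), 1.0)
        with pytest.raises(ValueError):
            mc_pvalue(a, [b])


@pytest.fixture()
def toy_geometry():
    boundary = box(0, 0, 2000, 1000)
    part = build_voronoi([(500.0, 500.0), (1500.0, 500.0)], boundary, ["a", "b"])
    grid = GridSpec(0, 0, 8, 4, 250.0)
    expected = Surface(grid, np.ones(grid.shape) * 0.5)
    return part, grid, expected


class TestDeconstruction:
    def test_counts_preserved_exactly(self, toy_geometry):
        part, grid, expected = toy_geometry
        rng = np.random.default_rng(1)
        pts = deconstruct_restricted({"a": 7, "b": 3}, part, expected, rng)
        assert len(pts) == 10
        # restriction: points stay in their own village half
        assert (pts[:, 0] < 1000).sum() == 7

    def test_single_cell_village_gets_all_cases(self):
        boundary = box(0, 0, 500, 250)
        part = build_voronoi([(125.0, 125.0), (375.0, 125.0)], boundary, ["a", "b"])
        grid = GridSpec(0, 0, 2, 1, 250.0)
        expected = Surface(grid, np.array([[1.0, 1.0]]))
        pts = deconstruct_restricted(
            {"a": 5, "b": 0}, part, expected, np.random.default_rng(0)
        )
        assert (pts == [125.0, 125.0]).all()

    def test_multinomial_mean_oracle(self):
        """A 2-cell village with 0.75/0.25 expected mass allocates 4 cases 3:1."""
        boundary = box(0, 0, 500, 250)
        part = build_voronoi([(250.0, 125.0)], boundary, ["a"])
        grid = GridSpec(0, 0, 2, 1, 250.0)
        expected = Surface(grid, np.array([[0.75, 0.25]]))
        rng = np.random.default_rng(42)
        n_rep, n_cases = 10_000, 4
        left = sum(
            (deconstruct_restricted({"a": n_cases}, part, expected, rng)[:, 0] < 250).sum()
            for _ in range(n_rep)
        )
        mean_left = left / n_rep
        sigma = np.sqrt(n_cases * 0.75 * 0.25 / n_rep)
        assert mean_left == pytest.approx(3.0, abs=4 * sigma)

    def test_cases_without_mass_rejected(self, toy_geometry):
        part, grid, _ = toy_geometry
        empty = Surface(grid, np.zeros(grid.shape))
        with pytest.raises(ValueError, match="zero expected mass"):
            deconstruct_restricted({"a": 1, "b": 0}, part, empty, np.random.default_rng(0))

    def test_negative_counts_rejected(self, toy_geometry):
        part, _, expected = toy_geometry
        with pytest.raises(ValueError):
            deconstruct_restricted({"a": -1, "b": 0}, part, expected, np.random.default_rng(0))


class TestNullSimulation:
    def test_zero_cases_empty(self, toy_geometry):
        _, _, expected = toy_geometry
        pts = simulate_null_unrestricted(0, expected, np.random.default_rng(0))
        assert pts.shape == (0, 2)

    def test_point_count_exact(self, toy_geometry):
        _, _, expected = toy_geometry
        pts = simulate_null_unrestricted(37, expected, np.random.default_rng(3))
        assert len(pts) == 37

    def test_binomial_frequency_oracle(self):
        grid = GridSpec(0, 0, 2, 1, 100.0)
        expected = Surface(grid, np.array([[0.9, 0.1]]))
        rng = np.random.default_rng(5)
        n = 10_000
        left = sum(
            (simulate_null_unrestricted(1, expected, rng)[:, 0] < 100).sum()
            for _ in range(n)
        )
        sigma = np.sqrt(0.9 * 0.1 / n)
        assert left / n == pytest.approx(0.9, abs=3 * sigma)

    def test_zero_mass_rejected(self):
        grid = GridSpec(0, 0, 2, 2, 1.0)
        with pytest.raises(ValueError):
            simulate_null_unrestricted(1, Surface.zeros(grid), np.random.default_rng(0))


class TestMcSpec:
    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            McSpec(k_sims=0)
        with pytest.raises(ValueError):
            McSpec(r_realizations=1)
        with pytest.raises(ValueError):
            McSpec(alpha=0.0)

    def test_unattainable_alpha_warns(self):
        with pytest.warns(UserWarning, match="no cell can ever be flagged"):
            McSpec(k_sims=199, alpha=0.001)


class TestRunMc:
    def _run(self, county, bg, seed, k_sims=199, alpha=0.005, r=5, h=1500.0):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            mc = McSpec(k_sims, r, alpha, seed=seed)
        return run_mc(
            county.cases_by_village(), county.partition, bg,
            KdeSpec("fixed", h=h), mc, rng=np.random.default_rng(seed),
        )

    def test_deterministic_under_seed(self, small_cluster_county, cluster_background):
        _, bg = cluster_background
        g1 = self._run(small_cluster_county, bg, seed=5)
        g2 = self._run(small_cluster_county, bg, seed=5)
        np.testing.assert_array_equal(g1.mean_p.values, g2.mean_p.values)
        np.testing.assert_array_equal(g1.std_p.values, g2.std_p.values)
        np.testing.assert_array_equal(g1.hotspot.values, g2.hotspot.values)

    def test_p_values_in_valid_range(self, small_cluster_county, cluster_background):
        _, bg = cluster_background
        g = self._run(small_cluster_county, bg, seed=2, k_sims=99)
        defined = ~np.isnan(g.mean_p.values)
        assert (g.mean_p.values[defined] >= 1 / 100).all()
        assert (g.mean_p.values[defined] <= 1.0).all()

    def test_hotspot_rule_more_conservative_than_mean_alone(
        self, small_cluster_county, cluster_background
    ):
        _, bg = cluster_background
        g = self._run(small_cluster_county, bg, seed=3, k_sims=999)
        flagged = g.hotspot.values == 1
        assert (g.mean_p.values[flagged] < 0.005).all()  # {H=1} ⊆ {mean_p < α}

    def test_null_p_values_super_uniform(self, small_null_county, null_background):
        """On a null county P(p ≤ t) ≤ t holds for the mean-p surface."""
        _, bg = null_background
        g = self._run(small_null_county, bg, seed=4, k_sims=199)
        vals = g.mean_p.values[~np.isnan(g.mean_p.values)]
        for t in (0.01, 0.05, 0.1, 0.25):
            # allow 3σ binomial slack on the cell fraction (cells correlate,
            # so this is a coarse guard against gross anti-conservatism)
            frac = (vals <= t).mean()
            assert frac <= t + 3 * np.sqrt(t * (1 - t) / len(vals)) + 0.05


class TestConsensus:
    def _masks(self, values):
        g = GridSpec(0, 0, 2, 2, 1.0)
        return [Surface(g, np.asarray(v, dtype=float)) for v in values]

    def test_all_zero(self):
        masks = self._masks([np.zeros((2, 2))] * 3)
        assert consensus_overlap(masks).sum() == 0

    def test_identical_masks(self):
        m = np.array([[1.0, 0.0], [0.0, 1.0]])
        counts = consensus_overlap(self._masks([m] * 8))
        assert set(np.unique(counts.values)) == {0.0, 8.0}

    def test_elementwise_sum_oracle(self):
        rng = np.random.default_rng(7)
        arrays = [rng.integers(0, 2, (2, 2)).astype(float) for _ in range(5)]
        counts = consensus_overlap(self._masks(arrays))
        np.testing.assert_array_equal(counts.values, np.sum(arrays, axis=0))

    def test_quorum_thresholding(self):
        arrays = [np.array([[1.0, 1.0], [0.0, 0.0]]), np.array([[1.0, 0.0], [0.0, 0.0]])]
        certain = consensus_overlap(self._masks(arrays), quorum=2)
        np.testing.assert_array_equal(certain.values, [[1.0, 0.0], [0.0, 0.0]])
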