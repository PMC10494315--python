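import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import brute_force_bh
from geniche import integrate as ig
from geniche.stats import bh_adjust, rank_sum_test


class TestScaling:
    def test_minmax_arithmetic(self):
        np.testing.assert_allclose(ig.scale_to_range([0, 5, 10]), [0.0, 0.45, 0.9])

    def test_constant_maps_to_lo(self):
        out = ig.scale_to_range([3.0, 3.0, 3.0])
        np.testing.assert_array_equal(out, 0.0)

    def test_absolute_value_rule_then_minmax(self):
        out = ig.scale_to_range([-0.4, 0.2], absolute=True)
        np.testing.assert_allclose(out, [0.9, 0.0])


class TestIndex:
    def test_endpoints_exact(self):
        rng = np.random.default_rng(1)
        B, C = rng.uniform(0, 0.9, 20), rng.uniform(0, 0.9, 20)
        np.testing.assert_array_equal(ig.genomic_niche_index(B, C, 1.0), B)
        np.testing.assert_array_equal(ig.genomic_niche_index(B, C, 0.0), C)

    def test_hand_value(self):
        assert ig.genomic_niche_index([0.36], [0.64], 0.5)[0] == pytest.approx(0.48)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        st.integers(min_value=0, max_value=10_000),
        st.floats(min_value=0.0, max_value=1.0),
    )
    def test_geometric_mean_bounds(self, seed, alpha):
        rng = np.random.default_rng(seed)
        B = rng.uniform(1e-6, 0.9, 200)
        C = rng.uniform(1e-6, 0.9, 200)
        A = ig.genomic_niche_index(B, C, alpha)
        assert (A >= np.minimum(B, C) - 1e-12).all()
        assert (A <= np.maximum(B, C) + 1e-12).all()

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_monotone_in_each_base(self, seed):
        rng = np.random.default_rng(seed)
        C = rng.uniform(0.01, 0.9, 50)
        B1 = rng.uniform(0.01, 0.9, 50)
        B2 = B1 + rng.uniform(0.0, 0.1, 50)
        alpha = rng.uniform(0.05, 0.95)
        assert (
            ig.genomic_niche_index(B2, C, alpha)
            >= ig.genomic_niche_index(B1, C, alpha) - 1e-12
        ).all()
        C2 = C + rng.uniform(0.0, 0.1, 50)
        assert (
            ig.genomic_niche_index(B1, C2, alpha)
            >= ig.genomic_niche_index(B1, C, alpha) - 1e-12
        ).all()

    def test_zero_base_gives_zero(self):
        assert ig.genomic_niche_index([0.0], [0.5], 0.5)[0] == 0.0


class TestOptimizer:
    def grid_min(self, B, C, objective):
        grid = np.arange(0.0, 1.0 + 1e-12, 1e-4)
        vals = [ig.deviation(B, C, a, objective) for a in grid]
        i = int(np.argmin(vals))
        return grid[i], vals[i]

    def test_equal_inputs_deviation_zero(self):
        B = np.array([0.2, 0.5, 0.7])
        a, d = ig.optimize_alpha(B, B, seed=0)
        assert d == pytest.approx(0.0, abs=1e-12)

    def test_single_cell_matches_grid_search(self):
        B, C = np.array([0.9]), np.array([0.1])
        a, _ = ig.optimize_alpha(B, C, seed=2, objective="l2")
        a_grid, _ = self.grid_min(B, C, "l2")
        assert abs(a - a_grid) < 1e-3

    @pytest.mark.parametrize("objective", ["l1", "l2"])
    def test_hundred_cells_match_grid_search(self, objective):
        rng = np.random.default_rng(21)
        B = rng.uniform(0, 0.9, 100)
        C = rng.uniform(0, 0.9, 100)
        a, d = ig.optimize_alpha(B, C, seed=21, objective=objective)
        _, d_grid = self.grid_min(B, C, objective)
        assert d <= d_grid + 1e-6

    def test_never_worse_than_endpoints(self):
        rng = np.random.default_rng(3)
        B = rng.uniform(0, 0.9, 60)
        C = rng.uniform(0, 0.9, 60)
        _, d = ig.optimize_alpha(B, C, seed=3)
        assert d <= ig.deviation(B, C, 0.0) + 1e-9
        assert d <= ig.deviation(B, C, 1.0) + 1e-9

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            ig.optimize_alpha(np.array([]), np.array([]))


class TestComparisons:
    def test_exact_wilcoxon_by_enumeration(self):
        x, y = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        _, p = rank_sum_test(x, y)
        # full enumeration oracle: rank-sum of group 1 over all 20 splits
        pooled = np.array(x + y)
        obs = sum(sorted(pooled).index(v) + 1 for v in x)
        stats_all = [
            sum(i + 1 for i in comb)
            for comb in itertools.combinations(range(6), 3)
        ]
        lo = sum(1 for s in stats_all if s <= obs)
        p_exact = 2 * lo / len(stats_all)
        assert p == pytest.approx(p_exact) == pytest.approx(0.1)

    def test_identical_groups_p_one(self):
        vals = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        labs = np.array(["a"] * 3 + ["b"] * 3)
        comp = ig.compare_clusters({"x": vals}, {"x": labs})
        assert comp.table["p"].iloc[0] == pytest.approx(1.0)

    def test_single_comparison_bh_identity(self):
        vals = np.random.default_rng(0).normal(size=10)
        labs = np.array(["a"] * 5 + ["b"] * 5)
        comp = ig.compare_clusters({"x": vals}, {"x": labs})
        assert comp.table["p_adj"].iloc[0] == pytest.approx(comp.table["p"].iloc[0])

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_bh_matches_brute_force(self, seed):
        p = np.random.default_rng(seed).uniform(size=17)
        np.testing.assert_allclose(bh_adjust(p), brute_force_bh(p), rtol=1e-10)


class TestRiskSurface:
    def make_surface(self, a_north, a_south):
        n = len(a_north) + len(a_south)
        return pd.DataFrame(
            {
                "B": 0.5,
                "C": 0.5,
                "A": np.concatenate([a_north, a_south]),
                "alpha": 0.5,
                "cluster": ["north"] * len(a_north) + ["south"] * len(a_south),
            }
        )

    def test_lowest_index_cluster_flagged(self):
        surf = self.make_surface(np.full(5, 0.513), np.full(5, 0.279))
        rep = ig.risk_report(surf)
        assert rep["highest_risk_cluster"] == "south"
        assert rep["cluster_means"] == {"north": 0.513, "south": 0.279}

    def test_all_equal_no_flag(self):
        surf = self.make_surface(np.full(3, 0.4), np.full(3, 0.4))
        rep = ig.risk_report(surf)
        assert rep["highest_risk_cluster"] is None

    def test_build_decreased_only_and_alpha_column(self):
        rng = np.random.default_rng(5)
        delta = rng.uniform(-0.5, 0.5, 200)
        offset = rng.uniform(0, 0.1, 200)
        clusters = np.where(rng.random(200) < 0.5, "north", "south")
        surf = ig.build_risk_surface(delta, offset, clusters, seed=1)
        assert len(surf) == (delta < 0).sum()
        assert surf["alpha"].nunique() == 1
        assert ((surf["B"] >= 0) & (surf["B"] <= 0.9)).all()
        assert ((surf["C"] >= 0) & (surf["C"] <= 0.9)).all()
        A = surf["A"].to_numpy()
        pos = (surf["B"] > 0) & (surf["C"] > 0)
        assert (
            A[pos] >= np.minimum(surf["B"], surf["C"])[pos] - 1e-12
        ).all()

    def test_deviation_continuity_coarse(self):
        rng = np.random.default_rng(9)
        B = rng.uniform(0, 0.9, 50)
        C = rng.uniform(0, 0.9, 50)
        grid = np.linspace(0, 1, 501)
        vals = np.array([ig.deviation(B, C, a) for a in grid])
        assert np.abs(np.diff(vals)).max() < 0.2  # no jumps on a fine grid
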