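"""kNN density estimator and permutation p-value maps."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oligoniche.datatypes import GridSpec, PointPattern, PValueMap
from oligoniche.density import (
    density_pvalue_map,
    knn_density_map,
    recenter_pattern,
    significant_region_area,
)
from oligoniche.synthetic import CohortSpec, gen_cohort_patterns


def brute_force_density(pattern, grid, k):
    """Independent oracle: all-pairs distances + explicit sort."""
    nodes = grid.nodes_xy()
    vals = np.empty(len(nodes))
    pts = pattern.xy
    for i, node in enumerate(nodes):
        d = np.sort(np.sqrt(((pts - node) ** 2).sum(axis=1)))
        dk = max(d[k - 1], grid.spacing / 2)
        vals[i] = k / (pattern.n * np.pi * dk**2)
    return vals.reshape(grid.shape)


class TestRecenter:
    def test_identity_and_single_point(self):
        p = PointPattern([[5.0, 5.0, 0.0]])
        assert np.allclose(recenter_pattern(p, (0, 0, 0)).coords, p.coords)
        assert np.allclose(recenter_pattern(p, (5, 5, 0)).coords, 0)

    @settings(max_examples=25, derandomize=True)
    @given(
        cx=st.floats(-100, 100), cy=st.floats(-100, 100),
        x=st.floats(-50, 50), y=st.floats(-50, 50),
    )
    def test_involution(self, cx, cy, x, y):
        p = PointPattern([[x, y, 0.0]])
        back = recenter_pattern(recenter_pattern(p, (cx, cy, 0)), (-cx, -cy, 0))
        np.testing.assert_allclose(back.coords, p.coords, atol=1e-9)

    def test_nonfinite_center_rejected(self):
        with pytest.raises(ValueError):
            recenter_pattern(PointPattern([[0, 0]]), (np.nan, 0, 0))


class TestKnnDensity:
    def test_unit_square_worked_value(self):
        """Four corner cells, k=2: density at the center node is 1/pi."""
        p = PointPattern([[0, 0], [1, 0], [0, 1], [1, 1]])
        grid = GridSpec((0, 1), (0, 1), 0.5)
        dg = knn_density_map(p, grid, k=2)
        assert dg.values[1, 1] == pytest.approx(1 / np.pi, abs=1e-12)

    def test_matches_bruteforce_oracle(self, rng):
        grid = GridSpec((-100, 100), (-100, 100), 25.0)
        for k in (1, 2, 8):
            pts = rng.uniform(-120, 120, size=(60, 2))
            p = PointPattern(pts)
            np.testing.assert_allclose(
                knn_density_map(p, grid, k).values,
                brute_force_density(p, grid, k),
                atol=1e-12,
            )

    def test_scaling_dimension(self, rng):
        """Scaling all lengths by s scales density by 1/s²."""
        pts = rng.uniform(-100, 100, size=(50, 2))
        g1 = GridSpec((-100, 100), (-100, 100), 50.0)
        s = 3.0
        g2 = GridSpec((-100 * s, 100 * s), (-100 * s, 100 * s), 50.0 * s)
        d1 = knn_density_map(PointPattern(pts), g1, k=4).values
        d2 = knn_density_map(PointPattern(pts * s), g2, k=4).values
        np.testing.assert_allclose(d2, d1 / s**2, rtol=1e-12)

    def test_homogeneous_pattern_recovered(self, rng):
        """Interior nodes of a dense uniform pattern track the flat density."""
        n = 1000
        pts = rng.uniform(0, 1000, size=(n, 2))
        grid = GridSpec((200, 800), (200, 800), 50.0)
        vals = knn_density_map(PointPattern(pts), grid, k=8).values
        true = 1.0 / 1000**2  # normalized density of a uniform pattern
        rel_err = np.abs(vals - true) / true
        assert np.median(rel_err) <= 0.30

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError, match="k=8"):
            knn_density_map(PointPattern([[0, 0], [1, 1]]), GridSpec(), k=8)

    def test_stacked_cells_floor_keeps_density_finite(self):
        p = PointPattern([[0.0, 0.0]] * 10)
        grid = GridSpec((-10, 10), (-10, 10), 2.0)
        vals = knn_density_map(p, grid, k=8).values
        assert np.all(np.isfinite(vals)) and np.all(vals > 0)


def _split(patterns):
    return ([p for p in patterns if p.group == "A"], [p for p in patterns if p.group == "B"])


class TestPValueMap:
    def test_identical_groups_degenerate(self, small_grid):
        pats = gen_cohort_patterns(CohortSpec(seed=0))
        ga, _ = _split(pats)
        pv = density_pvalue_map(ga, list(ga), small_grid, b_perm=99, seed=0)
        assert np.allclose(pv.delta, 0.0)
        assert np.all(pv.p == 1.0)

    def test_group_swap_antisymmetry(self, small_grid):
        """Swapping the groups negates delta; exhaustive p is unchanged."""
        ga, gb = _split(gen_cohort_patterns(
            CohortSpec(excess_ratio=1.0, n_sections_per_animal=1, seed=1)))
        pv1 = density_pvalue_map(ga, gb, small_grid, exhaustive_cap=20)
        pv2 = density_pvalue_map(gb, ga, small_grid, exhaustive_cap=20)
        assert pv1.exhaustive and pv2.exhaustive
        np.testing.assert_allclose(pv1.delta, -pv2.delta, atol=1e-15)
        np.testing.assert_allclose(pv1.p, pv2.p)
        # sampled mode: delta still antisymmetric, p equal in distribution
        pv3 = density_pvalue_map(ga, gb, small_grid, b_perm=300, seed=5, exhaustive_cap=0)
        pv4 = density_pvalue_map(gb, ga, small_grid, b_perm=300, seed=5, exhaustive_cap=0)
        np.testing.assert_allclose(pv3.delta, -pv4.delta, atol=1e-15)
        assert np.quantile(np.abs(pv3.p - pv4.p), 0.95) < 0.15

    def test_exhaustive_animal_level_enumeration(self, small_grid):
        """3v3 animals: exactly C(6,3)=20 arrangements, attainable p = i/20."""
        pats = gen_cohort_patterns(
            CohortSpec(excess_ratio=3.0, n_sections_per_animal=2, seed=1))
        ga, gb = _split(pats)
        pv = density_pvalue_map(ga, gb, small_grid, unit="animal")
        assert pv.exhaustive and pv.n_arrangements == 20
        np.testing.assert_allclose(pv.p * 20, np.round(pv.p * 20), atol=1e-9)
        assert pv.p.min() == pytest.approx(0.1)

    def test_exhaustive_and_sampled_agree(self, small_grid):
        """Sampled p converges to the exhaustive p when B >> arrangements."""
        pats = gen_cohort_patterns(
            CohortSpec(n_animals_per_group=3, n_sections_per_animal=1,
                       excess_ratio=2.0, seed=2))
        ga, gb = _split(pats)
        ex = density_pvalue_map(ga, gb, small_grid, unit="section", exhaustive_cap=20)
        assert ex.exhaustive
        sa = density_pvalue_map(ga, gb, small_grid, unit="section", exhaustive_cap=0,
                                b_perm=4999, seed=3)
        assert not sa.exhaustive
        assert np.quantile(np.abs(sa.p - ex.p), 0.95) < 0.05

    def test_small_groups_rejected(self, small_grid):
        pats = gen_cohort_patterns(CohortSpec(seed=0))
        ga, gb = _split(pats)
        with pytest.raises(ValueError):
            density_pvalue_map(ga[:1], gb, small_grid)

    def test_permutation_pvalues_valid_under_null(self, small_grid):
        """P(p <= alpha) <= alpha + MC error on exchangeable patterns."""
        rates = {0.01: [], 0.05: [], 0.1: []}
        for seed in range(8):
            ga, gb = _split(gen_cohort_patterns(CohortSpec(excess_ratio=0.0, seed=seed)))
            pv = density_pvalue_map(ga, gb, small_grid, b_perm=199, seed=seed)
            for a in rates:
                rates[a].append((pv.p <= a).mean())
        for a, r in rates.items():
            assert np.mean(r) <= a + 0.03


class TestSignificantRegion:
    def _flat_map(self, p_value, delta=1.0):
        grid = GridSpec((-100, 100), (-100, 100), 50.0)
        shape = grid.shape
        return PValueMap(grid=grid, delta=np.full(shape, delta),
                         p=np.full(shape, p_value))

    def test_all_null_map_has_zero_area(self):
        reg = significant_region_area(self._flat_map(1.0), 0.05, "B>A")
        assert reg["area_um2"] == 0.0 and not reg["centroid_defined"]

    def test_alpha_near_one_flags_full_grid(self):
        pv = self._flat_map(0.5)
        reg = significant_region_area(pv, 1 - 1e-9, "B>A")
        assert reg["node_count"] == pv.p.size
        assert reg["area_um2"] == pv.p.size * pv.grid.spacing**2

    def test_invalid_inputs_rejected(self):
        pv = self._flat_map(0.5)
        with pytest.raises(ValueError):
            significant_region_area(pv, 0.0, "B>A")
        with pytest.raises(ValueError):
            significant_region_area(pv, 0.05, "B<A")
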