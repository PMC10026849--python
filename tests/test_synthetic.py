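"""Generators: determinism, ground truth bookkeeping, and analytic means."""

import numpy as np
import pytest

from oligoniche.proximity import nearest_vessel_distances
from oligoniche.synthetic import (
    AttractionSpec,
    CohortSpec,
    gen_cohort_patterns,
    gen_fiber_set,
    gen_opc_positions,
    gen_section_areas,
    gen_vessel_network,
    gen_voxel_masks,
)


def _annulus_counts(patterns, annulus):
    r_in, r_out = annulus
    out = {}
    for g in ("A", "B"):
        counts = []
        for p in (q for q in patterns if q.group == g):
            r = np.hypot(p.coords[:, 0], p.coords[:, 1])
            counts.append(np.count_nonzero((r >= r_in) & (r <= r_out)))
        out[g] = np.array(counts)
    return out


class TestCohort:
    def test_determinism_bit_identical(self):
        spec = CohortSpec(excess_ratio=1.0, seed=42)
        a = gen_cohort_patterns(spec)
        b = gen_cohort_patterns(spec)
        assert len(a) == len(b) == 18
        for p, q in zip(a, b):
            assert (p.group, p.animal, p.section) == (q.group, q.animal, q.section)
            np.testing.assert_array_equal(p.coords, q.coords)

    def test_null_cohort_groups_identically_distributed(self):
        """excess_ratio=0: both groups drawn from the same uniform intensity."""
        spec = CohortSpec(excess_ratio=0.0, n_sections_per_animal=10, seed=3)
        pats = gen_cohort_patterns(spec)
        counts = _annulus_counts(pats, spec.annulus)
        mean_expected = spec.baseline_intensity * spec.annulus_area
        for g in ("A", "B"):
            se = np.sqrt(mean_expected / len(counts[g]))
            assert abs(counts[g].mean() - mean_expected) < 3 * se

    def test_annulus_excess_doubles_group_b_counts(self):
        """excess_ratio=1 doubles the expected annulus count for group B only."""
        spec = CohortSpec(
            cells_per_section_mean=200.0, excess_ratio=1.0,
            n_sections_per_animal=10, seed=11,
        )
        pats = gen_cohort_patterns(spec)
        counts = _annulus_counts(pats, spec.annulus)
        lam_ann = spec.baseline_intensity * spec.annulus_area
        n = len(counts["A"])
        assert abs(counts["A"].mean() - lam_ann) < 3 * np.sqrt(lam_ann / n)
        assert abs(counts["B"].mean() - 2 * lam_ann) < 3 * np.sqrt(2 * lam_ann / n)

    def test_poisson_count_mean_and_variance(self):
        spec = CohortSpec(n_animals_per_group=1, n_sections_per_animal=60, seed=5)
        pats = [p for p in gen_cohort_patterns(spec) if p.group == "A"]
        counts = np.array([p.n for p in pats])
        mu = spec.cells_per_section_mean
        assert abs(counts.mean() - mu) < 3 * np.sqrt(mu / len(counts))
        # Poisson variance ≈ mean; SE(var) ≈ mu * sqrt(2/(n-1))
        assert abs(counts.var(ddof=1) - mu) < 3 * mu * np.sqrt(2 / (len(counts) - 1))

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(cells_per_section_mean=-5)
        with pytest.raises(ValueError):
            CohortSpec(annulus=(500.0, 300.0))
        with pytest.raises(ValueError):
            CohortSpec(excess_ratio=-0.1)


class TestVesselNetwork:
    def test_single_branch_has_no_junctions(self):
        g = gen_vessel_network(n_branches=1, seed=0)
        assert g.meta["true_junction_count"] == 0 == g.junction_count

    def test_ground_truth_length_is_sum_of_segments(self):
        g = gen_vessel_network(n_branches=5, seed=2)
        assert g.meta["true_total_length"] == pytest.approx(g.segment_lengths().sum())

    def test_determinism(self):
        a = gen_vessel_network(n_branches=8, seed=9)
        b = gen_vessel_network(n_branches=8, seed=9)
        np.testing.assert_array_equal(a.nodes, b.nodes)
        np.testing.assert_array_equal(a.segments, b.segments)

    def test_zero_step_rejected(self):
        with pytest.raises(ValueError):
            gen_vessel_network(step=0.0)


class TestOpcPositions:
    def test_no_attraction_matches_uniform_baseline(self, vessel_net):
        """weight=0 mean NN distance agrees with a Monte-Carlo uniform baseline."""
        obs = []
        for s in range(10):
            p = gen_opc_positions(vessel_net, AttractionSpec(300, 0.0, 10.0, seed=s))
            obs.append(nearest_vessel_distances(p, vessel_net).distances.mean())
        # independent baseline: fresh uniform draws over the same domain
        rng = np.random.default_rng(10_000)
        (xmin, xmax), (ymin, ymax) = vessel_net.extent
        base = []
        for _ in range(10):
            from oligoniche.datatypes import PointPattern

            pts = rng.uniform([xmin, ymin], [xmax, ymax], size=(300, 2))
            base.append(nearest_vessel_distances(PointPattern(pts), vessel_net).distances.mean())
        pooled_se = np.sqrt(np.var(obs, ddof=1) / 10 + np.var(base, ddof=1) / 10)
        assert abs(np.mean(obs) - np.mean(base)) < 4 * pooled_se

    def test_full_attraction_zero_decay_limit(self, vessel_net):
        p = gen_opc_positions(vessel_net, AttractionSpec(200, 1.0, 1e-9, seed=1))
        d = nearest_vessel_distances(p, vessel_net)
        assert d.distances.max() < 0.01

    def test_vessel_channel_stochastically_closer(self, vessel_net):
        p = gen_opc_positions(vessel_net, AttractionSpec(400, 0.5, 10.0, seed=2))
        d = nearest_vessel_distances(p, vessel_net).distances
        ch = p.meta["channel"]
        from scipy.stats import mannwhitneyu

        _, pval = mannwhitneyu(d[ch == "vessel"], d[ch == "uniform"], alternative="less")
        assert pval < 1e-6

    def test_empty_graph_rejected(self):
        from oligoniche.datatypes import VesselGraph

        empty = VesselGraph(np.zeros((0, 3)), np.zeros((0, 2), dtype=int))
        with pytest.raises(ValueError):
            gen_opc_positions(empty, AttractionSpec(10, 0.5, 10.0, seed=0))


class TestFiberSet:
    def test_mean_g_recovery(self):
        fs = gen_fiber_set(300, mean_g=0.80, seed=4)
        assert abs(fs.g.mean() - 0.80) < 0.01

    def test_zero_sd_gives_constant_g(self):
        fs = gen_fiber_set(50, mean_g=0.7, sd_g=0.0, seed=0)
        np.testing.assert_allclose(fs.g, 0.7)

    def test_fiber_always_exceeds_axon(self):
        fs = gen_fiber_set(500, mean_g=0.9, sd_g=0.1, seed=6)
        assert np.all(fs.fiber_diameter >= fs.axon_diameter)
        assert np.all((fs.g > 0) & (fs.g <= 1))

    def test_invalid_mean_rejected(self):
        for bad in (0.0, 1.0, 1.3, -0.2):
            with pytest.raises(ValueError):
                gen_fiber_set(10, mean_g=bad)


class TestSectionAreas:
    def test_center_plane_closed_form(self):
        s = gen_section_areas((100.0, 80.0, 500.0), 40.0, n_sampled=1, noise_cv=0.0,
                              mode="grid")
        assert s.areas[0] == pytest.approx(np.pi * 100 * 80)

    def test_full_coverage_riemann_sum_recovers_volume(self):
        a, b, c = 300.0, 200.0, 500.0
        s = gen_section_areas((a, b, c), 40.0, n_sampled=25, noise_cv=0.0, mode="grid")
        v_riemann = s.areas.sum() * 40.0
        v_true = 4 / 3 * np.pi * a * b * c
        assert v_riemann == pytest.approx(v_true, rel=0.01)

    def test_out_of_lesion_plane_yields_zero_area(self):
        s = gen_section_areas((50.0, 50.0, 100.0), 300.0, n_sampled=3, noise_cv=0.0,
                              mode="grid")
        assert s.areas[0] == 0.0 and s.areas[-1] == 0.0  # planes at ±300 µm

    def test_determinism(self):
        a = gen_section_areas(seed=8)
        b = gen_section_areas(seed=8)
        np.testing.assert_array_equal(a.areas, b.areas)


class TestVoxelMasks:
    @pytest.mark.parametrize("frac", [0.0, 0.5, 1.0])
    def test_overlap_fraction_realized(self, frac):
        vessel, marker = gen_voxel_masks(overlap_fraction=frac, seed=3)
        n_marker = marker.data.sum()
        realized = (marker.data & vessel.data).sum() / n_marker
        assert abs(realized - frac) <= 1.0 / n_marker + 1e-12
        if frac == 1.0:
            assert not np.any(marker.data & ~vessel.data)
        if frac == 0.0:
            assert not np.any(marker.data & vessel.data)

    def test_impossible_fraction_rejected(self):
        # marker bigger than the whole vessel mask cannot be fully contained
        with pytest.raises(ValueError):
            gen_voxel_masks(shape=(8, 16, 16), overlap_fraction=1.0, seed=0,
                            vessel_fill=0.01, marker_fill=0.5)
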