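import numpy as np
import pytest

from punctakit import (
    ExperimentDesign,
    FOFParams,
    PunctaSet,
    ThomasParams,
    VolumeSpec,
    cluster_stats,
    fof_grid,
    match_objects,
    render_stack,
    simulate_coloc_objects,
    simulate_experiment,
    simulate_laminar_phantom,
    simulate_poisson_points,
    simulate_thomas_points,
)
from punctakit.errors import PackingError, ParameterError
from punctakit.simulate import gaussian_mass_in_box

BOX = VolumeSpec(100.0, 100.0, 10.0)


class TestPoissonField:
    def test_zero_intensity_is_empty(self):
        assert len(simulate_poisson_points(0.0, BOX, seed=0)) == 0

    def test_negative_intensity_rejected(self):
        with pytest.raises(ParameterError):
            simulate_poisson_points(-1.0, BOX, seed=0)

    def test_same_seed_is_bit_identical(self):
        a = simulate_poisson_points(0.01, BOX, seed=7)
        b = simulate_poisson_points(0.01, BOX, seed=7)
        np.testing.assert_array_equal(a.coords, b.coords)

    def test_mean_count_matches_rate(self):
        # lambda * V = 0.01 * 1e5 = 1000; check within 3 SE over 1000 seeds
        counts = np.array(
            [len(simulate_poisson_points(0.01, BOX, seed=s)) for s in range(1000)]
        )
        se = np.sqrt(1000.0 / 1000)
        assert abs(counts.mean() - 1000.0) < 3 * se

    def test_dispersion_index_near_one(self):
        counts = np.array(
            [len(simulate_poisson_points(0.002, BOX, seed=s)) for s in range(1000)]
        )
        dispersion = counts.var(ddof=1) / counts.mean()
        assert 0.9 < dispersion < 1.1

    def test_coordinates_inside_box(self):
        pts = simulate_poisson_points(0.01, BOX, seed=3).coords
        assert np.all(pts >= 0) and np.all(pts <= BOX.extents)


class TestThomasField:
    BOX20 = VolumeSpec(100.0, 100.0, 20.0)

    def test_invalid_sigma_rejected(self):
        with pytest.raises(ParameterError):
            ThomasParams(0.001, 10.0, 0.0)

    def test_determinism(self):
        p = ThomasParams(0.001, 10.0, 0.5, seed=11)
        np.testing.assert_array_equal(
            simulate_thomas_points(p, BOX).coords, simulate_thomas_points(p, BOX).coords
        )

    def test_mean_count_matches_analytic_expectation(self):
        # E[N] = parent_intensity * mean_offspring * V minus the (tiny)
        # Gaussian mass escaping the box; bounded by the padded-box excess.
        counts = np.array(
            [
                len(
                    simulate_thomas_points(
                        ThomasParams(0.001, 10.0, 0.5, seed=s), self.BOX20
                    )
                )
                for s in range(500)
            ]
        )
        expected = 0.001 * 10.0 * self.BOX20.volume_um3  # 2000 ignoring edges
        se = counts.std(ddof=1) / np.sqrt(len(counts))
        # boundary loss is at most the one-sided Gaussian mass near the faces:
        # for sigma = 0.5 on a 100x100x20 box this is under 3% of the total
        assert expected * 0.97 - 3 * se < counts.mean() < expected + 3 * se

    def test_pair_correlation_exceeds_poisson_at_short_range(self):
        # count close pairs (< 2 sigma) in Thomas vs matched-intensity Poisson
        sigma = 0.5
        thomas_pairs, poisson_pairs = 0, 0
        for s in range(30):
            t = simulate_thomas_points(ThomasParams(0.001, 10.0, sigma, seed=s), BOX)
            p = simulate_poisson_points(0.01, BOX, seed=10_000 + s)
            thomas_pairs += _n_close_pairs(t.coords, 2 * sigma)
            poisson_pairs += _n_close_pairs(p.coords, 2 * sigma)
        assert thomas_pairs > 5 * poisson_pairs

    def test_more_clustered_than_poisson_at_2um(self):
        params = FOFParams(linking_length_um=2.0)
        wins = 0
        for s in range(100):
            t = simulate_thomas_points(ThomasParams(0.0005, 10.0, 0.5, seed=s), BOX)
            p = simulate_poisson_points(0.005, BOX, seed=50_000 + s)
            ft = cluster_stats(fof_grid(t, params)).fraction_clustered
            fp = cluster_stats(fof_grid(p, params)).fraction_clustered
            wins += ft > fp
        assert wins == 100


def _n_close_pairs(coords, radius):
    from scipy.spatial import cKDTree

    return cKDTree(coords).count_neighbors(cKDTree(coords), radius) - len(coords)


class TestRenderer:
    def test_empty_set_renders_all_zero(self, small_volume):
        stack = render_stack(PunctaSet(np.zeros((0, 3))), small_volume)
        assert not np.any(stack.voxels)

    def test_single_central_punctum_peaks_at_center(self, small_volume):
        center = small_volume.extents / 2
        stack = render_stack(PunctaSet([center]), small_volume)
        peak = np.unravel_index(np.argmax(stack.voxels), stack.shape)
        from punctakit import voxel_to_physical

        peak_xyz = voxel_to_physical(np.array(peak, float), stack.voxel_size, stack.origin)
        assert np.all(np.abs(peak_xyz - center) <= np.array(stack.voxel_size) / 2 + 1e-9)

    def test_total_mass_matches_analytic_gaussian(self, small_volume):
        rng = np.random.default_rng(5)
        pts = PunctaSet(rng.uniform(2, 7, (40, 3)) * np.array([2, 2, 1]))
        stack = render_stack(pts, small_volume)
        voxvol = float(np.prod(stack.voxel_size))
        expected = sum(
            gaussian_mass_in_box(c, (0.3, 0.3, 0.6), small_volume.extents, voxvol, peak=1000.0)
            for c in pts.coords
        )
        assert stack.voxels.sum() == pytest.approx(expected, rel=0.01)

    def test_out_of_bounds_flag(self, small_volume):
        outside = PunctaSet([[-5.0, 5.0, 5.0]])
        with pytest.raises(ParameterError):
            render_stack(outside, small_volume, out_of_bounds="error")
        stack = render_stack(outside, small_volume, out_of_bounds="clip")
        assert not np.any(stack.voxels)

    def test_noise_models_are_seeded(self, small_volume):
        pts = PunctaSet([small_volume.extents / 2])
        a = render_stack(pts, small_volume, noise="poisson", seed=1)
        b = render_stack(pts, small_volume, noise="poisson", seed=1)
        np.testing.assert_array_equal(a.voxels, b.voxels)
        c = render_stack(pts, small_volume, noise="gaussian", noise_sd=5.0, seed=2)
        assert np.all(c.voxels >= 0)


class TestColocGenerator:
    VOL = VolumeSpec(500.0, 500.0, 50.0)

    def test_full_overlap(self):
        a, b = simulate_coloc_objects(8, 8, 1.0, 10.0, self.VOL, seed=0)
        t = match_objects(a, b, 10.0)
        assert (t.pct_a_over_b, t.pct_b_over_a) == (100.0, 100.0)

    def test_zero_overlap(self):
        a, b = simulate_coloc_objects(8, 8, 0.0, 10.0, self.VOL, seed=1)
        t = match_objects(a, b, 10.0)
        assert (t.pct_a_over_b, t.pct_b_over_a) == (0.0, 0.0)

    def test_asymmetric_percentages_forced_by_construction(self):
        a, b = simulate_coloc_objects(10, 20, 0.7, 10.0, self.VOL, seed=2)
        # brute-force distance check of the construction invariants
        d = np.linalg.norm(a.centroids[:, None] - b.centroids[None, :], axis=2)
        n_a_matched = int(np.sum(d.min(axis=1) <= 10.0))
        n_b_matched = int(np.sum(d.min(axis=0) <= 10.0))
        assert n_a_matched == 7 and n_b_matched == 7
        t = match_objects(a, b, 10.0)
        assert t.pct_a_over_b == pytest.approx(70.0)
        assert t.pct_b_over_a == pytest.approx(35.0)

    def test_unmatched_pairs_are_well_separated(self):
        a, b = simulate_coloc_objects(10, 20, 0.5, 10.0, self.VOL, seed=3)
        d = np.linalg.norm(a.centroids[:, None] - b.centroids[None, :], axis=2)
        per_a = d.min(axis=1)
        assert np.sum(per_a <= 10.0) == 5
        assert np.all(per_a[per_a > 10.0] > 20.0)  # > 2x radius by construction

    def test_infeasible_overlap_rejected(self):
        with pytest.raises(ParameterError):
            simulate_coloc_objects(10, 3, 0.9, 10.0, self.VOL, seed=0)

    def test_infeasible_packing_raises(self):
        with pytest.raises(PackingError):
            simulate_coloc_objects(5, 50, 0.2, 10.0, VolumeSpec(40, 40, 10), seed=0, max_attempts=200)


class TestExperimentDesign:
    def test_site_count(self):
        design = ExperimentDesign(n_animals=2, sections_per_hemisphere=2, sites_per_section=3, seed=0)
        sites = simulate_experiment(design, ThomasParams(0.002, 8.0, 0.5), VolumeSpec(50, 50, 10))
        assert len(sites) == 2 * 2 * 2 * 3  # animals x hemispheres x sections x sites
        per_animal = sum(1 for s in sites if s.animal_id == "animal00")
        assert per_animal == 12

    def test_count_effect_scales_treated_hemisphere(self):
        design = ExperimentDesign(n_animals=4, treatment_effect_count=0.5, seed=3)
        sites = simulate_experiment(design, ThomasParams(0.002, 8.0, 0.5), VolumeSpec(50, 50, 10))
        treated = np.mean([len(s.puncta) for s in sites if s.hemisphere == "treated"])
        control = np.mean([len(s.puncta) for s in sites if s.hemisphere == "control"])
        assert treated / control == pytest.approx(0.5, abs=0.1)

    def test_determinism(self):
        design = ExperimentDesign(n_animals=2, seed=9)
        base = ThomasParams(0.002, 8.0, 0.5)
        a = simulate_experiment(design, base, VolumeSpec(50, 50, 10))
        b = simulate_experiment(design, base, VolumeSpec(50, 50, 10))
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.puncta.coords, sb.puncta.coords)


class TestLaminarPhantom:
    def test_single_layer_constant(self):
        stack = simulate_laminar_phantom([0, 50], [7.0], voxel_size=(1, 1, 1))
        assert np.all(stack.voxels == 7.0)

    def test_two_layer_step(self):
        stack = simulate_laminar_phantom([0, 50, 100], [10.0, 50.0], voxel_size=(1, 1, 1))
        profile = stack.voxels.mean(axis=(0, 2))
        assert np.all(profile[:50] == 10.0) and np.all(profile[50:] == 50.0)

    def test_boundaries_must_increase(self):
        with pytest.raises(ParameterError):
            simulate_laminar_phantom([0, 50, 50], [1.0, 2.0])
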