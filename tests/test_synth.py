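import numpy as np
import pytest
from scipy import sparse, stats

from spotmap.io import PeakMatrix
from spotmap.spp import GaussianWindow, build_spp
from spotmap.synth import (
    GroundTruthPattern,
    add_gaussian_noise,
    add_intensity_artifacts,
    add_interference,
    dice,
    simulate_ct_cases,
    simulate_pattern,
    stability_scan,
)


class TestGroundTruth:
    def test_ring_geometry(self, ring_truth):
        assert ring_truth.high_area == pytest.approx(np.pi * (30**2 - 20**2))
        mask = ring_truth.truth_mask
        assert mask.shape == (100, 100)
        assert mask[50, 50] == False  # noqa: E712 - centre is inside the hole
        assert mask[50, 75]  # 25.5 units from centre: inside the annulus

    def test_circle_plus_four_area_ratio_16(self):
        t = GroundTruthPattern("circle_plus_four")
        ratio = t.params["central_radius"] ** 2 / t.params["peripheral_radius"] ** 2
        assert ratio == 16.0

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown pattern"):
            GroundTruthPattern("hexagon")


class TestSimulatePattern:
    def test_ring_point_count_matches_poisson_mean(self, ring_truth):
        # expected high-region count = 0.4 * pi * (30^2 - 20^2) ~ 628
        expected = ring_truth.high_density * ring_truth.high_area
        counts = []
        for s in range(50):
            sim = simulate_pattern(ring_truth, seed=s)
            inside = ring_truth.contains(sim.spp.x, sim.spp.y)
            counts.append(inside.sum())
        mc_sd = np.sqrt(expected / 50)
        assert np.mean(counts) == pytest.approx(expected, abs=3 * mc_sd)

    def test_zero_high_density_empty_region(self):
        t = GroundTruthPattern("ring", high_density=0.0)
        sim = simulate_pattern(t, seed=1)
        assert t.contains(sim.spp.x, sim.spp.y).sum() == 0

    def test_mark_contrast_ratio(self, ring_truth):
        sims = [simulate_pattern(ring_truth, seed=s) for s in range(10)]
        ratios = []
        for sim in sims:
            inside = ring_truth.contains(sim.spp.x, sim.spp.y)
            ratios.append(sim.spp.marks[inside].mean() / sim.spp.marks[~inside].mean())
        assert np.mean(ratios) == pytest.approx(2.3, rel=0.1)

    def test_seed_determinism(self, ring_truth):
        a = simulate_pattern(ring_truth, seed=3).spp
        b = simulate_pattern(ring_truth, seed=3).spp
        assert np.array_equal(a.x, b.x) and np.array_equal(a.marks, b.marks)


class TestGaussianNoise:
    def test_poisson_like_at_k_zero(self):
        rng = np.random.default_rng(0)
        marks = rng.lognormal(np.log(2000), 0.1, 20000)
        spp = _grid_spp(marks)
        noisy = add_gaussian_noise(spp, k=0, seed=1)
        added = noisy.marks - spp.marks
        # sigma_0 = sqrt(mu); clipping is negligible at this mean
        assert added.std() == pytest.approx(np.sqrt(marks.mean()), rel=0.05)

    def test_added_noise_mean(self):
        rng = np.random.default_rng(0)
        marks = rng.lognormal(np.log(5000), 0.2, 20000)
        spp = _grid_spp(marks)
        noisy = add_gaussian_noise(spp, k=1, seed=1)
        added = noisy.marks - spp.marks
        se = added.std() / np.sqrt(added.size)
        assert added.mean() == pytest.approx(marks.mean(), abs=3 * se)

    def test_marks_nonnegative_after_clipping(self):
        marks = np.full(5000, 10.0)
        noisy = add_gaussian_noise(_grid_spp(marks), k=0, seed=2)
        assert np.all(noisy.marks >= 0)

    def test_negative_k_rejected(self):
        with pytest.raises(ValueError):
            add_gaussian_noise(_grid_spp(np.ones(4)), k=-1, seed=0)


def _grid_spp(marks):
    from spotmap.spp import SpatialPointPattern

    n = marks.size
    side = int(np.ceil(np.sqrt(n)))
    win = np.ones((side, side), bool)
    idx = np.arange(n)
    return SpatialPointPattern((idx % side).astype(float), (idx // side).astype(float),
                               marks, win)


def _moi_pm(n_pixels=400, seed=0, m_moi=400.0):
    rng = np.random.default_rng(seed)
    coords = np.column_stack([np.arange(n_pixels) % 20, np.arange(n_pixels) // 20])
    vals = rng.lognormal(np.log(1000), 0.5, (n_pixels, 1))
    return PeakMatrix(coords, np.array([m_moi]), sparse.csr_matrix(vals))


class TestInterference:
    SIGMA_G = 0.002

    def test_interferent_column_position(self):
        pm = _moi_pm()
        out = add_interference(pm, 400.0, self.SIGMA_G, seed=1)
        assert out.mz_axis.size == 2
        assert 400.0 + 2 * self.SIGMA_G in out.mz_axis

    def test_gaussian_weighting_beats_uniform(self):
        pm = _moi_pm()
        win = GaussianWindow(400.0, self.SIGMA_G)
        clean = build_spp(pm, win, "gaussian")
        noisy = add_interference(pm, 400.0, self.SIGMA_G, seed=1)
        g = build_spp(noisy, win, "gaussian")
        u = build_spp(noisy, win, "uniform")
        mse_g = np.mean((g.marks - clean.marks) ** 2)
        mse_u = np.mean((u.marks - clean.marks) ** 2)
        assert mse_g < mse_u

    def test_outside_support_leaves_gaussian_image_unchanged(self):
        pm = _moi_pm()
        win = GaussianWindow(400.0, self.SIGMA_G)
        clean = build_spp(pm, win, "gaussian")
        noisy = add_interference(pm, 400.0, self.SIGMA_G, seed=1, offset_sigmas=4.0)
        g = build_spp(noisy, win, "gaussian")
        assert np.allclose(g.marks, clean.marks)


class TestIntensityArtifacts:
    def test_zero_artifacts_identity(self, ring_sim):
        out = add_intensity_artifacts(ring_sim.spp, n_pixels=0, seed=0)
        assert np.array_equal(out.marks, ring_sim.spp.marks)

    def test_count_of_extreme_values(self):
        pm = _moi_pm()
        pre_max = pm.dense().max()
        out = add_intensity_artifacts(pm, n_pixels=10, seed=0, m_moi=400.0)
        assert int((out.dense() > pre_max).sum()) == 10

    def test_too_many_pixels_rejected(self):
        pm = _moi_pm(n_pixels=20)
        with pytest.raises(ValueError, match="exceeds"):
            add_intensity_artifacts(pm, n_pixels=21, seed=0, m_moi=400.0)

    def test_spp_artifacts_deterministic(self, ring_sim):
        a = add_intensity_artifacts(ring_sim.spp, n_pixels=10, seed=5)
        b = add_intensity_artifacts(ring_sim.spp, n_pixels=10, seed=5)
        assert np.array_equal(a.marks, b.marks)


class TestDice:
    def test_hand_examples(self):
        a = np.zeros((3, 4), bool)
        b = np.zeros((3, 4), bool)
        a.flat[:4] = True
        b.flat[1:7] = True  # |A|=4, |B|=6, overlap 3 -> 0.6
        assert dice(a, b) == pytest.approx(0.6)
        assert dice(a, a) == 1.0
        assert dice(a, ~a) == 0.0
        assert dice(np.zeros((2, 2), bool), np.zeros((2, 2), bool)) == 1.0

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            dice(np.ones((2, 2), bool), np.ones((3, 3), bool))


class TestStabilityScan:
    def test_single_iteration_rejected(self, ring_sim):
        with pytest.raises(ValueError, match="2 iterations"):
            stability_scan(ring_sim.spp, n_iter=1)

    def test_ring_masks_stable_across_csr_redraws(self, ring_sim):
        res = stability_scan(ring_sim.spp, n_iter=8, base_seed=0, h=2.5)
        assert res.mean_hotspot_dsc >= 0.95
        cv = res.hotspot_fractions.std() / res.hotspot_fractions.mean()
        assert cv < 0.05


class TestCTCases:
    def test_invalid_case_rejected(self):
        with pytest.raises(ValueError, match="case"):
            simulate_ct_cases(4, seed=0)

    def test_determinism_and_shapes(self):
        t1, r1 = simulate_ct_cases(1, seed=9)
        t2, r2 = simulate_ct_cases(1, seed=9)
        assert np.array_equal(t1.x, t2.x) and np.array_equal(r1.marks, r2.marks)
        assert t1.window.shape == r1.window.shape

    def test_case1_marks_elevated_in_structure(self):
        t, r = simulate_ct_cases(1, seed=3)
        truth = GroundTruthPattern("central_circle")
        inside = truth.contains(t.x, t.y)
        assert t.marks[inside].mean() > 1.5 * t.marks[~inside].mean()
        assert abs(r.marks.mean() - 100) < 5
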