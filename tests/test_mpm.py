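import numpy as np
import pytest
from scipy import stats

from spotmap.mpm import (
    DEFAULT_BANDWIDTHS,
    compute_mpm,
    estimate_bandwidth,
    extract_contours,
    generate_csr,
    kde_density,
    kneedle,
    morans_i,
    pvalue_maps,
)
from spotmap.spp import RasterImage, SpatialPointPattern


def _uniform_spp(n=200, size=30, seed=0, marks=None):
    rng = np.random.default_rng(seed)
    win = np.ones((size, size), bool)
    x = rng.uniform(-0.5, size - 0.5 - 1e-9, n)
    y = rng.uniform(-0.5, size - 0.5 - 1e-9, n)
    m = rng.lognormal(3, 0.5, n) if marks is None else marks
    return SpatialPointPattern(x, y, m, win)


class TestGenerateCSR:
    def test_permutation_invariants(self):
        spp = _uniform_spp()
        csr = generate_csr(spp, seed=1)
        assert csr.n == spp.n
        assert csr.lambda_density == spp.lambda_density
        assert np.array_equal(np.sort(csr.marks), np.sort(spp.marks))
        assert np.array_equal(csr.window, spp.window)

    def test_seed_determinism(self):
        spp = _uniform_spp()
        a = generate_csr(spp, seed=5)
        b = generate_csr(spp, seed=5)
        c = generate_csr(spp, seed=6)
        assert np.array_equal(a.x, b.x) and np.array_equal(a.marks, b.marks)
        assert not np.array_equal(a.x, c.x)

    def test_empty_spp_rejected(self):
        win = np.ones((5, 5), bool)
        empty = SpatialPointPattern([], [], [], win)
        with pytest.raises(ValueError, match="empty"):
            generate_csr(empty, seed=0)

    def test_nearest_neighbor_distance_matches_poisson_theory(self):
        # E[NN distance] = 0.5 / sqrt(lambda) for a uniform Poisson process
        spp = _uniform_spp(n=400, size=40)
        lam = spp.lambda_density
        means = []
        for s in range(60):
            c = generate_csr(spp, seed=s)
            pts = np.column_stack([c.x, c.y])
            d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
            np.fill_diagonal(d2, np.inf)
            means.append(np.sqrt(d2.min(axis=1)).mean())
        expected = 0.5 / np.sqrt(lam)
        # modest positive bias from the bounded window's edge effect
        assert np.mean(means) == pytest.approx(expected, rel=0.05)


class TestKDE:
    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(0)
        size, n, h = 20, 30, 2.0
        win = np.ones((size, size), bool)
        x = rng.integers(0, size, n).astype(float)
        y = rng.integers(0, size, n).astype(float)
        m = rng.uniform(1, 5, n)
        rho = kde_density(SpatialPointPattern(x, y, m, win), h).values
        gx, gy = np.meshgrid(np.arange(size), np.arange(size))
        num = np.zeros((size, size))
        for i in range(n):
            num += m[i] * np.exp(-((gx - x[i]) ** 2 + (gy - y[i]) ** 2) / (2 * h * h))
        den = np.zeros((size, size))
        for yy in range(size):
            for xx in range(size):
                den[yy, xx] = np.exp(
                    -((gx - xx) ** 2 + (gy - yy) ** 2) / (2 * h * h)
                ).sum()
        oracle = num / den
        oracle /= oracle.sum()
        assert np.max(np.abs(rho - oracle)) < 1e-6

    def test_single_point_normalized_argmax(self):
        win = np.ones((15, 15), bool)
        spp = SpatialPointPattern([7.0], [4.0], [3.0], win)
        rho = kde_density(spp, 2.0)
        assert np.nansum(rho.values) == pytest.approx(1.0)
        assert np.unravel_index(np.nanargmax(rho.values), (15, 15)) == (4, 7)

    def test_two_equal_marks_symmetric_maxima(self):
        win = np.ones((11, 31), bool)
        spp = SpatialPointPattern([5.0, 25.0], [5.0, 5.0], [2.0, 2.0], win)
        rho = kde_density(spp, 1.5).values
        assert rho[5, 5] == pytest.approx(rho[5, 25], rel=1e-9)

    def test_invalid_inputs(self):
        win = np.ones((5, 5), bool)
        spp = SpatialPointPattern([2.0], [2.0], [1.0], win)
        with pytest.raises(ValueError):
            kde_density(spp, 0.0)
        with pytest.raises(ValueError):
            kde_density(SpatialPointPattern([], [], [], win), 1.0)


class TestMoransI:
    @staticmethod
    def _brute(vals):
        finite = np.isfinite(vals)
        idx = np.argwhere(finite)
        v = vals[finite]
        vbar = v.mean()
        n = v.size
        num = wsum = 0.0
        for a, (ya, xa) in enumerate(idx):
            for b, (yb, xb) in enumerate(idx):
                if a != b and abs(ya - yb) <= 1 and abs(xa - xb) <= 1:
                    num += (vals[ya, xa] - vbar) * (vals[yb, xb] - vbar)
                    wsum += 1
        return (n / wsum) * num / ((v - vbar) ** 2).sum()

    def test_checkerboard_negative(self):
        board = np.indices((3, 3)).sum(0) % 2
        got = morans_i(RasterImage(board.astype(float)))
        assert got < 0
        assert got == pytest.approx(self._brute(board.astype(float)), rel=1e-12)

    def test_block_halves_positive(self):
        img = np.zeros((3, 3))
        img[:, :2] = 1.0
        got = morans_i(RasterImage(img))
        assert got > 0
        assert got == pytest.approx(self._brute(img), rel=1e-12)

    def test_masked_pixels_excluded(self):
        img = np.arange(9.0).reshape(3, 3)
        img[0, 0] = np.nan
        assert morans_i(RasterImage(img)) == pytest.approx(self._brute(img), rel=1e-12)

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            morans_i(RasterImage(np.ones((3, 3))))


class TestBandwidthSelection:
    def test_moran_curve_nondecreasing_on_smooth_fixtures(self):
        for seed in range(5):
            spp = _uniform_spp(n=250, size=40, seed=seed)
            scan = estimate_bandwidth(spp, bandwidths=np.arange(1.0, 6.1, 0.5))
            assert np.all(np.diff(scan.moran_i) > -0.02)

    def test_knee_against_discrete_curvature_oracle(self):
        x = DEFAULT_BANDWIDTHS
        y = 1 - np.exp(-x)
        got = kneedle(x, y)
        xn = (x - x.min()) / np.ptp(x)
        yn = (y - y.min()) / np.ptp(y)
        d1 = np.gradient(yn, xn)
        kappa = np.abs(np.gradient(d1, xn)) / (1 + d1**2) ** 1.5
        oracle = x[np.argmax(kappa)]
        assert abs(got - oracle) <= 1.0

    def test_linear_curve_triggers_fallback(self):
        spp = _uniform_spp(n=150, size=30, seed=3)
        import spotmap.mpm as mpm_mod

        orig = mpm_mod.morans_i
        try:
            vals = iter(np.linspace(0.1, 0.9, 19))
            mpm_mod.morans_i = lambda img: next(vals)
            with pytest.warns(UserWarning, match="fallback"):
                scan = estimate_bandwidth(spp)
        finally:
            mpm_mod.morans_i = orig
        assert scan.fallback_used
        assert scan.knee in DEFAULT_BANDWIDTHS

    def test_knee_within_grid(self):
        spp = _uniform_spp(n=300, size=40, seed=1)
        scan = estimate_bandwidth(spp)
        assert scan.knee in scan.bandwidths


class TestPValueMaps:
    @staticmethod
    def _density(vals, h=3.0):
        from spotmap.mpm import DensityImage

        return DensityImage(RasterImage(np.asarray(vals, float)), h)

    def test_mean_pixel_has_half_pvalues(self):
        rng = np.random.default_rng(0)
        csr = rng.normal(1.0, 0.1, (10, 10))
        moi = csr.copy()
        moi[0, 0] = csr.mean()
        pv = pvalue_maps(self._density(moi), self._density(csr))
        assert pv.p_upr.values[0, 0] == pytest.approx(0.5, abs=1e-9)
        assert pv.p_lwr.values[0, 0] == pytest.approx(0.5, abs=1e-9)

    def test_bh_step_up_oracle(self):
        from statsmodels.stats.multitest import multipletests

        adj = multipletests([0.01, 0.02, 0.04, 0.05], method="fdr_bh")[1]
        assert np.allclose(adj, [0.04, 0.04, 0.05, 0.05])

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(1)
        moi = rng.normal(1, 0.2, (12, 12))
        csr = rng.normal(1, 0.2, (12, 12))
        pv = pvalue_maps(self._density(moi), self._density(csr))
        assert np.all(pv.p_upr_adj.values >= pv.p_upr.values - 1e-15)
        assert np.all(pv.p_lwr_adj.values >= pv.p_lwr.values - 1e-15)

    def test_zero_variance_null_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pvalue_maps(self._density(np.ones((4, 4))), self._density(np.ones((4, 4))))


class TestContours:
    def test_single_pixel_polygon(self):
        mask = np.zeros((5, 5), bool)
        mask[2, 2] = True
        polys = extract_contours(mask)
        assert len(polys) == 1
        assert np.array_equal(polys[0][0], polys[0][-1])  # closed

    def test_disk_area_matches(self):
        from shapely.geometry import Polygon

        yy, xx = np.mgrid[:25, :25]
        mask = (xx - 12) ** 2 + (yy - 12) ** 2 <= 100
        polys = extract_contours(mask)
        area = max(Polygon(p).area for p in polys)
        assert area == pytest.approx(np.pi * 100, rel=0.05)

    def test_two_blobs_two_polygons(self):
        mask = np.zeros((10, 20), bool)
        mask[2:4, 2:4] = True
        mask[6:8, 15:18] = True
        assert len(extract_contours(mask)) == 2

    def test_empty_mask(self):
        assert extract_contours(np.zeros((4, 4), bool)) == []


class TestComputeMPM:
    def test_masks_disjoint_and_deterministic(self, ring_sim):
        r1 = compute_mpm(ring_sim.spp, h=2.5, seed=3)
        r2 = compute_mpm(ring_sim.spp, h=2.5, seed=3)
        assert not np.any(r1.hotspot_mask & r1.coldspot_mask)
        assert np.array_equal(r1.hotspot_mask, r2.hotspot_mask)
        assert np.array_equal(r1.pvals.p_upr.values, r2.pvals.p_upr.values,
                              equal_nan=True)

    def test_alpha_monotone_nesting(self, ring_sim):
        strict = compute_mpm(ring_sim.spp, alpha=0.01, h=2.5, seed=3)
        loose = compute_mpm(ring_sim.spp, alpha=0.05, h=2.5, seed=3)
        assert np.all(loose.hotspot_mask[strict.hotspot_mask])
        assert np.all(loose.coldspot_mask[strict.coldspot_mask])

    def test_marks_carried_unmodified(self, ring_sim):
        before = ring_sim.spp.marks.copy()
        compute_mpm(ring_sim.spp, h=2.5, seed=3)
        assert np.array_equal(ring_sim.spp.marks, before)

    def test_csr_density_normality_improves_with_bandwidth(self):
        # the smoothed-null pixel distribution approaches a normal as the
        # kernel averages more marks (KS distance shrinks from h=1 to h=3)
        spp = _uniform_spp(n=1500, size=60, seed=2,
                           marks=np.random.default_rng(2).lognormal(3, 1.0, 1500))
        ks = {}
        for h in (1.0, 3.0):
            stats_h = []
            for s in (9, 10, 11):
                rho = kde_density(generate_csr(spp, seed=s), h).values
                v = rho[np.isfinite(rho)]
                z = (v - v.mean()) / v.std(ddof=1)
                stats_h.append(stats.kstest(z, "norm").statistic)
            ks[h] = np.mean(stats_h)
        assert ks[3.0] < ks[1.0]
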