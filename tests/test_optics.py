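"""Image functions, the magnified image profile, and pixel integrals."""

import numpy as np
import pytest

from pixtraj import (WHOLE_PLANE, Airy, BornWolf, Gaussian2D, OpticalMap,
                     Rect, UnsupportedRegionError)


class TestAiry:
    def test_central_value_is_small_argument_limit(self):
        a = Airy(alpha=13.23)
        assert np.isclose(a.density([0.0, 0.0]), 13.23 ** 2 / (4 * np.pi),
                          rtol=1e-12)
        assert np.isclose(a.density([0.0, 0.0]), 13.9287, atol=1e-4)

    def test_radial_symmetry(self):
        a = Airy(alpha=13.23)
        p = a.density
        assert np.isclose(p([0.3, 0.1]), p([0.1, 0.3]))
        assert np.isclose(p([0.3, 0.1]), p([-0.3, -0.1]))

    def test_grid_normalization(self):
        a = Airy(alpha=13.23)
        # the ring tail is heavy (~2/(pi*alpha*r) mass beyond radius r), so
        # the box must reach ~6 um before 1% of the mass is captured
        g = np.linspace(-6.0, 6.0, 2401)
        xx, yy = np.meshgrid(g, g)
        vals = a.density(np.stack([xx, yy], axis=-1))
        dx = g[1] - g[0]
        assert np.isclose(vals.sum() * dx * dx, 1.0, atol=1e-2)

    def test_alpha_from_na_and_wavelength(self):
        a = Airy(n_a=1.4, lambda_em=0.52)
        assert np.isclose(a.alpha, 2 * np.pi * 1.4 / 0.52)

    def test_density_approx_matches_exact_mass(self):
        # the interpolated density used in bulk quadrature conserves pixel mass
        a = Airy(alpha=13.23)
        om = OpticalMap(a, M=1.0, quad_order=16)
        r = Rect(-0.05, 0.05, -0.02, 0.08)
        exact = om.image_profile(np.zeros(2), _riemann_pts(r, 400)).mean() \
            * r_area(r)
        assert np.isclose(om.pixel_integral(np.zeros(2), r), exact, rtol=1e-3)


def _riemann_pts(rect, n):
    gx = np.linspace(rect.xmin, rect.xmax, n, endpoint=False) \
        + (rect.xmax - rect.xmin) / (2 * n)
    gy = np.linspace(rect.ymin, rect.ymax, n, endpoint=False) \
        + (rect.ymax - rect.ymin) / (2 * n)
    xx, yy = np.meshgrid(gx, gy)
    return np.stack([xx.ravel(), yy.ravel()], axis=-1)


def r_area(rect):
    return (rect.xmax - rect.xmin) * (rect.ymax - rect.ymin)


class TestGaussian:
    def test_peak_and_offset_values(self):
        g = Gaussian2D(sigma=0.1)
        assert np.isclose(g.density([0.0, 0.0]), 15.91549, atol=1e-5)
        assert np.isclose(g.density([0.1, 0.0]),
                          15.91549 * np.exp(-0.5), atol=1e-4)

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            Gaussian2D(sigma=0.0)


class TestBornWolf:
    def test_in_focus_reduces_to_airy(self):
        bw = BornWolf(n_a=1.4, lambda_em=0.52, n_o=1.515, z0=0.0)
        airy = Airy(n_a=1.4, lambda_em=0.52)
        pts = np.array([[0.0, 0.0], [0.05, 0.0], [0.1, 0.1], [0.0, 0.3]])
        assert np.allclose(bw.density(pts), airy.density(pts), rtol=1e-6)

    def test_radial_symmetry(self):
        bw = BornWolf(n_a=1.4, lambda_em=0.52, z0=0.4)
        assert np.isclose(bw.density([0.2, 0.1]), bw.density([0.1, 0.2]))

    def test_defocus_sign_symmetry(self):
        up = BornWolf(n_a=1.4, lambda_em=0.52, z0=0.5)
        down = BornWolf(n_a=1.4, lambda_em=0.52, z0=-0.5)
        pts = np.array([[0.0, 0.0], [0.2, 0.1], [0.5, 0.0]])
        assert np.allclose(up.density(pts), down.density(pts), rtol=1e-10)


class TestImageProfile:
    def test_unit_magnification_is_shifted_q(self):
        om = OpticalMap(Gaussian2D(0.1), M=1.0)
        x = np.array([0.3, -0.2])
        r = np.array([0.35, -0.1])
        assert np.isclose(om.image_profile(x, r),
                          Gaussian2D(0.1).density(r - x))

    def test_magnified_profile_peak_and_width(self):
        om = OpticalMap(Gaussian2D(0.1), M=100.0)
        x = np.array([1.0, 1.0])
        peak = om.image_profile(x, 100.0 * x)
        assert np.isclose(peak, 1.0 / (2 * np.pi * 100.0), rtol=1e-12)
        # 1/e^0.5 point at 10 um from the center in the image plane
        val = om.image_profile(x, 100.0 * x + np.array([10.0, 0.0]))
        assert np.isclose(val, peak * np.exp(-0.5), rtol=1e-12)

    def test_profile_normalization(self):
        om = OpticalMap(Gaussian2D(0.1), M=100.0)
        big = Rect(-100.0, 300.0, -100.0, 300.0)
        total = om.region_integral(np.array([[1.0, 1.0]]), big)
        assert np.isclose(total[0], 1.0, atol=1e-9)


class TestPixelIntegral:
    def test_whole_plane(self):
        om = OpticalMap(Airy(alpha=13.23), M=100.0)
        assert om.pixel_integral(np.array([1.0, 2.0]), WHOLE_PLANE) == 1.0

    def test_centered_pixel_erf_value(self):
        om = OpticalMap(Gaussian2D(0.1), M=100.0)
        x = np.array([0.0, 0.0])
        from scipy.special import erf
        expected = erf(8.0 / (10.0 * np.sqrt(2.0))) ** 2
        val = om.pixel_integral(x, Rect(-8.0, 8.0, -8.0, 8.0))
        assert np.isclose(val, expected, rtol=1e-12)
        assert np.isclose(val, 0.33211, atol=1e-5)

    def test_erf_value_against_riemann_oracle(self):
        om = OpticalMap(Gaussian2D(0.1), M=100.0)
        x = np.array([0.013, -0.021])
        r = Rect(-8.0, 8.0, -8.0, 8.0)
        pts = _riemann_pts(r, 600)
        oracle = om.image_profile(x, pts).mean() * r_area(r)
        assert np.isclose(om.pixel_integral(x, r), oracle, atol=1e-6)

    def test_airy_quadrature_against_riemann_oracle(self):
        om = OpticalMap(Airy(alpha=13.23), M=100.0)
        x = np.array([0.02, 0.01])
        r = Rect(-3.25, 3.25, -3.25, 3.25)
        pts = _riemann_pts(r, 500)
        oracle = om.image_profile(x, pts).mean() * r_area(r)
        assert np.isclose(om.pixel_integral(x, r), oracle, atol=1e-4)

    def test_far_pixel_negligible(self):
        om = OpticalMap(Gaussian2D(0.1), M=100.0)
        val = om.pixel_integral(np.array([0.0, 0.0]),
                                Rect(150.0, 166.0, 0.0, 16.0))
        assert val < 1e-10

    def test_unsupported_region(self):
        om = OpticalMap(Gaussian2D(0.1), M=100.0)
        with pytest.raises(UnsupportedRegionError):
            om.pixel_integral(np.zeros(2), "not a rect")

    def test_general_magnification_matches_diagonal(self):
        # quadrature path (non-diagonal M) against the erf closed form
        eps = 1e-12
        om_d = OpticalMap(Gaussian2D(0.1), M=np.diag([100.0, 100.0]))
        om_g = OpticalMap(Gaussian2D(0.1),
                          M=np.array([[100.0, eps], [0.0, 100.0]]),
                          quad_order=24)
        x = np.array([0.1, 0.05])
        r = Rect(6.0, 12.5, 3.0, 9.5)
        assert np.isclose(om_g.pixel_integral(x, r),
                          om_d.pixel_integral(x, r), atol=1e-8)


class TestPartitionOfUnity:
    @pytest.mark.parametrize("q,tol", [(Gaussian2D(0.1), 1e-9),
                                       (Airy(alpha=13.23), 1e-4)])
    def test_pixels_plus_complement_sum_to_one(self, q, tol):
        """Per-pixel integrals and the single-rectangle coverage integral are
        two independent computations of the same mass."""
        from pixtraj import PixelGrid

        om = OpticalMap(q, M=100.0)
        x = np.array([0.31, 0.27])
        # detector covering +/- ~6 image-space widths around the image of x
        grid = PixelGrid(n_rows=20, n_cols=20, pixel_width=6.5,
                         origin=(100 * x[0] - 65.0, 100 * x[1] - 65.0))
        per_pixel = sum(float(om.pixel_integral(x, grid.pixel_rect(k)))
                        for k in range(1, grid.K + 1))
        coverage = float(om.region_integral(x, grid.bounds)[0])
        assert np.isclose(per_pixel, coverage, atol=tol)

    def test_airy_matches_peak_matched_gaussian(self):
        """An Airy spot and the Gaussian with the same central intensity
        produce nearly identical pixel integrals near the center."""
        alpha = 13.23
        om_a = OpticalMap(Airy(alpha=alpha), M=100.0)
        om_g = OpticalMap(Gaussian2D(np.sqrt(2.0) / alpha), M=100.0)
        x = np.array([2.3, 2.3])
        c = 100.0 * x
        for dx in (0.0, 6.5):
            r = Rect(c[0] - 3.25 + dx, c[0] + 3.25 + dx,
                     c[1] - 3.25, c[1] + 3.25)
            pa = float(om_a.pixel_integral(x, r))
            pg = float(om_g.pixel_integral(x, r))
            assert abs(pa - pg) / pg < 0.05


class TestSampling:
    @pytest.mark.parametrize("q", [Gaussian2D(0.1), Airy(alpha=13.23),
                                   BornWolf(n_a=1.4, lambda_em=0.52, z0=0.3)])
    def test_samples_match_radial_cdf(self, q, rng):
        pts = q.sample(rng, 20_000)
        r = np.hypot(pts[:, 0], pts[:, 1])
        for rho in (0.05, 0.1, 0.3):
            frac = np.mean(r <= rho)
            expect = float(q.radial_cdf(rho))
            se = np.sqrt(expect * (1 - expect) / len(r)) + 1e-4
            assert abs(frac - expect) < 4 * se

    def test_impact_points_are_magnified(self, rng):
        om = OpticalMap(Gaussian2D(0.1), M=100.0)
        x = np.tile([1.5, -0.5], (30_000, 1))
        r = om.sample_impact(x, rng)
        assert np.allclose(r.mean(axis=0), [150.0, -50.0], atol=0.3)
        assert np.allclose(r.std(axis=0), 10.0, atol=0.2)
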