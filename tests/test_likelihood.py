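"""Monte Carlo and closed-form likelihoods of pixelated photon-count data."""

import itertools

import numpy as np
import pytest
from scipy.special import gammaln, logsumexp
from scipy.stats import norm

import pixtraj as px
from pixtraj import (MCConfig, ModelBundle, loglik_fundamental_mc,
                     loglik_noisy, loglik_practical_finite,
                     loglik_practical_infinite,
                     stationary_finite_closed_form,
                     stationary_practical_closed_form)


def _near_stationary(bundle, D=1e-12):
    """Force the Monte Carlo path while staying numerically stationary."""
    x0 = bundle.motion.x0
    return bundle.with_motion(px.MotionModel.ou(f=0.0, D=D, x0=x0))


class TestStationaryClosedForm:
    def test_half_plane_multinomial(self, half_plane_bundle):
        # emitter on the boundary: conditional Pr[z=(2,1)] = 3 * (1/2)^3
        b = half_plane_bundle
        ll = stationary_practical_closed_form(b, np.array([2, 1]))
        cond = ll - b.arrivals.log_p_L(3)
        assert np.isclose(np.exp(cond), 0.375, rtol=1e-9)

    def test_impossible_pixel_is_minus_inf(self, stationary_bundle):
        z = np.zeros(stationary_bundle.grid.K, dtype=int)
        z[0] = 1  # far corner pixel: zero mass under the image profile
        assert stationary_practical_closed_form(stationary_bundle, z) == -np.inf

    def test_L0_is_log_p0(self, stationary_bundle):
        z = np.zeros(stationary_bundle.grid.K, dtype=int)
        ll = stationary_practical_closed_form(stationary_bundle, z)
        assert np.isclose(ll, stationary_bundle.arrivals.log_p_L(0))

    def test_mc_estimator_converges_to_closed_form(self, stationary_bundle,
                                                   rng):
        img, _ = px.simulate_image(stationary_bundle, rng, n_photons=3)
        exact = stationary_practical_closed_form(stationary_bundle, img)
        mc_val = loglik_practical_infinite(_near_stationary(stationary_bundle),
                                           img, MCConfig(10, 200, seed=0))
        assert np.isclose(mc_val, exact, atol=1e-4)

    def test_finite_equals_thinned_poisson_oracle(self, stationary_bundle,
                                                  rng):
        """The finite-detector likelihood equals the explicit sum over missed
        photons of p_{L+miss} x multinomial over K+1 cells."""
        b = stationary_bundle
        img, _ = px.simulate_image(b, rng, n_photons=3)
        z = img.counts
        occ = np.flatnonzero(z)
        p_occ = np.array([float(b.optics.pixel_integral(
            b.motion.x0[:2], b.grid.pixel_rect(k + 1))) for k in occ])
        coverage = float(b.optics.region_integral(b.motion.x0[:2],
                                                  b.grid.bounds)[0])
        p_miss = max(1.0 - coverage, 1e-300)
        L = int(z.sum())
        terms = []
        for miss in range(60):
            tot = L + miss
            log_mult = (gammaln(tot + 1) - np.sum(gammaln(z[occ] + 1))
                        - gammaln(miss + 1)
                        + np.sum(z[occ] * np.log(p_occ))
                        + miss * np.log(p_miss))
            terms.append(b.arrivals.log_p_L(tot) + log_mult)
        oracle = logsumexp(terms)
        val = stationary_finite_closed_form(b, img)
        assert np.isclose(val, oracle, atol=1e-8)


class TestPracticalInfinite:
    def test_single_whole_plane_pixel_gives_log_pL(self, moving_bundle, rng):
        big = 1e5
        grid = px.PixelGrid(n_rows=1, n_cols=1, pixel_width=big,
                            origin=(-big / 2, -big / 2))
        b = ModelBundle(motion=moving_bundle.motion,
                        optics=moving_bundle.optics,
                        arrivals=moving_bundle.arrivals, grid=grid)
        ll = loglik_practical_infinite(b, np.array([4]), MCConfig(5, 50, seed=0))
        assert np.isclose(ll, b.arrivals.log_p_L(4), atol=1e-9)

    def test_L0_returns_log_p0(self, moving_bundle):
        z = np.zeros(moving_bundle.grid.K, dtype=int)
        ll = loglik_practical_infinite(moving_bundle, z, MCConfig(2, 2, seed=0))
        assert np.isclose(ll, moving_bundle.arrivals.log_p_L(0))

    def test_cap_guard(self, moving_bundle):
        z = np.zeros(moving_bundle.grid.K, dtype=int)
        z[:10] = 2  # 20!/2^10 label vectors
        with pytest.raises(px.TooManyConfigurationsError):
            loglik_practical_infinite(moving_bundle, z,
                                      MCConfig(2, 2, seed=0, label_cap=1000))

    def test_deterministic_given_seed(self, moving_bundle, rng):
        img, _ = px.simulate_image(moving_bundle, rng, n_photons=4)
        mc = MCConfig(6, 40, seed=7)
        assert loglik_practical_infinite(moving_bundle, img, mc) == \
            loglik_practical_infinite(moving_bundle, img, mc)

    def test_riemann_oracle_two_photon_two_pixel(self):
        """Label-sum Monte Carlo vs a dense Riemann-sum evaluation of the
        defining integral, on a quasi-1D two-photon, two-pixel system."""
        x0, y0 = 0.2, 0.0
        D, T, sig = 0.8, 0.02, 0.1
        motion = px.MotionModel(dim=2, F=0.0,
                                G=np.diag([np.sqrt(2 * D), 0.0]),
                                x0=(x0, y0))
        optics = px.OpticalMap(px.Gaussian2D(sig), M=1.0)
        arr = px.ArrivalProcess(0.0, T, rate=2 / T)
        wide = 0.8  # y-extent +/- 8 sigma: y-mass factor common to both paths
        grid = px.PixelGrid(n_rows=1, n_cols=2, pixel_width=0.25,
                            pixel_height=2 * wide, origin=(0.0, y0 - wide))
        b = ModelBundle(motion=motion, optics=optics, arrivals=arr, grid=grid)

        mc_val = loglik_practical_infinite(b, np.array([1, 1]),
                                           MCConfig(80, 4000, seed=0))

        # oracle: grid over (tau1 < tau2) x (x1, x2)
        n = 40
        taus = (np.arange(n) + 0.5) * T / n
        xs = np.linspace(x0 - 1.2, x0 + 1.2, 120)
        dx = xs[1] - xs[0]
        from scipy.special import erf
        y_mass = erf(wide / (sig * np.sqrt(2)))

        def ix(lo, hi, x):
            return 0.5 * (erf((hi - x) / (sig * np.sqrt(2)))
                          - erf((lo - x) / (sig * np.sqrt(2)))) * y_mass
        I1 = ix(0.0, 0.25, xs)
        I2 = ix(0.25, 0.5, xs)
        total = 0.0
        for i1, t1 in enumerate(taus):
            p1 = norm.pdf(xs, loc=x0, scale=np.sqrt(2 * D * t1))
            # diagonal cell: both times in one cell, transition ~ delta
            total += 0.5 * np.sum(p1 * 2.0 * I1 * I2) * dx
            for i2 in range(i1 + 1, n):
                dt = taus[i2] - t1
                trans = norm.pdf(xs[None, :], loc=xs[:, None],
                                 scale=np.sqrt(2 * D * dt))
                w2 = trans @ I2
                w2x = trans @ I1
                pair = np.sum(p1 * (I1 * w2 + I2 * w2x)) * dx * dx
                total += pair
        total *= 2.0 / n ** 2  # conditional time density 2/T^2, cell T/n each
        oracle = b.arrivals.log_p_L(2) + np.log(total)
        assert np.isclose(mc_val, oracle, atol=0.02)


class TestPracticalFinite:
    def test_matches_infinite_on_covering_detector(self, moving_bundle, rng):
        img, _ = px.simulate_image(moving_bundle, rng, n_photons=4)
        v_inf = loglik_practical_infinite(moving_bundle, img,
                                          MCConfig(60, 2000, seed=0))
        v_fin = loglik_practical_finite(moving_bundle, img,
                                        MCConfig(60, 2000, seed=0))
        assert np.isclose(v_inf, v_fin, atol=0.15)  # MC noise only

    def test_stationary_finite_vs_infinite_full_coverage(self,
                                                         stationary_bundle,
                                                         rng):
        img, _ = px.simulate_image(stationary_bundle, rng, n_photons=3)
        v_inf = stationary_practical_closed_form(stationary_bundle, img)
        v_fin = stationary_finite_closed_form(stationary_bundle, img)
        assert np.isclose(v_inf, v_fin, atol=1e-3)

    def test_normalization_tiny_system_stationary(self):
        """Total probability over all count vectors is 1 (partial-coverage
        detector, photons may be missed)."""
        motion = px.MotionModel.stationary((0.1, 0.05))
        optics = px.OpticalMap(px.Gaussian2D(0.1), M=1.0)
        arr = px.ArrivalProcess(0.0, 0.02, rate=40.0)  # mean 0.8 photons
        grid = px.PixelGrid(n_rows=1, n_cols=2, pixel_width=0.12,
                            pixel_height=0.3, origin=(-0.07, -0.1))
        b = ModelBundle(motion=motion, optics=optics, arrivals=arr, grid=grid)
        total = sum(np.exp(stationary_finite_closed_form(b, np.array([z1, z2])))
                    for z1 in range(10) for z2 in range(10))
        assert np.isclose(total, 1.0, atol=1e-6)

    def test_normalization_tiny_system_moving(self):
        # mean 0.4 photons keeps the enumerable count vectors tiny while the
        # truncated miss-sum still carries ~all the mass
        motion = px.MotionModel.ou(f=0.0, D=0.3, x0=(0.1, 0.05))
        optics = px.OpticalMap(px.Gaussian2D(0.1), M=1.0)
        arr = px.ArrivalProcess(0.0, 0.02, rate=20.0)
        grid = px.PixelGrid(n_rows=1, n_cols=2, pixel_width=0.12,
                            pixel_height=0.3, origin=(-0.07, -0.1))
        b = ModelBundle(motion=motion, optics=optics, arrivals=arr, grid=grid)
        mc = MCConfig(10, 400, seed=0, z_truncation=5)
        total = sum(np.exp(loglik_practical_finite(b, np.array([z1, z2]), mc))
                    for z1 in range(3) for z2 in range(3))
        assert np.isclose(total, 1.0, atol=0.05)


class TestFundamental:
    def test_requires_photons(self, moving_bundle):
        with pytest.raises(ValueError):
            loglik_fundamental_mc(moving_bundle, np.empty((0, 2)),
                                  MCConfig(2, 2, seed=0))

    def test_stationary_exact(self, stationary_bundle, rng):
        b = stationary_bundle
        imp = b.optics.sample_impact(np.tile(b.motion.x0, (3, 1)), rng)
        exact = float(np.sum(np.log(b.optics.image_profile(b.motion.x0, imp))))
        assert np.isclose(loglik_fundamental_mc(b, imp, MCConfig(2, 2, seed=0)),
                          exact)

    def test_single_photon_conjugate_gaussian_oracle(self):
        """L=1, pure diffusion, unit magnification: the impact density is a
        Gaussian with variance sigma^2 + 2 D tau, marginalized over the
        uniform arrival time by quadrature."""
        from scipy.integrate import quad

        D, T, sig = 1.0, 0.02, 0.1
        motion = px.MotionModel.ou(f=0.0, D=D, x0=(0.0, 0.0))
        optics = px.OpticalMap(px.Gaussian2D(sig), M=1.0)
        arr = px.ArrivalProcess(0.0, T, rate=1 / T)
        grid = px.PixelGrid(n_rows=1, n_cols=1, pixel_width=10.0,
                            origin=(-5.0, -5.0))
        b = ModelBundle(motion=motion, optics=optics, arrivals=arr, grid=grid)
        r = np.array([[0.12, -0.08]])

        def dens(tau):
            v = sig ** 2 + 2 * D * tau
            return norm.pdf(r[0, 0], scale=np.sqrt(v)) \
                * norm.pdf(r[0, 1], scale=np.sqrt(v)) / T
        oracle, _ = quad(dens, 0.0, T, limit=100)
        val = loglik_fundamental_mc(b, r, MCConfig(200, 10_000, seed=0))
        assert np.isclose(np.exp(val), oracle, rtol=0.01)

    def test_mc_variance_scales_inversely_with_samples(self):
        """Variance of the exp-scale pixel-probability estimate halves when
        M_c doubles (a near-instant exposure with a random initial location
        isolates the spatial Monte Carlo error)."""
        motion = px.MotionModel(dim=2, F=-10.0, G=np.sqrt(2.0),
                                init_mean=(2.4, 2.4),
                                init_cov=0.04 * np.eye(2))
        optics = px.OpticalMap(px.Gaussian2D(0.1), M=100.0)
        arr = px.ArrivalProcess(0.0, 1e-5, rate=1e5)
        grid = px.PixelGrid(n_rows=60, n_cols=60, pixel_width=16.0)
        b = ModelBundle(motion=motion, optics=optics, arrivals=arr, grid=grid)
        z = np.zeros(grid.K, dtype=int)
        z[grid.pixel_of([(240.0, 240.0)])[0] - 1] = 1
        sizes = [50, 200, 800]
        variances = []
        for M in sizes:
            vals = [np.exp(loglik_practical_infinite(b, z,
                                                     MCConfig(1, M, seed=s)))
                    for s in range(120)]
            variances.append(np.var(vals, ddof=1))
        slope = np.polyfit(np.log(sizes), np.log(variances), 1)[0]
        assert -1.35 < slope < -0.65


class TestNoisy:
    def _single_pixel_bundle(self, beta=0.0, eta=0.0, sigma=0.4):
        big = 1e5
        motion = px.MotionModel.stationary((0.0, 0.0))
        optics = px.OpticalMap(px.Gaussian2D(0.1), M=1.0)
        arr = px.ArrivalProcess(0.0, 0.02, rate=100.0)
        grid = px.PixelGrid(n_rows=1, n_cols=1, pixel_width=big,
                            origin=(-big / 2, -big / 2))
        noise = px.NoiseModel(beta=beta, eta=eta, sigma_read=sigma)
        return ModelBundle(motion=motion, optics=optics, arrivals=arr,
                           grid=grid, noise=noise)

    def test_single_pixel_mixture_oracle(self):
        b = self._single_pixel_bundle(eta=0.5, sigma=0.6)
        i = np.array([2.3])
        val = loglik_noisy(b, i, MCConfig(2, 2, seed=0))
        mu = b.arrivals.total_intensity
        Ls = np.arange(60)
        from scipy.stats import poisson
        oracle = np.sum(poisson.pmf(Ls, mu)
                        * norm.pdf(i[0], loc=Ls + 0.5, scale=0.6))
        assert np.isclose(np.exp(val), oracle, rtol=1e-6)

    def test_noiseless_limit_recovers_counts(self, rng):
        b = self._single_pixel_bundle(sigma=1e-6)
        val = loglik_noisy(b, np.array([3.0]), MCConfig(2, 2, seed=0))
        count_ll = b.arrivals.log_p_L(3)
        norm_const = -np.log(np.sqrt(2 * np.pi) * 1e-6)
        assert np.isclose(val - norm_const, count_ll, atol=1e-6)

    def test_shift_invariance_in_eta(self):
        b1 = self._single_pixel_bundle(eta=0.0, sigma=0.5)
        b2 = self._single_pixel_bundle(eta=2.0, sigma=0.5)
        mc = MCConfig(2, 2, seed=0)
        assert np.isclose(loglik_noisy(b1, np.array([1.4]), mc),
                          loglik_noisy(b2, np.array([3.4]), mc), rtol=1e-9)

    def test_degenerate_data_raises(self):
        b = self._single_pixel_bundle(sigma=0.01)
        with pytest.raises(px.DegenerateDataError):
            loglik_noisy(b, np.array([-5.0]), MCConfig(2, 2, seed=0))

    def test_requires_noise_model(self, moving_bundle):
        with pytest.raises(ValueError):
            loglik_noisy(moving_bundle, np.zeros(moving_bundle.grid.K),
                         MCConfig(2, 2, seed=0))


class TestReport:
    def test_report_fields(self, moving_bundle, rng):
        img, _ = px.simulate_image(moving_bundle, rng, n_photons=3)
        rep = px.likelihood_report(moving_bundle, img, MCConfig(5, 50, seed=1))
        assert {"loglik", "model", "n_temporal", "n_spatial",
                "seed"} <= set(rep)
        assert np.isfinite(rep["loglik"])
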