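"""Flux statistics, TUR bounds, force inference and the growth law."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from vesiclemc.synthetic import generate_synthetic_trajectories
from vesiclemc.thermo import (
    FluxEnsemble,
    entropy_bounds,
    fit_force_laws,
    flux_statistics,
    growth_law_invert,
    growth_law_predict,
    heaviside,
    infer_forces,
    linear_response_check,
    tur_bound,
)


def gaussian_fluxes(mean, cov, n, seed, tau=1000.0, **kw):
    rng = np.random.default_rng(seed)
    J = rng.multivariate_normal(mean, cov, size=n)
    return FluxEnsemble(("N", "V"), J, tau, **kw)


class TestFluxStatistics:
    def test_degenerate_ensemble_zero_covariance(self):
        J = np.tile([5.0, 2.0], (10, 1))
        fe = FluxEnsemble(("N", "V"), J, 100.0)
        assert np.allclose(fe.cov, 0.0)
        assert np.allclose(fe.mean, [5.0, 2.0])

    def test_random_walk_moments_match_closed_form(self):
        """Biased random walk: <J> = m*tau, D = s within 3 SE."""
        drift = [0.8, -0.3]
        D0 = np.array([[1.5, 0.4], [0.4, 0.9]])
        tau = 1000
        n = 500
        ens = generate_synthetic_trajectories(drift, D0, n, tau, seed=5)
        fe = flux_statistics(ens, tau)
        se_mean = np.sqrt(np.diag(2 * D0 * tau) / n)
        assert np.all(np.abs(fe.mean - np.array(drift) * tau)
                      < 3 * se_mean)
        se_d = np.diag(D0) * math.sqrt(2.0 / (n - 1))
        assert np.all(np.abs(np.diag(fe.D) - np.diag(D0)) < 3 * se_d)

    def test_missing_checkpoint_reports_samples(self):
        ens = generate_synthetic_trajectories([1.0, 0.0],
                                              np.eye(2), 5, 200, seed=1)
        with pytest.raises(KeyError):
            flux_statistics(ens, 123)

    def test_d_matches_cov_over_2tau(self):
        fe = gaussian_fluxes([10, 5], [[4, 1], [1, 2]], 50, 2, tau=250.0)
        assert np.allclose(fe.D, fe.cov / 500.0)


class TestTURBounds:
    def test_1d_closed_form(self):
        assert tur_bound(np.array([3.0]), np.array([[4.0]])) == \
            pytest.approx(2 * 9 / 4)

    def test_diagonal_additivity(self):
        m = np.array([3.0, -2.0])
        c = np.diag([4.0, 5.0])
        assert tur_bound(m, c) == pytest.approx(
            2 * 9 / 4 + 2 * 4 / 5)

    @given(st.integers(0, 10_000))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_more_observables_never_decrease_bound(self, seed):
        """Exact algebraic monotonicity of the TUR bound in the flux set."""
        rng = np.random.default_rng(seed)
        a = rng.standard_normal((2, 2))
        cov = a @ a.T + 1e-6 * np.eye(2)
        mean = rng.standard_normal(2)
        b2 = tur_bound(mean, cov)
        b1 = 2 * mean[0] ** 2 / cov[0, 0]
        assert b2 >= b1 - 1e-9 * abs(b1)

    def test_entropy_estimate_bundle(self):
        fe = gaussian_fluxes([200.0, 80.0], [[100, 20], [20, 60]],
                             400, 3, tau=1000.0)
        est = entropy_bounds(fe, drive=(1.0, 0.5), nboot=200)
        assert est.direct_no_eps == pytest.approx(
            1.0 * fe.mean[0] + 0.5 * fe.mean[1])
        assert not est.eps_included
        assert est.bound_2d >= est.bound_1d
        assert est.bound_1d > 0
        lo, hi = est.bound_1d_ci
        assert lo < est.bound_1d < hi

    def test_eps_diss_model_included_and_flagged(self):
        fe = gaussian_fluxes([200.0, 80.0], [[100, 20], [20, 60]],
                             100, 3, tau=1000.0)
        est = entropy_bounds(fe, drive=(1.0, 0.0),
                             eps_diss_model=lambda **kw: 0.01)
        assert est.eps_included
        assert est.direct == pytest.approx(est.direct_no_eps - 10.0)


class TestForceInference:
    def test_diagonal_inversion(self):
        fe = gaussian_fluxes([100.0, 40.0], np.diag([50.0, 20.0]),
                             4000, 7, tau=500.0)
        f = infer_forces(fe, nboot=0)
        expect = np.array([100.0 / 500, 40.0 / 500]) / \
            (np.array([50.0, 20.0]) / 1000.0)
        assert np.allclose(f.f, expect, rtol=0.1)

    def test_growth_law_round_trip(self):
        """Forces drawn through the growth law are recovered by
        inference on trajectories generated with those forces."""
        D0 = np.array([[2.0, 0.6], [0.6, 1.5]])
        f_true = np.array([1.2, 0.4])
        drift = growth_law_predict(D0, f_true)  # D f / kBT
        ens = generate_synthetic_trajectories(drift, D0, 600, 2000, seed=9)
        fe = flux_statistics(ens, 2000)
        est = infer_forces(fe, nboot=400, seed=1)
        assert np.all(est.ci_low <= f_true)
        assert np.all(f_true <= est.ci_high)

    def test_growth_law_inverse_is_exact(self):
        D0 = np.array([[2.0, 0.6], [0.6, 1.5]])
        f = np.array([0.7, -0.2])
        rates = growth_law_predict(D0, f)
        assert np.allclose(growth_law_invert(D0, rates), f, atol=1e-10)
        assert np.allclose(growth_law_predict(D0, np.zeros(2)), 0.0)

    def test_estimator_error_shrinks_as_sqrt_n(self):
        """Mean-flux estimator error scales as 1/sqrt(nsamples): a 16x
        sample-size increase should shrink the spread ~4x (assert > 2x
        to leave room for the noise of the spread estimate itself)."""
        D0 = np.eye(2)
        errs = []
        for n in (50, 800):
            reps = []
            for r in range(16):
                ens = generate_synthetic_trajectories(
                    [1.0, 0.5], D0, n, 500, seed=100 * n + r)
                fe = flux_statistics(ens, 500)
                reps.append(fe.mean[0] - 500.0)
            errs.append(np.std(reps))
        assert errs[1] < errs[0] / 2.0


class TestLinearResponse:
    def _fe(self, dmu, slope=1.0, seed=0, d=0.1, tau=1000.0, n=200):
        j = slope * d * dmu
        return gaussian_fluxes([j * tau, 0.0],
                               np.diag([2 * d * tau, 2 * d * tau]),
                               n, seed, tau=tau, delta_mu=dmu)

    def test_constructed_identity_gives_unit_slope(self):
        fes = [self._fe(d, seed=i) for i, d in
               enumerate([0.5, 1.0, 2.0, 4.0])]
        rep = linear_response_check(fes)
        assert rep["slope"] == pytest.approx(1.0, abs=3 * rep["slope_stderr"])
        assert rep["consistent_with_unity"]

    def test_far_from_equilibrium_deviation_flagged(self):
        fes = [self._fe(d, seed=i) for i, d in enumerate([0.5, 1, 2, 4])]
        # far point with strongly sub-linear response
        fes.append(self._fe(8.0, slope=0.3, seed=9))
        rep = linear_response_check(fes)
        assert rep["n_far"] == 1
        assert len(rep["far_points_deviating"]) == 1

    def test_too_few_points_raises(self):
        with pytest.raises(ValueError):
            linear_response_check([self._fe(0.5), self._fe(1.0)])


class TestForceLaws:
    def test_heaviside_convention(self):
        assert heaviside(0.0) == 1.0
        assert heaviside(-1e-12) == 0.0
        assert heaviside(3.0) == 1.0

    def test_hinge_regression_round_trip(self):
        """fV = cp*dp + zeta*(mu - mu*)Theta(mu - mu*) with
        (cp, zeta, mu*) = (0.9, 0.3, -2) is recovered within CI."""
        cp, zeta = 0.9, 0.3
        mu_star = {0.0: -2.0, 1.0: 0.5}
        rng = np.random.default_rng(4)
        rows = []
        for dp, ms in mu_star.items():
            mu_eq = -1.0 * dp  # mu_eq decreases with pressure
            for mu in np.linspace(-4, 6, 11):
                fv = cp * dp + zeta * max(mu - ms, 0.0) \
                    + 0.005 * rng.standard_normal()
                rows.append({"delta_mu": mu - mu_eq, "mu_eq": mu_eq,
                             "dp": dp, "fN": mu - mu_eq, "fV": fv,
                             "fV_se": 0.005})
        df = pd.DataFrame(rows)
        fit = fit_force_laws(df, window=100.0)
        assert fit.c_p == pytest.approx(cp, abs=0.05)
        assert fit.zeta == pytest.approx(zeta, abs=max(0.03,
                                                       3 * fit.zeta_stderr))
        for dp, ms in mu_star.items():
            assert fit.mu_star[dp] == pytest.approx(ms, abs=0.3)
        assert fit.fn_slope == pytest.approx(1.0, abs=0.01)

    def test_open_threshold_flagged(self):
        rows = []
        for mu in np.linspace(0, 3, 8):
            rows.append({"delta_mu": mu, "mu_eq": 0.0, "dp": 0.0,
                         "fN": mu, "fV": 0.0})
        for mu in np.linspace(0, 3, 8):
            rows.append({"delta_mu": mu, "mu_eq": 0.0, "dp": 1.0,
                         "fN": mu, "fV": 0.9})
        fit = fit_force_laws(pd.DataFrame(rows), window=100.0)
        # flat fV: the hinge never activates inside the scanned range
        assert np.isfinite(fit.c_p)
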