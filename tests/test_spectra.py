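"""Spherical-harmonic shape decomposition and elastic-shell fitting."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation
from scipy.special import sph_harm_y

from vesiclemc.mesh import build_icosphere
from vesiclemc.spectra import (
    NotStarShapedError,
    SpectrumEstimate,
    decompose_configuration,
    ensemble_spectrum,
    fit_parameter_slopes,
    fit_shell_spectrum,
    is_star_shaped,
    real_sph_harm_basis,
    shell_mode_stiffness,
    shell_spectrum,
    spectral_peak,
)
from vesiclemc.synthetic import generate_synthetic_spectrum


def shaped_icosphere(amplitudes, R=10.0, s=3):
    """Icosphere deformed to r = R(1 + sum a_lm Y_lm) (real, CS-free)."""
    m = build_icosphere(s, 1.0)
    ids = m.alive
    rel = m.pos[ids]
    r = np.linalg.norm(rel, axis=1)
    theta = np.arccos(np.clip(rel[:, 2] / r, -1, 1))
    phi = np.arctan2(rel[:, 1], rel[:, 0])
    bump = np.zeros(len(ids))
    for (l, mm), a in amplitudes.items():
        am = abs(mm)
        y = sph_harm_y(l, am, theta, phi)
        cs = (-1.0) ** am
        if mm == 0:
            yr = y.real
        elif mm > 0:
            yr = np.sqrt(2) * cs * y.real
        else:
            yr = np.sqrt(2) * cs * y.imag
        bump += a * yr
    m.pos[ids] = rel / r[:, None] * (R * (1.0 + bump))[:, None]
    return m


class TestDecomposition:
    def test_perfect_sphere_null_spectrum(self):
        m = build_icosphere(3, 7.0)
        dec = decompose_configuration(m, lmax=8)
        assert dec.R == pytest.approx(7.0, abs=1e-10)
        assert np.abs(dec.ulm[1:]).max() < 1e-10

    def test_forward_generate_invert(self):
        m = shaped_icosphere({(2, 0): 0.05})
        dec = decompose_configuration(m, lmax=8)
        assert dec.coefficient(2, 0) == pytest.approx(0.05, rel=0.02)
        others = [dec.ulm[i] for i in range(1, len(dec.ulm))
                  if i != 2 * 2 + 2 + 0]
        assert np.abs(others).max() < 5e-3

    def test_degree_power_rotation_invariant(self):
        m = shaped_icosphere({(2, 0): 0.04, (3, 2): 0.02, (5, -3): 0.01})
        dec = decompose_configuration(m, lmax=8)
        rot = Rotation.random(random_state=3).as_matrix()
        ids = m.alive
        m2 = m.copy()
        m2.pos[ids] = m.pos[ids] @ rot.T
        dec2 = decompose_configuration(m2, lmax=8)
        assert np.allclose(dec2.power(), dec.power(), rtol=1e-3,
                           atol=1e-12)

    def test_parseval_consistency(self):
        """Vertex-level anisotropic variance equals the summed degree
        power (orthonormal basis), within truncation error."""
        amps = {(2, 0): 0.04, (3, 1): 0.03, (4, -2): 0.02}
        m = shaped_icosphere(amps)
        dec = decompose_configuration(m, lmax=10)
        total_power = float(np.sum(dec.ulm[4:] ** 2))  # l >= 2
        expected = sum(a ** 2 for a in amps.values())
        assert total_power == pytest.approx(expected, rel=5e-3)

    def test_basis_orthonormality(self, rng):
        """Monte Carlo check of orthonormality over the sphere."""
        n = 40_000
        u = rng.random(n)
        theta = np.arccos(1 - 2 * u)
        phi = 2 * np.pi * rng.random(n)
        B = real_sph_harm_basis(4, theta, phi)
        G = 4 * np.pi * (B.T @ B) / n
        assert np.allclose(G, np.eye(B.shape[1]), atol=0.05)

    def test_lmax_guard(self):
        m = build_icosphere(1, 5.0)  # 42 vertices
        with pytest.raises(ValueError, match="lmax"):
            decompose_configuration(m, lmax=8)

    def test_non_star_shaped_detected(self):
        m = build_icosphere(2, 5.0)
        v = m.alive[0]
        m.pos[v] = -1.2 * m.pos[v]  # push a vertex through the far side
        assert not is_star_shaped(m)
        with pytest.raises(NotStarShapedError):
            decompose_configuration(m, lmax=6)


class TestEnsembleSpectrum:
    def test_degenerate_ensemble_zero_stderr(self):
        m = shaped_icosphere({(2, 0): 0.05})
        spec = ensemble_spectrum([m.copy(), m.copy(), m.copy()], lmax=6)
        assert spec.nsamples == 3
        assert np.allclose(spec.stderr, 0.0, atol=1e-15)
        assert spec.power[0] > 0

    def test_excluded_configurations_counted(self):
        good = shaped_icosphere({(2, 0): 0.03})
        bad = build_icosphere(3, 10.0)
        v = bad.alive[0]
        bad.pos[v] = -1.2 * bad.pos[v]
        spec = ensemble_spectrum([good.copy(), good.copy(), bad], lmax=6)
        assert spec.n_excluded == 1
        assert spec.nsamples == 2

    def test_all_excluded_raises(self):
        bad = build_icosphere(3, 10.0)
        v = bad.alive[0]
        bad.pos[v] = -1.2 * bad.pos[v]
        with pytest.raises(ValueError, match="usable"):
            ensemble_spectrum([bad.copy(), bad.copy()], lmax=6)


class TestShellFit:
    def test_round_trip_with_noise(self):
        spec = generate_synthetic_spectrum(-1.0, 30.0, 20.0, 15.0,
                                           noise=0.01, seed=3)
        fit = fit_shell_spectrum(spec)
        assert fit.valid
        assert abs(fit.gamma - (-1.0)) < 3 * fit.stderr_gamma
        assert abs(fit.Y - 30.0) < 3 * fit.stderr_Y
        assert abs(fit.kappa_eff - 20.0) < 3 * fit.stderr_kappa

    def test_noise_free_recovery_to_optimizer_tolerance(self):
        spec = generate_synthetic_spectrum(-2.0, 40.0, 15.0, 10.0,
                                           noise=0.0, seed=0)
        fit = fit_shell_spectrum(spec)
        assert fit.gamma == pytest.approx(-2.0, abs=1e-6)
        assert fit.Y == pytest.approx(40.0, rel=1e-6)
        assert fit.kappa_eff == pytest.approx(15.0, rel=1e-6)

    def test_unit_rescale_invariance(self):
        """Rescaling lengths l0 -> lam*l0 (gamma, Y in 1/lam^2, R in lam)
        leaves the dimensionless spectrum and the rescaled fit invariant."""
        lam = 2.5
        ell = np.arange(2, 25)
        base = shell_spectrum(ell, -1.0, 30.0, 20.0, 15.0)
        scaled = shell_spectrum(ell, -1.0 / lam ** 2, 30.0 / lam ** 2,
                                20.0, 15.0 * lam)
        assert np.allclose(base, scaled, rtol=1e-12)

    def test_helfrich_limit_at_large_ell(self):
        """At gamma = 0 and degrees far above the stretching scale
        l ~ sqrt(Y R^2 / kappa), the shell spectrum reduces to the classic
        bending-dominated Helfrich l^-4 decay."""
        kappa, Y, R = 20.0, 100.0, 5.0  # crossover near l ~ 11
        ell = np.arange(40, 80)
        a_shell = shell_mode_stiffness(ell, 0.0, Y, kappa, R)
        helfrich = 0.5 * kappa * ((ell - 1) * (ell + 2)) ** 2
        assert np.all(a_shell > helfrich)  # stretching only stiffens
        assert np.allclose(a_shell / helfrich, 1.0, rtol=0.01)
        # and the decay is l^-4-like: power drops ~16x per octave
        p = shell_spectrum(np.array([40, 80]), 0.0, Y, kappa, R)
        assert p[0] / p[1] == pytest.approx(16.0, rel=0.15)

    def test_spectral_peak_detection(self):
        ell = np.arange(2, 15)
        power = np.exp(-0.5 * (ell - 6.0) ** 2)
        spec = SpectrumEstimate(ell=ell, power=power, stderr=0.01 * power,
                                R=10.0, nsamples=10)
        l_star, lam_star = spectral_peak(spec)
        assert l_star == 6
        assert lam_star == pytest.approx(2 * np.pi * 10.0 / 6)
        mono = SpectrumEstimate(ell=ell, power=1.0 / ell ** 4,
                                stderr=np.full_like(ell, 1e-6, dtype=float),
                                R=10.0, nsamples=10)
        assert spectral_peak(mono) == (None, None)

    def test_parameter_slopes_recovered(self):
        dmus = [0.0, 0.5, 1.0, 2.0]
        fits = []
        for d in dmus:
            spec = generate_synthetic_spectrum(
                -0.5 - 1.2 * d, 30.0 + 2.0 * d, 20.0 - 0.8 * d, 15.0,
                noise=0.002, seed=int(10 * d))
            fits.append(fit_shell_spectrum(spec))
        slopes = fit_parameter_slopes(fits, dmus)
        assert slopes["c_gamma"] == pytest.approx(-1.2, abs=0.1)
        assert slopes["c_Y"] == pytest.approx(2.0, abs=1.0)
        assert slopes["c_kappa"] == pytest.approx(-0.8, abs=0.3)
        assert slopes["gamma_eq"] == pytest.approx(-0.5, abs=0.1)
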