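"""Shape-fluctuation spectroscopy of quasispherical vesicles.

A quasispherical configuration is written as a superposition of real
spherical harmonics,

    r(theta, phi) = R * [1 + sum_{l>=2} sum_m u_lm Y_lm(theta, phi)],

with R the fitted monopole radius; the l = 0, 1 terms are absorbed into R
and the centroid.  The degree-l fluctuation power is
|u_l|^2 = (2l+1)^{-1} sum_m u_lm^2.

Ensemble-averaged spectra are fitted with the harmonic spectrum of a
pressurized thermalized elastic shell,

    <|u_l|^2> = kBT / (2 A_l),
    A_l = (1/2) [ gamma R^2 (l-1)(l+2)
                + Y R^2 (l-1)(l+2) / (l (l+1))
                + kappa (l-1)^2 (l+2)^2 ],

whose large-l limit is the shallow-shell form kappa q^4 + gamma q^2 +
Y/R^2 (q^2 = l(l+1)/R^2) and whose Y=0 limit is the classic fluid-membrane
(Helfrich) spectrum with tension polynomial (l-1)(l+2).  Fitting a driven
ensemble with this equilibrium form yields *renormalized* effective
parameters gamma (tension), Y (2D Young's modulus) and kappa (bending
rigidity).  Strongly driven spectra develop an interior peak at a degree
l*; the corresponding wrinkle wavelength is lambda* = 2 pi R / l*.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares
from scipy.special import sph_harm_y

from .mesh import TriMesh

__all__ = [
    "SHDecomposition",
    "SpectrumEstimate",
    "ElasticFit",
    "NotStarShapedError",
    "real_sph_harm_basis",
    "decompose_configuration",
    "ensemble_spectrum",
    "shell_mode_stiffness",
    "shell_spectrum",
    "fit_shell_spectrum",
    "spectral_peak",
    "fit_parameter_slopes",
]


class NotStarShapedError(ValueError):
    """The configuration cannot be described as r(theta, phi)."""


def default_lmax(n_vertices: int) -> int:
    """Conservative default decomposition cutoff, l_max = floor(sqrt(N)/2)."""
    return int(math.floor(math.sqrt(n_vertices) / 2.0))


def real_sph_harm_basis(lmax: int, theta: np.ndarray,
                        phi: np.ndarray) -> np.ndarray:
    """Design matrix of orthonormal real spherical harmonics, without the
    Condon-Shortley phase, evaluated at polar angles theta and azimuths
    phi.  Columns ordered (l, m) with l = 0..lmax, m = -l..l."""
    cols = []
    for l in range(lmax + 1):
        ylm = {m: sph_harm_y(l, m, theta, phi) for m in range(l + 1)}
        for m in range(-l, l + 1):
            am = abs(m)
            cs = (-1.0) ** am  # undo the Condon-Shortley phase
            if m == 0:
                cols.append(ylm[0].real)
            elif m > 0:
                cols.append(math.sqrt(2.0) * cs * ylm[am].real)
            else:
                cols.append(math.sqrt(2.0) * cs * ylm[am].imag)
    return np.column_stack(cols)


def _lm_index(lmax: int):
    out = []
    for l in range(lmax + 1):
        for m in range(-l, l + 1):
            out.append((l, m))
    return out


@dataclass
class SHDecomposition:
    """Real spherical-harmonic amplitudes of one configuration."""

    R: float
    lmax: int
    ulm: np.ndarray          # flat (l, m) order, l = 0..lmax; u0m, u1m kept
    star_shaped: bool = True

    def power(self) -> np.ndarray:
        """|u_l|^2 = (2l+1)^{-1} sum_m u_lm^2 for l = 2..lmax."""
        out = np.zeros(self.lmax + 1)
        i = 0
        for l in range(self.lmax + 1):
            n = 2 * l + 1
            out[l] = np.sum(self.ulm[i:i + n] ** 2) / n
            i += n
        return out[2:]

    def coefficient(self, l: int, m: int) -> float:
        return float(self.ulm[l * l + l + m])


def _vertex_solid_angle_weights(mesh: TriMesh, ids: np.ndarray,
                                center: np.ndarray) -> np.ndarray:
    """Per-vertex solid-angle weights: barycentric vertex area / r^2."""
    f = mesh.faces()
    p0, p1, p2 = (mesh.pos[f[:, 0]], mesh.pos[f[:, 1]], mesh.pos[f[:, 2]])
    a2 = np.linalg.norm(np.cross(p1 - p0, p2 - p0), axis=1)
    a_bary = np.zeros(mesh.pos.shape[0])
    np.add.at(a_bary, f.ravel(), np.repeat(a2 / 6.0, 3))
    r2 = np.sum((mesh.pos[ids] - center) ** 2, axis=1)
    return a_bary[ids] / r2


def is_star_shaped(mesh: TriMesh, center: Optional[np.ndarray] = None) -> bool:
    """True when every ray from the centroid crosses the surface exactly
    once, i.e. every oriented face subtends positive signed solid angle."""
    if center is None:
        center = mesh.centroid
    f = mesh.faces()
    a = mesh.pos[f[:, 0]] - center
    b = mesh.pos[f[:, 1]] - center
    c = mesh.pos[f[:, 2]] - center
    det = np.einsum("ij,ij->i", a, np.cross(b, c))
    return bool(np.all(det > 0.0))


def decompose_configuration(mesh: TriMesh, lmax: Optional[int] = None,
                            require_star_shaped: bool = True
                            ) -> SHDecomposition:
    """Weighted least-squares spherical-harmonic decomposition.

    Vertices are mapped to (r, theta, phi) about the vertex centroid and
    the radius field is regressed on real spherical harmonics up to lmax
    with solid-angle weights (barycentric vertex area / r^2).  The fitted
    monopole gives R; amplitudes are u_lm = c_lm / R.

    Raises NotStarShapedError for overhanging configurations (unless
    ``require_star_shaped=False``, which only flags them) and ValueError
    when lmax demands more coefficients than the vertex count supports
    ((lmax+1)^2 <= 0.55 * N).
    """
    ids = mesh.alive
    n = len(ids)
    if lmax is None:
        lmax = default_lmax(n)
    ncoef = (lmax + 1) ** 2
    if ncoef > 0.55 * n:
        raise ValueError(
            f"lmax={lmax} needs {ncoef} coefficients but only {n} vertices "
            f"are available (require (lmax+1)^2 <= 0.55*N)")
    center = mesh.centroid
    star = is_star_shaped(mesh, center)
    if require_star_shaped and not star:
        raise NotStarShapedError(
            "configuration is not star-shaped about its centroid")
    rel = mesh.pos[ids] - center
    r = np.linalg.norm(rel, axis=1)
    theta = np.arccos(np.clip(rel[:, 2] / r, -1.0, 1.0))
    phi = np.arctan2(rel[:, 1], rel[:, 0])
    basis = real_sph_harm_basis(lmax, theta, phi)
    w = _vertex_solid_angle_weights(mesh, ids, center)
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(basis * sw[:, None], r * sw, rcond=None)
    R = coef[0] * float(sph_harm_y(0, 0, 0.0, 0.0).real)  # c00 * Y00
    return SHDecomposition(R=float(R), lmax=lmax, ulm=coef / R,
                           star_shaped=star)


@dataclass
class SpectrumEstimate:
    """Ensemble-averaged fluctuation spectrum at one time slice."""

    ell: np.ndarray            # degrees l = 2..lmax
    power: np.ndarray          # <|u_l|^2>
    stderr: np.ndarray         # across-sample standard error
    R: float                   # ensemble-mean monopole radius
    nsamples: int
    n_excluded: int = 0        # non-star-shaped configurations dropped
    tau: Optional[int] = None  # ensemble time (sweeps), if known
    kBT: float = 1.0


def ensemble_spectrum(meshes: Iterable[TriMesh],
                      lmax: Optional[int] = None,
                      tau: Optional[int] = None) -> SpectrumEstimate:
    """Average the degree power over an ensemble of configurations at a
    common elapsed time; non-star-shaped members are excluded and counted."""
    powers: List[np.ndarray] = []
    radii: List[float] = []
    excluded = 0
    for m in meshes:
        try:
            dec = decompose_configuration(m, lmax=lmax)
        except NotStarShapedError:
            excluded += 1
            continue
        powers.append(dec.power())
        radii.append(dec.R)
    if len(powers) < 2:
        raise ValueError(
            f"need at least 2 usable configurations, got {len(powers)} "
            f"({excluded} excluded as non-star-shaped)")
    arr = np.vstack(powers)
    lmax_eff = arr.shape[1] + 1
    return SpectrumEstimate(
        ell=np.arange(2, lmax_eff + 1),
        power=arr.mean(axis=0),
        stderr=arr.std(axis=0, ddof=1) / np.sqrt(len(powers)),
        R=float(np.mean(radii)),
        nsamples=len(powers),
        n_excluded=excluded,
        tau=tau,
    )


# ---------------------------------------------------------------------------
# elastic-shell spectrum model
# ---------------------------------------------------------------------------

def shell_mode_stiffness(ell, gamma: float, Y: float, kappa: float,
                         R: float) -> np.ndarray:
    """A_l of the pressurized-shell spectrum <|u_l|^2> = kBT/(2 A_l)."""
    ell = np.asarray(ell, dtype=float)
    pl = (ell - 1.0) * (ell + 2.0)
    return 0.5 * (gamma * R * R * pl
                  + Y * R * R * pl / (ell * (ell + 1.0))
                  + kappa * pl * pl)


def shell_spectrum(ell, gamma: float, Y: float, kappa: float, R: float,
                   kBT: float = 1.0) -> np.ndarray:
    a = shell_mode_stiffness(ell, gamma, Y, kappa, R)
    return kBT / (2.0 * a)


@dataclass
class ElasticFit:
    """Effective elastic parameters from a spectrum fit (kBT/l0 units)."""

    gamma: float
    Y: float
    kappa_eff: float
    R: float
    stderr_gamma: float
    stderr_Y: float
    stderr_kappa: float
    chi2_red: float
    fit_range: Tuple[int, int]
    valid: bool = True
    flags: List[str] = field(default_factory=list)
    ell_star: Optional[int] = None
    lambda_star: Optional[float] = None
    delta_mu: Optional[float] = None
    dp: Optional[float] = None

    @property
    def poor_fit(self) -> bool:
        return self.chi2_red > 10.0


def spectral_peak(spec: SpectrumEstimate) -> Tuple[Optional[int],
                                                   Optional[float]]:
    """Interior spectral maximum (l*, lambda* = 2 pi R / l*), or
    (None, None) for monotonically decreasing (peak-free) spectra."""
    i = int(np.argmax(spec.power))
    l_star = int(spec.ell[i])
    if i == 0 or i == len(spec.ell) - 1:
        return None, None
    return l_star, 2.0 * math.pi * spec.R / l_star


def fit_shell_spectrum(spec: SpectrumEstimate, kBT: float = 1.0,
                       fit_range: Tuple[int, int] = (2, 40),
                       p0: Optional[Tuple[float, float, float]] = None
                       ) -> ElasticFit:
    """Weighted nonlinear least squares of the measured spectrum against
    the pressurized-shell form, in log space.

    Fits (gamma, log Y, log kappa) with R fixed at the measured ensemble
    radius; weights are the relative standard errors of each degree.
    Flags (rather than silently accepting) fits with reduced chi^2 > 10,
    where the equilibrium shell form no longer describes the data and the
    effective parameters lose meaning.
    """
    lo, hi = fit_range
    sel = (spec.ell >= lo) & (spec.ell <= hi)
    ell = spec.ell[sel].astype(float)
    y = spec.power[sel]
    if np.any(y <= 0):
        raise ValueError("non-positive spectrum values in fit range")
    sig_log = np.clip(spec.stderr[sel] / y, 1e-3, None)
    logy = np.log(y)
    R = spec.R

    if p0 is None:
        # bending-dominated initial guess from the highest degrees
        pl = (ell - 1.0) * (ell + 2.0)
        k0 = float(np.median(kBT / (y * pl * pl)))
        p0 = (0.0, max(10.0 * k0 / R ** 2, 1e-4), max(k0, 1e-3))

    def resid(theta):
        g, logY, logk = theta
        a = shell_mode_stiffness(ell, g, math.exp(logY), math.exp(logk), R)
        bad = a <= 0
        if np.any(bad):
            out = np.full_like(ell, 1e6)
            out[~bad] = (np.log(kBT / (2.0 * a[~bad])) - logy[~bad]) \
                / sig_log[~bad]
            return out
        return (np.log(kBT / (2.0 * a)) - logy) / sig_log

    x0 = np.array([p0[0], math.log(p0[1]), math.log(p0[2])])
    res = least_squares(resid, x0, method="lm", max_nfev=5000)
    g, logY, logk = res.x
    Yv, kv = math.exp(logY), math.exp(logk)
    dof = max(len(ell) - 3, 1)
    chi2_red = float(2.0 * res.cost / dof)
    jtj = res.jac.T @ res.jac
    flags = []
    try:
        cov = np.linalg.inv(jtj) * max(chi2_red, 1.0)
        se = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        se = np.full(3, np.inf)
        flags.append("singular-fit")
    fit = ElasticFit(
        gamma=float(g), Y=float(Yv), kappa_eff=float(kv), R=float(R),
        stderr_gamma=float(se[0]), stderr_Y=float(Yv * se[1]),
        stderr_kappa=float(kv * se[2]), chi2_red=chi2_red,
        fit_range=(int(ell[0]), int(ell[-1])), flags=flags,
    )
    fit.ell_star, fit.lambda_star = spectral_peak(spec)
    if not res.success:
        fit.valid = False
        fit.flags.append("optimizer-failed")
    if fit.poor_fit:
        fit.flags.append("poor-fit-far-from-equilibrium")
    return fit


def fit_parameter_slopes(fits: Sequence[ElasticFit],
                         delta_mus: Sequence[float],
                         window: float = 4.0) -> dict:
    """Near-equilibrium slopes c_gamma, c_Y, c_kappa of the effective
    parameters vs delta_mu/kBT, from weighted linear regression over the
    points with delta_mu <= window."""
    out = {}
    dmu = np.asarray(delta_mus, dtype=float)
    sel = dmu <= window
    if sel.sum() < 2:
        raise ValueError("need >= 2 fits inside the linear window")
    for name, attr, sattr in (("c_gamma", "gamma", "stderr_gamma"),
                              ("c_Y", "Y", "stderr_Y"),
                              ("c_kappa", "kappa_eff", "stderr_kappa")):
        vals = np.array([getattr(f, attr) for f in fits])[sel]
        errs = np.array([getattr(f, sattr) for f in fits])[sel]
        w = 1.0 / np.clip(errs, np.max(errs) * 1e-3, None) ** 2
        x = dmu[sel]
        xm = np.average(x, weights=w)
        vm = np.average(vals, weights=w)
        sxx = np.sum(w * (x - xm) ** 2)
        slope = np.sum(w * (x - xm) * (vals - vm)) / sxx
        out[name] = float(slope)
        out[name + "_stderr"] = float(math.sqrt(1.0 / sxx))
        out[name.replace("c_", "") + "_eq"] = float(vm - slope * xm)
    return out
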