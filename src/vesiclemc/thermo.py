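"""Stochastic thermodynamics of growth trajectory ensembles.

Over an ensemble of trajectories of duration tau, each observable x
contributes a net flux J = x(tau) - x(0); the corresponding time-averaged
current is j = J/tau and the diffusivity matrix is D = Xi/(2 tau) with
Xi_ij = Cov(J_i, J_j).  This module provides:

* flux statistics (means, covariance, diffusivities, standard errors),
* the near-equilibrium linear-response check j_N ~ (D_N / kBT) * dmu,
* entropy-production estimates dS = (dmu*dN + dp*dV)/T - tau*eps_diss
  (the relative-entropy rate eps_diss of a growing system is pluggable
  and defaults to zero, with the inclusion recorded on every estimate),
* thermodynamic-uncertainty-relation (TUR) lower bounds
  dS >= 2 kB <J>^T Xi^{-1} <J>, which are monotone in the set of
  observed fluxes,
* inference of the conjugate thermodynamic forces f = kBT D^{-1} j,
* heuristic force laws: the tension form
  f_N = kBT c_gamma^{-1} (gamma - gamma_eq|dp) + phi(dp) and the hinge
  form f_V = c_p*dp + zeta*(mu - mu*(dp))*Theta(mu - mu*(dp)), and
* the low-dimensional growth law (Ndot, Vdot) = D f / kBT and its
  inverse (design mode).

Units: kB = 1, T = 1 unless stated, so entropies are in units of kB.
The Heaviside convention is Theta(x) = 1 for x >= 0, else 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .engine import TrajectoryEnsemble

__all__ = [
    "FluxEnsemble",
    "EntropyEstimate",
    "ForceEstimate",
    "ForceLawFit",
    "flux_statistics",
    "linear_response_check",
    "tur_bound",
    "entropy_bounds",
    "infer_forces",
    "fit_force_laws",
    "growth_law_predict",
    "growth_law_invert",
]


@dataclass
class FluxEnsemble:
    """Per-sample net fluxes at horizon tau and their moments."""

    observables: Tuple[str, ...]
    J: np.ndarray               # (nsamples, k) net fluxes
    tau: float
    delta_mu: Optional[float] = None
    dp: Optional[float] = None
    D_eq: Optional[np.ndarray] = None   # equilibrium diffusivity, if known

    def __post_init__(self):
        self.J = np.atleast_2d(np.asarray(self.J, dtype=float))
        if self.J.shape[0] < 3:
            raise ValueError("need >= 3 samples for flux statistics")

    @property
    def nsamples(self) -> int:
        return self.J.shape[0]

    @property
    def mean(self) -> np.ndarray:
        return self.J.mean(axis=0)

    @property
    def mean_se(self) -> np.ndarray:
        return self.J.std(axis=0, ddof=1) / math.sqrt(self.nsamples)

    @property
    def cov(self) -> np.ndarray:
        """Unbiased flux covariance Xi (k x k)."""
        return np.atleast_2d(np.cov(self.J, rowvar=False, ddof=1))

    @property
    def current(self) -> np.ndarray:
        return self.mean / self.tau

    @property
    def D(self) -> np.ndarray:
        """Diffusivity matrix D = Xi / (2 tau)."""
        return self.cov / (2.0 * self.tau)

    def var_se(self) -> np.ndarray:
        """Delta-method standard error of the flux variances."""
        return np.diag(self.cov) * math.sqrt(2.0 / (self.nsamples - 1))

    def subset(self, names: Sequence[str]) -> "FluxEnsemble":
        idx = [self.observables.index(n) for n in names]
        return FluxEnsemble(tuple(names), self.J[:, idx], self.tau,
                            self.delta_mu, self.dp,
                            None if self.D_eq is None
                            else self.D_eq[np.ix_(idx, idx)])


def flux_statistics(ensemble: TrajectoryEnsemble, tau: int,
                    observables: Sequence[str] = ("N", "V")
                    ) -> FluxEnsemble:
    """Net fluxes J = x(tau) - x(0) per sample at the checkpoint exactly
    matching tau (an error lists the missing samples otherwise)."""
    J = ensemble.fluxes(tau, observables)
    return FluxEnsemble(tuple(observables), J, float(tau),
                        delta_mu=ensemble.meta.get("delta_mu"),
                        dp=ensemble.meta.get("dp"))


def linear_response_check(fluxes: Sequence[FluxEnsemble],
                          kBT: float = 1.0, window: float = 5.0,
                          use_equilibrium_D: bool = False) -> Dict:
    """Regression of j_N / D_N on dmu / kBT over the near-equilibrium
    window (default dmu <= 5 kBT, where linear response is expected).

    Fluctuation-dissipation predicts slope 1.  Points beyond the window
    are evaluated against the fit and flagged as deviating when they fall
    more than 3 sigma below the linear-response line."""
    pts = []
    far = []
    for fe in fluxes:
        if fe.delta_mu is None:
            raise ValueError("flux ensemble lacks delta_mu metadata")
        i = fe.observables.index("N")
        n = fe.nsamples
        d = (fe.D_eq if (use_equilibrium_D and fe.D_eq is not None)
             else fe.D)[i, i]
        # E[1/Dhat] = (n-1)/(n-3) / D for a sample variance: debias the
        # plug-in ratio, and propagate the variance-estimation noise
        # (relative SE ~ sqrt(2/(n-1))) into the ratio error
        debias = (n - 3) / (n - 1) if n > 3 else 1.0
        y = debias * fe.current[i] / d
        se = math.hypot(fe.mean_se[i] / fe.tau / d,
                        y * math.sqrt(2.0 / max(n - 1, 1)))
        (pts if fe.delta_mu <= window else far).append(
            (fe.delta_mu / kBT, y, se))
    if len(pts) < 3:
        raise ValueError("need >= 3 ensembles inside the linear window")
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    se = np.clip(np.array([p[2] for p in pts]), 1e-12, None)
    w = 1.0 / se ** 2
    slope = float(np.sum(w * x * y) / np.sum(w * x * x))
    resid = (y - slope * x) / se
    dof = max(len(x) - 1, 1)
    scale = max(1.0, float(np.sqrt(resid @ resid / dof)))
    slope_se = float(scale / math.sqrt(np.sum(w * x * x)))
    deviating = [(p[0], p[1]) for p in far
                 if p[1] < slope * p[0] - 3.0 * math.hypot(p[2], slope_se)]
    return {
        "slope": slope,
        "slope_stderr": slope_se,
        "n_points": len(pts),
        "window": window,
        "consistent_with_unity": abs(slope - 1.0) <= 2.0 * slope_se,
        "far_points_deviating": deviating,
        "n_far": len(far),
    }


# ---------------------------------------------------------------------------
# entropy production
# ---------------------------------------------------------------------------

def tur_bound(mean: np.ndarray, cov: np.ndarray, kB: float = 1.0,
              rcond: Optional[float] = None) -> float:
    """Multidimensional TUR lower bound 2 kB <J>^T Xi^{-1} <J>."""
    mean = np.atleast_1d(mean)
    cov = np.atleast_2d(cov)
    if rcond is None:
        sol = np.linalg.solve(cov, mean)
    else:
        sol = np.linalg.pinv(cov, rcond=rcond) @ mean
    return float(2.0 * kB * mean @ sol)


@dataclass
class EntropyEstimate:
    """Direct entropy-production estimate and TUR lower bounds (units kB)."""

    direct: float               # (dmu*<dN> + dp*<dV>)/T - tau*eps_diss
    direct_no_eps: float        # same without the relative-entropy term
    eps_included: bool
    bound_1d: float             # 2 kB <dN>^2 / Var(dN)
    bound_2d: Optional[float]   # 2 kB <J>^T Xi^{-1} <J>, J = (dN, dV)
    df: int
    tau: float
    regularized: bool = False
    bound_1d_ci: Optional[Tuple[float, float]] = None
    bound_2d_ci: Optional[Tuple[float, float]] = None


def entropy_bounds(fluxes: FluxEnsemble, drive: Tuple[float, float],
                   eps_diss_model: Optional[Callable[..., float]] = None,
                   kBT: float = 1.0, nboot: int = 0,
                   seed: int = 0) -> EntropyEstimate:
    """Direct entropy production of a growing vesicle and its TUR bounds.

    ``drive`` is (delta_mu, dp).  The direct estimate is
    (dmu*<dN> + dp*<dV>)/kBT - tau*eps_diss; eps_diss defaults to zero
    (a pluggable estimate of the relative-entropy rate may be supplied
    and its inclusion is recorded).  The df=1 bound uses the particle
    flux only; the df=2 bound adds the volume flux and can only improve
    (monotonicity of the TUR in the observable set)."""
    dmu, dp = drive
    i = fluxes.observables.index("N")
    mean = fluxes.mean
    cov = fluxes.cov
    direct_raw = (dmu * mean[i]
                  + (dp * mean[fluxes.observables.index("V")]
                     if "V" in fluxes.observables and dp != 0.0 else 0.0)
                  ) / kBT
    eps = 0.0
    included = False
    if eps_diss_model is not None:
        eps = float(eps_diss_model(fluxes=fluxes, drive=drive, kBT=kBT))
        included = True
    b1 = 2.0 * mean[i] ** 2 / cov[i, i]
    b2 = None
    regularized = False
    if len(fluxes.observables) >= 2:
        try:
            b2 = tur_bound(mean, cov)
        except np.linalg.LinAlgError:
            b2 = tur_bound(mean, cov, rcond=1e-10)
            regularized = True
    est = EntropyEstimate(
        direct=float(direct_raw - fluxes.tau * eps),
        direct_no_eps=float(direct_raw), eps_included=included,
        bound_1d=float(b1), bound_2d=b2,
        df=len(fluxes.observables), tau=fluxes.tau,
        regularized=regularized)
    if nboot:
        rng = np.random.default_rng(seed)
        n = fluxes.nsamples
        s1, s2 = [], []
        for _ in range(nboot):
            J = fluxes.J[rng.integers(n, size=n)]
            m = J.mean(axis=0)
            c = np.atleast_2d(np.cov(J, rowvar=False, ddof=1))
            s1.append(2.0 * m[i] ** 2 / c[i, i])
            if b2 is not None:
                try:
                    s2.append(tur_bound(m, c))
                except np.linalg.LinAlgError:
                    pass
        est.bound_1d_ci = tuple(np.percentile(s1, [2.5, 97.5]))
        if s2:
            est.bound_2d_ci = tuple(np.percentile(s2, [2.5, 97.5]))
    return est


# ---------------------------------------------------------------------------
# force inference
# ---------------------------------------------------------------------------

@dataclass
class ForceEstimate:
    """Inferred conjugate forces f = kBT D^{-1} j with bootstrap CIs."""

    observables: Tuple[str, ...]
    f: np.ndarray
    ci_low: Optional[np.ndarray] = None
    ci_high: Optional[np.ndarray] = None
    delta_mu: Optional[float] = None
    dp: Optional[float] = None

    def __getitem__(self, name: str) -> float:
        return float(self.f[self.observables.index(name)])


def _wishart_debias(n: int, k: int) -> float:
    """E[inv(sample cov)] = inv(cov) * (n-1)/(n-k-2) for Gaussian data;
    multiply plug-in inverse-covariance estimates by this factor."""
    return (n - k - 2) / (n - 1) if n > k + 2 else 1.0


def infer_forces(fluxes: FluxEnsemble, kBT: float = 1.0,
                 nboot: int = 1000, seed: int = 0) -> ForceEstimate:
    """Thermodynamic driving forces conjugate to the observed fluxes,
    f = kBT D^{-1} j = 2 kBT Xi^{-1} <J>.

    The plug-in inverse covariance is biased upward for small ensembles;
    the standard Wishart correction (n-k-2)/(n-1) is applied."""
    cov = fluxes.cov
    if np.linalg.cond(cov) > 1e12:
        raise np.linalg.LinAlgError(
            "flux covariance is singular; drop redundant observables")
    n = fluxes.nsamples
    k = len(fluxes.observables)
    debias = _wishart_debias(n, k)
    f = debias * kBT * np.linalg.solve(fluxes.D, fluxes.current)
    est = ForceEstimate(fluxes.observables, f,
                        delta_mu=fluxes.delta_mu, dp=fluxes.dp)
    if nboot:
        rng = np.random.default_rng(seed)
        samples = []
        for _ in range(nboot):
            J = fluxes.J[rng.integers(n, size=n)]
            c = np.atleast_2d(np.cov(J, rowvar=False, ddof=1))
            try:
                samples.append(
                    debias * kBT * np.linalg.solve(
                        c / (2 * fluxes.tau),
                        J.mean(axis=0) / fluxes.tau))
            except np.linalg.LinAlgError:
                continue
        arr = np.vstack(samples)
        est.ci_low = np.percentile(arr, 2.5, axis=0)
        est.ci_high = np.percentile(arr, 97.5, axis=0)
    return est


# ---------------------------------------------------------------------------
# heuristic force laws
# ---------------------------------------------------------------------------

def heaviside(x) -> np.ndarray:
    """Theta(x) = 1 for x >= 0, else 0."""
    return np.where(np.asarray(x, dtype=float) >= 0.0, 1.0, 0.0)


@dataclass
class ForceLawFit:
    """Fitted coefficients of the heuristic force laws."""

    c_gamma: float = math.nan       # tension-vs-dmu slope (negative)
    c_gamma_stderr: float = math.nan
    phi_dp: Dict[float, float] = field(default_factory=dict)  # offsets
    c_p: float = math.nan           # fV ~ c_p * dp at equilibrium
    c_p_stderr: float = math.nan
    zeta: float = math.nan          # hinge slope of fV vs mu
    zeta_stderr: float = math.nan
    mu_star: Dict[float, float] = field(default_factory=dict)  # thresholds
    open_threshold: List[float] = field(default_factory=list)
    fn_slope: float = math.nan      # fN vs dmu near equilibrium
    fn_slope_stderr: float = math.nan


def _wls_slope(x, y, se=None, through_origin=True):
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    w = np.ones_like(x) if se is None else 1.0 / np.clip(se, 1e-12, None)**2
    if through_origin:
        sxx = np.sum(w * x * x)
        slope = np.sum(w * x * y) / sxx
        resid = y - slope * x
        dof = max(len(x) - 1, 1)
        scale = max(1.0, math.sqrt(float(np.sum(w * resid**2)) / dof))
        return slope, scale / math.sqrt(sxx)
    xm = np.average(x, weights=w)
    ym = np.average(y, weights=w)
    sxx = np.sum(w * (x - xm) ** 2)
    slope = np.sum(w * (x - xm) * (y - ym)) / sxx
    resid = y - ym - slope * (x - xm)
    dof = max(len(x) - 2, 1)
    scale = max(1.0, math.sqrt(float(np.sum(w * resid**2)) / dof))
    return slope, scale / math.sqrt(sxx)


def fit_force_laws(records: pd.DataFrame, kBT: float = 1.0,
                   window: float = 5.0,
                   c_gamma: Optional[float] = None,
                   c_p: Optional[float] = None) -> ForceLawFit:
    """Fit the heuristic force laws on a (mu, dp) grid of inferred forces.

    ``records`` needs columns (delta_mu, dp, fN, fV) and, for the tension
    law, (gamma, gamma_eq); optional *_se columns weight the fits.

    * f_N vs delta_mu slope (near equilibrium, through origin; expected 1),
    * c_gamma from the gamma-vs-delta_mu regression inside the linear
      window (unless supplied), with per-dp offsets phi(dp) of
      f_N - kBT c_gamma^{-1} (gamma - gamma_eq|dp),
    * c_p from the equilibrium volume force f_V(mu = mu_eq) vs dp,
    * (zeta, mu*(dp)) from joint piecewise-linear (hinge) regression of
      f_V - c_p*dp against mu across all dp.
    """
    out = ForceLawFit()
    df = records.copy()
    near = df[df["delta_mu"] <= window]

    nz = near[np.isfinite(near["fN"])]
    if len(nz) >= 3:
        se = nz["fN_se"] if "fN_se" in nz else None
        out.fn_slope, out.fn_slope_stderr = _wls_slope(
            nz["delta_mu"] / kBT, nz["fN"] / kBT, se)

    if c_gamma is None and "gamma" in df.columns:
        g = near[np.isfinite(near["gamma"])]
        if g["dp"].nunique() >= 1 and len(g) >= 3:
            slopes = []
            for dp, sub in g.groupby("dp"):
                if len(sub) >= 3:
                    se = sub["gamma_se"] if "gamma_se" in sub else None
                    s, s_se = _wls_slope(sub["delta_mu"], sub["gamma"], se,
                                         through_origin=False)
                    slopes.append((s, s_se, len(sub)))
            if slopes:
                wts = np.array([1.0 / s[1] ** 2 for s in slopes])
                vals = np.array([s[0] for s in slopes])
                out.c_gamma = float(np.sum(wts * vals) / np.sum(wts))
                out.c_gamma_stderr = float(1.0 / math.sqrt(np.sum(wts)))
    elif c_gamma is not None:
        out.c_gamma = c_gamma

    if np.isfinite(out.c_gamma) and "gamma" in df.columns:
        for dp, sub in near.groupby("dp"):
            sub = sub[np.isfinite(sub["gamma"])]
            if len(sub):
                pred = kBT / out.c_gamma * (sub["gamma"] - sub["gamma_eq"])
                out.phi_dp[float(dp)] = float((sub["fN"] - pred).mean())

    # c_p: equilibrium volume force vs dp (unless supplied)
    if c_p is not None:
        out.c_p = c_p
    else:
        eq = df[np.abs(df["delta_mu"]) <= min(1.0, window / 4)]
        if eq["dp"].nunique() >= 2:
            se = eq["fV_se"] if "fV_se" in eq else None
            out.c_p, out.c_p_stderr = _wls_slope(eq["dp"], eq["fV"], se)

    # hinge regression for fV: shared zeta, per-dp threshold mu*
    # (needs at least one residual dof beyond the 1 + len(dps) params)
    dps = sorted(df["dp"].unique())
    if len(df) >= len(dps) + 3 and np.isfinite(out.c_p):
        mu_col = df["delta_mu"] + df.get("mu_eq", 0.0)
        x = mu_col.to_numpy(float)
        yv = (df["fV"] - out.c_p * df["dp"]).to_numpy(float)
        dpv = df["dp"].to_numpy(float)
        se = (df["fV_se"].to_numpy(float) if "fV_se" in df
              else np.ones(len(df)))
        se = np.clip(se, 1e-9, None)
        dp_idx = np.searchsorted(dps, dpv)

        def resid(theta):
            zeta = theta[0]
            mus = theta[1:]
            pred = zeta * (x - mus[dp_idx]) * heaviside(x - mus[dp_idx])
            return (yv - pred) / se

        theta0 = np.concatenate([[0.3],
                                 [np.median(x[dpv == dp]) for dp in dps]])
        res = least_squares(resid, theta0, max_nfev=4000)
        out.zeta = float(res.x[0])
        dof = max(len(df) - len(res.x), 1)
        try:
            # weighted residuals: inv(J^T J) already carries the known
            # errors; inflate (never deflate) by the reduced chi-square
            cov = (np.linalg.inv(res.jac.T @ res.jac)
                   * max(2 * res.cost / dof, 1.0))
            out.zeta_stderr = float(math.sqrt(cov[0, 0]))
        except np.linalg.LinAlgError:
            out.zeta_stderr = math.nan
        for t, dp in enumerate(dps):
            ms = float(res.x[1 + t])
            lo, hi = x[dpv == dp].min(), x[dpv == dp].max()
            out.mu_star[float(dp)] = ms
            if not (lo <= ms <= hi):
                out.open_threshold.append(float(dp))
    return out


# ---------------------------------------------------------------------------
# growth law
# ---------------------------------------------------------------------------

def growth_law_predict(D: np.ndarray, f: np.ndarray,
                       kBT: float = 1.0) -> np.ndarray:
    """Mean growth rates (Ndot, Vdot) = D f / kBT from the diffusivity
    matrix and the conjugate forces."""
    return np.asarray(D, float) @ np.asarray(f, float) / kBT


def growth_law_invert(D: np.ndarray, rates: np.ndarray,
                      kBT: float = 1.0) -> np.ndarray:
    """Design mode: forces required for target mean rates,
    f = kBT D^{-1} (Ndot, Vdot)."""
    D = np.asarray(D, float)
    if np.linalg.cond(D) > 1e12:
        raise np.linalg.LinAlgError("diffusivity matrix is singular")
    return kBT * np.linalg.solve(D, np.asarray(rates, float))
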