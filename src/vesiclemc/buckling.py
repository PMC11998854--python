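"""Buckling thresholds for pressurized elastic shells, at zero and finite
temperature, and classification of driven vesicle states.

A thin spherical shell of radius R, bending rigidity kappa and 2D Young's
modulus Y buckles at the classical (zero-temperature) critical pressure

    P_c0 = (4 / R^2) sqrt(kappa Y),

equivalently at the negative critical tension

    gamma_c0 = -(2 / R) sqrt(kappa Y),

related by P_c0 = 2 |gamma_c0| / R.  Thermal fluctuations soften the
shell and reduce the threshold magnitude by a scaling function of the
elastothermal number

    ET = (kBT / kappa) sqrt(Y R^2 / kappa),
    gamma_c = gamma_c0 * Psi(ET),   0 < Psi <= 1, Psi(0) = 1.

Psi is consumed as a pluggable strategy: renormalization-group
calculations in the shell literature provide it as a tabulated curve.
The default here is a smooth analytic stand-in with the correct
qualitative properties (see :data:`PSI_APPROX_RG`); quantitative
classifications carry the Psi provenance with them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence, Tuple

import numpy as np
from scipy.interpolate import PchipInterpolator

__all__ = [
    "BucklingPrediction",
    "PsiModel",
    "PSI_ZERO_T",
    "PSI_APPROX_RG",
    "zero_T_thresholds",
    "elastothermal_number",
    "finite_T_critical_tension",
    "phase_boundary",
    "phase_diagram",
]


def _require_positive(**kw):
    for name, v in kw.items():
        if not (v > 0):
            raise ValueError(f"{name} must be positive, got {v}")


def zero_T_thresholds(kappa: float, Y: float, R: float
                      ) -> Tuple[float, float]:
    """(P_c0, gamma_c0): classical buckling pressure and tension of a
    sphere; satisfies P_c0 = 2|gamma_c0|/R."""
    _require_positive(kappa=kappa, Y=Y, R=R)
    root = math.sqrt(kappa * Y)
    return 4.0 * root / R ** 2, -2.0 * root / R


def elastothermal_number(kappa: float, Y: float, R: float,
                         kBT: float = 1.0) -> float:
    """ET = (kBT/kappa) * sqrt(Y R^2 / kappa): thermal vs elastic
    resistance to deformation.  kBT = 0 is allowed (ET = 0)."""
    _require_positive(kappa=kappa, Y=Y, R=R)
    if kBT < 0:
        raise ValueError("kBT must be non-negative")
    return (kBT / kappa) * math.sqrt(Y * R ** 2 / kappa)


class PsiModel:
    """Monotone non-increasing scaling function Psi with Psi(0) = 1.

    Wraps either a callable or a tabulated curve (monotone PCHIP
    interpolation, validated at construction).  ``provenance`` travels
    with every prediction so downstream classifications are auditable.
    """

    def __init__(self, fn: Callable[[float], float], provenance: str,
                 table: Optional[Tuple[np.ndarray, np.ndarray]] = None):
        self._fn = fn
        self.provenance = provenance
        self.table = table
        self._validate()

    @classmethod
    def from_table(cls, x: Sequence[float], y: Sequence[float],
                   provenance: str) -> "PsiModel":
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x[0] != 0.0 or abs(y[0] - 1.0) > 1e-9:
            raise ValueError("table must start at Psi(0) = 1")
        if np.any(np.diff(x) <= 0):
            raise ValueError("table abscissae must be increasing")
        if np.any(np.diff(y) > 1e-12):
            raise ValueError("Psi table must be non-increasing")
        interp = PchipInterpolator(x, y, extrapolate=False)
        xmax, ymax = float(x[-1]), float(y[-1])

        def fn(v: float) -> float:
            if v <= 0.0:
                return 1.0
            if v >= xmax:
                return ymax
            return float(interp(v))

        return cls(fn, provenance, table=(x, y))

    def _validate(self, n: int = 200, xmax: float = 20.0) -> None:
        xs = np.linspace(0.0, xmax, n)
        ys = np.array([self._fn(float(x)) for x in xs])
        if abs(ys[0] - 1.0) > 1e-9:
            raise ValueError("Psi(0) must equal 1")
        if np.any(np.diff(ys) > 1e-12):
            raise ValueError("Psi must be monotonically non-increasing")
        if np.any(ys <= 0.0) or np.any(ys > 1.0 + 1e-12):
            raise ValueError("Psi must lie in (0, 1]")

    def __call__(self, x: float) -> float:
        if x < 0:
            raise ValueError("elastothermal number must be >= 0")
        return float(self._fn(x))


#: zero-temperature limit: no fluctuation softening
PSI_ZERO_T = PsiModel(lambda x: 1.0, provenance="zero-temperature (Psi=1)")

#: smooth analytic stand-in for the RG softening curve: Psi = (1+x)^(-2/5).
#: SYNTHETIC approximation, not a transcription of a published table; it has
#: the documented qualitative properties (Psi(0)=1, monotone decreasing,
#: ~25% threshold reduction at ET ~ 1).  Replace with PsiModel.from_table
#: for quantitative comparisons against a specific RG calculation.
PSI_APPROX_RG = PsiModel(lambda x: (1.0 + x) ** -0.4,
                         provenance="approx-rg (1+ET)^(-2/5), synthetic "
                                    "stand-in for the RG curve")


@dataclass
class BucklingPrediction:
    """Buckling threshold bundle for one (kappa, Y, R, kBT) state."""

    gamma_c0: float     # zero-T critical tension (negative)
    P_c0: float         # zero-T critical pressure
    ET: float           # elastothermal number
    psi: float          # Psi(ET) in (0, 1]
    gamma_c: float      # finite-T critical tension = gamma_c0 * psi
    psi_provenance: str
    measured_gamma: Optional[float] = None
    buckled: Optional[bool] = None


def finite_T_critical_tension(kappa: float, Y: float, R: float,
                              kBT: float = 1.0,
                              psi_model: PsiModel = PSI_APPROX_RG,
                              measured_gamma: Optional[float] = None
                              ) -> BucklingPrediction:
    """Finite-temperature buckling prediction gamma_c = gamma_c0*Psi(ET).

    When a measured effective tension is supplied the state is classified
    as buckled iff gamma <= gamma_c (thresholds are negative, so the
    fluctuation softening |gamma_c| <= |gamma_c0| makes buckling easier)."""
    p_c0, g_c0 = zero_T_thresholds(kappa, Y, R)
    et = elastothermal_number(kappa, Y, R, kBT)
    psi = psi_model(et)
    g_c = g_c0 * psi
    pred = BucklingPrediction(gamma_c0=g_c0, P_c0=p_c0, ET=et, psi=psi,
                              gamma_c=g_c,
                              psi_provenance=psi_model.provenance,
                              measured_gamma=measured_gamma)
    if measured_gamma is not None:
        pred.buckled = bool(measured_gamma <= g_c)
    return pred


# ---------------------------------------------------------------------------
# phase diagram
# ---------------------------------------------------------------------------

def phase_boundary(delta_mus: Sequence[float], gamma: Sequence[float],
                   gamma_c: Sequence[float]) -> Optional[float]:
    """Interpolated crossing delta_mu* where gamma(delta_mu) first drops
    below gamma_c(delta_mu); None when no crossing occurs in the scan."""
    dmu = np.asarray(delta_mus, dtype=float)
    diff = np.asarray(gamma, dtype=float) - np.asarray(gamma_c, dtype=float)
    if len(dmu) == 0:
        raise ValueError("empty state-point series")
    order = np.argsort(dmu)
    dmu, diff = dmu[order], diff[order]
    if diff[0] <= 0:
        return float(dmu[0])
    for i in range(1, len(dmu)):
        if diff[i] <= 0:
            x0, x1 = dmu[i - 1], dmu[i]
            y0, y1 = diff[i - 1], diff[i]
            return float(x0 + (x1 - x0) * y0 / (y0 - y1))
    return None


def phase_diagram(series: dict) -> dict:
    """Morphological-transition boundary delta_mu*(dp).

    ``series`` maps dp -> (delta_mus, gamma, gamma_c) arrays for the scan
    at that pressure.  Returns the boundary points, the dp values with an
    open (uncrossed) boundary, and a linear fit delta_mu* ~ b0 + b1*dp of
    the closed points (requires >= 2)."""
    if not series:
        raise ValueError("empty fit series")
    points = []
    open_dps = []
    for dp, (dmus, g, gc) in sorted(series.items()):
        x = phase_boundary(dmus, g, gc)
        if x is None:
            open_dps.append(dp)
        else:
            points.append((float(dp), x))
    out = {"boundary": points, "open": open_dps, "fit": None}
    if len(points) >= 2:
        arr = np.asarray(points)
        b1, b0 = np.polyfit(arr[:, 0], arr[:, 1], 1)
        out["fit"] = {"intercept": float(b0), "slope": float(b1)}
    return out
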