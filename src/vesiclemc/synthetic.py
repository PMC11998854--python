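"""Synthetic fixtures with known ground truth.

Two generators make the analysis stack testable without running any
membrane simulation:

* correlated Gaussian random-walk trajectory ensembles in (N, V) with a
  prescribed drift vector and diffusion matrix — the closed-form oracle
  for flux statistics, TUR bounds and force inference, and
* elastic-shell fluctuation spectra evaluated exactly from the model
  A_l with multiplicative lognormal noise — the round-trip oracle for
  the spectrum fitter.
"""

from __future__ import annotations

from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .engine import TrajectoryEnsemble
from .spectra import SpectrumEstimate, shell_spectrum

__all__ = [
    "generate_synthetic_trajectories",
    "generate_synthetic_spectrum",
]


def generate_synthetic_trajectories(drift: Sequence[float],
                                    diffusion: np.ndarray,
                                    nsamples: int, tau: int,
                                    seed: int,
                                    checkpoint_every: int = 50,
                                    x0: Sequence[float] = (0.0, 0.0),
                                    observables: Tuple[str, ...] = ("N", "V")
                                    ) -> TrajectoryEnsemble:
    """Correlated Gaussian random walks with exact target moments.

    Increments over dt sweeps are N(drift*dt, 2*D*dt) with D the given
    diffusion matrix (must be symmetric positive definite), so that at
    horizon tau: <J> = drift*tau and Cov(J) = 2*D*tau.
    """
    drift = np.asarray(drift, dtype=float)
    D = np.asarray(diffusion, dtype=float)
    k = len(drift)
    if D.shape != (k, k) or not np.allclose(D, D.T):
        raise ValueError("diffusion must be a symmetric (k, k) matrix")
    w = np.linalg.eigvalsh(D)
    if np.any(w <= 0):
        raise ValueError(f"diffusion matrix not positive definite "
                         f"(eigenvalues {w})")
    L = np.linalg.cholesky(2.0 * D)
    rng = np.random.default_rng(seed)
    times = np.arange(0, tau + 1, checkpoint_every)
    rows = []
    for s in range(nsamples):
        x = np.asarray(x0, dtype=float).copy()
        t_prev = 0
        for t in times:
            dt = t - t_prev
            if dt > 0:
                x = x + drift * dt + L @ rng.standard_normal(k) \
                    * np.sqrt(dt)
            t_prev = t
            row = {"sample_id": s, "t_sweeps": int(t)}
            row.update({name: x[i] for i, name in enumerate(observables)})
            rows.append(row)
    meta = {
        "synthetic": True,
        "drift": drift.tolist(),
        "diffusion": D.tolist(),
        "delta_mu": None,
        "dp": None,
        "nsamples": nsamples,
        "seed": seed,
    }
    return TrajectoryEnsemble(pd.DataFrame(rows), meta)


def generate_synthetic_spectrum(gamma: float, Y: float, kappa: float,
                                R: float, noise: float, seed: int,
                                ell_max: int = 30, ell_min: int = 2,
                                nsamples: int = 100,
                                kBT: float = 1.0) -> SpectrumEstimate:
    """Exact elastic-shell spectrum with multiplicative lognormal noise.

    The noise-free model must be stable (A_l > 0) over the requested
    degree range; near the stability edge (gamma approaching the negative
    of the stretching+bending minimum over l) the softest mode diverges
    and a ValueError names it.
    """
    if Y <= 0 or kappa <= 0 or R <= 0:
        raise ValueError("Y, kappa, R must be positive")
    ell = np.arange(ell_min, ell_max + 1)
    power = shell_spectrum(ell, gamma, Y, kappa, R, kBT=kBT)
    if np.any(power <= 0):
        l_soft = int(ell[np.argmin(power[power != 0])]) if np.any(
            power != 0) else int(ell[0])
        raise ValueError(
            f"spectrum unstable: A_l <= 0 at l ~ {l_soft} "
            "(tension beyond the buckling stability edge)")
    rng = np.random.default_rng(seed)
    noisy = power * np.exp(noise * rng.standard_normal(len(ell))) \
        if noise > 0 else power.copy()
    stderr = np.maximum(noise, 1e-4) * noisy
    return SpectrumEstimate(ell=ell, power=noisy, stderr=stderr, R=R,
                            nsamples=nsamples, kBT=kBT)
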