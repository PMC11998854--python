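"""Configurational energies of the triangulated vesicle.

The total energy is

    E_tot = E_bend + E_tether + E_area

where

* ``E_bend`` is the discrete Helfrich bending energy
  (kappa/2) * integral (2H)^2 dA, evaluated with the cotangent-Laplacian
  vertex mean curvature and barycentric vertex areas (a dihedral-angle
  variant is available for cross-checks),
* ``E_tether`` is a hard square well on every edge length, keeping the
  triangulation geometrically sane (edge lengths near l0 = 1),
* ``E_area`` is a per-face harmonic penalty (k_a/2)(A_f - a0)^2 that fixes
  the mean vertex density rho0 ~ 1/(2*a0) so that surface area tracks
  particle number, A(t) ~ N(t)/rho0.

The grand-canonical sampler accepts moves by the change in

    Phi = E_tot - mu*N - dp*V

with mu the reservoir chemical potential of surface particles and dp the
osmotic pressure difference (inside minus outside).  All energies are in
kBT, lengths in l0.

The functions here recompute energies from scratch with vectorized numpy;
the Monte Carlo engine instead uses fused incremental kernels.  The two
paths are verified against each other in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .mesh import TriMesh, enclosed_volume

__all__ = [
    "EnergyParams",
    "EnergyBreakdown",
    "bending_energy",
    "tether_energy",
    "area_energy",
    "total_energy",
    "phi",
    "DegenerateFaceError",
]

#: face area of an equilateral triangle of unit edge; the default area
#: target so a fresh unit-edge icosphere starts near zero area energy
EQUILATERAL_AREA = math.sqrt(3.0) / 4.0

TETHER_SENTINEL = math.inf


class DegenerateFaceError(ValueError):
    """A zero-area face makes the cotangent energy ill-defined."""


@dataclass
class EnergyParams:
    """Energetic parameters of the vesicle model (kBT / l0 units).

    The tether bounds admit the midpoint edge split used by the
    grand-canonical move set: an edge of length up to ``tether_max`` splits
    into halves that must still exceed ``tether_min``, which requires
    ``tether_min <= tether_max / 2`` for insertions to be possible at all.
    ``area_stiffness`` is chosen so that *total* area (and hence the vertex
    density rho0 = N/A) is stiff at the percent level while individual
    faces stay soft enough for exchange moves to be accepted.
    """

    kappa: float = 20.0            # bending rigidity, kBT
    tether_min: float = 0.45       # hard lower edge bound, l0
    tether_max: float = 1.70       # hard upper edge bound, l0
    area_stiffness: float = 25.0   # k_a, kBT / l0^4
    target_face_area: float = EQUILATERAL_AREA  # a0, l0^2

    def __post_init__(self):
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if not (0 <= self.tether_min < self.tether_max):
            raise ValueError("need 0 <= tether_min < tether_max")
        if self.area_stiffness < 0:
            raise ValueError("area_stiffness must be >= 0")
        if self.target_face_area <= 0:
            raise ValueError("target_face_area must be positive")

    @property
    def rho0(self) -> float:
        """Target vertex density N/A = 1/(2*a0) (sphere topology,
        F = 2N - 4, so A ~ 2*N*a0 for large N)."""
        return 1.0 / (2.0 * self.target_face_area)


@dataclass
class EnergyBreakdown:
    """Energy components (kBT) and the grand-potential-like Phi."""

    bend: float
    tether: float
    area: float
    mu: float = 0.0
    dp: float = 0.0
    n_vertices: int = 0
    volume: float = 0.0

    @property
    def total(self) -> float:
        return self.bend + self.tether + self.area

    @property
    def phi(self) -> float:
        return self.total - self.mu * self.n_vertices - self.dp * self.volume


def _face_geometry(mesh: TriMesh):
    f = mesh.faces()
    p0 = mesh.pos[f[:, 0]]
    p1 = mesh.pos[f[:, 1]]
    p2 = mesh.pos[f[:, 2]]
    return f, p0, p1, p2


def bending_energy(mesh: TriMesh, params: EnergyParams,
                   method: str = "cotan") -> float:
    """Discrete Helfrich energy (kappa/2) * sum_v (2H_v)^2 A_v.

    ``method="cotan"`` (default) uses the cotangent-Laplacian mean
    curvature with barycentric vertex areas, which converges to the
    continuum energy (8*pi*kappa for a sphere).  ``method="dihedral"``
    returns the classic tethered-surface form
    2*sqrt(3)*kappa * sum_edges (1 - cos(theta_e)) — for near-uniform
    meshes sum(1-cos) -> (1/sqrt(3)) integral H^2 dA, so this prefactor
    matches the (kappa/2)(2H)^2 normalization.  Provided as an
    independent cross-check; it is a different discretization with
    slower convergence.
    """
    f, p0, p1, p2 = _face_geometry(mesh)
    cross = np.cross(p1 - p0, p2 - p0)
    a2 = np.linalg.norm(cross, axis=1)  # twice the face area
    if np.any(a2 < 1e-12):
        bad = int(np.argmin(a2))
        raise DegenerateFaceError(
            f"face {tuple(f[bad])} has (near) zero area")

    if method == "dihedral":
        normals = cross / a2[:, None]
        edge_face = {}
        e_sum = 0.0
        for fi, (a, b, c) in enumerate(f):
            for i, j in ((a, b), (b, c), (c, a)):
                key = (min(i, j), max(i, j))
                if key in edge_face:
                    e_sum += 1.0 - float(normals[edge_face[key]]
                                         @ normals[fi])
                else:
                    edge_face[key] = fi
        return 2.0 * math.sqrt(3.0) * params.kappa * e_sum
    if method != "cotan":
        raise ValueError(f"unknown bending method {method!r}")

    cap = mesh.pos.shape[0]
    s_vec = np.zeros((cap, 3))
    a_bary = np.zeros(cap)
    np.add.at(a_bary, f.ravel(), np.repeat(a2 / 6.0, 3))

    # cotangents at each corner (angle at corner t is opposite edge t)
    corners = (
        (f[:, 2], p2, p0, p1),  # angle at vertex 2, opposite edge (0,1)
        (f[:, 0], p0, p1, p2),  # angle at vertex 0, opposite edge (1,2)
        (f[:, 1], p1, p2, p0),  # angle at vertex 1, opposite edge (2,0)
    )
    edges_idx = ((f[:, 0], f[:, 1]), (f[:, 1], f[:, 2]), (f[:, 2], f[:, 0]))
    for (ci, o, u, v), (ea, eb) in zip(corners, edges_idx):
        du = u - o
        dv = v - o
        dot = np.einsum("ij,ij->i", du, dv)
        crs = np.linalg.norm(np.cross(du, dv), axis=1)
        cot = dot / np.maximum(crs, 1e-300)
        d = mesh.pos[ea] - mesh.pos[eb]
        np.add.at(s_vec, ea, cot[:, None] * d)
        np.add.at(s_vec, eb, -cot[:, None] * d)

    ids = mesh.alive
    s2 = np.einsum("ij,ij->i", s_vec[ids], s_vec[ids])
    return float(params.kappa * np.sum(s2 / (8.0 * a_bary[ids])))


def tether_energy(mesh: TriMesh, params: EnergyParams) -> float:
    """Hard square-well edge constraint: 0 when every edge length lies in
    [tether_min, tether_max], +inf (move-rejecting sentinel) otherwise."""
    ell = mesh.edge_lengths()
    if np.any(ell < params.tether_min) or np.any(ell > params.tether_max):
        return TETHER_SENTINEL
    return 0.0


def area_energy(mesh: TriMesh, params: EnergyParams) -> float:
    """(k_a/2) * sum_faces (A_f - a0)^2."""
    areas = mesh.face_areas()
    return float(0.5 * params.area_stiffness
                 * np.sum((areas - params.target_face_area) ** 2))


def total_energy(mesh: TriMesh, params: EnergyParams) -> float:
    return (bending_energy(mesh, params) + tether_energy(mesh, params)
            + area_energy(mesh, params))


def phi(mesh: TriMesh, params: EnergyParams, mu: float = 0.0,
        dp: float = 0.0) -> EnergyBreakdown:
    """Full energy breakdown with Phi = E_tot - mu*N - dp*V."""
    return EnergyBreakdown(
        bend=bending_energy(mesh, params),
        tether=tether_energy(mesh, params),
        area=area_energy(mesh, params),
        mu=mu,
        dp=dp,
        n_vertices=mesh.n_vertices,
        volume=enclosed_volume(mesh),
    )


def kernel_params_vector(params: EnergyParams, mu: float, dp: float,
                         step: float, pflip: float, pexchange: float,
                         h_cube: float) -> np.ndarray:
    """Pack parameters into the flat vector the numba kernels consume."""
    return np.array([
        params.kappa,
        params.area_stiffness,
        params.target_face_area,
        params.tether_min ** 2,
        params.tether_max ** 2,
        mu,
        dp,
        step,
        pflip,
        pexchange,
        h_cube,
    ])
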