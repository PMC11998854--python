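"""Closed triangulated surfaces and the topology moves of the vesicle sampler.

A :class:`TriMesh` is a closed, orientable, sphere-topology triangulation
specified by vertex positions and the one-ring adjacency of every vertex.
Neighbour rings are kept in cyclic order (counter-clockwise viewed from
outside), which makes faces implicit: for each vertex ``i`` and each
consecutive ring pair ``(j, k)``, the triangle ``(i, j, k)`` is an
outward-oriented face.

Three topology moves are supported, forming the reversible move set of the
grand-canonical sampler:

* **edge flip** — the shared edge of two adjacent triangles is exchanged
  for the opposite diagonal (in-plane fluidity),
* **vertex insertion** — an edge is split at its midpoint (N -> N+1),
* **vertex removal** — a degree-4 vertex is deleted and the quadrilateral
  hole re-triangulated with one of its diagonals (N -> N-1), the exact
  inverse of an insertion.

Every proposal records the generation probability of itself and of its
exact reverse, which the Metropolis rule needs to preserve the
transition-ratio identity of the grand-canonical ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import trimesh as _trimesh_io

from . import _kernels as K

__all__ = [
    "TriMesh",
    "TopologyProposal",
    "TopologyError",
    "build_icosphere",
    "enclosed_volume",
    "propose_edge_flip",
    "propose_vertex_insertion",
    "propose_vertex_removal",
    "apply_proposal",
    "load_mesh",
]

MAXDEG = 16

#: default side (in l0) of the uniform placement cube used by vertex
#: insertions; must match the engine's SimParams.h_cube for the recorded
#: generation densities to describe the sampler actually run
DEFAULT_H_CUBE = 0.5


class TopologyError(ValueError):
    """Raised when a mesh violates closed-manifold invariants."""


@dataclass
class TopologyProposal:
    """A proposed topology move with its generation-probability bookkeeping.

    ``pgen_forward`` is the probability that the proposal machinery
    generates this exact move from the current mesh; ``pgen_reverse`` is
    the probability that it would generate the exact inverse move from the
    post-move mesh.  Both are strictly positive for valid proposals.
    """

    kind: str                      # "flip" | "insert" | "remove"
    edge: Optional[tuple] = None   # (i, j) for flip/insert
    vertex: int = -1               # degree-4 vertex for removal
    diagonal: int = -1             # 0/1 diagonal selector for removal
    valid: bool = True
    reason: str = ""
    pgen_forward: float = 0.0
    pgen_reverse: float = 0.0

    @property
    def gen_ratio(self) -> float:
        return self.pgen_reverse / self.pgen_forward


class TriMesh:
    """Dynamically triangulated closed surface backed by flat numba arrays."""

    def __init__(self, vertices: np.ndarray, faces: np.ndarray,
                 capacity: Optional[int] = None, n_min: int = 12):
        vertices = np.asarray(vertices, dtype=np.float64)
        faces = np.asarray(faces, dtype=np.int64)
        n = len(vertices)
        if capacity is None:
            capacity = max(8 * n, 256)
        if capacity < n:
            raise ValueError("capacity smaller than vertex count")
        self.cap = int(capacity)
        self.pos = np.zeros((self.cap, 3))
        self.pos[:n] = vertices
        self.nbr = np.full((self.cap, MAXDEG), -1, dtype=np.int32)
        self.deg = np.zeros(self.cap, dtype=np.int32)
        self.sc_i = np.zeros(4, dtype=np.int64)
        self.sc_i[K.NV] = n
        self.sc_i[K.NMIN] = n_min
        self.sc_f = np.zeros(4)
        self._build_rings(n, faces)
        self._rebuild_bookkeeping()
        self.eb = np.zeros(self.cap)

    # -- construction -----------------------------------------------------

    def _build_rings(self, n: int, faces: np.ndarray) -> None:
        succ = [dict() for _ in range(n)]
        for a, b, c in faces:
            for i, j, k in ((a, b, c), (b, c, a), (c, a, b)):
                if j in succ[i]:
                    raise TopologyError(
                        f"directed edge ({i},{j}) shared by two faces with "
                        "the same orientation (non-manifold or inconsistent "
                        "winding)")
                succ[i][j] = k
        for i in range(n):
            ring = succ[i]
            d = len(ring)
            if d < 3:
                raise TopologyError(f"vertex {i} has degree {d} < 3")
            if d > MAXDEG:
                raise TopologyError(f"vertex {i} degree {d} exceeds {MAXDEG}")
            start = next(iter(ring))
            order = [start]
            while True:
                nxt = ring[order[-1]]
                if nxt == start:
                    break
                order.append(nxt)
                if len(order) > d:
                    raise TopologyError(f"vertex {i} one-ring is not a "
                                        "single cycle (non-manifold)")
            if len(order) != d:
                raise TopologyError(f"vertex {i} one-ring is not a single "
                                    "cycle (non-manifold)")
            self.deg[i] = d
            self.nbr[i, :d] = order

    def _rebuild_bookkeeping(self) -> None:
        """Recompute vlist/d4list/freelist compact indices from deg[]."""
        self.vlist = np.full(self.cap, -1, dtype=np.int32)
        self.vindex = np.full(self.cap, -1, dtype=np.int32)
        self.d4list = np.full(self.cap, -1, dtype=np.int32)
        self.d4index = np.full(self.cap, -1, dtype=np.int32)
        self.freelist = np.full(self.cap, -1, dtype=np.int32)
        nv = n4 = nfree = 0
        for v in range(self.cap):
            if self.deg[v] > 0:
                self.vlist[nv] = v
                self.vindex[v] = nv
                nv += 1
                if self.deg[v] == 4:
                    self.d4list[n4] = v
                    self.d4index[v] = n4
                    n4 += 1
        for v in range(self.cap - 1, -1, -1):
            if self.deg[v] == 0:
                self.freelist[nfree] = v
                nfree += 1
        self.sc_i[K.NV] = nv
        self.sc_i[K.N4] = n4
        self.sc_i[K.NFREE] = nfree

    @classmethod
    def from_vertices_faces(cls, vertices, faces, **kw) -> "TriMesh":
        return cls(vertices, faces, **kw)

    def copy(self) -> "TriMesh":
        out = object.__new__(TriMesh)
        out.cap = self.cap
        for name in ("pos", "nbr", "deg", "sc_i", "sc_f", "eb", "vlist",
                     "vindex", "d4list", "d4index", "freelist"):
            setattr(out, name, getattr(self, name).copy())
        return out

    # -- basic queries ----------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return int(self.sc_i[K.NV])

    @property
    def n_edges(self) -> int:
        return 3 * self.n_vertices - 6

    @property
    def n_faces(self) -> int:
        return 2 * self.n_vertices - 4

    @property
    def alive(self) -> np.ndarray:
        return np.sort(self.vlist[:self.n_vertices].copy())

    @property
    def vertex_positions(self) -> np.ndarray:
        """Positions of alive vertices, ordered by vertex id."""
        return self.pos[self.alive]

    def degrees(self) -> np.ndarray:
        return self.deg[self.alive]

    def edges(self) -> np.ndarray:
        """(E, 2) array of undirected edges (i < j), in internal vertex ids."""
        out = []
        for v in self.alive:
            for t in range(self.deg[v]):
                j = self.nbr[v, t]
                if v < j:
                    out.append((v, j))
        return np.array(out, dtype=np.int64)

    def faces(self) -> np.ndarray:
        """(F, 3) outward-oriented faces, each listed once."""
        out = []
        for v in self.alive:
            d = self.deg[v]
            for t in range(d):
                j = self.nbr[v, t]
                k = self.nbr[v, (t + 1) % d]
                if v < j and v < k:
                    out.append((v, j, k))
        return np.array(out, dtype=np.int64)

    def adjacency_matrix(self) -> np.ndarray:
        """Dense symmetric boolean adjacency over alive vertices (compacted
        to contiguous indices in ``alive`` order)."""
        ids = self.alive
        remap = {v: t for t, v in enumerate(ids)}
        a = np.zeros((len(ids), len(ids)), dtype=bool)
        for i, j in self.edges():
            a[remap[i], remap[j]] = True
            a[remap[j], remap[i]] = True
        return a

    def edge_lengths(self) -> np.ndarray:
        e = self.edges()
        return np.linalg.norm(self.pos[e[:, 0]] - self.pos[e[:, 1]], axis=1)

    def face_areas(self) -> np.ndarray:
        f = self.faces()
        u = self.pos[f[:, 1]] - self.pos[f[:, 0]]
        v = self.pos[f[:, 2]] - self.pos[f[:, 0]]
        return 0.5 * np.linalg.norm(np.cross(u, v), axis=1)

    @property
    def total_area(self) -> float:
        return float(self.face_areas().sum())

    @property
    def volume(self) -> float:
        return enclosed_volume(self)

    @property
    def centroid(self) -> np.ndarray:
        return self.vertex_positions.mean(axis=0)

    @property
    def mean_radius(self) -> float:
        r = self.vertex_positions - self.centroid
        return float(np.linalg.norm(r, axis=1).mean())

    @property
    def mean_edge_length(self) -> float:
        return float(self.edge_lengths().mean())

    def euler_characteristic(self) -> int:
        nv = self.n_vertices
        ne = len(self.edges())
        nf = len(self.faces())
        return nv - ne + nf

    # -- validation -------------------------------------------------------

    def validate(self) -> None:
        """Check all closed-manifold invariants; raise TopologyError if any
        fail.  Intended for tests and post-run audits, not the hot loop."""
        ids = self.alive
        if len(ids) != self.n_vertices:
            raise TopologyError("vertex bookkeeping inconsistent")
        for v in ids:
            d = self.deg[v]
            if d < 3:
                raise TopologyError(f"vertex {v} degree {d} < 3")
            ring = self.nbr[v, :d]
            if len(set(ring.tolist())) != d:
                raise TopologyError(f"vertex {v} ring has duplicates")
            for j in ring:
                if self.deg[j] == 0:
                    raise TopologyError(f"vertex {v} adjacent to dead {j}")
                if v not in self.nbr[j, :self.deg[j]]:
                    raise TopologyError(f"adjacency not symmetric: {v},{j}")
        # orientation consistency: every face's three directed edges agree
        faces = self.faces()
        for (a, b, c) in faces:
            for i, j, k in ((a, b, c), (b, c, a), (c, a, b)):
                d = self.deg[i]
                t = int(np.where(self.nbr[i, :d] == j)[0][0])
                if self.nbr[i, (t + 1) % d] != k:
                    raise TopologyError(
                        f"face ({a},{b},{c}) not consistently oriented")
        ne = len(self.edges())
        nf = len(faces)
        chi = self.n_vertices - ne + nf
        if chi != 2:
            raise TopologyError(f"Euler characteristic {chi} != 2")
        if 2 * ne != 3 * nf:
            raise TopologyError("edge/face count mismatch (open surface?)")
        if enclosed_volume(self) <= 0:
            raise TopologyError("signed volume not positive (inward "
                                "orientation or inverted geometry)")

    # -- export -----------------------------------------------------------

    def _compact(self):
        """Vertices/faces with contiguous indices (alive order)."""
        ids = self.alive
        remap = np.full(self.cap, -1, dtype=np.int64)
        remap[ids] = np.arange(len(ids))
        return self.pos[ids].copy(), remap[self.faces()]

    def to_trimesh(self) -> "_trimesh_io.Trimesh":
        v, f = self._compact()
        return _trimesh_io.Trimesh(vertices=v, faces=f, process=False)

    def save(self, path: str) -> None:
        """Write an ASCII OFF or PLY snapshot (by file extension)."""
        path = str(path)
        tm = self.to_trimesh()
        if path.endswith(".off"):
            tm.export(path, file_type="off")
        elif path.endswith(".ply"):
            tm.export(path, file_type="ply", encoding="ascii")
        else:
            raise ValueError("snapshot format must be .off or .ply")


def load_mesh(path: str, **kw) -> TriMesh:
    """Read an OFF or PLY snapshot back into a TriMesh."""
    tm = _trimesh_io.load(str(path), process=False)
    return TriMesh(np.asarray(tm.vertices), np.asarray(tm.faces), **kw)


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def build_icosphere(subdivisions: int, target_radius: float = 1.0,
                    **kw) -> TriMesh:
    """Subdivided-icosahedron sphere mesh with 10*4**s + 2 vertices.

    Vertices lie exactly on the sphere of the requested radius; the caller
    can use ``mesh.mean_edge_length`` to rescale to tether units.
    """
    if subdivisions < 0:
        raise ValueError("subdivisions must be >= 0")
    tm = _trimesh_io.creation.icosphere(subdivisions=subdivisions,
                                        radius=target_radius)
    mesh = TriMesh(np.asarray(tm.vertices), np.asarray(tm.faces), **kw)
    if enclosed_volume(mesh) < 0:  # enforce outward orientation
        f = np.asarray(tm.faces)[:, ::-1]
        mesh = TriMesh(np.asarray(tm.vertices), f, **kw)
    return mesh


def icosphere_matching_edge_length(subdivisions: int,
                                   edge_length: float = 1.0,
                                   **kw) -> TriMesh:
    """Icosphere rescaled so the mean edge length equals ``edge_length``."""
    m0 = build_icosphere(subdivisions, 1.0)
    scale = edge_length / m0.mean_edge_length
    return build_icosphere(subdivisions, scale, **kw)


def enclosed_volume(mesh: TriMesh) -> float:
    """Signed enclosed volume: sum of tetrahedra against the origin over
    oriented faces.  Positive for outward orientation; translation
    invariant for closed surfaces."""
    f = mesh.faces()
    if len(f) == 0:
        raise TopologyError("mesh has no faces")
    a = mesh.pos[f[:, 0]]
    b = mesh.pos[f[:, 1]]
    c = mesh.pos[f[:, 2]]
    return float(np.einsum("ij,ij->i", a, np.cross(b, c)).sum() / 6.0)


# ---------------------------------------------------------------------------
# topology proposals
# ---------------------------------------------------------------------------

def _pick_uniform_edge(mesh: TriMesh, rng: np.random.Generator):
    edges = mesh.edges()
    i, j = edges[rng.integers(len(edges))]
    return int(i), int(j)


def propose_edge_flip(mesh: TriMesh, rng: np.random.Generator,
                      edge: Optional[tuple] = None) -> TopologyProposal:
    """Select an edge uniformly and propose flipping it to the opposite
    diagonal.  Pgen is 1/E in both directions (the flip is an involution),
    so the generation ratio is always 1."""
    if edge is None:
        i, j = _pick_uniform_edge(mesh, rng)
    else:
        i, j = edge
    ne = mesh.n_edges
    prop = TopologyProposal(kind="flip", edge=(i, j),
                            pgen_forward=1.0 / ne, pgen_reverse=1.0 / ne)
    k, l = K.flip_partners(mesh.nbr, mesh.deg, i, j)
    if mesh.deg[i] <= 3 or mesh.deg[j] <= 3:
        prop.valid, prop.reason = False, "flip would create degree < 3"
    elif mesh.deg[k] >= MAXDEG or mesh.deg[l] >= MAXDEG:
        prop.valid, prop.reason = False, "flip would exceed max degree"
    elif K._adjacent(mesh.nbr, mesh.deg, int(k), int(l)):
        prop.valid, prop.reason = False, "opposite edge already exists"
    return prop


def propose_vertex_insertion(mesh: TriMesh, rng: np.random.Generator,
                             edge: Optional[tuple] = None,
                             h_cube: float = DEFAULT_H_CUBE
                             ) -> TopologyProposal:
    """Select an edge uniformly and propose splitting it, placing the new
    vertex uniformly in a cube of side ``h_cube`` centred on the edge
    midpoint.

    ``pgen_forward`` is the generation *density* 1/(E * h_cube^3): the
    finite placement window is what makes the insertion/removal pair
    measure-consistent in the continuous configuration space (a
    deterministic midpoint placement would have a delta-function density
    and no well-defined reverse ratio).  The reverse move is the removal
    of the new vertex with the diagonal that recreates the split edge,
    generated with probability 1 / (2 * n4') on the post-move mesh.
    """
    if edge is None:
        i, j = _pick_uniform_edge(mesh, rng)
    else:
        i, j = edge
    k, l = K.flip_partners(mesh.nbr, mesh.deg, i, j)
    prop = TopologyProposal(kind="insert", edge=(i, j),
                            pgen_forward=1.0 / (mesh.n_edges * h_cube ** 3))
    if mesh.deg[k] >= MAXDEG or mesh.deg[l] >= MAXDEG:
        prop.valid, prop.reason = False, "insertion would exceed max degree"
        return prop
    n4_post = int(mesh.sc_i[K.N4]) + 1
    for v in (int(k), int(l)):
        if mesh.deg[v] == 3:
            n4_post += 1
        elif mesh.deg[v] == 4:
            n4_post -= 1
    prop.pgen_reverse = 1.0 / (2.0 * n4_post)
    return prop


def propose_vertex_removal(mesh: TriMesh, rng: np.random.Generator,
                           vertex: int = -1, diagonal: int = -1,
                           h_cube: float = DEFAULT_H_CUBE
                           ) -> TopologyProposal:
    """Propose removing a degree-4 vertex, re-triangulating the hole with
    one of the two quadrilateral diagonals.

    The (vertex, diagonal) pair is drawn uniformly among the 2 * n4
    ordered pairs.  The proposal is invalid when the doomed vertex lies
    outside the cube of side ``h_cube`` around the diagonal midpoint,
    because the reverse edge split could never have generated its
    position.  ``pgen_reverse`` is the reverse generation density
    1/(E' * h_cube^3) on the post-removal mesh.
    """
    n4 = int(mesh.sc_i[K.N4])
    prop = TopologyProposal(kind="remove")
    if n4 == 0:
        prop.valid, prop.reason = False, "no removable (degree-4) vertex"
        return prop
    if mesh.n_vertices <= mesh.sc_i[K.NMIN]:
        prop.valid, prop.reason = False, "at minimum system size"
        return prop
    if vertex < 0:
        r = rng.integers(2 * n4)
        vertex = int(mesh.d4list[r >> 1])
        diagonal = int(r & 1)
    prop.vertex, prop.diagonal = vertex, diagonal
    prop.pgen_forward = 1.0 / (2.0 * n4)
    a, b, c, d = K.removal_quad(mesh.nbr, mesh.deg, vertex, diagonal)
    if mesh.deg[b] <= 3 or mesh.deg[d] <= 3:
        prop.valid, prop.reason = False, "removal would create degree < 3"
        return prop
    if K._adjacent(mesh.nbr, mesh.deg, int(a), int(c)):
        prop.valid, prop.reason = False, "diagonal edge already exists"
        return prop
    mid = 0.5 * (mesh.pos[int(a)] + mesh.pos[int(c)])
    if np.max(np.abs(mesh.pos[vertex] - mid)) > 0.5 * h_cube:
        prop.valid, prop.reason = False, \
            "vertex outside the reverse-insertion placement window"
        return prop
    prop.pgen_reverse = 1.0 / ((3 * (mesh.n_vertices - 1) - 6) * h_cube ** 3)
    return prop


def apply_proposal(mesh: TriMesh, prop: TopologyProposal,
                   rng: Optional[np.random.Generator] = None,
                   h_cube: float = DEFAULT_H_CUBE) -> int:
    """Apply a valid proposal to the mesh in place.

    Returns the id of the inserted vertex for insertions, else -1.  When
    ``rng`` is given, insertions draw the placement uniformly from the
    cube of side ``h_cube`` around the edge midpoint (as the sampler
    does); otherwise the vertex lands exactly at the midpoint.  The
    derived bookkeeping (alive/degree-4 lists) is rebuilt afterwards; use
    the engine's fused kernels when throughput matters.
    """
    if not prop.valid:
        raise ValueError(f"cannot apply invalid proposal: {prop.reason}")
    out = -1
    if prop.kind == "flip":
        i, j = prop.edge
        k, l = K.flip_partners(mesh.nbr, mesh.deg, i, j)
        K._apply_flip(mesh.nbr, mesh.deg, i, j, int(k), int(l))
    elif prop.kind == "insert":
        i, j = prop.edge
        k, l = K.flip_partners(mesh.nbr, mesh.deg, i, j)
        m = int(mesh.freelist[mesh.sc_i[K.NFREE] - 1])
        mesh.pos[m] = 0.5 * (mesh.pos[i] + mesh.pos[j])
        if rng is not None:
            mesh.pos[m] += h_cube * (rng.random(3) - 0.5)
        K._apply_insert(mesh.nbr, mesh.deg, i, j, int(k), int(l), m)
        out = m
    elif prop.kind == "remove":
        a, b, c, d = K.removal_quad(mesh.nbr, mesh.deg, prop.vertex,
                                    prop.diagonal)
        K._apply_remove(mesh.nbr, mesh.deg, prop.vertex,
                        int(a), int(b), int(c), int(d))
    else:
        raise ValueError(f"unknown proposal kind {prop.kind!r}")
    mesh._rebuild_bookkeeping()
    return out
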