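"""Topology and geometry of the dynamically triangulated mesh."""

import numpy as np
import pytest
from scipy.stats import chisquare

import vesiclemc._kernels as K
from vesiclemc.mesh import (
    TriMesh,
    TopologyError,
    apply_proposal,
    build_icosphere,
    enclosed_volume,
    icosphere_matching_edge_length,
    load_mesh,
    propose_edge_flip,
    propose_vertex_insertion,
    propose_vertex_removal,
)


def tetrahedron():
    v = np.array([[1.0, 1.0, 1.0], [1.0, -1.0, -1.0],
                  [-1.0, 1.0, -1.0], [-1.0, -1.0, 1.0]])
    f = np.array([[0, 1, 2], [0, 2, 3], [0, 3, 1], [1, 3, 2]])
    m = TriMesh(v, f, n_min=4)
    if enclosed_volume(m) < 0:
        m = TriMesh(v, f[:, ::-1], n_min=4)
    return m


def triangulated_cube():
    """Unit cube surface split into 12 triangles."""
    v = np.array([[x, y, z] for x in (0, 1) for y in (0, 1) for z in (0, 1)],
                 dtype=float)
    quads = [(0, 1, 3, 2), (4, 6, 7, 5), (0, 4, 5, 1),
             (2, 3, 7, 6), (0, 2, 6, 4), (1, 5, 7, 3)]
    f = []
    for a, b, c, d in quads:
        f += [(a, b, c), (a, c, d)]
    m = TriMesh(v, np.array(f), n_min=8)
    if enclosed_volume(m) < 0:
        m = TriMesh(v, np.array(f)[:, ::-1], n_min=8)
    return m


class TestIcosphere:
    def test_icosahedron_combinatorics(self, icosahedron):
        assert icosahedron.n_vertices == 12
        assert len(icosahedron.edges()) == 30
        assert len(icosahedron.faces()) == 20
        assert icosahedron.euler_characteristic() == 2

    @pytest.mark.parametrize("s", [0, 1, 2, 3])
    def test_subdivision_vertex_count(self, s):
        m = build_icosphere(s, 1.0)
        assert m.n_vertices == 10 * 4 ** s + 2
        m.validate()

    def test_radius_matches_target(self):
        m = build_icosphere(2, 7.5)
        assert abs(m.mean_radius - 7.5) / 7.5 < 0.01

    def test_unit_edge_icosphere_geometry(self):
        # with unit mean edge length at s=4 the subdivided icosahedron has
        # R/<l> ~ 13.2 (the geometric value; ~12% below the nominal 15)
        m = icosphere_matching_edge_length(4, 1.0)
        assert m.n_vertices == 2562
        assert abs(m.mean_edge_length - 1.0) < 1e-9
        assert 15.0 * 0.85 < m.mean_radius / m.mean_edge_length < 15.0 * 1.1

    def test_negative_subdivisions_rejected(self):
        with pytest.raises(ValueError):
            build_icosphere(-1)


class TestEnclosedVolume:
    def test_unit_cube(self):
        assert enclosed_volume(triangulated_cube()) == pytest.approx(1.0)

    def test_translation_invariance(self, unit_icosphere_s2):
        m = unit_icosphere_s2.copy()
        v0 = enclosed_volume(m)
        m.pos[m.alive] += np.array([3.7, -1.2, 9.9])
        assert enclosed_volume(m) == pytest.approx(v0, rel=1e-10)

    def test_sphere_convergence(self):
        """Inscribed polyhedral volume is below 4/3 pi R^3, converging up."""
        R = 2.0
        vols = [enclosed_volume(build_icosphere(s, R)) for s in range(1, 5)]
        exact = 4.0 / 3.0 * np.pi * R ** 3
        assert all(v < exact for v in vols)
        errs = [exact - v for v in vols]
        assert all(errs[i + 1] < errs[i] for i in range(len(errs) - 1))
        assert errs[-1] / exact < 0.01


class TestEdgeFlip:
    def test_tetrahedron_flips_all_invalid(self, rng):
        m = tetrahedron()
        for i, j in m.edges():
            prop = propose_edge_flip(m, rng, edge=(int(i), int(j)))
            assert not prop.valid

    def test_flip_is_involution(self, unit_icosphere_s2, rng):
        m = unit_icosphere_s2.copy()
        before = m.adjacency_matrix()
        prop = propose_edge_flip(m, rng)
        while not prop.valid:
            prop = propose_edge_flip(m, rng)
        i, j = prop.edge
        k, l = K.flip_partners(m.nbr, m.deg, i, j)
        apply_proposal(m, prop)
        m.validate()
        assert not np.array_equal(m.adjacency_matrix(), before)
        back = propose_edge_flip(m, rng, edge=(int(k), int(l)))
        assert back.valid
        apply_proposal(m, back)
        assert np.array_equal(m.adjacency_matrix(), before)

    def test_flip_generation_ratio_unity(self, unit_icosphere_s2, rng):
        prop = propose_edge_flip(unit_icosphere_s2, rng)
        assert prop.pgen_forward == pytest.approx(
            1.0 / unit_icosphere_s2.n_edges)
        assert prop.gen_ratio == pytest.approx(1.0)

    def test_edge_selection_uniform(self, unit_icosphere_s2, rng):
        """Chi-squared test of per-edge selection frequencies."""
        m = unit_icosphere_s2
        edges = {tuple(sorted(e)): 0 for e in map(tuple, m.edges())}
        n = 10_000
        for _ in range(n):
            prop = propose_edge_flip(m, rng)
            edges[tuple(sorted(prop.edge))] += 1
        counts = np.array(list(edges.values()))
        assert counts.sum() == n
        stat, p = chisquare(counts)
        assert p > 1e-4  # ~4 standard errors


class TestInsertionRemoval:
    def test_insertion_bookkeeping(self, icosahedron, rng):
        m = icosahedron.copy()
        prop = propose_vertex_insertion(m, rng)
        assert prop.valid
        mid = apply_proposal(m, prop)
        m.validate()
        assert m.n_vertices == 13
        assert len(m.edges()) == 33
        assert len(m.faces()) == 22
        assert m.euler_characteristic() == 2
        assert m.deg[mid] == 4

    def test_insertion_volume_increment_matches_full_recompute(
            self, unit_icosphere_s2, rng):
        m = unit_icosphere_s2.copy()
        v0 = enclosed_volume(m)
        prop = propose_vertex_insertion(m, rng)
        i, j = prop.edge
        k, l = (int(x) for x in K.flip_partners(m.nbr, m.deg, i, j))
        a1, w1 = K._face_area_vol(m.pos, i, j, k)
        a2, w2 = K._face_area_vol(m.pos, j, i, l)
        mid = apply_proposal(m, prop, rng=rng)
        dv = 0.0
        for (a, b, c) in ((i, mid, k), (mid, j, k), (j, mid, l),
                          (mid, i, l)):
            dv += K._face_area_vol(m.pos, a, b, c)[1]
        dv -= w1 + w2
        assert enclosed_volume(m) - v0 == pytest.approx(dv, abs=1e-12)

    def test_insert_then_remove_restores_adjacency(self, unit_icosphere_s2,
                                                   rng):
        m = unit_icosphere_s2.copy()
        before = m.adjacency_matrix()
        prop = propose_vertex_insertion(m, rng)
        i, j = prop.edge
        mid = apply_proposal(m, prop)
        # find the diagonal that reconnects (i, j)
        removed = False
        for diag in (0, 1):
            a, b, c, d = (int(x) for x in
                          K.removal_quad(m.nbr, m.deg, mid, diag))
            if {a, c} == {i, j}:
                back = propose_vertex_removal(m, rng, vertex=mid,
                                              diagonal=diag)
                assert back.valid
                apply_proposal(m, back)
                removed = True
        assert removed
        m.validate()
        assert np.array_equal(m.adjacency_matrix(), before)

    def test_icosahedron_has_no_removable_vertex(self, icosahedron, rng):
        prop = propose_vertex_removal(icosahedron, rng)
        assert not prop.valid
        assert "no removable" in prop.reason

    def test_reverse_proposal_probability_is_exact(self, unit_icosphere_s2,
                                                   rng):
        """The reverse Pgen recorded by an insertion equals what the
        removal proposer actually assigns on the post-insertion mesh."""
        m = unit_icosphere_s2.copy()
        for _ in range(20):
            prop = propose_vertex_insertion(m, rng)
            i, j = prop.edge
            mid = apply_proposal(m, prop, rng=rng)
            n4_post = int(m.sc_i[K.N4])
            assert prop.pgen_reverse == pytest.approx(1.0 / (2 * n4_post))
            for diag in (0, 1):
                a, b, c, d = (int(x) for x in
                              K.removal_quad(m.nbr, m.deg, mid, diag))
                if {a, c} == {i, j}:
                    rem = propose_vertex_removal(m, rng, vertex=mid,
                                                 diagonal=diag)
                    assert rem.valid
                    assert rem.pgen_forward == pytest.approx(
                        prop.pgen_reverse)
                    # and the removal's recorded reverse density is the
                    # insertion density on the restored mesh
                    assert rem.pgen_reverse == pytest.approx(
                        prop.pgen_forward)
                    apply_proposal(m, rem)

    def test_random_topology_sequence_keeps_invariants(self, rng):
        """Long random flip/insert/remove sequences preserve the closed
        sphere topology at every accepted step."""
        m = icosphere_matching_edge_length(1, 1.0)
        for step in range(600):
            kind = rng.integers(3)
            if kind == 0:
                prop = propose_edge_flip(m, rng)
            elif kind == 1:
                prop = propose_vertex_insertion(m, rng)
            else:
                prop = propose_vertex_removal(m, rng)
            if prop.valid:
                apply_proposal(m, prop, rng=rng)
            if step % 100 == 99:
                m.validate()
                assert m.euler_characteristic() == 2
        m.validate()


class TestIO:
    @pytest.mark.parametrize("ext", ["off", "ply"])
    def test_snapshot_round_trip(self, tmp_path, ext, unit_icosphere_s2):
        m = unit_icosphere_s2
        path = tmp_path / f"mesh.{ext}"
        m.save(str(path))
        assert path.read_bytes()[:200].isascii()
        m2 = load_mesh(str(path))
        assert m2.n_vertices == m.n_vertices
        assert np.allclose(m2.vertex_positions, m.vertex_positions,
                           atol=1e-5)
        assert enclosed_volume(m2) == pytest.approx(enclosed_volume(m),
                                                    rel=1e-5)

    def test_unknown_extension_rejected(self, tmp_path, icosahedron):
        with pytest.raises(ValueError):
            icosahedron.save(str(tmp_path / "mesh.stl"))


class TestValidation:
    def test_open_surface_rejected(self):
        v = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
        with pytest.raises(TopologyError):
            TriMesh(v, np.array([[0, 1, 2], [0, 1, 3]]), n_min=4)

    def test_inconsistent_winding_rejected(self):
        m = tetrahedron()
        f = m.faces()
        f[0] = f[0][::-1]
        with pytest.raises(TopologyError):
            TriMesh(m.vertex_positions, f, n_min=4)
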