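"""Polyp cloning (Bezier subdivision) and fusion (edge collapse)."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from coralclone.cloning import (
    CloneParams,
    bezier_midpoint,
    cloning_step,
    fusion_step,
)

from conftest import make_hex_patch, make_nonmanifold_collapse_fixture

SQ2 = math.sqrt(2.0)


def de_casteljau(control, t):
    """Independent oracle: generic de Casteljau recursion."""
    pts = [np.asarray(p, dtype=float) for p in control]
    while len(pts) > 1:
        pts = [(1 - t) * a + t * b for a, b in zip(pts, pts[1:])]
    return pts[0]


class TestBezierMidpoint:
    def test_planar_degenerates_to_chord_midpoint(self):
        m = bezier_midpoint((0, 0, 0), (0, 0, 1), (10, 0, 0), (0, 0, 1))
        np.testing.assert_allclose(m, [5, 0, 0], atol=1e-12)

    def test_symmetric_circular_arc_bulge(self):
        # endpoints at 45-degree outward normals: the arc bulges upward;
        # frozen value cross-checked with the generic de Casteljau oracle
        A, nA = (-5, 0, 0), (-1 / SQ2, 0, 1 / SQ2)
        B, nB = (5, 0, 0), (1 / SQ2, 0, 1 / SQ2)
        m = bezier_midpoint(A, nA, B, nB)
        np.testing.assert_allclose(m, [0.0, 0.0, 1.7677669529663687], atol=1e-12)
        L = 10.0
        P1 = np.array(A) + (L / 3) * np.array([1 / SQ2, 0, 1 / SQ2])
        P2 = np.array(B) + (L / 3) * np.array([-1 / SQ2, 0, 1 / SQ2])
        np.testing.assert_allclose(m, de_casteljau([A, P1, P2, B], 0.5), atol=1e-12)

    def test_closed_form_equals_de_casteljau_on_random_controls(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            P = rng.normal(size=(4, 3))
            closed = (P[0] + 3 * P[1] + 3 * P[2] + P[3]) / 8.0
            np.testing.assert_allclose(de_casteljau(P, 0.5), closed, atol=1e-12)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        ax=st.floats(-10, -1),
        bz=st.floats(-3, 3),
        tilt=st.floats(0.1, 1.4),
    )
    def test_mirror_symmetry(self, ax, bz, tilt):
        # mirror swap of A<->B with mirrored normals mirrors the output
        A, B = np.array([ax, 0.0, 0.0]), np.array([-ax, 0.0, bz])
        nA = np.array([-math.sin(tilt), 0.0, math.cos(tilt)])
        nB = np.array([math.sin(tilt), 0.0, math.cos(tilt)])
        m = bezier_midpoint(A, nA, B, nB)
        mirror = np.array([-1.0, 1.0, 1.0])
        m2 = bezier_midpoint(B * mirror, nB * mirror, A * mirror, nA * mirror)
        np.testing.assert_allclose(m * mirror, m2, atol=1e-9)

    def test_planar_limit_matches_euclidean_midpoint(self):
        # whenever both normals are perpendicular to the edge the Bezier
        # collapses onto the chord: oracle equivalence over random cases
        rng = np.random.default_rng(7)
        for _ in range(30):
            A, B = rng.normal(size=3), rng.normal(size=3)
            chord = B - A
            chord /= np.linalg.norm(chord)
            helper = rng.normal(size=3)
            n = np.cross(chord, helper)
            n /= np.linalg.norm(n)
            m = bezier_midpoint(A, n, B, n)
            np.testing.assert_allclose(m, 0.5 * (A + B), atol=1e-9)

    def test_coincident_endpoints_rejected(self):
        with pytest.raises(ValueError):
            bezier_midpoint((1, 2, 3), (0, 0, 1), (1, 2, 3), (0, 0, 1))


class TestCloningStep:
    def test_short_edges_untouched(self):
        mesh = make_hex_patch(rings=3, a=1.0)
        assert cloning_step(mesh, CloneParams(delta_sub=10.0)) == 0
        assert mesh.n_vertices == 16

    def test_single_overlong_edge_split_in_half(self):
        mesh = make_hex_patch(rings=1, a=11.0)  # flat: 4 vertices, 2 faces
        added = cloning_step(mesh, CloneParams(delta_sub=10.0))
        # every 11 mm edge halves to 5.5; the created cross edges measure
        # under delta_sub, so one pass suffices
        assert added == 5
        lengths = [l for _, l in mesh.edges_with_lengths()]
        assert max(lengths) <= 10.0
        assert min(lengths) == pytest.approx(5.5)

    def test_uniform_scaling_splits_every_original_edge_once(self):
        delta = 10.0
        mesh = make_hex_patch(rings=2, a=1.5 * delta)
        original = sorted(mesh.edges())
        cloning_step(mesh, CloneParams(delta_sub=delta))
        assert max(l for _, l in mesh.edges_with_lengths()) <= delta
        for u, v in original:
            # split exactly once: endpoints no longer adjacent, and the
            # midpoint clone sits halfway (flat patch => chord midpoint),
            # leaving daughters at 0.75*delta that are never re-split
            assert not mesh.has_edge(u, v)
            mid = 0.5 * (mesh.position(u) + mesh.position(v))
            m = [
                w
                for w in mesh.neighbors(u) & mesh.neighbors(v)
                if np.allclose(mesh.position(w), mid, atol=1e-9)
            ]
            assert len(m) == 1
            assert np.linalg.norm(
                mesh.position(m[0]) - mesh.position(u)
            ) == pytest.approx(0.75 * delta)

    def test_max_edge_bounded_after_step(self, seed_mesh):
        for v in seed_mesh.vertex_ids():  # inflate the seed 3x
            seed_mesh.set_position(v, seed_mesh.position(v) * 3.0)
        params = CloneParams(delta_sub=10.0)
        cloning_step(seed_mesh, params)
        assert max(l for _, l in seed_mesh.edges_with_lengths()) <= 10.0
        assert seed_mesh.validate().ok


class TestFusionStep:
    def test_no_short_edges_no_removal(self):
        mesh = make_hex_patch(rings=3, a=5.0)
        assert fusion_step(mesh, CloneParams(delta_sub=10.0)) == 0

    def test_short_interior_edge_fused_at_midpoint(self):
        # wide lattice: dragging v next to u leaves (u, v) the only short edge
        mesh = make_hex_patch(rings=4, a=30.0)
        interior = sorted(
            set(mesh.vertex_ids()) - mesh.boundary_vertices()
        )
        u, v = interior[0], sorted(
            mesh.neighbors(interior[0]) - mesh.boundary_vertices()
        )[0]
        # drag v next to u: edge length 1.9 < delta_fuse = 2
        pu = mesh.position(u)
        mesh.set_position(v, pu + np.array([1.9, 0, 0]))
        V = mesh.n_vertices
        removed = fusion_step(mesh, CloneParams(delta_sub=10.0))
        assert removed == 1
        assert mesh.n_vertices == V - 1
        survivor = u if mesh.has_vertex(u) else v
        np.testing.assert_allclose(
            mesh.position(survivor), pu + np.array([0.95, 0, 0]), atol=1e-12
        )

    def test_link_condition_violation_skipped(self):
        mesh, (u, v) = make_nonmanifold_collapse_fixture()
        mesh.set_position(v, mesh.position(u) + np.array([0.19, 0, 0]))
        assert fusion_step(mesh, CloneParams(delta_sub=1.0)) == 0
        assert mesh.has_vertex(u) and mesh.has_vertex(v)

    def test_leader_absorbs_nonleader(self, seed_mesh):
        seed_mesh.set_leader(0, True)
        apex = seed_mesh.position(0).copy()
        # drag rim vertex 1 up next to the apex leader
        seed_mesh._base.discard(1)
        seed_mesh.set_position(1, apex + np.array([0.5, 0, 0]))
        removed = fusion_step(seed_mesh, CloneParams(delta_sub=10.0))
        assert removed == 1
        assert seed_mesh.has_vertex(0) and seed_mesh.is_leader(0)
        np.testing.assert_allclose(seed_mesh.position(0), apex)


def test_delta_fuse_is_fifth_of_delta_sub():
    assert CloneParams(delta_sub=10.0).delta_fuse == pytest.approx(2.0)
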