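"""Self-regulated branching: rates, candidate bands, axes, leader growth."""

import numpy as np
import pytest

from coralclone.branching import (
    BranchNode,
    BranchParams,
    BranchRegistry,
    branch_direction,
    branch_rate,
    branching_step,
    candidate_vertices,
    leader_growth_step,
)
from coralclone.growth import GrowthParams
from coralclone.mesh import MeshError
from coralclone.simulator import make_hexacone_seed

from conftest import make_ladder_mesh

Z = np.array([0.0, 0.0, 1.0])


def trunk_registry(origin=(0.0, 0.0, 0.0), leader=0):
    return BranchRegistry(
        [BranchNode(origin=np.array(origin, dtype=float), axis=Z.copy(), leader=leader)]
    )


class TestBranchRate:
    def test_matches_formula_on_grid(self):
        # p_br = nu / (l_br * N_br), in 1/yr
        for nu in (5.0, 10.0, 12.0):
            for l_br in (20.0, 40.0, 60.0):
                for n_br in (1, 2, 7):
                    rate = branch_rate(
                        BranchParams(l_br=l_br), GrowthParams(nu=nu), n_br
                    )
                    assert rate == pytest.approx(nu / (l_br * n_br))

    def test_reference_value(self):
        # nu=10 mm/yr, l_br=40 mm, one branch: 0.25/yr (0.025 per 0.1-yr step)
        rate = branch_rate(BranchParams(l_br=40.0), GrowthParams(nu=10.0), 1)
        assert rate == pytest.approx(0.25)

    def test_doubling_branches_halves_rate(self):
        p, g = BranchParams(l_br=40.0), GrowthParams()
        assert branch_rate(p, g, 4) == pytest.approx(branch_rate(p, g, 2) / 2)

    def test_empty_registry_rejected(self):
        with pytest.raises(ValueError):
            branch_rate(BranchParams(l_br=40.0), GrowthParams(), 0)


class TestCandidates:
    def test_young_colony_has_no_candidates(self):
        state = make_hexacone_seed(10.0, branching=True)
        reg = state.registry
        params = BranchParams(l_br=40.0)
        assert candidate_vertices(state.mesh, reg, params) == []

    def test_band_selection_on_synthetic_trunk(self):
        # ladder rungs every 5 mm up to 60 mm; node at the bottom:
        # brute-force enumeration of distances is the oracle
        mesh = make_ladder_mesh(n_rungs=13, dz=5.0, width=5.0)
        reg = trunk_registry(origin=(0.0, 0.0, 0.0))
        params = BranchParams(l_br=40.0)  # band [30, 50]
        got = candidate_vertices(mesh, reg, params)
        expected = [
            v
            for v in sorted(mesh.vertex_ids())
            if 30.0 - 1e-9
            <= np.linalg.norm(mesh.position(v) - reg.branches[0].origin)
            <= 50.0 + 1e-9
        ]
        assert got == expected
        assert len(got) > 0

    def test_distance_exactly_lbr_included(self):
        mesh = make_ladder_mesh(n_rungs=9, dz=10.0, width=5.0)
        reg = trunk_registry()
        got = candidate_vertices(mesh, reg, BranchParams(l_br=40.0))
        exact = [
            v
            for v in mesh.vertex_ids()
            if np.linalg.norm(mesh.position(v)) == pytest.approx(40.0)
        ]
        assert exact and set(exact) <= set(got)

    def test_base_and_leader_vertices_excluded(self):
        mesh = make_ladder_mesh(n_rungs=13, dz=5.0)
        reg = trunk_registry()
        with_all = candidate_vertices(mesh, reg, BranchParams(l_br=40.0))
        mesh.set_leader(with_all[0], True)
        mesh._base.add(with_all[1])
        got = candidate_vertices(mesh, reg, BranchParams(l_br=40.0))
        assert with_all[0] not in got and with_all[1] not in got


class TestBranchDirection:
    def test_zero_angle_follows_parent_axis(self):
        d = branch_direction(np.array([0.3, 0.1, 0.9]), Z, 0.0)
        np.testing.assert_allclose(d, Z, atol=1e-12)

    def test_right_angle_is_horizontal_along_normal_azimuth(self):
        n = np.array([1.0, 0.0, 0.5])
        n /= np.linalg.norm(n)
        d = branch_direction(n, Z, 90.0)
        np.testing.assert_allclose(d, [1, 0, 0], atol=1e-12)

    def test_thirty_degrees_from_vertical(self):
        n = np.array([1.0, 0.0, 1.0]) / np.sqrt(2)
        d = branch_direction(n, Z, 30.0)
        np.testing.assert_allclose(d, [0.5, 0.0, np.sqrt(3) / 2], atol=1e-12)

    def test_angle_with_tilted_parent_axis(self):
        axis = np.array([1.0, 0.0, 1.0]) / np.sqrt(2)
        d = branch_direction(np.array([0.0, 1.0, 0.0]), axis, 25.0)
        assert np.degrees(np.arccos(np.clip(d @ axis, -1, 1))) == pytest.approx(25.0)

    def test_degenerate_projection_tie_break_is_perpendicular(self):
        rng = np.random.default_rng(3)
        d = branch_direction(Z, Z, 45.0, rng)
        assert np.linalg.norm(d) == pytest.approx(1.0)
        assert np.degrees(np.arccos(np.clip(d @ Z, -1, 1))) == pytest.approx(45.0)


class TestBranchingStep:
    def test_no_candidates_leaves_registry_unchanged(self):
        state = make_hexacone_seed(10.0, branching=True)
        created = branching_step(
            state.mesh,
            state.registry,
            BranchParams(l_br=40.0),
            GrowthParams(),
            np.random.default_rng(0),
        )
        assert created == 0
        assert state.registry.n_branches == 1

    def test_certain_selection_kicks_leader_four_alpha(self):
        # rate*dt >= 1 makes selection certain: the new leader is displaced
        # exactly kick*alpha = 4 mm along its branch axis
        mesh = make_ladder_mesh(n_rungs=13, dz=5.0)
        reg = trunk_registry()
        params = BranchParams(l_br=40.0, theta_deg=30.0)
        growth = GrowthParams(nu=1000.0, dt=0.1)  # alpha = 100 -> p = 1
        cands = candidate_vertices(mesh, reg, params)
        before = {v: mesh.position(v).copy() for v in cands}
        created = branching_step(mesh, reg, params, growth, np.random.default_rng(1))
        assert created == len(cands)
        for node in reg.branches[1:]:
            v = node.leader
            assert mesh.is_leader(v)
            np.testing.assert_allclose(node.origin, before[v])
            np.testing.assert_allclose(
                mesh.position(v), before[v] + 4 * growth.alpha * node.axis
            )
            assert node.parent == 0

    def test_selection_matches_binomial_expectation(self):
        # with C candidates the expected branches per step is C * p_br * dt;
        # Monte-Carlo over 1000 independent steps within 3 standard errors
        mesh = make_ladder_mesh(n_rungs=13, dz=5.0)
        reg = trunk_registry()
        params = BranchParams(l_br=40.0)
        growth = GrowthParams(nu=10.0, dt=0.1)
        C = len(candidate_vertices(mesh, reg, params))
        p = 0.25 * growth.dt
        rng = np.random.default_rng(12345)
        total = 0
        n_trials = 1000
        for _ in range(n_trials):
            m, r = mesh.copy(), trunk_registry()
            total += branching_step(m, r, params, growth, rng)
        expect = n_trials * C * p
        se = np.sqrt(n_trials * C * p * (1 - p))
        assert abs(total - expect) <= 3 * se


class TestLeaderGrowth:
    def test_trunk_leader_climbs_at_nu(self):
        state = make_hexacone_seed(10.0, branching=True)
        growth = GrowthParams(nu=10.0, dt=0.1)
        for _ in range(10):
            assert leader_growth_step(state.mesh, state.registry, growth) == 1
        np.testing.assert_allclose(state.mesh.position(0), [0, 0, 15.0])

    def test_horizontal_leader_advances_horizontally(self):
        mesh = make_ladder_mesh(n_rungs=3, dz=5.0)
        axis = np.array([0.0, 1.0, 0.0])
        mesh.set_leader(4, True)
        reg = BranchRegistry(
            [BranchNode(origin=mesh.position(4).copy(), axis=axis, leader=4)]
        )
        z_before = mesh.position(4)[2]
        leader_growth_step(mesh, reg, GrowthParams(nu=10.0, dt=0.1))
        assert mesh.position(4)[2] == z_before
        assert mesh.position(4)[1] == pytest.approx(1.0)

    def test_dangling_leader_detected(self):
        mesh = make_ladder_mesh(n_rungs=3)
        reg = BranchRegistry(
            [BranchNode(origin=np.zeros(3), axis=Z.copy(), leader=999)]
        )
        with pytest.raises(MeshError):
            leader_growth_step(mesh, reg, GrowthParams())
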