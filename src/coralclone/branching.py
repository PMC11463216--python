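"""Self-regulated branching with apical dominance.

Certain polyps take on a specialized leading role (as in *Acropora*):
a leader polyp elongates persistently at the colony's linear rate nu along
its branch axis, bypassing the growth-mode gate.  New leaders are recruited
from polyps lying at a distance l_br ± eps (eps = 0.25 * l_br) from the
nearest existing branching node, each with per-step probability
min(1, p_br * dt) where

    p_br = nu / (l_br * N_br)     [1/yr]

and N_br is the number of existing branches — the 1/N_br damping is the
self-regulation that keeps internode spacing near l_br as the colony
ramifies.  A newly selected leader is kicked a distance 4*alpha along its
branch axis, which makes angle theta with the parent branch axis; the
branch axis shares its azimuth (around the parent axis) with the polyp's
surface normal.  The trunk counts as branch 0, so N_br >= 1 always.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .growth import GrowthParams
from .mesh import ColonyMesh, MeshError

__all__ = [
    "BranchParams",
    "BranchNode",
    "BranchRegistry",
    "branch_rate",
    "candidate_vertices",
    "branch_direction",
    "branching_step",
    "leader_growth_step",
]

_TOL = 1e-9


@dataclass(frozen=True)
class BranchParams:
    """Mean inter-branching distance l_br (mm), branching angle theta (deg).

    Derived: selection band half-width eps = 0.25 * l_br; initial leader
    kick of 4 * alpha along the branch axis.
    """

    l_br: float
    theta_deg: float = 30.0
    kick: float = 4.0

    def __post_init__(self) -> None:
        if self.l_br <= 0:
            raise ValueError(f"l_br must be > 0, got {self.l_br}")
        if not (0.0 <= self.theta_deg <= 90.0):
            raise ValueError(f"theta must be in [0, 90] deg, got {self.theta_deg}")

    @property
    def epsilon(self) -> float:
        return 0.25 * self.l_br


@dataclass
class BranchNode:
    """A branch: where it started, the axis it elongates along, its leader."""

    origin: np.ndarray
    axis: np.ndarray
    leader: int
    parent: int | None = None


@dataclass
class BranchRegistry:
    branches: list[BranchNode] = field(default_factory=list)

    @property
    def n_branches(self) -> int:
        return len(self.branches)

    def origins(self) -> np.ndarray:
        return np.array([b.origin for b in self.branches], dtype=float).reshape(-1, 3)


def branch_rate(params: BranchParams, growth: GrowthParams, n_br: int) -> float:
    """Branching rate p_br = nu / (l_br * N_br) in 1/yr.

    The per-candidate per-step selection probability is min(1, rate * dt).
    """
    if n_br < 1:
        raise ValueError("N_br must be >= 1 (the trunk counts as branch 0)")
    return growth.nu / (params.l_br * n_br)


def candidate_vertices(
    mesh: ColonyMesh, registry: BranchRegistry, params: BranchParams
) -> list[int]:
    """Polyps eligible to lead a new branch, in ascending vertex-id order.

    A candidate is a non-leader, non-base polyp whose Euclidean distance to
    the nearest branching-node origin lies in the closed band
    [l_br - eps, l_br + eps]; being *nearest*, this also keeps candidates
    out of every other branch's exclusion zone.
    """
    if registry.n_branches == 0:
        raise ValueError("registry is empty; seed the trunk first")
    ids = [
        v
        for v in sorted(mesh.vertex_ids())
        if not mesh.is_leader(v) and not mesh.is_base(v)
    ]
    if not ids:
        return []
    pos = np.array([mesh.position(v) for v in ids])
    d = cdist(pos, registry.origins())
    nearest = d.min(axis=1)
    lo, hi = params.l_br - params.epsilon, params.l_br + params.epsilon
    sel = (nearest >= lo - _TOL) & (nearest <= hi + _TOL)
    return [v for v, s in zip(ids, sel) if s]


def branch_direction(
    vertex_normal: np.ndarray,
    parent_axis: np.ndarray,
    theta_deg: float,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Unit branch axis at angle theta from the parent axis.

    cos(theta)*parent_axis + sin(theta)*u, where u is the unit projection
    of the polyp's normal onto the plane perpendicular to the parent axis
    (for a vertical parent this is exactly "shares the horizontal direction
    with the normal").  Degenerate projection: u is drawn uniformly in the
    perpendicular plane when an RNG is supplied, else a fixed perpendicular.
    """
    a = np.asarray(parent_axis, dtype=float)
    a = a / np.linalg.norm(a)
    n = np.asarray(vertex_normal, dtype=float)
    proj = n - np.dot(n, a) * a
    norm = float(np.linalg.norm(proj))
    if norm < _TOL:
        u = _any_perpendicular(a, rng)
    else:
        u = proj / norm
    th = np.deg2rad(theta_deg)
    out = np.cos(th) * a + np.sin(th) * u
    return out / np.linalg.norm(out)


def _any_perpendicular(
    axis: np.ndarray, rng: np.random.Generator | None
) -> np.ndarray:
    helper = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(helper, axis)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(axis, helper)
    e1 /= np.linalg.norm(e1)
    if rng is None:
        return e1
    e2 = np.cross(axis, e1)
    phi = rng.uniform(0.0, 2.0 * np.pi)
    return np.cos(phi) * e1 + np.sin(phi) * e2


def branching_step(
    mesh: ColonyMesh,
    registry: BranchRegistry,
    params: BranchParams,
    growth: GrowthParams,
    rng: np.random.Generator,
) -> int:
    """Recruit new branch leaders; returns the number of branches created.

    Candidates are examined in ascending vertex-id order, each becoming a
    leader independently with probability min(1, p_br * dt) evaluated with
    N_br at step entry.  A selected polyp adopts the branch whose node is
    nearest as parent, gets its branch axis from :func:`branch_direction`,
    is flagged leader and kicked ``kick * alpha`` along the axis; its
    pre-kick position is registered as the new branching-node origin.
    """
    p = min(1.0, branch_rate(params, growth, registry.n_branches) * growth.dt)
    cands = candidate_vertices(mesh, registry, params)
    # parents are drawn from the nodes existing at step entry — the same
    # set candidates were vetted against, which is what guarantees the
    # parent-internode distance lies in the selection band
    entry_origins = registry.origins()
    created = 0
    for v in cands:
        if rng.random() >= p:
            continue
        pos = mesh.position(v).copy()
        d = np.linalg.norm(entry_origins - pos, axis=1)
        parent = int(np.argmin(d))
        axis = branch_direction(
            mesh.vertex_normal(v), registry.branches[parent].axis, params.theta_deg, rng
        )
        mesh.set_leader(v, True)
        mesh.set_position(v, pos + params.kick * growth.alpha * axis)
        registry.branches.append(
            BranchNode(origin=pos, axis=axis, leader=v, parent=parent)
        )
        created += 1
    return created


def leader_growth_step(
    mesh: ColonyMesh, registry: BranchRegistry, growth: GrowthParams
) -> int:
    """Advance every leader by alpha along its branch axis (gate bypassed)."""
    moved = 0
    for node in registry.branches:
        if not mesh.has_vertex(node.leader):
            raise MeshError(
                f"branch leader {node.leader} missing from mesh "
                "(fusion must never remove leaders)"
            )
        mesh.set_position(
            node.leader, mesh.position(node.leader) + growth.alpha * node.axis
        )
        moved += 1
    return moved
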