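"""Polyp cloning (adaptive edge subdivision) and polyp fusion (edge collapse).

Cloning: whenever two neighbouring polyps drift further apart than the
maximal inter-polyp distance ``delta_sub``, a clone is budded between them.
The new polyp is placed at the midpoint of a cubic Bezier arc interpolating
the parent polyps and their surface normals (evaluated by de Casteljau), so
clones land on the curved colony surface rather than on the chord.

Fusion: polyps closer than ``delta_fuse = 0.2 * delta_sub`` fuse (die /
are reabsorbed), which smooths the mesh and removes elongated triangles.
Cloning iterates to quiescence each step — it must guarantee the
``delta_sub`` density bound; fusion runs a single pass per step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh import ColonyMesh

__all__ = [
    "CloneParams",
    "RunawayGeometryError",
    "bezier_midpoint",
    "cloning_step",
    "fusion_step",
]

_MAX_PASSES = 20


class RunawayGeometryError(RuntimeError):
    """Subdivision failed to bound edge lengths within the pass cap."""


@dataclass(frozen=True)
class CloneParams:
    """Maximal inter-polyp distance delta_sub (mm); delta_fuse = 0.2*delta_sub."""

    delta_sub: float

    def __post_init__(self) -> None:
        if self.delta_sub <= 0:
            raise ValueError(f"delta_sub must be > 0, got {self.delta_sub}")

    @property
    def delta_fuse(self) -> float:
        return 0.2 * self.delta_sub


def bezier_midpoint(A, nA, B, nB) -> np.ndarray:
    """Midpoint (t=0.5) of the cubic Bezier interpolating (A, nA), (B, nB).

    Control points: P0 = A, P3 = B; P1 and P2 sit a third of the chord
    length along the unit projections of the chord onto the endpoint
    tangent planes, so the arc is tangent to the surface at both ends and
    degenerates to the chord midpoint on flat regions.  Evaluated by de
    Casteljau at t=1/2, which closes to (P0 + 3 P1 + 3 P2 + P3) / 8.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    nA = np.asarray(nA, dtype=float)
    nB = np.asarray(nB, dtype=float)
    chord = B - A
    L = float(np.linalg.norm(chord))
    if L < 1e-12:
        raise ValueError("bezier_midpoint requires distinct endpoints")
    P1 = A + (L / 3.0) * _tangent_handle(chord, nA)
    P2 = B + (L / 3.0) * _tangent_handle(-chord, nB)
    # de Casteljau at t = 1/2
    q0, q1, q2 = 0.5 * (A + P1), 0.5 * (P1 + P2), 0.5 * (P2 + B)
    r0, r1 = 0.5 * (q0 + q1), 0.5 * (q1 + q2)
    return 0.5 * (r0 + r1)


def _tangent_handle(direction: np.ndarray, normal: np.ndarray) -> np.ndarray:
    """Unit projection of ``direction`` onto the tangent plane of ``normal``.

    Degenerate projection (edge parallel to the normal) collapses the
    handle onto the endpoint, i.e. returns the zero vector.
    """
    proj = direction - np.dot(direction, normal) * normal
    n = float(np.linalg.norm(proj))
    if n < 1e-9 * np.linalg.norm(direction):
        return np.zeros(3)
    return proj / n


def cloning_step(mesh: ColonyMesh, params: CloneParams) -> int:
    """Split every over-long edge at its Bezier midpoint; returns clones added.

    Each pass collects edges longer than ``delta_sub`` (longest first, ties
    broken by vertex ids for determinism) and splits those still present;
    passes repeat until no edge exceeds ``delta_sub``.  A runaway pass cap
    guards against pathological geometry.
    """
    total = 0
    for _ in range(_MAX_PASSES):
        over = [
            (length, e)
            for e, length in mesh.edges_with_lengths()
            if length > params.delta_sub
        ]
        if not over:
            return total
        over.sort(key=lambda x: (-x[0], x[1]))
        for _, (u, v) in over:
            if not mesh.has_edge(u, v):
                continue  # invalidated by an earlier split this pass
            midpoint = bezier_midpoint(
                mesh.position(u),
                mesh.vertex_normal(u),
                mesh.position(v),
                mesh.vertex_normal(v),
            )
            mesh.split_edge((u, v), midpoint)
            total += 1
    if any(length > params.delta_sub for _, length in mesh.edges_with_lengths()):
        raise RunawayGeometryError(
            f"edges above delta_sub={params.delta_sub} after {_MAX_PASSES} passes"
        )
    return total


def fusion_step(mesh: ColonyMesh, params: CloneParams) -> int:
    """Collapse every under-short edge once; returns polyps removed.

    Edges shorter than ``delta_fuse`` at entry are examined shortest-first;
    ones invalidated by earlier collapses (or no longer short, since a
    collapse relocates the survivor) are skipped, and collapses refused by
    the link condition are skipped silently.  Leaders are never removed:
    the non-leader endpoint is absorbed into the leader.
    """
    short = [
        (length, e)
        for e, length in mesh.edges_with_lengths()
        if length < params.delta_fuse
    ]
    short.sort(key=lambda x: (x[0], x[1]))
    removed = 0
    for _, (u, v) in short:
        if not mesh.has_edge(u, v):
            continue
        if (
            float(np.linalg.norm(mesh.position(u) - mesh.position(v)))
            >= params.delta_fuse
        ):
            continue  # stretched past the threshold by an earlier collapse
        if mesh.collapse_edge((u, v)) is not None:
            removed += 1
    return removed
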