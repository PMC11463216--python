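"""Shape descriptors and parameter-sweep regressions.

Descriptors: mean inter-polyp distance (mean mesh edge length), mean
neighbour count over non-boundary polyps (the substrate rim is excluded —
its degree is an artefact of the open base), colony height and maximal
horizontal radius, and branch diameter measured from planar cross-sections
perpendicular to the branch axis.

A metric is "stabilized" when its relative change over 10 consecutive
steps falls below 1%; sweeps run each colony until stabilization and fit
an ordinary least-squares line (with intercept) of the stabilized metric
against delta_sub, pooled across morphotypes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
import trimesh
from trimesh.intersections import mesh_plane

from .branching import BranchNode, BranchRegistry
from .cloning import CloneParams
from .mesh import ColonyMesh
from .simulator import ColonyState, SimulationConfig, initial_state, step

__all__ = [
    "MetricsRecord",
    "SweepResult",
    "METRIC_COLUMNS",
    "mean_interpolyp_distance",
    "mean_degree",
    "colony_height",
    "colony_max_radius",
    "branch_diameter",
    "mean_branch_diameter",
    "collect",
    "run_until_stable",
    "run_sweep",
    "sweep_slope",
]

METRIC_COLUMNS = [
    "t",
    "n_polyps",
    "mean_interpolyp",
    "mean_degree",
    "height",
    "max_radius",
    "n_branches",
    "mean_branch_diameter",
]


@dataclass(frozen=True)
class MetricsRecord:
    t: float
    n_polyps: int
    mean_interpolyp: float
    mean_degree: float
    height: float
    max_radius: float
    n_branches: int
    mean_branch_diameter: float | None

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in METRIC_COLUMNS}


def mean_interpolyp_distance(mesh: ColonyMesh) -> float:
    """Arithmetic mean of all edge lengths (mm)."""
    ewl = mesh.edges_with_lengths()
    if not ewl:
        raise ValueError("mesh has no edges")
    return float(np.mean([l for _, l in ewl]))


def mean_degree(mesh: ColonyMesh) -> float:
    """Mean neighbour count over non-boundary vertices.

    Falls back to all vertices when every vertex is on the boundary
    (degenerate flat patches).
    """
    boundary = mesh.boundary_vertices()
    interior = [v for v in mesh.vertex_ids() if v not in boundary]
    pool = interior if interior else mesh.vertex_ids()
    return float(np.mean([mesh.degree(v) for v in pool]))


def colony_height(mesh: ColonyMesh) -> float:
    """Max z over vertices (mm) — vertical extent above the substrate."""
    _, pos, _ = mesh.arrays()
    return float(pos[:, 2].max())


def colony_max_radius(mesh: ColonyMesh) -> float:
    """Max horizontal distance from the colony z-axis (mm)."""
    _, pos, _ = mesh.arrays()
    return float(np.hypot(pos[:, 0], pos[:, 1]).max())


def _to_trimesh(mesh: ColonyMesh) -> trimesh.Trimesh:
    _, pos, fidx = mesh.arrays()
    return trimesh.Trimesh(vertices=pos, faces=fidx, process=False)


def _section_loops(points: np.ndarray, tol: float) -> list[np.ndarray]:
    """Group cross-section segment endpoints into connected loops."""
    keys = np.round(points / tol).astype(np.int64)
    uniq, inverse = np.unique(keys, axis=0, return_inverse=True)
    n = len(uniq)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    pairs = inverse.reshape(-1, 2)
    for a, b in pairs:
        ra, rb = find(int(a)), find(int(b))
        if ra != rb:
            parent[ra] = rb
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    # representative point row for each unique key: its first occurrence
    first = np.full(n, -1, dtype=np.int64)
    for row, g in enumerate(inverse.ravel()):
        if first[g] < 0:
            first[g] = row
    return [points[first[np.array(g)]] for g in groups.values()]


def branch_diameter(
    mesh: ColonyMesh,
    node: BranchNode,
    stations: int = 5,
    margin: float = 0.0,
) -> float:
    """Mean diameter of a branch from planar sections along its axis (mm).

    The branch extends from its node origin to its leader polyp; at
    ``stations`` evenly spaced positions (excluding ``margin`` at each
    end) the mesh is cut by the plane perpendicular to the branch axis,
    the connected intersection loop nearest the axis is kept, and the
    station diameter is twice the mean distance of the loop points to the
    axis line.  Stations with no intersection are skipped; all skipped is
    an error.
    """
    if stations < 1:
        raise ValueError("stations must be >= 1")
    axis = node.axis / np.linalg.norm(node.axis)
    tip = mesh.position(node.leader)
    length = float(np.dot(tip - node.origin, axis))
    if length <= 2.0 * margin:
        raise ValueError(
            f"branch too short ({length:.3g} mm) for margin {margin:.3g} mm"
        )
    tm = _to_trimesh(mesh)
    offsets = np.linspace(margin, length - margin, stations)
    tol = max(1e-6, 1e-9 * length)
    diameters = []
    for s in offsets:
        origin = node.origin + s * axis
        segments = mesh_plane(tm, plane_normal=axis, plane_origin=origin)
        if len(segments) == 0:
            continue
        points = np.asarray(segments).reshape(-1, 3)
        loops = _section_loops(points, tol)
        radial = []
        for loop in loops:
            rel = loop - origin
            rel = rel - np.outer(rel @ axis, axis)
            radial.append(np.linalg.norm(rel, axis=1))
        nearest = min(radial, key=lambda r: float(r.min()))
        diameters.append(2.0 * float(nearest.mean()))
    if not diameters:
        raise ValueError("no cross-section found at any station")
    return float(np.mean(diameters))


def mean_branch_diameter(
    mesh: ColonyMesh,
    registry: BranchRegistry,
    delta_sub: float,
    stations: int = 5,
) -> float | None:
    """Mean diameter over branches long enough to section (>= 2*delta_sub)."""
    values = []
    for node in registry.branches:
        if not mesh.has_vertex(node.leader):
            continue
        length = float(
            np.dot(mesh.position(node.leader) - node.origin, node.axis)
        )
        if length < 2.0 * delta_sub:
            continue
        try:
            values.append(
                branch_diameter(mesh, node, stations=stations, margin=delta_sub)
            )
        except ValueError:
            continue
    if not values:
        return None
    return float(np.mean(values))


def collect(state: ColonyState, clone: CloneParams) -> MetricsRecord:
    """One metrics row for a colony state."""
    mesh = state.mesh
    n_branches = state.registry.n_branches if state.registry is not None else 0
    mbd = None
    if state.registry is not None:
        mbd = mean_branch_diameter(mesh, state.registry, clone.delta_sub)
    return MetricsRecord(
        t=state.t,
        n_polyps=mesh.n_vertices,
        mean_interpolyp=mean_interpolyp_distance(mesh),
        mean_degree=mean_degree(mesh),
        height=colony_height(mesh),
        max_radius=colony_max_radius(mesh),
        n_branches=n_branches,
        mean_branch_diameter=mbd,
    )


def run_until_stable(
    config: SimulationConfig,
    metric: Callable[[ColonyMesh], float] = mean_interpolyp_distance,
    *,
    window: int = 10,
    rel_tol: float = 0.01,
    t_min: float = 3.0,
    t_max: float = 12.0,
) -> ColonyState:
    """Step a colony until ``metric`` stabilizes, then return the state.

    Stabilized: the spread (max - min) of the metric over ``window``
    consecutive steps is below ``rel_tol`` of its mean, evaluated no
    earlier than ``t_min`` (so the seed transient cannot trigger it) and
    capped at ``t_max``.
    """
    state = initial_state(config)
    history: list[float] = []
    n_max = int(round(t_max / config.growth.dt))
    for _ in range(n_max):
        step(state, config)
        history.append(metric(state.mesh))
        if state.t + 1e-9 >= t_min and len(history) >= window:
            w = np.array(history[-window:])
            if (w.max() - w.min()) < rel_tol * abs(w.mean()):
                break
    return state


@dataclass
class SweepResult:
    """Stabilized metric values over a delta_sub grid, pooled across shapes."""

    table: pd.DataFrame  # columns: shape, delta_sub, <metrics...>


def run_sweep(
    configs: dict[str, Callable[[float], SimulationConfig]],
    delta_subs: list[float],
    *,
    metric: Callable[[ColonyMesh], float] = mean_interpolyp_distance,
    t_min: float = 3.0,
    t_max: float = 12.0,
) -> SweepResult:
    """Run every (shape, delta_sub) combination until stabilization.

    ``configs`` maps shape labels to factories taking delta_sub.  Returns a
    table with one row per run holding the stabilized descriptors.
    """
    rows = []
    for shape, factory in configs.items():
        for ds in delta_subs:
            config = factory(ds)
            state = run_until_stable(
                config, metric, t_min=t_min, t_max=t_max
            )
            rec = collect(state, config.clone)
            row = {"shape": shape, "delta_sub": ds, **rec.as_dict()}
            rows.append(row)
    return SweepResult(table=pd.DataFrame(rows))


def sweep_slope(result: SweepResult, metric: str) -> tuple[float, float]:
    """Pooled OLS (slope, intercept) of a stabilized metric vs delta_sub."""
    df = result.table.dropna(subset=[metric])
    x = df["delta_sub"].to_numpy(dtype=float)
    y = df[metric].to_numpy(dtype=float)
    if len(np.unique(x)) < 3:
        raise ValueError("sweep regression needs >= 3 distinct delta_sub values")
    A = np.column_stack([x, np.ones_like(x)])
    (slope, intercept), *_ = np.linalg.lstsq(A, y, rcond=None)
    return float(slope), float(intercept)
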