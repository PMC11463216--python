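"""Hexacone seed and the top-level time loop.

The colony starts from a hexagonal pyramid (the "hexacone"): the apex is
the sexually produced founder polyp, the six base vertices its first clone
generation.  Base side length is delta_sub and pyramid height delta_sub/2.
Each step of length dt applies, in order: gated surface accretion, leader
elongation (branching runs), cloning to quiescence, one fusion pass, and
leader recruitment.  Runs are bitwise reproducible for a fixed RNG seed;
non-branching runs consume no randomness at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

from .branching import (
    BranchNode,
    BranchParams,
    BranchRegistry,
    branching_step,
    leader_growth_step,
)
from .cloning import CloneParams, cloning_step, fusion_step
from .growth import GrowthParams, GrowthSchedule, growth_step, mode_at
from .mesh import ColonyMesh, MeshError

__all__ = [
    "SimulationConfig",
    "ColonyState",
    "StepLog",
    "Snapshot",
    "make_hexacone_seed",
    "initial_state",
    "step",
    "run",
]


@dataclass(frozen=True)
class SimulationConfig:
    schedule: GrowthSchedule
    growth: GrowthParams
    clone: CloneParams
    branch: BranchParams | None = None
    t_end: float = 6.0
    rng_seed: int = 0
    snapshot_every: float = 2.0

    def __post_init__(self) -> None:
        if self.t_end <= 0:
            raise ValueError(f"t_end must be > 0, got {self.t_end}")
        if self.snapshot_every <= 0:
            raise ValueError(
                f"snapshot_every must be > 0, got {self.snapshot_every}"
            )


@dataclass
class ColonyState:
    """Mesh + branch registry + clock + RNG stream (single, owned here)."""

    mesh: ColonyMesh
    registry: BranchRegistry | None
    rng: np.random.Generator
    n_steps: int = 0
    dt: float = 0.1

    @property
    def t(self) -> float:
        return self.n_steps * self.dt

    def copy(self) -> "ColonyState":
        reg = None
        if self.registry is not None:
            reg = BranchRegistry(
                [
                    BranchNode(b.origin.copy(), b.axis.copy(), b.leader, b.parent)
                    for b in self.registry.branches
                ]
            )
        state = ColonyState(
            mesh=self.mesh.copy(),
            registry=reg,
            rng=np.random.default_rng(),
            n_steps=self.n_steps,
            dt=self.dt,
        )
        state.rng.bit_generator.state = self.rng.bit_generator.state
        return state


@dataclass(frozen=True)
class StepLog:
    t: float
    n_vertices: int
    moved: int
    splits: int
    fusions: int
    new_branches: int


@dataclass(frozen=True)
class Snapshot:
    t: float
    state: ColonyState
    metrics: "object"  # MetricsRecord; morphometrics imports this module


def make_hexacone_seed(
    delta_sub: float,
    *,
    branching: bool = False,
    rng: np.random.Generator | None = None,
    dt: float = 0.1,
) -> ColonyState:
    """Hexagonal-pyramid seed: apex at (0, 0, delta_sub/2), regular hexagonal
    base of side (= circumradius) delta_sub at z=0, six outward-wound side
    faces, open base.  With branching enabled the apex is registered as the
    leader of branch 0 (the trunk) with axis +z.
    """
    if delta_sub <= 0:
        raise ValueError(f"delta_sub must be > 0, got {delta_sub}")
    mesh = ColonyMesh()
    apex = mesh.add_vertex(
        (0.0, 0.0, delta_sub / 2.0), is_leader=branching
    )
    base = []
    for k in range(6):
        ang = k * np.pi / 3.0
        base.append(
            mesh.add_vertex(
                (delta_sub * np.cos(ang), delta_sub * np.sin(ang), 0.0),
                is_base=True,
            )
        )
    for k in range(6):
        mesh.add_face(apex, base[k], base[(k + 1) % 6])
    registry = None
    if branching:
        registry = BranchRegistry(
            [
                BranchNode(
                    origin=mesh.position(apex).copy(),
                    axis=np.array([0.0, 0.0, 1.0]),
                    leader=apex,
                    parent=None,
                )
            ]
        )
    return ColonyState(
        mesh=mesh,
        registry=registry,
        rng=rng if rng is not None else np.random.default_rng(0),
        dt=dt,
    )


def initial_state(config: SimulationConfig) -> ColonyState:
    return make_hexacone_seed(
        config.clone.delta_sub,
        branching=config.branch is not None,
        rng=np.random.default_rng(config.rng_seed),
        dt=config.growth.dt,
    )


def step(state: ColonyState, config: SimulationConfig) -> StepLog:
    """Advance the colony by one dt in place; returns per-step counts.

    Sub-step order: accretion -> leader elongation -> cloning -> fusion ->
    branching.  Cloning immediately consolidates leader kicks, and fusion
    never precedes the density restoration of cloning.
    """
    mode = mode_at(config.schedule, state.t)
    moved = growth_step(state.mesh, mode, config.growth)
    if config.branch is not None and state.registry is not None:
        leader_growth_step(state.mesh, state.registry, config.growth)
    splits = cloning_step(state.mesh, config.clone)
    fusions = fusion_step(state.mesh, config.clone)
    new_branches = 0
    if config.branch is not None and state.registry is not None:
        new_branches = branching_step(
            state.mesh, state.registry, config.branch, config.growth, state.rng
        )
    state.n_steps += 1
    return StepLog(
        t=state.t,
        n_vertices=state.mesh.n_vertices,
        moved=moved,
        splits=splits,
        fusions=fusions,
        new_branches=new_branches,
    )


def run(
    config: SimulationConfig,
    *,
    on_step: Callable[[StepLog], None] | None = None,
) -> list[Snapshot]:
    """Run from the seed to t_end, returning snapshots with metrics.

    Snapshots are emitted at every multiple of ``snapshot_every`` and at
    ``t_end``; each carries a deep copy of the state and its metrics row.
    """
    from .morphometrics import collect  # cycle-free late import

    state = initial_state(config)
    dt = config.growth.dt
    n_total = int(round(config.t_end / dt))
    every = max(1, int(round(config.snapshot_every / dt)))
    snaps: list[Snapshot] = []
    for k in range(1, n_total + 1):
        log = step(state, config)
        if on_step is not None:
            on_step(log)
        if k % every == 0 or k == n_total:
            snaps.append(
                Snapshot(
                    t=state.t,
                    state=state.copy(),
                    metrics=collect(state, config.clone),
                )
            )
    return snaps
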