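"""Surface accretion: the growth-mode gate and the per-step displacement rule.

Each polyp carries a normalized elevation angle

    xi(n) = (2/pi) * arctan(nz / sqrt(nx^2 + ny^2))    in [-1, 1],

of its unit surface normal n: xi = 1 for a polyp facing straight up, 0 for
one facing horizontally, negative for downward-facing polyps.  The growth
mode s = [smin, smax] gates accretion: a polyp relocates by
V -> V + alpha * n, alpha = nu * dt, only when smin <= xi <= smax (closed
interval).  Substrate-bound (base) polyps grow along their normal with the
vertical component suppressed, so their xi is exactly 0: they move, only
horizontally, iff smin = 0 — which anchors the colony base for any mode
with smin > 0.

``xi_variant="as_printed"`` selects the alternative functional
(2/pi) * arctan((1 - nz) / h), retained for comparison; it does not
reproduce the vertical/horizontal limits the gate semantics rely on.
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass, field

import numpy as np

from .mesh import ColonyMesh

__all__ = [
    "GrowthMode",
    "GrowthSchedule",
    "GrowthParams",
    "xi",
    "xi_as_printed",
    "xi_values",
    "is_growth_permitted",
    "base_direction",
    "growth_step",
    "mode_at",
]

_UNIT_TOL = 1e-9


@dataclass(frozen=True)
class GrowthMode:
    """Growth-mode interval s = [smin, smax], dimensionless in [0, 1]."""

    smin: float
    smax: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.smin <= self.smax <= 1.0):
            raise ValueError(
                f"growth mode requires 0 <= smin <= smax <= 1, got "
                f"[{self.smin}, {self.smax}]"
            )


@dataclass(frozen=True)
class GrowthParams:
    """Elongation rate nu (mm/yr), time step dt (yr), derived alpha = nu*dt (mm)."""

    nu: float = 10.0
    dt: float = 0.1
    xi_variant: str = "elevation"

    def __post_init__(self) -> None:
        if self.nu <= 0:
            raise ValueError(f"nu must be > 0, got {self.nu}")
        if self.dt <= 0:
            raise ValueError(f"dt must be > 0, got {self.dt}")
        if self.xi_variant not in ("elevation", "as_printed"):
            raise ValueError(f"unknown xi variant {self.xi_variant!r}")

    @property
    def alpha(self) -> float:
        return self.nu * self.dt


@dataclass(frozen=True)
class GrowthSchedule:
    """Piecewise-constant growth mode over time.

    ``entries`` is an ordered sequence of (t_start in yr, GrowthMode);
    t_starts strictly increasing, the first at 0.
    """

    entries: tuple[tuple[float, GrowthMode], ...]

    def __init__(self, entries) -> None:
        entries = tuple((float(t), m) for t, m in entries)
        if not entries:
            raise ValueError("schedule needs at least one entry")
        if abs(entries[0][0]) > 1e-12:
            raise ValueError("first schedule entry must start at t=0")
        starts = [t for t, _ in entries]
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError("schedule t_starts must be strictly increasing")
        object.__setattr__(self, "entries", entries)

    @classmethod
    def constant(cls, mode: GrowthMode) -> "GrowthSchedule":
        return cls(((0.0, mode),))


def xi(n) -> float:
    """Normalized elevation angle of a unit vector; in [-1, 1].

    Raises on non-unit input (no silent renormalization).  The vertical
    limits xi(0,0,±1) = ±1 are handled explicitly.
    """
    n = np.asarray(n, dtype=float)
    if abs(float(np.linalg.norm(n)) - 1.0) > _UNIT_TOL:
        raise ValueError(f"xi requires a unit vector, got |n|={np.linalg.norm(n)}")
    h = math.hypot(n[0], n[1])
    if h < _UNIT_TOL:
        return 1.0 if n[2] > 0 else -1.0
    return (2.0 / math.pi) * math.atan2(n[2], h)


def xi_as_printed(n) -> float:
    """The functional as printed in the source's Eq 2.1: (2/pi)arctan((1-nz)/h).

    Kept for comparison only; its limits do not match the vertical=1 /
    horizontal=0 convention the growth gate uses.
    """
    n = np.asarray(n, dtype=float)
    if abs(float(np.linalg.norm(n)) - 1.0) > _UNIT_TOL:
        raise ValueError(f"xi requires a unit vector, got |n|={np.linalg.norm(n)}")
    h = math.hypot(n[0], n[1])
    if h < _UNIT_TOL:
        # limit h -> 0: (1-nz) is 0 for the up pole, 2 for the down pole
        return 0.0 if n[2] > 0 else 1.0
    return (2.0 / math.pi) * math.atan2(1.0 - n[2], h)


def xi_values(normals: np.ndarray, variant: str = "elevation") -> np.ndarray:
    """Vectorized xi over rows of unit normals (rows of zeros give 0)."""
    n = np.asarray(normals, dtype=float)
    h = np.hypot(n[:, 0], n[:, 1])
    if variant == "elevation":
        return (2.0 / np.pi) * np.arctan2(n[:, 2], h)
    if variant == "as_printed":
        return (2.0 / np.pi) * np.arctan2(1.0 - n[:, 2], h)
    raise ValueError(f"unknown xi variant {variant!r}")


def is_growth_permitted(xi_value: float, mode: GrowthMode) -> bool:
    """Closed-interval gate: smin <= xi <= smax."""
    return mode.smin <= xi_value <= mode.smax


def base_direction(mesh: ColonyMesh, v: int) -> np.ndarray:
    """Growth direction of a substrate-bound polyp.

    The vertex normal with the vertical component suppressed, renormalized.
    Tie-break when the normal is (numerically) vertical: the outward radial
    direction from the colony's z-axis.
    """
    if not mesh.is_base(v):
        raise ValueError(f"vertex {v} is not a base vertex")
    n = mesh.vertex_normal(v)
    return _horizontalize(n, mesh.position(v))


def _horizontalize(n: np.ndarray, position: np.ndarray) -> np.ndarray:
    h = np.array([n[0], n[1], 0.0])
    nh = np.linalg.norm(h)
    if nh < _UNIT_TOL:
        r = np.array([position[0], position[1], 0.0])
        nr = np.linalg.norm(r)
        if nr < _UNIT_TOL:
            return np.array([1.0, 0.0, 0.0])
        return r / nr
    return h / nh


def growth_step(mesh: ColonyMesh, mode: GrowthMode, params: GrowthParams) -> int:
    """One accretion step: move every gate-permitted non-leader polyp.

    All normals are computed from the pre-step geometry (synchronous
    update), so the result is independent of vertex ordering.  Returns the
    number of polyps moved.
    """
    ids, normals = mesh.vertex_normals()
    _, pos, _ = mesh.arrays()
    dirs = normals.copy()
    norms = np.linalg.norm(dirs, axis=1)
    movable = norms > 0.5  # unit rows; zero rows are degenerate, frozen
    for i, v in enumerate(ids):
        if mesh.is_base(v):
            dirs[i] = _horizontalize(normals[i], pos[i])
        elif mesh.is_leader(v):
            movable[i] = False  # leaders advance in the branching module
    vals = xi_values(dirs, params.xi_variant)
    sel = movable & (vals >= mode.smin) & (vals <= mode.smax)
    alpha = params.alpha
    moved = 0
    for i, v in enumerate(ids):
        if sel[i]:
            mesh.set_position(v, pos[i] + alpha * dirs[i])
            moved += 1
    return moved


def mode_at(schedule: GrowthSchedule, t: float) -> GrowthMode:
    """Growth mode in force at time t (switch inclusive at each t_start)."""
    if t < -1e-12:
        raise ValueError(f"t must be >= 0, got {t}")
    starts = [ts for ts, _ in schedule.entries]
    i = bisect.bisect_right(starts, t + 1e-9) - 1
    return schedule.entries[max(i, 0)][1]
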