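"""Manifold triangular colony mesh.

Each vertex is a polyp: a point in space (mm) carrying two biological flags,
``is_base`` (substrate-bound polyp, confined to the z=0 plane) and
``is_leader`` (branch-leading polyp with apical dominance).  Faces are
oriented counter-clockwise seen from outside the colony.  The substrate is
not meshed: the rim of base vertices is the mesh boundary, so a colony grown
from the seed has disk topology (Euler characteristic 1).

The two topological primitives every growth rule builds on are
:meth:`ColonyMesh.split_edge` (polyp cloning) and
:meth:`ColonyMesh.collapse_edge` (polyp fusion).  Vertex ids are stable and
never reused after a fusion removes a vertex.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np

__all__ = [
    "MeshError",
    "EdgeNotFoundError",
    "IsolatedVertexError",
    "ValidationReport",
    "ColonyMesh",
]

_TINY = 1e-12
_BASE_Z_TOL = 1e-9


class MeshError(ValueError):
    """Corrupted or inconsistent mesh topology."""


class EdgeNotFoundError(MeshError):
    """The requested vertex pair is not an edge of the mesh."""


class IsolatedVertexError(MeshError):
    """A vertex has no incident face (corrupted topology)."""


@dataclass
class ValidationReport:
    ok: bool
    violations: list[str] = field(default_factory=list)

    def __bool__(self) -> bool:
        return self.ok


def _key(u: int, v: int) -> tuple[int, int]:
    return (u, v) if u < v else (v, u)


class ColonyMesh:
    """Triangular surface mesh with attribute-carrying polyp vertices."""

    def __init__(self) -> None:
        self._pos: dict[int, np.ndarray] = {}
        self._base: set[int] = set()
        self._leader: set[int] = set()
        self._faces: dict[int, tuple[int, int, int]] = {}
        self._vfaces: dict[int, set[int]] = {}
        self._next_vid = 0
        self._next_fid = 0

    # ------------------------------------------------------------------ #
    # construction

    def add_vertex(
        self,
        position: Iterable[float],
        *,
        is_base: bool = False,
        is_leader: bool = False,
    ) -> int:
        p = np.asarray(position, dtype=float).copy()
        if p.shape != (3,) or not np.all(np.isfinite(p)):
            raise MeshError(f"invalid vertex position {position!r}")
        vid = self._next_vid
        self._next_vid += 1
        if is_base:
            p[2] = 0.0
            self._base.add(vid)
        if is_leader:
            self._leader.add(vid)
        self._pos[vid] = p
        self._vfaces[vid] = set()
        return vid

    def add_face(self, a: int, b: int, c: int) -> int:
        tri = (a, b, c)
        if len(set(tri)) != 3:
            raise MeshError(f"degenerate face {tri}")
        for v in tri:
            if v not in self._pos:
                raise MeshError(f"face {tri} references unknown vertex {v}")
        fid = self._next_fid
        self._next_fid += 1
        self._faces[fid] = tri
        for v in tri:
            self._vfaces[v].add(fid)
        return fid

    def copy(self) -> "ColonyMesh":
        m = ColonyMesh()
        m._pos = {v: p.copy() for v, p in self._pos.items()}
        m._base = set(self._base)
        m._leader = set(self._leader)
        m._faces = dict(self._faces)
        m._vfaces = {v: set(f) for v, f in self._vfaces.items()}
        m._next_vid = self._next_vid
        m._next_fid = self._next_fid
        return m

    # ------------------------------------------------------------------ #
    # queries

    @property
    def n_vertices(self) -> int:
        return len(self._pos)

    @property
    def n_faces(self) -> int:
        return len(self._faces)

    @property
    def n_edges(self) -> int:
        return len(self.edges())

    def vertex_ids(self) -> list[int]:
        return list(self._pos)

    def has_vertex(self, v: int) -> bool:
        return v in self._pos

    def position(self, v: int) -> np.ndarray:
        return self._pos[v]

    def set_position(self, v: int, position: Iterable[float]) -> None:
        p = np.asarray(position, dtype=float).copy()
        if v in self._base:
            p[2] = 0.0
        self._pos[v] = p

    def is_base(self, v: int) -> bool:
        return v in self._base

    def is_leader(self, v: int) -> bool:
        return v in self._leader

    def set_leader(self, v: int, flag: bool) -> None:
        if v not in self._pos:
            raise MeshError(f"unknown vertex {v}")
        if flag:
            self._leader.add(v)
        else:
            self._leader.discard(v)

    def faces(self) -> Iterator[tuple[int, int, int]]:
        return iter(self._faces.values())

    def incident_faces(self, v: int) -> list[tuple[int, int, int]]:
        return [self._faces[f] for f in sorted(self._vfaces[v])]

    def edge_faces(self, u: int, v: int) -> list[int]:
        """Face ids incident to edge (u, v); empty if not an edge."""
        if u not in self._vfaces or v not in self._vfaces:
            return []
        return sorted(self._vfaces[u] & self._vfaces[v])

    def has_edge(self, u: int, v: int) -> bool:
        return len(self.edge_faces(u, v)) > 0

    def neighbors(self, v: int) -> set[int]:
        out: set[int] = set()
        for fid in self._vfaces.get(v, ()):
            out.update(self._faces[fid])
        out.discard(v)
        return out

    def degree(self, v: int) -> int:
        return len(self.neighbors(v))

    def edges(self) -> set[tuple[int, int]]:
        out: set[tuple[int, int]] = set()
        for a, b, c in self._faces.values():
            out.add(_key(a, b))
            out.add(_key(b, c))
            out.add(_key(c, a))
        return out

    def boundary_edges(self) -> set[tuple[int, int]]:
        count: dict[tuple[int, int], int] = {}
        for a, b, c in self._faces.values():
            for e in (_key(a, b), _key(b, c), _key(c, a)):
                count[e] = count.get(e, 0) + 1
        return {e for e, n in count.items() if n == 1}

    def boundary_vertices(self) -> set[int]:
        out: set[int] = set()
        for u, v in self.boundary_edges():
            out.add(u)
            out.add(v)
        return out

    # ------------------------------------------------------------------ #
    # array views (for vectorized per-step computations)

    def arrays(self) -> tuple[list[int], np.ndarray, np.ndarray]:
        """Return (vertex ids, positions (n,3), face index triples (m,3)).

        Face entries index into the returned position rows, not vertex ids.
        """
        ids = list(self._pos)
        index = {v: i for i, v in enumerate(ids)}
        pos = np.array([self._pos[v] for v in ids], dtype=float).reshape(-1, 3)
        if self._faces:
            fidx = np.array(
                [[index[a], index[b], index[c]] for a, b, c in self._faces.values()],
                dtype=np.intp,
            )
        else:
            fidx = np.zeros((0, 3), dtype=np.intp)
        return ids, pos, fidx

    def edges_with_lengths(self) -> list[tuple[tuple[int, int], float]]:
        """All edges as ((u, v), length) with u < v, vectorized."""
        if not self._faces:
            return []
        f = np.array(list(self._faces.values()), dtype=np.int64)
        e = np.vstack([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
        e.sort(axis=1)
        e = np.unique(e, axis=0)
        # id -> row lookup
        ids = np.array(list(self._pos), dtype=np.int64)
        pos = np.array([self._pos[v] for v in self._pos], dtype=float)
        lut = np.full(int(ids.max()) + 1, -1, dtype=np.int64)
        lut[ids] = np.arange(len(ids))
        d = pos[lut[e[:, 0]]] - pos[lut[e[:, 1]]]
        lengths = np.linalg.norm(d, axis=1)
        return [((int(u), int(v)), float(l)) for (u, v), l in zip(e, lengths)]

    def vertex_normals(self) -> tuple[list[int], np.ndarray]:
        """Area-weighted unit vertex normals for every vertex, vectorized.

        The area-weighted average of incident face normals is the sum of the
        (un-normalized) face cross products, since |cross|/2 is the face
        area.  Rows for isolated/degenerate vertices are left as zeros.
        """
        ids, pos, fidx = self.arrays()
        acc = np.zeros_like(pos)
        if len(fidx):
            tri = pos[fidx]
            fn = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
            np.add.at(acc, fidx[:, 0], fn)
            np.add.at(acc, fidx[:, 1], fn)
            np.add.at(acc, fidx[:, 2], fn)
        norms = np.linalg.norm(acc, axis=1)
        good = norms > _TINY
        acc[good] /= norms[good, None]
        acc[~good] = 0.0
        return ids, acc

    def vertex_normal(self, v: int) -> np.ndarray:
        """Area-weighted unit normal at a single vertex."""
        if v not in self._pos:
            raise MeshError(f"unknown vertex {v}")
        fids = self._vfaces[v]
        if not fids:
            raise IsolatedVertexError(f"vertex {v} has no incident face")
        acc = np.zeros(3)
        for fid in fids:
            a, b, c = self._faces[fid]
            pa, pb, pc = self._pos[a], self._pos[b], self._pos[c]
            acc += np.cross(pb - pa, pc - pa)
        n = np.linalg.norm(acc)
        if n <= _TINY:
            raise MeshError(f"degenerate normal at vertex {v}")
        return acc / n

    # ------------------------------------------------------------------ #
    # topological operations

    def split_edge(
        self, edge: tuple[int, int], new_position: Iterable[float]
    ) -> int:
        """Insert a vertex on an edge; 1-to-2 split of each incident face.

        The new vertex inherits ``is_base`` only when both endpoints are base
        (its z is then forced to 0); ``is_leader`` is never inherited.
        Orientation of the daughter faces matches the parent face.
        """
        u, v = edge
        fids = self.edge_faces(u, v)
        if not fids:
            raise EdgeNotFoundError(f"edge ({u}, {v}) not in mesh")
        p = np.asarray(new_position, dtype=float)
        if p.shape != (3,) or not np.all(np.isfinite(p)):
            raise MeshError(f"invalid split position {new_position!r}")
        both_base = u in self._base and v in self._base
        m = self.add_vertex(p, is_base=both_base)
        for fid in fids:
            tri = self._faces[fid]
            # rotate so the split edge occupies the first two slots,
            # preserving cyclic order (hence winding)
            for _ in range(3):
                if {tri[0], tri[1]} == {u, v}:
                    break
                tri = (tri[1], tri[2], tri[0])
            a, b, w = tri
            self._remove_face(fid)
            self.add_face(a, m, w)
            self.add_face(m, b, w)
        return m

    def collapse_edge(self, edge: tuple[int, int]) -> int | None:
        """Fuse the two endpoints of an edge into one vertex.

        Returns the surviving vertex id, or None when the collapse is
        refused (link condition violated, boundary pinch, or both endpoints
        leaders / conflicting base-leader roles).

        Survivor policy: a leader absorbs a non-leader (keeping the leader's
        position); a base vertex absorbs a non-base vertex (keeping the base
        position, which keeps the substrate rim intact); otherwise the
        lower-id endpoint survives at the edge midpoint (z forced to 0 when
        both endpoints are base).
        """
        u, v = edge
        fids = self.edge_faces(u, v)
        if not fids:
            raise EdgeNotFoundError(f"edge ({u}, {v}) not in mesh")
        # link condition: shared neighbours must be exactly the vertices
        # opposite the edge in its incident faces
        opposite = {w for fid in fids for w in self._faces[fid] if w not in (u, v)}
        shared = self.neighbors(u) & self.neighbors(v)
        if shared != opposite:
            return None
        # interior edge between two boundary vertices would pinch the rim
        boundary = self.boundary_vertices()
        if len(fids) == 2 and u in boundary and v in boundary:
            return None
        # refuse collapses that would strand a vertex without faces
        # (e.g. collapsing an edge of the last remaining triangle)
        doomed = set(fids)
        if (self._vfaces[u] | self._vfaces[v]) <= doomed:
            return None
        if any(self._vfaces[w] <= doomed for w in opposite):
            return None
        u_leader, v_leader = u in self._leader, v in self._leader
        u_base, v_base = u in self._base, v in self._base
        if u_leader and v_leader:
            return None
        if (u_leader and v_base) or (v_leader and u_base):
            return None  # cannot keep both the rim and the leader
        if u_leader or (u_base and not v_base):
            keep, drop = u, v
            target = self._pos[u].copy()
        elif v_leader or (v_base and not u_base):
            keep, drop = v, u
            target = self._pos[v].copy()
        else:
            keep, drop = (u, v) if u < v else (v, u)
            target = 0.5 * (self._pos[u] + self._pos[v])
            if u_base and v_base:
                target[2] = 0.0
        for fid in list(fids):
            self._remove_face(fid)
        for fid in list(self._vfaces[drop]):
            a, b, c = self._faces[fid]
            tri = tuple(keep if x == drop else x for x in (a, b, c))
            self._remove_face(fid)
            self.add_face(*tri)
        self._remove_vertex(drop)
        self._pos[keep] = target
        return keep

    def _remove_face(self, fid: int) -> None:
        tri = self._faces.pop(fid)
        for v in tri:
            self._vfaces[v].discard(fid)

    def _remove_vertex(self, v: int) -> None:
        if self._vfaces[v]:
            raise MeshError(f"cannot remove vertex {v} with incident faces")
        del self._pos[v]
        del self._vfaces[v]
        self._base.discard(v)
        self._leader.discard(v)
        # _next_vid is never decremented: ids are not reused

    # ------------------------------------------------------------------ #
    # validation

    def validate(self) -> ValidationReport:
        """Check all mesh invariants; diagnostic, never raises."""
        violations: list[str] = []
        # degenerate / duplicate faces
        seen: set[frozenset[int]] = set()
        for fid, tri in self._faces.items():
            if len(set(tri)) != 3:
                violations.append(f"degenerate face {fid}: {tri}")
                continue
            key = frozenset(tri)
            if key in seen:
                violations.append(f"duplicate face {fid}: {tri}")
            seen.add(key)
        # manifold edges and orientation consistency: each edge has 1 or 2
        # incident faces, and a 2-face edge is traversed once per direction
        directed: dict[tuple[int, int], int] = {}
        for tri in self._faces.values():
            a, b, c = tri
            for d in ((a, b), (b, c), (c, a)):
                directed[d] = directed.get(d, 0) + 1
        checked: set[tuple[int, int]] = set()
        for (a, b), n_ab in directed.items():
            e = _key(a, b)
            if e in checked:
                continue
            checked.add(e)
            n_ba = directed.get((b, a), 0)
            total = n_ab + n_ba
            if total > 2:
                violations.append(f"non-manifold edge {e}: {total} incident faces")
            elif total == 2 and (n_ab != 1 or n_ba != 1):
                violations.append(f"inconsistent winding across edge {e}")
        # isolated vertices
        for v in self._pos:
            if not self._vfaces[v]:
                violations.append(f"isolated vertex {v}")
        # base vertices on the substrate plane
        for v in sorted(self._base):
            if abs(self._pos[v][2]) > _BASE_Z_TOL:
                violations.append(
                    f"base vertex {v} off substrate plane (z={self._pos[v][2]:.3g})"
                )
        # global outward orientation: the colony's upper surface faces up
        if self._faces:
            _, pos, fidx = self.arrays()
            tri = pos[fidx]
            fn = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
            if float(fn[:, 2].sum()) <= 0.0:
                violations.append("orientation: mean face normal not upward")
        return ValidationReport(ok=not violations, violations=violations)

    def euler_characteristic(self) -> int:
        return self.n_vertices - self.n_edges + self.n_faces

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"ColonyMesh(V={self.n_vertices}, E={self.n_edges}, "
            f"F={self.n_faces}, base={len(self._base)}, leaders={len(self._leader)})"
        )
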