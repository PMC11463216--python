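"""Configuration files, morphotype presets, and mesh serialization.

Units are fixed repo-wide: mm for length, yr for time, degrees for the
branching angle in configuration files.  z is "up"; the substrate is z=0.

Presets reproduce the published morphotype parameterizations: all share
nu = 10 mm/yr, delta_sub = 10 mm, dt = 0.1 yr; the growth modes are
massive s=[0,1], cauliflower s=[0.01,1], columnar s=[0.375,1], branching
s=[0.375,1] with l_br=40 mm and theta=30 deg over 32 yr, tabular
s=[0.30,1] switching to s=[0,0.24] at t=3 yr, and the encrusting limit
s=[0,0].
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import trimesh
import yaml

from .branching import BranchParams
from .cloning import CloneParams
from .growth import GrowthMode, GrowthParams, GrowthSchedule, xi_values
from .mesh import ColonyMesh
from .simulator import ColonyState, SimulationConfig

__all__ = [
    "PRESET_NAMES",
    "preset",
    "load_config",
    "dump_config",
    "export_mesh",
    "import_mesh",
    "ConfigError",
]

PRESET_NAMES = (
    "massive",
    "cauliflower",
    "columnar",
    "branching",
    "tabular",
    "encrusting",
)

_PRESET_MODES = {
    "massive": ((0.0, (0.0, 1.0)),),
    "cauliflower": ((0.0, (0.01, 1.0)),),
    "columnar": ((0.0, (0.375, 1.0)),),
    "branching": ((0.0, (0.375, 1.0)),),
    "tabular": ((0.0, (0.30, 1.0)), (3.0, (0.0, 0.24))),
    "encrusting": ((0.0, (0.0, 0.0)),),
}


class ConfigError(ValueError):
    """Invalid configuration; the message lists every violation."""


def preset(name: str, **overrides) -> SimulationConfig:
    """Named morphotype configuration; overrides: t_end, rng_seed,
    snapshot_every, delta_sub, nu, dt, l_br, theta_deg, xi_variant."""
    if name not in PRESET_NAMES:
        raise ConfigError(
            f"unknown preset {name!r}; choose from {', '.join(PRESET_NAMES)}"
        )
    nu = float(overrides.pop("nu", 10.0))
    dt = float(overrides.pop("dt", 0.1))
    delta_sub = float(overrides.pop("delta_sub", 10.0))
    xi_variant = overrides.pop("xi_variant", "elevation")
    schedule = GrowthSchedule(
        [(t, GrowthMode(*mode)) for t, mode in _PRESET_MODES[name]]
    )
    branch = None
    default_t_end, default_snap = 6.0, 2.0
    if name == "branching":
        branch = BranchParams(
            l_br=float(overrides.pop("l_br", 40.0)),
            theta_deg=float(overrides.pop("theta_deg", 30.0)),
        )
        default_t_end, default_snap = 32.0, 10.0
    return SimulationConfig(
        schedule=schedule,
        growth=GrowthParams(nu=nu, dt=dt, xi_variant=xi_variant),
        clone=CloneParams(delta_sub=delta_sub),
        branch=branch,
        t_end=float(overrides.pop("t_end", default_t_end)),
        rng_seed=int(overrides.pop("rng_seed", 0)),
        snapshot_every=float(overrides.pop("snapshot_every", default_snap)),
        **overrides,  # unknown keys fail loudly in the dataclass
    )


_KNOWN_KEYS = {
    "preset",
    "smin",
    "smax",
    "schedule",
    "nu",
    "dt",
    "delta_sub",
    "l_br",
    "theta_deg",
    "t_end",
    "rng_seed",
    "snapshot_every",
    "xi_variant",
}


def load_config(path: str | Path) -> SimulationConfig:
    """Parse a flat YAML configuration into a SimulationConfig.

    Defaults: dt = 0.1 yr, and the derived quantities (delta_fuse,
    epsilon, alpha) follow from delta_sub, l_br and nu*dt.  Either a
    ``preset`` key, ``smin``/``smax``, or an explicit ``schedule`` (list of
    [t_start, smin, smax]) must define the growth mode.  Unknown keys and
    every invalid value are reported together.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    errors = [f"unknown key: {k}" for k in raw if k not in _KNOWN_KEYS]

    def grab(key, default=None, cast=float):
        if key not in raw:
            return default
        try:
            return cast(raw[key])
        except (TypeError, ValueError):
            errors.append(f"invalid value for {key}: {raw[key]!r}")
            return default

    base = None
    if "preset" in raw:
        try:
            base = preset(str(raw["preset"]))
        except ConfigError as e:
            errors.append(str(e))

    schedule = base.schedule if base is not None else None
    if "schedule" in raw:
        try:
            schedule = GrowthSchedule(
                [(float(t), GrowthMode(float(a), float(b))) for t, a, b in raw["schedule"]]
            )
        except (TypeError, ValueError) as e:
            errors.append(f"invalid schedule: {e}")
    elif "smin" in raw or "smax" in raw:
        smin = grab("smin", 0.0)
        smax = grab("smax", 1.0)
        try:
            schedule = GrowthSchedule.constant(GrowthMode(smin, smax))
        except ValueError as e:
            errors.append(str(e))
    if schedule is None:
        errors.append("growth mode missing: give preset, smin/smax, or schedule")

    nu = grab("nu", base.growth.nu if base else 10.0)
    dt = grab("dt", base.growth.dt if base else 0.1)
    xi_variant = grab(
        "xi_variant", base.growth.xi_variant if base else "elevation", str
    )
    delta_sub = grab("delta_sub", base.clone.delta_sub if base else 10.0)
    t_end = grab("t_end", base.t_end if base else 6.0)
    rng_seed = grab("rng_seed", base.rng_seed if base else 0, int)
    snapshot_every = grab(
        "snapshot_every", base.snapshot_every if base else 2.0
    )

    branch = base.branch if base is not None else None
    if "l_br" in raw or "theta_deg" in raw:
        l_br = grab("l_br", branch.l_br if branch else None)
        theta = grab("theta_deg", branch.theta_deg if branch else 30.0)
        if l_br is None:
            errors.append("theta_deg given without l_br")
        else:
            try:
                branch = BranchParams(l_br=l_br, theta_deg=theta)
            except ValueError as e:
                errors.append(str(e))

    growth = clone = None
    try:
        growth = GrowthParams(nu=nu, dt=dt, xi_variant=xi_variant)
    except ValueError as e:
        errors.append(str(e))
    try:
        clone = CloneParams(delta_sub=delta_sub)
    except ValueError as e:
        errors.append(str(e))

    if errors:
        raise ConfigError("; ".join(errors))
    try:
        return SimulationConfig(
            schedule=schedule,
            growth=growth,
            clone=clone,
            branch=branch,
            t_end=t_end,
            rng_seed=rng_seed,
            snapshot_every=snapshot_every,
        )
    except ValueError as e:
        raise ConfigError(str(e)) from e


def dump_config(config: SimulationConfig, path: str | Path) -> None:
    """Write a configuration back to flat YAML (round-trips with load_config)."""
    out: dict = {
        "schedule": [
            [float(t), float(m.smin), float(m.smax)]
            for t, m in config.schedule.entries
        ],
        "nu": float(config.growth.nu),
        "dt": float(config.growth.dt),
        "xi_variant": config.growth.xi_variant,
        "delta_sub": float(config.clone.delta_sub),
        "t_end": float(config.t_end),
        "rng_seed": int(config.rng_seed),
        "snapshot_every": float(config.snapshot_every),
    }
    if config.branch is not None:
        out["l_br"] = float(config.branch.l_br)
        out["theta_deg"] = float(config.branch.theta_deg)
    Path(path).write_text(yaml.safe_dump(out, sort_keys=False))


# --------------------------------------------------------------------- #
# mesh serialization


def export_mesh(state: ColonyState, path: str | Path, fmt: str | None = None) -> None:
    """Write the colony surface as OBJ, ascii PLY, or ascii STL.

    OBJ and STL carry geometry only; PLY additionally stores the
    per-vertex polyp attributes is_base, is_leader and xi.
    """
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    mesh = state.mesh
    ids, pos, fidx = mesh.arrays()
    if fmt == "obj":
        lines = [f"v {p[0]:.9f} {p[1]:.9f} {p[2]:.9f}" for p in pos]
        lines += [f"f {a + 1} {b + 1} {c + 1}" for a, b, c in fidx]
        path.write_text("\n".join(lines) + "\n")
    elif fmt == "ply":
        _, normals = mesh.vertex_normals()
        xi = xi_values(normals)
        header = [
            "ply",
            "format ascii 1.0",
            f"element vertex {len(ids)}",
            "property float x",
            "property float y",
            "property float z",
            "property uchar is_base",
            "property uchar is_leader",
            "property float xi",
            f"element face {len(fidx)}",
            "property list uchar int vertex_indices",
            "end_header",
        ]
        body = [
            f"{p[0]:.9f} {p[1]:.9f} {p[2]:.9f} "
            f"{int(mesh.is_base(v))} {int(mesh.is_leader(v))} {x:.6f}"
            for v, p, x in zip(ids, pos, xi)
        ]
        body += [f"3 {a} {b} {c}" for a, b, c in fidx]
        path.write_text("\n".join(header + body) + "\n")
    elif fmt == "stl":
        tm = trimesh.Trimesh(vertices=pos, faces=fidx, process=False)
        from trimesh.exchange.stl import export_stl_ascii

        path.write_text(export_stl_ascii(tm))
    else:
        raise ValueError(f"unsupported mesh format {fmt!r}")


def import_mesh(path: str | Path) -> ColonyMesh:
    """Read an OBJ or PLY file back into a ColonyMesh.

    PLY restores the is_base / is_leader flags; OBJ is read through
    trimesh and yields geometry only.
    """
    path = Path(path)
    fmt = path.suffix.lstrip(".").lower()
    mesh = ColonyMesh()
    if fmt == "ply":
        verts, faces = _read_ply_ascii(path)
        vids = [
            mesh.add_vertex((x, y, z), is_base=bool(b), is_leader=bool(l))
            for x, y, z, b, l in verts
        ]
        for a, b, c in faces:
            mesh.add_face(vids[a], vids[b], vids[c])
        return mesh
    tm = trimesh.load(path, process=False, maintain_order=True)
    vids = [mesh.add_vertex(p) for p in np.asarray(tm.vertices, dtype=float)]
    for a, b, c in np.asarray(tm.faces, dtype=int):
        mesh.add_face(vids[a], vids[b], vids[c])
    return mesh


def _read_ply_ascii(path: Path):
    lines = path.read_text().splitlines()
    n_vert = n_face = 0
    props: list[str] = []
    i = 0
    element = None
    for i, line in enumerate(lines):
        tok = line.split()
        if not tok:
            continue
        if tok[0] == "element":
            element = tok[1]
            if element == "vertex":
                n_vert = int(tok[2])
            elif element == "face":
                n_face = int(tok[2])
        elif tok[0] == "property" and element == "vertex" and tok[1] != "list":
            props.append(tok[2])
        elif tok[0] == "end_header":
            break
    body = lines[i + 1 :]
    verts = []
    idx = {name: j for j, name in enumerate(props)}
    for line in body[:n_vert]:
        f = line.split()
        verts.append(
            (
                float(f[idx["x"]]),
                float(f[idx["y"]]),
                float(f[idx["z"]]),
                int(f[idx["is_base"]]) if "is_base" in idx else 0,
                int(f[idx["is_leader"]]) if "is_leader" in idx else 0,
            )
        )
    faces = []
    for line in body[n_vert : n_vert + n_face]:
        f = [int(x) for x in line.split()]
        if f[0] != 3:
            raise ValueError("only triangular PLY faces are supported")
        faces.append((f[1], f[2], f[3]))
    return verts, faces
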