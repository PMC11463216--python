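# coralclone

An agent-based simulator of clonal growth in scleractinian (stony) coral
colonies. Polyps — the individual animals of the colony — are the vertices
of a triangular surface mesh; the surface is the living tissue sheet
covering the skeleton. Five parameters reproduce the most common colony
morphologies found on reefs: **massive** (hemispherical domes), **cauliflower**
(inverted cones), **columnar** (pillars), **branching** (*Acropora*-like
ramified structures with apical dominance), **tabular** (stem topped by a
horizontal disc), and the **encrusting** limit (flat sheets) — plus hybrid
forms from custom growth schedules.

Intended for coral-reef modellers, theoretical morphologists, and anyone
needing plausible synthetic colony geometry (e.g. for restoration design or
hydrodynamic studies).

## Model in brief

Starting from a hexagonal-pyramid seed, each time step `Δt` applies:

- **Surface accretion** — every polyp with unit surface normal
  `n̂ = (nx, ny, nz)` carries the normalized elevation angle
  `ξ(n̂) = (2/π)·arctan(nz/√(nx²+ny²)) ∈ [−1, 1]` (1 = facing up,
  0 = facing sideways). The *growth mode* `s = [smin, smax]` gates growth:
  a polyp at `V` relocates to `V + α·n̂` with `α = ν·Δt` iff
  `smin ≤ ξ ≤ smax`. Substrate polyps grow horizontally only (so `ξ = 0`),
  anchoring the base whenever `smin > 0`.
- **Cloning** — neighbours further apart than `δsub` bud a clone between
  them, placed on a cubic Bézier arc fitted to the local surface
  (de Casteljau evaluation).
- **Fusion** — polyps closer than `δfuse = 0.2·δsub` fuse.
- **Self-regulated branching** — polyps at distance `lbr ± 0.25·lbr` from
  existing branching nodes become branch *leaders* with probability rate
  `pbr = ν/(lbr·Nbr)` per year (`Nbr` = current branch count); a new leader
  is kicked `4α` along its branch axis at angle `θ` to the parent branch
  and then elongates persistently at `ν` (apical dominance).

The five parameters: growth mode `s`, elongation rate `ν` (mm/yr),
subdivision distance `δsub` (mm), inter-branching distance `lbr` (mm),
branching angle `θ` (deg). See `docs/methods.md` for the full account.

## Worked example

Grow a massive colony (`s = [0, 1]`, `ν = 10 mm/yr`, `δsub = 10 mm`) for
six simulated years and write snapshot meshes plus a metrics table:

```sh
coralclone run --preset massive --out demo/
```

`demo/metrics.csv`:

```text
t,n_polyps,mean_interpolyp,mean_degree,height,max_radius,n_branches,mean_branch_diameter
2.0,150,6.471798926922626,5.714285714285714,24.973387730936622,29.99969361398816,0,
4.0,461,6.330223467129675,5.868735083532219,44.918135749313016,49.999114090646046,0,
6.0,903,6.421013475903081,5.91527446300716,64.8902806505874,69.99755221635851,0,
```

Read: at t = 6 yr the colony has 903 polyps; height 64.9 mm ≈ `ν·t + δsub/2`
and radius 70.0 mm give the height/radius ratio ≈ 0.93 of a hemispherical
dome; the mean inter-polyp distance has settled at 6.4 mm ≈ 0.64·δsub
(polyp spacing is slaved to the subdivision distance); and the mean
neighbour count 5.9 shows the emergent hexagonal tiling of the surface.
Snapshot meshes (`colony_t2.obj`, …) open in any 3-D viewer; PLY export
additionally stores the per-polyp `is_base` / `is_leader` / `xi`
attributes.

Other subcommands:

```sh
coralclone run --preset branching --seed 1 --out br/   # 32-yr ramified colony
coralclone sweep --preset massive --delta-sub 2.5,5,10,20 --out sw/
coralclone metrics --mesh br/colony_t32.obj
```

The same functionality is available as a library (`coralclone.preset`,
`coralclone.run`, `coralclone.run_sweep`, ...), and custom YAML configs
(`coralclone run --config my.yaml`) support arbitrary growth-mode
schedules, e.g. hybrid morphologies.

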