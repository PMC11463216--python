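# Methods

## Model

`coralclone` simulates the clonal growth of a scleractinian coral colony as
an agent-based process on a manifold triangular mesh. Each vertex is a
polyp; the triangulated surface is the coenosarc covering the calcium
carbonate skeleton; the interior of the surface is implicitly the skeleton.
The colony starts from a hexagonal pyramid (the "hexacone"): the apex is the
sexually produced founder polyp, the six base vertices its first clone
generation (hexacorals organize in multiples of six). Base side length is
`delta_sub`, pyramid height `delta_sub / 2`. The substrate is not meshed:
the rim of base vertices is the mesh boundary, so the colony has disk
topology (Euler characteristic 1) throughout its life.

Each time step `dt` applies four processes in a fixed order:

1. **Surface accretion.** Every polyp carries the normalized elevation angle
   of its unit surface normal `n = (nx, ny, nz)`,

       xi(n) = (2/pi) * arctan( nz / sqrt(nx^2 + ny^2) )  in [-1, 1],

   equal to 1 facing straight up, 0 facing horizontally, negative facing
   down. The growth mode `s = [smin, smax]` gates accretion: a polyp at `V`
   relocates to `V + alpha * n`, `alpha = nu * dt`, iff
   `smin <= xi <= smax` (closed interval). Substrate polyps use their
   normal with the vertical component suppressed, making their xi exactly
   0: they expand horizontally iff `smin = 0`, which anchors the colony
   base for every mode with `smin > 0` without a special case.
2. **Leader elongation** (branching runs): leader polyps advance `alpha`
   along their branch axis, bypassing the gate (apical dominance).
3. **Polyp cloning.** Edges longer than `delta_sub` are split at the
   midpoint of a cubic Bezier arc interpolating the endpoint polyps and
   their normals (de Casteljau evaluation), iterated to quiescence so the
   mesh leaves every step with max edge `<= delta_sub`.
4. **Polyp fusion.** Edges shorter than `delta_fuse = 0.2 * delta_sub`
   collapse (one pass), removing polyps and the thin triangles growth
   produces.
5. **Branch recruitment** (branching runs): see below.

## The xi functional

The model's published formula for the growth functional is internally
inconsistent with its stated limits (value 1 for a fully vertical normal, 0
for a fully horizontal one); the variant printed maps vertical to 0. This
package uses the normalized elevation angle above, which satisfies both
limits, is strictly increasing in `nz` at fixed horizontal magnitude, and
reproduces every documented morphotype. The alternative printed form is
retained as `xi_variant="as_printed"` in `GrowthParams` for comparison.

## Gate semantics

The interval form `smin <= xi <= smax` is used (closed at both ends). This
subsumes the one-sided constraint `xi < s` and matches all morphotype
parameterizations: massive `[0, 1]`, cauliflower `[0.01, 1]`, columnar
`[0.375, 1]`, tabular `[0.30, 1]` switching to `[0, 0.24]` at t = 3 yr,
encrusting `[0, 0]`. Displacements are synchronous: all normals are
evaluated on the pre-step geometry, so the result is independent of vertex
ordering and non-branching runs are bit-identical across RNG seeds.

## Cloning geometry

The Bezier control points are `P0 = A`, `P3 = B`, with `P1` (`P2`) a third
of the chord length along the unit projection of the chord onto the tangent
plane of the normal at `A` (`B`). Handle length `L/3` reproduces a circular
arc's bulge to second order; on flat regions the construction degenerates
exactly to the chord midpoint. The clone inherits the substrate flag only
when both parents are substrate polyps (z then forced to 0) and never
inherits leadership. Splits are applied longest-edge-first, collapses
shortest-first, ties broken by vertex id — runs are deterministic given the
mesh.

Fusion survivor policy: a leader absorbs a non-leader at the leader's
position (branch tips must survive fusion); a base polyp absorbs a non-base
polyp at the base position (keeps the substrate rim intact); otherwise the
midpoint. Collapses are refused — silently, as a no-op — when the link
condition fails, when an interior edge joins two boundary vertices (rim
pinch), or when the collapse would strand a vertex with no incident faces
(e.g. the last triangle of a patch); all three refusals preserve
manifoldness under arbitrary operation sequences.

## Self-regulated branching

The trunk is branch 0: at t = 0 the seed apex is flagged leader with axis
+z, so the branch count `N_br >= 1` always. Candidates for new leaders are
non-leader, non-base polyps whose Euclidean distance to the *nearest*
branching node lies in `[l_br - eps, l_br + eps]`, `eps = 0.25 * l_br`
(being nearest keeps candidates out of every branch's inner exclusion
zone). Each candidate is selected independently per step with probability
`min(1, p_br * dt)`, where `p_br = nu / (l_br * N_br)` is a rate in 1/yr
evaluated with the branch count at step entry. A selected polyp takes the
nearest *entry* node as parent — vetting and parenting against the same
node set is what guarantees every node-to-parent internode distance lies in
the selection band. Its branch axis makes angle `theta` with the parent
axis, sharing the polyp normal's azimuth around that axis (degenerate
azimuth: drawn uniformly from the seeded RNG). The new leader is kicked
`4 * alpha` along the axis and then elongates persistently at `nu`: a
one-time kick alone cannot sustain a branch at large `theta` under a
columnar gate, so persistent leader growth plus the initial kick is the
adopted reading. Leaders are excluded from candidacy and never stop.

A single RNG stream owned by the colony state is consumed in a fixed
documented order (candidate draws in ascending vertex id, then any
azimuth tie-breaks), making branching runs reproducible bit-for-bit.

## Parameters

| parameter    | meaning                          | unit   | default  |
|--------------|----------------------------------|--------|----------|
| `smin, smax` | growth-mode gate on xi           | —      | preset   |
| `nu`         | linear elongation rate           | mm/yr  | 10       |
| `delta_sub`  | maximal inter-polyp distance     | mm     | 10       |
| `l_br`       | mean inter-branching distance    | mm     | 40       |
| `theta`      | branch angle from parent axis    | deg    | 30       |
| `dt`         | time step                        | yr     | 0.1      |

Derived, never set independently: `alpha = nu * dt`,
`delta_fuse = 0.2 * delta_sub`, `eps = 0.25 * l_br`, kick `4 * alpha`.
Presets run 6 yr (branching: 32 yr, the duration needed for a tall enough
structure to measure branch statistics).

## Morphometrics

Mean inter-polyp distance is the mean mesh edge length. Mean neighbour
count averages vertex degree over non-boundary vertices only: rim degree is
an artefact of the open base, and excluding it isolates the surface-tiling
property. Height is max z; horizontal extent is max cylindrical radius
about the z-axis. Branch diameter cuts the mesh with planes perpendicular
to the branch axis at evenly spaced stations (excluding one `delta_sub` at
each end), keeps the connected intersection loop nearest the axis, and
takes twice the mean radial distance of its points, averaged over stations.

A metric counts as stabilized when its spread over 10 consecutive steps is
below 1% of its mean, evaluated no earlier than t = 3 yr (so the seed
transient cannot trigger it) and capped at t = 12 yr; those bounds are this
package's choice of stabilization window. Sweep regressions are ordinary
least squares with intercept, pooled across morphotypes.

The midpoint-subdivision steady state explains the observed scaling: edges
stretch multiplicatively under accretion and halve when they exceed
`delta_sub`, so edge lengths approach a log-uniform distribution on
`[delta_sub/2, delta_sub]` with mean `(delta_sub/2)/ln 2 = 0.721 *
delta_sub`. The simulated pooled slope comes out slightly lower (~0.66)
because splits also create new cross edges below that band and fusion
trims the short tail.

## What the simulations do and do not show

All experiments here are synthetic colonies grown from the hexacone seed
under spatially uniform parameters. They demonstrate the emergent
morphotypes, the hexagonal tiling (mean neighbour count just under six —
curvature forces occasional pentagons), internode regularity, and the
parameter sensitivities. They do not model environmental modulation
(light, flow, nutrients), per-polyp parameter stochasticity, branch
collision or anastomosis — real colonies exhibit all of these, so
quantitative agreement with field colonies beyond the measured aggregate
statistics is not implied.

## Numerical choices and degenerate inputs

- Vertex normals are area-weighted averages of incident face normals
  (the sum of face cross products), the default notion in standard
  geometry-processing libraries; angle weighting would also be defensible
  but one convention must be fixed.
- `xi` requires unit input within 1e-9 and handles the poles explicitly;
  vertical-normal base polyps fall back to the outward radial direction.
- A Bezier handle degenerates to its endpoint when the edge is parallel to
  the normal.
- Cloning re-collects edges for at most 20 passes; exceeding the cap raises
  rather than looping on runaway geometry.
- Leaders never collapse into each other, and a leader-base collapse is
  refused outright (no survivor could satisfy both roles).

## Known limitations

- Branches do not detect collisions; dense parameterizations
  (small `l_br`, large `theta`, long runs) can self-intersect.
- The cauliflower morphotype reproduces the inverted-cone envelope but not
  the leaderless rounded ramification of real cauliflower corals; that
  requires an accretive-growth extension out of scope here.
- Encrusting colonies keep a residual tent of height `delta_sub / 2`
  inherited from the seed; only the base ring expands.
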