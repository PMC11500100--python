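# Methods

## Model overview

`fibresim` simulates a 2D tissue domain containing two kinds of off-lattice
agents: circular motile **cells** and rod-shaped **fibres** representing
extracellular-matrix elements such as collagen.  Fibres are thin cylinders
(typical collagen: 75 um long, 2 um radius) handled as closed line segments
with a nominal radius.  Dynamics are overdamped and centre-based: pairwise
potentials contribute directly to velocities (um/min), and positions are
integrated by forward Euler at the mechanics timestep (default 0.1 min).
There is no inertia and no fibre–fibre mechanics; fibres interact with each
other only through cross-link bookkeeping.

## Fibre initialisation

Each attempted fibre draws, in a fixed order from one global RNG stream:
centre (uniform over the domain), length and radius (normal, truncated below
at 0.1 um to avoid degenerate rods; exact means when the sds are zero), and
orientation angle (uniform on [0, 2pi) for an isotropic field, otherwise
normal about the prescribed mean angle).  A fibre whose axis endpoints are
not both inside the closed domain is disregarded; in the isotropic case it
receives up to ten fresh orientations (centre, length and radius fixed)
before being permanently discarded; anisotropic fibres are discarded
immediately, since redrawing a prescribed angle cannot help.  Containment
uses the axis endpoints only, matching the line-based visualisation.  The
procedure thins fibre density near the boundary and can align fibres with
it; this is accepted as-is because the behaviours of interest happen in the
domain interior.

## Geometry

* Nearest point on a fibre: clamped scalar projection onto the axis.
* Fibre–fibre closest approach: closed-form clamped parametric
  segment–segment distance (sampling is used only as a test oracle).
* Cross-link criterion: two fibres cross-link when the minimum axis–axis
  distance is at most the sum of their radii, so cylinders of finite girth
  can touch without their axes crossing.  The contact point is the midpoint
  of the closest-approach pair (the intersection point for crossing axes).
* Voxel rasterisation: a fibre registers to every voxel whose closed square
  intersects its axis, computed by slab clipping with inclusive ownership —
  an axis running along a voxel boundary registers to both sides.
  Over-registration is harmless for neighbour finding; under-registration
  would silently drop interactions.

## Neighbour search

Agents live on a uniform square voxel grid (default 30 um).  Cells register
to the voxel of their centre; fibres, at the start of every mechanics pass,
to every voxel their axis crosses, and after force evaluation they
de-register back to their centre voxel.  Neighbours are all agents
registered in the agent's voxels or within `adjacency_rings` surrounding
rings.  The default is two rings (a 5x5 block): one ring guarantees capture
only up to one voxel size of *axis* distance, which for 10-um cells against
2-um fibres is insufficient to guarantee finding every pair within one
voxel size of capsule distance (axis distance minus radii); two rings
guarantee capture to twice the voxel size, which covers it with a wide
margin for all parameter ranges used here.  Over-inclusion is safe because
every force is range-gated.

## Cell mechanics

Cell–cell contacts use the standard piecewise-quadratic pair force:
repulsion `c_r (1 - d/R)^2` inside the summed radii `R`, adhesion
`-c_a (1 - d/R_A)^2` out to `R_A = 1.25 R`, zero beyond.  Coefficients of
unlike definitions combine as geometric means so the pair force is exactly
antisymmetric.  Coincident centres fall back to a deterministic +x
repulsion direction.

Cell–fibre contacts reuse the same form against the nearest axis point
(with the fibre radius as partner radius), plus two fibre-directed terms
evaluated at the cell's previous-step velocity `v` against the fibre axis
direction `f`:

* adhesive pull along the fibre,
  `F_par = alpha (1 - |v|/v_max) (|v.f|/|v|)^s f`,
* frictional repulsion along the velocity,
  `F_perp = beta ((|v|^2 - |v.f|^2)/|v|^2)^(r/2) v`,

with net contribution `F_par - F_perp` added inside the adhesion range.
Defaults `s = 1`, `r = 2`.  Speeds above `v_max` clamp the pulling
prefactor to zero rather than erroring, since transient overshoot occurs
while forces assemble.  The axis sign is taken aligned with `v` (`f -> -f`
when `v.f < 0`): the scalar magnitude is unchanged (it depends on `|v.f|`),
and the pull then acts along the projection of the velocity onto the axis,
which is what lets cells track along a fibre in either direction.

## Fibre response to cells

A fibre responds to a contacting cell only if it has at most one
cross-link; with two or more it is considered tethered by the network and
fixed in place.  With `fibre_pushing` on, the fibre centre translates by
the cell->fibre repulsion scaled by the fibre's `fibre_sticky` and the
timestep; a push that would carry an endpoint outside the domain is
rejected, so fibres never leave.  With `fibre_rotation` on, the fibre spins
about its fixed centre by one rotation per mechanics step of magnitude
`omega = J / (0.5 L^2)` with impulse `J = k v M`, moment arm
`M = |p|` where `p` is the point of impact (nearest axis point to the cell)
relative to the fibre centre, `k` the fibre's stickiness and `v` the cell's
migration speed.  The sense of rotation comes from the sign of the 2D cross
product of `p` with the cell velocity — the only torque-consistent choice
in 2D; a zero cross product (velocity through the centre line) produces no
rotation.  `omega` is treated as radians per mechanics step; the units are
model-internal.  A consequence of the `M`-dependence is that impacts near a
fibre end rotate the fibre faster than impacts near its centre.  Pushing
and rotation may both act in the same step when both flags are set.

## Pressure and degradation

Each cell carries a dimensionless overlap pressure,
`sum (1 - d/R)^2` over contacting neighbours (centre–centre distance for
cells, centre-to-axis for fibres), zero when isolated.  A cell whose speed
stays below `fibre_stuck_threshold` (um/min, compared against the velocity
magnitude) accumulates a stuck counter in mechanics timesteps, reset the
moment the speed recovers.

Degradation removes fibres whole and instantly.  Per step each degrading
cell makes at most one removal attempt, choosing a target by two routes:

* **stuck route** — once the counter reaches `fibre_stuck_time`, the
  nearest neighbouring fibre *in the cell's path* (motility vector dotted
  with the vector to the nearest axis point strictly positive);
* **pressure route** (active with `fibre_custom_degradation`) — when the
  pressure exceeds `fibre_pressure_threshold`, the nearest contacting
  fibre.

The eligible fibre is removed with probability
`min(1, fibre_degradation_rate * dt_mech)` — the standard rate-to-
probability discretisation of a Poisson removal rate.  Removal de-registers
the fibre and decrements each cross-linked partner's count by one.  There
is no fibrogenesis, so the fibre count never increases.

## Substrate and chemotaxis

A single scalar attractant lives on the voxel grid: constant-rate secretion
into the secreting cell's voxel, explicit 5-point-stencil diffusion with
zero-flux boundaries and first-order decay, substepped at `dt_diffusion`
(validated against the stability bound `h^2/(4D)` at configuration time).
Chemotactic cells set their motility vector to the normalised
central-difference gradient at their voxel; a flat field leaves the heading
unchanged.  This is a deliberately minimal scheme — single substrate, no
uptake, no implicit solver — sufficient for the bundled chemotaxis
scenarios at their small scale.

## Step ordering

Per mechanics step: diffusion substeps; chemotaxis update; full fibre
registration; cross-link recomputation; cell velocity assembly (including
pressure and stuck counters); fibre pushing/rotation; degradation pass;
Euler integration of cell positions (clamped to the domain); fibre
de-registration.  Cross-links are recomputed only when some fibre has
moved, rotated or been removed since the last computation — the result is
bit-identical to recomputing every step, since nothing else can change it.
All randomness flows through one seeded generator with a documented draw
order, so a fixed seed yields bitwise-identical snapshot CSVs.

## Bundled scenarios and what they do (and do not) show

* **Initialisation fields** — 2,000 attempted fibres (75 x 2 um) in an
  800 x 800 um domain, isotropic / aligned at 0.2 rad / aligned with sd
  0.15 rad.  Because of boundary rejection the accepted count is always
  strictly below 2,000, and lower for aligned fields (no reorientation
  retries).
* **Rotation scenario** — five 30-um vertical fibres with 5-um tip gaps
  (so none cross-link and all remain rotation-eligible) form a barrier
  between a chemotactic cell and an attractant-secreting cell 120 um apart.
  With `fibre_rotation` on, the cell reaches the barrier, swings a fibre
  aside and crosses.
* **Degradation scenario** — a column of touching 40-um vertical fibres
  spans the domain (tip-to-tip contacts cross-link them, so the wall is
  both immobile and impassable: the gaps are far below a cell diameter),
  plus 60 random background fibres, between a chemotactic cell and the
  source 300 um apart.  With stuck-based degradation the cell chews through
  the wall and closes to within a cell diameter of the source well inside
  16 simulated hours; with degradation off it never passes the wall.  The
  wall is a designed construction rather than a purely random field, since
  a sparse random field cannot guarantee impassability.
* **Pressure pair** — a square fibre cage (each side cross-linked twice at
  its corners) around seven pre-seeded overlapping cells, in two variants
  differing only in `fibre_custom_degradation`.  The cluster is pre-seeded
  rather than proliferating: cell-cycle machinery is out of scope, and the
  pressure signal, not growth, is the object of the comparison.

Mechanics/degradation parameter values in these fixtures (adhesion 0.6 /
0.1, friction 0.3 / 0.2, `v_max` 10 um/min, migration speed 1 um/min,
stickiness 1, stuck time 30 steps, stuck threshold 0.5 um/min, degradation
rate 1/min, attractant D = 800 um^2/min, decay 0.02/min, secretion
10/min) are this package's own choices on biologically plausible scales;
the geometry (fibre dimensions, counts, domain, angles) is fixed by the
published setups.  The synthetic fields emulate fibre geometry and
placement statistics only — they contain no fibre waviness, bundling,
crosslink elasticity or realistic collagen density, so passing tests show
internal consistency of the mechanics and rules, not quantitative fidelity
to real ECM.

## Numerical notes and limitations

* Forward Euler with potentials mapped straight to velocities; no
  multistep integration.  Large coefficients with large `dt_mech` can
  oscillate; the defaults are stable for the bundled scenarios.
* Segment geometry uses closed forms with 1e-9-scale tolerances; voxel
  ownership is inclusive at boundaries.
* Cells clamp to the domain walls; fibres cannot be pushed out.
* 2D only; fibre rotation and pushing have no 3D counterpart here.
* Fibres are removed whole — no partial cleavage, no MMP diffusion field,
  no fibre creation.
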