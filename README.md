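# fibresim

A 2D agent-based simulator of cells interacting mechanically with
extracellular-matrix (ECM) fibres.  Classic centre-based tissue simulators
represent every agent as a circle (or sphere); the fibrous scaffold that
real cells crawl along, push aside and digest has no such shape.  `fibresim`
adds a rod-shaped agent — a line segment with a nominal cylinder radius —
and the mechanics that couple rods to circular motile cells, for anyone
studying matrix-mediated processes such as cancer invasion, fibrosis or
wound healing at the single-cell scale.

## The model in brief

Dynamics are overdamped: potentials add straight into velocities and
positions follow by forward Euler.  A cell in contact with a fibre feels,
besides the usual piecewise-quadratic repulsion/adhesion against the
nearest axis point, two fibre-directed forces that make it track along the
fibre axis f̂:

    F_par  = α (1 − |v|/v_max) (|v·f̂|/|v|)^s f̂          (adhesive pull)
    F_perp = β ((|v|² − |v·f̂|²)/|v|²)^{r/2} v            (friction)
    F      = F_par − F_perp

A motile cell can also push a fibre and rotate it about its centre with
angular speed ω = J/(½L²), where the impulse J = k·v·M grows with the cell
speed v and the moment arm M from the fibre centre to the point of impact —
hitting a fibre near its end spins it faster than hitting the middle.
Fibres cross-link wherever they touch; a fibre with two or more cross-links
is tethered and immobile.  Cells that are stuck (speed below a threshold
for long enough) or over-pressured can degrade the fibre in their path at a
prescribed rate.  A minimal diffusing attractant field drives chemotaxis.
See `docs/methods.md` for the full account.

## Worked example

The bundled rotation scenario puts a vertical barrier of free fibres
between a chemotactic cell and an attractant-secreting cell:

```python
import numpy as np
from fibresim import Simulation
from fibresim.scenarios import make_rotation_scenario

sim = Simulation(make_rotation_scenario(), seed=1)
cell = next(c for c in sim.cells.values()
            if c.definition_name == "chemotactic_cell")
barrier = {fid: f.segment.angle for fid, f in sim.fibres.items()}
while sim.time < 120.0:
    sim.step()
    if cell.position[0] > 10.0:
        break
rotated = max(abs(f.segment.angle - barrier[fid])
              for fid, f in sim.fibres.items())
print(f"barrier crossed at t = {sim.time:.1f} min")
print(f"largest fibre rotation so far: {rotated:.2f} rad")
print(f"cell position: ({cell.position[0]:.1f}, {cell.position[1]:.1f}) um")
```

prints

```
barrier crossed at t = 69.7 min
largest fibre rotation so far: 1.28 rad
cell position: (10.2, 10.6) um
```

— the cell migrates up the attractant gradient, reaches the barrier,
swings the blocking fibre through about 73° and passes.  With
`fibre_rotation` off it stays pinned on the left side indefinitely.

The same scenarios are available as XML configuration files under
`config/` and through the CLI:

```
fibresim run config/Cell_Fibre_Mechanics/fibre_rotating.xml --seed 1 --out out/
fibresim init-only config/Fibre_Initialisation/mymodel_initialisation_isotropic.xml
```

Each run writes per-interval snapshots: `cells_*.csv`
(id,x,y,radius,pressure), `fibres_*.csv`
(id,x,y,angle,length,radius,n_crosslinks) and an SVG in which fibres are
coloured by cross-link count (lightskyblue 0, steelblue 1, blue 2,
darkblue ≥3) and cells optionally by pressure (blue low → red high).

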