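"""Cross-link bookkeeping, cell pressure and rule-based fibre degradation.

Fibres cross-link wherever they touch or intersect; the cross-link count
decides whether a fibre is free to move (<= 1) or tethered (>= 2).  Cells
accumulate a dimensionless overlap pressure from their contacts, and can
remove fibres from the domain by two routes:

* stuck-based: a cell whose speed has stayed below ``fibre_stuck_threshold``
  for at least ``fibre_stuck_time`` mechanics steps tries to degrade the
  nearest fibre *in its path* (motility vector pointing towards the fibre);
* pressure-based (the custom route): a cell whose pressure exceeds
  ``fibre_pressure_threshold`` tries to degrade the nearest contacting fibre.

An eligible fibre is removed with per-step probability
``min(1, fibre_degradation_rate * dt)``; removal is whole and instantaneous.
There is no fibrogenesis, so the fibre count never increases.
"""

from __future__ import annotations

import numpy as np

from .agents import CellAgent, FibreAgent
from .geometry import check_fibre_crosslinks, nearest_point_on_fibre
from .grid import VoxelGrid

__all__ = [
    "add_crosslinks",
    "compute_pressure",
    "fibre_in_path",
    "maybe_degrade",
    "remove_fibre",
]


def add_crosslinks(fibres: dict[int, FibreAgent], grid: VoxelGrid) -> None:
    """Recompute cross-link points for all fibres from neighbouring pairs.

    Requires all fibres to be fully registered in the grid.  Each
    neighbouring pair is checked exactly once; a contact contributes one
    cross-link point to each member of the pair.
    """
    for f in fibres.values():
        f.crosslink_points.clear()
        f.crosslink_partners.clear()
    for fid in sorted(fibres):
        f = fibres[fid]
        for nid in grid.find_agent_neighbors(f):
            if nid <= fid or nid not in fibres:
                continue
            other = fibres[nid]
            pt = check_fibre_crosslinks(f.segment, other.segment)
            if pt is not None:
                f.crosslink_points.append(pt)
                f.crosslink_partners.append(nid)
                other.crosslink_points.append(pt)
                other.crosslink_partners.append(fid)


def compute_pressure(c: CellAgent, cell_neighbours: list[CellAgent],
                     fibre_neighbours: list[FibreAgent]) -> float:
    """Overlap pressure: sum of (1 - d/R)^2 over contacting neighbours.

    ``d`` is the centre-centre distance for cells and the centre-to-axis
    distance for fibres; ``R`` the summed radii.  Zero for an isolated cell.
    """
    pressure = 0.0
    for other in cell_neighbours:
        d = float(np.hypot(*(c.position - other.position)))
        rad_sum = c.radius + other.radius
        if d < rad_sum:
            pressure += (1.0 - d / rad_sum) ** 2
    for f in fibre_neighbours:
        d = float(np.hypot(*(c.position - nearest_point_on_fibre(c.position, f.segment))))
        rad_sum = c.radius + f.segment.radius
        if d < rad_sum:
            pressure += (1.0 - d / rad_sum) ** 2
    return pressure


def fibre_in_path(c: CellAgent, f: FibreAgent) -> bool:
    """True iff the cell's motility vector points towards the fibre.

    Strict inequality: a fibre exactly orthogonal to the motility direction
    is not in the path.
    """
    nearest = nearest_point_on_fibre(c.position, f.segment)
    return float(np.dot(c.motility_vector, nearest - c.position)) > 0.0


def maybe_degrade(c: CellAgent, f: FibreAgent, rng: np.random.Generator,
                  dt: float, p=None) -> bool:
    """Bernoulli removal draw for an eligible fibre; True if it is removed.

    The per-step removal probability is ``min(1, fibre_degradation_rate * dt)``.
    The caller is responsible for eligibility (flags, stuck/pressure gates)
    and for the actual removal bookkeeping via :func:`remove_fibre`.
    """
    if p is None:
        p = c.fibre_params
    prob = min(1.0, p.fibre_degradation_rate * dt)
    if prob >= 1.0 or float(rng.random()) < prob:
        f.flagged_for_removal = True
        return True
    return False


def remove_fibre(f: FibreAgent, fibres: dict[int, FibreAgent], grid: VoxelGrid) -> None:
    """Remove a fibre whole: grid, registry and partners' cross-link counts."""
    grid.remove_fibre(f)
    for pid in f.crosslink_partners:
        partner = fibres.get(pid)
        if partner is None:
            continue
        for i, qid in enumerate(partner.crosslink_partners):
            if qid == f.id:
                partner.crosslink_partners.pop(i)
                partner.crosslink_points.pop(i)
                break
    fibres.pop(f.id, None)


def select_degradation_target(c: CellAgent, fibre_neighbours: list[FibreAgent],
                              p=None) -> FibreAgent | None:
    """Pick the fibre this cell would try to degrade this step, if any.

    Stuck route first (nearest in-path fibre once the stuck counter reaches
    ``fibre_stuck_time``); otherwise, when the custom route is on and the
    cell's pressure exceeds the threshold, the nearest contacting fibre.
    Returns None when no route is eligible.
    """
    if p is None:
        p = c.fibre_params
    if not p.fibre_degradation or not fibre_neighbours:
        return None

    def axis_distance(f: FibreAgent) -> float:
        return float(np.hypot(*(c.position - nearest_point_on_fibre(c.position, f.segment))))

    if c.stuck_counter >= p.fibre_stuck_time:
        in_path = [f for f in fibre_neighbours if fibre_in_path(c, f)]
        if in_path:
            return min(in_path, key=lambda f: (axis_distance(f), f.id))
    if p.fibre_custom_degradation and c.pressure > p.fibre_pressure_threshold:
        contacting = [f for f in fibre_neighbours
                      if axis_distance(f) < c.radius + f.segment.radius]
        if contacting:
            return min(contacting, key=lambda f: (axis_distance(f), f.id))
    return None
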