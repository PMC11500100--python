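"""Forces and velocity updates for cells and fibres.

Dynamics are overdamped, centre-based: pairwise potentials contribute
directly to agent velocities (um/min) and positions are integrated by
forward Euler at the mechanics timestep.

Cell-cell contacts use the standard piecewise-quadratic repulsion/adhesion
pair force.  Cell-fibre contacts reuse the same form against the nearest
point on the fibre axis, plus two fibre-directed terms that let cells track
along fibres:

* an adhesive pull parallel to the fibre axis,
  ``F_par = alpha * (1 - |v|/v_max) * (|v . f|/|v|)^s * f``
* a frictional repulsion parallel to the cell's own velocity,
  ``F_perp = beta * ((|v|^2 - |v . f|^2)/|v|^2)^(r/2) * v``

with the net extra force ``F = F_par - F_perp``.

A motile cell can, in turn, push (translate) and rotate a contacted fibre,
provided that fibre has at most one cross-link; with two or more cross-links
it is considered tethered by the network and fixed in place.  Rotation uses
moment arm ``M = |p|`` (p = point of impact relative to the fibre centre),
impulse ``J = k * v * M`` and angular velocity ``omega = J / (0.5 * L^2)``,
applied as one rotation per mechanics step about the fibre centre.
"""

from __future__ import annotations

import numpy as np

from .agents import CellAgent, CellFibreParams, FibreAgent
from .geometry import nearest_point_on_fibre
from .initialization import Domain

__all__ = [
    "cell_cell_potential",
    "force_parallel",
    "force_perpendicular",
    "add_potentials_from_fibre",
    "moment_arm",
    "impulse",
    "angular_velocity",
    "rotate_orientation",
    "add_potentials_from_cell",
    "update_cell_velocity",
]

_FALLBACK_DIR = np.array([1.0, 0.0])  # deterministic direction for coincident centres


def _repulsion_adhesion(disp: np.ndarray, d: float, rad_sum: float,
                        c_r: float, c_a: float, scale: float) -> np.ndarray:
    """Piecewise-quadratic pair contribution along ``disp`` (centre a - centre b)."""
    r_a = scale * rad_sum
    if d >= r_a:
        return np.zeros(2)
    direction = disp / d if d > 0 else _FALLBACK_DIR
    out = -c_a * (1.0 - d / r_a) ** 2 * direction
    if d < rad_sum:
        out = out + c_r * (1.0 - d / rad_sum) ** 2 * direction
    return out


def cell_cell_potential(a: CellAgent, b: CellAgent) -> np.ndarray:
    """Velocity contribution to ``a`` from contact with cell ``b``.

    Repulsion inside the summed radii R, adhesion out to scale*R, zero
    beyond.  Coefficients of the two definitions are combined as geometric
    means, so the pair force is antisymmetric: the contribution to ``b``
    from ``a`` is the exact negative.
    """
    disp = a.position - b.position
    d = float(np.hypot(*disp))
    c_r = float(np.sqrt(a.params.cell_cell_repulsion * b.params.cell_cell_repulsion))
    c_a = float(np.sqrt(a.params.cell_cell_adhesion * b.params.cell_cell_adhesion))
    scale = 0.5 * (a.params.adhesion_scale + b.params.adhesion_scale)
    return _repulsion_adhesion(disp, d, a.radius + b.radius, c_r, c_a, scale)


def force_parallel(v: np.ndarray, f_hat: np.ndarray, p: CellFibreParams) -> np.ndarray:
    """Adhesive force parallel to the fibre axis.

    Vanishes for a stationary cell, for v perpendicular to the axis, and at
    the speed cap (|v| >= v_max clamps the prefactor to zero).
    """
    speed = float(np.hypot(*v))
    if speed == 0.0:
        return np.zeros(2)
    ratio = min(speed / p.cell_velocity_max, 1.0)
    along = abs(float(np.dot(v, f_hat))) / speed
    return p.vel_adhesion * (1.0 - ratio) * along ** p.s_exponent * np.asarray(f_hat, dtype=float)


def force_perpendicular(v: np.ndarray, f_hat: np.ndarray, p: CellFibreParams) -> np.ndarray:
    """Frictional repulsion parallel to the cell's velocity.

    Scales with the normalised rejection of v from the fibre axis; vanishes
    for v parallel to the axis or a stationary cell.
    """
    v = np.asarray(v, dtype=float)
    speed2 = float(np.dot(v, v))
    if speed2 == 0.0:
        return np.zeros(2)
    rej = (speed2 - float(np.dot(v, f_hat)) ** 2) / speed2
    rej = min(max(rej, 0.0), 1.0)  # guard tiny negatives from rounding
    return p.vel_contact * rej ** (0.5 * p.r_exponent) * v


def add_potentials_from_fibre(c: CellAgent, f: FibreAgent,
                              p: CellFibreParams | None = None) -> np.ndarray:
    """Velocity contribution to cell ``c`` from neighbouring fibre ``f``.

    Repulsion/adhesion against the nearest axis point (fibre radius as the
    partner radius) keeps cells from crossing fibres; within the adhesion
    range the fibre-directed terms ``F_par - F_perp`` are added, evaluated at
    the cell's previous-step velocity.  The axis sign is taken aligned with
    that velocity so the pull acts along the projection of v onto the axis.
    """
    if p is None:
        p = c.fibre_params
    contact = nearest_point_on_fibre(c.position, f.segment)
    disp = c.position - contact
    d = float(np.hypot(*disp))
    rad_sum = c.radius + f.segment.radius
    scale = c.params.adhesion_scale
    if d >= scale * rad_sum:
        return np.zeros(2)
    out = _repulsion_adhesion(disp, d, rad_sum,
                              c.params.cell_cell_repulsion,
                              c.params.cell_cell_adhesion, scale)
    v = c.previous_velocity
    if float(np.hypot(*v)) > 0.0:
        f_hat = f.segment.orientation
        if float(np.dot(v, f_hat)) < 0.0:
            f_hat = -f_hat
        out = out + force_parallel(v, f_hat, p) - force_perpendicular(v, f_hat, p)
    return out


def moment_arm(p: np.ndarray) -> float:
    """Moment arm magnitude M = |p|, p relative to the fibre centre."""
    return float(np.hypot(p[0], p[1]))


def impulse(k: float, v: float, m: float) -> float:
    """Impulse J = k * v * M (fibre friction x migration speed x moment arm)."""
    if k < 0 or v < 0 or m < 0:
        raise ValueError("impulse arguments must be non-negative")
    return k * v * m


def angular_velocity(j: float, length: float) -> float:
    """Angular velocity omega = J / (0.5 * L^2) (rod moment of inertia, approx)."""
    if length <= 0:
        raise ValueError("fibre length must be positive")
    return j / (0.5 * length * length)


def rotate_orientation(o: np.ndarray, omega: float) -> np.ndarray:
    """Rotate a unit orientation vector by ``omega`` radians (norm preserved)."""
    c, s = np.cos(omega), np.sin(omega)
    out = np.array([o[0] * c - o[1] * s, o[0] * s + o[1] * c])
    return out / np.hypot(out[0], out[1])


def add_potentials_from_cell(f: FibreAgent, c: CellAgent,
                             p: CellFibreParams | None = None,
                             domain: Domain | None = None,
                             dt: float = 0.1) -> None:
    """Displace and/or rotate fibre ``f`` in response to contacting cell ``c``.

    No-op if the fibre has two or more cross-links (tethered), if the cell is
    out of contact range, or if both ``fibre_pushing`` and ``fibre_rotation``
    are off.  Pushing translates the centre by the cell->fibre repulsion
    scaled by the fibre's stickiness (rejected if an endpoint would leave the
    domain); rotation spins the orientation about the fixed centre, with the
    sense given by the 2D cross product of the moment arm with the cell
    velocity.
    """
    if p is None:
        p = c.fibre_params
    if f.n_crosslinks >= 2:
        return
    if not (p.fibre_pushing or p.fibre_rotation):
        return
    contact = nearest_point_on_fibre(c.position, f.segment)
    disp = contact - c.position
    d = float(np.hypot(*disp))
    rad_sum = c.radius + f.segment.radius
    if d >= rad_sum:
        return
    k = f.params.fibre_sticky

    if p.fibre_pushing:
        direction = disp / d if d > 0 else _FALLBACK_DIR
        speed = c.params.cell_cell_repulsion * (1.0 - d / rad_sum) ** 2
        dv = k * speed * dt * direction
        if domain is not None:
            moved = f.segment.centre + dv
            half = 0.5 * f.segment.length * f.segment.orientation
            if not (domain.contains(moved + half) and domain.contains(moved - half)):
                dv = None
        if dv is not None and (dv[0] != 0.0 or dv[1] != 0.0):
            f.translate(dv)

    if p.fibre_rotation:
        arm = contact - f.segment.centre
        m = moment_arm(arm)
        j = impulse(k, c.migration_speed, m)
        omega = angular_velocity(j, f.segment.length)
        cross = arm[0] * c.velocity[1] - arm[1] * c.velocity[0]
        omega *= float(np.sign(cross))
        if omega != 0.0:
            f.set_orientation(rotate_orientation(f.segment.orientation, omega))


def update_cell_velocity(c: CellAgent, cell_neighbours: list[CellAgent],
                         fibre_neighbours: list[FibreAgent],
                         p: CellFibreParams | None = None) -> np.ndarray:
    """Assemble the cell's velocity for this mechanics step.

    velocity = motility (migration_speed * motility_vector) + sum of
    cell-cell pair contributions + sum of cell-fibre contributions.  Also
    updates the cell's pressure and stuck counter.
    """
    from .remodelling import compute_pressure  # local import avoids a cycle

    if p is None:
        p = c.fibre_params
    v = c.migration_speed * np.asarray(c.motility_vector, dtype=float)
    for other in cell_neighbours:
        v = v + cell_cell_potential(c, other)
    for f in fibre_neighbours:
        v = v + add_potentials_from_fibre(c, f, p)
    c.pressure = compute_pressure(c, cell_neighbours, fibre_neighbours)
    c.velocity = v
    if float(np.hypot(*v)) < p.fibre_stuck_threshold:
        c.stuck_counter += 1
    else:
        c.stuck_counter = 0
    return v
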