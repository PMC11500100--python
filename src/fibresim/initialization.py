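"""Fibre and cell placement: sampling, containment checks and retries.

Fibres are placed by drawing a centre uniformly over the domain, then a
length, radius and orientation angle (each optionally normally distributed).
A fibre not wholly contained in the domain is disregarded; in the isotropic
case it is given up to ten fresh orientations (centre fixed) before being
permanently discarded.  This rejection step is why attempting N fibres
yields fewer than N accepted, and it thins fibre density near the boundary
(accepted as-is; behaviour of interest is far from the boundary).

Agent centres can also be read from a PhysiCell-style ``x,y,z,type`` CSV.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np

from .agents import FibreAgent, FibreParams
from .geometry import Segment

__all__ = ["Domain", "sample_fibre", "place_fibres", "read_positions_csv",
           "MAX_REORIENTATIONS", "MIN_DIMENSION"]

#: Maximum number of fresh orientations given to a not-contained fibre.
MAX_REORIENTATIONS = 10

#: Floor applied to normally-drawn lengths/radii to avoid degenerate rods.
MIN_DIMENSION = 0.1


@dataclass
class Domain:
    """Rectangular simulation domain with a uniform square voxel grid."""

    x_min: float
    x_max: float
    y_min: float
    y_max: float
    voxel_size: float = 30.0

    def __post_init__(self) -> None:
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise ValueError("domain extents must be positive")
        if not self.voxel_size > 0:
            raise ValueError("voxel_size must be positive")

    @property
    def nx(self) -> int:
        return max(1, int(np.ceil((self.x_max - self.x_min) / self.voxel_size - 1e-9)))

    @property
    def ny(self) -> int:
        return max(1, int(np.ceil((self.y_max - self.y_min) / self.voxel_size - 1e-9)))

    def contains(self, p) -> bool:
        """Closed containment: points on the boundary count as inside."""
        return bool(self.x_min <= p[0] <= self.x_max and self.y_min <= p[1] <= self.y_max)

    def voxel_of(self, p) -> tuple[int, int]:
        """Voxel index of a point, clamped to the grid."""
        i = int(np.floor((p[0] - self.x_min) / self.voxel_size))
        j = int(np.floor((p[1] - self.y_min) / self.voxel_size))
        return (min(max(i, 0), self.nx - 1), min(max(j, 0), self.ny - 1))

    def clamp(self, p) -> np.ndarray:
        return np.array([min(max(p[0], self.x_min), self.x_max),
                         min(max(p[1], self.y_min), self.y_max)])


def _draw_angle(params: FibreParams, rng: np.random.Generator) -> float:
    if params.anisotropic_fibres:
        if params.angle_normdist_sd > 0:
            return float(rng.normal(params.fibre_angle, params.angle_normdist_sd))
        return params.fibre_angle
    return float(rng.uniform(0.0, 2.0 * np.pi))


def sample_fibre(params: FibreParams, domain: Domain,
                 rng: np.random.Generator) -> Segment:
    """Draw one fibre: centre, length, radius, angle — in that fixed order.

    Lengths and radii are normal draws truncated below at
    :data:`MIN_DIMENSION`; with zero sds every fibre gets the exact mean.
    """
    cx = rng.uniform(domain.x_min, domain.x_max)
    cy = rng.uniform(domain.y_min, domain.y_max)
    length = params.fibre_length
    if params.length_normdist_sd > 0:
        length = max(MIN_DIMENSION, float(rng.normal(length, params.length_normdist_sd)))
    radius = params.fibre_radius
    if params.radius_normdist_sd > 0:
        radius = max(MIN_DIMENSION, float(rng.normal(radius, params.radius_normdist_sd)))
    angle = _draw_angle(params, rng)
    return Segment.from_angle((cx, cy), angle, length, radius)


def _contained(seg: Segment, domain: Domain) -> bool:
    return domain.contains(seg.start) and domain.contains(seg.end)


def place_fibres(n_attempted: int, params: FibreParams, domain: Domain,
                 rng: np.random.Generator, *, definition_name: str = "fibre",
                 id_start: int = 0, stats: dict | None = None) -> list[FibreAgent]:
    """Attempt to place ``n_attempted`` fibres; return the accepted ones.

    Each attempt draws a fibre; if both endpoints lie in the (closed) domain
    it is accepted.  Otherwise, for an isotropic field only, the orientation
    is redrawn (centre, length and radius fixed) up to
    :data:`MAX_REORIENTATIONS` times; a fibre still not contained — or any
    not-contained anisotropic fibre — is permanently discarded.

    ``stats``, if given, is filled with ``accepted``, ``discarded`` and
    ``reorientation_attempts`` (per attempted fibre).
    """
    if n_attempted < 0:
        raise ValueError("n_attempted must be non-negative")
    accepted: list[FibreAgent] = []
    retries_per_fibre: list[int] = []
    next_id = id_start
    for _ in range(n_attempted):
        seg = sample_fibre(params, domain, rng)
        retries = 0
        ok = _contained(seg, domain)
        if not ok and not params.anisotropic_fibres:
            while retries < MAX_REORIENTATIONS:
                retries += 1
                angle = _draw_angle(params, rng)
                seg = Segment.from_angle(seg.centre, angle, seg.length, seg.radius)
                if _contained(seg, domain):
                    ok = True
                    break
        retries_per_fibre.append(retries)
        if ok:
            accepted.append(FibreAgent(id=next_id, segment=seg,
                                       definition_name=definition_name,
                                       params=params))
            next_id += 1
    if stats is not None:
        stats["accepted"] = len(accepted)
        stats["discarded"] = n_attempted - len(accepted)
        stats["reorientation_attempts"] = retries_per_fibre
    return accepted


def read_positions_csv(path) -> list[tuple[float, float, str]]:
    """Parse a PhysiCell-style ``x,y,z,type`` CSV of agent centres.

    The header row is optional, ``z`` is ignored (2D).  Returns
    ``(x, y, definition_name)`` tuples; sampling of fibre length/radius/angle
    for fibre-typed rows is done by the caller with that definition's
    parameters.  A malformed row raises ``ValueError`` naming the line.
    """
    out: list[tuple[float, float, str]] = []
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh), start=1):
            if not row or all(not c.strip() for c in row):
                continue
            first = row[0].strip().lower()
            if lineno == 1 and first in ("x", "#x", "position_x"):
                continue
            if len(row) < 4:
                raise ValueError(f"line {lineno}: expected x,y,z,type, got {row!r}")
            try:
                x, y = float(row[0]), float(row[1])
                float(row[2])  # z, validated but unused in 2D
            except ValueError as exc:
                raise ValueError(f"line {lineno}: non-numeric coordinate in {row!r}") from exc
            name = row[3].strip()
            if not name:
                raise ValueError(f"line {lineno}: empty definition name")
            out.append((x, y, name))
    return out
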