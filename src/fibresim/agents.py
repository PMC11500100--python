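"""Agent classes and their parameter blocks.

Two agent kinds coexist on the same grid: rod-shaped fibres (line-segment
agents, obstacles that may be pushed, rotated or degraded) and circular
motile cells.  Which kind a definition produces is decided purely by its
name: any definition whose name contains one of the recognised substrings
{ecm, fiber, fibre, matrix, rod} is a fibre definition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import Segment

__all__ = [
    "FIBRE_NAME_TOKENS",
    "classify_definition",
    "FibreAgent",
    "CellAgent",
    "FibreParams",
    "CellParams",
    "CellFibreParams",
]

FIBRE_NAME_TOKENS = ("ecm", "fiber", "fibre", "matrix", "rod")


def classify_definition(name: str) -> str:
    """Classify an agent definition name as ``"fibre"`` or ``"cell"``.

    Case-insensitive substring match against :data:`FIBRE_NAME_TOKENS`.
    """
    if not name:
        raise ValueError("definition name must be non-empty")
    low = name.lower()
    return "fibre" if any(tok in low for tok in FIBRE_NAME_TOKENS) else "cell"


@dataclass
class FibreParams:
    """Per-definition fibre initialisation parameters.

    ``fibre_length``/``fibre_radius`` are the means of (optionally truncated)
    normal distributions with sds ``length_normdist_sd``/``radius_normdist_sd``;
    an sd of zero gives every fibre the exact mean value.  If
    ``anisotropic_fibres`` is set, orientation angles are drawn from
    Normal(fibre_angle, angle_normdist_sd); otherwise uniformly on [0, 2pi).
    ``fibre_sticky`` (k) scales the impulse a cell imparts when pushing or
    rotating a fibre.
    """

    fibre_length: float = 75.0
    length_normdist_sd: float = 0.0
    fibre_radius: float = 2.0
    radius_normdist_sd: float = 0.0
    anisotropic_fibres: bool = False
    fibre_angle: float = 0.0
    angle_normdist_sd: float = 0.0
    fibre_sticky: float = 1.0

    def __post_init__(self) -> None:
        if self.fibre_length <= 0 or self.fibre_radius <= 0:
            raise ValueError("fibre_length and fibre_radius must be positive")
        if self.length_normdist_sd < 0 or self.radius_normdist_sd < 0 \
                or self.angle_normdist_sd < 0:
            raise ValueError("standard deviations must be non-negative")


@dataclass
class CellParams:
    """Cell phenotype parameters (minimal subset: mechanics + motility)."""

    radius: float = 10.0
    migration_speed: float = 1.0  # um/min
    chemotactic: bool = False
    secretion_rate: float = 0.0  # substrate units per voxel per min
    cell_cell_repulsion: float = 10.0
    cell_cell_adhesion: float = 0.4
    adhesion_scale: float = 1.25  # adhesion range = scale * (r_a + r_b)


@dataclass
class CellFibreParams:
    """Cell-fibre interaction parameters (expressed per cell definition).

    ``vel_adhesion`` (alpha) and ``vel_contact`` (beta) control the additional
    adhesive force parallel to a contacted fibre and the frictional repulsion
    orthogonal to it; ``cell_velocity_max`` caps the pulling effect.  The
    exponents s and r shape the two force laws (defaults 1 and 2).  The
    remaining fields switch on fibre pushing/rotation by cells and the two
    degradation routes (stuck-based and pressure-based).
    """

    vel_adhesion: float = 0.0
    vel_contact: float = 0.0
    cell_velocity_max: float = 10.0
    s_exponent: float = 1.0
    r_exponent: float = 2.0
    fibre_pushing: bool = False
    fibre_rotation: bool = False
    fibre_degradation: bool = False
    fibre_custom_degradation: bool = False
    fibre_stuck_time: int = 50          # mechanics timesteps
    fibre_stuck_threshold: float = 0.5  # um/min
    fibre_pressure_threshold: float = 0.25
    fibre_degradation_rate: float = 1.0  # 1/min
    color_cells_by_pressure: bool = False

    def __post_init__(self) -> None:
        if not self.cell_velocity_max > 0:
            raise ValueError("cell_velocity_max must be positive")
        if not self.s_exponent > 0 or not self.r_exponent > 0:
            raise ValueError("s and r exponents must be positive")


@dataclass
class FibreAgent:
    """A rod-shaped matrix agent.

    Cross-link points are contact points with other fibres; a fibre with two
    or more cross-links is considered tethered by the network and is immobile
    under cell contact.  ``registered_voxels`` mirrors the grid occupancy for
    this fibre (all crossed voxels while the mechanics pass runs, the centre
    voxel only between passes).
    """

    id: int
    segment: Segment
    definition_name: str = "fibre"
    crosslink_points: list = field(default_factory=list)
    crosslink_partners: list = field(default_factory=list)
    registered_voxels: set = field(default_factory=set)
    flagged_for_removal: bool = False
    params: FibreParams = field(default_factory=FibreParams)
    _voxel_cache: set | None = field(default=None, repr=False, compare=False)

    @property
    def n_crosslinks(self) -> int:
        return len(self.crosslink_points)

    def invalidate_voxel_cache(self) -> None:
        self._voxel_cache = None

    def translate(self, dv: np.ndarray) -> None:
        self.segment.centre = self.segment.centre + dv
        self.invalidate_voxel_cache()

    def set_orientation(self, o: np.ndarray) -> None:
        self.segment.orientation = np.asarray(o, dtype=float)
        self.invalidate_voxel_cache()


@dataclass
class CellAgent:
    """A circular motile cell.

    ``motility_vector`` is the unit direction of active migration (set by
    chemotaxis for chemotactic cells); ``previous_velocity`` is the velocity
    of the last mechanics step, used when evaluating the fibre-directed force
    terms.  ``stuck_counter`` counts consecutive mechanics steps with speed
    below ``fibre_stuck_threshold`` and resets to zero the moment the speed
    recovers.
    """

    id: int
    position: np.ndarray
    radius: float = 10.0
    definition_name: str = "cell"
    velocity: np.ndarray = field(default_factory=lambda: np.zeros(2))
    previous_velocity: np.ndarray = field(default_factory=lambda: np.zeros(2))
    motility_vector: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0]))
    migration_speed: float = 0.0
    pressure: float = 0.0
    stuck_counter: int = 0
    params: CellParams = field(default_factory=CellParams)
    fibre_params: CellFibreParams = field(default_factory=CellFibreParams)

    def __post_init__(self) -> None:
        self.position = np.array(self.position, dtype=float)
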