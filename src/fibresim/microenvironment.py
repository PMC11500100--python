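"""Minimal diffusing-substrate field for chemotaxis scenarios.

A single scalar attractant lives on the same voxel grid as the agents.  It
is secreted at a constant rate in the secreting cell's voxel, spreads by
explicit 5-point-stencil diffusion with zero-flux boundaries, and decays at
a first-order rate.  Chemotactic cells steer their motility vector up the
local concentration gradient (central differences; a flat field leaves the
previous direction unchanged).

Units are model-internal: concentrations are dimensionless per voxel,
diffusion in um^2/min, decay in 1/min.  The explicit scheme requires
``dt <= h^2 / (4 D)``; this is validated when the simulation is configured.
"""

from __future__ import annotations

import numpy as np

from .agents import CellAgent
from .initialization import Domain

__all__ = ["SubstrateField", "chemotaxis_motility"]


class SubstrateField:
    """Scalar concentration field on the domain's voxel grid."""

    def __init__(self, domain: Domain, diffusion_coefficient: float = 800.0,
                 decay_rate: float = 0.02):
        if diffusion_coefficient < 0 or decay_rate < 0:
            raise ValueError("diffusion_coefficient and decay_rate must be non-negative")
        self.domain = domain
        self.diffusion_coefficient = diffusion_coefficient
        self.decay_rate = decay_rate
        self.concentrations = np.zeros((domain.nx, domain.ny))

    def stable_dt(self) -> float:
        """Largest stable explicit timestep, h^2 / (4 D)."""
        if self.diffusion_coefficient == 0:
            return np.inf
        return self.domain.voxel_size ** 2 / (4.0 * self.diffusion_coefficient)

    def check_dt(self, dt: float) -> None:
        if dt > self.stable_dt() + 1e-12:
            raise ValueError(
                f"dt_diffusion={dt} exceeds the explicit stability limit "
                f"h^2/(4D)={self.stable_dt():.6g}")

    def add_secretion(self, voxel: tuple[int, int], rate: float, dt: float) -> None:
        """Add ``rate * dt`` of substrate to one voxel."""
        self.concentrations[voxel] += rate * dt

    def diffuse_decay_step(self, dt: float) -> None:
        """One explicit diffusion-decay step with zero-flux boundaries.

        With zero decay and no sources, total mass is conserved to rounding.
        Non-negativity is preserved under the stability condition.
        """
        self.check_dt(dt)
        c = self.concentrations
        h2 = self.domain.voxel_size ** 2
        padded = np.pad(c, 1, mode="edge")
        lap = (padded[:-2, 1:-1] + padded[2:, 1:-1]
               + padded[1:-1, :-2] + padded[1:-1, 2:] - 4.0 * c) / h2
        self.concentrations = c + dt * (self.diffusion_coefficient * lap
                                        - self.decay_rate * c)

    def total_mass(self) -> float:
        return float(self.concentrations.sum())

    def gradient_at(self, position) -> np.ndarray:
        """Concentration gradient at a point's voxel (central differences,
        one-sided at the grid edges)."""
        i, j = self.domain.voxel_of(position)
        c = self.concentrations
        h = self.domain.voxel_size
        i_lo, i_hi = max(i - 1, 0), min(i + 1, self.domain.nx - 1)
        j_lo, j_hi = max(j - 1, 0), min(j + 1, self.domain.ny - 1)
        gx = (c[i_hi, j] - c[i_lo, j]) / ((i_hi - i_lo) * h) if i_hi > i_lo else 0.0
        gy = (c[i, j_hi] - c[i, j_lo]) / ((j_hi - j_lo) * h) if j_hi > j_lo else 0.0
        return np.array([gx, gy])


def chemotaxis_motility(c: CellAgent, field: SubstrateField,
                        tol: float = 1e-15) -> np.ndarray:
    """Unit motility direction up the attractant gradient.

    A (numerically) zero gradient leaves the previous motility vector
    unchanged, so cells keep their heading until a signal arrives.
    """
    grad = field.gradient_at(c.position)
    norm = float(np.hypot(*grad))
    if norm <= tol:
        return np.asarray(c.motility_vector, dtype=float)
    return grad / norm
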