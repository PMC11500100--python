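"""Voxel-grid registration and neighbour search for mixed agent shapes.

Cells are point-registered to the voxel containing their centre.  Fibres
span many voxels, so at the start of every mechanics pass each fibre is
registered to every voxel its axis crosses; after force evaluation it is
de-registered from all voxels bar the one containing its centre.  Neighbours
of an agent are all agents registered in any voxel the agent occupies or in
the surrounding ring(s) of adjacent voxels.

The adjacency ring count is configurable (default 2).  One ring (the Moore
8-neighbourhood) only guarantees finding pairs within one voxel size of
*axis* distance; two rings guarantee completeness out to a full voxel size
of capsule distance (axis distance minus the agents' radii) for any
realistic cell/fibre radii.
"""

from __future__ import annotations

from .agents import CellAgent, FibreAgent
from .geometry import voxels_crossed
from .initialization import Domain

__all__ = ["VoxelGrid"]


class VoxelGrid:
    """Uniform 2D grid mapping voxel index -> set of registered agent ids."""

    def __init__(self, domain: Domain, adjacency_rings: int = 2):
        if adjacency_rings < 1:
            raise ValueError("adjacency_rings must be >= 1")
        self.domain = domain
        self.adjacency_rings = adjacency_rings
        self.occupancy: dict[tuple[int, int], set[int]] = {}

    # -- low-level occupancy -------------------------------------------------

    def _add(self, voxel: tuple[int, int], agent_id: int) -> None:
        self.occupancy.setdefault(voxel, set()).add(agent_id)

    def _discard(self, voxel: tuple[int, int], agent_id: int) -> None:
        ids = self.occupancy.get(voxel)
        if ids is not None:
            ids.discard(agent_id)
            if not ids:
                del self.occupancy[voxel]

    # -- cells ---------------------------------------------------------------

    def register_cell(self, c: CellAgent) -> None:
        self._add(self.domain.voxel_of(c.position), c.id)

    def update_cell(self, c: CellAgent, old_voxel: tuple[int, int]) -> None:
        new = self.domain.voxel_of(c.position)
        if new != old_voxel:
            self._discard(old_voxel, c.id)
            self._add(new, c.id)

    def remove_cell(self, c: CellAgent) -> None:
        self._discard(self.domain.voxel_of(c.position), c.id)

    # -- fibres --------------------------------------------------------------

    def register_fibre_voxels(self, f: FibreAgent) -> None:
        """Register ``f`` to every voxel its axis crosses (cached per shape)."""
        if f._voxel_cache is None:
            f._voxel_cache = voxels_crossed(f.segment, self.domain)
        for v in f._voxel_cache:
            if v not in f.registered_voxels:
                self._add(v, f.id)
        f.registered_voxels = set(f._voxel_cache)

    def deregister_fibre_voxels(self, f: FibreAgent) -> None:
        """De-register ``f`` from all voxels bar the one holding its centre."""
        centre = self.domain.voxel_of(f.segment.centre)
        for v in f.registered_voxels:
            if v != centre:
                self._discard(v, f.id)
        self._add(centre, f.id)
        f.registered_voxels = {centre}

    def remove_fibre(self, f: FibreAgent) -> None:
        for v in f.registered_voxels:
            self._discard(v, f.id)
        f.registered_voxels = set()

    # -- neighbour search ----------------------------------------------------

    def _base_voxels(self, agent) -> set[tuple[int, int]]:
        if isinstance(agent, FibreAgent):
            return agent.registered_voxels or {self.domain.voxel_of(agent.segment.centre)}
        return {self.domain.voxel_of(agent.position)}

    def find_agent_neighbors(self, agent) -> list[int]:
        """Ids of all other agents registered in or adjacent to the agent's voxels.

        Deterministic: the result is sorted.  Symmetric while all fibres are
        fully registered.
        """
        k = self.adjacency_rings
        nx, ny = self.domain.nx, self.domain.ny
        found: set[int] = set()
        seen: set[tuple[int, int]] = set()
        for (i0, j0) in self._base_voxels(agent):
            for i in range(max(0, i0 - k), min(nx - 1, i0 + k) + 1):
                for j in range(max(0, j0 - k), min(ny - 1, j0 + k) + 1):
                    v = (i, j)
                    if v in seen:
                        continue
                    seen.add(v)
                    ids = self.occupancy.get(v)
                    if ids:
                        found.update(ids)
        found.discard(agent.id)
        return sorted(found)
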