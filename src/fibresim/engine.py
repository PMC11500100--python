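"""Simulation loop, configuration and snapshots.

A configuration (XML or built programmatically) defines the domain, the
timesteps, a single optional substrate, and a set of agent definitions.
Definition names decide agent kind (see :func:`fibresim.agents.classify_definition`);
fibre definitions carry the initialisation parameters of Table-style keys
(``fibre_length``, ``length_normdist_sd``, ...), cell definitions the
mechanics and degradation keys (``vel_adhesion``, ``fibre_stuck_time``, ...).

Each mechanics step performs, in a fixed documented order:

1. diffusion substeps (secretion then diffuse-decay) up to the mechanics step,
2. chemotaxis update of motility vectors,
3. full voxel registration of all fibres,
4. cross-link recomputation (cached while no fibre has moved or been removed),
5. cell velocity assembly (cell-cell + cell-fibre potentials, pressure,
   stuck counters),
6. fibre pushing/rotation by contacting cells,
7. the degradation pass (at most one removal attempt per cell),
8. forward-Euler integration of cell positions (clamped to the domain),
9. de-registration of fibres back to their centre voxels.

All randomness flows through one ``numpy`` Generator seeded from the config,
so a fixed seed gives bitwise-identical trajectories and snapshot files.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from xml.etree import ElementTree as ET

import numpy as np

from .agents import (CellAgent, CellFibreParams, CellParams, FibreAgent,
                     FibreParams, classify_definition)
from .geometry import Segment
from .grid import VoxelGrid
from .initialization import Domain, place_fibres, read_positions_csv, sample_fibre
from .mechanics import add_potentials_from_cell, update_cell_velocity
from .microenvironment import SubstrateField, chemotaxis_motility
from .remodelling import (add_crosslinks, maybe_degrade, remove_fibre,
                          select_degradation_target)

__all__ = ["DefinitionConfig", "SimulationConfig", "parse_config",
           "write_config", "Simulation"]

_BOOL_FIBRE_KEYS = {"anisotropic_fibres"}
_BOOL_CELL_KEYS = {"fibre_pushing", "fibre_rotation", "fibre_degradation",
                   "fibre_custom_degradation", "color_cells_by_pressure",
                   "chemotactic"}
_INT_CELL_KEYS = {"fibre_stuck_time"}


@dataclass
class DefinitionConfig:
    """One agent definition: a fibre type or a cell type."""

    name: str
    initial_count: int = 0
    positions: list = field(default_factory=list)  # explicit (x, y) centres
    fibre_params: FibreParams | None = None
    cell_params: CellParams | None = None
    cell_fibre_params: CellFibreParams | None = None

    @property
    def kind(self) -> str:
        return classify_definition(self.name)


@dataclass
class SimulationConfig:
    domain: Domain = field(default_factory=lambda: Domain(-400, 400, -400, 400, 30.0))
    dt_mechanics: float = 0.1      # min
    dt_diffusion: float = 0.05     # min
    t_max: float = 60.0            # min
    output_interval: float = 10.0  # min
    rng_seed: int = 0
    adjacency_rings: int = 2
    diffusion_coefficient: float = 800.0  # um^2/min
    decay_rate: float = 0.02              # 1/min
    definitions: dict[str, DefinitionConfig] = field(default_factory=dict)
    positions_csv: str | None = None

    def validate(self) -> None:
        if not self.t_max > 0:
            raise ValueError("t_max must be positive")
        if self.dt_diffusion > self.dt_mechanics:
            raise ValueError("dt_diffusion must not exceed dt_mechanics")
        if not self.definitions:
            raise ValueError("configuration defines no agent definitions")


# --------------------------------------------------------------------------
# XML config I/O
# --------------------------------------------------------------------------

def _coerce(key: str, text: str, bools: set[str], ints: set[str]):
    text = text.strip()
    if key in bools:
        return text.lower() in ("1", "true", "yes")
    if key in ints:
        return int(float(text))
    return float(text)


def _parse_custom_data(elem: ET.Element, kind: str, name: str):
    fp_names = {f.name for f in dc_fields(FibreParams)}
    cfp_names = {f.name for f in dc_fields(CellFibreParams)}
    fibre_kwargs: dict = {}
    cell_fibre_kwargs: dict = {}
    seen_length_sd = 0
    for child in elem:
        key = child.tag
        text = child.text or ""
        if key == "length_normdist_sd":
            seen_length_sd += 1
            if seen_length_sd > 1:
                # duplicated key: the second occurrence is the radius sd
                fibre_kwargs["radius_normdist_sd"] = _coerce(
                    "radius_normdist_sd", text, _BOOL_FIBRE_KEYS, set())
                continue
        if key in fp_names:
            fibre_kwargs[key] = _coerce(key, text, _BOOL_FIBRE_KEYS, set())
        elif key in cfp_names:
            cell_fibre_kwargs[key] = _coerce(key, text, _BOOL_CELL_KEYS, _INT_CELL_KEYS)
        else:
            warnings.warn(f"definition {name!r}: unknown custom_data key {key!r}",
                          stacklevel=2)
    if kind == "fibre":
        if cell_fibre_kwargs:
            warnings.warn(f"fibre definition {name!r} carries cell-fibre keys "
                          f"{sorted(cell_fibre_kwargs)}; ignored", stacklevel=2)
        return FibreParams(**fibre_kwargs), None
    if fibre_kwargs:
        warnings.warn(f"cell definition {name!r} carries fibre keys "
                      f"{sorted(fibre_kwargs)}; ignored", stacklevel=2)
    return None, CellFibreParams(**cell_fibre_kwargs)


def parse_config(path) -> SimulationConfig:
    """Parse an XML configuration file into a :class:`SimulationConfig`.

    Unknown custom-data keys warn; missing keys take the documented defaults
    (fibre length 75 um, radius 2 um, ...).  Invalid values raise a
    descriptive ``ValueError``.
    """
    tree = ET.parse(path)
    root = tree.getroot()
    cfg = SimulationConfig(definitions={})

    dom = root.find("domain")
    if dom is not None:
        cfg.domain = Domain(float(dom.get("x_min")), float(dom.get("x_max")),
                            float(dom.get("y_min")), float(dom.get("y_max")),
                            float(dom.get("voxel_size", 30.0)))
    overall = root.find("overall")
    if overall is not None:
        cfg.dt_mechanics = float(overall.get("dt_mechanics", cfg.dt_mechanics))
        cfg.dt_diffusion = float(overall.get("dt_diffusion", cfg.dt_diffusion))
        cfg.t_max = float(overall.get("t_max", cfg.t_max))
        cfg.output_interval = float(overall.get("output_interval", cfg.output_interval))
    opts = root.find("options")
    if opts is not None:
        cfg.rng_seed = int(opts.get("rng_seed", cfg.rng_seed))
        cfg.adjacency_rings = int(opts.get("adjacency_rings", cfg.adjacency_rings))
    sub = root.find("substrate")
    if sub is not None:
        cfg.diffusion_coefficient = float(sub.get("diffusion_coefficient",
                                                  cfg.diffusion_coefficient))
        cfg.decay_rate = float(sub.get("decay_rate", cfg.decay_rate))
    init = root.find("initial_conditions")
    if init is not None:
        cfg.positions_csv = init.get("csv")

    defs = root.find("cell_definitions")
    if defs is not None:
        for elem in defs.findall("cell_definition"):
            name = elem.get("name", "")
            if not name:
                raise ValueError("cell_definition without a name")
            d = DefinitionConfig(name=name,
                                 initial_count=int(elem.get("initial_count", 0)))
            custom = elem.find("custom_data")
            if custom is not None:
                d.fibre_params, d.cell_fibre_params = _parse_custom_data(
                    custom, d.kind, name)
            elif d.kind == "fibre":
                d.fibre_params = FibreParams()
            else:
                d.cell_fibre_params = CellFibreParams()
            if d.kind == "cell":
                phen = elem.find("phenotype")
                kwargs: dict = {}
                if phen is not None:
                    for f in dc_fields(CellParams):
                        raw = phen.get(f.name)
                        if raw is not None:
                            kwargs[f.name] = _coerce(f.name, raw, _BOOL_CELL_KEYS, set())
                d.cell_params = CellParams(**kwargs)
            pos = elem.find("initial_positions")
            if pos is not None:
                for pe in pos.findall("position"):
                    d.positions.append((float(pe.get("x")), float(pe.get("y"))))
            cfg.definitions[name] = d
    cfg.validate()
    return cfg


def _fmt(v) -> str:
    if isinstance(v, bool):
        return "1" if v else "0"
    return repr(v) if isinstance(v, float) else str(v)


def write_config(cfg: SimulationConfig, path) -> None:
    """Serialise a configuration to XML (inverse of :func:`parse_config`)."""
    root = ET.Element("simulation")
    ET.SubElement(root, "domain",
                  x_min=_fmt(cfg.domain.x_min), x_max=_fmt(cfg.domain.x_max),
                  y_min=_fmt(cfg.domain.y_min), y_max=_fmt(cfg.domain.y_max),
                  voxel_size=_fmt(cfg.domain.voxel_size))
    ET.SubElement(root, "overall", dt_mechanics=_fmt(cfg.dt_mechanics),
                  dt_diffusion=_fmt(cfg.dt_diffusion), t_max=_fmt(cfg.t_max),
                  output_interval=_fmt(cfg.output_interval))
    ET.SubElement(root, "options", rng_seed=str(cfg.rng_seed),
                  adjacency_rings=str(cfg.adjacency_rings))
    ET.SubElement(root, "substrate",
                  diffusion_coefficient=_fmt(cfg.diffusion_coefficient),
                  decay_rate=_fmt(cfg.decay_rate))
    if cfg.positions_csv:
        ET.SubElement(root, "initial_conditions", csv=cfg.positions_csv)
    defs = ET.SubElement(root, "cell_definitions")
    for d in cfg.definitions.values():
        elem = ET.SubElement(defs, "cell_definition", name=d.name,
                             initial_count=str(d.initial_count))
        if d.kind == "cell" and d.cell_params is not None:
            attrs = {f.name: _fmt(getattr(d.cell_params, f.name))
                     for f in dc_fields(CellParams)}
            ET.SubElement(elem, "phenotype", **attrs)
        custom = ET.SubElement(elem, "custom_data")
        params = d.fibre_params if d.kind == "fibre" else d.cell_fibre_params
        if params is not None:
            for f in dc_fields(type(params)):
                ET.SubElement(custom, f.name).text = _fmt(getattr(params, f.name))
        if d.positions:
            pos = ET.SubElement(elem, "initial_positions")
            for (x, y) in d.positions:
                ET.SubElement(pos, "position", x=_fmt(float(x)), y=_fmt(float(y)))
    ET.indent(root)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    ET.ElementTree(root).write(path, encoding="unicode", xml_declaration=True)


# --------------------------------------------------------------------------
# Simulation
# --------------------------------------------------------------------------

class Simulation:
    """A running simulation state built from a :class:`SimulationConfig`."""

    def __init__(self, config: SimulationConfig, seed: int | None = None):
        config.validate()
        self.config = config
        self.rng = np.random.default_rng(config.rng_seed if seed is None else seed)
        self.domain = config.domain
        self.grid = VoxelGrid(self.domain, adjacency_rings=config.adjacency_rings)
        self.field = SubstrateField(self.domain, config.diffusion_coefficient,
                                    config.decay_rate)
        self.field.check_dt(config.dt_diffusion)
        self.time = 0.0
        self.fibres: dict[int, FibreAgent] = {}
        self.cells: dict[int, CellAgent] = {}
        self._next_id = 0
        self._crosslinks_dirty = True
        self._diffusion_debt = 0.0
        self._setup_agents()

    # -- setup ---------------------------------------------------------------

    def _new_id(self) -> int:
        self._next_id += 1
        return self._next_id - 1

    def _add_fibre_agent(self, f: FibreAgent) -> None:
        self.fibres[f.id] = f
        # between steps a fibre occupies only its centre voxel
        self.grid._add(self.domain.voxel_of(f.segment.centre), f.id)
        f.registered_voxels = {self.domain.voxel_of(f.segment.centre)}

    def _make_cell(self, d: DefinitionConfig, position) -> CellAgent:
        cp = d.cell_params or CellParams()
        theta = float(self.rng.uniform(0.0, 2.0 * np.pi))
        c = CellAgent(id=self._new_id(), position=np.asarray(position, dtype=float),
                      radius=cp.radius, definition_name=d.name,
                      motility_vector=np.array([np.cos(theta), np.sin(theta)]),
                      migration_speed=cp.migration_speed, params=cp,
                      fibre_params=d.cell_fibre_params or CellFibreParams())
        self.cells[c.id] = c
        self.grid.register_cell(c)
        return c

    def _setup_agents(self) -> None:
        for d in self.config.definitions.values():
            if d.kind == "fibre":
                fp = d.fibre_params or FibreParams()
                for (x, y) in d.positions:
                    seg = sample_fibre(fp, self.domain, self.rng)
                    seg = Segment(np.array([x, y]), seg.orientation,
                                  seg.length, seg.radius)
                    self._add_fibre_agent(FibreAgent(id=self._new_id(), segment=seg,
                                                     definition_name=d.name, params=fp))
                if d.initial_count:
                    placed = place_fibres(d.initial_count, fp, self.domain, self.rng,
                                          definition_name=d.name, id_start=0)
                    for f in placed:
                        f.id = self._new_id()
                        self._add_fibre_agent(f)
            else:
                for (x, y) in d.positions:
                    self._make_cell(d, (x, y))
                for _ in range(d.initial_count):
                    x = self.rng.uniform(self.domain.x_min, self.domain.x_max)
                    y = self.rng.uniform(self.domain.y_min, self.domain.y_max)
                    self._make_cell(d, (x, y))
        if self.config.positions_csv:
            for (x, y, name) in read_positions_csv(self.config.positions_csv):
                d = self.config.definitions.get(name)
                if d is None:
                    raise ValueError(f"CSV names unknown definition {name!r}")
                if d.kind == "fibre":
                    fp = d.fibre_params or FibreParams()
                    seg = sample_fibre(fp, self.domain, self.rng)
                    seg = Segment(np.array([x, y]), seg.orientation,
                                  seg.length, seg.radius)
                    self._add_fibre_agent(FibreAgent(id=self._new_id(), segment=seg,
                                                     definition_name=name, params=fp))
                else:
                    self._make_cell(d, (x, y))

    # -- stepping ------------------------------------------------------------

    def _diffusion_substeps(self) -> None:
        dt = self.config.dt_diffusion
        self._diffusion_debt += self.config.dt_mechanics
        while self._diffusion_debt > 1e-12:
            step = min(dt, self._diffusion_debt)
            for c in self.cells.values():
                rate = c.params.secretion_rate
                if rate > 0:
                    self.field.add_secretion(self.domain.voxel_of(c.position),
                                             rate, step)
            self.field.diffuse_decay_step(step)
            self._diffusion_debt -= step

    def step(self) -> None:
        """Advance the state by one mechanics timestep."""
        dt = self.config.dt_mechanics
        self._diffusion_substeps()
        for c in self.cells.values():
            if c.params.chemotactic:
                c.motility_vector = chemotaxis_motility(c, self.field)

        for f in self.fibres.values():
            self.grid.register_fibre_voxels(f)

        if self._crosslinks_dirty:
            add_crosslinks(self.fibres, self.grid)
            self._crosslinks_dirty = False

        neighbour_ids = {cid: self.grid.find_agent_neighbors(c)
                         for cid, c in self.cells.items()}

        for cid in sorted(self.cells):
            c = self.cells[cid]
            ids = neighbour_ids[cid]
            cell_nb = [self.cells[i] for i in ids if i in self.cells]
            fibre_nb = [self.fibres[i] for i in ids if i in self.fibres]
            update_cell_velocity(c, cell_nb, fibre_nb)

        # fibre pushing / rotation
        for cid in sorted(self.cells):
            c = self.cells[cid]
            p = c.fibre_params
            if not (p.fibre_pushing or p.fibre_rotation):
                continue
            for i in neighbour_ids[cid]:
                f = self.fibres.get(i)
                if f is None:
                    continue
                centre_before = f.segment.centre.copy()
                orient_before = f.segment.orientation.copy()
                add_potentials_from_cell(f, c, p, self.domain, dt)
                if (np.any(f.segment.centre != centre_before)
                        or np.any(f.segment.orientation != orient_before)):
                    self._crosslinks_dirty = True

        # degradation pass: at most one removal attempt per cell
        for cid in sorted(self.cells):
            c = self.cells[cid]
            if not c.fibre_params.fibre_degradation:
                continue
            fibre_nb = [self.fibres[i] for i in neighbour_ids[cid] if i in self.fibres]
            target = select_degradation_target(c, fibre_nb)
            if target is not None and maybe_degrade(c, target, self.rng, dt):
                remove_fibre(target, self.fibres, self.grid)
                self._crosslinks_dirty = True

        # integrate cell positions (clamped to the domain)
        for cid in sorted(self.cells):
            c = self.cells[cid]
            old_voxel = self.domain.voxel_of(c.position)
            c.position = self.domain.clamp(c.position + c.velocity * dt)
            c.previous_velocity = c.velocity.copy()
            self.grid.update_cell(c, old_voxel)

        for f in self.fibres.values():
            self.grid.deregister_fibre_voxels(f)
        self.time += dt

    def run(self, t_max: float | None = None, out_dir=None) -> None:
        """Step until ``t_max`` (default: the config's), optionally writing
        CSV + SVG snapshots every ``output_interval`` minutes."""
        t_end = self.config.t_max if t_max is None else t_max
        interval = self.config.output_interval
        next_out = 0.0
        n_steps = int(round((t_end - self.time) / self.config.dt_mechanics))
        for _ in range(n_steps):
            if out_dir is not None and self.time >= next_out - 1e-9:
                self.write_snapshot(out_dir)
                next_out += interval
            self.step()
        if out_dir is not None:
            self.write_snapshot(out_dir)

    # -- output --------------------------------------------------------------

    def snapshot_rows(self) -> tuple[list[str], list[str]]:
        """Snapshot CSV rows (cells, fibres), deterministically ordered."""
        cell_rows = ["id,x,y,radius,pressure"]
        for cid in sorted(self.cells):
            c = self.cells[cid]
            cell_rows.append(f"{cid},{c.position[0]:.10g},{c.position[1]:.10g},"
                             f"{c.radius:.10g},{c.pressure:.10g}")
        fibre_rows = ["id,x,y,angle,length,radius,n_crosslinks"]
        for fid in sorted(self.fibres):
            f = self.fibres[fid]
            s = f.segment
            fibre_rows.append(f"{fid},{s.centre[0]:.10g},{s.centre[1]:.10g},"
                              f"{s.angle:.10g},{s.length:.10g},{s.radius:.10g},"
                              f"{f.n_crosslinks}")
        return cell_rows, fibre_rows

    def write_snapshot(self, out_dir) -> None:
        from .render import fibre_agent_SVG

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        tag = f"t{self.time:08.1f}".replace(".", "m")
        cell_rows, fibre_rows = self.snapshot_rows()
        (out / f"cells_{tag}.csv").write_text("\n".join(cell_rows) + "\n")
        (out / f"fibres_{tag}.csv").write_text("\n".join(fibre_rows) + "\n")
        svg = fibre_agent_SVG(list(self.fibres.values()), list(self.cells.values()),
                              domain=self.domain)
        (out / f"snapshot_{tag}.svg").write_text(svg)

    def state_hash(self) -> str:
        """SHA-256 over the snapshot rows (positions, orientations, counts)."""
        cell_rows, fibre_rows = self.snapshot_rows()
        payload = "\n".join(cell_rows + fibre_rows).encode()
        return hashlib.sha256(payload).hexdigest()
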