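"""Ready-to-run example configurations.

Four worked setups exercise the full feature set:

* three fibre-initialisation fields (isotropic; aligned at 0.2 rad; aligned
  at 0.2 rad with sd 0.15) of 2,000 attempted 75 um x 2 um fibres in an
  800 um x 800 um domain;
* a rotation scenario: a vertical barrier of free (uncross-linked) fibres
  between a chemotactic cell and an attractant-secreting cell, with fibre
  rotation enabled so the cell can swing a fibre aside and pass;
* a degradation scenario: a cross-linked, impassable fibre wall plus a
  random background field between a chemotactic cell and the attractant
  source, with stuck-based degradation enabled so the cell can chew through;
* a pressure pair: a fibre cage around a pre-seeded overlapping cell
  cluster, identical except for the pressure-dependent (custom) degradation
  flag.

Mechanics and degradation parameter values for the latter three are this
package's own documented choices (see docs/methods.md); the initialisation
fields fix only the published geometry (counts, lengths, radii, angles).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .agents import CellFibreParams, CellParams, FibreParams
from .engine import DefinitionConfig, SimulationConfig, write_config
from .initialization import Domain

__all__ = [
    "make_initialisation_scenarios",
    "make_rotation_scenario",
    "make_degradation_scenarios",
    "write_all",
]


def make_initialisation_scenarios() -> dict[str, SimulationConfig]:
    """Three static fibre fields: isotropic, aligned, aligned-with-spread."""
    out: dict[str, SimulationConfig] = {}
    settings = {
        "isotropic": dict(anisotropic_fibres=False),
        "anisotropic_sd0": dict(anisotropic_fibres=True, fibre_angle=0.2,
                                angle_normdist_sd=0.0),
        "anisotropic_sd015": dict(anisotropic_fibres=True, fibre_angle=0.2,
                                  angle_normdist_sd=0.15),
    }
    for name, kw in settings.items():
        cfg = SimulationConfig(
            domain=Domain(-400.0, 400.0, -400.0, 400.0, 30.0),
            dt_mechanics=0.1, dt_diffusion=0.05, t_max=1.0,
            output_interval=1.0, rng_seed=0,
            definitions={
                "default_fibre": DefinitionConfig(
                    name="default_fibre", initial_count=2000,
                    fibre_params=FibreParams(fibre_length=75.0,
                                             length_normdist_sd=0.0,
                                             fibre_radius=2.0,
                                             radius_normdist_sd=0.0, **kw)),
            })
        out[name] = cfg
    return out


def make_rotation_scenario() -> SimulationConfig:
    """Vertical fibre barrier, one chemotactic cell, one attractant source."""
    barrier_y = [-75.0, -40.0, -5.0, 30.0, 65.0]  # gaps of 5 um: no cross-links
    return SimulationConfig(
        domain=Domain(-100.0, 100.0, -100.0, 100.0, 20.0),
        dt_mechanics=0.1, dt_diffusion=0.05, t_max=240.0,
        output_interval=30.0, rng_seed=0,
        diffusion_coefficient=800.0, decay_rate=0.02,
        definitions={
            "barrier_fibre": DefinitionConfig(
                name="barrier_fibre",
                positions=[(0.0, y) for y in barrier_y],
                fibre_params=FibreParams(fibre_length=30.0, fibre_radius=2.0,
                                         anisotropic_fibres=True,
                                         fibre_angle=float(np.pi / 2),
                                         fibre_sticky=1.0)),
            "chemotactic_cell": DefinitionConfig(
                name="chemotactic_cell", positions=[(-60.0, 2.0)],
                cell_params=CellParams(radius=10.0, migration_speed=1.0,
                                       chemotactic=True),
                cell_fibre_params=CellFibreParams(
                    vel_adhesion=0.6, vel_contact=0.3, cell_velocity_max=10.0,
                    fibre_rotation=True, fibre_pushing=False,
                    fibre_degradation=False)),
            "source_cell": DefinitionConfig(
                name="source_cell", positions=[(60.0, 0.0)],
                cell_params=CellParams(radius=10.0, migration_speed=0.0,
                                       secretion_rate=10.0),
                cell_fibre_params=CellFibreParams()),
        })


def _wall_positions(domain_half: float, length: float) -> list[tuple[float, float]]:
    """Vertical column of touching fibres spanning the whole domain height."""
    n = int(round(2 * domain_half / length))
    return [(0.0, -domain_half + length * (i + 0.5)) for i in range(n)]


def make_degradation_scenarios() -> dict[str, SimulationConfig]:
    """Fibre-wall chewing scenario plus the pressure-dependent pair."""
    out: dict[str, SimulationConfig] = {}

    # (a) impassable cross-linked wall + random field; stuck-based degradation
    wall = _wall_positions(200.0, 40.0)
    out["fibre_degradation"] = SimulationConfig(
        domain=Domain(-200.0, 200.0, -200.0, 200.0, 20.0),
        dt_mechanics=0.1, dt_diffusion=0.05, t_max=960.0,
        output_interval=120.0, rng_seed=0,
        diffusion_coefficient=800.0, decay_rate=0.02,
        definitions={
            "wall_fibre": DefinitionConfig(
                name="wall_fibre", positions=wall,
                fibre_params=FibreParams(fibre_length=40.0, fibre_radius=2.0,
                                         anisotropic_fibres=True,
                                         fibre_angle=float(np.pi / 2))),
            "ecm_field": DefinitionConfig(
                name="ecm_field", initial_count=60,
                fibre_params=FibreParams(fibre_length=40.0, fibre_radius=2.0)),
            "chemotactic_cell": DefinitionConfig(
                name="chemotactic_cell", positions=[(-150.0, 0.0)],
                cell_params=CellParams(radius=10.0, migration_speed=1.0,
                                       chemotactic=True),
                cell_fibre_params=CellFibreParams(
                    vel_adhesion=0.1, vel_contact=0.2, cell_velocity_max=10.0,
                    fibre_degradation=True, fibre_stuck_time=30,
                    fibre_stuck_threshold=0.5, fibre_degradation_rate=1.0)),
            "source_cell": DefinitionConfig(
                name="source_cell", positions=[(150.0, 0.0)],
                cell_params=CellParams(radius=10.0, migration_speed=0.0,
                                       secretion_rate=10.0),
                cell_fibre_params=CellFibreParams()),
        })

    # (b) trapped cluster in a fibre cage; pair differs only in the
    # pressure-dependent degradation flag
    cage = {  # square ring: every side crosses both neighbours (2 cross-links)
        "positions": [(0.0, 25.0), (0.0, -25.0), (25.0, 0.0), (-25.0, 0.0)],
        "angles": [0.0, 0.0, float(np.pi / 2), float(np.pi / 2)],
    }
    cluster = [(0.0, 0.0)] + [
        (15.0 * np.cos(a), 15.0 * np.sin(a))
        for a in np.linspace(0.0, 2 * np.pi, 7)[:-1]
    ]
    for variant, custom in (("independent", False), ("dependent", True)):
        defs: dict[str, DefinitionConfig] = {}
        for i, ((x, y), ang) in enumerate(zip(cage["positions"], cage["angles"])):
            defs[f"cage_fibre_{i}"] = DefinitionConfig(
                name=f"cage_fibre_{i}", positions=[(x, y)],
                fibre_params=FibreParams(fibre_length=60.0, fibre_radius=2.0,
                                         anisotropic_fibres=True,
                                         fibre_angle=ang))
        defs["trapped_cell"] = DefinitionConfig(
            name="trapped_cell",
            positions=[(float(x), float(y)) for (x, y) in cluster],
            cell_params=CellParams(radius=10.0, migration_speed=0.2),
            cell_fibre_params=CellFibreParams(
                vel_contact=0.2, cell_velocity_max=10.0,
                fibre_degradation=True, fibre_custom_degradation=custom,
                fibre_stuck_time=600, fibre_stuck_threshold=0.5,
                fibre_pressure_threshold=0.15, fibre_degradation_rate=0.5,
                color_cells_by_pressure=True))
        out[f"matrix_degradation_{variant}"] = SimulationConfig(
            domain=Domain(-100.0, 100.0, -100.0, 100.0, 20.0),
            dt_mechanics=0.1, dt_diffusion=0.05, t_max=120.0,
            output_interval=30.0, rng_seed=0,
            definitions=defs)
    return out


def write_all(config_dir) -> list[Path]:
    """Write every scenario config to ``config_dir``, mirroring the layout
    Fibre_Initialisation/ | Cell_Fibre_Mechanics/ | Fibre_Degradation/."""
    base = Path(config_dir)
    written: list[Path] = []
    for name, cfg in make_initialisation_scenarios().items():
        p = base / "Fibre_Initialisation" / f"mymodel_initialisation_{name}.xml"
        write_config(cfg, p)
        written.append(p)
    p = base / "Cell_Fibre_Mechanics" / "fibre_rotating.xml"
    write_config(make_rotation_scenario(), p)
    written.append(p)
    for name, cfg in make_degradation_scenarios().items():
        p = base / "Fibre_Degradation" / f"mymodel_{name}.xml"
        write_config(cfg, p)
        written.append(p)
    return written
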