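"""SVG rendering of the mixed agent population.

Fibres are drawn as lines from endpoint to endpoint, coloured on a blue
gradient by cross-link count: none -> lightskyblue, one -> steelblue,
two -> blue, three or more -> darkblue.  Cells are circles; optionally
filled by the pressure they experience, interpolating blue (low) to red
(high) over a configurable range.
"""

from __future__ import annotations

from xml.etree import ElementTree as ET

from .agents import CellAgent, FibreAgent, classify_definition
from .initialization import Domain

__all__ = ["crosslink_colour", "pressure_colour", "fibre_agent_SVG",
           "fibre_agent_legend"]

SVG_NS = "http://www.w3.org/2000/svg"

CROSSLINK_COLOURS = ("lightskyblue", "steelblue", "blue", "darkblue")


def crosslink_colour(n_crosslinks: int) -> str:
    """Stroke colour for a fibre with ``n_crosslinks`` cross-links."""
    return CROSSLINK_COLOURS[min(n_crosslinks, 3)]


def pressure_colour(pressure: float, p_min: float = 0.0, p_max: float = 1.0) -> str:
    """Blue (low) to red (high) fill colour over [p_min, p_max]."""
    if p_max <= p_min:
        frac = 0.0
    else:
        frac = min(max((pressure - p_min) / (p_max - p_min), 0.0), 1.0)
    return f"rgb({round(255 * frac)},0,{round(255 * (1 - frac))})"


def _svg_root(width: float, height: float) -> ET.Element:
    return ET.Element("svg", xmlns=SVG_NS, version="1.1",
                      width=f"{width:g}", height=f"{height:g}",
                      viewBox=f"0 0 {width:g} {height:g}")


def fibre_agent_SVG(fibres: list[FibreAgent], cells: list[CellAgent],
                    domain: Domain, *, color_cells_by_pressure: bool = False,
                    pressure_range: tuple[float, float] = (0.0, 1.0),
                    fibre_stroke_width: float = 2.0) -> str:
    """Render one state to an SVG 1.1 document string.

    SVG y runs downwards, so world y is flipped.  Fibre stroke colour follows
    the cross-link count gradient; cell fill is grey unless
    ``color_cells_by_pressure`` is set.
    """
    width = domain.x_max - domain.x_min
    height = domain.y_max - domain.y_min

    def tx(p) -> tuple[float, float]:
        return (p[0] - domain.x_min, domain.y_max - p[1])

    root = _svg_root(width, height)
    ET.SubElement(root, "rect", x="0", y="0", width=f"{width:g}",
                  height=f"{height:g}", fill="white", stroke="black")
    for f in fibres:
        (x1, y1), (x2, y2) = tx(f.segment.start), tx(f.segment.end)
        ET.SubElement(root, "line", x1=f"{x1:.3f}", y1=f"{y1:.3f}",
                      x2=f"{x2:.3f}", y2=f"{y2:.3f}",
                      stroke=crosslink_colour(f.n_crosslinks),
                      attrib={"stroke-width": f"{fibre_stroke_width:g}"})
    for c in cells:
        cx, cy = tx(c.position)
        fill = (pressure_colour(c.pressure, *pressure_range)
                if color_cells_by_pressure else "grey")
        ET.SubElement(root, "circle", cx=f"{cx:.3f}", cy=f"{cy:.3f}",
                      r=f"{c.radius:g}", fill=fill, stroke="black")
    return ET.tostring(root, encoding="unicode")


def fibre_agent_legend(definitions: list[str]) -> str:
    """SVG fragment with one legend entry per definition.

    Fibre definitions get a line swatch, cell definitions a circle swatch.
    An empty definition list yields an empty group.
    """
    g = ET.Element("g", attrib={"class": "legend"})
    y = 15.0
    for name in definitions:
        if classify_definition(name) == "fibre":
            ET.SubElement(g, "line", x1="5", y1=f"{y:.1f}", x2="35", y2=f"{y:.1f}",
                          stroke=crosslink_colour(0),
                          attrib={"stroke-width": "2"})
        else:
            ET.SubElement(g, "circle", cx="20", cy=f"{y:.1f}", r="6",
                          fill="grey", stroke="black")
        txt = ET.SubElement(g, "text", x="45", y=f"{y + 4:.1f}",
                            attrib={"font-size": "12"})
        txt.text = name
        y += 20.0
    return ET.tostring(g, encoding="unicode")
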