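"""Assembly of the electrical equivalent circuit network (EECN).

Each annular region of the mesh is represented by a vertical ladder from
the buffer surface down to the grounded plate:

    buffer-top --[R buffer]-- cell interface --[C membrane]-- cytoplasm top
    --[R || C cytoplasm]-- cytoplasm bottom --[C membrane]-- dish interface
    --[C dish]-- ground

Adjacent ladders are linked radially inside the two conducting layers, so
that cytoplasm current has both vertical and radial components: plain
resistors in the buffer, and in the cell layer a resistor in series with a
cell-junction capacitance.  The junction capacitance models the fact that
a confluent monolayer has no continuous lateral cytoplasm conductor —
lateral current must cross the apposed membranes of neighbouring cells, so
each ring boundary carries two lateral membranes in series,
C = eps_m * (2*pi*r_b*H_c) / (2*T_m).  Without it the lateral cytoplasm
path short-circuits the layer, the dose peaks off-axis at a radius
comparable to the buffer depth, and the predicted death radii collapse
onto the well wall; with it the dose is maximal on the axis and decays
monotonically outward.  The plain-resistor variant remains available
(``lateral_junctions=False``) for comparison.

The discharge plasma is approximated as a perfect conductor from the
needle to the liquid surface at the well centre: the ideal voltage source
drives only the buffer-top node of region 1, while the buffer-top nodes of
all outer regions see the insulating air above them.  All dish-bottom
nodes are tied to the grounded copper plate.  The exact topology used by
the original SPICE study is not public; the layout here is reconstructed
from the published description of the layers and the source attachment.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ElementSet",
    "Element",
    "CircuitNetwork",
    "element_values",
    "assemble_network",
    "export_netlist",
]

logger = logging.getLogger(__name__)


class NetworkError(ValueError):
    pass


@dataclass(frozen=True)
class ElementSet:
    """R/C element values for every region and interior boundary.

    Vertical elements (length n_regions): buffer resistance H_s/(sigma_s*A),
    cytoplasm resistance H_c/(sigma_c*A) in parallel with capacitance
    eps_c*A/H_c, one membrane capacitance eps_m*A/T_m for each of the top
    and bottom membranes, dish capacitance eps_d*A/H_d.  Radial elements
    (length n_regions-1) use the annular-log formula between adjacent ring
    centres, ln(r_{n+1}/r_n)/(2*pi*sigma*H), exact for purely radial flow.
    ``cytoplasm_junction_C`` is the lateral cell-junction capacitance in
    series with each cytoplasm radial resistor (None when lateral
    junctions are disabled).  A non-conducting layer (conductivity 0)
    yields an infinite resistance, i.e. an open circuit that is omitted at
    assembly.
    """

    buffer_vertical_R: np.ndarray
    cytoplasm_vertical_R: np.ndarray
    cytoplasm_vertical_C: np.ndarray
    membrane_C: np.ndarray  # same value for top and bottom membrane
    membrane_G: np.ndarray  # conductance across each membrane (0 = ideal dielectric)
    dish_C: np.ndarray
    buffer_radial_R: np.ndarray
    cytoplasm_radial_R: np.ndarray
    cytoplasm_junction_C: np.ndarray | None = None
    geometry: object = None
    materials: object = None

    @property
    def n_regions(self) -> int:
        return len(self.buffer_vertical_R)


def _vertical_R(height: float, sigma: float, areas: np.ndarray) -> np.ndarray:
    if sigma == 0.0:
        logger.info("layer with zero conductivity: vertical resistances omitted (open circuit)")
        return np.full_like(areas, np.inf)
    return height / (sigma * areas)


def _radial_R(center_radii: np.ndarray, sigma: float, height: float) -> np.ndarray:
    if sigma == 0.0:
        return np.full(len(center_radii) - 1, np.inf)
    return np.log(center_radii[1:] / center_radii[:-1]) / (2.0 * np.pi * sigma * height)


def element_values(mesh, geometry, materials, lateral_junctions: bool = True) -> ElementSet:
    """Compute all R/C element values from mesh geometry and materials."""
    A = mesh.annulus_areas
    g, m = geometry, materials
    junction_C = None
    if lateral_junctions:
        # two apposed lateral membranes in series at each ring boundary
        lateral_areas = 2.0 * np.pi * mesh.boundary_radii * g.cell_height
        junction_C = m.membrane_permittivity * lateral_areas / (2.0 * g.membrane_thickness)
    return ElementSet(
        buffer_vertical_R=_vertical_R(g.buffer_height, m.buffer_conductivity, A),
        cytoplasm_vertical_R=_vertical_R(g.cell_height, m.cytoplasm_conductivity, A),
        cytoplasm_vertical_C=m.cytoplasm_permittivity * A / g.cell_height,
        membrane_C=m.membrane_permittivity * A / g.membrane_thickness,
        membrane_G=(m.membrane_conductivity * A / g.membrane_thickness),
        dish_C=m.dish_permittivity * A / g.dish_height,
        buffer_radial_R=_radial_R(mesh.center_radii, m.buffer_conductivity, g.buffer_height),
        cytoplasm_radial_R=_radial_R(mesh.center_radii, m.cytoplasm_conductivity, g.cell_height),
        cytoplasm_junction_C=junction_C,
        geometry=geometry,
        materials=materials,
    )


@dataclass(frozen=True)
class Element:
    """One circuit element between two node indices.

    kind is "R" (value in ohm) or "C" (value in farad); current is taken
    positive from node_a to node_b, i.e. downward for vertical elements and
    outward for radial ones.  `role` tags the physical layer
    (buffer_vertical, membrane_top, cytoplasm_vertical_R,
    cytoplasm_vertical_C, membrane_bottom, dish, buffer_radial,
    cytoplasm_radial, membrane_top_G, membrane_bottom_G) and `region` the
    0-based region (for radial elements: the inner of the two regions).
    """

    kind: str
    value: float
    node_a: int
    node_b: int
    role: str
    region: int


# node layout: ground = 0; per region i (0-based), five stacked nodes
_NODES_PER_REGION = 5
_BUFFER_TOP, _CELL_TOP, _CYTO_TOP, _CYTO_BOT, _DISH_TOP = range(_NODES_PER_REGION)

_NODE_LABELS = ("buffer_top", "cell_interface", "cytoplasm_top", "cytoplasm_bottom", "dish_interface")


def node_index(region: int, level: int) -> int:
    """Global node index of `level` (0..4 from buffer-top down) in `region`."""
    return 1 + _NODES_PER_REGION * region + level


@dataclass
class CircuitNetwork:
    """Node/element graph of the assembled EECN.

    Node 0 is ground (the copper plate); the ideal voltage source drives
    `source_node` (region-1 buffer top).  `node_labels` names every node.
    """

    n_nodes: int
    elements: list
    source_node: int
    ground_node: int
    node_labels: list
    n_regions: int
    geometry: object = None
    materials: object = None

    def elements_by_role(self, role: str) -> list:
        return [e for e in self.elements if e.role == role]


def assemble_network(elements: ElementSet, mesh, drive) -> CircuitNetwork:
    """Assemble the circuit graph from the element values.

    Raises NetworkError if any node ends up disconnected from the
    source/ground component (a floating subgraph would make the nodal
    admittance matrix singular).
    """
    n = elements.n_regions
    if n != mesh.n_regions:
        raise NetworkError("element set and mesh disagree on region count")
    elems: list[Element] = []

    def add(kind, value, a, b, role, region):
        if not math.isfinite(value):
            return  # open circuit
        elems.append(Element(kind, float(value), a, b, role, region))

    for i in range(n):
        add("R", elements.buffer_vertical_R[i], node_index(i, _BUFFER_TOP), node_index(i, _CELL_TOP), "buffer_vertical", i)
        add("C", elements.membrane_C[i], node_index(i, _CELL_TOP), node_index(i, _CYTO_TOP), "membrane_top", i)
        if elements.membrane_G[i] > 0:
            add("R", 1.0 / elements.membrane_G[i], node_index(i, _CELL_TOP), node_index(i, _CYTO_TOP), "membrane_top_G", i)
        add("R", elements.cytoplasm_vertical_R[i], node_index(i, _CYTO_TOP), node_index(i, _CYTO_BOT), "cytoplasm_vertical_R", i)
        add("C", elements.cytoplasm_vertical_C[i], node_index(i, _CYTO_TOP), node_index(i, _CYTO_BOT), "cytoplasm_vertical_C", i)
        add("C", elements.membrane_C[i], node_index(i, _CYTO_BOT), node_index(i, _DISH_TOP), "membrane_bottom", i)
        if elements.membrane_G[i] > 0:
            add("R", 1.0 / elements.membrane_G[i], node_index(i, _CYTO_BOT), node_index(i, _DISH_TOP), "membrane_bottom_G", i)
        add("C", elements.dish_C[i], node_index(i, _DISH_TOP), 0, "dish", i)
    junction_base = 1 + _NODES_PER_REGION * n
    with_junctions = elements.cytoplasm_junction_C is not None
    for i in range(n - 1):
        add("R", elements.buffer_radial_R[i], node_index(i, _BUFFER_TOP), node_index(i + 1, _BUFFER_TOP), "buffer_radial", i)
        if with_junctions:
            add("R", elements.cytoplasm_radial_R[i], node_index(i, _CYTO_TOP), junction_base + i, "cytoplasm_radial", i)
            add("C", elements.cytoplasm_junction_C[i], junction_base + i, node_index(i + 1, _CYTO_TOP), "cytoplasm_junction", i)
        else:
            add("R", elements.cytoplasm_radial_R[i], node_index(i, _CYTO_TOP), node_index(i + 1, _CYTO_TOP), "cytoplasm_radial", i)

    n_nodes = junction_base + (n - 1 if with_junctions else 0)
    labels = ["ground"] + [
        f"{_NODE_LABELS[level]}[{i + 1}]" for i in range(n) for level in range(_NODES_PER_REGION)
    ]
    if with_junctions:
        labels += [f"cell_junction[{i + 1}|{i + 2}]" for i in range(n - 1)]
    network = CircuitNetwork(
        n_nodes=n_nodes,
        elements=elems,
        source_node=node_index(0, _BUFFER_TOP),
        ground_node=0,
        node_labels=labels,
        n_regions=n,
        geometry=elements.geometry,
        materials=elements.materials,
    )
    _check_connected(network)
    return network


def _check_connected(network: CircuitNetwork) -> None:
    adj: dict[int, list[int]] = {i: [] for i in range(network.n_nodes)}
    for e in network.elements:
        adj[e.node_a].append(e.node_b)
        adj[e.node_b].append(e.node_a)
    seen = {network.ground_node}
    stack = [network.ground_node]
    while stack:
        u = stack.pop()
        for v in adj[u]:
            if v not in seen:
                seen.add(v)
                stack.append(v)
    missing = [network.node_labels[i] for i in range(network.n_nodes) if i not in seen]
    if missing:
        raise NetworkError(
            f"floating subgraph: {len(missing)} node(s) not connected to ground, "
            f"e.g. {missing[:5]}"
        )


def export_netlist(network: CircuitNetwork, drive) -> str:
    """Emit the network as a SPICE netlist (SIN source, R and C cards).

    Node 0 is ground; other nodes are named N<i>.  Any SPICE-class
    simulator can run the netlist for cross-validation of the native
    solver.
    """

    def node(i: int) -> str:
        return "0" if i == network.ground_node else f"N{i}"

    lines = [
        "* equivalent-circuit network of a plasma-treated well",
        f"* {network.n_regions} radial regions, {len(network.elements)} elements",
        f"V1 {node(network.source_node)} 0 SIN(0 {drive.amplitude:.6g} {drive.frequency:.6g})",
    ]
    counters = {"R": 0, "C": 0}
    for e in network.elements:
        counters[e.kind] += 1
        lines.append(
            f"{e.kind}{counters[e.kind]} {node(e.node_a)} {node(e.node_b)} "
            f"{e.value:.9g} ; {e.role}[{e.region + 1}]"
        )
    lines.append(f".tran {1.0 / (200 * drive.frequency):.4g} {5.0 / drive.frequency:.4g}")
    lines.append(".end")
    return "\n".join(lines) + "\n"
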