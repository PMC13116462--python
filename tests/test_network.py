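"""Element values and circuit-graph assembly."""

import math

import numpy as np
import pytest

from plasmadose.config import EPSILON_0, DriveConfig, GeometryConfig, MaterialConfig
from plasmadose.mesh import build_mesh, uniform_mesh
from plasmadose.network import (
    CircuitNetwork,
    NetworkError,
    assemble_network,
    element_values,
    export_netlist,
)

# a single-region "mesh" whose area is exactly 1 mm^2, for hand-checkable values
A_1MM2_RADIUS = math.sqrt(1e-6 / math.pi)


@pytest.fixture(scope="module")
def unit_elements():
    mesh = uniform_mesh(1, A_1MM2_RADIUS)
    return element_values(mesh, GeometryConfig(well_radius=A_1MM2_RADIUS), MaterialConfig())


def test_buffer_vertical_resistance_hand_value(unit_elements):
    # R = H/(sigma*A) = 1e-4 / (0.172 * 1e-6) = 581.40 ohm
    assert unit_elements.buffer_vertical_R[0] == pytest.approx(581.3953, rel=1e-4)


def test_membrane_capacitance_hand_value(unit_elements):
    # C = eps_m*A/T_m = 5*eps0*1e-6/7.5e-9 = 5.90 nF
    assert unit_elements.membrane_C[0] == pytest.approx(5.9028e-9, rel=1e-3)


def test_dish_capacitance_hand_value(unit_elements):
    # C = 2.4*eps0*1e-6/1.5e-3 = 1.417e-14 F
    assert unit_elements.dish_C[0] == pytest.approx(1.4167e-14, rel=1e-3)


def test_cytoplasm_parallel_rc_values(unit_elements):
    assert unit_elements.cytoplasm_vertical_R[0] == pytest.approx(1e-5 / 1e-6, rel=1e-12)
    assert unit_elements.cytoplasm_vertical_C[0] == pytest.approx(
        30 * EPSILON_0 * 1e-6 / 1e-5, rel=1e-12
    )


def test_conductivity_scaling():
    mesh = build_mesh(GeometryConfig())
    base = element_values(mesh, GeometryConfig(), MaterialConfig())
    doubled = element_values(mesh, GeometryConfig(), MaterialConfig(buffer_conductivity=0.344))
    np.testing.assert_allclose(doubled.buffer_vertical_R, base.buffer_vertical_R / 2, rtol=1e-12)
    np.testing.assert_allclose(doubled.buffer_radial_R, base.buffer_radial_R / 2, rtol=1e-12)


def test_area_scaling_r_down_c_up():
    g1 = GeometryConfig(well_radius=A_1MM2_RADIUS)
    g2 = GeometryConfig(well_radius=A_1MM2_RADIUS * math.sqrt(2))  # doubles the area
    e1 = element_values(uniform_mesh(1, g1.well_radius), g1, MaterialConfig())
    e2 = element_values(uniform_mesh(1, g2.well_radius), g2, MaterialConfig())
    assert e2.buffer_vertical_R[0] == pytest.approx(e1.buffer_vertical_R[0] / 2, rel=1e-12)
    assert e2.dish_C[0] == pytest.approx(e1.dish_C[0] * 2, rel=1e-12)


def test_annular_log_converges_to_slab_formula():
    """For thin outer rings, ln(r2/r1)/(2 pi sigma H) -> dr/(2 pi sigma r H)."""
    mesh = build_mesh(GeometryConfig())
    m = MaterialConfig()
    g = GeometryConfig()
    elements = element_values(mesh, g, m)
    for b in range(34, 39):  # outermost boundaries: dr/r << 1
        r_mid = 0.5 * (mesh.center_radii[b] + mesh.center_radii[b + 1])
        dr = mesh.center_radii[b + 1] - mesh.center_radii[b]
        slab = dr / (m.buffer_conductivity * 2 * np.pi * r_mid * g.buffer_height)
        assert elements.buffer_radial_R[b] == pytest.approx(slab, rel=0.01)


def test_zero_conductivity_gives_open_circuit():
    mesh = uniform_mesh(2, 1e-3)
    e = element_values(mesh, GeometryConfig(well_radius=1e-3), MaterialConfig(), lateral_junctions=False)
    e0 = element_values(
        mesh, GeometryConfig(well_radius=1e-3),
        MaterialConfig(cytoplasm_conductivity=0.0), lateral_junctions=False,
    )
    assert np.isfinite(e.cytoplasm_vertical_R).all()
    assert np.isinf(e0.cytoplasm_vertical_R).all()


class TestAssembly:
    @pytest.fixture(scope="class")
    def network(self):
        g, m, d = GeometryConfig(), MaterialConfig(), DriveConfig()
        mesh = build_mesh(g)
        return assemble_network(element_values(mesh, g, m), mesh, d)

    def test_element_counts(self, network):
        counts = {}
        for e in network.elements:
            counts[e.role] = counts.get(e.role, 0) + 1
        assert counts["buffer_vertical"] == 40
        assert counts["membrane_top"] == 40
        assert counts["membrane_bottom"] == 40
        assert counts["cytoplasm_vertical_R"] == 40
        assert counts["cytoplasm_vertical_C"] == 40
        assert counts["dish"] == 40
        assert counts["buffer_radial"] == 39
        assert counts["cytoplasm_radial"] == 39
        assert counts["cytoplasm_junction"] == 39

    def test_node_count_closed_form(self, network):
        # ground + 5 per region + one junction node per interior boundary
        assert network.n_nodes == 1 + 5 * 40 + 39

    def test_source_and_ground(self, network):
        assert network.ground_node == 0
        assert network.node_labels[network.source_node] == "buffer_top[1]"


def test_node_count_matches_hand_enumeration_for_three_region_toy():
    """Hand count for 3 regions: ground, 3x(buffer top, cell interface,
    cytoplasm top/bottom, dish interface) = 15, plus 2 junction nodes."""
    g = GeometryConfig(well_radius=1.5e-3)
    mesh = uniform_mesh(3, g.well_radius)
    net = assemble_network(element_values(mesh, g, MaterialConfig()), mesh, DriveConfig())
    assert net.n_nodes == 1 + 15 + 2
    # and without lateral junctions, the 2 junction nodes disappear
    net2 = assemble_network(
        element_values(mesh, g, MaterialConfig(), lateral_junctions=False), mesh, DriveConfig()
    )
    assert net2.n_nodes == 1 + 15


def test_disconnected_graph_rejected():
    """Zero buffer conductivity leaves outer buffer-top nodes floating."""
    g = GeometryConfig()
    mesh = build_mesh(g)
    with pytest.raises(NetworkError, match="floating"):
        assemble_network(
            element_values(mesh, g, MaterialConfig(buffer_conductivity=0.0)), mesh, DriveConfig()
        )


def test_removing_radial_links_leaves_independent_ladders():
    """Without radial links only ladder 1 (driven) carries current."""
    from plasmadose.solve import solve_phasor

    g, m, d = GeometryConfig(), MaterialConfig(), DriveConfig()
    mesh = build_mesh(g)
    net = assemble_network(element_values(mesh, g, m, lateral_junctions=False), mesh, d)
    kept = [e for e in net.elements
            if e.role not in ("buffer_radial", "cytoplasm_radial")]
    stripped = CircuitNetwork(
        n_nodes=net.n_nodes, elements=kept, source_node=net.source_node,
        ground_node=net.ground_node, node_labels=net.node_labels,
        n_regions=net.n_regions, geometry=net.geometry, materials=net.materials,
    )
    sol = solve_phasor(stripped, d)
    for e, i in zip(kept, sol.branch_currents):
        if e.region == 0 and e.role != "dish":
            assert abs(i) > 0
        elif e.region > 0:
            assert abs(i) == pytest.approx(0.0, abs=1e-18)


class TestNetlist:
    def test_single_resistor_toy(self):
        net = CircuitNetwork(
            n_nodes=2, elements=[], source_node=1, ground_node=0,
            node_labels=["ground", "top"], n_regions=1,
        )
        from plasmadose.network import Element

        net.elements.append(Element("R", 100.0, 1, 0, "buffer_vertical", 0))
        text = export_netlist(net, DriveConfig())
        lines = [l for l in text.splitlines() if l and not l.startswith(("*", ".", ";"))]
        assert lines[0].startswith("V1 ")
        assert "SIN(0 10000 20000)" in lines[0]
        assert lines[1].startswith("R1 ")
        assert text.rstrip().endswith(".end")

    def test_card_count_matches_element_count(self, pipeline):
        text = export_netlist(pipeline.network, pipeline.drive)
        cards = [l for l in text.splitlines() if l[:1] in ("R", "C")]
        assert len(cards) == len(pipeline.network.elements)
        # every card parses: name, two nodes, positive value
        for card in cards:
            name, n1, n2, value = card.split(";")[0].split()
            assert float(value) > 0
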