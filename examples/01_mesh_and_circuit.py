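"""Build the radial mesh of a well and its equivalent circuit network.

The well bottom (diameter 6.4 mm) is tiled by 40 concentric rings with a
non-uniform width scheme (finer at the centre, under the needle electrode,
and at the rim).  Each ring becomes a vertical R/C ladder from the buffer
surface down to the grounded plate, with radial links inside the buffer
and cell layers.
"""

import plasmadose as pld

geometry, materials, drive = pld.default_configs()
mesh = pld.build_mesh(geometry)
elements = pld.element_values(mesh, geometry, materials)
network = pld.assemble_network(elements, mesh, drive)

print(f"well radius          : {geometry.well_radius * 1e3:.2f} mm")
print(f"regions              : {mesh.n_regions}")
print(f"innermost ring width : {mesh.widths[0] * 1e3:.4f} mm  (= R/128)")
print(f"central ring width   : {mesh.widths[19] * 1e3:.4f} mm  (= R/32)")
print(f"sum of widths        : {mesh.widths.sum() * 1e3:.4f} mm  (tiles the well exactly)")
print(f"network              : {network.n_nodes} nodes, {len(network.elements)} elements")
print(f"region-1 buffer R    : {elements.buffer_vertical_R[0] / 1e3:.1f} kOhm")
print(f"region-1 membrane C  : {elements.membrane_C[0] * 1e12:.2f} pF")

# the same network as a SPICE netlist, for cross-validation elsewhere
netlist = pld.export_netlist(network, drive)
print(f"netlist              : {len(netlist.splitlines())} lines, starts with:")
print("   " + netlist.splitlines()[2])
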