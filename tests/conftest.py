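import pytest

import plasmadose as pld


class Pipeline:
    """Default end-to-end solve, shared across the suite (read-only)."""

    def __init__(self):
        self.geometry = pld.GeometryConfig()
        self.materials = pld.MaterialConfig()
        self.drive = pld.DriveConfig()
        self.mesh = pld.build_mesh(self.geometry)
        self.elements = pld.element_values(self.mesh, self.geometry, self.materials)
        self.network = pld.assemble_network(self.elements, self.mesh, self.drive)
        self.solution = pld.solve_phasor(self.network, self.drive)
        self.field = pld.cytoplasm_current_density(self.solution, self.mesh, self.network)


@pytest.fixture(scope="session")
def pipeline():
    return Pipeline()


@pytest.fixture(scope="session")
def field(pipeline):
    return pipeline.field


@pytest.fixture(scope="session")
def mesh(pipeline):
    return pipeline.mesh
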