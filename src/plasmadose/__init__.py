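"""plasmadose: equivalent-circuit dose modelling and threshold-based
cell-death models for discharge-plasma treatment of well-plate cell layers.

Pipeline: build the 40-region radial mesh of a well, assemble the
electrical equivalent circuit network (EECN) of buffer, cell layer and
dish, solve it in sinusoidal steady state, convert cytoplasm currents into
a volumetric dose field, evaluate One-Step/Two-Step threshold death
models, and fit the thresholds to radius-vs-duration data.
"""

from .config import (
    EPSILON_0,
    DriveConfig,
    GeometryConfig,
    MaterialConfig,
    convert_energy_density,
    convert_power_density,
    default_configs,
    load_config,
)
from .death import (
    STANDARD_DURATIONS,
    DeathCurve,
    DeathModelParams,
    death_curve,
    death_radius,
    sensitivity_sweep,
    time_to_death,
    time_to_death_profile,
)
from .dose import (
    DoseField,
    cytoplasm_current_density,
    injected_energy,
    instantaneous_power_waveform,
    peak_power,
)
from .fit import (
    DurationThresholdProfile,
    ExperimentDataset,
    FitResult,
    GridSpec,
    effective_pth,
    fit_thresholds,
)
from .mesh import RadialMesh, build_mesh, region_at_radius, uniform_mesh
from .network import (
    CircuitNetwork,
    ElementSet,
    assemble_network,
    element_values,
    export_netlist,
)
from .solve import (
    PhasorSolution,
    TransientSolution,
    kcl_residual,
    phasor_fit,
    power_audit,
    solve_phasor,
    solve_transient,
)
from .synth import generate_dataset

__version__ = "0.1.0"


def default_dose_field(geometry=None, materials=None, drive=None, return_all=False):
    """Convenience: run mesh -> network -> phasor solve -> dose field with
    the default (or given) configuration.

    With ``return_all=True`` returns (field, mesh, network, solution).
    """
    geometry = geometry or GeometryConfig()
    materials = materials or MaterialConfig()
    drive = drive or DriveConfig()
    mesh = build_mesh(geometry)
    network = assemble_network(element_values(mesh, geometry, materials), mesh, drive)
    solution = solve_phasor(network, drive)
    field = cytoplasm_current_density(solution, mesh, network)
    if return_all:
        return field, mesh, network, solution
    return field, mesh
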