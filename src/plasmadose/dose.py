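"""Electrical dose delivered to the cell layer.

From the solved network this module derives, per annular region, the
cytoplasm current-density phasors (vertical component J_z = I/A over the
ring's horizontal area, radial component J_r from the boundary currents
over the cylindrical lateral areas 2*pi*r*H_c), the instantaneous
volumetric power p(t) = (J_r(t)^2 + J_z(t)^2)/sigma with sigma the
cytoplasm conductivity, and the injected energy density w = int_0^Tp p dt.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid

__all__ = [
    "DoseField",
    "cytoplasm_current_density",
    "instantaneous_power_waveform",
    "injected_energy",
    "peak_power",
]

DEFAULT_SAMPLES_PER_CYCLE = 1024


class DoseError(ValueError):
    pass


@dataclass
class DoseField:
    """Per-region cytoplasm current-density phasors and derived dose.

    Jr, Jz : complex ndarray (A/m^2) under the x(t)=Im(X exp(jwt))
    convention; pbar is the cycle-averaged power density
    (|Jr|^2+|Jz|^2)/(2 sigma) in W/m^3; sigma the cytoplasm conductivity
    used in the power law; center_radii mirrors the mesh.
    """

    center_radii: np.ndarray
    Jr: np.ndarray
    Jz: np.ndarray
    sigma: float
    frequency: float
    pbar: np.ndarray

    @property
    def n_regions(self) -> int:
        return len(self.Jr)

    @property
    def period(self) -> float:
        return 1.0 / self.frequency


def cytoplasm_current_density(solution, mesh, network) -> DoseField:
    """Assemble the dose field from the cytoplasm branch currents.

    The vertical current of region n is the total (conduction plus
    displacement) current through the cytoplasm layer; the radial density
    of a region is the mean of the densities at its two ring boundaries
    (regions 1 and 40 have a single interior boundary).
    """
    n = mesh.n_regions
    by_role = {}
    for role in ("cytoplasm_vertical_R", "cytoplasm_vertical_C", "cytoplasm_radial"):
        idx = [k for k, e in enumerate(network.elements) if e.role == role]
        by_role[role] = {network.elements[k].region: solution.branch_currents[k] for k in idx}
    if len(by_role["cytoplasm_vertical_R"]) != n:
        raise DoseError("missing cytoplasm vertical branches in network")

    Hc = network.geometry.cell_height
    sigma = network.materials.cytoplasm_conductivity
    if sigma <= 0:
        raise DoseError("cytoplasm conductivity must be positive")

    Iz = np.array(
        [by_role["cytoplasm_vertical_R"][i] + by_role["cytoplasm_vertical_C"].get(i, 0j) for i in range(n)]
    )
    Jz = Iz / mesh.annulus_areas

    # current density at each interior boundary, positive outward
    Jb = np.array(
        [
            by_role["cytoplasm_radial"].get(i, 0j) / mesh.lateral_area(i, Hc)
            for i in range(n - 1)
        ]
    )
    Jr = np.empty(n, dtype=complex)
    Jr[0] = Jb[0] if n > 1 else 0j
    Jr[-1] = Jb[-1] if n > 1 else 0j
    if n > 2:
        Jr[1:-1] = 0.5 * (Jb[:-1] + Jb[1:])

    pbar = (np.abs(Jr) ** 2 + np.abs(Jz) ** 2) / (2.0 * sigma)
    return DoseField(
        center_radii=mesh.center_radii.copy(),
        Jr=Jr,
        Jz=Jz,
        sigma=sigma,
        frequency=solution.frequency,
        pbar=pbar,
    )


def _waveform_samples(field: DoseField, region: int, samples_per_cycle: int):
    """One drive period of p(t) for 1-based `region`: samples_per_cycle + 1
    points including both endpoints (p[0] == p[-1] by periodicity)."""
    if samples_per_cycle < 64:
        raise DoseError("samples_per_cycle must be >= 64")
    if field.sigma <= 0:
        raise DoseError("sigma must be positive")
    i = region - 1
    if not (0 <= i < field.n_regions):
        raise DoseError(f"region {region} out of range 1..{field.n_regions}")
    t = np.linspace(0.0, field.period, samples_per_cycle + 1)
    omega = 2.0 * np.pi * field.frequency
    jr = np.abs(field.Jr[i]) * np.sin(omega * t + np.angle(field.Jr[i]))
    jz = np.abs(field.Jz[i]) * np.sin(omega * t + np.angle(field.Jz[i]))
    return t, (jr**2 + jz**2) / field.sigma


def instantaneous_power_waveform(
    field: DoseField, region: int, samples_per_cycle: int = DEFAULT_SAMPLES_PER_CYCLE
):
    """Sampled instantaneous power density p(t) over one drive period.

    Returns (t, p) arrays of length samples_per_cycle + 1; p is
    non-negative and periodic (the squared sinusoids repeat at twice the
    drive frequency, hence exactly once per drive period as well).
    """
    return _waveform_samples(field, region, samples_per_cycle)


def peak_power(field: DoseField, region: int) -> float:
    """Peak of p(t) over a cycle, in closed form.

    With a = |Jr|^2 exp(2j phi_r) and b = |Jz|^2 exp(2j phi_z),
    p(t) = [(|Jr|^2+|Jz|^2) - Re((a+b) e^{2jwt+...})]/(2 sigma) peaks at
    [(|Jr|^2+|Jz|^2) + |a+b|]/(2 sigma).
    """
    i = region - 1
    a = field.Jr[i] ** 2  # == |Jr|^2 exp(2j phi)
    b = field.Jz[i] ** 2
    s = np.abs(field.Jr[i]) ** 2 + np.abs(field.Jz[i]) ** 2
    return float((s + abs(a + b)) / (2.0 * field.sigma))


def peak_power_profile(field: DoseField) -> np.ndarray:
    """Peak instantaneous power density of every region (W/m^3)."""
    return np.array([peak_power(field, i + 1) for i in range(field.n_regions)])


def injected_energy(
    field: DoseField,
    region: int,
    Tp: float,
    samples_per_cycle: int = DEFAULT_SAMPLES_PER_CYCLE,
) -> float:
    """Energy density w (J/m^3) injected over treatment duration Tp.

    Trapezoidal integration of the sampled periodic waveform: whole drive
    periods contribute exactly the per-period energy; the final partial
    period is handled by interpolating the within-period cumulative
    integral.
    """
    if Tp < 0:
        raise DoseError("Tp must be non-negative")
    if Tp == 0:
        return 0.0
    t, p = _waveform_samples(field, region, samples_per_cycle)
    c = cumulative_trapezoid(p, t, initial=0.0)
    period = field.period
    n_full = np.floor(Tp / period)
    remainder = Tp - n_full * period
    return float(n_full * c[-1] + np.interp(remainder, t, c))
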