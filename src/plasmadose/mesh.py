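"""Radial discretization of the well into 40 concentric annular regions.

The well bottom is tiled by 40 rings with a fixed non-uniform width
scheme: the innermost four and outermost four rings have width R/128,
the next two on each side R/64, and the 28 central rings R/32
(4*1 + 2*2 + 28*4 + 2*2 + 4*1 = 128 parts of R/128, so the rings tile
[0, R] exactly).  The fine centre resolves the steep field gradient under
the needle electrode; the fine rim resolves the wall boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["RadialMesh", "build_mesh", "uniform_mesh", "region_at_radius"]

# Ring widths in units of R/128 (sums to 128).
_WIDTH_UNITS = np.array([1] * 4 + [2] * 2 + [4] * 28 + [2] * 2 + [1] * 4)


class MeshError(ValueError):
    pass


@dataclass(frozen=True)
class RadialMesh:
    """Concentric annular tiling of the well bottom.

    Arrays are indexed 0..n_regions-1; the conventional region number n
    (1-based, centre outward) is the array index + 1.

    Attributes
    ----------
    well_radius : float
        Outer radius R of the tiled disc (m).
    widths, inner_radii, outer_radii, center_radii : ndarray
        Per-region ring width and bounding/centre radii (m);
        center_radii is the arithmetic midpoint of each ring.
    annulus_areas : ndarray
        Horizontal cross-section pi*(r_out^2 - r_in^2) of each ring (m^2).
    """

    well_radius: float
    widths: np.ndarray
    inner_radii: np.ndarray
    outer_radii: np.ndarray
    center_radii: np.ndarray
    annulus_areas: np.ndarray

    @property
    def n_regions(self) -> int:
        return len(self.widths)

    @property
    def boundary_radii(self) -> np.ndarray:
        """Radii of the n_regions-1 interfaces between adjacent rings (m)."""
        return self.outer_radii[:-1]

    def lateral_area(self, boundary: int, layer_height: float) -> float:
        """Cylindrical interface area 2*pi*r*H at interior boundary `boundary`
        (0-based, between rings boundary and boundary+1) for a conducting
        layer of height `layer_height`."""
        return 2.0 * np.pi * self.boundary_radii[boundary] * layer_height

    def area_weighted_center_radii(self) -> np.ndarray:
        """Area-weighted centroid radius of each ring, an alternative to the
        midpoint convention: (2/3)(r_out^3 - r_in^3)/(r_out^2 - r_in^2)."""
        ri, ro = self.inner_radii, self.outer_radii
        return (2.0 / 3.0) * (ro**3 - ri**3) / (ro**2 - ri**2)


def _mesh_from_units(units: np.ndarray, well_radius: float, denom: int) -> RadialMesh:
    if not well_radius > 0:
        raise MeshError(f"well_radius must be strictly positive, got {well_radius!r}")
    # accumulate in exact integers so the rings tile [0, R] machine-exactly
    # (cum/denom is computed first: it is exactly 1.0 at the outer edge)
    cum = np.concatenate([[0], np.cumsum(units)])
    inner = well_radius * (cum[:-1] / denom)
    outer = well_radius * (cum[1:] / denom)
    widths = well_radius * (units / denom)
    center = 0.5 * (inner + outer)
    areas = np.pi * (outer**2 - inner**2)
    return RadialMesh(
        well_radius=well_radius,
        widths=widths,
        inner_radii=inner,
        outer_radii=outer,
        center_radii=center,
        annulus_areas=areas,
    )


def build_mesh(geometry) -> RadialMesh:
    """Build the fixed 40-region mesh for a well of the given geometry."""
    return _mesh_from_units(_WIDTH_UNITS, geometry.well_radius, 128)


def uniform_mesh(n_regions: int, well_radius: float) -> RadialMesh:
    """Uniform-width mesh with `n_regions` rings.

    Not part of the production discretization scheme; used to build small
    toy networks for solver validation.
    """
    if n_regions < 1:
        raise MeshError("n_regions must be >= 1")
    return _mesh_from_units(np.ones(n_regions, dtype=int), well_radius, n_regions)


def region_at_radius(mesh: RadialMesh, r: float) -> int:
    """Region number n (1-based) containing radius ``r``.

    Rings are half-open [inner, outer), except the outermost ring which is
    closed so that r = R maps to n = n_regions.
    """
    if not (0 <= r <= mesh.well_radius):
        raise MeshError(f"radius {r!r} outside [0, {mesh.well_radius}]")
    if r == mesh.well_radius:
        return mesh.n_regions
    idx = int(np.searchsorted(mesh.outer_radii, r, side="right"))
    return idx + 1
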