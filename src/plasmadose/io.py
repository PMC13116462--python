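"""CSV/JSON writers shared across the pipeline, plus the run manifest.

Dialect: comma-separated, header row, '.' decimal, UTF-8, no index column.
Lengths in files are mm, durations ms, thresholds uW/mm^3 and uJ/mm^3
(reporting units); everything in memory is SI.
"""

from __future__ import annotations

import datetime
import json
from importlib import metadata

import numpy as np
import pandas as pd

__all__ = [
    "mesh_frame",
    "dose_frame",
    "death_curve_frame",
    "sweep_frame",
    "write_manifest",
]


def mesh_frame(mesh) -> pd.DataFrame:
    """Mesh dump: n, width_mm, inner_mm, center_mm, outer_mm, annulus_area_mm2."""
    return pd.DataFrame(
        {
            "n": np.arange(1, mesh.n_regions + 1),
            "width_mm": mesh.widths * 1e3,
            "inner_mm": mesh.inner_radii * 1e3,
            "center_mm": mesh.center_radii * 1e3,
            "outer_mm": mesh.outer_radii * 1e3,
            "annulus_area_mm2": mesh.annulus_areas * 1e6,
        }
    )


def dose_frame(field) -> pd.DataFrame:
    """Dose field dump; the input contract for the death/fit stages."""
    return pd.DataFrame(
        {
            "region": np.arange(1, field.n_regions + 1),
            "center_radius_mm": field.center_radii * 1e3,
            "Jr_amp": np.abs(field.Jr),
            "Jr_phase": np.angle(field.Jr),
            "Jz_amp": np.abs(field.Jz),
            "Jz_phase": np.angle(field.Jz),
            "pbar_W_per_m3": field.pbar,
        }
    )


def load_dose_frame(df: pd.DataFrame, sigma: float, frequency: float):
    """Rebuild a DoseField from its CSV representation."""
    from .dose import DoseField

    Jr = df["Jr_amp"].to_numpy() * np.exp(1j * df["Jr_phase"].to_numpy())
    Jz = df["Jz_amp"].to_numpy() * np.exp(1j * df["Jz_phase"].to_numpy())
    return DoseField(
        center_radii=df["center_radius_mm"].to_numpy() * 1e-3,
        Jr=Jr,
        Jz=Jz,
        sigma=sigma,
        frequency=frequency,
        pbar=df["pbar_W_per_m3"].to_numpy(),
    )


def death_curve_frame(curve) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "duration_ms": curve.durations * 1e3,
            "radius_mm": curve.radii * 1e3,
            "saturated": curve.saturated,
            "censored": curve.censored,
        }
    )


def sweep_frame(curves) -> pd.DataFrame:
    frames = []
    for curve in curves:
        df = death_curve_frame(curve)
        df.insert(0, "Pth_uW_mm3", curve.params.pth_uW_mm3)
        df.insert(1, "Wth_uJ_mm3", curve.params.wth_uJ_mm3)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def _package_version() -> str:
    try:
        return metadata.version("plasmadose")
    except metadata.PackageNotFoundError:
        return "unknown"


def write_manifest(path, *, config: dict, inputs=None, outputs=None, seed=None, extra=None) -> dict:
    """Write a JSON run manifest sufficient to reproduce the run."""
    manifest = {
        "package": "plasmadose",
        "version": _package_version(),
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "seed": seed,
        "config": config,
        "inputs": inputs or [],
        "outputs": outputs or [],
    }
    if extra:
        manifest.update(extra)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def config_as_dict(geometry, materials, drive) -> dict:
    """Materialize all resolved configuration values (SI) for the manifest."""
    import dataclasses

    return {
        "geometry": dataclasses.asdict(geometry),
        "materials": dataclasses.asdict(materials),
        "drive": dataclasses.asdict(drive),
    }
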