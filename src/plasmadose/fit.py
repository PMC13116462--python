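"""Threshold fitting: grid search for (Pth, Wth) against radius-vs-duration
data, and per-duration effective-Pth estimation for the short-duration
regime.

The grid search evaluates the Two-Step forward model at the experimental
durations for every threshold pair on a coarse grid, scores the sum of
squared radius residuals against the per-duration mean radii (equal
weights), then refines once at 5x resolution around the coarse argmin.
Ties are broken toward the smallest Pth, then the smallest Wth, so the fit
is fully deterministic.

The effective-Pth estimator inverts the forward model per duration: it
finds, by bisection, the power threshold at which the predicted death
radius equals the observed one (the radius is non-increasing in Pth, so
the root is well defined whenever it is bracketed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from .death import (
    DEFAULT_SAMPLES_PER_CYCLE,
    DeathModelParams,
    _death_radius_from_profile,
)
from .dose import _waveform_samples

__all__ = [
    "ExperimentDataset",
    "GridSpec",
    "FitResult",
    "DurationThresholdProfile",
    "fit_thresholds",
    "effective_pth",
]


class FitError(ValueError):
    pass


@dataclass
class ExperimentDataset:
    """Radius-vs-duration measurements with replicates.

    ``data`` has columns ``duration`` (s), ``replicate`` (int) and
    ``radius`` (m).  The CSV dialect uses reporting units
    (duration_ms, replicate, radius_mm).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"duration", "replicate", "radius"}
        missing = required - set(self.data.columns)
        if missing:
            raise FitError(f"dataset missing columns: {sorted(missing)}")
        if (self.data["radius"] < 0).any():
            raise FitError("radii must be non-negative")
        if (self.data["duration"] <= 0).any():
            raise FitError("durations must be strictly positive")

    @classmethod
    def from_arrays(cls, durations, radii, replicates=None) -> "ExperimentDataset":
        durations = np.asarray(durations, dtype=float)
        radii = np.asarray(radii, dtype=float)
        if replicates is None:
            replicates = np.zeros(len(durations), dtype=int)
        return cls(pd.DataFrame({"duration": durations, "replicate": replicates, "radius": radii}))

    @classmethod
    def from_csv(cls, path) -> "ExperimentDataset":
        df = pd.read_csv(path)
        required = {"duration_ms", "replicate", "radius_mm"}
        missing = required - set(df.columns)
        if missing:
            raise FitError(f"dataset CSV missing columns: {sorted(missing)}")
        return cls(
            pd.DataFrame(
                {
                    "duration": df["duration_ms"] * 1e-3,
                    "replicate": df["replicate"].astype(int),
                    "radius": df["radius_mm"] * 1e-3,
                }
            )
        )

    def to_csv(self, path) -> None:
        out = pd.DataFrame(
            {
                "duration_ms": self.data["duration"] * 1e3,
                "replicate": self.data["replicate"].astype(int),
                "radius_mm": self.data["radius"] * 1e3,
            }
        )
        out.to_csv(path, index=False)

    def summary(self) -> pd.DataFrame:
        """Per-duration mean, SD (ddof=1; NaN for n=1) and replicate count."""
        g = self.data.groupby("duration")["radius"]
        out = g.agg(mean="mean", sd="std", n="count").reset_index()
        return out.sort_values("duration").reset_index(drop=True)

    @property
    def durations(self) -> np.ndarray:
        return np.sort(self.data["duration"].unique())


@dataclass(frozen=True)
class GridSpec:
    """Threshold search grid, in SI units (W/m^3 and J/m^3)."""

    pth_values: np.ndarray
    wth_values: np.ndarray
    refine_factor: int = 5

    @classmethod
    def default(cls) -> "GridSpec":
        # Pth 0..20 uW/mm^3 step 0.5; Wth 0.05..1.0 uJ/mm^3 step 0.05
        # (1 uW/mm^3 = 1e3 W/m^3): brackets the plausible range with headroom.
        return cls(
            pth_values=np.arange(0, 41) * 500.0,
            wth_values=np.arange(1, 21) * 50.0,
        )


@dataclass
class FitResult:
    """Outcome of the two-stage grid search.

    best_params attains the minimum of the refined objective; objective is
    the summed squared radius residual (m^2).  objective_grid holds the
    coarse surface (pth rows x wth columns); refinement the refined grids
    and surface.  ``degenerate`` flags an all-zero-radius dataset, for
    which the fit is a boundary solution (Wth at the grid maximum).
    """

    best_params: DeathModelParams
    objective: float
    pth_values: np.ndarray
    wth_values: np.ndarray
    objective_grid: np.ndarray
    refinement: dict
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "best_Pth_uW_mm3": self.best_params.pth_uW_mm3,
            "best_Wth_uJ_mm3": self.best_params.wth_uJ_mm3,
            "objective_mm2": self.objective * 1e6,
            "degenerate": self.degenerate,
            "grid": {
                "Pth_uW_mm3": (self.pth_values / 1e3).tolist(),
                "Wth_uJ_mm3": (self.wth_values / 1e3).tolist(),
            },
            "refinement": {
                "Pth_uW_mm3": (self.refinement["pth_values"] / 1e3).tolist(),
                "Wth_uJ_mm3": (self.refinement["wth_values"] / 1e3).tolist(),
                "objective_mm2": (self.refinement["objective_grid"] * 1e6).tolist(),
            },
        }


class CurveEvaluator:
    """Fast repeated evaluation of the Two-Step death curve.

    Samples each region's instantaneous-power waveform once; per Pth the
    gated within-period cumulative integral is cached, so sweeping Wth and
    durations costs only searchsorted lookups.
    """

    def __init__(self, dose_field, mesh, samples_per_cycle: int = DEFAULT_SAMPLES_PER_CYCLE):
        self.field = dose_field
        self.mesh = mesh
        self.period = dose_field.period
        waves = [
            _waveform_samples(dose_field, i + 1, samples_per_cycle)
            for i in range(dose_field.n_regions)
        ]
        self.t = waves[0][0]
        self.P = np.vstack([w[1] for w in waves])  # (n_regions, S+1)
        self._gate_cache: dict[float, tuple[np.ndarray, np.ndarray]] = {}

    def _gated(self, pth: float) -> tuple[np.ndarray, np.ndarray]:
        cached = self._gate_cache.get(pth)
        if cached is None:
            g = np.where(self.P >= pth, self.P, 0.0)
            c = cumulative_trapezoid(g, self.t, axis=1, initial=0.0)
            cached = (c, c[:, -1])
            if len(self._gate_cache) > 256:
                self._gate_cache.clear()
            self._gate_cache[pth] = cached
        return cached

    def t_star_profile(self, pth: float, wth: float) -> np.ndarray:
        c, e_period = self._gated(pth)
        out = np.full(self.field.n_regions, np.inf)
        for i in range(self.field.n_regions):
            ep = e_period[i]
            if ep <= 0:
                continue
            k = math.floor(wth / ep)
            rem = wth - k * ep
            if rem == 0.0 and k > 0:
                k -= 1
                rem = ep
            row = c[i]
            idx = int(np.searchsorted(row, rem, side="left"))
            if idx == 0:
                tau = 0.0
            else:
                tau = self.t[idx - 1] + (rem - row[idx - 1]) / (row[idx] - row[idx - 1]) * (
                    self.t[idx] - self.t[idx - 1]
                )
            out[i] = k * self.period + tau
        return out

    def radii(self, pth: float, wth: float, durations, interpolation="linear") -> np.ndarray:
        t_star = self.t_star_profile(pth, wth)
        return np.array(
            [
                _death_radius_from_profile(
                    t_star, self.mesh.center_radii, self.mesh.well_radius, Tp, interpolation
                )[0]
                for Tp in durations
            ]
        )


def _objective_surface(evaluator, pth_values, wth_values, durations, observed):
    obj = np.empty((len(pth_values), len(wth_values)))
    for i, pth in enumerate(pth_values):
        for j, wth in enumerate(wth_values):
            model = evaluator.radii(pth, wth, durations)
            obj[i, j] = float(np.sum((model - observed) ** 2))
    return obj


def _argmin_first(obj: np.ndarray) -> tuple[int, int]:
    # row-major argmin = smallest Pth, then smallest Wth, on exact ties
    flat = int(np.argmin(obj))
    return flat // obj.shape[1], flat % obj.shape[1]


def fit_thresholds(
    dataset: ExperimentDataset,
    dose_field,
    mesh,
    grid: GridSpec | None = None,
    samples_per_cycle: int = DEFAULT_SAMPLES_PER_CYCLE,
) -> FitResult:
    """Fit (Pth, Wth) to the dataset's per-duration mean radii.

    Coarse grid search followed by one local refinement at 5x resolution
    around the argmin; deterministic for identical inputs.  Requires at
    least two distinct durations (one duration leaves a ridge of
    equivalent optima).
    """
    if grid is None:
        grid = GridSpec.default()
    summary = dataset.summary()
    if len(summary) < 2:
        raise FitError("fit requires >= 2 distinct treatment durations")
    durations = summary["duration"].to_numpy()
    observed = summary["mean"].to_numpy()
    evaluator = CurveEvaluator(dose_field, mesh, samples_per_cycle)

    obj = _objective_surface(evaluator, grid.pth_values, grid.wth_values, durations, observed)

    if np.all(observed == 0.0):
        best = DeathModelParams(pth=float(grid.pth_values[0]), wth=float(grid.wth_values[-1]))
        return FitResult(
            best_params=best,
            objective=float(obj[0, -1]),
            pth_values=grid.pth_values,
            wth_values=grid.wth_values,
            objective_grid=obj,
            refinement={
                "pth_values": np.array([best.pth]),
                "wth_values": np.array([best.wth]),
                "objective_grid": np.array([[obj[0, -1]]]),
            },
            degenerate=True,
        )

    i0, j0 = _argmin_first(obj)

    pth_fine = grid.pth_values[i0] + np.arange(-grid.refine_factor, grid.refine_factor + 1) * (
        (np.median(np.diff(grid.pth_values)) if len(grid.pth_values) > 1 else 0.0)
        / grid.refine_factor
    )
    pth_fine = np.unique(pth_fine[pth_fine >= 0.0])
    wth_fine = grid.wth_values[j0] + np.arange(-grid.refine_factor, grid.refine_factor + 1) * (
        (np.median(np.diff(grid.wth_values)) if len(grid.wth_values) > 1 else 0.0)
        / grid.refine_factor
    )
    wth_fine = np.unique(wth_fine[wth_fine > 0.0])

    obj_fine = _objective_surface(evaluator, pth_fine, wth_fine, durations, observed)
    i1, j1 = _argmin_first(obj_fine)
    best = DeathModelParams(pth=float(pth_fine[i1]), wth=float(wth_fine[j1]))
    return FitResult(
        best_params=best,
        objective=float(obj_fine[i1, j1]),
        pth_values=grid.pth_values,
        wth_values=grid.wth_values,
        objective_grid=obj,
        refinement={
            "pth_values": pth_fine,
            "wth_values": wth_fine,
            "objective_grid": obj_fine,
        },
    )


@dataclass
class ProfileEntry:
    duration: float
    effective_pth: float | None
    converged: bool


@dataclass
class DurationThresholdProfile:
    """Per-duration effective power threshold (short-duration regime)."""

    entries: list
    wth: float
    bracket: tuple

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "duration_ms": [e.duration * 1e3 for e in self.entries],
                "effective_Pth_uW_mm3": [
                    (e.effective_pth / 1e3 if e.effective_pth is not None else np.nan)
                    for e in self.entries
                ],
                "converged": [e.converged for e in self.entries],
            }
        )


def effective_pth(
    dataset: ExperimentDataset,
    dose_field,
    mesh,
    wth: float,
    bracket: tuple = (0.0, 4.0e5),
    rtol: float = 0.005,
    max_duration: float = 10e-3,
    samples_per_cycle: int = DEFAULT_SAMPLES_PER_CYCLE,
) -> DurationThresholdProfile:
    """Per-duration Pth such that the predicted death radius matches the
    observed mean radius, for durations up to ``max_duration``.

    Bisection over ``bracket`` (W/m^3) to a tolerance of ``rtol`` times
    the bracket width; entries whose target radius lies outside the
    attainable range over the bracket are flagged non-convergent and carry
    no value.
    """
    lo0, hi0 = bracket
    if not (hi0 > lo0 >= 0):
        raise FitError("bracket must satisfy 0 <= lo < hi")
    summary = dataset.summary()
    short = summary[summary["duration"] <= max_duration * (1 + 1e-12)]
    if len(short) == 0:
        raise FitError(f"no durations <= {max_duration} in dataset")
    evaluator = CurveEvaluator(dose_field, mesh, samples_per_cycle)
    tol = rtol * (hi0 - lo0)

    entries = []
    for _, row in short.iterrows():
        T, target = float(row["duration"]), float(row["mean"])

        def f(p: float) -> float:
            return float(evaluator.radii(p, wth, [T])[0])

        f_lo, f_hi = f(lo0), f(hi0)
        # radius is non-increasing in pth: need f(hi) <= target <= f(lo)
        if not (f_hi <= target <= f_lo):
            entries.append(ProfileEntry(T, None, False))
            continue
        lo, hi = lo0, hi0
        while hi - lo > tol:
            mid = 0.5 * (lo + hi)
            if f(mid) >= target:
                lo = mid
            else:
                hi = mid
        entries.append(ProfileEntry(T, 0.5 * (lo + hi), True))
    return DurationThresholdProfile(entries=entries, wth=wth, bracket=(lo0, hi0))
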