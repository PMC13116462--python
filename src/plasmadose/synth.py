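"""Synthetic radius-vs-duration experiments.

Emulates the structure of the wet-lab dataset this pipeline consumes:
eleven log-spaced treatment durations between 2 and 100 ms, a handful of
replicate wells per duration (mean radius with SD, n = 4 wells), radii
monotonically increasing and roughly linear in log duration.  The
per-duration mean is the forward Two-Step death radius under the chosen
true thresholds; replicates add homoscedastic Gaussian noise truncated at
zero.  An optional short-duration suppression multiplicatively shrinks
radii for durations at or below 10 ms, mimicking the elevated apparent
power tolerance of cells under very brief stimuli; it exists to exercise
the effective-Pth estimator, not as a claim about biology.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .death import STANDARD_DURATIONS, DeathModelParams, death_curve
from .fit import ExperimentDataset

__all__ = ["generate_dataset", "suppression_factors"]

#: Default replicate count and radius noise (m): n = 4 wells, SD 0.02 mm,
#: small relative to the millimetre-scale radii being emulated.
DEFAULT_N_REP = 4
DEFAULT_NOISE_SD = 0.02e-3
SHORT_DURATION_CUTOFF = 10e-3


def suppression_factors(durations: np.ndarray, fraction_per_decade: float) -> np.ndarray:
    """Multiplicative radius deficit for short durations.

    factor = max(0, 1 - s*log10(cutoff/T)) for T <= 10 ms, 1 otherwise:
    the deficit grows by ``fraction_per_decade`` for every decade the
    duration falls below the cutoff.
    """
    durations = np.asarray(durations, dtype=float)
    factors = np.ones_like(durations)
    short = durations <= SHORT_DURATION_CUTOFF
    factors[short] = np.maximum(
        0.0, 1.0 - fraction_per_decade * np.log10(SHORT_DURATION_CUTOFF / durations[short])
    )
    return factors


def generate_dataset(
    dose_field,
    mesh,
    true_params: DeathModelParams,
    durations=STANDARD_DURATIONS,
    noise_sd: float = DEFAULT_NOISE_SD,
    n_rep: int = DEFAULT_N_REP,
    seed: int = 0,
    short_suppression: float | None = None,
) -> ExperimentDataset:
    """Generate a reproducible synthetic experiment.

    Per duration, the mean radius is the forward Two-Step death radius
    under ``true_params`` (optionally suppressed for durations <= 10 ms);
    each of ``n_rep`` replicates is mean + N(0, noise_sd), truncated at 0.
    Identical seeds give identical datasets.
    """
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    durations = np.asarray(list(durations), dtype=float)
    curve = death_curve(dose_field, mesh, true_params, durations)
    means = curve.radii.copy()
    if short_suppression is not None:
        means *= suppression_factors(durations, short_suppression)
    rng = np.random.default_rng(seed)
    rows = []
    for T, mean in zip(durations, means):
        noise = rng.normal(0.0, noise_sd, size=n_rep) if noise_sd > 0 else np.zeros(n_rep)
        radii = np.maximum(0.0, mean + noise)
        for rep, r in enumerate(radii):
            rows.append((T, rep, r))
    df = pd.DataFrame(rows, columns=["duration", "replicate", "radius"])
    return ExperimentDataset(df)
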