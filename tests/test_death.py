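"""One-Step / Two-Step time-to-death, radius inversion, and sweeps."""

import math

import numpy as np
import pytest

from plasmadose.death import (
    DeathModelError,
    DeathModelParams,
    death_curve,
    death_radius,
    gated_time_to_threshold,
    sensitivity_sweep,
    time_to_death,
    time_to_death_profile,
)
from plasmadose.dose import DoseField, _waveform_samples
from plasmadose.mesh import uniform_mesh

DURATIONS_MS = (2, 3, 4, 6, 8, 10, 20, 30, 40, 50, 100)
DURATIONS = tuple(d * 1e-3 for d in DURATIONS_MS)


class TestGatedAccumulation:
    def test_constant_power_closed_form(self):
        """p = 1000 W/m^3, no gate, Wth = 300 J/m^3 -> T* = 0.3 s."""
        p = np.full(129, 1000.0)
        assert gated_time_to_threshold(p, 1.0, 0.0, 300.0) == pytest.approx(0.3, rel=1e-12)

    def test_gate_never_opens(self):
        p = np.full(129, 1000.0)
        assert math.isinf(gated_time_to_threshold(p, 1.0, 1000.1, 300.0))

    def test_threshold_equality_accumulates(self):
        """H(0) = 1: power exactly at the gate still counts."""
        p = np.full(129, 1000.0)
        assert gated_time_to_threshold(p, 1.0, 1000.0, 300.0) == pytest.approx(0.3, rel=1e-12)

    def test_square_wave_hand_integration(self):
        """10 W/m^3 for the first half of each 1 s period, gate at 5:
        5 J accumulated by t=0.5, 9 J reached at t=1.4.  A target that
        falls exactly on the inter-burst plateau (e.g. 10 J at t=1.5) is a
        knife edge under sampling, so it is only bounded from below."""
        n = 4096
        p = np.where(np.arange(n + 1) < n // 2, 10.0, 0.0)
        t = gated_time_to_threshold(p, 1.0, 5.0, 9.0)
        assert t == pytest.approx(1.4, rel=2e-3)
        assert gated_time_to_threshold(p, 1.0, 5.0, 10.0) >= 1.5 - 1e-3

    def test_zero_threshold_is_immediate(self):
        p = np.full(129, 1.0)
        assert gated_time_to_threshold(p, 1.0, 0.0, 0.0) == 0.0

    def test_t_max_censoring(self):
        p = np.full(129, 1000.0)
        assert math.isinf(gated_time_to_threshold(p, 1.0, 0.0, 300.0, t_max=0.2))


def test_time_to_death_on_field_and_censoring(field):
    params = DeathModelParams.from_reporting_units(7.0, 0.3)
    t_inner = time_to_death(field, 1, params, Tp_max=0.1)
    assert t_inner is not None and 0 < t_inner < 1e-3
    # far outside the gated zone nothing accumulates
    assert time_to_death(field, 40, params, Tp_max=10.0) is None


def test_one_step_params_reject_nonzero_pth():
    with pytest.raises(DeathModelError):
        DeathModelParams(pth=1.0, wth=1.0, model_kind="one_step")
    with pytest.raises(DeathModelError):
        DeathModelParams(pth=0.0, wth=0.0)


def test_reduction_identity_bitwise(field):
    one = time_to_death_profile(field, DeathModelParams.one_step(300.0))
    two = time_to_death_profile(field, DeathModelParams(pth=0.0, wth=300.0))
    np.testing.assert_array_equal(one, two)


def test_profile_monotone_in_thresholds(field):
    base = time_to_death_profile(field, DeathModelParams(pth=3500.0, wth=300.0))
    higher_w = time_to_death_profile(field, DeathModelParams(pth=3500.0, wth=400.0))
    higher_p = time_to_death_profile(field, DeathModelParams(pth=5000.0, wth=300.0))
    assert np.all(higher_w >= base)
    assert np.all(higher_p >= base)


class TestDeathRadius:
    def test_unreachable_threshold_gives_zero(self, field, mesh):
        assert death_radius(field, mesh, DeathModelParams.one_step(1e12), 0.1) == 0.0

    def test_monotone_in_duration(self, field, mesh):
        params = DeathModelParams.from_reporting_units(7.0, 0.3)
        curve = death_curve(field, mesh, params, DURATIONS)
        assert np.all(np.diff(curve.radii) >= 0)
        assert len(curve.radii) == len(DURATIONS_MS)

    def test_radius_bounded_by_well(self, field, mesh):
        params = DeathModelParams.one_step(1.0)  # tiny threshold: everything dies
        r = death_radius(field, mesh, params, 1.0)
        assert r == mesh.well_radius

    def test_nearest_mode_snaps_to_ring_centers(self, field, mesh):
        params = DeathModelParams.from_reporting_units(7.0, 0.3)
        r = death_radius(field, mesh, params, 0.02, interpolation="nearest")
        assert r in mesh.center_radii

    def test_nonmonotone_profile_rejected(self):
        """A dose field with an interior hot spot breaks the disc premise."""
        mesh = uniform_mesh(5, 1e-3)
        jz = np.array([3.0, 1.0, 5.0, 1.0, 0.5])  # hot spot at region 3
        fld = DoseField(
            center_radii=mesh.center_radii, Jr=np.zeros(5, complex),
            Jz=jz.astype(complex), sigma=1.0, frequency=20e3, pbar=jz**2 / 2,
        )
        with pytest.raises(DeathModelError, match="monotone"):
            death_radius(fld, mesh, DeathModelParams.one_step(1e-2), 10.0)


def _brute_force_radius(field, mesh, params, Tp, samples_per_cycle=512):
    """Independent oracle: dense time integration over [0, Tp] for every
    region (no periodicity shortcut, no interpolation), nearest-region
    radius of the outermost region whose gated energy reaches Wth."""
    n_cycles = int(np.ceil(Tp * field.frequency))
    dead = np.zeros(field.n_regions, bool)
    for i in range(field.n_regions):
        t1, p1 = _waveform_samples(field, i + 1, samples_per_cycle)
        p = np.tile(p1[:-1], n_cycles + 1)
        t = np.arange(len(p)) * (t1[1] - t1[0])
        keep = t <= Tp
        p, t = p[keep], t[keep]
        g = np.where(p >= params.pth, p, 0.0)
        w = np.concatenate([[0.0], np.cumsum(0.5 * (g[1:] + g[:-1]) * np.diff(t))])
        dead[i] = w[-1] >= params.wth
    if not dead.any():
        return 0.0
    if dead.all():
        return mesh.well_radius
    return mesh.center_radii[np.max(np.where(dead)[0])]


def test_death_radius_matches_brute_force_oracle(field, mesh):
    rng = np.random.default_rng(7)
    for _ in range(20):
        params = DeathModelParams(
            pth=float(rng.uniform(0, 15e3)), wth=float(rng.uniform(100.0, 600.0))
        )
        Tp = float(rng.choice([2e-3, 5e-3, 10e-3, 20e-3]))
        r_model = death_radius(field, mesh, params, Tp)
        r_oracle = _brute_force_radius(field, mesh, params, Tp)
        idx = np.searchsorted(mesh.outer_radii, min(r_model, mesh.well_radius * 0.999))
        local_width = mesh.widths[min(idx + 1, 39)] + mesh.widths[idx]
        assert abs(r_model - r_oracle) <= local_width, (params, Tp)


class TestSweep:
    def test_curves_ordered_in_wth(self, field, mesh):
        grid = [DeathModelParams.one_step(w * 1e3) for w in (0.2, 0.3, 0.4)]
        curves = sensitivity_sweep(field, mesh, grid, DURATIONS)
        assert len(curves) == 3
        assert np.all(curves[0].radii >= curves[1].radii)
        assert np.all(curves[1].radii >= curves[2].radii)

    def test_curves_ordered_in_pth(self, field, mesh):
        grid = [DeathModelParams.from_reporting_units(p, 0.3) for p in (5.0, 7.0, 9.0)]
        curves = sensitivity_sweep(field, mesh, grid, DURATIONS)
        assert np.all(curves[0].radii >= curves[1].radii)
        assert np.all(curves[1].radii >= curves[2].radii)

    def test_empty_grid(self, field, mesh):
        assert sensitivity_sweep(field, mesh, [], DURATIONS) == []


def test_death_curve_rejects_bad_durations(field, mesh):
    params = DeathModelParams.one_step(300.0)
    with pytest.raises(DeathModelError):
        death_curve(field, mesh, params, [])
    with pytest.raises(DeathModelError):
        death_curve(field, mesh, params, [-1e-3])
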