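"""Stokes solver: benchmarks, linearity, inverse fit, cycle driver."""

import numpy as np
import pytest

from oftflow import flow, geometry, hemo
from oftflow.flow import (
    FluidProps,
    FlowError,
    StokesOperator,
    fit_inlet_traction,
    monitor_velocity,
    reynolds_womersley,
    simulate_cycle,
    solve_steady,
)

from conftest import cylinder_series


PROPS = FluidProps()


@pytest.fixture(scope="module")
def cyl_mesh():
    series = cylinder_series(radius=0.2, n_slices=51, spacing=0.02)
    return geometry.build_mesh(series, 0, 14, 16, 3,
                               extension_length_factor=1.0)


@pytest.fixture(scope="module")
def cyl_solution(cyl_mesh):
    return solve_steady(cyl_mesh, PROPS, 10.0)


class TestFluidProps:
    def test_defaults_are_embryonic_blood(self):
        assert PROPS.density_kg_m3 == 1060.0
        assert PROPS.viscosity_pa_s == 0.003

    def test_positivity_enforced(self):
        with pytest.raises(ValueError):
            FluidProps(density_kg_m3=-1.0)

    def test_quasi_steady_regime_diagnostics(self):
        """Stage-preset scales sit at Re < 5 and Wo ~ 0.1.

        Mean velocity is half the peak centerline value for a
        parabolic profile; the fastest preset (peak 90 mm/s,
        r = 0.17 mm) bounds the others.
        """
        re, wo = reynolds_womersley(PROPS, radius_mm=0.17,
                                    mean_velocity_mm_s=45.0, period_s=0.41)
        assert re < 5.0
        assert 0.03 < wo < 0.3


class TestSolveSteady:
    def test_zero_traction_gives_zero_field(self, cyl_mesh):
        f = solve_steady(cyl_mesh, PROPS, 0.0)
        assert np.allclose(f.velocity, 0.0, atol=1e-12)
        assert np.allclose(f.pressure, 0.0, atol=1e-12)

    def test_no_slip_on_walls(self, cyl_solution):
        wall = np.unique(cyl_solution.mesh.wall_nodes())
        assert np.abs(cyl_solution.velocity[wall]).max() < 1e-12

    def test_mass_conserved_within_one_percent(self, cyl_solution):
        assert cyl_solution.residuals["mass_imbalance_rel"] < 0.01

    def test_poiseuille_centerline_within_three_percent(self, cyl_solution):
        mesh = cyl_solution.mesh
        L = mesh.station_z[-1] - mesh.station_z[0]
        expected = 10.0 * 0.2**2 / (4 * PROPS.viscosity_pa_s * L)
        assert monitor_velocity(cyl_solution) == pytest.approx(expected,
                                                               rel=0.03)

    def test_poiseuille_flow_rate_within_three_percent(self, cyl_solution):
        mesh = cyl_solution.mesh
        L = mesh.station_z[-1] - mesh.station_z[0]
        expected = np.pi * 0.2**4 * 10.0 / (8 * PROPS.viscosity_pa_s * L)
        assert hemo.flow_rate(cyl_solution) == pytest.approx(expected,
                                                             rel=0.03)

    def test_stokes_linearity_in_traction(self, cyl_mesh):
        op = StokesOperator(cyl_mesh, PROPS)
        f1 = solve_steady(cyl_mesh, PROPS, 5.0, operator=op)
        f2 = solve_steady(cyl_mesh, PROPS, 10.0, operator=op)
        scale = np.abs(f2.velocity).max()
        assert np.abs(f2.velocity - 2.0 * f1.velocity).max() < 1e-10 * scale

    def test_axisymmetric_solution_has_no_swirl(self, cyl_solution):
        """Azimuthal velocity component stays at solver-noise level."""
        mesh = cyl_solution.mesh
        xy = mesh.nodes[:, :2]
        r = np.linalg.norm(xy, axis=1)
        interior = r > 1e-6
        t_hat = np.column_stack([-xy[interior, 1], xy[interior, 0]]) / r[
            interior, None]
        swirl = np.einsum("ni,ni->n", cyl_solution.velocity[interior, :2],
                          t_hat)
        # the O-grid is 4-fold symmetric, not axisymmetric, so a small
        # discretization-level azimuthal component remains
        assert np.abs(swirl).max() < 5e-3 * np.abs(
            cyl_solution.velocity).max()

    def test_nonfinite_traction_rejected(self, cyl_mesh):
        with pytest.raises(ValueError):
            solve_steady(cyl_mesh, PROPS, np.nan)

    def test_inertia_barely_changes_low_reynolds_flow(self, cyl_mesh):
        """At Re < 1 the Picard-converged field is close to Stokes."""
        stokes = solve_steady(cyl_mesh, PROPS, 2.0)
        ns = solve_steady(cyl_mesh, PROPS, 2.0, include_inertia=True)
        assert ns.residuals["picard_iterations"] >= 1
        rel = (np.abs(ns.velocity - stokes.velocity).max()
               / np.abs(stokes.velocity).max())
        assert rel < 0.05


class TestInverseFit:
    def test_two_solves_suffice_in_stokes(self, cyl_mesh):
        field, res = fit_inlet_traction(cyl_mesh, PROPS, 30.0,
                                        warm_start=5.0)
        assert res.converged
        assert res.n_solves <= 2
        assert res.final_relative_error < 0.01

    def test_zero_target_returns_zero_without_solving(self, cyl_mesh):
        field, res = fit_inlet_traction(cyl_mesh, PROPS, 0.0)
        assert res.n_solves == 0
        assert field.inlet_traction == 0.0
        assert np.allclose(field.velocity, 0.0)

    def test_round_trip_recovers_traction(self, cyl_mesh):
        op = StokesOperator(cyl_mesh, PROPS)
        ref = solve_steady(cyl_mesh, PROPS, 7.3, operator=op)
        target = monitor_velocity(ref)
        field, res = fit_inlet_traction(cyl_mesh, PROPS, target,
                                        tolerance=0.001, operator=op)
        assert field.inlet_traction == pytest.approx(7.3, rel=0.01)

    def test_negative_target_backflow(self, cyl_mesh):
        field, res = fit_inlet_traction(cyl_mesh, PROPS, -12.0)
        assert res.converged
        assert field.inlet_traction < 0
        assert monitor_velocity(field) == pytest.approx(-12.0, rel=0.01)


class TestSimulateCycle:
    def _rigid_setup(self, n_phases=6):
        series = cylinder_series(radius=0.18, n_slices=21, spacing=0.02)
        mesh = geometry.build_mesh(series, 0, 10, 16, 3,
                                   extension_length_factor=0.5)
        return {t: mesh for t in range(n_phases)}

    def test_rigid_tube_constant_target_constant_traction(self):
        meshes = self._rigid_setup()
        targets = {t: 25.0 for t in meshes}
        sim = simulate_cycle(meshes, targets, PROPS, n_phases=6)
        tr = [sim.fields[t].inlet_traction for t in sorted(sim.fields)]
        assert np.ptp(tr) < 1e-6 * abs(tr[0])
        assert sim.coverage == 1.0
        # warm start makes later phases one-solve
        assert all(sim.fits[t].n_solves <= 2 for t in sim.fits)

    def test_skipped_phases_recorded_and_coverage_reported(self):
        meshes = self._rigid_setup(6)
        for t in (2, 3):
            meshes.pop(t)
        targets = {t: 10.0 for t in range(6)}
        sim = simulate_cycle(meshes, targets, PROPS, n_phases=6,
                             min_coverage=0.6)
        assert sim.coverage == pytest.approx(4 / 6)
        assert set(sim.skipped) == {2, 3}

    def test_low_coverage_warns_but_does_not_fail(self):
        meshes = self._rigid_setup(6)
        targets = {0: 10.0}
        sim = simulate_cycle(meshes, targets, PROPS, n_phases=6)
        assert sim.coverage == pytest.approx(1 / 6)
        assert any("simulated" in w for w in sim.warnings)


class TestMeshIndependence:
    def test_doubling_elements_changes_observables_below_5pct(self):
        """Monitor velocity and mean WSS shift < 5% when the element
        count is roughly doubled."""
        series = cylinder_series(radius=0.2, n_slices=31, spacing=0.02)
        coarse = geometry.build_mesh(series, 0, 10, 16, 3,
                                     extension_length_factor=0.75)
        fine = geometry.build_mesh(series, 0, 16, 16, 5,
                                   extension_length_factor=0.75)
        assert 1.6 < fine.n_elements / coarse.n_elements < 2.8
        fc = solve_steady(coarse, PROPS, 10.0)
        ff = solve_steady(fine, PROPS, 10.0)
        v0, v1 = monitor_velocity(fc), monitor_velocity(ff)
        assert abs(v1 - v0) / abs(v0) < 0.05
        w0 = np.median(hemo.wall_shear(fc).tau_mag)
        w1 = np.median(hemo.wall_shear(ff).tau_mag)
        assert abs(w1 - w0) / w0 < 0.05
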