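"""Flow solver tests: boundary conditions, projection, steady states, vorticity."""

import numpy as np
import pytest

from medusim import fluid as fl
from medusim.geometry import TankGeometry


def stationary_params(**kw):
    return fl.FluidParams(lid_speed=0.0, inflow_peak=0.0, **kw)


class TestBoundaryConditions:
    def test_cavity_lid_tangential_speed(self):
        g = TankGeometry.for_scenario("cavity", spacing=0.5)
        params = fl.FluidParams()
        field = fl.FlowField.zeros(g)
        fl.apply_boundary_conditions(field, g, params)
        up = fl.padded_u(field, params)
        lid = 0.5 * (up[:, -1] + up[:, -2])  # wall value between ghost and interior
        assert np.allclose(lid, 0.4)
        assert np.allclose(field.v[:, -1], 0.0)  # lid stays impermeable

    def test_channel_inlet_profile(self):
        g = TankGeometry.for_scenario("channel", spacing=0.25)
        params = fl.FluidParams()
        field = fl.apply_boundary_conditions(fl.FlowField.zeros(g), g, params)
        yc = g.y_centers
        expected = -0.045 * 4 * ((yc - g.y_min) / g.ly) * (1 - (yc - g.y_min) / g.ly)
        assert np.allclose(field.u[-1, :], expected)
        assert field.u[-1, :].min() == pytest.approx(-0.045, rel=0.01)  # peak near mid

    def test_all_stationary_variant(self):
        g = TankGeometry.for_scenario("cavity", spacing=0.5)
        params = stationary_params()
        field = fl.apply_boundary_conditions(fl.FlowField.zeros(g), g, params)
        up = fl.padded_u(field, params)
        vp = fl.padded_v(field, params)
        assert np.allclose(0.5 * (up[:, -1] + up[:, -2]), 0.0)
        assert np.allclose(0.5 * (vp[0, :] + vp[1, :]), 0.0)
        assert field.u[0, :].max() == 0.0 and field.v[:, -1].max() == 0.0

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError):
            TankGeometry(0, 1, 0, 1, 11, 11, "vortex_street")


class TestStepFlow:
    def test_null_flow_fixed_point(self, small_cavity):
        """Zero field with stationary walls stays identically zero."""
        params = stationary_params(dt=0.005)
        field = fl.FlowField.zeros(small_cavity)
        for _ in range(20):
            fl.step_flow(field, params)
        assert np.all(field.u == 0.0) and np.all(field.v == 0.0)

    def test_projection_divergence_free(self, small_cavity, rng):
        """Any state is divergence free (to SOR tolerance) after projection."""
        params = stationary_params(dt=0.005)
        field = fl.FlowField.zeros(small_cavity)
        field.u[1:-1, :] = 0.1 * rng.standard_normal(field.u[1:-1, :].shape)
        field.v[:, 1:-1] = 0.1 * rng.standard_normal(field.v[:, 1:-1].shape)
        pre = np.abs(field.divergence()).max()
        fl.project(field, params)
        post = np.abs(field.divergence()).max()
        assert post < params.sor_tol * pre

    def test_poiseuille_steady_state(self):
        """The analytic channel profile is preserved through 1000 solver steps."""
        g = TankGeometry(-5.0, 5.0, 0.0, 2.5, 81, 21, "channel")
        params = fl.FluidParams(dt=0.001)
        field = fl.analytic_flow(g, params)
        u0 = field.u.copy()
        fl.apply_boundary_conditions(field, g, params)
        for _ in range(1000):
            fl.step_flow(field, params)
        rel = np.abs(field.u - u0).max() / np.abs(u0).max()
        assert rel < 1e-3
        assert np.abs(field.v).max() < 1e-4

    def test_cavity_develops_clockwise_gyre(self):
        """A rightward-moving lid drives net negative (clockwise) vorticity."""
        g = TankGeometry(0, 10, 0, 10, 41, 41, "cavity")
        params = fl.FluidParams(dt=0.002)
        field = fl.FlowField.zeros(g)
        fl.apply_boundary_conditions(field, g, params)
        for _ in range(300):
            fl.step_flow(field, params)
        assert fl.vorticity(field).mean() < 0.0

    def test_cfl_violation_raises(self, small_cavity):
        params = stationary_params(dt=1.0)
        field = fl.FlowField.zeros(small_cavity)
        field.u[1:-1, :] = 0.5
        with pytest.raises(fl.CFLError):
            fl.step_flow(field, params)

    def test_sor_nonconvergence_reports_residual(self, small_cavity, rng):
        params = stationary_params(dt=0.005, sor_max_iter=1, sor_tol=1e-14)
        field = fl.FlowField.zeros(small_cavity)
        field.u[1:-1, :] = 0.1 * rng.standard_normal(field.u[1:-1, :].shape)
        with pytest.raises(fl.SORConvergenceError, match="residual"):
            fl.project(field, params)

    def test_advection_diffusion_second_order(self):
        """Halving the spacing shrinks the truncation error ~4x (smooth field)."""
        errors = {}
        for n in (41, 81):
            g = TankGeometry(0, 1, 0, 1, n, n, "cavity")
            params = stationary_params()
            field = fl.FlowField.zeros(g)
            xu, yu = np.meshgrid(g.x_nodes, g.y_centers, indexing="ij")
            xv, yv = np.meshgrid(g.x_centers, g.y_nodes, indexing="ij")
            field.u = np.sin(np.pi * xu) * np.cos(np.pi * yu)
            field.v = -np.cos(np.pi * xv) * np.sin(np.pi * yv)
            ru, _ = fl.advection_diffusion_rhs(field, params)
            # analytic tendency at interior u faces
            xi, yi = xu[1:-1, :], yu[1:-1, :]
            u = np.sin(np.pi * xi) * np.cos(np.pi * yi)
            v = -np.cos(np.pi * xi) * np.sin(np.pi * yi)
            ux = np.pi * np.cos(np.pi * xi) * np.cos(np.pi * yi)
            uy = -np.pi * np.sin(np.pi * xi) * np.sin(np.pi * yi)
            exact = -(u * ux + v * uy) + params.nu * (-2 * np.pi**2 * u)
            k = 4  # stay clear of the wall ghosts
            errors[n] = np.abs(ru[k:-k, k:-k] - exact[k:-k, k:-k]).max()
        ratio = errors[41] / errors[81]
        assert 3.0 < ratio < 5.2


class TestVorticity:
    def _field_from_uv(self, g, ufun, vfun):
        field = fl.FlowField.zeros(g)
        xu, yu = np.meshgrid(g.x_nodes, g.y_centers, indexing="ij")
        xv, yv = np.meshgrid(g.x_centers, g.y_nodes, indexing="ij")
        field.u = ufun(xu, yu)
        field.v = vfun(xv, yv)
        return field

    def test_rigid_body_rotation(self, small_cavity):
        omega = 0.7
        field = self._field_from_uv(small_cavity,
                                    lambda x, y: -omega * (y - 0.5),
                                    lambda x, y: omega * (x - 0.5))
        abs_c, gx, gy = fl.vorticity_fields(field)
        assert np.allclose(abs_c, 2 * omega)
        assert np.allclose(gx, 0.0) and np.allclose(gy, 0.0)

    def test_plane_shear(self, small_cavity):
        gamma = 0.3
        field = self._field_from_uv(small_cavity,
                                    lambda x, y: gamma * y,
                                    lambda x, y: np.zeros_like(x))
        assert np.allclose(fl.vorticity(field), -gamma)

    def test_zero_field(self, small_cavity):
        field = fl.FlowField.zeros(small_cavity)
        abs_c, _, _ = fl.vorticity_fields(field)
        assert np.all(abs_c == 0.0)


class TestReynolds:
    def test_channel_value(self):
        assert fl.reynolds_number(fl.FluidParams(), 0.045, 40.0) == pytest.approx(4500.0)

    def test_zero_speed(self):
        assert fl.reynolds_number(fl.FluidParams(), 0.0, 10.0) == 0.0

    def test_cavity_value(self):
        # rho U L / mu with the printed cavity scales
        assert fl.reynolds_number(fl.FluidParams(), 0.4, 10.0) == pytest.approx(1e4)

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError):
            fl.reynolds_number(fl.FluidParams(), 0.1, 0.0)


class TestAnalyticFlows:
    @pytest.mark.parametrize("scenario", ["cavity", "channel", "double_gyre"])
    def test_divergence_free(self, scenario):
        g = TankGeometry.for_scenario(scenario, spacing=0.25)
        field = fl.analytic_flow(g)
        assert np.abs(field.divergence()).max() < 1e-12

    def test_double_gyre_counter_rotation(self):
        g = TankGeometry.for_scenario("double_gyre", spacing=0.25)
        field = fl.analytic_flow(g)
        c = fl.vorticity(field)
        left = c[: g.nx // 2, :].mean()
        right = c[g.nx // 2 :, :].mean()
        assert left < 0 < right  # clockwise left gyre, counter-clockwise right
        # side-wall-adjacent fluid moves upward
        assert field.v[0, g.ny // 2] > 0 and field.v[-1, g.ny // 2] > 0
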