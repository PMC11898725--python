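"""Radial porous-sphere solver against its closed-form oracles: analytic
convective-cooling series, steady generation profile, energy conservation,
maximum principle and convergence orders."""

import numpy as np
import pytest

from napacool import (
    BoundaryConditions,
    SphereGeometry,
    TemperatureField,
    analytic_sphere_cooling,
    analytic_sphere_volume_average,
    respiration_source,
    solve_transient,
    steady_state_generation,
    time_to_threshold,
)
from napacool.heat_solver import _sphere_eigenvalues
from napacool.thermophysics import ConstantProperties


class TestGeometry:
    def test_equivalent_radius_from_circumferences(self):
        """Class-2 mean circumferences (82.67, 51.89 cm) give semi-axes
        a=L/2pi, b=W/2pi and R=(a b^2)^(1/3) = 0.0965 m."""
        g = SphereGeometry.from_circumferences(82.67, 51.89, class_id=2)
        a = 0.8267 / (2 * np.pi)
        b = 0.5189 / (2 * np.pi)
        assert g.radius == pytest.approx((a * b * b) ** (1 / 3), rel=1e-12)
        assert g.radius == pytest.approx(0.0965, abs=5e-4)

    def test_oblate_input_rejected(self):
        with pytest.raises(ValueError):
            SphereGeometry.from_circumferences(50.0, 80.0)


class TestAnalyticOracle:
    def test_initial_condition_recovered(self):
        T = analytic_sphere_cooling(0.1, 0.5, 1e6, 50.0, 20.0, 4.0, r=0.05, t=0.0, n_terms=80)
        assert T == pytest.approx(20.0, abs=1e-3)

    def test_first_eigenvalue_unit_biot(self):
        # 1 - lam cot lam = 1 has the root lam = pi/2
        lam = _sphere_eigenvalues(1.0, 1)[0]
        assert lam == pytest.approx(np.pi / 2, abs=1e-10)

    def test_large_biot_limit(self):
        lam = _sphere_eigenvalues(1e8, 1)[0]
        assert lam == pytest.approx(np.pi, abs=1e-4)


class TestTransientSolver:
    def test_equilibrium_is_fixed_point(self, class2_geom, class2_props):
        bc = BoundaryConditions(h=270.0, T_inf=4.1, T0=4.1)
        field = solve_transient(class2_geom, class2_props, bc, t_end=600.0, dt=5.0, n_nodes=30)
        assert np.allclose(field.temperatures, 4.1, atol=1e-9)

    def test_matches_analytic_series(self, class2_geom, class2_constant_props):
        """Constant-property class-2 sphere, h=270: volume average within
        0.05 degC of the multi-term series at every output time."""
        bc = BoundaryConditions(h=270.0, T_inf=4.1, T0=20.0)
        p = class2_constant_props
        field = solve_transient(class2_geom, p, bc, t_end=8 * 3600.0, dt=5.0, n_nodes=200,
                                output_every=1200.0)
        exact = analytic_sphere_volume_average(
            class2_geom.radius, p.k_const, p.rho_cp_const, 270.0, 20.0, 4.1,
            field.times[1:], n_terms=80,
        )
        assert np.max(np.abs(field.volume_average[1:] - exact)) < 0.05

    def test_converges_to_steady_generation_profile(self):
        props = ConstantProperties(k_const=0.5, rho_cp_const=1e5)
        geom = SphereGeometry(radius=0.05)
        bc = BoundaryConditions(h=50.0, T_inf=4.0, T0=4.0)
        field = solve_transient(geom, props, bc, source=100.0, t_end=5000.0, dt=1.0, n_nodes=100)
        profile = steady_state_generation(0.05, 0.5, 50.0, 4.0, 100.0, r=field.node_radii)
        assert np.max(np.abs(field.temperatures[:, -1] - profile)) < 1e-3

    def test_discrete_energy_balance(self):
        """Stored-energy change per recorded step equals boundary flux plus
        integrated source, recomputed from the scheme's own conductances."""
        k, rho_cp, h, q = 0.5, 1e6, 40.0, 200.0
        R, n, dt = 0.05, 50, 10.0
        props = ConstantProperties(k_const=k, rho_cp_const=rho_cp)
        geom = SphereGeometry(radius=R)
        bc = BoundaryConditions(h=h, T_inf=2.0, T0=20.0)
        field = solve_transient(geom, props, bc, source=q, t_end=500.0, dt=dt, n_nodes=n,
                                output_every=dt)
        dr = R / n
        faces = np.linspace(0, R, n + 1)
        vols = 4 * np.pi / 3 * (faces[1:] ** 3 - faces[:-1] ** 3)
        g_out = 4 * np.pi * R**2 / (dr / (2 * k) + 1 / h)
        for j in range(1, field.temperatures.shape[1]):
            t_new = field.temperatures[:, j]
            t_old = field.temperatures[:, j - 1]
            stored = rho_cp * np.sum(vols * (t_new - t_old))
            supplied = dt * (g_out * (bc.T_inf - t_new[-1]) + q * vols.sum())
            assert stored == pytest.approx(supplied, rel=1e-6)

    def test_maximum_principle_without_source(self, class2_geom, class2_props):
        bc = BoundaryConditions(h=270.0, T_inf=4.1, T0=20.0)
        field = solve_transient(class2_geom, class2_props, bc, t_end=3600.0, dt=30.0, n_nodes=50)
        assert field.temperatures.min() >= 4.1 - 1e-9
        assert field.temperatures.max() <= 20.0 + 1e-9

    def test_volume_average_monotone_cooling(self, class2_geom, class2_props):
        bc = BoundaryConditions(h=270.0, T_inf=4.1, T0=20.0)
        field = solve_transient(class2_geom, class2_props, bc, t_end=3600.0, dt=30.0, n_nodes=50)
        assert np.all(np.diff(field.volume_average) <= 1e-12)

    def test_convergence_orders(self):
        """Second order in cell size, first order in time step (observed
        orders within +/-0.3)."""
        R, k, rho_cp, h = 0.05, 0.5, 1e6, 100.0
        props = ConstantProperties(k_const=k, rho_cp_const=rho_cp)
        geom = SphereGeometry(radius=R)
        bc = BoundaryConditions(h=h, T_inf=0.0, T0=10.0)
        t_end = 1000.0

        def err(dt, n):
            f = solve_transient(geom, props, bc, t_end=t_end, dt=dt, n_nodes=n,
                                output_every=t_end)
            exact = analytic_sphere_volume_average(R, k, rho_cp, h, 10.0, 0.0, t_end, n_terms=80)
            return abs(f.volume_average[-1] - exact)

        spatial = np.log2(err(0.05, 10) / err(0.05, 20))
        temporal = np.log2(err(20.0, 300) / err(10.0, 300))
        assert spatial == pytest.approx(2.0, abs=0.3)
        assert temporal == pytest.approx(1.0, abs=0.3)

    def test_respiration_source_warms_early_period(self, class2_geom, class2_props):
        """With the metabolic source on, the volume-average temperature
        strictly exceeds the source-off solution throughout the first 10 h."""
        bc = BoundaryConditions(h=270.0, T_inf=4.1, T0=20.0)
        src = respiration_source(class2_props)
        on = solve_transient(class2_geom, class2_props, bc, source=src,
                             t_end=10 * 3600.0, dt=60.0, n_nodes=60, output_every=1800.0)
        off = solve_transient(class2_geom, class2_props, bc, source=None,
                              t_end=10 * 3600.0, dt=60.0, n_nodes=60, output_every=1800.0)
        assert np.all(on.volume_average[1:] > off.volume_average[1:])

    def test_input_validation(self, class2_geom, class2_props, storage_bc):
        with pytest.raises(ValueError):
            solve_transient(class2_geom, class2_props, storage_bc, t_end=10.0, dt=-1.0)
        with pytest.raises(ValueError):
            solve_transient(class2_geom, class2_props, storage_bc, t_end=10.0, n_nodes=5)


class TestSteadyState:
    def test_zero_generation_uniform(self):
        prof = steady_state_generation(0.1, 0.02, 50.0, 4.0, 0.0)
        assert np.allclose(prof, 4.0)

    def test_surface_flux_balance(self):
        T_surface = steady_state_generation(0.1, 0.02, 50.0, 4.0, 30.0, r=0.1)
        assert T_surface == pytest.approx(4.0 + 30.0 * 0.1 / (3 * 50.0), rel=1e-12)

    def test_center_excess_hand_arithmetic(self):
        T_center = steady_state_generation(0.0965, 0.0211, 270.0, 0.0, 10.0, r=0.0)
        expected = 10 * 0.0965 / (3 * 270) + 10 * 0.0965**2 / (6 * 0.0211)
        assert T_center == pytest.approx(expected, rel=1e-12)


class TestTimeToThreshold:
    @staticmethod
    def _field(times, averages):
        n = len(times)
        return TemperatureField(
            node_radii=np.array([0.0]),
            times=np.asarray(times, dtype=float),
            temperatures=np.asarray(averages, dtype=float)[None, :],
            volume_average=np.asarray(averages, dtype=float),
            surface=np.zeros(n),
            center=np.zeros(n),
        )

    def test_linear_interpolation(self):
        fld = self._field([0.0, 100.0], [5.0, 4.0])
        assert time_to_threshold(fld, 4.25) == pytest.approx(75.0)

    def test_already_below(self):
        fld = self._field([0.0, 100.0], [4.0, 3.9])
        assert time_to_threshold(fld, 4.25) == 0.0

    def test_never_crossed(self):
        fld = self._field([0.0, 100.0], [5.0, 4.5])
        with pytest.raises(ValueError):
            time_to_threshold(fld, 4.25)
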