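import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flywind import odor
from flywind.grid import uniform_grid
from flywind.odor import (
    OdorProbeSeries,
    ParticleSet,
    ProbeSpec,
    VelocitySampler,
    advect_particles,
    advect_scalar,
    odor_flux,
    release_grid,
)


@pytest.fixture
def grid():
    return uniform_grid(((-2, 2), (-2, 2)), (80, 80))


def constant_sampler(grid, vel, t_span=(0.0, 10.0)):
    s = VelocitySampler(grid)
    shape = grid.shape
    for t in t_span:
        s.add_snapshot(t, [np.full(shape, v) for v in vel])
    return s


class TestParticles:
    def test_uniform_flow_exact_displacement(self, grid):
        s = constant_sampler(grid, (0.5, 0.0))
        ps = ParticleSet.release([[-1.0, 0.3], [-1.5, -0.7]], origin=0)
        out, _ = advect_particles(ps, s, dt=0.1, t0=0.0, n_steps=10)
        assert np.allclose(out.positions[:, 0], ps.positions[:, 0] + 0.5)
        assert np.allclose(out.positions[:, 1], ps.positions[:, 1])

    def test_zero_velocity_positions_unchanged(self, grid):
        s = constant_sampler(grid, (0.0, 0.0))
        ps = ParticleSet.release([[0.1, 0.2]], origin=1)
        out, _ = advect_particles(ps, s, dt=0.05, t0=0.0, n_steps=20)
        assert np.array_equal(out.positions, ps.positions)

    def test_solid_body_rotation_conserves_radius(self, grid):
        # oracle: circular orbit closed form; RK2 radius drift < 1e-3/rev
        s = VelocitySampler(grid)
        X, Y = grid.center_mesh()
        for t in (0.0, 10.0):
            s.add_snapshot(t, [-Y, X])  # omega = 1
        r0 = 0.8
        ps = ParticleSet.release([[r0, 0.0]], origin=0)
        n = 2000
        dt = 2 * np.pi / n
        out, _ = advect_particles(ps, s, dt=dt, t0=0.0, n_steps=n)
        r1 = np.linalg.norm(out.positions[0])
        assert abs(r1 - r0) / r0 < 1e-3

    def test_particles_deactivate_on_exit_count_conserved(self, grid):
        s = constant_sampler(grid, (1.0, 0.0))
        ps = ParticleSet.release([[1.8, 0.0], [-1.8, 0.0]], origin=[0, 1])
        out, _ = advect_particles(ps, s, dt=0.1, t0=0.0, n_steps=5)
        assert out.n == 2                      # count conserved
        assert not out.active[0]               # left the domain
        assert out.active[1]
        assert np.array_equal(out.origin, ps.origin)  # tags preserved

    def test_solid_projection_counted(self, grid):
        from flywind.bodies import Polygon2D, RigidBody

        th = np.linspace(0, 2 * np.pi, 48, endpoint=False)
        body = RigidBody(
            Polygon2D(0.5 * np.column_stack([np.cos(th), np.sin(th)])),
            name="disc", sample_spacing=0.05,
        )
        s = constant_sampler(grid, (1.0, 0.0))
        ps = ParticleSet.release([[-0.62, 0.0]], origin=0)
        out, stats = advect_particles(ps, s, dt=0.2, t0=0.0, n_steps=1, bodies=(body,))
        assert stats["n_projected"] == 1
        assert body.sdf(out.positions)[0] >= -1e-9

    def test_release_grid_tags_stratify(self):
        pts, tags = release_grid(-2.0, [(-1.0, 1.0, 40)], n_tags=4)
        assert pts.shape == (40, 2)
        assert set(tags) == {0, 1, 2, 3}
        assert np.all(np.diff(tags) >= 0)


class TestOdorFlux:
    def test_zero_velocity_zero_flux(self):
        assert odor_flux(np.zeros((3, 2)))[0] == 0.0

    def test_printed_constants_product(self):
        # C'=1, rho_odor=1.225 kg/m^3, |U*|=0.94 m/s -> 1.15 kg s^-1 m^-2
        flux = odor_flux(np.array([[0.94, 0.0]]), c_prime=1.0, rho_odor=1.225)
        assert flux[0] == pytest.approx(1.15, abs=0.005)

    def test_flux_nonnegative_property(self):
        rng = np.random.default_rng(0)
        u = rng.normal(size=(50, 3))
        assert np.all(odor_flux(u) >= 0)

    def test_antenna_is_mean_of_triplet(self):
        s = OdorProbeSeries()
        s.append(0.0, np.array([1.0, 2.0, 3.0, 9.0]))
        assert s.antenna_flux[0] == pytest.approx(2.0)

    def test_negative_flux_rejected(self):
        s = OdorProbeSeries()
        with pytest.raises(ValueError):
            s.append(0.0, np.array([-1.0, 0.0, 0.0]))

    def test_probe_spec_triplet_layout(self):
        spec = ProbeSpec(antenna=np.array([-0.3, 0.3]), offset=0.03, spacing=0.0125)
        pts = spec.points()
        assert pts.shape == (3, 2)
        assert np.allclose(pts[:, 1], 0.33)
        assert np.allclose(np.diff(pts[:, 0]), 0.0125)

    def test_probe_inside_solid_rejected_at_setup(self):
        from flywind.bodies import Polygon2D, RigidBody
        from flywind.grid import build_grid
        from flywind.odor import ProbeObserver
        from flywind.solver import Simulation, SolverSettings

        th = np.linspace(0, 2 * np.pi, 48, endpoint=False)
        body = RigidBody(
            Polygon2D(0.5 * np.column_stack([np.cos(th), np.sin(th)])),
            name="disc", sample_spacing=0.05,
        )
        g = build_grid(domain=((-2, 2), (-2, 2)), box=((-1, 1), (-1, 1)), delta=0.1)
        sim = Simulation(g, SolverSettings(re=50.0, dt=0.02), bodies=(body,))
        obs = ProbeObserver(ProbeSpec(antenna=np.array([0.0, -0.2])))
        with pytest.raises(ValueError, match="inside solid"):
            obs.start(sim)


class TestScalarAdvection:
    def test_top_hat_exact_translation_at_cfl_one(self):
        # classic upwind identity: CFL = 1 on a uniform grid translates the
        # profile exactly one cell per step
        g = uniform_grid(((0.0, 1.0),), (50,))
        c = np.zeros(50)
        c[10:20] = 1.0
        h = g.axes[0].widths[0]
        F = [np.full(51, 1.0)]
        out = advect_scalar(c, F, g, dt=h, inflow_value=0.0)
        assert np.allclose(out, np.roll(c, 1) * (np.arange(50) > 0))

    def test_uniform_unity_preserved(self, grid):
        c = np.ones(grid.shape)
        F = [np.ones((81, 80)), np.zeros((80, 81))]
        out = advect_scalar(c, F, grid, dt=0.01, inflow_value=1.0)
        assert np.allclose(out, 1.0)

    def test_monotone_no_new_extrema(self, grid):
        rng = np.random.default_rng(1)
        c = rng.uniform(0.2, 0.8, grid.shape)
        F = [0.5 * np.ones((81, 80)), 0.25 * np.ones((80, 81))]
        out = advect_scalar(c, F, grid, dt=0.02, inflow_value=0.5)
        assert out.max() <= max(c.max(), 1.0) + 1e-12
        assert out.min() >= min(c.min(), 0.0) - 1e-12

    def test_cfl_violation_rejected(self, grid):
        c = np.ones(grid.shape)
        F = [np.full((81, 80), 100.0), np.zeros((80, 81))]
        with pytest.raises(odor.CFLViolation):
            advect_scalar(c, F, grid, dt=0.05)

    @given(st.floats(min_value=0.1, max_value=0.9))
    @settings(max_examples=20, deadline=None)
    def test_constant_field_invariant(self, speed):
        g = uniform_grid(((0.0, 1.0),), (20,))
        c = np.full(20, 0.7)
        out = advect_scalar(c, [np.full(21, speed)], g, dt=0.01, inflow_value=0.7)
        assert np.allclose(out, 0.7)
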