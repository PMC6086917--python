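"""Flow-solver verification: exact solutions, convergence orders, and the
invariants every step must satisfy."""

import numpy as np
import pytest

from flywind.bodies import Polygon2D, RigidBody
from flywind.grid import build_grid, uniform_grid
from flywind.solver import (
    DivergenceError,
    Simulation,
    SolverSettings,
    kinetic_energy,
)


def tg_simulation(n, dt, re=100.0, rhie_chow=False):
    g = uniform_grid(((0, 2 * np.pi), (0, 2 * np.pi)), (n, n), periodic=True)
    sim = Simulation(g, SolverSettings(re=re, dt=dt, rhie_chow=rhie_chow), bcs="periodic")
    sim.initialize(
        [lambda x, y: np.cos(x) * np.sin(y), lambda x, y: -np.sin(x) * np.cos(y)],
        pressure_func=lambda x, y: -0.25 * (np.cos(2 * x) + np.cos(2 * y)),
    )
    return sim


class TestExactSolutions:
    def test_uniform_inflow_no_bodies_stays_uniform(self, small_windtunnel_grid):
        sim = Simulation(small_windtunnel_grid, SolverSettings(re=100.0, dt=0.02))
        for _ in range(25):
            sim.step()
        assert np.abs(sim.state.u[0] - 1.0).max() < 1e-12
        assert np.abs(sim.state.u[1]).max() < 1e-12
        assert sim.last_divergence < 1e-12

    def test_taylor_green_energy_decay(self):
        # oracle: closed-form decay E(t) = E0 exp(-4 t / Re) (wavenumber 1)
        T, re = 0.5, 100.0
        sim = tg_simulation(64, dt=T / 100, re=re)
        e0 = kinetic_energy(sim.state, sim.grid)
        for _ in range(100):
            sim.step()
        e1 = kinetic_energy(sim.state, sim.grid)
        assert e1 / e0 == pytest.approx(np.exp(-4 * T / re), rel=0.01)

    def test_taylor_green_pointwise_error_small(self):
        T, re = 0.5, 100.0
        sim = tg_simulation(64, dt=T / 100, re=re)
        for _ in range(100):
            sim.step()
        X, Y = sim.grid.center_mesh()
        dec = np.exp(-2 * T / re)
        err = np.sqrt(
            np.mean(
                (sim.state.u[0] - np.cos(X) * np.sin(Y) * dec) ** 2
                + (sim.state.u[1] + np.sin(X) * np.cos(Y) * dec) ** 2
            )
        )
        assert err < 1e-4


class TestConvergence:
    def test_temporal_order_two(self):
        # self-convergence triple (dt, dt/2, dt/4) against a dt/16 reference
        T = 0.5
        ref = tg_simulation(48, dt=T / 320)
        for _ in range(320):
            ref.step()
        errs = []
        for ns in (20, 40, 80):
            sim = tg_simulation(48, dt=T / ns)
            for _ in range(ns):
                sim.step()
            errs.append(
                np.sqrt(
                    np.mean(
                        (sim.state.u[0] - ref.state.u[0]) ** 2
                        + (sim.state.u[1] - ref.state.u[1]) ** 2
                    )
                )
            )
        orders = np.log2(np.array(errs[:-1]) / np.array(errs[1:]))
        assert np.all(orders >= 1.9)

    def test_spatial_order_two(self):
        # dt scaled with h so both error sources refine together
        T = 0.25
        errs = []
        for n, ns in ((16, 20), (32, 40), (64, 80)):
            sim = tg_simulation(n, dt=T / ns)
            for _ in range(ns):
                sim.step()
            X, Y = sim.grid.center_mesh()
            dec = np.exp(-2 * T / 100.0)
            errs.append(
                np.sqrt(
                    np.mean(
                        (sim.state.u[0] - np.cos(X) * np.sin(Y) * dec) ** 2
                        + (sim.state.u[1] + np.sin(X) * np.cos(Y) * dec) ** 2
                    )
                )
            )
        orders = np.log2(np.array(errs[:-1]) / np.array(errs[1:]))
        assert np.all(orders >= 1.9)


class TestCylinderDrag:
    @staticmethod
    def _run(delta, t_end=30.0, probe=0.1):
        from flywind.forces import surface_forces

        th = np.linspace(0, 2 * np.pi, 96, endpoint=False)
        circ = 0.5 * np.column_stack([np.cos(th), np.sin(th)])
        body = RigidBody(Polygon2D(circ), name="cyl", sample_spacing=0.4 * delta)
        g = build_grid(
            domain=((-6, 12), (-6, 6)), box=((-1.2, 2.0), (-1.2, 1.2)),
            delta=delta, stretch_ratio=1.15,
        )
        sim = Simulation(g, SolverSettings(re=40.0, cfl=0.4, max_speed=1.8), bodies=(body,))
        cds = []
        for _ in range(int(t_end / sim.dt)):
            sim.step()
            if sim.state.t > t_end - 5.0:
                _fl, ft, _fz, _m = surface_forces(sim.state, g, body, 40.0, probe_offset=probe)
                cds.append(-ft / 0.5)
        return float(np.mean(cds))

    def test_impulsively_started_cylinder_re40_self_converged(self):
        # oracle: the same solver on a refined grid (Richardson-style
        # self-convergence); steady Cd within 5%, and in the literature band
        cd_coarse = self._run(0.08)
        cd_fine = self._run(0.04)
        assert abs(cd_coarse - cd_fine) / cd_fine < 0.05
        assert 1.3 < cd_fine < 1.8


class TestInvariants:
    def test_divergence_free_every_step(self, small_windtunnel_grid):
        poly = 0.3 * np.column_stack(
            [np.cos(np.linspace(0, 2 * np.pi, 48, endpoint=False)),
             np.sin(np.linspace(0, 2 * np.pi, 48, endpoint=False))]
        )
        body = RigidBody(Polygon2D(poly), name="disc", sample_spacing=0.04)
        sim = Simulation(
            small_windtunnel_grid, SolverSettings(re=100.0, dt=0.02), bodies=(body,)
        )
        for _ in range(30):
            sim.step()
            assert sim.last_divergence <= 1e-6

    def test_classification_partitions_cells(self, small_windtunnel_grid):
        poly = 0.4 * np.column_stack(
            [np.cos(np.linspace(0, 2 * np.pi, 48, endpoint=False)),
             np.sin(np.linspace(0, 2 * np.pi, 48, endpoint=False))]
        )
        body = RigidBody(Polygon2D(poly), name="disc", sample_spacing=0.04)
        sim = Simulation(
            small_windtunnel_grid, SolverSettings(re=100.0, dt=0.02), bodies=(body,)
        )
        sim.step()
        st = sim.state
        assert st.solid.sum() > 0
        assert np.all(st.ghost <= st.solid)  # ghosts are solid cells
        assert np.isfinite(st.p).all()

    def test_no_spanwise_velocity_in_sagittal_analog(self, small_windtunnel_grid):
        # the 2-D sagittal analog carries no spanwise (out-of-plane)
        # component at all: the mirror-symmetry side force is identically 0
        sim = Simulation(small_windtunnel_grid, SolverSettings(re=100.0, dt=0.02))
        sim.step()
        assert len(sim.state.u) == 2

    def test_symmetric_flow_zero_lift(self):
        # top-bottom symmetric configuration: lift stays at roundoff level
        from flywind.forces import surface_forces

        th = np.linspace(0, 2 * np.pi, 64, endpoint=False)
        poly = np.column_stack([0.5 * np.cos(th), 0.3 * np.sin(th)])
        body = RigidBody(Polygon2D(poly), name="ellipse", sample_spacing=0.05)
        g = build_grid(
            domain=((-3, 6), (-3, 3)), box=((-1, 2), (-1, 1)), delta=0.1,
            stretch_ratio=1.15,
        )
        sim = Simulation(g, SolverSettings(re=40.0, dt=0.02), bodies=(body,))
        for _ in range(100):
            sim.step()
        fl, _ft, _fz, _m = surface_forces(sim.state, g, body, 40.0)
        assert abs(fl) < 1e-8

    def test_nan_detection_raises(self, small_windtunnel_grid):
        sim = Simulation(small_windtunnel_grid, SolverSettings(re=100.0, dt=0.02))
        sim.state.u[0][5, 5] = np.nan
        with pytest.raises(DivergenceError, match="component"):
            sim.step()


class TestRunCycles:
    def test_zero_cycles_returns_initial_state(self, small_windtunnel_grid):
        sim = Simulation(small_windtunnel_grid, SolverSettings(re=100.0, dt=0.02))
        out = sim.run_cycles(0, period=1.0)
        assert out.t == 0.0
        assert sim.step_count == 0

    def test_body_only_force_converges_to_constant(self):
        from flywind.forces import ForceObserver

        th = np.linspace(0, 2 * np.pi, 48, endpoint=False)
        poly = np.column_stack([0.4 * np.cos(th), 0.25 * np.sin(th)])
        body = RigidBody(Polygon2D(poly), name="body", sample_spacing=0.06)
        g = build_grid(
            domain=((-3, 6), (-3, 3)), box=((-1, 1.5), (-1, 1)), delta=0.1,
            stretch_ratio=1.15,
        )
        sim = Simulation(g, SolverSettings(re=40.0, dt=0.025), bodies=(body,))
        fo = ForceObserver(body, 40.0)
        sim.run(300, observers=(fo,))
        s = fo.series()
        late, earlier = s["f_thrust"][-50:], s["f_thrust"][-100:-50]
        assert abs(np.mean(late) - np.mean(earlier)) < 0.01 * abs(np.mean(late))

    def test_cycle_snapping(self, small_windtunnel_grid):
        sim = Simulation(small_windtunnel_grid, SolverSettings(re=100.0, dt=0.02))
        sim.run_cycles(2, period=0.5, steps_per_cycle=10)
        assert sim.step_count == 20
        assert sim.state.t == pytest.approx(1.0)


class TestSettings:
    def test_cfl_cap(self):
        with pytest.raises(ValueError, match="CFL"):
            SolverSettings(re=100.0, cfl=0.9)

    def test_dt_from_cfl(self):
        s = SolverSettings(re=100.0, cfl=0.4, max_speed=2.0)
        assert s.resolve_dt(0.1) == pytest.approx(0.02)
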