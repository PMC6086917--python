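"""Fractional-step incompressible Navier-Stokes solver with ghost-cell
immersed boundaries on a collocated nonuniform Cartesian grid.

Scheme
------
* Adams-Bashforth 2 for convection, Crank-Nicolson (or explicit) diffusion.
* Approximate projection: cell-centered velocities plus face-normal fluxes;
  the pressure Poisson equation is solved on the compact face stencil, so
  the face field is discretely divergence-free after every step.
  Rhie-Chow-style momentum interpolation suppresses pressure decoupling.
* Ghost-cell immersed boundaries: cells inside a body adjacent to fluid get
  mirrored values through an image point along the surface normal so the
  interpolated surface satisfies no-slip at the body velocity; interior
  solid cells carry the rigid-body velocity; fresh cells (newly uncovered
  by body motion) are seeded with the local body velocity.

Nondimensionalization: lengths by the wingspan R, velocities by the
freestream U_inf, time by R/U_inf.

Outer boundaries (``windtunnel`` preset): fixed inflow at the upstream x
face, zero-streamwise-gradient outflow with a global mass-flux correction,
zero-stress (free-slip) lateral faces, homogeneous Neumann pressure
everywhere.  A fully periodic preset exists for verification problems.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.interpolate import RegularGridInterpolator
from scipy.ndimage import binary_erosion

from . import operators as ops
from .bodies import RigidBody
from .grid import CartesianGrid

__all__ = [
    "SolverError",
    "DivergenceError",
    "SolverSettings",
    "FlowState",
    "Simulation",
    "kinetic_energy",
]


log = logging.getLogger("flywind.solver")


class SolverError(RuntimeError):
    pass


class DivergenceError(SolverError):
    pass


@dataclass
class SolverSettings:
    """Numerical controls for one run."""

    re: float = 173.0
    dt: float | None = None          # fixed step; if None, derived from CFL
    cfl: float = 0.4
    max_speed: float = 1.5           # velocity scale for the CFL estimate
    poisson_tol: float = 1e-8        # relative residual (iterative solver)
    poisson_maxiter: int = 4000
    poisson_solver: str = "direct"   # "direct" | "cg"
    diffusion: str = "cn"            # "cn" | "explicit"
    rhie_chow: bool = True
    check_divergence: bool = True
    divergence_tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.re <= 0:
            raise ValueError("re must be positive")
        if self.poisson_tol <= 0:
            raise ValueError("poisson_tol must be positive")
        if self.cfl > 0.5:
            raise ValueError("advective CFL capped at 0.5")

    def resolve_dt(self, min_width: float) -> float:
        if self.dt is not None:
            return self.dt
        return self.cfl * min_width / self.max_speed


@dataclass
class FlowState:
    """Velocity/pressure snapshot: cell-centered components, face fluxes,
    pressure, time, and the fluid/solid/ghost/fresh classification."""

    u: list[np.ndarray]
    faces: list[np.ndarray]
    p: np.ndarray
    t: float = 0.0
    solid: np.ndarray | None = None
    ghost: np.ndarray | None = None
    fresh: np.ndarray | None = None

    def copy(self) -> "FlowState":
        return FlowState(
            u=[c.copy() for c in self.u],
            faces=[f.copy() for f in self.faces],
            p=self.p.copy(),
            t=self.t,
            solid=None if self.solid is None else self.solid.copy(),
            ghost=None if self.ghost is None else self.ghost.copy(),
            fresh=None if self.fresh is None else self.fresh.copy(),
        )


def kinetic_energy(state: FlowState, grid: CartesianGrid) -> float:
    vols = grid.cell_volumes()
    return float(sum(0.5 * np.sum(c * c * vols) for c in state.u))


def _bc_table(kind: str, dim: int) -> list[tuple[str, str]]:
    if kind == "windtunnel":
        table = [("inflow", "outflow")] + [("slip", "slip")] * (dim - 1)
    elif kind == "periodic":
        table = [("periodic", "periodic")] * dim
    else:
        raise ValueError(f"unknown boundary preset {kind!r}")
    return table


class Simulation:
    """Orchestrates one flow computation on a fixed grid.

    Parameters
    ----------
    grid
        The (possibly stretched) Cartesian grid.
    settings
        Numerical controls.
    bcs
        ``"windtunnel"`` (inflow/outflow/slip) or ``"periodic"``.
    bodies
        Immersed :class:`~flywind.bodies.RigidBody` instances; their poses
        are advanced to the new time level before each step.
    inflow
        Freestream velocity vector (nondimensional, default unit +x).
    """

    def __init__(
        self,
        grid: CartesianGrid,
        settings: SolverSettings,
        bcs: str = "windtunnel",
        bodies: tuple[RigidBody, ...] = (),
        inflow: tuple[float, ...] | None = None,
    ):
        self.grid = grid
        self.settings = settings
        self.bc_kind = bcs
        self.bodies = tuple(bodies)
        dim = grid.ndim
        self.inflow = np.asarray(inflow if inflow is not None else (1.0,) + (0.0,) * (dim - 1))
        self.bc = _bc_table(bcs, dim)
        self.dt = settings.resolve_dt(grid.min_width())
        self._build_operators()
        self.state = self._initial_state()
        self._conv_prev: list[np.ndarray] | None = None
        self.step_count = 0
        self.last_divergence = 0.0
        self.last_poisson_residual = 0.0
        self._mesh = np.stack(grid.center_mesh(), axis=-1)  # (..., dim)

    # ------------------------------------------------------------------ setup
    def _vel_bc_tags(self) -> list[tuple[str, str]]:
        tags = []
        for lo, hi in self.bc:
            conv = {"inflow": "dirichlet", "outflow": "neumann",
                    "slip": "neumann", "periodic": "periodic"}
            tags.append((conv[lo], conv[hi]))
        return tags

    def _build_operators(self) -> None:
        g = self.grid
        vel_tags = self._vel_bc_tags()
        self._Lv, self._Lv_coeffs = ops.laplacian(g, tuple(vel_tags))
        p_tags = tuple(
            ("periodic", "periodic") if lo == "periodic" else ("neumann", "neumann")
            for lo, hi in self.bc
        )
        Lp, _ = ops.laplacian(g, p_tags)
        self._lu_p = None
        self._lu_v = None
        n = g.num_cells
        if self.settings.poisson_solver == "direct":
            # pin one cell (gauge phi[0] = 0): the all-Neumann/periodic
            # operator is singular
            Lpin = Lp.tolil()
            Lpin[0, :] = 0.0
            Lpin[0, 0] = 1.0
            self._Lp = Lpin.tocsr()
            self._lu_p = spla.splu(self._Lp.tocsc())
        else:
            # symmetrized flux-form operator (SPD up to sign, singular but
            # consistent) for conjugate gradients
            self._vol = self.grid.cell_volumes().ravel()
            self._Lp = Lp.tocsr()
            self._A_cg = (-sp.diags(self._vol) @ Lp).tocsr()
            self._M_cg = sp.diags(1.0 / np.maximum(self._A_cg.diagonal(), 1e-300))
        if self.settings.diffusion == "cn":
            a = self.dt / (2.0 * self.settings.re)
            A = sp.identity(n, format="csr") - a * self._Lv
            self._lu_v = spla.splu(A.tocsc())
        # Dirichlet RHS coefficient (inflow face only, windtunnel)
        if self.bc[0][0] == "inflow":
            self._dir_coeff = ops.dirichlet_rhs_coeff(g, self._Lv_coeffs, 0, 0)
        else:
            self._dir_coeff = None

    def _initial_state(self) -> FlowState:
        g = self.grid
        shape = g.shape
        u = [np.full(shape, self.inflow[i]) for i in range(g.ndim)]
        faces = [self._face_field(u, i) for i in range(g.ndim)]
        state = FlowState(u=u, faces=faces, p=np.zeros(shape), t=0.0)
        return state

    def initialize(self, velocity_funcs, pressure_func=None, t0: float = 0.0) -> None:
        """Set the initial condition from callables of the coordinate mesh."""
        mesh = self.grid.center_mesh()
        self.state.u = [np.asarray(f(*mesh), dtype=float) for f in velocity_funcs]
        if pressure_func is not None:
            self.state.p = np.asarray(pressure_func(*mesh), dtype=float)
        self.state.t = t0
        self.state.faces = [self._face_field(self.state.u, i) for i in range(self.grid.ndim)]
        self._conv_prev = None

    # ------------------------------------------------------------- body masks
    def _classify(self, t: float):
        g = self.grid
        shape = g.shape
        solid = np.zeros(shape, dtype=bool)
        per_body = []
        if not hasattr(self, "_static_masks"):
            self._static_masks: dict[int, np.ndarray] = {}
        for bi, body in enumerate(self.bodies):
            body.update(t)
            if body.static and bi in self._static_masks:
                mask = self._static_masks[bi]
            else:
                window = self._bbox_window(body)
                mask = np.zeros(shape, dtype=bool)
                if window is not None:
                    pts = self._mesh[window].reshape(-1, g.ndim)
                    inside = body.sdf(pts) < 0.0
                    mask[window] = inside.reshape(self._mesh[window].shape[:-1])
                if body.static:
                    self._static_masks[bi] = mask
            per_body.append(mask)
            solid |= mask
        eroded = binary_erosion(solid) if solid.any() else solid
        ghost = solid & ~eroded
        return solid, ghost, per_body

    def _bbox_window(self, body: RigidBody):
        g = self.grid
        margin = 4.0 * g.min_width()
        sl = []
        for ax, (lo, hi) in zip(g.axes, body.bbox(margin)):
            c = ax.centers
            i0 = int(np.searchsorted(c, lo))
            i1 = int(np.searchsorted(c, hi))
            if i0 >= i1:
                return None
            sl.append(slice(i0, i1))
        return tuple(sl)

    def _interp(self, field: np.ndarray):
        return RegularGridInterpolator(
            self.grid.centers, field, bounds_error=False, fill_value=None
        )

    def _apply_ghosts(self, u: list[np.ndarray], per_body, solid, ghost) -> None:
        g = self.grid
        interior = solid & ~ghost
        for body, mask in zip(self.bodies, per_body):
            bmask = mask & interior
            if bmask.any():
                vel = body.velocity_at(self._mesh[bmask])
                for i in range(g.ndim):
                    u[i][bmask] = vel[:, i]
        # image point pushed at least one refined cell into the fluid and a
        # linear wall profile with slope factor <= 1: keeps the ghost update
        # contraction-stable (two passes relax ghost-ghost coupling)
        h_img = g.min_width()
        for _pass in range(2):
            interps = [self._interp(c) for c in u]
            for body, mask in zip(self.bodies, per_body):
                gmask = mask & ghost
                if not gmask.any():
                    continue
                xg = self._mesh[gmask]
                xs, dist = body.nearest_surface(xg)
                dist = np.maximum(dist, 1e-12)
                n_hat = (xs - xg) / dist[:, None]
                h = np.maximum(dist, h_img)
                xi = xs + h[:, None] * n_hat
                u_wall = body.velocity_at(xs)
                scale = dist / h
                # image points that fall back inside a body get wall velocity
                bad = body.sdf(xi) < 0.0
                for i in range(g.ndim):
                    ui = interps[i](xi)
                    val = u_wall[:, i] - scale * (ui - u_wall[:, i])
                    val[bad] = u_wall[bad, i]
                    u[i][gmask] = val

    # ------------------------------------------------------------ ingredients
    def _face_field(self, u: list[np.ndarray], axis: int) -> np.ndarray:
        """Face-normal velocity for ``axis`` with outer BCs applied."""
        g = self.grid
        F = ops.face_interp(u[axis], g, axis)
        nd = g.ndim
        lo, hi = self.bc[axis]
        if lo == "inflow":
            F[ops._sl(nd, axis, 0)] = self.inflow[axis]
        elif lo == "slip":
            F[ops._sl(nd, axis, 0)] = 0.0
        if hi == "slip":
            F[ops._sl(nd, axis, -1)] = 0.0
        elif hi == "outflow":
            F[ops._sl(nd, axis, -1)] = u[axis][ops._sl(nd, axis, -1)]
        return F

    def _face_areas(self, axis: int) -> np.ndarray:
        g = self.grid
        widths = [ax.widths for i, ax in enumerate(g.axes) if i != axis]
        if not widths:
            return np.asarray(1.0)
        a = widths[0]
        for w in widths[1:]:
            a = np.multiply.outer(a, w)
        return a

    def _mass_correct(self, faces: list[np.ndarray]) -> None:
        """Scale/shift outflow faces so global mass is conserved exactly."""
        if self.bc_kind != "windtunnel":
            return
        nd = self.grid.ndim
        net = 0.0
        for axis, F in enumerate(faces):
            areas = self._face_areas(axis)
            net += np.sum(F[ops._sl(nd, axis, -1)] * areas)
            net -= np.sum(F[ops._sl(nd, axis, 0)] * areas)
        # distribute the defect uniformly over the outflow face
        areas = self._face_areas(0)
        total_area = np.sum(areas)
        faces[0][ops._sl(nd, 0, -1)] -= net / total_area

    def _convection(self, u: list[np.ndarray], faces: list[np.ndarray]) -> list[np.ndarray]:
        g = self.grid
        nd = g.ndim
        conv = []
        for i in range(nd):
            flux_faces = []
            for j in range(nd):
                ui_f = ops.face_interp(u[i], g, j)
                lo, hi = self.bc[j]
                if lo == "inflow":
                    ui_f[ops._sl(nd, j, 0)] = self.inflow[i]
                flux_faces.append(faces[j] * ui_f)
            conv.append(ops.divergence(flux_faces, g))
        return conv

    def _solve_poisson(self, rhs: np.ndarray) -> np.ndarray:
        flat = rhs.ravel().copy()
        if self._lu_p is not None:
            # gauge: the pinned row enforces phi[0] = 0; the dropped
            # divergence constraint at cell 0 is implied by global mass
            # compatibility
            flat[0] = 0.0
            sol = self._lu_p.solve(flat)
            self.last_poisson_residual = float(
                np.linalg.norm(self._Lp @ sol - flat) / max(np.linalg.norm(flat), 1e-300)
            )
        else:
            # consistent singular SPD system: -V L phi = -V rhs; remove the
            # nullspace component from the RHS, fix the gauge afterwards
            b = -self._vol * flat
            b -= self._vol * (b.sum() / self._vol.sum())
            sol, info = spla.cg(
                self._A_cg, b, M=self._M_cg, rtol=self.settings.poisson_tol,
                atol=0.0, maxiter=self.settings.poisson_maxiter,
            )
            sol -= sol.mean()
            res = float(
                np.linalg.norm(self._A_cg @ sol - b) / max(np.linalg.norm(b), 1e-300)
            )
            self.last_poisson_residual = res
            if info > 0 and res > 100 * self.settings.poisson_tol:
                raise SolverError(
                    f"pressure Poisson failed to converge: residual {res:.3e} "
                    f"after {self.settings.poisson_maxiter} iterations"
                )
        return sol.reshape(self.grid.shape)

    # ------------------------------------------------------------------ step
    def step(self) -> FlowState:
        """Advance one time step; returns the updated state."""
        g = self.grid
        nd = g.ndim
        dt = self.dt
        st = self.state
        t_new = st.t + dt

        solid, ghost, per_body = self._classify(t_new) if self.bodies else (None, None, [])
        if self.bodies:
            prev_solid = st.solid if st.solid is not None else np.zeros(g.shape, bool)
            fresh = prev_solid & ~solid
            if fresh.any():
                # seed freshly-cleared cells with the local body velocity
                sd = np.full(fresh.sum(), np.inf)
                vel = np.zeros((fresh.sum(), nd))
                pts = self._mesh[fresh]
                for body in self.bodies:
                    d = np.abs(body.sdf(pts))
                    closer = d < sd
                    if closer.any():
                        vel[closer] = body.velocity_at(pts[closer])
                        sd = np.minimum(sd, d)
                for i in range(nd):
                    st.u[i][fresh] = vel[:, i]
        else:
            fresh = None

        conv = self._convection(st.u, st.faces)
        if self._conv_prev is None:
            conv_ab = conv
        else:
            conv_ab = [1.5 * c - 0.5 * cp for c, cp in zip(conv, self._conv_prev)]
        self._conv_prev = conv

        gradp = [ops.center_gradient(st.p, g, i) for i in range(nd)]
        a = dt / (2.0 * self.settings.re)
        u_star = []
        for i in range(nd):
            rhs = st.u[i] + dt * (-conv_ab[i] - gradp[i])
            if self.settings.diffusion == "cn":
                Lu = (self._Lv @ st.u[i].ravel()).reshape(g.shape)
                rhs = rhs + a * Lu
                if self._dir_coeff is not None:
                    rhs = rhs + 2.0 * a * self._dir_coeff * self.inflow[i]
                ui = self._lu_v.solve(rhs.ravel()).reshape(g.shape)
            else:
                Lu = (self._Lv @ st.u[i].ravel()).reshape(g.shape)
                diff = Lu / self.settings.re
                if self._dir_coeff is not None:
                    diff = diff + self._dir_coeff * self.inflow[i] / self.settings.re
                ui = rhs + dt * diff
            u_star.append(ui)

        if self.bodies:
            self._apply_ghosts(u_star, per_body, solid, ghost)

        faces_star = [self._face_field(u_star, i) for i in range(nd)]
        if self.settings.rhie_chow:
            for i in range(nd):
                gp_f = ops.face_gradient(st.p, g, i)
                gp_c = ops.face_interp(gradp[i], g, i)
                corr = dt * (gp_f - gp_c)
                corr[ops._sl(nd, i, 0)] = 0.0
                corr[ops._sl(nd, i, -1)] = 0.0
                faces_star[i] = faces_star[i] - corr
        self._mass_correct(faces_star)

        rhs_p = ops.divergence(faces_star, g) / dt
        phi = self._solve_poisson(rhs_p)

        faces_new = []
        for i in range(nd):
            gphi = ops.face_gradient(phi, g, i)
            F = faces_star[i] - dt * gphi
            faces_new.append(F)
        u_new = [u_star[i] - dt * ops.center_gradient(phi, g, i) for i in range(nd)]
        p_new = st.p + phi

        if self.bodies:
            self._apply_ghosts(u_new, per_body, solid, ghost)

        for i in range(nd):
            if not np.isfinite(u_new[i]).all():
                raise DivergenceError(
                    f"NaN/Inf detected in velocity component {i} at step "
                    f"{self.step_count + 1} (t={t_new:.5f})"
                )

        if self.settings.check_divergence:
            div = ops.divergence(faces_new, g)
            if solid is not None:
                div = div[~solid]
            self.last_divergence = float(np.max(np.abs(div))) if div.size else 0.0

        self.state = FlowState(
            u=u_new, faces=faces_new, p=p_new, t=t_new,
            solid=solid, ghost=ghost, fresh=fresh,
        )
        self.step_count += 1
        if log.isEnabledFor(logging.DEBUG):
            log.debug(
                "step %d t=%.5f div=%.3e poisson_res=%.3e",
                self.step_count, t_new, self.last_divergence,
                self.last_poisson_residual,
            )
        return self.state

    # ------------------------------------------------------------------- runs
    def run(self, n_steps: int, observers: tuple = ()) -> FlowState:
        for obs in observers:
            obs.start(self)
        for _ in range(n_steps):
            self.step()
            for obs in observers:
                obs(self)
        return self.state

    def run_cycles(
        self,
        n_cycles: int,
        period: float,
        observers: tuple = (),
        steps_per_cycle: int | None = None,
    ) -> FlowState:
        """Run whole flapping cycles; the time step is snapped so each cycle
        is an integer number of steps and the final cycle is the analysis
        cycle."""
        if n_cycles == 0:
            for obs in observers:
                obs.start(self)
            return self.state
        if steps_per_cycle is None:
            steps_per_cycle = max(4, int(np.ceil(period / self.dt)))
        new_dt = period / steps_per_cycle
        if abs(new_dt - self.dt) > 1e-15:
            self.dt = new_dt
            self._build_operators()
        self.steps_per_cycle = steps_per_cycle
        return self.run(n_cycles * steps_per_cycle, observers=observers)


class Observer:
    """Base observer: called after every step with the simulation."""

    def start(self, sim: Simulation) -> None:  # pragma: no cover - trivial
        pass

    def __call__(self, sim: Simulation) -> None:  # pragma: no cover
        raise NotImplementedError
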