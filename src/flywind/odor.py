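"""Convection-dominated odor transport.

Three ingredients, all assuming the high-Peclet regime where diffusion is
negligible and odorant rides the air:

* Lagrangian tracers (:func:`advect_particles`) — RK2 midpoint advection of
  neutrally buoyant particles with multilinear space interpolation and
  linear time interpolation between stored flow snapshots.
* Odor-mass-flux probes (:func:`odor_flux`) — ``C' rho_odor |U*|`` sampled
  a fixed offset (0.03 R) above surface landmarks; the antenna value
  averages a triplet of probes.
* An optional Eulerian advected concentration (:func:`advect_scalar`) with
  a monotone first-order upwind flux and an inlet feeding ``C' = 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from . import operators as ops
from .grid import CartesianGrid

__all__ = [
    "OdorConfig",
    "ParticleSet",
    "ProbeSpec",
    "OdorProbeSeries",
    "VelocitySampler",
    "advect_particles",
    "odor_flux",
    "advect_scalar",
    "release_grid",
    "capture_fraction",
    "ProbeObserver",
    "ParticleTracer",
]

RHO_ODOR = 1.225          # kg/m^3, odor density = air density
PROBE_OFFSET = 0.03       # units of R above the surface landmark


@dataclass(frozen=True)
class OdorConfig:
    """Odor-transport parameters; diffusion is off by default (Pe >> 1)."""

    c_inlet: float = 1.0
    rho_odor: float = RHO_ODOR
    diffusion: bool = False
    diffusivity: float = 0.1      # cm^2/s, only used when diffusion is on
    tracer_dt: float | None = None


@dataclass
class ParticleSet:
    """Positions + provenance of Lagrangian tracers.

    Particles deactivate only by leaving the domain; the count is conserved
    otherwise.  ``origin`` tags the release location (color in the paper's
    visualizations)."""

    positions: np.ndarray
    origin: np.ndarray
    release_time: np.ndarray
    active: np.ndarray

    @classmethod
    def release(cls, positions: np.ndarray, origin, t: float = 0.0) -> "ParticleSet":
        positions = np.atleast_2d(np.asarray(positions, dtype=float))
        n = positions.shape[0]
        origin = np.broadcast_to(np.asarray(origin), (n,)).copy()
        return cls(
            positions=positions.copy(),
            origin=origin,
            release_time=np.full(n, t),
            active=np.ones(n, dtype=bool),
        )

    def merge(self, other: "ParticleSet") -> "ParticleSet":
        return ParticleSet(
            positions=np.vstack([self.positions, other.positions]),
            origin=np.concatenate([self.origin, other.origin]),
            release_time=np.concatenate([self.release_time, other.release_time]),
            active=np.concatenate([self.active, other.active]),
        )

    @property
    def n(self) -> int:
        return int(self.positions.shape[0])


def release_grid(
    x: float,
    spans: list[tuple[float, float, int]],
    tag_axis: int | None = None,
    n_tags: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Seed points on a plane/line at streamwise station ``x``.

    ``spans`` gives (lo, hi, count) per transverse axis.  Tags stratify the
    seeds into ``n_tags`` bands along ``tag_axis`` (default: the first
    transverse axis), emulating per-release-height particle colors.
    """
    axes = [np.linspace(lo, hi, n) for lo, hi, n in spans]
    mesh = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([np.full(mesh[0].size, x)] + [m.ravel() for m in mesh])
    if tag_axis is None:
        tag_axis = 0
    coord = mesh[tag_axis].ravel()
    lo, hi = coord.min(), coord.max()
    if hi <= lo:
        tags = np.zeros(pts.shape[0], dtype=int)
    else:
        tags = np.minimum((n_tags * (coord - lo) / (hi - lo)).astype(int), n_tags - 1)
    return pts, tags


class VelocitySampler:
    """Interpolates a flow history in space (multilinear) and time (linear).

    Built either from stored snapshots ``(t, [u_i fields])`` or updated live
    during a run."""

    def __init__(self, grid: CartesianGrid):
        self.grid = grid
        self._times: list[float] = []
        self._interps: list[list[RegularGridInterpolator]] = []
        self._lo = np.array([ax.faces[0] for ax in grid.axes])
        self._hi = np.array([ax.faces[-1] for ax in grid.axes])
        self._clo = np.array([ax.centers[0] for ax in grid.axes])
        self._chi = np.array([ax.centers[-1] for ax in grid.axes])

    def add_snapshot(self, t: float, u: list[np.ndarray]) -> None:
        interps = [
            RegularGridInterpolator(self.grid.centers, c.copy(), bounds_error=False, fill_value=None)
            for c in u
        ]
        self._times.append(t)
        self._interps.append(interps)

    @property
    def t_min(self) -> float:
        return self._times[0]

    @property
    def t_max(self) -> float:
        return self._times[-1]

    def _eval_at(self, k: int, pts: np.ndarray) -> np.ndarray:
        p = np.clip(pts, self._clo, self._chi)
        return np.column_stack([f(p) for f in self._interps[k]])

    def velocity(self, pts: np.ndarray, t: float) -> np.ndarray:
        """Velocity at points ``pts`` and time ``t`` (clamped to history)."""
        ts = self._times
        if not ts:
            raise ValueError("sampler has no snapshots")
        pts = np.atleast_2d(pts)
        if t <= ts[0]:
            return self._eval_at(0, pts)
        if t >= ts[-1]:
            return self._eval_at(len(ts) - 1, pts)
        k = int(np.searchsorted(ts, t)) - 1
        w = (t - ts[k]) / (ts[k + 1] - ts[k])
        return (1 - w) * self._eval_at(k, pts) + w * self._eval_at(k + 1, pts)

    def in_domain(self, pts: np.ndarray) -> np.ndarray:
        return np.all((pts >= self._lo) & (pts <= self._hi), axis=1)


def advect_particles(
    particles: ParticleSet,
    sampler: VelocitySampler,
    dt: float,
    t0: float,
    n_steps: int = 1,
    bodies: tuple = (),
) -> tuple[ParticleSet, dict]:
    """RK2 (midpoint) advection of active particles through the flow history.

    Particles leaving the domain deactivate; particles stepping inside a
    solid body are projected back to its surface and counted in the returned
    stats.  Origin tags are preserved.
    """
    ps = ParticleSet(
        positions=particles.positions.copy(),
        origin=particles.origin.copy(),
        release_time=particles.release_time.copy(),
        active=particles.active.copy(),
    )
    n_projected = 0
    t = t0
    for _ in range(n_steps):
        act = ps.active
        if act.any():
            x = ps.positions[act]
            v1 = sampler.velocity(x, t)
            xm = x + 0.5 * dt * v1
            v2 = sampler.velocity(xm, t + 0.5 * dt)
            xn = x + dt * v2
            for body in bodies:
                inside = body.sdf(xn) < 0
                if inside.any():
                    surf, _d = body.nearest_surface(xn[inside])
                    xn[inside] = surf
                    n_projected += int(inside.sum())
            ps.positions[act] = xn
            ps.active[act] = sampler.in_domain(xn)
        t += dt
    return ps, {"n_projected": n_projected, "t_end": t}


# ---------------------------------------------------------------------------
# probes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProbeSpec:
    """Antenna probe triplet plus optional body-site probes.

    The triplet sits ``offset`` above the antenna landmark, spaced one
    refined-grid cell apart along the body (x) axis.
    """

    antenna: np.ndarray                      # landmark position, units of R
    offset: float = PROBE_OFFSET
    spacing: float = 0.0125
    body_sites: np.ndarray | None = None     # (m, dim) landmark points
    body_normals: np.ndarray | None = None   # outward normals at those sites

    def points(self) -> np.ndarray:
        a = np.asarray(self.antenna, dtype=float)
        dim = a.size
        up = np.zeros(dim)
        up[1] = 1.0
        triplet = np.array(
            [a + self.offset * up + s * np.eye(dim)[0] for s in (-self.spacing, 0.0, self.spacing)]
        )
        if self.body_sites is None:
            return triplet
        sites = np.atleast_2d(self.body_sites)
        normals = (
            np.atleast_2d(self.body_normals)
            if self.body_normals is not None
            else np.tile(up, (sites.shape[0], 1))
        )
        return np.vstack([triplet, sites + self.offset * normals])


@dataclass
class OdorProbeSeries:
    """Time series of odor mass flux per probe (kg s^-1 m^-2).

    Probes 0..2 are the antenna triplet; ``antenna_flux`` is their mean.
    """

    times: list[float] = field(default_factory=list)
    flux: list[np.ndarray] = field(default_factory=list)

    def append(self, t: float, per_probe: np.ndarray) -> None:
        if np.any(per_probe < 0):
            raise ValueError("odor mass flux must be nonnegative")
        self.times.append(t)
        self.flux.append(np.asarray(per_probe, dtype=float))

    @property
    def t(self) -> np.ndarray:
        return np.asarray(self.times)

    @property
    def per_probe(self) -> np.ndarray:
        return np.asarray(self.flux)

    @property
    def antenna_flux(self) -> np.ndarray:
        return self.per_probe[:, :3].mean(axis=1)


def odor_flux(
    u_probe: np.ndarray,
    c_prime: float | np.ndarray = 1.0,
    rho_odor: float = RHO_ODOR,
    u_scale: float = 1.0,
) -> np.ndarray:
    """Odor mass flux ``C' rho_odor |U*|`` per probe, in kg s^-1 m^-2.

    ``u_probe`` holds probe velocities (any number of rows); ``u_scale``
    converts nondimensional velocities to m/s.  ``U*`` enters as a
    magnitude, so the flux is nonnegative by construction.
    """
    u_probe = np.atleast_2d(u_probe)
    mag = np.linalg.norm(u_probe, axis=1) * u_scale
    return np.asarray(c_prime) * rho_odor * mag


class ProbeObserver:
    """Records odor mass flux at a probe set during a run."""

    def __init__(
        self,
        spec: ProbeSpec,
        u_scale: float = 1.0,
        rho_odor: float = RHO_ODOR,
        c_prime: float = 1.0,
        every: int = 1,
    ):
        self.points = spec.points()
        self.u_scale = u_scale
        self.rho_odor = rho_odor
        self.c_prime = c_prime
        self.every = every
        self.series = OdorProbeSeries()

    def start(self, sim) -> None:
        for body in sim.bodies:
            if np.any(body.sdf(self.points) < 0):
                raise ValueError(
                    f"odor probe inside solid body {body.name!r}; move the probe"
                )
        self._count = 0

    def __call__(self, sim) -> None:
        self._count += 1
        if self._count % self.every:
            return
        pts = np.clip(
            self.points,
            [ax.centers[0] for ax in sim.grid.axes],
            [ax.centers[-1] for ax in sim.grid.axes],
        )
        u = np.column_stack(
            [
                RegularGridInterpolator(sim.grid.centers, c, bounds_error=False, fill_value=None)(pts)
                for c in sim.state.u
            ]
        )
        self.series.append(
            sim.state.t, odor_flux(u, self.c_prime, self.rho_odor, self.u_scale)
        )


class ParticleTracer:
    """Advects tracer particles inline with the flow solve (RK2 per step)."""

    def __init__(self, particles: ParticleSet, project_bodies: bool = True, every: int = 1):
        self.particles = particles
        self.project_bodies = project_bodies
        self.every = every
        self.snapshots: list[tuple[float, np.ndarray, np.ndarray]] = []
        self.n_projected = 0

    def start(self, sim) -> None:
        self._sampler = VelocitySampler(sim.grid)
        self._sampler.add_snapshot(sim.state.t, sim.state.u)
        self._count = 0

    def __call__(self, sim) -> None:
        self._sampler.add_snapshot(sim.state.t, sim.state.u)
        if len(self._sampler._times) > 2:
            self._sampler._times.pop(0)
            self._sampler._interps.pop(0)
        bodies = sim.bodies if self.project_bodies else ()
        self.particles, stats = advect_particles(
            self.particles, self._sampler, sim.dt, sim.state.t - sim.dt, 1, bodies
        )
        self.n_projected += stats["n_projected"]
        self._count += 1
        if self._count % self.every == 0:
            self.snapshots.append(
                (sim.state.t, self.particles.positions.copy(), self.particles.active.copy())
            )


CAPTURE_RADIUS = 0.05   # units of R, default antenna capture radius


def capture_fraction(
    snapshots: list[tuple[float, np.ndarray, np.ndarray]],
    origin: np.ndarray,
    target: np.ndarray,
    radius: float = CAPTURE_RADIUS,
) -> dict[int, float]:
    """Fraction of particles (per release-origin tag) that ever pass within
    ``radius`` of ``target`` over the stored snapshots.

    Used for the spatial-sampling anisotropy statistics (vertical vs
    lateral release origins).
    """
    if not snapshots:
        return {}
    target = np.asarray(target, dtype=float)
    n = snapshots[0][1].shape[0]
    min_d = np.full(n, np.inf)
    for _t, pos, active in snapshots:
        d = np.linalg.norm(pos - target, axis=1)
        d[~active] = np.inf
        min_d = np.minimum(min_d, d)
    captured = min_d <= radius
    return {int(tag): float(captured[origin == tag].mean()) for tag in np.unique(origin)}


# ---------------------------------------------------------------------------
# Eulerian scalar (optional mode)
# ---------------------------------------------------------------------------

class CFLViolation(RuntimeError):
    pass


def advect_scalar(
    c: np.ndarray,
    faces: list[np.ndarray],
    grid: CartesianGrid,
    dt: float,
    inflow_value: float = 1.0,
    peclet: float | None = None,
) -> np.ndarray:
    """One conservative upwind step of the advected concentration.

    The inlet (x-lo) feeds ``inflow_value``; with ``peclet`` given, an
    explicit diffusion term with coefficient 1/Pe is added.  Rejects the
    step when any face CFL exceeds 1 (the upwind stability/monotonicity
    bound); at CFL exactly 1 on a uniform grid the scheme translates the
    profile exactly.
    """
    nd = grid.ndim
    for axis, F in enumerate(faces):
        w = ops._shape1(grid.axes[axis].widths, nd, axis)
        lam = np.abs(F).max() * dt / w.min()
        if lam > 1.0 + 1e-12:
            raise CFLViolation(f"scalar CFL {lam:.3f} > 1 along axis {axis}")
    flux_div = np.zeros_like(c)
    for axis, F in enumerate(faces):
        up = np.where(
            F[ops._sl(nd, axis, slice(1, -1))] >= 0,
            c[ops._sl(nd, axis, slice(None, -1))],
            c[ops._sl(nd, axis, slice(1, None))],
        )
        shape = list(c.shape)
        shape[axis] += 1
        cf = np.zeros(shape)
        cf[ops._sl(nd, axis, slice(1, -1))] = up
        if grid.axes[axis].periodic:
            wrap = np.where(
                F[ops._sl(nd, axis, 0)] >= 0, c[ops._sl(nd, axis, -1)], c[ops._sl(nd, axis, 0)]
            )
            cf[ops._sl(nd, axis, 0)] = wrap
            cf[ops._sl(nd, axis, -1)] = wrap
        else:
            lo_val = inflow_value if axis == 0 else c[ops._sl(nd, axis, 0)]
            cf[ops._sl(nd, axis, 0)] = np.where(
                F[ops._sl(nd, axis, 0)] >= 0, lo_val, c[ops._sl(nd, axis, 0)]
            )
            cf[ops._sl(nd, axis, -1)] = c[ops._sl(nd, axis, -1)]
        w = ops._shape1(grid.axes[axis].widths, nd, axis)
        Ff = F * cf
        flux_div = flux_div + (
            Ff[ops._sl(nd, axis, slice(1, None))] - Ff[ops._sl(nd, axis, slice(None, -1))]
        ) / w
    out = c - dt * flux_div
    if peclet is not None:
        lap = np.zeros_like(c)
        for axis in range(nd):
            g = ops.face_gradient(c, grid, axis)
            w = ops._shape1(grid.axes[axis].widths, nd, axis)
            lap += (g[ops._sl(nd, axis, slice(1, None))] - g[ops._sl(nd, axis, slice(None, -1))]) / w
        out = out + dt * lap / peclet
    return out
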