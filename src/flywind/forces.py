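"""Surface-integrated aerodynamic forces, power, and coefficient definitions.

Forces are evaluated by probing pressure and velocity a short distance along
each surface element's outward normal and assembling the traction

    t = -p n + (1/Re) (du_t/dn) t_hat

per element (nondimensional: density 1, velocity U_inf, length R).  The
normal pressure gradient at a no-slip wall is neglected (thin boundary
layer) and the wall-normal velocity derivative is one-sided from the probe
point to the wall velocity.

Conventions: the freestream is along +x; thrust F_T = -F.x (the force
pushing the flyer upstream).  In 2-D (sagittal plane) vertical is +y, so
lift F_L = F.y.  In 3-D the sagittal mirror plane is y = 0: vertical is +z
(F_L = F.z) and the lateral force F.y is reported separately (~0 for
symmetric runs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .bodies import RigidBody
from .grid import CartesianGrid
from .solver import FlowState

__all__ = [
    "ForceRecord",
    "Coefficients",
    "surface_forces",
    "aero_power",
    "coefficients",
    "ForceObserver",
]

DRAG_AXIS = 0   # +x is the freestream direction; thrust is -x


def lift_axis(ndim: int) -> int:
    """Vertical axis: +y on the 2-D sagittal plane, +z in 3-D."""
    return 1 if ndim == 2 else 2


@dataclass
class ForceRecord:
    """Instantaneous force/power sample for one body."""

    t: float
    f_lift: float
    f_thrust: float
    f_lateral: float
    p_aero: float
    per_face_lift: np.ndarray

    @property
    def f_total(self) -> float:
        return float(np.sqrt(self.f_lift**2 + self.f_thrust**2))


def _tractions(
    state: FlowState,
    grid: CartesianGrid,
    body: RigidBody,
    re: float,
    probe_offset: float | None = None,
):
    """Per-element traction vectors (fluid on body) and element areas."""
    surf = body.surface()
    if grid.box is not None:
        lo_b = np.array([b[0] for b in grid.box])
        hi_b = np.array([b[1] for b in grid.box])
        if np.any(surf.centroids < lo_b) or np.any(surf.centroids > hi_b):
            warnings.warn(
                f"body {body.name!r} extends outside the refined box; "
                "force accuracy degraded",
                stacklevel=3,
            )
    d = probe_offset if probe_offset is not None else 1.6 * grid.min_width()
    probes = surf.centroids + d * surf.normals

    lo = np.array([ax.centers[0] for ax in grid.axes])
    hi = np.array([ax.centers[-1] for ax in grid.axes])
    probes = np.clip(probes, lo, hi)

    p_interp = RegularGridInterpolator(grid.centers, state.p, bounds_error=False, fill_value=None)
    u_interp = [
        RegularGridInterpolator(grid.centers, c, bounds_error=False, fill_value=None)
        for c in state.u
    ]
    p_s = p_interp(probes)
    u_probe = np.column_stack([ui(probes) for ui in u_interp])
    du = (u_probe - surf.velocities) / d          # one-sided normal derivative
    # remove the normal component: keep the shear part of the traction
    dun = np.sum(du * surf.normals, axis=1, keepdims=True)
    shear = (du - dun * surf.normals) / re
    traction = -p_s[:, None] * surf.normals + shear
    return traction, surf


def surface_forces(
    state: FlowState,
    grid: CartesianGrid,
    body: RigidBody,
    re: float,
    probe_offset: float | None = None,
) -> tuple[float, float, float, np.ndarray]:
    """Integrate tractions over the body surface.

    Returns ``(f_lift, f_thrust, f_lateral, per_face_lift)``; the per-face
    lift map sums to ``f_lift`` exactly.
    """
    traction, surf = _tractions(state, grid, body, re, probe_offset)
    f_elem = traction * surf.areas[:, None]
    force = f_elem.sum(axis=0)
    la = lift_axis(grid.ndim)
    per_face_lift = f_elem[:, la]
    f_lift = float(force[la])
    f_thrust = float(-force[DRAG_AXIS])
    f_lateral = float(force[1]) if grid.ndim == 3 else 0.0
    return f_lift, f_thrust, f_lateral, per_face_lift


def aero_power(
    state: FlowState,
    grid: CartesianGrid,
    body: RigidBody,
    re: float,
    probe_offset: float | None = None,
) -> float:
    """Power the body spends flapping against air resistance.

    ``P = -sum(traction_on_body . v_surface) dA``: positive when the body
    does net work on the fluid; exactly zero for a stationary body.
    """
    traction, surf = _tractions(state, grid, body, re, probe_offset)
    work = np.sum(traction * surf.velocities, axis=1) * surf.areas
    return float(-np.sum(work))


@dataclass(frozen=True)
class Coefficients:
    c_lift: float
    c_thrust: float
    c_force: float
    c_power: float

    @property
    def force_to_power(self) -> float:
        return self.c_force / self.c_power


def coefficients(
    f_lift: float,
    f_thrust: float,
    p_aero: float,
    u_tip: float,
    area: float,
    rho: float = 1.0,
    u_total: float | None = None,
) -> Coefficients:
    """Nondimensionalize forces and power.

    ``C_L = F_L / (0.5 rho U_tip^2 S)`` and likewise for thrust; the total
    force coefficient uses ``u_total`` (defaults to ``u_tip``, making C_F
    consistent with C_L/C_T); ``C_PW = P / (0.5 rho U_tip^3 S)``.
    """
    if u_tip <= 0 or area <= 0 or rho <= 0:
        raise ValueError("u_tip, area and rho must be positive")
    if u_total is None:
        u_total = u_tip
    q = 0.5 * rho * u_tip**2 * area
    f_total = np.sqrt(f_lift**2 + f_thrust**2)
    return Coefficients(
        c_lift=f_lift / q,
        c_thrust=f_thrust / q,
        c_force=f_total / (0.5 * rho * u_total**2 * area),
        c_power=p_aero / (0.5 * rho * u_tip**3 * area),
    )


class ForceObserver:
    """Per-step force/power recorder for one body."""

    def __init__(self, body: RigidBody, re: float, probe_offset: float | None = None):
        self.body = body
        self.re = re
        self.probe_offset = probe_offset
        self.times: list[float] = []
        self.records: list[ForceRecord] = []

    def start(self, sim) -> None:
        self.grid = sim.grid

    def __call__(self, sim) -> None:
        st = sim.state
        fl, ft, flat_, per_face = surface_forces(
            st, sim.grid, self.body, self.re, self.probe_offset
        )
        pw = aero_power(st, sim.grid, self.body, self.re, self.probe_offset)
        self.times.append(st.t)
        self.records.append(
            ForceRecord(t=st.t, f_lift=fl, f_thrust=ft, f_lateral=flat_,
                        p_aero=pw, per_face_lift=per_face)
        )

    def series(self) -> dict[str, np.ndarray]:
        return {
            "t": np.asarray(self.times),
            "f_lift": np.asarray([r.f_lift for r in self.records]),
            "f_thrust": np.asarray([r.f_thrust for r in self.records]),
            "f_lateral": np.asarray([r.f_lateral for r in self.records]),
            "p_aero": np.asarray([r.p_aero for r in self.records]),
        }
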