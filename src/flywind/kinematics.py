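"""Prescribed flapping-wing kinematics and dimensionless-group bookkeeping.

Euler-angle convention (all angles in degrees at the interface, radians
internally):

* position angle ``phi(t) = 0.5 * amplitude * cos(2 pi f t)`` — sweep within
  the stroke plane; the downstroke is the half-cycle where ``phi`` decreases
  (t in (0, T/2) for the cosine schedule).
* deviation angle ``theta`` — elevation out of the stroke plane, constant
  (0 by default).
* feathering angle ``alpha`` — pitch about the spanwise axis, measured from
  the stroke plane, positive nose-up.  Held at ``alpha_down`` during the
  downstroke plateau and ``alpha_up`` during the upstroke plateau, blended
  with a half-cosine across a reversal window of width
  ``reversal_fraction * T`` centered on each stroke reversal (the extrema
  of ``phi``).

The wing transform composes body incline ``chi`` (pitch of the body axis
above horizontal), stroke-plane tilt ``beta`` (measured against the body
axis), then the wing Euler angles about the hinge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "WingKinematics",
    "DimensionlessGroups",
    "wing_angles",
    "wing_transform",
    "dimensionless",
    "mean_tip_speed",
]


@dataclass(frozen=True)
class WingKinematics:
    """Flapping schedule parameters.  Angles in degrees, frequency in Hz."""

    amplitude: float = 140.0        # peak-to-peak stroke amplitude Phi
    frequency: float = 213.0        # wingbeat frequency f
    deviation: float = 0.0          # constant deviation theta
    alpha_up: float = 60.0          # feathering plateau, upstroke
    alpha_down: float = -30.0       # feathering plateau, downstroke
    reversal_fraction: float = 0.22  # fraction of T spent pitching at reversal
    stroke_plane: float = 20.0      # beta, vs the body axis
    body_incline: float = 45.0      # chi, body axis vs horizontal
    hinge: tuple[float, float, float] = (0.0, 0.0, 0.0)  # wing root, units of R

    def __post_init__(self) -> None:
        if not 0.0 < self.amplitude <= 180.0:
            raise ValueError("amplitude must be in (0, 180] degrees")
        if not 0.0 < self.reversal_fraction < 0.5:
            raise ValueError("reversal_fraction must be in (0, 0.5)")
        if self.frequency <= 0.0:
            raise ValueError("frequency must be positive")

    @property
    def period(self) -> float:
        return 1.0 / self.frequency


@dataclass(frozen=True)
class DimensionlessGroups:
    """Re, k, Sc, Pe and the dimensional scales they came from."""

    reynolds: float
    reduced_frequency: float
    schmidt: float
    peclet: float
    u_inf: float   # m/s
    nu: float      # m^2/s
    diffusivity: float  # cm^2/s

    def __post_init__(self) -> None:
        for name in ("reynolds", "reduced_frequency", "schmidt", "peclet"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def dimensionless(
    u_inf: float, span: float, nu: float, frequency: float, diffusivity: float = 0.1
) -> DimensionlessGroups:
    """Compute Re = U_inf R / nu, k = f R / U_inf, Sc = nu / D, Pe = Re Sc.

    Parameters
    ----------
    u_inf : m/s
    span : m (wingspan R)
    nu : m^2/s
    frequency : Hz
    diffusivity : cm^2/s (odorant diffusivity in air)
    """
    for name, val in [
        ("u_inf", u_inf), ("span", span), ("nu", nu),
        ("frequency", frequency), ("diffusivity", diffusivity),
    ]:
        if val <= 0:
            raise ValueError(f"{name} must be positive, got {val}")
    re = u_inf * span / nu
    k = frequency * span / u_inf
    sc = nu / (diffusivity * 1e-4)  # cm^2/s -> m^2/s
    return DimensionlessGroups(
        reynolds=re, reduced_frequency=k, schmidt=sc, peclet=re * sc,
        u_inf=u_inf, nu=nu, diffusivity=diffusivity,
    )


# ---------------------------------------------------------------------------
# angle schedules
# ---------------------------------------------------------------------------

def _alpha_schedule(tau: np.ndarray, kin: WingKinematics) -> np.ndarray:
    """Feathering angle at cycle phase tau = (t/T) mod 1, in degrees.

    Reversals sit at tau = 0 (dorsal, start of downstroke) and tau = 0.5
    (ventral).  Each blend window has width ``reversal_fraction`` and is
    centered on its reversal; the blend is a half cosine, C^1-continuous
    against the plateaus.
    """
    w = kin.reversal_fraction
    a_up, a_dn = kin.alpha_up, kin.alpha_down
    tau = np.mod(tau, 1.0)
    alpha = np.empty_like(tau)

    # downstroke plateau: tau in [w/2, 0.5 - w/2]
    # upstroke plateau:   tau in [0.5 + w/2, 1 - w/2]
    dn = (tau >= w / 2) & (tau <= 0.5 - w / 2)
    up = (tau >= 0.5 + w / 2) & (tau <= 1.0 - w / 2)
    alpha[dn] = a_dn
    alpha[up] = a_up

    # dorsal reversal (around tau=0): up -> down
    mask = (tau < w / 2) | (tau > 1.0 - w / 2)
    s = np.mod(tau[mask] + w / 2, 1.0) / w  # 0..1 across the window
    alpha[mask] = a_up + (a_dn - a_up) * 0.5 * (1 - np.cos(np.pi * s))

    # ventral reversal (around tau=0.5): down -> up
    mask = (tau > 0.5 - w / 2) & (tau < 0.5 + w / 2)
    s = (tau[mask] - (0.5 - w / 2)) / w
    alpha[mask] = a_dn + (a_up - a_dn) * 0.5 * (1 - np.cos(np.pi * s))
    return alpha


def wing_angles(t, kin: WingKinematics):
    """Euler angles (phi, theta, alpha) in degrees at time ``t`` (seconds).

    Accepts scalars or arrays; total function of t >= 0.
    """
    t = np.asarray(t, dtype=float)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    tau = t * kin.frequency
    phi = 0.5 * kin.amplitude * np.cos(2 * np.pi * tau)
    theta = np.full_like(phi, kin.deviation)
    alpha = _alpha_schedule(tau, kin)
    if scalar:
        return float(phi[0]), float(theta[0]), float(alpha[0])
    return phi, theta, alpha


# ---------------------------------------------------------------------------
# rigid transforms
# ---------------------------------------------------------------------------

def _rot(axis: int, angle_deg: float) -> np.ndarray:
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    m = np.eye(3)
    i, j = [(1, 2), (2, 0), (0, 1)][axis]
    m[i, i] = c
    m[j, j] = c
    m[i, j] = -s
    m[j, i] = s
    return m


@dataclass(frozen=True)
class RigidTransform:
    """x_lab = rotation @ x_wing + translation (the hinge position)."""

    rotation: np.ndarray
    translation: np.ndarray

    def apply(self, pts: np.ndarray) -> np.ndarray:
        return np.asarray(pts) @ self.rotation.T + self.translation


def wing_transform(t: float, kin: WingKinematics, side: str = "left") -> RigidTransform:
    """Rigid transform from the wing frame to the lab frame at time ``t``.

    Wing frame: root at origin, span axis +y (pointing out the left side),
    chord axis +x (pointing aft), freestream along +x in the lab frame.
    The composition is body incline ``chi``, stroke-plane tilt ``beta``
    (both pitches about the lab y-axis), then flapping ``phi`` (rotation
    about the stroke-plane x-axis), deviation ``theta`` and feathering
    ``alpha`` (about the spanwise axis).  ``side='right'`` mirrors about
    the sagittal (y=0) plane.
    """
    if side not in ("left", "right"):
        raise ValueError(f"unknown wing side {side!r}; use 'left' or 'right'")
    phi, theta, alpha = wing_angles(t, kin)
    # pitch of the stroke plane above horizontal; chi and beta oppose
    pitch = kin.body_incline - kin.stroke_plane
    rot = (
        _rot(1, -pitch)       # stroke plane orientation in the lab
        @ _rot(0, -phi)       # sweep within the stroke plane
        @ _rot(0, theta)      # elevation (constant)
        @ _rot(1, -alpha)     # feathering about the span axis
    )
    tr = np.asarray(kin.hinge, dtype=float)
    if side == "right":
        mirror = np.diag([1.0, -1.0, 1.0])
        rot = mirror @ rot @ mirror
        tr = mirror @ tr
    return RigidTransform(rotation=rot, translation=tr)


def wing_point_velocity(
    t: float, kin: WingKinematics, pts_wing: np.ndarray,
    side: str = "left", eps: float = 1e-7,
) -> np.ndarray:
    """Lab-frame velocity of material points by central differencing."""
    tp = wing_transform(t + eps, kin, side).apply(pts_wing)
    tm = wing_transform(max(t - eps, 0.0), kin, side).apply(pts_wing)
    dt = (t + eps) - max(t - eps, 0.0)
    return (tp - tm) / dt


def mean_tip_speed(kin: WingKinematics, span: float, n: int = 20000) -> float:
    """Cycle-mean wing-tip speed (units of span/s for span in those units).

    The tip sits on the spanwise axis at radius ``span``; with constant
    deviation its lab speed is ``span * |dphi/dt|``, whose cycle mean has
    the closed form ``2 * Phi * f * span`` (Phi in radians).  Computed here
    by quadrature of the transform for generality.
    """
    T = kin.period
    ts = (np.arange(n) + 0.5) * T / n
    tip = np.array([0.0, span, 0.0])
    speeds = np.linalg.norm(
        [wing_point_velocity(t, kin, tip[None, :])[0] for t in ts], axis=1
    )
    return float(np.mean(speeds))


def mean_tip_speed_analytic(kin: WingKinematics, span: float) -> float:
    """Closed-form cycle-mean tip speed: 2 Phi f R with Phi in radians."""
    return 2.0 * np.deg2rad(kin.amplitude) * kin.frequency * span


def schedule_table(kin: WingKinematics, n: int = 200) -> np.ndarray:
    """(t, phi, theta, alpha) rows over one period, for CSV export."""
    ts = np.linspace(0.0, kin.period, n, endpoint=False)
    phi, theta, alpha = wing_angles(ts, kin)
    return np.column_stack([ts, phi, theta, alpha])
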