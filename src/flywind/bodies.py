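"""Immersed rigid bodies for the ghost-cell procedure.

A body couples a *body-frame geometry provider* (signed distance, boundary
samples for nearest-point queries, surface quadrature elements) with a
*pose* callable ``t -> (rotation, translation)``.  Rigid-body velocities are
obtained by central differencing of the pose, so any smooth schedule works
without analytic derivatives.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Protocol

import numpy as np
import shapely
from scipy.spatial import cKDTree
from shapely.geometry import Polygon

__all__ = [
    "BodyFrameGeometry",
    "Polygon2D",
    "Ellipsoid3D",
    "ExtrudedPolygon3D",
    "RigidBody",
    "static_pose",
]

Pose = Callable[[float], tuple[np.ndarray, np.ndarray]]


def static_pose(dim: int) -> Pose:
    R = np.eye(dim)
    t = np.zeros(dim)
    return lambda _t: (R, t)


class BodyFrameGeometry(Protocol):
    dim: int

    def sdf(self, pts: np.ndarray) -> np.ndarray: ...
    def boundary_samples(self, spacing: float) -> np.ndarray: ...
    def surface_elements(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]: ...


class Polygon2D:
    """Closed polygon (counter-clockwise) in the body frame."""

    dim = 2

    def __init__(self, vertices: np.ndarray):
        v = np.asarray(vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise ValueError("polygon needs an (n>=3, 2) vertex array")
        self.vertices = v
        self.polygon = Polygon(v)
        if not self.polygon.is_valid:
            raise ValueError("polygon is self-intersecting")
        if self.polygon.exterior.is_ccw is False:
            self.vertices = v[::-1]
            self.polygon = Polygon(self.vertices)
        self._boundary = self.polygon.exterior

    def sdf(self, pts: np.ndarray) -> np.ndarray:
        geoms = shapely.points(pts)
        dist = shapely.distance(geoms, self._boundary)
        inside = shapely.contains_xy(self.polygon, pts[:, 0], pts[:, 1])
        return np.where(inside, -dist, dist)

    def boundary_samples(self, spacing: float) -> np.ndarray:
        per = self._boundary.length
        n = max(32, int(np.ceil(per / spacing)))
        return np.array(
            [self._boundary.interpolate(i / n, normalized=True).coords[0] for i in range(n)]
        )

    def surface_elements(self):
        v = self.vertices
        nxt = np.roll(v, -1, axis=0)
        mid = 0.5 * (v + nxt)
        edge = nxt - v
        lengths = np.linalg.norm(edge, axis=1)
        # outward normal of a CCW polygon: rotate edge by -90 degrees
        normals = np.column_stack([edge[:, 1], -edge[:, 0]]) / lengths[:, None]
        return mid, normals, lengths


class Ellipsoid3D:
    """Axis-aligned ellipsoid; approximate SDF (exact sign, near-exact scale)."""

    dim = 3

    def __init__(self, axes: tuple[float, float, float], n_lat: int = 16):
        self.axes = np.asarray(axes, dtype=float)
        self.n_lat = n_lat

    def sdf(self, pts: np.ndarray) -> np.ndarray:
        q = pts / self.axes
        r = np.linalg.norm(q, axis=1)
        return (r - 1.0) * self.axes.min()

    def boundary_samples(self, spacing: float) -> np.ndarray:
        n = max(12, int(np.ceil(np.pi * self.axes.max() / spacing)))
        th = np.linspace(0, np.pi, n)[1:-1]
        ph = np.linspace(0, 2 * np.pi, 2 * n, endpoint=False)
        T, P = np.meshgrid(th, ph, indexing="ij")
        pts = np.column_stack(
            [
                self.axes[0] * np.cos(T).ravel(),
                self.axes[1] * (np.sin(T) * np.cos(P)).ravel(),
                self.axes[2] * (np.sin(T) * np.sin(P)).ravel(),
            ]
        )
        poles = np.array([[self.axes[0], 0, 0], [-self.axes[0], 0, 0]])
        return np.vstack([pts, poles])

    def surface_elements(self):
        samples = self.boundary_samples(self.axes.min() / self.n_lat)
        q = samples / self.axes**2
        normals = q / np.linalg.norm(q, axis=1, keepdims=True)
        from .geometry import ellipsoid_area_thomsen

        area = ellipsoid_area_thomsen(*self.axes) / samples.shape[0]
        return samples, normals, np.full(samples.shape[0], area)


class ExtrudedPolygon3D:
    """Thin plate: a 2-D polygon (x=chordwise, y=spanwise) extruded in z."""

    dim = 3

    def __init__(self, polygon_xy: np.ndarray, thickness: float):
        self.flat = Polygon2D(np.asarray(polygon_xy, dtype=float))
        self.half = 0.5 * thickness

    def sdf(self, pts: np.ndarray) -> np.ndarray:
        dxy = self.flat.sdf(pts[:, :2])
        dz = np.abs(pts[:, 2]) - self.half
        outside = np.sqrt(np.maximum(dxy, 0) ** 2 + np.maximum(dz, 0) ** 2)
        inside = np.minimum(np.maximum(dxy, dz), 0.0)
        return np.where((dxy > 0) | (dz > 0), outside, inside)

    def boundary_samples(self, spacing: float) -> np.ndarray:
        xy = self.flat.boundary_samples(spacing)
        rim = np.column_stack([xy, np.zeros(len(xy))])
        # plus samples on both flat faces
        poly = self.flat.polygon
        xmin, ymin, xmax, ymax = poly.bounds
        xs = np.arange(xmin, xmax + spacing, spacing)
        ys = np.arange(ymin, ymax + spacing, spacing)
        gx, gy = np.meshgrid(xs, ys, indexing="ij")
        flatpts = np.column_stack([gx.ravel(), gy.ravel()])
        keep = shapely.contains_xy(poly, flatpts[:, 0], flatpts[:, 1])
        flatpts = flatpts[keep]
        top = np.column_stack([flatpts, np.full(len(flatpts), self.half)])
        bot = np.column_stack([flatpts, np.full(len(flatpts), -self.half)])
        return np.vstack([rim, top, bot])

    def surface_elements(self):
        poly = self.flat.polygon
        spacing = max(self.half, np.sqrt(poly.area) / 24)
        xmin, ymin, xmax, ymax = poly.bounds
        xs = np.arange(xmin + 0.5 * spacing, xmax, spacing)
        ys = np.arange(ymin + 0.5 * spacing, ymax, spacing)
        gx, gy = np.meshgrid(xs, ys, indexing="ij")
        pts = np.column_stack([gx.ravel(), gy.ravel()])
        keep = shapely.contains_xy(poly, pts[:, 0], pts[:, 1])
        pts = pts[keep]
        n = len(pts)
        cell = spacing * spacing
        top = np.column_stack([pts, np.full(n, self.half)])
        bot = np.column_stack([pts, np.full(n, -self.half)])
        centroids = np.vstack([top, bot])
        normals = np.vstack(
            [np.tile([0, 0, 1.0], (n, 1)), np.tile([0, 0, -1.0], (n, 1))]
        )
        areas = np.full(2 * n, cell)
        return centroids, normals, areas


@dataclass
class BodySurface:
    """Posed surface quadrature: element centroids, outward normals, areas,
    and rigid velocities in the lab frame."""

    centroids: np.ndarray
    normals: np.ndarray
    areas: np.ndarray
    velocities: np.ndarray


class RigidBody:
    """A rigid immersed body: body-frame geometry + pose schedule."""

    def __init__(
        self,
        geometry: BodyFrameGeometry,
        pose: Pose | None = None,
        name: str = "body",
        sample_spacing: float = 0.02,
        static: bool | None = None,
    ):
        self.geometry = geometry
        self.dim = geometry.dim
        self.static = static if static is not None else pose is None
        self.pose = pose if pose is not None else static_pose(self.dim)
        self.name = name
        self._samples_body = geometry.boundary_samples(sample_spacing)
        self._surf_body = geometry.surface_elements()
        self.update(0.0)

    # -- pose ---------------------------------------------------------------
    def update(self, t: float, eps: float = 1e-6) -> None:
        if self.static and hasattr(self, "R"):
            self.t = t
            return
        self.t = t
        self.R, self.trans = self.pose(t)
        Rp, tp = self.pose(t + eps)
        Rm, tm = self.pose(max(t - eps, 0.0))
        h = (t + eps) - max(t - eps, 0.0)
        self._v_trans = (tp - tm) / h
        Rdot = (Rp - Rm) / h
        self._omega_mat = Rdot @ self.R.T  # skew-symmetric spin tensor
        self._tree = cKDTree(self._samples_body @ self.R.T + self.trans)

    def to_lab(self, pts_body: np.ndarray) -> np.ndarray:
        return pts_body @ self.R.T + self.trans

    def to_body(self, pts_lab: np.ndarray) -> np.ndarray:
        return (pts_lab - self.trans) @ self.R

    # -- queries ------------------------------------------------------------
    def sdf(self, pts_lab: np.ndarray) -> np.ndarray:
        return self.geometry.sdf(self.to_body(np.atleast_2d(pts_lab)))

    def velocity_at(self, pts_lab: np.ndarray) -> np.ndarray:
        rel = np.atleast_2d(pts_lab) - self.trans
        return self._v_trans + rel @ self._omega_mat.T

    def nearest_surface(self, pts_lab: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        dist, idx = self._tree.query(np.atleast_2d(pts_lab))
        surf = self._tree.data[idx]
        return surf, dist

    def bbox(self, margin: float = 0.0) -> tuple[tuple[float, float], ...]:
        pts = self._tree.data
        return tuple(
            (pts[:, i].min() - margin, pts[:, i].max() + margin) for i in range(self.dim)
        )

    def surface(self) -> BodySurface:
        cen_b, nrm_b, areas = self._surf_body
        cen = self.to_lab(cen_b)
        nrm = nrm_b @ self.R.T
        return BodySurface(
            centroids=cen, normals=nrm, areas=areas, velocities=self.velocity_at(cen)
        )
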