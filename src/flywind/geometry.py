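"""Synthetic fly morphology: wing planform, trailing-edge clipping, and
surface meshes for the body and wings.

The wing planform is a parametric stand-in for a digitized *D. melanogaster*
wing: a smooth chord distribution with a pronounced trailing-edge bulge near
the root, scaled exactly to a requested area and span.  Wing-frame
convention: root at the origin, span axis +y, chord axis +x pointing aft
(trailing side), so a trailing-edge clip removes material at large +x.

Default morphometrics follow the fruit-fly scale: wing area 2.59 mm**2,
span 2.87 mm.  The clipped default removes the trailing-edge bulge down to
2.09 mm**2 (about 20% of the area), leaving the span unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy.optimize import brentq
from scipy.spatial import Delaunay
from shapely.geometry import LineString, Point, Polygon
from shapely.ops import split as shapely_split

__all__ = [
    "GeometryError",
    "ClippingError",
    "WingPlanform",
    "SurfaceMesh",
    "default_planform",
    "clip_trailing_edge",
    "default_clip_curve",
    "make_fly_geometry",
    "ellipsoid_area_thomsen",
    "sagittal_body_section",
]

DEFAULT_WING_AREA = 2.59   # mm^2
DEFAULT_WING_SPAN = 2.87   # mm
CLIPPED_WING_AREA = 2.09   # mm^2


class GeometryError(ValueError):
    pass


class ClippingError(GeometryError):
    pass


# ---------------------------------------------------------------------------
# planform
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WingPlanform:
    """Closed wing outline in the wing frame (mm), with span/area metadata.

    ``mean_chord`` is defined as area/span.  The stored outline is a simple
    polygon whose shoelace area equals ``area`` to machine precision.
    """

    outline: np.ndarray          # (n, 2), closed implicitly (last != first)
    span: float                  # mm
    area: float                  # mm^2
    mean_chord: float = field(init=False)

    def __post_init__(self) -> None:
        pts = np.asarray(self.outline, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
            raise GeometryError("outline must be an (n>=3, 2) array")
        poly = Polygon(pts)
        if not poly.is_valid or not poly.is_simple:
            raise GeometryError("outline must be a simple (non-self-intersecting) polygon")
        if self.area <= 0:
            raise GeometryError("planform area must be positive")
        if abs(poly.area - self.area) > 0.02 * self.area:
            raise GeometryError(
                f"outline area {poly.area:.4f} inconsistent with stated area {self.area:.4f}"
            )
        yspan = pts[:, 1].max() - pts[:, 1].min()
        if abs(yspan - self.span) > 0.02 * self.span:
            raise GeometryError(
                f"outline span {yspan:.4f} inconsistent with stated span {self.span:.4f}"
            )
        object.__setattr__(self, "outline", pts)
        object.__setattr__(self, "mean_chord", self.area / self.span)

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.outline)


def _raw_chord(s: np.ndarray) -> np.ndarray:
    """Normalized chord distribution along span fraction s in [0, 1].

    Elliptic-like base with a Gaussian trailing-edge bulge centered near
    22% span; chord pinches to zero at the tip and stays finite at the root.
    """
    base = np.sin(np.pi * (0.08 + 0.92 * s)) ** 0.6
    bulge = 1.0 + 0.8 * np.exp(-(((s - 0.22) / 0.30) ** 2))
    return base * bulge


_LE_FRACTION = 0.35  # leading edge sits 35% of local chord forward of the pitch axis


def default_planform(
    area: float = DEFAULT_WING_AREA,
    span: float = DEFAULT_WING_SPAN,
    n_outline: int = 241,
) -> WingPlanform:
    """Parametric fly-like planform scaled exactly to ``area`` and ``span``."""
    if area <= 0 or span <= 0:
        raise GeometryError("area and span must be positive")
    s = np.linspace(0.0, 1.0, n_outline)
    c = _raw_chord(s)
    # scale chord so the *polygon* area is exact (not just the integral)
    y = s * span
    x_le = -_LE_FRACTION * c
    x_te = (1.0 - _LE_FRACTION) * c
    outline = np.vstack(
        [
            np.column_stack([x_le, y]),                  # leading edge root -> tip
            np.column_stack([x_te[::-1][1:], y[::-1][1:]]),  # trailing edge tip -> root
        ]
    )
    poly_area = Polygon(outline).area
    outline[:, 0] *= area / poly_area
    return WingPlanform(outline=outline, span=span, area=area)


def default_clip_curve(
    planform: WingPlanform, target_area: float = CLIPPED_WING_AREA
) -> np.ndarray:
    """Straight spanwise clip line ``x = x*`` chosen so the kept (leading)
    area equals ``target_area``.

    Returns a two-point polyline extending past the outline on both ends.
    """
    if not 0 < target_area < planform.area:
        raise ClippingError("target_area must be in (0, planform area)")
    poly = planform.polygon
    xmin, ymin, xmax, ymax = poly.bounds

    def kept_area(xc: float) -> float:
        half = Polygon(
            [(xmin - 1, ymin - 1), (xc, ymin - 1), (xc, ymax + 1), (xmin - 1, ymax + 1)]
        )
        return poly.intersection(half).area

    xc = brentq(lambda x: kept_area(x) - target_area, xmin + 1e-9, xmax - 1e-9)
    return np.array([[xc, ymin - 0.1 * planform.span], [xc, ymax + 0.1 * planform.span]])


def clip_trailing_edge(planform: WingPlanform, clip_curve: np.ndarray) -> WingPlanform:
    """Remove the trailing-side region bounded by ``clip_curve``.

    The curve must cross the outline exactly twice, partitioning it into a
    kept (leading) and a removed (trailing) region.  The span is preserved;
    area and mean chord are recomputed.  A curve that never enters the
    outline (e.g. coincident with the trailing edge) returns the planform
    unchanged.
    """
    curve = np.asarray(clip_curve, dtype=float)
    if curve.ndim != 2 or curve.shape[1] != 2 or curve.shape[0] < 2:
        raise ClippingError("clip_curve must be an (n>=2, 2) polyline")
    poly = planform.polygon
    line = LineString(curve)

    inside = line.intersection(poly)
    if inside.is_empty or inside.length < 1e-12:
        return planform  # degenerate clip: nothing removed

    crossings = line.intersection(poly.exterior)
    n_cross = len(getattr(crossings, "geoms", [crossings])) if not crossings.is_empty else 0
    if n_cross != 2:
        raise ClippingError(
            f"clip curve must intersect the outline exactly twice (got {n_cross})"
        )

    pieces = shapely_split(poly, line)
    if len(pieces.geoms) != 2:
        raise ClippingError("clip curve does not partition the outline into two regions")

    # the kept piece contains the leading-edge reference point
    le_idx = int(np.argmin(planform.outline[:, 0]))
    le_ref = Point(planform.outline[le_idx])
    kept = None
    removed = None
    for g in pieces.geoms:
        if g.buffer(1e-9).contains(le_ref):
            kept = g
        else:
            removed = g
    if kept is None or removed is None:
        raise ClippingError("could not identify the kept (leading) region")
    if removed.bounds[0] < kept.bounds[0] - 1e-9:
        raise ClippingError("removed region extends onto the leading side")

    kept_y = kept.bounds[3] - kept.bounds[1]
    if abs(kept_y - planform.span) > 0.02 * planform.span:
        raise ClippingError("clip would change the wing span")

    outline = np.asarray(kept.exterior.coords[:-1], dtype=float)
    return WingPlanform(outline=outline, span=planform.span, area=kept.area)


# ---------------------------------------------------------------------------
# surface meshes
# ---------------------------------------------------------------------------

@dataclass
class SurfaceMesh:
    """Triangulated surface (3-D) or closed polyline (2-D section).

    ``faces`` holds triangle vertex indices for 3-D meshes and segment
    indices for 2-D polylines.  ``role`` tags the part; ``landmarks`` maps
    names to points.
    """

    vertices: np.ndarray
    faces: np.ndarray
    role: str = "body"
    landmarks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.face_areas().min() <= 0:
            raise GeometryError(f"{self.role}: mesh contains degenerate faces")

    @property
    def is_polyline(self) -> bool:
        return self.faces.shape[1] == 2

    def face_areas(self) -> np.ndarray:
        v = self.vertices
        if self.faces.shape[1] == 2:
            return np.linalg.norm(v[self.faces[:, 1]] - v[self.faces[:, 0]], axis=1)
        a = v[self.faces[:, 1]] - v[self.faces[:, 0]]
        b = v[self.faces[:, 2]] - v[self.faces[:, 0]]
        return 0.5 * np.linalg.norm(np.cross(a, b), axis=1)

    @property
    def area(self) -> float:
        return float(self.face_areas().sum())

    def is_closed(self) -> bool:
        """Watertightness: every edge shared by exactly two faces."""
        if self.is_polyline:
            edges = self.faces
            counts: dict[int, int] = {}
            for e in edges.ravel():
                counts[e] = counts.get(e, 0) + 1
            return all(c == 2 for c in counts.values())
        edges = np.sort(
            np.concatenate([self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]),
            axis=1,
        )
        _, cnt = np.unique(edges, axis=0, return_counts=True)
        return bool(np.all(cnt == 2))

    def mirrored(self, axis: int = 1) -> "SurfaceMesh":
        v = self.vertices.copy()
        v[:, axis] *= -1.0
        faces = self.faces[:, ::-1].copy()  # keep outward orientation
        lm = {k: p * np.where(np.arange(p.size) == axis, -1.0, 1.0) for k, p in self.landmarks.items()}
        return SurfaceMesh(vertices=v, faces=faces, role=self.role, landmarks=lm)


def ellipsoid_area_thomsen(a: float, b: float, c: float, p: float = 1.6075) -> float:
    """Thomsen's approximate surface area of an ellipsoid (error < 1.06%)."""
    t = ((a * b) ** p + (a * c) ** p + (b * c) ** p) / 3.0
    return 4.0 * np.pi * t ** (1.0 / p)


def _ellipsoid_mesh(axes: tuple[float, float, float], n_lat: int, n_lon: int) -> SurfaceMesh:
    """Watertight lat-long triangulation of an axis-aligned ellipsoid."""
    a, b, c = axes
    lats = np.linspace(0.0, np.pi, n_lat + 1)[1:-1]
    lons = np.linspace(0.0, 2 * np.pi, n_lon, endpoint=False)
    th, ph = np.meshgrid(lats, lons, indexing="ij")
    ring = np.column_stack(
        [
            a * np.cos(th).ravel(),
            b * np.sin(th).ravel() * np.cos(ph).ravel(),
            c * np.sin(th).ravel() * np.sin(ph).ravel(),
        ]
    )
    # poles along +-x: the body axis
    verts = np.vstack([[a, 0, 0], [-a, 0, 0], ring])
    idx = lambda i, j: 2 + i * n_lon + (j % n_lon)  # noqa: E731
    faces = []
    for j in range(n_lon):  # pole caps
        faces.append([0, idx(0, j), idx(0, j + 1)])
        faces.append([1, idx(n_lat - 2, j + 1), idx(n_lat - 2, j)])
    for i in range(n_lat - 2):
        for j in range(n_lon):
            faces.append([idx(i, j), idx(i + 1, j), idx(i + 1, j + 1)])
            faces.append([idx(i, j), idx(i + 1, j + 1), idx(i, j + 1)])
    return SurfaceMesh(vertices=verts, faces=np.asarray(faces), role="body")


def _triangulate_planform(planform: WingPlanform, h: float) -> SurfaceMesh:
    """Constrained-free Delaunay fill of the planform polygon with target
    edge length ``h``; triangles with centroids outside the outline are
    dropped."""
    poly = planform.polygon
    boundary = poly.exterior
    n_b = max(16, int(np.ceil(boundary.length / h)))
    bp = np.array(
        [boundary.interpolate(t, normalized=True).coords[0] for t in np.arange(n_b) / n_b]
    )
    xmin, ymin, xmax, ymax = poly.bounds
    xs = np.arange(xmin + 0.5 * h, xmax, h)
    ys = np.arange(ymin + 0.5 * h, ymax, h)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    interior = np.column_stack([gx.ravel(), gy.ravel()])
    inner = poly.buffer(-0.4 * h)
    if not inner.is_empty:
        keep = shapely.contains_xy(inner, interior[:, 0], interior[:, 1])
        interior = interior[keep]
    else:
        interior = interior[:0]
    pts = np.vstack([bp, interior])
    tri = Delaunay(pts)
    cen = pts[tri.simplices].mean(axis=1)
    inside = shapely.contains_xy(poly, cen[:, 0], cen[:, 1])
    faces = tri.simplices[inside]
    used = np.unique(faces)
    remap = -np.ones(pts.shape[0], dtype=np.int64)
    remap[used] = np.arange(used.size)
    verts3 = np.column_stack([pts[used], np.zeros(used.size)])
    return SurfaceMesh(vertices=verts3, faces=remap[faces], role="wing_left")


@dataclass
class FlyGeometry:
    """Assembled model: closed body plus two open thin wings, with landmarks."""

    body: SurfaceMesh
    wing_left: SurfaceMesh
    wing_right: SurfaceMesh
    landmarks: dict[str, np.ndarray]

    def parts(self) -> dict[str, SurfaceMesh]:
        return {"body": self.body, "wing_left": self.wing_left, "wing_right": self.wing_right}


def make_fly_geometry(
    planform: WingPlanform | None = None,
    body_axes: tuple[float, float, float] = (1.25, 0.45, 0.45),
    body_incline: float = 45.0,
    resolution: int = 16,
    hinge: tuple[float, float, float] = (0.0, 0.45, 0.35),
) -> FlyGeometry:
    """Build body + two mirrored wings.

    Parameters
    ----------
    planform
        Wing outline (defaults to the fly-scale planform).  Units mm.
    body_axes
        Ellipsoid semi-axes (mm), body axis along x before inclining.
    body_incline
        Pitch of the body axis above horizontal, degrees (head up, facing -x).
    resolution
        Target elements across the mean chord; must be >= 8.
    hinge
        Left wing-root position relative to the body center (mm), at the
        dorsal shoulder by default.
    """
    if planform is None:
        planform = default_planform()
    if resolution < 8:
        raise GeometryError("resolution too coarse to resolve the outline (need >= 8 per chord)")

    h = planform.mean_chord / resolution
    wing_left = _triangulate_planform(planform, h)
    wing_left.vertices = wing_left.vertices + np.asarray(hinge)
    wing_left.landmarks["hinge"] = np.asarray(hinge, dtype=float)
    wing_right = wing_left.mirrored(axis=1)
    wing_right.role = "wing_right"

    n_lat = max(12, 2 * resolution)
    body = _ellipsoid_mesh(body_axes, n_lat=n_lat, n_lon=2 * n_lat)
    chi = np.deg2rad(body_incline)
    # pitch about +y: head (-x pole) rises
    rot = np.array(
        [[np.cos(chi), 0, -np.sin(chi)], [0, 1, 0], [np.sin(chi), 0, np.cos(chi)]]
    )
    body.vertices = body.vertices @ rot.T
    a = body_axes[0]
    head = rot @ np.array([-a, 0.0, 0.0])
    tail = rot @ np.array([a, 0.0, 0.0])
    landmarks = {
        "antenna": head,  # anterior apex of the head, sagittal plane
        "head": head,
        "tail": tail,
        "hinge_left": np.asarray(hinge, dtype=float),
        "hinge_right": np.asarray(hinge, dtype=float) * np.array([1, -1, 1]),
    }
    body.landmarks.update({k: v for k, v in landmarks.items() if k in ("antenna", "head", "tail")})
    return FlyGeometry(body=body, wing_left=wing_left, wing_right=wing_right, landmarks=landmarks)


# ---------------------------------------------------------------------------
# 2-D sagittal analogs
# ---------------------------------------------------------------------------

def sagittal_body_section(
    axes: tuple[float, float] = (1.25, 0.45),
    incline: float = 45.0,
    center: tuple[float, float] = (0.0, 0.0),
    n: int = 96,
) -> np.ndarray:
    """Closed polyline of the inclined body ellipse on the sagittal plane.

    ``axes`` are the (along-body, transverse) semi-axes; ``incline`` pitches
    the body axis above horizontal with the head toward -x.  Returned as an
    (n, 2) counter-clockwise polygon.
    """
    t = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    pts = np.column_stack([axes[0] * np.cos(t), axes[1] * np.sin(t)])
    chi = np.deg2rad(incline)
    rot = np.array([[np.cos(chi), np.sin(chi)], [-np.sin(chi), np.cos(chi)]])
    return pts @ rot.T + np.asarray(center)
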