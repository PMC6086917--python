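"""Nonuniform Cartesian grids: a uniform refined box with geometrically
stretched outer regions.

All lengths are in units of the wingspan ``R``.  A grid is a tensor product
of 1-D axes; each axis stores cell *faces* (length ``n+1``), from which cell
centers and widths follow.  Inside the refined box the spacing is uniform to
machine precision; outside, cell widths grow geometrically with a ratio
bounded by ``stretch_ratio`` (default cap 1.2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = ["GridError", "Axis", "CartesianGrid", "build_grid"]

MAX_STRETCH_RATIO = 1.2


class GridError(ValueError):
    """Raised when a grid cannot be built within the stretching constraints."""


def _stretched_widths(total: float, first: float, ratio_cap: float) -> np.ndarray:
    """Cell widths of a geometric progression covering ``total``.

    The first stretched cell has width ``first * r`` for the solved ratio
    ``r <= ratio_cap`` so the junction with the uniform region also obeys the
    cap.  Falls back to uniform cells when the region is short.
    """
    if total <= 0:
        return np.empty(0)
    if total <= first * (1 + 1e-12):
        return np.asarray([total])

    def span(r: float, n: int) -> float:
        if r <= 1 + 1e-14:
            return first * n
        return first * r * (r**n - 1.0) / (r - 1.0)

    n = 1
    while span(ratio_cap, n) < total:
        n += 1
        if n > 1_000_000:  # pragma: no cover - absurd inputs
            raise GridError(
                "stretched region requires too many cells; "
                "increase delta or shrink the domain"
            )
    if span(1.0, n) >= total:
        # even ratio 1 with n cells overshoots: use uniform cells
        m = max(1, int(np.ceil(total / first)))
        return np.full(m, total / m)
    r = brentq(lambda rr: span(rr, n) - total, 1 + 1e-12, ratio_cap)
    return first * r ** np.arange(1, n + 1)


def _build_axis_faces(
    lo: float,
    hi: float,
    box_lo: float,
    box_hi: float,
    delta: float,
    ratio_cap: float,
) -> np.ndarray:
    if not (lo <= box_lo < box_hi <= hi):
        raise GridError(f"refined box [{box_lo},{box_hi}] not inside domain [{lo},{hi}]")
    n_box = max(1, int(round((box_hi - box_lo) / delta)))
    d_eff = (box_hi - box_lo) / n_box
    left = _stretched_widths(box_lo - lo, d_eff, ratio_cap)[::-1]
    right = _stretched_widths(hi - box_hi, d_eff, ratio_cap)
    widths = np.concatenate([left, np.full(n_box, d_eff), right])
    faces = lo + np.concatenate([[0.0], np.cumsum(widths)])
    faces[-1] = hi
    return faces


@dataclass(frozen=True)
class Axis:
    """One coordinate direction of a tensor-product grid."""

    faces: np.ndarray
    periodic: bool = False

    def __post_init__(self) -> None:
        f = np.asarray(self.faces, dtype=float)
        if f.ndim != 1 or f.size < 2:
            raise GridError("axis needs at least two faces")
        if not np.all(np.diff(f) > 0):
            raise GridError("axis faces must be strictly increasing")
        object.__setattr__(self, "faces", f)

    @property
    def n(self) -> int:
        return self.faces.size - 1

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.faces[:-1] + self.faces[1:])

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self.faces)

    @property
    def length(self) -> float:
        return float(self.faces[-1] - self.faces[0])

    def max_adjacent_ratio(self) -> float:
        w = self.widths
        if w.size < 2:
            return 1.0
        r = w[1:] / w[:-1]
        return float(np.max(np.maximum(r, 1.0 / r)))


@dataclass(frozen=True)
class CartesianGrid:
    """Tensor-product Cartesian grid (2-D or 3-D), lengths in units of R."""

    axes: tuple[Axis, ...]
    box: tuple[tuple[float, float], ...] | None = None
    delta: float | None = None
    _meta: dict = field(default_factory=dict, compare=False, repr=False)

    def __post_init__(self) -> None:
        if len(self.axes) not in (1, 2, 3):
            raise GridError("grid must be 1-, 2- or 3-dimensional")

    @property
    def ndim(self) -> int:
        return len(self.axes)

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(ax.n for ax in self.axes)

    @property
    def num_cells(self) -> int:
        return int(np.prod(self.shape))

    @property
    def num_points(self) -> int:
        """Grid-point (face-node) count, the convention used for grid sizes."""
        return int(np.prod([ax.n + 1 for ax in self.axes]))

    @property
    def centers(self) -> tuple[np.ndarray, ...]:
        return tuple(ax.centers for ax in self.axes)

    @property
    def periodic(self) -> tuple[bool, ...]:
        return tuple(ax.periodic for ax in self.axes)

    @property
    def extent(self) -> tuple[tuple[float, float], ...]:
        return tuple((float(ax.faces[0]), float(ax.faces[-1])) for ax in self.axes)

    def min_width(self) -> float:
        return min(float(ax.widths.min()) for ax in self.axes)

    def center_mesh(self) -> list[np.ndarray]:
        return list(np.meshgrid(*self.centers, indexing="ij"))

    def cell_volumes(self) -> np.ndarray:
        vols = self.axes[0].widths
        for ax in self.axes[1:]:
            vols = np.multiply.outer(vols, ax.widths)
        return vols


def uniform_grid(
    extents: tuple[tuple[float, float], ...],
    shape: tuple[int, ...],
    periodic: tuple[bool, ...] | bool = False,
) -> CartesianGrid:
    """Uniform grid helper (used for verification problems)."""
    if isinstance(periodic, bool):
        periodic = (periodic,) * len(shape)
    axes = tuple(
        Axis(np.linspace(lo, hi, n + 1), periodic=p)
        for (lo, hi), n, p in zip(extents, shape, periodic)
    )
    d = axes[0].widths[0]
    return CartesianGrid(axes=axes, box=tuple(extents), delta=float(d))


def build_grid(
    domain: tuple[tuple[float, float], ...],
    box: tuple[tuple[float, float], ...],
    delta: float,
    stretch_ratio: float = 1.12,
    dim: int | None = None,
) -> CartesianGrid:
    """Build a refined-box grid.

    Parameters
    ----------
    domain, box
        Per-axis ``(lo, hi)`` extents in units of R; the box must lie inside
        the domain.
    delta
        Uniform spacing inside the refined box, units of R.
    stretch_ratio
        Geometric growth ratio of cell widths outside the box; capped at 1.2.
    dim
        Optional dimensionality check against ``len(domain)``.
    """
    if delta <= 0:
        raise GridError("delta must be positive")
    if dim is not None and dim != len(domain):
        raise GridError(f"dim={dim} but domain has {len(domain)} axes")
    if len(domain) != len(box):
        raise GridError("domain and box must have the same number of axes")
    if stretch_ratio <= 1.0:
        raise GridError("stretch_ratio must exceed 1")
    if stretch_ratio > MAX_STRETCH_RATIO:
        raise GridError(f"stretch_ratio capped at {MAX_STRETCH_RATIO}")
    axes = tuple(
        Axis(_build_axis_faces(lo, hi, blo, bhi, delta, stretch_ratio))
        for (lo, hi), (blo, bhi) in zip(domain, box)
    )
    return CartesianGrid(axes=axes, box=tuple(box), delta=float(delta))
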