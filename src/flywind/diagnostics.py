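"""Vortex diagnostics: Q-criterion, vorticity, and patch circulation.

All derivatives use second-order central differences on the (possibly
nonuniform) grid coordinates via :func:`numpy.gradient`.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage

from .grid import CartesianGrid
from .solver import FlowState

__all__ = [
    "velocity_gradient",
    "q_criterion",
    "vorticity",
    "circulation",
    "circulation_loop",
]


def velocity_gradient(state: FlowState, grid: CartesianGrid) -> np.ndarray:
    """G[i, j, ...] = du_i/dx_j at cell centers."""
    nd = grid.ndim
    G = np.empty((nd, nd) + grid.shape)
    for i in range(nd):
        grads = np.gradient(state.u[i], *grid.centers, edge_order=2)
        if nd == 1:
            grads = [grads]
        for j in range(nd):
            G[i, j] = grads[j]
    return G


def q_criterion(state: FlowState, grid: CartesianGrid) -> np.ndarray:
    """Q = 0.5 (|Omega|^2 - |S|^2): positive where rotation beats strain."""
    G = velocity_gradient(state, grid)
    S = 0.5 * (G + np.swapaxes(G, 0, 1))
    Om = 0.5 * (G - np.swapaxes(G, 0, 1))
    return 0.5 * (np.sum(Om * Om, axis=(0, 1)) - np.sum(S * S, axis=(0, 1)))


def vorticity(state: FlowState, grid: CartesianGrid) -> np.ndarray:
    """Out-of-plane vorticity (2-D scalar) or the 3-vector field (3-D)."""
    G = velocity_gradient(state, grid)
    if grid.ndim == 2:
        return G[1, 0] - G[0, 1]
    return np.stack([G[2, 1] - G[1, 2], G[0, 2] - G[2, 0], G[1, 0] - G[0, 1]])


def circulation(
    omega: np.ndarray,
    coords: tuple[np.ndarray, np.ndarray],
    seed: tuple[float, float] | None = None,
    sign: int = 0,
    threshold_frac: float = 0.1,
    region: np.ndarray | None = None,
) -> float:
    """Circulation of a vortex patch on a 2-D slice.

    The patch is either given explicitly (``region`` boolean mask) or
    selected automatically: cells where ``|omega| >= threshold_frac * max``
    with vorticity sign matching ``sign`` (or the sign at the ``seed``
    point), restricted to the connected component containing/nearest the
    seed.  Gamma is the area integral of ``omega`` over the patch; an empty
    patch returns 0 with a warning.
    """
    xs, ys = coords
    wx = np.gradient(xs)
    wy = np.gradient(ys)
    dA = np.multiply.outer(wx, wy)
    if region is None:
        if seed is not None:
            i = int(np.argmin(np.abs(xs - seed[0])))
            j = int(np.argmin(np.abs(ys - seed[1])))
            if sign == 0:
                sign = int(np.sign(omega[i, j])) or 1
        elif sign == 0:
            sign = 1
        mag = omega * sign
        peak = mag.max()
        if peak <= 0:
            warnings.warn("no vorticity of the requested sign: circulation 0")
            return 0.0
        mask = mag >= threshold_frac * peak
        labels, n = ndimage.label(mask)
        if n == 0:
            warnings.warn("empty vortex patch: circulation 0")
            return 0.0
        if seed is not None:
            lab = labels[i, j]
            if lab == 0:
                # nearest labelled cell to the seed
                idx = np.argwhere(labels > 0)
                pos = np.array([xs[idx[:, 0]], ys[idx[:, 1]]]).T
                k = np.argmin(np.sum((pos - np.asarray(seed)) ** 2, axis=1))
                lab = labels[tuple(idx[k])]
            region = labels == lab
        else:
            # strongest component
            sums = ndimage.sum_labels(np.abs(omega), labels, index=np.arange(1, n + 1))
            region = labels == (1 + int(np.argmax(sums)))
    if not region.any():
        warnings.warn("empty vortex patch: circulation 0")
        return 0.0
    return float(np.sum(omega[region] * dA[region]))


def circulation_loop(
    state: FlowState,
    grid: CartesianGrid,
    rect: tuple[tuple[float, float], tuple[float, float]],
    n_per_side: int = 200,
) -> float:
    """Line integral of velocity around an axis-aligned rectangle
    (counter-clockwise); Stokes-theorem counterpart of :func:`circulation`."""
    from scipy.interpolate import RegularGridInterpolator

    (x0, x1), (y0, y1) = rect
    ui = [
        RegularGridInterpolator(grid.centers, c, bounds_error=False, fill_value=None)
        for c in state.u[:2]
    ]
    gamma = 0.0
    segs = [
        (np.linspace(x0, x1, n_per_side), np.full(n_per_side, y0), 0, +1),
        (np.full(n_per_side, x1), np.linspace(y0, y1, n_per_side), 1, +1),
        (np.linspace(x1, x0, n_per_side), np.full(n_per_side, y1), 0, -1),
        (np.full(n_per_side, x0), np.linspace(y1, y0, n_per_side), 1, -1),
    ]
    for xs, ys, comp, _sgn in segs:
        pts = np.column_stack([xs, ys])
        v = ui[comp](pts)
        ds = np.diff(xs) if comp == 0 else np.diff(ys)
        gamma += float(np.sum(0.5 * (v[1:] + v[:-1]) * ds))
    return gamma
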