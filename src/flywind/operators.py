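"""Finite-volume operators on tensor-product Cartesian grids.

Cell-centered scalar fields have shape ``grid.shape``; face-normal vector
components along axis ``i`` have one extra entry along that axis.  All
operators are second-order on smoothly stretched grids and annihilate
constants exactly.

Boundary-condition tags per axis end: ``dirichlet`` (value supplied via the
RHS helper), ``neumann`` (zero gradient), ``periodic``.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from .grid import CartesianGrid

__all__ = [
    "face_interp",
    "face_gradient",
    "divergence",
    "center_gradient",
    "laplacian",
    "dirichlet_rhs_coeff",
]


def _sl(ndim: int, axis: int, s) -> tuple:
    idx: list = [slice(None)] * ndim
    idx[axis] = s
    return tuple(idx)


def _shape1(arr: np.ndarray, ndim: int, axis: int) -> np.ndarray:
    """Reshape a 1-D per-axis array for broadcasting along ``axis``."""
    shape = [1] * ndim
    shape[axis] = arr.size
    return arr.reshape(shape)


def face_interp(u: np.ndarray, grid: CartesianGrid, axis: int) -> np.ndarray:
    """Linearly interpolate a cell-centered field to the faces of ``axis``.

    Boundary faces are copied from the adjacent cell for non-periodic axes
    (callers override them when applying boundary conditions).
    """
    ax = grid.axes[axis]
    nd = grid.ndim
    xc, xf = ax.centers, ax.faces
    w = (xf[1:-1] - xc[:-1]) / (xc[1:] - xc[:-1])  # weight of the right cell
    w = _shape1(w, nd, axis)
    shape = list(u.shape)
    shape[axis] += 1
    out = np.empty(shape, dtype=u.dtype)
    uL = u[_sl(nd, axis, slice(None, -1))]
    uR = u[_sl(nd, axis, slice(1, None))]
    out[_sl(nd, axis, slice(1, -1))] = (1.0 - w) * uL + w * uR
    if ax.periodic:
        half = 0.5  # periodic axes are uniform
        wrap = half * (u[_sl(nd, axis, 0)] + u[_sl(nd, axis, -1)])
        out[_sl(nd, axis, 0)] = wrap
        out[_sl(nd, axis, -1)] = wrap
    else:
        out[_sl(nd, axis, 0)] = u[_sl(nd, axis, 0)]
        out[_sl(nd, axis, -1)] = u[_sl(nd, axis, -1)]
    return out


def face_gradient(phi: np.ndarray, grid: CartesianGrid, axis: int) -> np.ndarray:
    """d(phi)/dx at the faces of ``axis``; boundary faces get zero gradient
    (homogeneous Neumann) unless the axis is periodic."""
    ax = grid.axes[axis]
    nd = grid.ndim
    xc = ax.centers
    d = _shape1(np.diff(xc), nd, axis)
    shape = list(phi.shape)
    shape[axis] += 1
    out = np.zeros(shape, dtype=phi.dtype)
    out[_sl(nd, axis, slice(1, -1))] = (
        phi[_sl(nd, axis, slice(1, None))] - phi[_sl(nd, axis, slice(None, -1))]
    ) / d
    if ax.periodic:
        h = ax.widths[0]
        g = (phi[_sl(nd, axis, 0)] - phi[_sl(nd, axis, -1)]) / h
        out[_sl(nd, axis, 0)] = g
        out[_sl(nd, axis, -1)] = g
    return out


def divergence(faces: list[np.ndarray], grid: CartesianGrid) -> np.ndarray:
    """Divergence of face-normal velocities (one array per axis)."""
    nd = grid.ndim
    out = np.zeros(grid.shape)
    for axis, F in enumerate(faces):
        w = _shape1(grid.axes[axis].widths, nd, axis)
        out += (F[_sl(nd, axis, slice(1, None))] - F[_sl(nd, axis, slice(None, -1))]) / w
    return out


def center_gradient(phi: np.ndarray, grid: CartesianGrid, axis: int) -> np.ndarray:
    """Cell-centered gradient: average of the two adjacent face gradients."""
    nd = grid.ndim
    g = face_gradient(phi, grid, axis)
    return 0.5 * (g[_sl(nd, axis, slice(None, -1))] + g[_sl(nd, axis, slice(1, None))])


def _laplacian_1d(
    ax, bc_lo: str, bc_hi: str
) -> tuple[sp.csr_matrix, np.ndarray, np.ndarray]:
    """1-D FV Laplacian plus Dirichlet RHS coefficient vectors per end.

    Returns ``(L, c_lo, c_hi)`` where a Dirichlet value ``g`` at an end
    contributes ``g * c`` to the RHS of ``L u = rhs``.
    """
    n = ax.n
    xc, xf, w = ax.centers, ax.faces, ax.widths
    L = sp.lil_matrix((n, n))
    c_lo = np.zeros(n)
    c_hi = np.zeros(n)
    d = np.diff(xc)
    for j in range(n):
        # face j (low side)
        if j > 0:
            L[j, j - 1] += 1.0 / (d[j - 1] * w[j])
            L[j, j] -= 1.0 / (d[j - 1] * w[j])
        else:
            if bc_lo == "dirichlet":
                h = xc[0] - xf[0]
                L[j, j] -= 1.0 / (h * w[j])
                c_lo[j] = 1.0 / (h * w[j])
            elif bc_lo == "periodic":
                h = 0.5 * (w[0] + w[-1])
                L[j, n - 1] += 1.0 / (h * w[j])
                L[j, j] -= 1.0 / (h * w[j])
            # neumann: zero flux
        # face j+1 (high side)
        if j < n - 1:
            L[j, j + 1] += 1.0 / (d[j] * w[j])
            L[j, j] -= 1.0 / (d[j] * w[j])
        else:
            if bc_hi == "dirichlet":
                h = xf[-1] - xc[-1]
                L[j, j] -= 1.0 / (h * w[j])
                c_hi[j] = 1.0 / (h * w[j])
            elif bc_hi == "periodic":
                h = 0.5 * (w[0] + w[-1])
                L[j, 0] += 1.0 / (h * w[j])
                L[j, j] -= 1.0 / (h * w[j])
    return L.tocsr(), c_lo, c_hi


def laplacian(
    grid: CartesianGrid, bcs: tuple[tuple[str, str], ...]
) -> tuple[sp.csr_matrix, list[tuple[np.ndarray, np.ndarray]]]:
    """Assemble the full Laplacian with per-axis-end boundary tags.

    Returns the sparse operator on row-major-flattened fields and, per axis,
    the pair of Dirichlet RHS coefficient vectors (zero for other BC types).
    """
    mats = []
    coeffs = []
    for ax, (lo, hi) in zip(grid.axes, bcs):
        tags = ("periodic", "periodic") if ax.periodic else (lo, hi)
        L1, c_lo, c_hi = _laplacian_1d(ax, *tags)
        mats.append(L1)
        coeffs.append((c_lo, c_hi))
    eyes = [sp.identity(ax.n, format="csr") for ax in grid.axes]
    full = None
    for i, Li in enumerate(mats):
        term = None
        for j, I in enumerate(eyes):
            m = Li if j == i else I
            term = m if term is None else sp.kron(term, m, format="csr")
        full = term if full is None else full + term
    return full.tocsr(), coeffs


def dirichlet_rhs_coeff(
    grid: CartesianGrid,
    coeffs: list[tuple[np.ndarray, np.ndarray]],
    axis: int,
    side: int,
) -> np.ndarray:
    """Full-shape RHS coefficient array for a Dirichlet value at one end."""
    nd = grid.ndim
    c = coeffs[axis][side]
    out = np.zeros(grid.shape)
    out += _shape1(c, nd, axis)
    return out
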