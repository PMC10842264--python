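"""Separable integrated-Gaussian gridding of atoms onto a voxel lattice.

Each atom deposits the product of per-axis integrated Gaussians: the weight
given to voxel u along one axis is the Gaussian probability mass in the
interval [u-1/2, u+1/2) voxels around the atom's fractional position.  The
kernel is truncated at a finite window and each axis is renormalized to unit
sum, so every atom whose window lies inside the grid contributes exactly its
weight (divided by the voxel volume, since grids store density).  Atoms whose
window is clipped by the grid edge lose the clipped mass, as a physical
density would.

A numba-compiled kernel does the scatter; a pure-numpy equivalent is kept as
a fallback and as a cross-check in the tests.
"""

from __future__ import annotations

import math

import numpy as np

try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(f):
            return f

        return deco(args[0]) if args and callable(args[0]) else deco


@njit(cache=True)
def _scatter(values, pos_vox, weights, sigma_vox, radius):
    nx, ny, nz = values.shape
    width = 2 * radius + 1
    wx = np.empty(width)
    wy = np.empty(width)
    wz = np.empty(width)
    inv = 1.0 / (math.sqrt(2.0) * sigma_vox)
    for a in range(pos_vox.shape[0]):
        cx, cy, cz = pos_vox[a, 0], pos_vox[a, 1], pos_vox[a, 2]
        ix = int(round(cx)) - radius
        iy = int(round(cy)) - radius
        iz = int(round(cz)) - radius
        sx = 0.0
        sy = 0.0
        sz = 0.0
        for m in range(width):
            wx[m] = 0.5 * (
                math.erf((ix + m + 0.5 - cx) * inv)
                - math.erf((ix + m - 0.5 - cx) * inv)
            )
            sx += wx[m]
            wy[m] = 0.5 * (
                math.erf((iy + m + 0.5 - cy) * inv)
                - math.erf((iy + m - 0.5 - cy) * inv)
            )
            sy += wy[m]
            wz[m] = 0.5 * (
                math.erf((iz + m + 0.5 - cz) * inv)
                - math.erf((iz + m - 0.5 - cz) * inv)
            )
            sz += wz[m]
        w = weights[a] / (sx * sy * sz)
        for m in range(width):
            i = ix + m
            if i < 0 or i >= nx:
                continue
            wxm = wx[m] * w
            for n in range(width):
                j = iy + n
                if j < 0 or j >= ny:
                    continue
                wxy = wxm * wy[n]
                for p in range(width):
                    k = iz + p
                    if k < 0 or k >= nz:
                        continue
                    values[i, j, k] += wxy * wz[p]


@njit(cache=True)
def scatter_rotated_batch(buf, matrices, centered, center, weights,
                          origin, voxel_size, sigma_vox, radius):
    """Grid a batch of rotated copies of one model into ``buf`` (float32).

    ``buf`` has shape (n_rotations, nx, ny, nz) and is assumed zeroed;
    rotation r of the batch deposits into ``buf[r]``.  Atom positions are
    ``matrices[r] @ centered[a] + center``; the kernel matches
    :func:`_scatter` (separable integrated Gaussian, renormalized window).
    """
    n_rot = matrices.shape[0]
    n_atoms = centered.shape[0]
    _, nx, ny, nz = buf.shape
    width = 2 * radius + 1
    wx = np.empty(width)
    wy = np.empty(width)
    wz = np.empty(width)
    inv = 1.0 / (math.sqrt(2.0) * sigma_vox)
    inv_h = 1.0 / voxel_size
    for r in range(n_rot):
        R = matrices[r]
        for a in range(n_atoms):
            x0, x1, x2 = centered[a, 0], centered[a, 1], centered[a, 2]
            cx = (R[0, 0] * x0 + R[0, 1] * x1 + R[0, 2] * x2
                  + center[0] - origin[0]) * inv_h
            cy = (R[1, 0] * x0 + R[1, 1] * x1 + R[1, 2] * x2
                  + center[1] - origin[1]) * inv_h
            cz = (R[2, 0] * x0 + R[2, 1] * x1 + R[2, 2] * x2
                  + center[2] - origin[2]) * inv_h
            ix = int(round(cx)) - radius
            iy = int(round(cy)) - radius
            iz = int(round(cz)) - radius
            sx = 0.0
            sy = 0.0
            sz = 0.0
            for m in range(width):
                wx[m] = 0.5 * (
                    math.erf((ix + m + 0.5 - cx) * inv)
                    - math.erf((ix + m - 0.5 - cx) * inv)
                )
                sx += wx[m]
                wy[m] = 0.5 * (
                    math.erf((iy + m + 0.5 - cy) * inv)
                    - math.erf((iy + m - 0.5 - cy) * inv)
                )
                sy += wy[m]
                wz[m] = 0.5 * (
                    math.erf((iz + m + 0.5 - cz) * inv)
                    - math.erf((iz + m - 0.5 - cz) * inv)
                )
                sz += wz[m]
            w = weights[a] / (sx * sy * sz)
            for m in range(width):
                i = ix + m
                if i < 0 or i >= nx:
                    continue
                wxm = wx[m] * w
                for n in range(width):
                    j = iy + n
                    if j < 0 or j >= ny:
                        continue
                    wxy = wxm * wy[n]
                    for p in range(width):
                        k = iz + p
                        if k < 0 or k >= nz:
                            continue
                        buf[r, i, j, k] += np.float32(wxy * wz[p])


def _scatter_numpy(values, pos_vox, weights, sigma_vox, radius):
    """Reference implementation of :func:`_scatter` without numba."""
    from scipy.special import erf

    nx, ny, nz = values.shape
    offsets = np.arange(-radius, radius + 1)
    inv = 1.0 / (math.sqrt(2.0) * sigma_vox)
    for a in range(pos_vox.shape[0]):
        center = np.round(pos_vox[a]).astype(np.int64)
        axis_w = []
        for d in range(3):
            edges = center[d] + np.concatenate(
                [offsets - 0.5, [offsets[-1] + 0.5]]
            )
            cdf = 0.5 * erf((edges - pos_vox[a, d]) * inv)
            w = np.diff(cdf)
            axis_w.append(w / w.sum())
        kernel = weights[a] * np.einsum(
            "i,j,k->ijk", axis_w[0], axis_w[1], axis_w[2]
        )
        idx = [center[d] + offsets for d in range(3)]
        keep = [(ix >= 0) & (ix < n) for ix, n in zip(idx, (nx, ny, nz))]
        values[np.ix_(idx[0][keep[0]], idx[1][keep[1]], idx[2][keep[2]])] += (
            kernel[np.ix_(keep[0], keep[1], keep[2])]
        )


def grid_atoms(values, positions, weights, origin, voxel_size, sigma,
               use_numba=_HAVE_NUMBA, truncation=4.0):
    """Accumulate atoms as integrated Gaussians into ``values`` (density).

    ``sigma`` is the real-space Gaussian standard deviation in Å.  The kernel
    window extends ``truncation`` sigma (at least one voxel) from each atom
    and is renormalized to unit mass within the window.  Values are density:
    the sum over voxels times voxel_size^3 equals the total weight of
    unclipped atoms.
    """
    pos_vox = (np.asarray(positions, dtype=np.float64) - origin) / voxel_size
    sigma_vox = sigma / voxel_size
    radius = max(1, int(math.ceil(truncation * sigma_vox)))
    w = np.asarray(weights, dtype=np.float64) / voxel_size**3
    if use_numba:
        _scatter(values, pos_vox, w, sigma_vox, radius)
    else:
        _scatter_numpy(values, pos_vox, w, sigma_vox, radius)
    return values
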