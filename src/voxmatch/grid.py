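"""Density volumes on regular grids and the map-conditioning utilities.

The central container is :class:`VoxelGrid`: a 3D scalar field sampled on a
regular isotropic lattice, with a physical voxel size in Å and an origin
giving the physical position of the *center* of voxel (0, 0, 0).  Values are
stored in a numpy array indexed ``values[ix, iy, iz]`` (x on the first axis),
so the physical coordinate of voxel (i, j, k) is
``origin + voxel_size * (i, j, k)``.

MRC2014/CCP4 files are read and written through gemmi.  On read, the axis
order is normalized to x-fastest regardless of the file's MAPC/MAPR/MAPS
permutation, and the header ORIGIN words (50-52) define the origin; the
NXSTART/NYSTART/NZSTART words are ignored.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path

import gemmi
import numpy as np
import scipy.fft as sfft


class MapFormatError(ValueError):
    """A density file violates the MRC2014/CCP4 contract (names the field)."""


@dataclasses.dataclass
class VoxelGrid:
    """A 3D scalar density on a regular grid.

    Parameters
    ----------
    values : numpy.ndarray
        Shape (nx, ny, nz), finite floats, x on the first axis.
    voxel_size : float
        Isotropic sampling in Å per voxel, > 0.
    origin : numpy.ndarray
        Physical position (Å) of the center of voxel (0, 0, 0).
    """

    values: np.ndarray
    voxel_size: float
    origin: np.ndarray = dataclasses.field(
        default_factory=lambda: np.zeros(3)
    )

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"values must be 3D, got ndim={self.values.ndim}")
        if min(self.values.shape) < 1:
            raise ValueError(f"all dims must be >= 1, got {self.values.shape}")
        if not np.isfinite(self.values).all():
            raise ValueError("grid values must all be finite")
        self.voxel_size = float(self.voxel_size)
        if not (self.voxel_size > 0):
            raise ValueError(f"voxel_size must be > 0, got {self.voxel_size}")
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3)
        if not np.isfinite(self.origin).all():
            raise ValueError("origin must be finite")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape

    def copy(self) -> "VoxelGrid":
        return VoxelGrid(self.values.copy(), self.voxel_size, self.origin.copy())

    def coordinate(self, index) -> np.ndarray:
        """Physical coordinate (Å) of the center of voxel ``index``."""
        return self.origin + self.voxel_size * np.asarray(index, dtype=float)


# ---------------------------------------------------------------------------
# MRC2014 I/O

def read_density(path) -> VoxelGrid:
    """Read an MRC2014/CCP4 volume into a :class:`VoxelGrid`.

    Requires float data (mode 2) and an isotropic voxel size (relative
    tolerance 1e-3 across axes).  Axis order is normalized to x-fastest.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        m = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError) as exc:
        raise MapFormatError(f"not a readable MRC2014/CCP4 map: {exc}") from exc
    mode = m.header_i32(4)
    if mode != 2:
        raise MapFormatError(
            f"unsupported MODE={mode} (header word 4); need float mode 2"
        )
    if m.grid.axis_order != gemmi.AxisOrder.XYZ:
        m.setup(float("nan"), gemmi.MapSetup.ReorderOnly)
    values = np.array(m.grid, copy=True)
    spacing = np.array(m.grid.spacing, dtype=float)
    if spacing.min() <= 0:
        raise MapFormatError(f"non-positive voxel spacing {spacing} (CELLA/M)")
    if (spacing.max() - spacing.min()) > 1e-3 * spacing.mean():
        raise MapFormatError(
            f"anisotropic voxel size {spacing} (CELLA vs MX/MY/MZ) beyond "
            "1e-3 relative tolerance"
        )
    origin = np.array([m.header_float(i) for i in (50, 51, 52)], dtype=float)
    if not np.isfinite(values).all():
        raise MapFormatError("map contains non-finite values (data block)")
    return VoxelGrid(values.astype(np.float64), float(spacing.mean()), origin)


def write_density(grid: VoxelGrid, path) -> None:
    """Write ``grid`` as an MRC2014 float (mode 2) volume.

    Cell dimensions are ``dims * voxel_size`` and the grid origin goes to the
    MRC ORIGIN header words, so ``read_density`` inverts this exactly for
    float32-representable values.  Refuses non-finite values.
    """
    if not np.isfinite(grid.values).all():
        raise ValueError("refusing to write non-finite values")
    g = gemmi.FloatGrid(np.ascontiguousarray(grid.values, dtype=np.float32))
    nx, ny, nz = grid.dims
    h = grid.voxel_size
    g.set_unit_cell(gemmi.UnitCell(nx * h, ny * h, nz * h, 90.0, 90.0, 90.0))
    m = gemmi.Ccp4Map()
    m.grid = g
    m.update_ccp4_header()
    for word, val in zip((50, 51, 52), grid.origin):
        m.set_header_float(word, float(val))
    m.write_ccp4_map(str(path))


# ---------------------------------------------------------------------------
# Map conditioning

def _freq_grid(dims, voxel_size, real=True):
    """|f| on the (r)fft grid, in 1/Å."""
    fx = sfft.fftfreq(dims[0], d=voxel_size)
    fy = sfft.fftfreq(dims[1], d=voxel_size)
    fz = (sfft.rfftfreq if real else sfft.fftfreq)(dims[2], d=voxel_size)
    return np.sqrt(
        fx[:, None, None] ** 2 + fy[None, :, None] ** 2 + fz[None, None, :] ** 2
    )


def lowpass_transfer(freq, resolution: float, shape: str = "gaussian"):
    """Filter amplitude at spatial frequency ``freq`` (1/Å).

    ``gaussian`` (default): exp(-ln2 * (freq*resolution)^2), i.e. amplitude
    falls to 1/2 exactly at freq = 1/resolution.  ``raised_cosine``:
    cos^2(pi*freq*resolution/4) for freq <= 2/resolution, zero beyond; also
    half-amplitude at 1/resolution.
    """
    freq = np.asarray(freq, dtype=float)
    x = freq * resolution
    if shape == "gaussian":
        return np.exp(-math.log(2.0) * x**2)
    if shape == "raised_cosine":
        return np.where(x < 2.0, np.cos(np.pi * x / 4.0) ** 2, 0.0)
    raise ValueError(f"unknown filter shape {shape!r}")


def lowpass_filter(grid: VoxelGrid, resolution: float,
                   shape: str = "gaussian") -> VoxelGrid:
    """Low-pass a map with half-amplitude at frequency 1/resolution.

    The DC component is unchanged.  ``resolution`` must be at least twice the
    voxel size (Nyquist).
    """
    if resolution < 2.0 * grid.voxel_size:
        raise ValueError(
            f"resolution {resolution} Å below Nyquist limit "
            f"{2.0 * grid.voxel_size} Å"
        )
    F = sfft.rfftn(grid.values)
    F *= lowpass_transfer(_freq_grid(grid.dims, grid.voxel_size), resolution,
                          shape)
    out = sfft.irfftn(F, s=grid.dims)
    return VoxelGrid(out, grid.voxel_size, grid.origin.copy())


def apply_cutoff(grid: VoxelGrid, cutoff: float) -> VoxelGrid:
    """Zero every voxel with value <= cutoff; values above are preserved."""
    out = np.where(grid.values > cutoff, grid.values, 0.0)
    return VoxelGrid(out, grid.voxel_size, grid.origin.copy())


def autocrop(grid: VoxelGrid, cutoff: float) -> VoxelGrid:
    """Crop to the minimal bounding box of voxels > cutoff.

    The origin is shifted so physical coordinates are preserved.  Raises if
    no voxel exceeds the cutoff.
    """
    mask = grid.values > cutoff
    if not mask.any():
        raise ValueError(f"no voxel above cutoff {cutoff}; nothing to keep")
    lo, hi = [], []
    for axis in range(3):
        proj = mask.any(axis=tuple(a for a in range(3) if a != axis))
        idx = np.nonzero(proj)[0]
        lo.append(int(idx[0]))
        hi.append(int(idx[-1]) + 1)
    values = grid.values[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]].copy()
    origin = grid.origin + grid.voxel_size * np.array(lo, dtype=float)
    return VoxelGrid(values, grid.voxel_size, origin)


EDGE_GUARD_EPS = 1e-3


def apply_edge_guard(grid: VoxelGrid, cutoff: float) -> VoxelGrid:
    """Pin the first and last voxel just above the cutoff.

    Automatic zero-margin cropping at the same cutoff then cannot shrink the
    box: ``autocrop(apply_edge_guard(g, c), c).dims == g.dims`` for every g.
    The guard value is ``cutoff * (1 + 1e-3)`` for positive cutoffs and
    ``cutoff + 1e-3 * (|cutoff| + 1)`` otherwise, so it is strictly greater
    than the cutoff for any sign.
    """
    if cutoff > 0:
        guard = cutoff * (1.0 + EDGE_GUARD_EPS)
    else:
        guard = cutoff + EDGE_GUARD_EPS * (abs(cutoff) + 1.0)
    out = grid.copy()
    out.values[0, 0, 0] = guard
    out.values[-1, -1, -1] = guard
    return out


# ---------------------------------------------------------------------------
# Fourier shell correlation

@dataclasses.dataclass
class FSCCurve:
    """Per-shell Fourier correlation between two maps.

    ``frequencies`` are shell-center spatial frequencies in 1/Å, strictly
    increasing from the DC shell; ``values`` are the real correlations in
    [-1, 1].  ``threshold`` is the resolution criterion (0.143 by default,
    the half-dataset convention).
    """

    frequencies: np.ndarray
    values: np.ndarray
    threshold: float = 0.143

    def __post_init__(self):
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.frequencies) != len(self.values):
            raise ValueError("frequencies and values length mismatch")
        if len(self.frequencies) > 1 and not np.all(
            np.diff(self.frequencies) > 0
        ):
            raise ValueError("frequencies must be strictly increasing")


def fsc(grid_a: VoxelGrid, grid_b: VoxelGrid) -> FSCCurve:
    """Fourier shell correlation between two commensurate maps.

    Per shell: Re(sum F_a conj(F_b)) / sqrt(sum |F_a|^2 * sum |F_b|^2), over
    concentric shells one Fourier voxel wide (shell k collects |f| nearest to
    k / (N * voxel_size) with N the largest box dimension), up to the Nyquist
    frequency of the grid.
    """
    if grid_a.dims != grid_b.dims:
        raise ValueError(
            f"shape mismatch: {grid_a.dims} vs {grid_b.dims}"
        )
    if abs(grid_a.voxel_size - grid_b.voxel_size) > 1e-6 * grid_a.voxel_size:
        raise ValueError("voxel size mismatch")
    h = grid_a.voxel_size
    Fa = sfft.fftn(grid_a.values)
    Fb = sfft.fftn(grid_b.values)
    freq = _freq_grid(grid_a.dims, h, real=False)
    dfreq = 1.0 / (max(grid_a.dims) * h)
    shell = np.rint(freq / dfreq).astype(np.int64)
    n_shell = int(math.floor((0.5 / h) / dfreq)) + 1
    keep = shell < n_shell
    shell = shell[keep]
    num = np.bincount(shell, (Fa * np.conj(Fb)).real[keep], minlength=n_shell)
    pa = np.bincount(shell, (Fa * np.conj(Fa)).real[keep], minlength=n_shell)
    pb = np.bincount(shell, (Fb * np.conj(Fb)).real[keep], minlength=n_shell)
    denom = np.sqrt(pa * pb)
    values = np.divide(num, denom, out=np.zeros_like(num),
                       where=denom > 0)
    frequencies = np.arange(n_shell) * dfreq
    return FSCCurve(frequencies, np.clip(values, -1.0, 1.0))


def resolution_at(curve: FSCCurve, threshold: float | None = None) -> float:
    """Resolution (Å) where the FSC first crosses the threshold.

    The crossing frequency is linearly interpolated between shells; if the
    curve never drops below the threshold, the last shell's resolution (the
    Nyquist limit of the measured band) is returned.
    """
    thr = curve.threshold if threshold is None else threshold
    c, f = curve.values, curve.frequencies
    for i in range(1, len(c)):
        if c[i] < thr <= c[i - 1]:
            frac = (c[i - 1] - thr) / (c[i - 1] - c[i])
            fc = f[i - 1] + frac * (f[i] - f[i - 1])
            return 1.0 / fc
    return 1.0 / f[-1]


def write_fsc(curve: FSCCurve, path) -> None:
    """Write an FSC curve as two-column TSV (frequency 1/Å, correlation)."""
    with open(path, "w") as fh:
        fh.write("# frequency_1_per_A\tfsc\n")
        for f, c in zip(curve.frequencies, curve.values):
            fh.write(f"{f:.8g}\t{c:.8g}\n")
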