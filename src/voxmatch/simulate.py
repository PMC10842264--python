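"""Simulate density maps from atomic models and corrupt maps with noise.

Each atom is blurred with an isotropic 3D Gaussian whose Fourier amplitude
falls to one half at spatial frequency 1/resolution — the same convention as
:func:`voxmatch.grid.lowpass_filter`, so simulated probes and low-passed
targets are directly comparable.  That fixes the real-space standard
deviation at

    sigma(resolution) = resolution * sqrt(ln 2 / 2) / pi  ~= 0.1874 * resolution.

Grids store density (weight per Å^3): the voxel sum times voxel_size^3
equals the total deposited weight.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from ._gridder import grid_atoms
from .grid import VoxelGrid
from .model import AtomicModel

SIGMA_PER_RESOLUTION = math.sqrt(math.log(2.0) / 2.0) / math.pi


def sigma_from_resolution(resolution: float) -> float:
    """Real-space Gaussian sigma (Å) for the half-amplitude convention."""
    return SIGMA_PER_RESOLUTION * resolution


@dataclasses.dataclass
class SimulationParams:
    """Model-to-map simulation settings.

    resolution : Å at which the atoms are blurred (>= 2 * voxel_size).
    voxel_size : Å per voxel of the output grid.
    padding : Å of empty margin around the model bounding box when no frame
        is given; defaults to 4 sigma + one voxel so atom kernels are whole.
    weight_mode : ``unit`` (1.0 per atom, times the model's own weights) or
        ``element-mass``.
    """

    resolution: float = 6.0
    voxel_size: float = 2.612
    padding: float | None = None
    weight_mode: str = "unit"

    def __post_init__(self):
        if self.resolution < 2.0 * self.voxel_size:
            raise ValueError(
                f"resolution {self.resolution} below Nyquist "
                f"{2.0 * self.voxel_size} for voxel {self.voxel_size}"
            )
        if self.padding is not None and self.padding < 0:
            raise ValueError("padding must be >= 0")
        if self.weight_mode not in ("unit", "element-mass"):
            raise ValueError(f"unknown weight_mode {self.weight_mode!r}")

    @property
    def sigma(self) -> float:
        return sigma_from_resolution(self.resolution)

    def effective_padding(self) -> float:
        if self.padding is not None:
            return self.padding
        return 4.0 * self.sigma + self.voxel_size


def _effective_weights(model: AtomicModel, params: SimulationParams):
    if params.weight_mode == "element-mass":
        return model.weights * model.element_masses()
    return model.weights


def simulate_map(model: AtomicModel, params: SimulationParams,
                 frame: VoxelGrid | None = None) -> VoxelGrid:
    """Render a model as a density map.

    With ``frame`` given, atoms are accumulated on an empty copy of the
    frame's lattice (same dims, voxel size and origin); the voxel sizes must
    match.  Otherwise a minimal padded grid around the model is built.
    Atom mass falling outside the frame is lost, as for a physical box.
    """
    h = params.voxel_size
    if frame is not None:
        if abs(frame.voxel_size - h) > 1e-6 * h:
            raise ValueError(
                f"frame voxel size {frame.voxel_size} != params {h}"
            )
        values = np.zeros(frame.dims)
        origin = frame.origin.copy()
    else:
        pad = params.effective_padding()
        lo = model.positions.min(axis=0) - pad
        hi = model.positions.max(axis=0) + pad
        dims = np.maximum(np.ceil((hi - lo) / h).astype(int) + 1, 1)
        values = np.zeros(tuple(dims))
        origin = lo
    grid_atoms(values, model.positions, _effective_weights(model, params),
               origin, h, params.sigma)
    return VoxelGrid(values, h, origin)


def add_noise(grid: VoxelGrid, sigma: float, seed: int) -> VoxelGrid:
    """Add i.i.d. zero-mean Gaussian noise; identical seed, identical map."""
    if sigma < 0:
        raise ValueError(f"noise sigma must be >= 0, got {sigma}")
    rng = np.random.default_rng(seed)
    noisy = grid.values + rng.normal(0.0, sigma, size=grid.dims)
    return VoxelGrid(noisy, grid.voxel_size, grid.origin.copy())
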