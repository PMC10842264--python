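"""Synthetic models, targets and planted-truth benchmark cases.

Everything here is a pure function of its arguments and seed, so complete
benchmark screens can be regenerated anywhere with no external data.  The
fixtures emulate the kind of density a segmented tomographic average
contains: helical bundles (the dominant fold of microtubule inner proteins)
and compact globular blobs, on boxes of ~50-150 voxels at 2.612 Å/voxel,
optionally repeated at the 16-nm axonemal period, with additive white
Gaussian noise.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path

import numpy as np

from .fitcore import FitParams, Pose
from .grid import VoxelGrid, apply_cutoff, write_density
from .model import AtomicModel, write_model
from .simulate import SimulationParams, add_noise, simulate_map

HELIX_RISE = 1.5  # Å per residue along the axis
HELIX_TWIST_DEG = 100.0  # degrees per residue
HELIX_RADIUS = 2.3  # Å, C-alpha distance from the helix axis
FILAMENT_PERIOD = 160.0  # Å; the 16-nm axonemal repeat


def _orthonormal_frame(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic pair of unit vectors completing ``axis`` to a frame."""
    a = np.asarray(axis, dtype=float)
    a = a / np.linalg.norm(a)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(a @ ref) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    u = np.cross(a, ref)
    u /= np.linalg.norm(u)
    v = np.cross(a, u)
    return u, v


def make_alpha_helix(n_res: int, start=(0.0, 0.0, 0.0),
                     axis=(0.0, 0.0, 1.0), phase: float = 0.0,
                     model_id: str = "helix") -> AtomicModel:
    """Ideal C-alpha trace of an alpha helix.

    Rise 1.5 Å/residue, twist 100 degrees/residue, helix radius 2.3 Å; the
    helix axis starts at ``start`` and runs along ``axis``.  ``phase`` (rad)
    rotates the first residue about the axis.
    """
    if n_res < 2:
        raise ValueError(f"a helix needs n_res >= 2, got {n_res}")
    a = np.asarray(axis, dtype=float)
    a = a / np.linalg.norm(a)
    u, v = _orthonormal_frame(a)
    i = np.arange(n_res)
    ang = phase + np.radians(HELIX_TWIST_DEG) * i
    pos = (
        np.asarray(start, dtype=float)
        + np.outer(HELIX_RISE * i, a)
        + HELIX_RADIUS * (np.outer(np.cos(ang), u) + np.outer(np.sin(ang), v))
    )
    return AtomicModel(model_id, ["C"] * n_res, pos)


def make_helix_bundle(n_helices: int, n_res: int, spacing: float,
                      seed: int, curvature: float = 0.0,
                      model_id: str | None = None) -> AtomicModel:
    """Antiparallel helix bundle on a regular polygon of axes.

    The polygon circumradius is chosen so nearest helix axes are ``spacing``
    Å apart.  Helix phases are drawn from the seed, so the same seed always
    yields the same coordinates.  ``curvature`` (Å^-1) adds a gentle
    quadratic bow along the bundle axis.  The bundle is centered on its
    centroid.
    """
    if n_helices < 1:
        raise ValueError(f"n_helices must be >= 1, got {n_helices}")
    if n_res < 2:
        raise ValueError(f"n_res must be >= 2, got {n_res}")
    if spacing <= 0:
        raise ValueError(f"spacing must be > 0, got {spacing}")
    rng = np.random.default_rng(seed)
    if n_helices == 1:
        circumradius = 0.0
    else:
        circumradius = spacing / (2.0 * math.sin(math.pi / n_helices))
    length = HELIX_RISE * (n_res - 1)
    parts = []
    for k in range(n_helices):
        ang = 2.0 * math.pi * k / n_helices
        foot = circumradius * np.array([math.cos(ang), math.sin(ang), 0.0])
        phase = float(rng.uniform(0.0, 2.0 * math.pi))
        if k % 2 == 0:
            h = make_alpha_helix(n_res, start=foot, axis=(0, 0, 1),
                                 phase=phase)
        else:  # antiparallel: run back down
            h = make_alpha_helix(n_res, start=foot + [0, 0, length],
                                 axis=(0, 0, -1), phase=phase)
        parts.append(h.positions)
    pos = np.vstack(parts)
    if curvature != 0.0:
        pos = pos.copy()
        pos[:, 0] += curvature * pos[:, 2] ** 2
    pos -= pos.mean(axis=0)
    mid = model_id or f"bundle{n_helices}x{n_res}_s{seed}"
    return AtomicModel(mid, ["C"] * pos.shape[0], pos)


def make_periodic_filament(unit: AtomicModel, n_copies: int,
                           period: float = FILAMENT_PERIOD) -> AtomicModel:
    """Translate ``n_copies`` of a unit along z at the given period (Å).

    The 160 Å default reproduces the 16-nm repeat of axonemal inner-protein
    features.
    """
    if n_copies < 1:
        raise ValueError(f"n_copies must be >= 1, got {n_copies}")
    if period <= 0:
        raise ValueError(f"period must be > 0, got {period}")
    parts = [
        unit.positions + np.array([0.0, 0.0, k * period])
        for k in range(n_copies)
    ]
    pos = np.vstack(parts)
    return AtomicModel(f"{unit.model_id}_x{n_copies}",
                       list(unit.elements) * n_copies, pos,
                       np.tile(unit.weights, n_copies))


def _make_blob(n_atoms: int, rng: np.random.Generator,
               model_id: str) -> AtomicModel:
    """Compact C-alpha random walk confined to a protein-like sphere."""
    radius = 2.4 * n_atoms ** (1.0 / 3.0)
    pos = np.zeros((n_atoms, 3))
    for i in range(1, n_atoms):
        for _ in range(50):
            step = rng.normal(size=3)
            step *= 3.8 / np.linalg.norm(step)
            cand = pos[i - 1] + step
            if np.linalg.norm(cand) <= radius:
                pos[i] = cand
                break
        else:  # pull back toward the center
            pos[i] = pos[i - 1] * (1.0 - 3.8 / np.linalg.norm(pos[i - 1]))
    pos -= pos.mean(axis=0)
    return AtomicModel(model_id, ["C"] * n_atoms, pos)


def make_decoy_library(n: int, size_range=(60, 240),
                       seed: int = 0) -> list[AtomicModel]:
    """Deterministic mixture of helix-bundle and globular-blob decoys.

    Bundles (60%) vary helix count (2-5), length and curvature — deliberate
    same-fold-class confounders for helical targets; blobs (40%) are compact
    random C-alpha clouds.  Atom counts stay within ``size_range`` and ids
    are unique.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    lo, hi = size_range
    if not (2 <= lo <= hi):
        raise ValueError(f"invalid size_range {size_range}")
    rng = np.random.default_rng(seed)
    models = []
    for i in range(n):
        target_atoms = int(rng.integers(lo, hi + 1))
        if rng.random() < 0.6:
            n_h = int(rng.integers(2, 6))
            n_h = max(2, min(n_h, target_atoms // 2, hi // 2))
            n_res = max(2, min(target_atoms // n_h, hi // n_h))
            models.append(
                make_helix_bundle(
                    n_h, n_res,
                    spacing=float(rng.uniform(8.0, 12.0)),
                    seed=int(rng.integers(2**31)),
                    curvature=float(rng.uniform(0.0, 0.003)),
                    model_id=f"decoy_{i:03d}_bundle",
                )
            )
        else:
            models.append(
                _make_blob(target_atoms, rng, f"decoy_{i:03d}_blob")
            )
    return models


@dataclasses.dataclass
class BenchmarkCase:
    """A complete planted-truth screen, reproducible from its seed.

    ``true_pose`` is the rotation/translation that placed the truth model in
    the target, for pose-error evaluation.
    """

    seed: int
    truth: AtomicModel
    library: list[AtomicModel]
    target: VoxelGrid
    noise_sigma: float
    params: FitParams
    true_pose: Pose

    def __post_init__(self):
        ids = {m.model_id for m in self.library}
        if self.truth.model_id not in ids:
            raise ValueError("truth model must be part of the library")


def _make_truth_bundle(seed: int, model_id: str) -> AtomicModel:
    """Asymmetric 3-helix bundle used as the planted truth.

    Unequal helix lengths (36/27/21 residues) break the pseudo two-fold
    symmetry of an equal-length antiparallel bundle, so the planted pose is
    uniquely identifiable and pose-recovery errors are well defined.
    """
    rng = np.random.default_rng(seed)
    spacing = 10.0
    circumradius = spacing / (2.0 * math.sin(math.pi / 3.0))
    parts = []
    for k, n_res in enumerate((36, 27, 21)):
        ang = 2.0 * math.pi * k / 3.0
        foot = circumradius * np.array([math.cos(ang), math.sin(ang), 0.0])
        phase = float(rng.uniform(0.0, 2.0 * math.pi))
        if k % 2 == 0:
            h = make_alpha_helix(n_res, start=foot, axis=(0, 0, 1),
                                 phase=phase)
        else:
            h = make_alpha_helix(
                n_res, start=foot + [0, 0, HELIX_RISE * (n_res - 1)],
                axis=(0, 0, -1), phase=phase,
            )
        parts.append(h.positions)
    pos = np.vstack(parts)
    pos -= pos.mean(axis=0)
    return AtomicModel(model_id, ["C"] * pos.shape[0], pos)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Haar-uniform rotation matrix from a seeded generator."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def make_benchmark_case(seed: int, n_decoys: int, snr: float,
                        params: FitParams | None = None,
                        box_dim: int = 48,
                        voxel_size: float = 2.612,
                        snap_rotation_to_set: bool = False) -> BenchmarkCase:
    """Planted-truth benchmark: a hidden 3-helix bundle among decoys.

    The truth model is rotated by a seeded random orientation, jittered off
    the box center, simulated at ``params.resolution``, thresholded, and
    corrupted with Gaussian noise of sigma = RMS(clean map) / snr.  The
    case's ``params.cutoff`` is set to half the noise sigma (the threshold
    used both to condition the target and later by the fits).

    With ``snap_rotation_to_set`` the planted orientation is drawn from the
    search's own rotation sample at ``params.step_deg``, making the case
    exactly recoverable — the construction used to check that a perfectly
    matched model scores ~1.
    """
    if n_decoys < 1:
        raise ValueError(f"n_decoys must be >= 1, got {n_decoys}")
    if not (snr > 0):
        raise ValueError(f"snr must be > 0, got {snr}")
    if params is None:
        params = FitParams()
    rng = np.random.default_rng(seed)
    truth = _make_truth_bundle(int(rng.integers(2**31)),
                               model_id=f"truth_{seed}")
    rotation = _random_rotation(rng)
    if snap_rotation_to_set:
        from .rotations import generate_rotations

        rset = generate_rotations(params.step_deg)
        rotation = rset.matrices[int(rng.integers(len(rset)))].copy()
    jitter = rng.uniform(-3.0 * voxel_size, 3.0 * voxel_size, size=3)
    origin = -voxel_size * (box_dim - 1) / 2.0 * np.ones(3)
    frame = VoxelGrid(np.zeros((box_dim,) * 3), voxel_size, origin)
    translation = -truth.centroid + jitter  # centroid lands near box center
    true_pose = Pose(rotation, translation)
    placed = truth.transformed(rotation, translation)
    clean = simulate_map(
        placed, SimulationParams(params.resolution, voxel_size), frame=frame
    )
    rms = float(np.sqrt((clean.values**2).mean()))
    noise_sigma = 0.0 if math.isinf(snr) else rms / snr
    cutoff = 0.5 * noise_sigma
    conditioned = apply_cutoff(clean, cutoff)
    target = add_noise(conditioned, noise_sigma, seed=int(rng.integers(2**31)))
    library = [truth] + make_decoy_library(n_decoys,
                                           seed=int(rng.integers(2**31)))
    case_params = dataclasses.replace(params, cutoff=cutoff)
    return BenchmarkCase(seed, truth, library, target, noise_sigma,
                         case_params, true_pose)


def write_benchmark_case(case: BenchmarkCase, outdir) -> Path:
    """Write target MRC, library PDBs and a JSON manifest to ``outdir``."""
    outdir = Path(outdir)
    lib = outdir / "library"
    lib.mkdir(parents=True, exist_ok=True)
    write_density(case.target, outdir / "target.mrc")
    for m in case.library:
        write_model(m, lib / f"{m.model_id}.pdb")
    manifest = {
        "seed": case.seed,
        "truth_id": case.truth.model_id,
        "noise_sigma": case.noise_sigma,
        "n_models": len(case.library),
        "params": {
            "resolution": case.params.resolution,
            "step_deg": case.params.step_deg,
            "cutoff": case.params.cutoff,
            "mode": case.params.mode,
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return outdir
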