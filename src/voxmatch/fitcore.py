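"""Exhaustive rigid-body fitting of an atomic model into a density segment.

The 6D search factorizes: orientations come from a deterministic quasi-
uniform SO(3) sample set at a nominal angular step, and for each orientation
every integer-voxel translation is scored at once through an FFT
cross-correlation scan.  The probe is always re-simulated from rotated
*atomic coordinates* — the probe map is never interpolated — which removes
interpolation artifacts and keeps one unambiguous convention.

Two scores are reported for every fit:

* ``cc_unnormalized`` — the raw inner product sum(target * probe).  It grows
  linearly with probe mass, so an oversized probe can push it past 1 even
  though nothing "correlates more than perfectly"; screening runs that rank
  by it reward bulk, not shape.
* ``cc_normalized`` — the same inner product divided by
  sqrt(sum(target^2) * sum(probe^2)) over the full box after the target
  cutoff; Cauchy-Schwarz bounds it to [-1, 1].

By default the search runs a two-stage pyramid: a circular correlation scan
on a decimated, extra-smoothed copy of the maps triages orientations, and
the best candidates are re-scored exactly (full resolution, zero-padded
linear correlation).  ``exhaustive=True`` forces the exact scan for every
orientation; on small problems the two give identical poses and the test
suite checks that.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import scipy.fft as sfft
from scipy import ndimage

from ._gridder import grid_atoms, scatter_rotated_batch
from .grid import VoxelGrid, apply_cutoff
from .model import AtomicModel
from .rotations import RotationSet, generate_rotations
from .simulate import SimulationParams, sigma_from_resolution, simulate_map


@dataclasses.dataclass
class Pose:
    """A proper rotation (about the model centroid) plus translation in Å.

    ``mirrored`` marks poses found for the mirror image of the model; the
    rotation then applies to the mirrored coordinates.
    """

    rotation: np.ndarray
    translation: np.ndarray
    mirrored: bool = False

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation,
                                      dtype=float).reshape(3)
        if not (np.isfinite(self.rotation).all()
                and np.isfinite(self.translation).all()):
            raise ValueError("pose components must be finite")


@dataclasses.dataclass
class FitParams:
    """Knobs of the rigid-body search.

    resolution : Å of the probe simulation (and the map the target is
        assumed to represent).
    step_deg : nominal SO(3) sampling step in degrees.
    cutoff : target density threshold; voxels <= cutoff are zeroed before
        any scoring.
    mode : ``standard`` plain cross-correlation, or ``laplacian`` to apply a
        discrete 3D Laplacian to target and probe before correlation
        (edge-enhanced matching).
    mirror : also search the mirror image of the model and keep the better
        of the two, flagged on the pose.
    weight_mode : atom weighting for the simulated probe (``unit`` or
        ``element-mass``).
    refine : sub-voxel translation refinement by parabolic interpolation of
        the score peak.
    exhaustive : score every orientation at full resolution instead of
        triaging with the decimated first pass.
    n_refine_rotations : number of coarse-pass candidates re-scored exactly.
    """

    resolution: float = 6.0
    step_deg: float = 15.0
    cutoff: float = 0.0
    mode: str = "standard"
    mirror: bool = False
    weight_mode: str = "unit"
    refine: bool = True
    exhaustive: bool = False
    n_refine_rotations: int = 16

    def __post_init__(self):
        if self.mode not in ("standard", "laplacian"):
            raise ValueError(f"unknown correlation mode {self.mode!r}")


@dataclasses.dataclass
class FitResult:
    """Best pose of one model with both score flavors."""

    model_id: str
    pose: Pose
    cc_normalized: float
    cc_unnormalized: float
    n_rotations: int
    n_atoms: int


# ---------------------------------------------------------------------------
# translational scan

def _laplacian(values: np.ndarray) -> np.ndarray:
    return ndimage.laplace(values, mode="constant")


def cc_translation_scan(target: VoxelGrid, probe: VoxelGrid,
                        mode: str = "standard") -> VoxelGrid:
    """Linear (zero-padded) cross-correlation over every integer displacement.

    Returns a score volume with ``score(d) = sum_v target(v) * probe(v - d)``
    for displacements d from ``-(probe_dims - 1)`` to ``target_dims - 1`` per
    axis.  The returned grid's coordinate frame is the physical translation:
    ``out.coordinate(m)`` is the Å shift that moves the probe grid onto the
    target grid for the displacement stored at index ``m``.
    """
    h = target.voxel_size
    if abs(probe.voxel_size - h) > 1e-6 * h:
        raise ValueError(
            f"voxel size mismatch: target {h}, probe {probe.voxel_size}"
        )
    t = target.values
    p = probe.values
    if mode == "laplacian":
        t, p = _laplacian(t), _laplacian(p)
    elif mode != "standard":
        raise ValueError(f"unknown correlation mode {mode!r}")
    nt = np.array(t.shape)
    npr = np.array(p.shape)
    out = nt + npr - 1
    L = [sfft.next_fast_len(int(n), real=True) for n in out]
    C = sfft.irfftn(sfft.rfftn(t, L) * np.conj(sfft.rfftn(p, L)), L)
    lin = np.roll(C, shift=tuple(npr - 1), axis=(0, 1, 2))[
        : out[0], : out[1], : out[2]
    ]
    origin = target.origin - probe.origin - h * (npr - 1)
    return VoxelGrid(lin, h, origin)


# ---------------------------------------------------------------------------
# single-pose scoring

def score_pose(target: VoxelGrid, model: AtomicModel, pose: Pose,
               params: FitParams) -> tuple[float, float]:
    """Score one placement: (cc_normalized, cc_unnormalized).

    The model is rotated about its centroid, translated, simulated on the
    target frame, and correlated against the cutoff-thresholded target over
    the full box.  With ``mode='laplacian'`` both maps are Laplacian-filtered
    before the sums.
    """
    t = apply_cutoff(target, params.cutoff)
    placed = model.mirrored() if pose.mirrored else model
    placed = placed.transformed(pose.rotation, pose.translation)
    probe = simulate_map(
        placed,
        SimulationParams(params.resolution, target.voxel_size,
                         weight_mode=params.weight_mode),
        frame=target,
    )
    if not probe.values.any():
        raise ValueError("model lies entirely outside the target frame")
    tv, pv = t.values, probe.values
    if params.mode == "laplacian":
        tv, pv = _laplacian(tv), _laplacian(pv)
    ccu = float((tv * pv).sum())
    denom = math.sqrt(float((tv * tv).sum()) * float((pv * pv).sum()))
    if denom == 0.0:
        raise ValueError("degenerate (all-zero) target after cutoff")
    return ccu / denom, ccu


# ---------------------------------------------------------------------------
# full 6D search

def _crop_nonzero(grid: VoxelGrid) -> VoxelGrid:
    """Bounding box of nonzero voxels (the automatic zero-edge crop)."""
    mask = grid.values != 0
    lo, hi = [], []
    for axis in range(3):
        proj = mask.any(axis=tuple(a for a in range(3) if a != axis))
        idx = np.nonzero(proj)[0]
        lo.append(int(idx[0]))
        hi.append(int(idx[-1]) + 1)
    return VoxelGrid(
        grid.values[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]].copy(),
        grid.voxel_size,
        grid.origin + grid.voxel_size * np.array(lo, dtype=float),
    )


COARSE_DECIMATION = 3


def _decimate(grid: VoxelGrid, q: int) -> VoxelGrid:
    """q-fold block-mean decimation (zero-padded to a multiple of q first)."""
    v = grid.values
    pad = [(0, (-n) % q) for n in v.shape]
    v = np.pad(v, pad)
    v = v.reshape(v.shape[0] // q, q, v.shape[1] // q, q,
                  v.shape[2] // q, q).mean(axis=(1, 3, 5))
    return VoxelGrid(v, q * grid.voxel_size,
                     grid.origin + 0.5 * (q - 1) * grid.voxel_size)


def _grid_probe(positions, weights, origin, n_side, h, sigma):
    values = np.zeros((n_side, n_side, n_side))
    grid_atoms(values, positions, weights, origin, h, sigma)
    return values


def _parabolic_vertex(y0: float, y1: float, y2: float) -> float:
    """Peak offset in [-1, 1] sample units from three bracketing samples.

    Log-domain when all samples are positive (exact for a Gaussian peak);
    the vertex is clamped to the sampled interval.
    """
    if y0 > 0 and y1 > 0 and y2 > 0:
        y0, y1, y2 = math.log(y0), math.log(y1), math.log(y2)
    denom = y0 - 2.0 * y1 + y2
    if denom >= 0:  # flat or not a maximum
        return 0.0
    return float(np.clip(0.5 * (y0 - y2) / denom, -1.0, 1.0))


def _refine_translation(target: VoxelGrid, model: AtomicModel,
                        rotation: np.ndarray, mirrored: bool,
                        translation: np.ndarray,
                        params: FitParams) -> np.ndarray:
    """Sub-voxel translation by parabolic interpolation of exact scores.

    Starting from the integer-voxel scan optimum, each axis is refined with
    a three-point parabola through scores computed at the exact (continuous)
    displacements, in two sweeps of shrinking spacing (h/2 then h/4).
    Sampling the true score function instead of the FFT lattice keeps the
    interpolation accurate even when the peak sits halfway between voxels.
    """
    h = target.voxel_size
    cache: dict[tuple, float] = {}

    def s(tau):
        key = tuple(np.round(tau, 9))
        if key not in cache:
            cache[key] = score_pose(
                target, model, Pose(rotation, tau, mirrored), params
            )[0]
        return cache[key]

    tau = np.asarray(translation, dtype=float)
    best = s(tau)
    for spacing in (0.25 * h, 0.125 * h):
        for ax in range(3):
            e = np.zeros(3)
            e[ax] = spacing
            lo, hi = s(tau - e), s(tau + e)
            if best >= lo and best >= hi:
                off = _parabolic_vertex(lo, best, hi) * spacing
            else:  # peak not bracketed: step toward the better neighbor
                off = spacing if hi > lo else -spacing
            cand = tau.copy()
            cand[ax] += off
            sc = s(cand)
            if sc >= best:
                best, tau = sc, cand
    return tau


def _upsampled_peak(spectrum: np.ndarray, L, out, n_p: int) -> np.ndarray:
    """Half-voxel peak location of a correlation via 2x Fourier upsampling.

    ``spectrum`` is the rfftn product of target and conjugated probe at
    transform size ``L``.  Zero-embedding it into the double-size transform
    (trigonometric interpolation) samples the correlation on the half-voxel
    lattice: a peak that falls between integer displacements — where every
    surrounding lattice sample is depressed and a secondary ridge can look
    taller — is then located correctly.  Returns the displacement in
    (possibly half-integer) voxels.
    """
    L2 = [2 * n for n in L]
    up = np.zeros((L2[0], L2[1], L2[2] // 2 + 1), dtype=spectrum.dtype)
    h0, h1 = L[0] // 2, L[1] // 2
    dst0 = (slice(0, h0 + 1), slice(L2[0] - (L[0] - h0 - 1), L2[0]))
    src0 = (slice(0, h0 + 1), slice(h0 + 1, L[0]))
    dst1 = (slice(0, h1 + 1), slice(L2[1] - (L[1] - h1 - 1), L2[1]))
    src1 = (slice(0, h1 + 1), slice(h1 + 1, L[1]))
    nz = spectrum.shape[2]
    for a_dst, a_src in zip(dst0, src0):
        for b_dst, b_src in zip(dst1, src1):
            up[a_dst, b_dst, :nz] = spectrum[a_src, b_src, :]
    C = sfft.irfftn(up, L2) * 8.0
    lin = np.roll(C, shift=(2 * (n_p - 1),) * 3, axis=(0, 1, 2))[
        : 2 * out[0] - 1, : 2 * out[1] - 1, : 2 * out[2] - 1
    ]
    peak = np.array(np.unravel_index(np.argmax(lin), lin.shape))
    return (peak - 2 * (n_p - 1)) / 2.0


@dataclasses.dataclass
class _Candidate:
    rot_index: int
    surrogate_ccn: float
    raw: float
    displacement: np.ndarray
    translation: np.ndarray | None = None


def _search_orientations(tc: VoxelGrid, model: AtomicModel,
                         rotations: RotationSet,
                         params: FitParams) -> _Candidate:
    """Best (rotation, integer translation) for one model chirality.

    ``tc`` is the cutoff-thresholded, zero-cropped target.  Ties broken by
    raw score, then by rotation index.
    """
    h = tc.voxel_size
    sigma = sigma_from_resolution(params.resolution)
    c = model.centroid
    n_p = 2 * int(math.ceil((model.radius + 4.0 * sigma) / h + 1.0)) + 1
    m = (n_p - 1) // 2
    o_p = tc.origin + h * np.round((c - h * m - tc.origin) / h)

    tv = _laplacian(tc.values) if params.mode == "laplacian" else tc.values
    tv = tv.astype(np.float32)
    out = np.array(tv.shape) + n_p - 1
    L = [sfft.next_fast_len(int(n), real=True) for n in out]
    Ft = sfft.rfftn(tv, L)
    st2 = float((tv.astype(np.float64) ** 2).sum())
    centered = model.positions - c
    weights = model.weights
    if params.weight_mode == "element-mass":
        weights = weights * model.element_masses()

    n_rot = len(rotations)
    candidates = range(n_rot)
    if not params.exhaustive and n_rot > params.n_refine_rotations:
        order = _coarse_triage(tc, centered, c, weights, n_p, rotations,
                               params)
        candidates = order[: params.n_refine_rotations]

    best = None
    best_spectrum = None
    for idx in candidates:
        R = rotations.matrices[idx]
        pos = centered @ R.T + c
        pv = _grid_probe(pos, weights, o_p, n_p, h, sigma)
        if params.mode == "laplacian":
            pv = _laplacian(pv)
        sp2 = float((pv * pv).sum())
        S = Ft * np.conj(sfft.rfftn(pv.astype(np.float32), L))
        C = sfft.irfftn(S, L)
        lin = np.roll(C, shift=(n_p - 1,) * 3, axis=(0, 1, 2))[
            : out[0], : out[1], : out[2]
        ]
        peak = np.array(np.unravel_index(np.argmax(lin), lin.shape))
        raw = float(lin[tuple(peak)])
        ccn = raw / math.sqrt(st2 * sp2)
        if best is None or (ccn, raw, -idx) > (
            best.surrogate_ccn, best.raw, -best.rot_index
        ):
            best = _Candidate(idx, ccn, raw,
                              (peak - (n_p - 1)).astype(float))
            best_spectrum = S
    if params.refine:
        best.displacement = _upsampled_peak(best_spectrum, L, out, n_p)
    best.translation = (tc.origin - o_p) + h * best.displacement
    return best


def _coarse_triage(tc, centered, c, weights, n_p, rotations, params):
    """Rank orientations with a decimated, extra-smoothed circular scan.

    The target is low-passed to q times the working resolution and q-fold
    block-decimated (q = 3); probes are simulated with the matching combined
    blur (sigma * sqrt(1 + q^2)).  The wider kernels make the correlation
    peak broad enough to be sampled reliably on the coarse lattice, at the
    price of angular discrimination — which is why several top candidates,
    not just one, are re-scored exactly.
    """
    from .grid import lowpass_filter

    q = COARSE_DECIMATION
    sigma_c = sigma_from_resolution(params.resolution) * math.sqrt(1 + q * q)
    smooth = lowpass_filter(tc, q * params.resolution)
    coarse = _decimate(smooth, q)
    # crop to the signal neighborhood: the heavy extra smoothing leaves any
    # real feature far above residual noise, so a fixed fraction of the
    # maximum bounds it safely (2-voxel margin)
    mask = coarse.values > 0.25 * coarse.values.max()
    lo = [max(0, int(np.nonzero(mask.any(axis=tuple(a for a in range(3)
                                                    if a != ax)))[0][0]) - 2)
          for ax in range(3)]
    hi = [min(coarse.dims[ax],
              int(np.nonzero(mask.any(axis=tuple(a for a in range(3)
                                                 if a != ax)))[0][-1]) + 3)
          for ax in range(3)]
    coarse = VoxelGrid(
        coarse.values[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]].copy(),
        coarse.voxel_size,
        coarse.origin + coarse.voxel_size * np.array(lo, dtype=float),
    )
    if params.mode == "laplacian":
        coarse = VoxelGrid(_laplacian(coarse.values), coarse.voxel_size,
                           coarse.origin)
    hc = coarse.voxel_size
    n_pc = int(math.ceil(n_p / q)) + 1
    mc = (n_pc - 1) / 2.0
    o_pc = coarse.origin + hc * np.round((c - hc * mc - coarse.origin) / hc)
    # circular scan: every displacement is covered modulo the box, which is
    # all the rotation triage needs; wrapped scores stay Cauchy-Schwarz
    # bounded, so they cannot displace a genuinely matching orientation
    Lc = [sfft.next_fast_len(max(int(n), n_pc), real=True)
          for n in coarse.dims]
    Ftc = sfft.rfftn(coarse.values.astype(np.float32), Lc)
    n_rot = len(rotations)
    scores = np.empty(n_rot)
    norms = np.empty(n_rot)
    # batched gridding and FFTs: per-call overhead would otherwise rival the
    # transforms themselves at this size
    sigma_vox = sigma_c / hc
    radius = max(1, int(math.ceil(2.0 * sigma_vox)))  # triage-grade window
    chunk = 64
    buf = np.zeros((chunk, *Lc), dtype=np.float32)
    for start in range(0, n_rot, chunk):
        stop = min(start + chunk, n_rot)
        b = stop - start
        buf[:b] = 0.0
        scatter_rotated_batch(
            buf[:b], rotations.matrices[start:stop], centered, c,
            weights / hc**3, o_pc, hc, sigma_vox, radius,
        )
        if params.mode == "laplacian":
            for i in range(b):
                buf[i] = _laplacian(buf[i])
        norms[start:stop] = np.einsum(
            "bijk,bijk->b", buf[:b], buf[:b], dtype=np.float64
        )
        Fp = sfft.rfftn(buf[:b], axes=(1, 2, 3))
        C = sfft.irfftn(np.conj(Fp) * Ftc[None], axes=(1, 2, 3),
                        s=Lc)
        scores[start:stop] = C.reshape(b, -1).max(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = np.where(norms > 0, scores / np.sqrt(norms), -np.inf)
    return np.argsort(-scores, kind="stable")


def fit_model(target: VoxelGrid, model: AtomicModel,
              params: FitParams | None = None) -> FitResult:
    """Best rigid-body pose of ``model`` in ``target`` over the 6D search.

    The target is thresholded at ``params.cutoff`` (and must not be all-zero
    after that), orientations are sampled at ``params.step_deg``, and every
    integer translation is scanned per orientation; the winning translation
    is refined to sub-voxel precision.  With ``mirror=True`` the mirror
    image competes too.  Reported scores are recomputed exactly at the final
    pose, so they agree with :func:`score_pose`.
    """
    if params is None:
        params = FitParams()
    t_cut = apply_cutoff(target, params.cutoff)
    if not t_cut.values.any():
        raise ValueError("degenerate (all-zero) target after cutoff")
    tc = _crop_nonzero(t_cut)
    rotations = generate_rotations(params.step_deg)

    variants = [False, True] if params.mirror else [False]
    best = None
    for mirrored in variants:
        mdl = model.mirrored() if mirrored else model
        cand = _search_orientations(tc, mdl, rotations, params)
        rotation = rotations.matrices[cand.rot_index].copy()
        translation = cand.translation
        if params.refine:
            translation = _refine_translation(target, model, rotation,
                                              mirrored, translation, params)
        pose = Pose(rotation, translation, mirrored)
        ccn, ccu = score_pose(target, model, pose, params)
        key = (ccn, ccu, -cand.rot_index)
        if best is None or key > best[0]:
            best = (key, pose, ccn, ccu)
    _, pose, ccn, ccu = best
    return FitResult(model.model_id, pose, ccn, ccu, len(rotations),
                     model.n_atoms)
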