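# Methods

voxmatch identifies proteins in segmented cryo-EM/cryo-ET densities by
exhaustive rigid-body docking: every atomic model of a candidate library is
placed into the target density at every sampled orientation and every
integer-voxel translation, scored by cross-correlation, and the library is
ranked by each model's best pose. This note records the model, the
conventions, the tunable parameters and the design choices, and what the
synthetic benchmark does and does not establish.

## Coordinate and map conventions

A density (`VoxelGrid`) is a scalar field on a regular isotropic lattice.
`values[i, j, k]` lives at physical position `origin + voxel_size*(i, j, k)`
(Å); the origin is the *center* of voxel (0,0,0). MRC2014 files are read
and written through gemmi in float mode 2; the header ORIGIN words define
the origin, the NXSTART words are ignored, and any axis permutation in the
header is normalized to x-fastest on load. Only isotropic voxels are
accepted (1e-3 relative tolerance), because the rigid search assumes one
grid constant.

A pose is a proper rotation applied about the model centroid followed by a
translation in Å. Mirror-image fits are opt-in (`mirror=True`) and flagged
on the pose; mirroring is never applied silently, since whether a segmented
map carries a hand flip is generally not deducible from the file.

## Density simulation and filtering share one blur convention

Each atom contributes an isotropic Gaussian whose Fourier amplitude falls to
1/2 at spatial frequency `1/resolution`:

    sigma(R) = R * sqrt(ln 2 / 2) / pi  ≈ 0.1874 R   (Å)

The low-pass filter uses the same half-amplitude convention (a raised-cosine
shape is available), so a probe simulated at resolution R and a target
low-passed to R are attenuated identically and their correlation is not
biased by mismatched blurs. A consistency test verifies that the spectral
ratio of 12 Å and 6 Å simulations equals the analytic Gaussian ratio to
5e-4.

Gridding integrates the Gaussian over each voxel (separable erf
differences) rather than sampling it, so the voxel sum times the voxel
volume equals the deposited weight exactly even when sigma is smaller than
a voxel — at the working point (6 Å on 2.612 Å voxels, sigma ≈ 1.12 Å) a
sampled kernel would misestimate mass by several percent. Kernels are
truncated at 4 sigma (at least one voxel) and renormalized per atom; maps
store density (weight per Å^3). Atom weights default to 1.0; element-mass
weighting is available. Which weighting a screening protocol "should" use
is genuinely open; unit weights make the score a pure shape term, which is
why they are the default.

## Orientation sampling

`generate_rotations(step)` builds a deterministic quasi-uniform cover of
SO(3) from the Hopf fibration: a Fibonacci lattice on the sphere of rotated
z-axes crossed with a uniform grid of spin angles, with the two resolutions
balanced (fiber half-spacing proportional to `step/sqrt(3)`, base covering
to `step*sqrt(2/3)`) to minimize the count for a given covering radius, and
a per-dimension density factor k = 2^(1/3) matching the sampling scale of
reference Euler-grid screens at the same nominal step. The closed-form
size is

    N(step) = 1 + ceil(pi*sqrt(3)*k/delta) * ceil(6*pi*0.76^2*k^2/delta^2),

delta in radians (N(15°) = 6832, N(30°) = 897); 0.76 is the empirical
covering constant of the Fibonacci sphere. Measured covering radius over
1000 Haar-random rotations is 9.7° at step 15° and 20.4° at step 30° —
always below one nominal step (orientation quantization is the dominant
score loss for a planted pose, so the density factor is what keeps a
correct model's fitted score above look-alike decoys at low SNR). The
identity is always member 0.

## Scoring

For a pose, the model is rotated about its centroid (coordinates, never
voxel interpolation), simulated on the target frame, and compared with the
cutoff-thresholded target over the full box:

    cc_unnormalized = sum(t * p)
    cc_normalized   = sum(t * p) / sqrt(sum(t^2) * sum(p^2))

The cutoff zeroes target voxels at or below the threshold, mirroring the
thresholding step of screening protocols. The normalized score is bounded
by 1 (Cauchy–Schwarz) and invariant to rescaling either map; the raw score
grows linearly with probe mass and map scale, which is exactly why screens
ranked by it can report "correlations" above 1 for oversized probes — the
package reproduces that pathology on demand and always reports both
flavors. Ranking uses `cc_normalized` (ties: raw score, then rotation
index, then model id — output is fully deterministic).

An optional `laplacian` mode applies a discrete 6-neighbor Laplacian to
both maps before correlation, emphasizing edges over bulk.

## The 6D search

Per orientation, all integer translations are scored at once by FFT
cross-correlation with zero padding (linear, not circular, correlation —
verified against a direct-sum oracle to 1e-8). The target is thresholded
and cropped to its nonzero bounding box first; removed voxels are zero, so
scores are unchanged while the transforms shrink.

The default search is a two-stage pyramid. Stage 1 ranks all orientations
on a 3x-decimated copy: the target is low-passed to three times the working
resolution and block-averaged, the probe is simulated with the matched
combined blur (sigma*sqrt(10)), and a circular FFT scan on the cropped
coarse box scores each orientation. The extra smoothing widens the
correlation peak past the coarse sampling so a peak cannot fall between
samples; circular wrap-around can inflate a wrong orientation's triage
score but never past the Cauchy–Schwarz bound, so a genuinely matching
orientation is not displaced. Stage 2 re-scores the best 16 candidates
(`n_refine_rotations`) exactly at full resolution. `exhaustive=True`
replaces the pyramid with the exact scan for every orientation; the suite
asserts both return identical poses on small problems. Reported scores are
always recomputed at the final pose with `score_pose`, so they are exact
regardless of the search path.

The winning orientation's translation is refined to sub-voxel precision in
two steps. First the correlation spectrum is zero-embedded into the
double-size transform (trigonometric interpolation), locating the peak on
a half-voxel lattice — necessary because a peak falling midway between
integer displacements depresses all its surrounding samples, and a
secondary ridge of the correlation (helix bundles have internally periodic
autocorrelations) can then look taller on the integer lattice. From that
start, each axis is polished with three-point parabolas through *exactly
computed* scores (the model re-simulated at continuous displacements) at
h/4 then h/8 spacing, log-domain when positive. Measured translation
accuracy on noiseless targets is ~0.03 voxel and a recovered planted pose
scores ccn ≥ 0.999; no gradient-based refinement, and no rotational
refinement below the sampling step, is attempted (deliberate scope
bounds).

## Library screening

`scan_library` walks a directory (recursively, sorted — file-system order
never affects output) or an in-memory model list, fits each model
independently, deduplicates to one best pose per model id and sorts.
Unreadable or unfittable entries are skipped with a warning and listed in
the table; a proteome-scale screen must not die on one bad file. Per-model
scoring is independent, so the loop is trivially parallelizable; ordering
is defined by the sort, not completion order. Rank tables serialize to TSV
with the parameters echoed as comments and poses as 12 numbers (row-major
rotation + translation).

`occupancy_ratio` compares two aligned maps through two masks:
`(mean_b(feature)/mean_b(ref)) / (mean_a(feature)/mean_a(ref))`. Means
rather than integrals are used so differing mask sizes cancel; a knockout
that removes 70% of a feature's density gives 0.3 exactly.

FSC uses shells one Fourier voxel wide with the conventional
`Re(sum Fa conj(Fb)) / sqrt(sum|Fa|^2 sum|Fb|^2)` estimator and linear
interpolation to the 0.143 threshold crossing (the half-dataset resolution
convention).

## The synthetic benchmark

`make_benchmark_case(seed, n_decoys, snr)` generates a complete planted-
truth screen, reproducible from the seed alone: a 48³ box at 2.612 Å/voxel
(the tomographic working pixel size), a truth model simulated at 6 Å at a
seeded random orientation and a ±3-voxel off-center jitter, additive white
Gaussian noise with sigma = RMS(clean map)/SNR, and a decoy library. The
case's cutoff is set to half the noise sigma — enough to strip most noise
voxels while keeping nearly all signal.

The truth is a 3-helix bundle with unequal helix lengths (36/27/21
residues): equal-length antiparallel bundles have a pseudo two-fold axis
that makes the planted pose non-identifiable (180° flips score nearly
identically), which would turn pose-recovery checks into coin flips.
Decoys (default 60–240 atoms, a realistic small-protein range for Cα-level
models) deliberately include same-fold confounders — other helix bundles of
varying helix count, length and curvature — alongside compact random-walk
blobs, because discriminating among near-paralogs is the hard part of real
screens. Helix geometry is the textbook Cα trace (rise 1.5 Å/residue,
twist 100°/residue, radius 2.3 Å); periodic filaments default to the
160 Å (16 nm) axonemal repeat.

What the benchmark does *not* emulate: tomographic noise is neither white
nor isotropic (missing wedge, CTF), real segmentations carry neighboring
density and boundary artifacts, and real libraries contain full-atom
predicted models with B-factor-like disorder. Passing the planted-truth
suite therefore shows the engine ranks and places correctly under
controlled conditions; it does not by itself calibrate expected scores on
experimental maps.

## Problem sizes and defaults

The shipped acceptance checks run 20 screening cases of 50 models each
(SNR 1, 48³ boxes, 15° step) plus pose-recovery, oracle-equivalence, FSC,
determinism and occupancy checks; a single 50-model screen takes ~40 s on
one CPU core. Defaults: resolution 6.0 Å, step 15.0°, cutoff 0.0 (the
benchmark overrides it per case), standard mode, unit weights, 16 refined
orientations, pyramid search on.

## Known limitations

- No rotational refinement below the sampling step; orientation accuracy is
  bounded by the covering radius (~0.85 step).
- Normalization during the translational scan uses the full probe mass;
  poses hanging off the box edge are normalized slightly pessimistically
  relative to `score_pose` (which clips). Interior optima are unaffected.
- The coarse triage assumes a mostly non-negative target after cutoff; a
  negative cutoff with strongly negative content degrades the stage-1
  ranking (stage 2 still rescoring exactly).
- FSC shells assume a common voxel size and use the largest box dimension
  for shell width; strongly anisotropic boxes coarsen the curve.
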