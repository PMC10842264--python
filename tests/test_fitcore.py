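"""Translational scan, pose scoring and the full 6D rigid-body search."""

import numpy as np
import pytest

from voxmatch import (
    FitParams,
    Pose,
    VoxelGrid,
    cc_translation_scan,
    fit_model,
    generate_rotations,
    geodesic_distance_deg,
    score_pose,
    simulate_map,
    SimulationParams,
)
from voxmatch.synthbench import _random_rotation


from _oracles import brute_force_scan, laplacian_stencil


def _grid(values, h=2.0, origin=(0.0, 0.0, 0.0)):
    return VoxelGrid(values, h, origin)


class TestTranslationScan:
    @pytest.mark.parametrize("mode", ["standard", "laplacian"])
    def test_fft_equals_bruteforce(self, mode, rng):
        t = rng.random((8, 8, 8))
        p = rng.random((4, 5, 3))
        out = cc_translation_scan(_grid(t), _grid(p), mode=mode)
        if mode == "laplacian":
            expected = brute_force_scan(laplacian_stencil(t),
                                        laplacian_stencil(p))
        else:
            expected = brute_force_scan(t, p)
        assert out.values.shape == expected.shape
        assert np.abs(out.values - expected).max() < 1e-8

    def test_self_correlation_peaks_at_zero_displacement(self, rng):
        t = rng.random((8, 8, 8))
        out = cc_translation_scan(_grid(t), _grid(t))
        peak = np.unravel_index(np.argmax(out.values), out.values.shape)
        assert peak == (7, 7, 7)  # d = 0
        # at d = 0 the physical translation is the origin difference
        assert np.allclose(out.coordinate(peak), (0.0, 0.0, 0.0))

    def test_shifted_probe_recovers_shift(self, rng):
        t = rng.random((8, 8, 8))
        probe = t[2:, :, 1:]  # probe(u) = t(u + (2, 0, 1))
        out = cc_translation_scan(_grid(t), _grid(probe))
        peak = np.array(np.unravel_index(np.argmax(out.values),
                                         out.values.shape))
        d = peak - (np.array(probe.shape) - 1)
        assert tuple(d) == (2, 0, 1)

    def test_voxel_size_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            cc_translation_scan(_grid(rng.random((4, 4, 4)), h=2.0),
                                _grid(rng.random((4, 4, 4)), h=1.0))


@pytest.fixture
def frame():
    return VoxelGrid(np.zeros((36, 36, 36)), 2.612,
                     origin=-2.612 * 17.5 * np.ones(3))


@pytest.fixture
def self_target(bundle, frame):
    return simulate_map(bundle, SimulationParams(6.0, 2.612), frame=frame)


class TestScorePose:
    def test_self_map_scores_one(self, bundle, self_target):
        ccn, ccu = score_pose(self_target, bundle,
                              Pose(np.eye(3), np.zeros(3)), FitParams())
        assert ccn == pytest.approx(1.0, abs=1e-6)

    def test_normalized_score_bounded(self, bundle, self_target, rng):
        for _ in range(5):
            pose = Pose(_random_rotation(rng), rng.uniform(-8, 8, 3))
            ccn, _ = score_pose(self_target, bundle, pose, FitParams())
            assert -1.0 <= ccn <= 1.0

    def test_oversized_probe_pathology(self, bundle, self_target):
        """A 10x-mass probe pushes the raw score past 1; the normalized
        score stays Cauchy-Schwarz bounded."""
        target = VoxelGrid(
            self_target.values / self_target.values.max(),  # peak-normalized
            self_target.voxel_size, self_target.origin,
        )
        from voxmatch import AtomicModel

        big = AtomicModel(bundle.model_id, list(bundle.elements),
                          bundle.positions, bundle.weights * 10.0)
        ccn, ccu = score_pose(target, big, Pose(np.eye(3), np.zeros(3)),
                              FitParams())
        assert ccu > 1.0
        assert ccn <= 1.0
        assert ccn == pytest.approx(1.0, abs=1e-6)

    def test_scaling_dichotomy(self, bundle, self_target):
        """Normalized score is scale-invariant; raw score scales linearly."""
        pose = Pose(np.eye(3), np.zeros(3))
        ccn, ccu = score_pose(self_target, bundle, pose, FitParams())
        scaled = VoxelGrid(3.0 * self_target.values,
                           self_target.voxel_size, self_target.origin)
        ccn3, ccu3 = score_pose(scaled, bundle, pose, FitParams())
        assert ccn3 == pytest.approx(ccn, rel=1e-12)
        assert ccu3 == pytest.approx(3.0 * ccu, rel=1e-12)

    def test_model_outside_frame_rejected(self, bundle, self_target):
        pose = Pose(np.eye(3), np.array([500.0, 0.0, 0.0]))
        with pytest.raises(ValueError, match="outside"):
            score_pose(self_target, bundle, pose, FitParams())


class TestFitModel:
    def test_noiseless_self_fit(self, bundle, self_target):
        res = fit_model(self_target, bundle, FitParams(step_deg=30.0))
        assert res.cc_normalized >= 0.99
        assert geodesic_distance_deg(res.pose.rotation, np.eye(3)) <= 30.0
        assert np.abs(res.pose.translation).max() < 0.5 * 2.612

    def test_rotated_by_member_recovered_exactly(self, bundle, frame):
        rset = generate_rotations(30.0)
        R = rset.matrices[17]
        shift = 2.612 * np.array([1.0, -2.0, 0.0])  # lattice translation
        target = simulate_map(bundle.transformed(R, shift),
                              SimulationParams(6.0, 2.612), frame=frame)
        res = fit_model(target, bundle, FitParams(step_deg=30.0))
        assert np.allclose(res.pose.rotation, R, atol=1e-12)
        assert np.allclose(res.pose.translation, shift, atol=1e-3)
        self_res = fit_model(
            simulate_map(bundle, SimulationParams(6.0, 2.612), frame=frame),
            bundle, FitParams(step_deg=30.0),
        )
        assert res.cc_normalized == pytest.approx(
            self_res.cc_normalized, abs=1e-6
        )

    def test_finer_step_scores_at_least_as_well(self, bundle, frame, rng):
        R = _random_rotation(rng)
        target = simulate_map(bundle.transformed(R, np.zeros(3)),
                              SimulationParams(6.0, 2.612), frame=frame)
        coarse = fit_model(target, bundle, FitParams(step_deg=360.0))
        fine = fit_model(target, bundle, FitParams(step_deg=30.0))
        assert fine.cc_normalized > coarse.cc_normalized
        assert fine.n_rotations > coarse.n_rotations

    def test_pyramid_matches_exhaustive(self, bundle, self_target):
        fast = fit_model(self_target, bundle, FitParams(step_deg=60.0))
        slow = fit_model(self_target, bundle,
                         FitParams(step_deg=60.0, exhaustive=True))
        assert np.allclose(fast.pose.rotation, slow.pose.rotation)
        assert np.allclose(fast.pose.translation, slow.pose.translation,
                           atol=1e-9)
        assert fast.cc_normalized == pytest.approx(slow.cc_normalized,
                                                   abs=1e-9)

    def test_mirror_search_recovers_chirality(self, bundle, frame):
        target = simulate_map(bundle.mirrored(),
                              SimulationParams(6.0, 2.612), frame=frame)
        plain = fit_model(target, bundle, FitParams(step_deg=30.0))
        with_mirror = fit_model(target, bundle,
                                FitParams(step_deg=30.0, mirror=True))
        assert with_mirror.pose.mirrored
        assert with_mirror.cc_normalized >= 0.99
        assert with_mirror.cc_normalized > plain.cc_normalized

    def test_degenerate_target_rejected(self, bundle):
        empty = VoxelGrid(np.zeros((16, 16, 16)), 2.612)
        with pytest.raises(ValueError, match="degenerate"):
            fit_model(empty, bundle, FitParams())

    def test_laplacian_mode_runs_and_ranks_self_fit_high(self, bundle,
                                                         self_target):
        res = fit_model(self_target, bundle,
                        FitParams(step_deg=60.0, mode="laplacian"))
        assert res.cc_normalized >= 0.95
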