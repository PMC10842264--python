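"""Density I/O and map-conditioning utilities."""

import math

import numpy as np
import pytest
import scipy.fft as sfft
from hypothesis import given, settings
from hypothesis import strategies as st

from voxmatch import (
    MapFormatError,
    VoxelGrid,
    apply_cutoff,
    apply_edge_guard,
    autocrop,
    lowpass_filter,
    read_density,
    write_density,
)
from voxmatch.grid import lowpass_transfer


class TestVoxelGrid:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            VoxelGrid(np.zeros((2, 2, 2)), voxel_size=0.0)
        with pytest.raises(ValueError):
            VoxelGrid(np.full((2, 2, 2), np.nan), 1.0)
        with pytest.raises(ValueError):
            VoxelGrid(np.zeros((2, 2)), 1.0)

    def test_coordinate_frame(self):
        g = VoxelGrid(np.zeros((3, 3, 3)), 2.0, origin=(1.0, 0.0, -1.0))
        assert np.allclose(g.coordinate((1, 2, 0)), [3.0, 4.0, -1.0])


class TestDensityIO:
    def test_round_trip_identity(self, tmp_path, rng):
        values = rng.random((2, 2, 2)).astype(np.float32).astype(np.float64)
        g = VoxelGrid(values, 2.612, origin=(1.5, -2.0, 3.25))
        write_density(g, tmp_path / "m.mrc")
        back = read_density(tmp_path / "m.mrc")
        assert np.array_equal(back.values, g.values)
        assert back.dims == g.dims
        assert back.voxel_size == pytest.approx(2.612, rel=1e-6)
        assert np.allclose(back.origin, g.origin)

    def test_calibrated_pixel_size(self, tmp_path, rng):
        # 2.612 Å/voxel, the working pixel size of the tomographic maps
        g = VoxelGrid(rng.random((8, 8, 8)), 2.612)
        write_density(g, tmp_path / "m.mrc")
        assert read_density(tmp_path / "m.mrc").voxel_size == pytest.approx(
            2.612, rel=1e-6
        )

    def test_random_bytes_is_format_error(self, tmp_path, rng):
        p = tmp_path / "garbage.mrc"
        p.write_bytes(rng.bytes(512))
        with pytest.raises(MapFormatError):
            read_density(p)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_density(tmp_path / "absent.mrc")

    def test_non_float_mode_rejected(self, tmp_path, rng):
        p = tmp_path / "m.mrc"
        write_density(VoxelGrid(rng.random((4, 4, 4)), 1.0), p)
        raw = bytearray(p.read_bytes())
        raw[12:16] = (1).to_bytes(4, "little")  # MODE word -> int16
        p.write_bytes(bytes(raw))
        with pytest.raises(MapFormatError):
            read_density(p)

    def test_anisotropic_voxel_rejected(self, tmp_path):
        import gemmi

        g = gemmi.FloatGrid(np.zeros((4, 4, 4), dtype=np.float32))
        g.set_unit_cell(gemmi.UnitCell(4.0, 4.0, 8.0, 90, 90, 90))
        m = gemmi.Ccp4Map()
        m.grid = g
        m.update_ccp4_header()
        m.write_ccp4_map(str(tmp_path / "aniso.mrc"))
        with pytest.raises(MapFormatError, match="anisotropic"):
            read_density(tmp_path / "aniso.mrc")

    def test_nan_refused_on_write(self, tmp_path):
        g = VoxelGrid(np.ones((2, 2, 2)), 1.0)
        g.values[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            write_density(g, tmp_path / "bad.mrc")
        assert not (tmp_path / "bad.mrc").exists()


class TestCutoff:
    def test_threshold_semantics(self, rng):
        g = VoxelGrid(rng.uniform(0, 0.01, (6, 6, 6)), 1.0)
        out = apply_cutoff(g, 0.0048)
        assert (out.values[g.values <= 0.0048] == 0).all()
        above = g.values > 0.0048
        assert np.array_equal(out.values[above], g.values[above])

    def test_cutoff_below_minimum_is_identity(self, random_grid):
        out = apply_cutoff(random_grid, random_grid.values.min() - 1.0)
        assert np.array_equal(out.values, random_grid.values)

    def test_cutoff_above_maximum_zeroes_all(self, random_grid):
        out = apply_cutoff(random_grid, random_grid.values.max() + 1.0)
        assert not out.values.any()


class TestAutocrop:
    def test_margin_planes_removed(self):
        k = 2
        inner = np.ones((3, 4, 5))
        values = np.pad(inner, k)
        g = VoxelGrid(values, 2.0, origin=(0.0, 0.0, 0.0))
        out = autocrop(g, 0.5)
        assert out.dims == (3, 4, 5)
        # exhaustive-scan oracle for the bounding box
        idx = np.argwhere(values > 0.5)
        assert np.array_equal(idx.min(axis=0), [k, k, k])
        assert np.allclose(out.origin, g.origin + 2.0 * k)
        # physical coordinates preserved
        assert np.allclose(out.coordinate((0, 0, 0)), g.coordinate((k, k, k)))

    def test_corner_content_unchanged(self, random_grid):
        g = random_grid.copy()
        g.values += 1.0  # every voxel above cutoff
        out = autocrop(g, 0.5)
        assert out.dims == g.dims
        assert np.array_equal(out.values, g.values)

    def test_all_zero_is_error(self):
        with pytest.raises(ValueError):
            autocrop(VoxelGrid(np.zeros((4, 4, 4)), 1.0), 0.0)


class TestEdgeGuard:
    def test_guards_exceed_cutoff(self, random_grid):
        out = apply_edge_guard(random_grid, 0.0048)
        assert out.values[0, 0, 0] > 0.0048
        assert out.values[-1, -1, -1] > 0.0048

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(
        seed=st.integers(0, 2**16),
        cutoff=st.floats(-2.0, 2.0, allow_nan=False),
        dims=st.tuples(st.integers(1, 7), st.integers(1, 7),
                       st.integers(1, 7)),
    )
    def test_guard_makes_autocrop_dimension_preserving(self, seed, cutoff,
                                                       dims):
        rng = np.random.default_rng(seed)
        g = VoxelGrid(rng.normal(size=dims), 1.0)
        guarded = apply_edge_guard(g, cutoff)
        assert autocrop(guarded, cutoff).dims == g.dims

    def test_idempotent_in_dims(self, random_grid):
        once = apply_edge_guard(random_grid, 0.01)
        twice = apply_edge_guard(once, 0.01)
        assert autocrop(twice, 0.01).dims == random_grid.dims
        assert np.array_equal(twice.values, once.values)


class TestLowpass:
    def test_constant_grid_unchanged(self):
        g = VoxelGrid(np.full((8, 8, 8), 3.7), 2.0)
        out = lowpass_filter(g, 10.0)
        assert np.allclose(out.values, 3.7, atol=1e-12)

    def test_sinusoid_attenuation_matches_transfer_function(self):
        # periods 6 Å and 20 Å on a 60-voxel 1 Å grid, 10 Å filter
        n = 60
        x = np.arange(n)
        for period in (6.0, 20.0):
            vals = np.tile(
                np.sin(2 * np.pi * x / period)[:, None, None], (1, 4, 4)
            )
            g = VoxelGrid(vals, 1.0)
            out = lowpass_filter(g, 10.0)
            k = int(round(n / period))
            amp_in = np.abs(sfft.fftn(g.values)[k, 0, 0])
            amp_out = np.abs(sfft.fftn(out.values)[k, 0, 0])
            expected = lowpass_transfer(k / n, 10.0)
            assert amp_out / amp_in == pytest.approx(expected, abs=1e-6)

    def test_below_nyquist_rejected(self):
        g = VoxelGrid(np.zeros((8, 8, 8)), 2.612)
        with pytest.raises(ValueError):
            lowpass_filter(g, 5.0)

    def test_repeated_filtering_never_amplifies(self, random_grid):
        once = lowpass_filter(random_grid, 12.0)
        twice = lowpass_filter(once, 12.0)
        a1 = np.abs(sfft.rfftn(once.values))
        a2 = np.abs(sfft.rfftn(twice.values))
        assert (a2 <= a1 + 1e-12).all()

    def test_power_never_increases_and_dc_invariant(self, random_grid):
        out = lowpass_filter(random_grid, 10.0)
        assert (out.values**2).sum() <= (random_grid.values**2).sum()
        assert out.values.mean() == pytest.approx(
            random_grid.values.mean(), rel=1e-12
        )

    def test_raised_cosine_shape(self):
        assert lowpass_transfer(0.1, 10.0, "raised_cosine") == pytest.approx(
            0.5
        )
        assert lowpass_transfer(0.3, 10.0, "raised_cosine") == 0.0
        with pytest.raises(ValueError):
            lowpass_transfer(0.1, 10.0, "boxcar")
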