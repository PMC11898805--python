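import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hsiq.grid import SWIR, VNIR, WavelengthGrid, make_wavelength_grid
from hsiq.spectra_io import (
    HyperCube,
    ROIMask,
    calibrate_reflectance,
    extract_roi_mean,
    merge_sensor_bands,
    read_envi_cube,
    write_envi_cube,
)


def _cube(values, kind="raw", centers=None):
    values = np.asarray(values, dtype=float)
    if centers is None:
        centers = np.linspace(500, 2400, values.shape[2])
    return HyperCube(values=values, grid=WavelengthGrid(centers), kind=kind)


class TestEnviIO:
    @pytest.mark.parametrize("interleave", ["bil", "bip", "bsq"])
    @pytest.mark.parametrize("byte_order", [0, 1])
    def test_write_read_round_trip(self, tmp_path, rng, interleave, byte_order):
        cube = _cube(rng.random((3, 4, 5)))
        path = tmp_path / "cube.hdr"
        write_envi_cube(cube, path, interleave=interleave, byte_order=byte_order)
        back = read_envi_cube(path)
        assert np.allclose(back.values, cube.values)
        assert np.allclose(back.grid.centers, cube.grid.centers)

    def test_hand_constructed_bil_fixture(self, tmp_path):
        """2x2x3 BIL cube written byte-by-byte, independent of the writer."""
        # BIL layout: for each line, bands x samples
        values = np.arange(12, dtype="<f4").reshape(2, 3, 2)  # line, band, sample
        (tmp_path / "fix.img").write_bytes(values.tobytes())
        (tmp_path / "fix.hdr").write_text(
            "ENVI\nsamples = 2\nlines = 2\nbands = 3\ndata type = 4\n"
            "interleave = bil\nbyte order = 0\n"
            "wavelength = { 500.0, 1000.0, 1500.0 }\n"
        )
        cube = read_envi_cube(tmp_path / "fix.hdr")
        assert cube.values.shape == (2, 2, 3)
        assert cube.grid.sensor_tags == (VNIR, SWIR, SWIR)
        # pixel (0, 1): line 0, sample 1 across bands -> columns 1, 3, 5
        assert np.array_equal(cube.values[0, 1], [1.0, 3.0, 5.0])

    def test_header_without_wavelength_names_the_field(self, tmp_path):
        (tmp_path / "bad.img").write_bytes(b"\x00" * 8)
        (tmp_path / "bad.hdr").write_text(
            "ENVI\nsamples = 1\nlines = 1\nbands = 2\ndata type = 4\n"
            "interleave = bip\n"
        )
        with pytest.raises(ValueError, match="wavelength"):
            read_envi_cube(tmp_path / "bad.hdr")

    def test_band_count_mismatch_is_rejected(self, tmp_path):
        (tmp_path / "bad.img").write_bytes(b"\x00" * 8)
        (tmp_path / "bad.hdr").write_text(
            "ENVI\nsamples = 1\nlines = 1\nbands = 2\ndata type = 4\n"
            "interleave = bip\nwavelength = { 500.0 }\n"
        )
        with pytest.raises(ValueError, match="wavelength"):
            read_envi_cube(tmp_path / "bad.hdr")


class TestCalibration:
    def _frames(self, raw_fill, shape=(2, 2, 3)):
        black = _cube(np.full(shape, 10.0), "black")
        white = _cube(np.full(shape, 110.0), "white")
        raw = _cube(np.full(shape, raw_fill), "raw")
        return raw, white, black

    def test_raw_equal_black_gives_zero_reflectance(self):
        refl = calibrate_reflectance(*self._frames(10.0))
        assert np.allclose(refl.values, 0.0)
        assert refl.kind == "reflectance"

    def test_raw_equal_white_gives_unit_reflectance(self):
        refl = calibrate_reflectance(*self._frames(110.0))
        assert np.allclose(refl.values, 1.0)

    def test_hand_arithmetic_midpoint(self):
        refl = calibrate_reflectance(*self._frames(60.0))
        assert np.allclose(refl.values, 0.5)

    def test_coincident_references_error_names_bands(self):
        raw, white, black = self._frames(60.0)
        white.values[..., 1] = black.values[..., 1]
        with pytest.raises(ValueError, match=r"\[1\]"):
            calibrate_reflectance(raw, white, black)

    def test_wrong_kind_is_rejected(self):
        raw, white, black = self._frames(60.0)
        with pytest.raises(ValueError, match="kind"):
            calibrate_reflectance(white, raw, black)

    def test_affine_transform_of_all_frames_leaves_reflectance_unchanged(self, rng):
        """(a*x+b applied to raw/white/black) cancels in the ratio."""
        for _ in range(100):
            shape = (2, 3, 4)
            black = _cube(rng.random(shape), "black")
            white = _cube(black.values + 0.5 + rng.random(shape), "white")
            raw = _cube(
                black.values + rng.random(shape) * (white.values - black.values),
                "raw",
            )
            base = calibrate_reflectance(raw, white, black).values
            a = float(rng.uniform(0.5, 3.0))
            b = float(rng.uniform(-5, 5))
            scaled = calibrate_reflectance(
                _cube(a * raw.values + b, "raw"),
                _cube(a * white.values + b, "white"),
                _cube(a * black.values + b, "black"),
            ).values
            assert np.allclose(scaled, base, atol=1e-10)


class TestRoiMean:
    def test_constant_cube_returns_the_constant(self):
        cube = _cube(np.full((3, 3, 4), 0.7), "reflectance")
        mask = ROIMask(np.ones((3, 3), dtype=bool))
        assert np.allclose(extract_roi_mean(cube, mask), 0.7)

    def test_single_pixel_mask_returns_that_pixel(self, rng):
        cube = _cube(rng.random((3, 3, 4)), "reflectance")
        mask = np.zeros((3, 3), dtype=bool)
        mask[1, 2] = True
        assert np.array_equal(extract_roi_mean(cube, ROIMask(mask)), cube.values[1, 2])

    def test_two_pixel_mean_is_hand_mean(self):
        values = np.zeros((1, 2, 1))
        values[0, 0, 0], values[0, 1, 0] = 0.2, 0.4
        cube = _cube(values, "reflectance")
        mask = ROIMask(np.ones((1, 2), dtype=bool))
        assert np.allclose(extract_roi_mean(cube, mask), 0.3)

    def test_mean_is_pixel_permutation_invariant_and_linear(self, rng):
        values = rng.random((4, 4, 3))
        mask = ROIMask(rng.random((4, 4)) < 0.6)
        base = extract_roi_mean(_cube(values, "reflectance"), mask)
        # permute masked pixels among themselves
        perm_values = values.copy()
        idx = np.argwhere(mask.mask)
        shuffled = idx[rng.permutation(len(idx))]
        perm_values[tuple(idx.T)] = values[tuple(shuffled.T)]
        assert np.allclose(
            extract_roi_mean(_cube(perm_values, "reflectance"), mask), base
        )
        assert np.allclose(
            extract_roi_mean(_cube(0.5 * values, "reflectance"), mask), 0.5 * base
        )

    def test_empty_mask_and_wrong_kind_are_rejected(self, rng):
        cube = _cube(rng.random((2, 2, 3)), "reflectance")
        with pytest.raises(ValueError, match="no pixels"):
            extract_roi_mean(cube, ROIMask(np.zeros((2, 2), dtype=bool)))
        with pytest.raises(ValueError, match="reflectance"):
            extract_roi_mean(
                _cube(cube.values, "raw"), ROIMask(np.ones((2, 2), dtype=bool))
            )


class TestMergeSensorBands:
    def test_seam_band_taken_from_swir_only(self):
        vnir_grid = WavelengthGrid(np.array([410.0, 700.0, 990.0]))
        swir_grid = WavelengthGrid(np.array([990.0, 1500.0, 2500.0]))
        spec, grid = merge_sensor_bands(
            np.array([0.1, 0.2, 0.3]), vnir_grid,
            np.array([0.4, 0.5, 0.6]), swir_grid, boundary_nm=990.0,
        )
        assert np.array_equal(grid.centers, [410, 700, 990, 1500, 2500])
        assert spec[2] == 0.4  # SWIR's 990 nm reading, not VNIR's
        assert grid.sensor_tags == (VNIR, VNIR, SWIR, SWIR, SWIR)

    def test_seam_flag_flips_the_convention(self):
        vnir_grid = WavelengthGrid(np.array([410.0, 990.0]))
        swir_grid = WavelengthGrid(np.array([990.0, 2500.0]))
        spec, _ = merge_sensor_bands(
            np.array([0.1, 0.2]), vnir_grid, np.array([0.4, 0.5]), swir_grid,
            boundary_nm=990.0, seam_from_swir=False,
        )
        assert spec[1] == 0.2  # VNIR keeps the seam band

    def test_disjoint_grids_concatenate(self):
        vnir_grid = WavelengthGrid(np.array([450.0, 600.0]))
        swir_grid = WavelengthGrid(np.array([1200.0, 1800.0]))
        spec, grid = merge_sensor_bands(
            np.array([0.1, 0.2]), vnir_grid, np.array([0.3, 0.4]), swir_grid
        )
        assert np.array_equal(grid.centers, [450, 600, 1200, 1800])
        assert np.array_equal(spec, [0.1, 0.2, 0.3, 0.4])

    def test_fusion_of_overlapping_sensor_grids_yields_396_band_working_grid(self):
        """Sensor fixtures overlap around the seam; fusion drops the overlap."""
        working = make_wavelength_grid(396, (410, 2500), 990)
        n_vnir = int((working.centers < 990).sum())
        # VNIR camera sees a few bands past the seam, SWIR a few before it
        vnir_grid = WavelengthGrid(np.append(working.centers[:n_vnir],
                                             [995.0, 1005.0, 1015.0]))
        swir_grid = WavelengthGrid(np.append([960.0, 975.0],
                                             working.centers[n_vnir:]))
        vnir_spec = np.concatenate([np.full(n_vnir, 0.3), [0.9, 0.9, 0.9]])
        swir_spec = np.concatenate([[0.8, 0.8], np.full(396 - n_vnir, 0.5)])
        spec, grid = merge_sensor_bands(vnir_spec, vnir_grid, swir_spec, swir_grid)
        assert len(grid) == 396
        assert np.array_equal(grid.centers, working.centers)
        assert set(spec.tolist()) == {0.3, 0.5}

    def test_fusion_retaining_no_bands_is_rejected(self):
        vnir_grid = WavelengthGrid(np.array([1200.0, 1300.0]))  # all >= seam
        swir_grid = WavelengthGrid(np.array([500.0, 600.0]))    # all < seam
        with pytest.raises(ValueError, match="empty|monotone"):
            merge_sensor_bands(
                np.array([0.1, 0.2]), vnir_grid,
                np.array([0.3, 0.4]), swir_grid, boundary_nm=990.0,
            )


@given(st.integers(2, 30), st.integers(0, 10))
def test_merge_length_law(n_vnir, n_extra):
    """|fused| = |VNIR < seam| + |SWIR >= seam| for abutting uniform grids."""
    vnir = WavelengthGrid(np.linspace(410, 989, n_vnir))
    swir = WavelengthGrid(np.linspace(990, 2500, n_extra + 2))
    spec, grid = merge_sensor_bands(
        np.zeros(n_vnir), vnir, np.ones(n_extra + 2), swir, 990.0
    )
    assert len(grid) == n_vnir + n_extra + 2
    assert np.all(np.diff(grid.centers) > 0)
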