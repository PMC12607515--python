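"""Calibration, ROI geometry, band windowing and ENVI/CSV round-trips."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from milletnir.containers import SpectrumSet
from milletnir.instrument_io import (
    CalibrationFrames,
    HyperCube,
    RoiSpec,
    calibrate_reflectance,
    extract_mean_spectrum,
    generate_roi_pixel_grid,
    read_envi,
    subset_bands,
    write_envi,
)


def _cube(data, wl=None):
    data = np.asarray(data, dtype=float)
    wl = np.arange(data.shape[2]) + 1000.0 if wl is None else wl
    return HyperCube(data=data, wavelengths=wl)


class TestCalibration:
    def setup_method(self):
        self.white = np.array([4000.0, 5000.0, 4500.0])
        self.dark = np.array([100.0, 120.0, 90.0])
        self.frames = CalibrationFrames(white=self.white, dark=self.dark)

    def test_raw_equal_white_gives_one(self):
        raw = _cube(np.broadcast_to(self.white, (4, 5, 3)))
        out = calibrate_reflectance(raw, self.frames)
        np.testing.assert_allclose(out.data, 1.0)

    def test_raw_equal_dark_gives_zero(self):
        raw = _cube(np.broadcast_to(self.dark, (4, 5, 3)))
        out = calibrate_reflectance(raw, self.frames)
        np.testing.assert_allclose(out.data, 0.0)

    def test_midpoint_gives_half(self):
        raw = _cube(np.broadcast_to((self.white + self.dark) / 2, (2, 2, 3)))
        out = calibrate_reflectance(raw, self.frames)
        np.testing.assert_allclose(out.data, 0.5)

    def test_white_equal_dark_is_reported_with_location(self):
        frames = CalibrationFrames(
            white=np.array([4000.0, 120.0, 4500.0]), dark=self.dark
        )
        raw = _cube(np.zeros((2, 2, 3)))
        with pytest.raises(ValueError, match="band 1"):
            calibrate_reflectance(raw, frames)

    @given(gain=st.floats(min_value=0.1, max_value=100.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_common_gain_invariance(self, gain):
        rng = np.random.default_rng(3)
        raw_data = rng.uniform(200, 3000, size=(3, 3, 3))
        base = calibrate_reflectance(_cube(raw_data), self.frames)
        scaled = calibrate_reflectance(
            _cube(raw_data * gain),
            CalibrationFrames(white=self.white * gain, dark=self.dark * gain),
        )
        np.testing.assert_allclose(scaled.data, base.data, rtol=1e-9)


class TestRoi:
    def test_degenerate_ellipse_is_center_pixel(self):
        pixels = generate_roi_pixel_grid(
            RoiSpec(center=(10, 12), semi_axes=(0, 0)), (30, 30)
        )
        assert pixels == [(10, 12)]

    def test_circle_count_matches_brute_force(self):
        spec = RoiSpec(center=(15, 15), semi_axes=(5, 5))
        pixels = generate_roi_pixel_grid(spec, (31, 31))
        brute = [
            (r, c)
            for r in range(31)
            for c in range(31)
            if ((r - 15) / 5) ** 2 + ((c - 15) / 5) ** 2 <= 1
        ]
        assert pixels == brute  # also checks row-major order

    def test_swapped_axes_transpose(self):
        a = generate_roi_pixel_grid(RoiSpec((20, 20), (10, 5)), (41, 41))
        b = generate_roi_pixel_grid(RoiSpec((20, 20), (5, 10)), (41, 41))
        assert len(a) == len(b)
        assert sorted((c, r) for r, c in a) == sorted((r, c) for r, c in b)

    def test_stride_subsamples_lattice(self):
        full = generate_roi_pixel_grid(RoiSpec((15, 15), (6, 6)), (31, 31))
        strided = generate_roi_pixel_grid(
            RoiSpec((15, 15), (6, 6), axial_interval=2), (31, 31)
        )
        assert strided == [
            (r, c) for r, c in full if (r - 15) % 2 == 0 and (c - 15) % 2 == 0
        ]

    def test_overflow_reports_extent(self):
        with pytest.raises(ValueError, match="left by 3px"):
            generate_roi_pixel_grid(RoiSpec((10, 2), (5, 5)), (21, 21))


class TestMeanSpectrum:
    def test_uniform_cube(self):
        cube = _cube(np.full((4, 4, 3), 0.7))
        np.testing.assert_allclose(
            extract_mean_spectrum(cube, [(0, 0), (1, 2)]), 0.7
        )

    def test_two_pixel_average(self):
        data = np.zeros((2, 1, 3))
        data[1, 0, :] = 1.0
        cube = _cube(data)
        np.testing.assert_allclose(
            extract_mean_spectrum(cube, [(0, 0), (1, 0)]), 0.5
        )

    def test_pooled_mean_equals_mean_of_acquisition_means(self, rng):
        # three acquisitions x 2400 ROI pixels each = 7200 pooled pixels
        acquisitions = [rng.normal(0.5, 0.05, size=(2400, 10)) for _ in range(3)]
        pooled = np.vstack(acquisitions)
        assert pooled.shape[0] == 7200
        per_acq = np.mean([a.mean(axis=0) for a in acquisitions], axis=0)
        np.testing.assert_allclose(pooled.mean(axis=0), per_acq, rtol=1e-12)

    def test_permutation_invariance(self, rng):
        cube = _cube(rng.uniform(size=(5, 5, 4)))
        pixels = [(0, 0), (1, 3), (4, 4), (2, 2)]
        a = extract_mean_spectrum(cube, pixels)
        b = extract_mean_spectrum(cube, pixels[::-1])
        np.testing.assert_allclose(a, b)

    def test_empty_pixels_error(self):
        with pytest.raises(ValueError, match="empty"):
            extract_mean_spectrum(_cube(np.zeros((2, 2, 2))), [])


class TestSubsetBands:
    def _spectra(self, wl):
        wl = np.asarray(wl, dtype=float)
        return SpectrumSet(["a"], np.arange(wl.size)[None, :], wl)

    def test_count_on_coarse_grid(self):
        out = subset_bands(self._spectra(np.arange(900, 1701, 50)), 950, 1650)
        assert out.n_bands == 15  # multiples of 50 in [950, 1650]

    def test_full_span_is_identity(self):
        s = self._spectra(np.arange(900, 1701, 50))
        out = subset_bands(s, 900, 1700)
        np.testing.assert_array_equal(out.reflectance, s.reflectance)

    def test_default_grid_yields_148_bands(self, dataset):
        _, spectra = dataset
        out = subset_bands(spectra, 950, 1650)
        assert out.n_bands == 148

    def test_nested_subsets_compose(self):
        s = self._spectra(np.arange(900, 1701, 10))
        once = subset_bands(s, 1000, 1500)
        twice = subset_bands(subset_bands(s, 950, 1650), 1000, 1500)
        np.testing.assert_array_equal(once.wavelengths, twice.wavelengths)
        np.testing.assert_array_equal(once.reflectance, twice.reflectance)

    def test_empty_window_error(self):
        with pytest.raises(ValueError, match="no bands"):
            subset_bands(self._spectra([1000.0, 1100.0]), 1300, 1400)


class TestEnviRoundTrip:
    def test_bit_identical_round_trip(self, tmp_path, rng):
        cube = _cube(rng.uniform(size=(4, 6, 5)))
        hdr = write_envi(cube, tmp_path / "cube.img", interleave="bil")
        back = read_envi(hdr)
        np.testing.assert_array_equal(back.data, cube.data)
        np.testing.assert_allclose(back.wavelengths, cube.wavelengths, atol=1e-6)

    @pytest.mark.parametrize("interleave", ["bil", "bip", "bsq"])
    def test_interleaves_agree(self, tmp_path, rng, interleave):
        cube = _cube(rng.uniform(size=(3, 4, 6)))
        hdr = write_envi(cube, tmp_path / f"c_{interleave}.img", interleave=interleave)
        np.testing.assert_array_equal(read_envi(hdr).data, cube.data)

    def test_missing_wavelength_metadata_error(self, tmp_path, rng):
        cube = _cube(rng.uniform(size=(2, 2, 3)))
        hdr = write_envi(cube, tmp_path / "c.img")
        text = "\n".join(
            line for line in hdr.read_text().splitlines() if "wavelength" not in line
        )
        hdr.write_text(text)
        with pytest.raises(ValueError, match="wavelength"):
            read_envi(hdr)


class TestSpectraCsv:
    def test_round_trip(self, tmp_path, rng):
        s = SpectrumSet(
            ["a", "b"], rng.uniform(size=(2, 4)), np.array([950.0, 1000.0, 1050.0, 1100.0])
        )
        s.to_csv(tmp_path / "s.csv")
        back = SpectrumSet.from_csv(tmp_path / "s.csv")
        np.testing.assert_allclose(back.reflectance, s.reflectance)
        assert back.sample_ids == s.sample_ids

    def test_single_row(self, tmp_path):
        s = SpectrumSet(["only"], [[0.1, 0.2]], np.array([1000.0, 1001.0]))
        s.to_csv(tmp_path / "one.csv")
        assert SpectrumSet.from_csv(tmp_path / "one.csv").n_samples == 1

    def test_malformed_header_error(self, tmp_path):
        (tmp_path / "bad.csv").write_text("foo,1000\nx,0.5\n")
        with pytest.raises(ValueError, match="sample_id"):
            SpectrumSet.from_csv(tmp_path / "bad.csv")
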