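"""Cube handling, panel calibration, ROI segmentation and table I/O."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spectrograin.dataset import SpectrumSet
from spectrograin.exceptions import (
    CalibrationError,
    InvalidArgumentError,
    SegmentationError,
    SpectraParseError,
)
from spectrograin.spectra_io import (
    HypercubeImage,
    PanelCalibration,
    average_sides,
    convert_reflectance,
    extract_roi_mean,
    read_envi_cube,
    read_spectra_table,
    write_spectra_table,
)
from spectrograin.synthetic import SyntheticConfig, generate_dataset


class TestConvertReflectance:
    def test_identity_when_dn_equals_panel(self):
        cal = PanelCalibration(dn_panel=[100.0, 200.0], r_panel=[0.5, 0.6])
        assert convert_reflectance([100, 200], cal) == pytest.approx([0.5, 0.6])

    def test_zero_dn_gives_zero(self):
        cal = PanelCalibration(dn_panel=[100.0], r_panel=[0.5])
        assert convert_reflectance([0.0], cal) == pytest.approx([0.0])

    def test_direct_evaluation(self):
        cal = PanelCalibration(dn_panel=[100.0], r_panel=[0.5])
        assert convert_reflectance([50.0], cal) == pytest.approx([0.25])

    def test_zero_panel_dn_rejected(self):
        with pytest.raises(CalibrationError):
            PanelCalibration(dn_panel=[0.0], r_panel=[0.5])

    def test_length_mismatch(self):
        cal = PanelCalibration(dn_panel=[100.0, 100.0], r_panel=[0.5, 0.5])
        with pytest.raises(InvalidArgumentError):
            convert_reflectance([50.0], cal)

    def test_dark_subtraction(self):
        cal = PanelCalibration(dn_panel=[110.0], r_panel=[0.5])
        # (60-10)/(110-10)*0.5 = 0.25
        assert convert_reflectance([60.0], cal, dark=np.array([10.0])) == pytest.approx(
            [0.25]
        )

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        k=st.floats(min_value=0, max_value=100),
        dn=st.lists(st.floats(min_value=0, max_value=1e4), min_size=1, max_size=8),
    )
    def test_homogeneity_in_dn(self, k, dn):
        dn = np.asarray(dn)
        cal = PanelCalibration(
            dn_panel=np.full(dn.size, 500.0), r_panel=np.full(dn.size, 0.5)
        )
        lhs = convert_reflectance(k * dn, cal)
        rhs = k * convert_reflectance(dn, cal)
        np.testing.assert_allclose(lhs, rhs, rtol=1e-12, atol=1e-12)


class TestRoiExtraction:
    def _cube(self, frame: np.ndarray, n_bands: int = 4) -> HypercubeImage:
        dn = np.repeat(frame[:, :, None], n_bands, axis=2).astype(float)
        wl = np.linspace(400, 900, n_bands)
        return HypercubeImage(dn=dn, wavelengths=wl)

    def test_uniform_cube(self):
        cube = self._cube(np.full((6, 6), 10.0))
        mean, mask = extract_roi_mean(cube, threshold_band=650, threshold=5)
        assert mask.all()
        assert mean == pytest.approx([10.0] * 4)

    def test_single_bright_square(self):
        frame = np.zeros((8, 8))
        frame[2:5, 3:6] = 100.0
        cube = self._cube(frame)
        mean, mask = extract_roi_mean(cube, threshold_band=650, threshold=50)
        assert mask.sum() == 9
        assert mean == pytest.approx([100.0] * 4)

    def test_largest_component_wins(self):
        """Two bright components: only the larger becomes the ROI (checked
        against a brute-force flood fill)."""
        frame = np.zeros((10, 10))
        frame[1:4, 1:4] = 80.0  # 9 px
        frame[6:8, 6:8] = 120.0  # 4 px
        cube = self._cube(frame)
        mean, mask = extract_roi_mean(cube, threshold_band=650, threshold=50)
        # brute-force 4-connected flood fill from every bright pixel
        bright = frame > 50
        seen, components = set(), []
        for start in zip(*np.nonzero(bright)):
            if start in seen:
                continue
            stack, comp = [start], set()
            while stack:
                r, c = stack.pop()
                if (r, c) in comp or not (0 <= r < 10 and 0 <= c < 10) or not bright[r, c]:
                    continue
                comp.add((r, c))
                stack += [(r + 1, c), (r - 1, c), (r, c + 1), (r, c - 1)]
            seen |= comp
            components.append(comp)
        largest = max(components, key=len)
        assert {tuple(p) for p in np.argwhere(mask)} == largest
        assert mean == pytest.approx([80.0] * 4)

    def test_padding_invariance(self):
        frame = np.zeros((6, 6))
        frame[2:4, 2:4] = 90.0
        cube = self._cube(frame)
        padded = self._cube(np.pad(frame, 3))
        m1, _ = extract_roi_mean(cube, 650, 50)
        m2, _ = extract_roi_mean(padded, 650, 50)
        np.testing.assert_allclose(m1, m2)

    def test_empty_mask_names_threshold(self):
        cube = self._cube(np.zeros((4, 4)))
        with pytest.raises(SegmentationError, match="99"):
            extract_roi_mean(cube, threshold_band=650, threshold=99)

    def test_band_outside_range(self):
        cube = self._cube(np.ones((4, 4)))
        with pytest.raises(InvalidArgumentError):
            extract_roi_mean(cube, threshold_band=2000, threshold=0)


class TestAverageSides:
    def test_equal_sides(self):
        v = np.array([0.1, 0.2, 0.3])
        np.testing.assert_allclose(average_sides(v, v), v)

    def test_zero_front(self):
        v = np.array([0.4, 0.8])
        np.testing.assert_allclose(average_sides(np.zeros(2), v), v / 2)

    def test_elementwise_mean(self):
        out = average_sides(np.array([0.2, 0.4]), np.array([0.4, 0.2]))
        np.testing.assert_allclose(out, [0.3, 0.3])

    def test_length_mismatch(self):
        with pytest.raises(InvalidArgumentError):
            average_sides(np.zeros(3), np.zeros(4))


class TestSpectraTable:
    def test_round_trip(self, tmp_path):
        sset = generate_dataset(
            SyntheticConfig(n_classes=3, samples_per_class=4, n_bands=16, rng_seed=1)
        )
        path = tmp_path / "spectra.csv"
        write_spectra_table(sset, path)
        back = read_spectra_table(path)
        np.testing.assert_allclose(back.reflectance, sset.reflectance, rtol=1e-10)
        np.testing.assert_allclose(back.wavelengths, sset.wavelengths, rtol=1e-10)
        assert np.array_equal(back.labels.astype(str), sset.labels.astype(str))
        assert np.array_equal(back.sample_ids, sset.sample_ids)

    def test_empty_table_rejected(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("sample_id,label,500.00,600.00\n")
        with pytest.raises(SpectraParseError, match="no samples"):
            read_spectra_table(path)

    def test_nan_cell_cited(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "sample_id,label,500.00,600.00\ns0,a,0.1,0.2\ns1,a,,0.3\n"
        )
        with pytest.raises(SpectraParseError, match="s1"):
            read_spectra_table(path)

    def test_duplicate_ids_rejected(self, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text("sample_id,label,500.00\ns0,a,0.1\ns0,b,0.2\n")
        with pytest.raises(SpectraParseError, match="duplicate"):
            read_spectra_table(path)

    def test_non_numeric_band_column(self, tmp_path):
        path = tmp_path / "col.csv"
        path.write_text("sample_id,label,banana\ns0,a,0.1\n")
        with pytest.raises(SpectraParseError, match="banana"):
            read_spectra_table(path)

    def test_missing_label_column(self, tmp_path):
        path = tmp_path / "nolabel.csv"
        path.write_text("sample_id,500.00\ns0,0.1\n")
        with pytest.raises(SpectraParseError, match="label"):
            read_spectra_table(path)


class TestEnviReader:
    @pytest.mark.parametrize("interleave", ["bsq", "bil", "bip"])
    @pytest.mark.parametrize("dtype_code,np_dtype", [(4, np.float32), (12, np.uint16)])
    def test_reads_all_layouts(self, tmp_path, interleave, dtype_code, np_dtype):
        rng = np.random.default_rng(0)
        lines, samples, bands = 3, 4, 5
        cube = (
            rng.uniform(0, 100, size=(lines, samples, bands)).astype(np_dtype)
            if dtype_code == 4
            else rng.integers(0, 1000, size=(lines, samples, bands)).astype(np_dtype)
        )
        if interleave == "bsq":
            raw = cube.transpose(2, 0, 1)
        elif interleave == "bil":
            raw = cube.transpose(0, 2, 1)
        else:
            raw = cube
        data = tmp_path / "scene.raw"
        raw.astype(np_dtype).tofile(data)
        wl = np.linspace(400, 900, bands)
        (tmp_path / "scene.hdr").write_text(
            "ENVI\n"
            f"samples = {samples}\nlines = {lines}\nbands = {bands}\n"
            f"data type = {dtype_code}\ninterleave = {interleave}\n"
            "byte order = 0\nheader offset = 0\n"
            "wavelength = {" + ", ".join(f"{w:.1f}" for w in wl) + "}\n"
        )
        img = read_envi_cube(tmp_path / "scene.hdr")
        np.testing.assert_allclose(img.dn, cube.astype(float))
        np.testing.assert_allclose(img.wavelengths, wl)

    def test_missing_magic(self, tmp_path):
        p = tmp_path / "bad.hdr"
        p.write_text("samples = 2\n")
        with pytest.raises(SpectraParseError, match="ENVI"):
            read_envi_cube(p)

    def test_unsupported_dtype(self, tmp_path):
        (tmp_path / "x.raw").write_bytes(b"\x00" * 8)
        p = tmp_path / "x.hdr"
        p.write_text(
            "ENVI\nsamples = 1\nlines = 1\nbands = 1\ndata type = 5\n"
            "interleave = bsq\nwavelength = {500.0}\n"
        )
        with pytest.raises(SpectraParseError, match="data type"):
            read_envi_cube(p)


class TestSpectrumSetValidation:
    def test_rejects_non_ascending_wavelengths(self):
        with pytest.raises(InvalidArgumentError):
            SpectrumSet(
                reflectance=np.ones((2, 3)),
                wavelengths=[500, 400, 600],
                labels=["a", "b"],
            )

    def test_rejects_nan(self):
        with pytest.raises(InvalidArgumentError):
            SpectrumSet(
                reflectance=np.array([[0.1, np.nan]]),
                wavelengths=[500, 600],
                labels=["a"],
            )

    def test_label_count_must_match(self):
        with pytest.raises(InvalidArgumentError):
            SpectrumSet(
                reflectance=np.ones((2, 2)),
                wavelengths=[500, 600],
                labels=["a"],
            )
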