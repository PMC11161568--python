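"""Spectrum IO, normalization, resampling, peak finding and selectivity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helicoid import (
    CellSpectrumPair,
    Spectrum,
    analyze_pair,
    classify_colour_bin,
    cp_selectivity,
    find_peak,
    normalize_to_reference,
    read_spectrum,
    resample_to_common_grid,
    summarize_cells,
)
from helicoid.spectra import COLOUR_BINS, PeakResult


def make_spectrum(w, r, channel="LCP", cell_id="c"):
    return Spectrum(np.asarray(w, float), np.asarray(r, float), channel, cell_id)


class TestReadSpectrum:
    def test_reads_two_columns(self, tmp_path):
        f = tmp_path / "cell1_LCP.csv"
        f.write_text("wavelength_nm,reflectance\n450,0.1\n460,0.2\n")
        s = read_spectrum(f)
        assert len(s) == 2
        assert s.channel == "LCP"
        assert s.cell_id == "cell1"

    @pytest.mark.parametrize("sep", [",", "\t", "  "])
    def test_delimiters(self, tmp_path, sep):
        f = tmp_path / "x_RCP.txt"
        f.write_text(f"450{sep}0.1\n460{sep}0.2\n")
        s = read_spectrum(f)
        assert s.channel == "RCP"
        np.testing.assert_allclose(s.wavelengths, [450, 460])

    def test_sorts_out_of_order_rows(self, tmp_path):
        f = tmp_path / "s.csv"
        f.write_text("500,0.3\n450,0.1\n470,0.2\n")
        s = read_spectrum(f)
        np.testing.assert_allclose(s.wavelengths, [450, 470, 500])
        np.testing.assert_allclose(s.reflectance, [0.1, 0.2, 0.3])

    def test_duplicate_wavelength_named_in_error(self, tmp_path):
        f = tmp_path / "s.csv"
        f.write_text("500,0.1\n510,0.2\n500,0.3\n")
        with pytest.raises(ValueError, match="500"):
            read_spectrum(f)

    def test_empty_file_rejected(self, tmp_path):
        f = tmp_path / "s.csv"
        f.write_text("\n")
        with pytest.raises(ValueError, match="empty"):
            read_spectrum(f)

    def test_non_numeric_row_rejected(self, tmp_path):
        f = tmp_path / "s.csv"
        f.write_text("450,0.1\noops,xx\n")
        with pytest.raises(ValueError, match="non-numeric"):
            read_spectrum(f)


class TestNormalize:
    w = np.arange(400.0, 500.0, 10.0)

    def test_raw_equals_white_gives_ones(self):
        raw = make_spectrum(self.w, np.full_like(self.w, 0.8))
        white = make_spectrum(self.w, np.full_like(self.w, 0.8))
        dark = make_spectrum(self.w, np.zeros_like(self.w))
        out = normalize_to_reference(raw, white, dark)
        np.testing.assert_allclose(out.reflectance, 1.0)

    def test_raw_equals_dark_gives_zeros(self):
        dark = make_spectrum(self.w, np.full_like(self.w, 0.05))
        white = make_spectrum(self.w, np.full_like(self.w, 0.9))
        out = normalize_to_reference(dark, white, dark)
        np.testing.assert_allclose(out.reflectance, 0.0)

    def test_midway_gives_half(self):
        dark = make_spectrum(self.w, np.full_like(self.w, 0.1))
        white = make_spectrum(self.w, np.full_like(self.w, 0.9))
        mid = make_spectrum(self.w, np.full_like(self.w, 0.5))
        out = normalize_to_reference(mid, white, dark)
        np.testing.assert_allclose(out.reflectance, 0.5)

    def test_white_below_dark_rejected(self):
        white = make_spectrum(self.w, np.zeros_like(self.w))
        dark = make_spectrum(self.w, np.full_like(self.w, 0.1))
        raw = make_spectrum(self.w, np.full_like(self.w, 0.5))
        with pytest.raises(ValueError, match="white <= dark"):
            normalize_to_reference(raw, white, dark)


class TestResample:
    def test_identical_grids_returned_unchanged(self):
        w = np.arange(400.0, 500.0, 5.0)
        pair = CellSpectrumPair(make_spectrum(w, w * 0 + 0.2), make_spectrum(w, w * 0 + 0.1, "RCP"))
        out = resample_to_common_grid(pair)
        np.testing.assert_array_equal(out.lcp.reflectance, pair.lcp.reflectance)

    def test_half_step_offset_matches_hand_interpolation(self):
        # 3-point spectra offset by half a step; oracle interpolated by hand
        lcp = make_spectrum([400.0, 410.0, 420.0], [0.0, 1.0, 0.0])
        rcp = make_spectrum([405.0, 415.0, 425.0], [0.2, 0.6, 0.2], "RCP")
        out = resample_to_common_grid(CellSpectrumPair(lcp, rcp), step_nm=5.0)
        np.testing.assert_allclose(out.lcp.wavelengths, [405.0, 410.0, 415.0, 420.0])
        # hand-computed linear interpolation
        np.testing.assert_allclose(out.lcp.reflectance, [0.5, 1.0, 0.5, 0.0])
        np.testing.assert_allclose(out.rcp.reflectance, [0.2, 0.4, 0.6, 0.4])

    def test_disjoint_ranges_rejected(self):
        lcp = make_spectrum([400.0, 410.0, 420.0], [0, 1, 0])
        rcp = make_spectrum([600.0, 610.0, 620.0], [0, 1, 0], "RCP")
        with pytest.raises(ValueError, match="overlap"):
            resample_to_common_grid(CellSpectrumPair(lcp, rcp), step_nm=5.0)


class TestFindPeak:
    def test_flat_spectrum_undefined(self):
        w = np.arange(400.0, 800.0, 10.0)
        s = make_spectrum(w, np.full_like(w, 0.3))
        _, _, prom, defined = find_peak(s)
        assert prom == 0.0 and not defined

    def test_tie_break_lowest_wavelength(self):
        w = np.arange(400.0, 801.0, 20.0)
        r = np.zeros_like(w)
        r[w == 460.0] = 1.0
        r[w == 520.0] = 1.0
        peak_w, _, _, _ = find_peak(make_spectrum(w, r), smooth_window=1)
        assert peak_w == 460.0

    def test_too_few_samples_rejected(self):
        s = make_spectrum([400.0, 500, 600, 700], [0, 1, 0, 0])
        with pytest.raises(ValueError, match="fewer than 5"):
            find_peak(s)

    def test_boundary_maximum_not_a_peak(self):
        w = np.arange(400.0, 801.0, 10.0)
        s = make_spectrum(w, np.linspace(1.0, 0.0, w.size))  # max at range edge
        _, _, prom, defined = find_peak(s, smooth_window=1)
        assert prom == 0.0 and not defined

    @settings(derandomize=True, deadline=None, max_examples=30)
    @given(offset=st.floats(min_value=-0.2, max_value=0.5))
    def test_offset_invariance(self, offset):
        w = np.arange(400.0, 801.0, 5.0)
        base = 0.1 + 0.7 * np.exp(-0.5 * ((w - 520.0) / 15.0) ** 2)
        p0 = find_peak(make_spectrum(w, base))
        p1 = find_peak(make_spectrum(w, np.clip(base + offset, None, None)))
        assert p0[0] == p1[0]
        assert p0[2] == pytest.approx(p1[2], abs=1e-12)


class TestSelectivity:
    def _pair(self, l_val, r_val):
        w = np.arange(400.0, 801.0, 5.0)
        l = 0.02 + l_val * np.exp(-0.5 * ((w - 480.0) / 10.0) ** 2)
        r = np.full_like(w, 0.02) + r_val * np.exp(-0.5 * ((w - 480.0) / 10.0) ** 2)
        return CellSpectrumPair(make_spectrum(w, l), make_spectrum(w, r, "RCP"))

    def test_strong_band_is_selective(self):
        ratio, docp, sel, dom, _ = cp_selectivity(self._pair(0.8, 0.08), 480.0)
        assert dom == "LCP" and sel
        assert ratio > 2.0 and docp > 0.5

    def test_equal_channels_not_selective(self):
        w = np.arange(400.0, 801.0, 5.0)
        y = 0.02 + 0.5 * np.exp(-0.5 * ((w - 480.0) / 10.0) ** 2)
        pair = CellSpectrumPair(make_spectrum(w, y), make_spectrum(w, y.copy(), "RCP"))
        ratio, docp, sel, _, _ = cp_selectivity(pair, 480.0)
        assert docp == pytest.approx(0.0)
        assert ratio == pytest.approx(1.0)
        assert not sel

    def test_window_arithmetic(self):
        # flat channels: L = 0.8, R = 0.1 -> ratio 8, docp 7/9
        w = np.arange(400.0, 801.0, 5.0)
        pair = CellSpectrumPair(
            make_spectrum(w, np.full_like(w, 0.8)), make_spectrum(w, np.full_like(w, 0.1), "RCP")
        )
        ratio, docp, _, dom, _ = cp_selectivity(pair, 480.0)
        assert ratio == pytest.approx(8.0)
        assert docp == pytest.approx(0.7 / 0.9)
        assert dom == "LCP"

    @settings(derandomize=True, deadline=None, max_examples=25)
    @given(scale=st.floats(min_value=0.05, max_value=1.2))
    def test_scale_invariance_of_ratio_and_docp(self, scale):
        pair = self._pair(0.8, 0.08)
        scaled = CellSpectrumPair(
            make_spectrum(pair.lcp.wavelengths, pair.lcp.reflectance * scale),
            make_spectrum(pair.rcp.wavelengths, pair.rcp.reflectance * scale, "RCP"),
        )
        r0, d0, *_ = cp_selectivity(pair, 480.0)
        r1, d1, *_ = cp_selectivity(scaled, 480.0)
        assert r1 == pytest.approx(r0, rel=1e-9)
        assert d1 == pytest.approx(d0, rel=1e-9)


class TestColourBins:
    @pytest.mark.parametrize(
        "lam, bin_", [(478.0, "blue"), (536.0, "green"), (450.0, "blue"), (420.0, "violet"), (600.0, "long")]
    )
    def test_assignments(self, lam, bin_):
        assert classify_colour_bin(lam) == bin_

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_colour_bin(399.0)

    @settings(derandomize=True, deadline=None)
    @given(lam=st.floats(min_value=400.0, max_value=800.0))
    def test_bins_partition_range(self, lam):
        assert classify_colour_bin(lam) in {name for name, *_ in COLOUR_BINS}

    def test_bin_edges_contiguous(self):
        edges = [lo for _, lo, _ in COLOUR_BINS] + [COLOUR_BINS[-1][2]]
        assert edges == sorted(edges)
        for (_, _, hi), (_, lo, _) in zip(COLOUR_BINS, COLOUR_BINS[1:]):
            assert hi == lo


class TestSummarize:
    def _result(self, lam):
        return PeakResult(
            cell_id="c", peak_wavelength_nm=lam, peak_reflectance=0.9, prominence=0.8,
            selectivity_ratio=5.0, docp=0.7, colour_bin="blue", is_selective=True,
            dominant_channel="LCP",
        )

    def test_mean_and_sample_sd(self):
        s = summarize_cells([self._result(x) for x in (470.0, 480.0, 490.0)])
        assert s.mean_peak_nm == pytest.approx(480.0)
        assert s.sd_peak_nm == pytest.approx(10.0)  # n-1 denominator
        assert s.n_cells == 3

    def test_single_cell_flagged(self):
        s = summarize_cells([self._result(480.0)])
        assert s.sd_peak_nm == 0.0
        assert "n=1" in s.flags

    def test_no_defined_peaks_rejected(self):
        r = self._result(480.0)
        r.peak_defined = False
        with pytest.raises(ValueError):
            summarize_cells([r])
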