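import numpy as np
import pytest

from glycomig.spectra import (
    CalibrationError,
    Peak,
    Spectrum,
    SpectrumFormatError,
    internal_calibrate,
    pick_peaks,
    read_spectrum,
    tophat_baseline,
    window_filter,
    write_spectrum,
)


# ---------------------------------------------------------------- ingest


class TestReadSpectrum:
    def test_three_row_text(self, tmp_path):
        p = tmp_path / "s.txt"
        p.write_text("2600 0.1\n2601 0.2\n2602 0.1\n")
        s = read_spectrum(p)
        assert len(s) == 3
        assert s.mz.tolist() == [2600.0, 2601.0, 2602.0]

    def test_comma_and_comments(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("# header\n2600,0.1\n\n2601, 0.2\n")
        s = read_spectrum(p)
        assert len(s) == 2

    def test_empty_file_errors(self, tmp_path):
        p = tmp_path / "empty.txt"
        p.write_text("")
        with pytest.raises(SpectrumFormatError):
            read_spectrum(p)

    def test_shuffled_rows_sorted_on_read(self, tmp_path):
        rng = np.random.default_rng(0)
        mz = np.arange(2000.0, 2050.0)
        inten = rng.random(mz.size)
        order = rng.permutation(mz.size)
        sorted_file = tmp_path / "a.txt"
        shuffled_file = tmp_path / "b.txt"
        sorted_file.write_text("".join(f"{m} {i}\n" for m, i in zip(mz, inten)))
        shuffled_file.write_text(
            "".join(f"{mz[j]} {inten[j]}\n" for j in order)
        )
        a, b = read_spectrum(sorted_file), read_spectrum(shuffled_file)
        np.testing.assert_array_equal(a.mz, b.mz)
        np.testing.assert_array_equal(a.intensity, b.intensity)

    def test_duplicate_mz_errors(self, tmp_path):
        p = tmp_path / "d.txt"
        p.write_text("2600 0.1\n2600 0.2\n2601 0.3\n")
        with pytest.raises(SpectrumFormatError):
            read_spectrum(p)

    def test_malformed_row_errors(self, tmp_path):
        p = tmp_path / "m.txt"
        p.write_text("2600 0.1 7\n")
        with pytest.raises(SpectrumFormatError):
            read_spectrum(p)

    def test_write_read_round_trip(self, tmp_path):
        s = Spectrum(np.arange(2000.0, 2010.0, 0.5), np.linspace(0, 1, 20))
        path = tmp_path / "rt.txt"
        write_spectrum(s, path)
        back = read_spectrum(path)
        np.testing.assert_allclose(back.mz, s.mz, atol=1e-4)
        np.testing.assert_allclose(back.intensity, s.intensity, atol=1e-6)


# ---------------------------------------------------------------- top-hat


def brute_force_opening(y: np.ndarray, n: int) -> np.ndarray:
    """Independent moving-min-then-moving-max with edge clipping."""
    h = n // 2
    eroded = np.array([y[max(0, i - h): i + h + 1].min() for i in range(y.size)])
    return np.array([eroded[max(0, i - h): i + h + 1].max() for i in range(y.size)])


class TestTophat:
    def test_constant_becomes_zero(self, make_spectrum):
        s = make_spectrum([], [], baseline=lambda g: np.full(g.size, 3.7))
        out = tophat_baseline(s, 20.0)
        np.testing.assert_allclose(out.intensity, 0.0, atol=1e-12)

    def test_matches_brute_force_oracle(self, make_spectrum):
        s = make_spectrum([2602.1, 2700.0], [1.0, 0.4],
                          baseline=lambda g: 0.05 * np.exp(-(g - 2300) / 600),
                          noise_sd=0.01, seed=3)
        out = tophat_baseline(s, 20.0)
        n = max(int(round(20.0 / np.median(np.diff(s.mz)))) | 1, 3)
        expected = s.intensity - brute_force_opening(s.intensity, n)
        np.testing.assert_allclose(out.intensity, expected, atol=1e-12)

    def test_gaussian_height_preserved(self, make_spectrum):
        s = make_spectrum([2602.1], [1.0])
        out = tophat_baseline(s, 20.0)
        assert out.intensity.max() == pytest.approx(1.0, rel=0.01)

    def test_gaussian_on_ramp(self, make_spectrum):
        s = make_spectrum([2602.1], [1.0], baseline=lambda g: 1e-4 * (g - 2300.0))
        out = tophat_baseline(s, 20.0)
        assert out.intensity.max() == pytest.approx(1.0, rel=0.02)

    def test_nonnegative_output(self, make_spectrum):
        s = make_spectrum([2500.0], [0.5], baseline=lambda g: 0.1 * np.sin(g / 200.0) + 0.2)
        out = tophat_baseline(s, 20.0)
        assert (out.intensity >= -1e-12).all()

    def test_idempotent(self, make_spectrum):
        s = make_spectrum([2602.1, 2634.0], [1.0, 0.5],
                          baseline=lambda g: 0.05 * np.exp(-(g - 2300) / 600))
        once = tophat_baseline(s, 20.0)
        twice = tophat_baseline(once, 20.0)
        np.testing.assert_allclose(twice.intensity, once.intensity, atol=1e-12)

    def test_window_below_spacing_errors(self, make_spectrum):
        s = make_spectrum([2602.1], [1.0])
        with pytest.raises(ValueError):
            tophat_baseline(s, 0.01)


# ---------------------------------------------------------------- peak picking


def brute_force_local_maxima(y: np.ndarray, threshold: float) -> list[int]:
    """Strict local maxima; plateaus resolved to their midpoint."""
    out = []
    i = 1
    while i < y.size - 1:
        if y[i] > y[i - 1]:
            j = i
            while j < y.size - 1 and y[j + 1] == y[j]:
                j += 1
            if j < y.size - 1 and y[j + 1] < y[j] and y[i] >= threshold:
                out.append((i + j) // 2)
            i = j + 1
        else:
            i += 1
    return out


class TestPickPeaks:
    def test_below_threshold_empty(self, make_spectrum):
        s = make_spectrum([2602.1], [0.04])
        assert pick_peaks(s, 0.050) == []

    def test_single_gaussian(self, make_spectrum):
        s = make_spectrum([2602.1], [1.0])
        peaks = pick_peaks(s, 0.050)
        assert len(peaks) == 1
        assert abs(peaks[0].mz - 2602.1) < 0.05
        assert peaks[0].height == pytest.approx(1.0, rel=0.01)

    def test_two_gaussians_six_da_apart(self, make_spectrum):
        s = make_spectrum([2602.0, 2608.0], [1.0, 0.8])
        peaks = pick_peaks(s, 0.050)
        assert len(peaks) == 2

    def test_matches_brute_force_oracle(self, make_spectrum):
        s = make_spectrum([2500.0, 2510.0, 2520.0], [0.3, 0.6, 0.1],
                          noise_sd=0.01, seed=11)
        picked = pick_peaks(s, 0.050)
        oracle_idx = brute_force_local_maxima(s.intensity, 0.050)
        assert len(picked) == len(oracle_idx)
        for p, i in zip(picked, oracle_idx):
            assert abs(p.mz - s.mz[i]) <= 0.1  # within one grid step of the apex

    def test_plateau_resolved_to_midpoint(self):
        y = np.array([0.0, 0.1, 1.0, 1.0, 1.0, 0.1, 0.0])
        s = Spectrum(np.arange(7, dtype=float), y)
        peaks = pick_peaks(s, 0.05)
        assert len(peaks) == 1
        assert peaks[0].mz == 3.0

    def test_heights_at_least_threshold(self, make_spectrum):
        s = make_spectrum([2450, 2500, 2550, 2600], [0.06, 0.2, 0.04, 1.0],
                          noise_sd=0.005, seed=2)
        for p in pick_peaks(s, 0.050):
            assert p.height >= 0.050

    def test_count_nonincreasing_in_threshold(self, make_spectrum):
        s = make_spectrum([2450, 2500, 2550], [0.06, 0.2, 1.0], noise_sd=0.01, seed=5)
        counts = [len(pick_peaks(s, t)) for t in (0.0, 0.05, 0.1, 0.5, 2.0)]
        assert counts == sorted(counts, reverse=True)


# ---------------------------------------------------------------- windowing


class TestWindowFilter:
    def test_basic(self):
        peaks = [Peak(2400, 1.0), Peak(2600, 1.0), Peak(3600, 1.0)]
        kept = window_filter(peaks, 2450, 3500)
        assert [p.mz for p in kept] == [2600]

    def test_empty_input(self):
        assert window_filter([], 2450, 3500) == []

    def test_identity_window(self):
        peaks = [Peak(2400, 1.0), Peak(3600, 1.0)]
        assert window_filter(peaks, 0, np.inf) == peaks

    def test_inclusive_bounds(self):
        peaks = [Peak(2450.0, 1.0), Peak(3500.0, 1.0)]
        assert window_filter(peaks, 2450, 3500) == peaks

    def test_bad_window_errors(self):
        with pytest.raises(ValueError):
            window_filter([], 3500, 2450)


# ---------------------------------------------------------------- calibration


CALS = [2602.05602, 2796.09868, 2958.1515, 3217.25708]


def lsq_affine_oracle(obs, theo):
    """Closed-form 2-parameter least squares."""
    obs = np.asarray(obs)
    theo = np.asarray(theo)
    A = np.column_stack([obs, np.ones_like(obs)])
    coef, *_ = np.linalg.lstsq(A, theo, rcond=None)
    return coef  # slope, offset


class TestInternalCalibrate:
    def test_identity(self):
        peaks = [Peak(m, 1.0) for m in CALS]
        out, fit = internal_calibrate(peaks, CALS)
        assert fit.slope == pytest.approx(1.0, abs=1e-9)
        assert fit.offset == pytest.approx(0.0, abs=1e-6)
        assert fit.n_calibrants_used == 4
        np.testing.assert_allclose(fit.residuals, 0.0, atol=1e-9)

    def test_constant_shift_recovered(self):
        peaks = [Peak(m + 0.5, 1.0) for m in CALS]
        out, fit = internal_calibrate(peaks, CALS)
        assert fit.slope == pytest.approx(1.0, abs=1e-12)
        assert fit.offset == pytest.approx(-0.5, abs=1e-9)
        for p, m in zip(out, CALS):
            assert p.mz == pytest.approx(m, abs=1e-9)

    def test_affine_distortion_recovered(self):
        slope_true, offset_true = 1.0002, -0.3
        peaks = [Peak(slope_true * m + offset_true, 1.0) for m in CALS]
        out, fit = internal_calibrate(peaks, CALS)
        oracle = lsq_affine_oracle([p.mz for p in peaks], CALS)
        assert fit.slope == pytest.approx(oracle[0], abs=1e-9)
        assert fit.offset == pytest.approx(oracle[1], abs=1e-6)
        for p, m in zip(out, CALS):
            assert p.mz == pytest.approx(m, abs=1e-6)

    def test_highest_peak_within_tolerance_wins(self):
        peaks = [Peak(CALS[0] + 0.8, 0.2), Peak(CALS[0] - 0.2, 1.0)] + [
            Peak(m, 1.0) for m in CALS[1:]
        ]
        _, fit = internal_calibrate(peaks, CALS, match_tol=1.5)
        # the taller peak at -0.2 is the matched partner for the first calibrant
        assert fit.n_calibrants_used == 4
        assert fit.offset != pytest.approx(0.0, abs=1e-3)

    def test_too_few_calibrants_errors(self):
        with pytest.raises(CalibrationError):
            internal_calibrate([Peak(CALS[0], 1.0)], CALS)

    def test_recalibration_is_stable(self):
        peaks = [Peak(1.0003 * m - 0.4, 1.0) for m in CALS]
        once, _ = internal_calibrate(peaks, CALS)
        twice, fit = internal_calibrate(once, CALS)
        for a, b in zip(once, twice):
            assert abs(a.mz - b.mz) < 1e-9
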