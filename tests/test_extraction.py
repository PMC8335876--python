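"""Peak/band extraction and the five characteristic parameters.

Includes a naive loop-based re-implementation of the whole extraction
(no shared code) used as an independent oracle on random sweeps.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from abcpe.extraction import (
    BandIncompleteError,
    DegenerateCurveError,
    band_mean,
    extract_baseline,
    extract_parameters,
    extract_series,
    find_3db_band,
    find_peak,
    parameters_to_frame,
)
from abcpe.io import CohortDataset, SweepRecord

from conftest import lorentzian_db


# ---------------------------------------------------------------------------
# Independent oracle: explicit loops, no numpy vector tricks, no shared code
# ---------------------------------------------------------------------------

def naive_extract(freq, amp, base_freq, base_amp):
    """Loop-based re-implementation of the five-parameter extraction."""

    def naive_peak(a):
        best, where = a[0], 0
        for i in range(1, len(a)):
            if a[i] > best:
                best, where = a[i], i
        return best, where

    def naive_band(f, a):
        pk, pi = naive_peak(a)
        level = pk - 3.0
        i = pi
        while a[i - 1] > level:
            i -= 1
        frac = (a[i] - level) / (a[i] - a[i - 1])
        f_lo = f[i] + frac * (f[i - 1] - f[i])
        j = pi
        while a[j + 1] > level:
            j += 1
        frac = (a[j] - level) / (a[j] - a[j + 1])
        f_hi = f[j] + frac * (f[j + 1] - f[j])
        return pk, f[pi], f_lo, f_hi

    def naive_mean(f, a, lo, hi):
        tot, cnt = 0.0, 0
        for x, y in zip(f, a):
            if lo <= x <= hi:
                tot += y
                cnt += 1
        return tot / cnt

    a0, f0, lo0, hi0 = naive_band(base_freq, base_amp)
    abar0 = naive_mean(base_freq, base_amp, lo0, hi0)
    ai, fi, loi, hii = naive_band(freq, amp)
    abar_i = naive_mean(freq, amp, lo0, hi0)
    abar_if = naive_mean(freq, amp, loi, hii)
    return (
        (ai - a0) / a0,
        (fi - f0) / f0,
        ((hii - loi) - (hi0 - lo0)) / (hi0 - lo0),
        (abar_i - abar0) / abar0,
        (abar_if - abar0) / abar0,
    )


class TestFindPeak:
    def test_unique_maximum(self, dense_grid):
        amp = lorentzian_db(dense_grid, peak_db=-15.2, f_center=57.56e6)
        rec = SweepRecord("S", 0, dense_grid, amp)
        pk = find_peak(rec)
        assert pk.amp_db == pytest.approx(-15.2, abs=1e-3)
        assert pk.freq_hz == pytest.approx(57.56e6, abs=1e5)
        assert not pk.at_boundary

    def test_tie_broken_to_lowest_frequency(self):
        freq = np.linspace(10e6, 80e6, 8)
        amp = np.array([-30, -30, -10.0, -30, -30, -10.0, -30, -30])
        pk = find_peak(SweepRecord("S", 0, freq, amp))
        assert pk.freq_hz == freq[2]

    def test_boundary_peak_flagged(self):
        freq = np.linspace(1e6, 8e6, 8)
        rec = SweepRecord("S", 0, freq, np.linspace(-30, -10, 8))
        pk = find_peak(rec)
        assert pk.at_boundary and pk.index == 7

    def test_flat_curve_rejected(self):
        rec = SweepRecord("S", 0, np.linspace(1e6, 8e6, 8), np.full(8, -20.0))
        with pytest.raises(DegenerateCurveError):
            find_peak(rec)


class TestBand:
    def test_lorentzian_half_power_width(self, dense_grid):
        """A Lorentzian with half-power full width 4 MHz yields bandwidth_hz
        = 4 MHz within one grid step (the -3 vs -3.0103 dB convention gap
        is far below a grid step here)."""
        rec = SweepRecord("S", 0, dense_grid, lorentzian_db(dense_grid, fwhm=4e6))
        band = find_3db_band(rec)
        step = dense_grid[1] - dense_grid[0]
        assert band.bandwidth_hz == pytest.approx(4e6, abs=step)
        assert band.f_lower_hz < 50e6 < band.f_upper_hz
        assert band.n_points >= 1

    def test_band_edges_sit_at_minus_3db(self, lorentzian_sweep):
        band = find_3db_band(lorentzian_sweep)
        for f_edge in (band.f_lower_hz, band.f_upper_hz):
            amp_at_edge = np.interp(
                f_edge, lorentzian_sweep.freq_hz, lorentzian_sweep.amp_db
            )
            assert amp_at_edge == pytest.approx(band.peak_amp_db - 3.0, abs=1e-6)

    @pytest.mark.parametrize("side, f_center", [("upper", 99e6), ("lower", 2e6)])
    def test_incomplete_band_names_side(self, dense_grid, side, f_center):
        amp = lorentzian_db(dense_grid, f_center=f_center, fwhm=8e6)
        rec = SweepRecord("S", 0, dense_grid, amp)
        with pytest.raises(BandIncompleteError, match=side):
            find_3db_band(rec)

    def test_uniform_shift_leaves_band_unchanged(self, lorentzian_sweep):
        """The -3 dB level shifts with the peak: +1 dB leaves f', f'', N."""
        b0 = find_3db_band(lorentzian_sweep)
        shifted = SweepRecord(
            "S", 0, lorentzian_sweep.freq_hz, lorentzian_sweep.amp_db + 1.0
        )
        b1 = find_3db_band(shifted)
        assert b1.f_lower_hz == pytest.approx(b0.f_lower_hz, abs=1e-3)
        assert b1.f_upper_hz == pytest.approx(b0.f_upper_hz, abs=1e-3)
        assert b1.n_points == b0.n_points

    def test_innermost_crossing_with_side_lobe(self):
        """A secondary lobe outside the main band must not widen it."""
        freq = np.linspace(1e6, 100e6, 1000)
        amp = lorentzian_db(freq, peak_db=-15, f_center=50e6, fwhm=4e6)
        amp = np.maximum(amp, lorentzian_db(freq, peak_db=-17.2, f_center=70e6, fwhm=4e6))
        band = find_3db_band(SweepRecord("S", 0, freq, amp))
        assert band.f_upper_hz < 60e6

    def test_band_mean_matches_loop_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            n = int(rng.integers(8, 200))
            freq = np.sort(rng.uniform(1e6, 1e8, 3 * n))[::3]
            amp = rng.uniform(-60, -10, n)
            rec = SweepRecord("S", 0, freq, amp)
            lo, hi = np.sort(rng.uniform(freq[0], freq[-1], 2))
            mask = (freq >= lo) & (freq <= hi)
            if not mask.any() or lo == hi:
                continue
            expected = sum(amp[mask]) / mask.sum()
            assert band_mean(rec, lo, hi) == pytest.approx(expected, abs=1e-12)

    def test_band_mean_single_point_and_simple_cases(self):
        freq = np.linspace(1e6, 8e6, 8)
        amp = np.array([-20.0, -21.0, -22.0, -30, -30, -30, -30, -30])
        rec = SweepRecord("S", 0, freq, amp)
        assert band_mean(rec, 0.9e6, 3.1e6) == pytest.approx(-21.0)
        assert band_mean(rec, 1.9e6, 2.1e6) == -21.0


class TestParameters:
    def test_identity_sweep_gives_exact_zeros(self, lorentzian_sweep):
        base = extract_baseline(lorentzian_sweep)
        p = extract_parameters(lorentzian_sweep, base)
        assert p.as_array().tolist() == [0.0, 0.0, 0.0, 0.0, 0.0]

    def test_uniform_shift_hand_values(self, dense_grid):
        """+1 dB everywhere: alpha = 1/A0, beta = gamma = 0, delta = rho = 1/abar0
        (negative denominators flip the sign of an amplitude increase)."""
        amp = lorentzian_db(dense_grid, peak_db=-20.0)
        rec0 = SweepRecord("S", 0.0, dense_grid, amp)
        base = extract_baseline(rec0)
        rec1 = SweepRecord("S", 1.0, dense_grid, amp + 1.0)
        p = extract_parameters(rec1, base)
        assert p.alpha == pytest.approx(1.0 / base.band.peak_amp_db, rel=1e-12)
        assert p.alpha == pytest.approx(-0.05, abs=1e-6)
        assert p.beta == 0.0
        assert p.gamma == pytest.approx(0.0, abs=1e-9)
        assert p.delta == pytest.approx(1.0 / base.mean_amp_db, rel=1e-12)
        assert p.rho == pytest.approx(p.delta, abs=1e-9)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(shift=st.floats(min_value=-3.0, max_value=3.0).filter(lambda c: abs(c) > 1e-6))
    def test_uniform_shift_law(self, shift):
        """For any constant c dB: beta = gamma = 0, alpha = c/A0, delta = rho = c/abar0."""
        grid = np.linspace(1e6, 100e6, 500)
        amp = lorentzian_db(grid, peak_db=-18.0, f_center=45e6, fwhm=6e6)
        base = extract_baseline(SweepRecord("S", 0.0, grid, amp))
        p = extract_parameters(SweepRecord("S", 1.0, grid, amp + shift), base)
        assert p.beta == 0.0
        assert p.gamma == pytest.approx(0.0, abs=1e-9)
        assert p.alpha == pytest.approx(shift / base.band.peak_amp_db, rel=1e-9)
        assert p.delta == pytest.approx(shift / base.mean_amp_db, rel=1e-9)
        assert p.rho == pytest.approx(p.delta, abs=1e-9)

    def test_frequency_translation_law(self):
        """Translating the curve by k grid steps changes beta by k*df/f0 and
        leaves alpha, gamma (and rho on the followed band) unchanged."""
        grid = np.linspace(1e6, 100e6, 1000)
        amp = lorentzian_db(grid, peak_db=-16.0, f_center=45e6, fwhm=5e6)
        base = extract_baseline(SweepRecord("S", 0.0, grid, amp))
        k = 7
        translated = np.roll(amp, k)
        translated[:k] = amp[0]
        p = extract_parameters(SweepRecord("S", 1.0, grid, translated), base)
        df = grid[1] - grid[0]
        assert p.beta == pytest.approx(k * df / base.band.peak_freq_hz, rel=1e-6)
        assert p.alpha == pytest.approx(0.0, abs=1e-9)
        assert abs(p.gamma) < 2 * df / base.band.bandwidth_hz
        assert p.rho == pytest.approx(0.0, abs=1e-4)

    def test_doubled_bandwidth_gives_gamma_one(self, dense_grid):
        """Halving the quality factor (FWHM 4 -> 8 MHz) at fixed peak gives
        gamma = 1 within grid tolerance, alpha = 0, beta ~ 0."""
        base = extract_baseline(
            SweepRecord("S", 0.0, dense_grid, lorentzian_db(dense_grid, fwhm=4e6))
        )
        wide = SweepRecord("S", 1.0, dense_grid, lorentzian_db(dense_grid, fwhm=8e6))
        p = extract_parameters(wide, base)
        step = dense_grid[1] - dense_grid[0]
        assert p.gamma == pytest.approx(1.0, abs=2 * step / 4e6)
        # peak is grid-sampled: off-grid center leaves a sub-step amplitude error
        assert p.alpha == pytest.approx(0.0, abs=1e-3)
        assert abs(p.beta) <= step / 50e6

    def test_delta_rho_coincide_when_bands_match(self, dense_grid):
        """Same grid points in F_i and F0 -> delta == rho to 1e-12."""
        amp = lorentzian_db(dense_grid)
        base = extract_baseline(SweepRecord("S", 0.0, dense_grid, amp))
        p = extract_parameters(SweepRecord("S", 1.0, dense_grid, amp + 0.5), base)
        assert p.delta == pytest.approx(p.rho, abs=1e-12)

    def test_non_baseline_record_rejected_as_reference(self, dense_grid):
        rec = SweepRecord("S", 2.0, dense_grid, lorentzian_db(dense_grid))
        with pytest.raises(ValueError, match="time_h == 0"):
            extract_baseline(rec)

    def test_extraction_is_pure(self, lorentzian_sweep):
        b1 = extract_baseline(lorentzian_sweep)
        b2 = extract_baseline(lorentzian_sweep)
        assert b1 == b2

    def test_matches_independent_oracle_on_random_sweeps(self):
        """Vectorized extraction agrees with the naive loop oracle to 1e-9
        relative on 100 random simulated Lorentzian sweeps."""
        rng = np.random.default_rng(2024)
        grid = np.linspace(1e6, 100e6, 700)
        for _ in range(100):
            base_amp = lorentzian_db(
                grid,
                peak_db=rng.uniform(-25, -10),
                f_center=rng.uniform(30e6, 70e6),
                fwhm=rng.uniform(3e6, 12e6),
                floor_db=-60,
            ) + rng.normal(0, 0.02, grid.size)
            cur_amp = lorentzian_db(
                grid,
                peak_db=rng.uniform(-25, -10),
                f_center=rng.uniform(30e6, 70e6),
                fwhm=rng.uniform(3e6, 12e6),
                floor_db=-60,
            ) + rng.normal(0, 0.02, grid.size)
            base = extract_baseline(SweepRecord("S", 0.0, grid, base_amp))
            p = extract_parameters(SweepRecord("S", 1.0, grid, cur_amp), base)
            expected = naive_extract(grid, cur_amp, grid, base_amp)
            got = (p.alpha, p.beta, p.gamma, p.delta, p.rho)
            for g, e in zip(got, expected):
                assert g == pytest.approx(e, rel=1e-9, abs=1e-12)


class TestSeries:
    def test_cohort_count_and_ordering(self, small_cohort):
        """2+2 subjects x 9 time points -> (9-1) vectors per subject, ordered
        by (subject, time) regardless of input record order."""
        params, errors = extract_series(small_cohort)
        assert not errors
        assert len(params) == 4 * 8
        keys = [(p.subject_id, p.time_h) for p in params]
        assert keys == sorted(keys)

        shuffled = CohortDataset(
            records=list(reversed(small_cohort.records)),
            group_of=dict(small_cohort.group_of),
        )
        params2, _ = extract_series(shuffled)
        assert [(p.subject_id, p.time_h) for p in params2] == keys
        np.testing.assert_allclose(
            [p.as_array() for p in params2], [p.as_array() for p in params]
        )

    def test_baseline_only_cohort_yields_empty(self):
        freq = np.linspace(30e6, 90e6, 200)
        recs = [
            SweepRecord(s, 0.0, freq, lorentzian_db(freq, f_center=60e6, fwhm=8e6))
            for s in ("A", "B")
        ]
        ds = CohortDataset(records=recs, group_of={"A": "Exp", "B": "Con"})
        params, errors = extract_series(ds)
        assert params == [] and errors == []

    def test_failing_record_reported_not_fatal(self):
        """A sweep whose -3 dB band leaves the span goes to the error report."""
        freq = np.linspace(30e6, 90e6, 200)
        good = lorentzian_db(freq, f_center=60e6, fwhm=8e6)
        bad = lorentzian_db(freq, f_center=89e6, fwhm=8e6)  # band exits above
        ds = CohortDataset(
            records=[
                SweepRecord("A", 0.0, freq, good),
                SweepRecord("A", 1.0, freq, bad),
                SweepRecord("A", 2.0, freq, good + 0.2),
            ],
            group_of={"A": "Exp"},
        )
        params, errors = extract_series(ds)
        assert len(params) == 1 and params[0].time_h == 2.0
        assert len(errors) == 1 and errors[0]["subject"] == "A"
        assert errors[0]["time_h"] == 1.0

    def test_parameters_frame_layout(self, small_cohort):
        params, _ = extract_series(small_cohort)
        df = parameters_to_frame(params, small_cohort.group_of)
        assert list(df.columns) == [
            "subject", "group", "time_h", "alpha", "beta", "gamma", "delta", "rho"
        ]
        assert len(df) == len(params)
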