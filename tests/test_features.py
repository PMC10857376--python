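"""Calendar alignment, cleansing rules and histogram construction."""

from __future__ import annotations

import datetime as dt

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from yieldtransfer.features import (
    CompositeSeries,
    CropCalendar,
    HistogramTensor,
    YieldRecord,
    align_period,
    clean_records,
    compute_bin_edges,
    histogramize,
)


def make_series(n_t=40, n_pix=20, start=dt.date(2010, 3, 23), seed=0, county="A"):
    rng = np.random.default_rng(seed)
    vals = rng.random((9, n_t, n_pix))
    return CompositeSeries(
        county_id=county, season_year=start.year, values=vals,
        mask_pixel_count=n_pix, start_date=start,
    )


us_calendar = CropCalendar("us", dt.date(2010, 3, 23), dt.date(2010, 12, 4))
ar_calendar = CropCalendar("ar", dt.date(2010, 11, 26), dt.date(2011, 8, 9))


class TestAlignPeriod:
    @pytest.mark.parametrize("calendar", [us_calendar, ar_calendar])
    def test_256_day_windows_give_32_composites(self, calendar):
        assert (calendar.end_date - calendar.window(calendar.start_date.year)[0]).days in (256, 257)
        assert calendar.n_composites == 32

    def test_full_window_alignment(self):
        s = make_series(n_t=40)
        out = align_period(s, us_calendar)
        assert out.n_timesteps == 32
        np.testing.assert_array_equal(out.values, s.values[:, :32, :])

    def test_short_period_keeps_first_14(self):
        for cal in (us_calendar, ar_calendar):
            s = make_series(n_t=40, start=cal.start_date)
            assert align_period(s, cal, short_period=True).n_timesteps == 14

    def test_offset_series_is_cropped_from_window_start(self):
        s = make_series(n_t=40, start=dt.date(2010, 3, 7))  # two composites early
        out = align_period(s, us_calendar)
        np.testing.assert_array_equal(out.values, s.values[:, 2:34, :])
        assert out.start_date == dt.date(2010, 3, 23)

    def test_single_composite_window_is_identity(self):
        cal = CropCalendar("x", dt.date(2010, 5, 1), dt.date(2010, 5, 9))
        s = make_series(n_t=1, start=dt.date(2010, 5, 1))
        out = align_period(s, cal)
        assert out.n_timesteps == 1
        np.testing.assert_array_equal(out.values, s.values)

    def test_uncovered_window_raises_naming_range(self):
        s = make_series(n_t=10)
        with pytest.raises(ValueError, match="missing the calendar range"):
            align_period(s, us_calendar)
        late = make_series(n_t=40, start=dt.date(2010, 4, 24))
        with pytest.raises(ValueError, match="not covering"):
            align_period(late, us_calendar)

    def test_southern_hemisphere_window_crosses_new_year(self):
        start, end = ar_calendar.window(2015)
        assert start == dt.date(2015, 11, 26)
        assert end == dt.date(2016, 8, 9)


class TestCleanRecords:
    def test_three_filters(self):
        recs = [
            YieldRecord("A", 2020, 40.0, "us"),
            YieldRecord("B", 2020, 50.0, "us"),
            YieldRecord("C", 2020, 0.0, "us"),
        ]
        counts = {"A": 2500, "B": 1999, "C": 2500}
        assert clean_records(recs, counts) == [recs[0]]

    def test_missing_county_and_missing_yield_dropped(self):
        recs = [
            YieldRecord(None, 2020, 40.0, "us"),
            YieldRecord("Z", 2020, 40.0, "us"),   # not in mask map
            YieldRecord("A", 2020, None, "us"),
        ]
        assert clean_records(recs, {"A": 3000}) == []

    def test_empty_input(self):
        assert clean_records([], {}) == []

    def test_noop_threshold_preserves_input_and_order(self):
        recs = [YieldRecord(c, 2020, 10.0 + i, "us") for i, c in enumerate("ABC")]
        counts = {c: 1 for c in "ABC"}
        assert clean_records(recs, counts, min_pixels=0) == recs


class TestBinEdges:
    def test_uniform_sample_gives_uniform_quantiles(self):
        samples = np.random.default_rng(0).random(200_000)
        edges = compute_bin_edges(samples, n_bins=4)
        np.testing.assert_allclose(edges, [0, 0.25, 0.5, 0.75, 1.0], atol=0.01)

    def test_single_bin_is_min_max(self):
        edges = compute_bin_edges(np.array([3.0, 1.0, 2.0]), n_bins=1)
        np.testing.assert_array_equal(edges, [1.0, 3.0])

    def test_default_is_32_bins(self):
        edges = compute_bin_edges(np.random.default_rng(1).random(10_000))
        assert edges.shape == (33,)

    def test_constant_samples_raise(self):
        with pytest.raises(ValueError, match="degenerate"):
            compute_bin_edges(np.full(100, 0.5), n_bins=4)


class TestHistogramize:
    edges = [np.linspace(0, 1, 5)] * 9

    def test_brute_force_counts(self):
        vals = np.zeros((9, 1, 4))
        vals[:, 0, :] = [0.1, 0.1, 0.6, 0.9]
        s = CompositeSeries("A", 2020, vals, 4, dt.date(2020, 1, 1))
        h = histogramize(s, self.edges)
        np.testing.assert_allclose(h.data[0, 0], [0.5, 0, 0.25, 0.25])

    def test_point_mass(self):
        vals = np.full((9, 2, 5), 0.3)
        h = histogramize(CompositeSeries("A", 2020, vals, 5, dt.date(2020, 1, 1)), self.edges)
        assert np.all(h.data[:, :, 1] == 1.0)
        assert np.all(h.data.sum(axis=2) == 1.0)

    def test_out_of_range_clipped_into_terminal_bins(self):
        vals = np.zeros((9, 1, 2))
        vals[:, 0, :] = [-5.0, 7.0]
        h = histogramize(CompositeSeries("A", 2020, vals, 2, dt.date(2020, 1, 1)), self.edges)
        np.testing.assert_allclose(h.data[3, 0], [0.5, 0, 0, 0.5])

    def test_no_valid_pixels_gives_zero_slice(self):
        vals = np.full((9, 1, 3), np.nan)
        h = histogramize(CompositeSeries("A", 2020, vals, 3, dt.date(2020, 1, 1)), self.edges)
        assert np.all(h.data == 0.0)

    def test_band_count_mismatch_raises(self):
        s = make_series(n_t=2, n_pix=4)
        with pytest.raises(ValueError, match="bands"):
            histogramize(s, self.edges[:5])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(1, 40))
    def test_normalization_and_permutation_invariance(self, seed, n_pix):
        rng = np.random.default_rng(seed)
        vals = rng.random((9, 3, n_pix))
        s = CompositeSeries("A", 2020, vals, n_pix, dt.date(2020, 1, 1))
        h = histogramize(s, self.edges)
        np.testing.assert_allclose(h.data.sum(axis=2), 1.0, atol=1e-9)
        perm = rng.permutation(n_pix)
        s2 = CompositeSeries("A", 2020, vals[:, :, perm], n_pix, dt.date(2020, 1, 1))
        np.testing.assert_array_equal(h.data, histogramize(s2, self.edges).data)

    def test_mass_conservation_before_normalization(self):
        rng = np.random.default_rng(5)
        n_pix = 37
        vals = rng.random((9, 2, n_pix))
        h = histogramize(
            CompositeSeries("A", 2020, vals, n_pix, dt.date(2020, 1, 1)), self.edges
        )
        counts = h.data * n_pix
        np.testing.assert_allclose(counts.sum(axis=2), n_pix, atol=1e-6)

    def test_shift_by_one_bin_width_shifts_histogram_one_bin(self):
        rng = np.random.default_rng(6)
        vals = rng.uniform(0.05, 0.65, (9, 1, 50))  # stays in range after shift
        edges = [np.linspace(0, 1, 11)] * 9  # width 0.1
        s1 = CompositeSeries("A", 2020, vals, 50, dt.date(2020, 1, 1))
        s2 = CompositeSeries("A", 2020, vals + 0.1, 50, dt.date(2020, 1, 1))
        h1 = histogramize(s1, edges).data
        h2 = histogramize(s2, edges).data
        np.testing.assert_allclose(h1[:, :, :-1], h2[:, :, 1:], atol=1e-12)


def test_histogram_tensor_rejects_bad_slices():
    bad = np.zeros((9, 1, 4))
    bad[0, 0] = [0.5, 0.2, 0.1, 0.1]  # sums to 0.9
    with pytest.raises(ValueError, match="slice"):
        HistogramTensor(bad)
    with pytest.raises(ValueError, match="non-negative"):
        HistogramTensor(np.full((9, 1, 4), -0.25))
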