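"""Feature engineering: calendar alignment, data cleansing and histogramization.

County-level yield regression from satellite imagery faces an awkward input
geometry: every county contributes a different, irregular set of masked
cropland pixels.  The standard remedy is *histogramization* — for each
spectral band and each 8-day composite, the masked pixel values of a county
are reduced to a normalized histogram, giving a rectangular
``[bands x timesteps x bins]`` tensor per county-season that a CNN can
consume.  Two growing regions in opposite hemispheres are made comparable by
aligning each domain to its own crop calendar window before histogramization,
so that composite index ``t`` means "t-th 8-day step of the growing season"
in both domains.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "CompositeSeries",
    "CropCalendar",
    "HistogramTensor",
    "YieldRecord",
    "align_period",
    "clean_records",
    "compute_bin_edges",
    "histogramize",
    "N_BANDS",
    "DEFAULT_N_BINS",
    "SHORT_PERIOD_STEPS",
]

#: Seven surface-reflectance bands (459-2155 nm) plus day and night
#: land-surface temperature.
N_BANDS = 9

#: Bin count of the normalized value histograms.
DEFAULT_N_BINS = 32

#: Number of leading 8-day composites kept for the in-season (short) forecast.
SHORT_PERIOD_STEPS = 14


@dataclass(frozen=True)
class CropCalendar:
    """Growing-season observation window of one domain.

    ``start_date``/``end_date`` anchor the window in a reference season; the
    same month/day window is reused for every season year via :meth:`window`.
    A window of ``D`` days yields ``D // composite_days`` composites.
    """

    domain: str
    start_date: _dt.date
    end_date: _dt.date
    composite_days: int = 8

    def __post_init__(self) -> None:
        if self.end_date <= self.start_date:
            raise ValueError("calendar end_date must be after start_date")
        if self.composite_days < 1:
            raise ValueError("composite_days must be >= 1")

    @property
    def n_composites(self) -> int:
        return (self.end_date - self.start_date).days // self.composite_days

    def window(self, season_year: int) -> tuple[_dt.date, _dt.date]:
        """The (start, end) dates of the window for a given season year.

        The season year labels the *start* of the window; a window crossing
        New Year (southern hemisphere) ends in ``season_year + 1``.
        """
        shift = season_year - self.start_date.year
        start = _shift_year(self.start_date, shift)
        end = _shift_year(self.end_date, shift)
        if end <= start:
            end = _shift_year(end, 1)
        return start, end


def _shift_year(d: _dt.date, shift: int) -> _dt.date:
    try:
        return d.replace(year=d.year + shift)
    except ValueError:  # Feb 29
        return d.replace(year=d.year + shift, day=28)


@dataclass
class CompositeSeries:
    """Masked pixel values of one county-season.

    ``values`` has shape ``[9 bands, T timesteps, n_pixels]``: the same pixel
    index set is observed at every timestep.  Reflectance bands are unitless
    in (0, 1); temperature bands are in the sensor's scaled units.  NaN marks
    an invalid observation.
    """

    county_id: str
    season_year: int
    values: np.ndarray
    mask_pixel_count: int
    start_date: _dt.date
    composite_days: int = 8

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3 or self.values.shape[0] != N_BANDS:
            raise ValueError(
                f"values must be [bands={N_BANDS}, timesteps, pixels], "
                f"got shape {self.values.shape}"
            )
        if self.mask_pixel_count < 0:
            raise ValueError("mask_pixel_count must be >= 0")

    @property
    def n_timesteps(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class YieldRecord:
    """One county-season ground-truth yield in bu/ac."""

    county_id: str | None
    season_year: int
    yield_bu_ac: float | None
    domain: str


@dataclass(frozen=True)
class HistogramTensor:
    """Normalized per-band, per-timestep value histograms of one county-season.

    Every nonempty ``(band, timestep)`` slice is a probability vector over the
    bins; a slice with no valid pixels is all-zero (kept, so tensors stay
    rectangular for batching).
    """

    data: np.ndarray
    county_id: str = ""
    season_year: int = 0
    domain: str = ""

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=np.float64)
        object.__setattr__(self, "data", data)
        if data.ndim != 3:
            raise ValueError("histogram tensor must be [bands, timesteps, bins]")
        if np.any(data < 0):
            raise ValueError("histogram entries must be non-negative")
        sums = data.sum(axis=2)
        ok = np.isclose(sums, 1.0, atol=1e-9) | (sums == 0.0)
        if not np.all(ok):
            b, t = np.argwhere(~ok)[0]
            raise ValueError(
                f"slice (band={b}, t={t}) sums to {sums[b, t]!r}; "
                "expected 1.0 or an all-zero slice"
            )


def align_period(
    series: CompositeSeries,
    calendar: CropCalendar,
    short_period: bool = False,
) -> CompositeSeries:
    """Crop a pixel series to the domain's calendar window.

    Keeps exactly ``T`` composites starting at the calendar's window start for
    the series' season year, where ``T`` is the full window length or
    :data:`SHORT_PERIOD_STEPS` when ``short_period`` — the in-season forecast
    that stops well before harvest.
    """
    if series.composite_days != calendar.composite_days:
        raise ValueError(
            f"composite length mismatch: series has {series.composite_days} d, "
            f"calendar has {calendar.composite_days} d"
        )
    start, end = calendar.window(series.season_year)
    n_keep = calendar.n_composites
    if short_period:
        n_keep = min(n_keep, SHORT_PERIOD_STEPS)

    offset_days = (start - series.start_date).days
    step = calendar.composite_days
    if offset_days < 0 or offset_days % step != 0:
        raise ValueError(
            f"series for {series.county_id}/{series.season_year} starts at "
            f"{series.start_date}, not covering (or not aligned to) the "
            f"calendar window starting {start}"
        )
    first = offset_days // step
    last = first + n_keep
    if last > series.n_timesteps:
        missing_from = series.start_date + _dt.timedelta(days=series.n_timesteps * step)
        raise ValueError(
            f"series for {series.county_id}/{series.season_year} ends at "
            f"{missing_from}, missing the calendar range up to {end}"
        )
    return replace(
        series,
        values=series.values[:, first:last, :],
        start_date=start,
    )


def clean_records(
    records: Sequence[YieldRecord],
    mask_counts: Mapping[str, int],
    min_pixels: int = 2000,
) -> list[YieldRecord]:
    """Apply the yield-data cleansing rules.

    Drops records that (a) cannot be assigned to a county, (b) have a missing
    or non-positive yield, or (c) belong to a county with fewer than
    ``min_pixels`` cropland-mask pixels — too little cropland for the county
    histogram to reflect crop state rather than noise.  Never raises on
    content; relative order is preserved.
    """
    kept: list[YieldRecord] = []
    for rec in records:
        if rec.county_id is None or rec.county_id not in mask_counts:
            continue
        y = rec.yield_bu_ac
        if y is None or not np.isfinite(y) or y <= 0:
            continue
        if mask_counts[rec.county_id] < min_pixels:
            continue
        kept.append(rec)
    return kept


def compute_bin_edges(
    samples: np.ndarray,
    n_bins: int = DEFAULT_N_BINS,
    band: int | None = None,
) -> np.ndarray:
    """Quantile bin edges for one band's pixel values.

    Equal-probability edges estimated from a pooled pixel sample; transfer
    between domains requires a *single shared* feature space, so edges are
    computed once (on source-domain training pixels) and reused everywhere.
    Returns ``n_bins + 1`` strictly increasing edges spanning the sample range.
    """
    samples = np.asarray(samples, dtype=np.float64).ravel()
    samples = samples[np.isfinite(samples)]
    if samples.size == 0:
        raise ValueError("cannot compute bin edges from an empty sample")
    edges = np.quantile(samples, np.linspace(0.0, 1.0, n_bins + 1))
    if np.any(np.diff(edges) <= 0):
        label = "" if band is None else f" for band {band}"
        raise ValueError(
            f"degenerate value range{label}: quantile edges are not strictly "
            "increasing (near-constant samples)"
        )
    return edges


def histogramize(
    series: CompositeSeries,
    edges_per_band: Sequence[np.ndarray] | np.ndarray,
) -> HistogramTensor:
    """Reduce a pixel series to its normalized histogram tensor.

    For each band/timestep the valid (finite) pixel values are counted into
    the band's bins and the counts divided by the number of valid pixels.
    Values outside the edge range are clipped into the terminal bins, so no
    probability mass is lost.  Timesteps with no valid pixel give an all-zero
    slice.
    """
    edges_list = [np.asarray(e, dtype=np.float64) for e in edges_per_band]
    if len(edges_list) != series.values.shape[0]:
        raise ValueError(
            f"got edges for {len(edges_list)} bands but series has "
            f"{series.values.shape[0]} bands"
        )
    n_bands, n_t, _ = series.values.shape
    n_bins = edges_list[0].size - 1
    for b, e in enumerate(edges_list):
        if e.ndim != 1 or e.size != n_bins + 1 or np.any(np.diff(e) <= 0):
            raise ValueError(f"invalid bin edges for band {b}")

    out = np.zeros((n_bands, n_t, n_bins), dtype=np.float64)
    for b in range(n_bands):
        vals = np.asarray(series.values[b], dtype=np.float64)  # [T, P]
        finite = np.isfinite(vals)
        # interior edges only: out-of-range values fall in the terminal bins
        idx = np.searchsorted(edges_list[b][1:-1], vals, side="right")
        for t in range(n_t):
            sel = finite[t]
            n_valid = int(sel.sum())
            if n_valid == 0:
                continue
            counts = np.bincount(idx[t][sel], minlength=n_bins)
            out[b, t] = counts / n_valid
    return HistogramTensor(
        data=out,
        county_id=series.county_id,
        season_year=series.season_year,
    )
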