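"""Synthetic two-domain yield benchmark.

Emulates the statistical structure the transfer framework assumes, so every
stage is testable without any satellite download:

* two growing regions ("source", data-rich; "target", data-poor) whose crop
  calendars are shifted by roughly half a year (opposite hemispheres);
* target yields systematically lower than source yields, both with a
  positive linear year trend;
* per-band pixel distributions whose location/shape is driven by a *shared*
  function of the latent yield signal — so histogram features carry the
  signal and the yield→histogram map transfers — plus a domain-specific
  distortion whose strength controls how hard the transfer is;
* a spatio-temporally correlated residual field (a Gaussian field over
  county centroids and season years, drawn from the same squared-exponential
  kernel family the GP head assumes), which no histogram feature can explain
  — the structure the GP correction exploits;
* a configurable fraction of counties with too little cropland, exercising
  the cleansing rules.

Reflectance-band pixels are logit-normal on (0, 1) (unimodal, "beta-like",
location-shifted by the yield signal); temperature-band pixels are Gaussian
in the sensor's scaled units.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .features import CompositeSeries, CropCalendar, YieldRecord, N_BANDS
from .gp_head import STIndex

__all__ = ["SynthConfig", "DomainBundle", "generate_domains", "iter_series",
           "oracle_predictor", "domain_truth"]

# fixed per-band response constants (reflectance bands 0-6, temperature 7-8)
_REFL_OFFSET = np.array([-1.5, -1.0, -0.5, 0.0, 0.4, -0.8, -1.2])
_REFL_GAIN = np.array([0.9, -0.7, 0.6, 0.8, -0.5, 0.7, -0.6])
_REFL_CURV = np.array([0.3, -0.2, 0.25, -0.3, 0.2, -0.25, 0.3])
_REFL_DOM = np.array([0.6, 0.5, -0.7, 0.4, 0.6, -0.5, 0.5])
_TEMP_BASE = np.array([14750.0, 14200.0])
_TEMP_AMP = 300.0
_TEMP_GAIN = np.array([90.0, -70.0])
_TEMP_CURV = np.array([0.2, -0.2])
_TEMP_DOM = np.array([60.0, -50.0])
_PIX_EFFECT_SD = 0.25
_Z_SCALE = 10.0
_ATMOS_TEMP_SCALE = 300.0  # logit-unit atmospheric offsets -> scaled LST units


@dataclass
class SynthConfig:
    """Benchmark generator settings.

    Sizes mirror a small-target transfer scenario: a source region an order
    of magnitude richer in county-seasons than the target.  Yield bases are
    in bu/ac; ``residual_sd`` is the scale of the spatio-temporally
    correlated noise (the floor any histogram-based model can reach, and
    what the GP head partially recovers); ``residual_corr_loc`` /
    ``residual_corr_year`` are its correlation lengths in degrees and years.
    ``shared_signal_weight`` scales the transferable yield→pixel response,
    ``domain_specific_weight`` a distortion of opposite sign in the two
    domains (0 = maximally favorable transfer).
    """

    n_source_counties: int = 150
    n_target_counties: int = 40
    seasons_source: tuple[int, int] = (2010, 2020)
    seasons_target: tuple[int, int] = (2016, 2020)
    pixels_per_county: tuple[int, int] = (2000, 2800)
    cleansing_min_pixels: int = 2000
    below_min_fraction: float = 0.05
    yield_base_source: float = 42.0
    yield_base_target: float = 30.0
    trend_per_year: float = 0.4
    county_effect_sd: float = 3.0
    residual_sd: float = 2.0
    residual_corr_loc: float = 0.5
    residual_corr_year: float = 1.5
    calendar_offset_days: int = 248
    window_days: int = 256
    shared_signal_weight: float = 1.0
    domain_specific_weight: float = 0.2
    pixel_noise_sd: float = 0.5
    atmos_sd: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        for lo, hi in (self.seasons_source, self.seasons_target):
            if hi < lo:
                raise ValueError("season ranges must be nonempty")
        if self.pixels_per_county[1] < self.pixels_per_county[0]:
            raise ValueError("pixels_per_county range must be nonempty")
        if min(self.shared_signal_weight, self.domain_specific_weight) < 0:
            raise ValueError("signal weights must be >= 0")


@dataclass
class DomainBundle:
    """One generated domain: pixel series, yields, ST indices, calendar.

    ``signal`` is the latent noise-free yield per record (the oracle's
    prediction); ``mask_counts`` maps county id to its cropland pixel count
    for the cleansing step.
    """

    domain: str
    calendar: CropCalendar
    series: list[CompositeSeries]
    records: list[YieldRecord]
    st_index: list[STIndex]
    signal: np.ndarray
    mask_counts: dict[str, int] = field(default_factory=dict)


def _calendars(config: SynthConfig) -> dict[str, CropCalendar]:
    ref = config.seasons_source[0]
    src_start = _dt.date(ref, 3, 23)
    tgt_start = src_start + _dt.timedelta(days=config.calendar_offset_days)
    return {
        "source": CropCalendar(
            "source", src_start, src_start + _dt.timedelta(days=config.window_days)
        ),
        "target": CropCalendar(
            "target", tgt_start, tgt_start + _dt.timedelta(days=config.window_days)
        ),
    }


def _domain_spec(config: SynthConfig, domain: str) -> dict:
    if domain == "source":
        return {
            "idx": 0,
            "n_counties": config.n_source_counties,
            "seasons": config.seasons_source,
            "base": config.yield_base_source,
            "box": ((-98.0, -88.0), (37.0, 45.0)),  # (lon range, lat range)
            "dom_sign": 1.0,
        }
    if domain == "target":
        return {
            "idx": 1,
            "n_counties": config.n_target_counties,
            "seasons": config.seasons_target,
            "base": config.yield_base_target,
            "box": ((-63.0, -59.0), (-33.0, -28.0)),
            "dom_sign": -1.0,
        }
    raise ValueError(f"unknown domain {domain!r}")


def _structure(config: SynthConfig, domain: str) -> dict:
    """Deterministic county/season scaffold of one domain."""
    spec = _domain_spec(config, domain)
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 1, spec["idx"])))
    n_c = spec["n_counties"]
    (lon0, lon1), (lat0, lat1) = spec["box"]
    centroids = np.column_stack(
        [rng.uniform(lon0, lon1, n_c), rng.uniform(lat0, lat1, n_c)]
    )
    county_effect = rng.normal(0.0, config.county_effect_sd, n_c)
    lo, hi = config.pixels_per_county
    counts = rng.integers(lo, hi + 1, n_c)
    n_below = int(round(config.below_min_fraction * n_c))
    if n_below > 0:
        below = rng.choice(n_c, size=n_below, replace=False)
        counts[below] = rng.integers(
            max(1, config.cleansing_min_pixels // 2),
            config.cleansing_min_pixels,
            n_below,
        )
    years = np.arange(spec["seasons"][0], spec["seasons"][1] + 1)

    # spatio-temporally correlated residual field over (county, year)
    ci, yi = np.meshgrid(np.arange(n_c), np.arange(years.size), indexing="ij")
    ci, yi = ci.ravel(), yi.ravel()
    d2 = ((centroids[ci][:, None, :] - centroids[ci][None, :, :]) ** 2).sum(axis=2)
    dy2 = (years[yi][:, None] - years[yi][None, :]) ** 2.0
    cov = config.residual_sd**2 * np.exp(
        -d2 / (2 * config.residual_corr_loc**2)
        - dy2 / (2 * config.residual_corr_year**2)
    )
    cov[np.diag_indices_from(cov)] += 1e-9
    field_rng = np.random.default_rng(
        np.random.SeedSequence((config.seed, 2, spec["idx"]))
    )
    eps = np.linalg.cholesky(cov) @ field_rng.standard_normal(ci.size)
    eps = eps.reshape(n_c, years.size)

    ref_year = config.seasons_source[0]
    signal = (
        spec["base"]
        + config.trend_per_year * (years[None, :] - ref_year)
        + county_effect[:, None]
    )
    return {
        "spec": spec,
        "centroids": centroids,
        "county_effect": county_effect,
        "mask_counts": counts,
        "years": years,
        "signal": signal,       # [n_c x n_years], noise-free
        "yields": signal + eps,  # observed
    }


def _season_profile(n_t: int) -> np.ndarray:
    t = np.arange(n_t)
    return np.exp(-((t - 0.45 * n_t) ** 2) / (2 * (0.18 * n_t) ** 2))


def _record_pixels(
    config: SynthConfig, domain: str, county_i: int, year: int,
    signal: float, n_pix: int, n_t: int,
) -> np.ndarray:
    """Pixel value cube [9, T, n_pix] for one county-season."""
    spec = _domain_spec(config, domain)
    rng = np.random.default_rng(
        np.random.SeedSequence((config.seed, 100 + spec["idx"], county_i, year))
    )
    z = (signal - _z_center(config)) / _Z_SCALE
    p = _season_profile(n_t)  # [T]

    # per-composite observation-condition offsets (atmosphere, view geometry).
    # The coherent part loads on the same band direction as the yield signal:
    # telling them apart requires the temporal response profile (signal
    # follows the season bump, atmosphere is white in t), which is the part
    # of the map that needs data to learn.
    coherent = rng.normal(0.0, config.atmos_sd, n_t)
    loading = np.concatenate([_REFL_GAIN, _TEMP_GAIN / _ATMOS_TEMP_SCALE])
    atmos = loading[:, None] * coherent[None, :] + rng.normal(
        0.0, 0.5 * config.atmos_sd, (N_BANDS, n_t)
    )
    # yield response is mildly nonlinear (saturating reflectance response) and
    # also widens/narrows the pixel distribution, so histogram *shape* carries
    # signal beyond a pure location shift
    z_refl = z + _REFL_CURV * z**2
    width = 1.0 + 0.2 * np.tanh(z)

    gain = (
        config.shared_signal_weight * _REFL_GAIN * z_refl
        + config.domain_specific_weight * spec["dom_sign"] * _REFL_DOM * z
    )
    mu_refl = _REFL_OFFSET[:, None] + np.outer(gain, p) + atmos[:7]  # [7, T]
    pix_eff = rng.normal(0.0, _PIX_EFFECT_SD, (N_BANDS, n_pix))
    noise = rng.standard_normal((7, n_t, n_pix)) * (config.pixel_noise_sd * width)
    u = mu_refl[:, :, None] + pix_eff[:7, None, :] + noise
    refl = 1.0 / (1.0 + np.exp(-u))

    gain_t = (
        config.shared_signal_weight * _TEMP_GAIN * (z + _TEMP_CURV * z**2)
        + config.domain_specific_weight * spec["dom_sign"] * _TEMP_DOM * z
    )
    mu_temp = (
        _TEMP_BASE[:, None]
        + _TEMP_AMP * p[None, :]
        + np.outer(gain_t, p)
        + _ATMOS_TEMP_SCALE * atmos[7:]
    )
    noise_t = rng.standard_normal((2, n_t, n_pix)) * (
        config.pixel_noise_sd * 160.0 * width
    )
    temp = mu_temp[:, :, None] + 480.0 * pix_eff[7:, None, :] + noise_t

    return np.concatenate([refl, temp], axis=0).astype(np.float32)


def _z_center(config: SynthConfig) -> float:
    mid = 0.5 * (config.seasons_source[0] + config.seasons_source[1])
    return (
        0.5 * (config.yield_base_source + config.yield_base_target)
        + config.trend_per_year * (mid - config.seasons_source[0])
    )


def iter_series(config: SynthConfig, domain: str) -> Iterator[CompositeSeries]:
    """Stream the pixel series of one domain, one county-season at a time.

    Record order (county-major, then year) and content are deterministic
    functions of the config seed, independent of how much of the iterator is
    consumed.
    """
    struct = _structure(config, domain)
    cal = _calendars(config)[domain]
    n_t = cal.n_composites
    for c in range(struct["spec"]["n_counties"]):
        for j, year in enumerate(struct["years"]):
            n_pix = int(struct["mask_counts"][c])
            values = _record_pixels(
                config, domain, c, int(year), float(struct["signal"][c, j]),
                n_pix, n_t,
            )
            start, _ = cal.window(int(year))
            yield CompositeSeries(
                county_id=f"{domain[0].upper()}{c:04d}",
                season_year=int(year),
                values=values,
                mask_pixel_count=n_pix,
                start_date=start,
            )


def _bundle(config: SynthConfig, domain: str, with_series: bool) -> DomainBundle:
    struct = _structure(config, domain)
    cal = _calendars(config)[domain]
    records: list[YieldRecord] = []
    st_index: list[STIndex] = []
    signal: list[float] = []
    mask_counts: dict[str, int] = {}
    for c in range(struct["spec"]["n_counties"]):
        cid = f"{domain[0].upper()}{c:04d}"
        mask_counts[cid] = int(struct["mask_counts"][c])
        for j, year in enumerate(struct["years"]):
            records.append(
                YieldRecord(
                    county_id=cid,
                    season_year=int(year),
                    yield_bu_ac=float(struct["yields"][c, j]),
                    domain=domain,
                )
            )
            st_index.append(
                STIndex(g_loc=tuple(struct["centroids"][c]), g_year=float(year))
            )
            signal.append(float(struct["signal"][c, j]))
    series = list(iter_series(config, domain)) if with_series else []
    return DomainBundle(
        domain=domain,
        calendar=cal,
        series=series,
        records=records,
        st_index=st_index,
        signal=np.array(signal),
        mask_counts=mask_counts,
    )


def generate_domains(
    config: SynthConfig, with_series: bool = True
) -> tuple[DomainBundle, DomainBundle]:
    """Generate the (source, target) datasets.

    ``with_series=False`` skips materializing the pixel cubes (use
    :func:`iter_series` to stream them instead — the full source domain can
    be several GiB of pixels).
    """
    return _bundle(config, "source", with_series), _bundle(config, "target", with_series)


def domain_truth(config: SynthConfig, domain: str) -> dict:
    """The latent scaffold of a domain (centroids, effects, yields)."""
    return _structure(config, domain)


def oracle_predictor(dataset: DomainBundle) -> np.ndarray:
    """Noise-free latent-yield predictions, aligned with ``dataset.records``.

    The oracle knows the true yield function (base + trend + county effect);
    its RMSE against the observed yields equals the injected correlated-noise
    scale, the floor against which trained models are compared.
    """
    return dataset.signal.copy()
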