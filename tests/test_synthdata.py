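"""Statistical structure of the synthetic two-domain benchmark."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from yieldtransfer.features import clean_records
from yieldtransfer.pipeline import prepare_benchmark
from yieldtransfer.synthdata import (
    SynthConfig,
    generate_domains,
    iter_series,
    oracle_predictor,
)


def light_config(**kw):
    base = dict(
        n_source_counties=10,
        n_target_counties=6,
        seasons_source=(2010, 2013),
        seasons_target=(2011, 2013),
        pixels_per_county=(80, 120),
        cleansing_min_pixels=60,
        below_min_fraction=0.2,
        seed=3,
    )
    base.update(kw)
    return SynthConfig(**base)


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        cfg = light_config()
        s1, t1 = generate_domains(cfg)
        s2, t2 = generate_domains(cfg)
        for a, b in ((s1, s2), (t1, t2)):
            assert [r.yield_bu_ac for r in a.records] == [r.yield_bu_ac for r in b.records]
            for x, y in zip(a.series, b.series):
                np.testing.assert_array_equal(x.values, y.values)

    def test_streaming_matches_materialized(self):
        cfg = light_config()
        src, _ = generate_domains(cfg)
        streamed = list(iter_series(cfg, "source"))
        assert len(streamed) == len(src.series)
        np.testing.assert_array_equal(streamed[3].values, src.series[3].values)


class TestYieldStructure:
    def test_target_lower_and_positive_trends(self):
        cfg = light_config(
            n_source_counties=30, n_target_counties=30,
            seasons_source=(2010, 2019), seasons_target=(2010, 2019),
        )
        src, tgt = generate_domains(cfg, with_series=False)
        ys = np.array([r.yield_bu_ac for r in src.records])
        yt = np.array([r.yield_bu_ac for r in tgt.records])
        assert len(ys) >= 200 and len(yt) >= 200
        assert yt.mean() < ys.mean()
        for bundle, y in ((src, ys), (tgt, yt)):
            seasons = np.array([r.season_year for r in bundle.records], dtype=float)
            A = np.column_stack([seasons, np.ones_like(seasons)])
            slope = np.linalg.lstsq(A, y, rcond=None)[0][0]
            assert slope > 0

    def test_calendars_shifted_and_equal_length(self):
        cfg = light_config()
        src, tgt = generate_domains(cfg, with_series=False)
        shift = (tgt.calendar.start_date - src.calendar.start_date).days
        assert shift == cfg.calendar_offset_days
        assert src.calendar.n_composites == tgt.calendar.n_composites == 32


class TestOracle:
    def test_rmse_matches_injected_noise_scale(self):
        cfg = light_config(
            n_source_counties=50, seasons_source=(2010, 2019), residual_sd=2.0
        )
        src, _ = generate_domains(cfg, with_series=False)
        y = np.array([r.yield_bu_ac for r in src.records])
        err = oracle_predictor(src) - y
        assert len(err) == 500
        assert abs(np.sqrt(np.mean(err**2)) - 2.0) < 0.5

    def test_zero_noise_gives_zero_rmse(self):
        cfg = light_config(residual_sd=1e-9)
        src, _ = generate_domains(cfg, with_series=False)
        y = np.array([r.yield_bu_ac for r in src.records])
        assert np.sqrt(np.mean((oracle_predictor(src) - y) ** 2)) < 1e-3

    def test_oracle_not_worse_than_linear_probe(self, small_bench):
        """The oracle floor lower-bounds a feature-based model's error."""
        src = small_bench.source
        tr = src.seasons < src.seasons.max()
        te = ~tr
        A = np.hstack([src.X.reshape(src.n, -1), np.ones((src.n, 1))])
        w = np.linalg.solve(
            A[tr].T @ A[tr] + 1e-2 * np.eye(A.shape[1]), A[tr].T @ src.y[tr]
        )
        probe_rmse = np.sqrt(np.mean((A[te] @ w - src.y[te]) ** 2))
        oracle_rmse = np.sqrt(np.mean((src.signal[te] - src.y[te]) ** 2))
        assert oracle_rmse <= probe_rmse


class TestCleansingExercise:
    def test_below_threshold_counties_removed_exactly(self):
        cfg = light_config()
        src, tgt = generate_domains(cfg, with_series=False)
        for bundle, n_counties in ((src, 10), (tgt, 6)):
            n_below = int(round(cfg.below_min_fraction * n_counties))
            kept = clean_records(
                bundle.records, bundle.mask_counts, cfg.cleansing_min_pixels
            )
            n_seasons = len({r.season_year for r in bundle.records})
            assert len(bundle.records) - len(kept) == n_below * n_seasons


class TestSignalAndTransferStructure:
    def test_histogram_means_regress_on_yield(self, small_bench):
        """Pooled per-band histogram means carry yield signal (R^2 > 0)."""
        src = small_bench.source
        bin_centers = (small_bench.edges[:, :-1] + small_bench.edges[:, 1:]) / 2
        means = (src.X * bin_centers[None, :, None, :]).sum(axis=3).mean(axis=2)
        tr = src.seasons < src.seasons.max()
        A = np.hstack([means, np.ones((src.n, 1))])
        w = np.linalg.lstsq(A[tr], src.y[tr], rcond=None)[0]
        pred = A[~tr] @ w
        y = src.y[~tr]
        ss_res = np.sum((y - pred) ** 2)
        ss_tot = np.sum((y - y.mean()) ** 2)
        assert 1 - ss_res / ss_tot > 0

    def test_zero_shot_degrades_with_domain_distortion(self):
        """A source-trained linear readout transfers worse as the
        domain-specific distortion grows."""
        errors = []
        for dw in (0.0, 1.0, 2.0):
            cfg = light_config(
                domain_specific_weight=dw,
                n_source_counties=40,
                n_target_counties=30,
                seasons_source=(2010, 2015),
                seasons_target=(2010, 2015),
                yield_base_target=42.0,  # same level: isolates the distortion
                county_effect_sd=6.0,
                pixels_per_county=(300, 400),
                cleansing_min_pixels=200,
                below_min_fraction=0.0,
                atmos_sd=0.05,
                seed=11,
            )
            bench = prepare_benchmark(cfg, edge_sample_records=12)
            src, tgt = bench.source, bench.target
            centers = (bench.edges[:, :-1] + bench.edges[:, 1:]) / 2

            def feats(dom):
                means = (dom.X * centers[None, :, None, :]).sum(axis=3)
                return np.hstack(
                    [means.reshape(dom.n, -1), np.ones((dom.n, 1))]
                )

            A, At = feats(src), feats(tgt)
            w = np.linalg.solve(
                A.T @ A + 1e-2 * np.eye(A.shape[1]), A.T @ (src.y - src.y.mean())
            )
            pred = At @ w + tgt.y.mean()
            errors.append(float(np.sqrt(np.mean((pred - tgt.y) ** 2))))
        assert errors[0] < errors[1] < errors[2]

    def test_identical_maps_when_distortion_zero(self):
        """With no domain-specific distortion and equal yield levels the two
        domains produce statistically identical pixel distributions."""
        cfg = light_config(
            domain_specific_weight=0.0,
            yield_base_target=42.0,  # match source
            county_effect_sd=0.0,
            residual_sd=1e-9,
            seasons_source=(2012, 2012),
            seasons_target=(2012, 2012),
            pixels_per_county=(4000, 4001),
            cleansing_min_pixels=100,
            below_min_fraction=0.0,
            atmos_sd=1e-9,
            n_source_counties=2,
            n_target_counties=2,
        )
        src, tgt = generate_domains(cfg)
        for b in range(9):
            ms = np.mean([s.values[b].mean() for s in src.series])
            mt = np.mean([s.values[b].mean() for s in tgt.series])
            scale = 1.0 if b < 7 else 500.0
            assert abs(ms - mt) / scale < 0.02
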