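import numpy as np
import pytest

from segfcs import (
    ACFCurve,
    LagGrid,
    SegmentLabel,
    average_acfs,
    compute_segment_map,
    make_segment_grid,
    segment_acf,
    select_segments,
    zone_acf,
)
from segfcs.benchmarks import bruteforce_cross_acf

LT = 1.0 / 1400.0


class TestLagGrid:
    def test_linear_grid_is_line_time_multiples(self):
        grid = LagGrid.linear(LT, 10 * LT)
        assert np.allclose(grid.lags, np.arange(1, 11) * LT)

    def test_multitau_structure(self):
        grid = LagGrid.multitau(LT, 1.0, points_per_octave=8)
        assert grid.lags[0] == pytest.approx(LT)
        assert np.all(np.diff(grid.lags) > 0)
        assert grid.lags[-1] <= 1.0
        # binning doubles per octave
        assert set(np.unique(grid.bin_factors)) >= {1, 2, 4}

    def test_multitau_spans_less_points_than_linear(self):
        lin = LagGrid.linear(LT, 0.5)
        mt = LagGrid.multitau(LT, 0.5)
        assert len(mt.lags) < len(lin.lags) / 5

    def test_rejects_sub_line_time_max_lag(self):
        with pytest.raises(ValueError):
            LagGrid.multitau(LT, LT / 2)


class TestSegmentACF:
    def test_constant_series_has_zero_correlation(self):
        grid = LagGrid.linear(LT, 5 * LT)
        ch = np.full(1000, 4)
        curve = segment_acf(ch, ch, LT, grid)
        assert np.allclose(curve.G, 0.0, atol=1e-12)

    def test_alternating_series_lag_one(self):
        # [1,0,1,0,...]: means 0.5, lag-1 product always 0 -> G = -1
        ch = np.tile([1, 0], 500)
        grid = LagGrid.linear(LT, LT)
        curve = segment_acf(ch, ch, LT, grid)
        assert curve.G[0] == pytest.approx(-1.0, abs=1e-12)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(5)
        grid = LagGrid.linear(LT, 20 * LT)
        for _ in range(10):
            ch1 = rng.poisson(2.0, 1000)
            ch2 = rng.poisson(3.0, 1000)
            fast = segment_acf(ch1, ch2, LT, grid).G
            brute = bruteforce_cross_acf(ch1, ch2, grid.lag_steps)
            assert np.abs(fast - brute).max() < 1e-10

    def test_multitau_binned_lags_match_binned_bruteforce(self):
        rng = np.random.default_rng(6)
        ch1 = rng.poisson(2.0, 4096)
        ch2 = rng.poisson(2.0, 4096)
        grid = LagGrid.multitau(LT, 200 * LT, points_per_octave=4)
        curve = segment_acf(ch1, ch2, LT, grid)
        for i in np.nonzero(grid.bin_factors == 2)[0]:
            b1 = ch1[: len(ch1) // 2 * 2].reshape(-1, 2).sum(axis=1)
            b2 = ch2[: len(ch2) // 2 * 2].reshape(-1, 2).sum(axis=1)
            brute = bruteforce_cross_acf(b1, b2, [grid.lag_steps[i]])[0]
            assert curve.G[i] == pytest.approx(brute, abs=1e-10)

    def test_zero_mean_channel_rejected(self):
        grid = LagGrid.linear(LT, 2 * LT)
        with pytest.raises(ValueError, match="zero-mean"):
            segment_acf(np.zeros(100, dtype=int), np.ones(100, dtype=int), LT, grid)

    def test_short_segment_rejected(self):
        grid = LagGrid.linear(LT, 30 * LT)
        with pytest.raises(ValueError, match="shorter"):
            segment_acf(np.ones(100, dtype=int), np.ones(100, dtype=int), LT, grid)


class TestAverageACFs:
    def _curve(self, g):
        lags = np.arange(1, 4) * LT
        return ACFCurve(lags=lags, G=np.asarray(g, dtype=float))

    def test_identical_curves(self):
        avg = average_acfs([self._curve([0.5, 0.2, 0.1])] * 2)
        assert np.allclose(avg.G, [0.5, 0.2, 0.1])
        assert np.allclose(avg.sem, 0.0)
        assert avg.n_segments_averaged == 2

    def test_two_point_statistics(self):
        avg = average_acfs([self._curve([0.1] * 3), self._curve([0.3] * 3)])
        assert np.allclose(avg.G, 0.2)
        assert np.allclose(avg.sem, 0.1)

    def test_mixed_grids_rejected(self):
        a = self._curve([0.1, 0.2, 0.3])
        b = ACFCurve(lags=np.arange(2, 5) * LT, G=np.zeros(3))
        with pytest.raises(ValueError):
            average_acfs([a, b])
        with pytest.raises(ValueError):
            average_acfs([])

    def test_sem_shrinks_like_sqrt_n(self):
        rng = np.random.default_rng(8)
        grid = LagGrid.linear(LT, 5 * LT)

        def batch(n):
            curves = []
            for _ in range(n):
                tot = rng.poisson(3.0, 600)
                ch1 = rng.binomial(tot, 0.5)
                curves.append(segment_acf(ch1, tot - ch1, LT, grid))
            return average_acfs(curves).sem.mean()

        s4, s16, s64 = batch(4), batch(16), batch(64)
        assert s16 == pytest.approx(s4 / 2, rel=0.5)
        assert s64 == pytest.approx(s4 / 4, rel=0.5)
        assert s4 > s16 > s64


class TestZoneACF:
    def test_identical_segments_reproduce_single_acf(self, small_meta_carpet=None):
        from segfcs import LineScanCarpet
        from conftest import make_meta

        meta = make_meta(n_lines=1200, n_pixels=8, damage_line_end=99, damage_pixels=(3, 4))
        rng = np.random.default_rng(2)
        column = rng.poisson(3.0, (2, 1100))
        counts = np.zeros((2, 1200, 8), dtype=np.int64)
        counts[:, 100:1200, :] = column[:, :, None]  # every column identical
        carpet = LineScanCarpet(counts=counts, meta=meta)
        grid = make_segment_grid(meta, n_segments_per_column=1)
        smap = compute_segment_map(carpet, grid)
        manual = np.full((8, 1), int(SegmentLabel.OUT))
        manual[3:5] = int(SegmentLabel.IN)
        sel = select_segments(smap, grid, meta, manual_labels=manual)
        lg = LagGrid.linear(meta.line_time, 10 * meta.line_time)
        zone = zone_acf(carpet, grid, sel, SegmentLabel.IN, lg, min_photons=1)
        single = segment_acf(counts[0, 100:, 3], counts[1, 100:, 3], meta.line_time, lg)
        assert np.allclose(zone.G, single.G)
        assert np.allclose(zone.sem, 0.0)

    def test_null_carpet_zones_indistinguishable(self, null_sim):
        # without a binding strip, forcing IN over the strip and OUT far away
        # must give statistically identical curves; columns are sampled with a
        # stride wider than the detection spot so the segments are independent
        # and the across-segment sem is a valid yardstick
        _, carpet, _ = null_sim
        meta = carpet.meta
        grid = make_segment_grid(meta, n_segments_per_column=10, analysis_start_line=0)
        smap = compute_segment_map(carpet, grid)
        manual = np.full((smap.n_columns, smap.n_segments), int(SegmentLabel.EXCLUDED))
        in_cols = np.arange(meta.damage_pixel_start, meta.damage_pixel_end + 1, 8)
        manual[in_cols, :] = int(SegmentLabel.IN)
        manual[np.arange(0, meta.damage_pixel_start - 8, 8), :] = int(SegmentLabel.OUT)
        sel = select_segments(smap, grid, meta, manual_labels=manual)
        lg = LagGrid.multitau(meta.line_time, grid.segment_duration(meta.line_time) / 4)
        cin = zone_acf(carpet, grid, sel, SegmentLabel.IN, lg)
        cout = zone_acf(carpet, grid, sel, SegmentLabel.OUT, lg)
        z = np.abs(cin.G - cout.G) / np.sqrt(cin.sem**2 + cout.sem**2)
        assert z.max() < 4.0
        assert z.mean() < 1.5

    def test_binding_strip_slows_in_zone_decay(self, binding_sim):
        _, carpet, _ = binding_sim
        meta = carpet.meta
        grid = make_segment_grid(meta, segment_duration=4.0)
        smap = compute_segment_map(carpet, grid)
        sel = select_segments(smap, grid, meta)
        lg = LagGrid.multitau(meta.line_time, grid.segment_duration(meta.line_time) / 4)
        cin = zone_acf(carpet, grid, sel, SegmentLabel.IN, lg)
        cout = zone_acf(carpet, grid, sel, SegmentLabel.OUT, lg)
        i = np.argmin(np.abs(cin.lags - 0.1))
        assert cin.G[i] / cin.G[0] > cout.G[i] / cout.G[0]

    def test_empty_zone_rejected(self, null_sim):
        _, carpet, _ = null_sim
        meta = carpet.meta
        grid = make_segment_grid(meta, n_segments_per_column=5, analysis_start_line=0)
        smap = compute_segment_map(carpet, grid)
        manual = np.full((smap.n_columns, smap.n_segments), int(SegmentLabel.EXCLUDED))
        manual[0, :] = int(SegmentLabel.OUT)
        manual[1, :] = int(SegmentLabel.IN)
        sel = select_segments(smap, grid, meta, manual_labels=manual)
        lg = LagGrid.linear(meta.line_time, 5 * meta.line_time)
        with pytest.raises(ValueError, match="no usable segments"):
            # min_photons high enough to reject every segment
            zone_acf(carpet, grid, sel, SegmentLabel.IN, lg, min_photons=10**9)


class TestSegmentationDetrending:
    def test_segmented_acf_beats_whole_trace_under_bleaching(self):
        # strong bleaching puts a slow positive tail in the un-segmented ACF;
        # segment-local normalization suppresses it at long lags
        from segfcs import SimulationConfig, simulate_carpet

        cfg = SimulationConfig(
            n_particles=150, n_pixels=32, n_lines=60_000, D_free=3.8,
            k_on=0.0, bleach_rate=0.6, damage_on_time=0.0, seed=17,
        )
        carpet, _ = simulate_carpet(cfg)
        meta = carpet.meta
        lg = LagGrid.multitau(meta.line_time, 2.0)
        long_lags = lg.lags > 1.0

        whole = make_segment_grid(meta, n_segments_per_column=1, analysis_start_line=0)
        seg = make_segment_grid(meta, n_segments_per_column=5, analysis_start_line=0)
        from segfcs import carpet_acf

        g_whole = carpet_acf(carpet, whole, lg).G
        g_seg = carpet_acf(carpet, seg, lg).G
        assert np.abs(g_seg[long_lags]).mean() < np.abs(g_whole[long_lags]).mean()
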