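import numpy as np
import pytest

from segfcs import (
    LineScanCarpet,
    SegmentLabel,
    SelectionError,
    compute_segment_map,
    make_segment_grid,
    select_segments,
)
from conftest import make_meta


class TestSegmentGrid:
    def test_protocol_segmentation(self):
        # a 417,690-line, 5-minute acquisition divided into 32 segments gives
        # 13,052-line segments lasting about 9.3 s at 1400 Hz
        meta = make_meta(n_lines=417_690, damage_line_end=1535)
        grid = make_segment_grid(meta, n_segments_per_column=32, analysis_start_line=0)
        assert grid.lines_per_segment == 13_052
        assert round(grid.segment_duration(meta.line_time), 1) == 9.3

    def test_exact_and_floor_division(self):
        meta = make_meta(n_lines=100, damage_line_end=0)
        grid = make_segment_grid(meta, n_segments_per_column=10, analysis_start_line=0)
        assert grid.lines_per_segment == 10

        meta = make_meta(n_lines=105, damage_line_end=0)
        grid = make_segment_grid(meta, n_segments_per_column=10, analysis_start_line=0)
        assert grid.lines_per_segment == 10  # 5 remainder lines discarded
        assert grid.n_lines_used == 100

    def test_duration_based_grid(self):
        meta = make_meta(n_lines=10_000, line_frequency=1000.0, damage_line_end=0)
        grid = make_segment_grid(meta, segment_duration=1.0, analysis_start_line=0)
        assert grid.lines_per_segment == 1000
        assert grid.n_segments_per_column == 10

    def test_analysis_starts_after_damage_by_default(self):
        meta = make_meta(n_lines=1000, damage_line_end=99)
        grid = make_segment_grid(meta, n_segments_per_column=9)
        assert grid.analysis_start_line == 100
        assert grid.line_slice(0).start == 100

    def test_invalid_requests(self):
        meta = make_meta(n_lines=1000)
        with pytest.raises(ValueError):
            make_segment_grid(meta)  # neither
        with pytest.raises(ValueError):
            make_segment_grid(meta, segment_duration=1.0, n_segments_per_column=4)
        with pytest.raises(ValueError):
            make_segment_grid(meta, segment_duration=1e-9)  # below line time
        with pytest.raises(ValueError):
            make_segment_grid(meta, n_segments_per_column=5000)  # zero-length segments

    def test_partition_covers_lines_once(self):
        meta = make_meta(n_lines=1000, damage_line_end=99)
        grid = make_segment_grid(meta, n_segments_per_column=7)
        seen = np.zeros(meta.n_lines, dtype=int)
        for j in range(grid.n_segments_per_column):
            seen[grid.line_slice(j)] += 1
        assert seen.max() == 1
        assert seen[: grid.analysis_start_line].sum() == 0
        assert seen.sum() == grid.n_lines_used


class TestSegmentMap:
    def test_constant_carpet(self, constant_carpet):
        grid = make_segment_grid(constant_carpet.meta, n_segments_per_column=9)
        smap = compute_segment_map(constant_carpet, grid)
        assert np.allclose(smap.raw, 6.0)  # both channels summed
        assert np.allclose(smap.normalized, 1.0)

    def test_row_normalization(self, small_meta):
        # one temporal row with column means [2,4,8,4] normalizes to /8
        counts = np.zeros((2, small_meta.n_lines, small_meta.n_pixels), dtype=np.int64)
        per_col = np.ones(small_meta.n_pixels, dtype=np.int64)
        per_col[:4] = [1, 2, 4, 2]
        counts[0] = per_col  # broadcast over lines; channel 2 stays zero
        carpet = LineScanCarpet(counts=counts, meta=small_meta)
        grid = make_segment_grid(carpet.meta, n_segments_per_column=4, analysis_start_line=0)
        smap = compute_segment_map(carpet, grid)
        assert np.allclose(smap.raw[:4, 0], [1, 2, 4, 2])
        assert np.allclose(smap.normalized[:4, 0], [0.25, 0.5, 1.0, 0.5])
        assert np.all(smap.normalized <= 1.0) and np.all(smap.normalized >= 0.0)

    def test_matches_bruteforce_means(self, small_meta):
        rng = np.random.default_rng(3)
        counts = rng.poisson(2.0, (2, small_meta.n_lines, small_meta.n_pixels))
        carpet = LineScanCarpet(counts=counts, meta=small_meta)
        grid = make_segment_grid(carpet.meta, n_segments_per_column=6)
        smap = compute_segment_map(carpet, grid)
        total = counts.sum(axis=0)
        for j in range(grid.n_segments_per_column):
            sl = grid.line_slice(j)
            for i in range(small_meta.n_pixels):
                assert smap.raw[i, j] == pytest.approx(total[sl, i].mean(), abs=1e-12)

    def test_all_zero_row_flagged(self, small_meta):
        counts = np.ones((2, small_meta.n_lines, small_meta.n_pixels), dtype=np.int64)
        grid = make_segment_grid(small_meta, n_segments_per_column=4)
        counts[:, grid.line_slice(2), :] = 0
        carpet = LineScanCarpet(counts=counts, meta=small_meta)
        smap = compute_segment_map(carpet, grid)
        assert smap.zero_rows[2]
        assert np.all(smap.normalized[:, 2] == 0.0)

    def test_every_nonzero_row_attains_one(self, small_meta):
        rng = np.random.default_rng(9)
        counts = rng.poisson(3.0, (2, small_meta.n_lines, small_meta.n_pixels))
        carpet = LineScanCarpet(counts=counts, meta=small_meta)
        grid = make_segment_grid(small_meta, n_segments_per_column=5)
        smap = compute_segment_map(carpet, grid)
        assert np.allclose(smap.normalized.max(axis=0), 1.0)


class TestSelection:
    def make_map_carpet(self, small_meta, hot_cols=(6, 7, 8, 9)):
        counts = np.ones((2, small_meta.n_lines, small_meta.n_pixels), dtype=np.int64)
        counts[:, :, hot_cols] = 10
        return LineScanCarpet(counts=counts, meta=small_meta)

    def test_threshold_classification(self, small_meta):
        carpet = self.make_map_carpet(small_meta)
        grid = make_segment_grid(small_meta, n_segments_per_column=4)
        smap = compute_segment_map(carpet, grid)
        sel = select_segments(smap, grid, small_meta, in_threshold=0.8, out_threshold=0.5)
        labels = sel.labels
        assert np.all(labels[6:10, :] == int(SegmentLabel.IN))
        # far columns: normalized 0.1 <= 0.5 -> OUT where allowed
        assert labels[0, 0] == int(SegmentLabel.OUT)
        assert sel.count(SegmentLabel.IN) == 16

    def test_pre_damage_segments_excluded(self, small_meta):
        carpet = self.make_map_carpet(small_meta)
        # force the grid to start before the end of damage induction
        grid = make_segment_grid(small_meta, n_segments_per_column=10, analysis_start_line=0)
        smap = compute_segment_map(carpet, grid)
        sel = select_segments(smap, grid, small_meta)
        for j in range(grid.n_segments_per_column):
            if grid.line_slice(j).start <= small_meta.damage_line_end:
                assert np.all(sel.labels[:, j] == int(SegmentLabel.EXCLUDED))

    def test_empty_selection_raises_with_thresholds(self, small_meta):
        counts = np.ones((2, small_meta.n_lines, small_meta.n_pixels), dtype=np.int64)
        carpet = LineScanCarpet(counts=counts, meta=small_meta)  # flat: no IN
        grid = make_segment_grid(small_meta, n_segments_per_column=4)
        smap = compute_segment_map(carpet, grid)
        with pytest.raises(SelectionError, match="in_threshold=0.8"):
            select_segments(smap, grid, small_meta)

    def test_selection_idempotent(self, small_meta):
        carpet = self.make_map_carpet(small_meta)
        grid = make_segment_grid(small_meta, n_segments_per_column=4)
        smap = compute_segment_map(carpet, grid)
        s1 = select_segments(smap, grid, small_meta)
        s2 = select_segments(smap, grid, small_meta)
        assert np.array_equal(s1.labels, s2.labels)

    def test_manual_mask(self, small_meta):
        carpet = self.make_map_carpet(small_meta)
        grid = make_segment_grid(small_meta, n_segments_per_column=4)
        smap = compute_segment_map(carpet, grid)
        manual = np.full((smap.n_columns, smap.n_segments), int(SegmentLabel.EXCLUDED))
        manual[7, :] = int(SegmentLabel.IN)
        manual[0, :] = int(SegmentLabel.OUT)
        sel = select_segments(smap, grid, small_meta, manual_labels=manual)
        assert sel.provenance == "manual"
        assert sel.count(SegmentLabel.IN) == smap.n_segments

    def test_in_brighter_than_out_on_binding_strip(self, binding_sim):
        cfg, carpet, _ = binding_sim
        meta = carpet.meta
        grid = make_segment_grid(meta, n_segments_per_column=5)
        smap = compute_segment_map(carpet, grid)
        sel = select_segments(smap, grid, meta)
        in_mean = np.mean([smap.raw[i, j] for i, j in sel.segments(SegmentLabel.IN)])
        out_mean = np.mean([smap.raw[i, j] for i, j in sel.segments(SegmentLabel.OUT)])
        assert in_mean > out_mean
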