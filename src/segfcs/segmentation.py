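"""Temporal segmentation of carpets and intensity-based zone selection.

The carpet is divided along its temporal axis into equal-duration segments,
one stack of segments per pixel column.  The per-segment mean intensity map
(columns x segments) is normalized row-wise — each temporal row is divided
by its maximum across columns — so that the damage strip stands out in every
row regardless of slow intensity trends such as photobleaching.  Segments
are then classified IN (damage region), OUT (undamaged reference region) or
EXCLUDED by thresholding the normalized map, restricted spatially so that
OUT segments are well clear of the strip.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import Iterator

import numpy as np
import pandas as pd

from .carpet_io import AcquisitionMeta, LineScanCarpet

__all__ = [
    "SegmentGrid",
    "SegmentIntensityMap",
    "SegmentLabel",
    "SegmentSelection",
    "SelectionError",
    "make_segment_grid",
    "compute_segment_map",
    "select_segments",
]


class SelectionError(ValueError):
    """Raised when a zone selection comes out empty."""


class SegmentLabel(IntEnum):
    EXCLUDED = 0
    IN = 1
    OUT = 2


@dataclass(frozen=True)
class SegmentGrid:
    """Partition of the analyzed lines into equal temporal segments.

    Lines before ``analysis_start_line`` and remainder lines after the last
    full segment are not covered by any segment.
    """

    lines_per_segment: int
    n_segments_per_column: int
    n_columns: int
    analysis_start_line: int

    def __post_init__(self) -> None:
        if self.lines_per_segment < 1 or self.n_segments_per_column < 1:
            raise ValueError("grid must contain at least one non-empty segment")

    def line_slice(self, j: int) -> slice:
        """Lines belonging to temporal segment ``j`` (same for every column)."""
        start = self.analysis_start_line + j * self.lines_per_segment
        return slice(start, start + self.lines_per_segment)

    def segment_duration(self, line_time: float) -> float:
        return self.lines_per_segment * line_time

    @property
    def n_lines_used(self) -> int:
        return self.lines_per_segment * self.n_segments_per_column


def make_segment_grid(
    meta: AcquisitionMeta,
    segment_duration: float | None = None,
    n_segments_per_column: int | None = None,
    analysis_start_line: int | None = None,
) -> SegmentGrid:
    """Build the segment grid from either a target duration or a segment count.

    Exactly one of ``segment_duration`` (seconds) and
    ``n_segments_per_column`` must be given.  ``analysis_start_line`` defaults
    to the first line after the damage induction, since the fluctuation
    analysis is applied to post-damage data only.  Remainder lines that do
    not fill a whole segment are discarded so all segments share one
    duration and their correlation functions are comparable.
    """
    if (segment_duration is None) == (n_segments_per_column is None):
        raise ValueError(
            "give exactly one of segment_duration / n_segments_per_column"
        )
    if analysis_start_line is None:
        analysis_start_line = meta.damage_line_end + 1
    if not 0 <= analysis_start_line < meta.n_lines:
        raise ValueError(
            f"analysis_start_line {analysis_start_line} outside 0..{meta.n_lines - 1}"
        )
    available = meta.n_lines - analysis_start_line

    if n_segments_per_column is not None:
        if n_segments_per_column < 1:
            raise ValueError("n_segments_per_column must be >= 1")
        lps = available // n_segments_per_column
        if lps < 1:
            raise ValueError(
                f"{available} lines cannot hold {n_segments_per_column} segments"
            )
        n_seg = n_segments_per_column
    else:
        if segment_duration < meta.line_time:
            raise ValueError(
                f"segment_duration {segment_duration} s is below the line time"
            )
        lps = int(round(segment_duration / meta.line_time))
        n_seg = available // lps
        if n_seg < 1:
            raise ValueError(
                f"segment of {lps} lines does not fit in {available} available lines"
            )
    return SegmentGrid(
        lines_per_segment=lps,
        n_segments_per_column=n_seg,
        n_columns=meta.n_pixels,
        analysis_start_line=analysis_start_line,
    )


@dataclass
class SegmentIntensityMap:
    """Per-(column, segment) mean intensities, raw and row-normalized.

    ``raw[i, j]`` is the mean channel-summed count per line of column ``i``
    in temporal segment ``j``.  ``normalized[:, j]`` is ``raw[:, j]`` divided
    by its maximum across columns; all-zero rows stay zero and are flagged in
    ``zero_rows``.
    """

    raw: np.ndarray
    normalized: np.ndarray
    zero_rows: np.ndarray  # bool per segment index

    @property
    def n_columns(self) -> int:
        return self.raw.shape[0]

    @property
    def n_segments(self) -> int:
        return self.raw.shape[1]

    def to_frame(self, labels: np.ndarray | None = None) -> pd.DataFrame:
        cols, segs = np.meshgrid(
            np.arange(self.n_columns), np.arange(self.n_segments), indexing="ij"
        )
        data = {
            "column_index": cols.ravel(),
            "segment_index": segs.ravel(),
            "raw_mean": self.raw.ravel(),
            "normalized": self.normalized.ravel(),
        }
        if labels is not None:
            data["label"] = [SegmentLabel(v).name for v in labels.ravel()]
        return pd.DataFrame(data)


def compute_segment_map(carpet: LineScanCarpet, grid: SegmentGrid) -> SegmentIntensityMap:
    """Mean channel-summed intensity per (column, temporal segment)."""
    if grid.n_columns != carpet.meta.n_pixels:
        raise ValueError("grid column count disagrees with the carpet")
    end = grid.analysis_start_line + grid.n_lines_used
    if end > carpet.meta.n_lines:
        raise ValueError("grid extends past the end of the carpet")
    total = carpet.total[grid.analysis_start_line : end].astype(np.float64)
    # (segments, lines_per_segment, columns) -> mean over each segment's lines
    per_seg = total.reshape(
        grid.n_segments_per_column, grid.lines_per_segment, grid.n_columns
    ).mean(axis=1)
    raw = per_seg.T  # columns x segments
    row_max = raw.max(axis=0)
    zero_rows = row_max == 0
    safe = np.where(zero_rows, 1.0, row_max)
    normalized = raw / safe
    normalized[:, zero_rows] = 0.0
    return SegmentIntensityMap(raw=raw, normalized=normalized, zero_rows=zero_rows)


@dataclass
class SegmentSelection:
    """Zone labels per (column, segment), plus the thresholds that produced them."""

    labels: np.ndarray  # int matrix [n_columns, n_segments] of SegmentLabel
    in_threshold: float
    out_threshold: float
    provenance: str = "automatic"

    def segments(self, label: SegmentLabel) -> Iterator[tuple[int, int]]:
        """Yield (column, segment) pairs carrying ``label``."""
        for i, j in zip(*np.nonzero(self.labels == int(label))):
            yield int(i), int(j)

    def count(self, label: SegmentLabel) -> int:
        return int((self.labels == int(label)).sum())

    def summary(self) -> dict:
        return {lab.name: self.count(lab) for lab in SegmentLabel}


def select_segments(
    smap: SegmentIntensityMap,
    grid: SegmentGrid,
    meta: AcquisitionMeta,
    in_threshold: float = 0.8,
    out_threshold: float = 0.5,
    x_restrict_in: tuple[int, int] | None = None,
    x_restrict_out: tuple[int, int] | None = None,
    manual_labels: np.ndarray | None = None,
) -> SegmentSelection:
    """Classify segments into the damage (IN) and reference (OUT) zones.

    A post-damage segment is IN when its normalized intensity is at least
    ``in_threshold`` and its column lies in ``x_restrict_in`` (default: the
    damage pixel range); OUT when its normalized intensity is at most
    ``out_threshold`` and its column lies in ``x_restrict_out`` (default:
    columns at least one full strip width away from the strip).  Everything
    else, and every segment overlapping lines up to the end of the damage
    induction, is EXCLUDED.  ``manual_labels`` bypasses the thresholds with
    a user-provided label matrix of the same shape.
    """
    if not (0.0 <= out_threshold <= in_threshold <= 1.0):
        raise ValueError(
            f"need 0 <= out_threshold <= in_threshold <= 1, got "
            f"out={out_threshold}, in={in_threshold}"
        )
    shape = (smap.n_columns, smap.n_segments)
    if manual_labels is not None:
        manual_labels = np.asarray(manual_labels, dtype=int)
        if manual_labels.shape != shape:
            raise ValueError("manual label matrix shape mismatch")
        sel = SegmentSelection(
            labels=manual_labels.copy(),
            in_threshold=in_threshold,
            out_threshold=out_threshold,
            provenance="manual",
        )
    else:
        cols = np.arange(smap.n_columns)
        dps, dpe = meta.damage_pixel_start, meta.damage_pixel_end
        if x_restrict_in is None:
            in_cols = (cols >= dps) & (cols <= dpe)
        else:
            in_cols = (cols >= x_restrict_in[0]) & (cols <= x_restrict_in[1])
        if x_restrict_out is None:
            width = dpe - dps + 1  # 2x strip half-width
            out_cols = (cols <= dps - width) | (cols >= dpe + width)
        else:
            out_cols = (cols >= x_restrict_out[0]) & (cols <= x_restrict_out[1])

        labels = np.full(shape, int(SegmentLabel.EXCLUDED), dtype=int)
        labels[np.ix_(in_cols, np.arange(smap.n_segments))] = np.where(
            smap.normalized[in_cols] >= in_threshold,
            int(SegmentLabel.IN),
            int(SegmentLabel.EXCLUDED),
        )
        labels[np.ix_(out_cols, np.arange(smap.n_segments))] = np.where(
            smap.normalized[out_cols] <= out_threshold,
            int(SegmentLabel.OUT),
            int(SegmentLabel.EXCLUDED),
        )
        sel = SegmentSelection(
            labels=labels,
            in_threshold=in_threshold,
            out_threshold=out_threshold,
            provenance="automatic",
        )

    # segments overlapping the damage induction (or earlier) carry no
    # interpretable post-damage signal
    for j in range(smap.n_segments):
        if grid.line_slice(j).start <= meta.damage_line_end:
            sel.labels[:, j] = int(SegmentLabel.EXCLUDED)

    if sel.count(SegmentLabel.IN) == 0:
        raise SelectionError(
            f"empty IN selection (in_threshold={in_threshold}, "
            f"out_threshold={out_threshold})"
        )
    if sel.count(SegmentLabel.OUT) == 0:
        raise SelectionError(
            f"empty OUT selection (in_threshold={in_threshold}, "
            f"out_threshold={out_threshold})"
        )
    return sel
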