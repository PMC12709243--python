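"""Segment-wise cross-channel correlation functions.

For a temporal segment of one pixel column the correlation amplitude at lag
``tau = k * line_time`` is

    G(tau) = <I1(t) I2(t + k)>_T / (<I1>_T <I2>_T) - 1,

where the two series are the photon counts of the two detection channels and
every average is taken over the segment only (segment-local normalization is
what suppresses slow drifts such as photobleaching — the heart of segmented
FCS).  Cross-correlating the two channels removes detector noise, which is
uncorrelated between them.  The estimate is symmetrized by averaging the two
shift directions.  Lags follow either a linear grid or the standard
multi-tau scheme, in which the series is progressively binned by a factor of
two per octave so that a millisecond-to-seconds lag span stays cheap and
low-variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .carpet_io import LineScanCarpet
from .segmentation import SegmentGrid, SegmentLabel, SegmentSelection

__all__ = [
    "LagGrid",
    "ACFCurve",
    "segment_acf",
    "average_acfs",
    "zone_acf",
    "carpet_acf",
]


@dataclass(frozen=True)
class LagGrid:
    """Lag times at which correlations are evaluated.

    ``lag_steps[i]`` is the lag in samples of the series *after* binning by
    ``bin_factors[i]``, so ``lags[i] = lag_steps[i] * bin_factors[i] *
    line_time``.
    """

    lags: np.ndarray  # seconds, strictly increasing
    lag_steps: np.ndarray
    bin_factors: np.ndarray
    line_time: float
    scheme: str
    points_per_octave: int | None = None

    def __post_init__(self) -> None:
        if len(self.lags) == 0:
            raise ValueError("empty lag grid")
        if np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be strictly increasing")

    @property
    def max_lag_lines(self) -> int:
        """Largest lag expressed in un-binned lines."""
        return int((self.lag_steps * self.bin_factors).max())

    @classmethod
    def linear(cls, line_time: float, max_lag: float) -> "LagGrid":
        """Every multiple of the line time up to ``max_lag``."""
        kmax = int(max_lag / line_time)
        if kmax < 1:
            raise ValueError("max_lag below one line time")
        k = np.arange(1, kmax + 1)
        return cls(
            lags=k * line_time,
            lag_steps=k,
            bin_factors=np.ones_like(k),
            line_time=line_time,
            scheme="linear",
        )

    @classmethod
    def multitau(
        cls, line_time: float, max_lag: float, points_per_octave: int = 8
    ) -> "LagGrid":
        """Quasi-logarithmic grid, binning the series by 2 per octave."""
        ppo = int(points_per_octave)
        if ppo < 1:
            raise ValueError("points_per_octave must be >= 1")
        steps, bins = [], []
        for k in range(1, 2 * ppo + 1):
            if k * line_time <= max_lag:
                steps.append(k)
                bins.append(1)
        b = 2
        while (ppo + 1) * b * line_time <= max_lag:
            for k in range(ppo + 1, 2 * ppo + 1):
                if k * b * line_time <= max_lag:
                    steps.append(k)
                    bins.append(b)
            b *= 2
        if not steps:
            raise ValueError("max_lag below one line time")
        steps = np.asarray(steps)
        bins = np.asarray(bins)
        return cls(
            lags=steps * bins * line_time,
            lag_steps=steps,
            bin_factors=bins,
            line_time=line_time,
            scheme="multitau",
            points_per_octave=ppo,
        )


@dataclass
class ACFCurve:
    """A correlation curve, possibly averaged over several segments."""

    lags: np.ndarray  # seconds
    G: np.ndarray
    sem: np.ndarray | None = None  # dispersion across averaged segments
    n_segments_averaged: int = 1

    def __post_init__(self) -> None:
        if len(self.lags) != len(self.G):
            raise ValueError("lags and G must have the same length")
        if self.sem is not None and np.any(self.sem < 0):
            raise ValueError("sem must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lag_s": self.lags,
                "G": self.G,
                "sem": np.zeros_like(self.G) if self.sem is None else self.sem,
                "n_segments": self.n_segments_averaged,
            }
        )


def _bin_counts(x: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return x
    n = (len(x) // factor) * factor
    return x[:n].reshape(-1, factor).sum(axis=1)


def segment_acf(
    ch1: np.ndarray, ch2: np.ndarray, line_time: float, grid: LagGrid
) -> ACFCurve:
    """Symmetrized cross-channel correlation of one segment.

    Both shift directions are averaged; the time average in the numerator
    runs over the overlapping range only, while the normalization uses the
    full-segment channel means.
    """
    ch1 = np.asarray(ch1, dtype=np.float64)
    ch2 = np.asarray(ch2, dtype=np.float64)
    if ch1.shape != ch2.shape or ch1.ndim != 1:
        raise ValueError("channels must be 1D series of equal length")
    if len(ch1) < 4 * grid.max_lag_lines:
        raise ValueError(
            f"segment of {len(ch1)} lines is shorter than 4x the max lag "
            f"({grid.max_lag_lines} lines)"
        )
    if ch1.mean() == 0 or ch2.mean() == 0:
        raise ValueError("zero-mean channel: correlation undefined")

    G = np.empty(len(grid.lags))
    for b in np.unique(grid.bin_factors):
        b1 = _bin_counts(ch1, int(b))
        b2 = _bin_counts(ch2, int(b))
        denom = b1.mean() * b2.mean()
        idx = np.nonzero(grid.bin_factors == b)[0]
        for i in idx:
            k = int(grid.lag_steps[i])
            fwd = np.mean(b1[:-k] * b2[k:])
            bwd = np.mean(b2[:-k] * b1[k:])
            G[i] = 0.5 * (fwd + bwd) / denom - 1.0
    return ACFCurve(lags=grid.lags.copy(), G=G, sem=None, n_segments_averaged=1)


def average_acfs(curves: list[ACFCurve]) -> ACFCurve:
    """Pointwise mean of same-grid curves, with the across-curve standard error."""
    if not curves:
        raise ValueError("no curves to average")
    lags = curves[0].lags
    for c in curves[1:]:
        if len(c.lags) != len(lags) or not np.allclose(c.lags, lags, rtol=0, atol=0):
            raise ValueError("curves do not share an identical lag grid")
    if len(curves) == 1:
        c = curves[0]
        return ACFCurve(lags=lags.copy(), G=c.G.copy(), sem=None, n_segments_averaged=1)
    stack = np.stack([c.G for c in curves])
    return ACFCurve(
        lags=lags.copy(),
        G=stack.mean(axis=0),
        sem=stack.std(axis=0, ddof=1) / np.sqrt(len(curves)),
        n_segments_averaged=len(curves),
    )


def _segment_series(
    carpet: LineScanCarpet, grid: SegmentGrid, col: int, j: int
) -> tuple[np.ndarray, np.ndarray]:
    sl = grid.line_slice(j)
    return carpet.counts[0, sl, col], carpet.counts[1, sl, col]


def zone_acf(
    carpet: LineScanCarpet,
    grid: SegmentGrid,
    selection: SegmentSelection,
    zone: SegmentLabel | str,
    lag_grid: LagGrid,
    min_photons: int = 100,
) -> ACFCurve:
    """Average correlation curve over all segments labelled with ``zone``.

    Segments with fewer than ``min_photons`` detected photons in either
    channel carry essentially no correlation information (the shot-noise
    error of their G estimate exceeds order unity) and are skipped; the
    curve's ``n_segments_averaged`` reflects the segments actually used.
    """
    if isinstance(zone, str):
        zone = SegmentLabel[zone]
    curves = []
    for col, j in selection.segments(zone):
        ch1, ch2 = _segment_series(carpet, grid, col, j)
        if ch1.sum() < max(min_photons, 1) or ch2.sum() < max(min_photons, 1):
            continue
        curves.append(segment_acf(ch1, ch2, carpet.meta.line_time, lag_grid))
    if not curves:
        raise ValueError(f"no usable segments labelled {zone.name}")
    return average_acfs(curves)


def carpet_acf(
    carpet: LineScanCarpet,
    grid: SegmentGrid,
    lag_grid: LagGrid,
    columns: np.ndarray | None = None,
) -> ACFCurve:
    """Average correlation over *all* segments (optionally restricted columns).

    Convenience for homogeneous data (e.g. no-damage acquisitions) where no
    zone selection applies.
    """
    if columns is None:
        columns = np.arange(grid.n_columns)
    curves = []
    for col in columns:
        for j in range(grid.n_segments_per_column):
            ch1, ch2 = _segment_series(carpet, grid, int(col), j)
            if ch1.mean() == 0 or ch2.mean() == 0:
                continue
            curves.append(segment_acf(ch1, ch2, carpet.meta.line_time, lag_grid))
    if not curves:
        raise ValueError("no usable segments")
    return average_acfs(curves)
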