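"""Line-scan carpet I/O and acquisition-metadata arithmetic.

A *carpet* is an XT image from repeated confocal line scanning: one spatial
axis (pixels along the scanned line) and one temporal axis (successive lines,
spaced by the line time).  Photon-counting detection is split 50/50 into two
channels so that the correlation analysis can cross-correlate them and cancel
detector noise.  Carpets are stored as integer TIFF stacks with a JSON sidecar
(``<name>.meta.json``) carrying the acquisition metadata; metadata is never
scraped from TIFF tags because tag conventions are vendor specific.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "AcquisitionMeta",
    "LineScanCarpet",
    "load_carpet",
    "write_carpet",
    "line_time_from_frequency",
    "irradiation_time",
]

_INT_TOL = 1e-6


@dataclass(frozen=True)
class AcquisitionMeta:
    """Acquisition metadata for one line-scan carpet.

    Parameters
    ----------
    line_frequency : float
        Line scanning frequency in Hz; the line time is its reciprocal.
    pixel_size : float
        Pixel size along the scanned line, in micrometres.
    n_pixels, n_lines : int
        Carpet dimensions: pixels per line and total number of lines.
    damage_line_start, damage_line_end : int
        First and last line index (0-based, inclusive) during which the
        damage-inducing irradiation is applied.
    damage_pixel_start, damage_pixel_end : int
        First and last pixel index (0-based, inclusive) of the irradiated
        strip along the line.
    excitation_power_label : str
        Free-text label of the excitation power setting (e.g. ``"0.3 uW"``).
    """

    line_frequency: float
    pixel_size: float
    n_pixels: int
    n_lines: int
    damage_line_start: int
    damage_line_end: int
    damage_pixel_start: int
    damage_pixel_end: int
    excitation_power_label: str = ""

    def __post_init__(self) -> None:
        if self.line_frequency <= 0:
            raise ValueError("line_frequency must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if not (0 <= self.damage_pixel_start <= self.damage_pixel_end < self.n_pixels):
            raise ValueError(
                "damage pixel range must satisfy "
                "0 <= start <= end < n_pixels "
                f"(got {self.damage_pixel_start}..{self.damage_pixel_end} "
                f"of {self.n_pixels})"
            )
        if not (0 <= self.damage_line_start <= self.damage_line_end < self.n_lines):
            raise ValueError(
                "damage line range must satisfy 0 <= start <= end < n_lines "
                f"(got {self.damage_line_start}..{self.damage_line_end} "
                f"of {self.n_lines})"
            )

    @property
    def line_time(self) -> float:
        """Temporal resolution in seconds, 1 / line_frequency."""
        return 1.0 / self.line_frequency

    @property
    def damage_end_time(self) -> float:
        """Time (s) at which irradiation ends: first post-damage line."""
        return (self.damage_line_end + 1) * self.line_time

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionMeta":
        return cls(**d)


@dataclass
class LineScanCarpet:
    """Two-channel photon-count carpet: ``counts[channel, line, pixel]``."""

    counts: np.ndarray
    meta: AcquisitionMeta

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 3 or counts.shape[0] != 2:
            raise ValueError(
                f"counts must have shape (2, n_lines, n_pixels), got {counts.shape}"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            raise ValueError("photon counts must be integers")
        if counts.min() < 0:
            raise ValueError("photon counts must be non-negative")
        if counts.shape[1] != self.meta.n_lines or counts.shape[2] != self.meta.n_pixels:
            raise ValueError(
                f"shape mismatch: counts {counts.shape[1:]} vs meta "
                f"({self.meta.n_lines}, {self.meta.n_pixels})"
            )
        self.counts = counts

    @property
    def total(self) -> np.ndarray:
        """Channel-summed counts, shape (n_lines, n_pixels)."""
        return self.counts.sum(axis=0)


def line_time_from_frequency(f: float) -> float:
    """Line time in seconds from the line scanning frequency ``f`` in Hz."""
    if f <= 0:
        raise ValueError(f"line frequency must be positive, got {f}")
    return 1.0 / f


def irradiation_time(n_lines: int, line_time: float) -> float:
    """Total irradiation time (s) for damage applied over ``n_lines`` lines."""
    if n_lines < 0:
        raise ValueError(f"n_lines must be non-negative, got {n_lines}")
    if line_time <= 0:
        raise ValueError(f"line_time must be positive, got {line_time}")
    return n_lines * line_time


def _meta_path(path: Path) -> Path:
    return path.parent / (path.stem + ".meta.json")


def write_carpet(carpet: LineScanCarpet, path: str | Path) -> Path:
    """Write a carpet as a 2-page TIFF (channel-major) plus JSON metadata sidecar.

    The integer container width is chosen automatically (uint16 when counts
    fit, uint32 otherwise) so the round trip through :func:`load_carpet` is
    bit exact.
    """
    path = Path(path)
    counts = carpet.counts
    dtype = np.uint16 if counts.max(initial=0) <= np.iinfo(np.uint16).max else np.uint32
    tifffile.imwrite(path, counts.astype(dtype), photometric="minisblack")
    meta_path = _meta_path(path)
    meta_path.write_text(json.dumps(carpet.meta.to_dict(), indent=2))
    return path


def load_carpet(
    path: str | Path,
    meta: AcquisitionMeta | None = None,
    *,
    channel_layout: str = "pages",
    second_path: str | Path | None = None,
) -> LineScanCarpet:
    """Load a two-channel carpet from TIFF.

    Parameters
    ----------
    path : path
        TIFF file.  With ``channel_layout="pages"`` (default) the file must
        resolve to exactly two pages/planes of identical shape, channel-major.
        With ``channel_layout="files"``, ``path`` holds channel 1 and
        ``second_path`` channel 2, each a single-plane TIFF.
    meta : AcquisitionMeta, optional
        Acquisition metadata.  When omitted, the JSON sidecar written by
        :func:`write_carpet` is read instead.

    Raises
    ------
    FileNotFoundError, ValueError
        Missing file, channel count != 2, non-integer pixel values, or a
        shape mismatch with the metadata.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if channel_layout == "pages":
        arr = tifffile.imread(path)
        arr = np.asarray(arr)
        if arr.ndim != 3 or arr.shape[0] != 2:
            raise ValueError(
                f"expected exactly 2 channel pages, got array of shape {arr.shape}"
            )
    elif channel_layout == "files":
        if second_path is None:
            raise ValueError("channel_layout='files' requires second_path")
        ch1 = np.asarray(tifffile.imread(path))
        ch2 = np.asarray(tifffile.imread(second_path))
        if ch1.shape != ch2.shape or ch1.ndim != 2:
            raise ValueError(
                f"channel files must be single planes of equal shape, "
                f"got {ch1.shape} and {ch2.shape}"
            )
        arr = np.stack([ch1, ch2])
    else:
        raise ValueError(f"unknown channel_layout {channel_layout!r}")

    if not np.issubdtype(arr.dtype, np.integer):
        rounded = np.rint(arr)
        if np.abs(arr - rounded).max() > _INT_TOL:
            raise ValueError(
                "pixel values are not integral photon counts "
                f"(max deviation {np.abs(arr - rounded).max():.3g})"
            )
        arr = rounded.astype(np.int64)

    if meta is None:
        meta_path = _meta_path(path)
        if not meta_path.exists():
            raise FileNotFoundError(
                f"no metadata given and sidecar {meta_path} not found"
            )
        meta = AcquisitionMeta.from_dict(json.loads(meta_path.read_text()))

    if arr.shape[1] != meta.n_lines or arr.shape[2] != meta.n_pixels:
        raise ValueError(
            f"shape mismatch: TIFF planes are {arr.shape[1:]}, metadata says "
            f"({meta.n_lines}, {meta.n_pixels})"
        )
    return LineScanCarpet(counts=arr, meta=meta)
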