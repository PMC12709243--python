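"""Ground-truth-paired synthetic data: particle-based carpets and kinetics traces.

The carpet simulator emulates the statistical structure the segmented-FCS
analysis assumes: point emitters diffusing in a 2D plane, detected through a
Gaussian profile sampled as a scanned line; a spatially confined binding
strip that switches on at a defined damage time, with exponential dwell
times; photobleaching whose rate scales with excitation power; Poisson
photon counting; and a 50/50 split of photons into two detection channels.
The 2D plane (no axial dimension) mirrors the analysis' 2D diffusion model,
which assumes the axial extent of the detection volume is much larger than
its lateral waist.

``simulate_intensity_trace`` generates recruitment/decay traces directly
from the closed-form accumulation and decay models, so the kinetics fitting
can be tested independently of the particle model.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._kernels import simulate_lines
from .carpet_io import AcquisitionMeta, LineScanCarpet

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "simulate_carpet",
    "simulate_intensity_trace",
]

#: default 1/e^2 lateral radius of the detection profile, in micrometres.
#: A configuration choice typical of a high-NA confocal spot, not a measured
#: instrument value.
DEFAULT_W0 = 0.3

#: margin between the ends of the scanned line and the box walls, in units
#: of w0, large enough that reflective walls do not deplete the focal region.
BOX_MARGIN_W0 = 6.0


@dataclass
class SimulationConfig:
    """Parameters of one synthetic carpet.

    Defaults reproduce the acquisition geometry of the line-scan protocol the
    analysis targets: 1400 Hz line frequency (0.71 ms line time), 128 pixels
    of 97 nm, a centred 25-pixel damage strip, damage switched on after 1024
    lines, and a 5-minute acquisition (417,690 lines).  Physical defaults are
    the measured regime for a nuclear DNA-damage sensor: free diffusion
    3.8 um^2/s, bound dwell time 0.8 s.  ``box_size`` and ``damage_strip``
    may be left ``None`` to be derived from the pixel geometry.
    """

    n_particles: int = 250
    box_size: tuple[float, float] | None = None  # (Lx, Ly) um
    D_free: float = 3.8  # um^2/s
    w0: float = DEFAULT_W0  # um
    brightness: float = 1.0  # photons / particle / line time at beam centre
    damage_strip: tuple[float, float] | None = None  # (x0, x1) um, box coords
    damage_on_time: float = 1024 / 1400.0  # s
    k_on: float = 20.0  # 1/s, binding rate inside the strip after damage
    tau_B: float = 0.8  # s, mean bound dwell time (1/k_off)
    bleach_rate: float = 0.05  # 1/s at beam centre, at power_factor 1
    power_factor: float = 1.0  # multiplies brightness and bleach_rate
    line_time: float = 1.0 / 1400.0  # s
    n_lines: int = 417_690
    n_pixels: int = 128
    pixel_size: float = 0.097  # um
    seed: int = 0

    def __post_init__(self) -> None:
        if self.box_size is None:
            margin = BOX_MARGIN_W0 * self.w0
            lx = self.n_pixels * self.pixel_size + 2 * margin
            ly = 2 * BOX_MARGIN_W0 * self.w0
            self.box_size = (lx, ly)
        if self.damage_strip is None:
            # centred strip of 25 pixels (or the whole line when narrower)
            width_px = min(25, self.n_pixels)
            p0 = (self.n_pixels - width_px) // 2
            x0 = self.pixel_margin + p0 * self.pixel_size
            self.damage_strip = (x0, x0 + width_px * self.pixel_size)
        self.validate()

    @property
    def pixel_margin(self) -> float:
        """Box x coordinate of the left edge of pixel 0."""
        return 0.5 * (self.box_size[0] - self.n_pixels * self.pixel_size)

    def validate(self) -> None:
        if self.w0 <= 0:
            raise ValueError("w0 must be positive")
        for name in (
            "n_particles",
            "D_free",
            "brightness",
            "k_on",
            "bleach_rate",
            "power_factor",
            "damage_on_time",
        ):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and non-negative, got {v}")
        if self.line_time <= 0 or self.pixel_size <= 0:
            raise ValueError("line_time and pixel_size must be positive")
        if self.n_lines <= 0 or self.n_pixels <= 0:
            raise ValueError("n_lines and n_pixels must be positive")
        if self.k_on > 0 and self.tau_B <= 0:
            raise ValueError("tau_B must be positive when k_on > 0")
        if self.pixel_margin < 0:
            raise ValueError("box does not enclose the scanned line")
        x0, x1 = self.damage_strip
        if not (0 <= x0 <= x1 <= self.box_size[0]):
            raise ValueError("damage_strip must lie inside the box")

    def pixel_center(self, p: int) -> float:
        return self.pixel_margin + (p + 0.5) * self.pixel_size

    def damage_pixel_range(self) -> tuple[int, int]:
        """(first, last) pixel index whose centre lies inside the strip."""
        x0, x1 = self.damage_strip
        centers = self.pixel_margin + (np.arange(self.n_pixels) + 0.5) * self.pixel_size
        inside = np.nonzero((centers >= x0) & (centers <= x1))[0]
        if inside.size == 0:
            # strip narrower than a pixel: use the enclosing pixel
            p = int(np.clip((0.5 * (x0 + x1) - self.pixel_margin) // self.pixel_size,
                            0, self.n_pixels - 1))
            return p, p
        return int(inside[0]), int(inside[-1])

    def acquisition_meta(self, excitation_power_label: str = "") -> AcquisitionMeta:
        """Metadata describing the simulated acquisition.

        The simulator switches damage on instantaneously at
        ``damage_on_time``; the corresponding line index is recorded as both
        start and end of the damage-induction window.
        """
        dline = int(round(self.damage_on_time / self.line_time))
        dline = min(max(dline, 0), self.n_lines - 1)
        dp0, dp1 = self.damage_pixel_range()
        label = excitation_power_label or f"power x{self.power_factor:g}"
        return AcquisitionMeta(
            line_frequency=1.0 / self.line_time,
            pixel_size=self.pixel_size,
            n_pixels=self.n_pixels,
            n_lines=self.n_lines,
            damage_line_start=dline,
            damage_line_end=dline,
            damage_pixel_start=dp0,
            damage_pixel_end=dp1,
            excitation_power_label=label,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["box_size"] = list(self.box_size)
        d["damage_strip"] = list(self.damage_strip)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for key in ("box_size", "damage_strip"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class SimulationTruth:
    """Ground truth paired with a synthetic carpet."""

    config: dict
    bound_per_line: np.ndarray
    bleached_per_line: np.ndarray
    realized_mean_dwell: float  # s; NaN when no binding event completed
    n_binding_events: int

    def __post_init__(self) -> None:
        n = int(self.config["n_particles"])
        if int((self.bound_per_line + self.bleached_per_line).max(initial=0)) > n:
            raise ValueError("bound + bleached counts exceed n_particles")

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "config": self.config,
            "bound_per_line": self.bound_per_line.tolist(),
            "bleached_per_line": self.bleached_per_line.tolist(),
            "realized_mean_dwell": None
            if math.isnan(self.realized_mean_dwell)
            else self.realized_mean_dwell,
            "n_binding_events": self.n_binding_events,
        }
        path.write_text(json.dumps(payload))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            config=d["config"],
            bound_per_line=np.asarray(d["bound_per_line"], dtype=np.int32),
            bleached_per_line=np.asarray(d["bleached_per_line"], dtype=np.int32),
            realized_mean_dwell=float("nan")
            if d["realized_mean_dwell"] is None
            else d["realized_mean_dwell"],
            n_binding_events=d["n_binding_events"],
        )


def simulate_carpet(
    config: SimulationConfig,
    initial_positions: np.ndarray | None = None,
) -> tuple[LineScanCarpet, SimulationTruth]:
    """Run the particle simulation and return the carpet with its ground truth.

    Deterministic given ``config.seed``: the initial positions (uniform over
    the box unless ``initial_positions``, an array of shape (n_particles, 2)
    in box coordinates, is given) and the dynamics both derive from it.
    """
    config.validate()
    lx, ly = config.box_size
    if initial_positions is None:
        rng = np.random.default_rng(config.seed)
        x0 = rng.uniform(0.0, lx, config.n_particles)
        y0 = rng.uniform(-0.5 * ly, 0.5 * ly, config.n_particles)
    else:
        initial_positions = np.asarray(initial_positions, dtype=np.float64)
        if initial_positions.shape != (config.n_particles, 2):
            raise ValueError("initial_positions must have shape (n_particles, 2)")
        x0 = initial_positions[:, 0].copy()
        y0 = initial_positions[:, 1].copy()
    counts, bound, bleached, dwell_sum, dwell_n = simulate_lines(
        int(config.seed),
        x0,
        y0,
        float(lx),
        float(ly),
        float(config.D_free),
        float(config.w0),
        float(config.brightness),
        float(config.damage_strip[0]),
        float(config.damage_strip[1]),
        float(config.damage_on_time),
        float(config.k_on),
        float(config.tau_B),
        float(config.bleach_rate),
        float(config.power_factor),
        float(config.line_time),
        int(config.n_lines),
        int(config.n_pixels),
        float(config.pixel_margin),
        float(config.pixel_size),
    )
    carpet = LineScanCarpet(counts=counts, meta=config.acquisition_meta())
    truth = SimulationTruth(
        config=config.to_dict(),
        bound_per_line=bound,
        bleached_per_line=bleached,
        realized_mean_dwell=dwell_sum / dwell_n if dwell_n else float("nan"),
        n_binding_events=int(dwell_n),
    )
    return carpet, truth


def simulate_intensity_trace(
    y_B: float,
    A_on: float,
    t_D: float,
    tau_ACC: float,
    y_0: float,
    A_off: float,
    t_0: float,
    tau_DEC: float,
    noise_sd: float,
    dt: float,
    duration: float,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise recruitment trace: baseline, exponential rise, exponential decay.

    Returns ``(t, y)`` with the noiseless series being ``y_B`` before the
    damage time ``t_D``, the saturating-exponential accumulation
    ``y_B + A_on (1 - exp(-(t - t_D)/tau_ACC))`` on ``[t_D, t_0]``, and the
    exponential decay ``y_0 + A_off exp(-(t - t_0)/tau_DEC)`` afterwards,
    plus additive Gaussian noise of standard deviation ``noise_sd``.
    """
    if tau_ACC <= 0 or tau_DEC <= 0:
        raise ValueError("tau_ACC and tau_DEC must be positive")
    if dt <= 0:
        raise ValueError("dt must be positive")
    if t_0 < t_D:
        raise ValueError(f"t_0 ({t_0}) must not precede t_D ({t_D})")
    t = np.arange(0.0, duration, dt)
    y = np.full_like(t, float(y_B))
    rise = (t >= t_D) & (t <= t_0)
    y[rise] = y_B + A_on * (1.0 - np.exp(-(t[rise] - t_D) / tau_ACC))
    fall = t > t_0
    y[fall] = y_0 + A_off * np.exp(-(t[fall] - t_0) / tau_DEC)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, size=t.shape)
    return t, y
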