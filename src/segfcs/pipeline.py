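"""End-to-end orchestration: carpet -> segmentation -> zone ACFs -> fits.

A run is described by a single :class:`RunConfig` (usually loaded from YAML
with strict key checking) and produces a :class:`RunReport`: the segment map
and selection, per-zone correlation curves with their model fits, the
damage-region recruitment trace with its accumulation/decay fits, quick-look
plots, and a JSON report echoing the configuration so the run can be
reproduced byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .carpet_io import AcquisitionMeta, LineScanCarpet, load_carpet, write_carpet
from .correlation import ACFCurve, LagGrid, zone_acf
from .fitmodels import (
    FcsFit,
    KineticsFit,
    damage_region_trace,
    fit_accumulation,
    fit_acf,
    fit_decay,
)
from .segmentation import (
    SegmentLabel,
    compute_segment_map,
    make_segment_grid,
    select_segments,
)
from .synthetic import SimulationConfig, simulate_carpet

__all__ = ["RunConfig", "RunReport", "PipelineError", "run_pipeline"]

logger = logging.getLogger("segfcs")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and the cause."""


@dataclass
class RunConfig:
    """Everything one pipeline run needs.

    Exactly one of ``input_path`` (a TIFF written by/compatible with
    :mod:`segfcs.carpet_io`, with metadata in ``meta`` or a sidecar) and
    ``simulation`` (a :class:`SimulationConfig`) must be given.
    """

    out_dir: str
    w0: float = 0.3  # um, calibration input for diffusion models
    input_path: str | None = None
    channel_layout: str = "pages"
    meta: AcquisitionMeta | None = None
    simulation: SimulationConfig | None = None
    # segmentation
    segment_duration: float | None = None  # s
    n_segments: int | None = None
    analysis_start_line: int | None = None
    in_threshold: float = 0.8
    out_threshold: float = 0.5
    x_restrict_in: tuple[int, int] | None = None
    x_restrict_out: tuple[int, int] | None = None
    # correlation
    lag_scheme: str = "multitau"
    points_per_octave: int = 8
    max_lag: float | None = None  # s; default segment_duration / 4
    # models: the low-power protocol fits binding-only IN (tau > 20 ms) and
    # diffusion-only OUT; two_component switches both zones to the mixture
    two_component: bool = False
    binding_tau_min: float = 0.020  # s
    # kinetics
    kinetics_bin: int = 64  # lines per block average of the damage trace
    seed: int | None = None
    plots: bool = True

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.simulation is None):
            raise ValueError("give exactly one of input_path / simulation")
        if self.segment_duration is not None and self.n_segments is not None:
            raise ValueError("give at most one of segment_duration / n_segments")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        raw = dict(raw)
        if raw.get("meta") is not None:
            raw["meta"] = AcquisitionMeta.from_dict(raw["meta"])
        if raw.get("simulation") is not None:
            raw["simulation"] = SimulationConfig.from_dict(raw["simulation"])
        for key in ("x_restrict_in", "x_restrict_out"):
            if raw.get(key) is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.meta is not None:
            d["meta"] = self.meta.to_dict()
        if self.simulation is not None:
            d["simulation"] = self.simulation.to_dict()
        return d


@dataclass
class RunReport:
    """Artifacts and fitted parameters of one pipeline run."""

    out_dir: str
    config: dict
    version: str
    selection_summary: dict
    files: dict
    fcs_fits: dict  # zone -> FcsFit record
    kinetics_fits: dict  # "accumulation"/"decay" -> KineticsFit record
    log: list

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, default=str))
        return path


def _stage(name: str, log: list):
    class _Ctx:
        def __enter__(self):
            logger.info("stage %s: start", name)
            log.append(f"stage {name}: start")
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                msg = f"stage {name}: failed: {exc}"
                logger.error(msg)
                log.append(msg)
                raise PipelineError(msg) from exc
            log.append(f"stage {name}: done")
            return False

    return _Ctx()


def _plot_map(smap, selection, path):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(8, 4))
    axes[0].imshow(smap.normalized.T, aspect="auto", origin="lower",
                   interpolation="nearest", cmap="viridis")
    axes[0].set(title="normalized segment map", xlabel="column", ylabel="segment")
    axes[1].imshow(selection.labels.T, aspect="auto", origin="lower",
                   interpolation="nearest", cmap="tab10", vmin=0, vmax=9)
    axes[1].set(title="selection (1=IN, 2=OUT)", xlabel="column")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def _plot_acfs(curves: dict, fits: dict, path):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for zone, curve in curves.items():
        err = curve.sem if curve.sem is not None else None
        ax.errorbar(curve.lags, curve.G, yerr=err, fmt="o", ms=3, label=zone)
        fit = fits.get(zone)
        if fit is not None:
            ax.plot(curve.lags, fit.evaluate(curve.lags), "-", lw=1)
    ax.set(xscale="log", xlabel="lag time (s)", ylabel="G", title="zone ACFs")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute load/simulate -> segment -> select -> correlate -> fit -> report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list = []
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    files: dict = {}

    try:
        with _stage("input", log):
            if config.simulation is not None:
                sim = config.simulation
                if config.seed is not None:
                    sim = SimulationConfig.from_dict(
                        {**sim.to_dict(), "seed": config.seed}
                    )
                carpet, truth = simulate_carpet(sim)
                files["carpet"] = str(write_carpet(carpet, out / "carpet.tif"))
                files["truth"] = str(truth.to_json(out / "truth.json"))
            else:
                carpet = load_carpet(
                    config.input_path,
                    meta=config.meta,
                    channel_layout=config.channel_layout,
                )
            meta = carpet.meta

        with _stage("segmentation", log):
            if config.segment_duration is None and config.n_segments is None:
                n_segments = 32
                grid = make_segment_grid(
                    meta,
                    n_segments_per_column=n_segments,
                    analysis_start_line=config.analysis_start_line,
                )
            else:
                grid = make_segment_grid(
                    meta,
                    segment_duration=config.segment_duration,
                    n_segments_per_column=config.n_segments,
                    analysis_start_line=config.analysis_start_line,
                )
            smap = compute_segment_map(carpet, grid)
            selection = select_segments(
                smap,
                grid,
                meta,
                in_threshold=config.in_threshold,
                out_threshold=config.out_threshold,
                x_restrict_in=config.x_restrict_in,
                x_restrict_out=config.x_restrict_out,
            )
            df = smap.to_frame(labels=selection.labels)
            df.to_csv(out / "segment_map.csv", index=False)
            files["segment_map"] = str(out / "segment_map.csv")
            if config.plots:
                _plot_map(smap, selection, out / "segment_map.png")
                files["segment_map_png"] = str(out / "segment_map.png")

        with _stage("correlation", log):
            seg_dur = grid.segment_duration(meta.line_time)
            max_lag = config.max_lag if config.max_lag is not None else seg_dur / 4
            max_lag = min(max_lag, seg_dur / 4)
            if config.lag_scheme == "multitau":
                lag_grid = LagGrid.multitau(
                    meta.line_time, max_lag, config.points_per_octave
                )
            elif config.lag_scheme == "linear":
                lag_grid = LagGrid.linear(meta.line_time, max_lag)
            else:
                raise ValueError(f"unknown lag scheme {config.lag_scheme!r}")
            curves = {}
            for zone in ("IN", "OUT"):
                curve = zone_acf(carpet, grid, selection, zone, lag_grid)
                curves[zone] = curve
                curve.to_frame().to_csv(out / f"acf_{zone}.csv", index=False)
                files[f"acf_{zone}"] = str(out / f"acf_{zone}.csv")

        with _stage("fcs_fits", log):
            fits: dict = {}
            if config.two_component:
                for zone in ("IN", "OUT"):
                    fits[zone] = fit_acf(
                        curves[zone], "diffusion_binding", w0=config.w0
                    )
            else:
                fits["IN"] = fit_acf(
                    curves["IN"],
                    "binding",
                    fit_range=(config.binding_tau_min, np.inf),
                )
                fits["OUT"] = fit_acf(curves["OUT"], "diffusion", w0=config.w0)
            if config.plots:
                _plot_acfs(curves, fits, out / "acf.png")
                files["acf_png"] = str(out / "acf.png")

        with _stage("kinetics", log):
            t, y = damage_region_trace(carpet, meta, bin=config.kinetics_bin)
            pd.DataFrame({"t_s": t, "intensity": y}).to_csv(
                out / "trace.csv", index=False
            )
            files["trace"] = str(out / "trace.csv")
            t_d = meta.damage_end_time
            kin: dict = {}
            kin["accumulation"] = fit_accumulation(t, y, t_D=t_d)
            kin["decay"] = fit_decay(t, y)

        with _stage("report", log):
            fit_rows = []
            for zone, fit in fits.items():
                row = {"zone": zone}
                row.update(fit.to_record())
                fit_rows.append(row)
            for name, fit in kin.items():
                row = {"zone": name}
                row.update(fit.to_record())
                fit_rows.append(row)
            pd.DataFrame(fit_rows).to_csv(out / "fits.csv", index=False)
            files["fits"] = str(out / "fits.csv")
            report = RunReport(
                out_dir=str(out),
                config=config.to_dict(),
                version=__version__,
                selection_summary=selection.summary(),
                files=files,
                fcs_fits={z: f.to_record() for z, f in fits.items()},
                kinetics_fits={k: f.to_record() for k, f in kin.items()},
                log=log,
            )
            files["report"] = str(report.to_json(out / "report.json"))
        return report
    finally:
        logger.removeHandler(handler)
        handler.close()
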