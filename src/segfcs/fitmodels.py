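"""Closed-form ACF models, kinetics models, and their least-squares fits.

Three correlation models are supported, all with a free offset G(inf):

* ``diffusion`` — 2D free diffusion through a Gaussian spot of 1/e^2 lateral
  radius ``w0``:  G(tau) = G(inf) + G / (1 + 4 D tau / w0^2).  The 2D form
  is appropriate when the axial extent of the detection volume is much
  larger than ``w0``.
* ``binding`` — exponential dwell at immobile sites:
  G(tau) = G(inf) + G exp(-tau / tau_B).
* ``diffusion_binding`` — two-component mixture with diffusing fraction F_D
  and binding fraction F_B = 1 - F_D.

Intensity-kinetics models describe the recruitment trace of the damage
region: a saturating-exponential accumulation with characteristic time
tau_ACC after the damage time t_D, and an exponential decay with
characteristic time tau_DEC after the trace maximum t_0.

``w0`` is a calibration input, never a fitted parameter.  For noisy curves
the binding model is fitted on a restricted lag range (tau > 20 ms by
default) so the fast diffusive decay does not contaminate the dwell-time
estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import lmfit
import numpy as np

from .carpet_io import AcquisitionMeta, LineScanCarpet
from .correlation import ACFCurve

__all__ = [
    "FcsFit",
    "KineticsFit",
    "FitConvergenceError",
    "ACF_MODELS",
    "eval_acf_model",
    "fit_acf",
    "damage_region_trace",
    "fit_accumulation",
    "fit_decay",
    "accumulation_model",
    "decay_model",
]

DEFAULT_BINDING_TAU_MIN = 0.020  # s; restricted binding-fit range


class FitConvergenceError(RuntimeError):
    """A nonlinear fit failed to converge; carries the final residual norm."""

    def __init__(self, message: str, residual_norm: float | None = None):
        super().__init__(message)
        self.residual_norm = residual_norm


def acf_diffusion(tau, g_inf, g, d, w0):
    return g_inf + g / (1.0 + 4.0 * d * tau / w0**2)


def acf_binding(tau, g_inf, g, tau_b):
    return g_inf + g * np.exp(-tau / tau_b)


def acf_diffusion_binding(tau, g_inf, g, d, f_d, tau_b, w0):
    diff = f_d / (1.0 + 4.0 * d * tau / w0**2)
    bind = (1.0 - f_d) * np.exp(-tau / tau_b)
    return g_inf + g * (diff + bind)


ACF_MODELS = {
    "diffusion": acf_diffusion,
    "binding": acf_binding,
    "diffusion_binding": acf_diffusion_binding,
}

_MODEL_PARAMS = {
    "diffusion": ("g_inf", "g", "d"),
    "binding": ("g_inf", "g", "tau_b"),
    "diffusion_binding": ("g_inf", "g", "d", "f_d", "tau_b"),
}


def eval_acf_model(
    model: str, params: dict, lags: np.ndarray, w0: float | None = None
) -> np.ndarray:
    """Evaluate a correlation model at the given positive lag times."""
    if model not in ACF_MODELS:
        raise ValueError(f"unknown model {model!r}")
    lags = np.asarray(lags, dtype=np.float64)
    if np.any(lags <= 0):
        raise ValueError("lags must be positive")
    kwargs = {}
    for name in _MODEL_PARAMS[model]:
        if name not in params:
            raise ValueError(f"model {model!r} is missing parameter {name!r}")
        kwargs[name] = params[name]
    if model in ("diffusion", "diffusion_binding"):
        w0 = params.get("w0", w0)
        if w0 is None or w0 <= 0:
            raise ValueError("w0 must be a positive calibration input")
        kwargs["w0"] = w0
    return ACF_MODELS[model](lags, **kwargs)


@dataclass
class FcsFit:
    """Converged correlation-model fit."""

    model: str
    params: dict
    stderr: dict
    w0: float | None
    fit_range: tuple[float, float]
    n_points: int
    redchi: float

    @property
    def G_inf(self) -> float:
        return self.params["g_inf"]

    @property
    def G(self) -> float:
        return self.params["g"]

    @property
    def D(self) -> float | None:
        return self.params.get("d")

    @property
    def tau_B(self) -> float | None:
        return self.params.get("tau_b")

    @property
    def F_D(self) -> float | None:
        return self.params.get("f_d")

    @property
    def F_B(self) -> float | None:
        f_d = self.params.get("f_d")
        return None if f_d is None else 1.0 - f_d

    def evaluate(self, lags: np.ndarray) -> np.ndarray:
        return eval_acf_model(self.model, self.params, lags, w0=self.w0)

    def to_record(self) -> dict:
        rec = {"model": self.model, "w0": self.w0, "n_points": self.n_points,
               "redchi": self.redchi, "tau_min": self.fit_range[0],
               "tau_max": self.fit_range[1]}
        rec.update(self.params)
        rec.update({f"{k}_stderr": v for k, v in self.stderr.items()})
        if self.F_B is not None:
            rec["f_b"] = self.F_B
        return rec


def _init_from_curve(curve: ACFCurve, mask: np.ndarray, w0: float | None) -> dict:
    """Heuristic starting values: offset from the tail, amplitude from the
    first fitted lag, D from the half-decay lag, tau_B from the 1/e crossing."""
    lags = curve.lags[mask]
    g = curve.G[mask]
    n_tail = max(3, len(g) // 10)
    tail = float(np.mean(g[-n_tail:]))
    amp = max(float(g[0] - tail), 1e-6)
    # half-decay lag
    below = np.nonzero(g - tail <= 0.5 * amp)[0]
    tau_half = float(lags[below[0]]) if below.size else float(lags[len(lags) // 2])
    d0 = (w0**2 / (4.0 * tau_half)) if w0 else 1.0
    below_e = np.nonzero(g - tail <= amp / np.e)[0]
    tau_b0 = float(lags[below_e[0]]) if below_e.size else float(lags[len(lags) // 2])
    return {"g_inf": tail, "g": amp, "d": max(d0, 1e-6),
            "tau_b": max(tau_b0, 1e-6), "f_d": 0.5}


def fit_acf(
    curve: ACFCurve,
    model: str,
    w0: float | None = None,
    fit_range: tuple[float, float] | None = None,
    init: dict | None = None,
    weight_by_sem: bool = False,
) -> FcsFit:
    """Nonlinear least-squares fit of a correlation model to a curve.

    The binding model defaults to the restricted range tau > 20 ms; the other
    models use the full curve.  Optional 1/sem^2 weighting is applied when the
    curve averages at least 4 segments.  Non-convergence raises
    :class:`FitConvergenceError` with the final residual norm.
    """
    if model not in ACF_MODELS:
        raise ValueError(f"unknown model {model!r}")
    needs_w0 = model in ("diffusion", "diffusion_binding")
    if needs_w0 and (w0 is None or w0 <= 0):
        raise ValueError("w0 is a required positive input for diffusion models")
    if fit_range is None:
        fit_range = (DEFAULT_BINDING_TAU_MIN, np.inf) if model == "binding" else (0.0, np.inf)
    mask = (curve.lags >= fit_range[0]) & (curve.lags <= fit_range[1])
    if mask.sum() < 5:
        raise ValueError(
            f"only {int(mask.sum())} points inside fit range {fit_range}; need >= 5"
        )
    lags = curve.lags[mask]
    g = curve.G[mask]

    start = _init_from_curve(curve, mask, w0)
    if init:
        start.update(init)

    params = lmfit.Parameters()
    params.add("g_inf", value=start["g_inf"], min=-1.0)
    params.add("g", value=start["g"], min=0.0)
    if model in ("diffusion", "diffusion_binding"):
        params.add("d", value=start["d"], min=0.0)
        params.add("w0", value=w0, vary=False)
    if model in ("binding", "diffusion_binding"):
        params.add("tau_b", value=start["tau_b"], min=1e-9)
    if model == "diffusion_binding":
        params.add("f_d", value=start["f_d"], min=0.0, max=1.0)

    weights = None
    if (
        weight_by_sem
        and curve.sem is not None
        and curve.n_segments_averaged >= 4
        and np.all(curve.sem[mask] > 0)
    ):
        weights = 1.0 / curve.sem[mask]

    lm = lmfit.Model(ACF_MODELS[model], independent_vars=["tau"])
    result = lm.fit(g, params=params, tau=lags, weights=weights,
                    method="least_squares")
    if not result.success:
        raise FitConvergenceError(
            f"{model} fit did not converge: {result.message}",
            residual_norm=float(np.linalg.norm(result.residual)),
        )
    fitted = {k: float(v.value) for k, v in result.params.items() if k != "w0"}
    stderr = {
        k: (float(v.stderr) if v.stderr is not None else float("nan"))
        for k, v in result.params.items()
        if k != "w0" and v.vary
    }
    return FcsFit(
        model=model,
        params=fitted,
        stderr=stderr,
        w0=w0,
        fit_range=(float(fit_range[0]), float(fit_range[1])),
        n_points=int(mask.sum()),
        redchi=float(result.redchi),
    )


# ---------------------------------------------------------------------------
# intensity-trace kinetics


def accumulation_model(t, y_b, a_on, tau_acc, t_d):
    """Saturating-exponential recruitment; baseline ``y_b`` before ``t_d``."""
    t = np.asarray(t, dtype=np.float64)
    rise = y_b + a_on * (1.0 - np.exp(-np.clip(t - t_d, 0.0, None) / tau_acc))
    return np.where(t < t_d, y_b, rise)


def decay_model(t, y_0, a_off, tau_dec, t_0):
    """Exponential relaxation from the peak at ``t_0``."""
    t = np.asarray(t, dtype=np.float64)
    return y_0 + a_off * np.exp(-(t - t_0) / tau_dec)


@dataclass
class KineticsFit:
    """Converged accumulation or decay fit."""

    model: str  # "accumulation" | "decay"
    params: dict
    stderr: dict
    window: tuple[float, float]
    n_points: int
    redchi: float

    @property
    def tau_ACC(self) -> float | None:
        return self.params.get("tau_acc")

    @property
    def tau_DEC(self) -> float | None:
        return self.params.get("tau_dec")

    def to_record(self) -> dict:
        rec = {"model": self.model, "n_points": self.n_points,
               "redchi": self.redchi, "window_start": self.window[0],
               "window_end": self.window[1]}
        rec.update(self.params)
        rec.update({f"{k}_stderr": v for k, v in self.stderr.items()})
        return rec


def damage_region_trace(
    carpet: LineScanCarpet,
    meta: AcquisitionMeta | None = None,
    bin: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean channel-summed intensity of the damage pixel strip, per line.

    Block-averaged by ``bin`` lines; timestamps are at block centres
    (line index times the line time).  Returns ``(t, y)``.
    """
    meta = meta or carpet.meta
    if bin < 1:
        raise ValueError("bin must be >= 1")
    if bin > meta.n_lines:
        raise ValueError(f"bin {bin} exceeds the {meta.n_lines} lines available")
    y = carpet.total[:, meta.damage_pixel_start : meta.damage_pixel_end + 1].mean(axis=1)
    t = np.arange(meta.n_lines) * meta.line_time
    if bin > 1:
        n = (len(y) // bin) * bin
        y = y[:n].reshape(-1, bin).mean(axis=1)
        t = t[:n].reshape(-1, bin).mean(axis=1)
    return t, y.astype(np.float64)


def _fit_kinetics(model_func, t, y, params, fixed_name, window):
    lm = lmfit.Model(model_func, independent_vars=["t"])
    result = lm.fit(y, params=params, t=t, method="least_squares")
    if not result.success:
        raise FitConvergenceError(
            f"kinetics fit did not converge: {result.message}",
            residual_norm=float(np.linalg.norm(result.residual)),
        )
    fitted = {k: float(v.value) for k, v in result.params.items()}
    stderr = {
        k: (float(v.stderr) if v.stderr is not None else float("nan"))
        for k, v in result.params.items()
        if v.vary
    }
    return fitted, stderr, float(result.redchi)


def fit_accumulation(
    t: np.ndarray,
    y: np.ndarray,
    t_D: float,
    window_end: float | None = None,
) -> KineticsFit:
    """Fit the recruitment rise on ``[t_D, window_end]``.

    ``t_D`` (end of damage induction, known from the acquisition metadata) is
    held fixed.  The window end defaults to the trace maximum.  The baseline
    ``y_B`` is initialized from the pre-damage mean, which must exist.
    """
    t = np.asarray(t, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    pre = t < t_D
    if not pre.any():
        raise ValueError("no pre-damage baseline available (no samples before t_D)")
    y_b0 = float(y[pre].mean())
    if window_end is None:
        post = t >= t_D
        window_end = float(t[post][np.argmax(y[post])])
    # the pre-damage baseline is part of the fitted window: the model is
    # constant there, which anchors y_B against trade-off with tau_ACC
    mask = t <= window_end
    if (mask & (t >= t_D)).sum() < 4:
        raise ValueError("accumulation window holds fewer than 4 points")
    tw, yw = t[mask], y[mask]
    rise = tw >= t_D
    a0 = max(float(yw[rise].max() - y_b0), 1e-9)
    # first crossing of the 1-1/e level sets the initial accumulation time
    crossed = np.nonzero(yw[rise] - y_b0 >= (1.0 - 1.0 / np.e) * a0)[0]
    tau0 = float(tw[rise][crossed[0]] - t_D) if crossed.size else float(
        0.5 * (window_end - t_D)
    )
    span = window_end - t_D
    params = lmfit.Parameters()
    params.add("y_b", value=y_b0, min=0.0)
    params.add("a_on", value=a0, min=0.0)
    # a characteristic time beyond ~10x the observed window is unidentifiable
    params.add("tau_acc", value=min(max(tau0, 1e-6), 10 * span), min=1e-9,
               max=10.0 * span)
    params.add("t_d", value=t_D, vary=False)
    fitted, stderr, redchi = _fit_kinetics(
        accumulation_model, tw, yw, params, "t_d", (t_D, window_end)
    )
    return KineticsFit(
        model="accumulation",
        params=fitted,
        stderr=stderr,
        window=(float(t_D), float(window_end)),
        n_points=int(mask.sum()),
        redchi=redchi,
    )


def fit_decay(
    t: np.ndarray,
    y: np.ndarray,
    t_0: float | None = None,
    window_end: float | None = None,
) -> KineticsFit:
    """Fit the long-term exponential decay after the trace maximum.

    ``t_0`` defaults to the time of the trace maximum and is held fixed.
    """
    t = np.asarray(t, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if t_0 is None:
        t_0 = float(t[np.argmax(y)])
    if window_end is None:
        window_end = float(t[-1])
    mask = (t >= t_0) & (t <= window_end)
    if mask.sum() < 4:
        raise ValueError("decay window holds fewer than 4 points")
    tw, yw = t[mask], y[mask]
    n_tail = max(3, len(yw) // 10)
    y00 = float(yw[-n_tail:].mean())
    a0 = max(float(yw[0] - y00), 1e-9)
    below = np.nonzero(yw - y00 <= a0 / np.e)[0]
    tau0 = float(tw[below[0]] - t_0) if below.size else float(
        0.5 * (window_end - t_0)
    )
    span = window_end - t_0
    params = lmfit.Parameters()
    params.add("y_0", value=max(y00, 0.0), min=0.0)
    params.add("a_off", value=a0, min=0.0)
    params.add("tau_dec", value=min(max(tau0, 1e-6), 10 * span), min=1e-9,
               max=10.0 * span)
    params.add("t_0", value=t_0, vary=False)
    fitted, stderr, redchi = _fit_kinetics(
        decay_model, tw, yw, params, "t_0", (t_0, window_end)
    )
    return KineticsFit(
        model="decay",
        params=fitted,
        stderr=stderr,
        window=(float(t_0), float(window_end)),
        n_points=int(mask.sum()),
        redchi=redchi,
    )
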