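"""Synthetic benchmark studies that validate the analysis chain end to end.

Each study generates ground-truth-paired synthetic data with
:mod:`segfcs.synthetic`, runs the same estimators a user would run on
microscope data, and returns plain dictionaries of numbers.  The studies are
deliberately sized to run on one CPU in minutes; the geometry follows the
line-scan protocol (1400 Hz, 97 nm pixels, centred 25-pixel damage strip)
with acquisitions shortened from the 5-minute originals to the window each
estimate actually needs.

Seeds: every study takes a base ``seed`` and derives per-run seeds from it,
so complete studies are reproducible from one integer.
"""

from __future__ import annotations

import numpy as np

from .carpet_io import irradiation_time, line_time_from_frequency
from .correlation import LagGrid, average_acfs, carpet_acf, segment_acf, zone_acf
from .fitmodels import damage_region_trace, fit_accumulation, fit_acf, fit_decay
from .segmentation import (
    SegmentGrid,
    SegmentLabel,
    compute_segment_map,
    make_segment_grid,
    select_segments,
)
from .synthetic import SimulationConfig, simulate_carpet, simulate_intensity_trace

__all__ = [
    "acquisition_arithmetic",
    "correlator_vs_bruteforce",
    "shot_noise_immunity",
    "diffusion_recovery",
    "binding_recovery",
    "kinetics_recovery",
    "power_ladder",
]

LINE_FREQUENCY = 1400.0  # Hz
W0 = 0.3  # um


def _derive_seed(seed: int, k: int) -> int:
    return int((seed * 1_000_003 + k) % (2**31 - 1))


# ---------------------------------------------------------------------------


def acquisition_arithmetic() -> dict:
    """Analytic acquisition arithmetic of the line-scan protocol.

    Line time from the 1400 Hz scan frequency, irradiation time of the
    512-line damage induction, and the duration of one temporal segment when
    a 417,690-line column is divided into 32 segments.
    """
    lt = line_time_from_frequency(LINE_FREQUENCY)
    n_lines, n_segments = 417_690, 32
    lines_per_segment = n_lines // n_segments
    return {
        "line_time_ms": lt * 1e3,
        "irradiation_time_s": irradiation_time(512, lt),
        "lines_per_segment": lines_per_segment,
        "segment_duration_s": lines_per_segment * lt,
    }


def bruteforce_cross_acf(ch1, ch2, lag_lines) -> np.ndarray:
    """Direct double-loop evaluation of the symmetrized cross-correlation.

    Independent oracle for the production estimator: per lag k,
    G = mean_t[I1(t) I2(t+k)] / (mean[I1] mean[I2]) - 1 over the overlapping
    range, averaged over the two shift directions.
    """
    ch1 = np.asarray(ch1, dtype=float)
    ch2 = np.asarray(ch2, dtype=float)
    n = len(ch1)
    m1, m2 = ch1.mean(), ch2.mean()
    out = np.empty(len(lag_lines))
    for i, k in enumerate(lag_lines):
        s_fwd = 0.0
        s_bwd = 0.0
        for t in range(n - k):
            s_fwd += ch1[t] * ch2[t + k]
            s_bwd += ch2[t] * ch1[t + k]
        out[i] = 0.5 * (s_fwd + s_bwd) / (n - k) / (m1 * m2) - 1.0
    return out


def correlator_vs_bruteforce(
    seed: int, n_series: int = 50, n_points: int = 1000, max_lag_lines: int = 25
) -> dict:
    """Max |fast estimator - brute force| over random Poisson series pairs."""
    rng = np.random.default_rng(seed)
    line_time = 1.0 / LINE_FREQUENCY
    grid = LagGrid.linear(line_time, max_lag_lines * line_time)
    worst = 0.0
    for _ in range(n_series):
        rate = rng.uniform(0.5, 5.0)
        ch1 = rng.poisson(rate, n_points)
        ch2 = rng.poisson(rate, n_points)
        fast = segment_acf(ch1, ch2, line_time, grid).G
        brute = bruteforce_cross_acf(ch1, ch2, grid.lag_steps)
        worst = max(worst, float(np.abs(fast - brute).max()))
    return {"max_abs_deviation": worst, "n_series": n_series}


def shot_noise_immunity(
    seed: int, n_segments: int = 128, n_lines: int = 4096, rate: float = 2.0
) -> dict:
    """Cross-channel ACF of binomially split constant-rate Poisson streams.

    Detector/shot noise is uncorrelated between the two channels, so the mean
    zone ACF must be zero at every lag within sampling error.  Returns the
    worst |mean G| / SEM over the lag grid.
    """
    rng = np.random.default_rng(seed)
    line_time = 1.0 / LINE_FREQUENCY
    grid = LagGrid.multitau(line_time, n_lines / 8 * line_time)
    curves = []
    for _ in range(n_segments):
        total = rng.poisson(rate, n_lines)
        ch1 = rng.binomial(total, 0.5)
        ch2 = total - ch1
        curves.append(segment_acf(ch1, ch2, line_time, grid))
    avg = average_acfs(curves)
    z = np.abs(avg.G) / avg.sem
    return {
        "max_abs_z": float(z.max()),
        "max_abs_mean_g": float(np.abs(avg.G).max()),
        "n_segments": n_segments,
    }


# ---------------------------------------------------------------------------


def _diffusion_config(d: float, seed: int) -> SimulationConfig:
    return SimulationConfig(
        n_particles=150,
        n_pixels=64,
        n_lines=32_768,
        D_free=d,
        w0=W0,
        k_on=0.0,
        bleach_rate=0.0,
        damage_on_time=0.0,
        brightness=1.0,
        line_time=1.0 / LINE_FREQUENCY,
        seed=seed,
    )


def diffusion_recovery(
    seed: int, d_values: tuple = (1.0, 3.8, 10.0), n_seeds: int = 10
) -> dict:
    """Fit the 2D diffusion model to pure-diffusion simulations.

    Homogeneous carpets (no damage strip, no bleaching), ~23 s acquisitions
    split into 16 segments; the ACF averaged over all segments is fitted with
    the one-component diffusion model.  Reports the median relative error of
    the recovered diffusion coefficient per condition.
    """
    out = {}
    for d in d_values:
        errors = []
        fitted = []
        for k in range(n_seeds):
            cfg = _diffusion_config(d, _derive_seed(seed, 100 * int(d * 10) + k))
            carpet, _ = simulate_carpet(cfg)
            grid = make_segment_grid(
                carpet.meta, n_segments_per_column=16, analysis_start_line=0
            )
            lg = LagGrid.multitau(
                carpet.meta.line_time, grid.segment_duration(carpet.meta.line_time) / 4
            )
            curve = carpet_acf(carpet, grid, lg)
            fit = fit_acf(curve, "diffusion", w0=W0)
            fitted.append(fit.D)
            errors.append(abs(fit.D - d) / d)
        out[d] = {
            "median_rel_error": float(np.median(errors)),
            "median_fitted_D": float(np.median(fitted)),
        }
    return out


def _binding_config(tau_b: float, seed: int) -> SimulationConfig:
    # 6 segments of 32*tau_B each fit the acquisition; k_on low enough that a
    # particle usually escapes the detection spot after unbinding (rebinding
    # would otherwise inflate the apparent dwell time over the microscopic one)
    segment = 32.0 * tau_b
    return SimulationConfig(
        n_particles=250,
        n_lines=int((6 * segment + 1.1) * LINE_FREQUENCY),
        D_free=3.8,
        w0=W0,
        k_on=5.0,
        tau_B=tau_b,
        bleach_rate=0.0,
        brightness=1.0,
        line_time=1.0 / LINE_FREQUENCY,
        seed=seed,
    )


def binding_recovery(
    seed: int, tau_values: tuple = (0.5, 0.8, 1.6), n_seeds: int = 10
) -> dict:
    """Recover the bound dwell time from IN-zone ACFs of binding-strip carpets.

    Acquisitions with an active 25-pixel binding strip, cut into 6 segments
    of 32*tau_B each so the exponential is equally resolved in every
    condition (max lag 8*tau_B); segments classified by the normalized
    intensity map; the IN-zone average ACF fitted with the one-component
    binding model restricted to lags > 20 ms.  For the reference dwell time
    (0.8 s) the two-component mixture is also fitted in both zones, yielding
    the binding-fraction contrast F_B(IN) vs F_B(OUT).
    """
    out = {}
    fb_in, fb_out = [], []
    for tau_b in tau_values:
        errors = []
        fitted = []
        for k in range(n_seeds):
            cfg = _binding_config(tau_b, _derive_seed(seed, 1000 * int(tau_b * 10) + k))
            carpet, _ = simulate_carpet(cfg)
            meta = carpet.meta
            grid = make_segment_grid(meta, segment_duration=32.0 * tau_b)
            smap = compute_segment_map(carpet, grid)
            sel = select_segments(smap, grid, meta)
            lg = LagGrid.multitau(
                meta.line_time, grid.segment_duration(meta.line_time) / 4
            )
            cin = zone_acf(carpet, grid, sel, SegmentLabel.IN, lg)
            fit = fit_acf(cin, "binding")
            fitted.append(fit.tau_B)
            errors.append(abs(fit.tau_B - tau_b) / tau_b)
            if tau_b == 0.8:
                cout = zone_acf(carpet, grid, sel, SegmentLabel.OUT, lg)
                fb_in.append(fit_acf(cin, "diffusion_binding", w0=W0).F_B)
                fb_out.append(fit_acf(cout, "diffusion_binding", w0=W0).F_B)
        out[tau_b] = {
            "median_rel_error": float(np.median(errors)),
            "median_fitted_tau_B": float(np.median(fitted)),
        }
    if fb_in:
        out["zone_contrast"] = {
            "median_f_b_in": float(np.median(fb_in)),
            "median_f_b_out": float(np.median(fb_out)),
            "n_seeds": len(fb_in),
        }
    return out


def kinetics_recovery(
    seed: int,
    tau_acc_true: float = 5.1,
    tau_dec_true: float = 90.0,
    n_seeds: int = 20,
) -> dict:
    """Recover accumulation/decay times from noisy closed-form traces.

    Truth values are the low-excitation recruitment (5.1 s) and dissociation
    (90 s) times; traces carry Gaussian noise of 5% of the rise amplitude.
    """
    t_d, a_on, y_b = 10.0, 80.0, 100.0
    t_0 = t_d + 5 * tau_acc_true
    y_peak = y_b + a_on * (1 - np.exp(-(t_0 - t_d) / tau_acc_true))
    acc_err, dec_err, acc_fit, dec_fit = [], [], [], []
    for k in range(n_seeds):
        t, y = simulate_intensity_trace(
            y_B=y_b,
            A_on=a_on,
            t_D=t_d,
            tau_ACC=tau_acc_true,
            y_0=y_b,
            A_off=y_peak - y_b,
            t_0=t_0,
            tau_DEC=tau_dec_true,
            noise_sd=0.05 * a_on,
            dt=0.25,
            duration=t_0 + 2.5 * tau_dec_true,
            seed=_derive_seed(seed, 7000 + k),
        )
        acc = fit_accumulation(t, y, t_D=t_d, window_end=t_0)
        dec = fit_decay(t, y, t_0=t_0)
        acc_fit.append(acc.tau_ACC)
        dec_fit.append(dec.tau_DEC)
        acc_err.append(abs(acc.tau_ACC - tau_acc_true) / tau_acc_true)
        dec_err.append(abs(dec.tau_DEC - tau_dec_true) / tau_dec_true)
    return {
        "tau_acc_median_fitted": float(np.median(acc_fit)),
        "tau_acc_median_rel_error": float(np.median(acc_err)),
        "tau_dec_median_fitted": float(np.median(dec_fit)),
        "tau_dec_median_rel_error": float(np.median(dec_err)),
        "n_seeds": n_seeds,
    }


# ---------------------------------------------------------------------------


def _ladder_config(power: float, seed: int) -> SimulationConfig:
    return SimulationConfig(
        n_particles=400,
        n_lines=200 * 1400,
        D_free=3.8,
        w0=W0,
        k_on=50.0,
        tau_B=0.4,
        bleach_rate=0.05,
        power_factor=power,
        brightness=1.0,
        line_time=1.0 / LINE_FREQUENCY,
        seed=seed,
    )


def power_ladder(
    seed: int, powers: tuple = (1.0, 2.0, 4.0, 8.0), n_seeds: int = 5
) -> dict:
    """Excitation-power dependence of recruitment kinetics vs segmented FCS.

    For each power the damage-region trace is fitted for the apparent
    accumulation time (30-s window) and decay time (post-peak), reported as
    medians over replicate runs.  The IN-zone dwell time is fitted once per
    power on the segment ACFs pooled over all replicates (8 segments of 8 s
    starting 15 s after damage, when the recruitment transient is over).
    Stronger excitation bleaches faster, so the apparent decay accelerates,
    while the segment-local normalization keeps the dwell-time estimate
    nearly power-independent.
    """
    out = {}
    for p in powers:
        acc_l, dec_l, curves = [], [], []
        for k in range(n_seeds):
            cfg = _ladder_config(p, _derive_seed(seed, 50_000 + 100 * int(p) + k))
            carpet, _ = simulate_carpet(cfg)
            meta = carpet.meta
            t_d = meta.damage_end_time
            t, y = damage_region_trace(carpet, meta, bin=512)
            acc_l.append(fit_accumulation(t, y, t_D=t_d, window_end=t_d + 30.0).tau_ACC)
            dec_l.append(fit_decay(t, y).tau_DEC)
            start = int(round((t_d + 15.0) / meta.line_time))
            base = make_segment_grid(
                meta, segment_duration=8.0, analysis_start_line=start
            )
            grid = SegmentGrid(
                lines_per_segment=base.lines_per_segment,
                n_segments_per_column=8,
                n_columns=base.n_columns,
                analysis_start_line=start,
            )
            smap = compute_segment_map(carpet, grid)
            sel = select_segments(smap, grid, meta)
            lg = LagGrid.multitau(
                meta.line_time, grid.segment_duration(meta.line_time) / 4
            )
            for col, j in sel.segments(SegmentLabel.IN):
                ch1 = carpet.counts[0, grid.line_slice(j), col]
                ch2 = carpet.counts[1, grid.line_slice(j), col]
                if ch1.sum() < 100 or ch2.sum() < 100:
                    continue
                curves.append(segment_acf(ch1, ch2, meta.line_time, lg))
        pooled = average_acfs(curves)
        tau_b = fit_acf(pooled, "binding").tau_B
        out[p] = {
            "median_tau_acc": float(np.median(acc_l)),
            "median_tau_dec": float(np.median(dec_l)),
            "pooled_tau_b": float(tau_b),
            "n_pooled_segments": pooled.n_segments_averaged,
        }
    taus = [out[p]["pooled_tau_b"] for p in powers]
    out["tau_b_variation"] = float((max(taus) - min(taus)) / np.median(taus))
    return out
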