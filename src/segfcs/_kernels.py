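"""Numba-compiled inner loop of the particle-based carpet simulator.

The simulation advances one scanned line at a time.  Per line each live
(unbleached) particle either takes a Brownian step (free) or stays put
(bound); free particles inside the damage strip may bind after the damage
onset, bound particles unbind with an exponential dwell time.  The expected
photon count at each pixel is the sum of Gaussian detection weights over
particles; pixel counts are Poisson draws split 50/50 into two channels.

Because the beam sweeps the full line every line time, a particle's
photobleaching exposure over one line is governed by its distance from the
scanned line (its y coordinate), so the per-line bleaching hazard is
``bleach_rate * power_factor * exp(-2 y^2 / w0^2) * line_time``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["simulate_lines"]


@njit(cache=True)
def _reflect(v: float, lo: float, hi: float) -> float:
    span = hi - lo
    u = (v - lo) % (2.0 * span)
    if u > span:
        u = 2.0 * span - u
    return lo + u


@njit(cache=True)
def simulate_lines(
    seed: int,
    x_init: np.ndarray,
    y_init: np.ndarray,
    lx: float,
    ly: float,
    d_free: float,
    w0: float,
    brightness: float,
    strip_x0: float,
    strip_x1: float,
    damage_on_time: float,
    k_on: float,
    tau_b: float,
    bleach_rate: float,
    power_factor: float,
    line_time: float,
    n_lines: int,
    n_pixels: int,
    pixel_x0: float,
    pixel_size: float,
):
    np.random.seed(seed)

    n_particles = len(x_init)
    counts = np.zeros((2, n_lines, n_pixels), dtype=np.int32)
    bound_per_line = np.zeros(n_lines, dtype=np.int32)
    bleached_per_line = np.zeros(n_lines, dtype=np.int32)

    x = x_init.copy()
    y = y_init.copy()
    bound = np.zeros(n_particles, dtype=np.bool_)
    bleached = np.zeros(n_particles, dtype=np.bool_)
    bind_line = np.zeros(n_particles, dtype=np.int64)

    dwell_sum = 0.0
    dwell_n = 0

    sigma = np.sqrt(2.0 * d_free * line_time)
    p_unbind = 1.0 - np.exp(-line_time / tau_b) if tau_b > 0.0 else 1.0
    p_bind = 1.0 - np.exp(-k_on * line_time) if k_on > 0.0 else 0.0
    half_ly = 0.5 * ly
    inv_w2 = 2.0 / (w0 * w0)
    bb = brightness * power_factor
    kb = bleach_rate * power_factor
    window = int(np.ceil(3.0 * w0 / pixel_size))
    lam = np.zeros(n_pixels)

    for t in range(n_lines):
        for p in range(n_pixels):
            lam[p] = 0.0
        damage_active = t * line_time >= damage_on_time

        for i in range(n_particles):
            if bleached[i]:
                continue
            if bound[i]:
                if np.random.random() < p_unbind:
                    bound[i] = False
                    dwell_sum += (t - bind_line[i]) * line_time
                    dwell_n += 1
            if not bound[i]:
                if sigma > 0.0:
                    x[i] = _reflect(x[i] + sigma * np.random.normal(), 0.0, lx)
                    y[i] = _reflect(
                        y[i] + sigma * np.random.normal(), -half_ly, half_ly
                    )
                if (
                    damage_active
                    and p_bind > 0.0
                    and strip_x0 <= x[i] <= strip_x1
                    and np.random.random() < p_bind
                ):
                    bound[i] = True
                    bind_line[i] = t

            gy = np.exp(-inv_w2 * y[i] * y[i])
            if bb > 0.0 and gy > 1e-8:
                pc = int(np.floor((x[i] - pixel_x0) / pixel_size))
                p0 = max(0, pc - window)
                p1 = min(n_pixels - 1, pc + window)
                for p in range(p0, p1 + 1):
                    dx = pixel_x0 + (p + 0.5) * pixel_size - x[i]
                    lam[p] += bb * gy * np.exp(-inv_w2 * dx * dx)

            if kb > 0.0 and gy > 1e-12:
                if np.random.random() < 1.0 - np.exp(-kb * gy * line_time):
                    bleached[i] = True
                    if bound[i]:
                        dwell_sum += (t - bind_line[i] + 1) * line_time
                        dwell_n += 1
                        bound[i] = False

        nb = 0
        nbl = 0
        for i in range(n_particles):
            if bleached[i]:
                nbl += 1
            elif bound[i]:
                nb += 1
        bound_per_line[t] = nb
        bleached_per_line[t] = nbl

        for p in range(n_pixels):
            if lam[p] > 0.0:
                n_tot = np.random.poisson(lam[p])
                if n_tot > 0:
                    c1 = np.random.binomial(n_tot, 0.5)
                    counts[0, t, p] = c1
                    counts[1, t, p] = n_tot - c1

    return counts, bound_per_line, bleached_per_line, dwell_sum, dwell_n
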