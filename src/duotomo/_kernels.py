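"""Numba inner loops for the acoustic forward models and delay-and-sum.

All kernels work in mm / microseconds / MHz.  Delay lookups use linear
interpolation between adjacent samples; out-of-window delays contribute zero
and are counted so callers can surface truncation warnings.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# apodization mode codes shared with pact_recon
APOD_NONE = 0
APOD_COSINE = 1
APOD_HANN = 2


PULSE_OVERSAMPLE = 8
PULSE_HALF_SIGMAS = 3.0


def make_pulse_table(kind, f0, sigma, fs):
    """Oversampled pulse waveform table for fast forward-model deposits.

    ``kind`` 'pa' is the N-shaped -sin(2*pi*f0*t)*exp(-t^2/2sigma^2) pulse,
    'us' the cosine tone burst with the same Gaussian envelope.  The table
    spans [-PULSE_HALF_SIGMAS*sigma, +...] at PULSE_OVERSAMPLE times the
    sampling rate; kernels interpolate it linearly.
    """
    half = PULSE_HALF_SIGMAS * sigma
    dt = 1.0 / (PULSE_OVERSAMPLE * fs)
    t = np.arange(-half, half + dt, dt)
    env = np.exp(-0.5 * (t / sigma) ** 2)
    if kind == "pa":
        vals = -np.sin(2.0 * math.pi * f0 * t) * env
    else:
        vals = np.cos(2.0 * math.pi * f0 * t) * env
    return np.ascontiguousarray(vals), half, dt


@njit(cache=True, inline="always")
def _deposit(out, d, tof, amp, fs, table, t_half, dt_tab, n_t):
    s0 = int(max((tof - t_half) * fs, 0.0))
    s1 = int(min((tof + t_half) * fs + 1.0, n_t))
    n_tab = table.size
    for s in range(s0, s1):
        u = (s / fs - tof + t_half) / dt_tab
        k = int(u)
        if k < 0 or k + 1 >= n_tab:
            continue
        frac = u - k
        out[s, d] += amp * (table[k] * (1.0 - frac) + table[k + 1] * frac)


@njit(cache=True)
def pa_forward_kernel(src_xy, src_amp, det_xy, fs, c, floor_mm, n_t,
                      table, t_half, dt_tab):
    """Deposit the tabulated N-shaped pulse centred at t = d/c per source.

    Amplitude decays as 1/max(distance, floor_mm); contributions superpose.
    Returns (n_t, n_det) samples.
    """
    n_det = det_xy.shape[0]
    out = np.zeros((n_t, n_det))
    for i in range(src_xy.shape[0]):
        sx = src_xy[i, 0]
        sy = src_xy[i, 1]
        a0 = src_amp[i]
        for d in range(n_det):
            dx = det_xy[d, 0] - sx
            dy = det_xy[d, 1] - sy
            dist = math.sqrt(dx * dx + dy * dy)
            _deposit(out, d, dist / c, a0 / max(dist, floor_mm), fs,
                     table, t_half, dt_tab, n_t)
    return out


@njit(cache=True)
def urct_forward_kernel(
    scat_xy, refl, e_xy, e_nrm, det_xy, cos_gate, fs, c, floor_mm, n_t,
    table, t_half, dt_tab,
):
    """Tone-burst pulse-echo frame for one emitter.

    Scatterers outside the emitter's transmit cone (angle to the emitter's
    inward normal >= acos(cos_gate)) contribute nothing.  Amplitude decays as
    1/(d1*d2) with both legs floored at ``floor_mm``.
    """
    n_det = det_xy.shape[0]
    out = np.zeros((n_t, n_det))
    for i in range(scat_xy.shape[0]):
        sx = scat_xy[i, 0]
        sy = scat_xy[i, 1]
        vx = sx - e_xy[0]
        vy = sy - e_xy[1]
        d1 = math.sqrt(vx * vx + vy * vy)
        if d1 <= 0.0:
            continue
        cosang = (vx * e_nrm[0] + vy * e_nrm[1]) / d1
        if cosang < cos_gate:
            continue
        a0 = refl[i]
        for d in range(n_det):
            dx = det_xy[d, 0] - sx
            dy = det_xy[d, 1] - sy
            d2 = math.sqrt(dx * dx + dy * dy)
            _deposit(out, d, (d1 + d2) / c,
                     a0 / (max(d1, floor_mm) * max(d2, floor_mm)), fs,
                     table, t_half, dt_tab, n_t)
    return out


@njit(cache=True)
def das_kernel(samples, det_xy, det_nrm, px, py, c, fs, apod_mode):
    """One-leg delay-and-sum of real channel data onto a pixel grid.

    ``samples`` is (n_t, n_det) with columns matching ``det_xy`` rows.
    Returns (image (n_y, n_x), truncation count).
    """
    n_t, n_det = samples.shape
    n_x = px.size
    n_y = py.size
    out = np.zeros((n_y, n_x))
    trunc = 0
    for d in range(n_det):
        ex = det_xy[d, 0]
        ey = det_xy[d, 1]
        nx = det_nrm[d, 0]
        ny = det_nrm[d, 1]
        for j in range(n_y):
            dy = py[j] - ey
            for i in range(n_x):
                dx = px[i] - ex
                dist = math.sqrt(dx * dx + dy * dy)
                tau = dist / c * fs
                k = int(tau)
                if k + 1 >= n_t or tau < 0.0:
                    trunc += 1
                    continue
                frac = tau - k
                val = samples[k, d] * (1.0 - frac) + samples[k + 1, d] * frac
                if apod_mode == APOD_NONE:
                    w = 1.0
                else:
                    cosq = (dx * nx + dy * ny) / max(dist, 1e-12)
                    if cosq <= 0.0:
                        w = 0.0
                    elif apod_mode == APOD_COSINE:
                        w = cosq
                    else:  # Hann over the detection angle [0, 90 deg]
                        w = cosq * cosq
                out[j, i] += w * val
    return out, trunc


@njit(cache=True)
def sa_das_kernel(analytic, e_xy, e_nrm, det_xy, det_nrm, px, py, c, fs,
                  cos_tx_gate, rx_apod):
    """Two-leg complex delay-and-sum for one synthetic-aperture frame.

    ``analytic`` is the (n_t, n_det) analytic (Hilbert) signal of the gated
    receivers only.  Pixels outside the emitter's transmit cone
    (angle to the emitter's inward normal >= acos(cos_tx_gate)) are not
    reconstructed in this frame; ``rx_apod`` != 0 applies cosine receive
    directivity weighting.  Returns (complex image, in-cone mask, truncation
    count).
    """
    n_t, n_det = analytic.shape
    n_x = px.size
    n_y = py.size
    out = np.zeros((n_y, n_x), dtype=np.complex128)
    cone = np.zeros((n_y, n_x), dtype=np.uint8)
    trunc = 0
    for j in range(n_y):
        for i in range(n_x):
            dx1 = px[i] - e_xy[0]
            dy1 = py[j] - e_xy[1]
            d1 = math.sqrt(dx1 * dx1 + dy1 * dy1)
            if d1 <= 0.0:
                continue
            if (dx1 * e_nrm[0] + dy1 * e_nrm[1]) / d1 < cos_tx_gate:
                continue
            cone[j, i] = 1
            acc = 0.0 + 0.0j
            for d in range(n_det):
                dx2 = px[i] - det_xy[d, 0]
                dy2 = py[j] - det_xy[d, 1]
                d2 = math.sqrt(dx2 * dx2 + dy2 * dy2)
                tau = (d1 + d2) / c * fs
                k = int(tau)
                if k + 1 >= n_t or tau < 0.0:
                    trunc += 1
                    continue
                frac = tau - k
                val = analytic[k, d] * (1.0 - frac) + analytic[k + 1, d] * frac
                if rx_apod != 0:
                    cosr = (dx2 * det_nrm[d, 0] + dy2 * det_nrm[d, 1]) / max(
                        d2, 1e-12
                    )
                    if cosr <= 0.0:
                        continue
                    val *= cosr
                acc += val
            out[j, i] = acc
    return out, cone, trunc
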