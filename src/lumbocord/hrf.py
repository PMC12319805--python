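"""Hemodynamic response modelling shared by the simulator and the GLM.

The canonical response is a double-gamma function (positive gamma peaking
~6 s after onset minus a scaled undershoot gamma peaking ~16 s).  Temporal
and dispersion derivatives provide a small basis that absorbs latency and
width mismatch; together with the canonical shape they form the GLM's
three-function basis.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import gamma as _gamma


def double_gamma(
    t: np.ndarray,
    peak_delay: float = 6.0,
    undershoot_delay: float = 16.0,
    undershoot_ratio: float = 1.0 / 6.0,
    dispersion: float = 1.0,
) -> np.ndarray:
    """Canonical double-gamma HRF sampled at times ``t`` (seconds).

    Peak normalized to 1.  ``dispersion`` scales the gamma time constant of
    the positive lobe (used by the dispersion derivative).
    """
    t = np.asarray(t, dtype=float)
    h = _gamma.pdf(t, peak_delay / dispersion, scale=dispersion) - (
        undershoot_ratio * _gamma.pdf(t, undershoot_delay, scale=1.0)
    )
    h = np.where(t < 0, 0.0, h)
    peak = h.max()
    return h / peak if peak > 0 else h


def hrf_basis(t: np.ndarray, peak_delay: float = 6.0) -> np.ndarray:
    """Three-column basis: canonical, temporal derivative, dispersion derivative.

    Derivatives are finite differences with respect to a 0.1 s onset shift
    and a 1% dispersion change, each rescaled to unit peak magnitude.
    """
    t = np.asarray(t, dtype=float)
    h = double_gamma(t, peak_delay=peak_delay)
    dt = 0.1
    tderiv = (double_gamma(t + dt, peak_delay=peak_delay) - h) / dt
    dd = 0.01
    ddisp = (double_gamma(t, peak_delay=peak_delay, dispersion=1.0 + dd) - h) / dd
    basis = np.column_stack([h, tderiv, ddisp])
    for j in (1, 2):
        m = np.abs(basis[:, j]).max()
        if m > 0:
            basis[:, j] /= m
    return basis


def block_boxcar(
    blocks: list[tuple[float, float, str]],
    duration_s: float,
    dt: float = 0.1,
    labels: set[str] | None = None,
) -> np.ndarray:
    """0/1 stimulus function sampled on a fine grid of step ``dt``.

    ``labels`` restricts to blocks with matching labels (None = all).
    """
    n = int(np.ceil(duration_s / dt))
    u = np.zeros(n)
    for onset, dur, label in blocks:
        if labels is not None and label not in labels:
            continue
        i0 = int(round(onset / dt))
        i1 = int(round((onset + dur) / dt))
        u[i0 : min(i1, n)] = 1.0
    return u


def convolve_blocks(
    blocks: list[tuple[float, float, str]],
    tr: float,
    n_volumes: int,
    peak_delay: float = 6.0,
    dt: float = 0.1,
    labels: set[str] | None = None,
) -> np.ndarray:
    """Block regressors: boxcar convolved with the three-function basis.

    Returns an ``(n_volumes, 3)`` array sampled at volume times ``i * tr``.
    The canonical column is normalized so that a sustained block reaches a
    plateau of 1 (HRF kernel scaled to unit sum would change with dt; here
    the kernel is normalized to unit integral).
    """
    total = n_volumes * tr
    u = block_boxcar(blocks, total, dt=dt, labels=labels)
    t_kernel = np.arange(0, 32.0, dt)
    basis = hrf_basis(t_kernel, peak_delay=peak_delay)
    # unit-integral canonical kernel -> plateau of a long block is 1
    area = basis[:, 0].sum() * dt
    out = np.empty((n_volumes, 3))
    sample = np.minimum((np.arange(n_volumes) * tr / dt).round().astype(int), len(u) - 1)
    for j in range(3):
        conv = np.convolve(u, basis[:, j] * dt / area)[: len(u)]
        out[:, j] = conv[sample]
    return out
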