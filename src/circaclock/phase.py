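"""Hilbert-phase goodness-of-fit diagnostics.

The analytic signal of a detrended series ``x(t)`` supplies a replica 90°
out of phase (the Hilbert transform ``x~``); the wrapped phase is
``F_H = atan2(x~, x)``.  Unwrapping the ±π discontinuities gives the
continuized phase ``F_C``, shifted to pass through the origin, and dividing
by 2π counts completed cycles ``M_C(t, 0)``.  Phase is functionally
independent of the periodogram (amplitude rescaling leaves it unchanged), so
it serves as a held-out test of a spectrum-fitted model: percentile bands of
``M_C`` across model cells are compared with the data's mean phase
trajectory.  The Kuramoto order parameter ``K = |<exp(i F_H)>_cells|``
(time-averaged) measures phase synchronization across the population.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from .ssa import GridSeries

__all__ = [
    "PhaseSeries",
    "PhaseBandSummary",
    "hilbert_phase",
    "phase_bands",
    "kuramoto_K",
    "band_exit_time",
]

#: Fraction of points at each end excluded from band summaries (analytic-
#: signal edge artifacts).
EDGE_FRACTION = 0.05


@dataclass
class PhaseSeries:
    """Phase measures of one cell."""

    t: np.ndarray
    F_H: np.ndarray   # wrapped phase, radians
    F_C: np.ndarray   # continuized phase, shifted through the origin
    M_C: np.ndarray   # cycles completed since t[0]


@dataclass
class PhaseBandSummary:
    """Pointwise 5th percentile, mean and 95th percentile of M_C across
    cells (edges excluded)."""

    t: np.ndarray
    p5: np.ndarray
    mean: np.ndarray
    p95: np.ndarray


def hilbert_phase(series: GridSeries | np.ndarray,
                  t: np.ndarray | None = None) -> PhaseSeries:
    """Analytic-signal phase of a detrended series.

    The wrapped phase is continuized (unwrapped) and shifted so the
    continuous phase passes through 0 at the first sample; ``M_C`` is the
    continuized phase divided by 2π.
    """
    if isinstance(series, GridSeries):
        y = np.asarray(series.values, dtype=float)
        t = series.t
    else:
        y = np.asarray(series, dtype=float)
        if t is None:
            t = np.arange(len(y), dtype=float)
    if len(y) < 8:
        raise ValueError("series too short for a phase estimate")
    if np.allclose(y, 0.0):
        raise ValueError("all-zero series has no phase")
    z = hilbert(y)
    F_H = np.angle(z)
    F_C = np.unwrap(F_H)
    F_C = F_C - F_C[0]
    M_C = F_C / (2.0 * np.pi)
    return PhaseSeries(t=np.asarray(t, float), F_H=F_H, F_C=F_C, M_C=M_C)


def _interior(n: int, edge_fraction: float = EDGE_FRACTION) -> slice:
    k = int(np.floor(n * edge_fraction))
    return slice(k, n - k if k > 0 else n)


def phase_bands(cells, edge_fraction: float = EDGE_FRACTION) -> PhaseBandSummary:
    """Pointwise percentiles and mean of M_C across ≥ 2 cells on one grid."""
    cells = list(cells)
    if len(cells) < 2:
        raise ValueError("need at least two cells")
    t0 = cells[0].t
    for c in cells[1:]:
        if len(c.t) != len(t0) or not np.allclose(c.t, t0):
            raise ValueError("cells must share one time grid")
    M = np.vstack([c.M_C for c in cells])
    sl = _interior(M.shape[1], edge_fraction)
    return PhaseBandSummary(
        t=t0[sl],
        p5=np.percentile(M[:, sl], 5, axis=0),
        mean=M[:, sl].mean(axis=0),
        p95=np.percentile(M[:, sl], 95, axis=0),
    )


def band_exit_time(model_band: PhaseBandSummary,
                   data_mean: np.ndarray,
                   t: np.ndarray | None = None) -> float | None:
    """First time the data's mean phase leaves the model's 5–95% band
    (the goodness-of-fit failure-time diagnostic); None if it never does."""
    t = model_band.t if t is None else np.asarray(t, float)
    data = np.interp(model_band.t, t, np.asarray(data_mean, float))
    outside = (data < model_band.p5) | (data > model_band.p95)
    idx = np.argmax(outside)
    if not outside.any():
        return None
    return float(model_band.t[idx])


def kuramoto_K(cells, window: tuple | None = None,
               edge_fraction: float = EDGE_FRACTION):
    """Kuramoto order parameter over a population of phase series.

    The across-cell resultant length ``r(t) = |mean_j exp(i F_H_j(t))|`` is
    averaged over the window (default: the interior of the experiment).
    Returns ``(K, se)`` with a standard error over time points.
    """
    cells = list(cells)
    if len(cells) < 2:
        raise ValueError("need at least two cells")
    t = cells[0].t
    Z = np.vstack([np.exp(1j * c.F_H) for c in cells])
    r_t = np.abs(Z.mean(axis=0))
    if window is not None:
        lo, hi = window
        mask = (t >= lo) & (t < hi)
        if not mask.any():
            raise ValueError("empty window")
        r_t = r_t[mask]
    else:
        r_t = r_t[_interior(len(r_t), edge_fraction)]
    K = float(r_t.mean())
    se = float(r_t.std(ddof=1) / np.sqrt(len(r_t))) if len(r_t) > 1 else 0.0
    return K, se
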