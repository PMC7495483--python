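"""Periodogram likelihood with detector-noise bias correction.

Single-cell fluorescence series are detrended with a centered moving average,
transformed with the FFT, and summarized by the one-sided periodogram
``Q(f_l) = |X_l|^2 / L`` at the sample frequencies ``f_l = l/T``,
``l = 1..[L/2]`` (DC is excluded: detrending annihilates it).  Averaging the
periodogram over cells captures period and amplitude of the population of
noisy oscillators while remaining independent of their phases.

Measurement (detector) noise of variance ``sigma_eps2`` — estimated from
doped-bead control series — biases the periodogram and inflates its variance.
With ``gamma_Q(l)`` and ``beta_Q(l)`` the response functions of the
detrend+FFT pipeline to white noise (functions of the moving-average weights
and L only), the bias is ``Q_bias = sigma_eps2/L * gamma_Q`` and the detector
contribution to the variance of the cell-averaged periodogram is

    (sigma_l^e)^2 = 2 sigma_eps2/(K L) [<Q> gamma_Q + Re(<R> conj(beta_Q))]
                    - sigma_eps2^2/(K L^2) [|gamma_Q|^2 + |beta_Q|^2]

where ``<R(f_l)> = <X_l^2>/L`` is the cell-averaged squared (not
modulus-squared) Fourier transform.  The fitting criterion is

    chi^2 = sum_l (<Q> - Q_bias - <Q_model>)^2 / (sigma_l^c)^2,

with corrected variance ``(sigma^c)^2 = sigma^2 - (sigma^e)^2`` (floored),
and likelihood proportional to ``exp(-chi^2 / (2 T_temp))`` under tempering.
Independent experiments multiply: their chi^2 values add.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .network import ReactionNetwork
from .ssa import DEFAULT_READOUT, GridSeries, simulate_grid_batch, uniform_grid

__all__ = [
    "DetrendKernel",
    "SpectrumSet",
    "detrend",
    "periodogram",
    "spectrum_from_cells",
    "detector_bias_terms",
    "chi_squared",
    "model_spectrum",
    "DEFAULT_WINDOW_POINTS",
]

#: Default moving-average window: 24 h at half-hour sampling (49 points).
DEFAULT_WINDOW_POINTS = 49

#: Corrected variances are floored at this fraction of their median to avoid
#: division blow-ups where the detector correction nearly cancels the total.
VARIANCE_FLOOR_FRACTION = 1e-3


@dataclass(frozen=True)
class DetrendKernel:
    """Centered moving-average detrender (uniform weights, edge-renormalized).

    The derived response functions ``gamma_Q(l)`` and ``beta_Q(l)`` depend
    only on the weights and the series length L, not on the data; they are
    computed exactly by propagating the linear detrend operator through the
    FFT and cached per (L, window).
    """

    window: int = DEFAULT_WINDOW_POINTS

    def __post_init__(self):
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError("window must be a positive odd point count")

    def weights(self) -> np.ndarray:
        return np.full(self.window, 1.0 / self.window)

    def apply(self, values: np.ndarray) -> np.ndarray:
        y = np.asarray(values, dtype=float)
        if self.window >= len(y):
            raise ValueError("window must be shorter than the series")
        ones = np.ones(self.window)
        num = np.convolve(y, ones, mode="same")
        den = np.convolve(np.ones_like(y), ones, mode="same")
        return y - num / den

    def response(self, L: int):
        """(gamma_Q, beta_Q) for series length L (cached)."""
        return _detrend_response(L, self.window)


@lru_cache(maxsize=32)
def _detrend_response(L: int, window: int):
    # columns of the residual operator R = I - M propagated through the FFT:
    # G = F R; gamma_Q(l) = sum_k |G_lk|^2, beta_Q(l) = sum_k G_lk^2.
    ones = np.ones(window)
    den = np.convolve(np.ones(L), ones, mode="same")
    R = np.eye(L)
    for k in range(L):
        col = np.zeros(L)
        col[k] = 1.0
        R[:, k] -= np.convolve(col, ones, mode="same") / den
    G = np.fft.fft(R, axis=0)[: L // 2 + 1, :]
    gamma = np.sum(np.abs(G) ** 2, axis=1)
    beta = np.sum(G * G, axis=1)
    return gamma[1:], beta[1:]  # drop DC, matching l = 1..[L/2]


def detrend(series: GridSeries, kernel: DetrendKernel | None = None) -> GridSeries:
    """Subtract the centered moving average (edge windows renormalized)."""
    kernel = kernel or DetrendKernel()
    return GridSeries(t=series.t, values=kernel.apply(series.values),
                      species=series.species)


def periodogram(series: GridSeries | np.ndarray) -> np.ndarray:
    """One-sided power ``|X_l|^2/L`` at ``l = 1..[L/2]`` (DC excluded)."""
    y = series.values if isinstance(series, GridSeries) else np.asarray(series, float)
    L = len(y)
    if L < 4:
        raise ValueError("series too short for a periodogram")
    X = np.fft.rfft(y)
    return (np.abs(X[1: L // 2 + 1]) ** 2) / L


def _squared_transform(y: np.ndarray) -> np.ndarray:
    L = len(y)
    X = np.fft.rfft(y)
    return (X[1: L // 2 + 1] ** 2) / L


@dataclass
class SpectrumSet:
    """Per-frequency summary of a population of cells (or model cells)."""

    f: np.ndarray                    # sample frequencies l/T, l = 1..[L/2]
    Q_avg: np.ndarray                # cell-averaged periodogram
    R_avg: np.ndarray                # cell-averaged squared Fourier transform
    var_total: np.ndarray            # variance of the cell-averaged periodogram
    K_cells: int
    L_points: int
    T_dur: float
    sigma_eps2: float = 0.0
    Q_bias: np.ndarray | None = None
    var_detector: np.ndarray | None = None
    var_corrected: np.ndarray | None = None
    used: np.ndarray | None = None   # frequencies retained for fitting

    @property
    def periods(self) -> np.ndarray:
        return 1.0 / self.f

    @property
    def n_frequencies(self) -> int:
        return len(self.f)

    @property
    def n_used(self) -> int:
        return int(self.used.sum()) if self.used is not None else len(self.f)

    def corrected_Q(self) -> np.ndarray:
        if self.Q_bias is None:
            return self.Q_avg
        return self.Q_avg - self.Q_bias

    def peak_period(self) -> float:
        """Period of the maximal spectral bin (of the corrected spectrum)."""
        return float(1.0 / self.f[int(np.argmax(self.corrected_Q()))])


def spectrum_from_cells(cells, T: float,
                        kernel: DetrendKernel | None = None,
                        sigma_eps2: float = 0.0,
                        already_detrended: bool = False) -> SpectrumSet:
    """Detrend each cell, average periodograms, and attach bias/variance
    terms.  ``cells`` is a sequence of equal-length series (GridSeries or
    arrays); ``var_total`` is the across-cell sample variance divided by K
    (the variance of the mean, by the central-limit argument)."""
    kernel = kernel or DetrendKernel()
    ys = [c.values if isinstance(c, GridSeries) else np.asarray(c, float)
          for c in cells]
    L = len(ys[0])
    if any(len(y) != L for y in ys):
        raise ValueError("cells must share one grid")
    K = len(ys)
    Q = np.empty((K, L // 2))
    R = np.empty((K, L // 2), dtype=complex)
    for i, y in enumerate(ys):
        d = y if already_detrended else kernel.apply(y)
        Q[i] = periodogram(d)
        R[i] = _squared_transform(d)
    Q_avg = Q.mean(axis=0)
    R_avg = R.mean(axis=0)
    var_total = Q.var(axis=0, ddof=1) / K if K > 1 else np.zeros(L // 2)
    spec = SpectrumSet(f=np.arange(1, L // 2 + 1) / T, Q_avg=Q_avg,
                       R_avg=R_avg, var_total=var_total, K_cells=K,
                       L_points=L, T_dur=T, sigma_eps2=sigma_eps2)
    if sigma_eps2 > 0:
        detector_bias_terms(spec, kernel)
    else:
        spec.Q_bias = np.zeros(L // 2)
        spec.var_detector = np.zeros(L // 2)
        spec.var_corrected = spec.var_total.copy()
        spec.used = spec.var_corrected > 0
    return spec


def detector_bias_terms(spec: SpectrumSet,
                        kernel: DetrendKernel | None = None):
    """Attach the detector bias ``Q_bias`` and variance contribution
    ``(sigma^e)^2`` to a spectrum set, and the floored corrected variance."""
    kernel = kernel or DetrendKernel()
    if spec.sigma_eps2 < 0:
        raise ValueError("sigma_eps2 must be nonnegative")
    gamma, beta = kernel.response(spec.L_points)
    s2 = spec.sigma_eps2
    L = spec.L_points
    K = spec.K_cells
    spec.Q_bias = (s2 / L) * gamma
    var_det = (2.0 * s2 / (K * L)) * (spec.Q_avg * gamma
                                      + np.real(spec.R_avg * np.conj(beta)))
    var_det -= (s2 ** 2 / (K * L ** 2)) * (np.abs(gamma) ** 2 + np.abs(beta) ** 2)
    spec.var_detector = var_det
    vc = spec.var_total - var_det
    pos = vc[vc > 0]
    if len(pos):
        floor = VARIANCE_FLOOR_FRACTION * np.median(pos)
        # detector-dominated bins (corrected variance at or below the floor)
        # carry no usable biological signal and are excluded from fitting —
        # which is why experiments contribute different frequency counts
        spec.used = vc > floor
        vc = np.maximum(vc, floor)
    else:
        spec.used = np.zeros_like(vc, dtype=bool)
    spec.var_corrected = vc
    return spec.Q_bias, spec.var_detector


def chi_squared(model_spec: SpectrumSet, data_spec: SpectrumSet,
                temperature: float = 1.0,
                include_model_variance: bool = False):
    """The ensemble-selection criterion: χ² of the bias-corrected data
    spectrum against the model spectrum, and the tempered log-likelihood
    (up to the Θ-independent normalization, which cancels in MCMC ratios).

    ``include_model_variance`` debiases the criterion for a finite model
    batch: the model spectrum's own Monte-Carlo variance (across its
    simulated trajectories, divided by their number) is subtracted from the
    squared residual — whose expectation otherwise contains it, penalizing
    parameter regions where the model fluctuates more — and added to the
    denominator.  At full scale (~1,000 model trajectories) both terms are
    negligible and the criterion reduces to the plain data-variance form.
    """
    if model_spec.n_frequencies != data_spec.n_frequencies or not np.allclose(
            model_spec.f, data_spec.f):
        raise ValueError("frequency grids do not match")
    v = data_spec.var_corrected
    if v is None:
        v = data_spec.var_total
    used = data_spec.used
    if used is None:
        used = np.ones_like(v, dtype=bool)
    if np.any(v[used] <= 0):
        raise ValueError("nonpositive corrected variance at a used frequency")
    denom = v[used]
    resid = (data_spec.corrected_Q() - model_spec.Q_avg)[used]
    sq = resid ** 2
    if include_model_variance and model_spec.var_total is not None:
        vm = model_spec.var_total[used]
        sq = sq - vm
        denom = denom + vm
    chi2 = float(np.sum(sq / denom))
    loglik = -chi2 / (2.0 * temperature)
    return chi2, loglik


def model_spectrum(network: ReactionNetwork, n_traj: int, L: int, T: float,
                   seed: int, kernel: DetrendKernel | None = None,
                   species: str = DEFAULT_READOUT,
                   drop_before: float = 0.0) -> SpectrumSet:
    """Model-generated average periodogram: simulate ``n_traj`` exact
    trajectories, grid-sample the read-out, detrend, average the
    periodograms.  No bias term (the model has no detector noise)."""
    if n_traj < 2:
        raise ValueError("n_traj must be >= 2")
    batch = simulate_grid_batch(network, n_traj, L, T, seed,
                                drop_before=drop_before)
    si = network.species_index(species)
    cells = [batch[i, :, si].astype(float) for i in range(n_traj)]
    return spectrum_from_cells(cells, T, kernel=kernel, sigma_eps2=0.0)
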