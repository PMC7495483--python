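"""Stochastic-resonance experiments over intracellular noise levels.

The RNA/DNA and protein/DNA ratios proxy "cell size": rescaling them with
compensating rate changes (see :func:`circaclock.network.rescale_ratios`)
varies the intracellular noise while leaving the mean-field dynamics
invariant.  Three experiments:

* a noise surface over a grid of ratio pairs (total periodogram-height
  variance summed over frequencies),
* power-versus-noise resonance curves at the driving and intrinsic
  frequencies over a multiplier set applied to both measured ratios,
* mean recorder/FRQ trajectories at selected multipliers to visualize
  amplification at the resonance and degradation away from it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import LightProgram, build_clock_network, rescale_ratios
from .params import MEASURED_RATIOS, RatioPair, ThetaVector
from .spectral import DetrendKernel, model_spectrum, periodogram
from .ssa import DEFAULT_READOUT, simulate_grid_batch

__all__ = ["FIG_MULTIPLIERS", "INTRINSIC_PERIOD_H", "NoiseSurfacePoint",
           "ResonancePoint", "noise_surface", "resonance_scan",
           "mean_species_trajectory", "power_at_period"]

#: The published resonance-scan multiplier set.
FIG_MULTIPLIERS = (1 / 7, 1 / 10, 1 / 12, 1 / 40, 1 / 100, 1 / 170,
                   4.0, 8.0, 12.0, 15.0, 30.0, 50.0)

#: The cellular oscillator's intrinsic period (h).
INTRINSIC_PERIOD_H = 21.0


@dataclass
class NoiseSurfacePoint:
    ratios: RatioPair
    total_noise: float


@dataclass
class ResonancePoint:
    multiplier: float
    experiment: str
    power_driving: float
    power_intrinsic: float


def power_at_period(spec, period_h: float, halfwidth_bins: int = 0) -> float:
    """Power at the frequency bin nearest ``1/period_h`` (optionally the
    maximum over ±halfwidth_bins neighboring bins)."""
    l = int(np.argmin(np.abs(spec.f - 1.0 / period_h)))
    lo = max(l - halfwidth_bins, 0)
    hi = min(l + halfwidth_bins + 1, len(spec.f))
    return float(np.max(spec.corrected_Q()[lo:hi]))


def _detrended_periodograms(network, n_traj, L, T, seed, kernel,
                            species=DEFAULT_READOUT):
    batch = simulate_grid_batch(network, n_traj, L, T, seed)
    si = network.species_index(species)
    kernel = kernel or DetrendKernel()
    return np.vstack([periodogram(kernel.apply(batch[i, :, si].astype(float)))
                      for i in range(n_traj)])


def noise_surface(theta: ThetaVector, ratio_grid, light: LightProgram,
                  n_traj: int = 128, L: int = 480, T: float = 240.0,
                  seed: int = 0, kernel: DetrendKernel | None = None,
                  reference: RatioPair = MEASURED_RATIOS) -> list:
    """Total stochastic noise per ratio pair: simulate the rescaled model,
    take the variance of periodogram heights over trajectories at each
    frequency, and sum over frequencies."""
    out = []
    for ratios in ratio_grid:
        th = rescale_ratios(theta, reference, ratios)
        net = build_clock_network(th, light)
        Q = _detrended_periodograms(net, n_traj, L, T, seed, kernel)
        var_per_freq = Q.var(axis=0, ddof=1) if len(Q) > 1 else np.zeros(Q.shape[1])
        out.append(NoiseSurfacePoint(ratios=ratios,
                                     total_noise=float(var_per_freq.sum())))
    return out


def resonance_scan(theta: ThetaVector, multipliers=FIG_MULTIPLIERS,
                   experiments=("D/D",), n_traj: int = 128, L: int = 480,
                   T: float = 240.0, seed: int = 0,
                   kernel: DetrendKernel | None = None,
                   reference: RatioPair = MEASURED_RATIOS,
                   halfwidth_bins: int = 0) -> pd.DataFrame:
    """Power at the driving and intrinsic frequencies as a function of the
    common ratio multiplier (the noise axis).

    For each multiplier both measured ratios are rescaled (dynamics-
    preserving), ``n_traj`` trajectories are simulated per experiment, and
    the average detrended periodogram is read out at the nearest bins to the
    driving period (the experiment's day length; undefined for D/D) and the
    ~21 h intrinsic period (the control).
    """
    from .synth import REGIMES
    rows = []
    for m in multipliers:
        if m <= 0:
            raise ValueError("multipliers must be positive")
        th = rescale_ratios(theta, reference, reference.scaled(m))
        for exp in experiments:
            day = REGIMES[exp]
            light = (LightProgram.dark(T) if day is None
                     else LightProgram.ld_day(day, T))
            net = build_clock_network(th, light)
            spec = model_spectrum(net, n_traj, L, T, seed, kernel=kernel)
            p_int = power_at_period(spec, INTRINSIC_PERIOD_H, halfwidth_bins)
            p_drv = (power_at_period(spec, day, halfwidth_bins)
                     if day is not None else np.nan)
            rows.append({"multiplier": m, "experiment": exp,
                         "power_driving": p_drv, "power_intrinsic": p_int})
    return pd.DataFrame(rows)


def argmax_multiplier(scan: pd.DataFrame, experiment: str = "D/D",
                      column: str | None = None) -> float:
    """The multiplier maximizing power for one experiment (driving-frequency
    power for L/D regimes, intrinsic power for D/D)."""
    sub = scan[scan.experiment == experiment]
    if column is None:
        column = "power_intrinsic" if experiment == "D/D" else "power_driving"
    return float(sub.loc[sub[column].idxmax(), "multiplier"])


def mean_species_trajectory(theta: ThetaVector, light: LightProgram,
                            multiplier: float = 1.0, n_traj: int = 128,
                            L: int = 480, T: float = 240.0, seed: int = 0,
                            species: str = "f_p",
                            reference: RatioPair = MEASURED_RATIOS):
    """Pointwise mean count trajectory (default: the FRQ oscillator protein)
    at a given noise multiplier — the at/off-resonance comparison view."""
    th = (theta if multiplier == 1.0
          else rescale_ratios(theta, reference, reference.scaled(multiplier)))
    net = build_clock_network(th, light)
    batch = simulate_grid_batch(net, n_traj, L, T, seed)
    si = net.species_index(species)
    from .ssa import uniform_grid
    return uniform_grid(L, T), batch[:, :, si].mean(axis=0)
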