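"""Metropolis–Hastings accumulation and ensemble summaries.

Each optimizer solution seeds a Metropolis–Hastings chain on the unit cube:
14,000 updates by default, of which the first 3,500 adapt the per-parameter
step widths and are discarded, with every 35th subsequent model retained
(300 per chain; 12 chains pool to 3,600 models).  Pooled samples summarize
per parameter as ensemble means with standard errors; a per-parameter trend
test over the sweep index is the completeness control (a finished
accumulation shows no trend).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .params import THETA_NAMES, ParameterBounds, ThetaVector, default_bounds

__all__ = ["MHChain", "EnsembleSample", "mh_accumulate",
           "pool_and_summarize", "trend_diagnostic"]

ACC_WINDOW = (0.6, 0.75)


@dataclass
class MHChain:
    """One thinned accumulation chain on the unit cube."""

    samples: np.ndarray        # (n_retained, dim)
    chi2: np.ndarray           # (n_retained,)
    seed: int
    updates: int
    burn: int
    thin: int
    acceptance: float

    def __len__(self) -> int:
        return len(self.samples)


@dataclass
class EnsembleSample:
    """Pooled accepted Θ points with per-parameter summaries."""

    pooled: np.ndarray          # (n_total, dim), unit-cube coordinates
    chi2: np.ndarray
    theta: np.ndarray           # (n_total, dim), natural units
    names: tuple
    mean: np.ndarray            # per-parameter ensemble mean (natural units)
    se: np.ndarray              # standard error across the pooled ensemble
    sd: np.ndarray              # plain ensemble standard deviation
    chain_sizes: tuple

    @property
    def n_models(self) -> int:
        return len(self.pooled)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"parameter": list(self.names),
                             "ensemble_mean": self.mean,
                             "ensemble_se": self.se})

    def interval(self, lo: float = 5.0, hi: float = 95.0):
        """Per-parameter pooled percentile interval (natural units)."""
        return (np.percentile(self.theta, lo, axis=0),
                np.percentile(self.theta, hi, axis=0))


def mh_accumulate(objective: Callable[[np.ndarray], float],
                  x_start: np.ndarray,
                  updates: int = 14_000, burn: int = 3_500, thin: int = 35,
                  seed: int = 0, step: float = 0.02,
                  temperature: float = 1.0,
                  refresh_current: bool = False) -> MHChain:
    """Metropolis–Hastings accumulation run.

    Component-wise Gaussian proposals on the unit cube (reflected at the
    boundaries); step widths adapt toward the (0.6, 0.75) acceptance window
    only during the burn-in, which is discarded; the retained count is
    ``floor((updates - burn)/thin)``.

    With a stochastic objective, ``refresh_current=True`` re-evaluates the
    held point's χ² at every update so the chain cannot stick to a lucky
    noise draw (Monte-Carlo-within-Metropolis; doubles the evaluation cost).
    """
    if burn >= updates:
        raise ValueError("burn must be smaller than updates")
    if thin < 1:
        raise ValueError("thin must be >= 1")
    rng = np.random.default_rng(seed)
    x = np.asarray(x_start, dtype=float).copy()
    dim = len(x)
    chi2 = float(objective(x))
    widths = np.full(dim, step)
    n_keep = (updates - burn) // thin
    samples = np.empty((n_keep, dim))
    chis = np.empty(n_keep)
    kept = 0
    accepted = proposed = 0
    for u in range(updates):
        adapt = u < burn
        if refresh_current:
            chi2 = float(objective(x))
        d = u % dim
        prop = x.copy()
        z = prop[d] + rng.normal(0.0, widths[d])
        z = np.abs(z) % 2.0
        prop[d] = 2.0 - z if z > 1.0 else z
        chi2_new = float(objective(prop))
        proposed += 1
        if np.log(rng.uniform() + 1e-300) < (chi2 - chi2_new) / (2.0 * temperature):
            x, chi2 = prop, chi2_new
            accepted += 1
            if adapt:
                widths[d] = min(widths[d] * 1.10, 0.5)
        elif adapt:
            # geometric pair targeting ~0.65 acceptance at equilibrium
            widths[d] = max(widths[d] * 0.84, 1e-5)
        if u >= burn and (u - burn) % thin == thin - 1 and kept < n_keep:
            samples[kept] = x
            chis[kept] = chi2
            kept += 1
    return MHChain(samples=samples[:kept], chi2=chis[:kept], seed=seed,
                   updates=updates, burn=burn, thin=thin,
                   acceptance=accepted / max(proposed, 1))


def pool_and_summarize(chains: Sequence[MHChain],
                       bounds: ParameterBounds | None = None,
                       se_mode: str = "standard-error") -> EnsembleSample:
    """Pool chains (no reweighting) and summarize per parameter.

    ``se_mode="standard-error"`` reports SD/√n across the pooled ensemble;
    ``"sd"`` reports the plain ensemble standard deviation.
    """
    chains = list(chains)
    if not chains:
        raise ValueError("need at least one chain")
    dim = chains[0].samples.shape[1]
    if any(c.samples.shape[1] != dim for c in chains):
        raise ValueError("inconsistent parameter schemas across chains")
    pooled = np.vstack([c.samples for c in chains])
    chi2 = np.concatenate([c.chi2 for c in chains])
    bounds = bounds or default_bounds()
    if dim == len(THETA_NAMES):
        theta = np.vstack([bounds.from_cube(x).as_array() for x in pooled])
        names = THETA_NAMES
    else:
        theta = pooled.copy()
        names = tuple(f"x{i}" for i in range(dim))
    mean = theta.mean(axis=0)
    sd = theta.std(axis=0, ddof=1) if len(theta) > 1 else np.zeros(dim)
    se = sd / np.sqrt(len(theta))
    if se_mode == "sd":
        se = sd
    elif se_mode != "standard-error":
        raise ValueError(f"unknown se_mode {se_mode!r}")
    return EnsembleSample(pooled=pooled, chi2=chi2, theta=theta, names=names,
                          mean=mean, se=se, sd=sd,
                          chain_sizes=tuple(len(c) for c in chains))


def trend_diagnostic(chain: MHChain | np.ndarray) -> pd.DataFrame:
    """Least-squares slope of every parameter against the sweep index with a
    two-sided p-value: trends indicate an unfinished accumulation."""
    samples = chain.samples if isinstance(chain, MHChain) else np.asarray(chain)
    n, dim = samples.shape
    if n < 30:
        raise ValueError("chain too short for a trend test")
    sweep = np.arange(n, dtype=float)
    rows = []
    for d in range(dim):
        y = samples[:, d]
        if np.allclose(y, y[0]):
            rows.append((d, 0.0, 1.0, 0.0))
            continue
        res = stats.linregress(sweep, y)
        rows.append((d, res.slope, res.pvalue, res.rvalue))
    names = (list(THETA_NAMES) if dim == len(THETA_NAMES)
             else [f"x{i}" for i in range(dim)])
    return pd.DataFrame(rows, columns=["index", "slope", "p_value", "r"]) \
        .assign(parameter=names)[["parameter", "slope", "p_value", "r"]]
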