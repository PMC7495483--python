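"""Parallel tempering over an adaptively constructed temperature grid.

K replicas of the tempered likelihood ``exp(-chi^2 / (2 T))`` run in-chain
Metropolis–Hastings updates (component-wise Gaussian random walks on the
unit cube, reflected at the boundaries) and exchange parameter vectors with
their neighbors at the swap acceptance

    rho_ij = min{1, exp[(1/T_i - 1/T_j)(chi2_i - chi2_j)/2]}.

Grid construction follows a three-stage protocol: (1) initialize K = √D
replicas with the top temperature ``T_K = chi2(theta0)/30`` tuned until the
in-chain acceptance falls in (0.6, 0.75); (2) grow the grid, inserting
``R = floor(sqrt(Q / ln 0.4))`` evenly spaced temperatures between neighbor
pairs whose mean log swap acceptance ``Q`` falls short of the 0.4 target
(three rounds); (3) shift interior temperatures so the up/down replica flow
fraction ``f(T) = n_up/(n_up + n_down)`` becomes linear in the grid index
(three rounds, monotone-regressed before inversion).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "TemperatureGrid",
    "Replica",
    "init_grid",
    "swap_probability",
    "swap_attempt",
    "grow_grid",
    "shift_temperatures",
    "run_parallel_tempering",
    "PTResult",
]

SWAP_TARGET = 0.4
ACC_WINDOW = (0.6, 0.75)
TUNE_ITERS = 200
GROW_SWEEPS = 200
FLOW_SWEEPS = 350
GRID_ROUNDS = 3


@dataclass
class TemperatureGrid:
    """Strictly increasing ladder T_1 < ... < T_K with T_1 = 1."""

    temperatures: np.ndarray

    def __post_init__(self):
        T = np.asarray(self.temperatures, dtype=float)
        if len(T) < 2 or T[0] != 1.0 or np.any(np.diff(T) <= 0):
            raise ValueError("grid must be strictly increasing with T_1 = 1")
        self.temperatures = T

    @property
    def K(self) -> int:
        return len(self.temperatures)


@dataclass
class Replica:
    x: np.ndarray
    chi2: float
    temp_index: int
    drift: int = 0          # +1 drifting up (last touched T_1), -1 down (T_K)


def swap_probability(chi2_i: float, chi2_j: float,
                     T_i: float, T_j: float) -> float:
    """Exact tempered-likelihood swap acceptance for neighboring replicas."""
    log_rho = (1.0 / T_i - 1.0 / T_j) * (chi2_i - chi2_j) / 2.0
    return float(min(1.0, np.exp(min(log_rho, 0.0)) if log_rho < 0 else 1.0))


def swap_attempt(rep_i: Replica, rep_j: Replica, grid: TemperatureGrid,
                 rng: np.random.Generator) -> bool:
    """Propose exchanging the Θ of two neighboring replicas; on acceptance
    the parameter vectors (and χ²) trade places across the two temperatures.
    Returns True if the swap was accepted."""
    T_i = grid.temperatures[rep_i.temp_index]
    T_j = grid.temperatures[rep_j.temp_index]
    rho = swap_probability(rep_i.chi2, rep_j.chi2, T_i, T_j)
    if rng.uniform() < rho:
        rep_i.x, rep_j.x = rep_j.x, rep_i.x
        rep_i.chi2, rep_j.chi2 = rep_j.chi2, rep_i.chi2
        rep_i.drift, rep_j.drift = rep_j.drift, rep_i.drift
        return True
    return False


class _Chain:
    """Component-wise Gaussian random-walk Metropolis on the unit cube with
    boundary reflection; per-temperature step widths adapted toward the
    (0.6, 0.75) in-chain acceptance window during tuning phases."""

    def __init__(self, dim: int, step: float = 0.05):
        self.step = np.full(dim, step)
        self.accepted = 0
        self.proposed = 0

    def sweep(self, rep: Replica, objective, T: float,
              rng: np.random.Generator, adapt: bool = False):
        for d in range(len(rep.x)):
            prop = rep.x.copy()
            z = prop[d] + rng.normal(0.0, self.step[d])
            z = np.abs(z) % 2.0
            prop[d] = 2.0 - z if z > 1.0 else z  # reflect into [0, 1]
            chi2_new = objective(prop)
            self.proposed += 1
            if np.log(rng.uniform() + 1e-300) < (rep.chi2 - chi2_new) / (2.0 * T):
                rep.x = prop
                rep.chi2 = chi2_new
                self.accepted += 1
                if adapt:
                    self.step[d] = min(self.step[d] * 1.10, 0.5)
            elif adapt:
                # geometric pair targeting the (0.6, 0.75) in-chain window
                self.step[d] = max(self.step[d] * 0.84, 1e-5)

    def acceptance(self) -> float:
        return self.accepted / max(self.proposed, 1)

    def reset_stats(self):
        self.accepted = 0
        self.proposed = 0


def _tune_top_temperature(objective, x0: np.ndarray, chi2_0: float,
                          T_top: float, rng, max_rounds: int = 12) -> float:
    """Adjust T_K until the in-chain acceptance over 200 iterations falls in
    the (0.6, 0.75) window."""
    for _ in range(max_rounds):
        rep = Replica(x=x0.copy(), chi2=chi2_0, temp_index=0)
        chain = _Chain(len(x0))
        for _ in range(TUNE_ITERS // max(len(x0), 1) + 1):
            chain.sweep(rep, objective, T_top, rng)
            if chain.proposed >= TUNE_ITERS:
                break
        acc = chain.acceptance()
        if ACC_WINDOW[0] < acc < ACC_WINDOW[1]:
            return T_top
        T_top = T_top * 2.0 if acc <= ACC_WINDOW[0] else T_top / 1.5
    return T_top


def init_grid(chi2_0: float, D: int, objective=None, x0=None,
              rng: np.random.Generator | None = None) -> TemperatureGrid:
    """Initial ladder: K = round(√D) replicas, geometric between T_1 = 1 and
    ``T_K = chi2(theta0)/30`` (optionally tuned to the in-chain acceptance
    window when an objective is supplied)."""
    if chi2_0 <= 0:
        raise ValueError("chi2 at theta0 must be positive")
    K = int(round(np.sqrt(D)))
    T_top = chi2_0 / 30.0
    if T_top <= 1.0:
        raise ValueError("degenerate grid: chi2(theta0)/30 must exceed T_1 = 1")
    if objective is not None and x0 is not None:
        rng = rng or np.random.default_rng(0)
        T_top = _tune_top_temperature(objective, np.asarray(x0, float),
                                      chi2_0, T_top, rng)
        T_top = max(T_top, 1.0 + 1e-6)
    return TemperatureGrid(np.geomspace(1.0, T_top, K))


def grow_grid(grid: TemperatureGrid, mean_log_rho: np.ndarray) -> TemperatureGrid:
    """Insert ``R = floor(sqrt(Q/ln 0.4))`` evenly spaced temperatures in
    every neighbor gap whose mean log swap acceptance Q is below ln(0.4)."""
    T = grid.temperatures
    if len(mean_log_rho) != len(T) - 1:
        raise ValueError("need one mean log acceptance per neighbor pair")
    out = [T[0]]
    ln_target = np.log(SWAP_TARGET)
    for i in range(len(T) - 1):
        Q = mean_log_rho[i]
        ratio = Q / ln_target          # ≥ 0 (both negative)
        R = int(np.floor(np.sqrt(ratio))) if ratio > 0 else 0
        if Q <= ln_target and R > 0:
            inner = np.linspace(T[i], T[i + 1], R + 2)[1:-1]
            out.extend(inner.tolist())
        out.append(T[i + 1])
    return TemperatureGrid(np.array(out))


def shift_temperatures(grid: TemperatureGrid, n_up: np.ndarray,
                       n_down: np.ndarray) -> TemperatureGrid:
    """Move interior temperatures so the flow fraction
    ``f(T_i) = n_up/(n_up + n_down)`` becomes linear in the ladder index.

    f is monotone (isotonic) regressed to be decreasing in T before the
    inverse ``g`` is evaluated at the equispaced targets 1 - (i-1)/(K-1);
    the endpoints stay fixed."""
    T = grid.temperatures
    K = len(T)
    if K <= 2:
        return TemperatureGrid(T.copy())
    tot = np.asarray(n_up, float) + np.asarray(n_down, float)
    f = np.where(tot > 0, np.asarray(n_up, float) / np.maximum(tot, 1), 0.5)
    f = _monotone_decreasing(f)
    f[0], f[-1] = 1.0, 0.0
    # strictly decreasing for a well-defined inverse
    for i in range(1, K):
        f[i] = min(f[i], f[i - 1] - 1e-9)
    targets = 1.0 - np.arange(K, dtype=float) / (K - 1)
    # invert by linear interpolation of T as a function of f (f decreasing)
    T_new = np.interp(targets[::-1], f[::-1], T[::-1])[::-1]
    T_new[0], T_new[-1] = T[0], T[-1]
    for i in range(1, K):  # enforce strict increase without moving endpoints
        if T_new[i] <= T_new[i - 1]:
            T_new[i] = np.nextafter(T_new[i - 1], np.inf)
    return TemperatureGrid(T_new)


def _monotone_decreasing(y: np.ndarray) -> np.ndarray:
    """Pool-adjacent-violators isotonic fit, decreasing."""
    y = -np.asarray(y, dtype=float)
    n = len(y)
    vals = y.copy()
    w = np.ones(n)
    blocks = [[i] for i in range(n)]
    merged = True
    while merged:
        merged = False
        i = 0
        while i < len(blocks) - 1:
            a = sum(vals[j] for j in blocks[i]) / len(blocks[i])
            b = sum(vals[j] for j in blocks[i + 1]) / len(blocks[i + 1])
            if a > b:
                blocks[i] = blocks[i] + blocks[i + 1]
                del blocks[i + 1]
                merged = True
            else:
                i += 1
    out = np.empty(n)
    for blk in blocks:
        m = sum(vals[j] for j in blk) / len(blk)
        for j in blk:
            out[j] = m
    return -out


@dataclass
class PTResult:
    best_x: np.ndarray
    best_chi2: float
    trace: np.ndarray                # best-so-far χ² at T_1 per update
    grid: TemperatureGrid
    seed: int
    swap_acceptance: np.ndarray      # empirical rate per neighbor pair


def run_parallel_tempering(objective: Callable[[np.ndarray], float],
                           x0: np.ndarray, updates: int, seed: int = 0,
                           dim: int | None = None,
                           grid: TemperatureGrid | None = None,
                           grow_rounds: int = GRID_ROUNDS,
                           shift_rounds: int = GRID_ROUNDS,
                           grow_sweeps: int = GROW_SWEEPS,
                           flow_sweeps: int = FLOW_SWEEPS) -> PTResult:
    """Full tempering protocol: grid initialization/tuning, three grow
    rounds, three flow-shift rounds, then the main update loop of
    alternating in-chain sweeps and odd/even neighbor swap sweeps.
    Returns the target-replica (T_1) best Θ and its χ² trace."""
    x0 = np.asarray(x0, dtype=float)
    dim = dim if dim is not None else len(x0)
    rng = np.random.default_rng(seed)
    chi2_0 = float(objective(x0))
    if grid is None:
        grid = init_grid(chi2_0, dim, objective=objective, x0=x0, rng=rng)

    def make_replicas(g: TemperatureGrid):
        reps = [Replica(x=x0.copy(), chi2=chi2_0, temp_index=i,
                        drift=+1 if i == 0 else (-1 if i == g.K - 1 else 0))
                for i in range(g.K)]
        chains = [_Chain(dim) for _ in range(g.K)]
        return reps, chains

    reps, chains = make_replicas(grid)

    def pt_sweep(g, reps, chains, log_acc=None, flow=None, adapt=False):
        for i, rep in enumerate(reps):
            chains[i].sweep(rep, objective, g.temperatures[i], rng, adapt=adapt)
        for parity in (0, 1):
            for i in range(parity, g.K - 1, 2):
                T_i, T_j = g.temperatures[i], g.temperatures[i + 1]
                rho = swap_probability(reps[i].chi2, reps[i + 1].chi2, T_i, T_j)
                if log_acc is not None:
                    log_acc[i].append(np.log(max(rho, 1e-300)))
                if rng.uniform() < rho:
                    swap_i = reps[i]
                    reps[i] = reps[i + 1]
                    reps[i + 1] = swap_i
                    reps[i].temp_index, reps[i + 1].temp_index = i, i + 1
        reps[0].drift = +1
        reps[-1].drift = -1
        if flow is not None:
            for i, rep in enumerate(reps):
                if rep.drift > 0:
                    flow[0][i] += 1
                elif rep.drift < 0:
                    flow[1][i] += 1

    # stage 2: grow the grid toward the 0.4 swap target
    for _ in range(grow_rounds):
        log_acc = [[] for _ in range(grid.K - 1)]
        for _ in range(grow_sweeps):
            pt_sweep(grid, reps, chains, log_acc=log_acc, adapt=True)
        mean_log = np.array([np.mean(a) if a else 0.0 for a in log_acc])
        new_grid = grow_grid(grid, mean_log)
        if new_grid.K == grid.K:
            break
        grid = new_grid
        reps, chains = make_replicas(grid)

    # stage 3: shift interior temperatures with flow statistics
    for _ in range(shift_rounds):
        flow = (np.zeros(grid.K), np.zeros(grid.K))
        for _ in range(flow_sweeps):
            pt_sweep(grid, reps, chains, flow=flow, adapt=True)
        grid = shift_temperatures(grid, flow[0], flow[1])

    # main accumulation of the target replica
    best_x = reps[0].x.copy()
    best_chi2 = reps[0].chi2
    trace = np.empty(updates)
    n_swaps = np.zeros(grid.K - 1)
    n_props = np.zeros(grid.K - 1)

    for u in range(updates):
        for i, rep in enumerate(reps):
            chains[i].sweep(rep, objective, grid.temperatures[i], rng)
        for parity in (0, 1):
            for i in range(parity, grid.K - 1, 2):
                n_props[i] += 1
                if swap_attempt(reps[i], reps[i + 1], grid, rng):
                    n_swaps[i] += 1
        reps[0].drift = +1
        reps[-1].drift = -1
        if reps[0].chi2 < best_chi2:
            best_chi2 = reps[0].chi2
            best_x = reps[0].x.copy()
        trace[u] = best_chi2

    swap_rate = n_swaps / np.maximum(n_props, 1)
    if updates >= 50 and np.any(swap_rate < 1e-3):
        warnings.warn("temperature(s) nearly isolated: swap acceptance "
                      f"below 0.1% at pair(s) {np.where(swap_rate < 1e-3)[0]}",
                      RuntimeWarning, stacklevel=2)
    return PTResult(best_x=best_x, best_chi2=float(best_chi2), trace=trace,
                    grid=grid, seed=seed, swap_acceptance=swap_rate)
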