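"""Exact Gillespie direct-method simulation with a light switch.

At each step the reaction propensities :math:`a_j(x)` and their sum
:math:`a_0` are evaluated, a waiting time is drawn from an exponential with
mean :math:`1/a_0`, the next reaction is drawn with probability
:math:`a_j/a_0`, and state and time are updated.  The exogenous square-wave
light signal makes the propensities time-dependent; waiting times that would
cross a light boundary are truncated there and redrawn under the new
propensities, which keeps the method exact for piecewise-constant driving.

Each trajectory owns an independent, reproducible random stream derived from
``(seed, trajectory index)``, so batches are order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .network import ReactionNetwork

__all__ = [
    "CellTrajectory",
    "GridSeries",
    "gillespie_direct",
    "sample_on_grid",
    "simulate_batch",
    "simulate_grid_batch",
    "uniform_grid",
]

#: Default observed read-out: the mCherry/CCG recorder protein.
DEFAULT_READOUT = "g_p"


@dataclass
class CellTrajectory:
    """Event-level history of one cell: the state after every reaction."""

    event_times: np.ndarray   # (n_events + 1,), starts at 0
    states: np.ndarray        # (n_events + 1, n_species)
    species_names: tuple
    rng_seed: int
    t_end: float

    def state_at(self, t: float) -> np.ndarray:
        """State after the last event at or before ``t``."""
        i = int(np.searchsorted(self.event_times, t, side="right")) - 1
        return self.states[max(i, 0)]


@dataclass
class GridSeries:
    """A species count sampled on the uniform observation grid
    ``t_j = (j-1) T/L``, j = 1..L (left-continuous piecewise-constant)."""

    t: np.ndarray
    values: np.ndarray
    species: str

    def __len__(self) -> int:
        return len(self.t)

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0]) if len(self.t) > 1 else 0.0


def uniform_grid(L: int, T: float) -> np.ndarray:
    """The observation grid t_j = (j-1)·T/L, j = 1..L."""
    j = np.arange(1, L + 1, dtype=float)
    return (j - 1.0) * T / L


def _kernel_args(network: ReactionNetwork, t_end: float):
    light = network.light
    if light is not None:
        sw_t = light.switch_times(t_end)
        sw_s = np.array([light.s(t) for t in sw_t], dtype=np.int64)
        s0 = np.int64(light.s(0.0))
    else:
        sw_t = np.empty(0, dtype=float)
        sw_s = np.empty(0, dtype=np.int64)
        s0 = np.int64(0)
    return sw_t, sw_s, s0


def _dependency_table(network: ReactionNetwork,
                      order: np.ndarray) -> np.ndarray:
    nr = network.n_reactions
    inv = np.empty(nr, dtype=np.int64)
    inv[order] = np.arange(nr)
    changed = []
    for r in network.reactions:
        changed.append(set(network.index[s] for s in r.net_change()))
    members = []
    for j in range(nr):
        m = set(int(i) for i in network.prop_idx[j] if i >= 0)
        members.append(m)
    deps = []
    for jp in range(nr):
        j = order[jp]
        deps.append(sorted(int(inv[d]) for d in range(nr)
                           if members[d] & changed[j]))
    width = max(1, max(len(d) for d in deps))
    table = np.full((nr, width + 1), -1, dtype=np.int64)
    for jp, d in enumerate(deps):
        table[jp, : len(d)] = d
    return table


def _hot_order(network: ReactionNetwork) -> np.ndarray:
    """Reaction permutation, most active channels first, so the direct
    method's linear selection scan terminates early.  Ranked by propensity
    at the deterministically rounded initial state (dark); deterministic
    given the network, so seeded runs stay reproducible."""
    x0 = network.initial_state(gene_init="round").astype(float)
    a = network.rates.copy()
    for j in range(network.n_reactions):
        if network.uses_light[j]:
            a[j] = 0.0
            continue
        for k in range(network.prop_idx.shape[1]):
            idx = network.prop_idx[j, k]
            if idx < 0:
                break
            a[j] *= max(x0[idx] - network.prop_off[j, k], 0.0)
    return np.argsort(-a, kind="stable").astype(np.int64)


def _prop_tables(network: ReactionNetwork, order: np.ndarray):
    """Propensity index/offset tables, permuted and trimmed to the widest
    used order."""
    used = (network.prop_idx >= 0).sum(axis=1)
    w = max(int(used.max()), 1)
    return (np.ascontiguousarray(network.prop_idx[order, :w]),
            np.ascontiguousarray(network.prop_off[order, :w]))


def _stoich_pairs(network: ReactionNetwork):
    nr = network.n_reactions
    st_sp = np.full((nr, 2), -1, dtype=np.int64)
    st_dl = np.zeros((nr, 2), dtype=np.int64)
    for j, r in enumerate(network.reactions):
        items = list(r.net_change().items())
        if len(items) > 2:
            raise ValueError(f"reaction {r.label}: more than 2 species change")
        for k, (s, d) in enumerate(items):
            st_sp[j, k] = network.index[s]
            st_dl[j, k] = d
    return st_sp, st_dl


def _traj_seed(seed: int, index: int) -> int:
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, int(index)])
    return int(ss.generate_state(1, dtype=np.uint64)[0])


def gillespie_direct(network: ReactionNetwork, t_end: float, seed: int,
                     x0: np.ndarray | None = None,
                     gene_init: str = "round",
                     max_events: int = 50_000_000) -> CellTrajectory:
    """Simulate one exact trajectory, returning the full event history.

    A frozen state (total propensity 0 with no further light switches) is
    valid: the trajectory simply stays constant until ``t_end``.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if x0 is None:
        rng = np.random.default_rng(_traj_seed(seed, 0))
        x0 = network.initial_state(rng=rng, gene_init=gene_init)
    x0 = np.asarray(x0, dtype=np.int64)
    if np.any(x0 < 0):
        raise ValueError("initial state must be nonnegative")
    sw_t, sw_s, s0 = _kernel_args(network, t_end)
    order = _hot_order(network)
    dep = _dependency_table(network, order)
    st_sp, st_dl = _stoich_pairs(network)
    st_sp, st_dl = st_sp[order], st_dl[order]
    prop_idx, prop_off = _prop_tables(network, order)
    times, states, n_ev, status = _kernels.ssa_events(
        network.rates[order], network.uses_light[order], prop_idx, prop_off,
        st_sp, st_dl, dep, x0, sw_t, sw_s, s0, float(t_end),
        np.uint64(_traj_seed(seed, 1)), int(max_events))
    if status == _kernels.MAX_EVENTS:
        raise RuntimeError(
            f"event budget exceeded ({max_events}); state counts may be "
            "diverging or the horizon is too long for an event-level record")
    return CellTrajectory(
        event_times=times, states=states,
        species_names=tuple(s.name for s in network.species),
        rng_seed=int(seed), t_end=float(t_end))


def sample_on_grid(traj: CellTrajectory, L: int, T: float,
                   species: str = DEFAULT_READOUT) -> GridSeries:
    """Sample the event history on the uniform grid (left-continuous)."""
    if T > traj.t_end + 1e-9:
        raise ValueError("grid horizon exceeds trajectory duration")
    if species not in traj.species_names:
        raise KeyError(f"unknown species {species!r}")
    si = traj.species_names.index(species)
    t = uniform_grid(L, T)
    idx = np.searchsorted(traj.event_times, t, side="right") - 1
    idx = np.maximum(idx, 0)
    return GridSeries(t=t, values=traj.states[idx, si].astype(float),
                      species=species)


def simulate_grid_batch(network: ReactionNetwork, n_traj: int, L: int, T: float,
                        seed: int, gene_init: str = "bernoulli",
                        max_events: int = 2_000_000_000,
                        drop_before: float = 0.0) -> np.ndarray:
    """Simulate ``n_traj`` independent trajectories recorded directly on the
    uniform grid; returns an array of shape ``(n_traj, L, n_species)``.

    ``drop_before`` shifts the recording grid: the simulation starts at time
    0 but the grid covers ``[drop_before, drop_before + T)`` (used for the
    synchronization pre-exposure, after which observation time is reset).
    """
    if n_traj < 1:
        raise ValueError("n_traj must be >= 1")
    t_grid = uniform_grid(L, T) + drop_before
    t_end = float(t_grid[-1]) + 1e-9
    sw_t, sw_s, s0 = _kernel_args(network, t_end)
    order = _hot_order(network)
    dep = _dependency_table(network, order)
    st_sp, st_dl = _stoich_pairs(network)
    st_sp, st_dl = st_sp[order], st_dl[order]
    prop_idx, prop_off = _prop_tables(network, order)
    rates_o = network.rates[order]
    light_o = network.uses_light[order]
    out = np.empty((n_traj, L, network.n_species), dtype=np.int64)
    for i in range(n_traj):
        rng = np.random.default_rng(_traj_seed(seed, 2 * i))
        x0 = network.initial_state(rng=rng, gene_init=gene_init)
        grid, _, status = _kernels.ssa_grid(
            rates_o, light_o, prop_idx, prop_off, st_sp, st_dl,
            dep, x0, sw_t, sw_s, s0, t_grid,
            np.uint64(_traj_seed(seed, 2 * i + 1)), int(max_events))
        if status == _kernels.MAX_EVENTS:
            raise RuntimeError(f"trajectory {i}: event budget exceeded")
        out[i] = grid
    return out


def simulate_batch(network: ReactionNetwork, n_traj: int, L: int, T: float,
                   seed: int, species: str = DEFAULT_READOUT,
                   gene_init: str = "bernoulli") -> list:
    """Batch of grid-sampled read-out series (one :class:`GridSeries` per
    cell), reproducible from ``(seed, index)`` with disjoint streams."""
    si = network.species_index(species)
    grid = simulate_grid_batch(network, n_traj, L, T, seed, gene_init=gene_init)
    t = uniform_grid(L, T)
    return [GridSeries(t=t, values=grid[i, :, si].astype(float), species=species)
            for i in range(n_traj)]
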