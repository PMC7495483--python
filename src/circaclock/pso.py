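"""Particle-swarm ensemble equilibration on the unit cube.

Two swarm algorithms drive the χ² objective over the unit-cube image of Θ:

* **DMS-PSO-CLS** — dynamic multi-swarm PSO with a cooperative learning
  strategy: MM swarms of NN = 4 particles move under local-best attraction
  during exploration; every generation the two worst particles per swarm are
  culled and recombined dimension-by-dimension from randomly drawn pairs of
  the population's personal bests (the better of each pair donates); every
  RR = 5 generations particles are randomly regrouped into new swarms.
* **PSO-DLS** — PSO with a dynamic (admixture) learning strategy: with
  probability ``p = t/iter`` (growing linearly over the exploration phase) a
  particle is attracted to the mean of all swarm local bests instead of its
  own swarm's; no culling or regrouping.

The first 90% of generations explore (inertia decays linearly 0.9 → 0.4),
the final 10% exploit with attraction to the global best and inertia fixed
at 0.2.  Velocities are clamped to ±0.2 per dimension; positions are clamped
to [0, 1] with the violating velocity component zeroed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.stats import qmc, ranksums

__all__ = ["PSOSettings", "PSOResult", "run_pso", "wilcoxon_compare"]

C1 = 1.49445
C2 = 1.49445
V_MAX = 0.2
W1, W2, W3 = 0.9, 0.4, 0.2
RR = 5
EXPLORE_FRACTION = 0.9


@dataclass
class PSOSettings:
    algorithm: str = "pso-dls"        # "dms-pso-cls" or "pso-dls"
    n_swarms: int = 10                # MM
    swarm_size: int = 4               # NN
    generations: int = 600
    init: str = "random"              # "random" or "sobol"
    dim: int = 35

    def __post_init__(self):
        if self.algorithm not in ("dms-pso-cls", "pso-dls"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.init not in ("random", "sobol"):
            raise ValueError(f"unknown init {self.init!r}")

    @property
    def n_particles(self) -> int:
        return self.n_swarms * self.swarm_size

    @property
    def explore_generations(self) -> int:
        """iter: the exploration-phase length (90% of the total)."""
        return int(round(EXPLORE_FRACTION * self.generations))


@dataclass
class PSOResult:
    best_x: np.ndarray
    best_value: float
    trace: np.ndarray           # per-generation best-so-far objective
    settings: PSOSettings
    seed: int
    evaluations: int


class _Swarms:
    """Particle bookkeeping: positions, velocities, personal/local/global
    bests.  Particles keep their pbest history across regroupings."""

    def __init__(self, settings: PSOSettings, objective, rng: np.random.Generator):
        self.s = settings
        n, d = settings.n_particles, settings.dim
        if settings.init == "sobol":
            eng = qmc.Sobol(d=d, scramble=True,
                            seed=int(rng.integers(2 ** 31)))
            self.x = eng.random(n)
        else:
            self.x = rng.uniform(size=(n, d))
        self.v = rng.uniform(-V_MAX, V_MAX, size=(n, d))
        self.value = np.array([objective(xi) for xi in self.x], dtype=float)
        self.evaluations = n
        self.pbest_x = self.x.copy()
        self.pbest_v = self.value.copy()
        self.group = np.repeat(np.arange(settings.n_swarms), settings.swarm_size)

    # -- bests -------------------------------------------------------------
    @property
    def gbest_index(self) -> int:
        return int(np.argmin(self.pbest_v))

    def lbest(self, m: int):
        idx = np.where(self.group == m)[0]
        j = idx[np.argmin(self.pbest_v[idx])]
        return self.pbest_x[j]

    def lbest_matrix(self) -> np.ndarray:
        return np.vstack([self.lbest(m) for m in range(self.s.n_swarms)])

    def evaluate_and_update(self, objective, indices=None):
        idx = range(len(self.x)) if indices is None else indices
        for i in idx:
            val = objective(self.x[i])
            self.evaluations += 1
            self.value[i] = val
            if val < self.pbest_v[i]:
                self.pbest_v[i] = val
                self.pbest_x[i] = self.x[i].copy()

    # -- moves -------------------------------------------------------------
    def _move(self, i: int, attractor: np.ndarray, w: float,
              rng: np.random.Generator):
        d = self.s.dim
        r1 = rng.uniform(size=d)
        r2 = rng.uniform(size=d)
        v = (w * self.v[i]
             + C1 * r1 * (self.pbest_x[i] - self.x[i])
             + C2 * r2 * (attractor - self.x[i]))
        v = np.clip(v, -V_MAX, V_MAX)
        x = self.x[i] + v
        low, high = x < 0.0, x > 1.0
        v[low | high] = 0.0          # zero the violating velocity component
        self.x[i] = np.clip(x, 0.0, 1.0)
        self.v[i] = v

    def step_exploration(self, w: float, rng, mean_lbest_prob: float = 0.0):
        """Eq-(3) moves toward the swarm local best; with probability
        ``mean_lbest_prob`` a particle instead communicates across swarms
        and is attracted to the mean of all local bests (Eq 5)."""
        lb = self.lbest_matrix()
        mean_lb = lb.mean(axis=0)
        for i in range(len(self.x)):
            if mean_lbest_prob > 0.0 and rng.uniform() < mean_lbest_prob:
                self._move(i, mean_lb, w, rng)
            else:
                self._move(i, lb[self.group[i]], w, rng)

    def step_exploitation(self, rng):
        """Eq-(4) moves toward the global best with inertia W3."""
        g = self.pbest_x[self.gbest_index]
        for i in range(len(self.x)):
            self._move(i, g, W3, rng)

    def cull_and_recombine(self, rng):
        """Replace the two worst particles of each swarm dimension-by-
        dimension: for every dimension draw two personal bests from the whole
        population and copy that dimension from the better donor."""
        n, d = self.x.shape
        for m in range(self.s.n_swarms):
            idx = np.where(self.group == m)[0]
            if len(idx) < 2:
                continue
            worst = idx[np.argsort(self.value[idx])[-2:]]
            for i in worst:
                child = np.empty(d)
                for dim in range(d):
                    a, b = rng.choice(n, size=2, replace=False)
                    donor = a if self.pbest_v[a] <= self.pbest_v[b] else b
                    child[dim] = self.pbest_x[donor, dim]
                self.x[i] = child
        # culled particles keep their velocities and pbest histories

    def regroup(self, rng):
        rng.shuffle(self.group)


def run_pso(objective: Callable[[np.ndarray], float],
            settings: PSOSettings | None = None,
            seed: int = 0,
            callback: Callable | None = None) -> PSOResult:
    """Minimize ``objective`` on ``[0, 1]^dim`` with the selected swarm
    algorithm; returns the global-best point, its value, and the
    per-generation best-so-far trace."""
    settings = settings or PSOSettings()
    rng = np.random.default_rng(seed)
    sw = _Swarms(settings, objective, rng)
    trace = np.empty(settings.generations)
    iter_explore = settings.explore_generations
    dms = settings.algorithm == "dms-pso-cls"
    for t in range(settings.generations):
        if t < iter_explore:
            w = W1 - (W1 - W2) * (t / max(iter_explore - 1, 1))
            p_mix = 0.0 if dms else t / iter_explore
            sw.step_exploration(w, rng, mean_lbest_prob=p_mix)
            sw.evaluate_and_update(objective)
            if dms:
                sw.cull_and_recombine(rng)
                sw.evaluate_and_update(objective)
                if (t + 1) % RR == 0:
                    sw.regroup(rng)
        else:
            sw.step_exploitation(rng)
            sw.evaluate_and_update(objective)
        trace[t] = sw.pbest_v[sw.gbest_index]
        if callback is not None:
            callback(t, sw)
    g = sw.gbest_index
    return PSOResult(best_x=sw.pbest_x[g].copy(),
                     best_value=float(sw.pbest_v[g]),
                     trace=trace, settings=settings, seed=seed,
                     evaluations=sw.evaluations)


def wilcoxon_compare(values_a: Sequence[float], values_b: Sequence[float],
                     alpha: float = 0.05) -> dict:
    """Wilcoxon rank-sum comparison of final objective values between two
    algorithm families (report utility)."""
    stat, p = ranksums(list(values_a), list(values_b))
    return {"statistic": float(stat), "p_value": float(p),
            "significant": bool(p < alpha), "alpha": alpha}
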