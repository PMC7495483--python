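"""The stochastic clock reaction network and its rescalings.

The model is a mass-action reaction network over 12 dynamical species — the
frq / wc-1 negative-feedback oscillator with a FRQ-mediated positive loop on
the *wc-1* transcript, plus a clock-controlled recorder gene — driven by an
exogenous square-wave light signal ``s(t)``.  WCC formation proceeds at rate
``C2 + C2*fIL*s(t)`` (the constant WC-2 pool is absorbed into ``C2``).  The
topology ships as a versioned JSON description (``data/clock_network.json``)
so it is data, not code.

Two rescalings are provided:

* :func:`convert_deterministic_units` — concentrations of a macroscopic
  (deterministic) parameter set are scaled box-by-box into molecular counts,
  with rate constants compensated so the mean-field dynamics are unchanged.
* :func:`rescale_ratios` — the RNA/DNA and protein/DNA ratios (proxies for
  cell size) are changed, scaling mRNA and protein counts and compensating
  the rates; this varies the intracellular noise level while leaving the
  deterministic (Langevin drift) dynamics invariant.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np

from .params import (
    COUNT_NAMES,
    GENE_STATE_NAMES,
    MEASURED_RATIOS,
    RatioPair,
    ThetaVector,
)

__all__ = [
    "Species",
    "Reaction",
    "LightProgram",
    "ReactionNetwork",
    "build_clock_network",
    "light_switch",
    "wcc_formation_propensity",
    "rescale_ratios",
    "convert_deterministic_units",
    "load_topology",
]


@dataclass(frozen=True)
class Species:
    name: str
    role: str = "protein"
    box: str = ""
    scale_class: str = "none"  # one of {"rna", "protein", "gene", "none"}


@dataclass(frozen=True)
class Reaction:
    """One mass-action channel.

    The propensity is ``rate * prod_s falling_factorial(x_s, m_s)`` over the
    multiset of reactants and catalysts; catalysts enter the propensity but
    are not changed by the reaction.  ``uses_light`` channels are multiplied
    by the light switch ``s(t)``.
    """

    label: str
    reactants: Mapping[str, int] = field(default_factory=dict)
    products: Mapping[str, int] = field(default_factory=dict)
    catalysts: Mapping[str, int] = field(default_factory=dict)
    rate: float = 0.0
    uses_light: bool = False

    def net_change(self) -> dict:
        net: dict = {}
        for s, m in self.reactants.items():
            net[s] = net.get(s, 0) - m
        for s, m in self.products.items():
            net[s] = net.get(s, 0) + m
        return {s: v for s, v in net.items() if v != 0}


@dataclass(frozen=True)
class LightProgram:
    """Square-wave light switch: alternating half-days of length ``t_LD``.

    Light/dark cycling starts with light at ``t_L0 + sync_hours``; the
    optional ``sync_hours`` window before it is continuously lit (the
    experimental 26 h synchronization exposure).  ``dark_only`` gives the
    free-running D/D protocol (s ≡ 0 outside the sync window).  Intervals are
    half-open: s jumps at boundaries, taking the value of the new interval.
    """

    t_LD: float = 0.0
    t_L0: float = 0.0
    duration: float = 240.0
    dark_only: bool = False
    sync_hours: float = 0.0
    intensity_lux: float = 5300.0  # informational only; absorbed into fIL

    def __post_init__(self):
        if not self.dark_only and self.t_LD <= 0:
            raise ValueError("t_LD must be positive for an L/D program")
        if self.duration <= 0:
            raise ValueError("duration must be positive")

    def s(self, t: float) -> int:
        """The light switch s(t) ∈ {0, 1}; total function of t."""
        if t < 0:
            return 0
        if self.sync_hours > 0 and t < self.sync_hours:
            return 1
        if self.dark_only:
            return 0
        tau = t - self.sync_hours - self.t_L0
        if tau < 0:
            return 0
        return 1 if (int(np.floor(tau / self.t_LD)) % 2 == 0) else 0

    def switch_times(self, t_end: float | None = None) -> np.ndarray:
        """Strictly increasing times in (0, t_end) where s(t) changes value."""
        t_end = self.duration if t_end is None else t_end
        times = []
        if self.sync_hours > 0 and 0 < self.sync_hours:
            times.append(self.sync_hours)
        if not self.dark_only:
            start = self.sync_hours + self.t_L0
            if self.t_L0 > 0:
                times.append(start)
            n = 1
            while start + n * self.t_LD < t_end:
                times.append(start + n * self.t_LD)
                n += 1
        times = sorted({t for t in times if 0 < t < t_end})
        return np.asarray(times, dtype=float)

    @classmethod
    def dark(cls, duration: float = 240.0, sync_hours: float = 0.0) -> "LightProgram":
        return cls(t_LD=1.0, duration=duration, dark_only=True, sync_hours=sync_hours)

    @classmethod
    def ld_day(cls, day_hours: float, duration: float = 240.0,
               sync_hours: float = 0.0) -> "LightProgram":
        """An L/D program with equal light and dark (half-day = day/2)."""
        return cls(t_LD=day_hours / 2.0, duration=duration, sync_hours=sync_hours)


def light_switch(t: float, light: LightProgram) -> int:
    """s(t): 1 during light half-days, 0 during dark; half-open intervals."""
    return light.s(t)


class ReactionNetwork:
    """A bound reaction network: topology + rates (+ optional light program).

    Provides propensity evaluation, the mean-field (Langevin-drift) right-hand
    side, conservation-box bookkeeping, and the packed arrays consumed by the
    stochastic simulator.
    """

    def __init__(self, species: Sequence[Species], reactions: Sequence[Reaction],
                 light: LightProgram | None = None,
                 initial_counts: Mapping[str, float] | None = None):
        names = [s.name for s in species]
        if len(set(names)) != len(names):
            raise ValueError("species names must be unique")
        self.species = list(species)
        self.reactions = list(reactions)
        self.light = light
        self.index = {n: i for i, n in enumerate(names)}
        self.initial_counts = dict(initial_counts or {})
        ns, nr = len(species), len(reactions)
        # stoichiometry and propensity structure (mass action up to order 8;
        # repeated members use falling factorials via the offset table)
        max_order = 8
        self.stoich = np.zeros((ns, nr), dtype=np.int64)
        prop_idx = np.full((nr, max_order), -1, dtype=np.int64)
        prop_off = np.zeros((nr, max_order), dtype=np.int64)
        for j, r in enumerate(self.reactions):
            for s, m in r.net_change().items():
                self.stoich[self.index[s], j] = m
            members = []
            for src in (r.reactants, r.catalysts):
                for s, m in src.items():
                    members.extend([self.index[s]] * m)
            members.sort()
            if len(members) > max_order:
                raise ValueError(
                    f"reaction {r.label}: propensity order > {max_order}")
            for k, idx in enumerate(members):
                prop_idx[j, k] = idx
                prop_off[j, k] = members[:k].count(idx)
        self.prop_idx = prop_idx
        self.prop_off = prop_off
        self.rates = np.array([r.rate for r in self.reactions], dtype=float)
        self.uses_light = np.array([r.uses_light for r in self.reactions], dtype=bool)
        if np.any(self.rates < 0):
            raise ValueError("rates must be nonnegative")

    # -- basic queries -----------------------------------------------------
    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    def species_index(self, name: str) -> int:
        return self.index[name]

    def conservation_boxes(self) -> dict:
        """Gene-state boxes: groups of species whose total count is conserved
        by every reaction (verified against the stoichiometry)."""
        boxes: dict = {}
        for s in self.species:
            if s.scale_class == "gene":
                boxes.setdefault(s.box, []).append(self.index[s.name])
        out = {}
        for box, idxs in boxes.items():
            if np.all(self.stoich[idxs, :].sum(axis=0) == 0):
                out[box] = tuple(idxs)
        return out

    # -- dynamics ----------------------------------------------------------
    def propensities(self, state: np.ndarray, t: float = 0.0) -> np.ndarray:
        state = np.asarray(state, dtype=float)
        if np.any(state < 0):
            raise ValueError("state must be nonnegative")
        s_t = self.light.s(t) if self.light is not None else 0
        a = self.rates.copy()
        for j in range(self.n_reactions):
            if self.uses_light[j]:
                a[j] *= s_t
            for k in range(self.prop_idx.shape[1]):
                idx = self.prop_idx[j, k]
                if idx < 0:
                    break
                a[j] *= max(state[idx] - self.prop_off[j, k], 0.0)
        return a

    def mean_field_rhs(self, t: float, x: np.ndarray) -> np.ndarray:
        """Deterministic drift dx/dt = S a(x, t) with x treated as continuous
        (products of means; the large-count limit of the master equation)."""
        s_t = self.light.s(t) if self.light is not None else 0
        a = self.rates.copy()
        for j in range(self.n_reactions):
            if self.uses_light[j]:
                a[j] *= s_t
            for k in range(self.prop_idx.shape[1]):
                idx = self.prop_idx[j, k]
                if idx < 0:
                    break
                a[j] *= x[idx]
        return self.stoich @ a

    def initial_state(self, rng: np.random.Generator | None = None,
                      gene_init: str = "round") -> np.ndarray:
        """Integer initial state from the (real-valued) initial counts.

        Gene-state occupancies are fractions of a conserved copy total; with
        ``gene_init="bernoulli"`` each box's copies are allocated at random
        with the active fraction as probability (per-cell), with ``"round"``
        they are allocated deterministically by largest fraction.
        """
        x = np.zeros(self.n_species, dtype=np.int64)
        for name, v in self.initial_counts.items():
            x[self.index[name]] = int(round(v))
        boxes = self.conservation_boxes()
        for idxs in boxes.values():
            vals = np.array([self.initial_counts.get(self.species[i].name, 0.0)
                             for i in idxs], dtype=float)
            total = int(round(vals.sum()))
            total = max(total, 1)
            x[list(idxs)] = 0
            if gene_init == "bernoulli":
                if rng is None:
                    raise ValueError("bernoulli gene_init requires an rng")
                p = vals / vals.sum() if vals.sum() > 0 else np.full(len(idxs), 1 / len(idxs))
                draws = rng.choice(len(idxs), size=total, p=p)
                for d in draws:
                    x[idxs[d]] += 1
            else:
                # largest-remainder deterministic allocation
                share = vals / vals.sum() * total if vals.sum() > 0 else np.full(len(idxs), total / len(idxs))
                base = np.floor(share).astype(int)
                rem = total - base.sum()
                order = np.argsort(-(share - base))
                for k in range(rem):
                    base[order[k]] += 1
                x[list(idxs)] = base
        return x


# -- the clock network ----------------------------------------------------

_TOPOLOGY = None


def load_topology() -> dict:
    """The shipped clock topology (species, reactions, light coupling)."""
    global _TOPOLOGY
    if _TOPOLOGY is None:
        path = resources.files("circaclock.data") / "clock_network.json"
        with path.open("r", encoding="utf-8") as fh:
            _TOPOLOGY = json.load(fh)
    return _TOPOLOGY


def _species_from_topology(topo) -> list:
    return [Species(s["name"], s["role"], s["box"],
                    {"rna": "rna", "protein": "protein",
                     "gene-state": "gene"}.get(s["role"], s["scale_class"]))
            for s in topo["species"]]


def build_clock_network(theta: ThetaVector, light: LightProgram) -> ReactionNetwork:
    """Bind Θ to the clock topology under a light program.

    Returns a network with 12 dynamical species and 23 reaction channels
    (22 rate-constant-labelled channels plus the light term ``C2IL`` whose
    rate is the derived product ``C2*fIL``).  The quorum-sensing branch is
    neutral (production rate zero) and therefore absent; WC-2 is constant and
    absorbed into ``C2``.
    """
    topo = load_topology()
    species = _species_from_topology(topo)
    reactions = []
    for r in topo["reactions"]:
        label = r["label"]
        rate = theta["C2"] * theta["fIL"] if label == "C2IL" else theta[label]
        reactions.append(Reaction(
            label=label,
            reactants=dict(r["reactants"]),
            products=dict(r["products"]),
            catalysts=dict(r["catalysts"]),
            rate=rate,
            uses_light=bool(r["uses_light"]),
        ))
    net = ReactionNetwork(species, reactions, light=light,
                          initial_counts=theta.initial_counts)
    net.theta = theta  # type: ignore[attr-defined]
    net.n_free_parameters = len(theta)  # type: ignore[attr-defined]
    return net


def wcc_formation_propensity(state: Mapping[str, float] | np.ndarray,
                             theta: ThetaVector, t: float,
                             light: LightProgram) -> float:
    """Propensity of WCC formation: ``C2*x_WC1*(1 + fIL*s(t))``.

    In the light the dark-formation rate is multiplied by ``1 + fIL``; the
    WC-2 count is constant and absorbed into ``C2``.
    """
    if isinstance(state, Mapping):
        x_wc1 = float(state["u_p"])
    else:
        topo_names = [s["name"] for s in load_topology()["species"]]
        x_wc1 = float(np.asarray(state)[topo_names.index("u_p")])
    if x_wc1 < 0:
        raise ValueError("state must be nonnegative")
    return theta["C2"] * x_wc1 * (1.0 + theta["fIL"] * light.s(t))


# -- rescalings -----------------------------------------------------------

def _species_scale_classes() -> dict:
    topo = load_topology()
    return {s["name"]: s["scale_class"] for s in topo["species"]}


def _rescale_theta(theta: ThetaVector, lam: Mapping[str, float]) -> ThetaVector:
    """Scale species counts by per-species factors ``lam`` and compensate all
    rate constants so the mean-field dynamics are invariant:
    ``k_new = k * lam(affected) / prod(lam(propensity members))``.
    Every reaction must change species of a single common scale factor.
    """
    topo = load_topology()
    new = theta.to_dict()
    for name in COUNT_NAMES:
        new[name] = theta[name] * lam[name]
    for r in topo["reactions"]:
        label = r["label"]
        if label == "C2IL":
            continue  # derived from C2*fIL
        changed = {}
        for s, m in r["products"].items():
            changed[s] = changed.get(s, 0) + m
        for s, m in r["reactants"].items():
            changed[s] = changed.get(s, 0) - m
        changed = {s: v for s, v in changed.items() if v != 0}
        lam_aff = {lam[s] for s in changed}
        if len(lam_aff) > 1:
            raise ValueError(
                f"reaction {label} changes species with mixed scale factors")
        factor = lam_aff.pop() if lam_aff else 1.0
        denom = 1.0
        for src in ("reactants", "catalysts"):
            for s, m in r[src].items():
                denom *= lam[s] ** m
        new[label] = theta[label] * factor / denom
    return ThetaVector(new)


def rescale_ratios(theta: ThetaVector, old: RatioPair, new: RatioPair) -> ThetaVector:
    """Dynamics-preserving rescaling by RNA/DNA and protein/DNA ratio changes.

    mRNA counts scale by ``new.rna_dna/old.rna_dna`` and protein counts by
    ``new.prot_dna/old.prot_dna``; rate constants are compensated box-by-box
    (e.g. a translation rate picks up the protein-to-RNA ratio of ratios,
    decay rates are unchanged) so the deterministic drift is invariant while
    the intracellular noise level changes.
    """
    lam_rna = new.rna_dna / old.rna_dna
    lam_prot = new.prot_dna / old.prot_dna
    classes = _species_scale_classes()
    lam = {s: {"rna": lam_rna, "protein": lam_prot}.get(c, 1.0)
           for s, c in classes.items()}
    return _rescale_theta(theta, lam)


def rescale_noise_multiplier(theta: ThetaVector, multiplier: float,
                             ratios: RatioPair = MEASURED_RATIOS) -> ThetaVector:
    """Rescale both measured ratios by a common multiplier (the resonance
    scan's noise axis: counts scale up, relative noise scales down)."""
    return rescale_ratios(theta, ratios, ratios.scaled(multiplier))


def convert_deterministic_units(det_params: Mapping[str, float],
                                box_scales: Mapping[str, float] | float = 1.0,
                                f_il: float = 2.0) -> ThetaVector:
    """Convert a deterministic (concentration-unit) parameter table to
    molecular-number units.

    The network is divided into boxes; each box's species concentrations are
    multiplied by that box's scale factor and the rate constants are
    compensated so the dynamics are unchanged.  ``box_scales`` may be a single
    number or a per-box mapping.  The deterministic table carries no
    illumination multiplier, so ``fIL`` is set to ``f_il`` (default 2, the
    pre-fit value).
    """
    topo = load_topology()
    missing = [n for n in COUNT_NAMES if n not in det_params]
    missing += [r["label"] for r in topo["reactions"]
                if r["label"] != "C2IL" and r["label"] not in det_params]
    if missing:
        raise ValueError(f"missing parameters: {missing}")
    vals = {n: float(det_params[n]) for n in det_params}
    vals.setdefault("fIL", f_il)
    theta = ThetaVector(vals)
    boxes = {s["name"]: s["box"] for s in topo["species"]}
    if isinstance(box_scales, Mapping):
        lam = {s: float(box_scales.get(b, 1.0)) for s, b in boxes.items()}
    else:
        lam = {s: float(box_scales) for s in boxes}
    for name, v in lam.items():
        if v <= 0:
            raise ValueError(f"box scale for {name} must be positive")
    # gene boxes keep integer copy numbers
    classes = _species_scale_classes()
    for s, c in classes.items():
        if c == "gene":
            lam[s] = 1.0
    return _rescale_theta(theta, lam)


def invert_deterministic_units(theta: ThetaVector,
                               box_scales: Mapping[str, float] | float = 1.0) -> dict:
    """Algebraic inverse of :func:`convert_deterministic_units` (same scales)."""
    topo = load_topology()
    boxes = {s["name"]: s["box"] for s in topo["species"]}
    if isinstance(box_scales, Mapping):
        lam = {s: 1.0 / float(box_scales.get(b, 1.0)) for s, b in boxes.items()}
    else:
        lam = {s: 1.0 / float(box_scales) for s in boxes}
    classes = _species_scale_classes()
    for s, c in classes.items():
        if c == "gene":
            lam[s] = 1.0
    back = _rescale_theta(theta, lam).to_dict()
    return back
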