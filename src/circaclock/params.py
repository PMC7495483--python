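"""Parameter vectors for the single-cell clock network.

The model state of the fitting problem is a 35-dimensional parameter point
:class:`ThetaVector`: 12 initial molecular counts (including the four
gene-state occupancies, which are fractions of a conserved gene copy) and 23
rate parameters (22 mass-action rate constants plus the dimensionless
illumination multiplier ``fIL``).  Optimizers operate on the unit-cube image
of Θ: every positive parameter is mapped log-uniformly over ±3 decades around
a reference value, while gene-state occupancies map linearly onto [0, 1].
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "COUNT_NAMES",
    "RATE_NAMES",
    "THETA_NAMES",
    "GENE_STATE_NAMES",
    "ThetaVector",
    "RatioPair",
    "MEASURED_RATIOS",
    "reference_table",
    "reference_theta",
]

#: The 12 initial molecular counts, in canonical order.
COUNT_NAMES = (
    "u_r0", "u_r1", "u_p", "f_0", "f_1", "f_r",
    "f_p", "w", "g_0", "g_1", "g_r", "g_p",
)

#: The 23 rate parameters (22 rate constants + the illumination multiplier).
RATE_NAMES = (
    "A", "Abar", "S1", "S3", "S4", "D1", "D3", "C1", "L1", "L3", "D4",
    "D6", "D7", "D8", "C2", "P", "Ac", "Bc", "Sc", "Lc", "Dcr", "Dcp",
    "fIL",
)

#: Canonical flattened ordering of the 35-dimensional Θ.
THETA_NAMES = COUNT_NAMES + RATE_NAMES

#: Gene-state occupancies: fractions of a conserved single gene copy, mapped
#: linearly (not log-uniformly) onto the unit cube.
GENE_STATE_NAMES = ("f_0", "f_1", "g_0", "g_1")

_NAME_INDEX = {n: i for i, n in enumerate(THETA_NAMES)}


def _load_reference():
    path = resources.files("circaclock.data") / "reference_parameters.json"
    with path.open("r", encoding="utf-8") as fh:
        return json.load(fh)


_REFERENCE = _load_reference()


def reference_table() -> dict:
    """The full published parameter table (all ensemble columns)."""
    return {k: dict(v) for k, v in _REFERENCE["parameters"].items()}


@dataclass(frozen=True)
class RatioPair:
    """RNA/DNA and protein/DNA ratios — the proxies for "cell size".

    Increasing the ratios amplifies molecular counts and therefore lowers
    relative intracellular noise; the dynamics-preserving rescaling in
    :func:`circaclock.network.rescale_ratios` compensates the rate constants.
    """

    rna_dna: float
    prot_dna: float

    def __post_init__(self):
        if self.rna_dna <= 0 or self.prot_dna <= 0:
            raise ValueError("ratios must be positive")

    def scaled(self, multiplier: float) -> "RatioPair":
        if multiplier <= 0:
            raise ValueError("multiplier must be positive")
        return RatioPair(self.rna_dna * multiplier, self.prot_dna * multiplier)


#: Experimentally measured reference ratios for the mCherry recorder strain.
MEASURED_RATIOS = RatioPair(
    _REFERENCE["measured_ratios"]["rna_dna"],
    _REFERENCE["measured_ratios"]["prot_dna"],
)


class ThetaVector:
    """A named, ordered 35-dimensional parameter point.

    Parameters
    ----------
    values
        Mapping from parameter name to nonnegative value.  All 35 canonical
        names must be present.
    """

    __slots__ = ("_values",)

    def __init__(self, values: Mapping[str, float]):
        missing = [n for n in THETA_NAMES if n not in values]
        if missing:
            raise ValueError(f"missing parameters: {missing}")
        unknown = [n for n in values if n not in _NAME_INDEX]
        if unknown:
            raise ValueError(f"unknown parameters: {unknown}")
        arr = np.array([float(values[n]) for n in THETA_NAMES], dtype=float)
        if np.any(arr < 0) or not np.all(np.isfinite(arr)):
            bad = [THETA_NAMES[i] for i in np.where(~(arr >= 0) | ~np.isfinite(arr))[0]]
            raise ValueError(f"parameters must be finite and nonnegative: {bad}")
        object.__setattr__(self, "_values", arr)

    # -- construction ------------------------------------------------------
    @classmethod
    def from_array(cls, arr: Iterable[float]) -> "ThetaVector":
        arr = np.asarray(list(arr), dtype=float)
        if arr.shape != (len(THETA_NAMES),):
            raise ValueError(f"expected {len(THETA_NAMES)} values, got {arr.shape}")
        return cls(dict(zip(THETA_NAMES, arr)))

    @classmethod
    def from_reference(cls, column: str = "ga_mean") -> "ThetaVector":
        """Build Θ from a column of the published table (default: the
        four-experiment PSO + Metropolis–Hastings ensemble means)."""
        tab = _REFERENCE["parameters"]
        vals = {}
        for n in THETA_NAMES:
            v = tab[n][column]
            if v is None:
                raise ValueError(f"reference column {column!r} has no value for {n}")
            vals[n] = v
        return cls(vals)

    # -- access ------------------------------------------------------------
    def __getitem__(self, name: str) -> float:
        return float(self._values[_NAME_INDEX[name]])

    def as_array(self) -> np.ndarray:
        return self._values.copy()

    def to_dict(self) -> dict:
        return {n: float(v) for n, v in zip(THETA_NAMES, self._values)}

    @property
    def initial_counts(self) -> dict:
        return {n: self[n] for n in COUNT_NAMES}

    @property
    def rates(self) -> dict:
        return {n: self[n] for n in RATE_NAMES}

    def replace(self, **updates: float) -> "ThetaVector":
        d = self.to_dict()
        d.update(updates)
        return ThetaVector(d)

    def __len__(self) -> int:
        return len(THETA_NAMES)

    def __eq__(self, other) -> bool:
        return isinstance(other, ThetaVector) and np.array_equal(
            self._values, other._values
        )

    def __repr__(self) -> str:
        parts = ", ".join(f"{n}={v:.4g}" for n, v in zip(THETA_NAMES, self._values))
        return f"ThetaVector({parts})"

    # -- JSON I/O ----------------------------------------------------------
    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ThetaVector":
        with open(path, "r", encoding="utf-8") as fh:
            return cls(json.load(fh))

    # -- unit-cube parameterization ---------------------------------------
    def to_unit_cube(self, bounds: "ParameterBounds | None" = None) -> np.ndarray:
        bounds = bounds or default_bounds()
        return bounds.to_cube(self)

    @classmethod
    def from_unit_cube(
        cls, x: np.ndarray, bounds: "ParameterBounds | None" = None
    ) -> "ThetaVector":
        bounds = bounds or default_bounds()
        return bounds.from_cube(x)


class ParameterBounds:
    """Box bounds defining the unit-cube image of Θ.

    Positive parameters use log-uniform boxes spanning ``decades`` decades on
    either side of a center value; gene-state occupancies use the linear box
    [0, 1].
    """

    def __init__(self, centers: Mapping[str, float], decades: float = 3.0):
        self.decades = float(decades)
        self._log_lo = np.zeros(len(THETA_NAMES))
        self._log_hi = np.zeros(len(THETA_NAMES))
        self._linear = np.zeros(len(THETA_NAMES), dtype=bool)
        for i, n in enumerate(THETA_NAMES):
            if n in GENE_STATE_NAMES:
                self._linear[i] = True
                continue
            c = float(centers[n])
            if c <= 0:
                raise ValueError(f"log-uniform bound center for {n} must be > 0")
            self._log_lo[i] = math.log10(c) - self.decades
            self._log_hi[i] = math.log10(c) + self.decades

    def to_cube(self, theta: ThetaVector) -> np.ndarray:
        v = theta.as_array()
        x = np.empty_like(v)
        lin = self._linear
        x[lin] = np.clip(v[lin], 0.0, 1.0)
        with np.errstate(divide="ignore"):
            lg = np.log10(np.where(v[~lin] > 0, v[~lin], np.nan))
        x[~lin] = (lg - self._log_lo[~lin]) / (self._log_hi[~lin] - self._log_lo[~lin])
        x[~lin] = np.where(np.isnan(x[~lin]), 0.0, x[~lin])  # zero maps to the floor
        return np.clip(x, 0.0, 1.0)

    def from_cube(self, x: np.ndarray) -> ThetaVector:
        x = np.clip(np.asarray(x, dtype=float), 0.0, 1.0)
        if x.shape != (len(THETA_NAMES),):
            raise ValueError(f"expected shape ({len(THETA_NAMES)},), got {x.shape}")
        v = np.empty_like(x)
        lin = self._linear
        v[lin] = x[lin]
        v[~lin] = 10.0 ** (
            self._log_lo[~lin] + x[~lin] * (self._log_hi[~lin] - self._log_lo[~lin])
        )
        return ThetaVector.from_array(v)


_DEFAULT_BOUNDS = None


def default_bounds() -> ParameterBounds:
    """Default unit-cube bounds: ±3 decades around the molecular-number
    conversion of the macroscopic ensemble (gene states linear on [0, 1]).
    Entries whose conversion is zero or absent fall back to the
    four-experiment ensemble mean as center; boxes are widened where needed
    so the fitted ensemble means always lie inside with half a decade of
    margin (a handful of fitted rates moved > 3 decades from the conversion
    values, and the cube must be able to represent the canonical Θ)."""
    global _DEFAULT_BOUNDS
    if _DEFAULT_BOUNDS is None:
        tab = _REFERENCE["parameters"]
        centers = {}
        for n in THETA_NAMES:
            if n in GENE_STATE_NAMES:
                centers[n] = 0.5  # unused (linear box)
                continue
            c = tab[n]["counts"]
            if c is None or c <= 0:
                c = tab[n]["ga_mean"]
            centers[n] = c
        b = ParameterBounds(centers)
        for i, n in enumerate(THETA_NAMES):
            if n in GENE_STATE_NAMES:
                continue
            ga = tab[n]["ga_mean"]
            if ga is not None and ga > 0:
                b._log_lo[i] = min(b._log_lo[i], math.log10(ga) - 0.5)
                b._log_hi[i] = max(b._log_hi[i], math.log10(ga) + 0.5)
        _DEFAULT_BOUNDS = b
    return _DEFAULT_BOUNDS


def reference_theta() -> ThetaVector:
    """The canonical fitted Θ: the four-experiment ensemble means."""
    return ThetaVector.from_reference("ga_mean")
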