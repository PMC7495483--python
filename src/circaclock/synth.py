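"""Study-shaped synthetic single-cell data.

Generates what the microfluidics experiments produce: per-cell fluorescence
series on the half-hour grid under one of four light regimes (D/D free run
or light/dark days of 6, 12 or 36 h), preceded by a 26 h light
synchronization exposure after which observation time restarts at zero.
The recorder read-out is an exact stochastic trajectory of the clock
network; additive detector noise of variance ``sigma_eps2`` and a
multiplicative reference-normalization step (a per-frame reference channel
with its own small noise, divided out as in Rhodamine-B normalization)
emulate the measurement chain.  Doped-bead control series — constant mean
plus intensity-scaled detector noise — support the ``sigma_eps2`` estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .network import LightProgram, build_clock_network
from .params import ThetaVector
from .ssa import DEFAULT_READOUT, simulate_grid_batch, uniform_grid

__all__ = ["ExperimentDesign", "SyntheticDataset", "REGIMES",
           "generate_cells", "generate_beads", "estimate_sigma_eps2",
           "load_cells_csv"]

#: The four study regimes: name -> day length in hours (None = D/D).
REGIMES = {"D/D": None, "L/D-6h": 6.0, "L/D-12h": 12.0, "L/D-36h": 36.0}

SYNC_HOURS = 26.0
SAMPLE_DT = 0.5


@dataclass(frozen=True)
class ExperimentDesign:
    """One experiment's acquisition protocol."""

    regime: str = "D/D"
    n_cells: int = 1000
    duration: float = 240.0          # observed hours, ≥ 10 days at full scale
    sigma_eps2: float = 4.0          # detector-noise variance (fluorescence²)
    seed: int = 0
    sync_hours: float = SYNC_HOURS
    sample_dt: float = SAMPLE_DT
    ref_jitter_sd: float = 0.01      # reference-channel relative noise

    def __post_init__(self):
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}; "
                             f"expected one of {sorted(REGIMES)}")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if abs(self.duration / self.sample_dt - round(self.duration / self.sample_dt)) > 1e-9:
            raise ValueError("duration must be a multiple of the sampling step")
        if self.sigma_eps2 < 0:
            raise ValueError("sigma_eps2 must be nonnegative")

    @property
    def L(self) -> int:
        return int(round(self.duration / self.sample_dt))

    def light_program(self) -> LightProgram:
        """The light protocol with the synchronization exposure prepended;
        observation time 0 corresponds to the end of the sync window."""
        total = self.sync_hours + self.duration
        day = REGIMES[self.regime]
        if day is None:
            return LightProgram.dark(total, sync_hours=self.sync_hours)
        return LightProgram.ld_day(day, total, sync_hours=self.sync_hours)


@dataclass
class SyntheticDataset:
    cells: pd.DataFrame            # columns: cell_id, t, fluorescence
    beads: pd.DataFrame | None
    theta_true: ThetaVector
    design: ExperimentDesign

    def cell_matrix(self) -> np.ndarray:
        """(n_cells, L) matrix of the corrected fluorescence series."""
        piv = self.cells.pivot(index="cell_id", columns="t",
                               values="fluorescence")
        return piv.sort_index().to_numpy()

    @property
    def t(self) -> np.ndarray:
        return uniform_grid(self.design.L, self.design.duration)


def generate_cells(theta_true: ThetaVector,
                   design: ExperimentDesign,
                   with_beads: bool = True,
                   n_beads: int = 200) -> SyntheticDataset:
    """Simulate the full measurement chain for one experiment.

    Per cell: 26 h of light for phase synchronization, then the regime's
    ``s(t)``; the exact trajectory's recorder count on the half-hour grid;
    additive detector noise; multiplication by a noisy reference channel and
    division by its measured value (the normalization correction downstream
    consumes).
    """
    light = design.light_program()
    net = build_clock_network(theta_true, light)
    batch = simulate_grid_batch(net, design.n_cells, design.L,
                                design.duration, seed=design.seed,
                                drop_before=design.sync_hours)
    si = net.species_index(DEFAULT_READOUT)
    signal = batch[:, :, si].astype(float)
    rng = np.random.default_rng(np.random.SeedSequence([design.seed, 0xC3]))
    t = uniform_grid(design.L, design.duration)
    noisy = signal + rng.normal(0.0, np.sqrt(design.sigma_eps2), signal.shape)
    # Rhodamine-B-style reference normalization: a common per-frame reference
    # with small noise multiplies the acquisition and is divided back out.
    ref = 1.0 + rng.normal(0.0, design.ref_jitter_sd, size=design.L)
    corrected = (noisy * ref[None, :]) / ref[None, :]
    frames = []
    for i in range(design.n_cells):
        frames.append(pd.DataFrame({"cell_id": i, "t": t,
                                    "fluorescence": corrected[i]}))
    cells = pd.concat(frames, ignore_index=True)
    beads = generate_beads(design, n_beads) if with_beads else None
    return SyntheticDataset(cells=cells, beads=beads,
                            theta_true=theta_true, design=design)


def generate_beads(design: ExperimentDesign, n_beads: int = 200,
                   intensity_levels=(0.5, 1.0, 2.0),
                   bead_mean: float = 500.0) -> pd.DataFrame:
    """Doped-bead control series: constant mean proportional to the incident
    intensity, detector noise with variance scaling linearly with intensity
    (shot-noise-like), ``sigma_eps2`` being the variance at unit intensity."""
    if len(intensity_levels) < 2:
        raise ValueError("need at least two intensity levels")
    rng = np.random.default_rng(np.random.SeedSequence([design.seed, 0xBEAD]))
    t = uniform_grid(design.L, design.duration)
    rows = []
    for b in range(n_beads):
        inten = intensity_levels[b % len(intensity_levels)]
        series = bead_mean * inten + rng.normal(
            0.0, np.sqrt(design.sigma_eps2 * inten), size=design.L)
        rows.append(pd.DataFrame({"bead_id": b, "intensity": inten,
                                  "t": t, "fluorescence": series}))
    return pd.concat(rows, ignore_index=True)


def estimate_sigma_eps2(bead_table: pd.DataFrame):
    """Detector-noise variance at unit intensity from bead controls.

    Per-bead sample variances are regressed through the origin on relative
    intensity; the slope estimates ``sigma_eps2`` averaged over beads and
    time points.  Returns ``(estimate, standard_error)``.
    """
    grouped = bead_table.groupby("bead_id")
    if grouped.ngroups < 30:
        raise ValueError("need at least 30 bead series")
    var = grouped["fluorescence"].var(ddof=1).to_numpy()
    inten = grouped["intensity"].first().to_numpy()
    w = inten ** 2
    slope = float(np.sum(inten * var) / np.sum(w))
    resid = var - slope * inten
    se = float(np.sqrt(np.sum((inten * resid) ** 2)) / np.sum(w))
    return slope, se


def load_cells_csv(path) -> pd.DataFrame:
    """Loader for the documented cell-series schema.

    Expects columns ``cell_id, t, fluorescence`` (the layout this package
    writes and the schema assumed for the public single-cell archives; the
    real archives' column naming is not standardized, so adapt upstream)."""
    df = pd.read_csv(path)
    missing = {"cell_id", "t", "fluorescence"} - set(df.columns)
    if missing:
        raise ValueError(f"cells table missing columns: {sorted(missing)}")
    return df
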