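"""Re-entrant pipeline stages with CSV/JSON artifacts.

Each stage reads the documented artifacts of its predecessors from a working
directory and writes its own, so any stage can be re-run from prior outputs:

* ``stage_synth``     — synthetic cells + beads + manifest per regime
* ``stage_spectrum``  — per-regime bias-corrected average periodograms
* ``stage_fit_pso``   — swarm fit of Θ against the spectra
* ``stage_fit_pt``    — parallel-tempering fit
* ``stage_accumulate``— Metropolis–Hastings accumulation + Table-style summary
* ``stage_phase``     — Hilbert-phase band summaries (model vs data)
* ``stage_resonance`` — the noise-multiplier resonance scan

Every stochastic stage records its seed in the artifact it writes.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import phase as phase_mod
from .ensemble import mh_accumulate, pool_and_summarize
from .network import LightProgram, build_clock_network
from .params import ThetaVector, default_bounds, reference_theta
from .pso import PSOSettings, run_pso
from .resonance import FIG_MULTIPLIERS, resonance_scan
from .spectral import (DetrendKernel, SpectrumSet, chi_squared,
                       model_spectrum, spectrum_from_cells)
from .ssa import uniform_grid
from .synth import REGIMES, ExperimentDesign, estimate_sigma_eps2, generate_cells
from .tempering import run_parallel_tempering

__all__ = ["stage_synth", "stage_spectrum", "stage_fit_pso", "stage_fit_pt",
           "stage_accumulate", "stage_phase", "stage_resonance",
           "make_chi2_objective", "load_spectrum_csv", "save_spectrum_csv"]


def _outdir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p


def save_spectrum_csv(spec: SpectrumSet, path):
    df = pd.DataFrame({
        "f_l": spec.f, "period": spec.periods, "Q_avg": spec.Q_avg,
        "Q_bias": spec.Q_bias if spec.Q_bias is not None else 0.0,
        "var_corrected": (spec.var_corrected if spec.var_corrected is not None
                          else spec.var_total),
        "R_avg_re": spec.R_avg.real, "R_avg_im": spec.R_avg.imag,
        "var_total": spec.var_total,
        "used": (spec.used if spec.used is not None
                 else np.ones_like(spec.f, dtype=bool)).astype(int),
    })
    df.to_csv(path, index=False)
    meta = {"K_cells": spec.K_cells, "L_points": spec.L_points,
            "T_dur": spec.T_dur, "sigma_eps2": spec.sigma_eps2}
    Path(str(path) + ".meta.json").write_text(json.dumps(meta))


def load_spectrum_csv(path) -> SpectrumSet:
    df = pd.read_csv(path)
    meta = json.loads(Path(str(path) + ".meta.json").read_text())
    spec = SpectrumSet(
        f=df["f_l"].to_numpy(), Q_avg=df["Q_avg"].to_numpy(),
        R_avg=df["R_avg_re"].to_numpy() + 1j * df["R_avg_im"].to_numpy(),
        var_total=df["var_total"].to_numpy(), K_cells=int(meta["K_cells"]),
        L_points=int(meta["L_points"]), T_dur=float(meta["T_dur"]),
        sigma_eps2=float(meta["sigma_eps2"]))
    spec.Q_bias = df["Q_bias"].to_numpy()
    spec.var_corrected = df["var_corrected"].to_numpy()
    spec.var_detector = spec.var_total - spec.var_corrected
    spec.used = df["used"].to_numpy().astype(bool) if "used" in df else None
    return spec


def stage_synth(outdir, theta: ThetaVector | None = None,
                regimes=("D/D",), n_cells: int = 100, duration: float = 240.0,
                sigma_eps2: float = 4.0, seed: int = 0) -> dict:
    """Generate synthetic cells + beads per regime; write cells_<regime>.csv,
    beads.csv and manifest.json."""
    out = _outdir(outdir)
    theta = theta or reference_theta()
    manifest = {"seed": seed, "theta_true": theta.to_dict(), "regimes": {}}
    for i, regime in enumerate(regimes):
        design = ExperimentDesign(regime=regime, n_cells=n_cells,
                                  duration=duration, sigma_eps2=sigma_eps2,
                                  seed=seed + i)
        ds = generate_cells(theta, design, with_beads=(i == 0))
        tag = regime.replace("/", "").replace("-", "_")
        ds.cells.to_csv(out / f"cells_{tag}.csv", index=False)
        if ds.beads is not None:
            ds.beads.to_csv(out / "beads.csv", index=False)
        manifest["regimes"][regime] = {
            "cells_file": f"cells_{tag}.csv", "L": design.L,
            "duration": duration, "sigma_eps2": sigma_eps2,
            "seed": design.seed}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def stage_spectrum(outdir, window: int | None = None) -> dict:
    """Compute bias-corrected average periodograms from the synth artifacts."""
    out = _outdir(outdir)
    manifest = json.loads((out / "manifest.json").read_text())
    kernel = DetrendKernel(window) if window else DetrendKernel()
    beads_path = out / "beads.csv"
    if beads_path.exists():
        sigma_eps2, sigma_se = estimate_sigma_eps2(pd.read_csv(beads_path))
    else:
        sigma_eps2, sigma_se = 0.0, 0.0
    result = {"sigma_eps2": sigma_eps2, "sigma_eps2_se": sigma_se,
              "window": kernel.window, "spectra": {}}
    for regime, info in manifest["regimes"].items():
        cells = pd.read_csv(out / info["cells_file"])
        mat = cells.pivot(index="cell_id", columns="t",
                          values="fluorescence").to_numpy()
        spec = spectrum_from_cells(list(mat), T=info["duration"],
                                   kernel=kernel, sigma_eps2=sigma_eps2)
        tag = regime.replace("/", "").replace("-", "_")
        save_spectrum_csv(spec, out / f"spectrum_{tag}.csv")
        result["spectra"][regime] = f"spectrum_{tag}.csv"
    (out / "spectra.json").write_text(json.dumps(result, indent=1))
    return result


def make_chi2_objective(data_specs: dict, n_traj: int = 32,
                        free_params=None, base_theta: ThetaVector | None = None,
                        kernel: DetrendKernel | None = None, seed: int = 0,
                        include_model_variance: bool = True):
    """Build the pooled χ² objective on the unit cube from per-regime data
    spectra (the joint likelihood of independent experiments multiplies, so
    the χ² values add).

    ``free_params`` restricts the search to a named subset of Θ (the rest
    pinned at ``base_theta``); the returned callable then takes a vector of
    that dimension.  The objective is stochastic: every invocation simulates
    a fresh batch of model trajectories (seeded from ``seed`` and a call
    counter, so the evaluation sequence is reproducible).  Accumulation runs
    therefore mix over the simulation noise, which is one of the two error
    sources the ensemble standard errors reflect.
    """
    bounds = default_bounds()
    base = base_theta or reference_theta()
    names = list(free_params) if free_params is not None else None
    kernel = kernel or DetrendKernel()

    def theta_from_x(x: np.ndarray) -> ThetaVector:
        if names is None:
            return ThetaVector.from_unit_cube(x, bounds)
        full = base.to_unit_cube(bounds)
        from .params import THETA_NAMES
        for xi, n in zip(x, names):
            full[THETA_NAMES.index(n)] = xi
        return ThetaVector.from_unit_cube(full, bounds)

    counter = [0]

    def objective(x: np.ndarray) -> float:
        theta = theta_from_x(np.asarray(x, float))
        counter[0] += 1
        call_seed = int(np.random.SeedSequence(
            [int(seed) & 0x7FFFFFFF, counter[0]]).generate_state(1)[0]
        ) & 0x7FFFFFFF
        total = 0.0
        for regime, dspec in data_specs.items():
            day = REGIMES[regime]
            T = dspec.T_dur
            light = (LightProgram.dark(T) if day is None
                     else LightProgram.ld_day(day, T))
            net = build_clock_network(theta, light)
            mspec = model_spectrum(net, n_traj, dspec.L_points, T, call_seed,
                                   kernel=kernel)
            chi2, _ = chi_squared(
                mspec, dspec, include_model_variance=include_model_variance)
            total += chi2
        return total

    objective.theta_from_x = theta_from_x
    objective.dim = len(names) if names is not None else len(base)
    return objective


def _load_data_specs(outdir) -> dict:
    out = Path(outdir)
    info = json.loads((out / "spectra.json").read_text())
    return {regime: load_spectrum_csv(out / fname)
            for regime, fname in info["spectra"].items()}


def stage_fit_pso(outdir, algorithm: str = "pso-dls", n_swarms: int = 5,
                  generations: int = 50, init: str = "random",
                  n_traj: int = 16, seed: int = 0, free_params=None) -> dict:
    """Swarm fit against the stored spectra; writes pso_result.json and a
    per-generation trace CSV."""
    out = Path(outdir)
    data_specs = _load_data_specs(out)
    obj = make_chi2_objective(data_specs, n_traj=n_traj,
                              free_params=free_params, seed=seed)
    settings = PSOSettings(algorithm=algorithm, n_swarms=n_swarms,
                           generations=generations, init=init, dim=obj.dim)
    res = run_pso(obj, settings, seed=seed)
    theta_best = obj.theta_from_x(res.best_x)
    pd.DataFrame({"generation": np.arange(len(res.trace)),
                  "best_chi2": res.trace}).to_csv(
        out / "pso_trace.csv", index=False)
    payload = {"algorithm": algorithm, "n_swarms": n_swarms,
               "generations": generations, "init": init, "seed": seed,
               "best_chi2": res.best_value, "evaluations": res.evaluations,
               "theta_best": theta_best.to_dict(),
               "best_x": res.best_x.tolist()}
    (out / "pso_result.json").write_text(json.dumps(payload, indent=1))
    return payload


def stage_fit_pt(outdir, updates: int = 200, n_traj: int = 16, seed: int = 0,
                 free_params=None, start_theta: ThetaVector | None = None) -> dict:
    """Parallel-tempering fit; writes pt_result.json + tempering trace CSV."""
    out = Path(outdir)
    data_specs = _load_data_specs(out)
    obj = make_chi2_objective(data_specs, n_traj=n_traj,
                              free_params=free_params, seed=seed)
    start = start_theta or reference_theta()
    if free_params is None:
        x0 = start.to_unit_cube()
    else:
        from .params import THETA_NAMES
        cube = start.to_unit_cube()
        x0 = np.array([cube[THETA_NAMES.index(n)] for n in free_params])
    res = run_parallel_tempering(obj, x0, updates=updates, seed=seed,
                                 grow_sweeps=25, flow_sweeps=30)
    theta_best = obj.theta_from_x(res.best_x)
    pd.DataFrame({"update": np.arange(len(res.trace)),
                  "best_chi2": res.trace}).to_csv(out / "pt_trace.csv",
                                                  index=False)
    payload = {"updates": updates, "seed": seed, "best_chi2": res.best_chi2,
               "K_temperatures": res.grid.K,
               "temperatures": res.grid.temperatures.tolist(),
               "swap_acceptance": res.swap_acceptance.tolist(),
               "theta_best": theta_best.to_dict(),
               "best_x": res.best_x.tolist()}
    (out / "pt_result.json").write_text(json.dumps(payload, indent=1))
    return payload


def stage_accumulate(outdir, updates: int = 1400, burn: int = 350,
                     thin: int = 35, n_chains: int = 2, n_traj: int = 16,
                     seed: int = 0, free_params=None) -> dict:
    """Metropolis–Hastings accumulation from the stored optimizer solution;
    writes ensemble.csv (one row per retained model) and summary CSV."""
    out = Path(outdir)
    data_specs = _load_data_specs(out)
    obj = make_chi2_objective(data_specs, n_traj=n_traj,
                              free_params=free_params, seed=seed)
    start = json.loads((out / "pso_result.json").read_text())["best_x"]
    chains = [mh_accumulate(obj, np.asarray(start), updates=updates,
                            burn=burn, thin=thin, seed=seed + c)
              for c in range(n_chains)]
    ens = pool_and_summarize(chains) if obj.dim == 35 else \
        pool_and_summarize(chains)
    df = pd.DataFrame(ens.theta, columns=list(ens.names))
    df["chi2"] = ens.chi2
    df.to_csv(out / "ensemble.csv", index=False)
    ens.summary_frame().to_csv(out / "ensemble_summary.csv", index=False)
    payload = {"n_models": ens.n_models, "chains": len(chains),
               "updates": updates, "burn": burn, "thin": thin, "seed": seed}
    (out / "ensemble.json").write_text(json.dumps(payload, indent=1))
    return payload


def stage_phase(outdir, n_traj: int = 64, seed: int = 0,
                theta: ThetaVector | None = None) -> dict:
    """Hilbert-phase band summary of model vs data; writes phase_<regime>.csv
    with (t, p5, mean, p95) for both."""
    out = Path(outdir)
    manifest = json.loads((out / "manifest.json").read_text())
    kernel = DetrendKernel()
    theta = theta or reference_theta()
    written = {}
    for regime, info in manifest["regimes"].items():
        cells = pd.read_csv(out / info["cells_file"])
        mat = cells.pivot(index="cell_id", columns="t",
                          values="fluorescence").to_numpy()
        T = info["duration"]
        L = info["L"]
        data_phase = [phase_mod.hilbert_phase(kernel.apply(row),
                                              t=uniform_grid(L, T))
                      for row in mat]
        day = REGIMES[regime]
        light = (LightProgram.dark(T) if day is None
                 else LightProgram.ld_day(day, T))
        net = build_clock_network(theta, light)
        from .ssa import simulate_grid_batch
        batch = simulate_grid_batch(net, n_traj, L, T, seed)
        si = net.species_index("g_p")
        model_phase = [phase_mod.hilbert_phase(
            kernel.apply(batch[i, :, si].astype(float)), t=uniform_grid(L, T))
            for i in range(n_traj)]
        db = phase_mod.phase_bands(data_phase)
        mb = phase_mod.phase_bands(model_phase)
        tag = regime.replace("/", "").replace("-", "_")
        pd.DataFrame({"t": db.t, "data_p5": db.p5, "data_mean": db.mean,
                      "data_p95": db.p95, "model_p5": mb.p5,
                      "model_mean": mb.mean, "model_p95": mb.p95}).to_csv(
            out / f"phase_{tag}.csv", index=False)
        exit_t = phase_mod.band_exit_time(mb, db.mean, db.t)
        K_data, K_se = phase_mod.kuramoto_K(data_phase)
        written[regime] = {"file": f"phase_{tag}.csv",
                           "band_exit_time": exit_t,
                           "kuramoto_K": K_data, "kuramoto_se": K_se}
    (out / "phase.json").write_text(json.dumps(written, indent=1))
    return written


def stage_resonance(outdir, multipliers=FIG_MULTIPLIERS,
                    experiments=("D/D",), n_traj: int = 64, seed: int = 0,
                    theta: ThetaVector | None = None,
                    T: float = 240.0, L: int = 480) -> pd.DataFrame:
    """Resonance scan at the stored/reference Θ; writes resonance.csv."""
    out = _outdir(outdir)
    theta = theta or reference_theta()
    scan = resonance_scan(theta, multipliers=multipliers,
                          experiments=experiments, n_traj=n_traj,
                          L=L, T=T, seed=seed)
    scan.insert(0, "seed", seed)
    scan.to_csv(out / "resonance.csv", index=False)
    return scan
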