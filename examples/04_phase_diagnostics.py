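"""Hilbert-phase goodness-of-fit diagnostics and synchrony.

Phase is functionally independent of the periodogram used for fitting, so
it serves as a held-out check: percentile bands of cumulative cycle counts
across model cells are compared between light regimes, and the Kuramoto
order parameter quantifies light-driven synchronization.
"""

import numpy as np

import circaclock as cc
from circaclock.phase import hilbert_phase, kuramoto_K, phase_bands
from circaclock.spectral import DetrendKernel
from circaclock.ssa import simulate_grid_batch, uniform_grid

theta = cc.reference_theta()
kern = DetrendKernel()
t = uniform_grid(288, 144.0)

for name, light in [("D/D", cc.LightProgram.dark(144.0)),
                    ("L/D 12 h day", cc.LightProgram.ld_day(12.0, 144.0))]:
    net = cc.build_clock_network(theta, light)
    batch = simulate_grid_batch(net, 40, 288, 144.0, seed=5)
    si = net.species_index("g_p")
    cells = [hilbert_phase(kern.apply(batch[i, :, si].astype(float)), t=t)
             for i in range(40)]
    band = phase_bands(cells)
    K, K_se = kuramoto_K(cells)
    slope = np.polyfit(band.t, band.mean, 1)[0]
    print(f"{name:14s}: mean phase slope {slope:.4f} cycles/h "
          f"(~{1/slope if slope > 0 else float('inf'):.0f} h per cycle), "
          f"band width at end {band.p95[-1]-band.p5[-1]:.2f} cycles, "
          f"Kuramoto K = {K:.3f} ± {K_se:.3f}")

# A larger Kuramoto K under the 12 h day than in constant darkness reflects
# light-driven phase synchronization across cells; the widening percentile
# band shows stochastic intracellular noise diffusing individual phases.
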