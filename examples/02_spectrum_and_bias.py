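"""Average periodograms with detector-noise bias correction.

Generates a synthetic dark-grown (D/D) experiment — exact trajectories plus
additive detector noise and bead controls — estimates the detector variance
from the beads, and prints the bias-corrected average periodogram summary.
"""

import numpy as np

import circaclock as cc
from circaclock.spectral import spectrum_from_cells
from circaclock.synth import ExperimentDesign, estimate_sigma_eps2, generate_cells

design = ExperimentDesign(regime="D/D", n_cells=64, duration=96.0,
                          sigma_eps2=4.0, seed=1)
ds = generate_cells(cc.reference_theta(), design, n_beads=200)

sigma2, sigma2_se = estimate_sigma_eps2(ds.beads)
print(f"detector variance from beads: {sigma2:.2f} ± {sigma2_se:.2f} "
      f"(injected {design.sigma_eps2})")

spec = spectrum_from_cells(list(ds.cell_matrix()), T=design.duration,
                           sigma_eps2=sigma2)
print(f"{spec.K_cells} cells, {spec.n_frequencies} positive frequencies, "
      f"{spec.n_used} carry usable biological signal after bias correction")
print(f"spectral peak at {spec.peak_period():.1f} h "
      f"(power {spec.corrected_Q().max():.0f})")
print(f"mean bias removed per bin: {np.mean(spec.Q_bias):.2f} "
      f"(~sigma_eps2, the white detector floor)")

# Frequencies whose variance is fully explained by detector noise are
# excluded from fitting — this is why different acquisition protocols
# contribute different frequency counts to the pooled likelihood.
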