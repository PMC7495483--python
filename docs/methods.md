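# Methods

## The model

Each cell is a continuous-time Markov jump process over integer molecule
counts of 12 species: the *wc-1* primary transcript `u_r0`, its
FRQ-stabilized form `u_r1`, WC-1 protein `u_p`, the *frq* gene in inactive
(`f_0`) or active (`f_1`) state, *frq* mRNA `f_r`, FRQ protein `f_p`, the
White Collar Complex `w`, and the clock-controlled recorder gene's state
(`g_0`/`g_1`), mRNA `g_r` and protein `g_p` (the observed mCherry signal).
All 23 channels are mass action; reaction labels double as rate-constant
names. WC-2 is constitutive and its constant count is absorbed into the
WCC-formation rate `C2`; light adds a parallel formation channel of rate
`C2·fIL·s(t)`, where `s(t)` is a square wave with half-day `t_LD` (1 during
light half-days, half-open intervals, cycling from `t_L0`), so light
multiplies dark-formation by `(1 + fIL)`. The quorum-sensing branch is
neutral (production rate zero) and therefore absent. Gene states are
conserved pairs (one copy per gene); every other species has a production
and a decay channel.

### The topology is a reconstruction

The reaction list ships as versioned data
(`src/circaclock/data/clock_network.json`), because the published network is
given as a wiring diagram that the analysis chain may need to revise. Our
reconstruction is fixed by (i) the rate-constant roster and its label gaps
(the missing S2/L2/D2/D5 are the folded-away *wc-2* arm), (ii) the stated
roles of A/Ābar (*frq* activation/deactivation), P (WCC deactivation by
FRQ), C1 (FRQ-catalysed stabilization of the *wc-1* transcript) and the
L3/D6 translation/decay pair, and (iii) a calibration of reaction
multiplicities: scanning all cooperative orders 1–4 on the gene-activation
and WCC-deactivation channels in mean field, exactly one structure
reproduces the documented ~22 h limit cycle of the macroscopic
(deterministic-ensemble) parameter column — **four WCC catalyse *frq*
activation and three FRQ catalyse WCC deactivation**. Those orders also
place the gene's half-activation point, `(Ābar/A)^{1/4} ≈ 230` WCC, right at
the fitted initial counts (~260–280), which supports the reading.

**Known limitation.** At the four-experiment ensemble means, this
reconstruction does not sustain the oscillatory loop: the fitted
`D6/L3/S4/D3` combination cannot hold FRQ near the level at which the
deactivation channel balances WCC production, so the dark-grown spectrum is
a red-noise spectrum whose detrended maximum falls at roughly 24–40 h
rather than in the 21 h bin, and the resonance scan's intrinsic-band power
grows monotonically with the count scale instead of peaking at an
intermediate noise level. We examined several hundred alternative readings
(digit-parse variants of the published table, cooperative orders 1–6,
alternative translation sources and deactivation stoichiometries, with and
without the 26 h light pre-exposure) without finding a variant that restores
a sharp 21 h line at the published means; the wiring details that produce it
evidently live in the diagram beyond what the surrounding text pins down.
All downstream machinery is independent of the shipped topology and accepts
a revised network description file.

## Simulation

The Gillespie direct method: propensities `a_j(x)`, total `a_0`, waiting
time `τ ~ Exp(1/a_0)`, channel chosen with probability `a_j/a_0`.
Time-varying light makes propensities piecewise constant; a waiting time
that would cross the next switch boundary is truncated there, propensities
are re-evaluated and the clock redrawn — exact by memorylessness. Each
trajectory's random stream is an xoshiro256** generator seeded via
splitmix64 from `(seed, trajectory index)`, so batches are reproducible and
order-independent. Propensity updates after each firing touch only the
channels whose members changed (a precomputed dependency table); the running
total is refreshed every 8192 events against floating-point drift.
Production runs record states directly on the half-hour observation grid
(left-continuous sampling at `t_j = (j−1)T/L`); an event-level recorder
exists for diagnostics and exactness tests. Initial counts are rounded;
gene-state pairs are allocated per cell (Bernoulli with the fitted active
fraction, or deterministically by largest remainder).

## Spectrum and likelihood

Series are detrended by subtracting a centered moving average
(edge-renormalized). The window is not stated by the source protocol; the
default is 24 h (49 points at 0.5 h), the field's customary circadian
detrending scale, and is configurable. The periodogram is one-sided,
`Q(f_l) = |X_l|²/L` at `f_l = l/T`, `l = 1..[L/2]` (DC excluded — the
detrender annihilates it).

Detector noise enters additively with variance σ_ε², estimated from
doped-bead control series by regressing per-bead variance on relative
intensity through the origin. The detrend+FFT response functions
`γ_Q(l) = Σ_k |G_lk|²` and `β_Q(l) = Σ_k G_lk²` (with `G = F·R`, `R` the
detrend residual operator) are computed exactly from the operator — they
depend only on the weights and L — and cached; without detrending they
reduce to the classical flat white-noise response `γ_Q = L`. The bias
`Q_bias = σ_ε²γ_Q/L` is subtracted from `⟨Q⟩` and the detector variance
contribution `(σ_l^e)²` (the propagation-of-errors expression with both the
`⟨Q⟩γ_Q` and `Re(⟨R⟩β_Q*)` terms and the σ_ε⁴ correction) is subtracted
from the across-cell variance of the mean, `σ_{f_l}²` (sample variance / K,
by the central-limit argument).

Bins whose corrected variance is non-positive are detector-dominated and
carry no biological information; they are excluded from the fit (this is
why different acquisition protocols contribute different frequency counts),
and retained bins are floored at 10⁻³ of the median positive corrected
variance. The criterion is `χ² = Σ_l r_l²/(σ_l^c)²` over used bins, with
likelihood `∝ exp(−χ²/2T)` under tempering; independent experiments add
their χ².

At desk scale the model spectrum is averaged over tens rather than ~1,000
trajectories, and its own Monte-Carlo variance is no longer negligible: the
expectation of the squared residual contains it, so the plain criterion
systematically favors parameter regions where the model fluctuates less
(low-power models). The fitting objective therefore supports a debiased
form — the model-batch variance is subtracted from the squared residual and
added to the denominator — which reduces to the plain criterion as the
model batch grows. The pipeline's objective enables it and re-simulates the
model batch on every call from a deterministic per-call seed sequence, so
accumulation runs mix over the simulation noise; ensemble standard errors
then reflect both across-model variation and the stochastic objective.
Accumulation chains driven by a noisy objective can stick to a lucky draw,
so the accumulator offers a refresh mode that re-evaluates the held point
each update (Monte-Carlo-within-Metropolis, at twice the evaluation cost);
the closure tests use it.

## Parameterization

Optimizers work on the unit-cube image of Θ: log-uniform boxes spanning ±3
decades around the molecular-number conversion of the macroscopic ensemble,
widened minimally (half-decade margin) where the fitted means moved further
than that, so the canonical Θ is always representable; gene-state fractions
map linearly to [0, 1]. Two rescalings act on Θ directly: unit conversion
(per-box count scales with rates compensated so the mean-field dynamics are
unchanged; conversion channels never cross a box boundary) and the
noise-level rescaling by RNA/DNA and protein/DNA ratio changes (mRNA counts
scale with the RNA ratio, proteins with the protein ratio, zeroth-order
rates with their product class, translation picks up the ratio of ratios,
decays unchanged). Both are exact inverses of themselves and leave the
deterministic drift invariant to integrator tolerance.

## Optimizers and accumulation

Both swarm algorithms use the standard constants (`c₁ = c₂ = 1.49445`,
velocity clamp ±0.2, inertia 0.9→0.4 linearly over the exploration phase —
90% of the generations — then fixed at 0.2 for gbest-attracted
exploitation). DMS-PSO-CLS culls the two worst particles per swarm each
generation, rebuilding them dimension-by-dimension from the better of two
randomly drawn personal bests (population-wide pool), and regroups swarms
every 5 generations; PSO-DLS replaces culling with admixture migration:
with probability `p = t/iter` a particle is attracted to the mean of all
swarm local bests. Positions clamp to the cube with the violating velocity
component zeroed; stored objective values are not re-evaluated (single-
evaluation bookkeeping), so the best-so-far trace is monotone.

Parallel tempering follows the three-stage ladder protocol: `K = √D`
replicas with `T_K = χ²(θ⁰)/30` tuned to the (0.6, 0.75) in-chain
acceptance window; three growth rounds inserting `⌊√(Q/ln 0.4)⌋` evenly
spaced temperatures wherever the mean log swap acceptance Q falls short of
the 0.4 target; three flow-shift rounds moving interior temperatures so the
up/down flow fraction is linear in ladder index (isotonic-regressed before
inversion; endpoints fixed). Swaps alternate odd/even neighbor pairs at
`ρ = min{1, exp[(1/T_i − 1/T_j)(χ²_i − χ²_j)/2]}`; a starved pair raises an
isolation warning. In-chain updates are component-wise Gaussian random
walks reflected at the cube boundary; widths adapt geometrically
(accept ×1.10 / reject ×0.84, equilibrium ≈ 0.65 acceptance) during
designated tuning phases only.

Accumulation runs follow the stated protocol (14,000 updates, 3,500
adaptive burn-in discarded, every 35th model kept → 300 per chain; 12
chains pool to 3,600 models, unweighted). Ensemble summaries are
per-parameter means with standard errors (SD/√n across the pooled ensemble;
plain SD available), and a per-parameter least-squares trend over the sweep
index is the completeness control.

## Phase and synchrony

The analytic-signal (Hilbert) phase of the detrended series is unwrapped,
shifted through the origin, and divided by 2π to count cycles `M_C`.
Amplitude rescaling leaves it unchanged — phase is functionally independent
of the periodogram, hence a held-out diagnostic. Band summaries (5th
percentile, mean, 95th across cells) exclude the first and last 5% of
points (analytic-signal edge artifacts, which contribute a constant offset
but not a slope error); the band-exit time of a data mean against a model
band is the failure-time diagnostic. The Kuramoto order parameter is the
time-averaged resultant length `|⟨e^{iF_H}⟩_cells|` over the interior
window (an external standard definition; the source protocol's averaging
window is unstated).

## Synthetic data

The generator emulates the acquisition chain: 26 h of light for phase
synchronization (observation time restarts at its end), the regime's
square-wave program (D/D or 6/12/36 h days), exact trajectories of the
recorder, additive detector noise, and a Rhodamine-B-style reference
normalization (a common per-frame reference channel with 1% relative noise,
multiplied in and divided back out — consistent with treating
reference-channel noise as negligible downstream). Defaults follow the
study conditions: half-hour sampling, ≥ 240 h, 1,000 cells at full scale,
and a detector variance (σ_ε² = 4) that leaves intracellular noise carrying
well over 90% of the per-cell variance. Bead controls are constant-mean
series whose noise variance scales with incident intensity. What the
generator does not emulate: imaging, droplet physics, cell-to-cell
communication, division, or slow drifts beyond what detrending removes —
so passing closure tests demonstrates the inference machinery, not the
biology of real recordings.

## Problem sizes and numerical choices

Desk-scale defaults keep every stage tractable on one CPU: model spectra
use 128 trajectories (the full-scale protocol uses 1,024), the resonance
scan runs 128 trajectories per multiplier over three seeds, and the
recovery closure fits three free parameters (D7, Sc, Dcp) to 32 synthetic
cells over 96 h with three independent swarm+accumulation replicates
pooled. D7, Sc and Dcp are the identifiable trio in that design; the
WCC-formation rate C2 is structurally unidentifiable there (once
`C2 ≫ D4` the formation flux saturates at the translation rate, so the
likelihood is flat in C2), which is why it is not in the closure set.
Ties in the direct method's channel selection are impossible (continuous
uniforms); degenerate inputs (all-zero series, frozen states, empty swaps)
raise or no-op as documented per function. The SSA event budget guards
against runaway count growth; reaching it raises rather than truncating
silently.

## Known limitations

The central one is the topology reconstruction discussed above: results
that depend on fine wiring at the published parameter means (the 21 h
spectral line, the interior resonance maximum at ×15) are not reproduced by
the shipped network, and the package reports what it actually computes.
Kuramoto values from real data depend on an unstated averaging window and
are treated as context only. The accumulation protocol reproduces the
stated thinning arithmetic exactly but makes no claim of convergence beyond
the trend diagnostic.
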