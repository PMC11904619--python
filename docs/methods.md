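# Methods

This note records the models, numerical choices and study conditions
implemented in `ikrfit`, and what the synthetic-data tests do and do
not establish about real recordings.

## Gating models

Each candidate model is a continuous-time Markov chain over channel
conformations.  With occupancy vector x and transition-rate matrix
Q(V) (Q[i,j] the i→j rate, rows summing to zero), the governing
equation is dx/dt = Qᵀx, and the observed current is
I_Kr = g·x_O·(V_m − E_Kr).  Voltage-dependent rates take the form
A·exp(+bV) or A·exp(−bV) with A > 0 (ms⁻¹) and b ≥ 0 (mV⁻¹); the Wang
structure additionally carries a voltage-independent pair kf/kb.
Units are fixed globally: ms, mV, ms⁻¹, mV⁻¹, nS, pA — so
1 nS × 1 mV = 1 pA and g is a pure scale factor.

The four structures:

| name    | states | kinetic params | total (incl. g) | I↔closed path avoiding O |
|---------|--------|----------------|-----------------|--------------------------|
| COI     | 3      | 8              | 9               | no                       |
| Beattie | 4      | 8              | 9               | yes (IC corner)          |
| Kemp    | 5      | 12             | 13              | yes                      |
| Wang    | 5      | 14             | 15              | no                       |

The Beattie structure is the Hodgkin–Huxley-equivalent square C–O–I–IC
with shared activation (k1/k2) and inactivation (k3/k4) pairs.  The
Kemp structure here is a transcription stand-in: its published diagram
was not available to this implementation, so the package ships a
five-state scheme (a slow closed state feeding the Beattie square)
with the same qualitative features — five states, an
inactivated-closed pathway and 12 kinetic parameters.  Conclusions
that depend on the exact Kemp topology should not be drawn from this
stand-in.

Default parameter values are implementer-chosen physiological
defaults (room-temperature hERG-like kinetics in the style of widely
reprinted literature values; conductance 100 nS); none are printed in
the source study.

Because every model's transition graph is connected, Qᵀx = 0 with
Σx = 1 has a unique solution; the steady state is computed by a
least-squares solve of that augmented linear system, never by
integration (long-time integration is used only as a test oracle).
Sweeps start from the steady state at the −80 mV holding potential, as
cells are left to equilibrate before each sweep.

## Voltage offset convention

Postprocessing infers an observed reversal potential E_obs (the
command voltage at which the corrected current crosses zero) and
defines V_off = E_Nernst − E_obs.  For these two statements to be
mutually consistent, the simulator takes the membrane potential as
V_m = V_cmd + V_off: the current then reverses exactly at
V_cmd = E_obs, and the offset recovered from a synthetic sweep equals
the offset used to generate it.  Equivalently, a positive V_off shifts
the observed reversal to more negative command voltages.

## Simulation

On constant-voltage segments the solution x(t) = exp(Qᵀt)x₀ is
evaluated through the eigendecomposition of Q (one decomposition per
segment, vectorised over the sample grid), with a stepwise
scaling-and-squaring fallback guarded by a probability-conservation
check.  On ramps, where Q is time-dependent, the default integrator is
a fourth-order commutator-free Magnus scheme: each substep applies two
matrix exponentials built from Q at the two Gauss nodes.  The scheme
is unconditionally stable for generator matrices, conserves
probability exactly, and — stepping at the 1 ms sample interval — 
agrees with LSODA at tolerance 1e−8 to better than 1e−8 in state
occupancy (the package's acceptance tests require 1e−5 on the
current).  An all-LSODA route (`method="numeric"`, rtol = atol = 1e−8)
is retained both as a user option and as the accuracy oracle in tests.
All propagator matrices for one trace are eigendecomposed in a single
batched call, which is what makes repeated objective evaluation cheap
enough for stochastic optimization.

The ramp substep defaults to the sample interval.  At a 10 ms grid the
Magnus error on the fast reversal ramp is ~3e−5 in occupancy; fitting
remains exactly self-consistent because the generator and the
objective use the identical discretisation.

## Synthetic experiments

The generator realises the statistical structure the downstream
analysis assumes:

* observed current I_out = I_Kr + g_L(V_cmd − E_L) + ε with
  ε ~ N(0, σ²) IID per sample;
* post-drug sweeps assume a complete specific block (g = 0), so drug
  subtraction isolates I_Kr on average;
* per well: a voltage offset V_off ~ N(0, 2 mV), leak conductance
  g_L ~ U(0.1, 2) nS with E_L ~ U(−30, 10) mV, noise σ = 20 pA, and a
  log-normal conductance factor (spread 0.3);
* kinetic heterogeneity applied on the (a = ln A, b) scale — Gaussian
  well and protocol effects re-centred to sum to zero, defaults
  sd(a) = 0.10 / 0.05 and sd(b) = 0.002 / 0.001 for wells/protocols —
  exactly the additive structure the two-way effects model later fits.

All these magnitudes are package defaults chosen to resemble a clean
automated patch-clamp well; they are deliberately tunable (power
studies need larger and smaller effects than the defaults).  The
schedule per well and drug state is: staircase (d1) twice, every other
protocol once, staircase twice more — 15 sweeps, of which 14 (all but
the validation-only protocol d6) are fitted.

What the generator does **not** emulate: capacitance transients,
series-resistance and amplifier artefacts, endogenous background
currents, nonlinear or time-varying leak (beyond an optional
drifting-leak QC fixture), temperature drift, and channel rundown.
Passing the package's tests therefore demonstrates correctness of the
analysis chain under its own assumptions — not that those assumptions
hold for any particular real recording.

## Postprocessing

Leak is fitted by OLS of current on command voltage over the ramp
portion of the leak section only (−120 → −80 mV, where I_Kr is small);
slope and intercept give g_L and E_L.  With g_L numerically zero the
leak model reports E_L = 0 with a degenerate flag rather than NaN.
Because the pre-drug trace still contains a little I_Kr in that
window, the pre-drug leak fit carries a small bias (~0.5 pA on default
synthetic data, i.e. ~1e−3 of the signal); the post-drug fit does not.
This bias is intrinsic to the method and bounds how exactly
postprocessing can return the simulator's I_Kr.

The reversal potential is inferred on the leak-corrected,
drug-subtracted trace: a degree-4 polynomial in time is fitted over
the reversal ramp, its real roots inside the window are found, and the
crossing where the fitted current descends through zero is taken
(along the descending ramp the driving force falls through zero from
above, so the physical crossing is positive-to-negative; the earliest
such crossing is used if several exist).  The quartic is an
approximation to the true current shape; on noiseless synthetic data
its bias is ~0.3 mV, which is why accuracy requirements on E_obs are
stated at 0.5–1 mV rather than machine precision.  The noise estimate
σ̂ is the sample SD over the initial holding section (the estimator is
package-defined; the source study uses a noise estimate without
printing its form).

QC defaults: σ̂ ≤ 50 pA, staircase first-vs-last NRMSE ≤ 0.2
(computed on raw pre-drug sweeps, where a drifting seal leak is
actually visible), |E_obs − E_Nernst| ≤ 15 mV, post/pre corrected RMS
ratio ≤ 0.5.  A well passes only if every criterion passes on all its
sweeps.  The full production rule set of the original experiments
lives with the archived data; these defaults cover the criteria the
methods describe and are config-overridable.

## Fitting

The per-sweep estimate minimises the sum of squared residuals (the
MLE under IID Gaussian noise).  The optimizer is the package's own
implementation of standard (μ/μ_w, λ)-CMA-ES (no maintained CMA-ES
library was available in the target environment), with population
size ⌊4 + 3 ln n_p⌋ and an override of 50 for the Wang model.
Search coordinates are log10 for A-type, constant and conductance
parameters and linear for b parameters; per-dimension scales (8
decades / 0.5 mV⁻¹) encode the prior range and the initial step
multiplier is 0.3 relative to those scales.

Initial guesses are log-uniform, log10(p) ~ U(−7, 1), rejected and
resampled until every rate satisfies 1.67×10⁻⁵ ≤ k_max ≤ 10⁵ ms⁻¹
over V ∈ [−120, +60] mV.  The conductance guess is log-uniform on the
overlap of that prior with the data-driven conductance bounds
(max |I| during the −120 mV scaffold step divided by the driving
force, times lenient factors 1e−4 and 1e4), or on the bounds
themselves when the overlap is empty — necessary because corrected
traces carry almost no I_Kr during that step, so the reference
conductance can sit far below the cell's true conductance.

Bounds are enforced by projection-with-penalty: proposals are
projected onto the feasible box (b clipped to [1e−9, 1], log10 A
clipped so k_max stays within bounds given b, log10 g clipped to the
conductance box) and the objective is charged (1 + SSE)·(squared
projection distance).  Each CMA run (budget 10⁴ evaluations,
relative f-tolerance 1e−7 over 20 generations) is followed by a
trust-region least-squares polish on the residual vector, which
performs the final descent far faster than CMA and is what takes
noiseless recovery from ~1% to machine precision.  Per-repeat seeds
derive from the master seed plus the repeat index.  Repeats whose RMSE
lies within 1% of the best are counted as the cluster diagnostic.

On noiseless self-generated staircase data (10 ms grid), 5 repeats
recover all kinetic parameters of the three- and four-state models to
far better than 1%; occasional seeds require the full 10⁴-evaluation
budget for at least one repeat to leave a prominent local optimum, so
the budget should not be reduced below that for recovery work.

## Validation metrics

NRMSE adopts the root-mean-square convention in numerator and
denominator, sqrt(Σ(zᵢ−yᵢ)²)/sqrt(Σzᵢ²), so the sample count cancels
and traces of different lengths and amplitudes are comparable.  In the
cross-validation table rows are fitting sweeps and columns validation
sweeps, with repeated staircase sweeps kept as separate entries.
E_fit is the mean of the matched entries.  E_predict sums all
unmatched entries and divides by (N_d − 1)² with N_d the number of
validation sweeps — the convention of the source formula, which
equals the plain mean when exactly one validation-only protocol is
present.  The consistency statistic T divides the ensemble bias by
σ̂ + std(y)/√N (the standard-error reading of an ambiguous printed
expression; a switch selects /N instead), and both T and the weighted
residuals are clipped to ±100 for display.

## Variability analysis

Estimates are transformed to (a = ln A, b); voltage-independent rates
are also log-transformed; the conductance column is dropped (cell-level
conductance variation is expected and uninformative about kinetics).
The two-way fixed-effects model is fitted column-wise by OLS with
sum-to-zero (effects) coding; a factor with a single level contributes
nothing, so the full model degenerates gracefully (one well ⇒ Mwd ≡
Md).  Error variances are maximum-likelihood (divide by N_trace, not
the residual degrees of freedom), consistent with reporting
likelihoods of ML fits; the total log-likelihood is the sum over
independent columns.  Repeated staircase sweeps share one protocol
level — the model has no repeat term.  LLD(−w) = ℓ(Mwd) − ℓ(Md) and
LLD(−d) = ℓ(Mwd) − ℓ(Mw) are non-negative by nesting; on synthetic
tables with strong well effects LLD(−w) exceeds the zero-effect
condition by well over an order of magnitude, the qualitative pattern
the analysis is designed to expose.  σ_k is floored at 1e−12 to keep
the log-likelihood finite on exactly collinear (noise-free) tables.

## Problem sizes

Simulations in the test-suite and the acceptance script are scaled to
a single CPU: a 10 ms sample grid for fitting work (1 ms where
postprocessing accuracy is measured), 5 CMA-ES repeats for recovery
experiments, 2 repeats with a 2.5×10³-evaluation budget inside the
small end-to-end pipeline (2 wells, a 5-protocol battery), 25–50
Monte-Carlo seeds for postprocessing recovery, and 8 wells × 14 sweeps
for the variability simulations (matching the shape of the post-QC
study data).  These sizes are package choices; every one of them can
be raised through the corresponding config objects.

## Known limitations

* The Kemp structure is a labelled stand-in (above), and default
  parameter values for all models are implementer-chosen.
* The optimised protocol designs of the original battery are not
  reconstructible from text; the package substitutes seeded random
  step designs with the documented scaffold and loads user-supplied
  waveforms from CSV.
* Leak-fit bias from residual I_Kr in the leak window (~1e−3 of the
  signal) bounds end-to-end postprocessing exactness.
* The fixed-effects analysis assumes independent Gaussian errors per
  column; no cross-parameter covariance and no random-effects
  formulation are implemented.
* Real-data artefacts (capacitance, series resistance, endogenous
  currents) are out of scope of both the simulator and the generator.
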