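# Methods

This note documents the models implemented in `popglm`, the choices made
where the design was genuinely open, and what the synthetic-data
generators do and do not emulate.

## The population encoding model

Each neuron's spiking on a 1 ms grid is modeled as conditionally Poisson
with intensity

    lambda_t = exp( k * x_t  +  h * r_{t-1}  +  c * s_t  +  b ) / dt

where `x_t` are task-event covariates (delta functions at target onset
and at saccade onset), `r_{t-1}` the neuron's own spike counts at lags
>= 1 ms, `s_t` the simultaneously recorded partner neurons' counts at
lags >= 1 ms, and `b` a baseline in log spikes per bin.  All temporal
filters are expanded in nonlinearly time-scaled raised-cosine bases:

* task kernels — 8 bumps over 800 ms, lag 0 included.  The saccade event
  delta is shifted 400 ms earlier so the kernel covers −400..+400 ms
  around saccade onset (peri-saccadic activity is largely pre-saccadic
  build-up); the lead is configurable (`ModelSpec.saccade_pre_ms`).
* history and coupling kernels — 10 bumps over 250 ms, strictly causal
  (support starts at lag 1 ms, so coupling is directional and history
  excludes the current bin).

Bump peaks are evenly spaced in `log(t + a)` with warp offset `a`
(default 10 ms for the 250 ms bases, 30 ms for the 800 ms bases), giving
~2 ms resolution at the earliest history lags and coarse resolution near
the window end.  Columns are normalized to peak 1 so a weight reads as a
log-gain amplitude; `exp(max kernel)` is then directly the maximum
multiplicative gain of a kernel.

Targets in versus out of the neuron's response field are fitted jointly
in one model with separate kernels per condition (`condition_split`,
default on).  The model deliberately ignores the exact target location
and its spatial jitter; location enters only through the IN/OUT split.

### Fitting

Weights are estimated per neuron by penalized maximum likelihood
(equivalently MAP under a zero-mean Gaussian prior on `k`, `h`, `c`; the
baseline is unpenalized):

    maximize  sum_t [ r_t eta_t − exp(eta_t) ]  −  lambda (‖k‖² + ‖h‖² + ‖c‖²)

The objective is concave, so the optimum is unique.  Optimization is
L-BFGS with analytic gradients, followed by a few Newton steps whenever
the gradient infinity-norm exceeds `1e-6 x total spike count`; a fit
that remains above 100x that bound raises.  The linear predictor is
clipped at 30 inside `exp` during line searches only.

The ridge strength is a fixed scalar (default `0.5`), not selected by
nested cross-validation on every fit: at the session sizes this package
targets (10 units x 300 one-second trials) the held-out likelihood is
flat between ~0.5 and ~5 and degrades beyond, and a nested grid search
would multiply every fit by the grid size. `select_ridge` implements the
grid search for deliberate use.  Attractor-network sessions are much
sparser (tens to hundreds of spikes per unit), and there the default is
`lambda = 10`, i.e. a prior SD of ~0.22 per basis weight — the
physiological expectation that per-pair coupling gains are modest
(max gains ≲ 1.5).  Unregularized fits on such sessions produce
non-physical kernels (summed log-gains of ±25).

Because history and coupling share one basis, a single set of per-unit
convolved spike blocks serves the whole population: the fitted neuron's
own block is its history, every other block is a coupling predictor.
Convolutions never cross trial boundaries and rows never mix trials, so
trials are exchangeable units for cross-validation and permutation.

### Scoring

* Cross-validation is 5-fold over *trials* (not bins), preserving
  within-trial dependence.
* **Bits per spike**: held-out log-likelihood minus that of a
  homogeneous mean-rate model (rate estimated on the training folds),
  divided by the held-out spike count and by log 2.
* **Deviance explained**: `1 − D_model / D_null` with Poisson deviance
  against the same mean-rate null, on held-out data.
* **Predictive indices**: coupling index
  `(dev_full − dev_no-coupling) / dev_full` clipped to [0, 1], and the
  analogous history index.
* **PSTH variance explained**: single-trial spike trains are sampled
  from the fitted model (sequentially over bins, so sampled history and
  coupling feed back), averaged into a predicted PSTH, and compared to
  the empirical PSTH by R².

## Coupling summaries

The coupling strength of a directed pair is the **sum of the
reconstructed time-domain kernel** over its 250 ms support (per-ms log
gain); summing the reconstruction rather than the raw weights makes the
statistic invariant to the basis parameterization.  The max gain
`exp(max kernel)` is reported alongside.  Significance is assessed
against the **trial-shuffle null**: each predictor unit's trials are
reordered by an independent random permutation and the model is refit;
the fitted neuron's spikes and the task covariates are untouched, so
within-trial spike times and signal correlations are preserved while
noise correlations are destroyed.  A pair is called significant when its
weight exceeds the pooled null mean + 2 SD (one-sided, excitatory; a
two-sided variant is available).  On independent ensembles this
exceedance calibrates to the Gaussian tail mass (~2.3%).

Predictor trials permuted across trials of unequal length are truncated
or zero-padded to the fitted trial's length; the attractor and
compact-trial generators produce equal-length trials, where this is a
no-op.

Kernel populations are summarized by PCA (mean-centered SVD; component
signs fixed by positive integral) and by double-exponential fits
`a1 e^{−t/tau1} + a2 e^{−t/tau2}` (multi-start bounded least squares;
the reported tau belongs to the larger positive amplitude).  Kernels are
excluded from the time-constant analysis when the fit R² is below 0.5 or
when they are refractory-dominated (most-negative value in the first
5 ms exceeding the positive peak); both thresholds are arguments.

Epoch-restricted models refit the same design on bins inside named,
equal-length windows (e.g. fixation vs delay, early vs late delay);
trials on which a window is unresolvable are dropped and counted.
Spatial tuning is a circular-Gaussian least-squares fit to mean rates in
angular bins of the target direction, and coupling-vs-tuning reports the
mean coupling weight per tuning-peak-distance bin.

## The ground-truth generator

`make_ground_truth_population` draws a `PopulationFit` from a library of
physiologically shaped components, projected onto the model bases so the
truth is exactly representable by the estimator:

* baseline rates uniform 12–28 spikes/s (matching the tens-of-spikes/s
  regime of frontoparietal recordings);
* target kernels: Gaussian transient peaking 60–140 ms after onset,
  amplitude 0.6–1.2 log-gain in-RF and 30% of that out-RF;
* saccade kernels: peri-saccadic bump, amplitude 0.4–0.8;
* history: −4 log-gain at lags 1–4 ms (absolute refractoriness) plus a
  slow component, amplitude −0.3..+0.2, tau 30–150 ms;
* coupling: exponential decays with tau 30–120 ms (the long network
  timescales of persistent-activity circuits) and peak amplitude ~0.15
  (max gains ~1.1–1.3), each directed pair coupled with probability
  0.35, excitatory with probability 0.5.

Two mechanisms keep the generative model dynamically stable, standing in
for the excitation/inhibition balance of real circuits: the summed
integral of excitatory coupling kernels converging on any neuron is
capped (default 12 log-gain·ms, rescaling the incoming excitatory
kernels), and validation routines redraw a parameter set whose
simulation still exceeds the rate cap (20 expected counts per 1 ms bin).
Simulation is sequential over 1 ms bins with conditionally Poisson
counts, so sampled history and coupling feed forward exactly as the
model assumes.

The compact trial generator places jittered task events (target on at
0.05–0.15 s, 200 ms flash, 0.15–0.35 s delay, saccade 50–90 ms after
the go signal) inside fixed 1 s trials so that both 800 ms task-kernel
supports are observable and many trials fit in a small compute budget;
`generate_task_trials` reproduces the real task's statistics instead
(1–1.5 s fixation, 0.5–2 s delays, Gaussian eccentricity 10° ± 5°,
condition by hemifield), at the price of 3–5 s trials.

What the generator does **not** emulate: non-Poisson dispersion,
nonstationarity across a session, electrode artifacts and sorting
errors, unobserved common input (every correlation has a synaptic
analogue in the truth), and spatial receptive-field structure beyond the
IN/OUT dichotomy.  Passing recovery tests therefore demonstrates
correctness of the estimator under its own assumptions, not robustness
to the full messiness of real recordings.

## The ring attractor network

A conductance-based LIF implementation of the classic spatial
working-memory ring model: 1024 excitatory and 256 inhibitory cells
(desk scale: 256/64 with the weight scaling raised from 2 to 8 to
preserve mean input), external Poisson drive of 1000 sources x 1.3 Hz
per cell through AMPA synapses (tau 2 ms), uniform all-to-all GABA
inhibition (tau 10 ms), and recurrent NMDA excitation (rise 2 ms, decay
65 ms, alpha 0.5/ms, magnesium block `1/(1 + 0.28 e^{−0.062V})`).  The
E→E profile is `w(Δθ) = J− + (J+ − J−) exp(−Δθ²/2σ²)` with σ = 20° and
J− set by the mean-weight-1 normalization.  Cell constants: E cells
Cm 0.5 nF, gL 25 nS, I cells 0.2 nF / 20 nS; threshold −50 mV, reset
−60 mV, refractory 2 ms (E) / 1 ms (I); integration is forward Euler at
0.1 ms (synaptic decays use exact exponential factors), JIT-compiled,
with NaN and spike-buffer guards.

Stimulus protocol per trial: center uniform on the ring, onset uniform
0.2–0.5 s, 200 ms duration, 1 s trials, 0.06 nA injected into cells
within ±`stim_width_deg` (30°) of the center.  The stimulated arc is
twice the nominal width: with the arc at ±width/2 the default current
cannot ignite the bump even at J+ = 2.3 (verified numerically), so the
wider footprint is the operational choice, and both the strength and
width are parameters.  Persistence is read out by the population vector
of excitatory spikes in the final 200 ms: sustained means resultant
amplitude > 0.2 *and* readout angle within the stimulus width of the
true center (the angle condition suppresses false positives from sparse
background spikes).  On the desk-scale grid J+ ∈ {1.0 … 2.2} the bump
decays at the low end and persists on > 80% of trials at the high end,
with the threshold near 1.9.

For the recurrent-strength sweep, each session's sampled ensemble
(fixed across trials; units with fewer than 20 spikes are dropped, as
silent cells would never be isolated in a recording) is fit with the
coupled GLM (target + history + coupling; no saccade event exists) and
three coupling summaries are reported per J+: the signed mean kernel
sum, the mean absolute sum, and the mean max gain.  At desk scale the
*signed* mean is non-monotone at strong recurrence: the winner-take-all
dynamics suppress distant pairs, whose large negative kernel sums
dominate the signed average.  The coupling *magnitude* (and the max
gain) increase monotonically with J+ and are the summaries that track
recurrent strength.

## Numerical conventions and edge cases

* Bins are half-open `[t, t + dt)`, 0-based, times relative to trial
  start; trials are ragged (no padding bins ever enter a likelihood).
* PSTHs average aligned counts over the trials covering each bin and
  smooth with a Gaussian (SD 30 ms default) using reflection padding.
  A condition with no trials yields `None`, never a zero-filled series.
* `bits_per_spike` with zero spikes and `deviance_explained` with a
  degenerate null return NaN rather than raising.
* Sampled multi-spike bins place spikes at deterministic sub-bin
  offsets so spike-time lists stay strictly sorted.
* Sessions serialize to HDF5 (units/trials/spikes/metadata groups) or to
  a directory with `spikes.csv` + `meta.json`; round trips are lossless
  to 1e-6 s.
* All stochastic stages derive their seeds from a master seed and a
  stage name via SHA-256, so a (config, seed) pair reproduces a run
  bit-for-bit.

## Validation benchmark sizes

The shipped benchmarks (`popglm.validation`, also run by
`scripts/acceptance.py`) use: recovery — 10 units x 300 one-second
trials; detection — 5 units whose truly coupled pairs form a directed
excitatory cycle (one strong input per target, so the excitation budget
is not split), 100 trials, 20 permutations; calibration — 20
independent sessions of 4 units x 40 trials (the acceptance script
reports 12 sessions to stay well inside its runtime target); model
comparison — 12 units x 150 trials, 5 folds, with a
one-directional excitatory ring so every unit receives one strong input
(~0.5 peak log-gain), and an 8-unit x 100-trial independent-data
negative control; sweep — J+ ∈ {1.0, 1.3, 1.6, 1.9, 2.2}, 100
trials and 10 sampled units per session on the 256-cell network; PSTH
self-consistency — 6 units x 150 trials with 5 simulation repeats and
elevated task amplitudes (1.0–1.5 log-gain) so every unit is strongly
task-modulated; a finite-trial PSTH of a weakly modulated unit is
noise-capped below the self-consistency bar regardless of model
quality.
These sizes were chosen so the full suite completes on a single CPU in
well under an hour while leaving comfortable statistical margins.

## Known limitations

* The permutation null refits with a warm start at relaxed tolerance;
  on pathological sessions the null SD could be slightly underestimated
  (the calibration benchmark bounds this empirically).  Pooling null
  weights across pairs with heterogeneous variances also inflates the
  2-SD tail slightly above the Gaussian 2.3% (mixture kurtosis);
  measured exceedance on independent ensembles is ~3–4%.
* The double-exponential time-constant fit is a non-convex least-squares
  problem; the multi-start grid is small and can in principle miss the
  global optimum for exotic kernel shapes.
* The attractor implementation fixes the cell and synapse constants of
  the classic model; only the parameters listed on `AttractorParams`
  are exposed.
* Epoch comparisons assume the epochs are resolvable on most trials;
  heavy trial dropping (logged in the comparison table) biases the pair
  set toward long-delay trials.
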