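# Methods

`tonedrift` implements a joint choice/response-time analysis of a
two-alternative auditory frequency-discrimination task in which expectations
come either from an instructed probability cue ("rule-based") or from a
temporal sequence of tone bursts preceding the test tone ("stimulus-based").
This note documents the model, the numerics, and the design choices made
where more than one reasonable implementation exists.

## Task and stimulus representation

A trial presents a test tone (low or high frequency) embedded in noise at
one of four signal-to-noise ratios.  The canonical dB levels
{−23, −18, −13, −6} are mapped linearly onto an unsigned unit scale
[0.05, 0.5]; the sign of the unit SNR encodes tone identity (high = +).
The linear map is the simplest monotone choice consistent with the published
endpoints; alternative monotone rescalings change coefficients but not the
qualitative structure of any analysis here.

Rule-based sessions hold 576 trials in twelve 48-trial mini-blocks; each
block fixes one of three cues with high:low odds 5:1, 1:1 or 1:5
(p(high) = 5/6, 1/2, 1/6), counterbalanced four blocks per cue in shuffled
order.  Stimulus-based sessions hold 480 trials; the test tone is fair
(p(high) = 1/2) and each trial carries a 2–14 tone pre-test sequence except
for 38 trials, placed uniformly at random, that have none and are excluded
from analysis (leaving 442).  Pre-test sequence lengths follow a geometric
distribution truncated to [2, 14] with success probability 0.45 (mode 2,
mean ≈ 3.2), matching the description of approximately exponential lengths
dominated by 2–3 tone sequences; sequences are resampled (up to 100 rounds)
until the session-level proportion of high tones is within ±2% of one half.
Mixed sessions combine both cue types (mixed-1: constant cue, variable
sequences; mixed-2: trial-wise cues, fixed 5-tone sequences).  The response
window defaults to 2 s (3 s supported).  The feedback-duration asymmetry of
the original task is not modelled.

## The generalized drift-diffusion model

Evidence x accumulates as dx = v dt + σ dW with σ = 1 between absorbing
bounds at ±(B − t_B·t); crossing the upper bound is a high-frequency choice.
The drift is

    v = v_SNR · SNR + bias_evidence + adapt · |SNR|

with

* `v_SNR` — drift gain (1 / unit-SNR / s);
* `bias_evidence` — rule-based: one of {v_Low, v_0, v_High} by cue;
  stimulus-based: v_0 + v_Bias · pt_Bias, where
  pt_Bias = Σ_{i∈high} e^(−p_i/τ_Bias) − Σ_{j∈low} e^(−p_j/τ_Bias) is an
  exponentially weighted tally of the pre-test tones, positions numbered in
  reverse chronological order starting at 0;
* `adapt` = va_High Σ_{i∈high} e^(−p_i/τ_va) − va_Low Σ_{j∈low} e^(−p_j/τ_va),
  an adaptation drive that multiplies |SNR|: with negative weights it pushes
  decisions away from recently repeated frequencies, and the effect grows
  with stimulus strength — the mechanism behind the attract-at-low-SNR /
  repel-at-high-SNR crossover.

The starting point is x0 = bias_start · 2B from the lower bound with
bias_start = g(z), g the logistic function; rule-based z is one of
{z_Low, z_0, z_High}, stimulus-based z = z_0 + z_Bias · pt_Bias.  We apply
the logistic transform in both conditions (fitting the rule-based starting
points on the logit scale throughout); a monotone reparameterization does
not change the model class and keeps one convention everywhere.
bias_start is clamped to [0.01, 0.99].  Non-decision time is
ndt = ndt_0 + ndt_Bias·|pt_Bias| (floored at 0), and a lapse rate λ mixes in
a uniform distribution over both choices × (0, window], density
1/(2·window).  A drift-variability variant replaces the collapsing bound
with a uniform drift distribution of width v_width centred on the trial's
drift, integrated by 15-point Gauss–Legendre quadrature.

Time constants are stored as τ (tone positions) but fitted and tabulated as
decay rates 1/τ, the convention of the parameter summary tables; the search
box [0.2, 20] on the rate scale covers the published means ± 3 SD.

### Variant lattice

| variant | rule k | stim k | notes |
|---|---|---|---|
| base | 6 | 6 | v_SNR, B, v_0, z_0, ndt_0, λ; fixed bound |
| collapsing | 7 | 7 | + t_B |
| bias_only | — | 11 | + v_Bias, z_Bias, 1/τ_Bias, ndt_Bias |
| starting_point_only | 9 | 13 | full minus cue/sequence evidence bias |
| evidence_only | 9 | 13 | full minus cue/sequence starting-point bias |
| full_fixed_bound | 10 | — | full minus t_B |
| full | 11 | 14 | all terms for the condition |
| drift_variability | 11 | — | full_fixed_bound + v_width |
| mixed_full | 18 | | both bias families |

## First-passage solver

`solve_fpt` propagates the probability mass on a fixed spatial grid
(defaults dt = 5 ms, dx = 0.005 evidence units) with a Crank–Nicolson theta
scheme; the first four steps are backward Euler (Rannacher start-up) to damp
the oscillations seeded by the delta initial condition.  The absorbed flux
at each bound is computed from the same discrete transfer coefficients as
the interior update, so total probability is conserved to machine precision.
The collapsing bound is tracked by shrinking the active grid window; the cut
is computed in whole grid cells and mirrored at both ends, which makes the
scheme exactly symmetric under (drift, x0) → (−drift, −x0).  Nodes overtaken
by the bound donate their mass to the nearer absorber; if the bound reaches
zero before the horizon, all remaining mass is absorbed there, split by the
sign of the decision variable (the task aborts such trials).  Fixed-bound
absorption probabilities match the closed form to ≈ 1e−5 at the default
resolution, and collapsing-bound densities match a 10^5–10^6-path Euler
oracle within Kolmogorov–Smirnov distance < 0.01.

The path simulators use Euler–Maruyama (default step 1 ms) with the
Broadie–Glasserman continuity correction — the bound is shrunk by
0.5826·σ·√dt — to remove the systematic late-crossing bias of discretely
monitored barriers.

## Likelihood and fitting

The likelihood of a responded trial is
(1 − λ)·f_DDM(choice, rt − ndt) + λ/(2·window), with f_DDM = 0 for
rt < ndt and a floor of 1e−10 per trial.  Dataset evaluation groups trials
by their (drift, starting-point) pair, solves each unique pair once
(batched, compiled), and linearly interpolates the defect densities at each
trial's decision time.  During global search the drivers are lightly
quantized (default drift to 0.005, starting fraction to 0.002) so that
solver work is shared across near-identical trials; the final polish always
re-optimizes the unquantized likelihood.

Estimation is maximum likelihood by differential evolution (rand/1/bin,
F = 0.7, CR = 0.9, population 15·dim, up to 300 generations, tolerance
1e−6, seeded) inside fixed search boxes: v_SNR ∈ [0, 20]; B ∈ [0.3, 3];
t_B ∈ [0, 3]; ndt_0 ∈ [0, 1]; ndt_Bias ∈ [−1, 1]; λ ∈ [0, 0.2]; bias terms
∈ [−5, 5]; rates 1/τ ∈ [0.2, 20]; va ∈ [−8, 8].  Two refinements matter in
practice:

* **warm start** — variants beyond `collapsing` seed half of the initial
  population around a cheap no-history anchor fit (`collapsing` or `base`),
  which pins the strongly coupled (v_SNR, B, t_B, ndt_0) ridge before the
  bias dimensions open up;
* **polish** — L-BFGS-B in box-normalized coordinates on the exact
  likelihood, with finite-difference steps (1e−4 then 1e−5 of the box)
  sized above the solver's interpolation noise.  The default scipy polish
  uses steps far below that noise floor and stalls.

Reduced-budget presets (`FAST_OPTIMIZER`: population 8·dim, 60–100
generations, solver grid dt = dx = 0.02) are used for the simulation
studies shipped with the package; at these settings a 14-parameter
stimulus-based fit to ~2000 trials takes a couple of minutes and recovers
the generating v_SNR, v_Bias, va_Low, va_High within ±25% (or ±0.3 for
near-zero values).  Simulation-study problem sizes throughout (one or two
synthetic subjects per condition, 1–2 × 10^3 trials each, 150 000 oracle
paths, 200–500 calibration cohorts) were chosen as the smallest sizes at
which the checked effects are comfortably resolved.

Likelihood-ratio tests compare nested variants with
χ² = max(0, 2·ΔLL) — the clip absorbs small negative ratios from local
minima near the global solution — and subjects are classified by which bias
mechanisms the data demand (both / evidence only / starting point only /
neither) from the two full-versus-reduced tests at α = 0.05.

## Model comparison

Goodness of fit is summarized by AIC (2k − 2LL) and BIC (k·ln n − 2LL),
averaged across subjects.  Cohort-level selection uses random-effects
Bayesian model selection: per-subject log evidences (approximated as
−AIC/2) enter a variational Dirichlet posterior over population model
frequencies (prior α0 = 1, convergence 1e−6 or 500 iterations).
Exceedance probabilities come from ≥ 10^5 seeded Dirichlet draws, and the
protected exceedance probability is
PEP = EP·(1 − BOR) + BOR/K, where the Bayes omnibus risk
BOR = 1/(1 + exp(F1 − F0)) compares the free energy of the random-effects
model with that of the null model in which all frequencies equal 1/K.
Under exchangeable evidences PEP calibrates to 1/K; a model better by ~10
log-evidence units per subject attains PEP > 0.95.

## Psychometric models

Choice is modelled as P(H) = λ + (1 − 2λ)/(1 + e^−f) with a single shared
lapse per fit (this matches the published parameter counts; a per-cue lapse
would change them).  Rule-based f = β0c + β_SNR·SNR with per-cue offsets
(and optionally per-cue slopes); stimulus-based
f = β0 + β_SNR·SNR + Σ β_pt,i·pt_i + Σ β_pta,i·pt_i·|SNR| with pre-test
tones contrast coded ±0.5 and positions numbered from 1 for the tone
immediately before the test tone (note the deliberate off-by-one relative
to the DDM sums, which start at 0; both conventions are preserved).  At
most the last six tones enter (n_back ≤ 6), with 2 the default.  Fitting is
multi-start (10 seeded starts) L-BFGS-B on the negative log-likelihood with
λ ∈ [0, 0.2] and coefficients capped at ±50; a fit touching the cap is
flagged (complete separation).  The behavioral bias summary is
β0_High − β0_Low.

Chronometric summaries take per-subject medians of correct RTs per
congruence × |SNR| cell and then across-subject means.  Group-level
congruence questions are answered by two-stage statistics (per-subject
estimates, then across-subject tests) rather than mixed-effects ANOVAs; on
synthetic cohorts, where the two-stage estimator is consistent, this
reproduces the same qualitative claims.  Bias coupling across subjects is
Spearman's ρ between the starting-point and evidence biases plus
least-squares slopes between the z-scored biases in both orientations.

## Performance landscapes

For a context (low/high cue, or LL/HH pre-test ending) the predicted
accuracy pc(z, v | c, θ) is computed for every candidate bias pair on a grid
(default 17 × 17), averaging P(correct) over tone identity (weighted by the
context's p(high)) and the four SNR levels (uniform).  The lapse responds
uniformly (correct with probability 1/2) and window expiry counts as
incorrect.  Grid conventions: for rule contexts the grid value z ∈ (.1, .9)
denotes the starting fraction itself and is injected through the logit
(z_c = logit(z)), so the grid covers start fractions 0.1–0.9 directly; for
stimulus contexts z is the gain z_Bias, and the default grid is the
symmetric (−0.9, 0.9) because fitted gains straddle zero.  The adaptation
weights stay at their fitted values.  Surfaces are normalized to
proportion-of-maximum; the 97% contour is extracted by marching squares
with bilinear interpolation, and a subject's proportion-of-maximum is the
normalized surface interpolated at their fitted biases (outside-hull points
snap to the nearest cell and are flagged).

## Pupillometry

Recordings are 1000-Hz pupil diameter plus gaze.  Cleaning: blink/missing
gaps expanded ±100 ms; velocity artifacts (|first difference| > 24 a.u./ms,
velocity defined on consecutive 1-ms samples) removed, with runs longer
than 16 ms also expanded ±100 ms; all spans linearly interpolated (nearest
value at recording edges, flagged), then low-pass filtered.  The filter is
a 3rd-order Butterworth at 8 Hz applied forward-backward (zero phase) — the
realization is our choice, checked by requiring ≥ 20 dB attenuation at
20 Hz and ≤ 1 dB at 1 Hz.  Order of operations: interpolate → filter →
z-score within block → baseline.  Cleaning is idempotent by construction
(a cleaned recording passes through unchanged).

Epochs are choice-aligned (default −500..+1500 ms) with the mean over
0–40 ms after test-tone onset subtracted per trial.  Exclusions: trials
with > 50% interpolated samples; whole recordings with > 60%; trials whose
gaze leaves the fixation circle for > 15 ms continuously (the circle is the
95th percentile of baseline-centred gaze radii per session unless given);
subjects with fewer than 75 surviving trials are flagged.  Statistics run
on 50-Hz data (means over 20-ms bins): per-subject OLS per bin with the
contrast codes plus nuisance covariates (tone identity, |SNR|, baseline
diameter, gaze), collinear covariates dropped with a flag; then one-sample
t-tests across subjects per bin, Benjamini–Hochberg adjusted jointly across
bins and contrasts.  Brain–behavior coupling is the across-subject Spearman
correlation between the per-subject contrast betas and the logistic choice
bias, per bin, BH-adjusted across bins.

## Synthetic cohorts

The generator draws subject-level parameters from independent truncated
Gaussians at published across-subject means/SDs per condition (truncation to
the fitting search boxes by resampling), except the rule-based (z_c, v_c)
pairs, which share a bivariate Gaussian with a configurable correlation
(default −0.6) — the explicit coupling finding; other between-parameter
covariances are unpublished and left at zero.  Behavior comes from the
generative DDM via the corrected Euler simulator; window expiries are
redrawn up to five times, then recorded as no-response.  Pupil traces are
built at 1000 Hz from a smoothed random-walk baseline, a choice-locked
gamma kernel (shape 2, scale 300 ms) whose amplitude gains `pupil_effect`
z-units on rule-incongruent choices, Poisson blinks (zeroed 100–150 ms
spans), sensor noise, and Gaussian gaze jitter.

What the generator does **not** emulate: learning or session-order effects,
RT autocorrelation, non-stationary lapsing, realistic pupil impulse-response
variability, eye-tracker drop-out structure, or any between-subject
covariance beyond the single coupled pair.  Passing tests therefore show
that the pipeline recovers the structure it assumes from data of realistic
size and noise — not that real data satisfy those assumptions.

## Known limitations

* The solver's defect densities are piecewise-linear in time; extremely
  short non-decision times combined with very fast collapses are resolved
  only to O(dt).
* Differential evolution at the reduced preset can under-explore the
  (τ_va, va) ridge for subjects with weak adaptation; the full-budget
  preset resolves this at ~10× the cost.
* The two-stage pupil statistics are conservative relative to trial-level
  mixed models when trial counts differ strongly across subjects.
* BIC is reported but model selection follows AIC-based evidences; with
  ~500-trial sessions BIC's stronger penalty can prefer reduced variants.
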