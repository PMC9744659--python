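# Methods

## Model

`popwarp` models simultaneously recorded spike trains from A brain areas
over C stimulus conditions with R repeated trials each, inside a fixed
analysis window [0, T] after stimulus onset (default T = 500 ms, 2-ms
bins). Per (area, condition), every neuron belongs to one of three latent
groups: an *interacting population* driven by a time-varying log-rate
template f_pop warped and scaled per trial; a *local* population with its
own static time-varying template f_local1; and a constant-rate group
f_local2. Merged group spike trains are treated as discretized Poisson
processes: the expected count in a bin is N_g · exp{f(t_k)} · Δt with Δt in
seconds and f the log rate in spikes/s.

Trial-to-trial variation of the interacting population is captured by three
features per area — a log-gain and a time shift for each of the two
response peaks — applied through a piecewise-linear warp whose join-points
are the identity outside two fixed peak intervals and move each peak
landmark by the trial's shift. The features of all areas stack into a
3A-vector with distribution N(0, Σ) across trials; Σ (inverse-Wishart
prior IW(2Φ₀, 3A+1), Φ₀ diagonal with per-area scales gain 0.3, peak-1
6 ms, peak-2 30 ms) carries all cross-area dependence. Membership
probabilities have a symmetric Dirichlet(5) prior.

### Likelihood convention (and a known limitation)

Spikes are mapped to template coordinates through the inverse warp and
re-binned; a spike contributes the template log-rate of its warped bin, and
the integral term is the template-time integral. There is deliberately no
change-of-variables (Jacobian) term, and the data-time integral of the
warped intensity — which in the generative model varies slightly with the
peak shifts (about −0.08 %/ms of peak-2 shift for the default templates) —
is treated as constant. Two measurable consequences:

* joint template re-estimation and alignment is an overfitting direction
  (sharpening the template and aligning noise spikes to it always raises
  the objective), which is why hard EM is stopped after few iterations
  (below);
* the trial's total spike count leaks into the gain feature a component
  proportional to the peak-2 shift, producing spurious negative
  gain/peak-2 correlation estimates of roughly −0.15 at the default
  simulation scale. This is the dominant systematic error on gain-involved
  feature pairs.

## Fitting

### Initialization

Neurons are ranked by total in-window spike count (merged over conditions
and trials) and split 25 / 50 / 25 into pop / local-1 / local-2. Templates
are penalized-Poisson spline fits from the top and middle groups; the
bottom group sets the constant rate. The roughness weight η is tuned per
(area, condition) by five-fold cross-validation over trials (grid 1…10⁴;
values selected in practice fall between 10 and 10³).

Warp landmarks are found from a deliberately stiff template fit (η = 10⁴,
relaxed stepwise if the stiff fit erases a peak): the two highest-prominence
local maxima give the peak times, and each interval boundary sits where the
rate falls by 70 % of the peak's local prominence, truncated at the valley
between peaks. The stiff fit matters — at the cross-validated η the
trial-averaged curve can carry spurious local maxima that misplace the
second peak by tens of ms. The 70 % fraction (rather than half-prominence)
keeps the warp domains wide enough to express the observed spread of
second-peak times (roughly ±60 ms), which a half-prominence interval of the
trial-blurred initial template would clip.

### Hard EM

E-like steps set memberships to their conditional argmax and each trial's
feature block to its conditional mode (block-coordinate over areas;
exhaustive bin-resolution grid search for the two shifts, whose warp
segments contribute separably, and 1-d Newton for the gain). M-like steps
refit templates on the warped (template-coordinate) spikes, set membership
probabilities to their regularized mode, and update Σ by the
maximum-likelihood rule E[qqᵀ]/(RC) where the expectation is approximated
by the conditional mode plus a Laplace (curvature-based) covariance per
trial. Two deviations from the plainest hard-EM recipe are deliberate:

* **Σ update.** Using the conditional-mode (MAP) update of Σ instead
  divides by RC + 3A + 11, which at RC = 60 shrinks Σ about 25 % per
  iteration; combined with mode-based (already shrunk) feature estimates
  this collapses the feature variance and strands the subsequent sampler in
  a low-variance state it escapes only very slowly. The ML-with-Laplace
  update has no such collapse.
* **Iteration cap.** The default is `em_max_iter = 2`. Because of the
  missing Jacobian, further template/alignment alternations monotonically
  *increase* the objective while measurably *degrading* feature recovery
  (template spikes sharpen and alignment chases noise). Two passes sharpen
  the template once and estimate the features; the sampler does the rest.

After each EM iteration an identifiability normalization moves the
across-trial mean of each area's features into the template: peak landmarks
absorb the mean shifts and the template level absorbs the mean gain
(adding a constant to every spline coefficient adds exactly that constant
to the curve, by partition of unity). Without this, the sampler's recentred
feature proposal (below) starts systematically off-center and stalls.

### Metropolis-within-Gibbs

One cycle updates templates → features → memberships → membership
probabilities → Σ. Proposal covariances are fixed at initialization:
inverse analytic Hessians of the penalized Poisson posterior for the
template blocks, and (prior precision + analytic gain curvature +
grid-profile curvatures of the shift likelihoods) inverted for the feature
blocks, each scaled by 0.05 (the 5.76/d rule at d ≈ 100; the 1-dim constant
block uses 5.76). Eigenvalues are floored at 1e-8 before inversion.
Acceptance rates are logged per block and a warning is emitted outside
[0.2, 0.8]; optional adaptive rescaling is off by default.

The feature proposal for trial r is N(q_r − 0.5·q̄, 0.05·Q) with q̄ the
across-trial mean of the condition; the drift enforces the identifiability
constraint mean(q) = 0. The drift is treated as symmetric in the
acceptance ratio: the exact reverse-density correction is of order
exp(−|q̄|²/proposal scale) and vetoes essentially every move whenever q̄ is
not already negligible, freezing the chain; accepting on the target ratio
alone keeps the chain mobile and self-centering at the cost of an O(q̄)
bias that vanishes as the constraint is satisfied. Candidates whose shifts
leave the open warp domains (2-ms safety margin) have zero target density
and count as rejections. Memberships are exact categorical draws
(log-sum-exp weights over per-neuron group log-likelihoods summed over
trials), membership probabilities exact Dirichlet draws
(N_g + α), and Σ an exact inverse-Wishart draw IW(Ψ₀ + qᵀq, ν₀ + RC).

Default chain settings: 2000 iterations, 500 burn-in, thinning 3 (the
recovery experiment uses 600 / 200 / 2, see below). Chains are
reproducible given a seed and persist to an `.npz` archive with one named
array per variable.

## Posterior summaries

Correlations, partial correlations, and regression slopes are computed
draw-by-draw from Σ; summaries report the median, a kernel-density mode
(Gaussian KDE, Scott bandwidth, 512-point grid), and the 0.025/0.975
quantiles. Per-trial peak times are the template landmark plus the
posterior median of the trial's shift; cross-area lags are their per-trial
differences, summarized across trials. The naive baseline smooths each
single-trial merged train with a penalized Poisson spline (stiffness by
interleaved-bin cross-validation per trial) and takes the argmax in a
configured search window.

## Goodness of fit

Time rescaling maps spike times through the cumulative fitted intensity;
under a correct model the intervals are unit-exponential, truncated by each
trial's total integrated intensity Λ(T). The corrected null is the exact
mixture over trials of Exp(1) truncated at Λ_r(T), and the 95% band is the
Monte-Carlo distribution of KS distances of samples drawn from that null
with matched per-trial interval counts. PSTH overlays report the
integrated absolute discrepancy between the trial-averaged fitted
population intensity and the member-neuron PSTH. Spike-count correlations
are Pearson correlations of per-trial window counts for all cross-area
pairs of population neurons, computed within condition and pooled;
cross-correlograms are count-normalized at integer bin lags.

## Simulator

The generator draws memberships per (neuron, area, condition), features
per (condition, trial) from N(0, Σ) (rejecting and resampling rows whose
shifts leave a warp domain; the rejection rate is logged), and spikes by
per-bin Poisson sampling at the 2-ms analysis resolution with uniform
jitter within bins. Default conditions emulate three-area drifting-gratings
recordings: 15 trials/condition, membership probabilities (0.25, 0.5,
0.25), two-peak templates with bursts near 57 and 216 ms, and feature SDs
gain 0.1, peak-1 5 ms, peak-2 30 ms with cross-area correlations 0.3 / 0.6
/ 0.85. Template rates (baseline 10, peaks 120 and 90 spikes/s/neuron, with
mild deterministic condition-to-condition variation) are calibrated so the
interacting population is a high-rate minority — about a quarter of the
neurons carrying over half the spikes, as reported for such recordings —
giving merged population trains of roughly 100 spikes per 500-ms trial.
Nuisance neurons follow a slow single-bump or constant rate clearly
distinct from the two-peak shape.

Per-neuron intensity noise adds an independent smooth random log-rate curve
per neuron (cubic spline, 10 random coefficients with SD 0.25·√scale,
centered to zero mean so the expected population rate is preserved);
scale 1 produces mild per-neuron count overdispersion comparable to the
trial-to-trial variability of the default simulation, scale 20 is the
stress setting. The template-shape library (sharp, broad, inverted,
rise-to-asymptote) exposes the landmark of each shape (argmax, argmin, or
the half-rise point of the incline), and two matching schemes for locating
a planted landmark in data: a normalized matched filter on fitted curves,
and a profile likelihood over a rigid shift of the reference with the gain
profiled out — the latter attains the Cramér-Rao bound for shift
estimation (about 1 ms SD for the sharp shape and 4 ms for the asymptote
shape at 10 neurons × 15 trials), so residual localization error on any
single replicate reflects the information in the spikes, not the scheme.

What the simulator does **not** emulate: non-Poisson spiking (refractory
or bursty interval statistics), behavioral covariates, condition-dependent
membership drift, electrode or sorting artifacts, and any cross-area
coupling beyond the feature covariance. Passing recovery tests on this
generator therefore demonstrates internal consistency of the estimator
under the model's own assumptions (plus the injected-noise deviation), not
performance on real recordings.

## The recovery experiment and its problem sizes

The recovery harness simulates, fits (hard EM + Gibbs), and summarizes per
correlation pair: bias, RMSE, and 95 %-interval coverage with Monte-Carlo
standard errors. The packaged study conditions are 3 areas, 4 conditions,
15 trials/condition (60 trials total), 30 neurons/area, 20 replicates, and
600 Gibbs iterations (burn-in 200, thinning 2) after the 2-pass hard EM —
sizes chosen so a full study runs in minutes on one CPU while keeping
roughly 8 interacting neurons per area and condition. Point estimates are
posterior medians of the correlation draws.

Two intrinsic limits of this scale are worth keeping in mind when reading
the output: with 60 trials the sampling floor for a zero-true correlation
is about 1/√60 ≈ 0.13 regardless of estimator quality, and the
gain-involved pairs additionally carry the integral-leak bias described
above (the per-trial gain measurement noise, ≈ 1/√count ≈ 0.1, is also
comparable to the true gain SD 0.1, so gain correlations are strongly
prior-shrunk). Both effects scale away with more conditions.

## Numerical choices

* Bins are half-open [t, t+Δt); a spike at exactly T is dropped.
* Activity-ranking ties break toward the smaller neuron id.
* Penalized Poisson fits: damped Newton with step halving, relative
  objective tolerance 1e-8; ridge-least-squares warm start on the log mean
  rate.
* The roughness matrix Ω is the exact second-derivative Gram matrix
  (2-point Gauss-Legendre per knot interval, exact for the
  piecewise-quadratic integrand).
* Degenerate groups (no members) skip their template update; a silent
  low group still gets a finite constant rate (half a pseudo-spike).
* Landmark search requires two local maxima of the stiff initial template;
  otherwise a screening error is raised rather than fitting a meaningless
  warp.
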