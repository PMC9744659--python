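# popwarp

Hierarchical warped point-process modelling of multi-area population spike
trains.

Sensory responses often take the form of brief *population bursts*: short
intervals in which many neurons in an area fire together. When several brain
areas are recorded simultaneously, the trial-by-trial timing of these bursts
— does the second burst in V1 come early on the same trials that it comes
early in LM? — is a sensitive probe of cross-area coordination, but naive
single-trial peak picking from smoothed population rates is far too noisy to
see it. `popwarp` implements a statistical model that denoises burst timing
by pooling all spikes of an *interacting subpopulation* through a shared
rate template, letting only three interpretable features vary per trial and
area, and coupling those features across areas through a latent covariance.

## The model

For area *a*, condition *c*, trial *r*, the merged spike train of neurons in
group *g* is an inhomogeneous Poisson process,

    y_{g,a,r,c}(t) ~ Poisson( N_{g,a,c} · λ_{g,a,r,c}(t) ),

with per-neuron log intensity

    log λ = f_pop(φ⁻¹(t; q_peak1, q_peak2)) + q_gain     (interacting group)
    log λ = f_local1(t)                                  (time-varying nuisance)
    log λ = f_local2                                     (constant nuisance).

Each neuron's group label z_{a,c}(n) is categorical with probabilities
p_{a,c} (Dirichlet prior). The templates f_pop and f_local1 are penalized
cubic B-splines (100 equally spaced knots over the 500-ms window, 102 basis
elements, second-derivative roughness penalty tuned by five-fold
cross-validation). The warp φ is piecewise linear through fixed landmarks
(two peak intervals found at initialization); the trial features
q = (gain, peak-1 shift, peak-2 shift) per area, stacked over A areas into a
3A-vector, follow N(0, Σ) across trials, with an inverse-Wishart prior
IW(2Φ₀, 3A+1) on Σ. All cross-area structure — correlations, partial
correlations, regressions, lags of burst times — follows from the posterior
of Σ and of the per-trial features.

Fitting is hard-EM initialization (activity-ranked membership split
25/50/25, penalized-spline templates, landmark search, conditional-mode
feature updates) followed by Metropolis-within-Gibbs sampling: fixed
curvature-based proposals scaled by 0.05 for the template and feature
blocks, exact conjugate draws for memberships, membership probabilities,
and Σ.

The package also ships the generative simulator (including per-neuron
intensity-noise injection and a template-shape library), the naive
single-trial baseline, a goodness-of-fit battery (time-rescaling KS with a
trial-length-corrected null, PSTH overlays, spike-count-correlation
histograms, cross-correlograms), and a parameter-recovery experiment
harness.

## Worked example

```python
from popwarp.config import ModelConfig, SimulationConfig
from popwarp.synthetic import simulate_dataset
from popwarp.fitting import initialize, hard_em, run_gibbs
from popwarp.inference import correlation_summary

sim = SimulationConfig(n_conditions=4, n_neurons=30, seed=11)
dataset, truth = simulate_dataset(sim)          # 3 areas, 15 trials/condition

model = ModelConfig()
state = initialize(dataset, model)               # memberships, templates, landmarks
hard_em(state)                                   # conditional-mode refinement
chain = run_gibbs(state, n_iter=800, burn_in=250, thin=2, seed=18)

s = correlation_summary(chain, "A1", "peak2", "A2", "peak2")
print(f"peak-2 correlation A1-A2: median {s.median:.2f}, "
      f"95% CI ({s.q025:.2f}, {s.q975:.2f}); truth {truth.corr()[2, 5]:.2f}")
```

Output from this exact run:

```
peak-2 correlation A1-A2: median 0.73, 95% CI (0.60, 0.82); truth 0.85
```

The posterior median recovers most of the strong cross-area coupling of
second-burst times (ground truth 0.85) from 60 trials of simulated spikes
(the remaining attenuation at this small scale is characterized in
`docs/methods.md`); a naive per-trial peak estimate on the same data is
attenuated far below this (see `popwarp.inference.naive_peak_times`).

The same pipeline is available from the shell:

```sh
popwarp simulate --config cfg.yaml --seed 3 --out sim/
popwarp fit sim/spikes.tsv --config cfg.yaml --seed 3 --out fit/
popwarp infer fit/chain.npz --out tables/
popwarp gof fit/chain.npz sim/spikes.tsv --out gofreport/
popwarp recover --config cfg.yaml --seed 1 --out recovery/
```

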