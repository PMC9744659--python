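"""Configuration for the model, priors, sampler, and simulator.

Every constant of the analysis (bin width, window length, knot count, prior
hyperparameters, proposal scale, chain length) lives here with its default,
so nothing is hard-coded deeper in the package.  Configurations round-trip
through YAML for the command-line interface.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class ModelConfig:
    """Model, prior, and sampler settings.

    Attributes
    ----------
    T : float
        Length of the analysis window in ms (spikes aligned to stimulus
        onset; everything outside [0, T] is ignored).
    bin_width : float
        Spike-count bin width in ms.
    n_knots : int
        Number of equally spaced spline knots over [0, T].  ``n_knots``
        knots yield ``n_knots + 2`` cubic B-spline basis elements.
    eta : float
        Smoothness penalty weight for the template log-rates.  The penalized
        objective subtracts ``eta * N * R * beta' Omega beta`` where Omega is
        the second-derivative Gram matrix.  Tunable by five-fold
        cross-validation (:func:`popwarp.splines.cv_select_eta`).
    alpha : float
        Symmetric Dirichlet prior concentration on the membership
        probabilities.
    prior_sd_gain, prior_sd_peak1, prior_sd_peak2 : float
        Scales (per area) used for the diagonal of Phi0; the inverse-Wishart
        scale matrix is Psi0 = 2 * Phi0 with nu0 = 3 * n_areas + 1 degrees
        of freedom, which keeps the prior on the feature covariance diffuse.
    proposal_scale : float
        Scale multiplying the curvature-based proposal covariance in every
        Metropolis-Hastings block (5.76/d with d ~ 100 gives about 0.05).
    landmark_fraction : float
        Peak-interval boundaries are placed where the template rate falls to
        this fraction of the peak's local prominence.
    peak_margin : float
        Safety margin (ms) keeping shifts strictly inside the open warp
        domain so no warp segment degenerates; one bin by default.
    """

    # window / binning
    T: float = 500.0
    bin_width: float = 2.0
    # templates
    n_knots: int = 100
    eta: float = 100.0
    eta_grid: tuple = tuple(10.0 ** e for e in (-2, -1, 0, 1, 2, 3, 4))
    cv_folds: int = 5
    cv_seed: int = 0
    # tune eta per (area, condition) by CV on the initial high-activity group
    cv_eta_init: bool = True
    init_eta_grid: tuple = (1.0, 10.0, 100.0, 1000.0, 10000.0)
    # priors
    alpha: float = 5.0
    prior_sd_gain: float = 0.3
    prior_sd_peak1: float = 6.0
    prior_sd_peak2: float = 30.0
    # initialization
    init_proportions: tuple = (0.25, 0.50, 0.25)  # pop / local-1 / local-2
    # peak-interval boundaries at this fraction of local prominence; 0.7
    # keeps the warp domains wide enough to express the observed range of
    # peak-2 times (95% of trials span roughly +-60 ms around the median,
    # wider than a half-prominence interval of the trial-averaged template)
    landmark_fraction: float = 0.7
    # landmarks come from a deliberately stiff template fit: peak positions
    # and interval boundaries should reflect the coarse burst structure,
    # not trial-level wiggles
    landmark_eta: float = 1e4
    peak_margin: float = 2.0
    # hard EM: few iterations by design -- repeated template refits on
    # self-aligned spikes overfit the alignment (the warped likelihood has
    # no change-of-variables term, so sharpening the template and chasing
    # noise spikes is always profitable); two passes suffice to sharpen the
    # template once and estimate the features
    em_max_iter: int = 2
    em_tol: float = 1e-6
    # Gibbs
    n_iter: int = 2000
    burn_in: int = 500
    thin: int = 3
    proposal_scale: float = 0.05
    adapt_proposals: bool = False
    acceptance_band: tuple = (0.2, 0.8)

    @property
    def n_bins(self) -> int:
        return int(round(self.T / self.bin_width))

    def phi0_diag(self, n_areas: int):
        """Diagonal of Phi0 stacked area-major: (gain, peak1, peak2) per area."""
        per_area = [self.prior_sd_gain ** 2, self.prior_sd_peak1 ** 2,
                    self.prior_sd_peak2 ** 2]
        return per_area * n_areas

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d = {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}
        Path(path).write_text(yaml.safe_dump({"model": d}, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ModelConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        d = raw.get("model", raw)
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - names
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {k: (tuple(v) if isinstance(v, list) else v) for k, v in d.items()}
        return cls(**kwargs)


@dataclass
class SimulationConfig:
    """Ground-truth settings for the generative simulator.

    Defaults emulate the drifting-gratings recordings the model was built
    for: 3 visual areas, 15 trials per condition, two evoked population
    bursts near 57 ms and 216 ms, and about a quarter of neurons in the
    interacting population.  The default feature covariance uses per-area
    SDs (gain 0.1, peak-1 5 ms, peak-2 30 ms) with cross-area correlations
    0.3 (gain), 0.6 (peak-1), and 0.85 (peak-2).
    """

    n_areas: int = 3
    n_conditions: int = 13
    n_trials: int = 15
    n_neurons: int = 90
    membership_probs: tuple = (0.25, 0.50, 0.25)
    # feature distribution
    sd_gain: float = 0.1
    sd_peak1: float = 5.0
    sd_peak2: float = 30.0
    corr_gain: float = 0.3
    corr_peak1: float = 0.6
    corr_peak2: float = 0.85
    # two-peak template shape (per-neuron rates, spikes/s).  The interacting
    # population is a high-rate minority: roughly a quarter of neurons carry
    # about two thirds of the spikes, as in the recordings being emulated.
    baseline_rate: float = 10.0
    peak1_center: float = 57.0
    peak1_rate: float = 120.0
    peak1_width: float = 8.0
    peak2_center: float = 216.0
    peak2_rate: float = 90.0
    peak2_width: float = 25.0
    # nuisance templates
    local1_rate: float = 12.0
    local2_rate: float = 3.0
    # per-neuron intensity noise (0 disables; 1 = calibrated scale)
    neuron_noise_scale: float = 0.0
    seed: int = 0

    def sigma_true(self):
        """Assemble the 9x9 (or 3A x 3A) ground-truth feature covariance."""
        import numpy as np

        A = self.n_areas
        sds = np.tile([self.sd_gain, self.sd_peak1, self.sd_peak2], A)
        corr = np.eye(3 * A)
        rhos = [self.corr_gain, self.corr_peak1, self.corr_peak2]
        for f in range(3):
            for a in range(A):
                for b in range(a + 1, A):
                    i, j = 3 * a + f, 3 * b + f
                    corr[i, j] = corr[j, i] = rhos[f]
        return corr * np.outer(sds, sds)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d = {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}
        Path(path).write_text(yaml.safe_dump({"simulate": d}, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        d = raw.get("simulate", raw)
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - names
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {k: (tuple(v) if isinstance(v, list) else v) for k, v in d.items()}
        return cls(**kwargs)
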