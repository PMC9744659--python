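"""Discretized point-process log-likelihood and intensity assembly.

Templates store log rate in spikes/s; the bin-width conversion to expected
counts happens inside :func:`pp_loglik` (mu = N * exp{f} * dt with dt in
seconds).  The log(y!) constants are retained so log-likelihoods are
comparable across candidate group assignments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from popwarp.warping import WarpSpec, build_warp

GROUPS = ("pop", "local-1", "local-2")


def pp_loglik(counts, mu, include_factorial=True) -> float:
    """Sum_k [ y_k log mu_k - mu_k - log(y_k!) ] for expected counts mu."""
    y = np.asarray(counts, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if np.any(mu <= 0):
        raise ValueError("expected counts must be strictly positive")
    ll = float(np.sum(y * np.log(mu) - mu))
    if include_factorial:
        ll -= float(gammaln(y + 1).sum())
    return ll


@dataclass
class Templates:
    """Per-(area, condition) template: spline coefficients and warp landmarks."""

    beta_pop: np.ndarray
    beta_local1: np.ndarray
    c_local2: float
    warp_spec: WarpSpec


@dataclass
class TemplateSet:
    """Templates for all (area, condition) pairs plus the shared basis."""

    basis: object  # SplineBasis
    entries: dict = field(default_factory=dict)  # (area, condition) -> Templates

    def __getitem__(self, key) -> Templates:
        return self.entries[key]

    def __setitem__(self, key, value: Templates):
        self.entries[key] = value

    def f_pop(self, area, condition) -> np.ndarray:
        return self.basis.B @ self.entries[(area, condition)].beta_pop

    def f_local1(self, area, condition) -> np.ndarray:
        return self.basis.B @ self.entries[(area, condition)].beta_local1


def warped_log_rate(f_grid, grid, warp, t) -> np.ndarray:
    """Evaluate f(phi^{-1}(t)) by linear interpolation of the grid values."""
    u = warp.inverse(np.asarray(t, dtype=float))
    return np.interp(u, grid, f_grid)


def population_intensity(templates: TemplateSet, group, area, condition,
                         q=(0.0, 0.0, 0.0), exposure=1.0) -> np.ndarray:
    """Population rate (spikes/s) per bin for one group on one trial.

    pop: exposure * exp{f_pop(phi^{-1}(t)) + gain}; local-1:
    exposure * exp{f_local1(t)}; local-2: exposure * exp{c_local2}.
    """
    entry = templates[(area, condition)]
    grid = templates.basis.grid
    if group == "pop":
        gain, p1, p2 = q
        warp = build_warp(entry.warp_spec, p1, p2)
        f = warped_log_rate(templates.f_pop(area, condition), grid, warp, grid)
        return exposure * np.exp(f + gain)
    if group == "local-1":
        return exposure * np.exp(templates.f_local1(area, condition))
    if group == "local-2":
        return exposure * np.exp(entry.c_local2) * np.ones_like(grid)
    raise ValueError(f"unknown group {group!r}; expected one of {GROUPS}")


def neuron_loglik_by_group(counts, templates: TemplateSet, area, condition,
                           q=(0.0, 0.0, 0.0), warped_counts=None) -> tuple:
    """Log-likelihood of one neuron's trial under each of the three groups.

    ``counts`` are the neuron's binned counts on the original time axis;
    ``warped_counts`` (if given) are the same spikes re-binned after mapping
    through the inverse warp, used for the pop group so the template stays
    on its own axis.  Exposure is 1 (a single neuron).
    """
    basis = templates.basis
    dt_s = basis.bin_width / 1000.0
    entry = templates[(area, condition)]
    gain, p1, p2 = q
    if warped_counts is None:
        # re-bin via the inverse warp applied to bin centers' spike mass is
        # not exact; callers on real spikes should pass warped_counts.
        warp = build_warp(entry.warp_spec, p1, p2)
        f = warped_log_rate(templates.f_pop(area, condition), basis.grid, warp,
                            basis.grid)
        ll_pop = pp_loglik(counts, np.exp(f + gain) * dt_s)
    else:
        f = templates.f_pop(area, condition)
        ll_pop = pp_loglik(warped_counts, np.exp(f + gain) * dt_s)
    ll_l1 = pp_loglik(counts, np.exp(templates.f_local1(area, condition)) * dt_s)
    ll_l2 = pp_loglik(counts, np.exp(entry.c_local2) * dt_s * np.ones(len(counts)))
    return (ll_pop, ll_l1, ll_l2)
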