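"""Goodness-of-fit battery: time-rescaling KS with trial-length truncation
correction, PSTH overlays, spike-count-correlation histograms, and
cross-correlograms.

The time-rescaling theorem says that under a correct intensity, rescaled
inter-spike intervals u_i = Lambda(s_i) - Lambda(s_{i-1}) are unit
exponential; because a trial of finite length only exposes intervals up to
the trial's total integrated intensity Lambda(T), the null distribution is
corrected to a mixture over trials of Exp(1) truncated at Lambda(T_r).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from popwarp.data import population_train, psth


def time_rescale(spike_times, intensity, bin_width, window=(0.0, 500.0)):
    """Rescaled inter-spike intervals for one trial.

    ``intensity`` is the fitted rate (spikes/s) at bin centers.  The
    cumulative integral Lambda is the trapezoid rule on the bin grid
    (linear interpolation between centers, constant extension at the
    edges).  Returns ``(intervals, Lambda_T)``; an empty trial yields no
    intervals but still reports its truncation point.
    """
    lam = np.asarray(intensity, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("intensity must be strictly positive")
    lo, hi = window
    K = lam.size
    centers = lo + (np.arange(K) + 0.5) * bin_width
    knots = np.concatenate([[lo], centers, [hi]])
    vals = np.concatenate([[lam[0]], lam, [lam[-1]]]) / 1000.0  # per ms
    cum = np.concatenate([[0.0], np.cumsum(np.diff(knots)
                                           * 0.5 * (vals[:-1] + vals[1:]))])
    t = np.sort(np.asarray(spike_times, dtype=float))
    Lam = np.interp(np.concatenate([[lo], t, [hi]]), knots, cum)
    total = float(Lam[-1])
    if t.size == 0:
        return np.empty(0), total
    u = np.diff(Lam[:-1])  # intervals from trial start through last spike
    return u, total


def truncated_exp_mixture_cdf(u, lambda_totals, weights=None):
    """CDF of the mixture over trials of Exp(1) truncated at Lambda(T_r)."""
    u = np.atleast_1d(np.asarray(u, dtype=float))
    lt = np.asarray(lambda_totals, dtype=float)
    w = (np.ones(lt.size) if weights is None
         else np.asarray(weights, dtype=float))
    w = w / w.sum()
    denom = -np.expm1(-lt)                     # 1 - exp(-Lambda_T)
    num = -np.expm1(-np.minimum(u[:, None], lt[None, :]))
    return (num / denom) @ w


@dataclass
class KSResult:
    statistic: float
    band: float
    null_quantiles: np.ndarray
    n_intervals: int

    @property
    def within_band(self) -> bool:
        return self.statistic <= self.band


def ks_plot_corrected(intervals_by_trial, lambda_totals, n_mc=500, seed=0,
                      level=0.95) -> KSResult:
    """KS distance of the rescaled intervals against the corrected null.

    The null CDF is the truncated-exponential mixture over trials; the
    acceptance band is the ``level`` quantile of KS distances of samples
    simulated from that corrected null (matched interval counts per trial).
    """
    groups = [np.asarray(g, dtype=float) for g in intervals_by_trial]
    lt = np.asarray(lambda_totals, dtype=float)
    counts = np.array([g.size for g in groups])
    all_u = np.concatenate(groups) if groups else np.empty(0)
    n = all_u.size
    if n < 10:
        warnings.warn("fewer than 10 rescaled intervals: KS test has low power",
                      stacklevel=2)
    if n == 0:
        return KSResult(np.nan, np.nan, np.empty(0), 0)
    weights = counts / counts.sum()

    def ks_of(sample):
        s = np.sort(sample)
        F = truncated_exp_mixture_cdf(s, lt, weights)
        emp_hi = np.arange(1, s.size + 1) / s.size
        emp_lo = np.arange(0, s.size) / s.size
        return float(np.max(np.maximum(np.abs(F - emp_hi), np.abs(F - emp_lo))))

    stat = ks_of(all_u)
    rng = np.random.default_rng(seed)
    null_stats = np.empty(n_mc)
    for m in range(n_mc):
        sim = []
        for cnt, tot in zip(counts, lt):
            if cnt == 0:
                continue
            v = rng.uniform(0, -np.expm1(-tot), size=cnt)
            sim.append(-np.log1p(-v))
        null_stats[m] = ks_of(np.concatenate(sim))
    band = float(np.quantile(null_stats, level))
    return KSResult(statistic=stat, band=band, null_quantiles=null_stats,
                    n_intervals=n)


def psth_overlay(dataset, fitted_intensity_by_trial, member_ids, condition,
                 bin_width=2.0):
    """Integrated absolute discrepancy between fitted and empirical rates.

    ``fitted_intensity_by_trial`` is an (R, K) array of population rates
    (spikes/s, whole population); the empirical side is the member-neuron
    PSTH scaled to the population.  Returns (discrepancy in spikes,
    fitted mean curve, empirical curve) -- the discrepancy is the integral
    over the window of |mean fitted - empirical population rate|.
    """
    fitted = np.atleast_2d(np.asarray(fitted_intensity_by_trial, dtype=float))
    emp = psth(dataset, member_ids, condition, bin_width) * len(list(member_ids))
    mean_fit = fitted.mean(axis=0)
    dt_s = bin_width / 1000.0
    disc = float(np.sum(np.abs(mean_fit - emp)) * dt_s)
    return disc, mean_fit, emp


def spike_count_correlations(dataset, members_by_area, area_a, area_b,
                             conditions=None) -> np.ndarray:
    """Pearson correlations of per-trial spike counts for all cross-area
    pairs of population neurons, computed within condition and pooled."""
    conditions = conditions if conditions is not None else dataset.conditions
    vals = []
    for c in conditions:
        trials = dataset.trials(c)
        counts = {}
        for area in (area_a, area_b):
            ids = members_by_area[area]
            M = np.zeros((len(ids), len(trials)))
            for j, r in enumerate(trials):
                for i, nid in enumerate(ids):
                    M[i, j] = dataset.spike_times(nid, c, r).size
            counts[area] = M
        Ma, Mb = counts[area_a], counts[area_b]
        sa = Ma.std(axis=1)
        sb = Mb.std(axis=1)
        Za = (Ma - Ma.mean(axis=1, keepdims=True))
        Zb = (Mb - Mb.mean(axis=1, keepdims=True))
        R = len(trials)
        C = (Za @ Zb.T) / R
        denom = np.outer(sa, sb)
        with np.errstate(invalid="ignore", divide="ignore"):
            rho = C / denom
        vals.append(rho[np.isfinite(rho)].ravel())
    return np.concatenate(vals) if vals else np.empty(0)


def spike_count_corr_fit(dataset, simulated_datasets, members_by_area,
                         area_a, area_b) -> dict:
    """Empirical vs model-simulated spike-count-correlation distributions.

    ``simulated_datasets`` are datasets simulated from posterior draws; the
    same pooled pairwise statistic is computed on each and concatenated.
    """
    emp = spike_count_correlations(dataset, members_by_area, area_a, area_b)
    sim = [spike_count_correlations(ds, mem, area_a, area_b)
           for ds, mem in simulated_datasets]
    return {"empirical": emp,
            "model": np.concatenate(sim) if sim else np.empty(0)}


def cross_correlogram(train1, train2, max_lag) -> pd.DataFrame:
    """Count-normalized cross-correlation at integer bin lags.

    corr(l) = sum_k x_k y_{k+l} / sqrt(sum x^2 sum y^2) for lags in
    [-max_lag, max_lag]; equal-length binned trains required.
    """
    x = np.asarray(train1, dtype=float)
    y = np.asarray(train2, dtype=float)
    if x.shape != y.shape:
        raise ValueError("trains must have equal length")
    norm = np.sqrt((x ** 2).sum() * (y ** 2).sum())
    lags = np.arange(-max_lag, max_lag + 1)
    vals = np.empty(lags.size)
    for idx, lag in enumerate(lags):
        if lag >= 0:
            vals[idx] = float(x[: x.size - lag] @ y[lag:])
        else:
            vals[idx] = float(x[-lag:] @ y[: y.size + lag])
    vals = vals / norm if norm > 0 else vals
    return pd.DataFrame({"lag": lags, "correlation": vals})


def gof_report(dataset, chain, templates_intensity, out_prefix=None) -> pd.DataFrame:
    """Machine-readable GOF summary (one row per area/condition statistic)."""
    rows = []
    for (a, c), spec in chain.warp_specs.items():
        members = [nid for nid, keep in
                   zip(chain.neuron_ids[(a, c)],
                       np.median(chain.z[(a, c)] == 0, axis=0) > 0.5) if keep]
        if not members:
            continue
        fitted = templates_intensity[(a, c)]
        disc, _, _ = psth_overlay(dataset, fitted, members, c)
        rows.append((a, c, "psth_discrepancy", disc))
    return pd.DataFrame(rows, columns=["area", "condition", "statistic", "value"])
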