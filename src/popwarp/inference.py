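"""Posterior summaries: correlations, partial correlations, peak times and
cross-area lags, the naive single-trial baseline, and Fisher-z intervals.

Every functional of the feature covariance (correlation, partial
correlation, regression slope) is applied draw-by-draw to the posterior
chain, so point estimates and interval endpoints come directly from the
posterior sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde, norm

from popwarp.data import population_train
from popwarp.splines import build_basis, build_penalty, fit_penalized_poisson


def corr_from_sigma(sigma) -> np.ndarray:
    """Correlation matrix rho_ij = Sigma_ij / sqrt(Sigma_ii Sigma_jj)."""
    sigma = np.asarray(sigma, dtype=float)
    d = np.diag(sigma)
    if np.any(d <= 0):
        raise ValueError("zero or negative variance in Sigma")
    s = np.sqrt(d)
    return sigma / np.outer(s, s)


def partial_corr(sigma, i, j, k) -> float:
    """Partial correlation of variables i and j given k (scalar or vector).

    For scalar k this is the classic recursion
    (rho_ij - rho_ik rho_jk) / sqrt((1 - rho_ik^2)(1 - rho_jk^2)); for
    vector k the inverse of the covariance of (i, j, k) is used.
    """
    rho = corr_from_sigma(sigma)
    ks = np.atleast_1d(k)
    if ks.size == 1:
        k0 = int(ks[0])
        rik, rjk = rho[i, k0], rho[j, k0]
        if abs(rik) >= 1.0 or abs(rjk) >= 1.0:
            raise ValueError("conditioning variable perfectly correlated")
        return float((rho[i, j] - rik * rjk)
                     / np.sqrt((1 - rik ** 2) * (1 - rjk ** 2)))
    idx = [i, j] + [int(v) for v in ks]
    sub = np.asarray(sigma)[np.ix_(idx, idx)]
    prec = np.linalg.inv(sub)
    return float(-prec[0, 1] / np.sqrt(prec[0, 0] * prec[1, 1]))


def regression_slope(sigma, y, x) -> float:
    """Slope of the regression of variable y on variable x from Sigma."""
    sigma = np.asarray(sigma, dtype=float)
    return float(sigma[y, x] / sigma[x, x])


@dataclass
class PosteriorSummary:
    samples: np.ndarray
    median: float
    mode: float
    q025: float
    q975: float

    @property
    def interval(self) -> tuple:
        return (self.q025, self.q975)


def _kde_mode(samples) -> float:
    s = np.asarray(samples, dtype=float)
    if np.ptp(s) < 1e-12:
        return float(s[0])
    kde = gaussian_kde(s)  # Scott's rule-of-thumb bandwidth
    grid = np.linspace(s.min(), s.max(), 512)
    return float(grid[int(np.argmax(kde(grid)))])


def posterior_functionals(chain, functional, over="sigma") -> PosteriorSummary:
    """Apply a functional to each posterior draw and summarize.

    ``functional`` receives one Sigma draw (``over='sigma'``) or one q draw
    of shape (C, R, 3A) (``over='q'``).  Returns samples, median, KDE mode,
    and the (0.025, 0.975) quantile interval.
    """
    draws = chain.sigma if over == "sigma" else chain.q
    if draws.shape[0] < 100:
        import warnings

        warnings.warn(f"only {draws.shape[0]} kept draws; posterior summaries "
                      "may be unstable", stacklevel=2)
    samples = np.array([functional(d) for d in draws], dtype=float)
    return PosteriorSummary(
        samples=samples,
        median=float(np.median(samples)),
        mode=_kde_mode(samples),
        q025=float(np.quantile(samples, 0.025)),
        q975=float(np.quantile(samples, 0.975)),
    )


def correlation_summary(chain, area_i, feat_i, area_j, feat_j) -> PosteriorSummary:
    """Posterior summary of one pairwise feature correlation."""
    i = chain.feature_index(area_i, feat_i)
    j = chain.feature_index(area_j, feat_j)
    return posterior_functionals(chain, lambda s: corr_from_sigma(s)[i, j])


def correlation_table(chain) -> pd.DataFrame:
    """Median/mode/q025/q975 for all pairwise feature correlations."""
    nf = chain.n_features
    feats = ["gain", "peak1", "peak2"]
    labels = [f"{a}:{f}" for a in chain.areas for f in feats]
    rows = []
    for i in range(nf):
        for j in range(i + 1, nf):
            s = posterior_functionals(chain, lambda m: corr_from_sigma(m)[i, j])
            rows.append((f"{labels[i]}|{labels[j]}", s.median, s.mode,
                         s.q025, s.q975))
    return pd.DataFrame(rows, columns=["pair", "median", "mode", "q025", "q975"])


def peak_times_and_lags(chain) -> dict:
    """Per-trial peak-time estimates and cross-area lag distributions.

    Per trial, the peak-k time in area a is the template landmark
    tpeak_k(a, c) plus the posterior median of the trial's peak-k shift;
    per-trial lags are differences of those peak times.  Summaries are the
    median and (0.025, 0.975) quantiles across trials.
    """
    q_med = np.median(chain.q, axis=0)          # (C, R, 3A)
    out = {"peak_times": {}, "lags": {}, "summaries": {}}
    for ai, a in enumerate(chain.areas):
        for k, feat in ((1, "peak1"), (2, "peak2")):
            col = 3 * ai + k
            times = []
            for ci, c in enumerate(chain.conditions):
                spec = chain.warp_specs[(a, c)]
                tpk = spec.tpeak1 if k == 1 else spec.tpeak2
                times.append(tpk + q_med[ci, :, col])
            times = np.concatenate(times)
            out["peak_times"][(a, feat)] = times
            out["summaries"][(a, feat)] = (
                float(np.median(times)),
                float(np.quantile(times, 0.025)),
                float(np.quantile(times, 0.975)))
    for k, feat in ((1, "peak1"), (2, "peak2")):
        for ai, a in enumerate(chain.areas):
            for bi, b in enumerate(chain.areas):
                if bi <= ai:
                    continue
                lag = (out["peak_times"][(b, feat)]
                       - out["peak_times"][(a, feat)])
                out["lags"][(a, b, feat)] = lag
                out["summaries"][(a, b, feat)] = (
                    float(np.median(lag)),
                    float(np.quantile(lag, 0.025)),
                    float(np.quantile(lag, 0.975)))
    return out


def summary_table(summaries: dict) -> pd.DataFrame:
    rows = []
    for key, (med, lo, hi) in summaries["summaries"].items():
        rows.append(("|".join(str(k) for k in key), med, lo, hi))
    return pd.DataFrame(rows, columns=["statistic", "median", "q025", "q975"])


# ---------------------------------------------------------------------------
# naive single-trial baseline
# ---------------------------------------------------------------------------

@dataclass
class NaiveSmoothing:
    """Settings for the naive per-trial spline-smoothed PSTH peak finder."""

    n_knots: int = 25
    eta_grid: tuple = (1e-6, 1e-5, 1e-4, 1e-3)
    n_folds: int = 5
    window: tuple = (150.0, 330.0)     # peak search window (peak-2 by default)


def naive_peak_times(dataset, member_ids, condition=None, smoothing=None,
                     bin_width=2.0) -> pd.DataFrame:
    """Per-trial peak time from a spline-smoothed single-trial population PSTH.

    For each trial the merged population train is fitted with a penalized
    Poisson spline (stiffness chosen per trial by k-fold cross-validation
    over interleaved bin folds) and the argmax within the configured search
    window is returned (ties -> earliest).  Empty trials yield NaN.
    """
    sm = smoothing or NaiveSmoothing()
    T = dataset.window[1]
    basis = build_basis(T=T, n_knots=sm.n_knots, bin_width=bin_width)
    penalty = build_penalty(basis)
    conditions = [condition] if condition is not None else dataset.conditions
    ids = list(member_ids)
    rows = []
    lo, hi = sm.window
    grid = basis.grid
    in_win = (grid >= lo) & (grid <= hi)
    for c in conditions:
        for r in dataset.trials(c):
            train = population_train(dataset, ids, c, r, bin_width)
            if train.total == 0:
                rows.append((c, r, np.nan))
                continue
            eta = _cv_eta_bins(train.counts, basis, penalty, sm, len(ids))
            beta = fit_penalized_poisson(train.counts, basis, penalty, eta,
                                         exposure=len(ids))
            f = basis.B @ beta
            k = int(np.argmax(f[in_win]))
            rows.append((c, r, float(grid[in_win][k])))
    return pd.DataFrame(rows, columns=["condition_id", "trial_id", "peak_time"])


def _cv_eta_bins(counts, basis, penalty, sm, exposure):
    """Stiffness by deterministic interleaved-bin cross-validation."""
    if len(sm.eta_grid) == 1:
        return sm.eta_grid[0]
    K = len(counts)
    folds = [np.arange(f, K, sm.n_folds) for f in range(sm.n_folds)]
    dt_s = basis.bin_width / 1000.0
    best, best_score = sm.eta_grid[0], -np.inf
    for eta in sm.eta_grid:
        score = 0.0
        for fold in folds:
            mask = np.ones(K, bool)
            mask[fold] = False
            w = counts.astype(float).copy()
            # fit on the training bins only by zero-weighting held-out bins
            beta = _fit_masked(w, mask, basis, penalty, eta, exposure)
            f = basis.B @ beta
            mu = exposure * np.exp(f[fold]) * dt_s
            score += float(np.sum(counts[fold] * np.log(mu) - mu))
        if score > best_score:
            best, best_score = eta, score
    return best


def _fit_masked(counts, mask, basis, penalty, eta, exposure):
    import numpy as _np

    sub_B = basis.B[mask]
    dt_s = basis.bin_width / 1000.0
    y = counts[mask]
    pen_w = 2.0 * eta * exposure
    beta = _np.zeros(basis.n_basis)
    obj_prev = -_np.inf
    for _ in range(60):
        f = _np.clip(sub_B @ beta, -30.0, 30.0)
        mu = exposure * dt_s * _np.exp(f)
        grad = sub_B.T @ (y - mu) - pen_w * (penalty.omega @ beta)
        H = (sub_B.T * mu) @ sub_B + pen_w * penalty.omega
        H[_np.diag_indices_from(H)] += 1e-6 * (1.0 + mu.mean())
        try:
            step = _np.linalg.solve(H, grad)
        except _np.linalg.LinAlgError:
            break
        t = 1.0
        for _ in range(30):
            cand = beta + t * step
            fc = _np.clip(sub_B @ cand, -30.0, 30.0)
            obj = float(y @ fc - exposure * dt_s * _np.exp(fc).sum()
                        - 0.5 * pen_w * cand @ penalty.omega @ cand)
            if _np.isfinite(obj) and obj >= obj_prev - 1e-9:
                break
            t *= 0.5
        beta, obj_new = cand, obj
        if abs(obj_new - obj_prev) < 1e-8 * (abs(obj_prev) + 1):
            break
        obj_prev = obj_new
    return beta


def fisher_z_ci(r, n, level=0.95) -> tuple:
    """Confidence interval for a correlation via the Fisher z transform.

    z = atanh(r) is approximately normal with SD 1/sqrt(n - 3); the interval
    is back-transformed by tanh, so endpoints stay strictly inside (-1, 1).
    """
    if n <= 3:
        raise ValueError("need n > 3 for the Fisher z interval")
    if abs(r) >= 1.0:
        return (float(r), float(r))
    zc = norm.ppf(0.5 + level / 2.0)
    z = np.arctanh(r)
    half = zc / np.sqrt(n - 3)
    return (float(np.tanh(z - half)), float(np.tanh(z + half)))
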