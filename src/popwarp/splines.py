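"""Cubic B-spline bases, second-derivative roughness penalties, and
penalized Poisson template fitting.

Templates are log firing rates f = B beta in spikes/s on the bin grid.
``n_knots`` equally spaced knot sites over [0, T], with full multiplicity at
the boundaries, give ``n_knots + 2`` cubic basis elements (100 knots -> 102).
The roughness penalty is the exact Gram matrix of second derivatives,
Omega_ij = int f_i'' f_j'', computed by Gauss-Legendre quadrature per knot
interval (exact for the piecewise-quadratic integrand).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline
from scipy.special import gammaln

DEGREE = 3  # cubic


@dataclass
class SplineBasis:
    knots: np.ndarray          # full knot vector with boundary multiplicity
    sites: np.ndarray          # the distinct, equally spaced knot sites
    grid: np.ndarray           # bin centers where B is evaluated
    B: np.ndarray              # (n_bins, n_basis) design matrix
    bin_width: float
    T: float

    @property
    def n_basis(self) -> int:
        return self.B.shape[1]

    def design(self, x) -> np.ndarray:
        """Dense design matrix of the basis at arbitrary points in [0, T]."""
        x = np.clip(np.asarray(x, dtype=float), 0.0, self.T)
        return BSpline.design_matrix(x, self.knots, DEGREE).toarray()

    def evaluate(self, beta, x=None) -> np.ndarray:
        if x is None:
            return self.B @ beta
        return self.design(x) @ beta


def build_basis(T=500.0, n_knots=100, bin_width=2.0) -> SplineBasis:
    """Cubic B-spline basis on ``n_knots`` equally spaced knots over [0, T]."""
    if n_knots < 4:
        raise ValueError("need at least 4 knots for a cubic basis")
    sites = np.linspace(0.0, T, n_knots)
    knots = np.concatenate([[0.0] * DEGREE, sites, [T] * DEGREE])
    n_bins = int(round(T / bin_width))
    grid = (np.arange(n_bins) + 0.5) * bin_width
    B = BSpline.design_matrix(grid, knots, DEGREE).toarray()
    return SplineBasis(knots=knots, sites=sites, grid=grid, B=B,
                       bin_width=float(bin_width), T=float(T))


@dataclass
class PenaltyMatrix:
    omega: np.ndarray

    @property
    def n_basis(self) -> int:
        return self.omega.shape[0]


def build_penalty(basis: SplineBasis) -> PenaltyMatrix:
    """Second-derivative Gram matrix Omega_ij = int_0^T f_i''(x) f_j''(x) dx.

    Second derivatives of cubic B-splines are piecewise linear, so their
    products are piecewise quadratic and 2-point Gauss-Legendre per knot
    interval integrates them exactly.  Omega is symmetric PSD with straight
    lines in its nullspace.
    """
    nb = basis.n_basis
    spl2 = BSpline(basis.knots, np.eye(nb), DEGREE).derivative(2)
    nodes, weights = np.polynomial.legendre.leggauss(2)
    omega = np.zeros((nb, nb))
    for a, b in zip(basis.sites[:-1], basis.sites[1:]):
        mid, half = 0.5 * (a + b), 0.5 * (b - a)
        x = mid + half * nodes
        D = spl2(x)                          # (2, nb)
        omega += half * (D.T * weights) @ D
    omega = 0.5 * (omega + omega.T)
    return PenaltyMatrix(omega=omega)


def penalized_poisson_loglik(beta, counts, basis, penalty, eta, offsets,
                             exposure, include_factorial=False):
    """Penalized log-likelihood Sum_r l(y_r, N exp{B beta + g_r} dt) - eta*N*R*beta'Omega beta."""
    counts = np.atleast_2d(counts)
    R = counts.shape[0]
    offsets = np.zeros(R) if offsets is None else np.asarray(offsets, dtype=float)
    dt_s = basis.bin_width / 1000.0
    f = basis.B @ beta
    log_mu = f[None, :] + offsets[:, None] + np.log(exposure * dt_s)
    ll = float(np.sum(counts * log_mu) - np.sum(np.exp(log_mu)))
    if include_factorial:
        ll -= float(gammaln(counts + 1).sum())
    pen = eta * exposure * R * float(beta @ penalty.omega @ beta)
    return ll - pen


def fit_penalized_poisson(counts, basis, penalty, eta, offsets=None,
                          exposure=1.0, beta0=None, max_iter=100, tol=1e-8):
    """Maximize the penalized Poisson log-likelihood over spline coefficients.

    Parameters
    ----------
    counts : (R, K) or (K,) array
        Spike counts per trial and bin.
    offsets : (R,) array, optional
        Per-trial additive log-rate offsets (gains).
    exposure : float
        Number of merged neurons N; expected counts are
        N * exp(B beta + offset) * dt with dt in seconds.

    Damped Newton iterations with step halving; converged when the relative
    objective change falls below ``tol``.
    """
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    R, K = counts.shape
    if eta < 0:
        raise ValueError("eta must be nonnegative")
    offs = np.zeros(R) if offsets is None else np.asarray(offsets, dtype=float)
    dt_s = basis.bin_width / 1000.0
    B, omega = basis.B, penalty.omega
    pen_w = 2.0 * eta * exposure * R

    if beta0 is None:
        # ridge LS on the log of the (lightly smoothed) mean rate
        mean_rate = counts.sum(0) / (R * exposure * dt_s * np.exp(offs).mean())
        target = np.log(np.maximum(mean_rate, np.maximum(mean_rate[mean_rate > 0].min()
                                                         if (mean_rate > 0).any() else 1.0, 1e-3) * 0.1))
        A = B.T @ B + 1e-6 * np.eye(B.shape[1]) + pen_w * omega
        beta = np.linalg.solve(A, B.T @ target)
    else:
        beta = np.asarray(beta0, dtype=float).copy()

    def objective(b):
        return penalized_poisson_loglik(b, counts, basis, penalty, eta, offs, exposure)

    obj = objective(beta)
    if not np.isfinite(obj):
        raise FloatingPointError("non-finite penalized objective at start")
    y_sum = counts.sum(0)
    eoffs = np.exp(offs).sum()
    for _ in range(max_iter):
        f = B @ beta
        mu_sum = exposure * dt_s * eoffs * np.exp(f)       # summed over trials
        grad = B.T @ (y_sum - mu_sum) - pen_w * (omega @ beta)
        H = (B.T * mu_sum) @ B + pen_w * omega
        H[np.diag_indices_from(H)] += 1e-10
        step = np.linalg.solve(H, grad)
        # damped update
        t = 1.0
        for _ in range(40):
            cand = beta + t * step
            new = objective(cand)
            if np.isfinite(new) and new >= obj - 1e-12:
                break
            t *= 0.5
        else:
            break
        beta, prev, obj = cand, obj, new
        if abs(obj - prev) <= tol * (abs(prev) + 1.0):
            break
    if not np.isfinite(obj):
        raise FloatingPointError("penalized Poisson fit diverged")
    return beta


def fit_constant_rate(counts, exposure, bin_width):
    """MLE of a constant log-rate (spikes/s): log(total / (N * R * T_s))."""
    counts = np.atleast_2d(counts)
    R, K = counts.shape
    dt_s = bin_width / 1000.0
    total = counts.sum()
    rate = max(total, 0.5) / (exposure * R * K * dt_s)  # 0.5 guards silent groups
    return float(np.log(rate))


def cv_select_eta(counts, basis, penalty, grid, offsets=None, exposure=1.0,
                  n_folds=5, seed=0):
    """Pick eta maximizing mean held-out Poisson log-likelihood over trial folds.

    Trials are split into ``n_folds`` folds by a deterministic seeded
    shuffle; for each grid value the model is fitted on the training trials
    and scored (unpenalized, per trial) on the held-out trials.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("empty eta grid")
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    R = counts.shape[0]
    if len(grid) == 1:
        return grid[0]
    if R < n_folds:
        raise ValueError("need at least n_folds trials for cross-validation")
    offs = np.zeros(R) if offsets is None else np.asarray(offsets, dtype=float)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(R)
    folds = np.array_split(perm, n_folds)
    dt_s = basis.bin_width / 1000.0
    scores = []
    for eta in grid:
        held = 0.0
        for fold in folds:
            train = np.setdiff1d(perm, fold)
            beta = fit_penalized_poisson(counts[train], basis, penalty, eta,
                                         offsets=offs[train], exposure=exposure)
            f = basis.B @ beta
            log_mu = f[None, :] + offs[fold, None] + np.log(exposure * dt_s)
            held += float(np.sum(counts[fold] * log_mu) - np.sum(np.exp(log_mu)))
        scores.append(held / R)
    return grid[int(np.argmax(scores))]
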