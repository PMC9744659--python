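"""Initialization, hard EM, and the Metropolis-within-Gibbs sampler.

The sampler state couples, per (area, condition): the population template
(spline coefficients beta_pop), a time-varying nuisance template
(beta_local1), a constant nuisance log-rate (c_local2), the neuron
memberships z and probabilities p; per (condition, trial): the feature
vector q (gain and two peak shifts per area, stacked area-major); and
globally the feature covariance Sigma with an inverse-Wishart prior.

One Gibbs cycle updates templates -> q -> z -> p -> Sigma.  Template and
feature blocks are Metropolis-Hastings with fixed curvature-based proposal
covariances scaled by 0.05; z, p, and Sigma are exact conjugate draws.

Likelihood convention: spikes are mapped to template coordinates through
the inverse warp and re-binned (no Jacobian term), so a spike's
contribution is the template log-rate in its warped bin.  This is the same
discretized likelihood everywhere (template, feature, and membership
updates), which keeps the blocks mutually consistent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from scipy.stats import invwishart

from popwarp.splines import (build_basis, build_penalty, fit_constant_rate,
                             fit_penalized_poisson)
from popwarp.warping import WarpSpec

logger = logging.getLogger(__name__)

GROUP_POP, GROUP_L1, GROUP_L2 = 0, 1, 2


class ScreeningError(RuntimeError):
    """Raised when an initial population template lacks a usable peak pattern."""


# ---------------------------------------------------------------------------
# states
# ---------------------------------------------------------------------------

@dataclass
class MembershipState:
    z: dict        # (area, cond) -> (N,) int8 in {0: pop, 1: local-1, 2: local-2}
    p: dict        # (area, cond) -> (3,) probabilities

    def counts(self, key):
        return np.bincount(self.z[key], minlength=3)


@dataclass
class CovarianceState:
    sigma: np.ndarray     # (3A, 3A) feature covariance
    psi0: np.ndarray      # inverse-Wishart scale (= 2 * Phi0)
    nu0: float            # degrees of freedom (= 3A + 1 per area count A... 3*A+1)
    alpha: float          # Dirichlet concentration


@dataclass
class ProposalState:
    """Fixed proposal covariances (Cholesky factors), estimated once."""

    chol_beta_pop: dict = field(default_factory=dict)   # (a,c) -> (nb, nb)
    chol_beta_l1: dict = field(default_factory=dict)
    sd_l2: dict = field(default_factory=dict)           # (a,c) -> float
    chol_q: dict = field(default_factory=dict)          # (c, r) -> (3A, 3A)
    prec_chol_q: dict = field(default_factory=dict)     # inverse factors for densities
    scale: float = 0.05


@dataclass
class PosteriorChain:
    """Kept Gibbs draws plus acceptance-rate logs and fit metadata."""

    areas: list
    conditions: list
    n_trials: int
    sigma: np.ndarray            # (n_keep, 3A, 3A)
    q: np.ndarray                # (n_keep, C, R, 3A)
    p: dict                      # (a, c) -> (n_keep, 3)
    z: dict                      # (a, c) -> (n_keep, N) int8
    beta_pop: dict               # (a, c) -> (n_keep, nb)
    beta_local1: dict
    c_local2: dict               # (a, c) -> (n_keep,)
    warp_specs: dict             # (a, c) -> WarpSpec
    neuron_ids: dict             # (a, c) -> list of neuron ids
    acceptance: dict             # block name -> rate
    burn_in: int = 0
    thin: int = 1

    @property
    def n_draws(self) -> int:
        return self.sigma.shape[0]

    @property
    def n_features(self) -> int:
        return self.sigma.shape[1]

    def feature_index(self, area, feature) -> int:
        """Column of (area, feature) in the stacked vector; feature in
        {'gain','peak1','peak2'}."""
        a = self.areas.index(area)
        f = {"gain": 0, "peak1": 1, "peak2": 2}[feature]
        return 3 * a + f

    # --- persistence -------------------------------------------------------
    def save(self, path) -> None:
        arrays = {"sigma": self.sigma, "q": self.q,
                  "burn_in": np.array(self.burn_in), "thin": np.array(self.thin),
                  "n_trials": np.array(self.n_trials)}
        meta = {"areas": [str(a) for a in self.areas],
                "conditions": [str(c) for c in self.conditions]}
        for (a, c), v in self.p.items():
            tag = f"{a}__{c}"
            arrays[f"p__{tag}"] = v
            arrays[f"z__{tag}"] = self.z[(a, c)]
            arrays[f"beta_pop__{tag}"] = self.beta_pop[(a, c)]
            arrays[f"beta_local1__{tag}"] = self.beta_local1[(a, c)]
            arrays[f"c_local2__{tag}"] = self.c_local2[(a, c)]
            spec = self.warp_specs[(a, c)]
            arrays[f"warp__{tag}"] = np.array([spec.t1l, spec.tpeak1, spec.t1r,
                                               spec.t2l, spec.tpeak2, spec.t2r,
                                               spec.T])
            arrays[f"neurons__{tag}"] = np.asarray(self.neuron_ids[(a, c)])
        arrays["accept_names"] = np.array(sorted(self.acceptance), dtype="U64")
        arrays["accept_rates"] = np.array(
            [self.acceptance[k] for k in sorted(self.acceptance)])
        arrays["areas"] = np.array(meta["areas"], dtype="U32")
        arrays["conditions"] = np.array(meta["conditions"], dtype="U32")
        np.savez_compressed(path, **arrays)

    @classmethod
    def load(cls, path) -> "PosteriorChain":
        with np.load(path, allow_pickle=False) as npz:
            areas = list(npz["areas"])
            conditions = list(npz["conditions"])
            p, z, bp, b1, c2, specs, neurons = {}, {}, {}, {}, {}, {}, {}
            for a in areas:
                for c in conditions:
                    tag = f"{a}__{c}"
                    key = (a, c)
                    p[key] = npz[f"p__{tag}"]
                    z[key] = npz[f"z__{tag}"]
                    bp[key] = npz[f"beta_pop__{tag}"]
                    b1[key] = npz[f"beta_local1__{tag}"]
                    c2[key] = npz[f"c_local2__{tag}"]
                    w = npz[f"warp__{tag}"]
                    specs[key] = WarpSpec(*w)
                    neurons[key] = list(npz[f"neurons__{tag}"])
            acc = dict(zip(npz["accept_names"].tolist(),
                           npz["accept_rates"].tolist()))
            return cls(areas=areas, conditions=conditions,
                       n_trials=int(npz["n_trials"]), sigma=npz["sigma"],
                       q=npz["q"], p=p, z=z, beta_pop=bp, beta_local1=b1,
                       c_local2=c2, warp_specs=specs, neuron_ids=neurons,
                       acceptance=acc, burn_in=int(npz["burn_in"]),
                       thin=int(npz["thin"]))


# ---------------------------------------------------------------------------
# landmark finding
# ---------------------------------------------------------------------------

def find_landmarks(f_grid, grid, T, fraction=0.5, margin=2.0) -> WarpSpec:
    """Warp landmarks from a fitted population log-rate template.

    The two peak times are the locations of the two largest local maxima of
    the rate (in time order); each peak's interval boundaries sit where the
    rate falls to ``fraction`` of the peak's local prominence, bounded so
    the intervals do not overlap.
    """
    from scipy.signal import find_peaks

    rate = np.exp(np.asarray(f_grid, dtype=float))
    idx, props = find_peaks(rate, prominence=0.0)
    if len(idx) < 2:
        raise ScreeningError("template does not show two local maxima")
    top = idx[np.argsort(props["prominences"])[-2:]]
    i1, i2 = sorted(top)
    prom = {i1: props["prominences"][list(idx).index(i1)],
            i2: props["prominences"][list(idx).index(i2)]}

    def boundaries(i):
        thr = rate[i] - fraction * prom[i]
        left = i
        while left > 0 and rate[left] > thr:
            left -= 1
        right = i
        while right < len(rate) - 1 and rate[right] > thr:
            right += 1
        return left, right

    l1, r1 = boundaries(i1)
    l2, r2 = boundaries(i2)
    # intervals may not overlap: cut both at the valley between the peaks
    if r1 >= l2:
        valley = i1 + int(np.argmin(rate[i1:i2 + 1]))
        r1 = l2 = valley
    step = float(grid[1] - grid[0])
    eps = 0.5 * step

    def t(i):
        return float(grid[i])

    t1l = max(t(l1), eps)
    t1r = max(t(r1), t(i1) + eps)
    t2l = min(max(t(l2), t1r), t(i2) - eps)
    t2r = min(t(r2), T - eps)
    if not t2r > t(i2):
        t2r = min(t(i2) + eps, T - eps)
    try:
        return WarpSpec(t1l=t1l, tpeak1=t(i1), t1r=t1r, t2l=t2l, tpeak2=t(i2),
                        t2r=t2r, T=float(T))
    except ValueError as err:
        raise ScreeningError(f"degenerate landmark layout: {err}") from err


# ---------------------------------------------------------------------------
# fit state (internal tensors)
# ---------------------------------------------------------------------------

class _ACData:
    """Precomputed per-(area, condition) tensors for fast updates."""

    __slots__ = ("neurons", "N", "Y", "counts_nr", "S_counts", "tot_n",
                 "times_r", "neu_r", "wbins_r", "warp_spec", "z", "p",
                 "beta_pop", "beta_l1", "c_l2", "f_pop", "sum_exp_fpop",
                 "f_l1", "sum_exp_fl1", "curv_p1", "curv_p2")

    def __init__(self, neurons, Y, times_r, neu_r):
        self.neurons = neurons
        self.N = len(neurons)
        self.Y = Y                          # (N, R, K) int16
        self.counts_nr = Y.sum(axis=2)      # (N, R)
        self.S_counts = Y.sum(axis=1).astype(float)  # (N, K)
        self.tot_n = self.counts_nr.sum(axis=1).astype(float)  # (N,)
        self.times_r = times_r              # list over r of float arrays
        self.neu_r = neu_r                  # list over r of int arrays
        self.wbins_r = None                 # warped bin index per spike
        self.warp_spec = None
        self.z = None
        self.p = None
        self.beta_pop = None
        self.beta_l1 = None
        self.c_l2 = None
        self.f_pop = None
        self.sum_exp_fpop = None
        self.f_l1 = None
        self.sum_exp_fl1 = None
        self.curv_p1 = None                 # (R,) shift curvature estimates
        self.curv_p2 = None

    @property
    def members(self):
        return self.z == GROUP_POP

    def set_beta_pop(self, beta, B):
        self.beta_pop = beta
        self.f_pop = B @ beta
        self.sum_exp_fpop = float(np.exp(self.f_pop).sum())

    def set_beta_l1(self, beta, B):
        self.beta_l1 = beta
        self.f_l1 = B @ beta
        self.sum_exp_fl1 = float(np.exp(self.f_l1).sum())


class FitState:
    """All mutable fitting state plus immutable precomputed structures."""

    def __init__(self, dataset, config):
        self.dataset = dataset
        self.config = config
        self.areas = dataset.areas
        self.conditions = dataset.conditions
        self.A = len(self.areas)
        self.C = len(self.conditions)
        self.K = config.n_bins
        self.dt = config.bin_width
        self.dt_s = config.bin_width / 1000.0
        self.basis = build_basis(config.T, config.n_knots, config.bin_width)
        self.penalty = build_penalty(self.basis)
        self.eta = config.eta
        self.eta_ac: dict = {}
        trials = dataset.trials(self.conditions[0])
        self.R = len(trials)
        self.trial_ids = {c: dataset.trials(c) for c in self.conditions}
        for c in self.conditions:
            if len(self.trial_ids[c]) != self.R:
                raise ValueError("all conditions must have the same trial count")
        self.ac: dict = {}
        self._build_tensors()
        nf = 3 * self.A
        self.q = {c: np.zeros((self.R, nf)) for c in self.conditions}
        self.sigma = np.diag(np.asarray(config.phi0_diag(self.A), dtype=float))
        self.psi0 = 2.0 * np.diag(np.asarray(config.phi0_diag(self.A), dtype=float))
        self.nu0 = 3 * self.A + 1
        self.alpha = config.alpha

    # -- construction -------------------------------------------------------
    def _build_tensors(self):
        ds = self.dataset
        df = ds.spikes
        K, dt = self.K, self.dt
        for a in self.areas:
            ids = ds.neurons(a)
            pos = {n: i for i, n in enumerate(ids)}
            sub_a = df[df["area"] == a]
            for c in self.conditions:
                sub = sub_a[sub_a["condition_id"] == c]
                N, R = len(ids), self.R
                Y = np.zeros((N, R, K), dtype=np.int16)
                times_r, neu_r = [], []
                by_trial = {r: g for r, g in sub.groupby("trial_id")}
                for ri, r in enumerate(self.trial_ids[c]):
                    g = by_trial.get(r)
                    if g is None:
                        times_r.append(np.empty(0))
                        neu_r.append(np.empty(0, dtype=np.int64))
                        continue
                    t = g["time_ms"].to_numpy(dtype=float)
                    n = g["neuron_id"].map(pos).to_numpy(dtype=np.int64)
                    bins = np.minimum((t / dt).astype(np.int64), K - 1)
                    np.add.at(Y[:, ri, :], (n, bins), 1)
                    times_r.append(t)
                    neu_r.append(n)
                self.ac[(a, c)] = _ACData(ids, Y, times_r, neu_r)

    # -- feature bookkeeping -------------------------------------------------
    def eta_for(self, a, c):
        return self.eta_ac.get((a, c), self.eta)

    def q_area(self, c, r, ai):
        """(gain, peak1, peak2) of area index ai on trial r of condition c."""
        v = self.q[c][r]
        return v[3 * ai], v[3 * ai + 1], v[3 * ai + 2]

    def gains(self, a, c):
        ai = self.areas.index(a)
        return self.q[c][:, 3 * ai]

    def in_domain(self, c, qvec) -> bool:
        m = self.config.peak_margin
        for ai, a in enumerate(self.areas):
            spec = self.ac[(a, c)].warp_spec
            d1 = spec.peak1_domain(m)
            d2 = spec.peak2_domain(m)
            if not (d1[0] < qvec[3 * ai + 1] < d1[1]):
                return False
            if not (d2[0] < qvec[3 * ai + 2] < d2[1]):
                return False
        return True

    # -- warped binning -----------------------------------------------------
    def warp_bins(self, a, c, r, p1, p2):
        """Warped bin index of every spike of (a, c, trial r) for shifts (p1, p2)."""
        acd = self.ac[(a, c)]
        t = acd.times_r[r]
        if t.size == 0:
            return np.empty(0, dtype=np.int64)
        spec = acd.warp_spec
        x = np.array([0.0, spec.t1l, spec.tpeak1, spec.t1r, spec.t2l,
                      spec.tpeak2, spec.t2r, spec.T])
        y = np.array([0.0, spec.t1l, spec.tpeak1 + p1, spec.t1r, spec.t2l,
                      spec.tpeak2 + p2, spec.t2r, spec.T])
        u = np.interp(t, y, x)
        return np.minimum((u / self.dt).astype(np.int64), self.K - 1)

    def refresh_wbins(self, keys=None):
        """Recompute cached warped bin indices from the current q."""
        items = keys if keys is not None else list(self.ac)
        for (a, c) in items:
            ai = self.areas.index(a)
            acd = self.ac[(a, c)]
            acd.wbins_r = [
                self.warp_bins(a, c, r, self.q[c][r, 3 * ai + 1],
                               self.q[c][r, 3 * ai + 2])
                for r in range(self.R)
            ]

    # -- warped population counts -------------------------------------------
    def warped_pop_counts(self, a, c):
        """(R, K) warped binned counts of the current pop members."""
        acd = self.ac[(a, c)]
        mem = acd.members
        out = np.zeros((self.R, self.K))
        for r in range(self.R):
            if acd.times_r[r].size == 0:
                continue
            sel = mem[acd.neu_r[r]]
            out[r] = np.bincount(acd.wbins_r[r][sel], minlength=self.K)
        return out

    def local1_counts(self, a, c):
        acd = self.ac[(a, c)]
        mask = acd.z == GROUP_L1
        return acd.Y[mask].sum(axis=0).astype(float)  # (R, K)

    # -- membership state ----------------------------------------------------
    def membership(self) -> MembershipState:
        return MembershipState(z={k: v.z.copy() for k, v in self.ac.items()},
                               p={k: v.p.copy() for k, v in self.ac.items()})

    def covariance(self) -> CovarianceState:
        return CovarianceState(sigma=self.sigma.copy(), psi0=self.psi0,
                               nu0=self.nu0, alpha=self.alpha)


# ---------------------------------------------------------------------------
# log-likelihood pieces (population form, factorials omitted where they
# cancel within a block)
# ---------------------------------------------------------------------------

def _pop_trial_loglik(state, a, c, r, qvec_area, wbins=None):
    """Warped pop-train log-likelihood of one trial (up to y! constants)."""
    acd = state.ac[(a, c)]
    g, p1, p2 = qvec_area
    Npop = int(acd.members.sum())
    if Npop == 0:
        return 0.0
    if wbins is None:
        wbins = state.warp_bins(a, c, r, p1, p2)
    sel = acd.members[acd.neu_r[r]] if acd.times_r[r].size else np.empty(0, bool)
    wb = wbins[sel]
    cnt = wb.size
    s_f = float(state.ac[(a, c)].f_pop[wb].sum()) if cnt else 0.0
    return (s_f + cnt * (g + np.log(Npop * state.dt_s))
            - Npop * state.dt_s * np.exp(g) * acd.sum_exp_fpop)


def _neuron_group_logliks(state, a, c):
    """(N, 3) per-neuron log-likelihoods summed over trials (shared y!
    constants omitted -- they cancel in the membership draw)."""
    acd = state.ac[(a, c)]
    N, R, K = acd.N, state.R, state.K
    dt_s = state.dt_s
    gains = state.gains(a, c)
    # pop: template log-rate at each spike's warped bin
    s_f = np.zeros(N)
    for r in range(R):
        if acd.times_r[r].size == 0:
            continue
        s_f += np.bincount(acd.neu_r[r], weights=acd.f_pop[acd.wbins_r[r]],
                           minlength=N)
    lp_pop = (s_f + acd.counts_nr @ gains + acd.tot_n * np.log(dt_s)
              - dt_s * np.exp(gains).sum() * acd.sum_exp_fpop)
    lp_l1 = (acd.S_counts @ acd.f_l1 + acd.tot_n * np.log(dt_s)
             - R * dt_s * acd.sum_exp_fl1)
    lp_l2 = (acd.tot_n * (acd.c_l2 + np.log(dt_s))
             - R * dt_s * K * np.exp(acd.c_l2))
    return np.column_stack([lp_pop, lp_l1, lp_l2])


def _beta_pop_logpost(state, a, c, beta, yw_tot, gain_sum_exp):
    """Warped-data log posterior of the pop template coefficients."""
    acd = state.ac[(a, c)]
    Npop = int(acd.members.sum())
    f = state.basis.B @ beta
    ll = float(yw_tot @ f) - Npop * state.dt_s * gain_sum_exp * float(np.exp(f).sum())
    pen = state.eta_for(a, c) * Npop * state.R * float(beta @ state.penalty.omega @ beta)
    return ll - pen


def _beta_l1_logpost(state, a, c, beta, y_tot):
    acd = state.ac[(a, c)]
    N1 = int((acd.z == GROUP_L1).sum())
    f = state.basis.B @ beta
    ll = float(y_tot @ f) - N1 * state.R * state.dt_s * float(np.exp(f).sum())
    pen = state.eta_for(a, c) * N1 * state.R * float(beta @ state.penalty.omega @ beta)
    return ll - pen


def _c_l2_logpost(state, a, c, cval, tot_count):
    acd = state.ac[(a, c)]
    N2 = int((acd.z == GROUP_L2).sum())
    return tot_count * cval - N2 * state.R * state.K * state.dt_s * np.exp(cval)


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

def initialize(dataset, config) -> FitState:
    """Build the fit state and initialize memberships, templates, landmarks.

    Neurons are ranked by total in-window spike count (merged over
    conditions and trials) and split high/medium/low with proportions
    25/50/25 into pop/local-1/local-2.  Templates are penalized-spline fits
    from the high and medium groups; the low group sets the constant
    log-rate.  Warp landmarks come from the initial population template;
    all features start at zero.
    """
    state = FitState(dataset, config)
    props = config.init_proportions
    for a in state.areas:
        ids = dataset.neurons(a)
        counts = dataset.total_counts().loc[ids]
        order = sorted(ids, key=lambda n: (-counts[n], n))
        N = len(ids)
        n_hi = int(round(props[0] * N))
        n_md = int(round(props[1] * N))
        group_of = {}
        for i, n in enumerate(order):
            group_of[n] = (GROUP_POP if i < n_hi
                           else GROUP_L1 if i < n_hi + n_md else GROUP_L2)
        for c in state.conditions:
            acd = state.ac[(a, c)]
            acd.z = np.array([group_of[n] for n in acd.neurons], dtype=np.int8)
            acd.p = np.asarray(props, dtype=float)
    if config.cv_eta_init:
        from popwarp.splines import cv_select_eta

        for (a, c), acd in state.ac.items():
            counts = acd.Y[acd.z == GROUP_POP].sum(axis=0).astype(float)
            n_pop = int((acd.z == GROUP_POP).sum())
            if n_pop and counts.sum() > 0:
                state.eta_ac[(a, c)] = cv_select_eta(
                    counts, state.basis, state.penalty,
                    list(config.init_eta_grid), exposure=n_pop,
                    n_folds=config.cv_folds, seed=config.cv_seed)
    _refit_templates(state, warped=False)
    for (a, c), acd in state.ac.items():
        counts = acd.Y[acd.z == GROUP_POP].sum(axis=0).astype(float)
        n_pop = max(int((acd.z == GROUP_POP).sum()), 1)
        # landmark pass: start from a deliberately stiff fit (coarse burst
        # structure), relaxing the stiffness if smoothing erases a peak
        err = None
        for eta_lm in (config.landmark_eta, config.landmark_eta / 10,
                       config.landmark_eta / 100, state.eta_for(a, c)):
            f_lm = state.basis.B @ fit_penalized_poisson(
                counts, state.basis, state.penalty, eta_lm, exposure=n_pop)
            try:
                acd.warp_spec = find_landmarks(
                    f_lm, state.basis.grid, config.T,
                    fraction=config.landmark_fraction,
                    margin=config.peak_margin)
                err = None
                break
            except ScreeningError as e:
                err = e
        if err is not None:
            raise ScreeningError(
                f"initial population template for area {a!r}, condition {c!r} "
                f"failed peak screening: {err}") from err
    state.refresh_wbins()
    return state


def _refit_templates(state, warped=True):
    """Penalized-spline M-step for all templates from current memberships."""
    for (a, c), acd in state.ac.items():
        mem = acd.members
        Npop = int(mem.sum())
        gains = state.gains(a, c)
        eta = state.eta_for(a, c)
        if Npop > 0:
            if warped:
                counts = state.warped_pop_counts(a, c)
            else:
                counts = acd.Y[mem].sum(axis=0).astype(float)
            beta = fit_penalized_poisson(counts, state.basis, state.penalty,
                                         eta, offsets=gains,
                                         exposure=Npop,
                                         beta0=acd.beta_pop)
            acd.set_beta_pop(beta, state.basis.B)
        n1 = int((acd.z == GROUP_L1).sum())
        if n1 > 0:
            counts1 = acd.Y[acd.z == GROUP_L1].sum(axis=0).astype(float)
            beta1 = fit_penalized_poisson(counts1, state.basis, state.penalty,
                                          eta, exposure=n1,
                                          beta0=acd.beta_l1)
            acd.set_beta_l1(beta1, state.basis.B)
        elif acd.beta_l1 is None:
            acd.set_beta_l1(np.zeros(state.basis.n_basis), state.basis.B)
        n2 = int((acd.z == GROUP_L2).sum())
        if n2 > 0:
            counts2 = acd.Y[acd.z == GROUP_L2].sum(axis=0).astype(float)
            acd.c_l2 = fit_constant_rate(counts2, n2, state.dt)
        elif acd.c_l2 is None:
            acd.c_l2 = 0.0


# ---------------------------------------------------------------------------
# hard EM
# ---------------------------------------------------------------------------

def _em_q_step(state, sweeps=1):
    """Conditional-mode update of every trial's feature block.

    Block-coordinate ascent over areas: for each area the two peak shifts
    are searched on a bin-resolution grid (the two peak regions of the warp
    contribute separably to the warped likelihood), the gain maximized by
    1-d Newton, all under the joint normal prior conditioned on the other
    areas' current features.  Grid curvatures are stored for the sampler's
    proposal covariances.
    """
    m = state.config.peak_margin
    prec = np.linalg.inv(state.sigma)
    for c in state.conditions:
        qc = state.q[c]
        for r in range(state.R):
            for _ in range(sweeps):
                for ai, a in enumerate(state.areas):
                    _em_q_area(state, a, ai, c, r, qc, prec, m)
    state.refresh_wbins()


def _em_q_area(state, a, ai, c, r, qc, prec, margin):
    acd = state.ac[(a, c)]
    Npop = int(acd.members.sum())
    spec = acd.warp_spec
    d1 = spec.peak1_domain(margin)
    d2 = spec.peak2_domain(margin)
    step = state.dt
    g1 = np.arange(d1[0] + 0.5 * step, d1[1], step)
    g2 = np.arange(d2[0] + 0.5 * step, d2[1], step)
    if g1.size == 0:
        g1 = np.array([0.5 * (d1[0] + d1[1])])
    if g2.size == 0:
        g2 = np.array([0.5 * (d2[0] + d2[1])])
    t = acd.times_r[r]
    sel = acd.members[acd.neu_r[r]] if t.size else np.empty(0, bool)
    tm = t[sel] if t.size else t
    cnt = tm.size

    # separable warped-likelihood profiles over each shift grid
    x1 = np.array([spec.t1l, spec.tpeak1, spec.t1r])
    x2 = np.array([spec.t2l, spec.tpeak2, spec.t2r])
    in1 = (tm > spec.t1l) & (tm < spec.t1r)
    in2 = (tm > spec.t2l) & (tm < spec.t2r)
    base = tm[~(in1 | in2)]
    base_bins = np.minimum((base / state.dt).astype(np.int64), state.K - 1)
    s_base = float(acd.f_pop[base_bins].sum()) if Npop else 0.0

    def profile(gridvals, xj, tsub):
        out = np.zeros(len(gridvals))
        if tsub.size == 0 or Npop == 0:
            return out
        for i, d in enumerate(gridvals):
            yj = xj.copy()
            yj[1] = yj[1] + d
            u = np.interp(tsub, yj, xj)
            bins = np.minimum((u / state.dt).astype(np.int64), state.K - 1)
            out[i] = float(acd.f_pop[bins].sum())
        return out

    h1 = profile(g1, x1, tm[in1])
    h2 = profile(g2, x2, tm[in2])

    # store local curvatures for the proposal covariance (per trial)
    if acd.curv_p1 is None:
        acd.curv_p1 = np.zeros(state.R)
        acd.curv_p2 = np.zeros(state.R)
    acd.curv_p1[r] = _grid_curvature(h1, step)
    acd.curv_p2[r] = _grid_curvature(h2, step)

    # prior conditional on the other features of this trial
    i_g, i_1, i_2 = 3 * ai, 3 * ai + 1, 3 * ai + 2

    # gain conditional maximizer given shifts: concave 1-d Newton
    def best_gain(gstart):
        g = gstart
        lam = Npop * state.dt_s * acd.sum_exp_fpop
        pg = prec[i_g, i_g]
        rest = qc[r].copy()
        for _ in range(30):
            rest[i_g] = g
            lin = float(prec[i_g] @ rest) - pg * g
            grad = cnt - lam * np.exp(g) - pg * g - lin
            hess = -lam * np.exp(g) - pg
            stepg = grad / hess
            g -= stepg
            if abs(stepg) < 1e-10:
                break
        return float(np.clip(g, -5.0, 5.0))

    ghat = best_gain(qc[r, i_g]) if Npop else 0.0
    lam = Npop * state.dt_s * acd.sum_exp_fpop
    ll_gain = cnt * (ghat + (np.log(Npop * state.dt_s) if Npop else 0.0)) \
        - lam * np.exp(ghat)
    # joint grid objective: separable likelihood + joint prior; the prior is
    # quadratic in (p1, p2), so evaluate it on the grid by expansion
    P = (h1[:, None] + h2[None, :]) + s_base + ll_gain
    rest = qc[r].copy()
    rest[i_g] = ghat
    rest[i_1] = 0.0
    rest[i_2] = 0.0
    b1 = float(prec[i_1] @ rest)
    b2 = float(prec[i_2] @ rest)
    pri = -0.5 * (prec[i_1, i_1] * g1[:, None] ** 2
                  + prec[i_2, i_2] * g2[None, :] ** 2
                  + 2 * prec[i_1, i_2] * g1[:, None] * g2[None, :]
                  + 2 * b1 * g1[:, None] + 2 * b2 * g2[None, :])
    i, j = np.unravel_index(np.argmax(P + pri), P.shape)
    qc[r, i_1], qc[r, i_2] = g1[i], g2[j]
    if Npop:
        qc[r, i_g] = best_gain(ghat)


def _grid_curvature(h, step):
    """Negative second difference of a grid profile at its max (floored >= 0)."""
    if len(h) < 3:
        return 0.0
    i = int(np.clip(np.argmax(h), 1, len(h) - 2))
    curv = -(h[i - 1] - 2 * h[i] + h[i + 1]) / step ** 2
    return float(max(curv, 0.0))


def _recenter_features(state):
    """Identifiability normalization: move the across-trial feature means
    into the template (landmark positions and log-rate level) so that the
    features represent zero-mean trial deviations.

    The peak landmarks absorb the mean shifts (clamped so they stay inside
    their intervals); the template level absorbs the mean gain exactly
    (adding a constant to every spline coefficient adds that constant to
    the curve, by partition of unity).
    """
    margin = state.config.peak_margin
    for c in state.conditions:
        qc = state.q[c]
        for ai, a in enumerate(state.areas):
            acd = state.ac[(a, c)]
            spec = acd.warp_spec
            ig, i1, i2 = 3 * ai, 3 * ai + 1, 3 * ai + 2
            m1 = float(np.clip(qc[:, i1].mean(),
                               spec.t1l - spec.tpeak1 + 2 * margin,
                               spec.t1r - spec.tpeak1 - 2 * margin))
            m2 = float(np.clip(qc[:, i2].mean(),
                               spec.t2l - spec.tpeak2 + 2 * margin,
                               spec.t2r - spec.tpeak2 - 2 * margin))
            mg = float(qc[:, ig].mean())
            acd.warp_spec = WarpSpec(spec.t1l, spec.tpeak1 + m1, spec.t1r,
                                     spec.t2l, spec.tpeak2 + m2, spec.t2r,
                                     spec.T)
            qc[:, i1] -= m1
            qc[:, i2] -= m2
            qc[:, ig] -= mg
            d1 = acd.warp_spec.peak1_domain(margin)
            d2 = acd.warp_spec.peak2_domain(margin)
            qc[:, i1] = np.clip(qc[:, i1], d1[0] + 1e-6, d1[1] - 1e-6)
            qc[:, i2] = np.clip(qc[:, i2], d2[0] + 1e-6, d2[1] - 1e-6)
            if acd.beta_pop is not None:
                acd.set_beta_pop(acd.beta_pop + mg, state.basis.B)
    state.refresh_wbins()


def _em_z_step(state):
    for (a, c), acd in state.ac.items():
        lw = _neuron_group_logliks(state, a, c) + np.log(np.maximum(acd.p, 1e-300))
        acd.z = lw.argmax(axis=1).astype(np.int8)


def _em_p_step(state):
    al = state.alpha
    for acd in state.ac.values():
        n = np.bincount(acd.z, minlength=3).astype(float)
        mode = np.maximum(n + al - 1.0, 1e-9)
        acd.p = mode / mode.sum()


def _em_sigma_step(state):
    """ML update of the feature covariance with a Laplace E-step correction.

    The EM stage targets maximum likelihood (the inverse-Wishart prior
    belongs to the posterior-sampling stage), so Sigma is the ML update
    E[q q']/RC.  Using the conditional modes alone collapses the variance
    (the modes are shrunk toward zero), so the expectation is approximated
    as mode outer product plus the Laplace covariance of each trial's
    conditional, built from the likelihood curvatures of the feature block.
    """
    prec = np.linalg.inv(state.sigma)
    nf = 3 * state.A
    total = np.zeros((nf, nf))
    n = 0
    for c in state.conditions:
        qc = state.q[c]
        for r in range(state.R):
            H = prec.copy()
            for ai, a in enumerate(state.areas):
                acd = state.ac[(a, c)]
                Npop = int(acd.members.sum())
                g = qc[r, 3 * ai]
                H[3 * ai, 3 * ai] += Npop * state.dt_s * np.exp(g) * acd.sum_exp_fpop
                if acd.curv_p1 is not None:
                    H[3 * ai + 1, 3 * ai + 1] += acd.curv_p1[r]
                    H[3 * ai + 2, 3 * ai + 2] += acd.curv_p2[r]
            H = 0.5 * (H + H.T)
            w, V = np.linalg.eigh(H)
            w = np.maximum(w, 1e-10)
            C = (V / w) @ V.T
            total += np.outer(qc[r], qc[r]) + C
            n += 1
    state.sigma = 0.5 * (total + total.T) / n
    # keep strictly positive definite
    w, V = np.linalg.eigh(state.sigma)
    state.sigma = (V * np.maximum(w, 1e-8)) @ V.T


def penalized_log_posterior(state) -> float:
    """Joint penalized log posterior at the current state (population form)."""
    from scipy.stats import dirichlet

    alpha3 = np.full(3, state.alpha)
    total = 0.0
    for (a, c), acd in state.ac.items():
        ai = state.areas.index(a)
        for r in range(state.R):
            total += _pop_trial_loglik(state, a, c, r,
                                       state.q_area(c, r, ai),
                                       wbins=acd.wbins_r[r])
        y1 = state.local1_counts(a, c)
        n1 = int((acd.z == GROUP_L1).sum())
        if n1 > 0:
            total += (float(y1.sum(axis=0) @ acd.f_l1)
                      + y1.sum() * np.log(n1 * state.dt_s)
                      - n1 * state.R * state.dt_s * acd.sum_exp_fl1)
        n2 = int((acd.z == GROUP_L2).sum())
        if n2 > 0:
            cnt2 = float(acd.tot_n[acd.z == GROUP_L2].sum())
            total += (cnt2 * (acd.c_l2 + np.log(n2 * state.dt_s))
                      - n2 * state.R * state.K * state.dt_s * np.exp(acd.c_l2))
        # membership prior and penalties
        total += float(np.log(np.maximum(acd.p, 1e-300))[acd.z].sum())
        total += float(dirichlet.logpdf(
            np.clip(acd.p, 1e-12, None) / np.clip(acd.p, 1e-12, None).sum(),
            alpha3))
        Npop = int(acd.members.sum())
        total -= state.eta_for(a, c) * Npop * state.R * float(
            acd.beta_pop @ state.penalty.omega @ acd.beta_pop)
        total -= state.eta_for(a, c) * n1 * state.R * float(
            acd.beta_l1 @ state.penalty.omega @ acd.beta_l1)
    # feature prior
    chol = np.linalg.cholesky(state.sigma)
    logdet = 2.0 * float(np.log(np.diag(chol)).sum())
    for c in state.conditions:
        x = np.linalg.solve(chol, state.q[c].T)
        total += -0.5 * float((x ** 2).sum()) - 0.5 * state.R * logdet
    total += float(invwishart.logpdf(state.sigma, df=state.nu0,
                                     scale=state.psi0))
    return total


def hard_em(state: FitState, max_iter=None, tol=None) -> FitState:
    """Hard EM: alternate conditional-mode updates of (q, z) and (beta, p, Sigma).

    Stops when the relative change of the penalized log posterior falls
    below ``tol`` or after ``max_iter`` iterations; warns and stops if the
    objective decreases for more than 3 consecutive iterations.
    """
    cfg = state.config
    max_iter = cfg.em_max_iter if max_iter is None else max_iter
    tol = cfg.em_tol if tol is None else tol
    prev = -np.inf
    n_down = 0
    for it in range(max_iter):
        _em_q_step(state, sweeps=2 if it == 0 else 1)
        _em_z_step(state)
        _recenter_features(state)
        _refit_templates(state, warped=True)
        _em_p_step(state)
        _em_sigma_step(state)
        obj = penalized_log_posterior(state)
        if obj < prev:
            n_down += 1
            if n_down > 3:
                logger.warning("hard EM objective non-increasing for >3 "
                               "iterations; stopping at iter %d", it)
                break
        else:
            n_down = 0
        if np.isfinite(prev) and abs(obj - prev) <= tol * (abs(prev) + 1.0):
            prev = obj
            break
        prev = obj
    state.em_objective = prev
    return state


# ---------------------------------------------------------------------------
# proposal construction
# ---------------------------------------------------------------------------

def _chol_of_scaled_inverse(H, scale, floor=1e-8):
    """Cholesky factor of scale * H^{-1} with eigenvalue flooring on H."""
    H = 0.5 * (H + H.T)
    w, V = np.linalg.eigh(H)
    w = np.maximum(w, floor)
    Q = (V / w) @ V.T
    Q = 0.5 * scale * (Q + Q.T)
    w2, V2 = np.linalg.eigh(Q)
    w2 = np.maximum(w2, 1e-14)
    return V2 * np.sqrt(w2) @ V2.T  # symmetric square root (valid factor)


def compute_proposals(state: FitState) -> ProposalState:
    """Curvature-based proposal covariances at the hard-EM mode, held fixed.

    Template blocks use the analytic Hessian of the penalized Poisson
    posterior.  Feature blocks combine the analytic gain curvature, grid
    curvatures of the shift profiles from the EM search, and the prior
    precision.
    """
    cfg = state.config
    scale = cfg.proposal_scale
    prop = ProposalState(scale=scale)
    B, omega = state.basis.B, state.penalty.omega
    for (a, c), acd in state.ac.items():
        gains = state.gains(a, c)
        Npop = max(int(acd.members.sum()), 1)
        eta = state.eta_for(a, c)
        mu = Npop * state.dt_s * np.exp(gains).sum() * np.exp(acd.f_pop)
        H = (B.T * mu) @ B + 2 * eta * Npop * state.R * omega
        prop.chol_beta_pop[(a, c)] = _chol_of_scaled_inverse(H, scale)
        n1 = max(int((acd.z == GROUP_L1).sum()), 1)
        mu1 = n1 * state.R * state.dt_s * np.exp(acd.f_l1)
        H1 = (B.T * mu1) @ B + 2 * eta * n1 * state.R * omega
        prop.chol_beta_l1[(a, c)] = _chol_of_scaled_inverse(H1, scale)
        n2 = max(int((acd.z == GROUP_L2).sum()), 1)
        h2 = n2 * state.R * state.K * state.dt_s * np.exp(acd.c_l2)
        # 1-dim block: the 5.76/d rule gives 5.76, not 0.05
        prop.sd_l2[(a, c)] = float(np.sqrt(5.76 / max(h2, 1e-8)))
    prec = np.linalg.inv(state.sigma)
    nf = 3 * state.A
    for c in state.conditions:
        for r in range(state.R):
            H = prec.copy()
            for ai, a in enumerate(state.areas):
                acd = state.ac[(a, c)]
                Npop = int(acd.members.sum())
                g = state.q[c][r, 3 * ai]
                H[3 * ai, 3 * ai] += Npop * state.dt_s * np.exp(g) * acd.sum_exp_fpop
                if acd.curv_p1 is not None:
                    H[3 * ai + 1, 3 * ai + 1] += acd.curv_p1[r]
                    H[3 * ai + 2, 3 * ai + 2] += acd.curv_p2[r]
            chol = _chol_of_scaled_inverse(H, scale)
            prop.chol_q[(c, r)] = chol
            prop.prec_chol_q[(c, r)] = np.linalg.inv(chol)
    return prop


# ---------------------------------------------------------------------------
# Gibbs steps
# ---------------------------------------------------------------------------

def mh_step(x, log_target, chol, rng, logpost_x=None):
    """One random-walk Metropolis step with proposal factor ``chol``.

    Returns (new_x, new_logpost, accepted).  The proposal is symmetric, so
    the acceptance ratio is the target ratio; a candidate with -inf target
    is always rejected.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    if logpost_x is None:
        logpost_x = log_target(x)
    eps = rng.standard_normal(x.shape[0])
    cand = x + chol @ eps
    lp_cand = log_target(cand)
    if np.log(rng.uniform()) < lp_cand - logpost_x:
        return cand, lp_cand, True
    return x, logpost_x, False


def gibbs_step_templates(state, prop, rng, accept_log):
    """MH updates of beta_pop, beta_local1, and c_local2 for every (a, c)."""
    for (a, c), acd in state.ac.items():
        gains = state.gains(a, c)
        Npop = int(acd.members.sum())
        if Npop > 0:
            yw = state.warped_pop_counts(a, c).sum(axis=0)
            gsum = float(np.exp(gains).sum())

            def target(b):
                return _beta_pop_logpost(state, a, c, b, yw, gsum)

            new, _, ok = mh_step(acd.beta_pop, target,
                                 prop.chol_beta_pop[(a, c)], rng)
            if ok:
                acd.set_beta_pop(new, state.basis.B)
            accept_log.add(f"beta_pop:{a}:{c}", ok)
        n1 = int((acd.z == GROUP_L1).sum())
        if n1 > 0:
            y1 = state.local1_counts(a, c).sum(axis=0)

            def target1(b):
                return _beta_l1_logpost(state, a, c, b, y1)

            new, _, ok = mh_step(acd.beta_l1, target1,
                                 prop.chol_beta_l1[(a, c)], rng)
            if ok:
                acd.set_beta_l1(new, state.basis.B)
            accept_log.add(f"beta_local1:{a}:{c}", ok)
        n2 = int((acd.z == GROUP_L2).sum())
        if n2 > 0:
            tot2 = float(acd.tot_n[acd.z == GROUP_L2].sum())

            def target2(v):
                return _c_l2_logpost(state, a, c, v[0], tot2)

            new, _, ok = mh_step(np.array([acd.c_l2]), target2,
                                 np.array([[prop.sd_l2[(a, c)]]]), rng)
            if ok:
                acd.c_l2 = float(new[0])
            accept_log.add(f"c_local2:{a}:{c}", ok)


def _q_target(state, c, r, qvec, sig_chol):
    """Warped-data log-likelihood plus N(0, Sigma) log prior of one trial."""
    x = np.linalg.solve(sig_chol, qvec)
    lp = -0.5 * float(x @ x)
    for ai, a in enumerate(state.areas):
        lp += _pop_trial_loglik(state, a, c, r,
                                (qvec[3 * ai], qvec[3 * ai + 1], qvec[3 * ai + 2]))
    return lp


def gibbs_step_q(state, prop, rng, accept_log):
    """MH update of every trial's 9-dim feature block.

    Proposal N(q_m - 0.5 * qbar, 0.05 Q) with qbar the across-trial mean of
    the condition; the drift toward the centered configuration enforces the
    identifiability constraint mean(q) = 0 and is treated as symmetric in
    the acceptance ratio (the exact reverse-density correction for the
    drift would veto every move once |qbar| exceeds the proposal scale,
    freezing the chain; accepting on the target ratio alone reproduces the
    published scheme, whose drift self-centers the features).  Candidates
    outside the warp domains have zero target density and are rejected.
    """
    sig_chol = np.linalg.cholesky(state.sigma)
    for c in state.conditions:
        qc = state.q[c]
        qbar = qc.mean(axis=0)
        for r in range(state.R):
            chol = prop.chol_q[(c, r)]
            cur = qc[r]
            cand = cur - 0.5 * qbar + chol @ rng.standard_normal(len(cur))
            if not state.in_domain(c, cand):
                accept_log.add(f"q:{c}", False)
                continue
            lt_cur = _q_target(state, c, r, cur, sig_chol)
            lt_cand = _q_target(state, c, r, cand, sig_chol)
            ok = np.log(rng.uniform()) < (lt_cand - lt_cur)
            if ok:
                qc[r] = cand
                for ai, a in enumerate(state.areas):
                    acd = state.ac[(a, c)]
                    acd.wbins_r[r] = state.warp_bins(
                        a, c, r, cand[3 * ai + 1], cand[3 * ai + 2])
            accept_log.add(f"q:{c}", bool(ok))


def gibbs_step_z(state, rng):
    """Exact categorical draw of every neuron's membership."""
    for (a, c), acd in state.ac.items():
        lw = _neuron_group_logliks(state, a, c) + np.log(np.maximum(acd.p, 1e-300))
        gumb = rng.gumbel(size=lw.shape)
        acd.z = (lw + gumb).argmax(axis=1).astype(np.int8)


def membership_probabilities(state, a, c) -> np.ndarray:
    """(N, 3) exact conditional membership probabilities (for tests/summaries)."""
    acd = state.ac[(a, c)]
    lw = _neuron_group_logliks(state, a, c) + np.log(np.maximum(acd.p, 1e-300))
    return np.exp(lw - logsumexp(lw, axis=1, keepdims=True))


def gibbs_step_p(state, rng):
    """Exact Dirichlet draw p ~ Dir(N_pop + alpha, N_l1 + alpha, N_l2 + alpha)."""
    al = state.alpha
    for acd in state.ac.values():
        n = np.bincount(acd.z, minlength=3).astype(float)
        acd.p = rng.dirichlet(n + al)


def gibbs_step_sigma(state, rng):
    """Exact inverse-Wishart draw Sigma ~ IW(Psi0 + q'q, nu0 + RC)."""
    Q = np.vstack([state.q[c] for c in state.conditions])
    psi_t = state.psi0 + Q.T @ Q
    psi_t = 0.5 * (psi_t + psi_t.T)
    try:
        np.linalg.cholesky(psi_t)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            f"posterior IW scale matrix not positive definite "
            f"(min eig {np.linalg.eigvalsh(psi_t).min():.3g})") from err
    nu_t = state.nu0 + Q.shape[0]
    state.sigma = invwishart.rvs(df=nu_t, scale=psi_t, random_state=rng)


class _AcceptLog:
    def __init__(self):
        self.acc = {}

    def add(self, name, ok):
        a, n = self.acc.get(name, (0, 0))
        self.acc[name] = (a + int(ok), n + 1)

    def rates(self):
        return {k: a / n for k, (a, n) in self.acc.items() if n}


# ---------------------------------------------------------------------------
# the full sampler
# ---------------------------------------------------------------------------

def run_gibbs(state: FitState, n_iter=None, burn_in=None, thin=None,
              seed=0, proposals=None) -> PosteriorChain:
    """Run the Metropolis-within-Gibbs sampler from the hard-EM state.

    Cycles templates -> q -> z -> p -> Sigma, storing every ``thin``-th draw
    after ``burn_in``.  Reproducible given ``seed``.  Acceptance rates are
    logged per MH block; rates outside the configured band trigger a
    warning (and optional adaptive rescaling if enabled in config).
    """
    cfg = state.config
    n_iter = cfg.n_iter if n_iter is None else n_iter
    burn_in = cfg.burn_in if burn_in is None else burn_in
    thin = cfg.thin if thin is None else thin
    rng = np.random.default_rng(seed)
    prop = proposals if proposals is not None else compute_proposals(state)
    accept = _AcceptLog()
    nf = 3 * state.A
    keep_iters = range(burn_in, n_iter, thin)
    n_keep = len(keep_iters)
    sig_draws = np.zeros((n_keep, nf, nf))
    q_draws = np.zeros((n_keep, state.C, state.R, nf))
    p_draws = {k: np.zeros((n_keep, 3)) for k in state.ac}
    z_draws = {k: np.zeros((n_keep, v.N), dtype=np.int8)
               for k, v in state.ac.items()}
    bpop_draws = {k: np.zeros((n_keep, state.basis.n_basis)) for k in state.ac}
    bl1_draws = {k: np.zeros((n_keep, state.basis.n_basis)) for k in state.ac}
    cl2_draws = {k: np.zeros(n_keep) for k in state.ac}
    kept = 0
    band = cfg.acceptance_band
    for it in range(n_iter):
        gibbs_step_templates(state, prop, rng, accept)
        gibbs_step_q(state, prop, rng, accept)
        gibbs_step_z(state, rng)
        gibbs_step_p(state, rng)
        gibbs_step_sigma(state, rng)
        if cfg.adapt_proposals and it < burn_in and it > 0 and it % 100 == 0:
            _adapt(prop, accept, band)
        if it >= burn_in and (it - burn_in) % thin == 0:
            sig_draws[kept] = state.sigma
            for ci, c in enumerate(state.conditions):
                q_draws[kept, ci] = state.q[c]
            for k, acd in state.ac.items():
                p_draws[k][kept] = acd.p
                z_draws[k][kept] = acd.z
                bpop_draws[k][kept] = acd.beta_pop
                bl1_draws[k][kept] = acd.beta_l1
                cl2_draws[k][kept] = acd.c_l2
            kept += 1
    rates = accept.rates()
    for name, rate in rates.items():
        if not band[0] <= rate <= band[1]:
            logger.warning("MH block %s acceptance rate %.2f outside [%.1f, %.1f]",
                           name, rate, band[0], band[1])
    return PosteriorChain(
        areas=state.areas, conditions=state.conditions, n_trials=state.R,
        sigma=sig_draws[:kept], q=q_draws[:kept],
        p={k: v[:kept] for k, v in p_draws.items()},
        z={k: v[:kept] for k, v in z_draws.items()},
        beta_pop={k: v[:kept] for k, v in bpop_draws.items()},
        beta_local1={k: v[:kept] for k, v in bl1_draws.items()},
        c_local2={k: v[:kept] for k, v in cl2_draws.items()},
        warp_specs={k: v.warp_spec for k, v in state.ac.items()},
        neuron_ids={k: v.neurons for k, v in state.ac.items()},
        acceptance=rates, burn_in=burn_in, thin=thin)


def _adapt(prop, accept, band):
    rates = accept.rates()
    lo, hi = band
    for name, rate in rates.items():
        factor = 0.7 if rate < lo else (1.4 if rate > hi else 1.0)
        if factor == 1.0:
            continue
        if name.startswith("beta_pop:"):
            _, a, c = name.split(":")
            key = _coerce_key(prop.chol_beta_pop, a, c)
            if key is not None:
                prop.chol_beta_pop[key] = prop.chol_beta_pop[key] * np.sqrt(factor)


def _coerce_key(d, a, c):
    for key in d:
        if str(key[0]) == a and str(key[1]) == c:
            return key
    return None
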