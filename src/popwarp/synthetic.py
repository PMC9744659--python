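"""Generative simulator, template shape library, noise injection, and the
parameter-recovery experiment harness.

The simulator draws, per (neuron, area, condition), a membership label from
the membership probabilities; per (condition, trial), a stacked feature
vector from N(0, Sigma) (rejected and resampled if a shift leaves its warp
domain, with the rejection rate logged); and then per neuron an
inhomogeneous Poisson spike train from the group's intensity using per-bin
Poisson counts at the analysis bin width (spike times jittered uniformly
within their bin).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from popwarp.config import ModelConfig, SimulationConfig
from popwarp.data import SpikeDataset
from popwarp.fitting import find_landmarks
from popwarp.splines import build_basis
from popwarp.warping import WarpSpec, build_warp

logger = logging.getLogger(__name__)

SHAPES = ("two-peak", "sharp-peak", "broad-peak", "inverted-peak",
          "rise-to-asymptote")


@dataclass
class TemplateCurve:
    """A log-rate curve on the bin grid with its landmark structure."""

    log_rate: np.ndarray
    grid: np.ndarray
    shape: str
    centers: tuple              # true landmark time(s), ms
    warp_spec: WarpSpec | None = None


def _gauss(t, center, width):
    return np.exp(-0.5 * ((t - center) / width) ** 2)


def make_template(shape, params=None, T=500.0, bin_width=2.0) -> TemplateCurve:
    """Template library used by the simulations.

    Shapes: ``two-peak`` (default analysis shape, peaks near 57 and 216 ms
    with peak rates of tens of spikes/s/neuron), ``sharp-peak``,
    ``broad-peak``, ``inverted-peak`` (landmark at the rate minimum), and
    ``rise-to-asymptote`` (landmark halfway up the incline).
    """
    p = dict(params or {})
    n_bins = int(round(T / bin_width))
    t = (np.arange(n_bins) + 0.5) * bin_width
    if shape == "two-peak":
        base = p.get("baseline_rate", 10.0)
        c1, a1, w1 = p.get("peak1_center", 57.0), p.get("peak1_rate", 120.0), \
            p.get("peak1_width", 8.0)
        c2, a2, w2 = p.get("peak2_center", 216.0), p.get("peak2_rate", 90.0), \
            p.get("peak2_width", 25.0)
        rate = base + a1 * _gauss(t, c1, w1) + a2 * _gauss(t, c2, w2)
        curve = TemplateCurve(np.log(rate), t, shape, (c1, c2))
        # generous landmark intervals so realistic shift magnitudes (peak-2
        # SD tens of ms) stay inside the warp domains
        mid = 0.5 * (c1 + c2)
        curve.warp_spec = WarpSpec(
            t1l=max(3 * bin_width, c1 - 4 * w1), tpeak1=c1,
            t1r=min(mid, c1 + 4 * w1), t2l=min(mid, c1 + 4 * w1), tpeak2=c2,
            t2r=min(T - 3 * bin_width, c2 + 3.5 * w2), T=T)
        return curve
    if shape == "sharp-peak":
        c, a, w = p.get("center", 216.0), p.get("rate", 40.0), p.get("width", 10.0)
        rate = p.get("baseline_rate", 4.0) + a * _gauss(t, c, w)
        return TemplateCurve(np.log(rate), t, shape, (c,))
    if shape == "broad-peak":
        c, a, w = p.get("center", 216.0), p.get("rate", 30.0), p.get("width", 60.0)
        rate = p.get("baseline_rate", 4.0) + a * _gauss(t, c, w)
        return TemplateCurve(np.log(rate), t, shape, (c,))
    if shape == "inverted-peak":
        c, a, w = p.get("center", 216.0), p.get("depth", 25.0), p.get("width", 25.0)
        base = p.get("baseline_rate", 30.0)
        rate = base - a * _gauss(t, c, w)
        return TemplateCurve(np.log(np.maximum(rate, 0.5)), t, shape, (c,))
    if shape == "rise-to-asymptote":
        c, a, s = p.get("center", 216.0), p.get("rate", 30.0), p.get("slope", 25.0)
        base = p.get("baseline_rate", 4.0)
        # logistic incline: the half-rise point (the landmark) is at `center`
        rate = base + a / (1.0 + np.exp(-(t - c) / s))
        return TemplateCurve(np.log(rate), t, shape, (c,))
    raise ValueError(f"unknown template shape {shape!r}; expected one of {SHAPES}")


def locate_template_center(curve_log_rate, grid, shape) -> float:
    """The template-matching landmark of a fitted curve, per shape.

    Peaked shapes use the argmax (argmin for an inverted peak);
    rise-to-asymptote uses the point halfway up the incline from the
    initial to the asymptotic rate.
    """
    rate = np.exp(np.asarray(curve_log_rate, dtype=float))
    if shape in ("sharp-peak", "broad-peak", "two-peak"):
        return float(grid[int(np.argmax(rate))])
    if shape == "inverted-peak":
        return float(grid[int(np.argmin(rate))])
    if shape == "rise-to-asymptote":
        lo = rate[: max(len(rate) // 10, 1)].mean()
        hi = rate[-max(len(rate) // 10, 1):].mean()
        half = 0.5 * (lo + hi)
        above = np.nonzero(rate >= half)[0]
        i = int(above[0]) if above.size else int(np.argmax(rate))
        if i > 0:  # linear interpolation across the crossing bin
            f = (half - rate[i - 1]) / max(rate[i] - rate[i - 1], 1e-12)
            return float(grid[i - 1] + f * (grid[i] - grid[i - 1]))
        return float(grid[i])
    raise ValueError(f"unknown template shape {shape!r}")


def match_center_by_likelihood(counts, reference: TemplateCurve, exposure,
                               bin_width=2.0, max_shift=60.0):
    """Locate a template's landmark from binned spike counts by profile
    likelihood over a rigid time shift of the reference log-rate.

    For each candidate shift the Poisson log-likelihood of the pooled
    counts is evaluated with the gain profiled out in closed form; the
    returned center is the reference landmark plus the maximizing shift
    (parabolic refinement around the grid optimum).  This is the
    minimum-variance matching scheme for a known shape and is what the
    warping model itself does per trial, applied here to the pooled data.
    """
    Y = np.atleast_2d(np.asarray(counts, dtype=float))
    R = Y.shape[0]
    y_sum = Y.sum(axis=0)
    total = float(y_sum.sum())
    g = reference.grid
    step = g[1] - g[0]
    dt_s = bin_width / 1000.0
    shifts = np.arange(-max_shift, max_shift + step / 2, step)
    score = np.empty(shifts.size)
    for i, d in enumerate(shifts):
        f = np.interp(g - d, g, reference.log_rate)
        integ = exposure * R * dt_s * float(np.exp(f).sum())
        # gain profiled: ghat = log(total / integ); ll up to constants
        score[i] = float(y_sum @ f) + total * (np.log(total / integ)
                                               if total > 0 else 0.0)
    k = int(np.argmax(score))
    best = shifts[k]
    if 0 < k < shifts.size - 1:
        denom = score[k - 1] - 2 * score[k] + score[k + 1]
        if denom < 0:
            best = shifts[k] + 0.5 * step * (score[k - 1] - score[k + 1]) / denom
    return float(reference.centers[0] + best)


def match_template_center(fitted_log_rate, grid, reference: TemplateCurve,
                          max_shift=60.0):
    """Locate a template's landmark in a fitted curve by matched filtering.

    Slides the reference log-rate over the fitted curve and returns the
    reference landmark plus the shift maximizing their centered inner
    product (with a parabolic refinement around the grid optimum).  Far
    more stable than an argmax for broad or asymptoting shapes, whose
    extremum sits on a noisy plateau.
    """
    f = np.asarray(fitted_log_rate, dtype=float)
    g = np.asarray(grid, dtype=float)
    ref = np.asarray(reference.log_rate, dtype=float)
    step = g[1] - g[0]
    shifts = np.arange(-max_shift, max_shift + step / 2, step)
    score = np.full(shifts.size, -np.inf)
    window = np.abs(g - reference.centers[0]) <= 150.0
    for i, d in enumerate(shifts):
        src = g - d
        valid = window & (src >= g[0]) & (src <= g[-1])
        if valid.sum() < 10:
            continue
        shifted = np.interp(src[valid], g, ref)
        a = shifted - shifted.mean()
        b = f[valid] - f[valid].mean()
        denom_n = np.linalg.norm(a) * np.linalg.norm(b)
        if denom_n > 0:
            score[i] = float(a @ b) / denom_n
    k = int(np.argmax(score))
    best = shifts[k]
    if 0 < k < shifts.size - 1:
        denom = score[k - 1] - 2 * score[k] + score[k + 1]
        if denom < 0:
            best = shifts[k] + 0.5 * step * (score[k - 1] - score[k + 1]) / denom
    return float(reference.centers[0] + best)


@dataclass
class GroundTruth:
    sigma: np.ndarray                 # (3A, 3A)
    q: dict                           # condition -> (R, 3A)
    z: dict                           # (area, condition) -> (N,) int8
    templates: dict                   # (area, condition) -> TemplateCurve
    local1_log_rate: dict             # (area, condition) -> (K,)
    local2_log_rate: dict             # (area, condition) -> float
    membership_probs: tuple = (0.25, 0.5, 0.25)
    rejection_rate: float = 0.0

    def corr(self) -> np.ndarray:
        d = np.sqrt(np.diag(self.sigma))
        return self.sigma / np.outer(d, d)


def _draw_features(rng, sigma, specs, margin, n_draws, max_tries=1000):
    """Draw q ~ N(0, Sigma); resample rows whose shifts leave a warp domain."""
    A = sigma.shape[0] // 3
    out = np.zeros((n_draws, sigma.shape[0]))
    chol = np.linalg.cholesky(sigma)
    n_rej = 0
    for i in range(n_draws):
        for attempt in range(max_tries):
            v = chol @ rng.standard_normal(sigma.shape[0])
            ok = True
            for ai in range(A):
                d1 = specs[ai].peak1_domain(margin)
                d2 = specs[ai].peak2_domain(margin)
                if not (d1[0] < v[3 * ai + 1] < d1[1] and
                        d2[0] < v[3 * ai + 2] < d2[1]):
                    ok = False
                    break
            if ok:
                out[i] = v
                break
            n_rej += 1
        else:
            raise RuntimeError("could not draw in-domain features; "
                               "Sigma too wide for the warp domains")
    return out, n_rej / max(n_rej + n_draws, 1)


def _condition_template(sim: SimulationConfig, ci: int, T, bin_width):
    """Two-peak template with mild deterministic condition-to-condition
    variation in amplitudes and the peak-2 center (conditions differ in the
    real recordings)."""
    f1 = 1.0 + 0.1 * np.cos(2.1 * ci)
    f2 = 1.0 + 0.15 * np.sin(1.7 * ci + 0.5)
    shift2 = 8.0 * np.sin(0.9 * ci)
    return make_template("two-peak", {
        "baseline_rate": sim.baseline_rate,
        "peak1_center": sim.peak1_center,
        "peak1_rate": sim.peak1_rate * f1,
        "peak1_width": sim.peak1_width,
        "peak2_center": sim.peak2_center + shift2,
        "peak2_rate": sim.peak2_rate * f2,
        "peak2_width": sim.peak2_width,
    }, T=T, bin_width=bin_width)


def _local1_curve(sim: SimulationConfig, ci: int, grid):
    """Slow, single-bump nuisance log-rate clearly distinct from the
    two-peak population template."""
    center = 300.0 + 20.0 * np.cos(1.3 * ci)
    rate = 2.0 + sim.local1_rate * _gauss(grid, center, 120.0)
    return np.log(rate)


def inject_neuron_noise(log_rates, rng, scale=1.0, n_coef=8, base_sd=0.25,
                        T=500.0):
    """Perturb each neuron's log-intensity by an independent smooth random curve.

    The perturbation is a cubic spline with i.i.d. normal coefficients
    (``base_sd`` at scale 1; variance multiplied by ``scale``), centered to
    zero mean on the grid so the population-level rate is approximately
    preserved in expectation.

    Parameters
    ----------
    log_rates : (N, K) array
        Per-neuron log-intensities to perturb (modified copies returned).
    scale : float
        Variance multiplier; 0 disables, 20 is the stress setting.
    """
    lr = np.atleast_2d(np.asarray(log_rates, dtype=float)).copy()
    if scale == 0:
        return lr
    N, K = lr.shape
    basis = build_basis(T=T, n_knots=n_coef, bin_width=T / K)
    sd = base_sd * np.sqrt(scale)
    coefs = rng.normal(0.0, sd, size=(N, basis.n_basis))
    pert = coefs @ basis.B.T
    pert -= pert.mean(axis=1, keepdims=True)
    return lr + pert


def simulate_dataset(sim: SimulationConfig = None, model: ModelConfig = None,
                     seed=None, rng=None):
    """Simulate a multi-area spike dataset from the generative model.

    Returns ``(SpikeDataset, GroundTruth)``.  Deterministic given the seed.
    """
    sim = sim or SimulationConfig()
    model = model or ModelConfig()
    if rng is None:
        rng = np.random.default_rng(sim.seed if seed is None else seed)
    T, dt = model.T, model.bin_width
    K = model.n_bins
    grid = (np.arange(K) + 0.5) * dt
    dt_s = dt / 1000.0
    A, C, R, N = sim.n_areas, sim.n_conditions, sim.n_trials, sim.n_neurons
    areas = [f"A{a+1}" for a in range(A)]
    conditions = list(range(C))
    sigma = sim.sigma_true()
    p = np.asarray(sim.membership_probs, dtype=float)

    templates, l1_curves, l2_rates, z_true = {}, {}, {}, {}
    q_true = {}
    total_rej = 0.0
    rows = []
    neuron_ids = {a: [100 * (ai + 1) + i for i in range(N)]
                  for ai, a in enumerate(areas)}
    for ci, c in enumerate(conditions):
        curves = []
        for ai, a in enumerate(areas):
            curve = _condition_template(sim, ci * A + ai, T, dt)
            templates[(a, c)] = curve
            l1_curves[(a, c)] = _local1_curve(sim, ci * A + ai, grid)
            l2_rates[(a, c)] = float(np.log(sim.local2_rate))
            curves.append(curve)
        specs = [curves[ai].warp_spec for ai in range(A)]
        q, rej = _draw_features(rng, sigma, specs, model.peak_margin, R)
        q_true[c] = q
        total_rej += rej
        for ai, a in enumerate(areas):
            z = rng.choice(3, size=N, p=p).astype(np.int8)
            z_true[(a, c)] = z
            curve = curves[ai]
            spec = curve.warp_spec
            # per-neuron log intensity per trial
            for r in range(R):
                gain, d1, d2 = q[r, 3 * ai], q[r, 3 * ai + 1], q[r, 3 * ai + 2]
                warp = build_warp(spec, d1, d2)
                u = warp.inverse(grid)
                f_warp = np.interp(u, grid, curve.log_rate) + gain
                log_int = np.empty((N, K))
                log_int[z == 0] = f_warp
                log_int[z == 1] = l1_curves[(a, c)][None, :]
                log_int[z == 2] = l2_rates[(a, c)]
                if sim.neuron_noise_scale > 0:
                    log_int = inject_neuron_noise(log_int, rng,
                                                  scale=sim.neuron_noise_scale,
                                                  T=T)
                mu = np.exp(log_int) * dt_s
                counts = rng.poisson(mu)
                n_idx, k_idx = np.nonzero(counts)
                reps = counts[n_idx, k_idx]
                n_rep = np.repeat(n_idx, reps)
                k_rep = np.repeat(k_idx, reps)
                times = (k_rep + rng.uniform(size=k_rep.size)) * dt
                times = np.minimum(times, T - 1e-9)
                ids = np.asarray(neuron_ids[a])[n_rep]
                rows.append(pd.DataFrame({
                    "neuron_id": ids, "area": a, "condition_id": c,
                    "trial_id": r, "time_ms": times}))
    df = (pd.concat(rows, ignore_index=True) if rows
          else pd.DataFrame(columns=["neuron_id", "area", "condition_id",
                                     "trial_id", "time_ms"]))
    neuron_area = {nid: a for a in areas for nid in neuron_ids[a]}
    ds = SpikeDataset(spikes=df, window=(0.0, T), neuron_area=neuron_area)
    truth = GroundTruth(sigma=sigma, q=q_true, z=z_true, templates=templates,
                        local1_log_rate=l1_curves, local2_log_rate=l2_rates,
                        membership_probs=tuple(p),
                        rejection_rate=total_rej / max(C, 1))
    if truth.rejection_rate > 0.05:
        logger.info("feature rejection rate %.3f", truth.rejection_rate)
    return ds, truth


# ---------------------------------------------------------------------------
# parameter-recovery experiment
# ---------------------------------------------------------------------------

def _pair_labels(A):
    names = []
    for a in range(A):
        for kind in ("gain", "peak1", "peak2"):
            names.append(f"A{a+1}:{kind}")
    return [(i, j, f"{names[i]}|{names[j]}")
            for i in range(3 * A) for j in range(i + 1, 3 * A)]


def fit_replicate(dataset, model: ModelConfig, seed, n_iter=600, burn_in=200,
                  thin=2, em_iter=2):
    """One simulate->fit pipeline stage: hard EM then Gibbs on a dataset."""
    from popwarp.fitting import hard_em, initialize, run_gibbs

    state = initialize(dataset, model)
    hard_em(state, max_iter=em_iter)
    return run_gibbs(state, n_iter=n_iter, burn_in=burn_in, thin=thin,
                     seed=seed)


def recovery_experiment(sim: SimulationConfig = None, model: ModelConfig = None,
                        n_replicates=20, seed=0, n_iter=600, burn_in=200,
                        thin=2, em_iter=2, keep_replicates=False):
    """Simulate -> fit -> summarize, replicated; per-pair bias/RMSE/coverage.

    For each replicate a dataset is drawn from the generative model, fitted
    by hard-EM initialization plus Gibbs sampling, and each of the pairwise
    feature correlations is estimated by the posterior median of the
    correlation computed from the Sigma draws; 95% intervals are the 0.025
    and 0.975 quantiles.  Returns a DataFrame with one row per correlation
    pair: truth, bias, RMSE, coverage, and Monte-Carlo standard errors.
    Failed replicates are recorded and excluded with a logged reason.
    """
    sim = sim or SimulationConfig()
    model = model or ModelConfig()
    A = sim.n_areas
    pairs = _pair_labels(A)
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2 ** 31 - 1, size=(n_replicates, 2))
    estimates, lowers, uppers, truths = [], [], [], []
    failures = []
    for rep in range(n_replicates):
        try:
            ds, truth = simulate_dataset(sim, model, seed=int(rep_seeds[rep, 0]))
            chain = fit_replicate(ds, model, seed=int(rep_seeds[rep, 1]),
                                  n_iter=n_iter, burn_in=burn_in, thin=thin,
                                  em_iter=em_iter)
            corr_true = truth.corr()
            d = np.sqrt(np.einsum("kii->ki", chain.sigma))
            corr_draws = chain.sigma / (d[:, :, None] * d[:, None, :])
            est = np.median(corr_draws, axis=0)
            lo = np.quantile(corr_draws, 0.025, axis=0)
            hi = np.quantile(corr_draws, 0.975, axis=0)
            estimates.append([est[i, j] for i, j, _ in pairs])
            lowers.append([lo[i, j] for i, j, _ in pairs])
            uppers.append([hi[i, j] for i, j, _ in pairs])
            truths.append([corr_true[i, j] for i, j, _ in pairs])
        except Exception as err:  # noqa: BLE001 - replicate-level isolation
            logger.warning("replicate %d failed: %s", rep, err)
            failures.append((rep, str(err)))
    if not estimates:
        raise RuntimeError(f"all replicates failed: {failures}")
    est = np.asarray(estimates)
    lo = np.asarray(lowers)
    hi = np.asarray(uppers)
    tru = np.asarray(truths)
    n_rep = est.shape[0]
    err = est - tru
    bias = err.mean(axis=0)
    rmse = np.sqrt((err ** 2).mean(axis=0))
    cover = ((lo <= tru) & (tru <= hi)).mean(axis=0)
    out = pd.DataFrame({
        "pair": [lab for _, _, lab in pairs],
        "truth": tru[0],
        "bias": bias,
        "rmse": rmse,
        "coverage": cover,
        "bias_se": err.std(axis=0, ddof=1) / np.sqrt(n_rep),
        "coverage_se": np.sqrt(cover * (1 - cover) / n_rep),
        "n_replicates": n_rep,
    })
    out.attrs["failures"] = failures
    if keep_replicates:
        out.attrs["estimates"] = est
        out.attrs["truths"] = tru
        out.attrs["lowers"] = lo
        out.attrs["uppers"] = hi
    return out


def summarize_recovery(table: pd.DataFrame) -> dict:
    """Scalar summaries of a recovery table (used by the acceptance report)."""
    return {
        "max_rmse": float(table["rmse"].max()),
        "mean_rmse": float(table["rmse"].mean()),
        "mean_bias": float(table["bias"].mean()),
        "mean_coverage": float(table["coverage"].mean()),
    }
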