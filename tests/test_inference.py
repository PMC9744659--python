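import numpy as np
import pandas as pd
import pytest

from popwarp.inference import (NaiveSmoothing, PosteriorSummary, corr_from_sigma,
                               fisher_z_ci, naive_peak_times, partial_corr,
                               peak_times_and_lags, posterior_functionals,
                               regression_slope)


class TestCorrFromSigma:
    def test_identity(self):
        assert np.allclose(corr_from_sigma(np.eye(4)), np.eye(4))

    def test_closed_form(self):
        rho = corr_from_sigma(np.array([[4.0, 3.0], [3.0, 9.0]]))
        assert rho[0, 1] == pytest.approx(0.5)

    def test_idempotent(self, rng):
        A = rng.standard_normal((5, 5))
        sigma = A @ A.T + 5 * np.eye(5)
        rho = corr_from_sigma(sigma)
        assert np.allclose(corr_from_sigma(rho), rho)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            corr_from_sigma(np.diag([1.0, 0.0]))


class TestPartialCorr:
    def sigma_from_corr(self, r12, r13, r23):
        return np.array([[1, r12, r13], [r12, 1, r23], [r13, r23, 1.0]])

    def test_closed_form_example(self):
        s = self.sigma_from_corr(0.9, 0.9, 0.9)
        assert partial_corr(s, 0, 1, 2) == pytest.approx(0.09 / 0.19)

    def test_uncorrelated_conditioner(self):
        s = self.sigma_from_corr(0.4, 0.0, 0.0)
        assert partial_corr(s, 0, 1, 2) == pytest.approx(0.4)

    def test_matches_residual_regression_oracle(self, rng):
        """Partial correlation equals the correlation of the residuals from
        least-squares regressions on the conditioning variable."""
        n = 200000
        z = rng.standard_normal(n)
        x = 0.7 * z + rng.standard_normal(n)
        y = -0.4 * z + 0.5 * x + rng.standard_normal(n)
        sigma = np.cov(np.vstack([x, y, z]))
        rx = x - np.polyval(np.polyfit(z, x, 1), z)
        ry = y - np.polyval(np.polyfit(z, y, 1), z)
        ref = np.corrcoef(rx, ry)[0, 1]
        assert partial_corr(sigma, 0, 1, 2) == pytest.approx(ref, abs=1e-10)

    def test_vector_conditioning_matches_scalar(self, rng):
        A = rng.standard_normal((4, 4))
        sigma = A @ A.T + 4 * np.eye(4)
        assert partial_corr(sigma, 0, 1, 2) == pytest.approx(
            partial_corr(sigma, 0, 1, [2]))

    def test_regression_slope(self):
        sigma = np.array([[4.0, 2.0], [2.0, 1.0]])
        assert regression_slope(sigma, 0, 1) == pytest.approx(2.0)


class TestFisherZ:
    def test_null_interval_width(self):
        lo, hi = fisher_z_ci(0.0, 195)
        assert hi == pytest.approx(np.tanh(1.96 / np.sqrt(192)), abs=5e-4)
        assert lo == pytest.approx(-hi)
        assert hi == pytest.approx(0.141, abs=1e-3)

    def test_r_half_closed_form(self):
        lo, hi = fisher_z_ci(0.5, 195)
        assert lo == pytest.approx(0.387, abs=1e-3)
        assert hi == pytest.approx(0.598, abs=1e-3)

    def test_endpoints_inside_unit_interval(self):
        for r in (-0.999, -0.5, 0.0, 0.9, 0.999):
            lo, hi = fisher_z_ci(r, 10)
            assert -1 < lo < hi < 1

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            fisher_z_ci(0.5, 3)


class _FakeChain:
    """Minimal chain with deterministic Sigma and q draws."""

    def __init__(self, sigmas, q=None, areas=("A1", "A2"), conditions=(0,)):
        self.sigma = np.asarray(sigmas)
        self.q = (np.zeros((len(sigmas), len(conditions), 4,
                            3 * len(areas))) if q is None else q)
        self.areas = list(areas)
        self.conditions = list(conditions)
        self.n_trials = self.q.shape[2]
        from popwarp.warping import WarpSpec

        self.warp_specs = {(a, c): WarpSpec(40, 57, 80, 150, 216, 300, 500)
                           for a in self.areas for c in self.conditions}

    def feature_index(self, area, feature):
        return 3 * self.areas.index(area) + {"gain": 0, "peak1": 1,
                                             "peak2": 2}[feature]


class TestPosteriorFunctionals:
    def test_constant_chain_zero_width(self):
        sig = np.tile(np.eye(6), (150, 1, 1))
        s = posterior_functionals(_FakeChain(sig), lambda m: m[0, 1])
        assert s.q025 == s.q975 == s.median == 0.0

    def test_quantiles_match_direct_sort(self, rng):
        vals = rng.standard_normal(400)
        sig = np.array([np.eye(6) * (1 + 0.0) + v * 0 for v in vals])
        # encode the sample in an off-diagonal entry of a PD matrix
        for i, v in enumerate(vals):
            sig[i] = np.eye(6)
            sig[i, 0, 1] = sig[i, 1, 0] = np.tanh(v) * 0.99
        s = posterior_functionals(_FakeChain(sig),
                                  lambda m: m[0, 1])
        samples = np.tanh(vals) * 0.99
        assert s.median == pytest.approx(np.median(samples))
        assert s.q025 == pytest.approx(np.quantile(samples, 0.025))
        assert s.q975 == pytest.approx(np.quantile(samples, 0.975))

    def test_monotone_transform_equivariance(self, rng):
        vals = rng.uniform(-0.8, 0.8, 300)
        sig = np.array([np.eye(6) for _ in vals])
        for i, v in enumerate(vals):
            sig[i, 0, 1] = sig[i, 1, 0] = v
        chain = _FakeChain(sig)
        s_raw = posterior_functionals(chain, lambda m: m[0, 1])
        s_tr = posterior_functionals(chain, lambda m: np.arctanh(m[0, 1]))
        # quantile interpolation does not commute exactly with nonlinear maps
        assert s_tr.q025 == pytest.approx(np.arctanh(s_raw.q025), abs=0.02)
        assert s_tr.q975 == pytest.approx(np.arctanh(s_raw.q975), abs=0.02)

    def test_few_draws_warns(self):
        sig = np.tile(np.eye(6), (20, 1, 1))
        with pytest.warns(UserWarning, match="kept draws"):
            posterior_functionals(_FakeChain(sig), lambda m: m[0, 1])


class TestPeakTimesAndLags:
    def test_zero_q_gives_template_landmarks(self):
        sig = np.tile(np.eye(6), (120, 1, 1))
        chain = _FakeChain(sig)
        out = peak_times_and_lags(chain)
        assert np.allclose(out["peak_times"][("A1", "peak1")], 57.0)
        assert np.allclose(out["peak_times"][("A1", "peak2")], 216.0)

    def test_identical_areas_zero_lags(self):
        sig = np.tile(np.eye(6), (120, 1, 1))
        q = np.zeros((120, 1, 4, 6))
        q[:, :, :, 2] = 10.0   # A1 peak2 shift
        q[:, :, :, 5] = 10.0   # A2 peak2 shift identical
        out = peak_times_and_lags(_FakeChain(sig, q=q))
        assert np.allclose(out["lags"][("A1", "A2", "peak2")], 0.0)

    def test_planted_lag_recovered(self):
        sig = np.tile(np.eye(6), (120, 1, 1))
        q = np.zeros((120, 1, 4, 6))
        q[:, :, :, 5] = 10.0   # A2 peak-2 later by 10 ms on every trial
        out = peak_times_and_lags(_FakeChain(sig, q=q))
        med = out["summaries"][("A1", "A2", "peak2")][0]
        assert med == pytest.approx(10.0, abs=2.0)


class TestNaivePeakTimes:
    def _dataset_with_bumps(self, centers_by_trial, rng, n_neurons=12,
                            rate=80.0, width=12.0):
        rows = []
        grid = np.arange(0.5, 500, 2.0)
        for r, center in enumerate(centers_by_trial):
            lam = (3 + rate * np.exp(-0.5 * ((grid - center) / width) ** 2)) \
                * 0.002
            for n in range(n_neurons):
                counts = rng.poisson(lam)
                for k in np.nonzero(counts)[0]:
                    for _ in range(counts[k]):
                        rows.append((n, "V1", 0, r,
                                     float(grid[k] + rng.uniform(-1, 1))))
        df = pd.DataFrame(rows, columns=["neuron_id", "area", "condition_id",
                                         "trial_id", "time_ms"])
        from popwarp.data import SpikeDataset

        return SpikeDataset(spikes=df.assign(
            time_ms=df.time_ms.clip(0, 499.9)), window=(0.0, 500.0))

    def test_noiseless_bump_located(self, rng):
        ds = self._dataset_with_bumps([216.0], rng, n_neurons=40, rate=200.0)
        out = naive_peak_times(ds, ds.neurons("V1"), condition=0)
        assert out.peak_time[0] == pytest.approx(216.0, abs=4.0)

    def test_shift_difference_recovered(self, rng):
        ds = self._dataset_with_bumps([206.0, 226.0], rng, n_neurons=40,
                                      rate=200.0)
        out = naive_peak_times(ds, ds.neurons("V1"), condition=0)
        diff = out.peak_time[1] - out.peak_time[0]
        assert diff == pytest.approx(20.0, abs=5.0)

    def test_empty_trial_gives_nan(self):
        from popwarp.data import SpikeDataset

        df = pd.DataFrame([(1, "V1", 0, 0, 100.0), (1, "V1", 0, 1, 1e9)],
                          columns=["neuron_id", "area", "condition_id",
                                   "trial_id", "time_ms"])
        df = df[df.time_ms < 500]
        df = pd.concat([df, pd.DataFrame(
            [(1, "V1", 0, 1, 100.0)],
            columns=df.columns)]).reset_index(drop=True)
        ds = SpikeDataset(spikes=df, window=(0.0, 500.0))
        out = naive_peak_times(ds, [1], condition=0,
                               smoothing=NaiveSmoothing(eta_grid=(1e-3,)))
        assert len(out) == 2
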