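import numpy as np
import pytest
from scipy.integrate import quad

from refrma import (
    NormexpParams,
    ProbeDataError,
    background_correct,
    estimate_normexp_params,
    median_polish,
    quantile_normalize_cohort,
    rma_cohort,
    summarize_cohort,
)
from refrma.synthetic import SimConfig, simulate_probe_data


def normexp_posterior_mean_quadrature(o, mu, sigma, beta):
    """Independent oracle: E[s | o] by adaptive quadrature of the
    (unnormalized) posterior, prior(s) x likelihood(o | s).

    The posterior mass concentrates within a few sigma of
    a = o - mu - sigma^2/beta, so a +-13 sigma window (clipped to s >= 0)
    captures it while keeping the spike resolvable; the integrand is
    rescaled by its peak magnitude so neither integral underflows.
    """
    a = o - mu - sigma**2 / beta
    lo = max(0.0, a - 13.0 * sigma)
    hi = max(a, 0.0) + 13.0 * sigma
    log_peak = -max(a, 0.0) / beta
    density = lambda s: np.exp(
        -s / beta - 0.5 * ((o - s - mu) / sigma) ** 2 - log_peak)
    num, _ = quad(lambda s: s * density(s), lo, hi, limit=500)
    den, _ = quad(density, lo, hi, limit=500)
    return num / den


class TestNormexpEstimation:
    def test_recovers_parameters_from_convolution_sample(self):
        rng = np.random.default_rng(42)
        x = rng.exponential(200, 100_000) + rng.normal(100, 15, 100_000)
        p = estimate_normexp_params(x)
        assert p.mu == pytest.approx(100, rel=0.10)
        assert p.sigma == pytest.approx(15, rel=0.10)
        assert p.signal_mean == pytest.approx(200, rel=0.10)

    def test_background_recovered_under_strong_signal(self):
        rng = np.random.default_rng(43)
        x = rng.exponential(2000, 100_000) + rng.normal(100, 15, 100_000)
        p = estimate_normexp_params(x)
        assert p.mu == pytest.approx(100, rel=0.15)
        assert p.signal_mean == pytest.approx(2000, rel=0.10)

    def test_constant_input_rejected(self):
        with pytest.raises(ProbeDataError, match="constant"):
            estimate_normexp_params(np.full(1000, 7.0))

    def test_tiny_input_rejected(self):
        with pytest.raises(ProbeDataError, match=">= 10"):
            estimate_normexp_params(np.arange(1, 6, dtype=float))


class TestBackgroundCorrection:
    def test_matches_quadrature_oracle_at_spec_point(self):
        params = NormexpParams(mu=100, sigma=50, signal_mean=200)
        got = background_correct(np.array([500.0]), params)[0]
        expected = normexp_posterior_mean_quadrature(500, 100, 50, 200)
        assert got == pytest.approx(expected, rel=1e-9)

    @pytest.mark.parametrize("o,mu,sigma,beta", [
        (120.0, 100.0, 15.0, 200.0),
        (80.0, 100.0, 15.0, 200.0),   # observation below background mean
        (5000.0, 100.0, 15.0, 2000.0),
        (30.0, 100.0, 30.0, 50.0),
    ])
    def test_matches_quadrature_oracle(self, o, mu, sigma, beta):
        got = background_correct(np.array([o]), NormexpParams(mu, sigma, beta))[0]
        expected = normexp_posterior_mean_quadrature(o, mu, sigma, beta)
        assert got == pytest.approx(expected, rel=1e-6)

    def test_deep_left_tail_is_small_and_positive(self):
        params = NormexpParams(mu=100, sigma=15, signal_mean=200)
        out = background_correct(np.array([100 - 5 * 15.0]), params)[0]
        # for a deeply negative observation the posterior mean collapses
        # toward sigma^2 / |a|, a small positive value
        assert 0 < out < 5.0

    def test_strictly_monotone_and_positive(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            params = NormexpParams(
                mu=rng.uniform(10, 500),
                sigma=rng.uniform(1, 100),
                signal_mean=rng.uniform(10, 5000),
            )
            o = np.sort(rng.uniform(-200, 10_000, 500))
            out = background_correct(o, params)
            assert np.all(out > 0)
            assert np.all(np.diff(out) > 0)


class TestQuantileNormalization:
    def test_hand_computed_two_columns(self):
        X = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]])
        out = quantile_normalize_cohort(X)
        expected = np.array([[1.5, 1.5], [3.5, 3.5], [5.5, 5.5]])
        np.testing.assert_allclose(out, expected)

    def test_identical_columns_are_a_fixed_point(self):
        col = np.array([4.0, 1.0, 9.0, 2.0])
        X = np.column_stack([col, col, col])
        np.testing.assert_allclose(quantile_normalize_cohort(X), X)

    def test_ties_share_mean_of_spanned_targets(self):
        # column 1 has a tie at ranks 2-3; target comes out [1.5, 4.5, 5.5]
        X = np.array([[5.0, 2.0], [5.0, 4.0], [1.0, 6.0]])
        out = quantile_normalize_cohort(X)
        np.testing.assert_allclose(out[:, 0], [5.0, 5.0, 1.5])
        np.testing.assert_allclose(out[:, 1], [1.5, 4.5, 5.5])

    def test_sorted_columns_equal_target_exactly(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(1, 1e4, size=(500, 6))
        out = quantile_normalize_cohort(X)
        target = np.sort(X, axis=0).mean(axis=1)
        for j in range(6):
            np.testing.assert_allclose(np.sort(out[:, j]), target, atol=1e-9, rtol=0)

    def test_single_sample_rejected(self):
        with pytest.raises(ProbeDataError, match="one-by-one"):
            quantile_normalize_cohort(np.ones((10, 1)))


def median_polish_oracle(matrix, tol=1e-6, max_iter=100):
    """Independent row/column median-sweep implementation (R medpolish style)."""
    r = np.array(matrix, dtype=float)
    overall = 0.0
    re_ = np.zeros(r.shape[0])
    ce = np.zeros(r.shape[1])
    for _ in range(max_iter):
        rd = np.median(r, axis=1)
        r = r - rd[:, None]
        re_ = re_ + rd
        d = np.median(ce)
        ce = ce - d
        overall += d
        cd = np.median(r, axis=0)
        r = r - cd[None, :]
        ce = ce + cd
        d = np.median(re_)
        re_ = re_ - d
        overall += d
        if max(np.abs(np.median(r, axis=1)).max(),
               np.abs(np.median(r, axis=0)).max()) <= tol:
            break
    d = np.median(re_); re_ -= d; overall += d
    d = np.median(ce); ce -= d; overall += d
    return overall, re_, ce, r


class TestMedianPolish:
    def test_recovers_exactly_additive_decomposition(self):
        r = np.array([-1.0, 0.0, 2.0, 0.0, -2.0])   # median 0
        c = np.array([3.0, 0.0, -3.0])              # median 0
        M = 5.0 + r[:, None] + c[None, :]
        overall, row_eff, col_eff, resid, converged = median_polish(M)
        assert converged
        assert overall == pytest.approx(5.0)
        np.testing.assert_allclose(row_eff, r, atol=1e-12)
        np.testing.assert_allclose(col_eff, c, atol=1e-12)
        np.testing.assert_allclose(resid, 0, atol=1e-12)

    def test_constant_matrix(self):
        overall, row_eff, col_eff, resid, _ = median_polish(np.full((4, 3), 2.5))
        assert overall == pytest.approx(2.5)
        np.testing.assert_allclose(row_eff, 0, atol=1e-12)
        np.testing.assert_allclose(col_eff, 0, atol=1e-12)

    def test_matches_independent_sweep_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            M = rng.normal(size=(11, 30))
            overall, row_eff, col_eff, resid, _ = median_polish(M)
            o2, r2, c2, res2 = median_polish_oracle(M)
            assert overall == pytest.approx(o2, abs=1e-12)
            np.testing.assert_allclose(row_eff, r2, atol=1e-12)
            np.testing.assert_allclose(col_eff, c2, atol=1e-12)
            np.testing.assert_allclose(resid, res2, atol=1e-12)

    def test_reconstruction_identity_and_residual_medians(self):
        rng = np.random.default_rng(12)
        M = rng.normal(size=(11, 30))
        overall, row_eff, col_eff, resid, converged = median_polish(M)
        recon = overall + row_eff[:, None] + col_eff[None, :] + resid
        np.testing.assert_allclose(recon, M, atol=1e-9)
        assert converged
        assert np.abs(np.median(resid, axis=1)).max() <= 1e-6
        assert np.abs(np.median(resid, axis=0)).max() <= 1e-6
        assert np.median(row_eff) == pytest.approx(0, abs=1e-12)
        assert np.median(col_eff) == pytest.approx(0, abs=1e-12)


class TestSummarizeCohort:
    def test_identical_probe_rows_give_common_row(self, toy_layout):
        row = np.array([6.0, 7.0, 8.5])
        X = np.tile(row, (6, 1))
        expr = summarize_cohort(X, toy_layout, ["a", "b", "c"])
        np.testing.assert_allclose(expr.values[0], row)
        np.testing.assert_allclose(expr.values[1], row)

    def test_single_probe_probeset_passthrough(self):
        from refrma import ChipLayout
        layout = ChipLayout(probe_ids=["p0"], probe_to_probeset={"p0": "ps0"})
        X = np.array([[3.0, 4.0]])
        expr = summarize_cohort(X, layout, ["a", "b"])
        np.testing.assert_allclose(expr.values, X)

    def test_matches_per_block_median_polish(self, toy_layout):
        rng = np.random.default_rng(5)
        X = rng.normal(7, 1, size=(6, 4))
        expr = summarize_cohort(X, toy_layout, list("abcd"))
        for k, ps in enumerate(toy_layout.probeset_ids):
            block = X[toy_layout.probe_rows(ps), :]
            overall, _, col_eff, _ = median_polish_oracle(block)
            np.testing.assert_allclose(expr.values[k], overall + col_eff, atol=1e-12)


@pytest.fixture(scope="module")
def small_cohort():
    cfg = SimConfig(n_probesets=60, probes_per_set=5, n_samples=8,
                    n_informative=0, seed=21)
    return simulate_probe_data(cfg)


class TestRmaCohort:
    def test_output_shape(self, small_cohort):
        pm, layout, _ = small_cohort
        expr = rma_cohort(pm, layout)
        assert expr.values.shape == (layout.n_probesets, pm.n_samples)

    def test_duplicated_sample_gives_identical_columns(self, small_cohort):
        from refrma import ProbeMatrix
        pm, layout, _ = small_cohort
        dup = ProbeMatrix(pm.probe_ids, ["x", "y", "z"],
                          np.column_stack([pm.intensities[:, 0]] * 2
                                          + [pm.intensities[:, 1]]))
        expr = rma_cohort(dup, layout)
        np.testing.assert_allclose(expr.values[:, 0], expr.values[:, 1], atol=1e-12)

    def test_tracks_simulated_true_signal(self):
        cfg = SimConfig(n_probesets=150, n_samples=20, n_informative=0,
                        noise_sd=0.4, seed=22)
        pm, layout, truth = simulate_probe_data(cfg)
        expr = rma_cohort(pm, layout).to_frame()
        rs = [np.corrcoef(expr.loc[ps], truth.signal.loc[ps])[0, 1]
              for ps in layout.probeset_ids]
        assert np.median(rs) >= 0.9
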