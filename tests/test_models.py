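"""GLS/LMM with ARMA errors, KPSS, AIC selection, LRT, Satterthwaite, diagnostics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import linalg, signal, stats

from bbbflux.models import (
    ArmaSpec,
    LinearMixedModel,
    MarginalGLS,
    _join_params,
    arma_correlation_matrix,
    compare_models_lrt,
    fit_linear_mixed,
    fit_marginal_gls,
    kpss_test,
    model_diagnostics,
    satterthwaite_df,
    select_arma_by_aic,
    type1_f_tests,
)


def _arma_blocks(spec, n_subj, n_i, rng, sigma=1.0):
    R = arma_correlation_matrix(spec, n_i)
    L = linalg.cholesky(R, lower=True)
    return [sigma * (L @ rng.standard_normal(n_i)) for _ in range(n_subj)]


def _design(n_subj, n_i, rng, beta=(1.0, 0.5, -0.3)):
    Xs, gs = [], []
    for i in range(n_subj):
        X = np.column_stack(
            [np.ones(n_i), np.linspace(-1, 1, n_i), rng.normal(size=n_i)]
        )
        Xs.append(X)
        gs.append(np.full(n_i, i))
    X = np.vstack(Xs)
    return X, np.concatenate(gs), X @ np.asarray(beta)


class TestArmaCorrelationMatrix:
    def test_white_noise_identity(self):
        assert np.allclose(arma_correlation_matrix(ArmaSpec(0, 0), 5), np.eye(5))

    def test_ar1_closed_form(self):
        R = arma_correlation_matrix(ArmaSpec(1, 0, (0.5,)), 6)
        for k in range(6):
            assert R[0, k] == pytest.approx(0.5**k)

    def test_arma11_lag_one_closed_form(self):
        phi, th = 0.976, 0.563
        R = arma_correlation_matrix(ArmaSpec(1, 1, (phi,), (th,)), 3)
        rho1 = (1 + phi * th) * (phi + th) / (1 + th**2 + 2 * phi * th)
        assert R[0, 1] == pytest.approx(rho1, abs=1e-12)
        assert R[0, 2] == pytest.approx(phi * rho1, abs=1e-12)

    def test_lag_one_matches_long_simulation(self):
        phi, th = 0.7, 0.3
        e = np.random.default_rng(3).standard_normal(1_000_000)
        x = signal.lfilter([1, th], [1, -phi], e)[1000:]
        sim = np.corrcoef(x[:-1], x[1:])[0, 1]
        R = arma_correlation_matrix(ArmaSpec(1, 1, (phi,), (th,)), 2)
        assert R[0, 1] == pytest.approx(sim, abs=3e-3)

    @given(phi=st.floats(-0.95, 0.95), th=st.floats(-0.95, 0.95))
    @settings(max_examples=40, deadline=None)
    def test_positive_definite_for_stationary_specs(self, phi, th):
        R = arma_correlation_matrix(ArmaSpec(1, 1, (phi,), (th,)), 12)
        linalg.cholesky(R)  # raises if not PD
        assert np.allclose(np.diag(R), 1.0)

    def test_non_stationary_rejected(self):
        with pytest.raises(ValueError):
            ArmaSpec(1, 0, (1.01,))
        with pytest.raises(ValueError):
            ArmaSpec(1, 1, (0.5,), (-1.2,))


class TestMarginalGLS:
    def test_order_zero_equals_ols(self, rng):
        X, g, mu = _design(5, 8, rng)
        y = mu + 0.5 * rng.standard_normal(len(mu))
        fit = fit_marginal_gls(y, X, g, order=(0, 0))
        b_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert np.allclose(fit.params["estimate"], b_ols, atol=1e-8)

    def test_optimum_beats_profile_likelihood_grid(self, rng):
        spec = ArmaSpec(1, 0, (0.6,))
        X, g, mu = _design(2, 6, rng, beta=(1.0, 0.5, 0.0))
        e = np.concatenate(_arma_blocks(spec, 2, 6, rng, sigma=0.5))
        model = MarginalGLS(mu + e, X, g, order=(1, 1))
        fit = model.fit(estimation="ml")
        grid_best = max(
            -model.nll(_join_params([p], [q]), reml=False)
            for p in np.linspace(-0.95, 0.95, 21)
            for q in np.linspace(-0.95, 0.95, 21)
        )
        assert fit.loglik_ml >= grid_best - 1e-4

    def test_aic_identity(self, rng):
        X, g, mu = _design(4, 10, rng)
        y = mu + rng.standard_normal(len(mu))
        for order in [(0, 0), (1, 0), (1, 1)]:
            fit = fit_marginal_gls(y, X, g, order=order, estimation="ml")
            assert fit.aic == -2 * fit.loglik + 2 * fit.n_params

    def test_parameter_recovery_at_large_n(self):
        """Estimates recover the generating coefficients at 50x study size."""
        rng = np.random.default_rng(7)
        beta = np.array([-1.13, -3.82, 0.665, 0.0247, -0.0676])
        spec = ArmaSpec(1, 1, (0.976,), (0.563,))
        n_subj, n_i = 800, 25
        R = arma_correlation_matrix(spec, n_i)
        L = linalg.cholesky(R, lower=True)
        Xs, ys, gs = [], [], []
        for i in range(n_subj):
            t = np.linspace(-1, 1, n_i)
            X = np.column_stack(
                [np.ones(n_i), t, t**2,
                 np.cumsum(rng.normal(size=n_i)) * 0.2,
                 np.cumsum(rng.normal(size=n_i)) * 0.2]
            )
            ys.append(X @ beta + 0.3 * (L @ rng.standard_normal(n_i)))
            Xs.append(X)
            gs.append(np.full(n_i, i))
        fit = fit_marginal_gls(
            np.concatenate(ys), np.vstack(Xs), np.concatenate(gs),
            order=(1, 1), estimation="ml", n_starts=2,
        )
        z = (fit.params["estimate"].to_numpy() - beta) / fit.params["se"].to_numpy()
        assert np.all(np.abs(z) < 3)
        assert fit.arma.phi[0] == pytest.approx(0.976, abs=0.01)
        assert fit.arma.theta[0] == pytest.approx(0.563, abs=0.05)

    def test_arma_cis_bracket_estimates(self, rng):
        spec = ArmaSpec(1, 1, (0.7,), (0.3,))
        X, g, mu = _design(8, 20, rng)
        e = np.concatenate(_arma_blocks(spec, 8, 20, rng, sigma=0.4))
        fit = fit_marginal_gls(mu + e, X, g, order=(1, 1))
        lo, hi = fit.arma.phi_ci[0]
        assert lo <= fit.arma.phi[0] <= hi
        lo, hi = fit.arma.theta_ci[0]
        assert lo <= fit.arma.theta[0] <= hi

    def test_singular_design_rejected(self, rng):
        X = np.ones((20, 2))
        with pytest.raises(ValueError):
            fit_marginal_gls(rng.normal(size=20), X, np.repeat([0, 1], 10))


class TestLinearMixed:
    def test_psi_zero_reduces_to_gls(self, rng):
        X, g, mu = _design(5, 8, rng)
        y = mu + 0.5 * rng.standard_normal(len(mu))
        z = X[:, 1]
        gls = MarginalGLS(y, X, g, order=(1, 1))
        lmm = LinearMixedModel(y, X, g, z, order=(1, 1))
        u = np.array([0.4, -0.1])
        assert lmm.nll(np.r_[u, 0.0, 0.0, 0.0], True) == pytest.approx(
            gls.nll(u, True), abs=1e-6
        )

    def test_random_intercept_variance_recovery(self):
        """Psi recovered within 10% of the realized random-effect variance
        (200 subjects), and the whole fit agrees with statsmodels MixedLM."""
        rng = np.random.default_rng(12)
        n_subj, n_i = 200, 6
        sigma, tau0, tau1 = 0.5, 0.8, 0.4
        Xs, ys, gs, zs, bs = [], [], [], [], []
        for i in range(n_subj):
            t = np.linspace(-1, 1, n_i)
            X = np.column_stack([np.ones(n_i), t])
            b = np.array([tau0 * rng.standard_normal(), tau1 * rng.standard_normal()])
            bs.append(b)
            ys.append(X @ np.array([1.0, -0.5]) + X @ b + sigma * rng.standard_normal(n_i))
            Xs.append(X)
            gs.append(np.full(n_i, i))
            zs.append(t)
        y = np.concatenate(ys)
        X = np.vstack(Xs)
        g = np.concatenate(gs)
        z = np.concatenate(zs)
        fit = fit_linear_mixed(y, X, g, z, order=(0, 0), estimation="reml")
        psi = fit.random_effects
        b_emp = np.var(np.array(bs), axis=0, ddof=1)
        assert psi[0, 0] == pytest.approx(b_emp[0], rel=0.10)
        assert psi[1, 1] == pytest.approx(b_emp[1], rel=0.15)
        assert fit.sigma2 == pytest.approx(sigma**2, rel=0.10)
        # independent oracle: statsmodels MixedLM on the same data
        smf = pytest.importorskip("statsmodels.formula.api")
        ref = smf.mixedlm(
            "y ~ t", pd.DataFrame({"y": y, "t": z, "g": g}), groups="g",
            re_formula="~t",
        ).fit(reml=True)
        assert np.allclose(psi, ref.cov_re.values, atol=1e-3)
        assert fit.sigma2 == pytest.approx(ref.scale, abs=1e-4)

    def test_boundary_psi_flagged_when_no_random_effects(self, rng):
        X, g, mu = _design(6, 10, rng)
        y = mu + 0.3 * rng.standard_normal(len(mu))
        fit = fit_linear_mixed(y, X, g, X[:, 1], order=(0, 0))
        assert fit.boundary_psi
        assert "marginal model" in fit.message

    def test_too_few_subjects_rejected(self, rng):
        X, g, mu = _design(2, 8, rng)
        with pytest.raises(ValueError):
            fit_linear_mixed(mu, X, g, X[:, 1])


class TestKpss:
    def test_hand_computed_statistic_truncation_zero(self):
        x = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 2.5, 3.5, 1.5])
        e = x - x.mean()
        s = np.cumsum(e)
        by_hand = np.sum(s**2) / (len(x) ** 2 * np.mean(e**2))
        res = kpss_test(x, lag_truncation=0)
        assert res.statistic == pytest.approx(by_hand, rel=1e-10)

    def test_default_truncation_rule(self):
        res = kpss_test(np.random.default_rng(0).standard_normal(200))
        assert res.lag_truncation == int(np.floor(4 * (200 / 100) ** 0.25))

    def test_white_noise_usually_not_rejected(self):
        rejections = sum(
            kpss_test(np.random.default_rng(i).standard_normal(200)).verdict
            == "rejected"
            for i in range(30)
        )
        assert rejections <= 5

    def test_random_walk_rejected(self):
        x = np.cumsum(np.random.default_rng(5).standard_normal(200))
        assert kpss_test(x).verdict == "rejected"

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            kpss_test(np.ones(50))
        with pytest.raises(ValueError):
            kpss_test(np.arange(4.0))


class TestSelectArma:
    def test_single_candidate_returned(self, rng):
        X, g, mu = _design(4, 8, rng)
        y = mu + rng.standard_normal(len(mu))
        best, table = select_arma_by_aic(y, X, g, candidates=[(1, 0)])
        assert (best.arma.p, best.arma.q) == (1, 0)
        assert len(table) == 1

    def test_selection_consistency_under_strong_arma11(self):
        hits = 0
        for rep in range(6):
            rng = np.random.default_rng(100 + rep)
            spec = ArmaSpec(1, 1, (0.8,), (0.5,))
            X, g, mu = _design(8, 30, rng)
            e = np.concatenate(_arma_blocks(spec, 8, 30, rng, sigma=0.5))
            best, _ = select_arma_by_aic(
                mu + e, X, g, candidates=[(0, 0), (1, 0), (0, 1), (1, 1)],
                estimation="ml",
            )
            hits += (best.arma.p, best.arma.q) == (1, 1)
        assert hits >= 5

    def test_independent_errors_prefer_white_noise_on_average(self):
        deltas = []
        for rep in range(8):
            rng = np.random.default_rng(200 + rep)
            X, g, mu = _design(6, 12, rng)
            y = mu + rng.standard_normal(len(mu))
            _, table = select_arma_by_aic(
                y, X, g, candidates=[(0, 0), (1, 1)], estimation="ml"
            )
            t = table.set_index(["p", "q"])["aic"]
            deltas.append(t.loc[(1, 1)] - t.loc[(0, 0)])
        assert np.mean(deltas) > 0


class TestLrtAndFTests:
    def _nested_fits(self, rng, effect=0.0, n_subj=6, n_i=10):
        X, g, mu = _design(n_subj, n_i, rng, beta=(1.0, 0.5, effect))
        y = mu + rng.standard_normal(len(mu))
        full = fit_marginal_gls(y, X, g, order=(0, 0), estimation="ml",
                                terms=("intercept", "time", "extra"))
        reduced = fit_marginal_gls(y, X[:, :2], g, order=(0, 0), estimation="ml",
                                   terms=("intercept", "time"))
        return full, reduced

    def test_identical_models_give_p_one(self, rng):
        full, _ = self._nested_fits(rng)
        res = compare_models_lrt(full, full)
        assert res.statistic == 0.0 and res.p == 1.0 and res.df == 0

    def test_large_effect_detected(self):
        rejections = 0
        for rep in range(10):
            rng = np.random.default_rng(300 + rep)
            full, reduced = self._nested_fits(rng, effect=2.0)
            rejections += compare_models_lrt(full, reduced).p <= 0.05
        assert rejections >= 9

    def test_non_nested_rejected(self, rng):
        full, reduced = self._nested_fits(rng)
        with pytest.raises(ValueError):
            compare_models_lrt(reduced, full)

    def test_type1_f_detects_entered_effect(self, rng):
        X, g, mu = _design(6, 10, rng, beta=(1.0, 2.0, 0.0))
        y = mu + 0.5 * rng.standard_normal(len(mu))
        fit = fit_marginal_gls(y, X, g, order=(0, 0),
                               terms=("intercept", "time", "noise"))
        table = type1_f_tests(fit)
        assert table.loc["time", "p"] < 0.001
        assert table.loc["noise", "p"] > 0.01


class TestSatterthwaite:
    def test_one_sample_reduction(self, rng):
        y = rng.normal(size=25)
        fit = fit_marginal_gls(y, np.ones((25, 1)), np.repeat("s", 25),
                               order=(0, 0), estimation="reml")
        df, p, fallback = satterthwaite_df(fit, [1.0])
        assert not fallback
        assert df == pytest.approx(24, rel=1e-3)

    def test_balanced_random_intercept_between_subject_df(self):
        rng = np.random.default_rng(21)
        n_subj, n_i = 12, 8
        ys, gs = [], []
        for i in range(n_subj):
            ys.append(1.0 + 1.5 * rng.standard_normal() + 0.3 * rng.standard_normal(n_i))
            gs.append(np.full(n_i, i))
        y = np.concatenate(ys)
        g = np.concatenate(gs)
        fit = fit_linear_mixed(y, np.ones((len(y), 1)), g, np.zeros(len(y)),
                               order=(0, 0), estimation="reml",
                               terms=("intercept",))
        df, _, fallback = satterthwaite_df(fit, "intercept")
        assert not fallback
        assert df == pytest.approx(n_subj - 1, rel=0.10)

    def test_large_n_p_value_close_to_normal(self, rng):
        X, g, mu = _design(20, 40, rng, beta=(0.3, 0.2, 0.1))
        y = mu + rng.standard_normal(len(mu))
        fit = fit_marginal_gls(y, X, g, order=(0, 0), estimation="reml",
                               terms=("intercept", "time", "x2"))
        df, p, _ = satterthwaite_df(fit, "time")
        t_val = fit.params.loc["time", "estimate"] / fit.params.loc["time", "se"]
        p_norm = 2 * stats.norm.sf(abs(t_val))
        assert p == pytest.approx(p_norm, abs=1e-3)


class TestDiagnostics:
    def test_perfect_fit_correlation_one(self, rng):
        X, g, mu = _design(4, 10, rng)
        y = mu + 1e-8 * rng.standard_normal(len(mu))
        fit = fit_marginal_gls(y, X, g, order=(0, 0))
        diag = model_diagnostics(fit)
        assert diag["fitted_observed_corr"] == pytest.approx(1.0, abs=1e-6)

    def test_white_noise_residual_acf_within_bands(self, rng):
        X, g, mu = _design(6, 40, rng)
        y = mu + rng.standard_normal(len(mu))
        fit = fit_marginal_gls(y, X, g, order=(0, 0))
        diag = model_diagnostics(fit, acf_lags=8)
        inside = total = 0
        for sid, acf in diag["residual_acf"].items():
            band = 2 / np.sqrt(40)
            inside += int(np.sum(np.abs(acf[1:]) < band))
            total += len(acf) - 1
        assert inside / total >= 0.90

    def test_spiked_subject_flagged(self, rng):
        X, g, mu = _design(8, 10, rng)
        y = mu + 0.3 * rng.standard_normal(len(mu))
        y[g == 3] = y[g == 3] * 10
        fit = fit_marginal_gls(y, X, g, order=(0, 0))
        diag = model_diagnostics(fit)
        assert 3 in diag["outlier_subjects"]
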