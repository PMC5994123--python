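"""Conditional logistic regression: likelihood, fitting, tests, ORs."""

import numpy as np
import pytest
from scipy.stats import chi2

from densethresh.matched_logit import (
    AnalysisDataset,
    conditional_loglik,
    fit_clogit,
    fit_interaction,
    lr_test,
    standardized_or,
)


def naive_loglik(beta, x, set_id, is_case):
    """Two-loop enumeration oracle for the conditional log-likelihood."""
    beta = np.atleast_1d(beta)
    total = 0.0
    for s in np.unique(set_id):
        rows = np.flatnonzero(set_id == s)
        etas = [float(x[r] @ beta) for r in rows]
        case_eta = [etas[i] for i, r in enumerate(rows) if is_case[r]][0]
        total += case_eta - np.log(sum(np.exp(e) for e in etas))
    return total


def _dataset(x, set_id, is_case, **kw):
    return AnalysisDataset(x=x, set_id=set_id, is_case=is_case, **kw)


class TestLoglik:
    def test_null_closed_form_three_sets(self):
        ds = _dataset(
            np.zeros((12, 1)), np.repeat(np.arange(3), 4),
            np.tile([True, False, False, False], 3),
        )
        assert conditional_loglik([0.0], ds) == pytest.approx(-3 * np.log(4), abs=1e-12)

    def test_single_set_direct_formula(self):
        ds = _dataset(
            np.array([[1.0], [0.0], [0.0], [0.0]]), np.zeros(4),
            np.array([True, False, False, False]),
        )
        assert conditional_loglik([np.log(2)], ds) == pytest.approx(
            np.log(2 / 5), abs=1e-12
        )

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_enumeration_oracle(self, small_matched_data, seed):
        rng = np.random.default_rng(seed)
        x, sid, case = small_matched_data(seed, n_sets=8, k=2)
        ds = _dataset(x, sid, case)
        for _ in range(3):
            beta = rng.standard_normal(2)
            assert conditional_loglik(beta, ds) == pytest.approx(
                naive_loglik(beta, x, sid, case), abs=1e-12
            )

    def test_overflow_guard(self):
        ds = _dataset(
            np.array([[600.0], [0.0], [0.0]]), np.zeros(3),
            np.array([True, False, False]),
        )
        assert np.isfinite(conditional_loglik([1.0], ds))

    def test_invariant_to_constant_predictor_shift(self, small_matched_data):
        x, sid, case = small_matched_data(4, n_sets=20, k=1)
        for beta in (0.3, -1.1):
            a = conditional_loglik([beta], _dataset(x, sid, case))
            b = conditional_loglik([beta], _dataset(x + 17.5, sid, case))
            assert a == pytest.approx(b, abs=1e-10)


class TestFit:
    def test_symmetric_toy_mle_zero(self):
        x = np.array([1.0, 0, 0, 0, 0, 1, 1, 1])[:, None]
        ds = _dataset(
            x, np.repeat([0, 1], 4),
            np.array([1, 0, 0, 0, 1, 0, 0, 0], bool),
        )
        fit = fit_clogit(ds)
        assert fit.converged
        assert fit.beta[0] == pytest.approx(0.0, abs=1e-8)
        assert fit.loglik == pytest.approx(-2 * np.log(4), abs=1e-10)
        assert fit.aic == pytest.approx(7.545177, abs=1e-6)

    @pytest.mark.parametrize("seed", range(8))
    def test_fitted_loglik_dominates_null_and_aic_identity(
        self, small_matched_data, seed
    ):
        x, sid, case = small_matched_data(seed, n_sets=40, k=2, beta=[0.5, -0.3])
        fit = fit_clogit(_dataset(x, sid, case))
        assert fit.loglik >= fit.loglik_null
        assert fit.aic == pytest.approx(2 * fit.k - 2 * fit.loglik, abs=0)
        assert fit.chisq >= 0
        cov = fit.covariance
        assert np.allclose(cov, cov.T)
        assert np.all(np.linalg.eigvalsh(cov) > 0)

    @pytest.mark.parametrize("seed", range(15))
    def test_grid_search_oracle_one_covariate(self, small_matched_data, seed):
        x, sid, case = small_matched_data(seed, n_sets=25, k=1, beta=[0.4])
        ds = _dataset(x, sid, case)
        fit = fit_clogit(ds)
        grid = np.arange(-1.5, 1.5, 1e-4)
        lls = [conditional_loglik([b], ds) for b in grid]
        assert abs(fit.beta[0] - grid[int(np.argmax(lls))]) < 1e-3

    def test_cross_check_against_statsmodels(self, small_matched_data):
        from statsmodels.discrete.conditional_models import ConditionalLogit

        x, sid, case = small_matched_data(11, n_sets=150, k=2, beta=[0.5, -0.2])
        fit = fit_clogit(_dataset(x, sid, case))
        sm = ConditionalLogit(case.astype(int), x, groups=sid).fit(disp=0)
        np.testing.assert_allclose(fit.beta, np.asarray(sm.params), atol=1e-4)
        np.testing.assert_allclose(fit.se, np.asarray(sm.bse), rtol=1e-3)
        assert fit.loglik == pytest.approx(sm.llf, abs=1e-6)

    def test_perfect_separation_raises_naming_column(self):
        # case always has the strictly largest x -> likelihood unbounded
        x = np.tile([5.0, 0.0, 0.0, 0.0], 30)[:, None]
        sid = np.repeat(np.arange(30), 4)
        case = np.tile([True, False, False, False], 30)
        from densethresh.matched_logit import SeparationError

        with pytest.raises(SeparationError, match="sep_col"):
            fit_clogit(_dataset(x, sid, case, columns=("sep_col",)))

    def test_exactly_one_case_per_set_enforced(self):
        with pytest.raises(ValueError, match="exactly one case"):
            _dataset(np.zeros((4, 1)), np.zeros(4), np.array([1, 1, 0, 0], bool))


class TestLrTestAndOr:
    def test_full_equals_nested(self, small_matched_data):
        x, sid, case = small_matched_data(2, n_sets=30, k=1, beta=[0.3])
        fit = fit_clogit(_dataset(x, sid, case, columns=("a",)))
        stat, df, p = lr_test(fit, fit)
        assert stat == 0 and df == 0 and p == 1

    def test_delta_aic_identity(self, small_matched_data):
        x, sid, case = small_matched_data(3, n_sets=60, k=2, beta=[0.4, 0.0])
        full = fit_clogit(_dataset(x, sid, case, columns=("a", "b")))
        nested = fit_clogit(_dataset(x[:, :1], sid, case, columns=("a",)))
        stat, df, p = lr_test(full, nested)
        assert df == 1
        d_aic = full.aic - nested.aic
        assert d_aic == pytest.approx(2 * 1 - stat, abs=1e-10)

    def test_non_nested_rejected(self, small_matched_data):
        x, sid, case = small_matched_data(5, n_sets=30, k=2)
        fa = fit_clogit(_dataset(x[:, :1], sid, case, columns=("a",)))
        fb = fit_clogit(_dataset(x[:, 1:], sid, case, columns=("b",)))
        with pytest.raises(ValueError, match="not nested"):
            lr_test(fa, fb)

    def test_null_lr_type_one_error(self, small_matched_data):
        """Adding a pure-noise column rejects at ~alpha under the null."""
        rej = 0
        n_rep = 1000
        for seed in range(n_rep):
            x, sid, case = small_matched_data(seed, n_sets=60, k=2, beta=[0.4, 0.0])
            full = fit_clogit(_dataset(x, sid, case, columns=("a", "b")))
            nested = fit_clogit(_dataset(x[:, :1], sid, case, columns=("a",)))
            _, _, p = lr_test(full, nested)
            rej += p < 0.05
        assert 0.03 <= rej / n_rep <= 0.07

    def test_standardized_or_closed_form(self, small_matched_data):
        x, sid, case = small_matched_data(1, n_sets=40, k=1)
        fit = fit_clogit(_dataset(x, sid, case, columns=("a",)))
        # synthetic coefficients: beta=0.5, se=0.1, sd=0.4
        fit.beta = np.array([0.5])
        fit.covariance = np.array([[0.01]])
        o, lo, hi = standardized_or(fit, [0.4])["a"]
        assert o == pytest.approx(np.exp(0.2), abs=1e-9)
        assert lo == pytest.approx(np.exp((0.5 - 1.959964 * 0.1) * 0.4), abs=1e-6)
        assert hi == pytest.approx(np.exp((0.5 + 1.959964 * 0.1) * 0.4), abs=1e-6)
        # sd=1 reduces to exp(beta); beta=0 gives OR 1 with log-symmetric CI
        assert standardized_or(fit, [1.0])["a"][0] == pytest.approx(np.exp(0.5))
        fit.beta = np.array([0.0])
        o, lo, hi = standardized_or(fit, [0.4])["a"]
        assert o == 1.0
        assert np.log(hi) == pytest.approx(-np.log(lo), abs=1e-12)


class TestInteraction:
    def _grouped_data(self, seed, n_sets, b_screen, b_interval):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(n_sets * 4)
        sid = np.repeat(np.arange(n_sets), 4)
        grp = np.repeat((rng.random(n_sets) < 0.5).astype(float), 4)
        beta = np.where(grp[::4] > 0, b_interval, b_screen)
        eta = (beta[:, None] * x.reshape(n_sets, 4))
        p = np.exp(eta - eta.max(1, keepdims=True))
        p /= p.sum(1, keepdims=True)
        pos = (p.cumsum(1) < rng.random((n_sets, 1))).sum(1)
        case = np.zeros(n_sets * 4, bool)
        case[np.arange(n_sets) * 4 + pos] = True
        return x[:, None], sid, case, grp

    def test_per_group_log_or_difference_is_beta2(self):
        x, sid, case, grp = self._grouped_data(0, 300, 0.2, 0.7)
        ds = _dataset(x, sid, case, columns=("pred",))
        res = fit_interaction(ds, "pred", grp)
        g0 = np.log(res["per_group_or"]["group0"]["or"]) / res["sd"]
        g1 = np.log(res["per_group_or"]["group1"]["or"]) / res["sd"]
        assert g1 - g0 == pytest.approx(res["fit"].beta[1], abs=1e-10)

    def test_indicator_varying_within_set_rejected(self):
        x, sid, case, grp = self._grouped_data(1, 20, 0.0, 0.0)
        grp = grp.copy()
        grp[1] = 1 - grp[1]
        ds = _dataset(x, sid, case, columns=("pred",))
        with pytest.raises(ValueError, match="varies within set"):
            fit_interaction(ds, "pred", grp)

    def test_null_interaction_type_one_error(self):
        rej = 0
        n_rep = 1000
        for seed in range(n_rep):
            x, sid, case, grp = self._grouped_data(seed, 80, 0.3, 0.3)
            ds = _dataset(x, sid, case, columns=("pred",))
            res = fit_interaction(ds, "pred", grp)
            rej += res["lr_p"] < 0.05
        assert 0.03 <= rej / n_rep <= 0.07
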