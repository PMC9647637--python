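"""Classical-inference layer: odds ratios, exact tests, transforms, LMM."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tmefib.stats import (
    boxcox_transform,
    fisher_exact_2x2,
    fit_random_intercept_lmm,
    log_transform,
    mann_whitney_u,
    odds_ratio_wald,
    spearman_matrix,
    two_sample_t,
)


class TestOddsRatio:
    @pytest.mark.parametrize(
        "cells, expected_or, expected_ci",
        [
            ((18, 7, 1, 4), 10.29, (0.97, 108.81)),
            ((11, 10, 8, 1), 0.14, None),
            ((4, 6, 14, 5), 0.24, None),
            ((3, 2, 8, 17), 3.19, None),
            ((10, 15, 1, 4), 2.67, None),
            ((5, 5, 5, 5), 1.00, None),
        ],
    )
    def test_printed_precision(self, cells, expected_or, expected_ci):
        res = odds_ratio_wald(*cells)
        assert round(res.odds_ratio, 2) == expected_or
        if expected_ci:
            assert (round(res.ci_low, 2), round(res.ci_high, 2)) == expected_ci

    def test_balanced_table_ci_symmetric_on_log_scale(self):
        res = odds_ratio_wald(5, 5, 5, 5)
        assert res.odds_ratio == pytest.approx(1.0)
        assert np.log(res.ci_low) == pytest.approx(-np.log(res.ci_high))

    @given(
        st.tuples(*[st.integers(1, 50)] * 4),
    )
    @settings(max_examples=50, deadline=None)
    def test_exposure_swap_inverts(self, cells):
        a, b, c, d = cells
        assert odds_ratio_wald(a, b, c, d).odds_ratio * odds_ratio_wald(
            b, a, d, c
        ).odds_ratio == pytest.approx(1.0)

    def test_zero_cell_continuity_flagged(self):
        res = odds_ratio_wald(5, 0, 3, 4)
        assert res.continuity_corrected
        assert np.isfinite(res.odds_ratio)


class TestFisher:
    def test_small_table_by_enumeration(self):
        # margins (2,2)x(2,2): three tables, p = P(prob <= observed)
        assert fisher_exact_2x2(2, 0, 0, 2) == pytest.approx(1 / 3)

    def test_modal_table(self):
        assert fisher_exact_2x2(5, 5, 5, 5) == pytest.approx(1.0)

    @given(st.tuples(*[st.integers(0, 20)] * 4))
    @settings(max_examples=50, deadline=None)
    def test_transpose_invariance(self, cells):
        a, b, c, d = cells
        if a + b + c + d == 0:
            return
        assert fisher_exact_2x2(a, b, c, d) == pytest.approx(
            fisher_exact_2x2(a, c, b, d)
        )

    def test_direction_agrees_with_or(self):
        res = odds_ratio_wald(18, 7, 1, 4)
        # OR > 1 iff cell a exceeds its hypergeometric expectation
        a, b, c, d = 18, 7, 1, 4
        expect_a = (a + b) * (a + c) / (a + b + c + d)
        assert (res.odds_ratio > 1) == (a > expect_a)


class TestTransforms:
    def test_lambda_one_is_shift(self, rng):
        y = rng.uniform(1, 5, 50)
        z, lam = boxcox_transform(y, lmbda=1.0)
        assert np.allclose(z, y - 1)

    def test_lambda_zero_is_log(self, rng):
        y = rng.uniform(1, 5, 50)
        z, _ = boxcox_transform(y, lmbda=0.0)
        assert np.allclose(z, np.log(y))

    def test_lognormal_data_selects_lambda_near_zero(self, rng):
        y = np.exp(rng.normal(1.0, 0.5, 500))
        _, lam = boxcox_transform(y)
        assert -0.2 <= lam <= 0.2

    def test_zero_counts_shifted(self):
        z = log_transform(np.array([0, 1, 3]))
        assert np.allclose(z, np.log([0.5, 1.5, 3.5]))


def _ols(y, X):
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return beta


class TestMixedModel:
    def test_zero_group_variance_limit_matches_ols(self, rng):
        g = np.repeat(np.arange(40), 4)
        x = rng.normal(size=160)
        y = 2.0 + 0.5 * x + rng.normal(0, 1, 160)  # no group effect
        X = pd.DataFrame({"const": 1.0, "x": x})
        fit = fit_random_intercept_lmm(y, X, g)
        ols = _ols(y, X.to_numpy())
        # REML detects (near-)zero variance ratio; GLS collapses to OLS
        assert np.allclose(fit.params.to_numpy(), ols, atol=5e-3)

    def test_matches_reml_oracle(self, rng):
        statsmodels = pytest.importorskip("statsmodels.regression.mixed_linear_model")
        g = np.repeat(np.arange(30), 5)
        x = rng.normal(size=150)
        y = 1.0 + 0.5 * x + rng.normal(0, 0.7, 30)[g] + rng.normal(0, 1, 150)
        X = pd.DataFrame({"const": 1.0, "x": x})
        fit = fit_random_intercept_lmm(y, X, g)
        m = statsmodels.MixedLM(y, X.to_numpy(), groups=g).fit(reml=True)
        assert np.allclose(fit.params.to_numpy(), np.asarray(m.params)[:2], atol=1e-4)
        assert np.allclose(fit.bse.to_numpy(), np.asarray(m.bse)[:2], rtol=2e-2)
        assert fit.group_var == pytest.approx(float(np.asarray(m.cov_re)[0, 0]), rel=1e-3)
        assert fit.resid_var == pytest.approx(m.scale, rel=1e-3)

    def test_singular_design_names_columns(self, rng):
        g = np.repeat([0, 1], 10)
        x = rng.normal(size=20)
        X = pd.DataFrame({"const": 1.0, "x": x, "x_copy": x})
        with pytest.raises(ValueError, match="x_copy"):
            fit_random_intercept_lmm(rng.normal(size=20), X, g)

    def test_single_group_refused(self, rng):
        X = pd.DataFrame({"const": np.ones(10)})
        with pytest.raises(ValueError, match="2 groups"):
            fit_random_intercept_lmm(rng.normal(size=10), X, np.zeros(10))


class TestRankTests:
    def test_mann_whitney_exact_small_sample(self):
        u, p = mann_whitney_u([1, 2], [3, 4])
        assert u == 0
        # oracle: enumerate all C(4,2) labelings of the pooled ranks
        vals = [1, 2, 3, 4]
        stats = []
        for combo in itertools.combinations(range(4), 2):
            x = [vals[i] for i in combo]
            y = [vals[i] for i in range(4) if i not in combo]
            stats.append(sum(xi > yi for xi in x for yi in y))
        p_exact = np.mean([min(s, 4 - s) <= 0 for s in stats])
        assert p == pytest.approx(p_exact) == pytest.approx(2 / 6)

    def test_identical_samples(self, rng):
        x = rng.normal(size=30)
        _, p = mann_whitney_u(x, x)
        assert p >= 0.99

    def test_swap_symmetry(self, rng):
        x, y = rng.normal(size=15), rng.normal(1, 1, 12)
        assert mann_whitney_u(x, y)[1] == pytest.approx(mann_whitney_u(y, x)[1])

    def test_t_equal_samples(self):
        x = np.arange(10.0)
        t, p = two_sample_t(x, x)
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_t_power_one_sd_shift(self, rng):
        hits = 0
        n_sim = 200
        for _ in range(n_sim):
            x = rng.normal(0, 1, 100)
            y = rng.normal(1, 1, 100)
            hits += two_sample_t(x, y)[1] < 0.01
        assert hits / n_sim >= 0.97


class TestSpearman:
    def test_monotone_transform_gives_unit_rho(self, rng):
        x = rng.normal(size=40)
        df = pd.DataFrame({"a": x})
        rho, _, _ = spearman_matrix(df, np.exp(x))
        assert rho.loc["a"].iloc[-1] == pytest.approx(1.0)

    def test_null_columns_mostly_small(self, rng):
        df = pd.DataFrame(rng.normal(size=(500, 8)))
        rho, _, _ = spearman_matrix(df)
        off = rho.to_numpy()[~np.eye(8, dtype=bool)]
        assert (np.abs(off) < 0.12).mean() >= 0.95
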