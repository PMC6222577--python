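"""Validation statistics: t-tests, Fisher exact, Spearman, IRLS logistic."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from panelmark.cohort import (
    SummaryStats,
    fisher_exact,
    logistic_fit,
    logistic_univariate,
    run_cohort_analysis,
    spearman,
    t_test_raw,
    t_test_summary,
)
from panelmark.errors import (
    ContractError,
    DegenerateDataError,
    InsufficientDataError,
    SeparationWarning,
)
from panelmark.simulate import GeneratorConfig, simulate_cohort


class TestTTests:
    def test_identical_groups_give_t_zero_p_one(self):
        x = [1.0, 2.0, 3.0]
        res = t_test_raw(x, x)
        assert res.t == 0.0 and res.p == pytest.approx(1.0)

    def test_separated_groups_drive_p_to_zero(self):
        a = np.array([0.0, 1e-6, -1e-6, 2e-6])
        res = t_test_raw(a, a + 100.0)
        assert res.p < 1e-20

    @pytest.mark.parametrize("method", ["pooled", "welch"])
    def test_summary_form_equals_raw_form(self, method):
        rng = np.random.default_rng(4)
        a, b = rng.normal(0, 1, 9), rng.normal(0.4, 2, 13)
        raw = t_test_raw(a, b, method=method)
        summ = t_test_summary(
            SummaryStats.from_values(a), SummaryStats.from_values(b), method=method
        )
        assert summ.t == pytest.approx(raw.t, abs=1e-12)
        assert summ.df == pytest.approx(raw.df, abs=1e-12)
        assert summ.p == pytest.approx(raw.p, abs=1e-12)

    @pytest.mark.parametrize("method,equal_var", [("pooled", True), ("welch", False)])
    def test_matches_scipy(self, method, equal_var):
        rng = np.random.default_rng(5)
        a, b = rng.normal(0, 1, 8), rng.normal(1, 1.5, 11)
        res = t_test_raw(a, b, method=method)
        ref = stats.ttest_ind(a, b, equal_var=equal_var)
        assert res.t == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_printed_group_summaries_reproduce_reported_p_values(self):
        """The chronic-stimulation and pressure-overload plasma comparisons.

        Group ns are partly unprinted; equal n per arm (10 and 6) is the
        consistency assumption under which the pooled test reproduces the
        reported p = 0.007 and p = 0.13.
        """
        iso = t_test_summary(
            SummaryStats(5.96, 2.66, 10), SummaryStats(3.18, 1.08, 10)
        )
        assert round(iso.p, 3) == 0.007
        tac = t_test_summary(
            SummaryStats(4.19, 2.33, 6), SummaryStats(2.22, 1.80, 6)
        )
        assert round(tac.p, 2) == 0.13
        human = t_test_summary(
            SummaryStats(1.20, 0.26, 270), SummaryStats(0.74, 0.40, 119),
            method="welch",
        )
        assert human.p < 1e-20  # reported as < 0.0001

    def test_p_close_to_permutation_oracle(self):
        """Student p vs the exact (Monte-Carlo) permutation null at n=6 vs 6.

        At 12 observations the t reference distribution approximates the
        permutation null to within a few hundredths at mid-range p.
        """
        rng = np.random.default_rng(6)
        a, b = rng.normal(0, 1, 6), rng.normal(0.8, 1, 6)
        res = t_test_raw(a, b, method="pooled")
        pooled = np.concatenate([a, b])
        obs = abs(a.mean() - b.mean())
        draws = 0
        hits = 0
        for _ in range(20_000):
            rng.shuffle(pooled)
            draws += 1
            hits += abs(pooled[:6].mean() - pooled[6:].mean()) >= obs - 1e-12
        assert res.p == pytest.approx(hits / draws, abs=0.06)

    def test_degenerate_groups_rejected(self):
        with pytest.raises(DegenerateDataError):
            t_test_raw([2.0, 2.0, 2.0], [2.0, 2.0])
        with pytest.raises(ContractError):
            t_test_raw([1.0], [2.0, 3.0])


def _hypergeom_table_p(a, b, c, d):
    """Probability of one 2x2 table under fixed margins (math.comb only)."""
    n = a + b + c + d
    return (
        math.comb(a + b, a) * math.comb(c + d, c) / math.comb(n, a + c)
    )


def _fisher_enumeration_oracle(a, b, c, d):
    """Two-sided probability-mass rule by full enumeration of tables."""
    r1, c1, n = a + b, a + c, a + b + c + d
    p_obs = _hypergeom_table_p(a, b, c, d)
    total = 0.0
    for aa in range(max(0, c1 - (n - r1)), min(r1, c1) + 1):
        p = _hypergeom_table_p(aa, r1 - aa, c1 - aa, n - r1 - c1 + aa)
        if p <= p_obs * (1 + 1e-10):
            total += p
    return min(total, 1.0)


class TestFisherExact:
    def test_balanced_table_gives_p_one(self):
        res = fisher_exact([[1, 1], [1, 1]])
        assert res.p == pytest.approx(1.0)
        assert res.odds_ratio == pytest.approx(1.0)

    def test_zero_margin_gives_p_one(self):
        assert fisher_exact([[0, 0], [3, 5]]).p == pytest.approx(1.0)

    def test_example_matches_enumeration_oracle(self):
        res = fisher_exact([[8, 2], [1, 5]])
        assert res.p == pytest.approx(_fisher_enumeration_oracle(8, 2, 1, 5), rel=1e-9)
        assert res.odds_ratio == pytest.approx(8 * 5 / (2 * 1))

    def test_random_tables_match_enumeration_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(60):
            a, b, c, d = rng.integers(0, 10, size=4)
            res = fisher_exact([[a, b], [c, d]])
            assert res.p == pytest.approx(
                _fisher_enumeration_oracle(int(a), int(b), int(c), int(d)), rel=1e-9
            )

    def test_doubled_tail_variant(self):
        res = fisher_exact([[8, 2], [1, 5]], method="doubled")
        a, n, r1, c1 = 8, 16, 10, 9
        less = stats.hypergeom.cdf(a, n, r1, c1)
        greater = stats.hypergeom.sf(a - 1, n, r1, c1)
        assert res.p == pytest.approx(min(1.0, 2 * min(less, greater)))

    def test_infinite_and_undefined_odds_ratios(self):
        assert fisher_exact([[3, 0], [1, 4]]).odds_ratio == math.inf
        res = fisher_exact([[0, 2], [3, 0]])
        assert res.odds_ratio == 0.0 or np.isnan(res.odds_ratio) is False
        und = fisher_exact([[0, 0], [0, 0]])
        assert und.or_undefined

    def test_non_integer_table_rejected(self):
        with pytest.raises(ContractError):
            fisher_exact([[1.5, 2], [3, 4]])


class TestSpearman:
    def test_monotone_pairs_give_plus_minus_one(self):
        x = np.array([1.0, 3.0, 4.0, 10.0, 20.0])
        assert spearman(x, np.exp(x)).rho == pytest.approx(1.0)
        assert spearman(x, -(x**3)).rho == pytest.approx(-1.0)

    def test_tied_data_matches_hand_midranks(self):
        # x: [1,1,2,3,3,3,4,5,5,6] -> midranks [1.5,1.5,3,5,5,5,7,8.5,8.5,10]
        x = np.array([1, 1, 2, 3, 3, 3, 4, 5, 5, 6], dtype=float)
        y = np.array([2, 1, 2, 4, 3, 5, 5, 7, 6, 9], dtype=float)
        rx = np.array([1.5, 1.5, 3, 5, 5, 5, 7, 8.5, 8.5, 10])
        ry = np.array([2.5, 1, 2.5, 5, 4, 6.5, 6.5, 9, 8, 10])
        oracle = np.corrcoef(rx, ry)[0, 1]
        res = spearman(x, y)
        assert res.rho == pytest.approx(oracle, abs=1e-12)
        ref = stats.spearmanr(x, y)
        assert res.rho == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_constant_input_flagged(self):
        res = spearman([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])
        assert res.constant_input and res.rho == 0.0 and res.p == 1.0

    def test_too_few_pairs_rejected(self):
        with pytest.raises(InsufficientDataError):
            spearman([1.0, 2.0], [3.0, 4.0])


class TestLogisticFit:
    def test_two_by_two_closed_form_odds_ratio(self):
        # exposed-case layout [[10,20],[30,40]]: OR = 10*40/(20*30)
        x = np.repeat([1.0, 1.0, 0.0, 0.0], [10, 20, 30, 40])
        y = np.repeat([1.0, 0.0, 1.0, 0.0], [10, 20, 30, 40])
        fit = logistic_univariate(x, y, name="exposed")
        assert fit.converged
        assert fit.odds_ratio[1] == pytest.approx(10 * 40 / (20 * 30), abs=1e-8)

    def test_intercept_only_closed_form(self):
        y = np.repeat([1.0, 0.0], [30, 70])
        fit = logistic_fit(np.ones((100, 1)), y, names=["intercept"])
        assert fit.coef[0] == pytest.approx(math.log(0.3 / 0.7), abs=1e-10)

    def test_matches_statsmodels_mle(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(8)
        X = np.column_stack([np.ones(300), rng.normal(size=300), rng.normal(size=300)])
        y = (rng.random(300) < 1 / (1 + np.exp(-(0.3 + 0.8 * X[:, 1] - X[:, 2])))).astype(float)
        fit = logistic_fit(X, y)
        ref = sm.Logit(y, X).fit(disp=0)
        np.testing.assert_allclose(fit.coef, ref.params, atol=1e-6)
        np.testing.assert_allclose(fit.se, ref.bse, atol=1e-6)
        assert fit.loglik == pytest.approx(ref.llf, abs=1e-8)

    def test_loglik_nondecreasing_and_score_below_tol(self):
        rng = np.random.default_rng(9)
        X = np.column_stack([np.ones(200), rng.normal(size=200)])
        y = (rng.random(200) < 1 / (1 + np.exp(-X[:, 1]))).astype(float)
        fit = logistic_fit(X, y, tol=1e-8)
        assert fit.converged
        assert all(b >= a - 1e-12 for a, b in itertools.pairwise(fit.loglik_trace))
        mu = 1 / (1 + np.exp(-(X @ fit.coef)))
        assert np.max(np.abs(X.T @ (y - mu))) < 1e-8

    def test_planted_effect_recovered_at_large_n(self):
        cfg = GeneratorConfig(n_cases=600, n_controls=1400, seed=12,
                              include_probnp=False,
                              continuous_covariates={}, binary_covariates={})
        cohort, truth = simulate_cohort(cfg)
        fit = logistic_univariate(
            np.log(cohort["biomarker_ng_ml"]), cohort["hf_status"].to_numpy(float),
            name="logb",
        )
        # within 3 Wald SEs of the planted log-odds coefficient
        assert abs(fit.coef[1] - truth.beta["log_biomarker"]) < 3 * fit.se[1]

    def test_separation_is_flagged_and_warned(self):
        x = np.concatenate([np.zeros(20), np.ones(20)])
        y = x.copy()  # perfectly separated
        with pytest.warns(SeparationWarning):
            fit = logistic_univariate(x, y)
        assert not fit.converged and fit.separation

    def test_contract_violations(self):
        with pytest.raises(ContractError):
            logistic_fit(np.ones((4, 1)), np.array([0.0, 1.0, 2.0, 1.0]))
        with pytest.raises(ContractError):
            logistic_fit(np.ones((4, 2)), np.array([0.0, 1.0, 0.0, 1.0]))

    def test_wald_ci_contains_or(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=150)
        y = (rng.random(150) < 0.4).astype(float)
        fit = logistic_univariate(x, y)
        assert (fit.ci_low <= fit.odds_ratio).all()
        assert (fit.odds_ratio <= fit.ci_high).all()


@pytest.fixture(scope="module")
def default_cohort():
    return simulate_cohort(GeneratorConfig(seed=15))


class TestRunCohortAnalysis:
    def test_protective_biomarker_recovered_in_both_models(self, default_cohort):
        cohort, _ = default_cohort
        rep = run_cohort_analysis(cohort, biomarker_scale="log")
        assert rep.biomarker_scale == "log"
        uni = rep.univariate["log_biomarker_ng_ml"].term("log_biomarker_ng_ml")
        multi = rep.multivariate.term("log_biomarker_ng_ml")
        assert uni["OR"] < 1 and uni["p"] < 0.001
        assert multi["OR"] < 1 and multi["p"] < 0.05
        assert rep.sensitivity is not None
        assert rep.sensitivity.term("log_biomarker_ng_ml")["OR"] < 1

    def test_report_table_mirrors_published_layout(self, default_cohort):
        cohort, _ = default_cohort
        rep = run_cohort_analysis(cohort)
        assert list(rep.table.columns) == [
            "variable", "OR_univariate", "p_univariate",
            "OR_multivariate", "p_multivariate",
        ]
        assert len(rep.table) == 7  # biomarker + six covariates
        assert rep.baseline["p"].between(0, 1).all()
        assert rep.probnp_correlation is not None
        assert rep.probnp_correlation.n == 42

    def test_missing_probnp_column_omits_correlation(self, default_cohort):
        cohort, _ = default_cohort
        rep = run_cohort_analysis(cohort.drop(columns=["probnp"]))
        assert rep.probnp_correlation is None

    def test_raw_scale_is_default_and_recorded(self, default_cohort):
        cohort, _ = default_cohort
        rep = run_cohort_analysis(cohort)
        assert rep.biomarker_scale == "raw"
        assert "biomarker_ng_ml" in rep.univariate

    def test_null_cohort_flags_biomarker_at_nominal_rate(self):
        """With no planted effects the multivariate Wald test is calibrated."""
        flags = 0
        n_rep = 200
        for rep_i in range(n_rep):
            cfg = GeneratorConfig(
                biomarker_beta=0.0, include_probnp=False, seed=40_000 + rep_i,
                continuous_covariates={"age_yr": (58.0, 7.0, 1.0)},
                binary_covariates={"htn": (0.3, 1.0)},
            )
            cohort, _ = simulate_cohort(cfg)
            rep = run_cohort_analysis(
                cohort, covariates=("age_yr", "htn"), biomarker_scale="log"
            )
            flags += rep.multivariate.term("log_biomarker_ng_ml")["p"] < 0.05
        # binomial(200, 0.05): 3 sigma ≈ 0.046
        assert 0.005 <= flags / n_rep <= 0.10
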