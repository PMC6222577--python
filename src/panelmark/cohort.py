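"""Case-control validation statistics for a plasma biomarker.

Covers the comparisons used to validate a candidate biomarker: two-sample
t-tests in raw and summary-statistic form (pooled by default, Welch always
available), Fisher's exact test for categorical baseline variables, Spearman
rank correlation against an established biomarker, and logistic regression
fitted by iteratively reweighted least squares (IRLS/Newton) with Wald odds
ratios and 95% confidence intervals, reported univariately per variable and
multivariately with the full covariate set.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    ContractError,
    DegenerateDataError,
    InsufficientDataError,
    SeparationWarning,
)

#: normal 97.5% quantile used for Wald intervals
Z_95 = 1.959964


# ---------------------------------------------------------------------------
# t-tests
# ---------------------------------------------------------------------------

@dataclass
class SummaryStats:
    """Group summary on the analyte's scale: mean, SD, n."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ContractError(f"sd must be >= 0, got {self.sd}")
        if self.n < 2:
            raise ContractError(f"n must be >= 2, got {self.n}")

    @classmethod
    def from_values(cls, x) -> "SummaryStats":
        x = np.asarray(x, dtype=float)
        if x.size < 2:
            raise ContractError(f"n must be >= 2, got {x.size}")
        return cls(mean=float(x.mean()), sd=float(x.std(ddof=1)), n=int(x.size))


@dataclass
class TTestResult:
    t: float
    df: float  # fractional under Welch
    p: float
    method: str


def t_test_summary(a: SummaryStats, b: SummaryStats, method: str = "pooled") -> TTestResult:
    """Two-sample t-test from group summaries (pooled or Welch)."""
    if method not in ("pooled", "welch"):
        raise ContractError(f"method must be 'pooled' or 'welch', got {method!r}")
    if a.sd == 0 and b.sd == 0:
        if a.mean == b.mean:
            raise DegenerateDataError("both variances zero and means equal")
        return TTestResult(t=math.inf if a.mean > b.mean else -math.inf,
                           df=a.n + b.n - 2, p=0.0, method=method)
    va, vb = a.sd**2, b.sd**2
    if method == "pooled":
        df = a.n + b.n - 2
        sp2 = ((a.n - 1) * va + (b.n - 1) * vb) / df
        se = math.sqrt(sp2 * (1.0 / a.n + 1.0 / b.n))
    else:
        se2a, se2b = va / a.n, vb / b.n
        se = math.sqrt(se2a + se2b)
        df = (se2a + se2b) ** 2 / (
            se2a**2 / (a.n - 1) + se2b**2 / (b.n - 1)
        )
    t = (a.mean - b.mean) / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return TTestResult(t=t, df=df, p=p, method=method)


def t_test_raw(group_a, group_b, method: str = "pooled") -> TTestResult:
    """Two-sample t-test on raw values; identical formulas to the summary form."""
    a = SummaryStats.from_values(group_a)
    b = SummaryStats.from_values(group_b)
    return t_test_summary(a, b, method=method)


# ---------------------------------------------------------------------------
# Fisher's exact test
# ---------------------------------------------------------------------------

@dataclass
class FisherResult:
    odds_ratio: float  # sample OR ad/bc; inf when bc = 0 with ad > 0
    p: float
    method: str
    or_undefined: bool = False  # 0/0 cross product


def fisher_exact(table, method: str = "prob") -> FisherResult:
    """Fisher's exact test on a 2x2 table of nonnegative integer counts.

    ``method="prob"`` (default) is the probability-mass two-sided rule: the
    sum of hypergeometric probabilities of all tables, with the observed
    margins, no more probable than the observed one.  ``method="doubled"``
    doubles the smaller one-sided tail (capped at 1).  The returned odds
    ratio is the sample cross-product ratio ad/bc.
    """
    if method not in ("prob", "doubled"):
        raise ContractError(f"method must be 'prob' or 'doubled', got {method!r}")
    tab = np.asarray(table)
    if tab.shape != (2, 2) or np.any(tab < 0) or not np.issubdtype(tab.dtype, np.integer):
        tab = tab.astype(float)
        if tab.shape != (2, 2) or np.any(tab < 0) or np.any(tab != np.round(tab)):
            raise ContractError("table must be 2x2 nonnegative integers")
        tab = tab.astype(int)
    a, b = int(tab[0, 0]), int(tab[0, 1])
    c, d = int(tab[1, 0]), int(tab[1, 1])
    undefined = a * d == 0 and b * c == 0
    if b * c == 0:
        odds = math.nan if undefined else math.inf
    else:
        odds = (a * d) / (b * c)
    if method == "prob":
        _, p = stats.fisher_exact(tab, alternative="two-sided")
    else:
        less = stats.hypergeom.cdf(a, a + b + c + d, a + b, a + c)
        greater = stats.hypergeom.sf(a - 1, a + b + c + d, a + b, a + c)
        p = min(1.0, 2.0 * min(less, greater))
    return FisherResult(odds_ratio=odds, p=float(p), method=method, or_undefined=undefined)


# ---------------------------------------------------------------------------
# Spearman rank correlation
# ---------------------------------------------------------------------------

@dataclass
class SpearmanResult:
    rho: float
    p: float
    n: int
    constant_input: bool = False


def spearman(x, y) -> SpearmanResult:
    """Spearman rank correlation (Pearson on midranks, p via t transform)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ContractError("x and y must be 1-d and paired")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise InsufficientDataError(f"need >= 3 complete pairs, got {n}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return SpearmanResult(rho=0.0, p=1.0, n=n, constant_input=True)
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if abs(rho) >= 1.0:
        return SpearmanResult(rho=float(np.sign(rho)), p=0.0, n=n)
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return SpearmanResult(rho=rho, p=float(p), n=n)


# ---------------------------------------------------------------------------
# logistic regression by IRLS
# ---------------------------------------------------------------------------

@dataclass
class LogisticFit:
    """Newton/IRLS logistic fit with Wald inference per term."""

    terms: list[str]
    coef: np.ndarray
    se: np.ndarray
    odds_ratio: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    p: np.ndarray
    converged: bool
    iterations: int
    loglik: float
    loglik_trace: list[float] = field(default_factory=list)
    separation: bool = False

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.terms,
                "coef": self.coef,
                "se": self.se,
                "OR": self.odds_ratio,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "p": self.p,
            }
        )

    def term(self, name: str) -> pd.Series:
        return self.summary_frame().set_index("term").loc[name]


def _bernoulli_loglik(y: np.ndarray, eta: np.ndarray) -> float:
    # numerically stable: log(1+exp(eta)) via logaddexp
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def logistic_fit(
    X,
    y,
    names: list[str] | None = None,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> LogisticFit:
    """Maximum-likelihood logistic regression via Newton/IRLS.

    ``X`` is the design matrix including the intercept column; ``y`` is the
    0/1 outcome.  Convergence requires the maximum absolute score to drop
    below ``tol``; step-halving keeps the log-likelihood non-decreasing.
    Quasi-complete separation (diverging coefficients, fitted probabilities
    saturating) is flagged and warned about, with partial results returned as
    non-converged rather than silently accepted.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ContractError("X must be (n, p) with one row per outcome")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ContractError("outcome must be binary 0/1")
    n, k = X.shape
    col_sd = X.std(axis=0)
    if (col_sd == 0).sum() > 1:
        raise ContractError("more than one constant column in the design matrix")
    if names is None:
        names = [f"x{j}" for j in range(k)]

    beta = np.zeros(k)
    ll = _bernoulli_loglik(y, X @ beta)
    trace = [ll]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        score = X.T @ (y - mu)
        if np.max(np.abs(score)) < tol:
            converged = True
            break
        H = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(H, score)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, score, rcond=None)[0]
        # step-halving: never let the log-likelihood decrease
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            ll_new = _bernoulli_loglik(y, X @ cand)
            if ll_new >= ll - 1e-12:
                break
            scale /= 2.0
        beta = beta + scale * step
        ll = _bernoulli_loglik(y, X @ beta)
        trace.append(ll)
    else:
        it = max_iter

    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    score = X.T @ (y - mu)
    if np.max(np.abs(score)) < tol:
        converged = True
    # diverging coefficients / broadly saturated probabilities mean the MLE
    # does not exist, even when the score has numerically vanished; a strong
    # but proper fit saturates at most a small tail of observations
    separation = np.max(np.abs(beta)) > 1e2 or np.mean(np.abs(eta) > 20.0) > 0.2
    if separation:
        converged = False
        warnings.warn(
            "quasi-complete separation detected; coefficients diverging, "
            "results flagged non-converged",
            SeparationWarning,
            stacklevel=2,
        )

    w = mu * (1.0 - mu)
    H = (X * w[:, None]).T @ X
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        se = np.full(k, np.nan)
    with np.errstate(over="ignore"):
        or_ = np.exp(beta)
        ci_low = np.exp(beta - Z_95 * se)
        ci_high = np.exp(beta + Z_95 * se)
    z = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    return LogisticFit(
        terms=list(names), coef=beta, se=se, odds_ratio=or_, ci_low=ci_low,
        ci_high=ci_high, p=p, converged=converged, iterations=it,
        loglik=ll, loglik_trace=trace, separation=separation,
    )


def logistic_univariate(x, y, name: str = "x", **kw) -> LogisticFit:
    """Intercept + one predictor convenience wrapper."""
    x = np.asarray(x, dtype=float)
    X = np.column_stack([np.ones_like(x), x])
    return logistic_fit(X, y, names=["intercept", name], **kw)


# ---------------------------------------------------------------------------
# full cohort analysis (baseline table + univariate/multivariate logistic)
# ---------------------------------------------------------------------------

DEFAULT_COVARIATES = ("age_yr", "bmi_kg_m2", "htn", "dm", "egfr", "ldl_mg_dl")


@dataclass
class CohortReport:
    baseline: pd.DataFrame
    univariate: dict[str, LogisticFit]
    multivariate: LogisticFit
    sensitivity: LogisticFit | None
    table: pd.DataFrame  # OR (95% CI) / p, univariate and multivariate
    biomarker_scale: str
    probnp_correlation: SpearmanResult | None = None


def _is_binary(col: pd.Series) -> bool:
    vals = set(col.dropna().unique())
    return vals <= {0, 1}


def _fmt_or(or_: float, lo: float, hi: float) -> str:
    return f"{or_:.3f} ({lo:.3f}-{hi:.3f})"


def run_cohort_analysis(
    cohort: pd.DataFrame,
    biomarker_col: str = "biomarker_ng_ml",
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    biomarker_scale: str = "raw",
    sensitivity_covariates: tuple[str, ...] = ("age_yr",),
    probnp_col: str = "probnp",
) -> CohortReport:
    """Baseline comparisons plus logistic models for a case-control cohort.

    The biomarker enters logistic models on the scale named by
    ``biomarker_scale`` (``"raw"`` ng/mL or ``"log"`` natural-log ng/mL); the
    scale used is recorded in the report.  Baseline comparisons use t-tests
    for continuous variables and Fisher's exact test for binary ones.  The
    sensitivity model is biomarker + age only.  The biomarker-vs-proBNP
    Spearman correlation is computed when a proBNP column with >= 3 complete
    pairs exists, and omitted otherwise.
    """
    if biomarker_scale not in ("raw", "log"):
        raise ContractError(f"biomarker_scale must be 'raw' or 'log', got {biomarker_scale!r}")
    covariates = tuple(c for c in covariates if c in cohort.columns)
    y = cohort["hf_status"].to_numpy(dtype=float)
    cases = cohort[cohort["hf_status"] == 1]
    controls = cohort[cohort["hf_status"] == 0]

    bio = cohort[biomarker_col].to_numpy(dtype=float)
    if np.any(bio <= 0):
        raise ContractError(f"{biomarker_col} must be strictly positive")
    bio_model = np.log(bio) if biomarker_scale == "log" else bio
    bio_name = biomarker_col if biomarker_scale == "raw" else f"log_{biomarker_col}"

    # baseline table
    base_rows = []
    for name in (biomarker_col, *covariates):
        ca, co = cases[name].dropna(), controls[name].dropna()
        if _is_binary(cohort[name]):
            tab = np.array(
                [[int(ca.sum()), int(len(ca) - ca.sum())],
                 [int(co.sum()), int(len(co) - co.sum())]]
            )
            fr = fisher_exact(tab)
            base_rows.append(
                {"variable": name, "type": "binary",
                 "case_summary": f"{int(ca.sum())}/{len(ca)}",
                 "control_summary": f"{int(co.sum())}/{len(co)}", "p": fr.p}
            )
        else:
            tr = t_test_raw(ca, co, method="pooled")
            base_rows.append(
                {"variable": name, "type": "continuous",
                 "case_summary": f"{ca.mean():.2f} ± {ca.std(ddof=1):.2f}",
                 "control_summary": f"{co.mean():.2f} ± {co.std(ddof=1):.2f}",
                 "p": tr.p}
            )
    baseline = pd.DataFrame(base_rows)

    # univariate logistic per variable
    univariate: dict[str, LogisticFit] = {}
    univariate[bio_name] = logistic_univariate(bio_model, y, name=bio_name)
    for name in covariates:
        univariate[name] = logistic_univariate(
            cohort[name].to_numpy(dtype=float), y, name=name
        )

    # multivariate: biomarker + full covariate set
    Xm = np.column_stack(
        [np.ones(len(cohort)), bio_model]
        + [cohort[c].to_numpy(dtype=float) for c in covariates]
    )
    multi = logistic_fit(Xm, y, names=["intercept", bio_name, *covariates])

    sens = None
    sens_cov = tuple(c for c in sensitivity_covariates if c in cohort.columns)
    if sens_cov:
        Xs = np.column_stack(
            [np.ones(len(cohort)), bio_model]
            + [cohort[c].to_numpy(dtype=float) for c in sens_cov]
        )
        sens = logistic_fit(Xs, y, names=["intercept", bio_name, *sens_cov])

    # published-layout summary: OR (95% CI) and p, univariate vs multivariate
    rows = []
    for name in (bio_name, *covariates):
        u = univariate[name].term(name)
        m = multi.term(name)
        rows.append(
            {
                "variable": name,
                "OR_univariate": _fmt_or(u["OR"], u["ci_low"], u["ci_high"]),
                "p_univariate": u["p"],
                "OR_multivariate": _fmt_or(m["OR"], m["ci_low"], m["ci_high"]),
                "p_multivariate": m["p"],
            }
        )
    table = pd.DataFrame(rows)

    probnp_res = None
    if probnp_col in cohort.columns:
        pairs = cohort[[biomarker_col, probnp_col]].dropna()
        if len(pairs) >= 3:
            probnp_res = spearman(pairs[biomarker_col], pairs[probnp_col])

    return CohortReport(
        baseline=baseline, univariate=univariate, multivariate=multi,
        sensitivity=sens, table=table, biomarker_scale=biomarker_scale,
        probnp_correlation=probnp_res,
    )
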