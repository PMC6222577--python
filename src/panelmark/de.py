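"""Two-group differential expression with an empirical-Bayes moderated t.

The model is the standard one for log-intensity microarray data: for each
probe g, a two-group comparison gives a log2 fold change (treated minus
control means), a pooled residual variance ``s2_g`` on ``d_g`` degrees of
freedom, and the per-probe variances are shrunk toward a common prior by
assuming ``s2_g | sigma2_g ~ sigma2_g * chi2(d_g)/d_g`` with a scaled
inverse-chi-square prior ``sigma2_g ~ s02 * d0 / chi2(d0)``.  The posterior
variance is the precision-weighted blend

    s2_post = (d0 * s02 + d_g * s2_g) / (d0 + d_g)

and the moderated t is the ordinary t with ``s2_post`` in place of ``s2_g``,
referred to a t distribution on ``d0 + d_g`` degrees of freedom.  The prior
hyperparameters ``(d0, s02)`` are estimated by closed-form moment matching of
the log residual variances against their theoretical (digamma/trigamma)
moments under the scaled-F sampling distribution.

Limits: ``d0 = 0`` reproduces the ordinary two-sample pooled t exactly;
``d0 -> inf`` shrinks every variance to ``s02`` and the reference
distribution approaches normal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .errors import ContractError, DegenerateDataError, ShrinkageFallbackWarning
from .io import ExpressionPanel


# ---------------------------------------------------------------------------
# per-probe two-group summaries
# ---------------------------------------------------------------------------

def log_fold_change(panel: ExpressionPanel, probe: str) -> float:
    """Log2 fold change for one probe: mean(treated) - mean(control)."""
    treated = panel.arm_columns("treated")
    control = panel.arm_columns("control")
    if not treated or not control:
        raise ContractError("both arms need at least one sample for a fold change")
    row = panel.values.loc[probe]
    return float(row[treated].mean() - row[control].mean())


def _group_summaries(panel: ExpressionPanel):
    """Vectorized per-probe logFC, AveExpr, pooled variance and residual df."""
    treated = panel.arm_columns("treated")
    control = panel.arm_columns("control")
    if not treated or not control:
        raise ContractError("both arms need at least one sample")
    x1 = panel.values[treated].to_numpy(dtype=float)
    x0 = panel.values[control].to_numpy(dtype=float)
    n1, n0 = x1.shape[1], x0.shape[1]
    df = n1 + n0 - 2
    if df < 1:
        raise ContractError(
            f"need at least 3 samples across arms for a residual variance (df={df})"
        )
    m1, m0 = x1.mean(axis=1), x0.mean(axis=1)
    ss = ((x1 - m1[:, None]) ** 2).sum(axis=1) + ((x0 - m0[:, None]) ** 2).sum(axis=1)
    s2 = ss / df
    logfc = m1 - m0
    ave_expr = panel.values.mean(axis=1).to_numpy()
    u = np.sqrt(1.0 / n1 + 1.0 / n0)  # design scale of the mean difference
    return logfc, ave_expr, s2, df, u


# ---------------------------------------------------------------------------
# empirical-Bayes variance shrinkage
# ---------------------------------------------------------------------------

def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton on a well-behaved scale)."""
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif / x) < 1e-10:
            break
    return float(x)


def estimate_prior(s2: np.ndarray, df: float | np.ndarray) -> tuple[float, float]:
    """Moment-matching estimates of the variance prior ``(d0, s02)``.

    Works on ``e_g = log s2_g - digamma(d_g/2) + log(d_g/2)``, whose mean and
    excess variance identify ``log s02`` and ``trigamma(d0/2)``.  When the
    observed spread of the log variances does not exceed its pure sampling
    expectation the moment equation has no finite solution and the estimate
    is ``d0 = inf`` (all variances shrink fully to ``s02``).
    """
    s2 = np.asarray(s2, dtype=float)
    if s2.size < 2:
        raise ContractError("need >= 2 probes to estimate the variance prior")
    if np.all(s2 <= 0):
        raise DegenerateDataError("all residual variances are zero")
    dfv = np.broadcast_to(np.asarray(df, dtype=float), s2.shape)
    ok = s2 > 0
    if not ok.all():
        warnings.warn(
            f"{(~ok).sum()} zero residual variances excluded from prior estimation",
            ShrinkageFallbackWarning,
            stacklevel=2,
        )
    z = np.log(s2[ok])
    d = dfv[ok]
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - np.mean(special.polygamma(1, d / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s02 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s02 = float(np.exp(emean))
    return float(d0), s02


def squeeze_variances(
    s2: np.ndarray, df: float | np.ndarray, d0: float, s02: float
) -> np.ndarray:
    """Posterior variances ``(d0*s02 + df*s2) / (d0 + df)``."""
    s2 = np.asarray(s2, dtype=float)
    if np.isinf(d0):
        return np.full_like(s2, s02)
    if d0 == 0:
        return s2.copy()
    return (d0 * s02 + np.asarray(df, dtype=float) * s2) / (d0 + np.asarray(df, dtype=float))


@dataclass
class ModeratedT:
    t: np.ndarray
    p: np.ndarray
    df_total: np.ndarray
    d0: float
    s02: float
    s2_post: np.ndarray


def moderated_t(
    s2: np.ndarray,
    df: float | np.ndarray,
    logfc: np.ndarray,
    u: float | np.ndarray,
    d0: float | None = None,
    s02: float | None = None,
) -> ModeratedT:
    """Moderated t statistics and two-sided p-values for per-probe summaries.

    ``u`` is the design scale of the contrast (``sqrt(1/n1 + 1/n0)`` for a
    two-group mean difference).  When ``d0``/``s02`` are not supplied they
    are estimated from the data by :func:`estimate_prior`; forcing ``d0=0``
    gives the ordinary t-test.
    """
    s2 = np.asarray(s2, dtype=float)
    logfc = np.asarray(logfc, dtype=float)
    if d0 is None:
        d0, s02 = estimate_prior(s2, df)
    elif d0 > 0 and s02 is None:
        raise ContractError("s02 must accompany a forced positive d0")
    s2_post = squeeze_variances(s2, df, d0, s02 if s02 is not None else 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = logfc / (np.sqrt(s2_post) * u)
    df_total = np.broadcast_to(np.asarray(df, dtype=float) + d0, s2.shape)
    if np.isinf(d0):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    return ModeratedT(t=t, p=p, df_total=df_total, d0=d0,
                      s02=float(s02) if s02 is not None else 0.0, s2_post=s2_post)


# ---------------------------------------------------------------------------
# Benjamini-Hochberg step-up adjustment
# ---------------------------------------------------------------------------

def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    ``p_adj[(i)] = min_{j >= i} ( m * p[(j)] / j )`` capped at 1, computed on
    the sorted vector and mapped back to input order.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ContractError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


# ---------------------------------------------------------------------------
# full DE stage
# ---------------------------------------------------------------------------

def run_de(
    panel: ExpressionPanel,
    annotation: pd.DataFrame | None = None,
    sort: str = "logfc",
    d0: float | None = None,
    s02: float | None = None,
) -> pd.DataFrame:
    """Differential expression over all probes of a panel.

    Returns one row per probe with columns ``probe_id symbol logFC AveExpr t
    p_value p_adj df_total``, sorted by |logFC| descending (``sort="logfc"``,
    the printed-table convention; ties broken by p ascending then probe id)
    or by p ascending (``sort="p"``).
    """
    if sort not in ("logfc", "p"):
        raise ContractError(f"sort must be 'logfc' or 'p', got {sort!r}")
    logfc, ave_expr, s2, df, u = _group_summaries(panel)
    if np.all(s2 <= 0):
        raise DegenerateDataError("all residual variances are zero")
    mt = moderated_t(s2, df, logfc, u, d0=d0, s02=s02)
    out = pd.DataFrame(
        {
            "probe_id": panel.values.index,
            "logFC": logfc,
            "AveExpr": ave_expr,
            "t": mt.t,
            "p_value": mt.p,
            "p_adj": bh_adjust(mt.p),
            "df_total": mt.df_total,
        }
    )
    if annotation is not None:
        out = out.merge(annotation[["probe_id", "symbol"]], on="probe_id", how="left")
    else:
        out["symbol"] = out["probe_id"]
    out = out[["probe_id", "symbol", "logFC", "AveExpr", "t", "p_value", "p_adj", "df_total"]]
    if sort == "logfc":
        out = out.sort_values(
            by=["logFC", "p_value", "probe_id"],
            key=lambda c: -c.abs() if c.name == "logFC" else c,
            kind="mergesort",
        )
    else:
        out = out.sort_values(by=["p_value", "probe_id"], kind="mergesort")
    out.attrs["d0"] = mt.d0
    out.attrs["s02"] = mt.s02
    return out.reset_index(drop=True)


def write_de_table(de: pd.DataFrame, path) -> None:
    """Write a DE table with the printed-table column headings."""
    out = de.rename(
        columns={"p_value": "P.Value", "p_adj": "adj.P.Val", "probe_id": "PROBE_ID",
                 "symbol": "SYMBOL"}
    )
    cols = ["PROBE_ID", "SYMBOL", "logFC", "AveExpr", "t", "P.Value", "adj.P.Val"]
    out[cols].to_csv(path, sep="\t", index=False, lineterminator="\n")
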