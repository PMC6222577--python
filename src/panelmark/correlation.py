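"""Transcript-trait correlation across a strain panel.

Expression is first collapsed to strain-level means within one treatment arm
(the endpoint arm by default, matching the design in which transcript levels
at the end of treatment are correlated with the change in the echo trait);
each probe's strain means are then correlated with the per-strain trait
change.  Pearson p-values come from the exact t transform

    t = r * sqrt((n - 2) / (1 - r^2)),  two-sided on n - 2 df,

and Spearman is Pearson on midranks with the same transform.  The join on
strain is pairwise-complete: strains missing the trait (or absent from one
input) are dropped per probe, with no imputation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ContractError, InsufficientDataError
from .io import ExpressionPanel


def strain_summarize(panel: ExpressionPanel, arm: str = "treated") -> pd.DataFrame:
    """Arithmetic mean over replicates per strain, for one arm.

    Returns a strain x probe DataFrame; strains with no samples in the arm
    are simply absent.
    """
    cols = panel.arm_columns(arm)
    if not cols:
        raise ContractError(f"no samples in arm {arm!r}")
    sub = panel.values[cols]
    strain_of = panel.sample_meta.loc[cols, "strain"]
    means = sub.T.groupby(strain_of.to_numpy()).mean()
    means.index.name = "strain"
    return means


def pearson_p(r: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Two-sided p for a Pearson r via the exact t transform on n-2 df."""
    r = np.asarray(r, dtype=float)
    n = np.asarray(n, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.abs(r) * np.sqrt((n - 2.0) / np.maximum(1.0 - r * r, 1e-300))
    return np.clip(2.0 * stats.t.sf(t, n - 2.0), 0.0, 1.0)


def correlate_trait(
    strain_expr: pd.DataFrame,
    trait: pd.DataFrame,
    method: str = "pearson",
    annotation: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Correlate each probe's strain means with the trait change.

    Parameters
    ----------
    strain_expr
        strain x probe matrix from :func:`strain_summarize`.
    trait
        DataFrame with ``strain`` and ``trait_delta`` columns; missing values
        are dropped pairwise.
    method
        ``"pearson"`` (default) or ``"spearman"``.

    Returns a table with columns ``probe_id symbol cor p_value n
    zero_variance``, sorted by p ascending.  A zero-variance probe gets
    r = 0, p = 1 and a flag rather than NaN.
    """
    if method not in ("pearson", "spearman"):
        raise ContractError(f"method must be 'pearson' or 'spearman', got {method!r}")
    t = trait.dropna(subset=["trait_delta"]).set_index("strain")["trait_delta"]
    common = strain_expr.index.intersection(t.index)
    if len(common) < 3:
        raise InsufficientDataError(
            f"need >= 3 strains common to expression and trait, got {len(common)}"
        )
    x = strain_expr.loc[common].to_numpy(dtype=float)  # strains x probes
    y = t.loc[common].to_numpy(dtype=float)
    n = len(common)
    if method == "spearman":
        x = np.apply_along_axis(stats.rankdata, 0, x)
        y = stats.rankdata(y)

    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((xc**2).sum(axis=0))
    sy = np.sqrt((yc**2).sum())
    zero_var = (sx == 0) | (sy == 0)
    denom = np.where(zero_var, 1.0, sx * sy)
    r = np.clip((xc * yc[:, None]).sum(axis=0) / denom, -1.0, 1.0)
    r[zero_var] = 0.0
    p = pearson_p(r, n)
    p[zero_var] = 1.0

    out = pd.DataFrame(
        {
            "probe_id": strain_expr.columns,
            "cor": r,
            "p_value": p,
            "n": n,
            "zero_variance": zero_var,
        }
    )
    if annotation is not None:
        out = out.merge(annotation[["probe_id", "symbol"]], on="probe_id", how="left")
    else:
        out["symbol"] = out["probe_id"]
    out = out[["probe_id", "symbol", "cor", "p_value", "n", "zero_variance"]]
    return out.sort_values(["p_value", "probe_id"], kind="mergesort").reset_index(
        drop=True
    )


def infer_panel_size(r: np.ndarray, p: np.ndarray, n_range=(5, 200)) -> int:
    """Infer the strain count behind printed (r, p) pairs.

    Scans integer n and returns the one whose t-transform p-values best match
    the printed ones (least squared log-p error).  Useful when a published
    correlation table prints r and p but not n.
    """
    r = np.asarray(r, dtype=float)
    p = np.asarray(p, dtype=float)
    best_n, best_err = None, np.inf
    for n in range(max(n_range[0], 4), n_range[1] + 1):
        model = pearson_p(r, np.full_like(r, n))
        err = float(((np.log(model) - np.log(p)) ** 2).sum())
        if err < best_err:
            best_n, best_err = n, err
    return best_n


def write_corr_table(corr: pd.DataFrame, path) -> None:
    """Write a correlation table with the printed-table column headings."""
    out = corr.rename(columns={"probe_id": "ilmn_id", "p_value": "p-value"})
    out[["ilmn_id", "symbol", "cor", "p-value"]].to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )
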