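"""Candidate nomination by overlaying top-DE and top-correlated gene lists.

The selection step is deliberately simple set intersection at the gene-symbol
level: a candidate must be among the most perturbed transcripts in the
treated-vs-control comparison *and* among the transcripts most correlated
with the remodeling trait.  Symbols already established as biomarkers are
flagged (``novel=False``) rather than removed, so no information is lost.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .io import DEFAULT_KNOWN_MARKERS


def _collapse(df: pd.DataFrame, stat_col: str, collapse: str) -> pd.DataFrame:
    """Collapse probe rows to one row per symbol.

    ``collapse="extreme"`` keeps the probe with the largest |stat| (default);
    ``"mean"`` averages the statistic across probes (keeping the extreme
    probe's id and p for reference).
    """
    if collapse not in ("extreme", "mean"):
        raise ConfigurationError(f"collapse must be 'extreme' or 'mean', got {collapse!r}")
    idx = df.groupby("symbol")[stat_col].apply(lambda s: s.abs().idxmax())
    out = df.loc[idx.to_numpy()].copy()
    if collapse == "mean":
        out[stat_col] = out["symbol"].map(df.groupby("symbol")[stat_col].mean())
    return out


def top_de(
    de_table: pd.DataFrame,
    min_abs_logfc: float | None = None,
    top_k: int | None = None,
    max_p: float | None = None,
    p_col: str = "p_adj",
    collapse: str = "extreme",
) -> pd.DataFrame:
    """Symbol-level top differentially expressed list.

    Probes collapse to symbols keeping the probe with the largest |logFC|;
    the collapsed list is then filtered by ``min_abs_logfc`` and/or ``max_p``
    or truncated to ``top_k`` by |logFC|.  At least one criterion must be
    set.
    """
    if min_abs_logfc is None and top_k is None:
        raise ConfigurationError("set min_abs_logfc and/or top_k for the top-DE list")
    if de_table.empty:
        return de_table.copy()
    out = _collapse(de_table, "logFC", collapse)
    if min_abs_logfc is not None:
        out = out[out["logFC"].abs() >= min_abs_logfc]
    if max_p is not None and p_col in out.columns:
        out = out[out[p_col].notna() & (out[p_col] < max_p)]
    out = out.sort_values(
        by="logFC", key=lambda c: -c.abs(), kind="mergesort"
    ).reset_index(drop=True)
    if top_k is not None:
        out = out.head(top_k)
    return out


def top_corr(
    corr_table: pd.DataFrame,
    max_p: float | None = None,
    top_k: int | None = None,
    collapse: str = "extreme",
) -> pd.DataFrame:
    """Symbol-level top trait-correlated list (collapse keeps max |cor|)."""
    if max_p is None and top_k is None:
        raise ConfigurationError("set max_p and/or top_k for the top-correlation list")
    if corr_table.empty:
        return corr_table.copy()
    out = _collapse(corr_table, "cor", collapse)
    if max_p is not None:
        out = out[out["p_value"] < max_p]
    out = out.sort_values(
        by="cor", key=lambda c: -c.abs(), kind="mergesort"
    ).reset_index(drop=True)
    if top_k is not None:
        out = out.head(top_k)
    return out


def overlay(
    top_de_list: pd.DataFrame,
    top_corr_list: pd.DataFrame,
    known_markers: set[str] | frozenset[str] = DEFAULT_KNOWN_MARKERS,
) -> pd.DataFrame:
    """Intersect the two symbol-level lists into candidate records.

    Returns one row per shared symbol with columns ``symbol de_probe
    corr_probe best_logfc best_cor de_direction corr_direction novel
    concordance``, ordered by |cor| descending.  ``concordance`` starts as
    ``not_tested`` and is filled by the cross-species stage.
    """
    shared = set(top_de_list.get("symbol", pd.Series(dtype=str))) & set(
        top_corr_list.get("symbol", pd.Series(dtype=str))
    )
    if not shared:
        return pd.DataFrame(
            columns=[
                "symbol", "de_probe", "corr_probe", "best_logfc", "best_cor",
                "de_direction", "corr_direction", "novel", "concordance",
            ]
        )
    de_idx = top_de_list.set_index("symbol")
    co_idx = top_corr_list.set_index("symbol")
    rows = []
    for sym in sorted(shared):
        lfc = float(de_idx.loc[sym, "logFC"])
        cor = float(co_idx.loc[sym, "cor"])
        rows.append(
            {
                "symbol": sym,
                "de_probe": de_idx.loc[sym, "probe_id"],
                "corr_probe": co_idx.loc[sym, "probe_id"],
                "best_logfc": lfc,
                "best_cor": cor,
                "de_direction": "up" if lfc > 0 else "down",
                "corr_direction": "pos" if cor > 0 else "neg",
                "novel": sym not in known_markers,
                "concordance": "not_tested",
            }
        )
    out = pd.DataFrame(rows)
    return out.sort_values(
        by=["best_cor", "symbol"],
        key=lambda c: -c.abs() if c.name == "best_cor" else c,
        kind="mergesort",
    ).reset_index(drop=True)


def novel_candidates(candidates: pd.DataFrame) -> set[str]:
    """Symbols of candidates not on the known-marker list."""
    if candidates.empty:
        return set()
    return set(candidates.loc[candidates["novel"], "symbol"])
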