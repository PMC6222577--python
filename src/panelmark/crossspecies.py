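"""Cross-species confirmation of mouse candidates in a human DE table.

Mouse symbols map to human symbols by the standard capitalization rule
(``Gpnmb`` -> ``GPNMB``), overridable per symbol by a user ortholog table
for the cases where mouse and human gene names genuinely differ (e.g. mouse
``Dtr`` vs human ``HBEGF``).  A candidate is *concordant* when it is
significant in the human table and its fold change points the same way as in
mouse, *discordant* when significant the other way, *not_significant* when
present but above alpha, and *absent* when unmapped or missing from the
table.  Candidates are annotated, never dropped.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ContractError, SchemaError

STATUSES = ("concordant", "discordant", "not_significant", "absent")


def map_symbols(
    mouse_symbols, ortholog_table: pd.DataFrame | None = None
) -> dict[str, str]:
    """Mouse -> human symbol map: uppercase rule plus optional overrides.

    ``ortholog_table`` is a two-column frame (mouse symbol, human symbol);
    a duplicated mouse symbol there is a schema error.
    """
    overrides: dict[str, str] = {}
    if ortholog_table is not None:
        mouse_col, human_col = ortholog_table.columns[:2]
        if ortholog_table[mouse_col].duplicated().any():
            dups = ortholog_table.loc[
                ortholog_table[mouse_col].duplicated(), mouse_col
            ].tolist()
            raise SchemaError(f"duplicate mouse symbols in ortholog table: {dups}")
        overrides = dict(
            zip(ortholog_table[mouse_col].astype(str), ortholog_table[human_col].astype(str))
        )
    return {s: overrides.get(s, s.upper()) for s in mouse_symbols}


def concordance(
    candidates: pd.DataFrame,
    human: pd.DataFrame,
    alpha: float = 0.05,
    ortholog_table: pd.DataFrame | None = None,
    linear_fc: bool = False,
) -> pd.DataFrame:
    """Directional/significance concordance of candidates in a human DE table.

    Parameters
    ----------
    candidates
        Overlay output (needs ``symbol`` and ``best_logfc``).
    human
        Table with ``symbol``, ``logFC`` and ``p_value`` columns.
    alpha
        Significance threshold on the human table's supplied p column (the
        caller decides whether that column is raw or adjusted).
    linear_fc
        Set when the human fold changes are linear ratios rather than log;
        they are converted with log2 before sign comparison.

    Returns one row per candidate with ``human_symbol human_logfc human_p
    status alpha``; the status partition over candidates is exhaustive.
    """
    if not 0 < alpha < 1:
        raise ContractError(f"alpha must be in (0, 1), got {alpha}")
    sym_map = map_symbols(candidates["symbol"], ortholog_table)
    hu = human.set_index("symbol")
    rows = []
    for _, cand in candidates.iterrows():
        hsym = sym_map[cand["symbol"]]
        rec = {
            "symbol": cand["symbol"],
            "human_symbol": hsym,
            "human_logfc": np.nan,
            "human_p": np.nan,
            "status": "absent",
            "alpha": alpha,
        }
        if hsym in hu.index:
            hlfc = hu.loc[hsym, "logFC"]
            if linear_fc and pd.notna(hlfc):
                if hlfc <= 0:
                    raise ContractError(f"linear fold change must be > 0 ({hsym})")
                hlfc = np.log2(hlfc)
            hp = hu.loc[hsym, "p_value"]
            rec["human_logfc"] = hlfc
            rec["human_p"] = hp
            if pd.isna(hp) or hp >= alpha:
                rec["status"] = "not_significant"
            elif pd.notna(hlfc) and np.sign(hlfc) == np.sign(cand["best_logfc"]):
                rec["status"] = "concordant"
            else:
                rec["status"] = "discordant"
        rows.append(rec)
    return pd.DataFrame(rows)


def annotate_candidates(
    candidates: pd.DataFrame, report: pd.DataFrame
) -> pd.DataFrame:
    """Copy concordance statuses back onto the candidate records."""
    out = candidates.copy()
    status = report.set_index("symbol")["status"]
    out["concordance"] = out["symbol"].map(status).fillna("not_tested")
    return out
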