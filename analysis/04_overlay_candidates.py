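#!/usr/bin/env python
"""Nominate biomarker candidates by overlaying the top-DE and top-correlated lists.

Two overlays are run: (a) the published printed tables packaged with this
repository — the headline worked example, whose novel candidate set is
{Cdo1, Gpnmb}; and (b) the synthetic panel's DE and correlation tables from
steps 02/03, which must recover the planted overlap genes.  Candidate tables
land in results/tables/.
"""

from pathlib import Path

import pandas as pd
import yaml

from panelmark import io, prioritize

ROOT = Path(__file__).resolve().parents[1]


def published_overlay(out: Path) -> None:
    cands = prioritize.overlay(
        prioritize.top_de(io.load_table1_fixture(), min_abs_logfc=1.0),
        prioritize.top_corr(io.load_table2_fixture(), max_p=1e-3),
    )
    cands.to_csv(out / "candidates_published.tsv", sep="\t", index=False)
    print("published tables: candidates",
          sorted(cands["symbol"]), "-> novel",
          sorted(prioritize.novel_candidates(cands)))


def synthetic_overlay(out: Path) -> None:
    de_table = pd.read_csv(out / "de.tsv", sep="\t").rename(
        columns={"PROBE_ID": "probe_id", "SYMBOL": "symbol",
                 "P.Value": "p_value", "adj.P.Val": "p_adj"})
    corr_table = pd.read_csv(out / "corr.tsv", sep="\t").rename(
        columns={"ilmn_id": "probe_id", "p-value": "p_value"})
    cands = prioritize.overlay(
        prioritize.top_de(de_table, min_abs_logfc=1.0, max_p=0.05),
        prioritize.top_corr(corr_table, max_p=1e-3),
        known_markers=set(),
    )
    cands.to_csv(out / "candidates_synthetic.tsv", sep="\t", index=False)
    truth = yaml.safe_load(
        (ROOT / "results/synthetic/panel/panel_truth.yaml").read_text())
    annot = io.read_annotation(ROOT / "results/synthetic/panel/annotation.tsv")
    overlap = sorted(set(truth["de_genes"]) & set(truth["trait_genes"]))
    want = set(annot.set_index("probe_id").loc[overlap, "symbol"])
    got = set(cands["symbol"])
    print(f"synthetic panel: {len(cands)} candidates; planted overlap genes "
          f"recovered: {sorted(want & got)} of {sorted(want)}")
    if want - got:
        print("  note: at the default planted correlations (|r| ~ 0.37, the "
              "published table's range) the stringent p < 1e-3 trait cutoff "
              "has limited per-gene power, so an overlap gene can miss the "
              "intersection in any one draw; recovery-rate checks use a "
              "stronger configured effect size")


def main() -> None:
    out = ROOT / "results/tables"
    out.mkdir(parents=True, exist_ok=True)
    published_overlay(out)
    synthetic_overlay(out)


if __name__ == "__main__":
    main()
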