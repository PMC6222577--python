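#!/usr/bin/env python
"""Check candidate direction/significance agreement in the human DE table.

Takes the published-overlay candidates plus the established markers and
classifies each against the packaged human failing-vs-non-failing values:
GPNMB comes out concordant (up in both species), TIMP1 discordant (up in the
mouse model, down in failing human hearts), NPPB not significant in the
human comparison.  Writes results/tables/concordance.tsv.
"""

from pathlib import Path

from panelmark.pipeline import demo

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    out = ROOT / "results/tables"
    out.mkdir(parents=True, exist_ok=True)
    res = demo()
    rep = res["concordance"]
    rep.to_csv(out / "concordance.tsv", sep="\t", index=False)
    print(rep[["symbol", "human_symbol", "human_logfc", "human_p", "status"]]
          .to_string(index=False))
    print(f"\nnovel candidates carried forward: {res['novel']}")
    print(f"wrote {out / 'concordance.tsv'}")


if __name__ == "__main__":
    main()
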