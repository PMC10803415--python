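#!/usr/bin/env python
"""Screen the simulated corpus and write every summary table.

Runs the full pipeline (dedup, drug matching, exclusion policy, ROR +
information-component screen under the joint criterion) on the files
written by 01_simulate_corpus.py and stores the result tables under
results/screen/: the per-pair statistics, demographics, SOC rollup,
top-PT ranking, cross-drug co-reported table and the injection/infusion
grouping, plus the attrition log.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import pandas as pd

from faerspv import screen_files

ROOT = Path(__file__).resolve().parents[1]
CORPUS = ROOT / "scratch" / "corpus"
OUT = ROOT / "results" / "screen"


def main() -> None:
    out = screen_files(CORPUS)
    OUT.mkdir(parents=True, exist_ok=True)
    for name, df in [
        ("results", out.results), ("demographics", out.demographics),
        ("soc_summary", out.soc_summary), ("top_pts", out.top_pts),
        ("co_reported", out.co_reported), ("injection_summary", out.injection_summary),
        ("attrition", pd.DataFrame(out.attrition)),
    ]:
        df.to_csv(OUT / f"{name}.tsv", sep="\t", index=False, lineterminator="\n")

    n_sig = int(out.results["is_signal"].sum())
    print(f"screened {len(out.cases)} deduplicated cases; "
          f"{len(out.results)} (drug, PT) pairs, {n_sig} signals")
    sig = out.results[out.results.is_signal]
    for drug, grp in sig.groupby("drug"):
        top = grp.sort_values("a", ascending=False).head(3)
        desc = "; ".join(f"{r.pt} (n={r.a}, ROR={r.ror:.2f})" for r in top.itertuples())
        print(f"  {drug}: {len(grp)} signal PTs — top: {desc}")
    print(f"tables written to {OUT}")


if __name__ == "__main__":
    main()
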