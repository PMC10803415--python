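#!/usr/bin/env python
"""Compare the detected signal set against the generator's ground truth.

Reads the screen written by 02_screen_signals.py and the truth record
from 01_simulate_corpus.py, reports which planted pairs were recovered
(with their estimated ROR vs the planted odds ratio) and how many
background pairs were flagged, and writes results/recovery.tsv.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    truth = json.loads((ROOT / "scratch" / "corpus" / "truth.json").read_text())
    planted = {(d, p): rho for d, p, rho in truth["planted_signals"]}
    res = pd.read_csv(ROOT / "results" / "screen" / "results.tsv", sep="\t")

    rows = []
    for (drug, pt), rho in sorted(planted.items()):
        hit = res[(res.drug == drug) & (res.pt == pt)]
        if len(hit):
            r = hit.iloc[0]
            rows.append((drug, pt, rho, r.a, round(r.ror, 2), round(r.ror_low, 2),
                         round(r.ror_high, 2), bool(r.is_signal)))
        else:
            rows.append((drug, pt, rho, 0, None, None, None, False))
    table = pd.DataFrame(rows, columns=["drug", "pt", "planted_rho", "a", "ror",
                                        "ror_low", "ror_high", "detected"])
    table.to_csv(ROOT / "results" / "recovery.tsv", sep="\t", index=False,
                 lineterminator="\n")

    sig = res[res.is_signal]
    false_pos = [t for t in sig[["drug", "pt"]].itertuples(index=False)
                 if (t.drug, t.pt) not in planted]
    n_det = int(table["detected"].sum())
    print(f"recovered {n_det}/{len(planted)} planted signals; "
          f"{len(false_pos)} background pairs flagged of {len(res)} screened")
    for r in table.itertuples(index=False):
        mark = "found" if r.detected else "MISSED"
        print(f"  [{mark}] {r.drug} / {r.pt}: rho={r.planted_rho}, "
              f"a={r.a}, ROR={r.ror} ({r.ror_low}, {r.ror_high})")
    if false_pos:
        print("background pairs flagged:",
              "; ".join(f"{t.drug}/{t.pt}" for t in false_pos))


if __name__ == "__main__":
    main()
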