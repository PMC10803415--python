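#!/usr/bin/env python
"""Simulate a FAERS-style corpus for the anti-CGRP mAb screening study.

Generates a 20,000-case quarterly-extract-shaped corpus with duplicate
submissions and a handful of planted drug–PT disproportionality signals
echoing the known post-marketing profile of the four drugs (constipation
and alopecia on erenumab, injection-site events on the subcutaneous mAbs,
fatigue/infusion events on eptinezumab), then emits the four dialect
files plus the ground-truth record under scratch/corpus/.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from faerspv.synthetic import SyntheticConfig, generate, emit

OUT = Path(__file__).resolve().parents[1] / "scratch" / "corpus"

PLANTED = (
    ("erenumab", "Constipation", 10.0),
    ("erenumab", "Alopecia", 3.0),
    ("erenumab", "Injection site pain", 5.0),
    ("galcanezumab", "Constipation", 4.0),
    ("galcanezumab", "Injection site pain", 8.0),
    ("galcanezumab", "Injection site erythema", 5.0),
    ("galcanezumab", "Weight increased", 3.0),
    ("fremanezumab", "Constipation", 6.0),
    ("fremanezumab", "Injection site pain", 6.0),
    ("fremanezumab", "Injection site pruritus", 4.0),
    ("eptinezumab", "Fatigue", 5.0),
    ("eptinezumab", "Infusion related reaction", 8.0),
)


def main() -> None:
    config = SyntheticConfig(n_cases=20_000, seed=20240109, planted_signals=PLANTED)
    corpus = generate(config)
    paths = emit(corpus, OUT)
    (OUT / "truth.json").write_text(json.dumps({
        "planted_signals": [list(t) for t in corpus.truth.planted_signals],
        "duplicate_map": corpus.truth.duplicate_map,
        "exposure_counts": corpus.truth.exposure_counts,
    }, indent=2, sort_keys=True) + "\n")

    print(f"simulated {config.n_cases} cases "
          f"({len(corpus.demo)} report versions incl. duplicates)")
    print(f"exposure counts: {corpus.truth.exposure_counts}")
    print(f"planted {len(PLANTED)} disproportionality signals")
    for name, p in paths.items():
        print(f"  wrote {p} ({p.stat().st_size} bytes)")


if __name__ == "__main__":
    main()
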