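"""End-to-end orchestration: files or corpus in, screen and tables out."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import pandas as pd

from . import aggregate
from .disproportionality import run_screen
from .faers_io import TableSchema, read_table, ParseReport
from .preprocess import DrugDictionary, ExclusionPolicy, build_cases, DEFAULT_AGE_EDGES
from .resources import (
    default_drug_dictionary,
    default_exclusion_policy,
    load_pt_soc_map,
)
from .synthetic import Corpus


@dataclass
class ScreenOutput:
    """Everything one screening run produces."""

    cases: pd.DataFrame
    results: pd.DataFrame
    attrition: list[dict]
    demographics: pd.DataFrame
    soc_summary: pd.DataFrame
    top_pts: pd.DataFrame
    co_reported: pd.DataFrame
    injection_summary: pd.DataFrame
    parse_reports: list[ParseReport]


def screen_corpus(
    corpus: Union[Corpus, Mapping[str, pd.DataFrame]],
    dictionary: Optional[DrugDictionary] = None,
    policy: Optional[ExclusionPolicy] = None,
    pt_soc_map: Optional[Mapping[str, str]] = None,
    *,
    roles: Optional[Sequence[str]] = ("PS", "SS"),
    unit: str = "pair",
    correction: str = "none",
    ic025_mode: str = "normal_approx",
    top_n: int = 30,
    min_drugs: int = 3,
    age_edges: Sequence[float] = DEFAULT_AGE_EDGES,
    country_of_interest: str = "US",
    parse_reports: Optional[list[ParseReport]] = None,
) -> ScreenOutput:
    """Run the full pipeline on in-memory tables.

    ``corpus`` is either a :class:`faerspv.synthetic.Corpus` or a mapping
    with keys ``demo``/``drug``/``reac``/``outc`` holding frames in the
    shape :func:`faerspv.read_table` returns.  Percentage consistency of
    every emitted table is asserted before returning.
    """
    dictionary = dictionary or default_drug_dictionary()
    policy = policy or default_exclusion_policy()
    pt_soc_map = pt_soc_map if pt_soc_map is not None else load_pt_soc_map()

    if isinstance(corpus, Corpus):
        frames = {"demo": corpus.demo, "drug": corpus.drug, "reac": corpus.reac, "outc": corpus.outc}
    else:
        frames = dict(corpus)

    cases, attrition = build_cases(
        frames["demo"], frames["drug"], frames["reac"], frames.get("outc"),
        dictionary, policy, pt_soc_map, roles=roles, age_edges=age_edges,
    )
    results = run_screen(
        cases, list(dictionary.labels), pt_soc_map,
        unit=unit, correction=correction, ic025_mode=ic025_mode,
    )

    demo_frames = []
    for label in sorted(dictionary.labels):
        summary = aggregate.demographics(cases, label, country_of_interest)
        frame = summary.to_frame()
        frame.attrs["age_mean"] = summary.age_mean
        frame.attrs["age_sd"] = summary.age_sd
        aggregate.verify_percentages(frame, "n", "pct", summary.total or 1)
        demo_frames.append(frame)
    demographics = pd.concat(demo_frames, ignore_index=True) if demo_frames else pd.DataFrame()

    soc = aggregate.soc_rollup(results, pt_soc_map)
    top = aggregate.top_pts(results, top_n)
    co = aggregate.co_reported(results, min_drugs, policy.injection_terms)
    inj = aggregate.injection_summary(results, policy.injection_terms)
    totals = aggregate.signal_totals(results)
    for drug, total in totals.items():
        aggregate.verify_percentages(soc[soc["drug"] == drug], "n", "pct", total)
        aggregate.verify_percentages(top[top["drug"] == drug], "n", "pct", total)
        aggregate.verify_percentages(inj[inj["drug"] == drug], "n", "pct", total)

    return ScreenOutput(
        cases=cases,
        results=results,
        attrition=attrition,
        demographics=demographics,
        soc_summary=soc,
        top_pts=top,
        co_reported=co,
        injection_summary=inj,
        parse_reports=parse_reports or [],
    )


def screen_files(
    in_dir: Union[str, Path],
    dictionary: Optional[DrugDictionary] = None,
    policy: Optional[ExclusionPolicy] = None,
    pt_soc_map: Optional[Mapping[str, str]] = None,
    **kwargs,
) -> ScreenOutput:
    """Run the pipeline on a directory of DEMO/DRUG/REAC/OUTC files.

    File stems are matched case-insensitively (``DEMO.txt``, ``demo23q1.txt``
    ... anything containing the table name).  OUTC is optional.
    """
    in_dir = Path(in_dir)
    frames: dict[str, pd.DataFrame] = {}
    reports: list[ParseReport] = []
    for schema in TableSchema:
        matches = sorted(
            p for p in in_dir.iterdir()
            if p.is_file() and schema.value.lower() in p.name.lower()
        )
        if not matches:
            if schema is TableSchema.OUTC:
                continue
            raise FileNotFoundError(f"no {schema.value} file found in {in_dir}")
        parts = []
        for p in matches:
            frame, report = read_table(p, schema)
            parts.append(frame)
            reports.append(report)
        frames[schema.value.lower()] = pd.concat(parts, ignore_index=True)
    return screen_corpus(
        frames, dictionary, policy, pt_soc_map, parse_reports=reports, **kwargs
    )
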