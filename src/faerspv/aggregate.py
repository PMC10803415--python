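"""Summary tables over a screened corpus.

Reproduces the table shapes a spontaneous-reporting safety study
publishes: a per-drug demographic table (sex, age buckets with mean(SD),
reporting year, serious outcomes, country-of-interest share), a SOC-level
rollup of signal-positive PTs, top-N PT frequency tables, a cross-drug
co-reported signal table, and an injection/infusion-site grouping.

Percentages are computed against explicitly stated denominators and
rounded half-up to two decimals so every printed share is re-derivable
from the counts next to it; :func:`verify_percentages` asserts exactly
that and is run on every pipeline output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .preprocess import AGE_BUCKET_LABELS, OUTCOME_LABELS, UNKNOWN

#: substring triggers marking a PT as injection/infusion related
INJECTION_SUBSTRINGS = ("injection site", "infusion site", "infusion related")

SERIOUS_OUTCOME_ORDER = ("HO", "DS", "LT", "DE")


def share_pct(n: float, denom: float) -> float:
    """Percentage share n/denom*100, rounded half-up to 2 decimals.

    A zero denominator yields 0.0 (an empty stratum has no shares).
    """
    if denom == 0:
        return 0.0
    q = (Decimal(str(n)) / Decimal(str(denom)) * 100).quantize(
        Decimal("0.01"), rounding=ROUND_HALF_UP
    )
    return float(q)


def verify_percentages(frame: pd.DataFrame, n_col: str, pct_col: str, denom: float) -> None:
    """Assert every percentage in ``frame`` re-derives from its count."""
    for n, pct in zip(frame[n_col], frame[pct_col]):
        if pd.isna(pct):
            continue
        expect = share_pct(float(n), denom)
        if abs(expect - float(pct)) > 1e-9:
            raise AssertionError(
                f"percentage {pct} not re-derivable from count {n} / {denom} (expected {expect})"
            )


# ---------------------------------------------------------------------------
# demographics


@dataclass
class DemographicSummary:
    """Per-drug demographic counts and shares (denominator = drug total)."""

    drug: str
    total: int
    sex: dict[str, tuple[int, float]]
    age_bucket: dict[str, tuple[int, float]]
    age_mean: float
    age_sd: float
    reporting_year: dict[int, tuple[int, float]]
    serious_outcomes: dict[str, tuple[int, float]]
    country_of_interest: str
    country_n: int
    country_pct: float

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cat, (n, p) in self.sex.items():
            rows.append(("Sex", cat, n, p))
        for cat, (n, p) in self.age_bucket.items():
            rows.append(("Age (years)", cat, n, p))
        for year, (n, p) in sorted(self.reporting_year.items()):
            rows.append(("Reporting year", str(year), n, p))
        for code, (n, p) in self.serious_outcomes.items():
            rows.append(("Serious outcomes", OUTCOME_LABELS.get(code, code), n, p))
        rows.append(
            (f"Reported from {self.country_of_interest}", self.country_of_interest,
             self.country_n, self.country_pct)
        )
        out = pd.DataFrame(rows, columns=["section", "category", "n", "pct"])
        out.insert(0, "drug", self.drug)
        return out


def demographics(
    cases: pd.DataFrame,
    drug: Optional[str] = None,
    country_of_interest: str = "US",
) -> DemographicSummary:
    """Demographic summary of (a drug's) deduplicated cases.

    ``drug=None`` summarises every case; otherwise only cases whose
    ``drug_hits`` contain the label.  All percentages use the drug-column
    case total as denominator; the age mean and sample SD are computed
    over cases with a known age only (the Unknown row carries the rest).
    """
    if drug is not None:
        cases = cases[cases["drug_hits"].map(lambda h: drug in h)]
    total = len(cases)

    def block(series: pd.Series, order: Iterable) -> dict:
        vc = series.value_counts()
        return {k: (int(vc.get(k, 0)), share_pct(int(vc.get(k, 0)), total)) for k in order}

    sex_map = {"M": "Male", "F": "Female", "UNK": UNKNOWN}
    sex_counts = cases["sex"].map(sex_map).fillna(UNKNOWN)
    sex = block(sex_counts, ["Male", "Female", UNKNOWN])

    age_bucket = block(cases["age_bucket"], list(AGE_BUCKET_LABELS) + [UNKNOWN])
    known = cases["age_years"].astype(float).dropna()
    age_mean = float(known.mean()) if len(known) else math.nan
    age_sd = float(known.std(ddof=1)) if len(known) > 1 else math.nan

    years = cases["reporting_year"]
    years = years[years > 0]
    year_counts = years.value_counts()
    reporting_year = {
        int(y): (int(c), share_pct(int(c), total)) for y, c in sorted(year_counts.items())
    }

    serious = {}
    for code in SERIOUS_OUTCOME_ORDER:
        n = int(cases["outcomes"].map(lambda o: code in o).sum())
        serious[code] = (n, share_pct(n, total))

    cn = int((cases["country"] == country_of_interest).sum())
    return DemographicSummary(
        drug=drug if drug is not None else "all",
        total=total,
        sex=sex,
        age_bucket=age_bucket,
        age_mean=age_mean,
        age_sd=age_sd,
        reporting_year=reporting_year,
        serious_outcomes=serious,
        country_of_interest=country_of_interest,
        country_n=cn,
        country_pct=share_pct(cn, total),
    )


# ---------------------------------------------------------------------------
# signal-table rollups


def _signals(results: pd.DataFrame) -> pd.DataFrame:
    return results[results["is_signal"]]


def signal_totals(results: pd.DataFrame) -> pd.Series:
    """Per-drug total signal-report sum (sum of a over signal PTs)."""
    sig = _signals(results)
    return sig.groupby("drug")["a"].sum()


def soc_rollup(results: pd.DataFrame, pt_soc_map: Mapping[str, str]) -> pd.DataFrame:
    """SOC-level rollup of signal-positive PTs, one block per drug.

    Columns: drug, soc, pt_count (distinct signal PTs under the SOC),
    n (summed report count), pct (share of the drug's total signal-report
    sum).  Sorted per drug by descending n, then SOC name.  PTs missing
    from the dictionary land in an "Unmapped" SOC (never dropped, so the
    rollup conserves mass).
    """
    sig = _signals(results).copy()
    if sig.empty:
        return pd.DataFrame(columns=["drug", "soc", "pt_count", "n", "pct"])
    sig["soc"] = [pt_soc_map.get(str(p).lower(), "Unmapped") for p in sig["pt"]]
    rows = []
    for drug, grp in sig.groupby("drug"):
        total = int(grp["a"].sum())
        roll = grp.groupby("soc").agg(pt_count=("pt", "nunique"), n=("a", "sum")).reset_index()
        roll = roll.sort_values(["n", "soc"], ascending=[False, True], kind="mergesort")
        for _, r in roll.iterrows():
            rows.append((drug, r["soc"], int(r["pt_count"]), int(r["n"]),
                         share_pct(int(r["n"]), total)))
    return pd.DataFrame(rows, columns=["drug", "soc", "pt_count", "n", "pct"])


def top_pts(results: pd.DataFrame, k: int = 30) -> pd.DataFrame:
    """Top-k signal PTs per drug, ranked by report count.

    Ties break lexicographically by PT.  ``pct`` is the share of the
    drug's total signal-report sum.  ``k`` below 1 is an error.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    sig = _signals(results)
    rows = []
    for drug, grp in sig.groupby("drug"):
        total = int(grp["a"].sum())
        top = grp.sort_values(["a", "pt"], ascending=[False, True], kind="mergesort").head(k)
        for rank, (_, r) in enumerate(top.iterrows(), start=1):
            rows.append((drug, rank, r["pt"], int(r["a"]), share_pct(int(r["a"]), total)))
    return pd.DataFrame(rows, columns=["drug", "rank", "pt", "n", "pct"])


def is_injection_related(pt: str, extra_terms: Sequence[str] = ()) -> bool:
    """Whether a PT describes an injection-/infusion-site or -related event.

    True when the lower-cased PT contains any built-in substring trigger
    ("injection site", "infusion site", "infusion related") or exactly
    equals a configured extra term (e.g. fear-of-injection families, which
    are not excluded by default).
    """
    p = pt.strip().lower()
    if any(s in p for s in INJECTION_SUBSTRINGS):
        return True
    return p in {t.strip().lower() for t in extra_terms}


def co_reported(
    results: pd.DataFrame,
    min_drugs: int = 3,
    injection_terms: Sequence[str] = (),
) -> pd.DataFrame:
    """Signal PTs shared across drugs, excluding injection-related terms.

    A PT qualifies when it is a signal for at least ``min_drugs`` drugs.
    Long format: one row per (pt, drug) signal with n, pct (share of the
    drug's total signal-report sum), ROR and CI; ``n_drugs`` repeats the
    number of drugs sharing the PT.  Ordered by descending n_drugs, then
    descending total n, then PT.
    """
    all_sig = _signals(results)
    # shares are against the drug's full signal-report sum, injection PTs included
    totals = all_sig.groupby("drug")["a"].sum()
    sig = all_sig[~all_sig["pt"].map(lambda p: is_injection_related(p, injection_terms))]
    if sig.empty:
        return pd.DataFrame(
            columns=["pt", "n_drugs", "drug", "n", "pct", "ror", "ror_low", "ror_high"]
        )
    by_pt = sig.groupby("pt")["drug"].nunique()
    keep = by_pt[by_pt >= min_drugs]
    sub = sig[sig["pt"].isin(keep.index)].copy()
    sub["n_drugs"] = sub["pt"].map(keep)
    sub["pct"] = [share_pct(int(a), int(totals[d])) for a, d in zip(sub["a"], sub["drug"])]
    pt_total = sub.groupby("pt")["a"].sum()
    sub["_tot"] = sub["pt"].map(pt_total)
    sub = sub.sort_values(
        ["n_drugs", "_tot", "pt", "drug"], ascending=[False, False, True, True], kind="mergesort"
    )
    out = sub[["pt", "n_drugs", "drug", "a", "pct", "ror", "ror_low", "ror_high"]]
    return out.rename(columns={"a": "n"}).reset_index(drop=True)


def injection_summary(
    results: pd.DataFrame, injection_terms: Sequence[str] = ()
) -> pd.DataFrame:
    """Per-drug injection/infusion-related signal burden.

    Columns: drug, pt_count (injection-related signal PTs), n (summed
    report count), pct (share of the drug's total signal-report sum —
    "share of all mined AEs").
    """
    sig = _signals(results).copy()
    rows = []
    for drug, grp in sig.groupby("drug"):
        total = int(grp["a"].sum())
        inj = grp[grp["pt"].map(lambda p: is_injection_related(p, injection_terms))]
        n = int(inj["a"].sum())
        rows.append((drug, int(inj["pt"].nunique()), n, share_pct(n, total)))
    return pd.DataFrame(rows, columns=["drug", "pt_count", "n", "pct"])
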