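"""From raw quarterly rows to a deduplicated, drug-attributed analysis set.

Spontaneous reports arrive in versions: the same case (CASEID) may be
submitted repeatedly by patients, clinicians and manufacturers, each
submission getting a fresh PRIMARYID.  Following the FDA's recommended
cleaning rule, one report is kept per case: the one with the latest
FDA receipt date (FDA_DT), ties broken by the numerically highest
PRIMARYID.  Target drugs are then attributed by case-insensitive keyword
matching (generic + brand names) against drug-mention rows, by default
counting suspect roles only (PS, SS).  Finally, adverse-event preferred
terms are filtered through an exclusion policy (product problems,
medication errors, off-label use, indication terms, disease states) before
any disproportionality is computed.

Every cleaning rule appends a structured line to an attrition log so the
row accounting of a run is auditable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

AGE_BUCKET_LABELS = ("<18", "18–45", "45–65", ">65")
DEFAULT_AGE_EDGES = (18.0, 45.0, 65.0)
UNKNOWN = "Unknown"

#: multiplicative factor from unit code to years
_AGE_FACTORS = {
    "DEC": 10.0,
    "YR": 1.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.1775,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
}
_AGE_PLAUSIBLE = (0.0, 120.0)

OUTCOME_LABELS = {
    "HO": "Hospitalization",
    "DS": "Disability",
    "LT": "Life-threatening",
    "DE": "Death",
    "CA": "Congenital anomaly",
    "RI": "Required intervention",
    "OT": "Other serious",
}


@dataclass(frozen=True)
class DrugDictionary:
    """Target label -> list of lowercase name keywords (generic + brands)."""

    keywords: Mapping[str, Sequence[str]]

    def __post_init__(self) -> None:
        if not self.keywords:
            raise ValueError("drug dictionary must not be empty")
        norm = {}
        for label, kws in self.keywords.items():
            kws = [str(k).strip().lower() for k in kws if str(k).strip()]
            if not kws:
                raise ValueError(f"drug {label!r} has no keywords")
            norm[label] = tuple(kws)
        object.__setattr__(self, "keywords", norm)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self.keywords)


@dataclass(frozen=True)
class ExclusionEntry:
    term: str
    match: str = "exact"  # "exact" or "substring"
    reason: str = "excluded"

    def __post_init__(self) -> None:
        if self.match not in ("exact", "substring"):
            raise ValueError(f"match rule must be 'exact' or 'substring', got {self.match!r}")
        object.__setattr__(self, "term", self.term.strip().lower())


@dataclass(frozen=True)
class ExclusionPolicy:
    """Which PTs are dropped before disproportionality, and why."""

    pt_terms: Sequence[ExclusionEntry] = ()
    excluded_socs: Sequence[str] = ()
    injection_terms: Sequence[str] = ()  # extra exact injection-related PTs

    def classify(self, pt: str, soc: Optional[str]) -> Optional[str]:
        """Exclusion reason for ``pt`` (mapped to ``soc``), or None to keep."""
        p = pt.strip().lower()
        for entry in self.pt_terms:
            if entry.match == "exact":
                if p == entry.term:
                    return entry.reason
            elif entry.term in p:
                return entry.reason
        if soc is not None and soc in set(self.excluded_socs):
            return f"soc:{soc}"
        return None


def convert_age(age_value, age_code) -> float:
    """Convert a (value, unit-code) pair to years; NaN when unusable.

    Unit codes: DEC decades, YR years, MON months, WK weeks, DY days,
    HR hours.  Unknown codes, missing values and results outside the
    plausible [0, 120] year range map to NaN.
    """
    if age_value is None or age_value is pd.NA:
        return math.nan
    try:
        v = float(age_value)
    except (TypeError, ValueError):
        return math.nan
    if math.isnan(v) or v < 0:
        return math.nan
    code = "" if age_code is None or age_code is pd.NA else str(age_code).strip().upper()
    if code == "":
        code = "YR"  # FAERS convention: blank unit accompanies year values
    factor = _AGE_FACTORS.get(code)
    if factor is None:
        return math.nan
    years = v * factor
    if not (_AGE_PLAUSIBLE[0] <= years <= _AGE_PLAUSIBLE[1]):
        return math.nan
    return years


def bucket_age(age_years, edges: Sequence[float] = DEFAULT_AGE_EDGES) -> str:
    """Assign an age in years to a half-open bucket.

    Buckets are [0, e0), [e0, e1), [e1, e2), [e2, inf); a boundary age
    belongs to the upper bucket, so 45.0 falls in "45–65".  Missing ages
    map to "Unknown".
    """
    if age_years is None or (isinstance(age_years, float) and math.isnan(age_years)):
        return UNKNOWN
    a = float(age_years)
    e0, e1, e2 = edges
    if a < e0:
        return AGE_BUCKET_LABELS[0]
    if a < e1:
        return AGE_BUCKET_LABELS[1]
    if a < e2:
        return AGE_BUCKET_LABELS[2]
    return AGE_BUCKET_LABELS[3]


def _fda_dt_key(demo: pd.DataFrame) -> pd.Series:
    """Sortable date key; unparseable/missing dates sort earliest (-1)."""
    key = pd.to_numeric(demo["fda_dt"], errors="coerce")
    if "fda_dt_valid" in demo.columns:
        key = key.where(demo["fda_dt_valid"].fillna(False).astype(bool))
    return key.fillna(-1).astype("int64")


def deduplicate(demo: pd.DataFrame) -> tuple[pd.DataFrame, list[dict]]:
    """Collapse report versions to one row per case.

    Keeps, within each CASEID, the row with the latest FDA_DT; among ties
    the numerically highest PRIMARYID wins.  Rows with a missing CASEID
    are dropped.  Idempotent and independent of input row order.

    Returns
    -------
    (deduplicated frame, attrition log)
        The log is a list of ``{"rule", "removed", "remaining"}`` dicts,
        one per cleaning rule applied.
    """
    log: list[dict] = []
    n0 = len(demo)
    demo = demo[demo["caseid"].notna()]
    log.append({"rule": "drop_missing_caseid", "removed": n0 - len(demo), "remaining": len(demo)})

    if len(demo) == 0:
        return demo.copy(), log

    pid = pd.to_numeric(demo["primaryid"], errors="coerce").fillna(-1)
    order = pd.DataFrame(
        {"date_key": _fda_dt_key(demo), "pid_key": pid.to_numpy(dtype="float64")},
        index=demo.index,
    )
    # stable argmax per caseid on (date, primaryid)
    order = order.sort_values(["date_key", "pid_key"], kind="mergesort")
    keep_idx = order.groupby(demo["caseid"].reindex(order.index), sort=False).tail(1).index
    kept = demo[demo.index.isin(keep_idx)].copy()  # original row order preserved
    log.append(
        {"rule": "dedup_caseid_latest_fda_dt_highest_primaryid",
         "removed": len(demo) - len(kept), "remaining": len(kept)}
    )
    return kept, log


def match_drugs(
    drug: pd.DataFrame,
    dictionary: DrugDictionary,
    roles: Optional[Sequence[str]] = ("PS", "SS"),
) -> dict[str, set[str]]:
    """Attribute reports to target drugs by keyword matching.

    Case-insensitive substring match of every dictionary keyword against
    DRUGNAME and, when present, PROD_AI.  Only mentions whose ROLE_COD is
    in ``roles`` count (None = all roles).  A report may match several
    targets.

    Returns a mapping primaryid -> set of matched target labels
    (reports with no match are absent).
    """
    if not dictionary.keywords:
        raise ValueError("drug dictionary must not be empty")
    df = drug
    if roles is not None:
        role = df["role_cod"].fillna("").str.upper()
        df = df[role.isin([r.upper() for r in roles])]
    if len(df) == 0:
        return {}
    name = df["drugname"].fillna("").str.lower()
    ai = df["prod_ai"].fillna("").str.lower() if "prod_ai" in df.columns else None
    hits: dict[str, set[str]] = {}
    for label, kws in dictionary.keywords.items():
        mask = pd.Series(False, index=df.index)
        for kw in kws:
            mask |= name.str.contains(kw, regex=False)
            if ai is not None:
                mask |= ai.str.contains(kw, regex=False)
        for pid in df.loc[mask, "primaryid"].dropna().unique():
            hits.setdefault(pid, set()).add(label)
    return hits


def apply_exclusions(
    pts: Iterable[str],
    policy: ExclusionPolicy,
    pt_soc_map: Optional[Mapping[str, str]] = None,
) -> tuple[list[str], list[tuple[str, str]]]:
    """Split PTs into retained and (pt, reason) removals.

    Exact entries compare whole lower-cased PTs, substring entries test
    containment, and PTs mapping to an excluded SOC are removed with
    reason ``soc:<name>``.  Retained + removed partition the input.
    """
    pt_soc_map = pt_soc_map or {}
    retained: list[str] = []
    removed: list[tuple[str, str]] = []
    cache: dict[str, Optional[str]] = {}
    for pt in pts:
        key = pt.strip().lower()
        if key not in cache:
            cache[key] = policy.classify(pt, pt_soc_map.get(key))
        reason = cache[key]
        if reason is None:
            retained.append(pt)
        else:
            removed.append((pt, reason))
    return retained, removed


def build_cases(
    demo: pd.DataFrame,
    drug: pd.DataFrame,
    reac: pd.DataFrame,
    outc: Optional[pd.DataFrame],
    dictionary: DrugDictionary,
    policy: ExclusionPolicy,
    pt_soc_map: Mapping[str, str],
    *,
    roles: Optional[Sequence[str]] = ("PS", "SS"),
    age_edges: Sequence[float] = DEFAULT_AGE_EDGES,
) -> tuple[pd.DataFrame, list[dict]]:
    """Assemble the per-case analysis table.

    Runs deduplication, drug attribution, age conversion/bucketing and PT
    exclusion, returning one row per surviving case with columns::

        primaryid caseid fda_dt reporting_year sex age_years age_bucket
        country outcomes pts drug_hits

    ``outcomes`` and ``drug_hits`` are frozensets, ``pts`` a sorted tuple
    of retained PTs.  The attrition log extends the dedup log with PT
    exclusion counts per reason.
    """
    kept, log = deduplicate(demo)
    kept = kept.copy()
    kept_ids = set(kept["primaryid"].dropna())

    # demographics
    ages = [convert_age(v, c) for v, c in zip(kept.get("age"), kept.get("age_cod"))]
    kept["age_years"] = ages
    kept["age_bucket"] = [bucket_age(a, age_edges) for a in ages]
    sex = kept["sex"].fillna("UNK").str.upper()
    kept["sex"] = sex.where(sex.isin(["M", "F"]), "UNK")
    country = kept["occr_country"] if "occr_country" in kept.columns else pd.Series(pd.NA, index=kept.index)
    if "reporter_country" in kept.columns:
        country = country.fillna(kept["reporter_country"])
    kept["country"] = country.fillna(UNKNOWN)
    date_key = _fda_dt_key(kept)
    kept["reporting_year"] = np.where(date_key > 0, date_key // 10000, -1)

    # drug attribution
    hits = match_drugs(drug[drug["primaryid"].isin(kept_ids)], dictionary, roles)
    kept["drug_hits"] = [frozenset(hits.get(p, ())) for p in kept["primaryid"]]

    # reactions, with exclusion policy applied per unique PT
    reac_kept = reac[reac["primaryid"].isin(kept_ids) & reac["pt"].notna()]
    uniq = reac_kept["pt"].unique().tolist()
    retained_u, removed_u = apply_exclusions(uniq, policy, pt_soc_map)
    keep_set = set(retained_u)
    removed_counts: dict[str, int] = {}
    if removed_u:
        removed_map = dict(removed_u)
        drop_mask = ~reac_kept["pt"].isin(keep_set)
        for pt, cnt in reac_kept.loc[drop_mask, "pt"].value_counts().items():
            reason = removed_map[pt]
            removed_counts[reason] = removed_counts.get(reason, 0) + int(cnt)
    pt_rows = reac_kept[reac_kept["pt"].isin(keep_set)]
    pts_by_pid = pt_rows.groupby("primaryid")["pt"].agg(lambda s: tuple(sorted(set(s))))
    kept["pts"] = [pts_by_pid.get(p, ()) for p in kept["primaryid"]]
    for reason, cnt in sorted(removed_counts.items()):
        log.append({"rule": f"exclude_pt:{reason}", "removed": cnt,
                    "remaining": int(len(pt_rows))})

    # outcomes
    if outc is not None and len(outc):
        oc = outc[outc["primaryid"].isin(kept_ids) & outc["outc_cod"].notna()]
        oc_by_pid = oc.groupby("primaryid")["outc_cod"].agg(lambda s: frozenset(x.upper() for x in s))
        kept["outcomes"] = [oc_by_pid.get(p, frozenset()) for p in kept["primaryid"]]
    else:
        kept["outcomes"] = [frozenset()] * len(kept)

    cols = ["primaryid", "caseid", "fda_dt", "reporting_year", "sex",
            "age_years", "age_bucket", "country", "outcomes", "pts", "drug_hits"]
    cases = kept[cols].reset_index(drop=True)
    assert cases["caseid"].is_unique, "deduplication must leave unique caseids"
    return cases, log
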