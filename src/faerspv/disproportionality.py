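"""Disproportionality statistics for drug–event pairs.

For each (target drug, preferred term) pair the corpus is collapsed to a
2x2 contingency table

    =====================  ==============  =============
    .                      AE of interest  all other AEs
    target drug            a               b
    all other drugs        c               d
    =====================  ==============  =============

and two frequentist/Bayesian-shrinkage-style screening statistics are
computed:

* the reporting odds ratio ``ROR = ad / bc`` with the Woolf 95% CI
  ``exp(ln ROR ± 1.96 sqrt(1/a + 1/b + 1/c + 1/d))``;
* the BCPNN information component ``IC = log2( a N / ((a+b)(a+c)) )``
  with N = a+b+c+d, whose lower 95% bound IC025 gates the signal.

Two IC025 variants are emitted side by side: a delta-method normal
approximation on the log2 scale,
``IC - 1.96 sqrt(1/a + 1/b + 1/c + 1/d) / ln 2`` (the default, defined for
every table with positive cells), and the literal expression
``exp(ln IC - 1.96 sqrt(1/a + 1/b + 1/c + 1/d)) * 0.5`` sometimes printed
in the applied literature, which is only defined when IC > 0 and is
reported for comparability, never silently substituted.

A pair is a signal when **all** of: a >= 3, ROR CI lower bound > 1,
IC025 > 0 (strict inequalities on the bounds).  No multiple-testing
adjustment is applied — the joint criterion is the screen.

Counting bases: the default "pair" basis counts case–PT pairs (a case with
three retained PTs contributes three units); the "case" basis counts
distinct cases, so b = target cases without the PT.  The basis in use is
recorded in every result row.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

Z95 = 1.96
LN2 = math.log(2.0)

RESULT_COLUMNS = [
    "drug", "pt", "soc", "a", "b", "c", "d",
    "ror", "ror_low", "ror_high", "ic", "ic025_printed", "ic025_approx",
    "is_signal", "flags",
]


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts for one (drug, PT) pair against the rest of the corpus."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if not float(v).is_integer() or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")
        if self.n == 0:
            raise ValueError("contingency table must contain at least one count")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


class RorResult(NamedTuple):
    ror: float
    low: float
    high: float
    zero_cell: bool


class IcResult(NamedTuple):
    ic: float
    ic025: float
    defined: bool


def ror_with_ci(table: ContingencyTable, correction: str = "none") -> RorResult:
    """Reporting odds ratio ad/bc with its Woolf 95% CI.

    ``correction="haldane"`` adds 0.5 to every cell before computing
    (Haldane–Anscombe), making every table finite.  With no correction a
    zero in b or c yields ROR = +inf, a zero in a yields ROR = 0; the CI
    is then undefined (NaN) and ``zero_cell`` is set.
    """
    if correction not in ("none", "haldane"):
        raise ValueError(f"unknown correction {correction!r}")
    a, b, c, d = (float(x) for x in table.cells())
    if correction == "haldane":
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    if min(a, b, c, d) <= 0.0:
        if b == 0.0 or c == 0.0:
            ror = math.inf if a > 0 and d > 0 else math.nan
        else:  # a == 0 or d == 0 with b, c > 0 -> numerator ad = 0
            ror = 0.0
        return RorResult(ror, math.nan, math.nan, True)
    ror = (a * d) / (b * c)
    se = math.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    log_ror = math.log(a) + math.log(d) - math.log(b) - math.log(c)
    return RorResult(ror, math.exp(log_ror - Z95 * se), math.exp(log_ror + Z95 * se), False)


def information_component(table: ContingencyTable) -> float:
    """IC = log2(a N / ((a+b)(a+c))); -inf when a = 0."""
    a, b, c, _ = table.cells()
    if a == 0:
        return -math.inf
    n = table.n
    # ratio form: exactly 0 on independent tables (a*n == (a+b)*(a+c))
    return math.log2((a * n) / ((a + b) * (a + c)))


def ic_with_ic025(table: ContingencyTable, mode: str = "normal_approx") -> IcResult:
    """Information component and its lower 95% bound.

    ``mode="normal_approx"`` (default): IC − 1.96·sqrt(Σ 1/cell)/ln 2, the
    delta-method bound on the log2 scale; needs all four cells > 0.
    ``mode="as_printed"``: exp(ln IC − 1.96·sqrt(Σ 1/cell))·0.5 evaluated
    literally; additionally needs IC > 0.  When the chosen expression is
    undefined, ``ic025`` is NaN and ``defined`` False.
    """
    if mode not in ("normal_approx", "as_printed"):
        raise ValueError(f"unknown ic025 mode {mode!r}")
    ic = information_component(table)
    a, b, c, d = (float(x) for x in table.cells())
    if min(a, b, c, d) <= 0.0 or math.isinf(ic):
        return IcResult(ic, math.nan, False)
    se = math.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    if mode == "normal_approx":
        return IcResult(ic, ic - Z95 * se / LN2, True)
    if ic <= 0.0:
        return IcResult(ic, math.nan, False)
    return IcResult(ic, math.exp(math.log(ic) - Z95 * se) * 0.5, True)


def evaluate_signal(a: int, ror_low: float, ic025: float) -> bool:
    """The joint screening criterion: a >= 3, ROR lower bound > 1, IC025 > 0.

    Undefined bounds (NaN) never qualify.
    """
    return bool(a >= 3) and bool(ror_low > 1.0) and bool(ic025 > 0.0)


# ---------------------------------------------------------------------------
# corpus counting


@dataclass
class Counts:
    """Marginal counts of a deduplicated corpus under one counting basis."""

    unit: str                                   # "pair" or "case"
    pt_totals: pd.Series                        # pt -> count over all cases
    drug_pt: Mapping[str, pd.Series]            # label -> (pt -> a)
    drug_pair_total: Mapping[str, int]          # label -> pairs in target cases
    total_pairs: int
    n_cases: int
    drug_case_total: Mapping[str, int]          # label -> number of target cases


def count_unit(cases: pd.DataFrame, targets: Sequence[str], unit: str = "pair") -> Counts:
    """Tally the corpus margins needed for every (drug, PT) table.

    ``cases`` is the frame from :func:`faerspv.preprocess.build_cases`
    (``pts`` tuple and ``drug_hits`` frozenset per row).  Because PTs are
    de-duplicated within a case, a (drug, PT) cell count is the same under
    both bases; the bases differ in the complementary margins b and d.
    """
    if unit not in ("pair", "case"):
        raise ValueError(f"unknown counting unit {unit!r}")
    pts_col = cases["pts"]
    n_per_case = pts_col.map(len).to_numpy()
    all_pts = [pt for pts in pts_col for pt in pts]
    pt_totals = pd.Series(all_pts, dtype="object").value_counts() if all_pts else pd.Series(dtype="int64")

    drug_pt: dict[str, pd.Series] = {}
    drug_pair_total: dict[str, int] = {}
    drug_case_total: dict[str, int] = {}
    hits_col = cases["drug_hits"]
    for label in targets:
        mask = hits_col.map(lambda h: label in h).to_numpy()
        t_pts = [pt for pts in pts_col[mask] for pt in pts]
        drug_pt[label] = (
            pd.Series(t_pts, dtype="object").value_counts() if t_pts else pd.Series(dtype="int64")
        )
        drug_pair_total[label] = int(n_per_case[mask].sum())
        drug_case_total[label] = int(mask.sum())
    return Counts(
        unit=unit,
        pt_totals=pt_totals,
        drug_pt=drug_pt,
        drug_pair_total=drug_pair_total,
        total_pairs=int(n_per_case.sum()),
        n_cases=int(len(cases)),
        drug_case_total=drug_case_total,
    )


def build_contingency(counts: Counts, drug: str, pt: str) -> ContingencyTable:
    """2x2 table for one (drug, PT) pair under the tallied basis.

    An unknown drug or PT yields a table with a = 0, not an error.
    """
    a = int(counts.drug_pt.get(drug, pd.Series(dtype="int64")).get(pt, 0))
    c_tot = int(counts.pt_totals.get(pt, 0))
    c = c_tot - a
    if counts.unit == "pair":
        t = counts.drug_pair_total.get(drug, 0)
        b = t - a
        d = counts.total_pairs - t - c
    else:
        t = counts.drug_case_total.get(drug, 0)
        b = t - a
        d = (counts.n_cases - t) - c
    return ContingencyTable(a, b, c, d)


# ---------------------------------------------------------------------------
# vectorised screen


def _stats_arrays(a, b, c, d, correction: str):
    """Vectorised ROR/CI/IC/IC025 over parallel integer cell arrays."""
    a = np.asarray(a, dtype="float64")
    b = np.asarray(b, dtype="float64")
    c = np.asarray(c, dtype="float64")
    d = np.asarray(d, dtype="float64")
    if correction == "haldane":
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    n = a + b + c + d
    zero = (a <= 0) | (b <= 0) | (c <= 0) | (d <= 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ror = np.where((b > 0) & (c > 0), (a * d) / (b * c),
                       np.where((a > 0) & (d > 0), np.inf, np.nan))
        se = np.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
        log_ror = np.log(a) + np.log(d) - np.log(b) - np.log(c)
        low = np.where(zero, np.nan, np.exp(log_ror - Z95 * se))
        high = np.where(zero, np.nan, np.exp(log_ror + Z95 * se))
        ic = np.where(a > 0, np.log2((a * n) / ((a + b) * (a + c))), -np.inf)
        ic025_approx = np.where(zero, np.nan, ic - Z95 * se / LN2)
        ic025_printed = np.where(zero | (ic <= 0), np.nan,
                                 np.exp(np.log(np.where(ic > 0, ic, np.nan)) - Z95 * se) * 0.5)
    return ror, low, high, ic, ic025_approx, ic025_printed, zero


def run_screen(
    cases: pd.DataFrame,
    targets: Sequence[str],
    pt_soc_map: Optional[Mapping[str, str]] = None,
    *,
    unit: str = "pair",
    correction: str = "none",
    ic025_mode: str = "normal_approx",
    min_a: int = 1,
) -> pd.DataFrame:
    """Screen every (target drug, retained PT) pair of a deduplicated corpus.

    Returns one row per pair with a >= ``min_a``, ordered by drug label,
    then descending a, then PT — a deterministic order invariant to input
    row permutation.  ``is_signal`` applies the joint criterion with the
    IC025 variant named by ``ic025_mode``; both variants are emitted.
    """
    if ic025_mode not in ("normal_approx", "as_printed"):
        raise ValueError(f"unknown ic025 mode {ic025_mode!r}")
    pt_soc_map = pt_soc_map or {}
    counts = count_unit(cases, targets, unit)
    frames = []
    for label in sorted(targets):
        apt = counts.drug_pt.get(label)
        if apt is None or apt.empty:
            continue
        pts = apt.index.to_numpy()
        a = apt.to_numpy(dtype="int64")
        c_tot = counts.pt_totals.reindex(pts).to_numpy(dtype="int64")
        c = c_tot - a
        if unit == "pair":
            t = counts.drug_pair_total[label]
            b = t - a
            d = counts.total_pairs - t - c
        else:
            t = counts.drug_case_total[label]
            b = t - a
            d = (counts.n_cases - t) - c
        keep = a >= min_a
        pts, a, b, c, d = pts[keep], a[keep], b[keep], c[keep], d[keep]
        ror, low, high, ic, ic_ap, ic_pr, zero = _stats_arrays(a, b, c, d, correction)
        gate = ic_ap if ic025_mode == "normal_approx" else ic_pr
        with np.errstate(invalid="ignore"):
            sig = (a >= 3) & (low > 1.0) & (gate > 0.0)
        base_flags = f"basis={unit};ic025={ic025_mode};correction={correction}"
        frames.append(pd.DataFrame({
            "drug": label,
            "pt": pts,
            "soc": [pt_soc_map.get(str(p).lower(), "Unmapped") for p in pts],
            "a": a, "b": b, "c": c, "d": d,
            "ror": ror, "ror_low": low, "ror_high": high,
            "ic": ic, "ic025_printed": ic_pr, "ic025_approx": ic_ap,
            "is_signal": sig,
            "flags": [base_flags + (";zero-cell" if z else "") for z in zero],
        }))
    if not frames:
        return pd.DataFrame(columns=RESULT_COLUMNS)
    out = pd.concat(frames, ignore_index=True)
    out = out.sort_values(
        ["drug", "a", "pt"], ascending=[True, False, True], kind="mergesort"
    ).reset_index(drop=True)
    return out[RESULT_COLUMNS]
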