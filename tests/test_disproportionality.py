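"""ROR, information component, signal criterion and the corpus screen."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from faerspv import ContingencyTable, ror_with_ci, ic_with_ic025, evaluate_signal, run_screen
from faerspv.disproportionality import (
    build_contingency,
    count_unit,
    information_component,
)

def oracle_stats(a, b, c, d):
    """Independent evaluation via exact rationals + integer-argument logs."""
    ror = Fraction(a * d, b * c)
    se = math.sqrt(float(Fraction(1, a) + Fraction(1, b) + Fraction(1, c) + Fraction(1, d)))
    log_ror = math.log(ror.numerator) - math.log(ror.denominator)
    n = a + b + c + d
    icr = Fraction(a * n, (a + b) * (a + c))
    ic = (math.log(icr.numerator) - math.log(icr.denominator)) / math.log(2)
    return {
        "ror": float(ror),
        "low": math.exp(log_ror - 1.96 * se),
        "high": math.exp(log_ror + 1.96 * se),
        "ic": ic,
        "ic025_approx": ic - 1.96 * se / math.log(2),
    }


# frozen from an arbitrary-precision (25-digit) evaluation of the closed forms
FROZEN = {
    (10, 90, 100, 9900): (11.0, 5.559514928894626, 21.76448872744693,
                          3.1987798641144975, 2.2143072578852047, 0.8083483822178214),
    (3, 7, 12, 9000): (321.42857142857144, 74.18217032190996, 1392.737986530672,
                       7.495375380944628, 5.380021588669705, 0.8649249982113769),
    (25, 500, 300, 50000): (8.333333333333334, 5.489601266335543, 12.650180054115385,
                            2.89663735892488, 2.294445033678955, 0.9540830468201318),
}


@pytest.mark.parametrize("cells,expected", FROZEN.items())
def test_frozen_reference_tables(cells, expected):
    t = ContingencyTable(*cells)
    ror, low, high = ror_with_ci(t)[:3]
    ic, ic025, _ = ic_with_ic025(t, "normal_approx")
    printed = ic_with_ic025(t, "as_printed").ic025
    for got, want in zip((ror, low, high, ic, ic025, printed), expected):
        assert got == pytest.approx(want, rel=1e-12)


def test_independence_table():
    t = ContingencyTable(5, 5, 5, 5)
    r = ror_with_ci(t)
    assert r.ror == 1.0
    assert r.low * r.high == pytest.approx(1.0)        # CI symmetric on log scale
    ic, ic025, _ = ic_with_ic025(t)
    assert ic == 0.0 and ic025 < 0


def test_zero_cell_flagged_and_haldane_recovers():
    t = ContingencyTable(3, 0, 7, 990)
    r = ror_with_ci(t, "none")
    assert math.isinf(r.ror) and math.isnan(r.low) and r.zero_cell
    rh = ror_with_ci(t, "haldane")
    assert math.isfinite(rh.ror) and not rh.zero_cell
    assert rh.ror == pytest.approx((3.5 * 990.5) / (0.5 * 7.5))


def test_empty_a_cell():
    t = ContingencyTable(0, 10, 10, 100)
    assert ror_with_ci(t).ror == 0.0
    ic, ic025, defined = ic_with_ic025(t)
    assert math.isinf(ic) and ic < 0 and not defined


def test_printed_ic025_undefined_for_nonpositive_ic():
    t = ContingencyTable(5, 5, 5, 5)  # ic == 0
    res = ic_with_ic025(t, "as_printed")
    assert math.isnan(res.ic025) and not res.defined


def test_invalid_tables_rejected():
    with pytest.raises(ValueError):
        ContingencyTable(-1, 0, 0, 5)
    with pytest.raises(ValueError):
        ContingencyTable(0, 0, 0, 0)
    with pytest.raises(ValueError):
        ror_with_ci(ContingencyTable(1, 1, 1, 1), "bogus")


cells = st.integers(min_value=1, max_value=20)


@given(cells, cells, cells, cells)
def test_transpose_invariance_and_ae_inversion(a, b, c, d):
    base = ror_with_ci(ContingencyTable(a, b, c, d)).ror
    transposed = ror_with_ci(ContingencyTable(a, c, b, d)).ror
    inverted = ror_with_ci(ContingencyTable(b, a, d, c)).ror
    assert transposed == pytest.approx(base, rel=1e-12)
    assert inverted == pytest.approx(1.0 / base, rel=1e-12)


@given(cells, cells, cells, cells)
def test_independence_iff_ad_equals_bc(x, y, w, z):
    # (a,b,c,d) = (x*y, x*z, w*y, w*z) satisfies ad = bc exactly
    t = ContingencyTable(x * y, x * z, w * y, w * z)
    assert ror_with_ci(t).ror == pytest.approx(1.0, rel=1e-12)
    assert information_component(t) == pytest.approx(0.0, abs=1e-12)


@given(cells, cells, cells, st.integers(min_value=1, max_value=19))
def test_ror_strictly_monotone_in_a(b, c, d, a):
    lo = ContingencyTable(a, b, c, d)
    hi = ContingencyTable(a + 1, b, c, d)
    assert ror_with_ci(hi).ror > ror_with_ci(lo).ror


def test_ic_not_monotone_in_a_but_monotone_when_margins_dominated():
    # IC = log2(aN/((a+b)(a+c))) is NOT monotone in a in general, because
    # both margins grow with a:
    assert information_component(ContingencyTable(4, 1, 1, 1)) < \
        information_component(ContingencyTable(3, 1, 1, 1))
    # ... but while the target cell is small against its margins it increases:
    chain = [information_component(ContingencyTable(a, 200, 200, 10_000))
             for a in range(1, 11)]
    assert all(x < y for x, y in zip(chain, chain[1:]))


@given(cells, cells, cells, cells)
def test_matches_independent_oracle(a, b, c, d):
    t = ContingencyTable(a, b, c, d)
    want = oracle_stats(a, b, c, d)
    r = ror_with_ci(t)
    ic, ic025, _ = ic_with_ic025(t)
    assert r.ror == pytest.approx(want["ror"], rel=1e-12)
    assert r.low == pytest.approx(want["low"], rel=1e-12)
    assert r.high == pytest.approx(want["high"], rel=1e-12)
    assert ic == pytest.approx(want["ic"], rel=1e-12, abs=1e-12)
    assert ic025 == pytest.approx(want["ic025_approx"], rel=1e-12, abs=1e-12)


@pytest.mark.parametrize("a,ror_low,ic025,expected", [
    (3, 1.01, 0.01, True),     # all criteria met at the margin
    (2, 5.0, 2.0, False),      # count rule
    (100, 0.99, 1.0, False),   # ROR rule
    (100, 1.0, 1.0, False),    # strict inequality on ror_low
    (100, 2.0, 0.0, False),    # strict inequality on ic025
    (100, 2.0, -0.01, False),
    (3, float("nan"), 1.0, False),
    (3, 2.0, float("nan"), False),
])
def test_signal_criterion(a, ror_low, ic025, expected):
    assert evaluate_signal(a, ror_low, ic025) is expected


# --- counting bases --------------------------------------------------------


def _cases(rows):
    """rows: (caseid, pts tuple, drug_hits set)"""
    return pd.DataFrame({
        "primaryid": [str(i) for i in range(len(rows))],
        "caseid": [r[0] for r in rows],
        "pts": [tuple(r[1]) for r in rows],
        "drug_hits": [frozenset(r[2]) for r in rows],
    })


def test_hand_tallied_margins_under_both_bases():
    cases = _cases([
        ("c1", ("X", "Y"), {"drugA"}),
        ("c2", ("X",), {"drugA"}),
        ("c3", ("Y",), set()),
        ("c4", ("X", "Z"), set()),
        ("c5", (), {"drugA"}),
    ])
    pair = count_unit(cases, ["drugA"], "pair")
    # pairs: c1 contributes 2, c2 1, c3 1, c4 2, c5 0 -> N = 6; target pairs = 3
    assert pair.total_pairs == 6 and pair.drug_pair_total["drugA"] == 3
    t = build_contingency(pair, "drugA", "X")
    assert t.cells() == (2, 1, 1, 2)
    case = count_unit(cases, ["drugA"], "case")
    t2 = build_contingency(case, "drugA", "X")
    # 3 target cases (incl. the empty one), 2 with X; 2 background cases, 1 with X
    assert t2.cells() == (2, 1, 1, 1)


def test_single_case_degenerate_table():
    cases = _cases([("c1", ("X",), {"drugA"})])
    counts = count_unit(cases, ["drugA"], "pair")
    assert build_contingency(counts, "drugA", "X").cells() == (1, 0, 0, 0)


def test_absent_pt_gives_a_zero_not_error():
    cases = _cases([("c1", ("X",), {"drugA"}), ("c2", ("Y",), set())])
    counts = count_unit(cases, ["drugA"], "pair")
    assert build_contingency(counts, "drugA", "Nope").a == 0
    assert build_contingency(counts, "nobody", "X").a == 0


# --- the screen ------------------------------------------------------------


def test_screen_deterministic_under_row_permutation():
    rng = np.random.default_rng(5)
    rows = []
    for i in range(400):
        pts = tuple(sorted(rng.choice(["X", "Y", "Z", "W"], rng.integers(1, 3), replace=False)))
        hits = {"drugA"} if rng.random() < 0.3 else set()
        rows.append((f"c{i}", pts, hits))
    cases = _cases(rows)
    out1 = run_screen(cases, ["drugA"])
    perm = cases.sample(frac=1.0, random_state=1).reset_index(drop=True)
    out2 = run_screen(perm, ["drugA"])
    pd.testing.assert_frame_equal(out1, out2)
    # ordering contract: descending a, then PT
    a = out1["a"].to_numpy()
    assert all(a[i] >= a[i + 1] for i in range(len(a) - 1))


def test_screen_empty_when_target_absent():
    cases = _cases([("c1", ("X",), set())])
    out = run_screen(cases, ["drugA"])
    assert len(out) == 0
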