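"""Synthetic FAERS-style corpora with known ground truth.

The generator emulates the structure of quarterly FAERS extracts —
versioned case submissions with injected duplicates, demographics with
mixed age-unit codes, multiple drug mentions per case with role codes,
multiple reaction PTs per case, serious-outcome flags — on top of a
simple, fully specified probability model:

* each case is exposed to at most one primary target drug (categorical
  over ``drug_prevalence``; the remainder of the mass is background),
  with a small chance of a second target mention in a suspect role;
* every PT in ``background_pt_rates`` is included in a case independently
  with its base probability q; for a planted signal (drug, pt, rho) the
  inclusion probability among cases exposed to that drug is tilted on the
  odds scale to q' = rho*q / (1 - q + rho*q), so the population odds ratio
  of pt given exposure is exactly rho — planted-parameter recovery is a
  well-posed test;
* a case whose draws produce no event receives a single policy-excluded
  filler PT ("Off label use") so every report has a REAC row, as in
  FAERS, without perturbing any inclusion odds;
* with probability ``duplicate_rate`` a case is re-submitted under the
  same CASEID with a fresh, higher PRIMARYID and an FDA_DT 1–90 days
  later — exactly the structure the deduplication rule collapses.

Everything is driven by one :class:`numpy.random.Generator` seed;
generation is reproducible bit for bit and the emitted files are
byte-identical across runs of the same config.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .faers_io import TableSchema, write_table

_DATE0 = np.datetime64("2018-01-01")
_DATE1 = np.datetime64("2023-03-31")

#: brand names per target, used to vary DRUGNAME strings
_BRANDS = {
    "erenumab": "AIMOVIG",
    "galcanezumab": "EMGALITY",
    "fremanezumab": "AJOVY",
    "eptinezumab": "VYEPTI",
}

_BACKGROUND_DRUGS = (
    "IBUPROFEN", "METFORMIN", "LISINOPRIL", "ATORVASTATIN", "SUMATRIPTAN",
    "TOPIRAMATE", "AMITRIPTYLINE", "PARACETAMOL", "SERTRALINE", "OMEPRAZOLE",
)

_FILLER_PT = "Off label use"

_RATE_CYCLE = (0.040, 0.025, 0.015, 0.010, 0.006, 0.004)


def default_pt_rates() -> dict[str, float]:
    """Background reporting rates over the bundled toy PT dictionary.

    Rates cycle through a fixed grid so the corpus has a realistic mix of
    common and rare events (about 1.3 PTs per case in expectation); the
    assignment is deterministic in the dictionary order.
    """
    pts = [p for p in _toy_pts() if p != _FILLER_PT]
    return {pt: _RATE_CYCLE[i % len(_RATE_CYCLE)] for i, pt in enumerate(pts)}


def _toy_pts() -> list[str]:
    """Display-cased PT names of the bundled toy dictionary, in file order."""
    from importlib import resources

    out = []
    text = (resources.files("faerspv") / "data" / "pt_soc_toy.tsv").read_text(encoding="utf-8")
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        out.append(line.split("\t")[0].strip())
    return out


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the generator; defaults give a mid-sized realistic corpus."""

    n_cases: int = 20_000
    seed: int = 0
    drug_prevalence: Mapping[str, float] = field(
        default_factory=lambda: {
            "erenumab": 0.040,
            "galcanezumab": 0.020,
            "fremanezumab": 0.008,
            "eptinezumab": 0.004,
        }
    )
    background_pt_rates: Optional[Mapping[str, float]] = None  # None -> toy defaults
    planted_signals: Sequence[tuple[str, str, float]] = ()
    duplicate_rate: float = 0.10
    co_mention_rate: float = 0.02
    sex_probs: Mapping[str, float] = field(
        default_factory=lambda: {"F": 0.72, "M": 0.12, "UNK": 0.16}
    )
    age_known_prob: float = 0.5
    age_mean: float = 48.7
    age_sd: float = 15.0
    country_probs: Mapping[str, float] = field(
        default_factory=lambda: {"US": 0.95, "CA": 0.02, "GB": 0.02, "JP": 0.01}
    )
    outcome_rates: Mapping[str, float] = field(
        default_factory=lambda: {"HO": 0.030, "DS": 0.010, "LT": 0.005, "DE": 0.006, "OT": 0.020}
    )

    def validate(self) -> None:
        rates = self.background_pt_rates or default_pt_rates()
        for name, probs in (
            ("drug_prevalence", self.drug_prevalence.values()),
            ("background_pt_rates", rates.values()),
            ("sex_probs", self.sex_probs.values()),
            ("country_probs", self.country_probs.values()),
            ("outcome_rates", self.outcome_rates.values()),
            ("scalars", (self.duplicate_rate, self.co_mention_rate, self.age_known_prob)),
        ):
            for p in probs:
                if not (0.0 <= float(p) <= 1.0):
                    raise ValueError(f"{name}: probability {p} outside [0, 1]")
        if sum(self.drug_prevalence.values()) > 1.0:
            raise ValueError("drug prevalences must sum to at most 1")
        if abs(sum(self.sex_probs.values()) - 1.0) > 1e-9:
            raise ValueError("sex probabilities must sum to 1")
        for drug, pt, rho in self.planted_signals:
            if drug not in self.drug_prevalence:
                raise ValueError(f"planted signal references unknown drug {drug!r}")
            if pt not in rates:
                raise ValueError(f"planted signal references PT without a background rate: {pt!r}")
            if not rho > 0:
                raise ValueError(f"planted odds multiplier must be positive, got {rho}")
        if self.n_cases < 0:
            raise ValueError("n_cases must be non-negative")


@dataclass
class GroundTruth:
    """What the generator actually planted."""

    planted_signals: list[tuple[str, str, float]]
    duplicate_map: dict[str, str]           # original primaryid -> duplicate primaryid
    exposure_counts: dict[str, int]         # label -> exposed cases (suspect role)
    config: SyntheticConfig


@dataclass
class Corpus:
    """In-memory corpus in the same shape :func:`faerspv.read_table` returns."""

    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    outc: pd.DataFrame
    truth: GroundTruth


def _categorical(rng: np.random.Generator, probs: Mapping[str, float], n: int) -> np.ndarray:
    keys = list(probs)
    p = np.asarray([probs[k] for k in keys], dtype=float)
    rest = 1.0 - p.sum()
    if rest > 1e-12:
        keys.append(None)
        p = np.append(p, rest)
    p = p / p.sum()
    idx = rng.choice(len(keys), size=n, p=p)
    return np.asarray([keys[i] for i in idx], dtype=object)


def generate(config: SyntheticConfig) -> Corpus:
    """Sample a corpus; see the module docstring for the generating model."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_cases
    rates = dict(config.background_pt_rates or default_pt_rates())
    labels = list(config.drug_prevalence)

    caseid = (10_000_001 + np.arange(n)).astype("int64")
    primaryid = caseid * 10 + 1

    # --- exposure ---------------------------------------------------------
    primary = _categorical(rng, config.drug_prevalence, n)  # label or None
    exposed = {lab: primary == lab for lab in labels}
    # occasional second target mention in a suspect role
    co = rng.random(n) < config.co_mention_rate
    co &= np.array([p is not None for p in primary], dtype=bool)
    co_label = np.full(n, None, dtype=object)
    if len(labels) > 1:
        for i in np.nonzero(co)[0]:
            others = [l for l in labels if l != primary[i]]
            pick = others[rng.integers(len(others))]
            co_label[i] = pick
            exposed[pick][i] = True

    # --- reactions: independent Bernoulli per PT with planted odds tilt ---
    planted = {(d, p): float(r) for d, p, r in config.planted_signals}
    pt_names = list(rates)
    pt_matrix = np.zeros((n, len(pt_names)), dtype=bool)
    for j, pt in enumerate(pt_names):
        q = float(rates[pt])
        prob = np.full(n, q)
        for lab in labels:
            rho = planted.get((lab, pt))
            if rho is not None and rho != 1.0:
                q_t = rho * q / (1.0 - q + rho * q)
                prob = np.where(exposed[lab], q_t, prob)
        pt_matrix[:, j] = rng.random(n) < prob

    # --- demographics -----------------------------------------------------
    sex = _categorical(rng, config.sex_probs, n)
    sex[pd.isna(sex)] = "UNK"
    known = rng.random(n) < config.age_known_prob
    age_years = np.clip(rng.normal(config.age_mean, config.age_sd, n), 5.0, 95.0)
    unit = _categorical(rng, {"YR": 0.92, "MON": 0.04, "DEC": 0.04}, n)
    age_val = np.where(unit == "MON", np.round(age_years * 12),
                       np.where(unit == "DEC", np.floor(age_years / 10), np.round(age_years)))
    country = _categorical(rng, config.country_probs, n)
    country[pd.isna(country)] = "OTHER"
    day_span = int((_DATE1 - _DATE0) / np.timedelta64(1, "D"))
    dates = _DATE0 + rng.integers(0, day_span + 1, n).astype("timedelta64[D]")

    # --- duplicates -------------------------------------------------------
    dup_mask = rng.random(n) < config.duplicate_rate
    dup_offset = rng.integers(1, 91, n).astype("timedelta64[D]")

    # --- assemble DEMO ----------------------------------------------------
    def fmt_dates(arr: np.ndarray) -> np.ndarray:
        return np.datetime_as_string(arr, unit="D")

    demo = pd.DataFrame(
        {
            "primaryid": primaryid.astype(str),
            "caseid": caseid.astype(str),
            "fda_dt": pd.Series(fmt_dates(dates)).str.replace("-", "", regex=False),
            "sex": sex.astype(str),
            "age": np.where(known, age_val.astype("int64").astype(str), ""),
            "age_cod": np.where(known, unit.astype(str), ""),
            "occr_country": country.astype(str),
            "occp_cod": "CN",
        }
    )

    # --- DRUG rows --------------------------------------------------------
    drug_rows: list[tuple[str, str, str, str, str]] = []
    n_bg = rng.integers(0, 3, n)  # background co-medications for every case
    bg_first = rng.integers(0, len(_BACKGROUND_DRUGS), n)
    use_brand = rng.random(n) < 0.5
    for i in range(n):
        pid = str(primaryid[i])
        seq = 1
        if primary[i] is not None:
            lab = primary[i]
            name = (f"{_BRANDS[lab]} ({lab.upper()})" if use_brand[i] else lab.upper())
            drug_rows.append((pid, str(seq), "PS", name, lab.upper()))
            seq += 1
            if co_label[i] is not None:
                lab2 = co_label[i]
                drug_rows.append((pid, str(seq), "SS", _BRANDS[lab2], lab2.upper()))
                seq += 1
            k_bg = int(n_bg[i])
            bg_roles = ["C"] * k_bg
        else:
            k_bg = int(n_bg[i]) + 1
            bg_roles = ["PS"] + ["C"] * (k_bg - 1)  # first background drug is the suspect
        for k in range(k_bg):
            name = _BACKGROUND_DRUGS[(bg_first[i] + k) % len(_BACKGROUND_DRUGS)]
            drug_rows.append((pid, str(seq), bg_roles[k], name, name))
            seq += 1
    drug = pd.DataFrame(drug_rows, columns=["primaryid", "drug_seq", "role_cod", "drugname", "prod_ai"])

    # --- REAC rows --------------------------------------------------------
    case_idx, pt_idx = np.nonzero(pt_matrix)
    reac_pids = primaryid[case_idx].astype(str)
    reac_pts = np.asarray(pt_names, dtype=object)[pt_idx]
    empty = np.nonzero(~pt_matrix.any(axis=1))[0]
    if len(empty):
        reac_pids = np.concatenate([reac_pids, primaryid[empty].astype(str)])
        reac_pts = np.concatenate([reac_pts, np.full(len(empty), _FILLER_PT, dtype=object)])
    reac = pd.DataFrame({"primaryid": reac_pids, "pt": reac_pts})
    reac = reac.sort_values("primaryid", kind="mergesort").reset_index(drop=True)

    # --- OUTC rows --------------------------------------------------------
    outc_frames = []
    for code, rate in config.outcome_rates.items():
        hit = rng.random(n) < float(rate)
        if hit.any():
            outc_frames.append(pd.DataFrame({"primaryid": primaryid[hit].astype(str), "outc_cod": code}))
    outc = (
        pd.concat(outc_frames, ignore_index=True)
        .sort_values(["primaryid", "outc_cod"], kind="mergesort")
        .reset_index(drop=True)
        if outc_frames
        else pd.DataFrame({"primaryid": pd.Series(dtype=str), "outc_cod": pd.Series(dtype=str)})
    )

    # --- inject duplicate submissions ------------------------------------
    duplicate_map: dict[str, str] = {}
    if dup_mask.any():
        di = np.nonzero(dup_mask)[0]
        dup_pid = (caseid[di] * 10 + 2).astype("int64")
        pid_map = {str(primaryid[i]): str(p) for i, p in zip(di, dup_pid)}
        duplicate_map = dict(pid_map)
        dup_demo = demo.iloc[di].copy()
        dup_demo["primaryid"] = dup_pid.astype(str)
        dup_dates = dates[di] + dup_offset[di]
        dup_demo["fda_dt"] = pd.Series(fmt_dates(dup_dates)).str.replace("-", "", regex=False).to_numpy()
        demo = pd.concat([demo, dup_demo], ignore_index=True)
        for name, frame in (("drug", drug), ("reac", reac), ("outc", outc)):
            sub = frame[frame["primaryid"].isin(pid_map)].copy()
            sub["primaryid"] = sub["primaryid"].map(pid_map)
            if name == "drug":
                drug = pd.concat([drug, sub], ignore_index=True)
            elif name == "reac":
                reac = pd.concat([reac, sub], ignore_index=True)
            else:
                outc = pd.concat([outc, sub], ignore_index=True)

    # match read_table's output conventions
    for frame in (demo, drug, reac, outc):
        for col in frame.columns:
            frame[col] = frame[col].astype("string")
        frame.replace("", pd.NA, inplace=True)
    demo["fda_dt_valid"] = True

    truth = GroundTruth(
        planted_signals=list(config.planted_signals),
        duplicate_map=duplicate_map,
        exposure_counts={lab: int(np.asarray(exposed[lab]).sum()) for lab in labels},
        config=config,
    )
    return Corpus(demo=demo, drug=drug, reac=reac, outc=outc, truth=truth)


def emit(corpus: Corpus, out_dir: Union[str, Path]) -> dict[str, Path]:
    """Write the corpus as FAERS-dialect DEMO/DRUG/REAC/OUTC files.

    Returns the mapping table-name -> path.  Reading the files back with
    :func:`faerspv.read_table` and running the pipeline gives the same
    screen as running it on the in-memory corpus.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, frame, schema in (
        ("DEMO", corpus.demo, TableSchema.DEMO),
        ("DRUG", corpus.drug, TableSchema.DRUG),
        ("REAC", corpus.reac, TableSchema.REAC),
        ("OUTC", corpus.outc, TableSchema.OUTC),
    ):
        paths[name] = write_table(frame, out_dir / f"{name}.txt", schema)
    return paths
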