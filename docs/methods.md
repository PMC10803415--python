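# Methods

## The screening procedure

`faerspv` implements the standard spontaneous-report disproportionality
workflow over FAERS-dialect quarterly extracts.

**Deduplication.** FAERS cases arrive in versions: the same CASEID may be
submitted repeatedly (patient, clinician, manufacturer), each submission
carrying a fresh PRIMARYID. Following the FDA's recommended cleaning
rule, one report survives per case: the version with the latest FDA
receipt date (FDA_DT), ties broken by the numerically highest PRIMARYID.
Rows with a missing CASEID are dropped and logged. Unparseable dates are
not dropped at parse time — they are flagged and treated as earliest
during deduplication, so attrition stays auditable in the structured
attrition log the pipeline emits.

**Drug attribution.** Target drugs are matched by case-insensitive
substring search of generic and brand-name keywords against DRUGNAME and
PROD_AI. By default only suspect-role mentions (PS, SS) attribute a case
to a drug, the usual convention in disproportionality work; concomitant
and interacting mentions can be included with a flag. A case may match
several targets and then counts for each (and in no drug's background
when that drug is screened).

**Exclusion policy.** Before any statistics, preferred terms belonging to
five families are removed: product problems, medication errors,
off-label/unlicensed use, indication terms, and disease states. The
families are conventional; the concrete term lists are an editable YAML
config with exact and substring entries, because no licensed MedDRA query
set can ship with the package. Removals are logged per reason.

**The 2×2 table.** For drug D and preferred term E: a = reports with D
and E, b = D without E, c = E without D, d = neither. "All other drugs"
means every report in the loaded corpus not attributed to D. Two
counting bases are implemented because the literature rarely states which
one a study used: the default *pair* basis counts case–PT pairs (a case
with three retained PTs contributes three units to the margins), the
*case* basis counts distinct cases. The cell a is identical under both
(PTs are de-duplicated within a case); the margins b and d differ. The
basis in use is stamped into every result row.

**Statistics.** ROR = ad/bc with the Woolf interval
exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d)). IC = log₂(aN/((a+b)(a+c))),
computed in ratio form so independent tables give exactly 0. IC025 is
reported in two variants, never silently merged:

* `normal_approx` (default): IC − 1.96·√(1/a+1/b+1/c+1/d)/ln 2, the
  delta-method lower bound on the log₂ scale, defined whenever all four
  cells are positive;
* `as_printed`: exp(ln IC − 1.96·√(1/a+1/b+1/c+1/d))·0.5, an expression
  that circulates in the applied literature. It is mathematically
  ill-formed for IC ≤ 0 (logarithm of a non-positive quantity) and its
  trailing ×0.5 has no derivation we can reconstruct; where undefined the
  value is NaN and a flag is set.

A pair is a signal when a ≥ 3, ROR CI lower bound > 1 (strict) and
IC025 > 0 (strict), all three jointly. No continuity correction is
applied by default; Haldane–Anscombe (+0.5 per cell) is available by
flag. No multiple-testing adjustment is applied anywhere — the joint
criterion *is* the screen, which is the convention this style of
pharmacovigilance study follows; consumers should read flagged pairs as
hypotheses, not confirmed associations.

**Reporting layer.** The summary tables (demographics with mean(SD) age
over known ages, SOC rollup, top-N PTs, cross-drug co-reported PTs,
injection/infusion grouping) all compute percentages against explicitly
stated denominators — the drug's case total for demographics, the drug's
total signal-report sum for the signal tables — rounded half-up to two
decimals, and every emitted percentage is re-derived from its own counts
on each run (an assertion, not a convention). Age buckets are the
half-open intervals [0,18), [18,45), [45,65), [65,∞): published bucket
labels overlap at the boundaries, so a partition had to be chosen; the
boundary age belongs to the upper bucket and the edges are configurable.
Injection/infusion-related PTs are matched by substring ("injection
site", "infusion site", "infusion related") plus a config-extendable
exact-term list that ships empty — fear-of-injection terms are
deliberately *not* excluded from the co-reported table, matching how
published comparisons treat them.

## The synthetic corpus generator

The generator emulates the *structure* of FAERS quarterly data — one DEMO
row per report version, drug mentions with role codes, multiple reaction
PTs per case, serious-outcome flags, duplicate submissions — on a fully
specified sampling model:

* exposure: each case draws at most one primary target drug from
  `drug_prevalence` (defaults 4.0/2.0/0.8/0.4% for the four mAbs, the
  remainder background), with a 2% chance of a second target mention in a
  suspect role;
* reactions: every PT in `background_pt_rates` enters a case
  independently with its base probability (defaults cycle through
  0.4–4% across the bundled 79-PT toy dictionary, ≈1.3 PTs per case).
  For a planted signal (drug, pt, ρ) the inclusion probability among
  exposed cases is tilted on the odds scale, q′ = ρq/(1−q+ρq), making
  the population odds ratio exactly ρ. Cases with no sampled event
  receive one policy-excluded filler PT ("Off label use") so every
  report has a REAC row without touching any inclusion odds;
* demographics: sex F/M/unknown at 72/12/16%, age known with
  probability 0.5 and then normal(48.7, 15) years expressed through
  mixed unit codes (YR/MON/DEC), country US at 95%, receipt dates
  uniform over 2018-01-01..2023-03-31, outcome flags at low independent
  rates — all chosen to mirror the reporting mix of the migraine-drug
  safety literature;
* duplicates: with probability `duplicate_rate` (default 0.10) a case is
  re-submitted under the same CASEID with a higher PRIMARYID and an
  FDA_DT 1–90 days later, content cloned — exactly what the dedup rule
  must collapse, with the original→duplicate mapping recorded as ground
  truth.

Everything derives from one seed; same config and seed give
byte-identical emitted files.

**What the generator does not emulate** — and hence what passing tests do
not show about real FAERS: real marginal PT frequencies and their heavy
tail, reporter-type mix, temporal reporting waves (Weber effect),
correlated PT co-occurrence within a case, free-text drug-name noise
beyond brand/generic variants, and non-duplicate near-matches that
probabilistic record linkage would catch. Results on synthetic corpora
validate the *mechanics* (counting, formulas, criteria, determinism),
not the epidemiology.

## Numerical and design choices

* IC uses the ratio form log₂(aN/((a+b)(a+c))) rather than a difference
  of logarithms: it is exact (0.0) on independent tables and accurate to
  ~1e-13 relative error near IC = 0, where the difference form cancels
  catastrophically.
* Zero cells: with no correction, b·c = 0 gives ROR = +∞ with an
  undefined CI and a `zero-cell` flag; a = 0 gives ROR = 0 and
  IC = −∞. Degeneracy is always flagged, never thrown.
* ROR is strictly increasing in a at fixed b, c, d; IC is *not* (both
  margins grow with a — counterexample (3,1,1,1)→(4,1,1,1)). IC is
  increasing in the rare-event regime where d dominates, which is the
  regime screening operates in.
* Parameter recovery is exact in expectation under the *case* basis,
  where the generator's odds tilt equals the table's odds ratio; under
  the default pair basis the pair margins dilute the estimate slightly.
  The recovery checks therefore run under the case basis.
* Ordering contracts: the screen sorts by (drug, descending a, PT); ties
  in every reporting table break lexicographically. Together with
  hash-free counting this makes every output invariant to input row
  permutation, byte for byte.
* Monte-Carlo problem sizes (corpora of 2·10³–5·10⁴ cases, 100–200
  seeded replicates) keep the full test suite and the acceptance script
  to a few minutes on one CPU while leaving the binomial noise on each
  checked proportion well inside the asserted margins.
* Age unit conversion: DEC×10, YR×1, MON÷12, WK÷52.1775, DY÷365.25,
  HR÷8766; results outside [0, 120] years are treated as missing and
  logged as implausible. A blank unit code is read as years, the FAERS
  convention.

## Known limitations

* Keyword drug matching is substring-based; it cannot resolve misspelled
  or compounded drug names, and a keyword contained in an unrelated name
  would over-match (the bundled keywords are safe for the four targets).
* The toy PT→SOC dictionary maps each PT to one plausible SOC for
  testing and demos; it is not MedDRA and SOC assignments should not be
  quoted.
* The dedup rule collapses only exact CASEID matches, as the source data
  model defines; cross-manufacturer duplicates with distinct CASEIDs
  survive.
* Disproportionality measures association against an all-other-drugs
  background; they are not incidence rates and support no causal
  reading.
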