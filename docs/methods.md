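# Methods

This note records the statistical model, data-handling conventions,
numerical choices and deliberate limitations of the package, in enough
detail to re-derive every number it produces.

## 1. Data model and ingestion

Input is a directory of FAERS-format quarterly ASCII tables — DEMO, DRUG,
REAC, OUTC, THER, INDI — "$"-delimited, Latin-1, no quoting. The reader is
hand-rolled rather than `pandas.read_csv` because the format's failure
modes need explicit policy: short rows are right-padded with empty fields,
overlong rows keep the first N fields (counted as malformed in the read
audit), and header aliases from older vintages (ISR → PRIMARYID, CASE →
CASEID, GNDR_COD → SEX) are normalised. Missing mandatory columns raise
`SchemaError`; extra columns are preserved in the audit but ignored.

Tables are pooled across quarters and joined on PRIMARYID into `ReportCase`
objects. A duplicate PRIMARYID within the pooled DEMO table is a hard
error; DRUG/REAC/OUTC/THER/INDI rows with no DEMO parent are counted as
orphans and dropped. Each case's reaction list is reduced to its set of
unique PTs (case-insensitive, whitespace-collapsed) at construction.

## 2. Deduplication

FAERS stores one row per report *version*; a case (CASEID) may have many.
Following FDA guidance, the package keeps, per CASEID, the row with the
latest FDA receipt date (FDA_DT), ties broken by the highest PRIMARYID.
PRIMARYID comparison is numeric when every candidate parses as an integer,
otherwise zero-padded lexicographic, so mixed legacy identifiers still
order deterministically. Dates compare on the raw YYYYMMDD string padded
with zeros, which orders partial dates (year- or month-precision) before
any fuller date in the same period; absent dates sort first. Deduplication
is idempotent and its audit partitions the input exactly (kept + dropped =
input), both properties enforced by tests.

## 3. Cohort definition

The target cohort is defined by a `CohortSpec`: drug-name synonyms matched
case-insensitively as substrings against DRUGNAME and PROD_AI (default
synonyms cover the 120 mg denosumab brand), restricted to reports where a
matching drug has suspect role PS, and optionally to oncology indications
attached to that drug's sequence number. Reports whose matched drug has no
indication rows are kept by default (`strict_indications=False`): in
spontaneous data, absence of an INDI row is missingness, not evidence of a
non-qualifying indication. Everything not in the cohort is the comparator
background — the "all other drugs" margin of the 2×2 table.

## 4. Disproportionality statistics

The counting unit is the (deduplicated report, unique PT) pair; a report
contributes one unit per distinct PT, and n is the total number of units,
not of reports. For each PT: a = cohort units with the PT, b = cohort units
without it, c/d likewise in the background.

**ROR.** ROR = ad/bc with Woolf 95% CI
exp(ln ROR ± 1.96·√(1/a + 1/b + 1/c + 1/d)). A zero cell leaves the ROR
undefined (reported as such, never infinite); an optional Haldane–Anscombe
0.5 continuity correction is available but off by default, since the
positivity rule already requires a ≥ 3. Positivity: a ≥ 3, ROR defined,
CI lower bound ≥ 1.

**BCPNN IC.** Closed-form posterior moments under the standard reference
priors (α₁ = β₁ = 1, α = β = 2, γ₁₁ = 1), with
γ = (n+2)²/((a+b+1)(a+c+1)):

- E(IC) = log₂[(a+1)(n+2)² / ((n+γ)(a+b+1)(a+c+1))]
- V(IC) = [(n−a+γ−1)/((a+1)(1+n+γ)) + (n−a−b+1)/((a+b+1)(n+3))
  + (n−a−c+1)/((a+c+1)(n+3))] / ln²2
- IC025 = E(IC) − 2√V(IC).

Positivity is IC025 > 0, strict. A `mode="raw"` variant reports the
maximum-likelihood point log₂(a·n/((a+b)(a+c))) with the same-width band
recentred on it; the Bayesian mode is the default and the one used for
grading.

**Grading.** Signal strength is graded on the *lower* bound of each
statistic. The bands have different boundary conventions, preserved
deliberately: ROR bands are left-closed — weak [1, 50), moderate
[50, 1000), high [1000, ∞) — while IC bands are right-closed — weak
(0, 1.5], moderate (1.5, 3], high (3, ∞). So ROR CI-low exactly 50 grades
moderate, but IC025 exactly 1.5 grades weak. The weak ROR band is
implemented as [1, 50) rather than an open-ended "≥ 1 to < 50 with gaps" so
that the three grades partition the positive range.

**Screen.** The novelty screen keeps signals positive by both methods with
IC025 > 1.5 (strictly above the weak band), removes SOCs that cannot
constitute drug harms in this design (social circumstances, product issues,
surgical/medical procedures) and administrative PTs (off-label use,
unapproved-indication use), then splits survivors by membership in a
product-label PT list into labeled vs new suspected reactions.

## 5. Descriptives

Demographics (sex, age bands <18 / 18–64 / ≥65, top-5 reporter countries
plus "Other"/"Not specified") are tabulated as counts and percentages of
total cohort reports, rounded to 2 decimals via one shared helper so every
surface uses identical arithmetic.

Seriousness: a report is serious iff it has at least one OUTC row. In the
default "worst" mode each serious report contributes once, to its worst
outcome under the ranking death > life-threatening > hospitalisation >
disability > congenital anomaly > required intervention > other;
"occurrence" mode counts every outcome code per report. Unknown codes map
to "other" with a warning.

Time-to-onset is earliest matched-drug therapy start to event date,
requiring day precision on both; negative intervals are treated as
missing/invalid. Bins: ≤90, 91–180, 181–360, >360 days, reported both as
percent of the cohort and percent of computable cases, overall and for
serious reports.

## 6. Synthetic database generator

No real FAERS extract ships with the package; the generator
(`faerspv.synthetic`) emulates the features of FAERS that the pipeline
must survive, with known ground truth:

- i.i.d. reports; each report is target-drug with probability
  `drug_share` (default 0.005, giving ~1,000 cohort reports at the default
  `n_reports=200000` — large enough for stable intervals, small enough to
  run in seconds).
- Each PT in a 27-term vocabulary is included per report as an independent
  Bernoulli draw; injected signals scale the target-arm probability by a
  rate ratio `rr`. Because a single injection changes both margins
  identically (S_target − rr·p = S_background − p for the complement
  sums), the expected-cell ROR equals `rr` exactly — the recovery target
  is analytic, not simulated.
- 15% of cases receive a follow-up version with a later FDA_DT (exercising
  dedup); 70% of therapy/event date pairs are uncomputable, split among
  blank event dates, month-precision event dates, and blank start dates
  (exercising the precision rules); sex/age/country and outcome profiles
  are fixed categorical draws.

All randomness flows through one `numpy.random.default_rng(seed)`; output
is byte-identical per seed. Generator defaults are the study conditions:
they were fixed before outcomes were inspected and are not tuned to make
tests pass. The bundled PT→SOC map and product-label PT list are synthetic
stand-ins (marked "synthetic" in filename and header) for licensed MedDRA
and label content.

## 7. Verification

- ROR and BCPNN implementations are checked against independent oracle
  re-implementations on 500 randomised tables at 1e-9 relative tolerance,
  plus hand-computed fixtures (e.g. a=10, b=90, c=100, d=9900 →
  ROR = 11, CI 5.5595–21.7582, E(IC) = 2.3825).
- End-to-end: the injected signal is recovered within ±20% of rr = 10
  across seeds, its CI covers the truth, and the 26 null PTs produce 0%
  false positives (bounded at ≤5% in tests).
- Property tests (hypothesis, derandomised) cover dedup idempotence and
  ordering invariance; round-trip tests cover the reader/writer and TTO
  date handling.

## 8. Limitations

- Disproportionality is hypothesis-generating only; no causal or incidence
  claims are supported, and the package does not adjust for masking,
  stratification or duplicate reporters beyond CASEID dedup.
- The generator's independence assumptions (i.i.d. reports, independent
  PTs) are simplifications; real FAERS has correlated reporting,
  time-varying volume and free-text noise the parser does not see.
- PT→SOC mapping is primary-SOC only and the bundled fixture covers only
  the generator vocabulary and the PTs used in tests; real analyses should
  supply a licensed MedDRA map via `--meddra-map`.
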