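# Methods

This note documents the statistical model behind `pvsignal`, the
conventions fixed where common practice varies, and what the synthetic
benchmark does and does not establish about real spontaneous-report data.

## Report universe and cleaning

All counting happens on a `CaseSet`: one row per retained report, linked
drug rows (name, role code, start date) and event rows (MedDRA preferred
term, onset date), plus a user-supplied PT→SOC vocabulary. The cleaning
rules mirror standard FAERS practice:

* **Deduplication.** Within each CASEID keep the submission with the most
  recent FDA receipt date; at a tied date keep the largest PRIMARYID
  (FAERS assigns larger PRIMARYIDs to later submissions). Receipt dates
  are partial-date strings (`YYYYMMDD`, `YYYYMM`, `YYYY`, empty) whose
  lexicographic order equals the (year, month, day) order with missing
  components treated as smallest — this makes the selection a total
  order, hence deterministic, idempotent and independent of row order.
  Non-numeric report ids fall back to lexicographic comparison (logged).
* **Deleted-case lists.** Applied after per-case deduplication, for
  quarters from 2019Q1 onward (the quarter in which such lists begin).
  JADER has no deleted-list mechanism; there, cleaning is exact-row
  deduplication of the DRUG and REAC tables.
* **Partial dates are first-class.** FAERS date fields arrive as 8-, 6-
  or 4-digit strings; each parses to day, month or year precision,
  anything else to missing. Downstream rules (onset intervals) depend on
  precision, so it is never silently coerced.
* **Cohort and exposure.** The sex filter (female, for this package's
  running use case) drops reports with missing or unknown sex and is
  applied *before* any counting, so the disproportionality background is
  the same-sex report universe. Exposure means: the report carries the
  target drug — matched case-insensitively, whitespace-collapsed, by
  exact name against a generic + brand synonym list (no substring
  matching, which would capture combination products) — in the
  primary-suspect (PS) role. Background reports stay in the CaseSet.
* **Age units** (YR/DEC/MON/WK/DY/HR) are converted to years; unknown
  codes yield missing. Multiple DEMO rows per PRIMARYID: first kept,
  logged.

## Counting unit

Cells count **distinct (report, term) pairs**. A report listing a PT
twice contributes once; at SOC level a report with two PTs in the same
SOC contributes once to that SOC. Consequences used as invariants: the
drug margin a+b is the drug's total distinct pair count, identical across
terms at a level; a+b+c+d is the same for every term; and a equals the
number of exposed reports mentioning the term. Pair-level counting is the
dominant convention in FAERS disproportionality work and is what makes a
drug's report count and its (larger) PT count coexist coherently.
Degenerate tables (d = 0) are retained; the statistics handle them
through the zero-cell policy.

## The four statistics

With N = a+b+c+d:

* **ROR** = ad/bc, SE(ln ROR) = √(1/a+1/b+1/c+1/d), 95% CI
  exp(ln ROR ± 1.96 SE). Positive: a ≥ 3 and CI lower limit > 1 (strict).
* **PRR** = [a/(a+b)]/[c/(c+d)], χ² = (ad−bc)²N/[(a+b)(c+d)(a+c)(b+d)]
  (no Yates correction). Positive: a ≥ 3 and χ² ≥ 4 (inclusive). A
  PRR ≥ 2 gate exists as an optional threshold, off by default.
* **BCPNN.** Point IC = log₂[aN/((a+b)(a+c))]. The Bayesian expectation
  and variance under Dirichlet priors:

  E(IC) = log₂[(a+γ₁₁)(N+α)(N+β) / ((N+γ)(a+b+α₁)(a+c+β₁))],
  γ = γ₁₁(N+α)(N+β)/((a+b+α₁)(a+c+β₁)),

  V(IC) = (ln 2)⁻² [ (N−a+γ−γ₁₁)/((a+γ₁₁)(1+N+γ))
  + (N−(a+b)+α−α₁)/((a+b+α₁)(1+N+α))
  + (N−(a+c)+β−β₁)/((a+c+β₁)(1+N+β)) ],

  IC025 = E(IC) − 2√V(IC). Positive: IC025 > 0 (strict). Prior constants
  default to the original BCPNN choice α₁ = β₁ = γ₁₁ = 1, α = β = 2,
  exposed in `BCPNNPriors`. IC025 here is an expectation-minus-2SD bound,
  not a posterior 2.5th percentile; published variants differ and the two
  are close only for well-filled tables.
* **EBGM** = aN/((a+b)(a+c)) — the relative reporting ratio — with
  SE(ln EBGM) = SE(ln ROR) and EBGM05 = exp(ln EBGM − 1.96 SE). Positive:
  EBGM05 > 2 (strict). Note the identity 2^IC = EBGM: the IC point
  estimate and EBGM are the same observed/expected ratio on two scales.
  This is the *unshrunken* form; a full gamma–Poisson mixture (MGPS)
  empirical-Bayes fit, which shrinks small-count cells, is out of scope —
  for rare events this EBGM05 is more liberal than true MGPS output.

A **consensus signal** is a term positive under all four algorithms
simultaneously; undefined statistics fail their flag.

**Zero cells.** Default policy `haldane`: a table containing any zero
gets 0.5 added to all four cells for the ROR/EBGM point estimates and
their shared SE. PRR/χ² and the Bayesian quantities use raw cells (the
priors already regularize them). Policy `none` reports NaN instead and
the flags stay False.

## Time to onset

TTO = onset date − drug start date in calendar days (a same-day event is
0, not 1). Only day-precise dates qualify; exclusions — missing start,
imprecise start, missing onset, imprecise onset, inconsistent (onset
before start) — are tallied, not raised. When a report carries several
target-drug rows the earliest day-precise start is used. The unit is one
record per (report, PT); overall summaries collapse to the earliest onset
per report to avoid double-counting multi-event reports.

* **Bins** [0,30], [31,60], … days; displayed percentages use
  largest-remainder allocation of tenths so they sum to exactly 100.0
  (independent per-bin rounding drifts by up to 0.05 per bin).
* **Quartiles** by linear interpolation between order statistics (the
  mainstream numerical default).
* **Weibull fit**: two-parameter MLE in (log shape, log scale) —
  Nelder–Mead polished by BFGS — with the shape CI from the observed
  information (finite-difference Hessian at the MLE), i.e. a normal
  approximation on log(shape). Zero days are replaced by 0.5 before
  fitting (Weibull support is positive); the adjusted count is reported.
  Classification: CI upper < 1 → *early* failure (decreasing risk), CI
  containing 1 → *random* (constant risk), CI lower > 1 → *wear-out*
  (increasing risk); a singular information matrix → *indeterminate*.
  Degenerate samples (all values equal) and n < 3 raise.
* **Kaplan–Meier / log-rank** go through lifelines
  (`KaplanMeierFitter`, `multivariate_logrank_test`). All events are
  treated as observed — spontaneous reports carry no censoring time — so
  cumulative incidence 1 − S(t) equals the empirical CDF; the k-sample
  log-rank statistic is referred to χ² with k−1 degrees of freedom. The
  in-package Weibull MLE is cross-checked against `lifelines.WeibullFitter`
  in the test suite.

## Sensitivity analysis and triage

The comparator drug is run through the *identical* pipeline (same PS-role
restriction, same cohort) and its table carries a minimum-count marker
(default a ≥ 3). The monotherapy subset keeps reports whose drug rows
name the target drug and nothing else. Each target consensus signal is
then triaged with fixed precedence: on the product label → *expected*;
else consensus-positive for the comparator → *disease-expected*; else
*unexpected*. Label precedence is a choice (the three classes could be
ordered otherwise); it matches how such tables are usually marked, and
label/PT matching is exact after normalization — no synonym expansion.

## Synthetic benchmark

The generator emulates the structural hazards of spontaneous-report
archives with fully known statistical content. Per case: one PS drug
(target with probability 1%, comparator 1%, else one of 40 background
drugs — a niche drug inside a large database); K = 1 + Poisson(1.2) event
draws (mean ≈ 2.2, matching the pair-to-report ratio typical of such
cohorts) from a 60-term categorical; 1–2 concomitant drugs on the 60% of
reports that are not monotherapy; demographic mixes (80% female, US-heavy
countries, two-thirds health-professional reporters); onset =
start + round(Weibull(shape 0.8, scale 20)) days, corrupted to month
precision at rate 0.1 per date and inverted (onset before start) at rate
0.02; 20% of cases resubmitted (same content, earlier FDA_DT or same
FDA_DT with a smaller PRIMARYID — duplicates differ only in the fields
the dedup rule keys on); 2% of cases on the deleted list.

A planted association (drug g, event e, RR) multiplies e's weight by RR
in the event distribution of g's reports, renormalized. The expected
distinct-pair cells are closed-form: a report with draw probability p
includes the PT with probability φ(p) = 1 − (1−p)e^(−1.2p), so
E[a] = n·q_g·φ(p_e(g)) and the margins follow by summation; these feed
the 4-standard-deviation round-trip tests. The planted event's baseline
probability is 0.002 so that RR = 50 remains representable
(50 × 0.002 ≪ 1).

Two honest consequences of this design, visible in the tests: the
renormalization slightly *depresses* non-planted events under the target
drug (their observed/expected sits near 0.91, not 1.0, with the default
plant); and the realized EBGM of a strongly planted pair is well below
the nominal RR (≈ 28 for RR = 50 at the default geometry) because the
planted pair dominates its own column margin (the classic masking effect)
and the tilt is renormalized. Recovery tests therefore compare against
the closed-form expectations, not naively against RR.

What the generator does **not** emulate: drug-name noise (misspellings,
combination products), correlated event clusters (real syndromes
co-report), reporting-rate drift over calendar time, country-specific
coding habits, or free-text fields. Passing the benchmark shows the
*pipeline arithmetic* is right under a known model; it does not validate
signal detection against clinical truth.

## Problem sizes and numerical tolerances

The test suite and acceptance script use: n = 20,000 reports for
planted-signal recovery and false-positive control; n = 1,500–2,500
across 20 seeds for round-trip count fidelity (4 binomial SDs); 100
replicates at n = 250 for Weibull CI coverage (pass mark ≥ 90%, nominal
95%); 50 replicates at n = 500 per shape for failure-type classification
rates; log-rank groups of 15–19. The identity 2^IC = EBGM is asserted to
1e-9 relative; frozen formula examples to 1e-6 or printed precision.
These sizes were chosen so every check is a routine desk-scale run.

## Known limitations

* EBGM is the unshrunken relative reporting ratio (see above); with
  a ≥ 3 gating this mainly affects borderline rare terms.
* The Wald ROR interval and the normal log-shape Weibull CI are
  asymptotic; at very small a or n they are approximate (profile
  likelihood would be tighter but is not needed for the classification
  rule's stated form).
* The IC025 bound is prior-sensitive for a ≤ 3.
* No HLT/HLGT intermediate MedDRA levels; no censoring or competing-risk
  models; the pipeline emits plot-ready tables, not styled figures.
* Real-archive headline counts can only be reproduced against the real
  FAERS/JADER downloads, which this repository deliberately does not
  bundle.
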