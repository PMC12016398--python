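# pvsignal

Disproportionality signal detection and time-to-onset analysis for
spontaneous adverse-event reporting systems.

## What this is for

Spontaneous reporting systems — FAERS (FDA Adverse Event Reporting
System) quarterly ASCII archives and JADER (the Japanese adverse drug
event report database) CSV tables — collect voluntary reports of
suspected adverse drug events (ADEs). They have no denominator: nobody
knows how many patients took the drug. Pharmacovigilance therefore works
by *disproportionality*: for a drug–event pair, compare how often the
event is reported under the drug against how often it is reported under
everything else in the same database, via a 2×2 table

|                | target event | other events |
|----------------|:---:|:---:|
| target drug    | a | b |
| other drugs    | c | d |

`pvsignal` implements the full analysis pipeline used in post-marketing
safety studies of this kind, with a reproductive-endocrinology use case
(a GnRH antagonist used in controlled ovarian stimulation, with a
same-indication comparator) as its running example:

1. **ingest** — parse FAERS `$`-delimited quarters and JADER CSV tables
   into one linked report/drug/event model; deduplicate cases (latest
   FDA_DT per CASEID, ties to the largest PRIMARYID), apply the
   deleted-case lists, filter the cohort by sex, match the target drug by
   normalized generic/brand synonyms restricted to the primary-suspect
   (PS) role.
2. **contingency** — count distinct (report, term) pairs into per-PT and
   per-SOC 2×2 tables (MedDRA preferred term / system organ class; the
   PT→SOC mapping is user-supplied, since MedDRA is licensed).
3. **signals** — four algorithms per table, a *consensus signal* requires
   all four:
   * ROR = ad/bc, positive when a ≥ 3 and exp(ln ROR − 1.96·SE) > 1 with
     SE = √(1/a + 1/b + 1/c + 1/d);
   * PRR = [a/(a+b)]/[c/(c+d)] with χ² = (ad−bc)²N/[(a+b)(c+d)(a+c)(b+d)],
     positive when a ≥ 3 and χ² ≥ 4;
   * BCPNN information component IC = log₂[aN/((a+b)(a+c))] with Bayesian
     E(IC), V(IC) under Dirichlet priors, positive when
     IC025 = E(IC) − 2√V(IC) > 0;
   * EBGM = aN/((a+b)(a+c)) with EBGM05 = exp(ln EBGM − 1.96·SE),
     positive when EBGM05 > 2.
4. **tto** — time to onset (onset date − drug start date, day-precise
   dates only), 30-day bins, median/IQR, a two-parameter Weibull fit whose
   shape CI classifies the hazard as early / random / wear-out failure,
   Kaplan–Meier cumulative incidence and k-sample log-rank tests.
5. **sensitivity** — the identical pipeline for a comparator drug, a
   monotherapy subset, and triage of each consensus signal as *expected*
   (on the product label), *disease-expected* (also positive for the
   comparator) or *unexpected*.
6. **synthetic_data** — a generator that writes FAERS/JADER-dialect
   archives with planted drug–event associations of known relative risk,
   duplicate submission lineage, partial/inconsistent dates and Weibull
   onset intervals, plus a ground-truth manifest, so the whole pipeline is
   testable without downloading the real databases.
7. **report** — baseline-characteristics and annual-trend tables.

## Worked example

Generate a small synthetic archive, ingest it, and screen for signals:

```python
from pvsignal import (GeneratorConfig, generate, parse_faers_quarter,
                      build_caseset, filter_cohort, detect, compute_tto,
                      tto_table)
from pvsignal.model import load_vocabulary

cfg = GeneratorConfig(n_reports=5000, seed=1)
truth = generate(cfg, "archive", dialect="FAERS")

raws = [parse_faers_quarter("archive", q) for q in cfg.quarters]
cases = build_caseset(raws, load_vocabulary("archive/vocabulary.tsv"))
cohort = filter_cohort(cases, "F")
print(f"retained {cases.n_reports} of {cfg.n_reports} submitted cases; "
      f"{cohort.n_reports} female")

table = detect(cohort, list(cfg.target_synonyms), level="PT")
hits = table[table["consensus"]]
cols = ["term", "a", "b", "c", "d", "ror", "ror_low", "chi2", "ic025", "ebgm05"]
print(hits[cols].round(2).to_string(index=False))

records, excluded = compute_tto(cohort, list(cfg.target_synonyms))
print(tto_table(records).round(2).to_string(index=False))
```

prints

```
retained 4894 of 5000 submitted cases; 3890 female
    term  a  b  c    d   ror  ror_low  chi2  ic025  ebgm05
EVT_OHSS  4 74 20 8351 22.57     7.53 65.22   0.57    6.02
  group  n  median  q1   q3  min  max  shape  shape_lo  shape_hi failure_type
overall 25    15.0 7.0 24.0  0.0 95.0   0.96      0.71      1.31       random
```

Reading this: duplicate resubmissions (about 20% of cases) were collapsed
to one report per case, and the 106 cases named on deleted-case lists
were removed, leaving 4,894 of the 5,000 generated cases; 3,890 are
female. The one planted association (`EVT_OHSS`, planted
relative risk 50) is the only term clearing all four thresholds — its
reporting odds ratio is 22.6 with lower confidence limit 7.5, χ² = 65.2,
IC025 = 0.57 > 0 and EBGM05 = 6.0 > 2. Of the exposed reports, 25 carry
day-precise start and onset dates; their median onset is 15 days
(IQR 7–24) and the fitted Weibull shape 0.96 has a CI spanning 1, so at
this sample size the hazard is classified as constant over time
("random failure").

The same pipeline is available from the shell:

```bash
pvsignal simulate --n-reports 5000 --seed 1 --out archive
pvsignal ingest --source faers --in archive --vocab archive/vocabulary.tsv \
    --sex F --out caseset
pvsignal signals --caseset caseset --drug-synonyms synonyms.txt --level pt \
    --out signals.tsv
pvsignal tto --caseset caseset --drug-synonyms synonyms.txt --out tto.tsv
```

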