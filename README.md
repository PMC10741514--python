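# disprop

Proportional reporting ratio (PRR) disproportionality analysis for
spontaneous adverse-event report databases, built around a worked case
study: drug-associated male-factor infertility (MFI) reporting in a
FAERS-like database. The package is aimed at pharmacovigilance analysts and
methods researchers who want a tested, scriptable implementation of the
classic PRR screen — including the inclusion filter, tiered signal
classification and the concomitant-medication "unmasking" re-analysis —
plus a seeded synthetic report generator with analytic ground truth for
validating the whole pipeline without access to a regulatory database.

## The statistic

For an index drug and an index reaction term (here the MedDRA preferred
term "Infertility male"), the individual cases of the database partition
into a 2×2 table: *A* cases name the drug as suspect and code the term, *B*
name the drug with any other event, *C* code the term under any other drug,
and *D* is the remainder. Then

```
PRR = (A / (A + B)) / (C / (C + D))
```

with the log-normal 95% interval
`exp(ln PRR ± 1.96·se)`, `se = sqrt(1/A − 1/(A+B) + 1/C − 1/(C+D))`.
A drug is a **signal of disproportionate reporting** when the lower CI
bound exceeds 1, and a **strong** signal when additionally PRR > 3. Only
drugs with more than 10 index-term cases enter the screen, and a case with
several suspect drugs counts once for each. The unmasking re-analysis
re-estimates the PRR of each signalled drug after removing its reports that
list any concomitant medication, exposing signals that are driven by
co-reported products rather than the drug itself.

## Worked example

`examples/02_synthetic_screen.py` generates a 60,000-report database from
the packaged masking scenario and runs the screen (abridged output):

```
database: 60000 reports, 1057 with the index term 'Infertility male'

               drug  n_cases  pct_of_total   prr  ci_low  ci_high             tier  true_prr
    MECHLORETHAMINE      228         21.57  7.96    6.93     9.16           STRONG      7.48
        FINASTERIDE      184         17.41 10.44    9.00    12.11           STRONG     10.19
 DIETHYLSTILBESTROL       92          8.70  6.92    5.65     8.48           STRONG      8.27
        ...
       TESTOSTERONE       32          3.03  1.70    1.20     2.41 DISPROPORTIONATE      1.64
```

Each included drug's estimated PRR tracks the analytic value implied by the
generator (`true_prr` column). Running `examples/03_unmasking.py` on the
same database shows why the re-analysis matters: the alkylating agent's
index-term reports are concentrated in its co-medicated stratum by
construction, so its crude signal collapses once co-medicated reports are
removed, while the genuinely associated drugs keep theirs:

```
           drug  crude_prr  unmasked_prr  n_excluded  tier_before  tier_after
MECHLORETHAMINE       7.96          0.12        1435       STRONG        NONE
    FINASTERIDE      10.44         10.33         228       STRONG      STRONG
```

`examples/01_published_screen_classification.py` applies the tier rule to
the published 20-drug MFI reference table shipped in `disprop.datasets`
(8 of 20 drugs flagged), and `examples/04_descriptives_and_io.py` shows the
descriptive breakdowns and lossless CSV/JSONL round trip. The same pipeline
is available from the shell via the `disprop` console script
(`disprop generate | analyze | unmask | describe`).

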