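# Methods

## Data model and normalization

An individual case (one report) carries drug mentions with a role — SUSPECT
or CONCOMITANT — an optional free-text reason for use per suspect mention,
one or more coded reaction terms, and reporter metadata (reporter type,
sex, age, weight, country, event year, seriousness, literature-reference
flag). Drug names are normalized by uppercasing and collapsing whitespace
only: the analysis works at active-ingredient granularity as printed, and
no salt/ingredient thesaurus is applied ("Amlodipine Besylate" stays
distinct from "Amlodipine"). Reaction terms are stored casefolded and
matched by exact equality — no substring or dictionary-hierarchy matching —
because an index query for "Infertility male" must not absorb related
preferred terms that code mere semen-parameter alterations. Missing
metadata is represented as absent and never imputed; descriptive means are
computed over present values only. Beyond report-id uniqueness no
case-level deduplication is attempted.

Two lossless file dialects are defined (CSV with `|`-joined multi-valued
cells and positionally aligned per-suspect reasons; JSONL with explicit
drug objects). Reading validates every row; the caller chooses between
aborting with a per-row error report and skipping invalid rows.

## The screen

Counting unit is the individual case: a report with k suspect drugs
contributes one index-term case to each of the k drugs, so per-drug counts
may sum to more than the number of index-term reports. Concomitant-role
mentions never contribute to the drug's own cells. The inclusion rule
retains drugs with more than 10 index-term cases (`min_reports = 11`,
configurable); results are ordered by descending case count, then name.

PRR is `(A/(A+B)) / (C/(C+D))` with no continuity correction: a zero A
yields PRR 0, while A+B = 0, C = 0 or C+D = 0 raise explicit
undefined-estimate errors rather than being silently corrected. The
confidence interval is the log-normal Wald construction,
`exp(ln PRR ± z·se)` with `se = sqrt(1/A − 1/(A+B) + 1/C − 1/(C+D))` and
`z` the standard-normal quantile of the configured two-sided level
(1.96 at 95%). This is the standard interval of the PRR literature; the
level, the strong-signal cutoff (PRR > 3) and the lower-bound threshold
(> 1) all live in one `SignalCriteria` object. Classification is tiered:
STRONG when PRR exceeds the strong cutoff and the lower bound exceeds 1,
DISPROPORTIONATE when only the lower bound exceeds 1, NONE otherwise —
including inverse associations, whose upper bound falls below 1.

Display rounding is half-away-from-zero, computed in decimal arithmetic
(the binary double nearest to 100·86/408 rounds to the wrong digit under
round-half-even); full precision is retained in the result objects.

## Unmasking

The re-analysis removes, for an index drug, every report that names it as a
suspect AND lists at least one CONCOMITANT-role mention — any product, not
only suspected ones — then reruns contingency, PRR, CI and classification
on the reduced database. Two conventions were genuinely open and are fixed
as follows: (i) only index-drug reports are removed, and C/D are recomputed
on the same reduced set, so the four cells still partition it (the most
conservative reading; removing complement reports as well would discard
information about the background rate); (ii) suspect-role co-drugs do not
trigger exclusion, since the rule is about concomitant medication. A drug
whose reduced A (or complement C) reaches zero gets an explicitly undefined
unmasked outcome with a logged warning instead of a crash or a corrected
estimate. By default only drugs flagged by the primary analysis are
unmasked; any included drug can be requested explicitly.

## Synthetic databases and ground truth

Each synthetic report draws one suspect drug from a multinomial over
exposure weights; with drug-specific probability q it lists one concomitant
drawn uniformly from the other drugs; the index term is coded with
probability π₀·ρ·(boost if a concomitant is present), where π₀ is the
baseline index-term probability, ρ the drug's event-rate ratio, and
boost ≥ 1 the concomitant-stratum multiplier that induces masking.
Non-index reports receive one filler reaction from a small fixed
vocabulary (their identity only populates B/D). Metadata — reporter type,
country, event year, age (with a missingness probability), sex, reason for
use, seriousness, literature flag — comes from configurable distributions;
index-term reports are male by construction. A single root seed is
streamed per component, so reconfiguring metadata never perturbs the
exposure/event draws, and one config yields byte-identical databases.

Under this mixture the population PRR has the closed form
`rate(index) / rate(others)` with
`rate(d) = π₀·ρ_d·(1 − q_d + q_d·boost_d)` and the complement rate the
exposure-weighted mean over the other drugs; conditioning on the
concomitant-free stratum replaces the numerator by `π₀·ρ` and leaves the
complement unchanged, which is exactly what the unmasking estimator
targets. `true_prr` is the ratio of expected rates (the large-sample limit
of the estimator), valid only for single-suspect configs; the multi-suspect
switch exists solely to exercise the counting convention.

Two packaged scenarios define the study conditions. The **masking
scenario** (60,000 reports, π₀ = 0.01) carries a 20-drug roster echoing the
pharmacological classes of a published MFI screen — a 5-α-reductase
inhibitor (ρ = 16) and a nonsteroidal estrogen (ρ = 14) with genuinely
elevated reporting, several near-null drugs, an inverse-association H2
antagonist (ρ = 0.1) — on top of a heavier background mass of eight common
drugs at baseline, as in a real database where the complement is dominated
by unrelated products. Three drugs are masked by construction: the
alkylating agent (ρ = 0.8, q = 0.7, boost = 20), whose crude PRR is strong
while its concomitant-free PRR sits below 1, and two calcium-channel
blockers with milder boosts. The **recovery scenario** (default 100,000
reports, π₀ = 0.04, 20 drugs, equal weights, ρ log-spaced on [0.5, 8], no
concomitants) is used for parameter recovery: π₀ and the ρ range were
chosen once so that every drug keeps informative counts down to a
1,000-report database while PRRs span an order of magnitude.

What the generator does not emulate: duplicate and follow-up reports,
reporting trends over calendar time, drug–drug interactions beyond the
single-concomitant stratum, multi-reaction reports, and any fit of the
exposure margins to real FAERS frequencies. Passing recovery tests
therefore demonstrates correctness of the estimator under the assumed
mixture, not robustness to real-world reporting artifacts.

## Verification strategy and problem sizes

The statistics path is checked three ways: exhaustively enumerated small
fixtures; a brute-force oracle (double loops, the 2×2 arithmetic written by
hand, a hard-coded 95% quantile) that must agree cell-for-cell and to
12 significant digits on hundreds of random databases; and analytic ground
truth from the generator (CI coverage of `true_prr` at 100,000 reports,
with a nominal ~95% per-drug rate, and median relative error decreasing
across 10³/10⁴/10⁵ reports). The coverage count over 20 drugs is a
stochastic quantity: per-drug coverage is at the nominal level, but the
shared complement correlates failures slightly, so individual replicates
occasionally fall below 18/20 while the long-run rate does not. Published
reference values (the 20-row screen and its derived percentages) validate
the classification rule and the rounding conventions; the reference
database itself is not redistributable, so the published PRRs are inputs to
the classification check, not recomputation targets. Two printed values are
knowingly irreproducible from their own printed numerators and denominators
under any standard rounding (7.42% for 32/408 and 82.3% for 14/17) and are
documented rather than targeted.

## Known limitations

The screen inherits every caveat of spontaneous-report disproportionality:
no causality, no exposure denominators, reporting and notoriety biases.
Exact-term matching means hierarchy-coded synonyms are invisible. The
unmasking convention (per-drug reduced dataset) is one defensible reading
of the procedure; recomputing the complement on the full database is
another, and the two differ in small ways that the packaged scenarios do
not adjudicate. The CI is asymptotic and its coverage degrades for very
small A; the package surfaces this only through the width of the interval.
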