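"""Naive brute-force re-implementation of the screen, used as an oracle.

Everything here is deliberately independent of the package's analysis path:
double loops over reports, the 2x2 arithmetic written out by hand, and a
hard-coded 95% normal quantile. Report objects are built directly (the
oracle checks the statistics, not the I/O layer).
"""

import math
import random

from disprop.reports import AdverseEventReport, DrugMention, DrugRole, ReportSet

Z95 = 1.959963984540054

_DRUG_POOL = [
    "Finasteride",
    "Testosterone",
    "Valproic Acid",
    "Verapamil",
    "Ranitidine",
    "Prednisone",
    "Lovastatin",
    "Minoxidil",
]
_FILLERS = ["Headache", "Nausea", "Rash", "Dizziness"]


def _norm(s):
    return " ".join(s.split()).casefold()


def _is_match(report, term):
    t = _norm(term)
    return any(_norm(x) == t for x in report.reactions)


def _suspects(report):
    return {d.drug_name for d in report.drugs if d.role is DrugRole.SUSPECT}


def naive_counts(reports, term):
    counts = {}
    for r in reports:
        if _is_match(r, term):
            for name in _suspects(r):
                counts[name] = counts.get(name, 0) + 1
    return counts


def naive_table(reports, drug, term):
    drug = _norm(drug).upper()
    a = b = c = d = 0
    for r in reports:
        suspect = drug in _suspects(r)
        match = _is_match(r, term)
        if suspect and match:
            a += 1
        elif suspect and not match:
            b += 1
        elif match:
            c += 1
        else:
            d += 1
    return a, b, c, d


def naive_prr(a, b, c, d):
    return (a / (a + b)) / (c / (c + d))


def naive_ci(a, b, c, d, z=Z95):
    prr = naive_prr(a, b, c, d)
    se = math.sqrt(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d))
    return math.exp(math.log(prr) - z * se), math.exp(math.log(prr) + z * se)


def random_report_set(rng: random.Random, n_max: int = 500, term: str = "Infertility male"):
    """A random small ReportSet drawn with stdlib random (not the generator)."""
    n = rng.randint(20, n_max)
    reports = []
    for i in range(n):
        suspects = rng.sample(_DRUG_POOL, rng.randint(1, 3))
        drugs = [DrugMention(s, DrugRole.SUSPECT) for s in suspects]
        for c in rng.sample(_DRUG_POOL, rng.randint(0, 2)):
            drugs.append(DrugMention(c, DrugRole.CONCOMITANT))
        reactions = []
        if rng.random() < 0.3:
            reactions.append(term)
        if not reactions or rng.random() < 0.5:
            reactions.append(rng.choice(_FILLERS))
        reports.append(
            AdverseEventReport(
                report_id=f"S{i}",
                drugs=tuple(drugs),
                reactions=tuple(reactions),
                event_year=rng.randint(1981, 2021) if rng.random() < 0.8 else None,
                age_years=rng.uniform(18, 80) if rng.random() < 0.6 else None,
            )
        )
    return ReportSet(tuple(reports))
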