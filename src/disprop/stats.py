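"""Proportional reporting ratio (PRR) disproportionality analysis.

For an index drug and an index reaction term, the individual cases of a
spontaneous-report database partition into the classic 2x2 table::

                        index term      any other event
    index drug suspect      A                 B
    all other drugs         C                 D

    PRR = (A / (A + B)) / (C / (C + D))

A PRR above 1 suggests the index event is disproportionally reported for the
index drug. The confidence interval uses the log-normal (Wald) construction
with standard error ``sqrt(1/A - 1/(A+B) + 1/C - 1/(C+D))``; the classic
signal-of-disproportionate-reporting rule flags a drug when the lower
confidence bound exceeds 1, and calls the signal *strong* when additionally
PRR > 3.

The counting unit is the individual case: a report naming k suspect drugs
contributes one count to each of the k drugs. Concomitant-role mentions never
contribute to A/B (they matter only for the unmasking re-analysis).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Union

import pandas as pd
from scipy.stats import norm

from .reports import ReportSet, matches_term, normalize_drug_name, normalize_term

logger = logging.getLogger(__name__)

__all__ = [
    "ContingencyTable",
    "SignalCriteria",
    "SignalTier",
    "AnalysisLabel",
    "DisproportionalityResult",
    "UndefinedEstimateError",
    "count_term_cases",
    "filter_min_reports",
    "build_contingency",
    "compute_prr",
    "compute_prr_ci",
    "classify_signal",
    "run_primary_analysis",
    "results_to_frame",
]


class UndefinedEstimateError(ZeroDivisionError):
    """A contingency cell needed by the estimator is zero."""


class SignalTier(str, Enum):
    NONE = "NONE"
    DISPROPORTIONATE = "DISPROPORTIONATE"
    STRONG = "STRONG"


class AnalysisLabel(str, Enum):
    PRIMARY = "PRIMARY"
    UNMASKED = "UNMASKED"


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 case counts for one (drug, term) pair; cells partition the database."""

    a: int  # index drug & index term
    b: int  # index drug & any other event
    c: int  # other drugs & index term
    d: int  # other drugs & any other event

    def __post_init__(self):
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or isinstance(v, bool):
                if isinstance(v, float) and v.is_integer():
                    object.__setattr__(self, name, int(v))
                else:
                    raise ValueError(f"cell {name} must be an integer, got {v!r}")
            if getattr(self, name) < 0:
                raise ValueError(f"cell {name} must be non-negative, got {v}")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def n_drug(self) -> int:
        return self.a + self.b

    @property
    def n_term(self) -> int:
        return self.a + self.c


@dataclass(frozen=True)
class SignalCriteria:
    """All thresholds of the screening rule in one configurable object.

    ``min_reports`` defaults to 11 — the "more than 10 index-term reports"
    inclusion rule. ``prr_strong_cutoff`` (3.0) and ``prr_elevated_cutoff``
    (1.0, applied to the lower CI bound) encode the tiered signal rule.
    """

    min_reports: int = 11
    prr_strong_cutoff: float = 3.0
    prr_elevated_cutoff: float = 1.0
    confidence_level: float = 0.95

    def __post_init__(self):
        if self.min_reports < 1:
            raise ValueError("min_reports must be >= 1")
        if self.prr_strong_cutoff <= 0 or self.prr_elevated_cutoff <= 0:
            raise ValueError("PRR cutoffs must be positive")
        if not (0.0 < self.confidence_level < 1.0):
            raise ValueError("confidence_level must lie in (0, 1)")

    @property
    def z_value(self) -> float:
        """Standard-normal quantile for the two-sided confidence level."""
        return float(norm.ppf(0.5 + self.confidence_level / 2.0))


@dataclass(frozen=True)
class DisproportionalityResult:
    drug_name: str
    table: ContingencyTable
    prr: float
    ci_low: float
    ci_high: float
    signal_tier: SignalTier
    analysis_label: AnalysisLabel = AnalysisLabel.PRIMARY

    @property
    def n_cases(self) -> int:
        return self.table.a


def count_term_cases(rs: ReportSet, term: str) -> dict[str, int]:
    """Per-drug count of distinct index-term cases in which it is a suspect.

    A report with k suspect drugs contributes 1 to each of the k drugs, so
    the counts may sum to more than the number of term-matching reports.
    """
    counts: dict[str, int] = {}
    for r in rs:
        if matches_term(r, term):
            for name in set(r.suspect_names):
                counts[name] = counts.get(name, 0) + 1
    return counts


def filter_min_reports(counts: dict[str, int], criteria: SignalCriteria) -> dict[str, int]:
    """Keep drugs with count >= min_reports, ordered by descending count then name."""
    kept = [(name, n) for name, n in counts.items() if n >= criteria.min_reports]
    kept.sort(key=lambda kv: (-kv[1], kv[0]))
    return dict(kept)


def build_contingency(rs: ReportSet, drug: str, term: str) -> ContingencyTable:
    """Partition the database into the A/B/C/D cells for one (drug, term) pair."""
    drug = normalize_drug_name(drug)
    if not drug:
        raise ValueError("drug is empty")
    if not normalize_term(term):
        raise ValueError("term is empty")
    a = b = c = d = 0
    for r in rs:
        is_suspect = drug in r.suspect_names
        is_match = matches_term(r, term)
        if is_suspect and is_match:
            a += 1
        elif is_suspect:
            b += 1
        elif is_match:
            c += 1
        else:
            d += 1
    return ContingencyTable(a, b, c, d)


def compute_prr(t: ContingencyTable) -> float:
    """Point estimate (A/(A+B)) / (C/(C+D)); no continuity correction.

    Raises :class:`UndefinedEstimateError` when the drug has no reports
    (A+B = 0), the complement is empty (C+D = 0), or the index term is
    exclusive to the drug (C = 0); a zero A yields PRR = 0.0.
    """
    if t.a + t.b == 0:
        raise UndefinedEstimateError("A+B = 0: index drug has no reports")
    if t.c + t.d == 0:
        raise UndefinedEstimateError("C+D = 0: no reports for remaining drugs")
    if t.c == 0:
        raise UndefinedEstimateError("C = 0: index term absent among remaining drugs")
    return (t.a / (t.a + t.b)) / (t.c / (t.c + t.d))


def compute_prr_ci(
    t: ContingencyTable, criteria: SignalCriteria = SignalCriteria()
) -> tuple[float, float]:
    """Log-normal Wald interval around the PRR.

    ``exp(ln PRR ± z * se)`` with ``se = sqrt(1/A - 1/(A+B) + 1/C - 1/(C+D))``.
    Requires A > 0 and C > 0.
    """
    if t.a == 0:
        raise UndefinedEstimateError("A = 0: CI undefined (zero index-drug cases)")
    prr = compute_prr(t)  # validates the remaining cells
    se = math.sqrt(1.0 / t.a - 1.0 / (t.a + t.b) + 1.0 / t.c - 1.0 / (t.c + t.d))
    half = criteria.z_value * se
    log_prr = math.log(prr)
    return math.exp(log_prr - half), math.exp(log_prr + half)


def classify_signal(
    prr: float, ci_low: float, criteria: SignalCriteria = SignalCriteria()
) -> SignalTier:
    """Tiered signal rule on the point estimate and the lower CI bound.

    STRONG when PRR > 3 and the lower bound exceeds 1; DISPROPORTIONATE when
    only the lower bound exceeds 1; otherwise NONE (including inverse
    associations, whose upper bound falls below 1).
    """
    if prr < 0:
        raise ValueError("prr must be non-negative")
    if ci_low > criteria.prr_elevated_cutoff:
        if prr > criteria.prr_strong_cutoff:
            return SignalTier.STRONG
        return SignalTier.DISPROPORTIONATE
    return SignalTier.NONE


def run_primary_analysis(
    rs: ReportSet,
    term: str,
    criteria: SignalCriteria = SignalCriteria(),
    analysis_label: AnalysisLabel = AnalysisLabel.PRIMARY,
) -> list[DisproportionalityResult]:
    """Full screen: count -> inclusion filter -> PRR/CI -> tier, per drug.

    Returns one result per drug surviving the inclusion filter, ordered by
    descending case count then name. Uses a single pass over the database to
    accumulate per-drug totals; the cells are identical to calling
    :func:`build_contingency` drug by drug.
    """
    n_total = len(rs)
    n_term = 0
    n_drug: dict[str, int] = {}
    a_drug: dict[str, int] = {}
    for r in rs:
        is_match = matches_term(r, term)
        if is_match:
            n_term += 1
        for name in set(r.suspect_names):
            n_drug[name] = n_drug.get(name, 0) + 1
            if is_match:
                a_drug[name] = a_drug.get(name, 0) + 1

    included = filter_min_reports(a_drug, criteria)
    if not included:
        logger.info("no drug reaches min_reports=%d for term %r", criteria.min_reports, term)

    results = []
    for name, a in included.items():
        b = n_drug[name] - a
        c = n_term - a
        d = n_total - n_drug[name] - c
        table = ContingencyTable(a, b, c, d)
        prr = compute_prr(table)
        ci_low, ci_high = compute_prr_ci(table, criteria)
        tier = classify_signal(prr, ci_low, criteria)
        results.append(
            DisproportionalityResult(name, table, prr, ci_low, ci_high, tier, analysis_label)
        )
    return results


def results_to_frame(
    results: list[DisproportionalityResult], denominator: Optional[int] = None
) -> pd.DataFrame:
    """Results as a table in the style of a published disproportionality screen.

    ``pct_of_total`` uses *denominator* (e.g. the number of analyzed index-term
    cases) and half-away-from-zero rounding to 2 decimals; PRR and CI bounds
    are displayed at 2 decimals, full precision retained in the result objects.
    """
    from .descriptives import share_of_total

    rows = []
    for res in results:
        row = {
            "drug": res.drug_name,
            "n_cases": res.n_cases,
            "pct_of_total": (
                share_of_total(res.n_cases, denominator, 2) if denominator else float("nan")
            ),
            "prr": round(res.prr, 2),
            "ci_low": round(res.ci_low, 2),
            "ci_high": round(res.ci_high, 2),
            "tier": res.signal_tier.value,
        }
        rows.append(row)
    return pd.DataFrame(
        rows, columns=["drug", "n_cases", "pct_of_total", "prr", "ci_low", "ci_high", "tier"]
    )
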