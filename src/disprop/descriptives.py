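"""Descriptive summaries of a report database.

Shares of totals, reporter-type / reason-for-use / country / year breakdowns
and mean ages, scoped either to the whole database or to the reports naming a
given suspect drug. Percentages use half-away-from-zero rounding computed in
exact decimal arithmetic (100*count/denominator has no binary-float
representation in general, and round-half-even on the nearest double gives
the wrong digit for many printed values). Missing metadata is never imputed:
means run over present values only and missing labels are tallied as their
own UNSPECIFIED row, which stays inside the percent denominator (the
denominator is always the scoped report count).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from typing import Optional, Union

import pandas as pd

from .reports import AdverseEventReport, ReportSet, matches_term, normalize_drug_name

__all__ = [
    "BreakdownDimension",
    "BreakdownTable",
    "share_of_total",
    "round_half_away",
    "breakdown",
    "mean_age",
    "yearly_counts",
]

UNSPECIFIED = "UNSPECIFIED"


class BreakdownDimension(str, Enum):
    REPORTER_TYPE = "REPORTER_TYPE"
    REASON_FOR_USE = "REASON_FOR_USE"
    COUNTRY = "COUNTRY"
    YEAR = "YEAR"


@dataclass(frozen=True)
class BreakdownTable:
    dimension: BreakdownDimension
    rows: tuple[tuple[str, int, float], ...]  # (label, count, percent)
    denominator: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(list(self.rows), columns=["label", "count", "percent"])

    def __getitem__(self, label: str) -> tuple[int, float]:
        for lab, count, pct in self.rows:
            if lab == label:
                return count, pct
        raise KeyError(label)


def round_half_away(x: Union[float, Decimal], decimals: int) -> float:
    """Round half away from zero at *decimals* places (decimal arithmetic)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(str(x)).quantize(q, rounding=ROUND_HALF_UP))


def share_of_total(count: int, denominator: int, decimals: int = 1) -> float:
    """100*count/denominator, half-away-from-zero at *decimals* places.

    The quotient is formed in decimal arithmetic so e.g. 86/408 at 2 decimals
    is exactly 21.08 and 240/408 at 1 decimal is exactly 58.8.
    """
    if denominator <= 0:
        raise ZeroDivisionError("share undefined: denominator must be positive")
    if count < 0:
        raise ValueError("count must be non-negative")
    q = Decimal(1).scaleb(-decimals)
    share = (Decimal(count) * 100) / Decimal(denominator)
    return float(share.quantize(q, rounding=ROUND_HALF_UP))


def _scope(rs: ReportSet, scope_drug: Optional[str]) -> list[AdverseEventReport]:
    if scope_drug is None:
        return list(rs)
    name = normalize_drug_name(scope_drug)
    return [r for r in rs if name in r.suspect_names]


def _label(r: AdverseEventReport, dimension: BreakdownDimension, scope_drug: Optional[str]) -> str:
    if dimension is BreakdownDimension.REPORTER_TYPE:
        return r.reporter_type.value
    if dimension is BreakdownDimension.COUNTRY:
        return r.country or UNSPECIFIED
    if dimension is BreakdownDimension.YEAR:
        return str(r.event_year) if r.event_year is not None else UNSPECIFIED
    # REASON_FOR_USE: the reason attached to the scoped drug's suspect mention
    # (first suspect mention of the report when unscoped).
    if scope_drug is not None:
        reason = r.reason_for(scope_drug)
    else:
        reason = next((d.reason_for_use for d in r.drugs if d.reason_for_use), None)
    return reason if reason else UNSPECIFIED


def breakdown(
    rs: ReportSet,
    dimension: Union[str, BreakdownDimension],
    scope_drug: Optional[str] = None,
    decimals: int = 1,
) -> BreakdownTable:
    """Counts and percentages per label over the scoped reports.

    Rows are ordered by descending count then label; missing values form an
    UNSPECIFIED row. The percent denominator is the scoped report count, so
    row counts always sum to it exactly.
    """
    if not isinstance(dimension, BreakdownDimension):
        dimension = BreakdownDimension(str(dimension).upper())
    scoped = _scope(rs, scope_drug)
    denominator = len(scoped)
    counts: dict[str, int] = {}
    for r in scoped:
        lab = _label(r, dimension, scope_drug)
        counts[lab] = counts.get(lab, 0) + 1
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    rows = tuple(
        (lab, n, share_of_total(n, denominator, decimals)) for lab, n in ordered
    )
    return BreakdownTable(dimension, rows, denominator)


def mean_age(rs: ReportSet, scope_drug: Optional[str] = None) -> Optional[float]:
    """Mean age (1 decimal) over scoped reports with age present; None if none."""
    ages = [r.age_years for r in _scope(rs, scope_drug) if r.age_years is not None]
    if not ages:
        return None
    return round_half_away(sum(ages) / len(ages), 1)


def yearly_counts(rs: ReportSet, term: str) -> dict[int, int]:
    """Term-matching reports per event year (reports without a year excluded)."""
    counts: dict[int, int] = {}
    for r in rs:
        if r.event_year is not None and matches_term(r, term):
            counts[r.event_year] = counts.get(r.event_year, 0) + 1
    return dict(sorted(counts.items()))
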