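"""Unmasking re-analysis: recompute the PRR after dropping co-medicated reports.

Competition ("masking") bias arises when co-reported products absorb or
inflate an index drug's apparent disproportionality. The conservative
re-analysis implemented here removes, for each signalled drug, every report
that names the drug as a suspect AND lists at least one concomitant-role
medication — irrespective of which product it is — then reruns the full
contingency/PRR/CI/classification machinery on the reduced database.

Convention: only index-drug reports are removed; the complement cells C and D
are recomputed on the same reduced set so the partition invariant holds.
Suspect-role co-drugs do not trigger exclusion (the rule is about concomitant
medications).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .reports import ReportSet, normalize_drug_name
from .stats import (
    AnalysisLabel,
    DisproportionalityResult,
    SignalCriteria,
    SignalTier,
    UndefinedEstimateError,
    build_contingency,
    classify_signal,
    compute_prr,
    compute_prr_ci,
    run_primary_analysis,
)

logger = logging.getLogger(__name__)

__all__ = ["UnmaskingOutcome", "exclude_concomitant_reports", "run_unmasking", "outcomes_to_frame"]


@dataclass(frozen=True)
class UnmaskingOutcome:
    """Crude vs unmasked result for one drug.

    ``unmasked_result`` is None when the estimate is undefined on the reduced
    set (all index-drug index-term reports carried concomitants, or no
    index-term report remains among the other drugs).
    """

    drug_name: str
    primary_result: DisproportionalityResult
    unmasked_result: Optional[DisproportionalityResult]
    n_excluded_reports: int

    @property
    def is_undefined(self) -> bool:
        return self.unmasked_result is None


def exclude_concomitant_reports(rs: ReportSet, drug: str) -> ReportSet:
    """Drop every report naming *drug* as suspect that lists >=1 concomitant."""
    name = normalize_drug_name(drug)
    return rs.filter(
        lambda r: not (name in r.suspect_names and r.has_concomitant),
        provenance=f"{rs.provenance}[unmasked:{name}]",
    )


def run_unmasking(
    rs: ReportSet,
    term: str,
    criteria: SignalCriteria = SignalCriteria(),
    drugs: Optional[Sequence[str]] = None,
) -> list[UnmaskingOutcome]:
    """Re-estimate the PRR of each signalled drug on its concomitant-free subset.

    By default *drugs* is the set flagged non-NONE by the primary analysis;
    pass an explicit list to unmask other drugs (e.g. all included ones).
    """
    primary = run_primary_analysis(rs, term, criteria)
    by_name = {res.drug_name: res for res in primary}
    if drugs is None:
        names = [res.drug_name for res in primary if res.signal_tier is not SignalTier.NONE]
    else:
        names = [normalize_drug_name(d) for d in drugs]

    outcomes = []
    for name in names:
        if name not in by_name:
            raise KeyError(f"{name!r} is not among the drugs retained by the primary analysis")
        reduced = exclude_concomitant_reports(rs, name)
        n_excluded = len(rs) - len(reduced)
        table = build_contingency(reduced, name, term)
        try:
            prr = compute_prr(table)
            ci_low, ci_high = compute_prr_ci(table, criteria)
        except UndefinedEstimateError as exc:
            logger.warning("unmasked estimate undefined for %s: %s", name, exc)
            outcomes.append(UnmaskingOutcome(name, by_name[name], None, n_excluded))
            continue
        tier = classify_signal(prr, ci_low, criteria)
        unmasked = DisproportionalityResult(
            name, table, prr, ci_low, ci_high, tier, AnalysisLabel.UNMASKED
        )
        outcomes.append(UnmaskingOutcome(name, by_name[name], unmasked, n_excluded))
    return outcomes


def outcomes_to_frame(outcomes: list[UnmaskingOutcome]) -> pd.DataFrame:
    """Crude-vs-unmasked comparison table (one row per drug)."""
    rows = []
    for o in outcomes:
        p, u = o.primary_result, o.unmasked_result
        rows.append(
            {
                "drug": o.drug_name,
                "crude_prr": round(p.prr, 2),
                "crude_ci_low": round(p.ci_low, 2),
                "crude_ci_high": round(p.ci_high, 2),
                "unmasked_prr": None if u is None else round(u.prr, 2),
                "unmasked_ci_low": None if u is None else round(u.ci_low, 2),
                "unmasked_ci_high": None if u is None else round(u.ci_high, 2),
                "n_excluded": o.n_excluded_reports,
                "tier_before": p.signal_tier.value,
                "tier_after": "UNDEFINED" if u is None else u.signal_tier.value,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "drug",
            "crude_prr",
            "crude_ci_low",
            "crude_ci_high",
            "unmasked_prr",
            "unmasked_ci_low",
            "unmasked_ci_high",
            "n_excluded",
            "tier_before",
            "tier_after",
        ],
    )
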