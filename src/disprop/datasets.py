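"""Reference values from a published FAERS male-factor-infertility screen.

A pharmacovigilance screen of the FAERS Public Dashboard (data harvested
January 2023, reports 1981-2021) identified 955 individual cases coded with
the MedDRA preferred term "Infertility male"; 408 of them (42.7%) involved
the 20 medications that each exceeded the 10-report inclusion threshold, and
the screen published per-drug case counts, PRRs with 95% confidence
intervals, and a bold-face marking of the drugs whose lower confidence bound
exceeded 1. Those printed numbers are transcribed here so they can be used
as worked-example inputs: the underlying database is not redistributable,
but the classification rule and every percentage derivable from printed
numerator/denominator pairs can be recomputed from this table alone.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "TOTAL_MFI_REPORTS",
    "ANALYZED_MFI_REPORTS",
    "INDEX_TERM",
    "published_mfi_table",
]

TOTAL_MFI_REPORTS = 955
ANALYZED_MFI_REPORTS = 408
INDEX_TERM = "Infertility male"

# (pharmacological class, drug, n cases, printed %, PRR, ci_low, ci_high, flagged)
_ROWS = [
    ("5 alpha-reductase inhibitors", "Finasteride", 86, 21.08, 16.04, 12.67, 20.30, True),
    ("Steroid hormones", "Testosterone", 33, 8.09, 3.03, 2.12, 4.32, True),
    ("Anticonvulsants", "Valproic Acid", 32, 7.42, 1.72, 1.20, 2.47, True),
    ("Anticonvulsants", "Carbamazepine", 17, 4.17, 1.07, 0.66, 1.74, False),
    ("SSRIs", "Sertraline", 29, 7.11, 0.94, 0.64, 1.37, False),
    ("SSRIs", "Paroxetine", 17, 4.17, 0.92, 0.56, 1.50, False),
    ("SSRIs", "Fluoxetine", 15, 3.68, 0.51, 0.30, 0.85, False),
    ("Direct Vasodilators", "Minoxidil", 24, 5.88, 0.95, 0.62, 1.43, False),
    ("Nonsteroidal estrogens", "Diethylstilbestrol", 20, 4.90, 14.30, 9.13, 22.37, True),
    ("Calcium-channel blockers", "Amlodipine Besylate", 19, 4.66, 0.69, 0.43, 1.09, False),
    ("Calcium-channel blockers", "Verapamil", 14, 3.43, 1.83, 1.07, 3.12, True),
    ("Calcium-channel blockers", "Nifedipine", 12, 2.94, 1.85, 1.04, 3.28, True),
    ("Calcium-channel blockers", "Diltiazem Hydrochloride", 11, 2.70, 1.49, 0.82, 2.72, False),
    ("Skin and Mucous Membrane Agents", "Isotretinoin", 19, 4.66, 0.84, 0.53, 1.33, False),
    ("Alkylating agents", "Mechlorethamine", 17, 4.17, 58.71, 36.30, 94.94, True),
    ("Histamine H2-Antagonists", "Ranitidine", 16, 3.92, 0.10, 0.06, 0.16, False),
    ("Antineoplastic Agents", "Vincristine", 13, 3.19, 1.12, 0.65, 1.95, False),
    ("Glucocorticoids", "Prednisone", 13, 3.19, 0.28, 0.16, 0.48, False),
    ("Statins", "Lovastatin", 13, 3.19, 2.51, 1.44, 4.36, True),
    ("Immunosuppressive Agents", "Mycophenolate Mofetil", 11, 2.70, 0.47, 0.26, 0.86, False),
]


def published_mfi_table() -> pd.DataFrame:
    """The published 20-drug screen as a DataFrame.

    Columns: ``drug_class, drug, n_cases, pct_printed, prr, ci_low, ci_high,
    flagged`` — ``flagged`` reproduces the publication's bold-face marking of
    signals of disproportionate reporting.
    """
    return pd.DataFrame(
        _ROWS,
        columns=[
            "drug_class",
            "drug",
            "n_cases",
            "pct_printed",
            "prr",
            "ci_low",
            "ci_high",
            "flagged",
        ],
    )
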