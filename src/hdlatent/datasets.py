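"""Published summary-level data for the humidifier-disinfectant cohort.

The underlying CT images of the 121-subject cohort (96 reporting
humidifier-disinfectant exposure, 25 unexposed, all with
normal-appearing CT and PFT) are not public, but the published
group-level summary statistics and the exposure-by-cluster counts are,
and every statistic computable from them can be reproduced exactly.
These tables feed the summary-statistics forms of the tests in
:mod:`hdlatent.stats`.
"""

from __future__ import annotations

import pandas as pd

from .stats import GroupSummary

__all__ = [
    "hd_cohort_summaries",
    "hd_gender_counts",
    "hd_cluster_exposure_table",
]


def hd_cohort_summaries() -> dict[str, tuple[GroupSummary, GroupSummary]]:
    """Demographics/PFT mean (SD) for exposed (n=96) vs unexposed (n=25)
    subjects, as (exposed, unexposed) summary pairs."""
    rows = {
        "age": ((49.86, 15.43), (45.44, 11.38)),
        "bmi": ((23.40, 3.21), (24.72, 2.94)),
        "height_cm": ((163.95, 7.89), (169.96, 8.15)),
        "weight_kg": ((63.11, 10.94), (71.76, 12.06)),
        "fvc_pct_pred": ((87.16, 16.64), (99.28, 7.17)),
        "fev1_pct_pred": ((89.53, 20.86), (107.72, 10.51)),
    }
    return {
        name: (
            GroupSummary("exposed", 96, m1, s1),
            GroupSummary("unexposed", 25, m2, s2),
        )
        for name, ((m1, s1), (m2, s2)) in rows.items()
    }


def hd_gender_counts() -> pd.DataFrame:
    """2x2 gender-by-exposure counts reconstructed from the published
    percentages (female/male 45.8/54.2 of 96 exposed; 16.0/84.0 of 25
    unexposed)."""
    return pd.DataFrame(
        {"exposed": [44, 52], "unexposed": [4, 21]},
        index=["female", "male"],
    )


def hd_cluster_exposure_table(include_minor: bool = True) -> pd.DataFrame:
    """Exposed/unexposed subject counts per k-means subject cluster
    (C0..C5).  C3 and C4 are the minor clusters (1 and 4 members); set
    ``include_minor=False`` to drop them."""
    df = pd.DataFrame(
        {
            "unexposed": [1, 3, 5, 0, 0, 16],
            "exposed": [31, 20, 23, 1, 4, 17],
        },
        index=["C0", "C1", "C2", "C3", "C4", "C5"],
    )
    if not include_minor:
        df = df.drop(index=["C3", "C4"])
    return df
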