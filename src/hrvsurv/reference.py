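"""Published summary counts of the hospice cohort, usable as analysis inputs.

Patient-level data for the original 138-patient hospice cohort were never
deposited; what is public is the descriptive table: group sizes by 7-day
survival status (29 events / 109 non-events) and, for each binary covariate,
the count of positives within each group.  Those counts fully determine every
covariate-by-outcome 2x2 table, and therefore every univariate odds ratio,
without patient-level data.

:func:`cohort_from_table_counts` expands the counts into a patient-level
table that is *count-faithful*: each binary covariate's cross-tabulation
against the 7-day event matches the published counts exactly.  The joint
distribution across covariates is arbitrary (covariates are assigned
independently within outcome groups) and continuous covariates are filled
with their group means — the reconstruction supports contingency-table and
descriptive analyses only, not multivariable modelling.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import ContingencyTable2x2

__all__ = [
    "EVENTS_N",
    "NONEVENTS_N",
    "BINARY_EXPOSED_COUNTS",
    "GROUP_MEANS",
    "table_contingency",
    "cohort_from_table_counts",
]

#: patients dead within 7 days of admission / surviving beyond 7 days
EVENTS_N = 29
NONEVENTS_N = 109

#: positives among (events, non-events) for each binary covariate
BINARY_EXPOSED_COUNTS: dict[str, tuple[int, int]] = {
    "male": (18, 58),
    "cognitive_impairment": (18, 39),
    "edema": (15, 58),
    "jaundice": (14, 38),
    "ascites": (14, 29),
    "ecog_34": (24, 64),
}

#: (event-group mean, non-event-group mean) for the continuous covariates
GROUP_MEANS: dict[str, tuple[float, float]] = {
    "age": (67.8, 67.3),
    "muscle_power": (3.1, 3.6),
    "ln_tp": (4.76, 5.49),
    "ln_hfp": (0.92, 2.25),
    "ln_lf_hf": (-0.33, -0.18),
}


def table_contingency(variable: str) -> ContingencyTable2x2:
    """2x2 table (exposure x 7-day event) for one published binary covariate."""
    try:
        a, c = BINARY_EXPOSED_COUNTS[variable]
    except KeyError:
        raise KeyError(
            f"unknown binary covariate {variable!r}; "
            f"known: {sorted(BINARY_EXPOSED_COUNTS)}"
        ) from None
    return ContingencyTable2x2(a=a, b=EVENTS_N - a, c=c, d=NONEVENTS_N - c)


def cohort_from_table_counts() -> pd.DataFrame:
    """Patient-level expansion of the published counts (see module docstring).

    Within each outcome group the first ``k`` patients carry each binary
    trait, where ``k`` is the published positive count; survival days are
    filled deterministically (events on days 1-7, non-events beyond day 7,
    all deaths observed).
    """
    n = EVENTS_N + NONEVENTS_N
    event = np.concatenate([np.ones(EVENTS_N, int), np.zeros(NONEVENTS_N, int)])
    df = pd.DataFrame({"patient_id": np.arange(1, n + 1), "event_7d": event})
    for var, (k_event, k_nonevent) in BINARY_EXPOSED_COUNTS.items():
        col = np.zeros(n, dtype=int)
        col[:k_event] = 1
        col[EVENTS_N: EVENTS_N + k_nonevent] = 1
        df[var] = col
    df["sex"] = np.where(df.pop("male") == 1, "M", "F")
    df["ecog"] = np.where(df["ecog_34"] == 1, 3, 2)
    for var, (mean_event, mean_nonevent) in GROUP_MEANS.items():
        df[var] = np.where(event == 1, mean_event, mean_nonevent)
    df["lnhfp_lt2"] = (df["ln_hfp"] < 2).astype(int)
    df["survival_days"] = np.where(
        event == 1,
        1 + np.arange(n) % 7,
        8 + np.arange(n) % 30,
    )
    df["death_observed"] = 1
    return df
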