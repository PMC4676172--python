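"""Packaged reference tables.

The 21-patient transplant-cohort clinical fixture: 9 patients recurred
within the 24-month follow-up window (their recurrence month is recorded);
the 12 tumor-free patients carry no time and are censored at the follow-up
horizon.  All patients but one were cirrhotic, so cirrhosis is not a usable
covariate in this cohort.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

GRADE_ORDINAL = {"I": 1.0, "I-II": 1.5, "II": 2.0, "II-III": 2.5, "III": 3.0}


def load_olt_cohort(age_cut: float = 49.0, follow_up_months: float = 24.0) -> pd.DataFrame:
    """Load the transplant-cohort clinical table with analysis encodings.

    Adds ``time`` (recurrence month, or the follow-up horizon for censored
    patients), ``event`` (recurrence indicator), ordinal ``grade_ordinal``,
    binary ``male`` and ``age_lt_cut`` (age below ``age_cut``).
    """
    ref = resources.files("oltrecur.data") / "olt_cohort_clinical.tsv"
    with resources.as_file(ref) as path:
        t = pd.read_csv(path, sep="\t")
    t["event"] = t["recurrent"].astype(int)
    t["time"] = np.where(t["event"] == 1, t["recurrence_month"], follow_up_months)
    t["grade_ordinal"] = t["grade"].map(GRADE_ORDINAL)
    t["male"] = (t["sex"] == "M").astype(int)
    t["age_lt_cut"] = (t["age"] < age_cut).astype(int)
    return t
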