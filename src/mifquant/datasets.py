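"""Published-cohort characteristics for the TNBC case-control study.

The per-patient table below is a synthetic reconstruction: for each
categorical characteristic the published per-group level counts fully
determine the per-patient values (order is arbitrary), so a patient-level
frame rebuilt from those aggregate counts reproduces the published summary
table exactly.  Continuous characteristics (age, BMI, follow-up) are only
published as quartiles and are not reconstructable per patient; they are
omitted.

Groups: 49 African American (AA) cases, 51 non-AA (NAA) controls.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["published_cohort_manifest", "PUBLISHED_COVARIATES"]

UNKNOWN = "Unknown"

# level -> (count in AA, count in NAA); None stands for unknown/not reported
_CATEGORICAL_COUNTS: dict[str, dict[str | None, tuple[int, int]]] = {
    "Ethnicity": {
        "Hispanic or Latino": (1, 0),
        "Non-Hispanic": (40, 38),
        None: (8, 13),
    },
    "Stage": {
        "IA": (17, 18),
        "IIA": (17, 19),
        "IIB": (13, 8),
        "IIIA": (2, 4),
        "IIIB": (0, 2),
    },
    "Grade": {
        "2": (6, 10),
        "3": (43, 41),
    },
    "Histology": {
        "AdenoSquamous": (1, 0),
        "Fibromatoid nodule": (1, 0),
        "IDC": (40, 44),
        "IDC-medullary": (1, 0),
        "IDC-micropapillary": (1, 3),
        "ILC": (0, 1),
        "IMC": (2, 1),
        "Metaplastic": (0, 1),
        "Squamoid": (0, 1),
        None: (3, 0),
    },
    "Chemotherapy": {
        "Yes": (37, 38),
        "No": (12, 6),
        None: (0, 7),
    },
    "XRT": {
        "Yes": (41, 31),
        "No": (8, 13),
        None: (0, 7),
    },
}

PUBLISHED_COVARIATES = {name: "categorical" for name in _CATEGORICAL_COUNTS}

_GROUP_SIZES = {"AA": 49, "NAA": 51}


def published_cohort_manifest() -> pd.DataFrame:
    """Patient-level frame (100 rows) matching the published group counts."""
    rows = []
    for group, n in _GROUP_SIZES.items():
        for i in range(n):
            rows.append({"section_id": f"{group}{i + 1:03d}", "group": group})
    df = pd.DataFrame(rows)
    for cov, counts in _CATEGORICAL_COUNTS.items():
        for gi, group in enumerate(_GROUP_SIZES):
            values: list[str] = []
            for level, per_group in counts.items():
                values += [UNKNOWN if level is None else level] * per_group[gi]
            if len(values) != _GROUP_SIZES[group]:
                raise AssertionError(
                    f"{cov}/{group}: counts sum to {len(values)}"
                )
            df.loc[df["group"] == group, cov] = values
    return df
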