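"""Published linear clinical risk score for ventricular-arrhythmia risk.

The score combines demographics, rhythm status, general cardiac status and
laboratory values:

    score = -0.2*age + 4*male + 5*atrial_fibrillation - 8*amiodarone
            + 7*pacemaker - 3*smoking - 0.2*|QRS - 130|
            - 8*anemia + 1.77*creatinine

with age in years, QRS duration in milliseconds, creatinine in mg/dL and
anemia defined as hemoglobin < 12 g/dL.  The original score also carries
nonsustained-VT and digoxin terms; they are omitted here, matching cohorts
in which those variables are unavailable.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import pandas as pd

__all__ = ["ClinicalRecord", "clinical_risk_score", "add_score_column"]

_FLAGS = ("male", "atrial_fibrillation", "amiodarone", "pacemaker", "smoking", "anemia")


@dataclass(frozen=True)
class ClinicalRecord:
    """Covariates entering the clinical risk score."""

    age: float
    male: int
    atrial_fibrillation: int
    amiodarone: int
    pacemaker: int
    smoking: int
    qrs_ms: float
    anemia: int
    creatinine: float

    def __post_init__(self) -> None:
        for name in _FLAGS:
            v = getattr(self, name)
            if v not in (0, 1):
                raise ValueError(f"{name} must be 0 or 1, got {v!r}")
        for name in ("age", "qrs_ms", "creatinine"):
            v = getattr(self, name)
            if v is None or not v >= 0:
                raise ValueError(f"{name} must be a nonnegative number, got {v!r}")


def clinical_risk_score(record: ClinicalRecord) -> float:
    """Evaluate the printed linear score; no imputation of missing fields."""
    return (
        -0.2 * record.age
        + 4.0 * record.male
        + 5.0 * record.atrial_fibrillation
        - 8.0 * record.amiodarone
        + 7.0 * record.pacemaker
        - 3.0 * record.smoking
        - 0.2 * abs(record.qrs_ms - 130.0)
        - 8.0 * record.anemia
        + 1.77 * record.creatinine
    )


def add_score_column(df: pd.DataFrame, column: str = "clinical_score") -> pd.DataFrame:
    """Append the score to a cohort table holding the covariate columns."""
    required = [f.name for f in fields(ClinicalRecord)]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table missing covariates: {missing}")
    out = df.copy()
    out[column] = [
        clinical_risk_score(ClinicalRecord(**{c: row[c] for c in required}))
        for _, row in df.iterrows()
    ]
    return out
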