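"""Stratification of attributed fusions by FDA-approval status.

A fusion's clinical context is the pair (driver gene, patient's cancer
type): pan-cancer drivers are approved everywhere, emerging drivers nowhere,
and the remaining actionable drivers only in the indications the approval
matrix lists.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

from .model import (
    ActionabilityMatrix,
    AttributedFusion,
    FusionValidationError,
    PatientRecord,
    normalize_symbol,
)

EMERGING = "emerging"


def classify(
    fusion: AttributedFusion, cancer_type: str, matrix: ActionabilityMatrix
) -> str:
    """Approval status of one attributed fusion in one indication:
    ``approved`` / ``not_approved`` / ``emerging``."""
    driver = normalize_symbol(fusion.driver)
    if driver in matrix.emerging_drivers:
        return EMERGING
    if driver not in matrix.actionable_drivers:
        raise FusionValidationError(
            f"driver {driver} is neither actionable nor emerging"
        )
    return matrix.status_for(driver, cancer_type)


def stratify(
    attributed: Sequence[AttributedFusion],
    patients: Sequence[PatientRecord] | Mapping[str, str],
    matrix: ActionabilityMatrix,
) -> pd.DataFrame:
    """Count fusions by approval status x analyte category x driver.

    ``patients`` is either a sequence of :class:`PatientRecord` or a mapping
    ``patient_id -> cancer_type``; every attributed fusion must join to a
    cancer type. Returns a long-format frame with one row per fusion margin
    (columns ``driver, cancer_type, category, approval, count``); marginal
    sums are conserved (approved + not_approved = total actionable fusions).
    """
    if isinstance(patients, Mapping):
        ct_of = dict(patients)
    else:
        ct_of = {p.patient_id: p.cancer_type for p in patients}
    rows = []
    for f in attributed:
        if f.patient_id not in ct_of:
            raise FusionValidationError(
                f"attributed fusion for unknown patient {f.patient_id!r}"
            )
        ct = ct_of[f.patient_id]
        rows.append(
            {
                "driver": f.driver,
                "cancer_type": ct,
                "category": f.category.value,
                "approval": classify(f, ct, matrix),
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["driver", "cancer_type", "category", "approval", "count"]
        )
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["driver", "cancer_type", "category", "approval"], sort=True)
        .size()
        .rename("count")
        .reset_index()
    )
    return out


def approval_shares(strata: pd.DataFrame) -> pd.DataFrame:
    """Collapse a `stratify` table to counts and percentage shares per
    approval status (emerging drivers tallied separately from the
    approved/not_approved denominator)."""
    if strata.empty:
        return pd.DataFrame(columns=["approval", "count", "share_pct"])
    counts = strata.groupby("approval")["count"].sum()
    actionable_total = int(
        counts.reindex(["approved", "not_approved"]).fillna(0).sum()
    )
    rows = []
    for status, n in counts.items():
        denom = actionable_total if status in ("approved", "not_approved") else int(
            counts.get(EMERGING, 0)
        )
        rows.append(
            {
                "approval": status,
                "count": int(n),
                "share_pct": 100.0 * n / denom if denom else float("nan"),
            }
        )
    return pd.DataFrame(rows)
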