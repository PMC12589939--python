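"""Cohort selection and tumor-mutational-burden classification.

The study design restricts analysis to adult patients with metastatic or
stage IV solid tumors, tissue samples with at least 30% tumor purity, one
sample per patient (the one closest to but after the metastatic/stage IV
diagnosis), and excludes hematologic malignancies and patients with missing
or conflicting primary diagnoses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from typing import Mapping, Optional, Sequence

from .model import FusionValidationError, PatientRecord, Stage, Thresholds

#: Cancer-type labels treated as hematologic malignancies (excluded).
HEMATOLOGIC_TYPES = frozenset(
    {"leukemia", "lymphoma", "myeloma", "AML", "ALL", "CLL", "CML", "MDS"}
)

#: Audit reasons, in reporting order.
AUDIT_REASONS = (
    "retained",
    "not_metastatic_or_stage_iv",
    "missing_or_conflicting_diagnosis",
    "hematologic_malignancy",
    "no_sample_with_sufficient_purity",
    "no_sample_after_diagnosis",
)


@dataclass
class CohortAudit:
    """Per-reason exclusion tally; sums to the number of input patients."""

    counts: dict[str, int] = field(
        default_factory=lambda: {r: 0 for r in AUDIT_REASONS}
    )

    def total(self) -> int:
        return sum(self.counts.values())


def select_cohort(
    patients: Sequence[PatientRecord],
    samples: Mapping[str, Sequence[tuple[str, Optional[date], Optional[float]]]],
    thr: Thresholds = Thresholds(),
) -> tuple[list[tuple[str, str]], CohortAudit]:
    """Apply the cohort-selection rules.

    Parameters
    ----------
    patients
        One record per candidate patient.
    samples
        Mapping patient_id -> iterable of ``(sample_id, biopsy_date,
        tumor_purity_pct)``.
    thr
        Thresholds; only ``min_tumor_purity_pct`` is used here.

    Returns
    -------
    (eligible, audit)
        ``eligible`` holds at most one ``(patient_id, sample_id)`` per
        retained patient. ``audit`` counts every input patient exactly once.

    Notes
    -----
    Among samples with sufficient purity, the one with the smallest
    non-negative ``biopsy_date - metastatic_dx_date`` is chosen; samples
    preceding the diagnosis are never used. When the diagnosis date is
    missing but the patient is stage IV/metastatic, the earliest sample is
    used (diagnosis recency cannot be assessed, but eligibility can).
    """
    eligible: list[tuple[str, str]] = []
    audit = CohortAudit()
    for p in patients:
        if p.stage not in (Stage.IV, Stage.METASTATIC):
            audit.counts["not_metastatic_or_stage_iv"] += 1
            continue
        if p.cancer_type is None or p.conflicting_diagnosis:
            audit.counts["missing_or_conflicting_diagnosis"] += 1
            continue
        if p.cancer_type in HEMATOLOGIC_TYPES:
            audit.counts["hematologic_malignancy"] += 1
            continue
        cand = [
            (sid, bdate, purity)
            for sid, bdate, purity in samples.get(p.patient_id, ())
            if purity is not None and purity >= thr.min_tumor_purity_pct
        ]
        if not cand:
            audit.counts["no_sample_with_sufficient_purity"] += 1
            continue
        if p.metastatic_dx_date is None:
            # eligibility via stage alone; fall back to the earliest sample
            dated = [c for c in cand if c[1] is not None]
            chosen = min(dated, key=lambda c: c[1])[0] if dated else cand[0][0]
        else:
            after = [
                (bdate - p.metastatic_dx_date, sid)
                for sid, bdate, _ in cand
                if bdate is not None and bdate >= p.metastatic_dx_date
            ]
            if not after:
                audit.counts["no_sample_after_diagnosis"] += 1
                continue
            chosen = min(after)[1]
        eligible.append((p.patient_id, chosen))
        audit.counts["retained"] += 1
    return eligible, audit


def compute_tmb(n_nonsyn: int, panel_mb: float) -> float:
    """Tumor mutational burden: nonsynonymous mutations per megabase.

    ``n_nonsyn`` must already be restricted to nonsilent somatic coding
    variants with coverage > 100x and allelic fraction > 5% (an upstream
    contract; no read-level filtering happens here).
    """
    if panel_mb <= 0:
        raise FusionValidationError(f"panel size must be > 0 Mb, got {panel_mb}")
    if n_nonsyn < 0:
        raise FusionValidationError("mutation count must be >= 0")
    return n_nonsyn / panel_mb


TMB_LOW = "TMB_low"
TMB_HIGH = "TMB_high"
TMB_UNKNOWN = "TMB_unknown"


def classify_tmb(value: Optional[float], thr: Thresholds = Thresholds()) -> str:
    """``TMB_high`` iff value >= the cut (default 10 mut/Mb, boundary high);
    ``None`` maps to ``TMB_unknown``."""
    if value is None:
        return TMB_UNKNOWN
    return TMB_HIGH if value >= thr.tmb_high_cut else TMB_LOW


def patient_tmb_class(p: PatientRecord, thr: Thresholds = Thresholds()) -> str:
    """TMB class for a patient record (unknown when the count is missing)."""
    if p.n_nonsynonymous_mutations is None:
        return TMB_UNKNOWN
    return classify_tmb(compute_tmb(p.n_nonsynonymous_mutations, thr.panel_size_mb), thr)
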