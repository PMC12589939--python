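"""Cohort-level aggregation and statistical comparisons.

Builds stratified counts (per driver, per cancer type, combined/pan-cancer)
from attributed fusions, and exposes the study-style derived quantities:
prevalence, analyte breakdown (RNA-only / DNA-only / both shares), the
detection increase attributable to adding RNA sequencing
(RNA-only / DNA-detected), group comparisons (chi-square, Mann-Whitney),
the fusion-vs-expression random-intercept contrast, and the partner
distribution test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .lmm import fit_random_intercept
from .model import (
    AttributedFusion,
    Category,
    FusionValidationError,
    PatientRecord,
)

logger = logging.getLogger(__name__)

COMBINED = "combined"
PAN_CANCER = "pan-cancer"


@dataclass
class StratumCounts:
    """Counts for one (driver-or-combined, cancer-type-or-pan-cancer) cell.

    ``n_positive`` counts distinct fusion-positive patients; the per-category
    counts are fusion-level (a patient with two different drivers contributes
    two fusions), so ``n_rna_only + n_dna_only + n_both = n_fusions >=
    n_positive``.
    """

    n_total: int = 0
    n_positive: int = 0
    n_rna_only: int = 0
    n_dna_only: int = 0
    n_both: int = 0

    @property
    def n_fusions(self) -> int:
        return self.n_rna_only + self.n_dna_only + self.n_both


@dataclass
class CohortSummary:
    strata: dict[tuple[str, str], StratumCounts] = field(default_factory=dict)

    def get(self, driver: str = COMBINED, cancer_type: str = PAN_CANCER) -> StratumCounts:
        return self.strata.get((driver, cancer_type), StratumCounts())


def report_round(pct: float, kind: str = "prevalence") -> float:
    """Report-style rounding: percentages to 1 decimal, prevalences below
    0.2% to 2 decimals, detection increases to whole percent."""
    if kind == "increase":
        return round(pct)
    if kind == "prevalence" and pct < 0.2:
        return round(pct, 2)
    return round(pct, 1)


def summarize(
    attributed: Sequence[AttributedFusion],
    patients: Sequence[PatientRecord],
    min_type_size: Optional[int] = None,
) -> CohortSummary:
    """Aggregate attribution output over a cohort.

    Produces strata for every driver x {each cancer type, pan-cancer} plus
    ``combined`` x each cancer type and ``combined`` x pan-cancer. With
    ``min_type_size`` set (the figure-style convention is 500), cancer types
    with fewer patients are aggregated into an ``other`` type; totals are
    conserved.
    """
    ct_of = {p.patient_id: p.cancer_type for p in patients}
    type_counts: dict[str, int] = {}
    for p in patients:
        type_counts[p.cancer_type] = type_counts.get(p.cancer_type, 0) + 1

    def bucket(ct: str) -> str:
        if min_type_size is not None and type_counts.get(ct, 0) < min_type_size:
            return "other"
        return ct

    totals: dict[str, int] = {}
    for ct, n in type_counts.items():
        totals[bucket(ct)] = totals.get(bucket(ct), 0) + n
    n_all = sum(type_counts.values())

    summary = CohortSummary()

    def cell(driver: str, ct: str) -> StratumCounts:
        key = (driver, ct)
        if key not in summary.strata:
            n_total = n_all if ct == PAN_CANCER else totals.get(ct, 0)
            summary.strata[key] = StratumCounts(n_total=n_total)
        return summary.strata[key]

    # combined strata always exist, even with no attributed fusions
    cell(COMBINED, PAN_CANCER)
    for ct in totals:
        cell(COMBINED, ct)

    positive_patients: dict[tuple[str, str], set] = {}
    for f in attributed:
        if f.patient_id not in ct_of:
            raise FusionValidationError(
                f"attributed fusion for unknown patient {f.patient_id!r}"
            )
        ct = bucket(ct_of[f.patient_id])
        attr = {
            Category.RNA_ONLY: "n_rna_only",
            Category.DNA_ONLY: "n_dna_only",
            Category.BOTH: "n_both",
        }[f.category]
        for key in ((f.driver, ct), (f.driver, PAN_CANCER), (COMBINED, ct), (COMBINED, PAN_CANCER)):
            c = cell(*key)
            setattr(c, attr, getattr(c, attr) + 1)
            positive_patients.setdefault(key, set()).add(f.patient_id)
    for key, pts in positive_patients.items():
        summary.strata[key].n_positive = len(pts)
    return summary


def prevalence(
    summary: CohortSummary,
    driver: str = COMBINED,
    cancer_type: str = PAN_CANCER,
) -> Optional[float]:
    """Percent of patients in the stratum with a detected fusion
    (patient-level; unrounded). ``None`` when the stratum is empty."""
    c = summary.get(driver, cancer_type)
    if c.n_total == 0:
        return None
    return 100.0 * c.n_positive / c.n_total


def analyte_breakdown(
    summary: CohortSummary,
    driver: str = COMBINED,
    cancer_type: str = PAN_CANCER,
) -> Optional[tuple[float, float, float]]:
    """Fusion-level shares (pct RNA-only, DNA-only, both), summing to 100."""
    c = summary.get(driver, cancer_type)
    if c.n_fusions == 0:
        return None
    n = c.n_fusions
    return (
        100.0 * c.n_rna_only / n,
        100.0 * c.n_dna_only / n,
        100.0 * c.n_both / n,
    )


def detection_increase(
    summary: CohortSummary,
    driver: str = COMBINED,
    cancer_type: str = PAN_CANCER,
) -> Optional[float]:
    """Percent increase in detected fusions from adding RNA sequencing,
    relative to DNA alone: 100 * RNA_only / (DNA_only + both)."""
    c = summary.get(driver, cancer_type)
    dna_detected = c.n_dna_only + c.n_both
    if dna_detected == 0:
        return None
    return 100.0 * c.n_rna_only / dna_detected


def compare_groups(
    data,
    kind: str,
    *,
    labels=None,
    correction: bool = False,
) -> tuple[float, float]:
    """Two-group comparison used throughout the cohort analysis.

    ``kind='chi2'``: ``data`` is a contingency table (rows = groups);
    Pearson chi-square without continuity correction by default.
    ``kind='mannwhitney'``: ``data`` is a sequence of values and ``labels``
    the two group labels; two-sided Mann-Whitney U.
    """
    if kind == "chi2":
        table = np.asarray(data)
        if (table < 0).any():
            raise FusionValidationError("contingency cells must be non-negative")
        row_sums, col_sums = table.sum(axis=1), table.sum(axis=0)
        if (row_sums == 0).any():
            raise FusionValidationError(
                f"degenerate table: zero row margin at index {int(np.argmin(row_sums))}"
            )
        if (col_sums == 0).any():
            raise FusionValidationError(
                f"degenerate table: zero column margin at index {int(np.argmin(col_sums))}"
            )
        res = sps.chi2_contingency(table, correction=correction)
        return float(res.statistic), float(res.pvalue)
    if kind == "mannwhitney":
        values = np.asarray(data, dtype=float)
        labels = np.asarray(labels)
        uniq = np.unique(labels)
        if len(uniq) != 2:
            raise FusionValidationError("mannwhitney needs exactly 2 groups")
        a, b = values[labels == uniq[0]], values[labels == uniq[1]]
        res = sps.mannwhitneyu(a, b, alternative="two-sided")
        return float(res.statistic), float(res.pvalue)
    raise FusionValidationError(f"unknown test kind {kind!r}")


@dataclass
class ExpressionModelResult:
    """Fixed effect of fusion status on TPM from the random-intercept model
    (cancer type as the random effect), with Satterthwaite df, plus per-type
    Mann-Whitney p-values."""

    fixed_effect: float
    fixed_effect_se: float
    satterthwaite_df: float
    p_value: float
    per_type_mannwhitney: dict[str, float]
    sigma2: float
    tau2: float


def expression_contrast(
    tpm: Sequence[float],
    fusion_positive: Sequence[bool],
    cancer_types: Sequence[str],
    log_transform: bool = False,
) -> ExpressionModelResult:
    """Contrast expression between fusion-positive and -negative patients.

    Per cancer type: two-sided Mann-Whitney U (types with a single status
    are dropped with a warning). Overall: random-intercept linear model of
    TPM on fusion status with a per-cancer-type intercept, REML fit,
    Satterthwaite df for the fusion-status effect. TPM is modeled on the
    natural scale by default; ``log_transform`` applies log1p first.
    """
    y = np.asarray(tpm, dtype=float)
    if log_transform:
        y = np.log1p(y)
    status = np.asarray(fusion_positive, dtype=bool)
    ct = np.asarray(cancer_types)

    per_type: dict[str, float] = {}
    usable_types = []
    for t in pd.unique(ct):
        m = ct == t
        if status[m].all() or (~status[m]).all():
            warnings.warn(
                f"cancer type {t!r} has a single fusion status; "
                "dropped from per-type tests",
                stacklevel=2,
            )
            continue
        usable_types.append(t)
        _, p = compare_groups(y[m], "mannwhitney", labels=status[m])
        per_type[str(t)] = p

    if len(pd.unique(ct)) < 2:
        raise FusionValidationError(
            "mixed model needs >= 2 cancer types; only per-type tests are "
            "meaningful for a single type"
        )
    X = np.column_stack([np.ones(len(y)), status.astype(float)])
    fit = fit_random_intercept(y, X, ct)
    return ExpressionModelResult(
        fixed_effect=float(fit.beta[1]),
        fixed_effect_se=float(fit.se[1]),
        satterthwaite_df=float(fit.df[1]),
        p_value=float(fit.pvalues[1]),
        per_type_mannwhitney=per_type,
        sigma2=fit.sigma2,
        tau2=fit.tau2,
    )


def partner_distribution(
    partners: Sequence[str],
    groups: Sequence[str],
    patient_ids: Optional[Sequence[str]] = None,
    collapse_max_patients: int = 1,
) -> tuple[pd.DataFrame, Optional[float], Optional[float]]:
    """Partner-by-group contingency table with rare partners collapsed.

    Partners observed in at most ``collapse_max_patients`` distinct patients
    (over the whole input) are pooled into ``other`` before a chi-square
    test of partner composition across groups (e.g. approved vs
    not_approved indications). Returns (table, statistic, p); the test is
    skipped (``None, None``) with a warning when fewer than two partner
    categories or groups remain.
    """
    partners = np.asarray(partners, dtype=object)
    groups = np.asarray(groups, dtype=object)
    if patient_ids is None:
        patient_ids = np.arange(len(partners))
    df = pd.DataFrame(
        {"partner": partners, "group": groups, "patient_id": list(patient_ids)}
    )
    n_patients = df.groupby("partner")["patient_id"].nunique()
    rare = set(n_patients[n_patients <= collapse_max_patients].index)
    df["partner"] = df["partner"].map(lambda s: "other" if s in rare else s)
    table = pd.crosstab(df["partner"], df["group"])
    if table.shape[0] < 2 or table.shape[1] < 2:
        warnings.warn(
            "fewer than two partner or group categories after collapsing; "
            "chi-square test skipped",
            stacklevel=2,
        )
        return table, None, None
    stat, p = compare_groups(table.to_numpy(), "chi2")
    return table, stat, p
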