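"""Per patient x driver analyte attribution — the pipeline's core decision.

Rules
-----
* An RNA call is positive when its total supporting reads exceed the limit
  of blank (default LOB 3, so >= 4 reads).
* A DNA breakend is positive when its supporting reads are >= 15 *and* an
  RNA call with the same unordered, alias-normalized gene pair passed the
  LOB, or >= 35 regardless of RNA support.
* A driver with any positive RNA call and any positive DNA call is
  ``both`` on the per-patient level, regardless of whether partners or
  breakpoints agree. Positive in one analyte only gives ``RNA_only`` /
  ``DNA_only``; drivers with no positive call are absent from the output.
* When several RNA partners are in play, the partner whose breakpoints
  keep the driver's functional domain intact and has the highest support is
  reported; for DNA, simply the highest-support partner. Ties break to the
  lexicographically smallest partner symbol.
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional, Sequence

from .model import (
    Analyte,
    AttributedFusion,
    Category,
    DomainTable,
    FusionEvidence,
    FusionValidationError,
    Thresholds,
    normalize_symbol,
)

logger = logging.getLogger(__name__)


def rna_positive(e: FusionEvidence, thr: Thresholds = Thresholds()) -> bool:
    """True iff an RNA call clears the limit of blank (support >= LOB + 1)."""
    if e.analyte is not Analyte.RNA:
        raise FusionValidationError("rna_positive expects RNA evidence")
    return e.read_support >= thr.rna_call_min_reads


def partner_match(
    dna_call: FusionEvidence,
    rna_calls: Iterable[FusionEvidence],
    thr: Thresholds = Thresholds(),
) -> bool:
    """True iff some LOB-passing RNA call shares the DNA call's unordered,
    alias-normalized gene pair. Sub-LOB RNA evidence never counts as a
    detected match."""
    if dna_call.analyte is not Analyte.DNA:
        raise FusionValidationError("partner_match expects a DNA call")
    pair = dna_call.gene_pair
    return any(
        r.gene_pair == pair and rna_positive(r, thr) for r in rna_calls
    )


def dna_positive(
    dna_call: FusionEvidence,
    rna_calls: Iterable[FusionEvidence],
    thr: Thresholds = Thresholds(),
) -> bool:
    """True iff support >= 35, or support >= 15 with a matching RNA partner."""
    if dna_call.analyte is not Analyte.DNA:
        raise FusionValidationError("dna_positive expects a DNA call")
    if dna_call.read_support >= thr.dna_min_without_match:
        return True
    return dna_call.read_support >= thr.dna_min_with_rna_match and partner_match(
        dna_call, rna_calls, thr
    )


def domain_intact(
    call: FusionEvidence, driver: str, domains: DomainTable
) -> bool:
    """Whether the retained driver segment contains the whole functional
    domain.

    With the domain on the retained 5' side, the segment up to the 5'
    breakpoint is kept, so the breakpoint must lie at or beyond the domain
    end; with a retained 3' side, the segment from the 3' breakpoint onward
    is kept, so the breakpoint must lie at or before the domain start. A
    breakpoint exactly on the boundary counts as intact. A driver found on
    the opposite side from its retained side loses the domain. Drivers with
    no table entry are treated as intact (nothing to check against).
    """
    spec = domains.get(driver)
    if spec is None:
        return True
    side, bp = call.driver_breakpoint(driver)
    if side != spec.retained_side:
        return False
    if side == "5p":
        return bp.pos >= spec.domain_end
    return bp.pos <= spec.domain_start


def select_rna_partner(
    rna_calls: Sequence[FusionEvidence],
    driver: str,
    domains: DomainTable,
) -> tuple[str, int]:
    """Pick the reported RNA partner among LOB-passing calls for one driver.

    Candidates keeping the driver's domain intact are preferred; among those
    the highest support wins, ties breaking to the lexicographically
    smallest partner symbol. If no candidate keeps the domain intact the
    selection falls back to all candidates (logged).
    """
    if not rna_calls:
        raise FusionValidationError("select_rna_partner needs >= 1 candidate")
    driver = normalize_symbol(driver)
    intact = [c for c in rna_calls if domain_intact(c, driver, domains)]
    pool = intact or list(rna_calls)
    if not intact:
        logger.debug(
            "no RNA candidate keeps the %s domain intact; falling back to "
            "highest support over all candidates", driver,
        )
    best = min(pool, key=lambda c: (-c.read_support, c.partner_of(driver)))
    return best.partner_of(driver), best.read_support


def select_dna_partner(
    dna_calls: Sequence[FusionEvidence], driver: str
) -> tuple[str, int]:
    """Highest-support DNA partner; ties break lexicographically."""
    if not dna_calls:
        raise FusionValidationError("select_dna_partner needs >= 1 candidate")
    driver = normalize_symbol(driver)
    best = min(dna_calls, key=lambda c: (-c.read_support, c.partner_of(driver)))
    return best.partner_of(driver), best.read_support


def attribute(
    patient_evidence: Sequence[FusionEvidence],
    drivers: Iterable[str],
    thr: Thresholds = Thresholds(),
    domains: Optional[DomainTable] = None,
) -> list[AttributedFusion]:
    """Attribute every driver gene for one patient's pooled evidence.

    Returns at most one :class:`AttributedFusion` per driver, sorted by
    driver symbol. Evidence must belong to a single patient.
    """
    if domains is None:
        domains = DomainTable.default()
    pids = {e.patient_id for e in patient_evidence}
    if len(pids) > 1:
        raise FusionValidationError(
            f"attribute() expects evidence for one patient, got {sorted(pids)}"
        )
    driver_set = {normalize_symbol(d) for d in drivers}
    rna_all = [e for e in patient_evidence if e.analyte is Analyte.RNA]
    dna_all = [e for e in patient_evidence if e.analyte is Analyte.DNA]

    out: list[AttributedFusion] = []
    for driver in sorted(driver_set):
        rna = [e for e in rna_all if driver in e.gene_pair]
        dna = [e for e in dna_all if driver in e.gene_pair]
        rna_pos = [e for e in rna if rna_positive(e, thr)]
        # the matching RNA pool is the whole patient's RNA evidence: a DNA
        # call's pair is matched against RNA calls of the same pair, which
        # necessarily involve the same driver
        dna_pos = [e for e in dna if dna_positive(e, rna_all, thr)]
        if not rna_pos and not dna_pos:
            continue
        if rna_pos and dna_pos:
            category = Category.BOTH
        elif rna_pos:
            category = Category.RNA_ONLY
        else:
            category = Category.DNA_ONLY
        rna_partner = rna_support = dna_partner = dna_support = None
        if rna_pos:
            rna_partner, rna_support = select_rna_partner(rna_pos, driver, domains)
        if dna_pos:
            dna_partner, dna_support = select_dna_partner(dna_pos, driver)
        out.append(
            AttributedFusion(
                patient_id=next(iter(pids)) if pids else "",
                driver=driver,
                category=category,
                rna_partner=rna_partner,
                dna_partner=dna_partner,
                rna_support=rna_support,
                dna_support=dna_support,
            )
        )
    return out


def attribute_cohort(
    evidence: Sequence[FusionEvidence],
    drivers: Iterable[str],
    thr: Thresholds = Thresholds(),
    domains: Optional[DomainTable] = None,
) -> list[AttributedFusion]:
    """Group pooled evidence by patient and attribute each patient."""
    if domains is None:
        domains = DomainTable.default()
    by_patient: dict[str, list[FusionEvidence]] = {}
    for e in evidence:
        by_patient.setdefault(e.patient_id, []).append(e)
    out: list[AttributedFusion] = []
    for pid in sorted(by_patient):
        out.extend(attribute(by_patient[pid], drivers, thr, domains))
    return out
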