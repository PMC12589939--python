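"""Domain types shared by every stage of the dual-analyte fusion pipeline.

The pipeline reasons about *fusion evidence* (one candidate call in one
analyte), *patients* (clinical covariates needed for cohort selection and
stratification) and a small amount of reference data: calling thresholds,
an FDA-approval matrix over (driver gene, cancer type), and per-driver
functional-domain intervals used for partner selection.

Gene symbols are uppercased and alias-normalized on construction (e.g. the
legacy symbol ``ACPP`` and the current ``ACP3`` map to one symbol) so that
cross-analyte matching never fails on nomenclature.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from datetime import date
from enum import Enum
from importlib import resources
from typing import Iterable, Mapping, Optional


class FusionFormatError(ValueError):
    """A file does not conform to the expected dialect (e.g. missing column)."""


class FusionValidationError(ValueError):
    """Well-formed input carries values that violate a domain invariant."""


class Analyte(str, Enum):
    RNA = "RNA"
    DNA = "DNA"


class Category(str, Enum):
    """Per patient x driver analyte attribution of a detected fusion."""

    RNA_ONLY = "RNA_only"
    DNA_ONLY = "DNA_only"
    BOTH = "both"


class Stage(str, Enum):
    EARLY = "I-III"
    IV = "IV"
    METASTATIC = "metastatic"
    UNKNOWN = "unknown"


def _load_csv(name: str) -> list[dict[str, str]]:
    ref = resources.files("dualfusion.data").joinpath(name)
    with ref.open("r", encoding="utf-8") as fh:
        return list(csv.DictReader(fh))


def _load_aliases() -> dict[str, str]:
    return {
        row["alias"].strip().upper(): row["symbol"].strip().upper()
        for row in _load_csv("gene_aliases.csv")
    }


_ALIASES = _load_aliases()


def normalize_symbol(symbol: str) -> str:
    """Uppercase a gene symbol and map known aliases to one canonical symbol.

    Raises
    ------
    FusionValidationError
        If the symbol is empty or whitespace.
    """
    s = str(symbol).strip().upper()
    if not s:
        raise FusionValidationError("gene symbol must be non-empty")
    return _ALIASES.get(s, s)


@dataclass(frozen=True)
class Breakpoint:
    """Genomic breakpoint: chromosome label, 1-based position, strand."""

    chrom: str
    pos: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if int(self.pos) < 1:
            raise FusionValidationError(
                f"breakpoint position must be >= 1, got {self.pos}"
            )
        if self.strand not in ("+", "-"):
            raise FusionValidationError(f"strand must be + or -, got {self.strand!r}")


@dataclass(frozen=True)
class FusionEvidence:
    """One candidate fusion call in one analyte for one sample.

    ``read_support`` is the total supporting read count: for RNA calls the
    sum of junction and spanning reads, for DNA calls the supporting-read
    count of the paired breakend.
    """

    patient_id: str
    sample_id: str
    analyte: Analyte
    gene_5p: str
    gene_3p: str
    breakpoint_5p: Breakpoint
    breakpoint_3p: Breakpoint
    read_support: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "analyte", Analyte(self.analyte))
        object.__setattr__(self, "gene_5p", normalize_symbol(self.gene_5p))
        object.__setattr__(self, "gene_3p", normalize_symbol(self.gene_3p))
        if int(self.read_support) < 0:
            raise FusionValidationError(
                f"read_support must be >= 0, got {self.read_support}"
            )
        object.__setattr__(self, "read_support", int(self.read_support))

    @property
    def gene_pair(self) -> tuple[str, str]:
        """Unordered, alias-normalized gene pair (sorted tuple)."""
        return tuple(sorted((self.gene_5p, self.gene_3p)))  # type: ignore[return-value]

    def partner_of(self, driver: str) -> str:
        """The non-driver gene of the pair (the other driver if both are drivers)."""
        driver = normalize_symbol(driver)
        if self.gene_5p == driver:
            return self.gene_3p
        if self.gene_3p == driver:
            return self.gene_5p
        raise FusionValidationError(f"{driver} is not part of {self.gene_pair}")

    def driver_breakpoint(self, driver: str) -> tuple[str, Breakpoint]:
        """Return which side (``5p``/``3p``) the driver sits on and its breakpoint."""
        driver = normalize_symbol(driver)
        if self.gene_5p == driver:
            return "5p", self.breakpoint_5p
        if self.gene_3p == driver:
            return "3p", self.breakpoint_3p
        raise FusionValidationError(f"{driver} is not part of {self.gene_pair}")


@dataclass
class PatientRecord:
    """Clinical covariates for one patient, as used by cohort selection,
    TMB stratification and the expression contrast."""

    patient_id: str
    cancer_type: Optional[str]
    stage: Stage = Stage.UNKNOWN
    age_at_biopsy: Optional[float] = None
    gender: Optional[str] = None
    race: Optional[str] = None
    smoking_status: Optional[str] = None
    tumor_purity: Optional[float] = None
    biopsy_date: Optional[date] = None
    metastatic_dx_date: Optional[date] = None
    n_nonsynonymous_mutations: Optional[int] = None
    expression_tpm: Optional[dict[str, float]] = None
    conflicting_diagnosis: bool = False

    def __post_init__(self) -> None:
        self.stage = Stage(self.stage)
        if self.tumor_purity is not None and not (0 <= self.tumor_purity <= 100):
            raise FusionValidationError(
                f"tumor_purity must be in [0, 100], got {self.tumor_purity}"
            )
        if self.expression_tpm is not None:
            bad = {g: v for g, v in self.expression_tpm.items() if v < 0}
            if bad:
                raise FusionValidationError(f"TPM values must be >= 0: {bad}")


@dataclass(frozen=True)
class Thresholds:
    """Calling thresholds and cohort cutoffs.

    Defaults encode the validated assay behaviour: the limit of blank is 3
    total supporting reads, so an RNA call needs >= 4 reads; a DNA breakend
    needs >= 15 supporting reads when an RNA call with the same gene pair
    passed the LOB, and >= 35 otherwise.
    """

    lob_reads: int = 3
    rna_call_min_reads: int = 4
    dna_min_with_rna_match: int = 15
    dna_min_without_match: int = 35
    min_tumor_purity_pct: float = 30.0
    tmb_high_cut: float = 10.0
    tmb_min_coverage: float = 100.0
    tmb_min_vaf_pct: float = 5.0
    panel_size_mb: float = 1.0
    ci_confidence: float = 0.95

    def __post_init__(self) -> None:
        if self.rna_call_min_reads != self.lob_reads + 1:
            raise FusionValidationError(
                "rna_call_min_reads must equal lob_reads + 1 "
                f"({self.rna_call_min_reads} != {self.lob_reads} + 1)"
            )
        if self.dna_min_with_rna_match > self.dna_min_without_match:
            raise FusionValidationError(
                "dna_min_with_rna_match must be <= dna_min_without_match"
            )
        for name in (
            "rna_call_min_reads",
            "dna_min_with_rna_match",
            "dna_min_without_match",
            "min_tumor_purity_pct",
            "tmb_high_cut",
            "tmb_min_coverage",
            "tmb_min_vaf_pct",
            "panel_size_mb",
            "ci_confidence",
        ):
            if getattr(self, name) <= 0:
                raise FusionValidationError(f"{name} must be > 0")


PAN_CANCER_DRIVERS = frozenset({"NTRK1", "NTRK2", "NTRK3", "RET"})
ACTIONABLE_DRIVERS = frozenset(
    {"ALK", "RET", "ROS1", "NTRK1", "NTRK2", "NTRK3", "FGFR2", "FGFR3", "NRG1"}
)
EMERGING_DRIVERS = frozenset({"BRAF", "EGFR"})


class ActionabilityMatrix:
    """FDA-approval status per (driver gene, cancer type).

    Pan-cancer drivers (RET, NTRK1/2/3) are approved in every indication.
    Emerging drivers (BRAF, EGFR) have no approval anywhere. Remaining
    actionable drivers are approved only where the matrix says so; unlisted
    pairs default to ``not_approved``.
    """

    APPROVED = "approved"
    NOT_APPROVED = "not_approved"

    def __init__(
        self,
        status: Mapping[tuple[str, str], str] | None = None,
        pan_cancer_drivers: Iterable[str] = PAN_CANCER_DRIVERS,
        actionable_drivers: Iterable[str] = ACTIONABLE_DRIVERS,
        emerging_drivers: Iterable[str] = EMERGING_DRIVERS,
    ) -> None:
        self.pan_cancer_drivers = frozenset(normalize_symbol(g) for g in pan_cancer_drivers)
        self.actionable_drivers = frozenset(normalize_symbol(g) for g in actionable_drivers)
        self.emerging_drivers = frozenset(normalize_symbol(g) for g in emerging_drivers)
        if self.actionable_drivers & self.emerging_drivers:
            raise FusionValidationError(
                "actionable and emerging driver sets must be disjoint"
            )
        if not self.pan_cancer_drivers <= self.actionable_drivers:
            raise FusionValidationError("pan-cancer drivers must be actionable")
        self._status: dict[tuple[str, str], str] = {}
        for (driver, cancer_type), st in (status or {}).items():
            driver = normalize_symbol(driver)
            if st not in (self.APPROVED, self.NOT_APPROVED):
                raise FusionValidationError(f"unknown status {st!r}")
            if driver in self.pan_cancer_drivers and st != self.APPROVED:
                raise FusionValidationError(
                    f"pan-cancer driver {driver} cannot be not_approved "
                    f"(listed for {cancer_type})"
                )
            if driver in self.emerging_drivers and st == self.APPROVED:
                raise FusionValidationError(
                    f"emerging driver {driver} cannot be approved"
                )
            self._status[(driver, cancer_type)] = st

    @classmethod
    def default(cls) -> "ActionabilityMatrix":
        """The bundled approval grid (editable data, not code)."""
        status = {
            (row["driver"], row["cancer_type"]): row["status"]
            for row in _load_csv("actionability_matrix.csv")
        }
        return cls(status=status)

    def status_for(self, driver: str, cancer_type: str) -> str:
        driver = normalize_symbol(driver)
        if driver in self.pan_cancer_drivers:
            return self.APPROVED
        if driver in self.emerging_drivers:
            return self.NOT_APPROVED
        return self._status.get((driver, cancer_type), self.NOT_APPROVED)

    @property
    def all_drivers(self) -> frozenset[str]:
        return self.actionable_drivers | self.emerging_drivers


@dataclass(frozen=True)
class DomainSpec:
    """Functional-domain interval for a driver, on a named contig/transcript.

    ``retained_side`` says which side of the chimera must retain the driver
    for the fusion product to keep the domain (kinase domains of ALK/RET/
    ROS1/NTRK/BRAF fusions sit 3', FGFR2/3 and EGFR fusion products retain
    the 5' driver segment).
    """

    retained_side: str  # "5p" or "3p"
    domain_start: int
    domain_end: int
    chrom: str = "chr1"

    def __post_init__(self) -> None:
        if self.retained_side not in ("5p", "3p"):
            raise FusionValidationError("retained_side must be '5p' or '3p'")
        if not (1 <= self.domain_start <= self.domain_end):
            raise FusionValidationError("need 1 <= domain_start <= domain_end")


class DomainTable:
    """Mapping driver gene -> DomainSpec used for RNA partner selection."""

    def __init__(self, specs: Mapping[str, DomainSpec]):
        self._specs = {normalize_symbol(g): s for g, s in specs.items()}

    @classmethod
    def default(cls) -> "DomainTable":
        """Bundled table with illustrative (synthetic) coordinates for the
        eleven drivers; real deployments should override it with transcript
        annotation."""
        specs = {
            row["driver"]: DomainSpec(
                retained_side=row["retained_side"],
                domain_start=int(row["domain_start"]),
                domain_end=int(row["domain_end"]),
                chrom=row["chrom"],
            )
            for row in _load_csv("domains_illustrative.csv")
        }
        return cls(specs)

    def get(self, driver: str) -> Optional[DomainSpec]:
        return self._specs.get(normalize_symbol(driver))

    def __contains__(self, driver: str) -> bool:
        return normalize_symbol(driver) in self._specs

    def __iter__(self):
        return iter(self._specs)

    def __len__(self) -> int:
        return len(self._specs)


@dataclass(frozen=True)
class AttributedFusion:
    """Per patient x driver verdict with reconciled partners."""

    patient_id: str
    driver: str
    category: Category
    rna_partner: Optional[str] = None
    dna_partner: Optional[str] = None
    rna_support: Optional[int] = None
    dna_support: Optional[int] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "driver", normalize_symbol(self.driver))
        object.__setattr__(self, "category", Category(self.category))


@dataclass(frozen=True)
class BlankMeasurement:
    """One replicate run of a fusion-negative (blank) sample."""

    sample_id: str
    reagent_lot: str
    replicate: int
    read_support: int

    def __post_init__(self) -> None:
        if int(self.read_support) < 0:
            raise FusionValidationError("blank read_support must be >= 0")


@dataclass(frozen=True)
class ConcordanceResult:
    """Agreement of the assay against an orthogonal truth set."""

    tp: int
    fp: int
    fn: int
    tn: int
    ppa: Optional[float]
    npa: Optional[float]
    ppa_ci: Optional[tuple[float, float]]
    npa_ci: Optional[tuple[float, float]]

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise FusionValidationError(f"{name} must be >= 0")
        if self.ppa is not None and self.ppa_ci is not None:
            lo, hi = self.ppa_ci
            if not (lo <= self.ppa <= hi):
                raise FusionValidationError("PPA outside its own CI")
        if self.npa is not None and self.npa_ci is not None:
            lo, hi = self.npa_ci
            if not (lo <= self.npa <= hi):
                raise FusionValidationError("NPA outside its own CI")

    @property
    def universe_size(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def load_partner_table() -> dict[str, list[tuple[str, str]]]:
    """Bundled per-driver fusion-partner symbols (with chromosome labels),
    used by the synthetic generator to draw realistic partner categories."""
    table: dict[str, list[tuple[str, str]]] = {}
    for row in _load_csv("fusion_partners.csv"):
        table.setdefault(normalize_symbol(row["driver"]), []).append(
            (normalize_symbol(row["partner"]), row["chrom"])
        )
    return table
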