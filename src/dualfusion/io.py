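"""Readers and writers for the file dialects the pipeline touches.

* RNA fusion calls: TSV with one row per candidate call; total supporting
  reads are ``junction_reads + spanning_frags``.
* DNA structural variants: VCF 4.2 breakend (BND) pairs carrying gene
  annotations in INFO (``GENEA``/``GENEB``) and supporting reads in ``SR``;
  or a TSV mirror of the RNA dialect with a single ``read_support`` column.
* Actionability matrix and domain table: small CSVs.
* Cohort metadata: CSV, one row per patient.

All coordinates are 1-based inclusive (VCF convention).
"""

from __future__ import annotations

import csv
import json
import logging
from datetime import date
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import pysam

from .model import (
    ActionabilityMatrix,
    Analyte,
    AttributedFusion,
    Breakpoint,
    Category,
    DomainSpec,
    DomainTable,
    FusionEvidence,
    FusionFormatError,
    FusionValidationError,
    PatientRecord,
    Stage,
)

logger = logging.getLogger(__name__)

RNA_TSV_COLUMNS = [
    "patient_id",
    "sample_id",
    "gene_5p",
    "gene_3p",
    "chrom_5p",
    "pos_5p",
    "strand_5p",
    "chrom_3p",
    "pos_3p",
    "strand_3p",
    "junction_reads",
    "spanning_frags",
]

DNA_TSV_COLUMNS = RNA_TSV_COLUMNS[:10] + ["read_support"]


def _require_columns(df: pd.DataFrame, columns: Sequence[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise FusionFormatError(f"{path}: missing mandatory column(s) {missing}")


def read_rna_fusions(path) -> list[FusionEvidence]:
    """Read RNA fusion calls from TSV; ``read_support`` is junction + spanning.

    Row order is preserved. A missing mandatory column raises
    :class:`FusionFormatError`; a negative count raises
    :class:`FusionValidationError` naming the offending row.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, RNA_TSV_COLUMNS, path)
    out: list[FusionEvidence] = []
    for i, row in enumerate(df.itertuples(index=False)):
        junction, spanning = int(row.junction_reads), int(row.spanning_frags)
        if junction < 0 or spanning < 0:
            raise FusionValidationError(
                f"{path}: negative read count at data row {i + 1} "
                f"(junction={junction}, spanning={spanning})"
            )
        try:
            out.append(
                FusionEvidence(
                    patient_id=row.patient_id,
                    sample_id=row.sample_id,
                    analyte=Analyte.RNA,
                    gene_5p=row.gene_5p,
                    gene_3p=row.gene_3p,
                    breakpoint_5p=Breakpoint(row.chrom_5p, int(row.pos_5p), row.strand_5p),
                    breakpoint_3p=Breakpoint(row.chrom_3p, int(row.pos_3p), row.strand_3p),
                    read_support=junction + spanning,
                )
            )
        except FusionValidationError as exc:
            raise FusionValidationError(f"{path}: data row {i + 1}: {exc}") from exc
    return out


def write_rna_fusions(evidence: Sequence[FusionEvidence], path) -> None:
    """Write RNA calls to the TSV dialect; support is split as
    junction = read_support, spanning = 0 (the decomposition is not retained
    in memory and only the total is meaningful downstream)."""
    rows = []
    for e in evidence:
        if e.analyte is not Analyte.RNA:
            raise FusionValidationError("write_rna_fusions expects RNA evidence")
        rows.append(
            {
                "patient_id": e.patient_id,
                "sample_id": e.sample_id,
                "gene_5p": e.gene_5p,
                "gene_3p": e.gene_3p,
                "chrom_5p": e.breakpoint_5p.chrom,
                "pos_5p": e.breakpoint_5p.pos,
                "strand_5p": e.breakpoint_5p.strand,
                "chrom_3p": e.breakpoint_3p.chrom,
                "pos_3p": e.breakpoint_3p.pos,
                "strand_3p": e.breakpoint_3p.strand,
                "junction_reads": e.read_support,
                "spanning_frags": 0,
            }
        )
    pd.DataFrame(rows, columns=RNA_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def read_dna_svs(path) -> list[FusionEvidence]:
    """Read DNA structural-variant calls.

    ``.vcf`` paths are parsed as VCF 4.2 BND records: mates are paired via
    ``MATEID`` and merged into one :class:`FusionEvidence` per event, taking
    the gene pair from ``GENEA``/``GENEB`` and support from ``SR``. Unmated
    or unannotated breakends are dropped with a logged warning. Any other
    extension is read as a TSV mirror of the RNA dialect with a
    ``read_support`` column.
    """
    path = Path(path)
    if path.suffix.lower() == ".vcf":
        return _read_dna_vcf(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, DNA_TSV_COLUMNS, path)
    out = []
    for i, row in enumerate(df.itertuples(index=False)):
        support = int(row.read_support)
        if support < 0:
            raise FusionValidationError(
                f"{path}: negative read_support at data row {i + 1}"
            )
        out.append(
            FusionEvidence(
                patient_id=row.patient_id,
                sample_id=row.sample_id,
                analyte=Analyte.DNA,
                gene_5p=row.gene_5p,
                gene_3p=row.gene_3p,
                breakpoint_5p=Breakpoint(row.chrom_5p, int(row.pos_5p), row.strand_5p),
                breakpoint_3p=Breakpoint(row.chrom_3p, int(row.pos_3p), row.strand_3p),
                read_support=support,
            )
        )
    return out


def _read_dna_vcf(path: Path) -> list[FusionEvidence]:
    try:
        vcf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise FusionFormatError(f"{path}: unparseable VCF: {exc}") from exc
    records = {}
    order = []
    with vcf:
        for rec in vcf.fetch() if vcf.index is not None else vcf:
            if rec.info.get("SVTYPE") != "BND":
                continue
            records[rec.id] = rec
            order.append(rec.id)

    def info_str(rec, key):
        try:
            v = rec.info.get(key)
        except (KeyError, ValueError):  # key absent from the header
            return None
        if isinstance(v, tuple):
            v = v[0]
        return v

    out: list[FusionEvidence] = []
    seen: set[str] = set()
    for rid in order:
        if rid in seen:
            continue
        rec = records[rid]
        mate_id = info_str(rec, "MATEID")
        mate = records.get(mate_id)
        if mate is None:
            logger.warning("%s: BND %s has no mate %s; dropped", path, rid, mate_id)
            seen.add(rid)
            continue
        seen.update((rid, mate_id))
        gene_a, gene_b = info_str(rec, "GENEA"), info_str(rec, "GENEB")
        if not gene_a or not gene_b:
            logger.warning("%s: BND pair %s/%s lacks gene annotation; dropped",
                           path, rid, mate_id)
            continue
        support = rec.info.get("SR")
        if isinstance(support, tuple):
            support = support[0]
        out.append(
            FusionEvidence(
                patient_id=info_str(rec, "PATIENT"),
                sample_id=info_str(rec, "SAMPLE"),
                analyte=Analyte.DNA,
                gene_5p=gene_a,
                gene_3p=gene_b,
                breakpoint_5p=Breakpoint(
                    rec.chrom, rec.pos, info_str(rec, "STR5") or "+"
                ),
                breakpoint_3p=Breakpoint(
                    mate.chrom, mate.pos, info_str(rec, "STR3") or "+"
                ),
                read_support=int(support),
            )
        )
    return out


_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">
##INFO=<ID=MATEID,Number=1,Type=String,Description="ID of mate breakend">
##INFO=<ID=GENEA,Number=1,Type=String,Description="5-prime gene of the fusion">
##INFO=<ID=GENEB,Number=1,Type=String,Description="3-prime gene of the fusion">
##INFO=<ID=SR,Number=1,Type=Integer,Description="Supporting read count">
##INFO=<ID=PATIENT,Number=1,Type=String,Description="Patient identifier">
##INFO=<ID=SAMPLE,Number=1,Type=String,Description="Sample identifier">
##INFO=<ID=STR5,Number=1,Type=String,Description="Strand of the 5-prime breakpoint">
##INFO=<ID=STR3,Number=1,Type=String,Description="Strand of the 3-prime breakpoint">
"""


def write_dna_svs(evidence: Sequence[FusionEvidence], path) -> None:
    """Serialize DNA calls as paired VCF 4.2 BND records (two lines per event)."""
    chroms = sorted(
        {e.breakpoint_5p.chrom for e in evidence}
        | {e.breakpoint_3p.chrom for e in evidence}
    )
    lines = [_VCF_HEADER]
    for c in chroms:
        lines.append(f"##contig=<ID={c},length=400000000>\n")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
    for i, e in enumerate(evidence):
        if e.analyte is not Analyte.DNA:
            raise FusionValidationError("write_dna_svs expects DNA evidence")
        ida, idb = f"bnd_{i:06d}_a", f"bnd_{i:06d}_b"
        b5, b3 = e.breakpoint_5p, e.breakpoint_3p
        common = (
            f"GENEA={e.gene_5p};GENEB={e.gene_3p};SR={e.read_support};"
            f"PATIENT={e.patient_id};SAMPLE={e.sample_id};"
            f"STR5={b5.strand};STR3={b3.strand}"
        )
        lines.append(
            f"{b5.chrom}\t{b5.pos}\t{ida}\tN\tN[{b3.chrom}:{b3.pos}[\t.\tPASS\t"
            f"SVTYPE=BND;MATEID={idb};{common}\n"
        )
        lines.append(
            f"{b3.chrom}\t{b3.pos}\t{idb}\tN\tN]{b5.chrom}:{b5.pos}]\t.\tPASS\t"
            f"SVTYPE=BND;MATEID={ida};{common}\n"
        )
    Path(path).write_text("".join(lines))


def read_actionability(path) -> ActionabilityMatrix:
    """Read the (driver, cancer type) approval grid from CSV or JSON.

    Unlisted pairs default to ``not_approved``; a pan-cancer driver listed as
    ``not_approved`` anywhere is a validation error.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        rows = json.loads(path.read_text())
    else:
        with open(path, newline="") as fh:
            rows = list(csv.DictReader(fh))
    try:
        status = {(r["driver"], r["cancer_type"]): r["status"] for r in rows}
    except KeyError as exc:
        raise FusionFormatError(f"{path}: missing field {exc}") from exc
    return ActionabilityMatrix(status=status)


def read_domain_table(path) -> DomainTable:
    """Read driver domain intervals (`driver,retained_side,domain_start,
    domain_end[,chrom]`) used for RNA partner selection."""
    with open(path, newline="") as fh:
        rows = list(csv.DictReader(fh))
    specs = {}
    for r in rows:
        try:
            specs[r["driver"]] = DomainSpec(
                retained_side=r["retained_side"],
                domain_start=int(r["domain_start"]),
                domain_end=int(r["domain_end"]),
                chrom=r.get("chrom", "chr1"),
            )
        except KeyError as exc:
            raise FusionFormatError(f"{path}: missing field {exc}") from exc
    return DomainTable(specs)


COHORT_CSV_COLUMNS = [
    "patient_id",
    "cancer_type",
    "stage",
    "age_at_biopsy",
    "gender",
    "race",
    "smoking_status",
    "tumor_purity",
    "biopsy_date",
    "metastatic_dx_date",
    "n_nonsynonymous_mutations",
]


def _parse_date(s: Optional[str]) -> Optional[date]:
    if s is None or s == "" or pd.isna(s):
        return None
    return date.fromisoformat(str(s))


def read_cohort(path) -> list[PatientRecord]:
    """Read patient metadata from CSV (dates ISO-8601, purity in percent)."""
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, COHORT_CSV_COLUMNS, path)
    out = []
    for row in df.itertuples(index=False):
        out.append(
            PatientRecord(
                patient_id=row.patient_id,
                cancer_type=None if pd.isna(row.cancer_type) else row.cancer_type,
                stage=Stage(row.stage) if not pd.isna(row.stage) else Stage.UNKNOWN,
                age_at_biopsy=None if pd.isna(row.age_at_biopsy) else float(row.age_at_biopsy),
                gender=None if pd.isna(row.gender) else row.gender,
                race=None if pd.isna(row.race) else row.race,
                smoking_status=None if pd.isna(row.smoking_status) else row.smoking_status,
                tumor_purity=None if pd.isna(row.tumor_purity) else float(row.tumor_purity),
                biopsy_date=_parse_date(row.biopsy_date),
                metastatic_dx_date=_parse_date(row.metastatic_dx_date),
                n_nonsynonymous_mutations=(
                    None
                    if pd.isna(row.n_nonsynonymous_mutations)
                    else int(float(row.n_nonsynonymous_mutations))
                ),
            )
        )
    return out


def write_cohort(patients: Sequence[PatientRecord], path) -> None:
    rows = []
    for p in patients:
        rows.append(
            {
                "patient_id": p.patient_id,
                "cancer_type": p.cancer_type,
                "stage": p.stage.value,
                "age_at_biopsy": p.age_at_biopsy,
                "gender": p.gender,
                "race": p.race,
                "smoking_status": p.smoking_status,
                "tumor_purity": p.tumor_purity,
                "biopsy_date": p.biopsy_date.isoformat() if p.biopsy_date else None,
                "metastatic_dx_date": (
                    p.metastatic_dx_date.isoformat() if p.metastatic_dx_date else None
                ),
                "n_nonsynonymous_mutations": p.n_nonsynonymous_mutations,
            }
        )
    pd.DataFrame(rows, columns=COHORT_CSV_COLUMNS).to_csv(path, index=False)


ATTRIBUTED_TSV_COLUMNS = [
    "patient_id",
    "driver",
    "category",
    "rna_partner",
    "dna_partner",
    "rna_support",
    "dna_support",
]


def write_attributed(attributed: Sequence[AttributedFusion], path) -> None:
    rows = [
        {
            "patient_id": a.patient_id,
            "driver": a.driver,
            "category": a.category.value,
            "rna_partner": a.rna_partner,
            "dna_partner": a.dna_partner,
            "rna_support": a.rna_support,
            "dna_support": a.dna_support,
        }
        for a in attributed
    ]
    pd.DataFrame(rows, columns=ATTRIBUTED_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def read_attributed(path) -> list[AttributedFusion]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, ATTRIBUTED_TSV_COLUMNS, path)
    out = []
    for row in df.itertuples(index=False):
        out.append(
            AttributedFusion(
                patient_id=row.patient_id,
                driver=row.driver,
                category=Category(row.category),
                rna_partner=None if pd.isna(row.rna_partner) else row.rna_partner,
                dna_partner=None if pd.isna(row.dna_partner) else row.dna_partner,
                rna_support=None if pd.isna(row.rna_support) else int(float(row.rna_support)),
                dna_support=None if pd.isna(row.dna_support) else int(float(row.dna_support)),
            )
        )
    return out
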