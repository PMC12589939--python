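import pytest

import dualfusion as df
from dualfusion.model import Analyte, Breakpoint, FusionEvidence


def make_rna(
    gene_5p="EML4",
    gene_3p="ALK",
    support=10,
    patient="P1",
    pos_5p=5000,
    pos_3p=3000,
    chrom_5p="chr2",
    chrom_3p="chr2",
):
    return FusionEvidence(
        patient_id=patient,
        sample_id=f"{patient}_S1",
        analyte=Analyte.RNA,
        gene_5p=gene_5p,
        gene_3p=gene_3p,
        breakpoint_5p=Breakpoint(chrom_5p, pos_5p),
        breakpoint_3p=Breakpoint(chrom_3p, pos_3p),
        read_support=support,
    )


def make_dna(
    gene_5p="EML4",
    gene_3p="ALK",
    support=40,
    patient="P1",
    pos_5p=5000,
    pos_3p=3000,
    chrom_5p="chr2",
    chrom_3p="chr2",
):
    return FusionEvidence(
        patient_id=patient,
        sample_id=f"{patient}_S1",
        analyte=Analyte.DNA,
        gene_5p=gene_5p,
        gene_3p=gene_3p,
        breakpoint_5p=Breakpoint(chrom_5p, pos_5p),
        breakpoint_3p=Breakpoint(chrom_3p, pos_3p),
        read_support=support,
    )


@pytest.fixture(scope="session")
def domains():
    return df.DomainTable.default()


@pytest.fixture(scope="session")
def matrix():
    return df.ActionabilityMatrix.default()


@pytest.fixture(scope="session")
def pan_cancer_run():
    """Calibrated pan-cancer scenario pushed through the whole pipeline once
    per session (simulate -> attribute -> stratify -> summarize)."""
    cfg = df.presets.pan_cancer_config()
    cohort = df.generate(cfg, seed=20_240_917)
    drivers = sorted({c.driver for c in cfg.cells})
    attributed = df.attribute_cohort(cohort.rna_calls + cohort.dna_calls, drivers)
    summary = df.summarize(attributed, cohort.patients)
    matrix = df.ActionabilityMatrix.default()
    strata = df.stratify(attributed, cohort.patients, matrix)
    return {
        "config": cfg,
        "cohort": cohort,
        "attributed": attributed,
        "summary": summary,
        "matrix": matrix,
        "strata": strata,
    }


@pytest.fixture(scope="session")
def emerging_run():
    cfg = df.presets.emerging_config()
    cohort = df.generate(cfg, seed=7)
    attributed = df.attribute_cohort(
        cohort.rna_calls + cohort.dna_calls, ["BRAF", "EGFR"]
    )
    summary = df.summarize(attributed, cohort.patients)
    return {
        "config": cfg,
        "cohort": cohort,
        "attributed": attributed,
        "summary": summary,
    }
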