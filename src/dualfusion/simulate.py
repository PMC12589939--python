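"""Synthetic-cohort generation with the statistical structure the pipeline
assumes.

Two modes:

* **calibrated** — every (driver, cancer type, analyte category) cell gets an
  exact configured count, so pushing the output through attribution and
  summarisation is an arithmetic identity. This stands in for the
  controlled-access clinical database in acceptance testing.
* **stochastic** — per-driver prevalences and category probabilities are
  sampled, for property tests.

In both modes sampled read supports satisfy the attribution rules for the
intended category exactly: ``both`` fusions get RNA support >= 4 and a
matching DNA breakend with support >= 15; ``RNA_only`` fusions get RNA >= 4
and either no DNA evidence or a matching breakend below 15 reads;
``DNA_only`` fusions get DNA >= 35 with any RNA evidence kept at or below
the limit of blank. Noise calls injected into fusion-negative patients never
pass any rule. Identical seeds give identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .model import (
    Analyte,
    BlankMeasurement,
    Breakpoint,
    Category,
    DomainTable,
    FusionEvidence,
    PatientRecord,
    Stage,
    Thresholds,
    load_partner_table,
    normalize_symbol,
)
from . import io as dfio


class SimulationConfigError(ValueError):
    """The configuration is internally inconsistent or infeasible."""


@dataclass(frozen=True)
class SupportModel:
    """Negative-binomial read-support generator truncated to a feasible
    region by rejection (over-dispersed counts, guaranteed category
    consistency)."""

    mean: float
    dispersion: float = 3.0  # nbinom size; smaller = more over-dispersed

    def sample(self, rng: np.random.Generator, low: int, high: Optional[int] = None) -> int:
        if high is not None and high < low:
            raise SimulationConfigError(f"empty support range [{low}, {high}]")
        r = self.dispersion
        p = r / (r + self.mean)
        for _ in range(1000):
            x = int(rng.negative_binomial(r, p))
            if x >= low and (high is None or x <= high):
                return x
        # pathological parameterisation: fall back to a uniform draw in range
        hi = high if high is not None else low + int(3 * self.mean) + 1
        return int(rng.integers(low, hi + 1))


@dataclass(frozen=True)
class FusionCell:
    """Exact calibrated counts for one (driver, cancer type) cell."""

    driver: str
    cancer_type: str
    n_rna_only: int = 0
    n_dna_only: int = 0
    n_both: int = 0

    @property
    def total(self) -> int:
        return self.n_rna_only + self.n_dna_only + self.n_both

    def category_counts(self) -> list[tuple[Category, int]]:
        return [
            (Category.RNA_ONLY, self.n_rna_only),
            (Category.DNA_ONLY, self.n_dna_only),
            (Category.BOTH, self.n_both),
        ]


@dataclass(frozen=True)
class MultiFusionPatient:
    """A patient carrying two driver fusions (counted as two fusions,
    one patient)."""

    cancer_type: str
    fusions: tuple[tuple[str, Category], tuple[str, Category]]


@dataclass(frozen=True)
class TMBCounts:
    """Exact TMB-class counts for one fusion-status arm."""

    high: int
    low: int
    unknown: int = 0

    @property
    def total(self) -> int:
        return self.high + self.low + self.unknown


@dataclass(frozen=True)
class NoiseConfig:
    """Sub-threshold calls injected into fusion-negative patients."""

    rna_rate: float = 0.02
    dna_rate: float = 0.01
    rna_support: tuple[int, int] = (1, 3)    # at or below the LOB
    dna_support: tuple[int, int] = (15, 34)  # below the unmatched cut, unmatched


@dataclass(frozen=True)
class ExpressionConfig:
    """Log-normal TPM baselines per cancer type with an upward shift in
    fusion-positive samples (shift in log2 units)."""

    drivers: tuple[str, ...]
    baseline_log2: float = 4.0
    type_spread_log2: float = 1.0
    sd_log2: float = 1.0
    shift_log2: float = 2.0


@dataclass(frozen=True)
class CalibratedCohortConfig:
    cancer_type_counts: Mapping[str, int]
    cells: tuple[FusionCell, ...] = ()
    multi_patients: tuple[MultiFusionPatient, ...] = ()
    tmb_positive: Optional[TMBCounts] = None
    tmb_negative: Optional[TMBCounts] = None
    noise: NoiseConfig = NoiseConfig()
    rna_support: SupportModel = SupportModel(mean=25.0)
    dna_matched_support: SupportModel = SupportModel(mean=45.0)
    dna_high_support: SupportModel = SupportModel(mean=60.0)
    rna_only_dna_present_prob: float = 0.3
    dna_only_sub_lob_rna_prob: float = 0.3
    expression: Optional[ExpressionConfig] = None
    thresholds: Thresholds = Thresholds()

    @property
    def n_patients(self) -> int:
        return int(sum(self.cancer_type_counts.values()))

    def n_positive_patients(self) -> int:
        return sum(c.total for c in self.cells) + len(self.multi_patients)

    def n_fusions(self) -> int:
        return sum(c.total for c in self.cells) + 2 * len(self.multi_patients)

    def validate(self) -> None:
        per_type: dict[str, int] = {}
        for c in self.cells:
            if min(c.n_rna_only, c.n_dna_only, c.n_both) < 0:
                raise SimulationConfigError(f"negative count in cell {c}")
            per_type[c.cancer_type] = per_type.get(c.cancer_type, 0) + c.total
        for m in self.multi_patients:
            per_type[m.cancer_type] = per_type.get(m.cancer_type, 0) + 1
        for ct, n_pos in per_type.items():
            avail = int(self.cancer_type_counts.get(ct, 0))
            if n_pos > avail:
                raise SimulationConfigError(
                    f"{ct}: {n_pos} positive patients configured but only "
                    f"{avail} patients in the cohort"
                )
        n_pos = self.n_positive_patients()
        n_neg = self.n_patients - n_pos
        if self.tmb_positive is not None and self.tmb_positive.total != n_pos:
            raise SimulationConfigError(
                f"tmb_positive sums to {self.tmb_positive.total}, expected {n_pos}"
            )
        if self.tmb_negative is not None and self.tmb_negative.total != n_neg:
            raise SimulationConfigError(
                f"tmb_negative sums to {self.tmb_negative.total}, expected {n_neg}"
            )


@dataclass(frozen=True)
class StochasticCohortConfig:
    n_patients: int
    cancer_type_weights: Mapping[str, float]
    prevalence: Mapping[str, float]  # driver -> per-patient prevalence
    category_probs: Mapping[Category, float] = field(
        default_factory=lambda: {
            Category.RNA_ONLY: 0.17,
            Category.DNA_ONLY: 0.13,
            Category.BOTH: 0.70,
        }
    )
    tmb_high_prob: float = 0.15
    noise: NoiseConfig = NoiseConfig()
    rna_support: SupportModel = SupportModel(mean=25.0)
    dna_matched_support: SupportModel = SupportModel(mean=45.0)
    dna_high_support: SupportModel = SupportModel(mean=60.0)
    rna_only_dna_present_prob: float = 0.3
    dna_only_sub_lob_rna_prob: float = 0.3
    expression: Optional[ExpressionConfig] = None
    thresholds: Thresholds = Thresholds()

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise SimulationConfigError("n_patients must be > 0")
        if any(w < 0 for w in self.cancer_type_weights.values()):
            raise SimulationConfigError("cancer type weights must be >= 0")
        if any(not (0 <= p <= 1) for p in self.prevalence.values()):
            raise SimulationConfigError("prevalences must be in [0, 1]")
        if abs(sum(self.category_probs.values()) - 1.0) > 1e-9:
            raise SimulationConfigError("category probabilities must sum to 1")


@dataclass
class SyntheticCohort:
    patients: list[PatientRecord]
    rna_calls: list[FusionEvidence]
    dna_calls: list[FusionEvidence]
    truth: pd.DataFrame  # patient_id, driver, cancer_type, category, partner

    def write(self, out_dir) -> dict[str, Path]:
        """Serialize to the exact dialects the readers consume."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "rna": out / "rna_fusions.tsv",
            "dna": out / "dna_svs.vcf",
            "cohort": out / "cohort.csv",
            "truth": out / "truth.tsv",
        }
        dfio.write_rna_fusions(self.rna_calls, paths["rna"])
        dfio.write_dna_svs(self.dna_calls, paths["dna"])
        dfio.write_cohort(self.patients, paths["cohort"])
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        return paths


_GENDERS = ("female", "male")
_RACES = ("White", "Black or African American", "Asian", "Other", "Unknown")
_SMOKING = ("Current or former smoker", "Nonsmoker", "Unknown")


class _CallFactory:
    """Draws analyte evidence consistent with an intended category."""

    def __init__(self, rng, rna_support, dna_matched_support, dna_high_support,
                 rna_only_dna_present_prob, dna_only_sub_lob_rna_prob,
                 thresholds: Thresholds, domains: DomainTable):
        self.rng = rng
        self.rna_support = rna_support
        self.dna_matched = dna_matched_support
        self.dna_high = dna_high_support
        self.p_rna_only_dna = rna_only_dna_present_prob
        self.p_sub_lob_rna = dna_only_sub_lob_rna_prob
        self.thr = thresholds
        self.domains = domains
        self.partners = load_partner_table()

    def _pick_partner(self, driver: str) -> tuple[str, str]:
        options = self.partners.get(driver)
        if not options:
            return f"{driver}P1", "chr1"
        idx = int(self.rng.integers(0, len(options)))
        return options[idx]

    def _breakpoints(self, driver, partner_chrom):
        spec = self.domains.get(driver)
        offset = int(self.rng.integers(10, 200))
        partner_bp = Breakpoint(partner_chrom, int(self.rng.integers(1000, 100000)), "+")
        if spec is None:
            driver_bp = Breakpoint("chr1", 1000 + offset, "+")
            return "5p", driver_bp, partner_bp
        if spec.retained_side == "5p":
            driver_bp = Breakpoint(spec.chrom, spec.domain_end + offset, "+")
        else:
            driver_bp = Breakpoint(spec.chrom, max(1, spec.domain_start - offset), "+")
        return spec.retained_side, driver_bp, partner_bp

    def _evidence(self, pid, driver, partner, partner_chrom, analyte, support):
        side, driver_bp, partner_bp = self._breakpoints(driver, partner_chrom)
        if side == "5p":
            g5, g3, b5, b3 = driver, partner, driver_bp, partner_bp
        else:
            g5, g3, b5, b3 = partner, driver, partner_bp, driver_bp
        return FusionEvidence(
            patient_id=pid,
            sample_id=f"{pid}_S1",
            analyte=analyte,
            gene_5p=g5,
            gene_3p=g3,
            breakpoint_5p=b5,
            breakpoint_3p=b3,
            read_support=support,
        )

    def make_fusion(self, pid: str, driver: str, category: Category):
        """RNA/DNA evidence for one intended fusion; returns
        (rna_calls, dna_calls, partner)."""
        thr = self.thr
        partner, pchrom = self._pick_partner(driver)
        rna, dna = [], []
        if category is Category.BOTH:
            rna.append(self._evidence(
                pid, driver, partner, pchrom, Analyte.RNA,
                self.rna_support.sample(self.rng, thr.rna_call_min_reads)))
            dna.append(self._evidence(
                pid, driver, partner, pchrom, Analyte.DNA,
                self.dna_matched.sample(self.rng, thr.dna_min_with_rna_match)))
        elif category is Category.RNA_ONLY:
            rna.append(self._evidence(
                pid, driver, partner, pchrom, Analyte.RNA,
                self.rna_support.sample(self.rng, thr.rna_call_min_reads)))
            if self.rng.random() < self.p_rna_only_dna:
                dna.append(self._evidence(
                    pid, driver, partner, pchrom, Analyte.DNA,
                    self.dna_matched.sample(
                        self.rng, 1, thr.dna_min_with_rna_match - 1)))
        else:  # DNA_only: every RNA candidate at or below the LOB
            dna.append(self._evidence(
                pid, driver, partner, pchrom, Analyte.DNA,
                self.dna_high.sample(self.rng, thr.dna_min_without_match)))
            if self.rng.random() < self.p_sub_lob_rna:
                rna.append(self._evidence(
                    pid, driver, partner, pchrom, Analyte.RNA,
                    int(self.rng.integers(1, thr.lob_reads + 1))))
        return rna, dna, partner

    def make_noise(self, pid: str, drivers: Sequence[str], noise: NoiseConfig):
        """Sub-threshold calls for a fusion-negative patient."""
        rna, dna = [], []
        if self.rng.random() < noise.rna_rate:
            driver = drivers[int(self.rng.integers(0, len(drivers)))]
            partner, pchrom = self._pick_partner(driver)
            lo, hi = noise.rna_support
            rna.append(self._evidence(
                pid, driver, partner, pchrom, Analyte.RNA,
                int(self.rng.integers(lo, hi + 1))))
        if self.rng.random() < noise.dna_rate:
            driver = drivers[int(self.rng.integers(0, len(drivers)))]
            partner, pchrom = self._pick_partner(driver)
            lo, hi = noise.dna_support
            dna.append(self._evidence(
                pid, driver, partner, pchrom, Analyte.DNA,
                int(self.rng.integers(lo, hi + 1))))
        return rna, dna


def _make_patient(rng, pid, cancer_type) -> PatientRecord:
    dx = date(2019, 1, 1) + timedelta(days=int(rng.integers(0, 1500)))
    return PatientRecord(
        patient_id=pid,
        cancer_type=cancer_type,
        stage=Stage.IV,
        age_at_biopsy=float(np.clip(rng.normal(65, 10), 18, 95)),
        gender=_GENDERS[int(rng.integers(0, 2))],
        race=_RACES[int(rng.integers(0, len(_RACES)))],
        smoking_status=_SMOKING[int(rng.integers(0, len(_SMOKING)))],
        tumor_purity=float(rng.uniform(30, 95)),
        biopsy_date=dx + timedelta(days=int(rng.integers(0, 90))),
        metastatic_dx_date=dx,
    )


def _assign_tmb(rng, pids: Sequence[str], counts: Optional[TMBCounts],
                patients: Mapping[str, PatientRecord], thr: Thresholds) -> None:
    """Assign nonsynonymous mutation counts matching exact TMB-class counts."""
    if counts is None:
        return
    order = list(pids)
    perm = rng.permutation(len(order))
    hi_cut = int(np.ceil(thr.tmb_high_cut * thr.panel_size_mb))
    for rank, idx in enumerate(perm):
        p = patients[order[idx]]
        if rank < counts.high:
            p.n_nonsynonymous_mutations = int(rng.integers(hi_cut, hi_cut + 40))
        elif rank < counts.high + counts.low:
            p.n_nonsynonymous_mutations = int(rng.integers(0, hi_cut))
        else:
            p.n_nonsynonymous_mutations = None


def _apply_expression(rng, patients: list[PatientRecord], truth: pd.DataFrame,
                      cfg: ExpressionConfig) -> None:
    types = sorted({p.cancer_type for p in patients})
    offsets = {
        t: cfg.baseline_log2 + cfg.type_spread_log2 * ((i % 5) - 2) / 2.0
        for i, t in enumerate(types)
    }
    positive = {
        (r.patient_id, normalize_symbol(r.driver)) for r in truth.itertuples()
    }
    drivers = tuple(normalize_symbol(d) for d in cfg.drivers)
    for p in patients:
        tpm = {}
        for d in drivers:
            mu = offsets[p.cancer_type]
            if (p.patient_id, d) in positive:
                mu += cfg.shift_log2
            tpm[d] = float(2.0 ** rng.normal(mu, cfg.sd_log2))
        p.expression_tpm = tpm


def generate(config, seed: int) -> SyntheticCohort:
    """Generate a synthetic cohort (calibrated or stochastic mode).

    The same ``(config, seed)`` always produces identical output.
    """
    if isinstance(config, CalibratedCohortConfig):
        return _generate_calibrated(config, seed)
    if isinstance(config, StochasticCohortConfig):
        return _generate_stochastic(config, seed)
    raise SimulationConfigError(f"unknown config type {type(config).__name__}")


def _generate_calibrated(config: CalibratedCohortConfig, seed: int) -> SyntheticCohort:
    config.validate()
    rng = np.random.default_rng(seed)
    domains = DomainTable.default()
    factory = _CallFactory(
        rng, config.rna_support, config.dna_matched_support, config.dna_high_support,
        config.rna_only_dna_present_prob, config.dna_only_sub_lob_rna_prob,
        config.thresholds, domains)

    patients: dict[str, PatientRecord] = {}
    type_pools: dict[str, list[str]] = {}
    idx = 0
    for ct in sorted(config.cancer_type_counts):
        pool = []
        for _ in range(int(config.cancer_type_counts[ct])):
            pid = f"PT{idx:06d}"
            idx += 1
            patients[pid] = _make_patient(rng, pid, ct)
            pool.append(pid)
        type_pools[ct] = pool

    cursors = {ct: 0 for ct in type_pools}

    def take_patient(ct: str) -> str:
        pid = type_pools[ct][cursors[ct]]
        cursors[ct] += 1
        return pid

    rna_calls: list[FusionEvidence] = []
    dna_calls: list[FusionEvidence] = []
    truth_rows: list[dict] = []
    positive_pids: list[str] = []

    def emit(pid, ct, driver, category):
        rna, dna, partner = factory.make_fusion(pid, normalize_symbol(driver), category)
        rna_calls.extend(rna)
        dna_calls.extend(dna)
        truth_rows.append(
            {
                "patient_id": pid,
                "driver": normalize_symbol(driver),
                "cancer_type": ct,
                "category": category.value,
                "partner": partner,
            }
        )

    for cell in config.cells:
        for category, count in cell.category_counts():
            for _ in range(count):
                pid = take_patient(cell.cancer_type)
                positive_pids.append(pid)
                emit(pid, cell.cancer_type, cell.driver, category)
    for m in config.multi_patients:
        pid = take_patient(m.cancer_type)
        positive_pids.append(pid)
        for driver, category in m.fusions:
            emit(pid, m.cancer_type, driver, Category(category))

    positive_set = set(positive_pids)
    negative_pids = [pid for pid in patients if pid not in positive_set]
    noise_drivers = sorted({c.driver for c in config.cells}) or ["ALK"]
    for pid in negative_pids:
        rna, dna = factory.make_noise(pid, noise_drivers, config.noise)
        rna_calls.extend(rna)
        dna_calls.extend(dna)

    thr = config.thresholds
    _assign_tmb(rng, positive_pids, config.tmb_positive, patients, thr)
    _assign_tmb(rng, negative_pids, config.tmb_negative, patients, thr)

    truth = pd.DataFrame(
        truth_rows, columns=["patient_id", "driver", "cancer_type", "category", "partner"]
    )
    patient_list = [patients[pid] for pid in sorted(patients)]
    if config.expression is not None:
        _apply_expression(rng, patient_list, truth, config.expression)
    return SyntheticCohort(
        patients=patient_list, rna_calls=rna_calls, dna_calls=dna_calls, truth=truth
    )


def _generate_stochastic(config: StochasticCohortConfig, seed: int) -> SyntheticCohort:
    config.validate()
    rng = np.random.default_rng(seed)
    domains = DomainTable.default()
    factory = _CallFactory(
        rng, config.rna_support, config.dna_matched_support, config.dna_high_support,
        config.rna_only_dna_present_prob, config.dna_only_sub_lob_rna_prob,
        config.thresholds, domains)

    types = sorted(config.cancer_type_weights)
    weights = np.array([config.cancer_type_weights[t] for t in types], dtype=float)
    weights = weights / weights.sum()
    drivers = sorted(config.prevalence)
    cats = [Category.RNA_ONLY, Category.DNA_ONLY, Category.BOTH]
    cat_p = np.array([config.category_probs[c] for c in cats])

    patients: list[PatientRecord] = []
    rna_calls: list[FusionEvidence] = []
    dna_calls: list[FusionEvidence] = []
    truth_rows: list[dict] = []
    for i in range(config.n_patients):
        pid = f"PT{i:06d}"
        ct = types[int(rng.choice(len(types), p=weights))]
        p = _make_patient(rng, pid, ct)
        p.n_nonsynonymous_mutations = (
            int(rng.integers(10, 50))
            if rng.random() < config.tmb_high_prob
            else int(rng.integers(0, 10))
        )
        patients.append(p)
        positive = False
        for driver in drivers:
            if rng.random() < config.prevalence[driver]:
                positive = True
                category = cats[int(rng.choice(3, p=cat_p))]
                rna, dna, partner = factory.make_fusion(pid, driver, category)
                rna_calls.extend(rna)
                dna_calls.extend(dna)
                truth_rows.append(
                    {
                        "patient_id": pid,
                        "driver": driver,
                        "cancer_type": ct,
                        "category": category.value,
                        "partner": partner,
                    }
                )
        if not positive:
            rna, dna = factory.make_noise(pid, drivers, config.noise)
            rna_calls.extend(rna)
            dna_calls.extend(dna)

    truth = pd.DataFrame(
        truth_rows, columns=["patient_id", "driver", "cancer_type", "category", "partner"]
    )
    if config.expression is not None:
        _apply_expression(rng, patients, truth, config.expression)
    return SyntheticCohort(
        patients=patients, rna_calls=rna_calls, dna_calls=dna_calls, truth=truth
    )


@dataclass(frozen=True)
class BlankRunConfig:
    """Blank-panel design: wild-type samples run in duplicate on two reagent
    lots; optionally one (or more) outlier measurements with non-zero
    support, emulating an isolated blank signal."""

    n_samples: int = 24
    n_lots: int = 2
    n_replicates: int = 2
    outlier_value: int = 3
    n_outliers: int = 1


def generate_blanks(config: BlankRunConfig = BlankRunConfig(), seed: int = 0
                    ) -> list[BlankMeasurement]:
    """Generate the blank replicate panel (default 24 x 2 lots x 2 reps = 96
    measurements, one of which reads 3 supporting reads)."""
    rng = np.random.default_rng(seed)
    measurements = []
    slots = []
    for s in range(config.n_samples):
        for lot in range(config.n_lots):
            for rep in range(config.n_replicates):
                slots.append((f"BLANK{s:03d}", f"lot{lot + 1}", rep + 1))
    outlier_idx = set(
        rng.choice(len(slots), size=min(config.n_outliers, len(slots)), replace=False).tolist()
    ) if config.n_outliers else set()
    for i, (sid, lot, rep) in enumerate(slots):
        measurements.append(
            BlankMeasurement(
                sample_id=sid,
                reagent_lot=lot,
                replicate=rep,
                read_support=config.outlier_value if i in outlier_idx else 0,
            )
        )
    return measurements


@dataclass(frozen=True)
class TruthsetConfig:
    """Orthogonal-panel concordance design with exact confusion counts."""

    tp: int = 168
    fp: int = 1
    fn: int = 3
    tn: int = 14285


def generate_truthset(config: TruthsetConfig = TruthsetConfig(), seed: int = 0
                      ) -> tuple[set, set, int]:
    """Generate (calls, truth, universe_size) with the configured confusion
    matrix; identifiers are synthetic (sample, variant) pairs."""
    rng = np.random.default_rng(seed)
    n_pos = config.tp + config.fn
    universe = config.tp + config.fp + config.fn + config.tn
    ids = [f"S{i // 60:04d}:V{i % 60:02d}" for i in range(universe)]
    perm = rng.permutation(universe)
    truth = {ids[i] for i in perm[:n_pos]}
    called_true = {ids[i] for i in perm[: config.tp]}
    false_pos = {ids[i] for i in perm[n_pos: n_pos + config.fp]}
    return called_true | false_pos, truth, universe
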