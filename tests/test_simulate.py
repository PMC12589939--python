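"""Synthetic-cohort generator: determinism, calibrated-count recovery,
category consistency of sampled supports, and the blank / truth-set designs."""

import hashlib

import numpy as np
import pandas as pd
import pytest

import dualfusion as df
from dualfusion.model import Category
from dualfusion.simulate import SimulationConfigError


def small_calibrated():
    return df.CalibratedCohortConfig(
        cancer_type_counts={"NSCLC": 120, "breast": 80},
        cells=(
            df.FusionCell("ALK", "NSCLC", n_rna_only=3, n_dna_only=2, n_both=5),
            df.FusionCell("NRG1", "breast", n_rna_only=4, n_dna_only=1, n_both=2),
        ),
        multi_patients=(
            df.MultiFusionPatient(
                "NSCLC", (("ALK", Category.BOTH), ("RET", Category.BOTH))
            ),
        ),
        tmb_positive=df.TMBCounts(high=3, low=14, unknown=1),
        tmb_negative=df.TMBCounts(high=30, low=150, unknown=2),
    )


def file_hashes(cohort, out_dir):
    paths = cohort.write(out_dir)
    return {k: hashlib.sha256(p.read_bytes()).hexdigest() for k, p in paths.items()}


class TestDeterminism:
    def test_same_seed_same_files(self, tmp_path):
        cfg = small_calibrated()
        h1 = file_hashes(df.generate(cfg, seed=5), tmp_path / "a")
        h2 = file_hashes(df.generate(cfg, seed=5), tmp_path / "b")
        assert h1 == h2

    def test_different_seed_different_supports(self, tmp_path):
        cfg = small_calibrated()
        h1 = file_hashes(df.generate(cfg, seed=5), tmp_path / "a")
        h2 = file_hashes(df.generate(cfg, seed=6), tmp_path / "b")
        assert h1 != h2

    def test_stochastic_mode_deterministic_too(self, tmp_path):
        cfg = df.StochasticCohortConfig(
            n_patients=500,
            cancer_type_weights={"NSCLC": 2.0, "breast": 1.0},
            prevalence={"ALK": 0.03, "RET": 0.01},
        )
        h1 = file_hashes(df.generate(cfg, seed=9), tmp_path / "a")
        h2 = file_hashes(df.generate(cfg, seed=9), tmp_path / "b")
        assert h1 == h2


class TestCalibratedRecovery:
    def test_attribution_recovers_every_truth_label(self):
        """Noise-free calibrated cohorts round-trip: attribution equals the
        generator's truth for 100% of patient x driver pairs."""
        cfg = small_calibrated()
        cohort = df.generate(cfg, seed=13)
        attributed = df.attribute_cohort(
            cohort.rna_calls + cohort.dna_calls, ["ALK", "RET", "NRG1"]
        )
        got = {
            (a.patient_id, a.driver): a.category.value for a in attributed
        }
        want = {
            (r.patient_id, r.driver): r.category for r in cohort.truth.itertuples()
        }
        assert got == want

    def test_zero_prevalence_gives_empty_attribution(self):
        cfg = df.CalibratedCohortConfig(
            cancer_type_counts={"NSCLC": 200},
            cells=(),
            noise=df.NoiseConfig(rna_rate=0.5, dna_rate=0.5),
        )
        cohort = df.generate(cfg, seed=3)
        assert cohort.truth.empty
        # noise calls exist but never pass any positivity rule
        assert len(cohort.rna_calls) + len(cohort.dna_calls) > 0
        attributed = df.attribute_cohort(
            cohort.rna_calls + cohort.dna_calls, ["ALK", "RET", "NRG1"]
        )
        assert attributed == []

    def test_supports_satisfy_category_constraints(self):
        cfg = small_calibrated()
        cohort = df.generate(cfg, seed=21)
        rna_by_pid = {}
        for e in cohort.rna_calls:
            rna_by_pid.setdefault(e.patient_id, []).append(e)
        dna_by_pid = {}
        for e in cohort.dna_calls:
            dna_by_pid.setdefault(e.patient_id, []).append(e)
        for r in cohort.truth.itertuples():
            rna = [e for e in rna_by_pid.get(r.patient_id, []) if r.driver in e.gene_pair]
            dna = [e for e in dna_by_pid.get(r.patient_id, []) if r.driver in e.gene_pair]
            if r.category == "RNA_only":
                assert max(e.read_support for e in rna) >= 4
                assert all(e.read_support < 15 for e in dna)
            elif r.category == "DNA_only":
                assert all(e.read_support <= 3 for e in rna)
                assert max(e.read_support for e in dna) >= 35
            else:
                assert max(e.read_support for e in rna) >= 4
                assert max(e.read_support for e in dna) >= 15

    def test_infeasible_counts_raise_before_output(self):
        cfg = df.CalibratedCohortConfig(
            cancer_type_counts={"NSCLC": 5},
            cells=(df.FusionCell("ALK", "NSCLC", n_both=6),),
        )
        with pytest.raises(SimulationConfigError, match="positive patients"):
            df.generate(cfg, seed=1)

    def test_tmb_count_mismatch_raises(self):
        cfg = df.CalibratedCohortConfig(
            cancer_type_counts={"NSCLC": 10},
            cells=(df.FusionCell("ALK", "NSCLC", n_both=2),),
            tmb_positive=df.TMBCounts(high=1, low=0, unknown=0),
        )
        with pytest.raises(SimulationConfigError, match="tmb_positive"):
            df.generate(cfg, seed=1)

    def test_tmb_classes_match_configured_counts(self):
        from dualfusion.cohort import patient_tmb_class

        cfg = small_calibrated()
        cohort = df.generate(cfg, seed=2)
        pos = set(cohort.truth["patient_id"])
        classes = {"pos": [], "neg": []}
        for p in cohort.patients:
            classes["pos" if p.patient_id in pos else "neg"].append(
                patient_tmb_class(p)
            )
        assert sorted(classes["pos"]).count("TMB_high") == 3
        assert sorted(classes["pos"]).count("TMB_low") == 14
        assert sorted(classes["pos"]).count("TMB_unknown") == 1
        assert sorted(classes["neg"]).count("TMB_high") == 30


class TestStochasticMode:
    def test_prevalence_within_three_binomial_se(self):
        p, n = 0.02, 10_000
        cfg = df.StochasticCohortConfig(
            n_patients=n,
            cancer_type_weights={"NSCLC": 1.0},
            prevalence={"ALK": p},
        )
        cohort = df.generate(cfg, seed=17)
        observed = len(cohort.truth) / n
        se = np.sqrt(p * (1 - p) / n)
        assert abs(observed - p) <= 3 * se

    def test_categories_follow_probabilities_roughly(self):
        cfg = df.StochasticCohortConfig(
            n_patients=4000,
            cancer_type_weights={"NSCLC": 1.0},
            prevalence={"ALK": 0.5},
            category_probs={
                Category.RNA_ONLY: 0.5,
                Category.DNA_ONLY: 0.25,
                Category.BOTH: 0.25,
            },
        )
        cohort = df.generate(cfg, seed=23)
        share = (cohort.truth["category"] == "RNA_only").mean()
        assert abs(share - 0.5) < 0.05


class TestExpression:
    def test_fusion_positive_tpm_shifted_up(self):
        cfg = df.CalibratedCohortConfig(
            cancer_type_counts={"NSCLC": 400},
            cells=(df.FusionCell("NRG1", "NSCLC", n_both=60),),
            expression=df.ExpressionConfig(drivers=("NRG1",), shift_log2=2.0),
        )
        cohort = df.generate(cfg, seed=31)
        pos = set(cohort.truth["patient_id"])
        tpm_pos = [p.expression_tpm["NRG1"] for p in cohort.patients if p.patient_id in pos]
        tpm_neg = [p.expression_tpm["NRG1"] for p in cohort.patients if p.patient_id not in pos]
        assert np.median(tpm_pos) > 2.5 * np.median(tpm_neg)


class TestBlanks:
    def test_default_design_reproduces_lob(self):
        blanks = df.generate_blanks(seed=1)
        assert len(blanks) == 96
        assert len({b.sample_id for b in blanks}) == 24
        assert len({b.reagent_lot for b in blanks}) == 2
        assert df.estimate_lob(blanks) == (3, 4)

    def test_outlier_disabled(self):
        blanks = df.generate_blanks(df.BlankRunConfig(n_outliers=0), seed=1)
        assert df.estimate_lob(blanks) == (0, 1)

    def test_outlier_value_five(self):
        blanks = df.generate_blanks(df.BlankRunConfig(outlier_value=5), seed=1)
        assert df.estimate_lob(blanks) == (5, 6)


class TestTruthset:
    def test_default_reproduces_confusion_matrix(self):
        calls, truth, universe = df.generate_truthset(seed=2)
        res = df.concordance(calls, truth, universe)
        assert (res.tp, res.fp, res.fn, res.tn) == (168, 1, 3, 14285)
        assert round(100 * res.ppa, 1) == 98.2

    def test_perfect_config(self):
        calls, truth, universe = df.generate_truthset(
            df.TruthsetConfig(tp=20, fp=0, fn=0, tn=100), seed=2
        )
        res = df.concordance(calls, truth, universe)
        assert res.ppa == res.npa == 1.0

    def test_zero_tp_config(self):
        calls, truth, universe = df.generate_truthset(
            df.TruthsetConfig(tp=0, fp=0, fn=5, tn=50), seed=2
        )
        res = df.concordance(calls, truth, universe)
        assert res.ppa == 0.0
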