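"""Cohort summaries against direct-counting oracles, group comparisons, the
partner-distribution test, and the expression mixed model."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import dualfusion as df
from dualfusion.lmm import fit_random_intercept
from dualfusion.model import (
    AttributedFusion,
    Category,
    FusionValidationError,
    PatientRecord,
    Stage,
)

CATS = [Category.RNA_ONLY, Category.DNA_ONLY, Category.BOTH]


def pt(pid, ct):
    return PatientRecord(patient_id=pid, cancer_type=ct, stage=Stage.IV)


def random_instance(rng):
    types = ["A", "B", "C"]
    n = int(rng.integers(5, 40))
    patients = [pt(f"P{i}", types[int(rng.integers(0, 3))]) for i in range(n)]
    attributed = []
    for p in patients:
        for driver in ("ALK", "RET"):
            if rng.random() < 0.3:
                attributed.append(
                    AttributedFusion(
                        patient_id=p.patient_id,
                        driver=driver,
                        category=CATS[int(rng.integers(0, 3))],
                    )
                )
    return patients, attributed


class TestSummaryAgainstCountingOracle:
    def test_thousand_random_cohorts(self):
        """summarize/prevalence/analyte_breakdown equal direct set counting
        on 1,000 random small cohorts."""
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            patients, attributed = random_instance(rng)
            summary = df.summarize(attributed, patients)
            ct_of = {p.patient_id: p.cancer_type for p in patients}

            # oracle: pan-cancer combined
            pos_patients = {a.patient_id for a in attributed}
            assert summary.get().n_positive == len(pos_patients)
            assert summary.get().n_total == len(patients)
            prev = df.prevalence(summary)
            assert prev == pytest.approx(100 * len(pos_patients) / len(patients))

            # oracle: one random driver stratum and one type stratum
            c = summary.get("ALK")
            alk = [a for a in attributed if a.driver == "ALK"]
            assert c.n_rna_only == sum(a.category is Category.RNA_ONLY for a in alk)
            assert c.n_both == sum(a.category is Category.BOTH for a in alk)
            bd = df.analyte_breakdown(summary, "ALK")
            if alk:
                assert bd[0] == pytest.approx(
                    100 * c.n_rna_only / len(alk)
                )
                assert sum(bd) == pytest.approx(100.0)
            else:
                assert bd is None

            ca = summary.get("combined", "A")
            in_a = [a for a in attributed if ct_of[a.patient_id] == "A"]
            assert ca.n_fusions == len(in_a)
            assert ca.n_positive == len({a.patient_id for a in in_a})

    def test_detection_increase_definition(self):
        patients = [pt(f"P{i}", "X") for i in range(300)]
        attributed = (
            [AttributedFusion(f"P{i}", "BRAF", Category.RNA_ONLY) for i in range(122)]
            + [AttributedFusion(f"P{i + 122}", "BRAF", Category.DNA_ONLY) for i in range(40)]
            + [AttributedFusion(f"P{i + 162}", "BRAF", Category.BOTH) for i in range(56)]
        )
        s = df.summarize(attributed, patients)
        assert df.detection_increase(s) == pytest.approx(100 * 122 / 96)
        assert df.report_round(df.detection_increase(s), "increase") == 127

    def test_zero_rna_only_gives_zero_increase(self):
        patients = [pt("P0", "X"), pt("P1", "X")]
        attributed = [AttributedFusion("P0", "ALK", Category.BOTH)]
        s = df.summarize(attributed, patients)
        assert df.detection_increase(s) == 0.0

    def test_no_dna_detection_reported_absent(self):
        patients = [pt("P0", "X")]
        attributed = [AttributedFusion("P0", "ALK", Category.RNA_ONLY)]
        s = df.summarize(attributed, patients)
        assert df.detection_increase(s) is None

    def test_empty_stratum_reported_absent(self):
        s = df.summarize([], [pt("P0", "X")])
        assert df.prevalence(s) == 0.0
        assert df.analyte_breakdown(s) is None
        assert df.prevalence(s, cancer_type="no-such-type") is None

    def test_small_types_aggregate_into_other_conserving_totals(self):
        patients = [pt(f"P{i}", "big") for i in range(600)] + [
            pt(f"Q{i}", f"tiny{i % 3}") for i in range(30)
        ]
        attributed = [AttributedFusion("Q0", "ALK", Category.BOTH),
                      AttributedFusion("P0", "ALK", Category.BOTH)]
        s = df.summarize(attributed, patients, min_type_size=500)
        assert s.get("combined", "other").n_total == 30
        assert s.get("combined", "other").n_positive == 1
        assert s.get("combined", "big").n_total == 600
        total = sum(
            c.n_total for (d, ct), c in s.strata.items()
            if d == "combined" and ct != "pan-cancer"
        )
        assert total == 630


class TestReportRound:
    @pytest.mark.parametrize(
        "value,kind,expected",
        [
            (2.2250958, "prevalence", 2.2),
            (0.1456642, "prevalence", 0.15),
            (127.08333, "increase", 127),
            (70.55296, "share", 70.6),
        ],
    )
    def test_report_rounding(self, value, kind, expected):
        assert df.report_round(value, kind) == expected


class TestCompareGroups:
    def test_balanced_table_gives_zero_statistic_p_one(self):
        stat, p = df.compare_groups([[10, 10], [10, 10]], "chi2")
        assert stat == 0.0 and p == 1.0

    def test_tmb_style_contingency_highly_significant(self):
        stat, p = df.compare_groups([[1369, 56030], [127, 9708]], "chi2")
        assert p < 0.001

    def test_uncorrected_pearson_by_default(self):
        table = [[12, 5], [6, 9]]
        stat, _ = df.compare_groups(table, "chi2")
        ref = sps.chi2_contingency(np.array(table), correction=False).statistic
        assert stat == pytest.approx(float(ref))
        stat_c, _ = df.compare_groups(table, "chi2", correction=True)
        assert stat_c < stat

    def test_degenerate_margin_named(self):
        with pytest.raises(FusionValidationError, match="column"):
            df.compare_groups([[0, 10], [0, 10]], "chi2")
        with pytest.raises(FusionValidationError, match="row"):
            df.compare_groups([[0, 0], [5, 10]], "chi2")

    def test_identical_samples_mannwhitney_p_one(self):
        values = [1.2, 3.4, 5.6, 7.8] * 2
        labels = ["a"] * 4 + ["b"] * 4
        _, p = df.compare_groups(values, "mannwhitney", labels=labels)
        assert p == pytest.approx(1.0)


class TestPartnerDistribution:
    def test_single_partner_skips_test(self):
        with pytest.warns(UserWarning, match="skipped"):
            table, stat, p = df.partner_distribution(
                ["TACC3"] * 8, ["approved"] * 4 + ["not_approved"] * 4,
                patient_ids=list(range(8)),
            )
        assert stat is None and p is None

    def test_disjoint_partners_highly_significant(self):
        partners = ["BICC1"] * 10 + ["TACC3"] * 10
        groups = ["approved"] * 10 + ["not_approved"] * 10
        table, stat, p = df.partner_distribution(
            partners, groups, patient_ids=list(range(20))
        )
        # exact arithmetic: 2x2 table [[10,0],[0,10]], uncorrected chi2 = 20
        assert stat == pytest.approx(20.0)
        assert p == pytest.approx(float(sps.chi2.sf(20.0, 1)))
        assert p < 0.01

    def test_singletons_collapse_into_other(self):
        partners = ["BICC1"] * 5 + ["ODD1", "ODD2"]
        groups = ["approved"] * 5 + ["not_approved"] * 2
        table, stat, p = df.partner_distribution(
            partners, groups, patient_ids=list(range(7))
        )
        assert set(table.index) == {"BICC1", "other"}
        assert table.loc["other"].sum() == 2

    def test_collapse_threshold_configurable(self):
        partners = ["ACP3", "ACP3", "BICC1", "BICC1", "BICC1"]
        groups = ["approved"] * 5
        table, _, _ = df.partner_distribution(
            partners, groups, patient_ids=list(range(5)), collapse_max_patients=2
        )
        assert set(table.index) == {"BICC1", "other"}


def _expression_data(rng, shift_log2, n_pos=50, n_neg=500, n_types=5):
    tpm, status, types = [], [], []
    for t in range(n_types):
        base = 4.0 + 0.5 * (t - 2)
        for _ in range(n_pos):
            tpm.append(2 ** rng.normal(base + shift_log2, 1.0))
            status.append(True)
            types.append(f"T{t}")
        for _ in range(n_neg):
            tpm.append(2 ** rng.normal(base, 1.0))
            status.append(False)
            types.append(f"T{t}")
    return tpm, status, types


class TestExpressionContrast:
    def test_recovers_positive_shift(self):
        rng = np.random.default_rng(99)
        tpm, status, types = _expression_data(rng, shift_log2=2.0)
        res = df.expression_contrast(tpm, status, types)
        assert res.fixed_effect > 0
        assert res.p_value < 0.001
        assert set(res.per_type_mannwhitney) == {f"T{t}" for t in range(5)}
        assert all(p < 0.001 for p in res.per_type_mannwhitney.values())

    def test_single_status_type_dropped_with_warning(self):
        rng = np.random.default_rng(3)
        tpm, status, types = _expression_data(rng, 1.0, n_pos=10, n_neg=30, n_types=3)
        tpm += [5.0] * 10
        status += [False] * 10
        types += ["allneg"] * 10
        with pytest.warns(UserWarning, match="single fusion status"):
            res = df.expression_contrast(tpm, status, types)
        assert "allneg" not in res.per_type_mannwhitney

    def test_single_cancer_type_refused(self):
        rng = np.random.default_rng(4)
        tpm, status, types = _expression_data(rng, 1.0, n_pos=5, n_neg=20, n_types=1)
        with pytest.raises(FusionValidationError, match="2 cancer types"):
            df.expression_contrast(tpm, status, types)

    def test_null_p_values_approximately_uniform(self):
        """Under no expression shift, the fixed-effect p-value is ~U(0,1)
        across 200 simulated cohorts."""
        rng = np.random.default_rng(1234)
        pvals = []
        for _ in range(200):
            tpm, status, types = _expression_data(
                rng, shift_log2=0.0, n_pos=15, n_neg=60, n_types=4
            )
            res = df.expression_contrast(tpm, status, types)
            pvals.append(res.p_value)
        pvals = np.array(pvals)
        ks = sps.kstest(pvals, "uniform")
        assert ks.pvalue > 0.001
        assert 0.005 <= (pvals < 0.05).mean() <= 0.12


class TestRandomInterceptModel:
    def test_matches_statsmodels_mixedlm(self):
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(42)
        types = np.repeat([f"T{i}" for i in range(5)], 110)
        status = np.tile(np.r_[np.ones(10), np.zeros(100)], 5)
        mu = np.repeat(rng.normal(16, 4, 5), 110)
        y = mu + 6.0 * status + rng.normal(0, 3, len(status))
        fit = fit_random_intercept(
            y, np.column_stack([np.ones(len(y)), status]), types
        )
        frame = pd.DataFrame({"y": y, "status": status, "ct": types})
        ref = smf.mixedlm("y ~ status", frame, groups=frame["ct"]).fit(reml=True)
        assert fit.beta[1] == pytest.approx(ref.params["status"], abs=1e-5)
        assert fit.se[1] == pytest.approx(ref.bse["status"], rel=1e-4)

    def test_satterthwaite_df_matches_lmertest(self, tmp_path):
        """Cross-check df and p against the reference mixed-model t-test in R
        (lmerTest) on one small dataset."""
        import subprocess

        rng = np.random.default_rng(7)
        types = np.repeat([f"T{i}" for i in range(4)], 50)
        status = np.tile(np.r_[np.ones(8), np.zeros(42)], 4)
        mu = np.repeat(rng.normal(10, 3, 4), 50)
        y = mu + 2.0 * status + rng.normal(0, 2, len(status))
        fit = fit_random_intercept(
            y, np.column_stack([np.ones(len(y)), status]), types
        )
        csv = tmp_path / "d.csv"
        pd.DataFrame({"y": y, "status": status, "ct": types}).to_csv(csv, index=False)
        script = (
            "suppressMessages(library(lmerTest));"
            f"d <- read.csv('{csv}');"
            "m <- lmer(y ~ status + (1|ct), data=d);"
            "co <- coef(summary(m));"
            "cat(co['status','Estimate'], co['status','df'], co['status','Pr(>|t|)'])"
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        est, rdf, rp = map(float, out.stdout.split())
        assert fit.beta[1] == pytest.approx(est, rel=1e-5)
        assert fit.df[1] == pytest.approx(rdf, rel=1e-2)
        assert fit.pvalues[1] == pytest.approx(rp, rel=1e-3)

    def test_single_group_rejected(self):
        with pytest.raises(FusionValidationError):
            fit_random_intercept(
                [1.0, 2.0, 3.0], np.ones((3, 1)), ["a", "a", "a"]
            )
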