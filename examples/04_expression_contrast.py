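"""Does a detected fusion come with elevated driver-gene expression?

Generates a cohort in which fusion-positive samples carry a +2 log2-fold
shift in NRG1 TPM, then fits the random-intercept model of TPM on fusion
status with cancer type as the random effect (Satterthwaite df for the
fixed effect) alongside per-cancer-type Mann-Whitney tests.
"""

import dualfusion as df

cfg = df.CalibratedCohortConfig(
    cancer_type_counts={"NSCLC": 600, "pancreatic": 600, "breast": 600},
    cells=(
        df.FusionCell("NRG1", "NSCLC", n_both=40),
        df.FusionCell("NRG1", "pancreatic", n_both=40),
        df.FusionCell("NRG1", "breast", n_both=40),
    ),
    expression=df.ExpressionConfig(drivers=("NRG1",), shift_log2=2.0),
)
cohort = df.generate(cfg, seed=5)

positive = set(cohort.truth["patient_id"])
tpm = [p.expression_tpm["NRG1"] for p in cohort.patients]
status = [p.patient_id in positive for p in cohort.patients]
types = [p.cancer_type for p in cohort.patients]

res = df.expression_contrast(tpm, status, types)
print(f"fixed effect of fusion status on TPM: {res.fixed_effect:.1f} "
      f"(SE {res.fixed_effect_se:.1f})")
print(f"Satterthwaite df = {res.satterthwaite_df:.1f}, p = {res.p_value:.3g}")
for t, p in res.per_type_mannwhitney.items():
    print(f"  {t}: Mann-Whitney p = {p:.3g}")
# A positive fixed effect with p << 0.05 says fusion-positive samples
# express the driver more highly than fusion-negative samples of the same
# cancer type — evidence the fusion is transcribed and functional.
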