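# Methods

## Attribution model

The unit of analysis is the patient × driver-gene pair. All evidence for a
patient is pooled across samples of the profiled biopsy; gene symbols are
uppercased and alias-normalized (bundled alias table, e.g. ACPP → ACP3)
before any cross-analyte comparison, and gene pairs are compared unordered
because DNA breakend orientation does not fix transcript 5′/3′ order.

Positivity rules, with default thresholds:

* **RNA**: total supporting reads (junction + spanning) strictly above the
  limit of blank. Default LOB = 3, so ≥ 4 reads. The decomposition of total
  support into junction vs spanning reads is not used anywhere downstream;
  the sum is the definition.
* **DNA**: supporting reads ≥ 35 unconditionally, or ≥ 15 when some
  LOB-passing RNA call carries the same unordered gene pair. Sub-LOB RNA
  evidence does **not** unlock the 15-read cut: "detected in RNA" means
  passing the LOB, consistently with the RNA rule itself.
* **Category**: *both* when any positive RNA call and any positive DNA call
  exist for the driver, regardless of partner or breakpoint agreement;
  otherwise *RNA_only* / *DNA_only*; drivers with no positive call are
  absent from the output.

These rules are exhaustively equivalence-tested against a brute-force
enumeration over supports 0–40 × match ∈ {T, F}, and detection is provably
monotone in read support (a driver never leaves detection, and never flips
RNA_only ↔ DNA_only without passing through *both*, as support grows).

### Partner selection

When several RNA partners pass the LOB for one driver, the reported partner
must keep the driver's functional domain intact: with the domain on the
retained 5′ side the driver breakpoint must lie at or beyond the domain end;
with a retained 3′ side, at or before the domain start (boundary = intact;
driver observed on the non-retained side = broken). Among intact candidates
the highest support wins; ties break to the lexicographically smallest
partner symbol so output is deterministic. If no candidate keeps the domain
intact, selection falls back to highest support over all candidates (the
rule set does not cover this case; the fallback is logged). DNA partner
selection is simply highest support with the same tie-break.

The bundled domain table (`data/domains_illustrative.csv`) carries
**synthetic, illustrative coordinates**: plausible kinase/EGF-domain
intervals on transcript-scale coordinates with the conventional retained
side per driver (3′ for ALK/RET/ROS1/NTRK1-3/NRG1/BRAF, 5′ for
FGFR2/FGFR3/EGFR). Real deployments should override it with transcript
annotation via `read_domain_table`.

## Cohort selection and TMB

Patients must have metastatic or stage IV disease; hematologic malignancies
and missing/conflicting diagnoses are excluded. Samples need ≥ 30% tumor
purity (boundary inclusive). Among eligible samples the one closest to but
not before the metastatic/stage IV diagnosis is used; patients whose only
samples precede the diagnosis are excluded under their own audit reason.
When the diagnosis date is missing but stage qualifies, the earliest sample
is used (stage alone establishes eligibility). The audit tally partitions
the input exactly.

TMB = nonsynonymous mutations / panel megabases, computed on counts that
upstream already restricted to coverage > 100× and allelic fraction > 5%
(a documented contract, not re-implemented on reads). TMB ≥ 10/Mb is high,
boundary high. Panel size has no universal value and is a configuration
parameter; the illustrative default of 1.0 Mb is used only in tests and
synthetic scenarios. Patients without a mutation count form an explicit
`TMB_unknown` class rather than being silently dropped, so TMB strata need
not sum to the cohort.

## Assay validation

The LOB estimator is the maximum read support over all blank measurements
(the blank design: 24 wild-type samples × 2 reagent lots × 2 replicates =
96 measurements); an empirical-percentile option exists for larger blank
panels but the maximum is the default and the validated behaviour. The call
threshold is LOB + 1.

Concordance against an orthogonal panel is computed by set algebra over
(sample, variant) identifiers with true negatives derived from the count of
evaluable slots. PPA = TP/(TP+FN), NPA = TN/(TN+FP); an empty denominator
reports the proportion as absent rather than zero. Intervals are Wilson
score by default — the closed form is implemented directly and swept against
an independent implementation for all k ≤ n ≤ 500 at 1e-12 — with
Clopper–Pearson as an option. With the default truth-set design
(TP 168, FP 1, FN 3, TN 14,285) the PPA is 98.2% (95% CI 94.97–99.40%) and
the NPA 99.993%. The TP/TN values are reconstructions consistent with those
intervals, not independently measured quantities.

## Cohort statistics

* Prevalence is patient-level (positive patients / stratum patients);
  analyte breakdown and detection increase are fusion-level. The two
  coincide except for multi-fusion patients, which is why 1,501 fusions can
  live in 1,497 patients; `StratumCounts` carries both.
* Detection increase = 100 × RNA_only / (DNA_only + both): the relative
  gain in detected fusions from adding RNA-NGS to DNA-NGS.
* χ² tests are uncorrected Pearson by default (Yates available by flag);
  Mann–Whitney U tests are two-sided. Degenerate contingency margins raise
  an error naming the margin.
* Report-style rounding: percentages to 1 d.p., prevalences below 0.2% to
  2 d.p., detection increases to whole percent. Library functions always
  return unrounded values; `report_round` is applied only at reporting time.
* The expression contrast fits a random-intercept linear model of TPM on
  fusion status with cancer type as the grouping factor. The REML fit
  exploits the block structure (V_g = σ²I + τ²J) for closed-form per-group
  algebra; the fixed-effect test uses Satterthwaite degrees of freedom,
  computed from the gradient of the coefficient variance w.r.t. (σ², τ²)
  against the inverse observed REML information (central finite
  differences). The fit is cross-checked in the test suite against
  statsmodels MixedLM (estimates/SEs) and against the reference R
  implementation of the Satterthwaite mixed-model t-test (df and p agree to
  ~1%). TPM is modeled on the natural scale by default; log1p is an option.
  Cancer types with a single fusion status are dropped from per-type tests
  with a warning; the mixed model requires ≥ 2 cancer types.
* The partner-distribution test collapses partners seen in ≤ 1 patient
  (configurable, e.g. ≤ 2 for drivers with slightly larger rare-partner
  tails) into "other" before a χ² test across approval groups, and is
  skipped with a warning when fewer than two partner or group categories
  remain.

## Synthetic cohorts

The generator emulates the data layer the pipeline expects: per-cancer-type
patient counts, per (driver, cancer type, category) fusion counts or
prevalences, over-dispersed read supports (negative binomial, dispersion 3,
truncated by rejection to each category's feasible region), sub-threshold
noise calls in fusion-negative patients (RNA support 1–3; DNA support 15–34
without an RNA match — both provably negative under the rules), blank
panels, orthogonal truth sets, and log-normal TPM with a configurable
upward shift (default +2 log2-fold) in fusion-positive samples. Support
means default to 25 (RNA), 45 (matched DNA) and 60 (high-support DNA),
placing typical calls well above their respective cuts while the truncation
guarantees consistency. Identical (config, seed) pairs produce
byte-identical files.

**Calibrated mode** assigns exact counts, so the pipeline output is an
arithmetic identity of the configuration; this is the mechanism behind the
acceptance checks. The bundled pan-cancer scenario fixes 67,278 patients
across 13 cancer-type buckets, 1,501 fusions in 1,497 patients (four
patients carry two driver fusions each), ALK 497 and NRG1 98 fusions,
approval split 1,059/442 under the bundled matrix, cholangiocarcinoma
134/1,102, pancreatic RNA-only 23/63, thyroid 2/55, and TMB strata
1,369/57,399 (low) vs 127/9,835 (high) with 44 TMB-unknown patients. Cell
values not pinned by those marginals — the per-driver split of the
remaining 906 fusions and most per-cell category mixes — are fixed
editorial choices respecting the scenario's qualitative structure
(RNA-only fractions lowest for RET at 2.3%, highest for NRG1 at 41.8%).
The emerging-driver scenario fixes 218 positives (BRAF 176 / EGFR 42), 122
RNA-only fusions, 114 BRAF RNA-only, yielding a 127% detection increase.

What the synthetic data does **not** emulate: read-level artifacts
(mapping ambiguity, FFPE degradation), assay failure, breakpoint sequence
content, correlated multi-analyte noise, or clinical covariate
distributions beyond simple draws. Passing calibrated tests therefore
demonstrates the correctness of the rules, aggregation and statistics — not
the field performance of any assay.

## Numerical choices and degenerate inputs

* Tie-breaks are lexicographic everywhere a maximum is taken over partners.
* Wilson bounds are clamped to [0, 1] with exact endpoints at k = 0 / k = n.
* The REML optimizer is Nelder–Mead on log-variance coordinates; if the
  observed information is degenerate the Satterthwaite df falls back to the
  residual df n − p.
* Empty strata report `None` rather than 0 for undefined proportions.
* Infeasible calibrated configurations (cell counts exceeding a type's
  patients, TMB tallies not matching arm sizes) fail validation before any
  output is produced.

## Limitations

Upstream callers, manual review, transcript-level annotation and
therapy-outcome analysis are out of scope. The bundled actionability matrix
and domain table are editable data files, not maintained clinical
references. Patient-level and fusion-level denominators differ in
multi-fusion patients; both are exposed and the distinction matters when
comparing percentage figures computed on different denominators.
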