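"""Limit-of-blank estimation and orthogonal-panel concordance.

The blank panel runs 24 fusion-negative samples in duplicate on two reagent
lots (96 measurements); the LOB is the highest support observed in any
blank, and a positive call needs strictly more reads. Concordance against
an orthogonal assay is summarised as PPA/NPA with Wilson 95% intervals.
"""

import dualfusion as df

blanks = df.generate_blanks(seed=7)
lob, threshold = df.estimate_lob(blanks)
print(f"blank measurements: {len(blanks)}, max blank support = LOB = {lob}")
print(f"=> a positive RNA fusion call requires >= {threshold} total supporting reads")

calls, truth, universe = df.generate_truthset(seed=7)
res = df.concordance(calls, truth, universe)
print(f"confusion: TP={res.tp} FP={res.fp} FN={res.fn} TN={res.tn:,}")
print(f"PPA = {100 * res.ppa:.1f}%  "
      f"(95% CI {100 * res.ppa_ci[0]:.2f}%-{100 * res.ppa_ci[1]:.2f}%)")
print(f"NPA = {100 * res.npa:.3f}%  "
      f"(95% CI {100 * res.npa_ci[0]:.3f}%-{100 * res.npa_ci[1]:.4f}%)")
# PPA is the sensitivity analogue (agreement on orthogonal-positive
# variants); NPA the specificity analogue over the evaluable variant slots.
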