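"""Analytic validation of the RNA assay: limit of blank and orthogonal
concordance (PPA/NPA with score confidence intervals).

The limit of blank (LOB) is the highest total supporting read count
observed across replicate runs of fusion-negative material; a positive call
requires support strictly above it. Agreement against an orthogonal panel
is summarised as positive / negative percent agreement with 95% Wilson
score intervals (Clopper-Pearson available as an option).
"""

from __future__ import annotations

import math
from functools import lru_cache
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .model import BlankMeasurement, ConcordanceResult, FusionValidationError


@lru_cache(maxsize=16)
def _z_quantile(conf: float) -> float:
    return float(stats.norm.ppf(0.5 + conf / 2.0))


def estimate_lob(
    blanks: Sequence[BlankMeasurement], percentile: Optional[float] = None
) -> tuple[int, int]:
    """Estimate the limit of blank from replicate blank runs.

    By default the LOB is the maximum observed read support over all
    measurements (lots and replicates pooled); ``percentile`` (0-100)
    switches to an empirical percentile for larger blank panels. The call
    threshold is LOB + 1.
    """
    if not blanks:
        raise FusionValidationError("estimate_lob needs >= 1 blank measurement")
    supports = np.array([b.read_support for b in blanks])
    if percentile is None:
        lob = int(supports.max())
    else:
        if not (0 <= percentile <= 100):
            raise FusionValidationError("percentile must be in [0, 100]")
        lob = int(math.ceil(np.percentile(supports, percentile)))
    return lob, lob + 1


def wilson_ci(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion k/n.

    Closed form: with z the two-sided normal quantile and p = k/n,

        center = (p + z^2/2n) / (1 + z^2/n)
        half   = z * sqrt(p(1-p)/n + z^2/4n^2) / (1 + z^2/n)
    """
    if n <= 0:
        raise FusionValidationError("wilson_ci needs n > 0")
    if not (0 <= k <= n):
        raise FusionValidationError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not (0 < conf < 1):
        raise FusionValidationError("conf must be in (0, 1)")
    z = _z_quantile(conf)
    p = k / n
    denom = 1.0 + z * z / n
    center = (p + z * z / (2.0 * n)) / denom
    half = z * math.sqrt(p * (1.0 - p) / n + z * z / (4.0 * n * n)) / denom
    lo = 0.0 if k == 0 else max(0.0, center - half)  # exact boundary cases
    hi = 1.0 if k == n else min(1.0, center + half)
    return lo, hi


def clopper_pearson_ci(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Exact (Clopper-Pearson) binomial interval, via beta quantiles."""
    if n <= 0:
        raise FusionValidationError("clopper_pearson_ci needs n > 0")
    alpha = 1.0 - conf
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


_CI_METHODS = {"wilson": wilson_ci, "clopper-pearson": clopper_pearson_ci}


def concordance(
    calls: Iterable,
    truth: Iterable,
    universe_size: int,
    conf: float = 0.95,
    ci_method: str = "wilson",
) -> ConcordanceResult:
    """Variant-level agreement between assay calls and an orthogonal truth set.

    ``calls`` and ``truth`` are collections of hashable (sample, variant)
    identifiers; ``universe_size`` is the number of evaluable (sample,
    variant) slots, from which true negatives are derived. PPA = TP/(TP+FN),
    NPA = TN/(TN+FP); an undefined proportion (empty denominator) is
    reported as ``None``, not 0.
    """
    calls, truth = set(calls), set(truth)
    if universe_size < len(calls | truth):
        raise FusionValidationError(
            "universe_size smaller than the union of calls and truth"
        )
    ci = _CI_METHODS[ci_method]
    tp = len(calls & truth)
    fp = len(calls - truth)
    fn = len(truth - calls)
    tn = universe_size - tp - fp - fn

    ppa = npa = ppa_ci = npa_ci = None
    if tp + fn > 0:
        ppa = tp / (tp + fn)
        ppa_ci = ci(tp, tp + fn, conf)
    if tn + fp > 0:
        npa = tn / (tn + fp)
        npa_ci = ci(tn, tn + fp, conf)
    return ConcordanceResult(
        tp=tp, fp=fp, fn=fn, tn=tn, ppa=ppa, npa=npa, ppa_ci=ppa_ci, npa_ci=npa_ci
    )
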