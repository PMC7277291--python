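"""Two-person DNA mixture detection probabilities.

A mixture of two unrelated individuals is "detected" at a locus when the
pooled profile shows at least three distinct alleles — impossible for the
four allele draws of two HWE genotypes at a locus with only two alleles,
and increasingly likely as the effective number of alleles grows.  No
dropout, stutter or analytic-threshold modelling is attempted: detection is
purely an allele-count event.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .panel_model import AlleleFrequencySet

__all__ = [
    "MixtureDetectionResult",
    "mixture_detection_probability",
    "mixture_detection_probability_equal",
    "mixture_probability_oracle",
    "panel_mixture_probability",
]


@dataclass
class MixtureDetectionResult:
    """p_detect: probability of >=3 distinct alleles among two unrelated
    HWE individuals; method is closed_form, enumeration or simulation."""

    locus_id: str
    p_detect: float
    method: str = "closed_form"


def _freq_vector(freqs) -> np.ndarray:
    if isinstance(freqs, AlleleFrequencySet):
        return freqs.frequencies
    return np.asarray(freqs, dtype=float)


def mixture_detection_probability(freqs) -> float:
    """P(>=3 distinct alleles among 4 i.i.d. draws), by inclusion-exclusion.

    p = 1 - [sum_a p_a^4 + sum_{a<b} ((p_a+p_b)^4 - p_a^4 - p_b^4)], i.e. the
    complement of the draws landing in at most two alleles.  Zero whenever
    the locus has fewer than three alleles.
    """
    p = _freq_vector(freqs)
    one_allele = np.sum(p**4)
    two_alleles = 0.0
    for a, b in itertools.combinations(range(len(p)), 2):
        two_alleles += (p[a] + p[b]) ** 4 - p[a] ** 4 - p[b] ** 4
    return float(1.0 - one_allele - two_alleles)


def mixture_detection_probability_equal(k: int) -> float:
    """Closed form at p_i = 1/k: 1 - [k + C(k,2) (2^4 - 2)] / k^4.

    This is also the maximum of :func:`mixture_detection_probability` over
    spectra with k alleles.  k = 3 gives 4/9, k = 4 gives 21/32.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k < 3:
        return 0.0
    return 1.0 - (k + math.comb(k, 2) * 14) / k**4


def mixture_probability_oracle(freqs) -> float:
    """Exact enumeration over all ordered allele 4-tuples (test oracle).

    Independent of the inclusion-exclusion route; bounded at 12 alleles
    (12^4 tuples).
    """
    p = _freq_vector(freqs)
    if len(p) > 12:
        raise ValueError("enumeration oracle bounded at 12 alleles")
    total = 0.0
    for combo in itertools.product(range(len(p)), repeat=4):
        if len(set(combo)) >= 3:
            total += math.prod(p[i] for i in combo)
    return float(total)


def panel_mixture_probability(ae_values) -> float:
    """Cumulative mixture-detection probability from per-locus Ae values.

    Each locus contributes the equal-frequency probability at its *floored*
    Ae (the minimal integral value); floors below 3 contribute nothing.
    Cumulative value is 1 - prod(1 - p_locus).
    """
    ae_values = list(ae_values)
    if any(ae < 1.0 for ae in ae_values):
        raise ValueError("Ae values must be >= 1")
    if not ae_values:
        return 0.0
    log_miss = sum(
        math.log1p(-mixture_detection_probability_equal(math.floor(ae)))
        for ae in ae_values
    )
    return -math.expm1(log_miss)
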