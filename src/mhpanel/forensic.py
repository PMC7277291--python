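"""Forensic summary statistics for microhaplotype loci and panels.

Per locus: the effective number of alleles Ae = 1/sum p_i^2, observed and
expected heterozygosity, the matching probability MP (chance two random
individuals share a genotype), its complement the power of discrimination
PD, and the power of exclusion PE computed from observed heterozygosity.
Panel level: complement-product cumulation (CPD, CPE), the combined
matching probability CMP as a straight product, and the theta-corrected
combined match probability of Balding & Nichols for structured populations.

Cumulative quantities are accumulated in log space: a 20-locus CMP sits at
the 1e-18 scale.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter

import numpy as np

from . import mixture as _mixture
from .panel_model import (
    AlleleFrequencySet,
    LocusStats,
    MatchProbabilityParams,
    PanelStats,
)

__all__ = [
    "effective_num_alleles",
    "expected_heterozygosity",
    "observed_heterozygosity",
    "matching_probability",
    "power_of_discrimination",
    "power_of_exclusion",
    "empirical_allele_freqs",
    "compute_locus_stats",
    "combine_panel",
    "bn_homozygote_match",
    "bn_heterozygote_match",
    "bn_match_probability",
    "combined_bn_match_probability",
]


def effective_num_alleles(freqs: AlleleFrequencySet) -> float:
    """Ae = 1 / sum p_i^2: the equivalent count of equally frequent alleles."""
    return float(1.0 / np.sum(freqs.frequencies**2))


def expected_heterozygosity(freqs: AlleleFrequencySet) -> float:
    """He = 1 - sum p_i^2 = 1 - 1/Ae."""
    return float(1.0 - np.sum(freqs.frequencies**2))


def _non_missing(column) -> list[tuple[str, str]]:
    observed = [g for g in column if g is not None]
    if not observed:
        raise ValueError("no non-missing genotypes")
    return observed


def observed_heterozygosity(column) -> float:
    """Fraction of non-missing genotypes carrying two distinct alleles."""
    observed = _non_missing(column)
    return sum(a != b for a, b in observed) / len(observed)


def matching_probability(column) -> float:
    """MP = sum over observed genotypes of (count/n)^2.

    Computed from observed genotype counts, not HWE expectations, following
    forensic convention.
    """
    observed = _non_missing(column)
    n = len(observed)
    counts = Counter(observed)
    return float(sum((c / n) ** 2 for c in counts.values()))


def power_of_discrimination(column) -> float:
    """PD = 1 - MP."""
    return 1.0 - matching_probability(column)


def power_of_exclusion(ho: float) -> float:
    """PE as a function of observed heterozygosity: Ho^2 (1 - 2 Ho (1-Ho)^2).

    The classic exclusion-power formula of PowerStats-style calculators;
    monotone nondecreasing on [0, 1] with PE(0) = 0 and PE(1) = 1.
    """
    if not 0.0 <= ho <= 1.0:
        raise ValueError(f"Ho must be in [0, 1], got {ho}")
    return ho * ho * (1.0 - 2.0 * ho * (1.0 - ho) ** 2)


def empirical_allele_freqs(column, locus_id: str = "locus") -> AlleleFrequencySet:
    """Allele frequencies by direct gene counting over non-missing genotypes."""
    observed = _non_missing(column)
    counts = Counter(itertools.chain.from_iterable(observed))
    alleles = tuple(sorted(counts))
    total = sum(counts.values())
    freqs = np.array([counts[a] / total for a in alleles])
    return AlleleFrequencySet(locus_id, alleles, freqs)


def compute_locus_stats(
    locus_id: str,
    column,
    freqs: AlleleFrequencySet | None = None,
) -> LocusStats:
    """All per-locus parameters from one genotype column.

    ``freqs`` supplies the population spectrum for Ae/He; when omitted, the
    sample's own gene-count frequencies are used (so He = 1 - 1/Ae holds
    exactly in either case).
    """
    observed = _non_missing(column)
    if freqs is None:
        freqs = empirical_allele_freqs(observed, locus_id)
    ho = observed_heterozygosity(observed)
    mp = matching_probability(observed)
    return LocusStats(
        locus_id=locus_id,
        n_samples=len(observed),
        ae=effective_num_alleles(freqs),
        ho=ho,
        he=expected_heterozygosity(freqs),
        mp=mp,
        pd=1.0 - mp,
        pe=power_of_exclusion(ho),
    )


def combine_panel(stats: list[LocusStats]) -> PanelStats:
    """Cumulative panel parameters from per-locus statistics.

    CPD = 1 - prod(1 - PD_i), CPE likewise, CMP = prod MP_i; products run in
    log space.  The cumulative mixture-detection probability applies the
    per-locus Ae floor rule of :func:`mhpanel.mixture.panel_mixture_probability`.
    """
    if not stats:
        raise ValueError("need at least one locus")
    log_one_minus_cpd = sum(math.log1p(-s.pd) for s in stats)
    log_one_minus_cpe = sum(math.log1p(-s.pe) for s in stats)
    log_cmp = sum(math.log(s.mp) for s in stats)
    return PanelStats(
        locus_stats=list(stats),
        cpd=-math.expm1(log_one_minus_cpd),
        cpe=-math.expm1(log_one_minus_cpe),
        cmp=math.exp(log_cmp),
        mixture_probability=_mixture.panel_mixture_probability([s.ae for s in stats]),
    )


# ---------------------------------------------------------------------------
# Theta-corrected (Balding-Nichols) match probability


def bn_homozygote_match(p: float, theta: float) -> float:
    """P(second individual is {i,i} | first is {i,i}), coancestry theta:
    (2 theta + (1-theta) p)(3 theta + (1-theta) p) / ((1+theta)(1+2 theta))."""
    denom = (1.0 + theta) * (1.0 + 2.0 * theta)
    return (2.0 * theta + (1.0 - theta) * p) * (3.0 * theta + (1.0 - theta) * p) / denom


def bn_heterozygote_match(p_i: float, p_j: float, theta: float) -> float:
    """P(second individual is {i,j} | first is {i,j}), i != j:
    2 (theta + (1-theta) p_i)(theta + (1-theta) p_j) / ((1+theta)(1+2 theta))."""
    denom = (1.0 + theta) * (1.0 + 2.0 * theta)
    return 2.0 * (theta + (1.0 - theta) * p_i) * (theta + (1.0 - theta) * p_j) / denom


def bn_match_probability(
    freqs: AlleleFrequencySet, params: MatchProbabilityParams | float = 0.0
) -> float:
    """Per-locus match probability under HWE priors with theta correction.

    MP = sum over genotypes G of P_HWE(G) * P(same G in a second individual
    | first has G, theta).  At theta = 0 this reduces to sum_G P(G)^2.
    """
    theta = params.theta if isinstance(params, MatchProbabilityParams) else float(params)
    if not 0.0 <= theta < 1.0:
        raise ValueError(f"theta must be in [0, 1), got {theta}")
    p = freqs.frequencies
    mp = 0.0
    for i in range(len(p)):
        mp += p[i] ** 2 * bn_homozygote_match(p[i], theta)
        for j in range(i + 1, len(p)):
            mp += 2.0 * p[i] * p[j] * bn_heterozygote_match(p[i], p[j], theta)
    return float(mp)


def combined_bn_match_probability(
    freq_sets: list[AlleleFrequencySet], params: MatchProbabilityParams | float = 0.0
) -> float:
    """Combined match probability across loci: product of per-locus values."""
    log_mp = sum(math.log(bn_match_probability(fs, params)) for fs in freq_sets)
    return math.exp(log_mp)
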