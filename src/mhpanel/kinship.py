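"""Duo (single parent + child) paternity testing with microhaplotypes.

Per locus the paternity index PI is the likelihood ratio
P(child genotype | parent is a true parent) / P(child genotype | unrelated),
with transmission probability 1/2 per parental allele and the untransmitted
allele drawn from the population spectrum; the combined paternity index CPI
is the product over loci, with CPI >= 10 000 the conventional confirmation
threshold.  The default policy is no-mutation: a Mendelian exclusion (no
shared allele) gives PI = 0 and hence CPI = 0.  An optional
mutation-tolerant policy rescales transmission probabilities by a
single-step uniform replacement model instead.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping

from .panel_model import AlleleFrequencySet, DuoRecord, KinshipResult

__all__ = [
    "KinshipPolicy",
    "mendelian_check",
    "duo_pi",
    "cpi",
    "classify_cpi",
]

logger = logging.getLogger(__name__)

DEFAULT_CPI_THRESHOLD = 10_000.0


@dataclass
class KinshipPolicy:
    """mutation_rate 0 = no-mutation policy (exclusions zero out the CPI).
    ``rare_allele_db_size`` sets the minimum-allele-count floor frequency
    5/(2n+2) applied when an observed allele is absent from the frequency
    database.  ``exclude_loci`` are dropped from the product (e.g. loci
    flagged by LD tests)."""

    mutation_rate: float = 0.0
    rare_allele_db_size: int = 50
    threshold: float = DEFAULT_CPI_THRESHOLD
    min_exclusions_for_verdict: int = 1
    exclude_loci: tuple[str, ...] = ()

    def __post_init__(self):
        if not 0.0 <= self.mutation_rate < 1.0:
            raise ValueError("mutation_rate must be in [0, 1)")

    @property
    def floor_frequency(self) -> float:
        return 5.0 / (2.0 * self.rare_allele_db_size + 2.0)


def mendelian_check(parent: tuple[str, str], child: tuple[str, str]) -> bool:
    """True iff parent and child genotypes share at least one allele."""
    return bool(set(parent) & set(child))


def duo_pi(
    parent: tuple[str, str],
    child: tuple[str, str],
    freqs: AlleleFrequencySet,
    policy: KinshipPolicy | None = None,
) -> float:
    """Single-locus paternity index for a duo.

    PI = P(child | parent, parentage) / P(child | unrelated).  The
    numerator sums over the parent transmitting each of its alleles with
    probability 1/2 (optionally mutated under the policy's single-step
    uniform replacement model) and the child's other allele drawn from the
    population; the denominator is the child's HWE genotype probability.
    Invariant to allele ordering within either genotype.
    """
    policy = policy or KinshipPolicy()
    floor = policy.floor_frequency
    p = {a: _freq(freqs, a, floor) for a in set(parent) | set(child)}
    c1, c2 = child
    k = len(freqs.alleles)
    mu = policy.mutation_rate

    def transmit(allele: str) -> float:
        # P(parent passes `allele`) under the replacement mutation model
        direct = sum(0.5 for pa in parent if pa == allele)
        if mu == 0.0:
            return direct
        mutated = sum(0.5 for pa in parent if pa != allele) * (mu / max(k - 1, 1))
        return direct * (1.0 - mu) + mutated

    if c1 == c2:
        numerator = transmit(c1) * p[c1]
        denominator = p[c1] ** 2
    else:
        numerator = transmit(c1) * p[c2] + transmit(c2) * p[c1]
        denominator = 2.0 * p[c1] * p[c2]
    return numerator / denominator


def _freq(freqs: AlleleFrequencySet, allele: str, floor: float) -> float:
    table = freqs.as_dict()
    if allele not in table:
        logger.info(
            "%s: allele %r absent from frequency database; floor %.4g applied",
            freqs.locus_id, allele, floor,
        )
        return floor
    return max(table[allele], 1e-12)


def cpi(
    duo: DuoRecord,
    freq_db: Mapping[str, AlleleFrequencySet],
    policy: KinshipPolicy | None = None,
) -> KinshipResult:
    """Combined paternity index over all loci with data and frequencies.

    Loci with a missing genotype or no frequency set — or listed in the
    policy's ``exclude_loci`` — are skipped (and logged); exclusion loci
    (no shared allele) are always listed, and zero the CPI under the
    no-mutation policy.
    """
    policy = policy or KinshipPolicy()
    pi_by_locus: dict[str, float] = {}
    exclusions, skipped = [], []
    for locus in duo.loci:
        parent, child = duo.parent[locus], duo.child[locus]
        if locus in policy.exclude_loci or parent is None or child is None or locus not in freq_db:
            skipped.append(locus)
            logger.info("duo %s: locus %s skipped from CPI", duo.duo_id, locus)
            continue
        if not mendelian_check(parent, child):
            exclusions.append(locus)
        pi_by_locus[locus] = duo_pi(parent, child, freq_db[locus], policy)
    if not pi_by_locus:
        raise ValueError(f"duo {duo.duo_id}: no loci available for CPI")

    if any(pi == 0.0 for pi in pi_by_locus.values()):
        cpi_value, log10_cpi = 0.0, float("-inf")
    else:
        log10_cpi = sum(math.log10(pi) for pi in pi_by_locus.values())
        cpi_value = 10.0**log10_cpi
    verdict = classify_cpi(
        cpi_value,
        threshold=policy.threshold,
        n_exclusions=len(exclusions),
        min_exclusions=policy.min_exclusions_for_verdict,
    )
    return KinshipResult(
        duo_id=duo.duo_id,
        pi=pi_by_locus,
        cpi=cpi_value,
        log10_cpi=log10_cpi,
        exclusions=exclusions,
        skipped=skipped,
        verdict=verdict,
    )


def classify_cpi(
    cpi_value: float,
    threshold: float = DEFAULT_CPI_THRESHOLD,
    n_exclusions: int = 0,
    min_exclusions: int = 1,
) -> str:
    """"supported" at CPI >= threshold, "excluded" at CPI = 0 or enough
    exclusion loci, otherwise "inconclusive"."""
    if cpi_value < 0:
        raise ValueError("CPI must be nonnegative")
    if cpi_value == 0.0 or n_exclusions >= max(min_exclusions, 1):
        return "excluded"
    if cpi_value >= threshold:
        return "supported"
    return "inconclusive"
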