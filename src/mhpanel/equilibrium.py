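"""Hardy-Weinberg and linkage-disequilibrium testing for multi-allelic loci.

The HWE "exact" test is a Guo-Thompson-style Monte-Carlo test: the 2n
observed alleles are repeatedly re-paired at random and the conditional
probability of each resulting genotype table (given the allele counts) is
compared with the observed table's; a full-enumeration version is provided
for tiny samples as an oracle.  LD between two microhaplotype loci is a
chi-square statistic on EM-estimated two-locus haplotype frequencies,
calibrated by permuting one locus's genotypes across samples.  The
multi-allelic r-squared summary is the frequency-weighted average of the
per-allele-pair squared correlations.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .popstruct import em_haplotype_freqs

__all__ = [
    "HweTestResult",
    "LDResult",
    "hwe_exact_test",
    "hwe_exact_test_full",
    "bonferroni_threshold",
    "ld_permutation_test",
    "multiallelic_r2",
    "joint_haplotype_freqs",
]


@dataclass
class HweTestResult:
    """Add-one permutation p-value: p >= 1/(n_permutations + 1) always."""

    locus_id: str
    p_value: float
    n_permutations: int
    seed: int
    statistic: float


@dataclass
class LDResult:
    """Pairwise LD: permutation p-value for the chi-square statistic on the
    EM-estimated joint haplotype table, plus the r2 summary and D table
    (D_ij = h_ij - p_i q_j; rows and columns sum to 0)."""

    loci: tuple[str, str]
    p_value: float
    r2: float
    chi2: float
    d_table: pd.DataFrame
    n_permutations: int
    seed: int


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Corrected per-test significance threshold alpha / n_tests."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


# ---------------------------------------------------------------------------
# HWE


def _column_to_codes(column) -> tuple[np.ndarray, list]:
    observed = [g for g in column if g is not None]
    alleles = sorted({a for g in observed for a in g})
    index = {a: i for i, a in enumerate(alleles)}
    codes = np.array([[index[a], index[b]] for a, b in observed])
    return codes, alleles


def _table_log_prob_stat(lo: np.ndarray, hi: np.ndarray, k: int) -> np.ndarray:
    """Variable part of log P(genotype table | allele counts): h ln2 - sum ln n_g!

    ``lo``/``hi`` are (m, n) sorted allele-index pairs for m tables.
    """
    m, n = lo.shape
    codes = lo * k + hi + (np.arange(m) * k * k)[:, None]
    counts = np.bincount(codes.ravel(), minlength=m * k * k).reshape(m, k * k)
    het = np.sum(lo != hi, axis=1)
    return het * math.log(2.0) - gammaln(counts + 1.0).sum(axis=1)


def hwe_exact_test(
    column,
    n_permutations: int = 100_000,
    seed: int = 0,
    locus_id: str = "locus",
) -> HweTestResult:
    """Monte-Carlo exact test for HWE on one genotype column.

    The 2n alleles are shuffled into n pairs ``n_permutations`` times; the
    p-value is the add-one fraction of shuffles whose table is as probable
    or less probable (conditional on allele counts) than the observed one.
    A locus with fewer than two distinct alleles is untestable (p = 1, with
    a warning).
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    codes, alleles = _column_to_codes(column)
    k = len(alleles)
    if k < 2:
        warnings.warn(f"{locus_id}: HWE test undefined for <2 alleles; p = 1", stacklevel=2)
        return HweTestResult(locus_id, 1.0, n_permutations, seed, 0.0)
    n = codes.shape[0]
    lo, hi = codes.min(axis=1)[None, :], codes.max(axis=1)[None, :]
    stat_obs = float(_table_log_prob_stat(lo, hi, k)[0])

    pool = codes.ravel()
    rng = np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(23,)))
    count_le = 0
    remaining = n_permutations
    chunk = max(1, min(5000, (2_000_000 // (2 * n)) or 1))
    while remaining > 0:
        m = min(chunk, remaining)
        perms = rng.permuted(np.tile(pool, (m, 1)), axis=1)
        a, b = perms[:, :n], perms[:, n:]
        stats = _table_log_prob_stat(np.minimum(a, b), np.maximum(a, b), k)
        count_le += int(np.sum(stats <= stat_obs + 1e-9))
        remaining -= m
    p = (count_le + 1) / (n_permutations + 1)
    return HweTestResult(locus_id, p, n_permutations, seed, stat_obs)


def hwe_exact_test_full(column, locus_id: str = "locus") -> HweTestResult:
    """Full-enumeration exact HWE test (oracle; n <= 10 and <= 3 alleles).

    Enumerates every genotype table consistent with the observed allele
    counts and sums the conditional probabilities of tables no more
    probable than the observed one.
    """
    codes, alleles = _column_to_codes(column)
    k, n = len(alleles), codes.shape[0]
    if n > 10 or k > 3:
        raise ValueError("enumeration oracle limited to n <= 10 and <= 3 alleles")
    if k < 2:
        return HweTestResult(locus_id, 1.0, 0, 0, 0.0)
    allele_counts = np.bincount(codes.ravel(), minlength=k)
    cells = [(i, j) for i in range(k) for j in range(i, k)]

    def table_stat(cnt: dict) -> float:
        het = sum(c for (i, j), c in cnt.items() if i != j)
        return het * math.log(2.0) - sum(math.lgamma(c + 1) for c in cnt.values())

    obs_counts = {}
    for a, b in codes:
        key = (min(a, b), max(a, b))
        obs_counts[key] = obs_counts.get(key, 0) + 1
    stat_obs = table_stat(obs_counts)

    # log of the constant factor: ln n! + sum ln c_a! - ln (2n)!
    log_const = (
        math.lgamma(n + 1)
        + sum(math.lgamma(c + 1) for c in allele_counts)
        - math.lgamma(2 * n + 1)
    )

    total_p = 0.0
    extreme_p = 0.0

    def recurse(idx: int, left: np.ndarray, used: int, cnt: dict):
        nonlocal total_p, extreme_p
        if idx == len(cells):
            if used == n and not left.any():
                stat = table_stat(cnt)
                prob = math.exp(log_const + stat)
                total_p += prob
                if stat <= stat_obs + 1e-9:
                    extreme_p += prob
            return
        i, j = cells[idx]
        max_c = min(left[i] // 2, n - used) if i == j else min(left[i], left[j], n - used)
        for c in range(max_c + 1):
            new_left = left.copy()
            new_left[i] -= 2 * c if i == j else c
            if i != j:
                new_left[j] -= c
            cnt[cells[idx]] = c
            recurse(idx + 1, new_left, used + c, cnt)
        del cnt[cells[idx]]

    recurse(0, allele_counts.copy(), 0, {})
    assert abs(total_p - 1.0) < 1e-9, "enumeration probabilities must sum to 1"
    return HweTestResult(locus_id, min(extreme_p, 1.0), 0, 0, stat_obs)


# ---------------------------------------------------------------------------
# LD


def joint_haplotype_freqs(col_a, col_b) -> pd.DataFrame:
    """EM-estimated joint haplotype frequency matrix for two loci.

    Each locus is treated as one multi-allelic 'site'; the EM resolves the
    double-heterozygote phase ambiguity exactly as for within-locus SNPs.
    Rows are locus-A alleles, columns locus-B alleles; entries sum to 1.
    """
    pairs = [
        (ga, gb) for ga, gb in zip(col_a, col_b) if ga is not None and gb is not None
    ]
    if not pairs:
        raise ValueError("no samples typed at both loci")
    genotypes = [(ga, gb) for ga, gb in pairs]
    est = em_haplotype_freqs(genotypes, locus_id="joint")
    alleles_a = sorted({a for ga, _ in pairs for a in ga})
    alleles_b = sorted({b for _, gb in pairs for b in gb})
    mat = pd.DataFrame(0.0, index=alleles_a, columns=alleles_b)
    for (ha, hb), f in zip(est.haplotypes, est.frequencies):
        mat.at[ha, hb] += f
    return mat


def multiallelic_r2(joint) -> float:
    """Frequency-weighted average r2 over allele pairs of two loci.

    D_ij = h_ij - p_i q_j; r2_ij = D_ij^2 / (p_i (1-p_i) q_j (1-q_j));
    r2 = sum_ij p_i q_j r2_ij.  Allele pairs with a fixed allele
    (denominator 0) are skipped and the weights renormalized.
    """
    h = joint.to_numpy(dtype=float) if isinstance(joint, pd.DataFrame) else np.asarray(joint, dtype=float)
    if abs(h.sum() - 1.0) > 1e-6:
        raise ValueError("joint frequencies must sum to 1")
    p = h.sum(axis=1)
    q = h.sum(axis=0)
    d = h - np.outer(p, q)
    denom = np.outer(p * (1.0 - p), q * (1.0 - q))
    valid = denom > 1e-15
    if not valid.any():
        return 0.0
    r2 = np.zeros_like(h)
    r2[valid] = d[valid] ** 2 / denom[valid]
    weights = np.outer(p, q)
    wsum = weights[valid].sum()
    return float((weights[valid] * r2[valid]).sum() / wsum)


def _ld_chi2(joint: pd.DataFrame, n: int) -> float:
    h = joint.to_numpy(dtype=float)
    p = h.sum(axis=1)
    q = h.sum(axis=0)
    expected = np.outer(p, q)
    valid = expected > 1e-15
    return float(2 * n * np.sum((h[valid] - expected[valid]) ** 2 / expected[valid]))


def ld_permutation_test(
    col_a,
    col_b,
    n_permutations: int = 10_000,
    seed: int = 0,
    loci: tuple[str, str] = ("locusA", "locusB"),
) -> LDResult:
    """Permutation-calibrated chi-square LD test between two loci.

    The observed statistic is the chi-square of the EM-estimated joint
    haplotype table against the product of its marginals; the null
    distribution is obtained by permuting locus B's genotypes across
    samples (breaking any inter-locus association while preserving both
    single-locus distributions).  Monomorphic loci yield p = 1.
    """
    keep = [i for i, (ga, gb) in enumerate(zip(col_a, col_b)) if ga is not None and gb is not None]
    a = [col_a[i] for i in keep]
    b = [col_b[i] for i in keep]
    n = len(keep)
    if n == 0:
        raise ValueError("no samples typed at both loci")
    mono_a = len({x for g in a for x in g}) < 2
    mono_b = len({x for g in b for x in g}) < 2
    if mono_a or mono_b:
        warnings.warn(f"{loci}: monomorphic locus, LD test undefined; p = 1", stacklevel=2)
        empty = pd.DataFrame()
        return LDResult(loci, 1.0, 0.0, 0.0, empty, n_permutations, seed)

    joint = joint_haplotype_freqs(a, b)
    chi2_obs = _ld_chi2(joint, n)
    r2 = multiallelic_r2(joint)
    p_a = joint.sum(axis=1).to_numpy()
    q_b = joint.sum(axis=0).to_numpy()
    d_table = joint - pd.DataFrame(np.outer(p_a, q_b), index=joint.index, columns=joint.columns)

    rng = np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(29,)))
    count_ge = 0
    for _ in range(n_permutations):
        order = rng.permutation(n)
        chi2 = _ld_chi2(joint_haplotype_freqs(a, [b[i] for i in order]), n)
        if chi2 >= chi2_obs - 1e-9:
            count_ge += 1
    p = (count_ge + 1) / (n_permutations + 1)
    return LDResult(loci, p, r2, chi2_obs, d_table, n_permutations, seed)
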