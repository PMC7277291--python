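"""Population-level analyses: haplotype-frequency EM, pairwise Fst, NJ trees.

The EM estimator recovers haplotype frequencies from unphased multi-site
genotypes (the desk-scale substitute for Bayesian phasing tools): the
E-step distributes each ambiguous genotype over its consistent haplotype
pairs in proportion to current frequency products, the M-step re-counts.
Pairwise population differentiation uses a Hudson-style Fst on haplotype
frequencies, and trees over populations are built with neighbour-joining
(Saitou-Nei) with deterministic label-order tie-breaking.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from skbio import TreeNode

from .panel_model import AlleleFrequencySet, DistanceMatrix, GenotypeTable

__all__ = [
    "EmEstimate",
    "consistent_haplotype_pairs",
    "em_haplotype_freqs",
    "hudson_fst",
    "pairwise_fst",
    "fst_from_genotypes",
    "nj_tree",
]

MAX_EM_SITES = 6  # haplotype space bound: at most 3^6 haplotypes per locus


@dataclass
class EmEstimate:
    """EM result: haplotypes are tuples of per-site alleles; the
    log-likelihood trace is nondecreasing across iterations."""

    locus_id: str
    haplotypes: tuple[tuple, ...]
    frequencies: np.ndarray
    loglik_trace: list[float]
    iterations: int
    converged: bool

    @property
    def loglik(self) -> float:
        return self.loglik_trace[-1]

    def frequency_set(self) -> AlleleFrequencySet:
        """As an AlleleFrequencySet with concatenated allele strings (for
        single-character per-site alleles, i.e. SNP bases)."""
        return AlleleFrequencySet(
            self.locus_id,
            tuple("".join(map(str, h)) for h in self.haplotypes),
            self.frequencies,
        )


def consistent_haplotype_pairs(genotype: Sequence[tuple]) -> list[tuple[tuple, tuple]]:
    """All unordered haplotype pairs consistent with one multi-site genotype.

    A genotype is a tuple of per-site unordered allele pairs.  With s
    heterozygous sites there are 2^(s-1) distinct configurations (the first
    heterozygous site anchors hap1, removing the global swap symmetry); a
    fully homozygous genotype has exactly one.
    """
    het_sites = [i for i, (a, b) in enumerate(genotype) if a != b]
    base1 = [a for a, _ in genotype]
    base2 = [b for _, b in genotype]
    if not het_sites:
        h = tuple(base1)
        return [(h, h)]
    pairs = []
    for flips in itertools.product((False, True), repeat=len(het_sites) - 1):
        h1, h2 = list(base1), list(base2)
        for site, flip in zip(het_sites[1:], flips):
            if flip:
                h1[site], h2[site] = h2[site], h1[site]
        pairs.append((tuple(h1), tuple(h2)))
    return pairs


def em_haplotype_freqs(
    genotypes: Sequence[Sequence[tuple] | None],
    tol: float = 1e-8,
    max_iter: int = 500,
    n_restarts: int = 1,
    seed: int = 0,
    locus_id: str = "locus",
) -> EmEstimate:
    """Haplotype-frequency EM from unphased multi-site genotypes.

    ``genotypes``: per sample, a tuple of per-site unordered allele pairs
    (``None`` samples are skipped).  Restart 0 initializes uniformly over
    the observed-compatible haplotypes; further restarts draw Dirichlet(1)
    initial frequencies from ``seed`` and the best final log-likelihood
    wins (ties to the earliest restart).
    """
    observed = [g for g in genotypes if g is not None]
    if not observed:
        raise ValueError("no non-missing genotypes")
    n_sites = len(observed[0])
    if n_sites > MAX_EM_SITES:
        raise ValueError(f"EM supports at most {MAX_EM_SITES} sites, got {n_sites}")
    if any(len(g) != n_sites for g in observed):
        raise ValueError("inconsistent site counts across samples")

    # Expand each sample once; the pair structure is fixed across iterations.
    hap_index: dict[tuple, int] = {}
    pair_h1, pair_h2, pair_sample = [], [], []
    for s, g in enumerate(observed):
        for h1, h2 in consistent_haplotype_pairs(g):
            pair_h1.append(hap_index.setdefault(h1, len(hap_index)))
            pair_h2.append(hap_index.setdefault(h2, len(hap_index)))
            pair_sample.append(s)
    haps = tuple(sorted(hap_index, key=hap_index.get))
    h1 = np.asarray(pair_h1)
    h2 = np.asarray(pair_h2)
    smp = np.asarray(pair_sample)
    het_mult = np.where(h1 != h2, 2.0, 1.0)
    n, k = len(observed), len(haps)

    rng = np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(17,)))
    best = None
    for restart in range(max(1, n_restarts)):
        f = np.full(k, 1.0 / k) if restart == 0 else rng.dirichlet(np.ones(k))
        trace, converged = [], False
        for it in range(max_iter):
            w = f[h1] * f[h2] * het_mult
            per_sample = np.zeros(n)
            np.add.at(per_sample, smp, w)
            loglik = float(np.sum(np.log(per_sample)))
            if trace and loglik < trace[-1] - 1e-9:
                raise AssertionError("EM log-likelihood decreased")
            done = bool(trace) and abs(loglik - trace[-1]) < tol
            trace.append(loglik)
            if done:
                converged = True
                break
            resp = w / per_sample[smp]
            counts = np.zeros(k)
            np.add.at(counts, h1, resp)
            np.add.at(counts, h2, resp)
            f = counts / (2.0 * n)
        est = EmEstimate(locus_id, haps, f, trace, len(trace), converged)
        if best is None or est.loglik > best.loglik + 1e-12:
            best = est
    return best


# ---------------------------------------------------------------------------
# Fst


def _aligned_freqs(a: AlleleFrequencySet, b: AlleleFrequencySet):
    alleles = sorted(set(a.alleles) | set(b.alleles))
    da, db = a.as_dict(), b.as_dict()
    return (
        np.array([da.get(x, 0.0) for x in alleles]),
        np.array([db.get(x, 0.0) for x in alleles]),
    )


def hudson_fst(
    freqs_a: Mapping[str, AlleleFrequencySet],
    freqs_b: Mapping[str, AlleleFrequencySet],
    n_a: Mapping[str, int] | None = None,
    n_b: Mapping[str, int] | None = None,
) -> float:
    """Multi-locus Hudson-style Fst between two populations.

    Per locus, F = (Hb - Hw) / Hb with Hb = 1 - sum p q (between-population
    heterozygosity) and Hw the average within-population heterozygosity,
    bias-corrected by n/(n-1) when haplotype sample sizes are supplied.
    Loci are combined as a ratio of averages; the raw estimate may be
    slightly negative in undifferentiated populations.
    """
    shared = sorted(set(freqs_a) & set(freqs_b))
    if not shared:
        raise ValueError("populations share no loci")
    num = den = 0.0
    for locus in shared:
        p, q = _aligned_freqs(freqs_a[locus], freqs_b[locus])
        hw_a = 1.0 - np.sum(p**2)
        hw_b = 1.0 - np.sum(q**2)
        if n_a is not None and n_a[locus] > 1:
            hw_a *= n_a[locus] / (n_a[locus] - 1)
        if n_b is not None and n_b[locus] > 1:
            hw_b *= n_b[locus] / (n_b[locus] - 1)
        hb = 1.0 - np.sum(p * q)
        num += hb - 0.5 * (hw_a + hw_b)
        den += hb
    if den == 0.0:  # both populations fixed for the same alleles everywhere
        return 0.0
    return float(num / den)


def pairwise_fst(
    pop_freqs: Mapping[str, Mapping[str, AlleleFrequencySet]],
    pop_sizes: Mapping[str, Mapping[str, int]] | None = None,
) -> DistanceMatrix:
    """All pairwise Hudson Fst values as a DistanceMatrix.

    ``pop_freqs`` maps population label -> {locus -> AlleleFrequencySet};
    ``pop_sizes`` optionally maps label -> {locus -> haplotype count} for
    the within-heterozygosity bias correction.  Negative estimates are
    truncated to 0 in ``values``; ``raw`` keeps them.
    """
    labels = tuple(sorted(pop_freqs))
    if len(labels) < 2:
        raise ValueError("need at least 2 populations")
    raw = np.zeros((len(labels), len(labels)))
    for i, j in itertools.combinations(range(len(labels)), 2):
        a, b = labels[i], labels[j]
        raw[i, j] = raw[j, i] = hudson_fst(
            pop_freqs[a],
            pop_freqs[b],
            pop_sizes.get(a) if pop_sizes else None,
            pop_sizes.get(b) if pop_sizes else None,
        )
    return DistanceMatrix(labels, np.maximum(raw, 0.0), raw=raw)


def fst_from_genotypes(tables: Mapping[str, GenotypeTable]) -> DistanceMatrix:
    """Pairwise Fst from per-population genotype tables (gene counting)."""
    from .forensic import empirical_allele_freqs

    pop_freqs, pop_sizes = {}, {}
    for label, table in tables.items():
        freqs, sizes = {}, {}
        for locus in table.loci:
            col = table.column(locus, drop_missing=True)
            if col:
                freqs[locus] = empirical_allele_freqs(col, locus)
                sizes[locus] = 2 * len(col)
        if not freqs:
            raise ValueError(f"population {label!r} has no genotypes at any locus")
        pop_freqs[label] = freqs
        pop_sizes[label] = sizes
    return pairwise_fst(pop_freqs, pop_sizes)


# ---------------------------------------------------------------------------
# Neighbour-joining


def nj_tree(distances: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbour-joining over a population distance matrix.

    Standard Q-criterion agglomeration with the usual branch-length
    formulas; ties in Q are broken by the lexicographically smallest pair
    of subtree labels (each subtree is keyed by its smallest leaf name), so
    the result is deterministic.  Returns an unrooted tree represented with
    a trifurcating (or, for 2 taxa, bifurcating) root.
    """
    labels = list(distances.labels)
    if len(labels) < 2:
        raise ValueError("need at least 2 taxa")
    nodes = [TreeNode(name=l) for l in labels]
    keys = [(l,) for l in labels]  # smallest leaf name per subtree
    d = distances.values.astype(float).copy()

    while len(nodes) > 3:
        n = len(nodes)
        r = d.sum(axis=1)
        best_pair, best_q = None, np.inf
        for i, j in itertools.combinations(range(n), 2):
            q = (n - 2) * d[i, j] - r[i] - r[j]
            tie_key = tuple(sorted((keys[i][0], keys[j][0])))
            if q < best_q - 1e-12 or (
                abs(q - best_q) <= 1e-12 and best_pair and tie_key < best_pair[2]
            ):
                best_pair, best_q = (i, j, tie_key), q
        i, j, _ = best_pair
        vi = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (n - 2))
        vj = d[i, j] - vi
        parent = TreeNode()
        nodes[i].length = float(vi)
        nodes[j].length = float(vj)
        parent.extend([nodes[i], nodes[j]])
        d_new = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [m for m in range(n) if m not in (i, j)]
        d = np.pad(d[np.ix_(keep, keep)], ((0, 1), (0, 1)))
        d[-1, :-1] = d[:-1, -1] = d_new[keep]
        nodes = [nodes[m] for m in keep] + [parent]
        keys = [keys[m] for m in keep] + [min(keys[i], keys[j])]

    root = TreeNode()
    if len(nodes) == 2:
        half = 0.5 * d[0, 1]
        nodes[0].length = nodes[1].length = float(half)
        root.extend(nodes)
    else:
        va = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
        vb = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
        vc = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
        for node, v in zip(nodes, (va, vb, vc)):
            node.length = float(v)
        root.extend(nodes)
    return root
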