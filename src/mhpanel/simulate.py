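"""Synthetic genotype data with known ground truth.

Everything the pipeline consumes can be generated here: Dirichlet allele
frequency spectra, Hardy-Weinberg genotype tables, Mendelian parent/child
duos, two-person mixtures, Balding-Nichols drifted subpopulations, and VCF
fixtures for marker screening.  The default panel mirrors the study
conditions of the bundled reference panel: 20 loci whose spectra are tuned
to the published effective-allele (Ae) values — 15 loci with Ae in [3, 4),
4 with Ae >= 4 and 1 with Ae < 3 — typed in samples of 50 individuals.

Reproducibility: one global seed expands into per-operation substreams
(numpy ``SeedSequence`` spawn keys), so adding loci or operations does not
perturb earlier draws.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np

from .panel_model import (
    AlleleFrequencySet,
    DuoRecord,
    GenotypeTable,
    MicrohapLocus,
    make_locus_name,
)

__all__ = [
    "SimulationConfig",
    "sample_allele_freqs",
    "hwe_genotypes",
    "hwe_genotype_table",
    "simulate_duos",
    "bn_population_freqs",
    "simulate_mixture_profiles",
    "unphased_from_haplotypes",
    "haplotype_alphabet",
    "spectrum_with_ae",
    "synthetic_panel_freqs",
    "REFERENCE_AE_TARGETS",
    "write_variants_vcf",
    "WindowSpec",
    "write_screening_vcf",
]

# Published per-locus Ae values of the reference panel; the default
# synthetic panel reproduces exactly this spectrum shape (floors 15x3, 4x4, 1x2).
REFERENCE_AE_TARGETS = (
    3.021, 3.247, 2.818, 4.647, 3.709, 3.484, 3.251, 4.129, 3.971, 3.133,
    4.219, 3.820, 3.903, 3.834, 3.674, 3.519, 3.808, 4.995, 3.737, 3.559,
)

# substream codes for SeedSequence spawn keys
_FREQS, _GENO, _DUOS, _BN, _MIX, _VCF = range(6)


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=key))


@dataclass
class SimulationConfig:
    """Study-scale defaults: 20 loci typed in 50 individuals (duo count 12)."""

    seed: int = 0
    n_samples: int = 50
    n_loci: int = 20
    n_duos: int = 12
    alleles_per_locus: int = 6
    dirichlet_concentration: float = 1.0
    theta_drift: float = 0.05
    mutation_rate: float = 0.0

    def __post_init__(self):
        if not 0 < self.theta_drift < 1:
            raise ValueError("theta_drift must be in (0, 1)")
        if self.dirichlet_concentration <= 0:
            raise ValueError("dirichlet_concentration must be positive")
        if not 0 <= self.mutation_rate < 1:
            raise ValueError("mutation_rate must be in [0, 1)")


def haplotype_alphabet(k: int, n_snps: int = 3) -> tuple[str, ...]:
    """``k`` phase-identifiable haplotype strings of length ``n_snps`` over A/C/G/T.

    Haplotypes are chosen greedily so that no two *disjoint* pairs from the
    set produce the same unphased multi-SNP genotype — otherwise simulated
    truth would be unrecoverable in principle from phase-stripped data
    (e.g. AAC/ACA and AAA/ACC collapse to the same genotype).
    """

    def genotype_key(h1: str, h2: str) -> tuple:
        return tuple(tuple(sorted(p)) for p in zip(h1, h2))

    chosen: list[str] = []
    seen_keys: set[tuple] = set()
    # diagonal-first order spreads alleles across sites before reusing them
    candidates = sorted(
        ("".join(h) for h in itertools.product("ACGT", repeat=n_snps)),
        key=lambda h: (len(set(h)) < min(n_snps, 4), h),
    )
    for cand in candidates:
        keys = {genotype_key(cand, h) for h in chosen}
        if len(keys) == len(chosen) and not (keys & seen_keys):
            chosen.append(cand)
            seen_keys |= keys
            if len(chosen) == k:
                return tuple(chosen)
    raise ValueError(f"cannot form {k} phase-identifiable haplotypes from {n_snps} SNPs")


def sample_allele_freqs(
    k: int,
    concentration: float = 1.0,
    seed: int = 0,
    locus_id: str = "mh01sim001",
    n_snps: int = 3,
) -> AlleleFrequencySet:
    """Draw a k-allele spectrum from a symmetric Dirichlet(concentration)."""
    if k < 2:
        raise ValueError(f"need at least 2 alleles, got {k}")
    rng = _rng(seed, _FREQS)
    freqs = rng.dirichlet(np.full(k, float(concentration)))
    return AlleleFrequencySet(locus_id, haplotype_alphabet(k, n_snps), freqs)


def hwe_genotypes(freqs: AlleleFrequencySet, n: int, seed: int = 0) -> list[tuple[str, str]]:
    """``n`` genotypes as two independent allele draws each (random mating)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _rng(seed, _GENO)
    draws = rng.choice(len(freqs.alleles), size=(n, 2), p=freqs.frequencies)
    return [tuple(sorted((freqs.alleles[a], freqs.alleles[b]))) for a, b in draws]


def hwe_genotype_table(
    freq_sets: list[AlleleFrequencySet], n: int, seed: int = 0, prefix: str = "S"
) -> GenotypeTable:
    """HWE genotype table over a panel; per-locus substreams keyed by index."""
    samples = [f"{prefix}{i + 1:03d}" for i in range(n)]
    columns = {}
    for j, fs in enumerate(freq_sets):
        rng = _rng(seed, _GENO, j)
        draws = rng.choice(len(fs.alleles), size=(n, 2), p=fs.frequencies)
        columns[fs.locus_id] = [
            tuple(sorted((fs.alleles[a], fs.alleles[b]))) for a, b in draws
        ]
    return GenotypeTable.from_dict(
        {s: {l: columns[l][i] for l in columns} for i, s in enumerate(samples)}
    )


def simulate_duos(
    freq_sets: list[AlleleFrequencySet],
    n_duos: int,
    seed: int = 0,
    mutation_rate: float = 0.0,
) -> list[DuoRecord]:
    """Mendelian parent/child duos under HWE.

    The parent is drawn under HWE; the child receives one uniformly chosen
    parental allele — replaced by a uniformly chosen *different* allele with
    probability ``mutation_rate`` — plus one allele drawn from the
    population spectrum.
    """
    if not 0 <= mutation_rate <= 1:
        raise ValueError("mutation_rate must be in [0, 1]")
    duos = []
    for d in range(n_duos):
        parent, child = {}, {}
        for j, fs in enumerate(freq_sets):
            rng = _rng(seed, _DUOS, d, j)
            k = len(fs.alleles)
            p1, p2 = rng.choice(k, size=2, p=fs.frequencies)
            transmitted = p1 if rng.random() < 0.5 else p2
            if mutation_rate > 0 and rng.random() < mutation_rate:
                others = [a for a in range(k) if a != transmitted]
                transmitted = others[rng.integers(len(others))]
            untransmitted = rng.choice(k, p=fs.frequencies)
            parent[fs.locus_id] = tuple(sorted((fs.alleles[p1], fs.alleles[p2])))
            child[fs.locus_id] = tuple(
                sorted((fs.alleles[transmitted], fs.alleles[untransmitted]))
            )
        duos.append(DuoRecord(f"D{d + 1:03d}", parent, child))
    return duos


def bn_population_freqs(
    ancestral: AlleleFrequencySet,
    theta_drift: float,
    n_pops: int,
    seed: int = 0,
) -> list[AlleleFrequencySet]:
    """Drifted subpopulation spectra under the Balding-Nichols model.

    Each population's frequencies are drawn from Dirichlet(p_i (1-theta)/theta);
    E[x_i] = p_i and Var[x_i] = theta p_i (1 - p_i), so theta plays the role
    of Fst between each population and the ancestral pool.
    """
    if not 0 < theta_drift < 1:
        raise ValueError("theta_drift must be in (0, 1)")
    freqs = ancestral.frequencies
    alleles = ancestral.alleles
    if np.any(freqs <= 0):
        warnings.warn(
            f"{ancestral.locus_id}: dropping zero-frequency ancestral alleles",
            stacklevel=2,
        )
        keep = freqs > 0
        alleles = tuple(a for a, m in zip(alleles, keep) if m)
        freqs = freqs[keep] / freqs[keep].sum()
    alpha = freqs * (1.0 - theta_drift) / theta_drift
    rng = _rng(seed, _BN)
    return [
        AlleleFrequencySet(ancestral.locus_id, alleles, rng.dirichlet(alpha))
        for _ in range(n_pops)
    ]


def simulate_mixture_profiles(
    freqs: AlleleFrequencySet, n_mixtures: int, seed: int = 0
) -> list[frozenset]:
    """Distinct-allele sets from pooling two unrelated HWE individuals.

    Each mixture is the union of two independent HWE genotypes, i.e. of four
    i.i.d. allele draws, giving 1-4 distinct alleles.
    """
    rng = _rng(seed, _MIX)
    draws = rng.choice(len(freqs.alleles), size=(n_mixtures, 4), p=freqs.frequencies)
    return [frozenset(freqs.alleles[a] for a in row) for row in draws]


def unphased_from_haplotypes(
    column: list[tuple[str, str] | None], locus: MicrohapLocus | None = None
) -> list[tuple[tuple[str, str], ...] | None]:
    """Strip phase: haplotype pairs -> per-SNP unordered single-base genotypes.

    The result feeds the EM haplotype-frequency estimator; a double
    heterozygote at two SNPs becomes ambiguous between the two consistent
    phase configurations, exactly the information loss the EM must resolve.
    """
    out = []
    for pair in column:
        if pair is None:
            out.append(None)
            continue
        h1, h2 = pair
        if len(h1) != len(h2):
            raise ValueError(f"haplotype length mismatch in pair {pair}")
        out.append(tuple(tuple(sorted((a, b))) for a, b in zip(h1, h2)))
    return out


# ---------------------------------------------------------------------------
# Ae-targeted spectra


def spectrum_with_ae(target_ae: float, k: int = 6) -> np.ndarray:
    """A k-allele spectrum (one major allele, k-1 equal minors) with exactly
    the requested effective number of alleles, solved by bisection."""
    if not 1.0 < target_ae <= k:
        raise ValueError(f"target Ae must be in (1, {k}], got {target_ae}")

    def ae_of(p0: float) -> float:
        return 1.0 / (p0**2 + (1.0 - p0) ** 2 / (k - 1))

    lo, hi = 1.0 / k, 1.0 - 1e-12  # Ae monotone decreasing in p0 on this range
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if ae_of(mid) > target_ae:
            lo = mid
        else:
            hi = mid
    p0 = 0.5 * (lo + hi)
    return np.concatenate([[p0], np.full(k - 1, (1.0 - p0) / (k - 1))])


def synthetic_panel_freqs(
    ae_targets: tuple[float, ...] = REFERENCE_AE_TARGETS,
    alleles_per_locus: int = 6,
    n_snps: int = 3,
    lab_code: str = "sim",
) -> list[AlleleFrequencySet]:
    """Deterministic default panel: one locus per target Ae, chromosomes 1..n."""
    sets = []
    for i, ae in enumerate(ae_targets):
        locus_id = make_locus_name(min(i + 1, 22), lab_code, i + 1)
        freqs = spectrum_with_ae(ae, alleles_per_locus)
        sets.append(
            AlleleFrequencySet(locus_id, haplotype_alphabet(alleles_per_locus, n_snps), freqs)
        )
    return sets


# ---------------------------------------------------------------------------
# VCF fixtures


def _vcf_header(contigs: list[str], samples: list[str]) -> "pysam.VariantHeader":
    import pysam

    header = pysam.VariantHeader()
    header.add_line('##INFO=<ID=AF,Number=A,Type=Float,Description="Allele Frequency">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for c in contigs:
        header.add_line(f"##contig=<ID={c}>")
    for s in samples:
        header.add_sample(s)
    return header


def write_variants_vcf(path, n_variants: int = 200, seed: int = 0, chrom: str = "1") -> None:
    """A simple n-variant biallelic/tri-allelic SNP VCF with AF fields only."""
    import pysam

    rng = _rng(seed, _VCF)
    header = _vcf_header([chrom], [])
    pos = np.cumsum(rng.integers(500, 5000, size=n_variants)) + 10_000
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for i in range(n_variants):
            tri = rng.random() < 0.3
            ref, *alts = rng.permutation(list("ACGT"))[: 3 if tri else 2]
            af = rng.dirichlet(np.ones(len(alts) + 1))[1:]
            rec = vcf.new_record(
                contig=chrom,
                start=int(pos[i]) - 1,
                alleles=(ref, *alts),
                id=f"rs{900000 + i}",
            )
            rec.info["AF"] = tuple(round(float(x), 6) for x in af)
            vcf.write(rec)


@dataclass
class WindowSpec:
    """Ground-truth description of one plantable screening window.

    ``haplotypes`` are tuples of per-SNP allele indices; ``hap_freqs`` their
    population frequencies.  ``n_alleles_per_snp`` fixes each SNP's alphabet
    size (3 = tri-allelic).  The defaults describe a window that passes every
    screening filter.
    """

    chrom: str = "1"
    start: int = 1_000_000
    positions_offsets: tuple[int, ...] = (0, 70, 149)
    n_alleles_per_snp: tuple[int, ...] = (3, 2, 2)
    haplotypes: tuple[tuple[int, ...], ...] = ((0, 0, 0), (1, 1, 0), (2, 0, 1), (0, 1, 1))
    hap_freqs: tuple[float, ...] = (0.32, 0.26, 0.24, 0.18)
    label: str = "pass"

    def __post_init__(self):
        if abs(sum(self.hap_freqs) - 1.0) > 1e-9:
            raise ValueError(f"window {self.label}: haplotype frequencies must sum to 1")
        for h in self.haplotypes:
            if len(h) != len(self.positions_offsets):
                raise ValueError(f"window {self.label}: haplotype arity mismatch")

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(self.start + o for o in self.positions_offsets)


def write_screening_vcf(
    path, windows: list[WindowSpec], n_samples: int = 200, seed: int = 0
) -> None:
    """Write a GT-bearing VCF realizing the planted windows.

    For each window, ``2 * n_samples`` haplotypes are drawn from its spectrum
    and emitted as unphased per-SNP genotypes, so downstream EM estimation
    sees realistic sampling noise around the planted truth.
    """
    import pysam

    samples = [f"S{i + 1:03d}" for i in range(n_samples)]
    contigs = sorted({w.chrom for w in windows}, key=str)
    header = _vcf_header(contigs, samples)
    bases = "ACGT"
    records = []
    for w_idx, w in enumerate(windows):
        rng = _rng(seed, _VCF, w_idx)
        hap_idx = rng.choice(len(w.haplotypes), size=(n_samples, 2), p=np.asarray(w.hap_freqs))
        for s_idx, pos in enumerate(w.positions):
            alleles = tuple(bases[: w.n_alleles_per_snp[s_idx]])
            gts = [
                (w.haplotypes[h1][s_idx], w.haplotypes[h2][s_idx])
                for h1, h2 in hap_idx
            ]
            records.append((w.chrom, pos, f"rs{800000 + 10 * w_idx + s_idx}", alleles, gts))
    records.sort(key=lambda r: (r[0], r[1]))
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for chrom, pos, rsid, alleles, gts in records:
            rec = vcf.new_record(contig=chrom, start=pos - 1, alleles=alleles, id=rsid)
            for sample, gt in zip(samples, gts):
                rec.samples[sample]["GT"] = tuple(sorted(gt))
            vcf.write(rec)
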