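import numpy as np
import pytest

import mhpanel as mh
from mhpanel.simulate import WindowSpec, write_screening_vcf


@pytest.fixture(scope="session")
def reference_panel():
    """Bundled 20-locus panel: (loci, published per-locus statistics)."""
    return mh.load_reference_panel()


@pytest.fixture(scope="session")
def synthetic_panel():
    """Deterministic 20-locus Ae-targeted frequency spectra."""
    return mh.synthetic_panel_freqs()


def planted_screening_windows():
    """20 screening windows with known ground truth: 8 that pass every
    filter and 12 that each violate specific, known criteria.

    Returns (windows, expected) where expected maps window key ->
    (accepted, frozenset of rejection reason codes).
    """
    pass_freqs = [
        (0.32, 0.26, 0.24, 0.18), (0.35, 0.25, 0.22, 0.18), (0.30, 0.28, 0.24, 0.18),
        (0.33, 0.27, 0.22, 0.18), (0.31, 0.29, 0.23, 0.17), (0.34, 0.24, 0.23, 0.19),
        (0.36, 0.26, 0.21, 0.17),
    ]
    windows = [
        WindowSpec(chrom=str(i + 1), start=1_000_000, hap_freqs=f, label=f"pass{i+1}")
        for i, f in enumerate(pass_freqs)
    ]
    # same-chromosome pair 1.5 Mb apart: the lower-Ae window loses on spacing
    windows.append(WindowSpec(chrom="9", start=1_000_000, hap_freqs=(0.32, 0.26, 0.24, 0.18), label="spacing_loser"))
    windows.append(WindowSpec(chrom="9", start=2_500_000, hap_freqs=(0.28, 0.26, 0.24, 0.22), label="pass8"))
    maf_haps = ((0, 0, 0), (1, 1, 0), (2, 0, 0), (0, 1, 1), (1, 0, 1))
    windows.append(WindowSpec(chrom="10", start=1_000_000, haplotypes=maf_haps, hap_freqs=(0.30, 0.32, 0.32, 0.03, 0.03), label="maf1"))
    windows.append(WindowSpec(chrom="11", start=1_000_000, haplotypes=maf_haps, hap_freqs=(0.32, 0.31, 0.31, 0.03, 0.03), label="maf2"))
    bi = ((0, 0, 0), (1, 1, 0), (0, 1, 1), (1, 0, 1))
    windows.append(WindowSpec(chrom="12", start=1_000_000, n_alleles_per_snp=(2, 2, 2), haplotypes=bi, hap_freqs=(0.30, 0.26, 0.24, 0.20), label="notri1"))
    windows.append(WindowSpec(chrom="13", start=1_000_000, n_alleles_per_snp=(2, 2, 2), haplotypes=bi, hap_freqs=(0.28, 0.27, 0.24, 0.21), label="notri2"))
    dup = ((0, 0, 0), (1, 1, 1), (2, 0, 0), (0, 1, 1))  # SNP2 duplicates SNP1
    windows.append(WindowSpec(chrom="14", start=1_000_000, haplotypes=dup, hap_freqs=(0.30, 0.30, 0.20, 0.20), label="dedup1"))
    windows.append(WindowSpec(chrom="15", start=1_000_000, haplotypes=dup, hap_freqs=(0.32, 0.28, 0.22, 0.18), label="dedup2"))
    low = ((0, 0, 0), (1, 1, 1), (2, 1, 0))  # 3 haplotypes, Ae ~ 2.7
    windows.append(WindowSpec(chrom="16", start=1_000_000, haplotypes=low, hap_freqs=(0.45, 0.35, 0.20), label="lowae1"))
    windows.append(WindowSpec(chrom="17", start=1_000_000, haplotypes=low, hap_freqs=(0.44, 0.36, 0.20), label="lowae2"))
    windows.append(WindowSpec(chrom="20", start=1_000_000, haplotypes=low, hap_freqs=(0.46, 0.34, 0.20), label="lowae3"))
    # compound defects
    windows.append(WindowSpec(chrom="18", start=1_000_000, n_alleles_per_snp=(2, 2, 2), haplotypes=((0, 0, 0), (1, 1, 1)), hap_freqs=(0.6, 0.4), label="multi1"))
    windows.append(WindowSpec(chrom="19", start=1_000_000, n_alleles_per_snp=(2, 2, 2), haplotypes=bi, hap_freqs=(0.50, 0.44, 0.03, 0.03), label="multi2"))

    expected = {}
    for w in windows:
        key = f"{w.chrom}:{w.positions[0]}-{w.positions[-1]}"
        if w.label.startswith("pass"):
            expected[key] = (True, frozenset())
        elif w.label == "spacing_loser":
            expected[key] = (False, frozenset({"spacing"}))
        elif w.label.startswith("maf"):
            expected[key] = (False, frozenset({"maf"}))
        elif w.label.startswith("notri"):
            expected[key] = (False, frozenset({"no_triallelic"}))
        elif w.label.startswith("dedup"):
            expected[key] = (False, frozenset({"insufficient_snps_after_dedup"}))
        elif w.label.startswith("lowae"):
            expected[key] = (False, frozenset({"low_ae"}))
        elif w.label == "multi1":
            expected[key] = (False, frozenset({"no_triallelic", "low_ae", "heterozygosity", "insufficient_snps_after_dedup"}))
        elif w.label == "multi2":
            expected[key] = (False, frozenset({"maf", "no_triallelic", "low_ae", "heterozygosity"}))
    return windows, expected


@pytest.fixture(scope="session")
def planted_vcf(tmp_path_factory):
    """(path, expected-verdict map) for the planted screening VCF."""
    windows, expected = planted_screening_windows()
    path = tmp_path_factory.mktemp("screen") / "planted.vcf"
    write_screening_vcf(path, windows, n_samples=200, seed=42)
    return path, expected
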