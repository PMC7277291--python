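# mhpanel

Forensic construction and evaluation of **microhaplotype panels** built on
tri-allelic SNPs.

A microhaplotype (MH) is a genomic window shorter than 200 bp containing two
or more SNPs; the joint, phased alleles of those SNPs form one multi-allelic
marker that can be read in a single massively-parallel-sequencing read.
Panels of such markers are used for individual identification, two-person
mixture detection, parentage testing and biogeographic ancestry inference.
`mhpanel` implements the full desk-side analysis chain for building and
evaluating such a panel, and ships a synthetic-data generator so every
statistic can be exercised against known ground truth.  A published
20-locus tri-allelic reference panel (ids `mh02zha012` … `mh22zha008`,
GRCh37 coordinates, 50 Han Chinese individuals) is bundled as a fixture.

## What it computes

Per locus, from a frequency spectrum *p₁…p_k* and a genotype column:

- **Ae** — effective number of alleles, `Ae = 1/Σpᵢ²`; expected
  heterozygosity `He = 1 − 1/Ae`
- **Ho** — observed heterozygosity; **PE** — power of exclusion,
  `PE = Ho²(1 − 2Ho(1−Ho)²)`
- **MP / PD** — matching probability `MP = Σ(gₙ/n)²` over observed genotype
  counts, and the power of discrimination `PD = 1 − MP`; optionally the
  θ-corrected (Balding–Nichols) match probability for structured populations
- **mixture detection** — the probability that pooling two unrelated HWE
  individuals shows ≥3 distinct alleles, in closed form
  `1 − [Σp_a⁴ + Σ_{a<b}((p_a+p_b)⁴ − p_a⁴ − p_b⁴)]`, with an exact
  enumeration oracle and a simulation route

Panel-wide: `CPD = 1 − Π(1−PDᵢ)`, `CPE = 1 − Π(1−PEᵢ)`, `CMP = ΠMPᵢ`
(accumulated in log space — a 20-locus CMP sits at 10⁻¹⁸), and the
cumulative mixture-detection probability using the floor-of-Ae rule.

Around these sit: Guo–Thompson-style Monte-Carlo exact tests for
Hardy–Weinberg equilibrium, permutation-calibrated χ² linkage-disequilibrium
tests with multi-allelic r², duo paternity indices
(`PI = P(child | parent)/P(child | unrelated)`, `CPI = ΠPIᵢ`, confirmation
threshold CPI ≥ 10⁴), EM haplotype-frequency estimation from unphased
genotypes, Hudson-style pairwise Fst, neighbour-joining population trees,
and the VCF screening pipeline that selects candidate windows by span,
per-SNP MAF, tri-allelic content, redundancy, Ae, heterozygosity and
inter-locus spacing.

## Worked example

```python
import mhpanel as mh

# 20-locus synthetic panel whose spectra hit the reference Ae values,
# typed in 50 individuals under HWE
panel = mh.synthetic_panel_freqs()
table = mh.hwe_genotype_table(panel, 50, seed=7)
stats = [mh.compute_locus_stats(l, table.column(l), f)
         for l, f in zip(table.loci, panel)]
summary = mh.combine_panel(stats)
s0 = stats[0]
print(f"{s0.locus_id}: Ae={s0.ae:.3f} Ho={s0.ho:.2f} PD={s0.pd:.3f} PE={s0.pe:.3f}")
print(f"panel: CPE={summary.cpe:.10f} CMP={summary.cmp:.3e} "
      f"mixture={summary.mixture_probability:.9f}")

duos = mh.simulate_duos(panel, 3, seed=11)
db = {f.locus_id: f for f in panel}
for d in duos:
    r = mh.cpi(d, db)
    print(f"{r.duo_id}: log10 CPI = {r.log10_cpi:.2f} -> {r.verdict}")
```

prints

```
mh01sim001: Ae=3.021 Ho=0.68 PD=0.855 PE=0.398
panel: CPE=0.9999995086 CMP=7.505e-20 mixture=0.999997930
D001: log10 CPI = 7.61 -> supported
D002: log10 CPI = 5.42 -> supported
D003: log10 CPI = 4.66 -> supported
```

The first locus carries an effective 3.02 alleles, so on its own it
discriminates ~85% of random pairs; across all 20 loci two random
individuals match with probability ~10⁻¹⁹ (CMP), a random non-parent is
excluded with probability 1 − 5×10⁻⁷ (CPE), and a two-person mixture
reveals a third allele at ≥1 locus with probability 0.99999793.  All three
simulated parent/child duos clear the CPI ≥ 10⁴ confirmation threshold.

The same analyses are scriptable through the `mhpanel` CLI
(`simulate`, `stats`, `mixture`, `hwe`, `ld`, `kinship`, `fst`, `screen`).

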