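# Methods

This note records the statistical models behind `mhpanel`, the conventions
and defaults it adopts, what the synthetic-data generator does and does not
emulate, and the numerical choices that matter for reproducing its output.

## Markers and coordinates

A microhaplotype locus is modelled as ≥2 SNPs inside a window of fewer than
200 bp on one autosome.  Coordinates are 1-based inclusive and the span is
`end − start + 1`; this convention is validated against the bundled
20-locus reference panel, whose recomputed spans match the published
lengths for all 20 rows.  Locus identifiers follow the mh nomenclature:
`mh` + zero-padded two-digit chromosome + lowercase lab code + three-digit
serial + optional single lowercase suffix for same-region variants
(`mh11zha006a`).

Haplotype alleles are represented as concatenated base strings in ascending
positional order (`"ACT"` for a 3-SNP locus).  The original data release
does not expose its allele string encoding, so this is a package
convention, applied consistently by every reader and writer.  Genotypes
are unordered pairs, stored canonically sorted; missing data is `./.` on
disk.  Missing genotypes are excluded pairwise, per locus, from every
statistic.

## Forensic parameters

For a spectrum p₁…p_k: `Ae = 1/Σpᵢ²` and `He = 1 − 1/Ae`.  Ho is the
fraction of heterozygous genotypes among non-missing ones.  MP is computed
from *observed* genotype counts, `MP = Σ(n_g/n)²`, not from HWE
expectations — the forensic convention — and `PD = 1 − MP` holds exactly by
construction.  PE uses the classic exclusion-power function of observed
heterozygosity,

    PE(Ho) = Ho² (1 − 2 Ho (1 − Ho)²),

adopted because it reproduces 19 of the 20 bundled reference rows to
3 d.p.; the remaining row (`mh17zha001`: Ho 0.64 printed next to PE 0.562,
which equals PE(0.78)) is internally inconsistent in the source and is
flagged in the tests as an anomaly rather than silently corrected.

Panel-level quantities are complement-products (`CPD`, `CPE`) and the
product `CMP = ΠMPᵢ`, all accumulated in log space (`log1p`/`expm1`).
Note that since MPᵢ = 1 − PDᵢ exactly, CMP *is* the complement 1 − CPD; at
the 10⁻¹⁸ scale `1 − cpd` underflows in double precision, so consumers who
need the complement should read `cmp`.

The θ-corrected match probability follows the Balding–Nichols conditional
genotype probabilities: given a first individual with genotype {i,i} or
{i,j}, a second individual from the same subpopulation with coancestry θ
matches with probability

    (2θ + (1−θ)pᵢ)(3θ + (1−θ)pᵢ) / ((1+θ)(1+2θ))        homozygote
    2(θ + (1−θ)pᵢ)(θ + (1−θ)p_j) / ((1+θ)(1+2θ))        heterozygote

weighted by the HWE prior over first-individual genotypes; θ = 0 recovers
ΣP(G)².  θ defaults to 0 (the source analysis does not state the θ it
used) and is exposed as a parameter.

## Mixture detection

"Detecting" a two-person mixture is operationalized purely combinatorially:
the union of two independent HWE genotypes (four i.i.d. allele draws)
contains at least three distinct alleles.  No dropout, stutter or analytic
threshold is modelled.  The closed form is the inclusion–exclusion
complement of the four draws landing in at most two alleles; an exhaustive
enumeration over all ordered 4-tuples (≤12 alleles) serves as an
independent oracle, and both agree with seeded simulation in the tests.
At equal frequencies `p = 1/k` the probability is
`1 − [k + C(k,2)·14]/k⁴` — 4/9 at k = 3, 21/32 at k = 4 — and equal
frequencies maximize it for fixed k.

The panel-cumulative probability follows the floor rule: each locus
contributes the equal-frequency probability at `floor(Ae)` (floors below 3
contribute nothing), combined as `1 − Π(1 − pᵢ)`.  The bundled panel's Ae
column (15 floors of 3, 4 floors of 4, 1 floor of 2) yields 0.999997930 at
full precision; the published arithmetic, which rounds the k = 3 term to
0.4444, gives 0.999997927.  The two agree to 3.5×10⁻⁹ and the acceptance
test tolerates both.

## Equilibrium testing

The HWE "exact" test is a Monte-Carlo conditional test in the
Guo–Thompson style: the 2n observed alleles are re-paired uniformly at
random B times, and each table is scored by the variable part of its
conditional probability given the allele counts, `h·ln2 − Σ ln n_g!` (h =
heterozygote count).  The p-value is the add-one fraction
`(#{stat ≤ observed} + 1)/(B + 1)`, so p ≥ 1/(B+1) always.  Default
B = 10⁵.  A full-enumeration version (n ≤ 10, ≤3 alleles) is provided and
used as the oracle in tests.  Loci with fewer than two alleles are
untestable and report p = 1 with a warning.

LD between two loci treats each locus as one multi-allelic "site" and
EM-estimates the joint haplotype table from unphased genotype pairs; the
statistic is χ² of the joint table against the product of its marginals,
calibrated by permuting one locus's genotypes across samples (default
B = 10⁴).  This approximates the likelihood-ratio permutation procedure of
standard population-genetics packages, which do not publish their exact
algorithm.  The r² summary is the frequency-weighted average of per-pair
squared correlations, `Σᵢⱼ pᵢqⱼ·Dᵢⱼ²/(pᵢ(1−pᵢ)qⱼ(1−qⱼ))` with
`Dᵢⱼ = hᵢⱼ − pᵢqⱼ`; conventions for multi-allelic r² differ between tools,
so this definition is stated prominently.  Fixed alleles are skipped with
weight renormalization.  Bonferroni correction is `α/n_tests`.

## Kinship

Duos only (one parent, one child).  The per-locus paternity index is the
likelihood ratio with transmission probability ½ per parental allele and
the untransmitted child allele drawn from the population spectrum; the
denominator is the child's HWE genotype probability.  The default policy is
no-mutation: a pair sharing no allele has PI = 0 and zeroes the CPI.  An
optional mutation-tolerant policy replaces the transmission probability
with a single-step uniform replacement model at rate μ (off by default —
the markers are chosen for low mutation rates and the source reports
STR-side, not microhaplotype, mismatches).  Alleles absent from the
frequency database receive the minimum-allele-count floor `5/(2n+2)`
(n = database sample size, default 50), logged when applied.  Verdicts:
"supported" at CPI ≥ 10⁴, "excluded" at CPI = 0 or at a configurable
number of exclusion loci, otherwise "inconclusive".

## Population structure

Haplotype frequencies from unphased genotypes use standard haplotype EM
(the desk-scale substitute for Bayesian phasing, and labelled as such): the
E-step distributes each genotype over its 2^(s−1) consistent haplotype
pairs proportional to current frequency products, the M-step re-counts;
convergence at |Δlog L| < 10⁻⁸, cap 500 iterations, haplotype space bounded
at 6 sites.  The log-likelihood is asserted nondecreasing at every
iteration.  Initialization is uniform (deterministic); optional random
restarts draw Dirichlet(1) starts from a seed and the best final
log-likelihood wins.  Uniform initialization can sit on symmetric
stationary points for pathologically symmetric data (e.g. two perfectly
coupled loci), which restarts escape; the LD test is unaffected because
observed and permuted datasets are scored by the same procedure.

Pairwise Fst is Hudson-style on haplotype frequencies:
`F = (H_b − H_w)/H_b` per locus with `H_b = 1 − Σp q` and H_w the average
within-population heterozygosity (bias-corrected by n/(n−1) when haplotype
counts are known), combined across loci as a ratio of averages.  Negative
estimates are truncated to 0 for distance-matrix consumers; raw values are
retained.  The estimator's name is recorded here because AMOVA-based tools
define distances differently and numeric equality with any particular
tool's matrix is not claimed.

Neighbour-joining is the standard Saitou–Nei agglomeration (Q-criterion,
usual branch-length formulas), with ties broken by the lexicographically
smallest pair of subtree labels so results are fully deterministic;
branch lengths are not clamped, so slightly negative estimates can appear
on non-additive inputs.  Trees are scikit-bio `TreeNode`s and serialize to
Newick.

## Marker screening

The selection chain for panel construction from a VCF: (1) window sorted
SNPs into maximal same-chromosome candidates of ≥3 SNPs spanning <200 bp;
(2) filter each candidate — per-SNP MAF > 0.10, a tri-allelic SNP present,
same-window SNPs with numerically identical allele spectra deduplicated
(identical spectra signal complete LD; configurable to reject the whole
candidate) with the SNP minimum re-checked, haplotype Ae > 3.0, and
expected heterozygosity ≥ 0.6; (3) enforce >2 Mb spacing between accepted
loci on one chromosome, keeping the higher-Ae locus (ties by window key);
(4) assign mh names serially per chromosome.  All filters accumulate
reasons rather than short-circuiting, so acceptance is order-independent
and every rejection is fully attributed.

Two conventions deserve note.  MAF for a multi-allelic SNP is the
frequency of the *second-most-frequent* allele (the standard minor-allele
definition).  The heterozygosity criterion is directionally ambiguous in
the source (stated as ≤0.6 while every reported locus exceeds 0.6, and
Ae > 3 forces He > 2/3); the default keeps diverse loci (≥0.6) and the
literal ≤ rule is available via configuration.  Candidate haplotype
spectra come from the EM estimator when the VCF carries genotypes, else
from the product of per-SNP frequencies (a linkage-equilibrium
approximation, flagged by a warning).  Sequencing-depth quality control is
out of scope; screening here is frequency-based only.

## Synthetic data

The generator emulates the study conditions end to end with known ground
truth: symmetric-Dirichlet frequency spectra; HWE genotypes (two
independent allele draws); Mendelian duos (parent HWE, child receives one
uniformly chosen parental allele plus one population allele, with optional
single-step uniform replacement mutation, default rate 0); two-person
mixtures (unions of two HWE genotypes); Balding–Nichols drifted
subpopulations (Dirichlet with parameters `pᵢ(1−θ)/θ`, so θ is the
expected Fst to the ancestral pool); and VCF fixtures with planted
screening defects.  The default panel is deterministic: 20 loci of 6
haplotypes each whose spectra are solved (one major allele, equal minors,
bisection) to hit the reference panel's published Ae values exactly,
reproducing its floor composition (15 loci in [3,4), 4 at ≥4, 1 below 3);
default sample size 50 individuals and 12 duos.

Haplotype string sets are chosen greedily so that no two disjoint
haplotype pairs collapse to the same unphased genotype — otherwise the
simulated truth would be unidentifiable in principle from phase-stripped
data and EM-recovery experiments would be meaningless.

One global seed expands into per-operation, per-locus substreams via numpy
`SeedSequence` spawn keys, so enlarging a panel does not perturb earlier
draws, and every output is byte-reproducible under a fixed seed.

What the generator does **not** emulate — and what passing tests therefore
do not establish about real data: sequencing reads, base-calling or
phasing error (genotypes are exact); within-locus recombination (treated
as absent over <200 bp); mutation processes beyond uniform replacement;
admixed or non-equilibrium populations (drift is pure Balding–Nichols);
and missingness patterns (simulated tables are complete).

## Problem sizes

Distributional checks in the test suite run at sizes chosen to make their
standard errors decisive for the property under test: 10⁵ genotypes for
heterozygosity convergence, 2×10⁵ mixtures per spectrum, EM recovery at
500 individuals, Fst calibration over 200 loci × 20 replicates, HWE null
calibration over 150 datasets, LD type-I error over 100 replicates, and
kinship cohorts of 1 200 duos / 1 200 unrelated pairs.  Acceptance-script
quantities are exact (enumeration over 81 and 256 ordered tuples) with a
2×10⁵-draw simulation as a guard.

## Known limitations

- Trio parentage, sibship indices and STR mutation-step models are out of
  scope; kinship covers duos only.
- The EM estimator is a point estimator; no uncertainty is attached to
  haplotype frequencies, and Bayesian phasing is not re-implemented.
- Admixture-style model-based clustering and ancestry-informativeness
  ranking are out of scope; population differentiation is summarized only
  by Fst and NJ trees.
- VCF ingestion keeps multi-allelic records whole and expects SNPs;
  indels and structural alleles are not handled.
- Cumulative statistics inherit whatever rounding their inputs carry:
  published 3-d.p. per-locus values reproduce cumulative complements only
  to about a percent (CPE) or to order of magnitude (CPD).
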