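"""Candidate microhaplotype screening from population SNP data.

Reproduces the frequency-based selection chain for building a tri-allelic
microhaplotype panel from a VCF: window nearby SNPs into sub-200 bp
candidates, then filter each candidate on per-SNP minor allele frequency,
presence of a tri-allelic member, redundancy (SNPs with identical spectra
are in effectively complete LD — one is dropped), haplotype-level effective
number of alleles, and expected heterozygosity; finally enforce a minimum
molecular distance between accepted loci on the same chromosome to keep
the panel in linkage equilibrium, and assign mh-nomenclature names.

All filters accumulate failure reasons rather than short-circuiting, so a
rejected candidate reports every criterion it violates and acceptance is
order-independent.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from .forensic import effective_num_alleles, expected_heterozygosity
from .panel_model import AlleleFrequencySet, MicrohapLocus, VcfVariant, make_locus_name, read_vcf_candidates
from .popstruct import em_haplotype_freqs

__all__ = [
    "ScreeningParams",
    "Candidate",
    "FilterVerdict",
    "ScreeningReport",
    "candidate_windows",
    "candidate_haplotype_freqs",
    "apply_filters",
    "enforce_spacing",
    "screen",
]

# rejection reason codes
R_MAF = "maf"
R_NO_TRIALLELIC = "no_triallelic"
R_INSUFFICIENT_SNPS = "insufficient_snps_after_dedup"
R_LOW_AE = "low_ae"
R_HETEROZYGOSITY = "heterozygosity"
R_UNEVALUABLE = "unevaluable"
R_SPACING = "spacing"


@dataclass
class ScreeningParams:
    """Thresholds of the selection chain (strict inequalities where noted).

    ``het_direction`` resolves an ambiguity in the published criterion: the
    stated rule is heterozygosity <= 0.6, yet every reported locus has
    Ho > 0.6 (and Ae > 3 forces He > 2/3), so the default keeps loci with
    He >= ``het_threshold``; set ``het_direction="<="`` for the literal rule.
    ``dedup_mode`` controls criterion handling for same-window SNPs with
    identical allele spectra: drop the redundant SNP (default) or reject
    the whole candidate.
    """

    maf_min: float = 0.10          # per-SNP minor allele frequency, exclusive
    span_max_bp: int = 200         # window span, exclusive
    min_snps: int = 3
    require_triallelic: bool = True
    ae_min: float = 3.0            # haplotype Ae, exclusive
    het_threshold: float = 0.6
    het_direction: str = ">="
    spacing_min_bp: int = 2_000_000  # same-chromosome distance, exclusive
    dedup_mode: str = "remove_snp"   # or "reject"

    def __post_init__(self):
        if self.het_direction not in (">=", "<="):
            raise ValueError("het_direction must be '>=' or '<='")
        if self.dedup_mode not in ("remove_snp", "reject"):
            raise ValueError("dedup_mode must be 'remove_snp' or 'reject'")
        for name in ("maf_min", "span_max_bp", "min_snps", "ae_min", "het_threshold", "spacing_min_bp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class Candidate:
    """A windowed set of nearby SNPs, prior to filtering."""

    chrom: str
    variants: list[VcfVariant]

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(v.pos for v in self.variants)

    @property
    def span_bp(self) -> int:
        return self.positions[-1] - self.positions[0] + 1

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.positions[0]}-{self.positions[-1]}"


@dataclass
class FilterVerdict:
    """Outcome of the filter chain for one candidate; ``reasons`` holds
    (code, detail) for every violated criterion."""

    candidate: Candidate
    accepted: bool
    reasons: list[tuple[str, str]]
    kept_variant_idx: list[int]
    ae: float | None = None
    he: float | None = None

    @property
    def reason_codes(self) -> set[str]:
        return {code for code, _ in self.reasons}


@dataclass
class ScreeningReport:
    """Full accept/reject report plus the named accepted panel."""

    params: ScreeningParams
    verdicts: list[FilterVerdict]
    accepted: list[MicrohapLocus]
    accepted_freqs: dict[str, AlleleFrequencySet]

    def to_json(self) -> str:
        payload = {
            "params": asdict(self.params),
            "candidates": [
                {
                    "window": v.candidate.key,
                    "accepted": v.accepted,
                    "reasons": [list(r) for r in v.reasons],
                    "ae": v.ae,
                    "he": v.he,
                }
                for v in self.verdicts
            ],
            "panel": [
                {
                    "id": l.id,
                    "chromosome": l.chromosome,
                    "snp_positions": list(l.snp_positions),
                    "snp_ids": list(l.snp_ids),
                    "triallelic_snp": l.triallelic_snp,
                    "span_bp": l.span_bp,
                }
                for l in self.accepted
            ],
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def candidate_windows(variants: list[VcfVariant], params: ScreeningParams) -> list[Candidate]:
    """Maximal same-chromosome windows of >= min_snps SNPs spanning < span_max_bp.

    Input must be sorted by (chromosome, position).  Windows contained in a
    longer window are not re-emitted; overlapping maximal windows may both
    appear.  MAF is *not* filtered here — it is a reported criterion of
    :func:`apply_filters`.
    """
    order = [(v.chrom, v.pos) for v in variants]
    if order != sorted(order):
        raise ValueError("variants must be sorted by chromosome and position")
    out = []
    by_chrom: dict[str, list[VcfVariant]] = {}
    for v in variants:
        by_chrom.setdefault(v.chrom, []).append(v)
    for chrom in sorted(by_chrom):
        snps = by_chrom[chrom]
        prev_end = -1
        for i in range(len(snps)):
            j = i
            while j + 1 < len(snps) and snps[j + 1].pos - snps[i].pos + 1 < params.span_max_bp:
                j += 1
            if j - i + 1 >= params.min_snps and j > prev_end:
                out.append(Candidate(chrom, snps[i : j + 1]))
                prev_end = j
    return out


def candidate_haplotype_freqs(
    candidate: Candidate, kept_idx: list[int] | None = None
) -> AlleleFrequencySet | None:
    """Haplotype-allele spectrum of a candidate window.

    With GT columns the spectrum is EM-estimated from the unphased per-SNP
    genotypes; without genotypes it falls back to the product of per-SNP
    frequencies (a linkage-equilibrium approximation, flagged by warning).
    Returns None when neither is possible.
    """
    idx = kept_idx if kept_idx is not None else list(range(len(candidate.variants)))
    variants = [candidate.variants[i] for i in idx]
    if all(v.genotypes is not None for v in variants):
        n_samples = len(variants[0].genotypes)
        genotypes = []
        for s in range(n_samples):
            per_snp = []
            for v in variants:
                gt = v.genotypes[s]
                if gt is None:
                    per_snp = None
                    break
                per_snp.append(tuple(sorted((v.alleles[gt[0]], v.alleles[gt[1]]))))
            genotypes.append(tuple(per_snp) if per_snp is not None else None)
        if any(g is not None for g in genotypes):
            est = em_haplotype_freqs(genotypes, locus_id=candidate.key)
            return est.frequency_set()
    warnings.warn(
        f"{candidate.key}: no genotypes; haplotype spectrum approximated as the "
        "product of per-SNP frequencies (linkage equilibrium assumed)",
        stacklevel=2,
    )
    alleles, freqs = [""], np.array([1.0])
    for v in variants:
        alleles = [a + base for a in alleles for base in v.alleles]
        freqs = np.outer(freqs, v.frequencies).ravel()
    keep = freqs > 1e-12
    return AlleleFrequencySet(
        candidate.key,
        tuple(a for a, m in zip(alleles, keep) if m),
        freqs[keep] / freqs[keep].sum(),
    )


def _dedup_identical_spectra(candidate: Candidate, params: ScreeningParams):
    """Indices of SNPs to keep after removing same-window SNPs whose allele
    spectra are (numerically) identical — a signature of complete LD."""
    kept: list[int] = []
    dropped: list[int] = []
    for i, v in enumerate(candidate.variants):
        spectrum = v.frequencies
        duplicate = any(
            len(candidate.variants[k].frequencies) == len(spectrum)
            and np.allclose(candidate.variants[k].frequencies, spectrum, atol=1e-9)
            for k in kept
        )
        (dropped if duplicate else kept).append(i)
    return kept, dropped


def apply_filters(
    candidate: Candidate,
    hap_freqs: AlleleFrequencySet | None,
    params: ScreeningParams,
) -> FilterVerdict:
    """Run the full criterion chain on one candidate, accumulating reasons.

    Checks: per-SNP MAF > maf_min; a tri-allelic SNP present (if required);
    same-window SNPs with identical spectra deduplicated with min_snps
    re-checked; haplotype Ae > ae_min; expected heterozygosity vs the
    threshold/direction.  ``hap_freqs`` of None marks the candidate
    unevaluable.
    """
    reasons: list[tuple[str, str]] = []
    for v in candidate.variants:
        if not v.maf > params.maf_min:
            reasons.append((R_MAF, f"{v.id or v.pos}: MAF {v.maf:.3f} <= {params.maf_min}"))
    if params.require_triallelic and not any(v.is_triallelic for v in candidate.variants):
        reasons.append((R_NO_TRIALLELIC, "no tri-allelic SNP in window"))

    kept, dropped = _dedup_identical_spectra(candidate, params)
    if dropped:
        detail = "identical allele spectra: " + ",".join(
            str(candidate.variants[i].id or candidate.variants[i].pos) for i in dropped
        )
        if params.dedup_mode == "reject":
            reasons.append((R_INSUFFICIENT_SNPS, detail))
        elif len(kept) < params.min_snps:
            reasons.append((R_INSUFFICIENT_SNPS, f"{len(kept)} SNPs left after dedup ({detail})"))

    if hap_freqs is None:
        reasons.append((R_UNEVALUABLE, "no haplotype frequency data"))
        return FilterVerdict(candidate, False, reasons, kept)

    ae = effective_num_alleles(hap_freqs)
    he = expected_heterozygosity(hap_freqs)
    if not ae > params.ae_min:
        reasons.append((R_LOW_AE, f"Ae {ae:.3f} <= {params.ae_min}"))
    het_ok = he >= params.het_threshold if params.het_direction == ">=" else he <= params.het_threshold
    if not het_ok:
        reasons.append((R_HETEROZYGOSITY, f"He {he:.3f} fails {params.het_direction} {params.het_threshold}"))
    return FilterVerdict(candidate, not reasons, reasons, kept, ae=ae, he=he)


def enforce_spacing(
    verdicts: list[FilterVerdict], spacing_min_bp: int
) -> tuple[list[FilterVerdict], list[FilterVerdict]]:
    """Greedy same-chromosome spacing: retain candidates in descending Ae
    order (ties by window key); drop any within spacing_min_bp of an
    already-retained candidate.  Returns (retained, dropped) and appends a
    spacing reason to dropped verdicts."""
    ranked = sorted(verdicts, key=lambda v: (-(v.ae if v.ae is not None else -math.inf), v.candidate.key))
    retained: list[FilterVerdict] = []
    dropped: list[FilterVerdict] = []
    for v in ranked:
        conflict = next(
            (
                r
                for r in retained
                if r.candidate.chrom == v.candidate.chrom
                and abs(r.candidate.positions[0] - v.candidate.positions[0]) <= spacing_min_bp
            ),
            None,
        )
        if conflict is None:
            retained.append(v)
        else:
            v.accepted = False
            v.reasons.append((R_SPACING, f"within {spacing_min_bp} bp of {conflict.candidate.key}"))
            dropped.append(v)
    retained.sort(key=lambda v: (v.candidate.chrom, v.candidate.positions[0]))
    return retained, dropped


def screen(
    vcf_path,
    params: ScreeningParams | None = None,
    lab_code: str = "sim",
    region: str | None = None,
) -> ScreeningReport:
    """Full screening pipeline: VCF -> windows -> filters -> spacing -> names.

    Accepted loci are named with mh nomenclature, serially per chromosome in
    position order.  The report is fully deterministic for a given input
    and parameter set.
    """
    params = params or ScreeningParams()
    variants = read_vcf_candidates(vcf_path, region=region)
    verdicts = []
    for cand in candidate_windows(variants, params):
        kept, _ = _dedup_identical_spectra(cand, params)
        hap_freqs = candidate_haplotype_freqs(cand, kept)
        verdicts.append(apply_filters(cand, hap_freqs, params))

    retained, _ = enforce_spacing([v for v in verdicts if v.accepted], params.spacing_min_bp)

    accepted: list[MicrohapLocus] = []
    accepted_freqs: dict[str, AlleleFrequencySet] = {}
    serial_by_chrom: dict[str, int] = {}
    for v in retained:
        cand = v.candidate
        chrom_num = int(str(cand.chrom).removeprefix("chr"))
        serial = serial_by_chrom.get(cand.chrom, 0) + 1
        serial_by_chrom[cand.chrom] = serial
        name = make_locus_name(chrom_num, lab_code, serial)
        kept_variants = [cand.variants[i] for i in v.kept_variant_idx]
        locus = MicrohapLocus(
            id=name,
            chromosome=chrom_num,
            snp_positions=tuple(x.pos for x in kept_variants),
            snp_ids=tuple(x.id or f"{cand.chrom}:{x.pos}" for x in kept_variants),
            triallelic_snp=next(
                (x.id or f"{cand.chrom}:{x.pos}" for x in kept_variants if x.is_triallelic), None
            ),
        )
        accepted.append(locus)
        freqs = candidate_haplotype_freqs(cand, v.kept_variant_idx)
        accepted_freqs[name] = AlleleFrequencySet(name, freqs.alleles, freqs.frequencies)
    return ScreeningReport(params, verdicts, accepted, accepted_freqs)
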