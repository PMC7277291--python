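"""Core domain types and file formats for microhaplotype panels.

A microhaplotype (MH) is a short genomic window (< 200 bp) containing two or
more SNPs whose joint, phased alleles form a single multi-allelic marker.
This module defines the in-memory model — loci, allele-frequency spectra,
genotype tables, per-locus/panel statistics, duos, distance matrices — and
the readers/writers for every format the pipeline touches: CSV tables for
panels/frequencies/genotypes/duos, VCF for marker screening input, and
Newick for population trees.

Conventions
-----------
* Genomic coordinates are 1-based inclusive; ``span_bp = end - start + 1``.
* Haplotype alleles are concatenated base strings, one base per SNP in
  ascending positional order (e.g. ``"ACT"`` for a 3-SNP locus).
* Genotypes are unordered pairs, stored canonically sorted; missing cells
  are encoded ``"./."`` on disk and ``None`` in memory.
"""

from __future__ import annotations

import io
import math
import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
import skbio

__all__ = [
    "MISSING_GENOTYPE",
    "LOCUS_ID_PATTERN",
    "MicrohapLocus",
    "AlleleFrequencySet",
    "GenotypeTable",
    "LocusStats",
    "PanelStats",
    "DuoRecord",
    "KinshipResult",
    "DistanceMatrix",
    "MatchProbabilityParams",
    "VcfVariant",
    "make_locus_name",
    "parse_panel_definition",
    "load_reference_panel",
    "read_frequency_table",
    "write_frequency_table",
    "read_genotype_table",
    "write_genotype_table",
    "read_duo_table",
    "write_duo_table",
    "read_vcf_candidates",
    "write_newick",
]

MISSING_GENOTYPE = "./."

#: mh + zero-padded 2-digit chromosome + lowercase lab code + 3-digit serial
#: + optional single lowercase suffix distinguishing same-region variants.
LOCUS_ID_PATTERN = re.compile(r"^mh(0[1-9]|1[0-9]|2[0-2])([a-z]+?)([0-9]{3})([a-z]?)$")


def make_locus_name(chromosome: int, lab_code: str, serial: int, suffix: str | None = None) -> str:
    """Build a microhaplotype identifier, e.g. ``make_locus_name(2, "zha", 12)``
    -> ``"mh02zha012"`` and ``make_locus_name(11, "zha", 6, "a")`` -> ``"mh11zha006a"``.
    """
    if not 1 <= int(chromosome) <= 22:
        raise ValueError(f"chromosome must be in 1-22, got {chromosome}")
    if serial < 1:
        raise ValueError(f"serial must be >= 1, got {serial}")
    if not lab_code or not lab_code.isalpha() or not lab_code.islower():
        raise ValueError(f"lab code must be lowercase letters, got {lab_code!r}")
    sfx = suffix or ""
    if sfx and (len(sfx) != 1 or not "a" <= sfx <= "z"):
        raise ValueError(f"suffix must be a single letter a-z, got {suffix!r}")
    return f"mh{chromosome:02d}{lab_code}{serial:03d}{sfx}"


@dataclass(frozen=True)
class MicrohapLocus:
    """A named short genomic window of >=2 SNPs forming one multi-allelic marker.

    ``snp_positions`` holds the known 1-based coordinates in ascending order;
    when only the window boundaries are published these are the first and
    last SNP.  ``triallelic_snp`` names the designated tri-allelic member
    (``None`` if the locus has none).
    """

    id: str
    chromosome: int
    snp_positions: tuple[int, ...]
    snp_ids: tuple[str, ...]
    triallelic_snp: str | None = None
    build: str = "GRCh37"

    def __post_init__(self):
        if not LOCUS_ID_PATTERN.match(self.id):
            raise ValueError(f"malformed microhaplotype id: {self.id!r}")
        if not 1 <= self.chromosome <= 22:
            raise ValueError(f"{self.id}: chromosome must be in 1-22, got {self.chromosome}")
        pos = tuple(int(p) for p in self.snp_positions)
        if len(pos) < 2 or any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError(f"{self.id}: SNP positions must be >=2 and strictly increasing")
        object.__setattr__(self, "snp_positions", pos)
        ids = tuple(str(s) for s in self.snp_ids)
        if len(ids) < 2:
            raise ValueError(f"{self.id}: a microhaplotype needs at least 2 SNPs")
        object.__setattr__(self, "snp_ids", ids)
        if self.triallelic_snp is not None and self.triallelic_snp not in ids:
            raise ValueError(f"{self.id}: tri-allelic SNP {self.triallelic_snp!r} not among snp_ids")
        if self.span_bp >= 200:
            warnings.warn(
                f"{self.id}: span {self.span_bp} bp exceeds the 200 bp screening contract",
                stacklevel=2,
            )

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def span_bp(self) -> int:
        return self.snp_positions[-1] - self.snp_positions[0] + 1


@dataclass
class AlleleFrequencySet:
    """Per-locus haplotype-allele frequency spectrum (the p_i of Ae = 1/sum p_i^2)."""

    locus_id: str
    alleles: tuple[str, ...]
    frequencies: np.ndarray

    def __post_init__(self):
        self.alleles = tuple(str(a) for a in self.alleles)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if len(self.alleles) != self.frequencies.size or not self.alleles:
            raise ValueError(f"{self.locus_id}: alleles and frequencies must align and be non-empty")
        if len(set(self.alleles)) != len(self.alleles):
            raise ValueError(f"{self.locus_id}: duplicate alleles")
        if len({len(a) for a in self.alleles}) != 1:
            raise ValueError(f"{self.locus_id}: allele strings must all have the same length")
        if np.any(self.frequencies < 0):
            raise ValueError(f"{self.locus_id}: negative frequency")
        total = float(self.frequencies.sum())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"{self.locus_id}: frequencies sum to {total}, not 1")

    @property
    def k(self) -> int:
        return len(self.alleles)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.alleles, self.frequencies))

    def frequency_of(self, allele: str, floor: float | None = None) -> float:
        """Frequency of ``allele``; unseen alleles get ``floor`` if given, else KeyError."""
        try:
            return self.as_dict()[allele]
        except KeyError:
            if floor is not None:
                return floor
            raise


def _canonical_pair(pair) -> tuple[str, str] | None:
    if pair is None:
        return None
    a, b = pair
    return (a, b) if a <= b else (b, a)


class GenotypeTable:
    """Sample x locus table of unordered haplotype-allele pairs.

    Cells are canonically sorted ``(allele1, allele2)`` tuples or ``None``
    for missing.  Backed by a pandas DataFrame of object cells.
    """

    def __init__(self, data: pd.DataFrame):
        self.data = data.copy()
        for locus in self.data.columns:
            self.data[locus] = [
                _canonical_pair(g) if isinstance(g, tuple) else None
                for g in self.data[locus]
            ]

    @classmethod
    def from_dict(cls, genotypes: Mapping[str, Mapping[str, tuple | None]]) -> "GenotypeTable":
        """Build from ``{sample: {locus: (a1, a2) | None}}``."""
        df = pd.DataFrame.from_dict({s: dict(row) for s, row in genotypes.items()}, orient="index")
        return cls(df)

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    @property
    def loci(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return len(self.data.index)

    def column(self, locus: str, drop_missing: bool = False) -> list[tuple[str, str] | None]:
        col = list(self.data[locus])
        if drop_missing:
            col = [g for g in col if g is not None]
        return col

    def genotype(self, sample: str, locus: str) -> tuple[str, str] | None:
        return self.data.at[sample, locus]

    def row(self, sample: str) -> dict[str, tuple[str, str] | None]:
        return dict(self.data.loc[sample])

    def equals(self, other: "GenotypeTable") -> bool:
        return (
            self.samples == other.samples
            and self.loci == other.loci
            and all(
                self.genotype(s, l) == other.genotype(s, l)
                for s in self.samples
                for l in self.loci
            )
        )


@dataclass
class LocusStats:
    """Per-locus forensic parameters.

    Ae: effective number of alleles (1/sum p_i^2).  Ho/He: observed/expected
    heterozygosity.  MP: matching probability (two random individuals share a
    genotype); PD = 1 - MP.  PE: power of exclusion, from Ho.
    """

    locus_id: str
    n_samples: int
    ae: float
    ho: float
    he: float
    mp: float
    pd: float
    pe: float


@dataclass
class PanelStats:
    """Panel-level combination of per-locus forensic parameters.

    CPD = 1 - prod(1 - PD_i); CPE = 1 - prod(1 - PE_i); CMP = prod MP_i;
    ``mixture_probability`` is the cumulative two-person mixture-detection
    probability from the per-locus Ae floors.
    """

    locus_stats: list[LocusStats]
    cpd: float
    cpe: float
    cmp: float
    mixture_probability: float

    def summary(self) -> pd.DataFrame:
        """Mean / min / max of each per-locus column."""
        df = pd.DataFrame(
            {
                "ae": [s.ae for s in self.locus_stats],
                "ho": [s.ho for s in self.locus_stats],
                "he": [s.he for s in self.locus_stats],
                "mp": [s.mp for s in self.locus_stats],
                "pd": [s.pd for s in self.locus_stats],
                "pe": [s.pe for s in self.locus_stats],
            },
            index=[s.locus_id for s in self.locus_stats],
        )
        return df.agg(["mean", "min", "max"])


@dataclass
class DuoRecord:
    """A single-parent/child pairing: one genotype row each, same locus set."""

    duo_id: str
    parent: dict[str, tuple[str, str] | None]
    child: dict[str, tuple[str, str] | None]

    def __post_init__(self):
        self.parent = {l: _canonical_pair(g) for l, g in self.parent.items()}
        self.child = {l: _canonical_pair(g) for l, g in self.child.items()}
        if set(self.parent) != set(self.child):
            raise ValueError(f"duo {self.duo_id}: parent and child locus sets differ")

    @property
    def loci(self) -> list[str]:
        return list(self.parent)


@dataclass
class KinshipResult:
    """Per-locus paternity indices and their combination for one duo.

    CPI = prod PI over included loci; log10_cpi = sum log10 PI (``-inf``
    when CPI = 0 under the no-mutation policy).
    """

    duo_id: str
    pi: dict[str, float]
    cpi: float
    log10_cpi: float
    exclusions: list[str]
    skipped: list[str]
    verdict: str


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative matrix with zero diagonal over population labels.

    ``values`` has negative estimates truncated to 0 (tree/heatmap input);
    ``raw`` retains untruncated estimates when they differ.
    """

    labels: tuple[str, ...]
    values: np.ndarray
    raw: np.ndarray | None = None

    def __post_init__(self):
        self.labels = tuple(self.labels)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.abs(np.diag(self.values)) > 1e-12):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.values < 0):
            raise ValueError("distance matrix entries must be nonnegative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.labels), columns=list(self.labels))

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])


@dataclass
class MatchProbabilityParams:
    """theta: coancestry coefficient for the Balding-Nichols match probability."""

    theta: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.theta < 1.0:
            raise ValueError(f"theta must be in [0, 1), got {self.theta}")


# ---------------------------------------------------------------------------
# Panel definition tables


def parse_panel_definition(table) -> list[MicrohapLocus]:
    """Parse a panel definition CSV (path or DataFrame) into validated loci.

    Requires columns ``id``, ``chromosome``, ``snp_ids`` and either
    ``snp_positions`` (';'-separated 1-based coordinates) or ``start``/``end``.
    An optional ``length_bp`` column is cross-checked against the recomputed
    span; a mismatch raises.
    """
    df = table if isinstance(table, pd.DataFrame) else pd.read_csv(table)
    required = {"id", "chromosome", "snp_ids"}
    if missing := required - set(df.columns):
        raise ValueError(f"panel definition missing columns: {sorted(missing)}")
    loci = []
    for _, row in df.iterrows():
        if "snp_positions" in df.columns and not _is_na(row.get("snp_positions")):
            positions = tuple(int(p) for p in str(row["snp_positions"]).split(";"))
        else:
            positions = (int(row["start"]), int(row["end"]))
        tri = row.get("triallelic_snp")
        locus = MicrohapLocus(
            id=str(row["id"]),
            chromosome=int(row["chromosome"]),
            snp_positions=positions,
            snp_ids=tuple(str(row["snp_ids"]).split(";")),
            triallelic_snp=None if _is_na(tri) else str(tri),
        )
        if "length_bp" in df.columns and not _is_na(row.get("length_bp")):
            stated = int(row["length_bp"])
            if stated != locus.span_bp:
                raise ValueError(
                    f"{locus.id}: stated length {stated} != span {locus.span_bp}"
                )
        loci.append(locus)
    return loci


def _is_na(value) -> bool:
    return value is None or (isinstance(value, float) and math.isnan(value)) or value == ""


def load_reference_panel() -> tuple[list[MicrohapLocus], pd.DataFrame]:
    """Load the bundled 20-locus tri-allelic microhaplotype reference panel.

    Returns the validated loci plus a DataFrame (indexed by locus id) of the
    published per-locus forensic parameters (ae, ho, pd, pe, length_bp) for
    50 unrelated Han Chinese individuals.
    """
    with resources.files("mhpanel.data").joinpath("reference_panel.csv").open() as fh:
        df = pd.read_csv(fh)
    loci = parse_panel_definition(df)
    stats = df.set_index("id")[["length_bp", "ae", "ho", "pd", "pe"]]
    return loci, stats


# ---------------------------------------------------------------------------
# Frequency tables


def read_frequency_table(path) -> list[AlleleFrequencySet]:
    """Read a long-format CSV (locus_id, allele, frequency) into frequency sets.

    Per-locus frequencies are renormalized when their sum is within 1e-6 of
    1; larger deviations, negative values and duplicate allele rows raise.
    """
    df = pd.read_csv(path, dtype={"locus_id": str, "allele": str})
    if missing := {"locus_id", "allele", "frequency"} - set(df.columns):
        raise ValueError(f"frequency table missing columns: {sorted(missing)}")
    sets = []
    for locus_id, grp in df.groupby("locus_id", sort=False):
        alleles = tuple(grp["allele"])
        if len(set(alleles)) != len(alleles):
            raise ValueError(f"{locus_id}: duplicate allele rows")
        freqs = grp["frequency"].to_numpy(dtype=float)
        if np.any(freqs < 0):
            raise ValueError(f"{locus_id}: negative frequency")
        total = float(freqs.sum())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"{locus_id}: frequencies sum to {total}, outside 1 +/- 1e-6")
        sets.append(AlleleFrequencySet(locus_id, alleles, freqs / total))
    return sets


def write_frequency_table(sets: Iterable[AlleleFrequencySet], path) -> None:
    rows = [
        {"locus_id": s.locus_id, "allele": a, "frequency": f}
        for s in sets
        for a, f in zip(s.alleles, s.frequencies)
    ]
    pd.DataFrame(rows, columns=["locus_id", "allele", "frequency"]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Genotype and duo tables


def _format_genotype(pair: tuple[str, str] | None) -> str:
    return MISSING_GENOTYPE if pair is None else f"{pair[0]}/{pair[1]}"


def _parse_genotype(cell: str, locus: str, n_snps: int | None) -> tuple[str, str] | None:
    cell = str(cell).strip()
    if cell == MISSING_GENOTYPE or cell in ("", "nan"):
        return None
    try:
        a, b = cell.split("/")
    except ValueError:
        raise ValueError(f"{locus}: malformed genotype cell {cell!r}") from None
    if n_snps is not None and (len(a) != n_snps or len(b) != n_snps):
        raise ValueError(
            f"{locus}: allele length in {cell!r} inconsistent with {n_snps} SNPs"
        )
    return _canonical_pair((a, b))


def read_genotype_table(path, panel: Sequence[MicrohapLocus] | None = None) -> GenotypeTable:
    """Read a wide CSV (sample_id + one column per locus, cells "A1/A2" or "./.").

    When ``panel`` is supplied, allele string lengths are validated against
    each locus's SNP count.
    """
    df = pd.read_csv(path, dtype=str).set_index("sample_id")
    n_snps = {l.id: l.n_snps for l in panel} if panel else {}
    parsed = {
        sample: {
            locus: _parse_genotype(df.at[sample, locus], locus, n_snps.get(locus))
            for locus in df.columns
        }
        for sample in df.index
    }
    return GenotypeTable.from_dict(parsed)


def write_genotype_table(table: GenotypeTable, path) -> None:
    out = pd.DataFrame(
        {locus: [_format_genotype(g) for g in table.column(locus)] for locus in table.loci},
        index=pd.Index(table.samples, name="sample_id"),
    )
    out.to_csv(path)


def read_duo_table(path, panel: Sequence[MicrohapLocus] | None = None) -> list[DuoRecord]:
    """Read duos from a wide CSV with ``duo_id`` and ``role`` (parent|child) columns."""
    df = pd.read_csv(path, dtype=str)
    loci = [c for c in df.columns if c not in ("duo_id", "role")]
    n_snps = {l.id: l.n_snps for l in panel} if panel else {}
    duos = []
    for duo_id, grp in df.groupby("duo_id", sort=False):
        rows = {r["role"]: r for _, r in grp.iterrows()}
        if set(rows) != {"parent", "child"}:
            raise ValueError(f"duo {duo_id}: need exactly one parent and one child row")
        duos.append(
            DuoRecord(
                duo_id=str(duo_id),
                parent={l: _parse_genotype(rows["parent"][l], l, n_snps.get(l)) for l in loci},
                child={l: _parse_genotype(rows["child"][l], l, n_snps.get(l)) for l in loci},
            )
        )
    return duos


def write_duo_table(duos: Iterable[DuoRecord], path) -> None:
    rows = []
    for duo in duos:
        for role, geno in (("parent", duo.parent), ("child", duo.child)):
            row = {"duo_id": duo.duo_id, "role": role}
            row.update({l: _format_genotype(g) for l, g in geno.items()})
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# VCF ingestion


@dataclass
class VcfVariant:
    """One VCF record: multi-allelic records are kept whole, not split.

    ``frequencies`` covers REF then ALTs in order and sums to 1;
    ``genotypes`` (if the VCF had GT columns) holds per-sample allele-index
    pairs or ``None``.
    """

    chrom: str
    pos: int
    id: str | None
    ref: str
    alts: tuple[str, ...]
    frequencies: np.ndarray
    genotypes: list[tuple[int, int] | None] | None = None

    @property
    def is_triallelic(self) -> bool:
        """True for records with 3+ total alleles (REF + >=2 ALTs)."""
        return len(self.alts) >= 2

    @property
    def alleles(self) -> tuple[str, ...]:
        return (self.ref,) + self.alts

    @property
    def maf(self) -> float:
        """Minor allele frequency: the second-most-frequent allele's frequency."""
        return float(np.sort(self.frequencies)[-2]) if len(self.frequencies) > 1 else 0.0


def _parse_region(region: str) -> tuple[str, int, int]:
    m = re.match(r"^([^:]+)(?::([\d,]+)-([\d,]+))?$", region)
    if not m:
        raise ValueError(f"malformed region {region!r}")
    chrom, lo, hi = m.groups()
    return (
        chrom,
        int(lo.replace(",", "")) if lo else 1,
        int(hi.replace(",", "")) if hi else 2**62,
    )


def read_vcf_candidates(path, region: str | None = None) -> list[VcfVariant]:
    """Read SNP candidates from a VCF v4.x file.

    Allele frequencies are taken from the AF (or AC+AN) INFO fields when
    present, otherwise computed from the GT columns; a record with neither
    raises.  ``region`` ("chr" or "chr:start-end", 1-based inclusive)
    filters during iteration, so plain uncompressed VCFs need no index.
    """
    want = _parse_region(region) if region else None
    out = []
    with pysam.VariantFile(str(path)) as vcf:
        has_samples = len(vcf.header.samples) > 0
        for rec in vcf:
            pos = rec.pos  # pysam reports the 1-based POS
            if want and not (rec.chrom == want[0] and want[1] <= pos <= want[2]):
                continue
            alts = tuple(rec.alts or ())
            n_all = 1 + len(alts)
            genotypes = None
            if has_samples:
                genotypes = []
                for sample in rec.samples.values():
                    gt = sample.get("GT")
                    if gt is None or any(a is None for a in gt):
                        genotypes.append(None)
                    else:
                        a, b = int(gt[0]), int(gt[1])
                        genotypes.append((a, b) if a <= b else (b, a))
            freqs = _variant_frequencies(rec, n_all, genotypes)
            out.append(
                VcfVariant(
                    chrom=rec.chrom,
                    pos=pos,
                    id=rec.id,
                    ref=rec.ref,
                    alts=alts,
                    frequencies=freqs,
                    genotypes=genotypes,
                )
            )
    return out


def _variant_frequencies(rec, n_alleles: int, genotypes) -> np.ndarray:
    info = rec.info
    if "AF" in info:
        af = np.atleast_1d(np.asarray(info["AF"], dtype=float))
        return np.concatenate([[1.0 - af.sum()], af])
    if "AC" in info and "AN" in info:
        ac = np.atleast_1d(np.asarray(info["AC"], dtype=float))
        an = float(info["AN"])
        return np.concatenate([[(an - ac.sum()) / an], ac / an])
    if genotypes:
        counts = np.zeros(n_alleles)
        for gt in genotypes:
            if gt is not None:
                counts[gt[0]] += 1
                counts[gt[1]] += 1
        if counts.sum() > 0:
            return counts / counts.sum()
    raise ValueError(
        f"{rec.chrom}:{rec.pos}: no AF/AC+AN INFO fields and no usable GT columns"
    )


# ---------------------------------------------------------------------------
# Newick export


def write_newick(tree: skbio.TreeNode) -> str:
    """Serialize a tree (e.g. from population_structure.nj_tree) to Newick."""
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()
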