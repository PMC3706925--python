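"""Shared genomic data model: sites, phased parents, plasma counts, site classes.

Everything downstream (simulation, fetal-fraction estimation, the transmission
HMM, the site-by-site baseline) operates on the structures defined here.
Alleles are stored as alt-allele indicators (0 = ref, 1 = alt) in numpy
arrays aligned to a shared, position-sorted :class:`SiteTable`; the base
letters live on the table itself.  Positions are 1-based at every external
interface (VCF convention).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

AUTOSOMES = tuple(f"chr{i}" for i in range(1, 23))
CHRX = "chrX"
VALID_CHROMS = AUTOSOMES + (CHRX,)
_BASES = frozenset("ACGT")


def normalize_chrom(name: str) -> str:
    """Map '1'..'22', 'X', 'chr1'..'chrX' to canonical 'chr*' names.

    chrY and mitochondrial contigs are rejected: the model covers autosomes
    and the maternally transmitted X only.
    """
    s = str(name)
    if not s.startswith("chr"):
        s = "chr" + s
    if s == "chrx":
        s = "chrX"
    if s not in VALID_CHROMS:
        raise ValueError(f"unsupported chromosome {name!r} (autosomes and chrX only)")
    return s


def is_x(chrom: str) -> bool:
    return normalize_chrom(chrom) == CHRX


class SiteClass(enum.IntEnum):
    """Informativeness class of a marker given the two parental genotypes."""

    UNINFORMATIVE = 0       # both parents homozygous, same allele
    PATERNAL_ONLY_HET = 1   # father het, mother hom
    MATERNAL_ONLY_HET = 2   # mother het, father hom
    BIPARENTAL_HET = 3      # both het
    DISCORDANT_HOM = 4      # parents homozygous for opposite alleles


#: Classes that enter the HMM chain (fetal allele is not determined a priori).
HMM_CLASSES = (
    SiteClass.PATERNAL_ONLY_HET,
    SiteClass.MATERNAL_ONLY_HET,
    SiteClass.BIPARENTAL_HET,
)


@dataclass(frozen=True)
class Site:
    """A biallelic SNV marker."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str

    def __post_init__(self):
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if self.ref not in _BASES or self.alt not in _BASES:
            raise ValueError(f"alleles must be single bases, got {self.ref}/{self.alt}")
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")
        if self.pos < 1:
            raise ValueError("positions are 1-based and must be >= 1")


class SiteTable:
    """Ordered list of biallelic sites, grouped by chromosome.

    Sites must be contiguous per chromosome and strictly increasing in
    position within each chromosome.
    """

    def __init__(self, chrom: Sequence[str], pos: Sequence[int],
                 ref: Sequence[str], alt: Sequence[str]):
        self.chrom = np.asarray([normalize_chrom(c) for c in chrom], dtype=object)
        self.pos = np.asarray(pos, dtype=np.int64)
        self.ref = np.asarray(ref, dtype="U1")
        self.alt = np.asarray(alt, dtype="U1")
        n = len(self.pos)
        if not (len(self.chrom) == len(self.ref) == len(self.alt) == n):
            raise ValueError("site columns must have equal length")
        if np.any(self.ref == self.alt):
            raise ValueError("ref == alt at some site")
        # build chromosome -> slice index; require contiguous grouping
        self._slices: dict[str, slice] = {}
        i = 0
        while i < n:
            c = self.chrom[i]
            j = i
            while j < n and self.chrom[j] == c:
                j += 1
            if c in self._slices:
                raise ValueError(f"chromosome {c} not contiguous in site table")
            block = self.pos[i:j]
            if np.any(np.diff(block) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")
            self._slices[c] = slice(i, j)
            i = j

    def __len__(self) -> int:
        return len(self.pos)

    @property
    def chroms(self) -> list[str]:
        return list(self._slices)

    def chrom_slice(self, chrom: str) -> slice:
        return self._slices[normalize_chrom(chrom)]

    @property
    def is_x(self) -> np.ndarray:
        return self.chrom == CHRX

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"chrom": self.chrom, "pos": self.pos, "ref": self.ref, "alt": self.alt}
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "SiteTable":
        return cls(df["chrom"].to_numpy(), df["pos"].to_numpy(),
                   df["ref"].to_numpy(), df["alt"].to_numpy())

    def same_sites(self, other: "SiteTable") -> bool:
        return (
            len(self) == len(other)
            and np.array_equal(self.chrom, other.chrom)
            and np.array_equal(self.pos, other.pos)
            and np.array_equal(self.ref, other.ref)
            and np.array_equal(self.alt, other.alt)
        )


@dataclass
class PhasedParent:
    """Two ordered haplotypes for one parent over a shared site list.

    ``hap0`` / ``hap1`` hold alt-allele indicators (int8).  For a father,
    chrX is hemizygous: ``hap1`` carries ``-1`` on X sites and ``hap0`` is
    the single X allele.
    """

    role: str  # "mother" | "father"
    sites: SiteTable
    hap0: np.ndarray
    hap1: np.ndarray

    def __post_init__(self):
        if self.role not in ("mother", "father"):
            raise ValueError("role must be 'mother' or 'father'")
        self.hap0 = np.asarray(self.hap0, dtype=np.int8)
        self.hap1 = np.asarray(self.hap1, dtype=np.int8)
        n = len(self.sites)
        if len(self.hap0) != n or len(self.hap1) != n:
            raise ValueError("haplotype length must equal site count")

    @property
    def haploid_x(self) -> bool:
        x = self.sites.is_x
        return self.role == "father" and bool(np.any(x)) and bool(np.all(self.hap1[x] == -1))

    def dosage(self) -> np.ndarray:
        """Alt-allele dosage; hemizygous X sites of a father count their
        single allele twice (hom-equivalent) for classification purposes."""
        d = (self.hap0 + np.where(self.hap1 < 0, self.hap0, self.hap1)).astype(np.int8)
        return d

    def genotype(self, i: int) -> tuple[str, ...]:
        """Unordered genotype at site i as base letters (length 1 on a
        hemizygous X site)."""
        alleles = [self.sites.ref[i], self.sites.alt[i]]
        if self.hap1[i] < 0:
            return (alleles[self.hap0[i]],)
        return tuple(sorted((alleles[self.hap0[i]], alleles[self.hap1[i]])))


@dataclass
class PlasmaCounts:
    """Per-site non-duplicate ref/alt read counts from maternal plasma."""

    sites: SiteTable
    n_ref: np.ndarray
    n_alt: np.ndarray

    def __post_init__(self):
        self.n_ref = np.asarray(self.n_ref, dtype=np.int64)
        self.n_alt = np.asarray(self.n_alt, dtype=np.int64)
        n = len(self.sites)
        if len(self.n_ref) != n or len(self.n_alt) != n:
            raise ValueError("count arrays must align 1:1 with the site list")
        if np.any(self.n_ref < 0) or np.any(self.n_alt < 0):
            raise ValueError("read counts must be non-negative")

    @property
    def depth(self) -> np.ndarray:
        return self.n_ref + self.n_alt

    def to_dataframe(self) -> pd.DataFrame:
        df = self.sites.to_dataframe()
        df["n_ref"] = self.n_ref
        df["n_alt"] = self.n_alt
        return df


@dataclass
class FetalFractionEstimate:
    """Cell-free fetal DNA fraction estimate from discordant-homozygous sites."""

    f_hat: float
    n_sites_used: int
    per_chromosome: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if not 0.0 <= self.f_hat <= 1.0:
            raise ValueError("f_hat must lie in [0, 1]")
        for c, v in self.per_chromosome.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"per-chromosome fraction for {c} outside [0, 1]")


def _gt_to_dosage(gt: Iterable[str], ref: str, alt: str) -> int:
    d = 0
    for a in gt:
        if a == alt:
            d += 1
        elif a != ref:
            raise ValueError(f"allele {a!r} is neither ref {ref!r} nor alt {alt!r}")
    return d


def classify_site(mother_gt: Sequence[str], father_gt: Sequence[str],
                  chrom: str, fetal_sex: str = "male") -> SiteClass:
    """Classify one site from unordered parental genotypes (base letters).

    ``father_gt`` must be a single allele on chrX when the fetus is male
    (the father transmits Y, not X).  Raises on unknown chromosomes and on
    non-biallelic genotype combinations.
    """
    chrom = normalize_chrom(chrom)
    mother_gt = tuple(mother_gt)
    father_gt = tuple(father_gt)
    alleles = sorted(set(mother_gt) | set(father_gt))
    if len(alleles) > 2:
        raise ValueError(f"non-biallelic genotypes: mother {mother_gt}, father {father_gt}")
    if len(mother_gt) != 2:
        raise ValueError("mother genotype must be diploid")
    ref = alleles[0]
    alt = alleles[1] if len(alleles) == 2 else "N"  # monomorphic: dosages all 0
    m = _gt_to_dosage(mother_gt, ref, alt)
    xsite = chrom == CHRX
    if xsite and fetal_sex == "male":
        if len(father_gt) != 1:
            raise ValueError("father genotype must be haploid on chrX for a male fetus")
        return SiteClass.MATERNAL_ONLY_HET if m == 1 else SiteClass.UNINFORMATIVE
    if len(father_gt) == 1:
        if not xsite:
            raise ValueError("haploid father genotype only valid on chrX")
        father_gt = father_gt * 2  # hemizygous allele behaves as homozygous
    elif xsite and father_gt[0] != father_gt[1]:
        raise ValueError("father cannot be heterozygous on chrX")
    p = _gt_to_dosage(father_gt, ref, alt)
    return _classify_from_dosage(m, p)


def _classify_from_dosage(m: int, p: int) -> SiteClass:
    if m == 1 and p == 1:
        return SiteClass.BIPARENTAL_HET
    if m == 1:
        return SiteClass.MATERNAL_ONLY_HET
    if p == 1:
        return SiteClass.PATERNAL_ONLY_HET
    if m != p:
        return SiteClass.DISCORDANT_HOM
    return SiteClass.UNINFORMATIVE


def classify_sites(mother_dosage: np.ndarray, father_dosage: np.ndarray,
                   x_mask: np.ndarray, fetal_sex: str = "male") -> np.ndarray:
    """Vectorised site classification from alt-dosage arrays.

    ``father_dosage`` on hemizygous X sites is the single allele counted
    twice (as produced by :meth:`PhasedParent.dosage`).
    """
    m = np.asarray(mother_dosage)
    p = np.asarray(father_dosage)
    out = np.full(m.shape, SiteClass.UNINFORMATIVE, dtype=np.int8)
    m_het = m == 1
    p_het = p == 1
    out[m_het & p_het] = SiteClass.BIPARENTAL_HET
    out[m_het & ~p_het] = SiteClass.MATERNAL_ONLY_HET
    out[~m_het & p_het] = SiteClass.PATERNAL_ONLY_HET
    out[~m_het & ~p_het & (m != p)] = SiteClass.DISCORDANT_HOM
    if fetal_sex == "male":
        x = np.asarray(x_mask, dtype=bool)
        out[x] = np.where(m_het[x], SiteClass.MATERNAL_ONLY_HET, SiteClass.UNINFORMATIVE)
    return out
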