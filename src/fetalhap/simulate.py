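"""Synthetic plasma-sequencing data generator.

Emulates the study design end to end: a three-generation pedigree on a
SNP-array-like marker panel, meiosis with Poisson crossovers under the
Haldane (no-interference) map, and maternal plasma as a mixture of maternal
and fetal cell-free DNA read out by binomial sampling with a symmetric
per-read error.  The generator's defaults reproduce the study's operating
point: fetal fraction 5.69%, mean non-duplicate depth 33.6X, ~375,000
markers genome-wide, a male fetus, and 1.2 cM/Mb genetic maps.

The observation law per autosomal site is

    n ~ Poisson(mean_depth)
    k ~ Binomial(n, theta_err),   theta = (1-f) g_M/2 + f g_F/2

with g_M, g_F the maternal and fetal alt-allele dosages and
theta_err = theta (1-eps) + (1-theta) eps.  On chrX with a male fetus the
fetus contributes a single maternal-origin X, so

    n ~ Poisson(mean_depth (2-f)/2)
    theta = [(1-f) g_M + f a_m] / (2-f)

where a_m is the transmitted maternal X allele.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (CHRX, PhasedParent, PlasmaCounts, SiteClass, SiteTable,
                   classify_sites)

# GRCh37-scale chromosome lengths (bp).
DEFAULT_CHROM_LENGTHS: dict[str, int] = {
    "chr1": 249_000_000, "chr2": 243_000_000, "chr3": 198_000_000,
    "chr4": 191_000_000, "chr5": 181_000_000, "chr6": 171_000_000,
    "chr7": 159_000_000, "chr8": 146_000_000, "chr9": 141_000_000,
    "chr10": 136_000_000, "chr11": 135_000_000, "chr12": 134_000_000,
    "chr13": 115_000_000, "chr14": 107_000_000, "chr15": 103_000_000,
    "chr16": 90_000_000, "chr17": 81_000_000, "chr18": 78_000_000,
    "chr19": 59_000_000, "chr20": 63_000_000, "chr21": 48_000_000,
    "chr22": 51_000_000, CHRX: 155_000_000,
}

GRANDPARENT_IDS = ("pgf", "pgm", "mgf", "mgm")  # paternal/maternal grandfather/-mother


@dataclass
class SimParams:
    """Generator parameters; defaults are the study regime."""

    n_autosomal_sites: int = 370_000   # length-scaled across the 22 autosomes
    n_chrx_sites: int = 5_200          # array-like sparse X coverage (~1,900 maternal-het)
    chrom_lengths: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_CHROM_LENGTHS))
    chroms: tuple[str, ...] | None = None  # subset; None = all in chrom_lengths
    af_low: float = 0.05               # per-site alt frequency ~ U(af_low, af_high)
    af_high: float = 0.95
    f: float = 0.0569                  # true fetal fraction
    mean_depth: float = 33.6           # non-duplicate autosomal depth
    fixed_depth: bool = False          # use exactly mean_depth reads (analytic tests)
    eps: float = 0.005                 # symmetric per-read error probability
    r_maternal: float = 1.2            # cM/Mb
    r_paternal: float = 1.2
    fetal_sex: str = "male"
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.f < 1.0:
            raise ValueError("fetal fraction f must lie in (0, 1)")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if not 0.0 <= self.eps < 0.5:
            raise ValueError("eps must lie in [0, 0.5)")
        if self.r_maternal < 0 or self.r_paternal < 0:
            raise ValueError("recombination rates must be non-negative")
        if self.n_autosomal_sites <= 0:
            raise ValueError("need at least one site")
        for c, L in self.chrom_lengths.items():
            if L <= 0:
                raise ValueError(f"chromosome length for {c} must be positive")
        if self.fetal_sex not in ("male", "female"):
            raise ValueError("fetal_sex must be 'male' or 'female'")

    def active_chroms(self) -> list[str]:
        if self.chroms is None:
            return list(self.chrom_lengths)
        return [c for c in self.chrom_lengths if c in set(self.chroms)]

    def sites_per_chrom(self) -> dict[str, int]:
        chroms = self.active_chroms()
        autos = [c for c in chroms if c != CHRX]
        total_len = sum(self.chrom_lengths[c] for c in autos)
        out: dict[str, int] = {}
        for c in chroms:
            if c == CHRX:
                out[c] = self.n_chrx_sites
            else:
                out[c] = max(2, round(self.n_autosomal_sites * self.chrom_lengths[c] / total_len))
        return out


@dataclass
class SimTruth:
    """Ground truth of one simulated pregnancy.

    ``path_pat`` / ``path_mat`` record, per site, which parental haplotype
    (0/1) the fetus inherited; they change value only at crossovers.
    ``fetal_pat`` is -1 on chrX for a male fetus (the father transmits Y).
    """

    sites: SiteTable
    mother: PhasedParent
    father: PhasedParent
    grandparent_haps: dict[str, tuple[np.ndarray, np.ndarray]]
    path_pat: np.ndarray
    path_mat: np.ndarray
    fetal_pat: np.ndarray
    fetal_mat: np.ndarray
    crossovers: dict[str, dict[str, np.ndarray]]  # parent -> chrom -> positions (bp)
    f: float
    fetal_sex: str
    denovo: pd.DataFrame | None = None

    def site_classes(self) -> np.ndarray:
        return classify_sites(self.mother.dosage(), self.father.dosage(),
                              self.sites.is_x, self.fetal_sex)

    def fetal_dosage(self) -> np.ndarray:
        """Fetal alt dosage; hemizygous male-X sites count the single
        maternal allele once."""
        g = np.where(self.fetal_pat < 0, 0, self.fetal_pat) + self.fetal_mat
        return g.astype(np.int8)


def _random_sites(params: SimParams, rng: np.random.Generator) -> tuple[SiteTable, np.ndarray]:
    chroms, poss, refs, alts = [], [], [], []
    afs = []
    bases = np.array(list("ACGT"))
    per_chrom = params.sites_per_chrom()
    for c in params.active_chroms():
        n = per_chrom[c]
        L = params.chrom_lengths[c]
        pos = np.sort(rng.choice(L, size=n, replace=False)) + 1
        ref_i = rng.integers(0, 4, size=n)
        alt_i = (ref_i + rng.integers(1, 4, size=n)) % 4
        chroms.extend([c] * n)
        poss.append(pos)
        refs.append(bases[ref_i])
        alts.append(bases[alt_i])
        afs.append(rng.uniform(params.af_low, params.af_high, size=n))
    table = SiteTable(chroms, np.concatenate(poss), np.concatenate(refs),
                      np.concatenate(alts))
    return table, np.concatenate(afs)


def _n_crossovers(length_bp: int, rate_cm_per_mb: float, rng: np.random.Generator) -> int:
    # expected crossovers = genetic length in Morgans = L_Mb * r / 100
    lam = length_bp / 1e6 * rate_cm_per_mb / 100.0
    return int(rng.poisson(lam))


def _gamete(hap0: np.ndarray, hap1: np.ndarray, pos: np.ndarray, length_bp: int,
            rate: float, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One meiotic product of a haplotype pair.

    Returns (gamete alleles, per-site source-haplotype path, crossover bp).
    """
    nx = _n_crossovers(length_bp, rate, rng)
    xpos = np.sort(rng.uniform(0, length_bp, size=nx))
    start = int(rng.integers(0, 2))
    path = (start + np.searchsorted(xpos, pos)) % 2
    path = path.astype(np.int8)
    gamete = np.where(path == 0, hap0, hap1).astype(np.int8)
    return gamete, path, xpos


def simulate_pedigree(params: SimParams) -> SimTruth:
    """Draw a three-generation pedigree and the fetal transmission truth.

    Grandparental haplotypes are drawn site-independently from the per-site
    allele frequency; each parental haplotype is a recombinant of one
    grandparent's pair; the fetus recombines each parent's pair.  A male
    fetus receives one maternal recombinant X and no paternal X.
    """
    rng = np.random.default_rng(params.seed)
    sites, af = _random_sites(params, rng)
    n = len(sites)
    male = params.fetal_sex == "male"

    gp_haps: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for gp in GRANDPARENT_IDS:
        h0 = (rng.random(n) < af).astype(np.int8)
        h1 = (rng.random(n) < af).astype(np.int8)
        if gp in ("pgf", "mgf"):  # grandfathers are hemizygous on X
            h1 = h1.copy()
            h1[sites.is_x] = -1
        gp_haps[gp] = (h0, h1)

    def meiosis(gp: str, rate: float) -> tuple[np.ndarray, np.ndarray, dict[str, np.ndarray]]:
        h0, h1 = gp_haps[gp]
        gam = np.empty(n, dtype=np.int8)
        path = np.empty(n, dtype=np.int8)
        xovers: dict[str, np.ndarray] = {}
        for c in sites.chroms:
            sl = sites.chrom_slice(c)
            if c == CHRX and gp in ("pgf", "mgf"):
                # hemizygous: the single X passes without recombination
                gam[sl] = h0[sl]
                path[sl] = 0
                xovers[c] = np.empty(0)
                continue
            g, p, x = _gamete(h0[sl], h1[sl], sites.pos[sl],
                              params.chrom_lengths[c], rate, rng)
            gam[sl], path[sl] = g, p
            xovers[c] = x
        return gam, path, xovers

    # parents: hap0 from the grandfather's meiosis, hap1 from the grandmother's
    f_h0, _, _ = meiosis("pgf", params.r_paternal)
    f_h1, _, _ = meiosis("pgm", params.r_maternal)
    m_h0, _, _ = meiosis("mgf", params.r_paternal)
    m_h1, _, _ = meiosis("mgm", params.r_maternal)

    xmask = sites.is_x
    if np.any(xmask):
        f_h0 = f_h0.copy()
        f_h0[xmask] = f_h1[xmask]  # father's single X comes from his mother
        f_h1 = f_h1.copy()
        f_h1[xmask] = -1
    father = PhasedParent("father", sites, f_h0, f_h1)
    mother = PhasedParent("mother", sites, m_h0, m_h1)

    # fetal meiosis
    fetal_mat = np.empty(n, dtype=np.int8)
    path_mat = np.empty(n, dtype=np.int8)
    fetal_pat = np.empty(n, dtype=np.int8)
    path_pat = np.empty(n, dtype=np.int8)
    xovers_m: dict[str, np.ndarray] = {}
    xovers_p: dict[str, np.ndarray] = {}
    for c in sites.chroms:
        sl = sites.chrom_slice(c)
        g, p, x = _gamete(mother.hap0[sl], mother.hap1[sl], sites.pos[sl],
                          params.chrom_lengths[c], params.r_maternal, rng)
        fetal_mat[sl], path_mat[sl] = g, p
        xovers_m[c] = x
        if c == CHRX and male:
            fetal_pat[sl] = -1
            path_pat[sl] = 0
            xovers_p[c] = np.empty(0)
        elif c == CHRX:
            fetal_pat[sl] = father.hap0[sl]  # female fetus: father's X verbatim
            path_pat[sl] = 0
            xovers_p[c] = np.empty(0)
        else:
            g, p, x = _gamete(father.hap0[sl], father.hap1[sl], sites.pos[sl],
                              params.chrom_lengths[c], params.r_paternal, rng)
            fetal_pat[sl], path_pat[sl] = g, p
            xovers_p[c] = x

    return SimTruth(sites=sites, mother=mother, father=father,
                    grandparent_haps=gp_haps,
                    path_pat=path_pat, path_mat=path_mat,
                    fetal_pat=fetal_pat, fetal_mat=fetal_mat,
                    crossovers={"paternal": xovers_p, "maternal": xovers_m},
                    f=params.f, fetal_sex=params.fetal_sex)


def plasma_theta(truth: SimTruth) -> np.ndarray:
    """Error-free expected alt-read fraction per site under the mixture law."""
    f = truth.f
    g_m = truth.mother.dosage().astype(float)
    g_f = truth.fetal_dosage().astype(float)
    theta = (1 - f) * g_m / 2.0 + f * g_f / 2.0
    if truth.fetal_sex == "male":
        x = truth.sites.is_x
        theta[x] = ((1 - f) * g_m[x] + f * truth.fetal_mat[x]) / (2.0 - f)
    return theta


def simulate_plasma(truth: SimTruth, params: SimParams,
                    rng: np.random.Generator | None = None) -> PlasmaCounts:
    """Sample plasma read counts for a simulated pregnancy.

    Depth is Poisson with mean ``mean_depth`` on autosomes and
    ``mean_depth*(2-f)/2`` on chrX for a male fetus (one fetal X fewer);
    ``fixed_depth`` replaces the Poisson draw by the rounded mean.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed + 1_000_003)
    n = len(truth.sites)
    mean = np.full(n, params.mean_depth, dtype=float)
    if truth.fetal_sex == "male":
        mean[truth.sites.is_x] *= (2.0 - truth.f) / 2.0
    if params.fixed_depth:
        depth = np.round(mean).astype(np.int64)
    else:
        depth = rng.poisson(mean)
    theta = plasma_theta(truth)
    theta_err = theta * (1 - params.eps) + (1 - theta) * params.eps
    k_alt = rng.binomial(depth, theta_err)
    return PlasmaCounts(truth.sites, depth - k_alt, k_alt)


def spike_denovo(truth: SimTruth, n_mutations: int, seed: int) -> tuple[SimTruth, pd.DataFrame]:
    """Flip one fetal allele to the non-parental allele at uninformative sites.

    Models point de-novo mutations at sites where both parents are
    homozygous for the same allele, so any read of the other allele in
    plasma is fetus-specific.  Returns a modified copy of ``truth`` and the
    mutation list for sensitivity evaluation.
    """
    rng = np.random.default_rng(seed)
    classes = truth.site_classes()
    eligible = np.flatnonzero(
        (classes == SiteClass.UNINFORMATIVE) & ~truth.sites.is_x
    )
    if n_mutations > len(eligible):
        raise ValueError(f"requested {n_mutations} mutations but only "
                         f"{len(eligible)} uninformative autosomal sites")
    if n_mutations == 0:
        return truth, pd.DataFrame(columns=["chrom", "pos", "parent_origin", "new_allele"])
    idx = np.sort(rng.choice(eligible, size=n_mutations, replace=False))
    new = copy.copy(truth)
    new.fetal_pat = truth.fetal_pat.copy()
    new.fetal_mat = truth.fetal_mat.copy()
    origin = rng.integers(0, 2, size=n_mutations)  # 0 = paternal copy, 1 = maternal
    rows = []
    for j, i in enumerate(idx):
        flipped = np.int8(1 - truth.fetal_mat[i])  # both copies equal at these sites
        if origin[j] == 0:
            new.fetal_pat[i] = flipped
        else:
            new.fetal_mat[i] = flipped
        rows.append((truth.sites.chrom[i], int(truth.sites.pos[i]),
                     "paternal" if origin[j] == 0 else "maternal", int(flipped)))
    new.denovo = pd.DataFrame(rows, columns=["chrom", "pos", "parent_origin", "new_allele"])
    return new, new.denovo
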