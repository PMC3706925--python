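"""Parental haplotype construction from trio genotypes plus a panel.

A parent is phased against its own two parents by Mendelian transmission:
at most sites the grandparental genotypes uniquely orient the parent's
alleles; sites where all three individuals are heterozygous (and similar
configurations) stay ambiguous, and Mendelian-impossible sites are flagged
for exclusion.  Remaining ambiguous heterozygous sites are oriented by a
windowed majority vote over a reference haplotype panel: each panel
haplotype is matched against the two partially built haplotypes over the
nearest phased heterozygous sites and votes its own allele onto the
better-matching one.  This is a deliberately small stand-in for
population-scale statistical phasing, preserving the interface
(partial trio phase in, complete phase out).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import PhasedParent, SiteTable

# per-site codes in PartialPhase.hap_gf
AMBIGUOUS = -1
INCONSISTENT = -2

# phase-source codes
SOURCE_TRIO = 0
SOURCE_PANEL = 1
SOURCE_RANDOM = 2


@dataclass
class PartialPhase:
    """Trio-phasing result: ordered (grandfather, grandmother) alleles.

    ``hap_gf`` holds the allele transmitted by the grandfather (alt
    indicator), or AMBIGUOUS / INCONSISTENT; the grandmother allele is
    implied as dosage - hap_gf at resolved sites.
    """

    sites: SiteTable
    dosage: np.ndarray   # parent alt dosage
    hap_gf: np.ndarray   # int8: 0/1 allele, -1 ambiguous, -2 inconsistent

    @property
    def hap_gm(self) -> np.ndarray:
        out = np.where(self.hap_gf >= 0, self.dosage - self.hap_gf, self.hap_gf)
        return out.astype(np.int8)

    @property
    def inferred_rate(self) -> float:
        """Fraction of Mendelian-consistent sites already phased."""
        ok = self.hap_gf != INCONSISTENT
        if ok.sum() == 0:
            return 0.0
        return float((self.hap_gf[ok] >= 0).sum() / ok.sum())


def trio_phase(parent_dosage: np.ndarray, grandfather_dosage: np.ndarray,
               grandmother_dosage: np.ndarray, sites: SiteTable) -> PartialPhase:
    """Phase a parent by Mendelian transmission from its own parents.

    All inputs are alt-allele dosage vectors over a common site list.  At a
    heterozygous parent site the alt allele is assigned to the grandfather
    side iff only that assignment is compatible with both grandparental
    genotypes; sites where both assignments are compatible are AMBIGUOUS and
    impossible configurations are INCONSISTENT.
    """
    d_p = np.asarray(parent_dosage)
    d_gf = np.asarray(grandfather_dosage)
    d_gm = np.asarray(grandmother_dosage)
    if not (len(d_p) == len(d_gf) == len(d_gm) == len(sites)):
        raise ValueError("genotype vectors must align with the site list")
    hap_gf = np.full(len(d_p), AMBIGUOUS, dtype=np.int8)

    hom = d_p != 1
    a = (d_p // 2).astype(np.int8)  # the homozygous allele
    # each grandparent must carry allele a
    carries_gf = np.where(a == 1, d_gf >= 1, d_gf <= 1)
    carries_gm = np.where(a == 1, d_gm >= 1, d_gm <= 1)
    hap_gf[hom & carries_gf & carries_gm] = a[hom & carries_gf & carries_gm]
    hap_gf[hom & ~(carries_gf & carries_gm)] = INCONSISTENT

    het = d_p == 1
    alt_from_gf = (d_gf >= 1) & (d_gm <= 1)  # alt via grandfather, ref via grandmother
    alt_from_gm = (d_gm >= 1) & (d_gf <= 1)
    hap_gf[het & alt_from_gf & ~alt_from_gm] = 1
    hap_gf[het & alt_from_gm & ~alt_from_gf] = 0
    hap_gf[het & ~alt_from_gf & ~alt_from_gm] = INCONSISTENT
    return PartialPhase(sites=sites, dosage=d_p.astype(np.int8), hap_gf=hap_gf)


def panel_resolve(partial: PartialPhase, panel: np.ndarray, role: str,
                  window: int = 10, rng: np.random.Generator | None = None
                  ) -> tuple[PhasedParent, np.ndarray, dict]:
    """Orient remaining ambiguous het sites against a haplotype panel.

    ``panel`` is (n_haplotypes, n_sites) of alt indicators.  Per ambiguous
    heterozygous site, each panel haplotype is compared with the two
    partially phased parental haplotypes over the nearest ``window`` phased
    het sites on the same chromosome; it votes its allele onto the closer
    one, weighted by the match margin, and the weighted majority decides.
    Ties (or an empty panel) fall back to a
    seeded coin flip with a logged source code.  Mendelian-inconsistent
    sites keep a coin-flip phase too but are reported for exclusion
    upstream.  Returns the completed parent, per-site phase-source codes,
    and a stats dict with inferred rates before/after.
    """
    rng = rng or np.random.default_rng(0)
    panel = np.asarray(panel)
    sites = partial.sites
    n = len(sites)
    hap_gf = partial.hap_gf.astype(np.int8).copy()
    dosage = partial.dosage
    source = np.full(n, SOURCE_TRIO, dtype=np.int8)
    rate_before = partial.inferred_rate

    for c in sites.chroms:
        sl = sites.chrom_slice(c)
        gf = hap_gf[sl]
        dos = dosage[sl]
        pan = panel[:, sl] if panel.size else panel
        het = dos == 1
        phased_het = np.flatnonzero(het & (gf >= 0))
        pending = np.flatnonzero(gf == AMBIGUOUS)
        for j in pending:
            if dos[j] != 1:
                # ambiguous hom site cannot occur (hom sites phase trivially)
                gf[j] = dos[j] // 2
                continue
            vote = 0  # +1: alt on grandfather side, -1: ref on grandfather side
            if panel.size and len(phased_het):
                lo = np.searchsorted(phased_het, j)
                take = np.concatenate([phased_het[max(0, lo - window // 2):lo],
                                       phased_het[lo:lo + window // 2]])
                if len(take):
                    h_gf = gf[take].astype(np.int8)
                    h_gm = (dos[take] - gf[take]).astype(np.int8)
                    m0 = (pan[:, take] == h_gf).sum(axis=1)
                    m1 = (pan[:, take] == h_gm).sum(axis=1)
                    allele = pan[:, j]
                    sign = np.where(allele == 1, 1, -1)
                    # margin-weighted vote: a perfect window match outweighs
                    # partial matches from related haplotypes
                    vote = int((sign * (m0 - m1)).sum())
            if vote > 0:
                gf[j] = 1
                source[sl.start + j] = SOURCE_PANEL
            elif vote < 0:
                gf[j] = 0
                source[sl.start + j] = SOURCE_PANEL
            else:
                gf[j] = np.int8(rng.integers(0, 2))
                source[sl.start + j] = SOURCE_RANDOM
            # resolved sites join the reference window for later sites
            phased_het = np.insert(phased_het, np.searchsorted(phased_het, j), j)
        # inconsistent sites: random phase, flagged for exclusion upstream
        bad = np.flatnonzero(gf == INCONSISTENT)
        for j in bad:
            if dos[j] == 1:
                gf[j] = np.int8(rng.integers(0, 2))
            else:
                gf[j] = dos[j] // 2
            source[sl.start + j] = SOURCE_RANDOM
        hap_gf[sl] = gf

    parent = PhasedParent(role, sites, hap_gf, (dosage - hap_gf).astype(np.int8))
    stats = {
        "inferred_rate_before": rate_before,
        "inferred_rate_after": 1.0,
        "n_inconsistent": int((partial.hap_gf == INCONSISTENT).sum()),
        "n_random": int((source == SOURCE_RANDOM).sum()),
        "n_panel": int((source == SOURCE_PANEL).sum()),
    }
    return parent, source, stats


def switch_error_rate(inferred: PhasedParent, truth: PhasedParent) -> float | None:
    """Fraction of consecutive het-site pairs with discordant relative phase.

    Counted per chromosome over heterozygous sites; counting phase *flips*
    makes the metric invariant to the global hap0/hap1 labeling.  Returns
    None when fewer than two het sites exist genome-wide.
    """
    if not inferred.sites.same_sites(truth.sites):
        raise ValueError("site lists differ")
    if np.any(inferred.dosage() != truth.dosage()):
        raise ValueError("genotypes differ between inferred and truth")
    switches = 0
    pairs = 0
    for c in inferred.sites.chroms:
        sl = inferred.sites.chrom_slice(c)
        het = inferred.dosage()[sl] == 1
        if het.sum() < 2:
            continue
        match0 = inferred.hap0[sl][het] == truth.hap0[sl][het]
        switches += int((match0[1:] != match0[:-1]).sum())
        pairs += het.sum() - 1
    if pairs == 0:
        return None
    return switches / pairs
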