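"""Site-by-site strategy (SBSS) baseline.

Calls each marker independently from its own reads, without haplotype
context: paternal transmission by presence of the paternal-specific allele,
maternal transmission by the sign of the allelic imbalance, and de-novo
candidates by non-parental reads at biparentally uninformative sites.  At
low fetal fraction and moderate depth these rules fail often — quantifying
that failure is the baseline's purpose, and the transmission HMM is the
remedy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import PlasmaCounts, SiteClass


@dataclass
class SBSSCall:
    """Per-site SBSS results (rows only at the relevant site classes)."""

    paternal: pd.DataFrame    # paternal-only het sites: detected flag + reads
    maternal: pd.DataFrame    # maternal-only het sites: called allele / tie
    summary: dict


def paternal_absence_rate(counts: PlasmaCounts, classes: np.ndarray,
                          mother_dosage: np.ndarray,
                          transmitted_truth: np.ndarray | None = None,
                          threshold: int = 1) -> tuple[float, pd.DataFrame]:
    """Fraction of transmitted paternal-specific alleles with < threshold reads.

    At paternal-only het sites the paternal-specific allele is the father
    allele absent from the maternal genotype.  ``transmitted_truth`` (bool
    per site, True where the fetus actually inherited the paternal-specific
    allele) restricts the denominator to truly transmitted alleles; without
    truth every paternal-only het site counts.
    """
    classes = np.asarray(classes)
    mask = classes == SiteClass.PATERNAL_ONLY_HET
    if not np.any(mask):
        raise ValueError("no paternal-only heterozygous sites")
    # mother hom: her dosage is 0 or 2; the paternal-specific allele is the other one
    pat_reads = np.where(np.asarray(mother_dosage) == 0, counts.n_alt, counts.n_ref)
    detected = pat_reads >= threshold
    denom = mask if transmitted_truth is None else (mask & np.asarray(transmitted_truth, bool))
    if denom.sum() == 0:
        raise ValueError("no transmitted paternal-specific alleles to score")
    absent = (~detected) & denom
    rate = float(absent.sum() / denom.sum())
    calls = pd.DataFrame({
        "chrom": counts.sites.chrom[mask], "pos": counts.sites.pos[mask],
        "paternal_specific_reads": pat_reads[mask], "detected": detected[mask],
    })
    return rate, calls


def maternal_imbalance_call(counts: PlasmaCounts, classes: np.ndarray,
                            mother_hap0: np.ndarray | None = None,
                            truth_transmitted_alt: np.ndarray | None = None
                            ) -> tuple[pd.DataFrame, float | None]:
    """Call maternal transmission by read-count imbalance at maternal-only sites.

    The maternal allele with the higher read count is called transmitted;
    equal counts give a tie (no call).  When the truly transmitted maternal
    allele is supplied (alt indicator per site), returns the opposite-
    imbalance rate: the fraction of non-tie sites whose call contradicts it.
    """
    classes = np.asarray(classes)
    mask = classes == SiteClass.MATERNAL_ONLY_HET
    if not np.any(mask):
        raise ValueError("no maternal-only heterozygous sites")
    n_ref, n_alt = counts.n_ref[mask], counts.n_alt[mask]
    call = np.where(n_alt > n_ref, 1, np.where(n_ref > n_alt, 0, -1))  # -1 = tie
    df = pd.DataFrame({
        "chrom": counts.sites.chrom[mask], "pos": counts.sites.pos[mask],
        "n_ref": n_ref, "n_alt": n_alt, "called_alt": call,
    })
    opposite = None
    if truth_transmitted_alt is not None:
        truth = np.asarray(truth_transmitted_alt)[mask]
        informative = call >= 0
        if informative.sum() > 0:
            opposite = float((call[informative] != truth[informative]).sum()
                             / informative.sum())
    return df, opposite


def denovo_scan(counts: PlasmaCounts, classes: np.ndarray,
                parent_allele: np.ndarray, min_reads: int = 1,
                truth_sites: pd.DataFrame | None = None
                ) -> tuple[pd.DataFrame, float | None]:
    """Flag uninformative sites carrying non-parental-allele reads.

    ``parent_allele`` is the shared parental alt indicator at uninformative
    sites (both parents homozygous for it); reads of the other allele are
    candidate de-novo signal.  With a spiked-mutation truth table the
    sensitivity (detected / spiked) is returned.
    """
    classes = np.asarray(classes)
    mask = classes == SiteClass.UNINFORMATIVE
    nonparental = np.where(np.asarray(parent_allele) == 0, counts.n_alt, counts.n_ref)
    hit = mask & (nonparental >= min_reads)
    cand = pd.DataFrame({
        "chrom": counts.sites.chrom[hit], "pos": counts.sites.pos[hit],
        "nonparental_reads": nonparental[hit],
    })
    sensitivity = None
    if truth_sites is not None and len(truth_sites):
        spiked = set(zip(truth_sites["chrom"], truth_sites["pos"]))
        found = set(zip(cand["chrom"], cand["pos"]))
        sensitivity = len(spiked & found) / len(spiked)
    return cand, sensitivity


def mle_allele_concentration(counts: PlasmaCounts) -> pd.DataFrame:
    """Per-site binomial ML alt-allele concentration k/n, averaged per chromosome."""
    depth = counts.depth
    with np.errstate(invalid="ignore"):
        c_hat = np.where(depth > 0, counts.n_alt / np.maximum(depth, 1), np.nan)
    df = pd.DataFrame({"chrom": counts.sites.chrom, "c_hat": c_hat})
    return df.groupby("chrom", sort=False)["c_hat"].mean().reset_index()
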