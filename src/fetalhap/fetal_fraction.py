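"""Fetal-fraction (cff-DNA concentration) estimation.

At discordant-homozygous sites — mother homozygous for one allele, father
for the other — every paternal-allele read in plasma is fetus-derived, and
its expected fraction is f/2.  The estimator pools reads across sites
(method of moments) and inverts the symmetric read-error model:

    p_hat = sum(paternal-allele reads) / sum(depth)
    f_hat = 2 (p_hat - eps) / (1 - 2 eps),  clipped to [0, 1].

With ``eps=0`` the correction is disabled.
"""

from __future__ import annotations

import numpy as np

from .core import FetalFractionEstimate, PlasmaCounts, SiteClass


def _pooled_fraction(pat_reads: np.ndarray, depth: np.ndarray, eps: float) -> float:
    p_hat = pat_reads.sum() / depth.sum()
    return float(np.clip(2.0 * (p_hat - eps) / (1.0 - 2.0 * eps), 0.0, 1.0))


def estimate_ff(counts: PlasmaCounts, classes: np.ndarray,
                mother_dosage: np.ndarray, eps: float = 0.0,
                min_depth: int = 1) -> FetalFractionEstimate:
    """Estimate the fetal fraction from discordant-homozygous sites.

    ``mother_dosage`` identifies the paternal-specific allele per site (the
    allele the mother lacks): alt where the mother is hom-ref, ref where
    hom-alt.  Sites with depth < ``min_depth`` are excluded.
    """
    classes = np.asarray(classes)
    depth = counts.depth
    mask = (classes == SiteClass.DISCORDANT_HOM) & (depth >= min_depth)
    if not np.any(mask):
        raise ValueError("no discordant-homozygous sites with sufficient depth")
    if depth[mask].sum() == 0:
        raise ValueError("zero total depth at qualifying sites")
    pat_reads = np.where(np.asarray(mother_dosage) == 0, counts.n_alt, counts.n_ref)

    per_chrom: dict[str, float] = {}
    for c in counts.sites.chroms:
        sl = counts.sites.chrom_slice(c)
        m = mask[sl]
        if m.any() and depth[sl][m].sum() > 0:
            per_chrom[c] = _pooled_fraction(pat_reads[sl][m], depth[sl][m], eps)
    return FetalFractionEstimate(
        f_hat=_pooled_fraction(pat_reads[mask], depth[mask], eps),
        n_sites_used=int(mask.sum()),
        per_chromosome=per_chrom,
    )
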