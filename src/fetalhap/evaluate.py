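"""Accuracy metrics, error taxonomy, and depth-downsampling curves.

Recovered fetal alleles are scored against truth separately for the
paternal contribution (paternal-only plus biparental het autosomal sites),
the maternal autosomal contribution (maternal-only plus biparental het),
and the maternal chrX contribution; genotype accuracy is unordered-pair
equality per heterozygosity class.  Errors are attributed to three causes:
type III inside centromere/chromosome-edge annotations, type II within a
window of a true or inferred recombination breakpoint, type I (residual
haplotype-inference noise) otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import PlasmaCounts, SiteClass
from .hmm import FetalCall, TransitionModel, call_fetal_genome
from .simulate import SimTruth


@dataclass
class Metric:
    n_sites: int
    n_correct: int
    error_types: dict[int, int] = field(default_factory=dict)

    @property
    def accuracy(self) -> float:
        return self.n_correct / self.n_sites if self.n_sites else float("nan")


@dataclass
class AccuracyReport:
    """Per-class recovery accuracy with error-type attribution."""

    metrics: dict[str, Metric]

    def accuracy(self, key: str) -> float:
        return self.metrics[key].accuracy

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k, m in self.metrics.items():
            rows.append({
                "metric": k, "n_sites": m.n_sites, "n_correct": m.n_correct,
                "accuracy": m.accuracy,
                "type_I": m.error_types.get(1, 0),
                "type_II": m.error_types.get(2, 0),
                "type_III": m.error_types.get(3, 0),
            })
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {k: {"n_sites": m.n_sites, "n_correct": m.n_correct,
                    "accuracy": m.accuracy, "error_types": m.error_types}
                for k, m in self.metrics.items()}


ALLELE_METRICS = ("paternal_allele", "maternal_allele", "chrx_maternal_allele")
GENOTYPE_METRICS = {
    "genotype_paternal_only": SiteClass.PATERNAL_ONLY_HET,
    "genotype_maternal_only": SiteClass.MATERNAL_ONLY_HET,
    "genotype_biparental": SiteClass.BIPARENTAL_HET,
}


def default_edge_regions(chrom_lengths: dict[str, int],
                         edge_bp: int = 1_000_000) -> pd.DataFrame:
    """Centromere/edge stand-in annotation: first and last ``edge_bp`` of
    each chromosome (0-based half-open intervals)."""
    rows = []
    for c, L in chrom_lengths.items():
        rows.append({"chrom": c, "start": 0, "end": edge_bp})
        rows.append({"chrom": c, "start": max(0, L - edge_bp), "end": L})
    return pd.DataFrame(rows)


def classify_errors(error_chrom: np.ndarray, error_pos: np.ndarray,
                    true_bkpts: dict[str, list] | dict[str, np.ndarray],
                    inferred_bkpts: dict[str, list],
                    regions: pd.DataFrame | None,
                    window_bp: int = 1_000_000) -> np.ndarray:
    """Attribute each error site to type 3 (annotated region), 2 (near a
    true or inferred breakpoint), or 1 (residual noise); 3 takes precedence."""
    out = np.ones(len(error_pos), dtype=np.int8)
    reg_by_chrom: dict[str, np.ndarray] = {}
    if regions is not None and len(regions):
        for c, grp in regions.groupby("chrom", sort=False):
            reg_by_chrom[c] = grp[["start", "end"]].to_numpy()
    for i, (c, p) in enumerate(zip(error_chrom, error_pos)):
        reg = reg_by_chrom.get(c)
        if reg is not None:
            # BED half-open, pos 1-based: 0-based coordinate is p-1
            if np.any((reg[:, 0] <= p - 1) & (p - 1 < reg[:, 1])):
                out[i] = 3
                continue
        near = False
        for bk in (true_bkpts.get(c, []), inferred_bkpts.get(c, [])):
            for b in np.atleast_1d(np.asarray(bk, dtype=object)):
                lo, hi = (b, b) if np.isscalar(b) or isinstance(b, float) else (b[0], b[1])
                if lo - window_bp <= p <= hi + window_bp:
                    near = True
                    break
            if near:
                break
        if near:
            out[i] = 2
    return out


def _score(call_alleles, truth_alleles, mask) -> tuple[Metric, np.ndarray]:
    wrong = mask & (call_alleles != truth_alleles)
    m = Metric(n_sites=int(mask.sum()), n_correct=int(mask.sum() - wrong.sum()))
    return m, wrong


def allele_accuracy(call: FetalCall, truth: SimTruth,
                    regions: pd.DataFrame | None = None,
                    window_bp: int = 1_000_000) -> AccuracyReport:
    """Score a fetal call against simulation truth.

    Allele accuracies per parental contribution, genotype accuracies per
    heterozygosity class, and — when breakpoints are available — error-type
    attribution for the allele metrics.
    """
    if not call.sites.same_sites(truth.sites):
        raise ValueError("call and truth site lists differ")
    cls = np.asarray(call.classes)
    x = call.sites.is_x
    pat_mask = ~x & np.isin(cls, (SiteClass.PATERNAL_ONLY_HET, SiteClass.BIPARENTAL_HET))
    mat_mask = ~x & np.isin(cls, (SiteClass.MATERNAL_ONLY_HET, SiteClass.BIPARENTAL_HET))
    x_mask = x & (cls == SiteClass.MATERNAL_ONLY_HET)

    metrics: dict[str, Metric] = {}
    truth_bk = {c: v for c, v in truth.crossovers["paternal"].items()}
    truth_bk_m = {c: v for c, v in truth.crossovers["maternal"].items()}
    for key, mask, call_a, truth_a, true_bk, inf_bk in (
        ("paternal_allele", pat_mask, call.fetal_pat, truth.fetal_pat,
         truth_bk, call.breakpoints["paternal"]),
        ("maternal_allele", mat_mask, call.fetal_mat, truth.fetal_mat,
         truth_bk_m, call.breakpoints["maternal"]),
        ("chrx_maternal_allele", x_mask, call.fetal_mat, truth.fetal_mat,
         truth_bk_m, call.breakpoints["maternal"]),
    ):
        m, wrong = _score(call_a, truth_a, mask)
        if m.n_sites:
            types = classify_errors(call.sites.chrom[wrong], call.sites.pos[wrong],
                                    true_bk, inf_bk, regions, window_bp)
            m.error_types = {t: int((types == t).sum()) for t in (1, 2, 3)}
        metrics[key] = m

    call_g = call.fetal_dosage()
    truth_g = truth.fetal_dosage()
    for key, sc in GENOTYPE_METRICS.items():
        m, _ = _score(call_g, truth_g, (cls == sc) & ~x)
        metrics[key] = m
    return AccuracyReport(metrics=metrics)


def thin_counts(counts: PlasmaCounts, fraction: float,
                rng: np.random.Generator) -> PlasmaCounts:
    """Binomially downsample each site's reads to an expected ``fraction``."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    if fraction == 1.0:
        return PlasmaCounts(counts.sites, counts.n_ref.copy(), counts.n_alt.copy())
    return PlasmaCounts(counts.sites,
                        rng.binomial(counts.n_ref, fraction),
                        rng.binomial(counts.n_alt, fraction))


def downsample_curve(truth: SimTruth, counts: PlasmaCounts, fractions: list[float],
                     f_hat: float | None = None, eps: float = 0.005,
                     transition: TransitionModel | None = None,
                     seed: int = 0) -> pd.DataFrame:
    """Recovery accuracy as a function of retained sequencing depth.

    Thins the counts binomially at each fraction, reruns the full recovery,
    and tabulates per-metric accuracy; the emission model keeps the true
    (or supplied) fetal fraction — only depth changes.
    """
    rng = np.random.default_rng(seed)
    f_use = truth.f if f_hat is None else f_hat
    rows = []
    for frac in fractions:
        thinned = thin_counts(counts, frac, rng)
        call = call_fetal_genome(truth.mother, truth.father, thinned, f_use,
                                 eps=eps, transition=transition,
                                 fetal_sex=truth.fetal_sex, compute_log_odds=False)
        rep = allele_accuracy(call, truth)
        row = {"fraction": frac, "mean_depth": float(thinned.depth.mean())}
        for k, m in rep.metrics.items():
            row[k] = m.accuracy
        rows.append(row)
    return pd.DataFrame(rows).sort_values("fraction").reset_index(drop=True)
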