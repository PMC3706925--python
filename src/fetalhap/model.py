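"""Model/Results front end for non-invasive fetal genome recovery.

:class:`FetalGenomeModel` bundles the phased parents, the plasma counts and
the emission/transition parameters; :meth:`~FetalGenomeModel.fit` estimates
the fetal fraction when not supplied, decodes the transmitted-haplotype HMM
genome-wide, and returns a :class:`FetalGenomeResults` carrying the fetal
call, per-site transmission log-odds, breakpoint intervals and a printable
summary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import io as fio
from .core import (PhasedParent, PlasmaCounts, SiteClass,
                   FetalFractionEstimate, classify_sites)
from .evaluate import AccuracyReport, allele_accuracy
from .fetal_fraction import estimate_ff
from .hmm import FetalCall, TransitionModel, call_fetal_genome


class FetalGenomeModel:
    """Transmitted-haplotype HMM for one pregnancy.

    Parameters
    ----------
    mother, father
        Fully phased parents over a shared site list (father hemizygous on
        chrX for a male fetus).
    counts
        Per-site plasma allele counts aligned to the same sites.
    fetal_fraction
        Known cfDNA fetal fraction; ``None`` estimates it at fit time from
        the discordant-homozygous sites.
    eps
        Symmetric per-read error probability of the emission model.
    r_maternal, r_paternal
        Genetic map rates (cM/Mb) for the Haldane transition model.
    fetal_sex
        'male' uses the 2-state maternal-only chain on chrX.
    """

    def __init__(self, mother: PhasedParent, father: PhasedParent,
                 counts: PlasmaCounts, *, fetal_fraction: float | None = None,
                 eps: float = 0.005, r_maternal: float = 1.2,
                 r_paternal: float = 1.2, fetal_sex: str = "male"):
        if not mother.sites.same_sites(father.sites) \
                or not mother.sites.same_sites(counts.sites):
            raise ValueError("parents and counts must share one site list")
        self.mother = mother
        self.father = father
        self.counts = counts
        self.fetal_fraction = fetal_fraction
        self.eps = eps
        self.transition = TransitionModel(r_maternal=r_maternal, r_paternal=r_paternal)
        self.fetal_sex = fetal_sex

    @classmethod
    def from_files(cls, parents_vcf: str, counts_tsv: str,
                   mother_sample: str = "MOTHER", father_sample: str = "FATHER",
                   **kwargs) -> "FetalGenomeModel":
        """Build from a phased parental VCF and a plasma counts TSV."""
        sites, gts = fio.read_vcf_genotypes(parents_vcf,
                                            [mother_sample, father_sample],
                                            require_phased=True)
        mother = PhasedParent("mother", sites, *gts[mother_sample])
        father = PhasedParent("father", sites, *gts[father_sample])
        counts = fio.read_counts_tsv(counts_tsv, sites)
        return cls(mother, father, counts, **kwargs)

    def site_classes(self) -> np.ndarray:
        return classify_sites(self.mother.dosage(), self.father.dosage(),
                              self.mother.sites.is_x, self.fetal_sex)

    def estimate_fetal_fraction(self, min_depth: int = 1) -> FetalFractionEstimate:
        return estimate_ff(self.counts, self.site_classes(),
                           self.mother.dosage(), eps=self.eps,
                           min_depth=min_depth)

    def fit(self, compute_log_odds: bool = True) -> "FetalGenomeResults":
        """Estimate f if needed, decode the fetal genome, return results."""
        ff_est = None
        if self.fetal_fraction is None:
            ff_est = self.estimate_fetal_fraction()
            f_use = ff_est.f_hat
        else:
            f_use = self.fetal_fraction
        call = call_fetal_genome(self.mother, self.father, self.counts, f_use,
                                 eps=self.eps, transition=self.transition,
                                 fetal_sex=self.fetal_sex,
                                 compute_log_odds=compute_log_odds)
        return FetalGenomeResults(model=self, fetal_call=call,
                                  fetal_fraction_used=f_use,
                                  fetal_fraction_estimate=ff_est)


@dataclass
class FetalGenomeResults:
    """Fitted fetal genome: call, fractions, diagnostics."""

    model: FetalGenomeModel
    fetal_call: FetalCall
    fetal_fraction_used: float
    fetal_fraction_estimate: FetalFractionEstimate | None = None

    @property
    def breakpoints(self):
        return self.fetal_call.breakpoints

    def n_breakpoints(self, parent: str) -> int:
        return sum(len(v) for v in self.breakpoints[parent].values())

    def class_census(self) -> pd.Series:
        cls = pd.Series(self.fetal_call.classes).map(
            lambda v: SiteClass(v).name)
        return cls.value_counts()

    def accuracy(self, truth, regions: pd.DataFrame | None = None,
                 window_bp: int = 1_000_000) -> AccuracyReport:
        """Score against a simulation truth (or truth-shaped object)."""
        return allele_accuracy(self.fetal_call, truth, regions=regions,
                               window_bp=window_bp)

    def to_vcf(self, path: str) -> None:
        fio.write_fetal_vcf(path, self.fetal_call)

    def breakpoints_to_bed(self, path: str) -> None:
        fio.write_breakpoints_bed(self.fetal_call, path)

    def summary(self) -> str:
        """Human-readable fit summary."""
        call = self.fetal_call
        census = self.class_census()
        lines = [
            "Fetal genome recovery (transmitted-haplotype HMM)",
            "=" * 52,
            f"sites:               {len(call.sites):>10d}",
            f"chromosomes:         {len(call.sites.chroms):>10d}",
            f"fetal sex:           {call.fetal_sex:>10s}",
            f"fetal fraction used: {self.fetal_fraction_used:>10.4f}"
            + ("  (estimated)" if self.fetal_fraction_estimate is not None
               else "  (supplied)"),
            f"emission eps:        {self.model.eps:>10.4f}",
            f"map (cM/Mb) mat/pat: {self.model.transition.r_maternal:>6.2f} /"
            f" {self.model.transition.r_paternal:.2f}",
            "",
            "site classes:",
        ]
        for name, n in census.items():
            lines.append(f"  {name:<20s} {n:>10d}")
        lines += [
            "",
            f"paternal breakpoints: {self.n_breakpoints('paternal'):>6d}",
            f"maternal breakpoints: {self.n_breakpoints('maternal'):>6d}",
            f"total path log-likelihood: {sum(call.loglik.values()):.1f}",
        ]
        return "\n".join(lines)

    def plot_log_odds(self, chrom: str, ax=None):
        """Per-site transmission log-odds along one chromosome (both parents)."""
        import matplotlib.pyplot as plt

        call = self.fetal_call
        sl = call.sites.chrom_slice(chrom)
        pos = call.sites.pos[sl] / 1e6
        if ax is None:
            _, ax = plt.subplots(figsize=(10, 3))
        ax.plot(pos, call.log_odds_pat[sl], ".", ms=2, label="paternal", alpha=0.5)
        ax.plot(pos, call.log_odds_mat[sl], ".", ms=2, label="maternal", alpha=0.5)
        ax.axhline(0.0, color="k", lw=0.5)
        ax.set_xlabel(f"{chrom} position (Mb)")
        ax.set_ylabel("ln odds hap1 : hap0")
        ax.legend(loc="upper right", markerscale=4)
        return ax
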