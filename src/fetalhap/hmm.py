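"""Hidden Markov model over parentally transmitted haplotypes.

The hidden state at each informative marker is which haplotype (0/1) each
parent transmitted to the fetus: four states ``(h_p, h_m)`` on autosomes,
two states ``h_m`` on chrX for a male fetus.  Emissions are binomial on the
plasma alt-read count with the cfDNA mixture law

    theta = (1-f) g_M/2 + f g_F(state)/2            (autosome)
    theta = [(1-f) g_M + f a_m(state)] / (2-f)      (male-fetus chrX)

error-adjusted as theta_err = theta(1-eps) + (1-theta)eps.  Transitions are
per-parent Haldane switch probabilities rho = (1-exp(-2d))/2 for inter-site
genetic distance d in Morgans, independent across the two meioses.  Decoding
is exact Viterbi (ties broken toward no-switch, then the lower state index);
per-site transmission posteriors come from the forward-backward recursion
and are reported as the natural-log odds of transmitting haplotype 1 versus
haplotype 0 per parent.  All arithmetic is in log space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp

from .core import (CHRX, HMM_CLASSES, PhasedParent, PlasmaCounts, SiteTable,
                   classify_sites)

# autosomal state order: s = 2*h_p + h_m
AUTOSOMAL_STATES = ((0, 0), (0, 1), (1, 0), (1, 1))


@dataclass
class EmissionModel:
    """Binomial plasma emission parameters."""

    f: float        # fetal fraction
    eps: float = 0.005

    def __post_init__(self):
        if not 0.0 < self.f < 1.0:
            raise ValueError("fetal fraction f must lie in (0, 1)")
        if not 0.0 <= self.eps < 0.5:
            raise ValueError("eps must lie in [0, 0.5)")


@dataclass
class TransitionModel:
    """Per-parent recombination rates (cM/Mb) under the Haldane map."""

    r_maternal: float = 1.2
    r_paternal: float = 1.2

    def __post_init__(self):
        if self.r_maternal < 0 or self.r_paternal < 0:
            raise ValueError("recombination rates must be non-negative")

    def switch_prob(self, delta_bp, rate: float) -> np.ndarray:
        """Haldane switch probability for physical distance(s) in bp."""
        delta_bp = np.asarray(delta_bp, dtype=float)
        if np.any(delta_bp < 0):
            raise ValueError("inter-site distance must be non-negative")
        d_morgans = delta_bp * rate / 1e8  # bp * (cM/Mb) -> Morgans
        return 0.5 * (1.0 - np.exp(-2.0 * d_morgans))


def state_thetas(mother_h0, mother_h1, father_h0, father_h1,
                 model: EmissionModel, chrx_male: bool = False) -> np.ndarray:
    """Expected alt-read fraction per site per hidden state (error-free).

    Returns (n_sites, 4) on autosomes with state order s = 2*h_p + h_m, or
    (n_sites, 2) over the maternal haplotype on male-fetus chrX.
    """
    f = model.f
    m0 = np.asarray(mother_h0, dtype=float)
    m1 = np.asarray(mother_h1, dtype=float)
    g_m = m0 + m1
    if chrx_male:
        out = np.stack(
            [((1 - f) * g_m + f * m) / (2.0 - f) for m in (m0, m1)], axis=1
        )
        return np.clip(out, 0.0, 1.0)  # guard one-ulp overshoot at hom sites
    p0 = np.asarray(father_h0, dtype=float)
    p1 = np.asarray(father_h1, dtype=float)
    cols = []
    for hp, hm in AUTOSOMAL_STATES:
        g_f = (p1 if hp else p0) + (m1 if hm else m0)
        cols.append((1 - f) * g_m / 2.0 + f * g_f / 2.0)
    return np.clip(np.stack(cols, axis=1), 0.0, 1.0)


def emission_logprob(k, n, theta: np.ndarray, eps: float) -> np.ndarray:
    """log Binomial(k; n, theta_err) per site per state; 0 where n == 0."""
    k = np.asarray(k, dtype=float)[:, None]
    n = np.asarray(n, dtype=float)[:, None]
    t = theta * (1 - eps) + (1 - theta) * eps
    t = np.clip(t, 1e-12, 1 - 1e-12)
    logpmf = (gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
              + k * np.log(t) + (n - k) * np.log1p(-t))
    return np.where(n == 0, 0.0, logpmf)


def transition_logmatrix(delta_bp: float, model: TransitionModel,
                         chrx_male: bool = False) -> np.ndarray:
    """Log transition matrix for one inter-site interval.

    Autosomes: 4x4 Kronecker product of the paternal and maternal 2x2
    switch matrices (independent meioses); male-fetus chrX: the maternal
    2x2 alone.  Rows sum to one in probability space.
    """
    rho_m = float(model.switch_prob(delta_bp, model.r_maternal))
    t_m = np.array([[1 - rho_m, rho_m], [rho_m, 1 - rho_m]])
    if chrx_male:
        return np.log(np.clip(t_m, 1e-300, None))
    rho_p = float(model.switch_prob(delta_bp, model.r_paternal))
    t_p = np.array([[1 - rho_p, rho_p], [rho_p, 1 - rho_p]])
    return np.log(np.clip(np.kron(t_p, t_m), 1e-300, None))


def _transition_stack(pos: np.ndarray, model: TransitionModel,
                      chrx_male: bool) -> np.ndarray:
    """(T-1, S, S) log transition matrices along a chain of positions."""
    delta = np.diff(pos).astype(float)
    rho_m = model.switch_prob(delta, model.r_maternal)
    stay_m, sw_m = np.log(np.clip(1 - rho_m, 1e-300, None)), np.log(np.clip(rho_m, 1e-300, None))
    if chrx_male:
        out = np.empty((len(delta), 2, 2))
        out[:, 0, 0] = out[:, 1, 1] = stay_m
        out[:, 0, 1] = out[:, 1, 0] = sw_m
        return out
    rho_p = model.switch_prob(delta, model.r_paternal)
    stay_p, sw_p = np.log(np.clip(1 - rho_p, 1e-300, None)), np.log(np.clip(rho_p, 1e-300, None))
    lp = np.stack([np.stack([stay_p, sw_p], -1), np.stack([sw_p, stay_p], -1)], 1)
    lm = np.stack([np.stack([stay_m, sw_m], -1), np.stack([sw_m, stay_m], -1)], 1)
    # joint[s, s'] with s = 2*h_p + h_m
    return (lp[:, :, None, :, None] + lm[:, None, :, None, :]).reshape(len(delta), 4, 4)


def viterbi(log_emission: np.ndarray, log_trans: np.ndarray) -> tuple[np.ndarray, float]:
    """Most probable state path under a uniform initial distribution.

    ``log_emission`` is (T, S); ``log_trans`` is (T-1, S, S).  Ties are
    broken toward staying in the previous state, then toward the lower
    state index.  Returns (path, path log-probability).
    """
    T, S = log_emission.shape
    if T == 0:
        raise ValueError("empty chain")
    delta = np.log(1.0 / S) + log_emission[0]
    back = np.empty((T, S), dtype=np.int32)
    idx = np.arange(S)
    for t in range(1, T):
        scores = delta[:, None] + log_trans[t - 1]
        best = scores.max(axis=0)
        arg = scores.argmax(axis=0)  # lowest index on ties
        diag = scores[idx, idx]
        arg = np.where(diag == best, idx, arg)  # prefer no-switch
        back[t] = arg
        delta = best + log_emission[t]
    path = np.empty(T, dtype=np.int32)
    path[-1] = int(np.argmax(delta))
    loglik = float(delta[path[-1]])
    for t in range(T - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path, loglik


def forward_backward(log_emission: np.ndarray,
                     log_trans: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-site log posterior state probabilities and the data log-likelihood."""
    T, S = log_emission.shape
    if T == 0:
        raise ValueError("empty chain")
    alpha = np.empty((T, S))
    alpha[0] = np.log(1.0 / S) + log_emission[0]
    for t in range(1, T):
        a = alpha[t - 1][:, None] + log_trans[t - 1]
        m = a.max(axis=0)
        alpha[t] = log_emission[t] + m + np.log(np.exp(a - m).sum(axis=0))
    beta = np.zeros((T, S))
    for t in range(T - 2, -1, -1):
        b = log_trans[t] + (log_emission[t + 1] + beta[t + 1])[None, :]
        m = b.max(axis=1)
        beta[t] = m + np.log(np.exp(b - m[:, None]).sum(axis=1))
    loglik = float(logsumexp(alpha[-1]))
    log_post = alpha + beta - loglik
    return log_post, loglik


def parental_log_odds(log_post: np.ndarray, chrx_male: bool) -> tuple[np.ndarray, np.ndarray]:
    """Per-parent log P(transmit hap1)/P(transmit hap0) from state posteriors.

    Returns (paternal, maternal); paternal is NaN on male-fetus chrX.
    """
    if chrx_male:
        lod_m = log_post[:, 1] - log_post[:, 0]
        return np.full(len(log_post), np.nan), lod_m
    lod_p = logsumexp(log_post[:, 2:4], axis=1) - logsumexp(log_post[:, 0:2], axis=1)
    lod_m = logsumexp(log_post[:, [1, 3]], axis=1) - logsumexp(log_post[:, [0, 2]], axis=1)
    return lod_p, lod_m


@dataclass
class FetalCall:
    """Inferred fetal genome: per-site alleles, log-odds, and breakpoints.

    ``hp``/``hm`` are the decoded transmitted-haplotype indices (-1 at sites
    outside the HMM chain); ``fetal_pat`` is -1 on male-fetus chrX.
    Breakpoint intervals span the last informative site before and the
    first after a decoded switch (1-based, inclusive of both flanks).
    """

    sites: SiteTable
    classes: np.ndarray
    hp: np.ndarray
    hm: np.ndarray
    fetal_pat: np.ndarray
    fetal_mat: np.ndarray
    log_odds_pat: np.ndarray
    log_odds_mat: np.ndarray
    breakpoints: dict[str, dict[str, list[tuple[int, int]]]]
    loglik: dict[str, float]
    f: float
    fetal_sex: str = "male"

    def fetal_dosage(self) -> np.ndarray:
        g = np.where(self.fetal_pat < 0, 0, self.fetal_pat) + self.fetal_mat
        return g.astype(np.int8)

    def genotype_string(self, i: int) -> str:
        alleles = (self.sites.ref[i], self.sites.alt[i])
        m = alleles[self.fetal_mat[i]]
        if self.fetal_pat[i] < 0:
            return m
        return alleles[self.fetal_pat[i]] + "/" + m


def _extract_breakpoints(path: np.ndarray, pos: np.ndarray) -> list[tuple[int, int]]:
    sw = np.flatnonzero(np.diff(path) != 0)
    return [(int(pos[i]), int(pos[i + 1])) for i in sw]


def call_fetal_genome(mother: PhasedParent, father: PhasedParent,
                      counts: PlasmaCounts, f_hat: float,
                      eps: float = 0.005,
                      transition: TransitionModel | None = None,
                      fetal_sex: str = "male",
                      compute_log_odds: bool = True) -> FetalCall:
    """Decode the fetal genome from phased parents and plasma counts.

    Per chromosome the informative-site chain (paternal-only, maternal-only
    and biparental het sites) is decoded by Viterbi; forward-backward
    supplies per-parent transmission log-odds.  Sites outside the chain
    (uninformative / discordant-homozygous) have their fetal genotype
    implied directly by the parental genotypes.
    """
    if not mother.sites.same_sites(father.sites) or not mother.sites.same_sites(counts.sites):
        raise ValueError("mother, father and counts must share one site list")
    if np.any(mother.hap0 < 0) or np.any(mother.hap1 < 0):
        raise ValueError("mother haplotypes must be fully phased")
    transition = transition or TransitionModel()
    emis_model = EmissionModel(f_hat, eps)
    sites = mother.sites
    n = len(sites)
    classes = classify_sites(mother.dosage(), father.dosage(), sites.is_x, fetal_sex)

    hp = np.full(n, -1, dtype=np.int8)
    hm = np.full(n, -1, dtype=np.int8)
    lod_p = np.full(n, np.nan)
    lod_m = np.full(n, np.nan)
    bkpts: dict[str, dict[str, list[tuple[int, int]]]] = {"paternal": {}, "maternal": {}}
    loglik: dict[str, float] = {}

    informative = np.isin(classes, [int(c) for c in HMM_CLASSES])
    for c in sites.chroms:
        sl = sites.chrom_slice(c)
        idx = np.flatnonzero(informative[sl]) + sl.start
        bkpts["paternal"][c] = []
        bkpts["maternal"][c] = []
        if len(idx) == 0:
            continue
        chrx_male = (c == CHRX and fetal_sex == "male")
        theta = state_thetas(mother.hap0[idx], mother.hap1[idx],
                             father.hap0[idx], father.hap1[idx],
                             emis_model, chrx_male=chrx_male)
        log_e = emission_logprob(counts.n_alt[idx], counts.depth[idx], theta, eps)
        log_t = _transition_stack(sites.pos[idx], transition, chrx_male)
        path, ll = viterbi(log_e, log_t)
        loglik[c] = ll
        if compute_log_odds:
            log_post, _ = forward_backward(log_e, log_t)
            lp, lm = parental_log_odds(log_post, chrx_male)
            lod_p[idx], lod_m[idx] = lp, lm
        if chrx_male:
            hm[idx] = path
            bkpts["maternal"][c] = _extract_breakpoints(path, sites.pos[idx])
        else:
            hp[idx] = path // 2
            hm[idx] = path % 2
            bkpts["paternal"][c] = _extract_breakpoints(hp[idx], sites.pos[idx])
            bkpts["maternal"][c] = _extract_breakpoints(hm[idx], sites.pos[idx])

    # fetal alleles: decoded on the chain, implied by parental genotypes elsewhere
    fetal_mat = np.where(hm >= 0, np.choose(np.clip(hm, 0, 1), (mother.hap0, mother.hap1)),
                         mother.dosage() // 2).astype(np.int8)
    father_hom_allele = np.where(father.hap1 < 0, father.hap0, father.dosage() // 2)
    fetal_pat = np.where(hp >= 0, np.choose(np.clip(hp, 0, 1), (father.hap0, father.hap1)),
                         father_hom_allele).astype(np.int8)
    if fetal_sex == "male":
        fetal_pat[sites.is_x] = -1
    return FetalCall(sites=sites, classes=classes, hp=hp, hm=hm,
                     fetal_pat=fetal_pat, fetal_mat=fetal_mat,
                     log_odds_pat=lod_p, log_odds_mat=lod_m,
                     breakpoints=bkpts, loglik=loglik, f=f_hat, fetal_sex=fetal_sex)
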