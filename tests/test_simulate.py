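"""Generator correctness: mixture law, recombination, determinism."""

import numpy as np
import pytest

from fetalhap.core import SiteClass, SiteTable, PhasedParent
from fetalhap.simulate import (SimParams, SimTruth, plasma_theta,
                               simulate_pedigree, simulate_plasma,
                               spike_denovo)


def _params(**kw):
    base = dict(n_autosomal_sites=3000, n_chrx_sites=400,
                chroms=("chr21", "chr22", "chrX"), seed=5)
    base.update(kw)
    return SimParams(**base)


class TestPedigree:
    def test_no_recombination_copies_one_haplotype(self):
        p = _params(r_maternal=0.0, r_paternal=0.0)
        truth = simulate_pedigree(p)
        for c in truth.sites.chroms:
            sl = truth.sites.chrom_slice(c)
            path = truth.path_mat[sl]
            assert len(np.unique(path)) == 1
            src = truth.mother.hap0 if path[0] == 0 else truth.mother.hap1
            assert np.array_equal(truth.fetal_mat[sl], src[sl])

    def test_fixed_seed_reproducible(self):
        t1 = simulate_pedigree(_params())
        t2 = simulate_pedigree(_params())
        assert np.array_equal(t1.fetal_mat, t2.fetal_mat)
        assert np.array_equal(t1.path_pat, t2.path_pat)
        assert all(np.array_equal(t1.crossovers["maternal"][c],
                                  t2.crossovers["maternal"][c])
                   for c in t1.sites.chroms)

    def test_crossover_count_mean_matches_poisson(self):
        """100 Mb at 1.2 cM/Mb: mean crossover count 1.2 over many meioses."""
        from fetalhap.simulate import _n_crossovers
        rng = np.random.default_rng(17)
        counts = [_n_crossovers(100_000_000, 1.2, rng) for _ in range(10_000)]
        mean = np.mean(counts)
        se = np.std(counts) / np.sqrt(len(counts))
        assert abs(mean - 1.2) < 3 * se

    def test_fetal_haplotype_conserves_path(self, small_truth):
        """Fetal alleles equal the parental alleles selected by the path."""
        m = np.where(small_truth.path_mat == 0, small_truth.mother.hap0,
                     small_truth.mother.hap1)
        assert np.array_equal(small_truth.fetal_mat, m)
        auto = ~small_truth.sites.is_x
        p = np.where(small_truth.path_pat == 0, small_truth.father.hap0,
                     small_truth.father.hap1)
        assert np.array_equal(small_truth.fetal_pat[auto], p[auto])
        assert np.all(small_truth.fetal_pat[~auto] == -1)  # male fetus

    def test_path_changes_only_at_crossovers(self, small_truth):
        for c in small_truth.sites.chroms:
            if c == "chrX":
                continue
            sl = small_truth.sites.chrom_slice(c)
            sw = np.flatnonzero(np.diff(small_truth.path_pat[sl]))
            xs = np.sort(small_truth.crossovers["paternal"][c])
            pos = small_truth.sites.pos[sl]
            for i in sw:
                assert np.any((xs > pos[i]) & (xs <= pos[i + 1]))

    def test_parent_genotypes_mendelian_with_grandparents(self, small_truth):
        """Each parental haplotype is carried by the matching grandparent."""
        gp = small_truth.grandparent_haps
        auto = ~small_truth.sites.is_x
        for hap, (h0, h1) in ((small_truth.father.hap0, gp["pgf"]),
                              (small_truth.father.hap1, gp["pgm"]),
                              (small_truth.mother.hap0, gp["mgf"]),
                              (small_truth.mother.hap1, gp["mgm"])):
            assert np.all((hap[auto] == h0[auto]) | (hap[auto] == h1[auto]))


class TestPlasma:
    def test_theta_formula_values(self):
        """Frozen evaluations of the mixture law."""
        sites = SiteTable(["chr1", "chr1", "chrX"], [100, 200, 300],
                          ["A"] * 3, ["G"] * 3)
        mother = PhasedParent("mother", sites, np.array([0, 0, 0]),
                              np.array([1, 1, 1]))
        father = PhasedParent("father", sites, np.array([1, 0, 0]),
                              np.array([1, 0, -1]))
        truth = SimTruth(sites=sites, mother=mother, father=father,
                         grandparent_haps={},
                         path_pat=np.array([0, 0, 0], dtype=np.int8),
                         path_mat=np.array([1, 1, 1], dtype=np.int8),
                         fetal_pat=np.array([1, 0, -1], dtype=np.int8),
                         fetal_mat=np.array([1, 1, 1], dtype=np.int8),
                         crossovers={"paternal": {}, "maternal": {}},
                         f=0.0569, fetal_sex="male")
        theta = plasma_theta(truth)
        # mother ref/alt, father alt/alt, fetus alt/alt(mat alt): 0.5 + f/2
        assert theta[0] == pytest.approx(0.52845, abs=1e-5)
        # mother ref/alt, father ref/ref, fetus het: exactly 1/2
        assert theta[1] == pytest.approx(0.5, abs=1e-12)
        # chrX male, mother ref/alt, fetus inherits alt
        assert theta[2] == pytest.approx((0.9431 * 1 + 0.0569) / (2 - 0.0569), abs=1e-9)

    def test_limit_pure_fetal_altalt(self):
        p = _params(eps=0.0, f=0.999999)
        truth = simulate_pedigree(p)
        theta = plasma_theta(truth)
        hom_alt = (truth.fetal_dosage() == 2) & ~truth.sites.is_x
        assert np.allclose(theta[hom_alt], 1.0, atol=1e-5)

    def test_mean_depth_and_x_scaling(self):
        p = _params(n_autosomal_sites=100_000, n_chrx_sites=20_000,
                    chroms=("chr21", "chr22", "chrX"))
        truth = simulate_pedigree(p)
        counts = simulate_plasma(truth, p)
        auto = ~truth.sites.is_x
        assert counts.depth[auto].mean() == pytest.approx(p.mean_depth, rel=0.01)
        assert counts.depth[~auto].mean() == pytest.approx(
            p.mean_depth * (2 - p.f) / 2, rel=0.01)

    def test_discordant_hom_alt_fraction_tracks_f(self):
        """At discordant-hom sites the paternal-allele fraction is f/2 plus
        the symmetric error shift (what the fetal-fraction estimator inverts)."""
        p = _params(n_autosomal_sites=120_000, chroms=("chr1",), f=0.10)
        truth = simulate_pedigree(p)
        counts = simulate_plasma(truth, p)
        cls = truth.site_classes()
        mask = cls == SiteClass.DISCORDANT_HOM
        m_dos = truth.mother.dosage()
        pat = np.where(m_dos == 0, counts.n_alt, counts.n_ref)[mask]
        n = counts.depth[mask]
        theta = p.f / 2
        expected = theta * (1 - p.eps) + (1 - theta) * p.eps
        p_hat = pat.sum() / n.sum()
        se = np.sqrt(expected * (1 - expected) / n.sum())
        assert abs(p_hat - expected) < 3 * se

    def test_fixed_depth_mode(self):
        p = _params(fixed_depth=True)
        truth = simulate_pedigree(p)
        counts = simulate_plasma(truth, p)
        auto = ~truth.sites.is_x
        assert np.all(counts.depth[auto] == round(p.mean_depth))


class TestSpikeDenovo:
    def test_zero_mutations_identity(self, small_truth):
        out, muts = spike_denovo(small_truth, 0, seed=1)
        assert out is small_truth
        assert len(muts) == 0

    def test_fixed_seed_identical_list(self, small_truth):
        _, m1 = spike_denovo(small_truth, 25, seed=9)
        _, m2 = spike_denovo(small_truth, 25, seed=9)
        assert m1.equals(m2)

    def test_mutations_flip_to_nonparental_allele(self, small_truth):
        out, muts = spike_denovo(small_truth, 25, seed=9)
        cls = small_truth.site_classes()
        pos_index = {(c, p): i for i, (c, p) in
                     enumerate(zip(small_truth.sites.chrom, small_truth.sites.pos))}
        for _, row in muts.iterrows():
            i = pos_index[(row["chrom"], row["pos"])]
            assert cls[i] == SiteClass.UNINFORMATIVE
            parental = small_truth.mother.dosage()[i] // 2
            assert row["new_allele"] == 1 - parental
            assert out.fetal_dosage()[i] != small_truth.fetal_dosage()[i]

    def test_insufficient_sites_raises(self, small_truth):
        with pytest.raises(ValueError, match="uninformative"):
            spike_denovo(small_truth, 10**7, seed=1)


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        _params(f=0.0)
    with pytest.raises(ValueError):
        _params(eps=0.6)
    with pytest.raises(ValueError):
        _params(mean_depth=-1)
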