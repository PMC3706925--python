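"""HMM correctness: emissions, Haldane transitions, exact decoding."""

import numpy as np
import pytest
from scipy.stats import binom

from conftest import enumerate_paths
from fetalhap.core import PhasedParent
from fetalhap.hmm import (EmissionModel, TransitionModel, call_fetal_genome,
                          emission_logprob, forward_backward,
                          parental_log_odds, state_thetas,
                          transition_logmatrix, viterbi, _transition_stack)
from fetalhap.simulate import SimParams, simulate_pedigree, simulate_plasma


class TestEmission:
    def test_zero_depth_is_uninformative(self):
        theta = np.array([[0.1, 0.5, 0.7, 0.9]])
        le = emission_logprob([0], [0], theta, eps=0.005)
        assert np.all(le == 0.0)

    def test_maternal_state_thetas_at_father_hom_site(self):
        """Mother A|G phased, father A/A, f=0.0569: transmitting hap1 (G)
        gives theta 0.5; hap0 gives 0.5 - f/2."""
        em = EmissionModel(0.0569, eps=0.0)
        theta = state_thetas([0], [1], [0], [0], em)
        # states (hp, hm): hm=1 -> 0.5; hm=0 -> 0.47155 regardless of hp
        assert theta[0, 1] == pytest.approx(0.5, abs=1e-12)
        assert theta[0, 3] == pytest.approx(0.5, abs=1e-12)
        assert theta[0, 0] == pytest.approx(0.47155, abs=1e-5)
        assert theta[0, 2] == pytest.approx(0.47155, abs=1e-5)

    def test_symmetric_count_log_ratio_identity(self):
        """At a father-hom-alt maternal het site with k = n/2 and eps = 0 the
        two maternal states' log-emissions differ by
        n/2 * log[(1/2+f/2)(1/2-f/2)/(1/4)]."""
        f = 0.0569
        em = EmissionModel(f, eps=0.0)
        n = 40
        theta = state_thetas([0], [1], [1], [1], em)
        le = emission_logprob([n // 2], [n], theta, eps=0.0)
        observed = le[0, 1] - le[0, 0]  # hm=1 vs hm=0
        expected = n / 2 * np.log((0.5 + f / 2) * (0.5 - f / 2) / 0.25)
        assert observed == pytest.approx(expected, abs=1e-10)

    def test_matches_scipy_binomial(self):
        theta = np.array([[0.3, 0.52]])
        le = emission_logprob([7], [20], theta, eps=0.01)
        t_err = theta * 0.99 + (1 - theta) * 0.01
        assert np.allclose(le, binom.logpmf(7, 20, t_err))

    def test_chrx_two_state_thetas(self):
        em = EmissionModel(0.0569, eps=0.0)
        theta = state_thetas([0], [1], None, None, em, chrx_male=True)
        f = 0.0569
        assert theta[0, 1] == pytest.approx((1 - f + f) / (2 - f), abs=1e-12)
        assert theta[0, 0] == pytest.approx((1 - f) / (2 - f), abs=1e-12)

    def test_invalid_f_rejected(self):
        with pytest.raises(ValueError):
            EmissionModel(0.0)


class TestTransition:
    def test_haldane_value(self):
        tm = TransitionModel(r_maternal=1.2, r_paternal=1.2)
        rho = tm.switch_prob(1_000_000, 1.2)
        assert rho == pytest.approx(0.5 * (1 - np.exp(-0.024)), abs=1e-9)
        assert rho == pytest.approx(0.0118576, abs=1e-6)

    def test_zero_distance_identity(self):
        lt = transition_logmatrix(0.0, TransitionModel())
        assert np.allclose(np.diag(lt), 0.0)
        off = lt[~np.eye(4, dtype=bool)]
        assert np.all(off < -600)  # effectively log 0

    def test_large_distance_uniform(self):
        lt = transition_logmatrix(1e12, TransitionModel())
        assert np.allclose(np.exp(lt), 0.25, atol=1e-6)

    def test_rows_sum_to_one(self):
        for d in (1e3, 1e6, 1e8):
            for xmale in (False, True):
                lt = transition_logmatrix(d, TransitionModel(1.0, 2.0), xmale)
                assert np.allclose(np.exp(lt).sum(axis=1), 1.0, atol=1e-12)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            transition_logmatrix(-1.0, TransitionModel())

    def test_stack_matches_single_matrix(self):
        pos = np.array([100, 5_000, 2_000_000])
        tm = TransitionModel(0.8, 1.7)
        stack = _transition_stack(pos, tm, False)
        for i, d in enumerate(np.diff(pos)):
            assert np.allclose(stack[i], transition_logmatrix(float(d), tm))


class TestDecodingOracle:
    def _random_instance(self, rng, T, S=4):
        le = rng.normal(size=(T, S)) * 2
        rho = rng.uniform(0.001, 0.4, size=(T - 1, 2))
        lt = np.empty((T - 1, S, S))
        for t in range(T - 1):
            tp = np.array([[1 - rho[t, 0], rho[t, 0]], [rho[t, 0], 1 - rho[t, 0]]])
            tm = np.array([[1 - rho[t, 1], rho[t, 1]], [rho[t, 1], 1 - rho[t, 1]]])
            lt[t] = np.log(np.kron(tp, tm))
        return le, lt

    def test_viterbi_matches_enumeration(self):
        """Decoded path log-probability equals the max over all enumerated
        paths on 100 random chains of length <= 8."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            T = int(rng.integers(1, 9))
            le, lt = self._random_instance(rng, T)
            path, ll = viterbi(le, lt)
            paths, logp = enumerate_paths(le, lt)
            assert ll == pytest.approx(logp.max(), abs=1e-9)
            best = paths[int(np.argmax(logp))]
            path_lp = logp[np.all(paths == path, axis=1)][0]
            assert path_lp == pytest.approx(logp.max(), abs=1e-9), best

    def test_forward_backward_matches_enumeration(self):
        """Marginal posteriors equal brute-force path sums within 1e-9."""
        from scipy.special import logsumexp
        rng = np.random.default_rng(43)
        for _ in range(100):
            T = int(rng.integers(1, 9))
            le, lt = self._random_instance(rng, T)
            log_post, ll = forward_backward(le, lt)
            paths, logp = enumerate_paths(le, lt)
            total = logsumexp(logp)
            assert ll == pytest.approx(total, abs=1e-9)
            for t in range(T):
                for s in range(4):
                    m = logp[paths[:, t] == s]
                    expect = np.exp(logsumexp(m) - total) if len(m) else 0.0
                    assert np.exp(log_post[t, s]) == pytest.approx(expect, abs=1e-9)

    def test_posteriors_normalize(self):
        rng = np.random.default_rng(44)
        le, lt = self._random_instance(rng, 50)
        log_post, _ = forward_backward(le, lt)
        assert np.allclose(np.exp(log_post).sum(axis=1), 1.0, atol=1e-9)

    def test_flat_emissions_constant_path(self):
        """With no data the tie-break keeps the initial (lowest) state."""
        T = 20
        le = np.zeros((T, 4))
        lt = _transition_stack(np.arange(T) * 10_000 + 1, TransitionModel(), False)
        path, _ = viterbi(le, lt)
        assert np.all(path == path[0])

    def test_single_site_no_data_posterior_uniform(self):
        log_post, _ = forward_backward(np.zeros((1, 4)), np.empty((0, 4, 4)))
        assert np.allclose(np.exp(log_post), 0.25, atol=1e-12)
        lp, lm = parental_log_odds(log_post, chrx_male=False)
        assert lp[0] == pytest.approx(0.0, abs=1e-12)
        assert lm[0] == pytest.approx(0.0, abs=1e-12)

    def test_empty_chain_rejected(self):
        with pytest.raises(ValueError):
            viterbi(np.empty((0, 4)), np.empty((0, 4, 4)))


class TestCallFetalGenome:
    def test_no_recombination_high_depth_exact(self):
        """With r = 0 and deep data the decoded path equals truth everywhere."""
        p = SimParams(n_autosomal_sites=2_000, n_chrx_sites=300,
                      chroms=("chr21", "chrX"), r_maternal=0.0, r_paternal=0.0,
                      mean_depth=200.0, seed=7)
        truth = simulate_pedigree(p)
        counts = simulate_plasma(truth, p)
        call = call_fetal_genome(truth.mother, truth.father, counts, p.f,
                                 eps=p.eps,
                                 transition=TransitionModel(1e-9, 1e-9))
        chain = call.hm >= 0
        assert np.array_equal(call.fetal_mat[chain], truth.fetal_mat[chain])
        auto_chain = chain & (call.hp >= 0)
        assert np.array_equal(call.fetal_pat[auto_chain], truth.fetal_pat[auto_chain])
        assert call.breakpoints["maternal"]["chr21"] == []

    def test_haplotype_label_swap_invariance(self, small_truth, small_counts):
        """Relabeling mother's hap0/hap1 leaves the called alleles unchanged."""
        call1 = call_fetal_genome(small_truth.mother, small_truth.father,
                                  small_counts, small_truth.f,
                                  compute_log_odds=False)
        swapped = PhasedParent("mother", small_truth.sites,
                               small_truth.mother.hap1.copy(),
                               small_truth.mother.hap0.copy())
        call2 = call_fetal_genome(swapped, small_truth.father, small_counts,
                                  small_truth.f, compute_log_odds=False)
        assert np.array_equal(call1.fetal_mat, call2.fetal_mat)
        assert np.array_equal(call1.fetal_pat, call2.fetal_pat)

    def test_implied_genotypes_outside_chain(self, small_truth, small_counts):
        """Uninformative/discordant-hom sites take the parental implication."""
        call = call_fetal_genome(small_truth.mother, small_truth.father,
                                 small_counts, small_truth.f,
                                 compute_log_odds=False)
        outside = (call.hm < 0) & ~small_truth.sites.is_x
        assert np.array_equal(call.fetal_mat[outside],
                              small_truth.mother.dosage()[outside] // 2)
        assert np.array_equal(call.fetal_pat[outside],
                              small_truth.father.dosage()[outside] // 2)
        # at those sites the implied genotype is necessarily the true one
        assert np.array_equal(call.fetal_dosage()[outside],
                              small_truth.fetal_dosage()[outside])

    def test_breakpoints_match_path_switches(self, small_truth, small_counts):
        call = call_fetal_genome(small_truth.mother, small_truth.father,
                                 small_counts, small_truth.f,
                                 compute_log_odds=False)
        for c in ("chr21", "chr22"):
            sl = small_truth.sites.chrom_slice(c)
            idx = np.flatnonzero(call.hp[sl] >= 0) + sl.start
            sw = np.flatnonzero(np.diff(call.hp[idx]))
            expected = [(int(small_truth.sites.pos[idx[i]]),
                         int(small_truth.sites.pos[idx[i + 1]])) for i in sw]
            assert call.breakpoints["paternal"][c] == expected

    def test_unphased_mother_rejected(self, small_truth, small_counts):
        broken = PhasedParent("mother", small_truth.sites,
                              small_truth.mother.hap0,
                              np.full(len(small_truth.sites), -1, dtype=np.int8))
        with pytest.raises(ValueError, match="phased"):
            call_fetal_genome(broken, small_truth.father, small_counts, 0.05)
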