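import math
from collections import Counter

import numpy as np
import pytest

from hlabayes.model import FreqPrior, Hyperparams, ModelState, log_posterior
from hlabayes.sampler import (
    GeneModel,
    PosteriorSummary,
    SamplerConfig,
    call_genotype,
    call_sequences,
    run_mcmc,
)
from conftest import make_panel, make_placed
from oracles import brute_indicator_marginal, brute_seq_marginal

SYM = "ACGTN-"


@pytest.fixture
def mini_model(hp, fp):
    panel = make_panel(
        "A",
        {"A*01:01": "ACGT", "A*02:01": "ACTT", "A*03:01": "GCGA"},
        imputed={"A*03:01": [3]},
    )
    reads = [
        make_placed("r0", [0, 1, 2, 3], "ACGT", [30, 30, 30, 30]),
        make_placed("r1", [1, 2, 3], "CTT", [25, 25, 25]),
        make_placed("r2", [0, 1], "GC", [20, 20]),
    ]
    return GeneModel(panel, reads, hp, fp, n_decoy=1)


def random_state(model, rng):
    R = rng.integers(0, model.A, size=model.K)
    S = rng.integers(0, 6, size=(model.K, model.n_cols)).astype(np.int8)
    I = rng.integers(0, model.K, size=len(model.reads))
    return ModelState(R, S, I)


class TestFullConditionals:
    """Each Gibbs conditional equals the renormalized restriction of the
    module-level log_posterior (the independent scalar-path density)."""

    def test_S_conditional(self, mini_model, hp, fp):
        rng = np.random.default_rng(1)
        state = random_state(mini_model, rng)
        cond = mini_model.S_full_conditional(state, k=1)
        for n in range(mini_model.n_cols):
            lps = []
            for s in range(6):
                st = state.copy()
                st.S[1, n] = s
                lps.append(log_posterior(st, mini_model.reads, mini_model.panel, hp, fp))
            lps = np.array(lps)
            expected = np.exp(lps - lps.max())
            expected /= expected.sum()
            np.testing.assert_allclose(cond[n], expected, rtol=1e-9)

    def test_R_conditional(self, mini_model, hp, fp):
        rng = np.random.default_rng(2)
        state = random_state(mini_model, rng)
        for k in range(mini_model.K):
            logits = mini_model.R_logits(state, k)
            got = np.exp(logits - logits.max())
            got /= got.sum()
            lps = []
            for a in range(mini_model.A):
                st = state.copy()
                st.R[k] = a
                lps.append(log_posterior(st, mini_model.reads, mini_model.panel, hp, fp))
            lps = np.array(lps)
            expected = np.exp(lps - lps.max())
            expected /= expected.sum()
            np.testing.assert_allclose(got, expected, rtol=1e-9)

    def test_I_conditional(self, mini_model, hp, fp):
        rng = np.random.default_rng(3)
        state = random_state(mini_model, rng)
        cond = mini_model.I_full_conditional(state)
        for i in range(len(mini_model.reads)):
            lps = []
            for k in range(mini_model.K):
                st = state.copy()
                st.I[i] = k
                lps.append(log_posterior(st, mini_model.reads, mini_model.panel, hp, fp))
            lps = np.array(lps)
            expected = np.exp(lps - lps.max())
            expected /= expected.sum()
            np.testing.assert_allclose(cond[i], expected, rtol=1e-9)

    def test_temperature_flattens_S_conditional(self, mini_model):
        rng = np.random.default_rng(4)
        state = random_state(mini_model, rng)
        cond_hot = mini_model.S_full_conditional(state, k=0, temperature=1e9)
        np.testing.assert_allclose(cond_hot, 1.0 / 6.0, atol=1e-6)


class TestBuildSN:
    def test_no_reads_assigned_all_N(self, mini_model):
        state = random_state(mini_model, np.random.default_rng(0))
        state.I[:] = 0
        sn = mini_model.build_SN(state, 2)
        assert (sn == 4).all()

    def test_full_coverage_unchanged(self, mini_model):
        state = random_state(mini_model, np.random.default_rng(0))
        state.I[:] = 0  # r0 covers all 4 columns
        sn = mini_model.build_SN(state, 0)
        np.testing.assert_array_equal(sn, state.S[0])

    def test_partial_coverage(self, mini_model):
        state = random_state(mini_model, np.random.default_rng(0))
        state.I[:] = 2
        state.I[2] = 0  # r2 covers columns 0-1 only
        sn = mini_model.build_SN(state, 0)
        np.testing.assert_array_equal(sn[:2], state.S[0, :2])
        assert (sn[2:] == 4).all()


class TestMhUncovered:
    def test_same_type_ratio_is_one(self, mini_model):
        state = random_state(mini_model, np.random.default_rng(5))
        assert mini_model.mh_uncovered_logr(state, 0, int(state.R[0])) == pytest.approx(0.0)

    def test_ratio_matches_brute_force(self, mini_model, hp, fp):
        rng = np.random.default_rng(6)
        state = random_state(mini_model, rng)
        k = 0
        assigned = [i for i in range(len(mini_model.reads)) if state.I[i] == k]
        sn = mini_model.build_SN(state, k)
        sn_chars = "".join(SYM[s] for s in sn)
        from oracles import naive_seq_prior

        for r_star in range(mini_model.A):
            got = mini_model.mh_uncovered_logr(state, k, r_star)
            num = naive_seq_prior(sn_chars, mini_model.panel, int(state.R[k]), hp) * \
                brute_seq_marginal(mini_model.reads, assigned, mini_model.panel, r_star, hp)
            den = naive_seq_prior(sn_chars, mini_model.panel, r_star, hp) * \
                brute_seq_marginal(mini_model.reads, assigned, mini_model.panel, int(state.R[k]), hp)
            expected = math.log(num / den)
            assert abs(got - expected) <= 1e-9 * max(1.0, abs(expected))

    def test_free_exchange_between_types_equal_on_covered(self, hp, fp):
        # two alleles differing only at an uncovered column: p(S^N|R) equal,
        # marginals equal => log r* == 0 exactly
        panel = make_panel("A", {"A*01:01": "ACGT", "A*02:01": "ACGA"})
        reads = [make_placed("r0", [0, 1, 2], "ACG", [30] * 3)]
        model = GeneModel(panel, reads, hp, fp, n_decoy=1)
        state = ModelState(
            np.array([0, 1, 0]), panel.ref[[0, 1, 0]].copy(), np.array([0])
        )
        assert model.mh_uncovered_logr(state, 0, 1) == pytest.approx(0.0, abs=1e-12)

    def test_decoy_component_rejected(self, mini_model):
        state = random_state(mini_model, np.random.default_rng(7))
        with pytest.raises(ValueError):
            mini_model.mh_uncovered_proposal(state, 2, 1.0, np.random.default_rng(0))


class TestMhDecoySwap:
    def test_identical_components_ratio_one(self, hp, fp):
        panel = make_panel("A", {"A*01:01": "ACGT", "A*02:01": "ACTT"})
        reads = [make_placed("r0", [0, 1], "AC", [30, 30])]
        model = GeneModel(panel, reads, hp, fp, n_decoy=1)
        state = ModelState(np.array([0, 1, 0]), panel.ref[[0, 1, 0]].copy(), np.array([0]))
        assert model.mh_decoy_swap_logr(state, 0, 2) == pytest.approx(0.0, abs=1e-12)

    def test_ratio_matches_brute_force(self, mini_model, hp, fp):
        rng = np.random.default_rng(8)
        for trial in range(3):
            state = random_state(mini_model, rng)
            j, d = int(rng.integers(0, 2)), 2
            got = mini_model.mh_decoy_swap_logr(state, j, d)
            S_chars = tuple("".join(SYM[s] for s in row) for row in state.S)
            S_sw = list(S_chars)
            S_sw[j], S_sw[d] = S_sw[d], S_sw[j]
            num = fp.type_prior("A", mini_model.panel.names,
                                mini_model.panel.names[state.R[d]], False) * \
                brute_indicator_marginal(mini_model.reads, tuple(S_sw), 1, hp)
            den = fp.type_prior("A", mini_model.panel.names,
                                mini_model.panel.names[state.R[j]], False) * \
                brute_indicator_marginal(mini_model.reads, S_chars, 1, hp)
            expected = math.log(num / den)
            assert abs(got - expected) <= 1e-9 * max(1.0, abs(expected))

    def test_swapping_away_good_fit_unlikely(self, hp, fp):
        panel = make_panel("A", {"A*01:01": "ACGT", "A*02:01": "TTTT"})
        reads = [
            make_placed("r0", [0, 1, 2, 3], "ACGT", [30] * 4),
            make_placed("r1", [0, 1, 2, 3], "ACGT", [30] * 4),
        ]
        model = GeneModel(panel, reads, hp, fp, n_decoy=1)
        # both reads fit S_1 only; the other components are garbage, so
        # swapping the good component into the decoy slot costs the epsilon
        # prior on both reads
        state = ModelState(
            np.array([0, 1, 1]), panel.ref[[0, 1, 1]].copy(), np.array([0, 0])
        )
        assert model.mh_decoy_swap_logr(state, 0, 2) < -5.0

    def test_detailed_balance_flow(self, hp, fp):
        """Enumerate a one-column instance and check pi(x)P(x->y)=pi(y)P(y->x)
        for the decoy-swap kernel."""
        import itertools

        panel = make_panel("A", {"A*01:01": "A", "A*02:01": "C"})
        reads = [make_placed("r0", [0], "A", [13])]
        model = GeneModel(panel, reads, hp, fp, n_decoy=1)

        def pi(R, S, I):
            st = ModelState(np.array(R), np.array(S, dtype=np.int8).reshape(3, 1), np.array(I))
            return math.exp(model.log_posterior(st))

        def q_and_acc(R, S, I, j):
            st = ModelState(np.array(R), np.array(S, dtype=np.int8).reshape(3, 1), np.array(I))
            logr = model.mh_decoy_swap_logr(st, j, 2)
            ll = model.loglik_matrix(st.S)
            ll[:, [j, 2]] = ll[:, [2, j]]
            logits = ll[0] + model.log_ind
            q = np.exp(logits - logits.max())
            q /= q.sum()
            return q, min(1.0, math.exp(logr))

        checked = 0
        for R in itertools.product(range(2), repeat=3):
            for S in itertools.product(range(6), repeat=3):
                for I in itertools.product(range(3), repeat=1):
                    for j in (0, 1):
                        Rs = list(R); Ss = list(S)
                        Rs[j], Rs[2] = Rs[2], Rs[j]
                        Ss[j], Ss[2] = Ss[2], Ss[j]
                        q_fwd, acc_fwd = q_and_acc(R, S, I, j)
                        for I_new in range(3):
                            q_rev, acc_rev = q_and_acc(tuple(Rs), tuple(Ss), (I_new,), j)
                            flow_fwd = pi(R, S, I) * 0.5 * q_fwd[I_new] * acc_fwd
                            flow_rev = pi(tuple(Rs), tuple(Ss), (I_new,)) * 0.5 * q_rev[I[0]] * acc_rev
                            assert flow_fwd == pytest.approx(flow_rev, rel=1e-8)
                            checked += 1
        assert checked == 8 * 216 * 3 * 2 * 3


class TestRunMcmc:
    def _cfg(self, seed, **kw):
        base = dict(
            temperatures=(1.0,),
            n_burnin=100,
            n_samples=300,
            n_multistart=2,
            multistart_sweeps=20,
            ref_copy_period=50,
            mh_period=10,
            trace_every=50,
            n_decoy=1,
        )
        base.update(kw)
        return SamplerConfig(seed=seed, **base)

    def test_zero_reads_error(self, tiny_panel, hp, fp):
        with pytest.raises(ValueError, match="filter log"):
            run_mcmc(tiny_panel, [], hp, fp, self._cfg(1))

    def test_determinism(self, tiny_panel, hp, fp):
        reads = [make_placed("r0", [0, 1, 2, 3], "ACGT", [30] * 4)]
        s1 = run_mcmc(tiny_panel, reads, hp, fp, self._cfg(7))
        s2 = run_mcmc(tiny_panel, reads, hp, fp, self._cfg(7))
        assert s1.genotype_counts == s2.genotype_counts
        np.testing.assert_array_equal(s1.seq_counts, s2.seq_counts)
        assert s1.trace == s2.trace

    def test_recovers_obvious_genotype(self, tiny_panel, hp, fp):
        reads = [make_placed(f"r{i}", [0, 1, 2, 3], "ACGT", [35] * 4) for i in range(8)]
        reads += [make_placed(f"q{i}", [0, 1, 2, 3], "ACTT", [35] * 4) for i in range(8)]
        summary = run_mcmc(tiny_panel, reads, hp, fp, self._cfg(3, n_samples=500))
        top = call_genotype(summary)[0]
        assert {top[0], top[1]} == {"A*01:01", "A*02:01"}

    def test_seed_recorded(self, tiny_panel, hp, fp):
        reads = [make_placed("r0", [0, 1], "AC", [30, 30])]
        summary = run_mcmc(tiny_panel, reads, hp, fp, self._cfg(99))
        assert summary.seed == 99


class TestCalls:
    def _summary(self, counts, seq_counts, n):
        return PosteriorSummary(
            gene="A",
            names=[],
            genotype_counts=Counter(counts),
            seq_counts=np.array(seq_counts),
            n_samples=n,
            acceptance={},
            trace=[],
            seed=0,
        )

    def test_genotype_ranking(self):
        s = self._summary({("a", "b"): 800, ("a", "c"): 200}, np.zeros((2, 1, 6)), 1000)
        ranked = call_genotype(s)
        assert ranked[0] == ("a", "b", 0.8)
        assert ranked[1] == ("a", "c", 0.2)

    def test_unordered_pooling_happens_at_accumulation(self, tiny_panel, hp, fp):
        # keys produced by run_mcmc are sorted tuples; identical pairs pool
        s = self._summary({("a", "b"): 1000}, np.zeros((2, 1, 6)), 1000)
        assert call_genotype(s)[0][2] == 1.0

    def test_consensus_all_agree(self):
        sc = np.zeros((2, 3, 6), dtype=int)
        sc[0, :, 0] = 100
        sc[1, :, 1] = 100
        s = self._summary({}, sc, 100)
        seqs, support = call_sequences(s)
        assert seqs == ["AAA", "CCC"]
        assert (support == 1.0).all()

    def test_consensus_split_becomes_N(self):
        sc = np.zeros((2, 1, 6), dtype=int)
        sc[:, 0, 0] = 50
        sc[:, 0, 1] = 50
        s = self._summary({}, sc, 100)
        seqs, support = call_sequences(s, threshold=0.9)
        assert seqs[0] == "N" and seqs[1] == "N"
        assert support[0, 0] == pytest.approx(0.5)

    def test_empty_summary_errors(self):
        s = self._summary({}, np.zeros((2, 1, 6)), 0)
        with pytest.raises(ValueError):
            call_genotype(s)


class TestSamplerConfigValidation:
    def test_ladder_must_start_at_one(self):
        with pytest.raises(ValueError):
            SamplerConfig(seed=1, temperatures=(1.5, 2.0))

    def test_periods_positive(self):
        with pytest.raises(ValueError):
            SamplerConfig(seed=1, mh_period=0)
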