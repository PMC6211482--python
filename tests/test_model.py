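import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hlabayes.model import (
    DeltaSet,
    FreqPrior,
    Hyperparams,
    ModelState,
    base_likelihood,
    indicator_log_prior,
    indicator_prior,
    log_posterior,
    prior_log_table,
    read_log_table,
    read_loglik,
    seq_prior_base,
)
from conftest import make_panel, make_placed
from oracles import naive_joint

SYMBOLS = "ACGTN-"


class TestBaseLikelihood:
    def test_match_case(self, hp):
        hp = Hyperparams(gamma_del=0.001, gamma_ins=0.001, gamma_N=0.001)
        expected = 0.999 * 0.999 * 0.99
        assert base_likelihood("A", "A", 0.01, hp) == pytest.approx(expected, rel=1e-12)

    def test_read_gap_is_gamma_del(self):
        hp = Hyperparams(gamma_del=0.001)
        assert base_likelihood("-", "A", 0.5, hp) == pytest.approx(0.001)

    def test_both_gap(self):
        hp = Hyperparams(gamma_ins=0.002)
        assert base_likelihood("-", "-", 0.3, hp) == pytest.approx(0.998)

    def test_mismatch_splits_three_ways(self, hp):
        m = base_likelihood("C", "A", 0.03, hp)
        assert m == pytest.approx((1 - hp.gamma_del) * (1 - hp.gamma_N) * 0.01)

    def test_invalid_symbol(self, hp):
        with pytest.raises(ValueError):
            base_likelihood("X", "A", 0.1, hp)

    def test_invalid_p_hat(self, hp):
        with pytest.raises(ValueError):
            base_likelihood("A", "A", 1.5, hp)

    @pytest.mark.parametrize("seq_symbol", list(SYMBOLS))
    def test_normalization(self, hp, seq_symbol):
        total = sum(base_likelihood(x, seq_symbol, 0.013, hp) for x in SYMBOLS)
        assert total == pytest.approx(1.0, abs=1e-12)


class TestSeqPriorBase:
    def test_match_case(self):
        hp = Hyperparams(delta_normal=DeltaSet(0.001, 0.001, 0.001, 0.001))
        assert seq_prior_base("A", "A", False, hp) == pytest.approx(0.999**3, rel=1e-12)

    def test_substitution_case(self):
        hp = Hyperparams(delta_normal=DeltaSet(0.003, 0.001, 0.001, 0.001))
        assert seq_prior_base("C", "A", False, hp) == pytest.approx(
            0.999 * 0.999 * 0.001, rel=1e-12
        )

    def test_gap_gap(self):
        hp = Hyperparams(delta_normal=DeltaSet(0.005, 0.001, 0.001, 0.0001))
        assert seq_prior_base("-", "-", False, hp) == pytest.approx(0.999)

    def test_imputed_flag_switches_delta_set(self, hp):
        loose = seq_prior_base("C", "A", True, hp)
        tight = seq_prior_base("C", "A", False, hp)
        assert loose > tight  # imputed positions tolerate more variation

    @pytest.mark.parametrize("ref_symbol", list(SYMBOLS))
    @pytest.mark.parametrize("imputed", [False, True])
    def test_normalization(self, hp, ref_symbol, imputed):
        total = sum(seq_prior_base(s, ref_symbol, imputed, hp) for s in SYMBOLS)
        assert total == pytest.approx(1.0, abs=1e-12)


class TestIndicatorPrior:
    def test_nondecoy(self):
        assert indicator_prior(1, 2, 0.01) == pytest.approx(1 / 2.02)

    def test_decoy(self):
        assert indicator_prior(3, 2, 0.01) == pytest.approx(0.01 / 2.02)

    def test_epsilon_one_uniform(self):
        for i in range(1, 5):
            assert indicator_prior(i, 2, 1.0) == pytest.approx(0.25)

    def test_sums_to_one(self):
        total = sum(indicator_prior(i, 3, 0.07) for i in range(1, 6))
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_log_vector_matches_scalar(self):
        v = indicator_log_prior(2, 0.01)
        for i in range(4):
            assert v[i] == pytest.approx(math.log(indicator_prior(i + 1, 2, 0.01)))

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            indicator_prior(5, 2, 0.01)


class TestFreqPrior:
    def test_uniform_fallback(self):
        fp = FreqPrior()
        names = [f"A*{i:02d}:01" for i in range(1, 21)]
        assert fp.type_prior("A", names, names[0], False) == pytest.approx(0.05)

    def test_table_no_smoothing(self):
        fp = FreqPrior({"A": {"A*01:01": 0.9, "A*02:01": 0.1}}, pseudo=0.0)
        names = ["A*01:01", "A*02:01"]
        assert fp.type_prior("A", names, "A*01:01", False) == pytest.approx(0.9)

    def test_decoy_constant(self):
        fp = FreqPrior({"A": {"A*01:01": 0.99, "A*02:01": 0.01}})
        names = [f"A*{i:02d}:01" for i in range(1, 21)]
        assert fp.type_prior("A", names, "A*01:01", True) == pytest.approx(0.05)

    def test_smoothing_keeps_unlisted_positive(self):
        fp = FreqPrior({"A": {"A*01:01": 1.0}})
        names = ["A*01:01", "A*02:01"]
        assert fp.type_prior("A", names, "A*02:01", False) > 0

    def test_unknown_type(self):
        fp = FreqPrior()
        with pytest.raises(KeyError):
            fp.type_prior("A", ["A*01:01"], "A*99:01", False)


class TestReadLogTable:
    def test_matches_scalar_function(self, hp):
        rng = np.random.default_rng(0)
        syms = rng.integers(0, 6, size=12).astype(np.int8)
        quals = rng.integers(2, 41, size=12)
        L = read_log_table(syms, quals, hp)
        for pos in range(12):
            p_hat = 10 ** (-quals[pos] / 10)
            for s in range(6):
                expected = math.log(base_likelihood(SYMBOLS[syms[pos]], SYMBOLS[s], p_hat, hp))
                assert L[pos, s] == pytest.approx(expected, rel=1e-12)

    def test_negative_quality_rejected(self, hp):
        with pytest.raises(ValueError):
            read_log_table(np.array([0], dtype=np.int8), [-1], hp)


class TestReadLoglik:
    def test_identical_read(self, hp):
        hp = Hyperparams(gamma_del=0.001, gamma_ins=0.001, gamma_N=0.001)
        read = make_placed("r", range(10), "ACGTACGTAC", [20] * 10)
        seq = np.array([0, 1, 2, 3, 0, 1, 2, 3, 0, 1], dtype=np.int8)
        expected = 10 * math.log(0.999 * 0.999 * 0.99)
        assert read_loglik(read, seq, hp) == pytest.approx(expected, rel=1e-12)

    def test_empty_coverage(self, hp):
        read = make_placed("r", [], "")
        assert read_loglik(read, np.zeros(5, dtype=np.int8), hp) == 0.0

    def test_single_N_column(self, hp):
        read = make_placed("r", [2], "N")
        seq = np.zeros(5, dtype=np.int8)
        expected = math.log((1 - hp.gamma_del) * hp.gamma_N)
        assert read_loglik(read, seq, hp) == pytest.approx(expected)


class TestPriorLogTable:
    def test_matches_scalar(self, hp):
        tab = prior_log_table(hp)
        for imp in (0, 1):
            for r in range(6):
                for s in range(6):
                    expected = math.log(seq_prior_base(SYMBOLS[s], SYMBOLS[r], bool(imp), hp))
                    assert tab[imp, r, s] == pytest.approx(expected, rel=1e-12)


class TestLogPosterior:
    def test_no_reads_closed_form(self, tiny_panel, hp, fp):
        # S identical to the reference of each R: only priors contribute
        R = np.array([0, 1, 2])
        S = tiny_panel.ref[R].copy()
        state = ModelState(R, S, np.zeros(0, dtype=int))
        lp = log_posterior(state, [], tiny_panel, hp, fp)
        expected = 2 * math.log(1 / 3) + math.log(1 / 3)  # type priors
        d = hp.delta_normal
        match_n = math.log((1 - d.dele) * (1 - d.n) * (1 - d.sub))
        di = hp.delta_imputed
        match_i = math.log((1 - di.dele) * (1 - di.n) * (1 - di.sub))
        # A*03:01 (index 2 in sorted order) has one imputed column
        expected += 11 * match_n + 1 * match_i
        assert lp == pytest.approx(expected, rel=1e-9)

    def test_flipping_base_decreases_density(self, tiny_panel, hp, fp):
        read = make_placed("r", [0, 1, 2, 3], "ACGT")
        R = np.array([0, 1, 2])
        S = tiny_panel.ref[R].copy()
        state = ModelState(R, S, np.array([0]))
        lp0 = log_posterior(state, [read], tiny_panel, hp, fp)
        state.S[0, 1] = 2  # G: disagrees with both read and reference
        lp1 = log_posterior(state, [read], tiny_panel, hp, fp)
        assert lp1 < lp0

    def test_matches_naive_oracle(self, tiny_panel, hp, fp):
        rng = np.random.default_rng(3)
        reads = [
            make_placed("r0", [0, 1, 2], "ACG", [25, 30, 17]),
            make_placed("r1", [1, 2, 3], "C-T", [30, 0, 30]),
        ]
        for _ in range(5):
            R = rng.integers(0, 3, size=3)
            S = rng.integers(0, 6, size=(3, 4)).astype(np.int8)
            I = rng.integers(0, 3, size=2)
            state = ModelState(R.copy(), S.copy(), I.copy())
            lp = log_posterior(state, reads, tiny_panel, hp, fp)
            naive = naive_joint(
                tuple(R),
                tuple("".join(SYMBOLS[s] for s in row) for row in S),
                tuple(I),
                reads,
                tiny_panel,
                hp,
                fp,
            )
            assert lp == pytest.approx(math.log(naive), rel=1e-9)

    def test_density_ratio_matches_naive(self, tiny_panel, hp, fp):
        # differences of log_posterior equal log ratios of the naive density
        read = make_placed("r0", [0, 1], "AC", [30, 30])
        s1 = ModelState(np.array([0, 1, 2]), tiny_panel.ref[[0, 1, 2]].copy(), np.array([0]))
        s2 = ModelState(np.array([1, 1, 0]), tiny_panel.ref[[1, 1, 0]].copy(), np.array([2]))
        d_fast = log_posterior(s1, [read], tiny_panel, hp, fp) - log_posterior(
            s2, [read], tiny_panel, hp, fp
        )
        def naive_of(st):
            return naive_joint(
                tuple(st.R),
                tuple("".join(SYMBOLS[s] for s in row) for row in st.S),
                tuple(st.I),
                [read],
                tiny_panel,
                hp,
                fp,
            )
        assert d_fast == pytest.approx(math.log(naive_of(s1) / naive_of(s2)), rel=1e-9)

    def test_invalid_state(self, tiny_panel, hp, fp):
        state = ModelState(np.array([0, 1]), tiny_panel.ref[[0, 1]].copy(), np.array([5]))
        with pytest.raises(ValueError):
            log_posterior(state, [make_placed("r", [0], "A")], tiny_panel, hp, fp)


class TestHyperparamValidation:
    def test_imputed_must_dominate(self):
        with pytest.raises(ValueError):
            Hyperparams(
                delta_normal=DeltaSet(0.2, 0.01, 0.01, 0.01),
                delta_imputed=DeltaSet(0.1, 0.01, 0.01, 0.01),
            )

    def test_gamma_range(self):
        with pytest.raises(ValueError):
            Hyperparams(gamma_del=0.0)


@settings(max_examples=30, deadline=None)
@given(
    gd=st.floats(1e-6, 0.3),
    gi=st.floats(1e-6, 0.3),
    gn=st.floats(1e-6, 0.3),
    p=st.floats(0.0, 1.0),
)
def test_base_likelihood_normalizes_for_random_rates(gd, gi, gn, p):
    hp = Hyperparams(gamma_del=gd, gamma_ins=gi, gamma_N=gn)
    for seq_symbol in SYMBOLS:
        total = sum(base_likelihood(x, seq_symbol, p, hp) for x in SYMBOLS)
        assert abs(total - 1.0) <= 1e-12
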