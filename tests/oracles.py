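"""Independent brute-force oracles used to validate the fast implementations.

Everything here works from the scalar probability functions and explicit
enumeration (itertools over symbol/assignment spaces), deliberately avoiding
the vectorized tables and factorizations used by the package internals.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from hlabayes.model import (
    FreqPrior,
    Hyperparams,
    ReferencePanel,
    base_likelihood,
    indicator_prior,
    seq_prior_base,
)

SYM = "ACGTN-"


def naive_read_lik(read, seq_chars: str, hp: Hyperparams) -> float:
    """Product of scalar base likelihoods over the read's covered columns."""
    out = 1.0
    for pos, col in enumerate(read.cols):
        p_hat = 10.0 ** (-float(read.quals[pos]) / 10.0)
        out *= base_likelihood(SYM[read.syms[pos]], seq_chars[col], p_hat, hp)
    return out


def naive_seq_prior(seq_chars: str, panel: ReferencePanel, a: int, hp: Hyperparams) -> float:
    out = 1.0
    for n, s in enumerate(seq_chars):
        out *= seq_prior_base(s, SYM[panel.ref[a, n]], bool(panel.mask[a, n]), hp)
    return out


def naive_joint(
    R: tuple[int, ...],
    S: tuple[str, ...],
    I: tuple[int, ...],
    reads,
    panel: ReferencePanel,
    hp: Hyperparams,
    fp: FreqPrior,
) -> float:
    """Unnormalized joint density from scalar functions only."""
    K = len(R)
    n_decoy = K - 2
    out = 1.0
    for i, read in enumerate(reads):
        out *= naive_read_lik(read, S[I[i]], hp)
        out *= indicator_prior(I[i] + 1, n_decoy, hp.epsilon)
    for k in range(K):
        out *= fp.type_prior(panel.gene, panel.names, panel.names[R[k]], k >= 2)
        out *= naive_seq_prior(S[k], panel, R[k], hp)
    return out


def brute_seq_marginal(
    reads, assigned: list[int], panel: ReferencePanel, a: int, hp: Hyperparams
) -> float:
    """Sum over all sequences of component k: sum_S p(reads_k|S) p(S|R=a).

    ``assigned`` indexes the reads currently assigned to the component.
    Full enumeration over 6^n_columns sequences.
    """
    total = 0.0
    for seq in itertools.product(SYM, repeat=panel.n_columns):
        seq_chars = "".join(seq)
        term = naive_seq_prior(seq_chars, panel, a, hp)
        for i in assigned:
            term *= naive_read_lik(reads[i], seq_chars, hp)
        total += term
    return total


def brute_indicator_marginal(
    reads, S: tuple[str, ...], n_decoy: int, hp: Hyperparams
) -> float:
    """Sum over all assignments: sum_I prod_i p(I_i) p(x_i|S_{I_i})."""
    K = 2 + n_decoy
    total = 0.0
    for I in itertools.product(range(K), repeat=len(reads)):
        term = 1.0
        for i, k in enumerate(I):
            term *= indicator_prior(k + 1, n_decoy, hp.epsilon)
            term *= naive_read_lik(reads[i], S[k], hp)
        total += term
    return total


def enumerate_genotype_marginal(
    reads, panel: ReferencePanel, hp: Hyperparams, fp: FreqPrior, n_decoy: int
) -> dict[tuple[str, str], float]:
    """Exact posterior marginal of the unordered non-decoy type pair.

    Sequences are collapsed analytically per (component, column) given the
    read assignment; assignments and types are enumerated. Validated against
    the fully naive enumeration in test_oracles.py.
    """
    A = panel.n_alleles
    n_reads = len(reads)
    K = 2 + n_decoy
    n_cols = panel.n_columns

    # per-read, per-column-position likelihood of each sequence symbol
    def read_sym_lik(read, pos: int) -> np.ndarray:
        p_hat = 10.0 ** (-float(read.quals[pos]) / 10.0)
        return np.array(
            [base_likelihood(SYM[read.syms[pos]], s, p_hat, hp) for s in SYM]
        )

    # F[a][subset] = prod_n sum_s p(s|ref_a_n) * prod_{i in subset covering n} p(x_i_n|s)
    F = np.zeros((A, 1 << n_reads))
    prior_vec = np.empty((A, n_cols, 6))
    for a in range(A):
        for n in range(n_cols):
            prior_vec[a, n] = [
                seq_prior_base(s, SYM[panel.ref[a, n]], bool(panel.mask[a, n]), hp)
                for s in SYM
            ]
    for sub in range(1 << n_reads):
        lik = np.ones((n_cols, 6))
        for i in range(n_reads):
            if sub >> i & 1:
                for pos, col in enumerate(reads[i].cols):
                    lik[col] *= read_sym_lik(reads[i], pos)
        for a in range(A):
            F[a, sub] = float(np.log((prior_vec[a] * lik).sum(axis=1)).sum())

    freq = fp.nondecoy_probs(panel.gene, panel.names)
    log_freq = np.log(freq)
    log_flat = -math.log(A)
    out = np.full((A, A), -np.inf)
    for I in itertools.product(range(K), repeat=n_reads):
        subs = [0] * K
        for i, k in enumerate(I):
            subs[k] |= 1 << i
        lp_I = sum(
            math.log(indicator_prior(k + 1, n_decoy, hp.epsilon)) for k in I
        )
        lp_decoy = sum(
            float(np.logaddexp.reduce(log_flat + F[:, subs[d]])) for d in range(2, K)
        )
        term = lp_I + lp_decoy
        block = (
            term
            + (log_freq + F[:, subs[0]])[:, None]
            + (log_freq + F[:, subs[1]])[None, :]
        )
        out = np.logaddexp(out, block)
    out -= np.logaddexp.reduce(out, axis=None)
    probs = np.exp(out)
    marg: dict[tuple[str, str], float] = {}
    for a in range(A):
        for b in range(A):
            key = tuple(sorted((panel.names[a], panel.names[b])))
            marg[key] = marg.get(key, 0.0) + probs[a, b]
    return marg
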