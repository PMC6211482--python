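"""Bayesian model for genotype and sequence inference from placed reads.

The model couples three layers of latent variables:

* ``R`` — a pair of database types plus decoy types absorbing off-target reads,
* ``S`` — the personal sequences generated from the types via a per-column
  substitution/indel prior,
* ``I`` — per-read indicators assigning each read to one of the sequences.

All densities factorise per column / per read, so the joint log density and
every full conditional can be evaluated exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alphabet import GAP, N, N_SYMBOLS, is_base, symbol_code


@dataclass(frozen=True)
class DeltaSet:
    """Per-column sequence-prior rates: substitution, deletion, insertion, N."""

    sub: float
    dele: float
    ins: float
    n: float

    def __post_init__(self) -> None:
        for v in (self.sub, self.dele, self.ins, self.n):
            if not (0.0 < v < 1.0):
                raise ValueError(f"delta rates must lie in (0,1), got {v}")


@dataclass(frozen=True)
class Hyperparams:
    """Error/variant rates of the likelihood and priors.

    ``gamma_*`` govern read errors relative to the generating sequence,
    ``delta_*`` govern true differences between a sequence and its reference
    type (with a looser set at imputed reference columns), and ``epsilon``
    is the prior odds of a read coming from a decoy component.

    Defaults are tunable package choices; none are dictated by data.
    """

    # indel read errors are far rarer than substitutions on short-read
    # platforms; a loose rate here lets true mixed-cell indels be written
    # off as errors instead of being absorbed by a decoy component
    gamma_del: float = 1e-4
    gamma_ins: float = 1e-4
    gamma_N: float = 1e-4
    delta_normal: DeltaSet = field(default_factory=lambda: DeltaSet(5e-3, 1e-3, 1e-3, 1e-4))
    # looser than the normal set, but not so loose that the per-column
    # normalization tax at matching imputed columns swamps the evidence
    # distinguishing an exonic-only allele from its imputation donor
    delta_imputed: DeltaSet = field(default_factory=lambda: DeltaSet(0.05, 0.01, 0.01, 1e-3))
    epsilon: float = 0.01

    def __post_init__(self) -> None:
        for v in (self.gamma_del, self.gamma_ins, self.gamma_N):
            if not (0.0 < v < 1.0):
                raise ValueError(f"gamma rates must lie in (0,1), got {v}")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        for a, b in zip(
            (self.delta_imputed.sub, self.delta_imputed.dele, self.delta_imputed.ins, self.delta_imputed.n),
            (self.delta_normal.sub, self.delta_normal.dele, self.delta_normal.ins, self.delta_normal.n),
        ):
            if a < b:
                raise ValueError("imputed-position delta values must be >= normal values")


def base_likelihood(read_symbol: str, seq_symbol: str, p_hat: float, hp: Hyperparams) -> float:
    """Probability of observing ``read_symbol`` given generating ``seq_symbol``.

    ``p_hat`` is the quality-implied mismatch probability of the read base.
    """
    if not (0.0 <= p_hat <= 1.0):
        raise ValueError("p_hat must lie in [0,1]")
    x = symbol_code(read_symbol)
    s = symbol_code(seq_symbol)
    gd, gi, gn = hp.gamma_del, hp.gamma_ins, hp.gamma_N
    if is_base(s):
        if x == s:
            return (1 - gd) * (1 - gn) * (1 - p_hat)
        if is_base(x):
            return (1 - gd) * (1 - gn) * p_hat / 3.0
        if x == N:
            return (1 - gd) * gn
        return gd  # read gap: deletion error
    if s == N:
        if is_base(x):
            return (1 - gd) * (1 - gn) / 4.0
        if x == N:
            return (1 - gd) * gn
        return gd
    # s == GAP
    if is_base(x):
        return gi * (1 - gn) / 4.0
    if x == N:
        return gi * gn
    return 1 - gi


def seq_prior_base(seq_symbol: str, ref_symbol: str, imputed: bool, hp: Hyperparams) -> float:
    """Prior probability of a sequence symbol given its reference-type symbol."""
    s = symbol_code(seq_symbol)
    r = symbol_code(ref_symbol)
    d = hp.delta_imputed if imputed else hp.delta_normal
    if is_base(r):
        if s == r:
            return (1 - d.dele) * (1 - d.n) * (1 - d.sub)
        if is_base(s):
            return (1 - d.dele) * (1 - d.n) * d.sub / 3.0
        if s == N:
            return (1 - d.dele) * d.n
        return d.dele
    if r == N:
        if is_base(s):
            return (1 - d.dele) * (1 - d.n) / 4.0
        if s == N:
            return (1 - d.dele) * d.n
        return d.dele
    # r == GAP
    if is_base(s):
        return d.ins * (1 - d.n) / 4.0
    if s == N:
        return d.ins * d.n
    return 1 - d.ins


def mismatch_prob_from_qual(quals) -> np.ndarray:
    """Quality-implied mismatch probabilities ``10^(-q/10)``."""
    q = np.asarray(quals, dtype=float)
    if np.any(q < 0):
        raise ValueError("base qualities must be non-negative")
    return 10.0 ** (-q / 10.0)


def read_log_table(syms: np.ndarray, quals: np.ndarray, hp: Hyperparams) -> np.ndarray:
    """Per-position log base-likelihood for every possible sequence symbol.

    Returns an ``(m, 6)`` array ``L`` with ``L[pos, s] = log p(x_pos | s)``.
    This is the workhorse table consumed by the sampler: a read's log
    likelihood against any sequence is a fancy-indexed row sum.
    """
    syms = np.asarray(syms, dtype=np.int8)
    p = mismatch_prob_from_qual(quals)
    m = len(syms)
    if len(p) != m:
        raise ValueError("symbols and qualities must have equal length")
    gd, gi, gn = hp.gamma_del, hp.gamma_ins, hp.gamma_N
    L = np.empty((m, N_SYMBOLS))
    base_mask = syms < 4
    n_mask = syms == N
    gap_mask = syms == GAP
    with np.errstate(divide="ignore"):
        # seq symbol in B
        for s in range(4):
            col = np.empty(m)
            match = base_mask & (syms == s)
            mismatch = base_mask & (syms != s)
            col[match] = np.log((1 - gd) * (1 - gn)) + np.log1p(-p[match])
            col[mismatch] = np.log((1 - gd) * (1 - gn) / 3.0) + np.log(p[mismatch])
            col[n_mask] = np.log((1 - gd) * gn)
            col[gap_mask] = np.log(gd)
            L[:, s] = col
        # seq symbol N
        col = np.empty(m)
        col[base_mask] = np.log((1 - gd) * (1 - gn) / 4.0)
        col[n_mask] = np.log((1 - gd) * gn)
        col[gap_mask] = np.log(gd)
        L[:, N] = col
        # seq symbol gap
        col = np.empty(m)
        col[base_mask] = np.log(gi * (1 - gn) / 4.0)
        col[n_mask] = np.log(gi * gn)
        col[gap_mask] = np.log1p(-gi)
        L[:, GAP] = col
    return L


def prior_log_table(hp: Hyperparams) -> np.ndarray:
    """Log sequence-prior table indexed ``[imputed, ref_symbol, seq_symbol]``."""
    tab = np.empty((2, N_SYMBOLS, N_SYMBOLS))
    for imp in (0, 1):
        for r in range(N_SYMBOLS):
            for s in range(N_SYMBOLS):
                tab[imp, r, s] = np.log(
                    seq_prior_base("ACGTN-"[s], "ACGTN-"[r], bool(imp), hp)
                )
    return tab


def indicator_prior(index: int, n_decoy: int, epsilon: float) -> float:
    """Prior probability of read-assignment index (1-based; 1,2 = non-decoy)."""
    k = 2 + n_decoy
    if not (1 <= index <= k):
        raise ValueError(f"indicator index {index} outside [1,{k}]")
    z = 2.0 + n_decoy * epsilon
    return (1.0 if index <= 2 else epsilon) / z


def indicator_log_prior(n_decoy: int, epsilon: float) -> np.ndarray:
    """Log prior vector over the ``2 + n_decoy`` components (0-based)."""
    z = 2.0 + n_decoy * epsilon
    v = np.full(2 + n_decoy, epsilon / z)
    v[:2] = 1.0 / z
    return np.log(v)


class FreqPrior:
    """Type prior from optional population allele frequencies.

    Non-decoy components use smoothed frequencies ``p ∝ freq + λ`` (uniform
    when no table is supplied); decoy components use a flat ``1/|db|`` prior.
    """

    def __init__(self, tables: dict[str, dict[str, float]] | None = None, pseudo: float = 1e-3):
        self.tables = tables or {}
        self.pseudo = float(pseudo)

    def nondecoy_probs(self, gene: str, names: list[str]) -> np.ndarray:
        table = self.tables.get(gene)
        if table is None:
            return np.full(len(names), 1.0 / len(names))
        for name in table:
            if name not in names:
                raise KeyError(f"frequency table lists unknown type {name!r}")
        f = np.array([table.get(n, 0.0) for n in names], dtype=float)
        p = f + self.pseudo
        return p / p.sum()

    def log_nondecoy(self, gene: str, names: list[str]) -> np.ndarray:
        return np.log(self.nondecoy_probs(gene, names))

    def type_prior(self, gene: str, names: list[str], name: str, is_decoy: bool) -> float:
        if name not in names:
            raise KeyError(f"unknown type {name!r}")
        if is_decoy:
            return 1.0 / len(names)
        return float(self.nondecoy_probs(gene, names)[names.index(name)])


@dataclass
class ReferencePanel:
    """Encoded reference alleles of one gene in integrated MSA columns."""

    gene: str
    names: list[str]
    ref: np.ndarray  # (A, n_cols) int8 symbol codes
    mask: np.ndarray  # (A, n_cols) bool, True where imputed

    @property
    def n_alleles(self) -> int:
        return len(self.names)

    @property
    def n_columns(self) -> int:
        return self.ref.shape[1]

    def index(self, name: str) -> int:
        return self.names.index(name)


@dataclass
class ModelState:
    """One MCMC state: types ``R``, sequences ``S``, read indicators ``I``.

    ``R`` holds indices into the panel's allele list; the first two components
    are non-decoy, the rest decoys. ``I`` is 0-based into the rows of ``S``.
    """

    R: np.ndarray
    S: np.ndarray
    I: np.ndarray

    def copy(self) -> "ModelState":
        return ModelState(self.R.copy(), self.S.copy(), self.I.copy())

    def validate(self, panel: ReferencePanel, n_reads: int) -> None:
        if len(self.R) != self.S.shape[0] or len(self.R) < 2:
            raise ValueError("state must have len(R)==len(S) >= 2")
        if self.S.shape[1] != panel.n_columns:
            raise ValueError("sequence length mismatch with panel")
        if len(self.I) != n_reads:
            raise ValueError("indicator length mismatch with reads")
        if np.any(self.I < 0) or np.any(self.I >= len(self.R)):
            raise ValueError("indicator index out of range")
        if np.any(self.R < 0) or np.any(self.R >= panel.n_alleles):
            raise ValueError("type index out of range")


def read_loglik(read, seq: np.ndarray, hp: Hyperparams) -> float:
    """Log likelihood of a placed read against a sequence (covered columns only)."""
    if len(read.cols) == 0:
        return 0.0
    L = read_log_table(read.syms, read.quals, hp)
    seq = np.asarray(seq, dtype=np.int8)
    return float(L[np.arange(len(read.cols)), seq[read.cols]].sum())


def log_posterior(state: ModelState, reads, panel: ReferencePanel, hp: Hyperparams, fp: FreqPrior) -> float:
    """Unnormalized log posterior density of a full model state."""
    state.validate(panel, len(reads))
    total = 0.0
    for i, read in enumerate(reads):
        total += read_loglik(read, state.S[state.I[i]], hp)
    ptab = prior_log_table(hp)
    log_freq = fp.log_nondecoy(panel.gene, panel.names)
    n_alleles = panel.n_alleles
    for k in range(len(state.R)):
        a = state.R[k]
        total += float(log_freq[a]) if k < 2 else -np.log(n_alleles)
        total += float(
            ptab[panel.mask[a].astype(np.intp), panel.ref[a], state.S[k]].sum()
        )
    n_decoy = len(state.R) - 2
    log_ind = indicator_log_prior(n_decoy, hp.epsilon)
    total += float(log_ind[state.I].sum())
    return total
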