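"""MCMC inference: Gibbs sweeps, two bespoke Metropolis-Hastings proposals,
parallel tempering, and posterior summarisation.

Gibbs sampling performs the local moves; two MH proposals provide global
jumps: one resamples a (type, sequence) pair jointly using the sequence
masked to N at uncovered columns, the other swaps a non-decoy component
with a decoy and resamples the read indicators. Chains at higher
temperatures exchange states with the cold chain; only cold, post-burn-in
samples are counted.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .alphabet import N, N_SYMBOLS
from .model import (
    FreqPrior,
    Hyperparams,
    ModelState,
    ReferencePanel,
    indicator_log_prior,
    prior_log_table,
    read_log_table,
)


@dataclass
class SamplerConfig:
    """Chain layout and schedule. The seed is mandatory and recorded."""

    seed: int
    temperatures: tuple[float, ...] = (1.0, 1.3, 1.7, 2.2)
    n_burnin: int = 2000
    n_samples: int = 8000
    thin: int = 1
    mh_period: int = 25
    n_multistart: int = 8
    multistart_sweeps: int = 200
    ref_copy_period: int = 250
    n_decoy: int = 2
    trace_every: int = 1
    swap_period: int = 2  # sweeps between tempering swap attempts

    def __post_init__(self) -> None:
        if self.temperatures[0] != 1.0:
            raise ValueError("temperature ladder must start at 1.0")
        if min(self.mh_period, self.thin, self.ref_copy_period, self.trace_every, self.swap_period) < 1:
            raise ValueError("periods must be >= 1")
        if self.n_decoy < 0:
            raise ValueError("n_decoy must be >= 0")


@dataclass
class PosteriorSummary:
    """Counted genotype and per-column sequence samples from the cold chain."""

    gene: str
    names: list[str]
    genotype_counts: Counter
    seq_counts: np.ndarray  # (2, n_cols, 6)
    n_samples: int
    acceptance: dict
    trace: list
    seed: int
    n_reads: int = 0
    decoy_assigned_fraction: float = 0.0
    read_decoy_counts: np.ndarray | None = None  # per read: samples with I>2


class GeneModel:
    """Precomputed tables binding one gene's panel, reads, and hyperparameters."""

    def __init__(
        self,
        panel: ReferencePanel,
        reads,
        hp: Hyperparams,
        fp: FreqPrior,
        n_decoy: int = 2,
    ):
        self.panel = panel
        self.reads = reads
        self.hp = hp
        self.n_decoy = n_decoy
        self.K = 2 + n_decoy
        self.n_cols = panel.n_columns
        self.A = panel.n_alleles
        ptab = prior_log_table(hp)
        # (A, n_cols, 6): per allele, per column, log prior of each sequence symbol
        self.refp = ptab[panel.mask.astype(np.intp), panel.ref]
        self.log_freq = fp.log_nondecoy(panel.gene, panel.names)
        self.log_decoy = -np.log(self.A)
        self.L = [read_log_table(r.syms, r.quals, hp) for r in reads]
        self.cols = [r.cols for r in reads]
        self.log_ind = indicator_log_prior(n_decoy, hp.epsilon)

    # ------------------------------------------------------------- utilities

    def initial_state(self, rng: np.random.Generator) -> ModelState:
        R = rng.integers(0, self.A, size=self.K)
        S = self.panel.ref[R].copy()
        I = rng.integers(0, self.K, size=len(self.reads))
        return ModelState(R, S, I)

    def read_sums(self, state: ModelState, k: int) -> np.ndarray:
        """Accumulated read log-likelihood table for component k: (n_cols, 6)."""
        buf = np.zeros((self.n_cols, N_SYMBOLS))
        for i in np.flatnonzero(state.I == k):
            buf[self.cols[i]] += self.L[i]
        return buf

    def loglik_matrix(self, S: np.ndarray) -> np.ndarray:
        """Read x component log likelihood matrix: (n_reads, K)."""
        out = np.empty((len(self.reads), S.shape[0]))
        for i, (cols, L) in enumerate(zip(self.cols, self.L)):
            if len(cols) == 0:
                out[i] = 0.0
                continue
            sub = S[:, cols]  # (K, m)
            out[i] = L[np.arange(len(cols))[None, :], sub].sum(axis=1)
        return out

    def seq_prior_loglik(self, S_k: np.ndarray) -> np.ndarray:
        """log p(S_k | R=a) for every allele a: (A,)."""
        return self.refp[:, np.arange(self.n_cols), S_k].sum(axis=1)

    def log_posterior(self, state: ModelState) -> float:
        total = 0.0
        for i, (cols, L) in enumerate(zip(self.cols, self.L)):
            if len(cols):
                seq = state.S[state.I[i]]
                total += float(L[np.arange(len(cols)), seq[cols]].sum())
        for k in range(self.K):
            prior = self.log_freq[state.R[k]] if k < 2 else self.log_decoy
            total += float(prior)
            total += float(
                self.refp[state.R[k], np.arange(self.n_cols), state.S[k]].sum()
            )
        total += float(self.log_ind[state.I].sum())
        return total

    # ----------------------------------------------------------- Gibbs moves

    def gibbs_update_S(self, state: ModelState, temperature: float, rng: np.random.Generator) -> None:
        for k in range(self.K):
            logits = (self.refp[state.R[k]] + self.read_sums(state, k)) / temperature
            state.S[k] = np.argmax(logits + rng.gumbel(size=logits.shape), axis=1).astype(np.int8)

    def S_full_conditional(self, state: ModelState, k: int, temperature: float = 1.0) -> np.ndarray:
        """Normalized per-column full conditional of S_k: (n_cols, 6)."""
        logits = (self.refp[state.R[k]] + self.read_sums(state, k)) / temperature
        logits -= logsumexp(logits, axis=1, keepdims=True)
        return np.exp(logits)

    def gibbs_update_R(self, state: ModelState, temperature: float, rng: np.random.Generator) -> None:
        for k in range(self.K):
            logits = self.R_logits(state, k) / temperature
            state.R[k] = int(np.argmax(logits + rng.gumbel(size=logits.shape)))

    def R_logits(self, state: ModelState, k: int) -> np.ndarray:
        prior = self.log_freq if k < 2 else np.full(self.A, self.log_decoy)
        return prior + self.seq_prior_loglik(state.S[k])

    def gibbs_update_I(self, state: ModelState, temperature: float, rng: np.random.Generator) -> None:
        ll = self.loglik_matrix(state.S)
        logits = (ll + self.log_ind[None, :]) / temperature
        state.I = np.argmax(logits + rng.gumbel(size=logits.shape), axis=1)

    def I_full_conditional(self, state: ModelState, temperature: float = 1.0) -> np.ndarray:
        logits = (self.loglik_matrix(state.S) + self.log_ind[None, :]) / temperature
        logits -= logsumexp(logits, axis=1, keepdims=True)
        return np.exp(logits)

    def sweep(self, state: ModelState, temperature: float, rng: np.random.Generator) -> None:
        self.gibbs_update_S(state, temperature, rng)
        self.gibbs_update_R(state, temperature, rng)
        self.gibbs_update_I(state, temperature, rng)

    # ------------------------------------------------------------- S^N masking

    def build_SN(self, state: ModelState, k: int) -> np.ndarray:
        cov = np.zeros(self.n_cols, dtype=bool)
        for i in np.flatnonzero(state.I == k):
            cov[self.cols[i]] = True
        return np.where(cov, state.S[k], np.int8(N)).astype(np.int8)

    # -------------------------------------------------------------- MH moves

    def mh_uncovered_logr(
        self, state: ModelState, k: int, r_star_idx: int, temperature: float = 1.0
    ) -> float:
        """Log acceptance ratio of the uncovered-position type jump."""
        SN = self.build_SN(state, k)
        lp_SN = self.refp[:, np.arange(self.n_cols), SN].sum(axis=1)
        buf = self.read_sums(state, k)
        def marg(a: int) -> float:
            return float(logsumexp((self.refp[a] + buf) / temperature, axis=1).sum())
        return (
            (float(lp_SN[state.R[k]]) - float(lp_SN[r_star_idx])) / temperature
            + marg(r_star_idx)
            - marg(state.R[k])
        )

    def mh_uncovered_proposal(
        self, state: ModelState, k: int, temperature: float, rng: np.random.Generator
    ) -> bool:
        """Jointly repropose (R_k, S_k) through the N-masked sequence."""
        if k not in (0, 1):
            raise ValueError("uncovered proposal applies to non-decoy components")
        SN = self.build_SN(state, k)
        lp_SN = self.refp[:, np.arange(self.n_cols), SN].sum(axis=1)
        prior = self.log_freq if k < 2 else np.full(self.A, self.log_decoy)
        logits = (prior + lp_SN) / temperature
        r_star = int(np.argmax(logits + rng.gumbel(size=logits.shape)))
        log_r = self.mh_uncovered_logr(state, k, r_star, temperature)
        if np.log(rng.random()) < log_r:
            buf = self.read_sums(state, k)
            s_logits = (self.refp[r_star] + buf) / temperature
            state.R[k] = r_star
            state.S[k] = np.argmax(s_logits + rng.gumbel(size=s_logits.shape), axis=1).astype(np.int8)
            return True
        return False

    def mh_decoy_swap_logr(
        self, state: ModelState, j: int, d: int, temperature: float = 1.0
    ) -> float:
        """Log acceptance ratio of swapping non-decoy j with decoy d."""
        ll = self.loglik_matrix(state.S)
        ll_new = ll.copy()
        ll_new[:, [j, d]] = ll[:, [d, j]]
        lse_old = logsumexp((ll + self.log_ind[None, :]) / temperature, axis=1).sum()
        lse_new = logsumexp((ll_new + self.log_ind[None, :]) / temperature, axis=1).sum()
        # decoy type prior is flat, so only the frequency prior of the
        # non-decoy slot changes under the swap
        d_prior = float(self.log_freq[state.R[d]] - self.log_freq[state.R[j]])
        return d_prior / temperature + float(lse_new - lse_old)

    def mh_decoy_swap(
        self, state: ModelState, temperature: float, rng: np.random.Generator
    ) -> bool:
        if self.n_decoy < 1:
            raise ValueError("decoy swap requires at least one decoy")
        j = int(rng.integers(0, 2))
        d = 2 + int(rng.integers(0, self.n_decoy))
        log_r = self.mh_decoy_swap_logr(state, j, d, temperature)
        ll = self.loglik_matrix(state.S)
        ll[:, [j, d]] = ll[:, [d, j]]
        logits = (ll + self.log_ind[None, :]) / temperature
        I_star = np.argmax(logits + rng.gumbel(size=logits.shape), axis=1)
        if np.log(rng.random()) < log_r:
            state.R[[j, d]] = state.R[[d, j]]
            state.S[[j, d]] = state.S[[d, j]]
            state.I = I_star
            return True
        return False


def run_mcmc(
    panel: ReferencePanel,
    reads,
    hp: Hyperparams,
    fp: FreqPrior,
    cfg: SamplerConfig,
) -> PosteriorSummary:
    """Sample the posterior and summarise the cold chain.

    Burn-in uses a multi-start warm-up and periodic reference copy; both
    break detailed balance and are confined to the burn-in period.
    """
    if len(reads) == 0:
        raise ValueError(
            "no accepted reads for this gene; inspect the filter log and thresholds"
        )
    model = GeneModel(panel, reads, hp, fp, cfg.n_decoy)
    rng = np.random.default_rng(cfg.seed)
    temps = cfg.temperatures

    # multi-start warm-up: short cold chains, best states seed the ladder
    seeds: list[tuple[float, ModelState]] = []
    for _ in range(max(cfg.n_multistart, len(temps))):
        st = model.initial_state(rng)
        for _ in range(cfg.multistart_sweeps):
            model.sweep(st, 1.0, rng)
        seeds.append((model.log_posterior(st), st))
    seeds.sort(key=lambda t: -t[0])
    chains = [seeds[c % len(seeds)][1].copy() for c in range(len(temps))]

    acc = {
        "uncovered": [0, 0],
        "decoy_swap": [0, 0],
        "temper_swap": [0, 0],
    }
    genotype_counts: Counter = Counter()
    seq_counts = np.zeros((2, model.n_cols, N_SYMBOLS), dtype=np.int64)
    trace: list[tuple[int, float, float, str]] = []
    last_mh_flags = "."
    n_samples = 0
    decoy_reads = 0
    total_assign = 0
    read_decoy_counts = np.zeros(len(reads), dtype=np.int64)

    total_sweeps = cfg.n_burnin + cfg.n_samples * cfg.thin
    for sweep_i in range(total_sweeps):
        in_burnin = sweep_i < cfg.n_burnin
        for c, temp in enumerate(temps):
            model.sweep(chains[c], temp, rng)
        if (sweep_i + 1) % cfg.mh_period == 0:
            for c, temp in enumerate(temps):
                flags = []
                for k in (0, 1):
                    ok = model.mh_uncovered_proposal(chains[c], k, temp, rng)
                    acc["uncovered"][0] += 1
                    acc["uncovered"][1] += int(ok)
                    flags.append(f"u{k + 1}:{int(ok)}")
                if cfg.n_decoy >= 1:
                    ok = model.mh_decoy_swap(chains[c], temp, rng)
                    acc["decoy_swap"][0] += 1
                    acc["decoy_swap"][1] += int(ok)
                    flags.append(f"d:{int(ok)}")
                if c == 0:
                    last_mh_flags = ",".join(flags)
        if len(temps) > 1 and (sweep_i + 1) % cfg.swap_period == 0:
            start = sweep_i % 2
            lps = [model.log_posterior(st) for st in chains]
            for c in range(start, len(temps) - 1, 2):
                d_beta = 1.0 / temps[c] - 1.0 / temps[c + 1]
                log_r = d_beta * (lps[c + 1] - lps[c])
                acc["temper_swap"][0] += 1
                if np.log(rng.random()) < log_r:
                    chains[c], chains[c + 1] = chains[c + 1], chains[c]
                    lps[c], lps[c + 1] = lps[c + 1], lps[c]
                    acc["temper_swap"][1] += 1
        if in_burnin and (sweep_i + 1) % cfg.ref_copy_period == 0:
            for st in chains:
                st.S = model.panel.ref[st.R].copy()
        if (sweep_i + 1) % cfg.trace_every == 0:
            trace.append((sweep_i + 1, model.log_posterior(chains[0]), temps[0], last_mh_flags))
            last_mh_flags = "."
        if not in_burnin and (sweep_i - cfg.n_burnin) % cfg.thin == 0:
            st = chains[0]
            pair = tuple(sorted((panel.names[st.R[0]], panel.names[st.R[1]])))
            genotype_counts[pair] += 1
            # label switching: match the sampled pair to the running consensus
            if n_samples > 0:
                cons = np.argmax(seq_counts, axis=2)
                m_id = int((st.S[0] != cons[0]).sum() + (st.S[1] != cons[1]).sum())
                m_sw = int((st.S[0] != cons[1]).sum() + (st.S[1] != cons[0]).sum())
                order = (1, 0) if m_sw < m_id else (0, 1)
            else:
                order = (0, 1)
            for slot, k in enumerate(order):
                seq_counts[slot, np.arange(model.n_cols), st.S[k]] += 1
            read_decoy_counts += (st.I >= 2)
            decoy_reads += int((st.I >= 2).sum())
            total_assign += len(st.I)
            n_samples += 1

    return PosteriorSummary(
        gene=panel.gene,
        names=list(panel.names),
        genotype_counts=genotype_counts,
        seq_counts=seq_counts,
        n_samples=n_samples,
        acceptance={k: tuple(v) for k, v in acc.items()},
        trace=trace,
        seed=cfg.seed,
        n_reads=len(reads),
        decoy_assigned_fraction=(decoy_reads / total_assign) if total_assign else 0.0,
        read_decoy_counts=read_decoy_counts,
    )


def call_genotype(summary: PosteriorSummary) -> list[tuple[str, str, float]]:
    """Rank unordered genotype pairs by sample count (ties lexicographic)."""
    if summary.n_samples == 0:
        raise ValueError("no posterior samples")
    items = sorted(summary.genotype_counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [(a, b, cnt / summary.n_samples) for (a, b), cnt in items]


def call_sequences(
    summary: PosteriorSummary, threshold: float = 0.9
) -> tuple[list[str], np.ndarray]:
    """Per-column modal symbols of the two inferred sequences with support.

    Columns whose modal fraction falls below ``threshold`` are reported as N.
    """
    if summary.n_samples == 0:
        raise ValueError("no posterior samples")
    counts = summary.seq_counts
    modal = np.argmax(counts, axis=2)
    support = np.take_along_axis(counts, modal[:, :, None], axis=2)[:, :, 0] / summary.n_samples
    out = []
    for k in range(2):
        syms = np.where(support[k] >= threshold, modal[k], np.int64(N))
        out.append("".join("ACGTN-"[s] for s in syms))
    return out, support
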