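"""Germline, somatic, and LOH calls from posterior consensus sequences.

Germline variants compare a sample consensus with the reference of its
called type; somatic mutations compare matched normal/tumor consensus
sequences; LOH evidence is a depth log odds ratio at heterozygous SNP
columns between the tumor and normal read sets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .alphabet import GAP_CHAR

_Z95 = 1.959963984540054


@dataclass(frozen=True)
class VariantCall:
    gene: str
    column: int  # 0-based MSA column
    kind: str  # substitution | deletion | insertion
    ref_symbol: str
    obs_symbol: str
    support: float
    imputed: bool

    def __post_init__(self) -> None:
        if self.ref_symbol == self.obs_symbol:
            raise ValueError("variant requires differing symbols")
        if not (0.0 <= self.support <= 1.0):
            raise ValueError("support must lie in [0,1]")


@dataclass(frozen=True)
class SomaticCall:
    gene: str
    column: int
    normal_symbol: str
    tumor_symbol: str
    normal_support: float
    tumor_support: float
    kind: str

    def __post_init__(self) -> None:
        if self.normal_symbol == self.tumor_symbol:
            raise ValueError("somatic call requires differing symbols")
        if "N" in (self.normal_symbol, self.tumor_symbol):
            raise ValueError("somatic call cannot involve N")


@dataclass
class LohColumn:
    column: int
    normal_counts: tuple[int, int]
    tumor_counts: tuple[int, int]
    log_or: float
    ci_low: float
    ci_high: float


@dataclass
class LohReport:
    gene: str
    flagged: bool
    reason: str | None
    columns: list[LohColumn]

    def mean_log_or(self) -> float:
        if not self.columns:
            return math.nan
        return float(np.mean([c.log_or for c in self.columns]))


def _kind(ref_symbol: str, obs_symbol: str) -> str:
    if obs_symbol == GAP_CHAR:
        return "deletion"
    if ref_symbol == GAP_CHAR:
        return "insertion"
    return "substitution"


def call_germline_variants(
    consensus: str,
    support: np.ndarray,
    reference: str,
    imputed_mask: np.ndarray,
    gene: str,
    min_support: float = 0.9,
) -> list[VariantCall]:
    """One call per column where consensus differs from the called type's
    reference, is not N, and is sufficiently supported."""
    if len(consensus) != len(reference):
        raise ValueError("consensus and reference must share the column space")
    calls = []
    for n, (c, r) in enumerate(zip(consensus, reference)):
        if c == r or c == "N":
            continue
        if support[n] < min_support:
            continue
        calls.append(
            VariantCall(gene, n, _kind(r, c), r, c, float(support[n]), bool(imputed_mask[n]))
        )
    return calls


def match_allele_pairs(
    normal_seqs: list[str], tumor_seqs: list[str]
) -> list[tuple[int, int]]:
    """Pair normal and tumor consensus sequences by minimal total mismatch."""
    def mism(a: str, b: str) -> int:
        return sum(1 for x, y in zip(a, b) if x != y)

    straight = mism(normal_seqs[0], tumor_seqs[0]) + mism(normal_seqs[1], tumor_seqs[1])
    crossed = mism(normal_seqs[0], tumor_seqs[1]) + mism(normal_seqs[1], tumor_seqs[0])
    return [(0, 0), (1, 1)] if straight <= crossed else [(0, 1), (1, 0)]


def call_somatic_mutations(
    normal_seqs: list[str],
    normal_support: np.ndarray,
    tumor_seqs: list[str],
    tumor_support: np.ndarray,
    gene: str,
    min_support: float = 0.9,
) -> list[SomaticCall]:
    """Columns where a matched normal/tumor sequence pair differs with high
    support on both sides and neither symbol is N."""
    if len(normal_seqs) != 2 or len(tumor_seqs) != 2:
        raise ValueError("expected two consensus sequences per sample")
    calls = []
    for ni, ti in match_allele_pairs(normal_seqs, tumor_seqs):
        for n, (a, b) in enumerate(zip(normal_seqs[ni], tumor_seqs[ti])):
            if a == b or "N" in (a, b):
                continue
            if normal_support[ni, n] < min_support or tumor_support[ti, n] < min_support:
                continue
            calls.append(
                SomaticCall(
                    gene, n, a, b,
                    float(normal_support[ni, n]), float(tumor_support[ti, n]),
                    _kind(a, b),
                )
            )
    return calls


def loh_log_odds(
    normal_counts: tuple[int, int],
    tumor_counts: tuple[int, int],
    pseudocount: float = 0.5,
) -> tuple[float, float, float]:
    """Log odds ratio of tumor vs normal allele depths with a Woolf 95% CI.

    With pseudocount ``c``: ``logOR = ln[((b1+c)/(b2+c)) / ((a1+c)/(a2+c))]``
    and ``CI = logOR ± 1.96·sqrt(Σ 1/(count+c))``. The CI construction is a
    reconstruction (normal approximation with Haldane-Anscombe correction);
    the source figures show 95% CIs without stating a formula.
    """
    a1, a2 = normal_counts
    b1, b2 = tumor_counts
    if min(a1, a2, b1, b2) < 0:
        raise ValueError("counts must be non-negative")
    c = pseudocount
    if c == 0.0 and (a1 + a2 == 0 or b1 + b2 == 0 or 0 in (a1, a2, b1, b2)):
        raise ValueError("zero counts undefined without pseudocount")
    # difference of logs keeps antisymmetry exact under label swap
    log_or = (math.log(b1 + c) - math.log(b2 + c)) - (math.log(a1 + c) - math.log(a2 + c))
    # fsum: summation-order-insensitive, so the CI mirrors exactly on swap
    se = math.sqrt(math.fsum([1 / (a1 + c), 1 / (a2 + c), 1 / (b1 + c), 1 / (b2 + c)]))
    return log_or, log_or - _Z95 * se, log_or + _Z95 * se


def heterozygous_snp_columns(seq1: str, seq2: str) -> list[int]:
    """Columns where the two called normal alleles carry different non-gap,
    non-N symbols."""
    return [
        n
        for n, (a, b) in enumerate(zip(seq1, seq2))
        if a != b and a in "ACGT" and b in "ACGT"
    ]


def snp_read_counts(reads, seq1: str, seq2: str, columns: list[int]) -> dict[int, tuple[int, int]]:
    """Reads supporting each allele's symbol at the given columns."""
    counts = {n: [0, 0] for n in columns}
    colset = set(columns)
    for read in reads:
        for pos, col in enumerate(read.cols):
            col = int(col)
            if col not in colset:
                continue
            ch = "ACGTN-"[read.syms[pos]]
            if ch == seq1[col]:
                counts[col][0] += 1
            elif ch == seq2[col]:
                counts[col][1] += 1
    return {n: (v[0], v[1]) for n, v in counts.items()}


def screen_loh(
    normal_genotype: list[tuple[str, str, float]],
    tumor_genotype: list[tuple[str, str, float]],
    uniqueness_threshold: float = 0.9,
) -> tuple[bool, str | None]:
    """Flag a gene for LOH follow-up.

    Condition (i): the normal genotype is uniquely determined but the tumor
    genotype is not. Condition (ii): both unique but different.
    """
    n_top = normal_genotype[0]
    t_top = tumor_genotype[0]
    n_unique = n_top[2] >= uniqueness_threshold
    t_unique = t_top[2] >= uniqueness_threshold
    if n_unique and not t_unique:
        return True, "normal-unique-tumor-ambiguous"
    if n_unique and t_unique and (n_top[0], n_top[1]) != (t_top[0], t_top[1]):
        return True, "unique-but-different"
    return False, None


def loh_report(
    gene: str,
    normal_genotype,
    tumor_genotype,
    normal_reads,
    tumor_reads,
    normal_seqs: list[str],
    pseudocount: float = 0.5,
    uniqueness_threshold: float = 0.9,
) -> LohReport:
    """Per-heterozygous-SNP depth log odds of the tumor against the normal."""
    flagged, reason = screen_loh(normal_genotype, tumor_genotype, uniqueness_threshold)
    het = heterozygous_snp_columns(normal_seqs[0], normal_seqs[1])
    n_counts = snp_read_counts(normal_reads, normal_seqs[0], normal_seqs[1], het)
    t_counts = snp_read_counts(tumor_reads, normal_seqs[0], normal_seqs[1], het)
    columns = []
    for n in het:
        lo, lo_l, lo_h = loh_log_odds(n_counts[n], t_counts[n], pseudocount)
        columns.append(LohColumn(n, n_counts[n], t_counts[n], lo, lo_l, lo_h))
    return LohReport(gene, flagged, reason, columns)


def pooled_log_odds(report: LohReport, pseudocount: float = 0.5) -> tuple[float, float, float]:
    """Log odds ratio over summed counts across all heterozygous columns."""
    a1 = sum(c.normal_counts[0] for c in report.columns)
    a2 = sum(c.normal_counts[1] for c in report.columns)
    b1 = sum(c.tumor_counts[0] for c in report.columns)
    b2 = sum(c.tumor_counts[1] for c in report.columns)
    return loh_log_odds((a1, a2), (b1, b2), pseudocount)
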