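"""Read scoring, filtering, and realignment into MSA columns.

Each candidate read is scored against every reference type with an
alignment-based log score (quality-weighted mismatches, affine gap
penalties, N penalty, and a per-base length reward). Reads whose best
target-gene score is high enough in absolute terms and relative to the
best non-target score are kept and realigned into the integrated MSA.

Natural logarithm throughout.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .alphabet import GAP, encode
from .model import mismatch_prob_from_qual
from .reference import IntegratedMsa, UnrepresentableInsertionError, project_alignment

logger = logging.getLogger(__name__)

_B = set("ACGT")
_BN = set("ACGTN")


@dataclass
class RawRead:
    """An input read (optionally paired) with per-base Phred qualities."""

    id: str
    bases: str
    quals: list[int]
    mate_bases: str | None = None
    mate_quals: list[int] | None = None

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise ValueError("bases and quals must have equal length")
        if (self.mate_bases is None) != (self.mate_quals is None):
            raise ValueError("mate bases and quals must be given together")
        if self.mate_bases is not None and len(self.mate_bases) != len(self.mate_quals):
            raise ValueError("mate bases and quals must have equal length")

    @property
    def is_paired(self) -> bool:
        return self.mate_bases is not None


@dataclass(frozen=True)
class ScoreParams:
    """Scoring constants: gap/N penalties, length reward, filter thresholds.

    The five alpha penalties are negative; ``beta`` is a positive per-base
    reward. Threshold defaults are package choices exposed in config.
    """

    alpha_del_open: float = -6.0
    alpha_del_ext: float = -1.0
    alpha_ins_open: float = -6.0
    alpha_ins_ext: float = -1.0
    alpha_N: float = -2.0
    beta: float = 0.25
    theta_u_m: float = -20.0
    theta_u_d: float = 2.0
    theta_p_m: float = -40.0
    theta_p_d: float = 0.0
    # DP mismatch cost uses this quality; chosen so a mismatch stays cheaper
    # than opening a gap and alignments do not turn errors into indels
    ref_quality: int = 20
    # alignment-search gap costs, deliberately stiffer than the alpha
    # penalties so the DP opens gaps only for real indels; the HR score of
    # the chosen alignment still uses the alpha values above
    dp_gap_open: float = -12.0
    dp_gap_ext: float = -8.0

    def __post_init__(self) -> None:
        for v in (self.alpha_del_open, self.alpha_del_ext, self.alpha_ins_open,
                  self.alpha_ins_ext, self.alpha_N):
            if v >= 0:
                raise ValueError("alpha penalties must be negative")
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.theta_p_m > self.theta_u_m:
            raise ValueError("theta_p_m must be <= theta_u_m")
        if self.theta_p_d > self.theta_u_d:
            raise ValueError("theta_p_d must be <= theta_u_d")


@dataclass
class TypeAlignment:
    """A pairwise read/type alignment in gapped-string form."""

    aligned_read: str
    aligned_type: str
    type_start: int  # 0-based offset into the type's ungapped sequence


@dataclass
class HrScoreTable:
    """Per-read scores against every type, with target-gene summaries."""

    read_id: str
    scores: dict[str, float]
    genes: dict[str, str]  # type name -> gene
    target_gene: str
    s_star: float = -math.inf
    s_bar_star: float = -math.inf
    best_type: str | None = None
    best_alignment: TypeAlignment | None = None
    alignments: dict[str, TypeAlignment] = field(default_factory=dict)
    anchor_placement: tuple[np.ndarray, str] | None = None  # MSA-anchored route

    def finalize(self) -> "HrScoreTable":
        for name in sorted(self.scores):
            s = self.scores[name]
            if self.genes[name] == self.target_gene:
                if s > self.s_star:  # strict: ties keep lexicographically first
                    self.s_star = s
                    self.best_type = name
            else:
                s_bar = s
                if s_bar > self.s_bar_star:
                    self.s_bar_star = s_bar
        if self.best_type is not None:
            self.best_alignment = self.alignments.get(self.best_type)
        return self


def mismatch_prob(q: int) -> float:
    """Phred quality to mismatch probability, ``10^(-q/10)``."""
    if q < 0:
        raise ValueError("quality must be non-negative")
    return 10.0 ** (-q / 10.0)


def hr_score(aligned_read: str, aligned_type: str, quals, params: ScoreParams) -> float:
    """Alignment log score of a read against one reference type.

    ``quals`` holds one Phred value per read base (non-gap read symbol),
    consumed left to right. Case priority per column: base/base mismatch,
    read gap (deletion), type gap (insertion), N vs anything, else 0;
    every column with a read symbol additionally earns ``beta``.
    """
    if len(aligned_read) != len(aligned_type):
        raise ValueError("aligned strings must have equal length")
    score = 0.0
    qi = 0
    for n, (x, t) in enumerate(zip(aligned_read, aligned_type)):
        if x == "-" and t == "-":
            raise ValueError("column with gap in both read and type")
        p = None
        if x != "-":
            p = mismatch_prob(quals[qi])
            qi += 1
        if x in _B and t in _B and x != t:
            score += math.log(p / 3.0)
        elif x == "-":
            prev = aligned_read[n - 1] if n > 0 else ""
            score += params.alpha_del_ext if prev == "-" else params.alpha_del_open
        elif t == "-":
            prev = aligned_type[n - 1] if n > 0 else ""
            score += params.alpha_ins_ext if prev == "-" else params.alpha_ins_open
        elif (x == "N" and t in _BN) or (x in _BN and t == "N"):
            score += params.alpha_N
        if x in _BN:
            score += params.beta
    return score


def make_aligner(params: ScoreParams) -> Align.PairwiseAligner:
    """Affine-gap semi-global aligner with costs induced by the score formula.

    Mismatch cost uses the reference quality (actual qualities are applied
    afterwards by :func:`hr_score` on the chosen alignment). Target = type,
    query = read; end gaps in the query (type overhang) are free.
    """
    p_ref = mismatch_prob(params.ref_quality)
    letters = "ACGTN"
    mat = substitution_matrices.Array(letters, dims=2)
    for a in letters:
        for b in letters:
            if a == "N" or b == "N":
                mat[a, b] = params.alpha_N + params.beta
            elif a == b:
                mat[a, b] = params.beta
            else:
                mat[a, b] = math.log(p_ref / 3.0) + params.beta
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = mat
    # gap in target (= type) is an insertion in the read; gap in query
    # (= read) is a deletion; end deletions (type overhang) are free.
    # Reads must be contained in the type, so end insertions (read overhang)
    # are effectively forbidden rather than letting noisy tails gap out.
    aligner.open_internal_insertion_score = params.dp_gap_open + params.beta
    aligner.extend_internal_insertion_score = params.dp_gap_ext + params.beta
    aligner.open_left_insertion_score = -1e6
    aligner.extend_left_insertion_score = -1e6
    aligner.open_right_insertion_score = -1e6
    aligner.extend_right_insertion_score = -1e6
    aligner.open_internal_deletion_score = params.dp_gap_open
    aligner.extend_internal_deletion_score = params.dp_gap_ext
    aligner.end_deletion_score = 0.0
    return aligner


def align_to_type(read_bases: str, type_seq: str, aligner: Align.PairwiseAligner) -> TypeAlignment:
    """Best semi-global alignment of a read to one type's ungapped sequence.

    Insertion runs at the alignment edges (a DP artefact of free end
    deletions absorbing noisy read tails) are flattened back onto the
    adjacent reference bases so that reads stay contained in the type.
    """
    aln = aligner.align(type_seq, read_bases)[0]
    t_gapped = str(aln[0])
    r_gapped = str(aln[1])
    # trim end columns where the read is absent (type overhang)
    start = 0
    end = len(r_gapped)
    while start < end and r_gapped[start] == "-":
        start += 1
    while end > start and r_gapped[end - 1] == "-":
        end -= 1
    t_start = sum(1 for ch in t_gapped[:start] if ch != "-")
    r_al, t_al = r_gapped[start:end], t_gapped[start:end]
    # flatten trailing read-insertion run onto the following reference bases
    k = 0
    while k < len(t_al) and t_al[-1 - k] == "-":
        k += 1
    if k:
        consumed = t_start + sum(1 for ch in t_al if ch != "-")
        avail = min(k, len(type_seq) - consumed)
        if avail:
            t_al = t_al[: len(t_al) - k] + type_seq[consumed : consumed + avail] + "-" * (k - avail)
    # flatten leading read-insertion run onto the preceding reference bases
    k = 0
    while k < len(t_al) and t_al[k] == "-":
        k += 1
    if k:
        avail = min(k, t_start)
        if avail:
            t_al = type_seq[t_start - avail : t_start] + "-" * (k - avail) + t_al[k:]
            t_start -= avail
    return TypeAlignment(r_al, t_al, t_start)


def score_read_against_db(
    read_bases: str,
    quals,
    db: list[tuple[str, str, str]],
    target_gene: str,
    params: ScoreParams,
    read_id: str = "read",
    aligner: Align.PairwiseAligner | None = None,
) -> HrScoreTable:
    """Score one read against every type in ``db`` (gene, name, ungapped seq).

    The default route aligns the read to each type with the built-in
    affine-gap aligner and evaluates the exact score on the chosen alignment.
    """
    if not db:
        raise ValueError("reference database is empty")
    if aligner is None:
        aligner = make_aligner(params)
    table = HrScoreTable(read_id, {}, {}, target_gene)
    for gene, name, seq in db:
        ta = align_to_type(read_bases, seq, aligner)
        table.scores[name] = hr_score(ta.aligned_read, ta.aligned_type, quals, params)
        table.genes[name] = gene
        table.alignments[name] = ta
    return table.finalize()


# ----------------------------------------------------------- MSA-anchored path


def _column_scores(
    read_chars: str,
    quals_by_col: np.ndarray,
    type_rows: np.ndarray,
    params: ScoreParams,
) -> np.ndarray:
    """Vectorized score of one column-placed read against many allele rows.

    ``type_rows`` is (A, m) of symbol codes over the read's columns; the read
    is fixed, so read-gap terms are shared while type-gap runs differ per row.
    """
    m = len(read_chars)
    read = encode(read_chars)
    A = type_rows.shape[0]
    read_base = read < 4
    read_n = read == 4
    read_gap = read == GAP
    with np.errstate(divide="ignore"):
        logp3 = np.where(read_base, np.log(mismatch_prob_from_qual(quals_by_col) / 3.0), 0.0)
    type_base = type_rows < 4
    type_n = type_rows == 4
    type_gap = type_rows == GAP
    mismatch = read_base[None, :] & type_base & (type_rows != read[None, :])
    # read-gap (deletion) terms: run structure from the read only; columns
    # where the allele row is also gapped contribute nothing
    prev_gap = np.zeros(m, dtype=bool)
    prev_gap[1:] = read_gap[:-1]
    del_val = np.where(read_gap, np.where(prev_gap, params.alpha_del_ext, params.alpha_del_open), 0.0)
    del_term = (del_val[None, :] * ~type_gap).sum(axis=1)
    # type-gap (insertion) terms per row; not applicable where the read gaps too
    tg = type_gap & ~read_gap[None, :]
    tg_prev = np.zeros_like(type_gap)
    tg_prev[:, 1:] = type_gap[:, :-1]
    ins_term = np.where(tg, np.where(tg_prev, params.alpha_ins_ext, params.alpha_ins_open), 0.0)
    n_term = (
        (read_n[None, :] & (type_base | type_n)) | (read_base[None, :] & type_n)
    ) & ~tg & ~read_gap[None, :]
    score = (
        (mismatch * logp3[None, :]).sum(axis=1)
        + del_term
        + ins_term.sum(axis=1)
        + n_term.sum(axis=1) * params.alpha_N
        + (~read_gap).sum() * params.beta
    )
    return score


def score_read_msa_anchored(
    read_bases: str,
    quals,
    msas: dict[str, IntegratedMsa],
    anchors: dict[str, str],
    target_gene: str,
    params: ScoreParams,
    read_id: str = "read",
    aligner: Align.PairwiseAligner | None = None,
) -> HrScoreTable:
    """Fast scoring: one alignment per gene to an anchor allele, then score
    every allele of that gene through the shared MSA columns.

    Exact when alleles are column-aligned (no read-specific indels against
    non-anchor alleles); used by the pipeline for throughput. The per-type
    DP route remains the reference implementation.
    """
    if not msas:
        raise ValueError("reference database is empty")
    if aligner is None:
        aligner = make_aligner(params)
    table = HrScoreTable(read_id, {}, {}, target_gene)
    for gene, msa in msas.items():
        anchor = anchors[gene]
        ta = align_to_type(read_bases, msa.degapped(anchor), aligner)
        try:
            cols, read_chars = project_alignment(
                msa, anchor, ta.aligned_read, ta.aligned_type, ta.type_start
            )
        except UnrepresentableInsertionError:
            for name in msa.names:
                table.scores[name] = -math.inf
                table.genes[name] = gene
            continue
        quals_by_col = np.zeros(len(read_chars))
        qi = 0
        for j, ch in enumerate(read_chars):
            if ch != "-":
                quals_by_col[j] = quals[qi]
                qi += 1
        rows = np.stack([msa.encoded(n)[cols] for n in msa.names])
        scores = _column_scores(read_chars, quals_by_col, rows, params)
        for name, s in zip(msa.names, scores):
            table.scores[name] = float(s)
            table.genes[name] = gene
        if gene == target_gene:
            table.anchor_placement = (cols, read_chars)
    return table.finalize()


# ------------------------------------------------------------------- filtering


@dataclass
class FilterRecord:
    read_id: str
    paired: bool
    s_star: float
    s_bar_star: float
    accepted: bool


def filter_reads(
    entries: list[tuple[HrScoreTable, ...]],
    params: ScoreParams,
) -> tuple[list[int], list[FilterRecord]]:
    """Accept/reject decisions; one entry per read (singleton) or pair (2-tuple).

    Unpaired: ``s* > theta_u_m`` and ``s* - s_bar* > theta_u_d`` (strict).
    Paired: the summed inequalities with the paired thresholds. ``-inf``
    never passes. Returns indices of accepted entries and a log.
    """
    accepted: list[int] = []
    log: list[FilterRecord] = []
    for idx, tables in enumerate(entries):
        if len(tables) == 1:
            t = tables[0]
            s, sbar = t.s_star, t.s_bar_star
            ok = s > params.theta_u_m and (s - sbar) > params.theta_u_d
            paired = False
            rid = t.read_id
        else:
            t1, t2 = tables
            s = t1.s_star + t2.s_star
            sbar = t1.s_bar_star + t2.s_bar_star
            ok = s > params.theta_p_m and (s - sbar) > params.theta_p_d
            paired = True
            rid = t1.read_id
        if math.isinf(s) and s < 0:
            ok = False
        log.append(FilterRecord(rid, paired, s, sbar, bool(ok)))
        if ok:
            accepted.append(idx)
    return accepted, log


# ----------------------------------------------------------------- realignment


@dataclass
class PlacedRead:
    """A read (or concatenated pair) in MSA columns with qualities.

    ``cols`` are the covered MSA columns (sorted, unique); ``syms`` the read
    symbol codes there ('-' for read deletions); ``quals`` per-position Phred
    values (0 at read-gap positions, where quality is unused).
    """

    id: str
    cols: np.ndarray
    syms: np.ndarray
    quals: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.cols) == len(self.syms) == len(self.quals)):
            raise ValueError("cols, syms, quals must have equal length")

    @property
    def n_covered(self) -> int:
        return len(self.cols)


def _place_single(
    msa: IntegratedMsa, best_type: str, ta: TypeAlignment, quals
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    cols, read_chars = project_alignment(
        msa, best_type, ta.aligned_read, ta.aligned_type, ta.type_start
    )
    syms = encode(read_chars)
    q = np.zeros(len(read_chars), dtype=np.int16)
    qi = 0
    for j, ch in enumerate(read_chars):
        if ch != "-":
            q[j] = quals[qi]
            qi += 1
    order = np.argsort(cols, kind="stable")
    return cols[order], syms[order], q[order]


def realign_accepted(
    reads: list[RawRead],
    entries: list[tuple[HrScoreTable, ...]],
    accepted: list[int],
    msa: IntegratedMsa,
) -> tuple[list[PlacedRead], int]:
    """Project accepted reads into MSA columns via their best target type.

    Mates are concatenated into one record; columns between mates stay
    uncovered; overlapping mate columns keep the first mate's observation.
    Reads with unrepresentable insertions are dropped (counted).
    """
    placed: list[PlacedRead] = []
    n_dropped = 0
    for idx in accepted:
        tables = entries[idx]
        read = reads[idx]
        try:
            parts = []
            quals_parts = [read.quals] + ([read.mate_quals] if read.is_paired else [])
            for t, q in zip(tables, quals_parts):
                if t.anchor_placement is not None:
                    cols, read_chars = t.anchor_placement
                    syms = encode(read_chars)
                    qv = np.zeros(len(read_chars), dtype=np.int16)
                    qi = 0
                    for j, ch in enumerate(read_chars):
                        if ch != "-":
                            qv[j] = q[qi]
                            qi += 1
                    order = np.argsort(cols, kind="stable")
                    parts.append((cols[order], syms[order], qv[order]))
                    continue
                if t.best_type is None or t.best_alignment is None:
                    raise UnrepresentableInsertionError("no target-gene alignment")
                parts.append(_place_single(msa, t.best_type, t.best_alignment, q))
        except UnrepresentableInsertionError:
            n_dropped += 1
            continue
        cols = np.concatenate([p[0] for p in parts])
        syms = np.concatenate([p[1] for p in parts])
        quals = np.concatenate([p[2] for p in parts])
        # deduplicate overlapping mate columns, keeping the first occurrence
        _, first = np.unique(cols, return_index=True)
        first.sort()
        placed.append(PlacedRead(read.id, cols[first], syms[first], quals[first]))
    if n_dropped:
        logger.warning("dropped %d reads with unrepresentable insertions", n_dropped)
    return placed, n_dropped


# ----------------------------------------------------- external alignments


def _gapped_from_cigar(rec, ref_seq: str) -> tuple[str, str, int] | None:
    """Rebuild (aligned_read, aligned_type, type_start) from a SAM record.

    Soft-clipped read bases are excluded from the scored columns.
    """
    if rec.is_unmapped or rec.cigartuples is None:
        return None
    read = rec.query_sequence
    if read is None:
        return None
    r_parts: list[str] = []
    t_parts: list[str] = []
    qpos = 0
    rpos = rec.reference_start
    t_start = rec.reference_start
    for op, length in rec.cigartuples:
        if op in (0, 7, 8):  # M/=/X
            r_parts.append(read[qpos : qpos + length])
            t_parts.append(ref_seq[rpos : rpos + length])
            qpos += length
            rpos += length
        elif op == 1:  # I
            r_parts.append(read[qpos : qpos + length])
            t_parts.append("-" * length)
            qpos += length
        elif op in (2, 3):  # D/N
            r_parts.append("-" * length)
            t_parts.append(ref_seq[rpos : rpos + length])
            rpos += length
        elif op == 4:  # S: excluded from scoring
            qpos += length
        elif op == 5:  # H
            continue
        else:  # pragma: no cover - unsupported op
            return None
    return "".join(r_parts), "".join(t_parts), t_start


def score_reads_from_alignments(
    alignment_path,
    quals_by_read: dict[str, list[int]],
    db: list[tuple[str, str, str]],
    target_gene: str,
    params: ScoreParams,
) -> dict[str, HrScoreTable]:
    """Score reads from an external all-hits alignment file (e.g. bwa -a).

    Reference names in the file must be type names present in ``db``
    (gene, name, ungapped sequence). A type without any alignment record
    for a read keeps score -inf. Soft-clipped bases are excluded from the
    scored columns; qualities come from ``quals_by_read`` keyed by read id
    (secondary records often omit quality strings).
    """
    import pysam  # local import: only this route needs it

    seqs = {name: seq for _gene, name, seq in db}
    genes = {name: gene for gene, name, _seq in db}
    tables: dict[str, HrScoreTable] = {}
    with pysam.AlignmentFile(str(alignment_path), check_sq=False) as fh:
        for rec in fh.fetch(until_eof=True):
            if rec.is_unmapped or rec.reference_name not in seqs:
                continue
            rid = rec.query_name
            built = _gapped_from_cigar(rec, seqs[rec.reference_name])
            if built is None:
                continue
            aligned_read, aligned_type, t_start = built
            quals = quals_by_read.get(rid)
            if quals is None:
                continue
            # map qualities onto the aligned (non-soft-clipped) read bases
            clip_left = 0
            if rec.cigartuples and rec.cigartuples[0][0] == 4:
                clip_left = rec.cigartuples[0][1]
            n_bases = sum(1 for ch in aligned_read if ch != "-")
            q = quals[clip_left : clip_left + n_bases]
            score = hr_score(aligned_read, aligned_type, q, params)
            table = tables.get(rid)
            if table is None:
                table = HrScoreTable(rid, {}, {}, target_gene)
                tables[rid] = table
            name = rec.reference_name
            if score > table.scores.get(name, -math.inf):
                table.scores[name] = score
                table.genes[name] = genes[name]
                table.alignments[name] = TypeAlignment(aligned_read, aligned_type, t_start)
    for table in tables.values():
        for _gene, name, _seq in db:
            table.scores.setdefault(name, -math.inf)
            table.genes.setdefault(name, genes[name])
        table.finalize()
    return tables
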