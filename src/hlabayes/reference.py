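"""Integrated per-gene reference alignments.

Genomic (full-length) and exonic-only allele alignments are merged into one
column space. Exonic-only alleles keep their own exon symbols; non-coding
columns are imputed from the most similar genomic allele and flagged so that
downstream priors can distrust them.

Coordinates: MSA columns are 0-based in the API; all text outputs are
1-based closed intervals. Gap character is '-', unknown is 'N'.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .alphabet import encode
from .model import ReferencePanel

_NAME_RE = re.compile(r"^[A-Z0-9]+\*\d+(?::\d+){0,3}[A-Z]?$")
_ALPHABET = set("ACGTN-")


class AlignmentInconsistencyError(ValueError):
    """Exonic alignment cannot be reconciled with the genomic exon blocks."""


class UnrepresentableInsertionError(ValueError):
    """A read insertion has no accommodating gap column in the MSA."""


@dataclass(frozen=True)
class Allele:
    """One reference allele in its source alignment."""

    gene: str
    name: str
    level: str  # "genomic" | "exonic"
    raw_sequence: str

    def __post_init__(self) -> None:
        if self.level not in ("genomic", "exonic"):
            raise ValueError(f"level must be genomic/exonic, got {self.level!r}")
        if not self.raw_sequence:
            raise ValueError("raw_sequence must be non-empty")
        bad = set(self.raw_sequence) - _ALPHABET
        if bad:
            raise ValueError(f"sequence contains symbols outside ACGTN-: {bad}")
        if not _NAME_RE.match(self.name):
            raise ValueError(f"allele name does not parse: {self.name!r}")


@dataclass
class IntegratedMsa:
    """Per-gene unified column space for all alleles.

    ``alleles`` maps name -> aligned sequence of length ``n_columns``;
    ``imputed`` maps name -> boolean vector marking imputed columns.
    """

    gene: str
    names: list[str]
    alleles: dict[str, str]
    feature_map: list[str]
    imputed: dict[str, np.ndarray]
    levels: dict[str, str] = field(default_factory=dict)

    @property
    def n_columns(self) -> int:
        return len(self.feature_map)

    def sequence(self, name: str) -> str:
        return self.alleles[name]

    def encoded(self, name: str) -> np.ndarray:
        return encode(self.alleles[name])

    def degapped(self, name: str) -> str:
        return self.alleles[name].replace("-", "")

    def exon_columns(self) -> np.ndarray:
        return np.array([f.startswith("exon") for f in self.feature_map], dtype=bool)

    def panel(self) -> ReferencePanel:
        ref = np.stack([encode(self.alleles[n]) for n in self.names])
        mask = np.stack([self.imputed[n] for n in self.names])
        return ReferencePanel(self.gene, list(self.names), ref, mask)

    # ---------------------------------------------------------------- I/O

    def write(self, directory: str | Path) -> None:
        """Write aligned FASTA, a feature/metadata TSV, and the imputation mask."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        with open(directory / f"{self.gene}.aln.fasta", "w") as fh:
            for name in self.names:
                fh.write(f">{name}\n{self.alleles[name]}\n")
        with open(directory / f"{self.gene}.meta.tsv", "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["gene", "allele", "level"])
            for name in self.names:
                w.writerow([self.gene, name, self.levels.get(name, "genomic")])
        with open(directory / f"{self.gene}.features.tsv", "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["column", "feature"])
            for i, feat in enumerate(self.feature_map):
                w.writerow([i + 1, feat])
        with open(directory / f"{self.gene}.mask.tsv", "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["allele", "column", "imputed"])
            for name in self.names:
                mask = self.imputed[name]
                for col in np.flatnonzero(mask):
                    w.writerow([name, int(col) + 1, 1])

    @classmethod
    def read(cls, directory: str | Path, gene: str) -> "IntegratedMsa":
        directory = Path(directory)
        names: list[str] = []
        alleles: dict[str, str] = {}
        name = None
        chunks: list[str] = []
        with open(directory / f"{gene}.aln.fasta") as fh:
            for line in fh:
                line = line.strip()
                if line.startswith(">"):
                    if name is not None:
                        alleles[name] = "".join(chunks)
                    name = line[1:].split()[0]
                    names.append(name)
                    chunks = []
                elif line:
                    chunks.append(line)
            if name is not None:
                alleles[name] = "".join(chunks)
        feature_map: list[str] = []
        with open(directory / f"{gene}.features.tsv") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                feature_map.append(row["feature"])
        levels: dict[str, str] = {}
        with open(directory / f"{gene}.meta.tsv") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                levels[row["allele"]] = row["level"]
        n = len(feature_map)
        imputed = {nm: np.zeros(n, dtype=bool) for nm in names}
        mask_path = directory / f"{gene}.mask.tsv"
        if mask_path.exists():
            with open(mask_path) as fh:
                for row in csv.DictReader(fh, delimiter="\t"):
                    if int(row["imputed"]):
                        imputed[row["allele"]][int(row["column"]) - 1] = True
        return cls(gene, names, alleles, feature_map, imputed, levels)


def _exon_blocks(feature_map: list[str]) -> list[tuple[str, int, int]]:
    """Contiguous (label, start, stop) runs of exon-labelled columns, in order."""
    blocks: list[tuple[str, int, int]] = []
    i = 0
    n = len(feature_map)
    while i < n:
        if feature_map[i].startswith("exon"):
            label = feature_map[i]
            j = i
            while j < n and feature_map[j] == label:
                j += 1
            blocks.append((label, i, j))
            i = j
        else:
            i += 1
    return blocks


def impute_noncoding(
    target_seq: list[str] | str,
    defined: np.ndarray,
    donors: list[tuple[str, str]],
) -> tuple[str, np.ndarray, str]:
    """Fill undefined columns of ``target_seq`` from the most similar donor.

    Similarity is the count of identical non-gap symbols over columns where
    the target is defined; ties break by lexicographic donor name so builds
    are deterministic. Returns (filled sequence, imputed mask, donor name).
    """
    if not donors:
        raise ValueError("impute_noncoding requires at least one genomic donor")
    target = list(target_seq)
    defined = np.asarray(defined, dtype=bool)
    best_name, best_seq, best_score = None, None, -1
    for name, seq in sorted(donors, key=lambda d: d[0]):
        score = sum(
            1
            for i in np.flatnonzero(defined)
            if target[i] == seq[i] and target[i] != "-"
        )
        if score > best_score:
            best_name, best_seq, best_score = name, seq, score
    mask = ~defined
    for i in np.flatnonzero(mask):
        target[i] = best_seq[i]
    return "".join(target), mask, best_name


def build_integrated_msa(
    genomic_alleles: list[Allele],
    exonic_alleles: list[Allele],
    feature_map: list[str],
    exon_widths: list[int] | None = None,
) -> IntegratedMsa:
    """Merge genomic and exonic alignments into one column space.

    ``feature_map`` annotates each genomic-MSA column. Exonic alignments are
    the concatenation of exon blocks; when an exonic block is wider than the
    genomic one, gap columns are appended to the genomic exon block (and vice
    versa the exonic block is gap-padded), keeping relative symbol order.
    """
    genes = {a.gene for a in genomic_alleles} | {a.gene for a in exonic_alleles}
    if len(genes) != 1:
        raise ValueError(f"alleles span multiple genes: {sorted(genes)}")
    gene = genes.pop()
    if not genomic_alleles:
        raise ValueError("at least one genomic allele is required")
    gen_len = len(feature_map)
    for a in genomic_alleles:
        if len(a.raw_sequence) != gen_len:
            raise AlignmentInconsistencyError(
                f"genomic allele {a.name} length {len(a.raw_sequence)} != feature map {gen_len}"
            )
    blocks = _exon_blocks(feature_map)
    gen_widths = [stop - start for _, start, stop in blocks]
    if exonic_alleles:
        exo_len = len(exonic_alleles[0].raw_sequence)
        for a in exonic_alleles:
            if len(a.raw_sequence) != exo_len:
                raise AlignmentInconsistencyError("exonic alleles have unequal aligned lengths")
        if exon_widths is None:
            if exo_len != sum(gen_widths):
                raise AlignmentInconsistencyError(
                    "exonic alignment length does not match genomic exon blocks; "
                    "pass exon_widths explicitly"
                )
            exon_widths = list(gen_widths)
        if len(exon_widths) != len(blocks):
            raise AlignmentInconsistencyError("exon count mismatch between alignments")
        if sum(exon_widths) != exo_len:
            raise AlignmentInconsistencyError("exon_widths do not sum to exonic alignment length")
    else:
        exon_widths = list(gen_widths)

    # Integrated width per exon block; extra columns appended at block end.
    out_feature: list[str] = []
    # per genomic column -> slices into integrated space
    col_plan: list[tuple[str, int, int, int]] = []  # (label, gen_start, gen_stop, pad)
    cursor = 0
    exon_idx = 0
    n = gen_len
    i = 0
    insert_plan: list[tuple[int, int, str]] = []  # (gen_col_after, n_pad, label)
    while i < n:
        feat = feature_map[i]
        if feat.startswith("exon"):
            label, start, stop = blocks[exon_idx]
            width = stop - start
            target_width = max(width, exon_widths[exon_idx])
            out_feature.extend([label] * target_width)
            if target_width > width:
                insert_plan.append((stop, target_width - width, label))
            exon_idx += 1
            i = stop
        else:
            out_feature.append(feat)
            i += 1
    # map: build integrated genomic sequences by inserting pad gaps after blocks
    pads = {pos: pad for pos, pad, _ in insert_plan}

    def widen(seq: str) -> str:
        out = []
        for j, ch in enumerate(seq):
            out.append(ch)
            if j + 1 in pads:
                out.append("-" * pads[j + 1])
        if 0 in pads:  # pragma: no cover - defensive
            out.insert(0, "-" * pads[0])
        return "".join(out)

    n_out = len(out_feature)
    names: list[str] = []
    alleles: dict[str, str] = {}
    imputed: dict[str, np.ndarray] = {}
    levels: dict[str, str] = {}
    donors: list[tuple[str, str]] = []
    for a in genomic_alleles:
        seq = widen(a.raw_sequence)
        assert len(seq) == n_out
        names.append(a.name)
        alleles[a.name] = seq
        imputed[a.name] = np.zeros(n_out, dtype=bool)
        levels[a.name] = "genomic"
        donors.append((a.name, seq))

    # integrated exon column ranges in output space
    out_blocks = _exon_blocks(out_feature)
    for a in exonic_alleles:
        target = ["-"] * n_out
        defined = np.zeros(n_out, dtype=bool)
        off = 0
        for (label, start, stop), width in zip(out_blocks, exon_widths):
            chunk = a.raw_sequence[off : off + width]
            off += width
            chunk = chunk + "-" * ((stop - start) - len(chunk))
            for j, ch in enumerate(chunk):
                target[start + j] = ch
                defined[start + j] = True
        filled, mask, _donor = impute_noncoding(target, defined, donors)
        names.append(a.name)
        alleles[a.name] = filled
        imputed[a.name] = mask
        levels[a.name] = "exonic"

    return IntegratedMsa(gene, names, alleles, out_feature, imputed, levels)


def project_alignment(
    msa: IntegratedMsa,
    allele_name: str,
    aligned_read: str,
    aligned_allele: str,
    start_offset: int,
) -> tuple[np.ndarray, str]:
    """Place a read/allele pairwise alignment into MSA columns.

    ``aligned_allele`` degapped must be a substring of the allele's degapped
    sequence starting at ``start_offset`` (0-based). Returns the MSA column of
    each alignment column (read gaps included) and the read string. Read
    insertions are placed into gap columns of the allele when available;
    otherwise an :class:`UnrepresentableInsertionError` is raised.
    """
    if len(aligned_read) != len(aligned_allele):
        raise ValueError("aligned strings must have equal length")
    row = msa.sequence(allele_name)
    if aligned_allele.replace("-", "") != row.replace("-", "")[
        start_offset : start_offset + len(aligned_allele.replace("-", ""))
    ]:
        raise ValueError("aligned_allele is not a substring of the allele at start_offset")
    # column index of each ungapped allele position
    base_cols = [i for i, ch in enumerate(row) if ch != "-"]
    pos = start_offset  # next ungapped allele position to consume
    cols: list[int] = []
    read_chars: list[str] = []
    for rch, ach in zip(aligned_read, aligned_allele):
        if ach != "-":
            col = base_cols[pos]
            pos += 1
            cols.append(col)
            read_chars.append(rch)
        else:
            # insertion relative to the allele: need a gap column in this
            # allele strictly between the previous and next consumed columns.
            prev_col = cols[-1] if cols else (base_cols[pos - 1] if pos > 0 else -1)
            next_col = base_cols[pos] if pos < len(base_cols) else msa.n_columns
            found = None
            for c in range(prev_col + 1, next_col):
                if row[c] == "-" and c not in cols:
                    found = c
                    break
            if found is None:
                raise UnrepresentableInsertionError(
                    f"insertion at read position {len(read_chars)} has no gap column"
                )
            cols.append(found)
            read_chars.append(rch)
    return np.asarray(cols, dtype=np.int64), "".join(read_chars)
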