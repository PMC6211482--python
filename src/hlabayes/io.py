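"""Plain-text I/O: FASTQ reads, report tables, manifests, candidate extraction.

All outputs are tab-separated text or JSON; column schemas are documented in
FORMATS.md at the repository root. Coordinates in files are 1-based.
"""

from __future__ import annotations

import csv
import hashlib
import json
from pathlib import Path

import numpy as np
import pysam

from .scoring import FilterRecord, PlacedRead, RawRead

__version__ = "0.1.0"


# ----------------------------------------------------------------- FASTQ


def write_fastq_pairs(reads: list[RawRead], path1: str | Path, path2: str | Path) -> None:
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for r in reads:
            q1 = "".join(chr(q + 33) for q in r.quals)
            f1.write(f"@{r.id}/1\n{r.bases}\n+\n{q1}\n")
            if r.is_paired:
                q2 = "".join(chr(q + 33) for q in r.mate_quals)
                f2.write(f"@{r.id}/2\n{r.mate_bases}\n+\n{q2}\n")


def _read_fastq(path: str | Path) -> dict[str, tuple[str, list[int]]]:
    out: dict[str, tuple[str, list[int]]] = {}
    with open(path) as fh:
        while True:
            header = fh.readline().strip()
            if not header:
                break
            bases = fh.readline().strip()
            fh.readline()
            quals = fh.readline().strip()
            rid = header[1:].split()[0]
            if rid.endswith("/1") or rid.endswith("/2"):
                rid = rid[:-2]
            out[rid] = (bases, [ord(c) - 33 for c in quals])
    return out


def read_fastq_pairs(path1: str | Path, path2: str | Path | None = None) -> list[RawRead]:
    first = _read_fastq(path1)
    second = _read_fastq(path2) if path2 is not None else {}
    reads = []
    for rid, (bases, quals) in first.items():
        mate = second.get(rid)
        if mate is not None:
            reads.append(RawRead(rid, bases, quals, mate[0], mate[1]))
        else:
            reads.append(RawRead(rid, bases, quals))
    return reads


# ------------------------------------------------------------ candidate reads


def parse_region(spec: str) -> tuple[str, int, int]:
    """Parse ``chrom:start-end`` with optional thousands separators."""
    chrom, _, rest = spec.partition(":")
    start, _, end = rest.partition("-")
    return chrom, int(start.replace(",", "")), int(end.replace(",", ""))


def extract_candidate_reads(alignment_path: str | Path, region_spec: str) -> list[RawRead]:
    """Reads overlapping the region, unmapped reads, and mates of selected
    reads, paired up and deduplicated by (id, mate flag)."""
    chrom, start, end = parse_region(region_spec)
    selected: dict[tuple[str, bool], tuple[str, list[int]]] = {}
    wanted: set[str] = set()
    records = []
    with pysam.AlignmentFile(str(alignment_path), check_sq=False) as fh:
        for rec in fh.fetch(until_eof=True):
            if rec.is_secondary or rec.is_supplementary:
                continue
            records.append(
                (
                    rec.query_name,
                    bool(rec.is_read2),
                    rec.query_sequence or "",
                    list(rec.query_qualities or []),
                    rec.is_unmapped,
                    rec.reference_name,
                    rec.reference_start,
                    rec.reference_end,
                )
            )
    for name, is_r2, seq, quals, unmapped, ref, rstart, rend in records:
        hit = unmapped or (
            ref == chrom and rstart is not None and rend is not None
            and rstart < end and rend > start
        )
        if hit:
            wanted.add(name)
    for name, is_r2, seq, quals, unmapped, ref, rstart, rend in records:
        if name in wanted and (name, is_r2) not in selected and seq:
            selected[(name, is_r2)] = (seq, quals)
    reads: list[RawRead] = []
    for name in sorted(wanted):
        r1 = selected.get((name, False))
        r2 = selected.get((name, True))
        if r1 and r2:
            reads.append(RawRead(name, r1[0], r1[1], r2[0], r2[1]))
        elif r1:
            reads.append(RawRead(name, r1[0], r1[1]))
        elif r2:
            reads.append(RawRead(name, r2[0], r2[1]))
    return reads


# ----------------------------------------------------------------- reports


def write_genotype_table(path: str | Path, gene: str, ranked: list[tuple[str, str, float]]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["gene", "rank", "allele1", "allele2", "posterior_fraction"])
        for rank, (a, b, frac) in enumerate(ranked, start=1):
            w.writerow([gene, rank, a, b, f"{frac:.6f}"])


def read_genotype_table(path: str | Path) -> list[tuple[str, str, float]]:
    out = []
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out.append((row["allele1"], row["allele2"], float(row["posterior_fraction"])))
    return out


def write_consensus(
    fasta_path: str | Path, support_path: str | Path, gene: str,
    seqs: list[str], support: np.ndarray,
) -> None:
    with open(fasta_path, "w") as fh:
        for k, seq in enumerate(seqs, start=1):
            fh.write(f">{gene}_seq{k}\n{seq}\n")
    with open(support_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["sequence", "column", "support"])
        for k, seq in enumerate(seqs, start=1):
            for n in range(len(seq)):
                w.writerow([k, n + 1, f"{support[k - 1, n]:.6f}"])


def read_consensus(fasta_path: str | Path, support_path: str | Path) -> tuple[list[str], np.ndarray]:
    seqs = []
    with open(fasta_path) as fh:
        cur = []
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if cur:
                    seqs.append("".join(cur))
                cur = []
            elif line:
                cur.append(line)
        if cur:
            seqs.append("".join(cur))
    support = np.zeros((len(seqs), len(seqs[0])))
    with open(support_path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            support[int(row["sequence"]) - 1, int(row["column"]) - 1] = float(row["support"])
    return seqs, support


def write_filter_log(path: str | Path, records: list[FilterRecord]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["read_id", "paired", "s_star", "s_bar_star", "accepted"])
        for r in records:
            w.writerow([r.read_id, int(r.paired), f"{r.s_star:.4f}", f"{r.s_bar_star:.4f}", int(r.accepted)])


def write_placed_reads(path: str | Path, reads: list[PlacedRead]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["read_id", "columns", "symbols", "qualities"])
        for r in reads:
            w.writerow(
                [
                    r.id,
                    ",".join(str(c + 1) for c in r.cols),
                    "".join("ACGTN-"[s] for s in r.syms),
                    ",".join(str(int(q)) for q in r.quals),
                ]
            )


def read_placed_reads(path: str | Path) -> list[PlacedRead]:
    out = []
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            cols = np.array([int(c) - 1 for c in row["columns"].split(",")], dtype=np.int64)
            syms = np.array(["ACGTN-".index(c) for c in row["symbols"]], dtype=np.int8)
            quals = np.array([int(q) for q in row["qualities"].split(",")], dtype=np.int16)
            out.append(PlacedRead(row["read_id"], cols, syms, quals))
    return out


def write_trace(path: str | Path, trace: list[tuple], seed: int) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["# seed", seed])
        w.writerow(["sweep", "log_posterior", "temperature", "mh_accept"])
        for sweep, lp, temp, flags in trace:
            w.writerow([sweep, f"{lp:.6f}", temp, flags])


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path: str | Path, manifest: dict) -> None:
    manifest = {"software_version": __version__, **manifest}
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
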