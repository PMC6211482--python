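"""Synthetic reference bundles and reads for testing and benchmarking.

Generates a mock allele database (one target gene plus an optional diverged
homolog), paired reads with quality-implied substitution errors, and planted
scenarios: germline SNPs are implicit in the allele divergence; somatic
single-base indels, allelic imbalance, contamination, and reference
misimputation are explicit options.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .reference import Allele, IntegratedMsa, build_integrated_msa
from .scoring import RawRead

_BASES = np.array(list("ACGT"))

DEFAULT_LAYOUT: tuple[tuple[str, int], ...] = (
    ("utr5", 60),
    ("exon1", 150),
    ("intron1", 100),
    ("exon2", 180),
    ("intron2", 100),
    ("exon3", 150),
    ("utr3", 60),
)


@dataclass
class SimConfig:
    """Knobs of the simulator; the seed is mandatory."""

    seed: int
    n_alleles: int = 20
    layout: tuple[tuple[str, int], ...] = DEFAULT_LAYOUT
    divergence: float = 0.02
    exonic_fraction: float = 0.3
    homolog_divergence: float = 0.05
    read_length: int = 100
    insert_size: int = 250
    depth: float = 10.0
    base_quality: int = 30
    tail_quality: int = 15
    tail_length: int = 5
    indel_rate: float = 0.0
    gene: str = "A"
    homolog_gene: str = "B"

    def __post_init__(self) -> None:
        if not (0.0 <= self.divergence < 1.0) or not (0.0 <= self.homolog_divergence < 1.0):
            raise ValueError("divergences must lie in [0,1)")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.insert_size < self.read_length:
            raise ValueError("insert size must be >= read length")

    @property
    def length(self) -> int:
        return sum(w for _, w in self.layout)

    @property
    def feature_map(self) -> list[str]:
        out: list[str] = []
        for label, width in self.layout:
            out.extend([label] * width)
        return out


@dataclass
class MockDb:
    """Reference bundle with ground truth for every allele."""

    msa: IntegratedMsa
    homolog_msa: IntegratedMsa | None
    truth: dict[str, str]

    def msas(self) -> dict[str, IntegratedMsa]:
        out = {self.msa.gene: self.msa}
        if self.homolog_msa is not None:
            out[self.homolog_msa.gene] = self.homolog_msa
        return out

    def flat_db(self) -> list[tuple[str, str, str]]:
        out = [(self.msa.gene, n, self.msa.degapped(n)) for n in self.msa.names]
        if self.homolog_msa is not None:
            out += [
                (self.homolog_msa.gene, n, self.homolog_msa.degapped(n))
                for n in self.homolog_msa.names
            ]
        return out

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        self.msa.write(directory)
        if self.homolog_msa is not None:
            self.homolog_msa.write(directory)
        with open(directory / "truth.json", "w") as fh:
            json.dump({"alleles": self.truth}, fh, indent=1, sort_keys=True)


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    out = seq.copy()
    hit = np.flatnonzero(rng.random(len(seq)) < rate)
    for i in hit:
        choices = [b for b in "ACGT" if b != out[i]]
        out[i] = choices[rng.integers(0, 3)]
    return out


def _gene_alleles(
    gene: str,
    ancestral: np.ndarray,
    rng: np.random.Generator,
    cfg: SimConfig,
    exonic_fraction: float,
) -> tuple[list[Allele], list[Allele], dict[str, str]]:
    feature = cfg.feature_map
    exon_cols = [i for i, f in enumerate(feature) if f.startswith("exon")]
    genomic, exonic, truth = [], [], {}
    n_exonic = int(round(cfg.n_alleles * exonic_fraction))
    for i in range(cfg.n_alleles):
        name = f"{gene}*{i + 1:02d}:01"
        seq = _mutate(ancestral, cfg.divergence, rng)
        truth[name] = "".join(seq)
        if i >= cfg.n_alleles - n_exonic:
            exon_seq = "".join(seq[exon_cols])
            exonic.append(Allele(gene, name, "exonic", exon_seq))
        else:
            genomic.append(Allele(gene, name, "genomic", "".join(seq)))
    return genomic, exonic, truth


def generate_mock_db(cfg: SimConfig, with_homolog: bool = True) -> MockDb:
    """Deterministic mock reference bundle for ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    ancestral = _BASES[rng.integers(0, 4, size=cfg.length)]
    genomic, exonic, truth = _gene_alleles(cfg.gene, ancestral, rng, cfg, cfg.exonic_fraction)
    msa = build_integrated_msa(genomic, exonic, cfg.feature_map)
    homolog_msa = None
    if with_homolog:
        anc_h = _mutate(ancestral, cfg.homolog_divergence, rng)
        gen_h, exo_h, truth_h = _gene_alleles(cfg.homolog_gene, anc_h, rng, cfg, 0.0)
        homolog_msa = build_integrated_msa(gen_h, exo_h, cfg.feature_map)
        truth.update(truth_h)
    return MockDb(msa, homolog_msa, truth)


def misimpute_reference(
    db: MockDb, allele_name: str, rng: np.random.Generator
) -> tuple[MockDb, int, str, str]:
    """Replace one SNP-column base of ``allele_name`` with another allele's
    variant, returning a new bundle plus (column, old, new)."""
    msa = db.msa
    seqs = [msa.alleles[n] for n in msa.names]
    target = msa.alleles[allele_name]
    snp_cols = [
        n
        for n in range(msa.n_columns)
        if target[n] in "ACGT"
        and any(s[n] in "ACGT" and s[n] != target[n] for s in seqs)
    ]
    if not snp_cols:
        raise ValueError("no SNP columns available for misimputation")
    col = int(snp_cols[rng.integers(0, len(snp_cols))])
    variants = sorted({s[col] for s in seqs if s[col] in "ACGT" and s[col] != target[col]})
    new = variants[int(rng.integers(0, len(variants)))]
    old = target[col]
    alleles = dict(msa.alleles)
    alleles[allele_name] = target[:col] + new + target[col + 1 :]
    msa2 = IntegratedMsa(
        msa.gene,
        list(msa.names),
        alleles,
        list(msa.feature_map),
        {k: v.copy() for k, v in msa.imputed.items()},
        dict(msa.levels),
    )
    return MockDb(msa2, db.homolog_msa, dict(db.truth)), col, old, new


@dataclass
class SomaticEvent:
    """A planted single-base somatic event on one haplotype."""

    column: int
    kind: str = "deletion"  # deletion | insertion
    cell_fraction: float = 0.5
    haplotype: int = 0
    insert_base: str = "A"


@dataclass
class ReadTruth:
    read_id: str
    haplotype: int
    start: int
    contaminant: bool
    mutated: bool


def _quality_profile(cfg: SimConfig) -> np.ndarray:
    q = np.full(cfg.read_length, cfg.base_quality, dtype=int)
    if cfg.tail_length > 0:
        q[-cfg.tail_length :] = cfg.tail_quality
    return q


def _apply_errors(bases: np.ndarray, quals: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    p = 10.0 ** (-quals / 10.0)
    out = bases.copy()
    hit = np.flatnonzero(rng.random(len(bases)) < p)
    for i in hit:
        choices = [b for b in "ACGT" if b != out[i]]
        out[i] = choices[rng.integers(0, 3)]
    return out


def simulate_reads(
    cfg: SimConfig,
    genotype: tuple[str, str],
    db: MockDb,
    rng: np.random.Generator | None = None,
    imbalance: float = 1.0,
    somatic: SomaticEvent | None = None,
    contamination: float = 0.0,
) -> tuple[list[RawRead], list[ReadTruth]]:
    """Paired reads from the two haplotypes of ``genotype``.

    ``imbalance`` is the haplotype-1:haplotype-2 sampling ratio; ``somatic``
    plants a single-base indel on one haplotype at the stated cell fraction;
    ``contamination`` draws a fraction of pairs from a random homolog allele.
    """
    for name in genotype:
        if name not in db.truth:
            raise KeyError(f"genotype allele {name!r} not in database")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    haplotypes = [db.truth[genotype[0]], db.truth[genotype[1]]]
    mutated = None
    if somatic is not None:
        base_seq = haplotypes[somatic.haplotype]
        if somatic.kind == "deletion":
            mutated = base_seq[: somatic.column] + base_seq[somatic.column + 1 :]
        elif somatic.kind == "insertion":
            mutated = base_seq[: somatic.column] + somatic.insert_base + base_seq[somatic.column :]
        else:
            raise ValueError(f"unknown somatic kind {somatic.kind!r}")
    hom_names = db.homolog_msa.names if db.homolog_msa is not None else []
    length = len(haplotypes[0])
    n_pairs = int(round(cfg.depth * length / (2 * cfg.read_length)))
    p1 = imbalance / (1.0 + imbalance)
    qprof = _quality_profile(cfg)
    reads: list[RawRead] = []
    truths: list[ReadTruth] = []
    for i in range(n_pairs):
        contaminant = bool(contamination > 0 and rng.random() < contamination)
        is_mut = False
        if contaminant:
            name = hom_names[rng.integers(0, len(hom_names))]
            template = db.truth[name]
            hap = -1
        else:
            hap = 0 if rng.random() < p1 else 1
            template = haplotypes[hap]
            if somatic is not None and hap == somatic.haplotype and rng.random() < somatic.cell_fraction:
                template = mutated
                is_mut = True
        tlen = len(template)
        insert = min(cfg.insert_size, tlen)
        start = int(rng.integers(0, tlen - insert + 1))
        r1 = np.array(list(template[start : start + cfg.read_length]))
        m_start = start + insert - cfg.read_length
        r2 = np.array(list(template[m_start : m_start + cfg.read_length]))
        r1 = _apply_errors(r1, qprof, rng)
        r2 = _apply_errors(r2, qprof, rng)
        rid = f"sim{i:05d}"
        reads.append(
            RawRead(rid, "".join(r1), list(map(int, qprof)), "".join(r2), list(map(int, qprof)))
        )
        truths.append(ReadTruth(rid, hap, start, contaminant, is_mut))
    return reads, truths


def truth_manifest(cfg: SimConfig, genotype, truths: list[ReadTruth]) -> dict:
    return {
        "config": {**asdict(cfg), "layout": [list(b) for b in cfg.layout]},
        "genotype": list(genotype),
        "reads": [asdict(t) for t in truths],
    }
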