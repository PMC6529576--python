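"""Toy exome model: genes with coordinates, strand and coding sequence.

The model stands in for a reference exome (gene bodies are pure coding
sequence; no introns or UTRs).  Coordinates are stored internally as 0-based
half-open intervals; :func:`to_vcf_pos` / :func:`from_vcf_pos` convert to the
1-based inclusive convention used in the emitted VCF files.

Genes never touch the chromosome edges, so every coding position has defined
5' and 3' neighbours for trinucleotide-context lookup.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .contexts import revcomp

#: Minimum gap kept between genes and between a gene and a chromosome edge.
EDGE_PAD = 25


@dataclass(frozen=True)
class Gene:
    gene_id: str
    chrom: str
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive
    strand: str  # '+' or '-'

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.end <= self.start:
            raise ValueError(f"empty gene interval for {self.gene_id}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GenomeModel:
    """A toy exome: chromosome sequences plus non-overlapping gene intervals."""

    chromosome_sequences: dict[str, str]
    genes: list[Gene]
    _by_chrom: dict[str, tuple[list[int], list[Gene]]] = field(
        default_factory=dict, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        self.validate()
        self._index()

    def validate(self) -> None:
        for g in self.genes:
            if g.chrom not in self.chromosome_sequences:
                raise ValueError(f"gene {g.gene_id} on unknown chromosome {g.chrom}")
            seq_len = len(self.chromosome_sequences[g.chrom])
            if g.start < 1 or g.end > seq_len - 1:
                raise ValueError(
                    f"gene {g.gene_id} touches the edge of {g.chrom} "
                    f"(flanking context undefined)"
                )
            if g.length % 3 != 0:
                raise ValueError(f"gene {g.gene_id} CDS length not divisible by 3")
        by_chrom: dict[str, list[Gene]] = {}
        for g in self.genes:
            by_chrom.setdefault(g.chrom, []).append(g)
        for chrom, gs in by_chrom.items():
            gs = sorted(gs, key=lambda g: g.start)
            for a, b in zip(gs, gs[1:]):
                if b.start < a.end:
                    raise ValueError(
                        f"overlapping genes {a.gene_id} and {b.gene_id} on {chrom}"
                    )

    def _index(self) -> None:
        by_chrom: dict[str, list[Gene]] = {}
        for g in self.genes:
            by_chrom.setdefault(g.chrom, []).append(g)
        self._by_chrom = {}
        for chrom, gs in by_chrom.items():
            gs = sorted(gs, key=lambda g: g.start)
            self._by_chrom[chrom] = ([g.start for g in gs], gs)

    # -- queries ----------------------------------------------------------

    def gene_by_id(self, gene_id: str) -> Gene:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def gene_at(self, chrom: str, pos0: int) -> Gene | None:
        """Gene containing a 0-based position, or None if intergenic."""
        if chrom not in self._by_chrom:
            return None
        starts, gs = self._by_chrom[chrom]
        i = bisect.bisect_right(starts, pos0) - 1
        if i >= 0 and gs[i].start <= pos0 < gs[i].end:
            return gs[i]
        return None

    def base_at(self, chrom: str, pos0: int) -> str:
        seq = self.chromosome_sequences[chrom]
        if not 0 <= pos0 < len(seq):
            raise ValueError(f"position {pos0} outside chromosome {chrom}")
        return seq[pos0]

    def trinucleotide(self, chrom: str, pos0: int) -> str:
        """Reference trinucleotide centred on a 0-based position (+ strand)."""
        seq = self.chromosome_sequences[chrom]
        if not 1 <= pos0 <= len(seq) - 2:
            raise ValueError(
                f"position {pos0} on {chrom} lacks a flanking base for context lookup"
            )
        return seq[pos0 - 1 : pos0 + 2]

    def coding_sequence(self, gene: Gene) -> str:
        """CDS of a gene in translation orientation."""
        s = self.chromosome_sequences[gene.chrom][gene.start : gene.end]
        return s if gene.strand == "+" else revcomp(s)

    @property
    def total_coding_bases(self) -> int:
        return sum(g.length for g in self.genes)

    # -- serialization ----------------------------------------------------

    def write(self, fasta_path: str | Path, genes_path: str | Path) -> None:
        """Write chromosomes as FASTA and the gene table as TSV (0-based half-open)."""
        with open(fasta_path, "w") as fh:
            for chrom in sorted(self.chromosome_sequences):
                fh.write(f">{chrom}\n")
                seq = self.chromosome_sequences[chrom]
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")
        with open(genes_path, "w") as fh:
            fh.write("gene_id\tchrom\tstart\tend\tstrand\n")
            for g in sorted(self.genes, key=lambda g: (g.chrom, g.start)):
                fh.write(f"{g.gene_id}\t{g.chrom}\t{g.start}\t{g.end}\t{g.strand}\n")

    @classmethod
    def read(cls, fasta_path: str | Path, genes_path: str | Path) -> "GenomeModel":
        from Bio import SeqIO

        seqs = {
            rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(fasta_path), "fasta")
        }
        genes = []
        with open(genes_path) as fh:
            header = fh.readline()
            if not header.startswith("gene_id"):
                raise ValueError(f"unexpected gene-table header in {genes_path}")
            for line in fh:
                gid, chrom, start, end, strand = line.rstrip("\n").split("\t")
                genes.append(Gene(gid, chrom, int(start), int(end), strand))
        return cls(chromosome_sequences=seqs, genes=genes)


def to_vcf_pos(pos0: int) -> int:
    """0-based position -> 1-based VCF POS."""
    return pos0 + 1


def from_vcf_pos(pos1: int) -> int:
    """1-based VCF POS -> 0-based position."""
    return pos1 - 1


def build_toy_exome(
    n_genes: int, mean_cds_length: int = 900, seed: int = 0, chrom: str = "chr1"
) -> GenomeModel:
    """Generate a random toy exome on one chromosome.

    Gene CDS lengths are drawn around ``mean_cds_length`` (always a multiple
    of 3, at least 30 bp); base composition is uniform over A/C/G/T; strands
    alternate at random.  Deterministic given ``seed``.
    """
    if n_genes < 1:
        raise ValueError(f"n_genes must be >= 1, got {n_genes}")
    if mean_cds_length < 30:
        raise ValueError(f"mean_cds_length must be >= 30, got {mean_cds_length}")
    if mean_cds_length % 3 != 0:
        raise ValueError(
            f"mean_cds_length must be divisible by 3, got {mean_cds_length}"
        )
    rng = np.random.default_rng([seed, 0x0E0])
    mean_codons = mean_cds_length // 3
    # lengths in codons: Poisson around the mean, floored at 10 codons
    codons = np.maximum(rng.poisson(mean_codons, size=n_genes), 10)
    lengths = codons * 3
    gaps = rng.integers(EDGE_PAD, 4 * EDGE_PAD, size=n_genes + 1)
    total = int(lengths.sum() + gaps.sum())
    seq = "".join(rng.choice(list("ACGT"), size=total))
    genes = []
    cursor = 0
    for i in range(n_genes):
        cursor += int(gaps[i])
        start = cursor
        end = start + int(lengths[i])
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(Gene(f"G{i + 1:04d}", chrom, start, end, strand))
        cursor = end
    return GenomeModel(chromosome_sequences={chrom: seq}, genes=genes)
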