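"""Gene models and the annotation container.

Coordinates are 0-based half-open internally; GFF3/bedGraph I/O converts
to and from the 1-based inclusive convention of those formats.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

from intervaltree import IntervalTree


@dataclass(frozen=True)
class Gene:
    """A gene model: transcript span plus (for coding genes) a CDS.

    ``start``/``end`` delimit the annotated transcript span; ``cds_start``/
    ``cds_end`` the coding sequence for biotype ``coding`` (None for ncRNA).
    """

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    biotype: str  # "coding" | "ncRNA"
    cds_start: int | None = None
    cds_end: int | None = None

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"{self.gene_id}: start must be < end")
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        if self.biotype == "coding":
            if self.cds_start is None or self.cds_end is None:
                raise ValueError(f"{self.gene_id}: coding gene without CDS")
            if not (self.start <= self.cds_start < self.cds_end <= self.end):
                raise ValueError(f"{self.gene_id}: CDS outside transcript span")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def cds_length(self) -> int | None:
        if self.cds_start is None:
            return None
        return self.cds_end - self.cds_start

    def overlaps(self, start: int, end: int) -> bool:
        return self.start < end and start < self.end


class Annotation:
    """Indexed collection of gene models on one assembly."""

    def __init__(self, genes: Iterable[Gene], chrom_lengths: dict[str, int] | None = None):
        self.genes: dict[str, Gene] = {}
        self._trees: dict[tuple[str, str], IntervalTree] = {}
        for g in genes:
            if g.gene_id in self.genes:
                raise ValueError(f"duplicate gene id {g.gene_id}")
            self.genes[g.gene_id] = g
            self._trees.setdefault((g.chromosome, g.strand), IntervalTree()).addi(
                g.start, g.end, g.gene_id
            )
        self.chrom_lengths = dict(chrom_lengths or {})
        if not self.chrom_lengths:
            for g in self.genes.values():
                cur = self.chrom_lengths.get(g.chromosome, 0)
                self.chrom_lengths[g.chromosome] = max(cur, g.end)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[Gene]:
        return iter(self.genes.values())

    def __getitem__(self, gene_id: str) -> Gene:
        return self.genes[gene_id]

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self.chrom_lengths)

    def coding_ids(self) -> list[str]:
        return [g.gene_id for g in self if g.biotype == "coding"]

    def ncrna_ids(self) -> list[str]:
        return [g.gene_id for g in self if g.biotype != "coding"]

    def overlapping(
        self, chromosome: str, start: int, end: int, strand: str | None = None
    ) -> list[Gene]:
        """Genes overlapping [start, end) by >= 1 bp, in genomic order.

        With ``strand`` given, only that strand's genes are searched.
        """
        strands = [strand] if strand else ["+", "-"]
        hits: list[Gene] = []
        for s in strands:
            tree = self._trees.get((chromosome, s))
            if tree is None:
                continue
            hits.extend(self.genes[iv.data] for iv in tree.overlap(start, end))
        return sorted(hits, key=lambda g: (g.start, g.end, g.gene_id))

    def on_strand(self, chromosome: str, strand: str) -> list[Gene]:
        """All genes on one chromosome strand, sorted by start."""
        return sorted(
            (g for g in self if g.chromosome == chromosome and g.strand == strand),
            key=lambda g: (g.start, g.end),
        )


def five_prime_edge(gene: Gene) -> int:
    """Genomic coordinate of the transcript 5' end (strand-aware)."""
    return gene.start if gene.strand == "+" else gene.end


def three_prime_edge(gene: Gene) -> int:
    return gene.end if gene.strand == "+" else gene.start
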