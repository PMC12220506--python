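"""Shared genomic containers.

All coordinates are 0-based half-open internally; GFF3 readers/writers in
:mod:`oxgrid.formats_io` convert at the boundary.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

from intervaltree import IntervalTree

STRANDS = ("+", "-")

Interval = tuple[int, int]


class PlacementError(ValueError):
    """Raised when intervals cannot be placed as requested."""


def _check_strand(strand: str) -> None:
    if strand not in STRANDS:
        raise ValueError(
            f"strand must be one of {STRANDS!r}, got {strand!r} "
            "('.' / unknown strands are rejected by strand-gated operations)"
        )


@dataclass
class GeneModel:
    """A stranded gene locus with optional exon structure.

    ``source`` records provenance of the model: ``iso`` (full-length
    transcript cluster), ``braker1``/``braker2`` (ab initio rounds), or
    ``denovo`` (rescued from de novo transcriptome mappings). ``sim`` marks
    simulator-made truth genes.
    """

    id: str
    chromosome: str
    start: int
    end: int
    strand: str
    source: str = "sim"
    exons: list[Interval] = field(default_factory=list)
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"gene {self.id}: start must be < end ({self.start}, {self.end})")
        _check_strand(self.strand)
        if not self.exons:
            self.exons = [(self.start, self.end)]
        self.exons = sorted((int(a), int(b)) for a, b in self.exons)
        prev_end = None
        for a, b in self.exons:
            if a >= b:
                raise ValueError(f"gene {self.id}: empty exon ({a}, {b})")
            if a < self.start or b > self.end:
                raise ValueError(f"gene {self.id}: exon ({a}, {b}) outside gene span")
            if prev_end is not None and a < prev_end:
                raise ValueError(f"gene {self.id}: overlapping exons")
            prev_end = b

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def span(self) -> Interval:
        return (self.start, self.end)


@dataclass
class Transcript:
    id: str
    start: int
    end: int
    exons: Optional[list[Interval]] = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"transcript {self.id}: start must be < end")
        if self.exons:
            self.exons = sorted((int(a), int(b)) for a, b in self.exons)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class TranscriptCluster:
    """A collapsed full-length transcript cluster, treated as direct gene evidence."""

    id: str
    chromosome: str
    strand: str
    transcripts: list[Transcript] = field(default_factory=list)

    def __post_init__(self) -> None:
        _check_strand(self.strand)
        if not self.transcripts:
            raise ValueError(f"cluster {self.id}: needs at least one transcript")

    @property
    def span(self) -> Interval:
        return (min(t.start for t in self.transcripts), max(t.end for t in self.transcripts))


class AssemblyLayout:
    """Ordered chromosomes with lengths and cumulative offsets.

    The order is the assembly order; linearized coordinates concatenate the
    chromosomes in this order.
    """

    def __init__(self, chromosomes: Iterable[tuple[str, int]]):
        self.names: list[str] = []
        self.lengths: dict[str, int] = {}
        self._offsets: dict[str, int] = {}
        running = 0
        for name, length in chromosomes:
            if name in self.lengths:
                raise ValueError(f"duplicate chromosome name {name!r}")
            if length <= 0:
                raise ValueError(f"chromosome {name!r}: non-positive length {length}")
            self.names.append(name)
            self.lengths[name] = int(length)
            self._offsets[name] = running
            running += int(length)
        self.total_length = running

    def __contains__(self, name: str) -> bool:
        return name in self.lengths

    def __len__(self) -> int:
        return len(self.names)

    def offset(self, name: str) -> int:
        try:
            return self._offsets[name]
        except KeyError:
            raise KeyError(f"unknown chromosome {name!r}") from None

    def index(self, name: str) -> int:
        return self.names.index(name)

    def items(self) -> Iterator[tuple[str, int]]:
        return ((n, self.lengths[n]) for n in self.names)

    def renamed(self, mapping: dict[str, str]) -> "AssemblyLayout":
        return AssemblyLayout((mapping.get(n, n), l) for n, l in self.items())

    def subset(self, keep: Iterable[str]) -> "AssemblyLayout":
        keep = set(keep)
        return AssemblyLayout((n, l) for n, l in self.items() if n in keep)


class AnnotationSet:
    """A genome layout plus gene models, indexed by id and by interval."""

    def __init__(self, layout: AssemblyLayout, genes: Iterable[GeneModel] = ()):
        self.layout = layout
        self._genes: dict[str, GeneModel] = {}
        self._trees: dict[str, IntervalTree] = {}
        for g in genes:
            self.add(g)

    def add(self, gene: GeneModel) -> None:
        if gene.id in self._genes:
            raise ValueError(f"duplicate gene id {gene.id!r}")
        if gene.chromosome not in self.layout:
            raise KeyError(f"gene {gene.id}: unknown chromosome {gene.chromosome!r}")
        if gene.end > self.layout.lengths[gene.chromosome]:
            raise ValueError(
                f"gene {gene.id}: end {gene.end} beyond chromosome "
                f"{gene.chromosome} length {self.layout.lengths[gene.chromosome]}"
            )
        self._genes[gene.id] = gene
        self._trees.setdefault(gene.chromosome, IntervalTree())[gene.start:gene.end] = gene.id

    def remove(self, gene_id: str) -> None:
        g = self._genes.pop(gene_id)
        self._trees[g.chromosome].removei(g.start, g.end, g.id)

    def __len__(self) -> int:
        return len(self._genes)

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(self._genes.values())

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._genes

    def get(self, gene_id: str) -> GeneModel:
        return self._genes[gene_id]

    @property
    def gene_ids(self) -> list[str]:
        return list(self._genes)

    def overlapping(
        self, chromosome: str, start: int, end: int, strand: Optional[str] = None
    ) -> list[GeneModel]:
        """Genes overlapping [start, end) on a chromosome, optionally strand-gated."""
        tree = self._trees.get(chromosome)
        if tree is None:
            return []
        out = [self._genes[iv.data] for iv in tree.overlap(start, end)]
        if strand is not None:
            _check_strand(strand)
            out = [g for g in out if g.strand == strand]
        return sorted(out, key=lambda g: (g.start, g.id))

    def exon_overlapping(
        self, chromosome: str, exons: Iterable[Interval], strand: str
    ) -> list[GeneModel]:
        """Genes with at least one exon overlapping any of the given exons (same strand)."""
        hits: dict[str, GeneModel] = {}
        for a, b in exons:
            for g in self.overlapping(chromosome, a, b, strand=strand):
                if g.id in hits:
                    continue
                for ea, eb in g.exons:
                    if ea < b and a < eb:
                        hits[g.id] = g
                        break
        return sorted(hits.values(), key=lambda g: (g.start, g.id))

    def sorted_genes(self) -> list[GeneModel]:
        order = {n: i for i, n in enumerate(self.layout.names)}
        return sorted(self, key=lambda g: (order[g.chromosome], g.start, g.id))

    def counts_by_source(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for g in self:
            out[g.source] = out.get(g.source, 0) + 1
        return dict(sorted(out.items()))

    def genes_per_chromosome(self) -> dict[str, int]:
        out = {n: 0 for n in self.layout.names}
        for g in self:
            out[g.chromosome] += 1
        return out

    def copy(self) -> "AnnotationSet":
        import copy as _copy

        return AnnotationSet(self.layout, (_copy.deepcopy(g) for g in self))


def overlap_len(a: Interval, b: Interval) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def overlap_fraction(a: Interval, b: Interval) -> float:
    """Overlap length divided by the shorter interval length.

    Symmetric; containment of the shorter interval gives 1.0.
    """
    shorter = min(a[1] - a[0], b[1] - b[0])
    if shorter <= 0:
        return 0.0
    return overlap_len(a, b) / shorter


def contains(outer: Interval, inner: Interval) -> bool:
    return outer[0] <= inner[0] and inner[1] <= outer[1]
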