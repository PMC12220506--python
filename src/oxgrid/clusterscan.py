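"""Conserved gene-cluster integrity assessment.

Given member-query-vs-genome alignment hits and a gene annotation, assigns
cluster members (Hox, NK, NK2, SINE, HRO+Isl, Irx, ...) to gene models,
then reports copy numbers, missing members, genomic order (a uniformly
reversed cluster still counts as ordered; orientation is reported
separately), strand uniformity, span, intervening non-member models, and
syntenic blocks. Member identities are by best alignment hit and therefore
putative; phylogenetic confirmation is out of scope. Also tallies
presence/absence completeness for conserved microRNA families.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .core import AnnotationSet

DEFAULT_EVALUE_CUTOFF = 1e-20
RELAXED_EVALUE_CUTOFF = 1e-10


@dataclass
class ExpectedCluster:
    """A named cluster with its members in ancestral genomic order."""

    name: str
    members: list[str]

    def __post_init__(self) -> None:
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"cluster {self.name}: duplicate member labels")


#: The putatively ten-member ancestral arthropod Hox cluster, in order.
HOX_CLUSTER = ExpectedCluster(
    "Hox",
    ["Hox1", "Hox2", "Hox3", "Hox4", "Hox5", "Hox6", "Hox7", "Hox8", "Hox9", "Hox10"],
)


@dataclass
class MemberHit:
    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    evalue: float


MemberAssignment = dict[str, list[MemberHit]]


@dataclass
class ClusterReport:
    name: str
    copy_number: dict[str, int]
    missing: list[str]
    chromosomes: list[str]
    single_chromosome: bool
    ordered: bool
    breakpoints: int
    orientation: Optional[str]  # "ascending" | "descending" | None
    strand_uniform: bool
    strand: Optional[str]
    span: Optional[int]
    member_order: list[str] = field(default_factory=list)


def assign_members_from_hits(
    hits: pd.DataFrame,
    annotation: AnnotationSet,
    evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF,
) -> tuple[MemberAssignment, list[tuple[str, str, int, int]]]:
    """Map member-query genome hits onto gene models.

    ``hits`` needs columns ``qseqid`` (member label), ``tseqid``
    (chromosome), ``tstart``/``tend`` (1-based genomic positions) and
    ``evalue``. Hits at or above the cutoff are discarded; surviving hits
    map to the overlapping gene model(s), and per (member, gene) only the
    best e-value is kept. Hits overlapping no gene model are returned as
    unmapped, not fatal.
    """
    best: dict[tuple[str, str], MemberHit] = {}
    unmapped: list[tuple[str, str, int, int]] = []
    for row in hits.itertuples(index=False):
        evalue = float(row.evalue)
        if evalue >= evalue_cutoff:
            continue
        member = str(row.qseqid)
        chrom = str(row.tseqid)
        a, b = int(row.tstart), int(row.tend)
        if a > b:
            a, b = b, a
        genes = annotation.overlapping(chrom, a - 1, b)
        if not genes:
            unmapped.append((member, chrom, a, b))
            continue
        for g in genes:
            key = (member, g.id)
            if key not in best or evalue < best[key].evalue:
                best[key] = MemberHit(g.id, g.chromosome, g.start, g.end, g.strand, evalue)
    assignment: MemberAssignment = {}
    for (member, _gid), hit in sorted(best.items()):
        assignment.setdefault(member, []).append(hit)
    return assignment, unmapped


def assess_cluster(assignment: MemberAssignment, expected: ExpectedCluster) -> ClusterReport:
    """Judge a cluster's integrity against its expected composition.

    Order is evaluated over single-copy members on the shared chromosome
    only (multi-copy members do not break it): their coordinate sequence,
    taken in expected-member order, must be strictly ascending or strictly
    descending. Breakpoints count adjacent violations of the better
    direction. Span is max end - min start, defined only on a single
    chromosome.
    """
    present = {m: assignment[m] for m in expected.members if assignment.get(m)}
    copy_number = {m: len(present.get(m, [])) for m in expected.members}
    missing = [m for m in expected.members if copy_number[m] == 0]
    all_hits = [h for hs in present.values() for h in hs]
    chromosomes = sorted({h.chromosome for h in all_hits})
    single_chromosome = len(chromosomes) == 1
    strands = {h.strand for h in all_hits}
    strand_uniform = len(strands) == 1 and bool(all_hits)
    strand = strands.pop() if strand_uniform else None

    singles = [
        m for m in expected.members
        if copy_number[m] == 1 and present[m][0].chromosome == (chromosomes[0] if single_chromosome else None)
    ] if single_chromosome else []
    coords = [present[m][0].start for m in singles]
    asc_breaks = sum(1 for a, b in zip(coords, coords[1:]) if not a < b)
    desc_breaks = sum(1 for a, b in zip(coords, coords[1:]) if not a > b)
    if len(coords) < 2:
        ordered, breakpoints, orientation = bool(coords), 0, None
    elif asc_breaks == 0:
        ordered, breakpoints, orientation = True, 0, "ascending"
    elif desc_breaks == 0:
        ordered, breakpoints, orientation = True, 0, "descending"
    else:
        breakpoints = min(asc_breaks, desc_breaks)
        orientation = "ascending" if asc_breaks <= desc_breaks else "descending"
        ordered = False

    span = None
    member_order: list[str] = []
    if single_chromosome and all_hits:
        span = max(h.end for h in all_hits) - min(h.start for h in all_hits)
        member_order = [
            m
            for _, m in sorted(
                (h.start, m) for m, hs in present.items() for h in hs
            )
        ]
    return ClusterReport(
        name=expected.name,
        copy_number=copy_number,
        missing=missing,
        chromosomes=chromosomes,
        single_chromosome=single_chromosome,
        ordered=ordered,
        breakpoints=breakpoints,
        orientation=orientation,
        strand_uniform=strand_uniform,
        strand=strand,
        span=span,
        member_order=member_order,
    )


def detect_syntenic_blocks(assignment: MemberAssignment) -> dict[str, list[str]]:
    """Group assigned members into per-chromosome syntenic blocks.

    A block is simply the set of members co-located on one chromosome,
    listed in coordinate order with one entry per copy; intervening
    non-member genes and strand are ignored (no maximum-gap parameter).
    Every assigned copy appears in exactly one block.
    """
    blocks: dict[str, list[tuple[int, str]]] = {}
    for member, hits in assignment.items():
        for h in hits:
            blocks.setdefault(h.chromosome, []).append((h.start, member))
    return {
        chrom: [m for _, m in sorted(entries)]
        for chrom, entries in sorted(blocks.items())
    }


def find_intervening_models(
    annotation: AnnotationSet,
    assignment: MemberAssignment,
    report: ClusterReport,
) -> list[tuple[str, Optional[str], Optional[str]]]:
    """Non-member gene models inside the cluster span, with flanking members.

    Requires a single-chromosome cluster (defined span); returns
    ``(gene_id, upstream_member, downstream_member)`` tuples.
    """
    if not report.single_chromosome or report.span is None:
        raise ValueError("cluster span undefined: members are not on a single chromosome")
    chrom = report.chromosomes[0]
    member_genes = {h.gene_id for hs in assignment.values() for h in hs}
    member_pos = sorted(
        (h.start, m) for m, hs in assignment.items() for h in hs
    )
    lo = min(h.start for hs in assignment.values() for h in hs)
    hi = max(h.end for hs in assignment.values() for h in hs)
    out = []
    for g in annotation.overlapping(chrom, lo, hi):
        if g.id in member_genes:
            continue
        upstream = None
        downstream = None
        for pos, m in member_pos:
            if pos <= g.start:
                upstream = m
            elif downstream is None:
                downstream = m
        out.append((g.id, upstream, downstream))
    return out


def completeness_score(
    found: Iterable[str], expected: Iterable[str]
) -> tuple[float, list[str]]:
    """Presence/absence completeness of an expected family set.

    Returns the percentage (rounded to one decimal for reporting) of
    expected labels that were found, plus the sorted missing list.
    """
    found_set, expected_set = set(found), set(expected)
    if not expected_set:
        raise ValueError("expected set must be non-empty")
    pct = round(100.0 * len(found_set & expected_set) / len(expected_set), 1)
    return pct, sorted(expected_set - found_set)


def flag_identical_duplicates(
    annotation: AnnotationSet,
    sequences: dict[str, str],
    gene_ids: Optional[Sequence[str]] = None,
    same_chromosome_only: bool = True,
) -> list[tuple[str, str]]:
    """Flag gene pairs with exactly identical nucleotide sequences.

    Identical same-chromosome pairs hint at misassembly and are flagged
    for manual review (set ``same_chromosome_only=False`` to widen scope).
    Genes without a sequence are skipped with a warning.
    """
    import warnings

    ids = list(gene_ids) if gene_ids is not None else sorted(annotation.gene_ids)
    seqs: dict[str, str] = {}
    for gid in ids:
        if gid not in sequences:
            warnings.warn(f"no sequence for gene {gid}; skipped")
            continue
        seqs[gid] = sequences[gid]
    flagged = []
    id_list = sorted(seqs)
    for i, a in enumerate(id_list):
        for b in id_list[i + 1:]:
            if seqs[a] != seqs[b]:
                continue
            if same_chromosome_only and annotation.get(a).chromosome != annotation.get(b).chromosome:
                continue
            flagged.append((a, b))
    return flagged
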