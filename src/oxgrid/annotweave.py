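"""Multi-round reconciliation of gene models from heterogeneous evidence.

Round 1 treats full-length transcript clusters as genes and drops ab
initio models that significantly overlap them (same strand, any sequence
overlap as candidacy). Significance uses two rules: when a model overlaps
transcripts from exactly one cluster, it merges if at least 40% of the
cluster's transcripts fully contain the model or are fully contained in
it; otherwise the mean transcript/model overlap fraction must exceed 50%.
Overlap fractions are overlap length divided by the shorter of the two
interval lengths, so containment is the limiting case at 1.0.

Round 2 incorporates novel ab initio models by exon-level cross-reference:
a model is added only if none of its exons overlaps (same strand) an exon
of an existing gene. The third round rescues loci from complete-ORF de
novo transcript mappings: mappings overlapping the annotation are
discarded, the rest are grouped by pairwise intersection against an
anchor stage, and each group collapses to one gene spanning its union.

The priority ordering is iso > braker1 > braker2 > denovo: a
lower-priority model never displaces a higher-priority gene.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from intervaltree import IntervalTree

from .core import (
    AnnotationSet,
    GeneModel,
    Interval,
    TranscriptCluster,
    contains,
    overlap_fraction,
    overlap_len,
)

DEFAULT_MIN_CONTAINMENT = 0.40
DEFAULT_MIN_MEAN_OVERLAP = 0.50


@dataclass
class MergeDecision:
    """Record of one model-vs-cluster significance decision."""

    model_id: str
    cluster_id: str
    rule_fired: str  # "single-cluster-containment" | "mean-overlap" | "none"
    containment_fraction: float
    mean_overlap: float


def significant_overlap(
    model: GeneModel,
    clusters: Sequence[TranscriptCluster],
    min_containment: float = DEFAULT_MIN_CONTAINMENT,
    min_mean_overlap: float = DEFAULT_MIN_MEAN_OVERLAP,
) -> list[MergeDecision]:
    """Evaluate the two merge rules for a model against candidate clusters.

    Candidates are same-chromosome, same-strand clusters with at least one
    transcript overlapping the model span by >= 1 bp. The containment rule
    is only evaluated when the model overlaps transcripts from exactly one
    cluster; with several candidates each is judged by mean overlap alone.
    Returns one decision per candidate (``rule_fired="none"`` when no rule
    applies).
    """
    span = model.span
    candidates = []
    for c in clusters:
        if c.chromosome != model.chromosome or c.strand != model.strand:
            continue
        if any(overlap_len(span, (t.start, t.end)) > 0 for t in c.transcripts):
            candidates.append(c)
    single = len(candidates) == 1
    decisions = []
    for c in candidates:
        n = len(c.transcripts)
        contained = sum(
            1
            for t in c.transcripts
            if contains((t.start, t.end), span) or contains(span, (t.start, t.end))
        )
        containment_fraction = contained / n
        mean_overlap = sum(overlap_fraction(span, (t.start, t.end)) for t in c.transcripts) / n
        if single and containment_fraction >= min_containment:
            rule = "single-cluster-containment"
        elif mean_overlap > min_mean_overlap:
            rule = "mean-overlap"
        else:
            rule = "none"
        decisions.append(MergeDecision(model.id, c.id, rule, containment_fraction, mean_overlap))
    return decisions


def cluster_to_gene(cluster: TranscriptCluster) -> GeneModel:
    """Represent a transcript cluster as a gene (union span, union exons)."""
    a, b = cluster.span
    exon_ivs: list[Interval] = []
    for t in cluster.transcripts:
        exon_ivs.extend(t.exons or [(t.start, t.end)])
    return GeneModel(
        id=cluster.id,
        chromosome=cluster.chromosome,
        start=a,
        end=b,
        strand=cluster.strand,
        source="iso",
        exons=_merge_intervals(exon_ivs),
    )


def _merge_intervals(ivs: Iterable[Interval]) -> list[Interval]:
    ivs = sorted(ivs)
    out: list[Interval] = []
    for a, b in ivs:
        if out and a <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], b))
        else:
            out.append((a, b))
    return out


def reconcile_round1(
    models: Sequence[GeneModel],
    clusters: Sequence[TranscriptCluster],
    layout=None,
    min_containment: float = DEFAULT_MIN_CONTAINMENT,
    min_mean_overlap: float = DEFAULT_MIN_MEAN_OVERLAP,
) -> tuple[AnnotationSet, list[MergeDecision]]:
    """Merge ab initio models with transcript clusters (round 1).

    Every cluster becomes a gene; a model is retained only if it fires no
    significance rule against any cluster. The conservation law
    ``|genes| = |clusters| + |retained models|`` holds exactly and is
    asserted on every run. Returns the annotation plus all non-trivial
    merge decisions.
    """
    if layout is None:
        from .core import AssemblyLayout

        extent: dict[str, int] = {}
        for m in models:
            extent[m.chromosome] = max(extent.get(m.chromosome, 0), m.end)
        for c in clusters:
            extent[c.chromosome] = max(extent.get(c.chromosome, 0), c.span[1])
        layout = AssemblyLayout(sorted(extent.items()))
    by_chrom: dict[str, list[TranscriptCluster]] = {}
    for c in clusters:
        by_chrom.setdefault(c.chromosome, []).append(c)
    # per-chromosome transcript interval index so candidacy is not O(models x clusters)
    trees: dict[str, IntervalTree] = {}
    for chrom, cs in by_chrom.items():
        tree = IntervalTree()
        for c in cs:
            a, b = c.span
            tree[a:b] = c
        trees[chrom] = tree

    annotation = AnnotationSet(layout)
    for c in sorted(clusters, key=lambda c: c.id):
        annotation.add(cluster_to_gene(c))
    decisions: list[MergeDecision] = []
    retained = 0
    for m in sorted(models, key=lambda m: m.id):
        tree = trees.get(m.chromosome)
        nearby = [iv.data for iv in tree.overlap(m.start, m.end)] if tree is not None else []
        ds = significant_overlap(m, nearby, min_containment, min_mean_overlap)
        decisions.extend(ds)
        if not any(d.rule_fired != "none" for d in ds):
            annotation.add(
                GeneModel(m.id, m.chromosome, m.start, m.end, m.strand, "braker1",
                          list(m.exons), dict(m.attrs))
            )
            retained += 1
    assert len(annotation) == len(clusters) + retained, "round-1 conservation law violated"
    return annotation, decisions


def mask_annotated_evidence(
    evidence: Sequence[tuple], annotation: AnnotationSet
) -> list[tuple]:
    """Keep only evidence intervals with zero overlap against any gene span.

    Evidence items are ``(chromosome, start, end, ...)`` tuples; masking is
    strand-agnostic (any overlap removes the interval).
    """
    kept = []
    for item in evidence:
        chrom, start, end = item[0], int(item[1]), int(item[2])
        if not annotation.overlapping(chrom, start, end):
            kept.append(item)
    return kept


def incorporate_novel_models(
    annotation: AnnotationSet,
    new_models: Sequence[GeneModel],
    id_prefix: str = "r2_",
) -> tuple[AnnotationSet, list[str]]:
    """Add round-2 models whose exons are all novel (exon-level, same strand).

    A model is added iff none of its exons overlaps an exon of an existing
    gene on the same strand; added genes get ``id_prefix`` prepended.
    Returns the updated annotation and the list of added ids.
    """
    out = annotation.copy()
    added: list[str] = []
    for m in sorted(new_models, key=lambda m: m.id):
        if out.exon_overlapping(m.chromosome, m.exons, m.strand):
            continue
        new_id = f"{id_prefix}{m.id}"
        if new_id in out:
            raise ValueError(f"duplicate id after prefixing: {new_id!r}")
        out.add(
            GeneModel(new_id, m.chromosome, m.start, m.end, m.strand, "braker2",
                      list(m.exons), dict(m.attrs))
        )
        added.append(new_id)
    return out, added


def reconcile_denovo(
    annotation: AnnotationSet,
    stage_maps: dict[str, Sequence[GeneModel]],
    anchor_stage: str,
    id_prefix: str = "at_DN",
    min_nonanchor_stages: int = 2,
) -> tuple[AnnotationSet, list[str]]:
    """Rescue gene loci from complete-ORF de novo transcript mappings.

    Mappings whose exons overlap the existing annotation (same strand) are
    discarded first. The remainder are grouped by same-strand interval
    overlap; a group forms a locus if it contains an anchor-stage mapping,
    or if at least ``min_nonanchor_stages`` distinct non-anchor stages
    agree on it. Each locus collapses to one gene spanning the union of
    its mappings, with ids ``<prefix><n>`` assigned in genome order.
    Residual overlaps among the new genes are resolved by keeping the
    longer model (ties: lexicographically smaller id).
    """
    if anchor_stage not in stage_maps:
        raise ValueError(f"unknown anchor stage {anchor_stage!r}; have {sorted(stage_maps)}")
    survivors: list[tuple[str, GeneModel]] = []
    for stage, models in stage_maps.items():
        for m in models:
            if not annotation.exon_overlapping(m.chromosome, m.exons, m.strand):
                survivors.append((stage, m))

    # group by same-strand interval overlap (union-find over sorted sweeps)
    groups: list[list[tuple[str, GeneModel]]] = []
    by_key: dict[tuple[str, str], list[tuple[str, GeneModel]]] = {}
    for stage, m in survivors:
        by_key.setdefault((m.chromosome, m.strand), []).append((stage, m))
    for key, items in sorted(by_key.items()):
        items.sort(key=lambda sm: (sm[1].start, sm[1].id))
        current: list[tuple[str, GeneModel]] = []
        current_end = -1
        for stage, m in items:
            if current and m.start < current_end:
                current.append((stage, m))
                current_end = max(current_end, m.end)
            else:
                if current:
                    groups.append(current)
                current = [(stage, m)]
                current_end = m.end
        if current:
            groups.append(current)

    loci: list[GeneModel] = []
    for group in groups:
        stages = {s for s, _ in group}
        if anchor_stage not in stages and len(stages - {anchor_stage}) < min_nonanchor_stages:
            continue
        ms = [m for _, m in group]
        start = min(m.start for m in ms)
        end = max(m.end for m in ms)
        exons = _merge_intervals(e for m in ms for e in m.exons)
        loci.append(
            GeneModel("pending", ms[0].chromosome, start, end, ms[0].strand, "denovo",
                      exons, {"n_mappings": len(ms), "stages": ",".join(sorted(stages))})
        )

    # residual overlaps between new loci: keep the longer, then smaller id
    order = {n: i for i, n in enumerate(annotation.layout.names)}
    loci.sort(key=lambda g: (order.get(g.chromosome, len(order)), g.start))
    for i, g in enumerate(loci, 1):
        g.id = f"{id_prefix}{i}"
    dropped: set[str] = set()
    for i in range(len(loci)):
        for j in range(i + 1, len(loci)):
            a, b = loci[i], loci[j]
            if a.id in dropped or b.id in dropped:
                continue
            if a.chromosome != b.chromosome or a.strand != b.strand:
                continue
            if overlap_len(a.span, b.span) > 0:
                loser = min((a, b), key=lambda g: (g.length, [-ord(ch) for ch in g.id]))
                dropped.add(loser.id)

    out = annotation.copy()
    added = []
    for g in loci:
        if g.id in dropped:
            continue
        out.add(g)
        added.append(g.id)
    return out, added


def finalize_annotation(annotation: AnnotationSet) -> tuple[list[GeneModel], dict[str, int]]:
    """Sort the annotation and report counts by source class.

    Residual same-strand overlapping genes (manual-merge candidates) are
    reported with a warning; resolving them is left to curation.
    """
    genes = annotation.sorted_genes()
    residual = []
    prev_by_strand: dict[tuple[str, str], GeneModel] = {}
    for g in genes:
        key = (g.chromosome, g.strand)
        prev = prev_by_strand.get(key)
        if prev is not None and g.start < prev.end:
            residual.append((prev.id, g.id))
        if prev is None or g.end > prev.end:
            prev_by_strand[key] = g
    if residual:
        warnings.warn(
            f"{len(residual)} residual same-strand overlap(s) left for manual review: "
            f"{residual[:10]}{'...' if len(residual) > 10 else ''}"
        )
    return genes, annotation.counts_by_source()
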