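"""Synthetic genomes, duplication scenarios, and noisy evidence with known truth.

The simulator emits every input the analysis stages consume — genome
layouts, gene annotations, transcript-cluster and ab initio gene-model
evidence, all-vs-all protein self-alignment tables, per-scaffold taxonomic
hit tables, and read repeat profiles — together with a ground-truth record,
so every stage can be exercised and its parameter recovery measured without
real data.

There is no sequence-evolution model: the detectability of a true paralog
pair is modelled directly as a probability, and alignment statistics are
drawn from ranges that separate signal (log10 e-value uniform on [-80, -20])
from noise (uniform on [-10, -4]) by construction, so that the standard
analysis thresholds (1e-5, 1e-60) fall between the two ranges.

All randomness comes from a single :class:`numpy.random.Generator`
(PCG64), seeded once per operation call; identical inputs give
byte-identical outputs.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Union

import numpy as np
import pandas as pd

from .core import (
    AnnotationSet,
    AssemblyLayout,
    GeneModel,
    PlacementError,
    Transcript,
    TranscriptCluster,
)
from .formats_io import HIT_COLUMNS

DENOVO_STAGES = ("instarII", "instarIII", "instarV")
ANCHOR_STAGE = "instarIII"


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(int(seed))


@dataclass
class EvidenceNoise:
    """Noise model for annotation evidence.

    p_cluster_cover: probability a (round-1 visible) gene is covered by a
        transcript cluster.
    p_fusion: probability an ab initio model fuses a gene with its next
        neighbour on the chromosome.
    p_split: probability an ab initio model splits a gene in two.
    p_novel: probability a gene is withheld from round-1 evidence entirely
        and surfaces later as a round-2 model or a de novo transcript
        mapping (chosen 50/50 per gene).
    """

    p_cluster_cover: float = 1.0
    p_fusion: float = 0.0
    p_split: float = 0.0
    p_novel: float = 0.0

    def validate(self) -> None:
        for name in ("p_cluster_cover", "p_fusion", "p_split", "p_novel"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class SimConfig:
    """Free parameters of the simulator.

    Defaults describe a mid-sized invertebrate-like toy genome: 10
    chromosomes of 1 Mb carrying 200 non-overlapping genes of 2-4 kb each,
    a balanced post-duplication scenario (half the duplicates retained,
    90% of true pairs detectable by alignment), light tandem duplication,
    sparse spurious alignment hits, and a small contaminant load.
    """

    n_chromosomes: int = 10
    chromosome_length: int = 1_000_000
    n_genes_per_chromosome: int = 200
    gene_length: tuple[int, int] = (2_000, 4_000)
    seed: int = 0
    wgd_retention: float = 0.5
    wgd_detectability: float = 0.9
    tandem_rate: float = 0.1
    tandem_max_copies: int = 3
    spurious_hit_rate: float = 0.05
    contaminant_fraction: float = 0.05
    hits_per_scaffold: int = 50
    metazoan_fraction_clean: float = 0.95
    metazoan_fraction_contam: float = 0.30
    evidence_noise: EvidenceNoise = field(default_factory=EvidenceNoise)

    def validate(self) -> None:
        if self.n_chromosomes <= 0 or self.n_genes_per_chromosome <= 0:
            raise ValueError("counts must be positive")
        if self.chromosome_length <= 0:
            raise ValueError("chromosome_length must be positive")
        lo, hi = self.gene_length
        if not (0 < lo <= hi):
            raise ValueError(f"bad gene_length range {self.gene_length}")
        for name in (
            "wgd_retention",
            "wgd_detectability",
            "tandem_rate",
            "contaminant_fraction",
            "metazoan_fraction_clean",
            "metazoan_fraction_contam",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.tandem_max_copies < 2:
            raise ValueError("tandem_max_copies must be >= 2")
        if self.spurious_hit_rate < 0:
            raise ValueError("spurious_hit_rate must be >= 0")
        if self.hits_per_scaffold <= 0:
            raise ValueError("hits_per_scaffold must be positive")
        self.evidence_noise.validate()


@dataclass
class TruthTable:
    """Ground truth for a simulated scenario.

    paralog_pairs maps an unordered gene-id pair (stored as a sorted tuple)
    to its origin tag, ``wgd`` or ``tandem``; the tags partition the pair
    set. gene_to_source_gene maps every duplicated gene to the gene it was
    copied from.
    """

    paralog_pairs: dict[tuple[str, str], str] = field(default_factory=dict)
    gene_to_source_gene: dict[str, str] = field(default_factory=dict)
    contaminant_scaffolds: set[str] = field(default_factory=set)

    def add_pair(self, a: str, b: str, origin: str) -> None:
        if origin not in ("wgd", "tandem"):
            raise ValueError(f"unknown origin {origin!r}")
        self.paralog_pairs[tuple(sorted((a, b)))] = origin

    def pairs(self, origin: Optional[str] = None) -> set[tuple[str, str]]:
        if origin is None:
            return set(self.paralog_pairs)
        return {p for p, o in self.paralog_pairs.items() if o == origin}

    def check_consistency(self, genome: AnnotationSet) -> None:
        for a, b in self.paralog_pairs:
            if a not in genome or b not in genome:
                raise ValueError(f"truth pair ({a}, {b}) references missing gene")


# ---------------------------------------------------------------------------
# genome construction
# ---------------------------------------------------------------------------

def simulate_base_genome(config: SimConfig) -> AnnotationSet:
    """Build a genome of non-overlapping, uniquely-labelled genes.

    Genes are packed left-to-right with multinomially sampled inter-gene
    gaps; each gene gets a unique id, a random strand, and a unique family
    label. Raises :class:`PlacementError` when the requested genes cannot
    fit on a chromosome.
    """
    config.validate()
    rng = _rng(config.seed)
    K, n, L = config.n_chromosomes, config.n_genes_per_chromosome, config.chromosome_length
    layout = AssemblyLayout((f"pchr_{k + 1}", L) for k in range(K))
    genome = AnnotationSet(layout)
    gid = 0
    for k in range(K):
        chrom = f"pchr_{k + 1}"
        lengths = rng.integers(config.gene_length[0], config.gene_length[1] + 1, size=n)
        slack = L - int(lengths.sum())
        if slack < 0:
            raise PlacementError(
                f"{chrom}: total gene length {int(lengths.sum())} exceeds "
                f"chromosome length {L}"
            )
        gaps = rng.multinomial(slack, np.full(n + 1, 1.0 / (n + 1)))
        pos = 0
        for i in range(n):
            pos += int(gaps[i])
            gid += 1
            start, end = pos, pos + int(lengths[i])
            strand = "+" if rng.random() < 0.5 else "-"
            genome.add(
                GeneModel(
                    id=f"g{gid}",
                    chromosome=chrom,
                    start=start,
                    end=end,
                    strand=strand,
                    source="sim",
                    attrs={"family": f"fam{gid}"},
                )
            )
            pos = end
    return genome


def apply_wgd(
    genome: AnnotationSet, retention: float, seed: int
) -> tuple[AnnotationSet, TruthTable]:
    """Duplicate every chromosome; retain each duplicated gene independently.

    Homolog chromosomes are named ``<name>_B`` and appended after all
    original chromosomes in assembly order, so original linearized
    coordinates are unchanged. Empty homolog chromosomes are kept.
    """
    if not 0.0 <= retention <= 1.0:
        raise ValueError(f"retention must be in [0, 1], got {retention}")
    rng = _rng(seed)
    layout = AssemblyLayout(
        list(genome.layout.items())
        + [(f"{n}_B", l) for n, l in genome.layout.items()]
    )
    out = AnnotationSet(layout)
    truth = TruthTable()
    for g in genome.sorted_genes():
        out.add(
            GeneModel(g.id, g.chromosome, g.start, g.end, g.strand, g.source,
                      list(g.exons), dict(g.attrs))
        )
    for g in genome.sorted_genes():
        if rng.random() < retention:
            dup_id = f"{g.id}_B"
            out.add(
                GeneModel(dup_id, f"{g.chromosome}_B", g.start, g.end, g.strand,
                          g.source, list(g.exons), dict(g.attrs))
            )
            truth.add_pair(g.id, dup_id, "wgd")
            truth.gene_to_source_gene[dup_id] = g.id
    return out, truth


def apply_tandem(
    genome: AnnotationSet, rate: float, max_copies: int, seed: int
) -> tuple[AnnotationSet, TruthTable]:
    """Seed tandem arrays: adjacent same-strand copies next to their source.

    Each gene independently seeds an array with probability ``rate``; the
    array size (source included) is uniform on {2, ..., max_copies}. The
    chromosome is re-packed left-to-right so copies sit immediately
    adjacent to their source and downstream genes shift right; chromosome
    lengths grow by the inserted copy length. Truth pairs connect every
    copy in an array to the source gene.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"rate must be in [0, 1], got {rate}")
    if max_copies < 2:
        raise PlacementError("tandem arrays need max_copies >= 2")
    rng = _rng(seed)
    truth = TruthTable()
    new_lengths: dict[str, int] = dict(genome.layout.lengths)
    placed: list[GeneModel] = []
    order = {n: i for i, n in enumerate(genome.layout.names)}
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in sorted(genome, key=lambda g: (order[g.chromosome], g.start, g.id)):
        by_chrom.setdefault(g.chromosome, []).append(g)
    for chrom in genome.layout.names:
        shift = 0
        for g in by_chrom.get(chrom, []):
            start, end = g.start + shift, g.end + shift
            placed.append(
                GeneModel(g.id, chrom, start, end, g.strand, g.source,
                          [(a + shift, b + shift) for a, b in g.exons], dict(g.attrs))
            )
            if rng.random() < rate:
                n_copies = int(rng.integers(2, max_copies + 1)) - 1
                for c in range(1, n_copies + 1):
                    cid = f"{g.id}_t{c}"
                    cstart = end + (c - 1) * g.length
                    placed.append(
                        GeneModel(cid, chrom, cstart, cstart + g.length, g.strand,
                                  g.source, None, dict(g.attrs))
                    )
                    truth.add_pair(g.id, cid, "tandem")
                    truth.gene_to_source_gene[cid] = g.id
                shift += n_copies * g.length
        new_lengths[chrom] = genome.layout.lengths[chrom] + shift
    layout = AssemblyLayout((n, new_lengths[n]) for n in genome.layout.names)
    return AnnotationSet(layout, placed), truth


# ---------------------------------------------------------------------------
# alignment evidence
# ---------------------------------------------------------------------------

def transcript_to_gene(seq_id: str) -> str:
    """Map simulator transcript ids (``<gene>.t<k>``) back to their gene."""
    return seq_id.rsplit(".t", 1)[0] if ".t" in seq_id else seq_id


def emit_self_hits(
    genome: AnnotationSet,
    truth: TruthTable,
    detectability: float,
    spurious_hit_rate: float,
    seed: int,
) -> pd.DataFrame:
    """Emit a 13-column all-vs-all self-alignment table.

    Every gene gets a perfect self-hit. Each truth pair yields a reciprocal
    hit pair with probability ``detectability`` (log10 e-value uniform on
    [-80, -20]); some true pairs additionally emit a second, weaker
    isoform-level row to exercise downstream collapsing. Spurious hits
    (expected ``spurious_hit_rate`` per gene) connect random non-truth gene
    pairs with weak e-values (log10 uniform on [-10, -4]).
    """
    if not 0.0 <= detectability <= 1.0:
        raise ValueError("detectability must be in [0, 1]")
    if spurious_hit_rate < 0:
        raise ValueError("spurious_hit_rate must be >= 0")
    rng = _rng(seed)
    genes = [g.id for g in genome.sorted_genes()]
    plen = {g.id: max(50, g.length // 3) for g in genome}
    rows: list[tuple] = []

    def _row(q: str, t: str, evalue: float, bits: float, fident: float,
             qiso: int = 1, tiso: int = 1) -> tuple:
        alnlen = min(plen[q], plen[t])
        mism = int(round(alnlen * (1 - fident)))
        return (
            f"{q}.t{qiso}", f"{t}.t{tiso}", round(fident, 3), alnlen, mism,
            0, 1, alnlen, 1, alnlen, evalue, round(bits, 1), plen[q],
        )

    for gid in genes:
        rows.append(_row(gid, gid, 0.0, 2.0 * plen[gid], 1.0))
    for (a, b) in sorted(truth.pairs()):
        if rng.random() >= detectability:
            continue
        log_e = rng.uniform(-80, -20)
        fident = rng.uniform(0.5, 0.95)
        bits = rng.uniform(150, 600)
        rows.append(_row(a, b, 10.0 ** log_e, bits, fident))
        rows.append(_row(b, a, 10.0 ** log_e, bits, fident))
        if rng.random() < 0.3:  # isoform-level duplicate row, strictly weaker
            rows.append(_row(a, b, 10.0 ** (log_e + 5), bits * 0.8, fident, qiso=2))
    n_spurious = int(rng.poisson(spurious_hit_rate * len(genes)))
    truth_pairs = truth.pairs()
    for _ in range(n_spurious):
        for _attempt in range(20):
            a, b = (genes[i] for i in rng.integers(0, len(genes), size=2))
            if a != b and tuple(sorted((a, b))) not in truth_pairs:
                break
        else:
            continue
        log_e = rng.uniform(-10, -4)
        rows.append(_row(a, b, 10.0 ** log_e, rng.uniform(40, 90), rng.uniform(0.2, 0.4)))
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


# ---------------------------------------------------------------------------
# annotation evidence
# ---------------------------------------------------------------------------

def emit_annotation_evidence(
    genome: AnnotationSet, noise: EvidenceNoise, seed: int
) -> tuple[list[TranscriptCluster], list[GeneModel], list[GeneModel], dict[str, list[GeneModel]]]:
    """Emit transcript clusters and ab initio / de novo gene-model evidence.

    Returns ``(clusters, models_r1, models_r2, denovo_maps)``. Every
    emitted record carries its ground-truth gene id(s) in
    ``attrs['true_genes']``. See :class:`EvidenceNoise` for the noise
    semantics.
    """
    noise.validate()
    rng = _rng(seed)
    order = {n: i for i, n in enumerate(genome.layout.names)}
    genes = sorted(genome, key=lambda g: (order[g.chromosome], g.start, g.id))

    withheld: dict[str, str] = {}  # gene id -> "r2" | "denovo"
    for g in genes:
        if rng.random() < noise.p_novel:
            withheld[g.id] = "r2" if rng.random() < 0.5 else "denovo"

    clusters: list[TranscriptCluster] = []
    cl_counter = 0
    cluster_of: dict[str, str] = {}
    for g in genes:
        if g.id in withheld:
            continue
        if rng.random() < noise.p_cluster_cover:
            cl_counter += 1
            cid = f"PB.{cl_counter}"
            n_tr = int(rng.integers(1, 6))
            transcripts = []
            jmax = max(1, g.length // 10)
            for j in range(1, n_tr + 1):
                a = max(0, g.start - int(rng.integers(0, jmax)))
                b = min(genome.layout.lengths[g.chromosome], g.end + int(rng.integers(0, jmax)))
                transcripts.append(Transcript(f"{cid}.{j}", a, b))
            clusters.append(TranscriptCluster(cid, g.chromosome, g.strand, transcripts))
            cluster_of[g.id] = cid

    models_r1: list[GeneModel] = []
    m_counter = 0
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        if g.id not in withheld:
            by_chrom.setdefault(g.chromosome, []).append(g)
    for chrom in genome.layout.names:
        row = by_chrom.get(chrom, [])
        i = 0
        while i < len(row):
            g = row[i]
            u = rng.random()
            if u < noise.p_fusion and i + 1 < len(row):
                nxt = row[i + 1]
                m_counter += 1
                models_r1.append(
                    GeneModel(f"g{m_counter}", chrom, g.start, nxt.end, g.strand,
                              "braker1", None,
                              {"true_genes": f"{g.id},{nxt.id}", "fused": True})
                )
                i += 2
                continue
            if u < noise.p_fusion + noise.p_split:
                mid = (g.start + g.end) // 2
                for part, (a, b) in enumerate(((g.start, mid), (mid + 1, g.end)), 1):
                    m_counter += 1
                    models_r1.append(
                        GeneModel(f"g{m_counter}", chrom, a, b, g.strand, "braker1",
                                  None, {"true_genes": g.id, "split_part": part})
                    )
            else:
                m_counter += 1
                models_r1.append(
                    GeneModel(f"g{m_counter}", chrom, g.start, g.end, g.strand,
                              "braker1", list(g.exons), {"true_genes": g.id})
                )
            i += 1

    models_r2: list[GeneModel] = []
    denovo_maps: dict[str, list[GeneModel]] = {s: [] for s in DENOVO_STAGES}
    r2_counter = 0
    dn_counter = 0
    other_stages = [s for s in DENOVO_STAGES if s != ANCHOR_STAGE]
    for g in genes:
        route = withheld.get(g.id)
        if route == "r2":
            r2_counter += 1
            models_r2.append(
                GeneModel(f"g{r2_counter}", g.chromosome, g.start, g.end, g.strand,
                          "braker2", list(g.exons), {"true_genes": g.id})
            )
        elif route == "denovo":
            dn_counter += 1
            other = other_stages[int(rng.integers(0, len(other_stages)))]
            for stage, tag in ((ANCHOR_STAGE, "a"), (other, "b")):
                denovo_maps[stage].append(
                    GeneModel(f"DN{dn_counter}{tag}", g.chromosome, g.start, g.end,
                              g.strand, "denovo", list(g.exons), {"true_genes": g.id})
                )
    return clusters, models_r1, models_r2, denovo_maps


# ---------------------------------------------------------------------------
# taxonomic hits and read repeat profiles
# ---------------------------------------------------------------------------

_METAZOAN_LINEAGE = "Eukaryota;Metazoa;Arthropoda"
_CONTAM_LINEAGES = ("Eukaryota;Fungi", "Bacteria;Proteobacteria", "Eukaryota;Viridiplantae")


def emit_tax_hits(
    scaffolds: Union[AnnotationSet, AssemblyLayout, list[str]],
    contaminant_fraction: float,
    hits_per_scaffold: int,
    metazoan_fraction_clean: float,
    metazoan_fraction_contam: float,
    seed: int,
) -> tuple[pd.DataFrame, set[str]]:
    """Emit a per-scaffold taxonomic hit table plus the truth contaminant set.

    Each scaffold is a contaminant with probability ``contaminant_fraction``;
    its hits are metazoan with the corresponding metazoan probability.
    """
    for name, v in (
        ("contaminant_fraction", contaminant_fraction),
        ("metazoan_fraction_clean", metazoan_fraction_clean),
        ("metazoan_fraction_contam", metazoan_fraction_contam),
    ):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    if isinstance(scaffolds, AnnotationSet):
        names = list(scaffolds.layout.names)
    elif isinstance(scaffolds, AssemblyLayout):
        names = list(scaffolds.names)
    else:
        names = list(scaffolds)
    rng = _rng(seed)
    rows = []
    contaminants: set[str] = set()
    for s in names:
        is_contam = rng.random() < contaminant_fraction
        if is_contam:
            contaminants.add(s)
        p = metazoan_fraction_contam if is_contam else metazoan_fraction_clean
        for h in range(1, hits_per_scaffold + 1):
            if rng.random() < p:
                lineage = _METAZOAN_LINEAGE
            else:
                lineage = _CONTAM_LINEAGES[int(rng.integers(0, len(_CONTAM_LINEAGES)))]
            rows.append((s, f"{s}_hit{h}", lineage, float(np.round(rng.uniform(50, 300), 1))))
    return pd.DataFrame(rows, columns=["scaffold_id", "hit_id", "lineage", "score"]), contaminants


def emit_read_repeat_profiles(
    n_reads: int,
    repeat_fraction_sampler: Union[Callable[[np.random.Generator, int], np.ndarray], tuple],
    seed: int,
) -> pd.DataFrame:
    """Emit read repeat profiles: read length and repeat-masked fraction.

    ``repeat_fraction_sampler`` is either a callable ``(rng, n) -> array``
    or a spec tuple ``("uniform", lo, hi)`` / ``("constant", value)``.
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    rng = _rng(seed)
    if callable(repeat_fraction_sampler):
        fractions = np.asarray(repeat_fraction_sampler(rng, n_reads), dtype=float)
    else:
        kind = repeat_fraction_sampler[0]
        if kind == "uniform":
            _, lo, hi = repeat_fraction_sampler
            fractions = rng.uniform(lo, hi, size=n_reads)
        elif kind == "constant":
            fractions = np.full(n_reads, float(repeat_fraction_sampler[1]))
        else:
            raise ValueError(f"unknown sampler spec {repeat_fraction_sampler!r}")
    if ((fractions < 0) | (fractions > 1)).any():
        raise ValueError("sampled repeat fractions must be in [0, 1]")
    lengths = rng.integers(1_000, 20_001, size=n_reads)
    repeat_bases = np.rint(fractions * lengths).astype(int)
    df = pd.DataFrame(
        {
            "read_id": [f"read{i + 1}" for i in range(n_reads)],
            "read_length": lengths,
            "repeat_bases": repeat_bases,
        }
    )
    df["repeat_fraction"] = df["repeat_bases"] / df["read_length"]
    return df
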