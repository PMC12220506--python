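"""Genome self-synteny: Oxford grid and chromosome contribution matrix.

Screens a genome for whole-genome duplication (WGD) signatures from an
all-vs-all protein self-alignment. Transcript-level alignment rows are
collapsed to gene pairs (best score per directed pair), self-pairs are
dropped, an e-value threshold is applied, and per query gene only the best
hit per target chromosome is kept — so two chromosomes sharing a large
gene family do not inflate their connection. Surviving pairs are plotted
on a linearized Oxford grid (gene midpoints on concatenated chromosomes)
and aggregated into a K x K contribution matrix whose cell (x, y) is the
percentage of genes on chromosome x with a retained putative paralog on
chromosome y. A WGD leaves strong off-diagonal blocks pairing homologous
chromosomes; tandem-duplication-dominated genomes concentrate signal on
the diagonal.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .core import AnnotationSet, AssemblyLayout

DEFAULT_THRESHOLDS = (1e-5, 1e-60)

PAIR_COLUMNS = [
    "query_gene",
    "target_gene",
    "query_chromosome",
    "target_chromosome",
    "evalue",
    "bits",
    "same_chromosome",
]


@dataclass
class GenePosition:
    gene_id: str
    chromosome: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"gene {self.gene_id}: bad interval ({self.start}, {self.end})")


def positions_from_annotation(annotation: AnnotationSet) -> dict[str, GenePosition]:
    return {
        g.id: GenePosition(g.id, g.chromosome, g.start, g.end) for g in annotation
    }


def _resolve(mapping: Union[Mapping[str, str], Callable[[str], str]], seq_id: str) -> str:
    if callable(mapping):
        return mapping(seq_id)
    return mapping[seq_id]


def filter_self_hits(
    hits: pd.DataFrame,
    transcript_to_gene: Union[Mapping[str, str], Callable[[str], str]],
    positions: Mapping[str, GenePosition],
    evalue_threshold: float,
    min_query_coverage: Optional[float] = None,
    best_by: str = "bits",
) -> pd.DataFrame:
    """Reduce an all-vs-all alignment table to filtered gene-level paralog pairs.

    Steps, in order: (1) collapse transcript/isoform rows to directed gene
    pairs keeping the best-scoring row per pair (``best_by``: "bits",
    the scoring column, or "evalue"); (2) drop self-pairs; (3) apply
    ``evalue <= evalue_threshold``; (4) per query gene and target
    chromosome keep only the best e-value pair (ties: higher bitscore,
    then lexicographically smaller target id). ``min_query_coverage``
    optionally drops rows with alnlen/qlen below the given fraction at
    ingest (the table carries no target length, so only query-relative
    coverage can be enforced). Unresolvable sequence ids raise with the
    offenders listed.
    """
    if best_by not in ("bits", "evalue"):
        raise ValueError("best_by must be 'bits' or 'evalue'")
    df = hits.copy()
    if min_query_coverage is not None:
        df = df[df["alnlen"] / df["qlen"] >= min_query_coverage]
    if df.empty:
        return pd.DataFrame(columns=PAIR_COLUMNS)

    bad: list[str] = []

    def to_gene(seq_id: str) -> str:
        try:
            return _resolve(transcript_to_gene, seq_id)
        except KeyError:
            bad.append(seq_id)
            return seq_id

    df = df.assign(
        query_gene=df["qseqid"].map(to_gene), target_gene=df["tseqid"].map(to_gene)
    )
    if bad:
        raise KeyError(f"unresolvable sequence ids: {sorted(set(bad))[:10]}")
    missing = sorted(
        {g for g in pd.concat([df["query_gene"], df["target_gene"]]).unique() if g not in positions}
    )
    if missing:
        raise KeyError(f"gene ids without a genome position: {missing[:10]}")

    # (1) best row per directed gene pair
    if best_by == "bits":
        rank = df.sort_values(["bits", "evalue"], ascending=[False, True], kind="mergesort")
    else:
        rank = df.sort_values(["evalue", "bits"], ascending=[True, False], kind="mergesort")
    collapsed = rank.drop_duplicates(subset=["query_gene", "target_gene"], keep="first")
    # (2) self-pairs out
    collapsed = collapsed[collapsed["query_gene"] != collapsed["target_gene"]]
    # (3) analysis threshold
    collapsed = collapsed[collapsed["evalue"] <= evalue_threshold]
    if collapsed.empty:
        return pd.DataFrame(columns=PAIR_COLUMNS)
    collapsed = collapsed.assign(
        query_chromosome=collapsed["query_gene"].map(lambda g: positions[g].chromosome),
        target_chromosome=collapsed["target_gene"].map(lambda g: positions[g].chromosome),
    )
    # (4) best e-value per (query gene, target chromosome);
    # e-value 0 is the most significant possible value, ties by bitscore
    # then lexicographic target id
    collapsed = collapsed.sort_values(
        ["evalue", "bits", "target_gene"], ascending=[True, False, True], kind="mergesort"
    ).drop_duplicates(subset=["query_gene", "target_chromosome"], keep="first")
    out = collapsed.assign(
        same_chromosome=collapsed["query_chromosome"] == collapsed["target_chromosome"]
    )[PAIR_COLUMNS]
    return out.sort_values(["query_gene", "target_gene"], kind="mergesort").reset_index(drop=True)


def linear_coordinate(gene: GenePosition, layout: AssemblyLayout) -> float:
    """Linearized coordinate: chromosome offset plus the gene midpoint."""
    if gene.chromosome not in layout:
        raise KeyError(f"gene {gene.gene_id}: unknown chromosome {gene.chromosome!r}")
    return layout.offset(gene.chromosome) + (gene.start + gene.end) / 2.0


def build_oxford_grid(
    pairs: pd.DataFrame,
    positions: Mapping[str, GenePosition],
    layout: AssemblyLayout,
) -> pd.DataFrame:
    """One grid point per pair: x = target coordinate, y = query coordinate."""
    if pairs.empty:
        return pd.DataFrame(columns=["x", "y", "same_chromosome"])
    xs = [linear_coordinate(positions[g], layout) for g in pairs["target_gene"]]
    ys = [linear_coordinate(positions[g], layout) for g in pairs["query_gene"]]
    return pd.DataFrame(
        {"x": xs, "y": ys, "same_chromosome": pairs["same_chromosome"].to_numpy()}
    )


def contribution_matrix(
    pairs: pd.DataFrame,
    gene_counts: Mapping[str, int],
    chromosomes: Optional[Sequence[str]] = None,
    mode: str = "caption",
) -> pd.DataFrame:
    """K x K percentage matrix of cross-chromosome paralog contributions.

    In the default ``caption`` mode, cell (x, y) is 100 x (distinct genes
    on chromosome x with a surviving pair to a gene on chromosome y) /
    gene_count(x). ``donor`` mode normalizes the same count by the gene
    count of the contributing chromosome y instead. The diagonal is
    computed the same way from same-chromosome pairs. The counting unit is
    distinct genes, so a gene contributes at most 1 per cell.
    """
    if mode not in ("caption", "donor"):
        raise ValueError("mode must be 'caption' or 'donor'")
    if chromosomes is None:
        chromosomes = sorted(gene_counts)
    for c in chromosomes:
        if gene_counts.get(c, 0) <= 0:
            incident = (
                not pairs.empty
                and ((pairs["query_chromosome"] == c) | (pairs["target_chromosome"] == c)).any()
            )
            if incident:
                raise ValueError(f"chromosome {c!r} has incident pairs but zero genes")
    mat = pd.DataFrame(0.0, index=list(chromosomes), columns=list(chromosomes))
    if not pairs.empty:
        counts = (
            pairs.groupby(["query_chromosome", "target_chromosome"])["query_gene"]
            .nunique()
            .reset_index(name="n_genes")
        )
        for row in counts.itertuples(index=False):
            x, y = row.query_chromosome, row.target_chromosome
            if x not in mat.index or y not in mat.columns:
                continue
            denom = gene_counts[x] if mode == "caption" else gene_counts[y]
            mat.loc[x, y] = 100.0 * row.n_genes / denom
    mat.attrs["mode"] = mode
    return mat


def summarize_contributions(matrix: pd.DataFrame) -> dict[str, float]:
    """Off-diagonal mean/min/max, diagonal mean, and the contrast ratio.

    The contrast ratio is diagonal mean over off-diagonal mean (reported
    as ``inf`` when the off-diagonal mean is zero): a diagonal-dominated
    matrix is the tandem-duplication signature, strong off-diagonal cells
    the WGD one.
    """
    a = matrix.to_numpy(dtype=float)
    if a.shape[0] != a.shape[1]:
        raise ValueError("matrix must be square")
    if a.shape[0] < 2:
        raise ValueError("off-diagonal statistics undefined for a 1x1 matrix")
    off = a[~np.eye(a.shape[0], dtype=bool)]
    diag = np.diag(a)
    off_mean = float(off.mean())
    diag_mean = float(diag.mean())
    contrast = float("inf") if off_mean == 0 else diag_mean / off_mean
    return {
        "offdiag_mean": off_mean,
        "offdiag_min": float(off.min()),
        "offdiag_max": float(off.max()),
        "diag_mean": diag_mean,
        "contrast_ratio": contrast,
    }


def paralog_content_distribution(
    hits: pd.DataFrame,
    transcript_to_gene: Union[Mapping[str, str], Callable[[str], str]],
    positions: Mapping[str, GenePosition],
    gene_counts: Mapping[str, int],
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    **filter_kwargs,
) -> pd.DataFrame:
    """Per-chromosome fraction of genes with a cross-chromosome paralog.

    Computed for each e-value threshold (normalized to descending
    stringency internally); fractions are monotonically non-increasing as
    thresholds get stricter, since the surviving pair set only shrinks.
    """
    thresholds = sorted(set(float(t) for t in thresholds), reverse=True)
    rows = []
    for t in thresholds:
        pairs = filter_self_hits(hits, transcript_to_gene, positions, t, **filter_kwargs)
        cross = pairs[~pairs["same_chromosome"]] if not pairs.empty else pairs
        per_chrom = (
            cross.groupby("query_chromosome")["query_gene"].nunique()
            if not cross.empty
            else pd.Series(dtype=int)
        )
        for chrom, n_genes in gene_counts.items():
            frac = float(per_chrom.get(chrom, 0)) / n_genes if n_genes else 0.0
            rows.append({"threshold": t, "chromosome": chrom, "fraction": frac})
    return pd.DataFrame(rows)


def score_duplication_signal(
    matrix: pd.DataFrame, min_cell: float = 5.0
) -> tuple[dict[str, Optional[tuple[str, float]]], list[tuple[str, str]]]:
    """Per-chromosome best off-diagonal partner plus a mutual-best matching.

    For each chromosome the arg-max off-diagonal cell is its candidate
    partner; candidates below ``min_cell`` (percent) are reported as
    ``None``. The genome-level report is the greedy mutual-best matching:
    pairs (a, b) where each is the other's partner.
    """
    if matrix.shape[0] != matrix.shape[1] or matrix.shape[0] < 2:
        raise ValueError("matrix must be square with K >= 2")
    partners: dict[str, Optional[tuple[str, float]]] = {}
    for x in matrix.index:
        row = matrix.loc[x].drop(labels=[x])
        best = row.idxmax()
        val = float(row[best])
        partners[x] = (best, val) if val >= min_cell else None
    matching = []
    for x in matrix.index:
        p = partners[x]
        if p is None:
            continue
        y = p[0]
        q = partners.get(y)
        if q is not None and q[0] == x and str(x) < str(y):
            matching.append((x, y))
    return partners, matching


# ---------------------------------------------------------------------------
# plotting (minimal exports; aesthetics unspecified)
# ---------------------------------------------------------------------------

def plot_oxford_grid(grid: pd.DataFrame, layout: AssemblyLayout, path=None):
    """Scatter the grid (same-chromosome points highlighted); optionally save."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    if not grid.empty:
        same = grid[grid["same_chromosome"].astype(bool)]
        diff = grid[~grid["same_chromosome"].astype(bool)]
        ax.scatter(diff["x"], diff["y"], s=3, c="gray", label="different chromosome")
        ax.scatter(same["x"], same["y"], s=3, c="red", label="same chromosome")
    edges = np.cumsum([0] + [l for _, l in layout.items()])
    for e in edges:
        ax.axvline(e, lw=0.3, c="k", alpha=0.3)
        ax.axhline(e, lw=0.3, c="k", alpha=0.3)
    ax.set_xlabel("target coordinate (bp, linearized)")
    ax.set_ylabel("query coordinate (bp, linearized)")
    ax.set_xlim(0, layout.total_length)
    ax.set_ylim(0, layout.total_length)
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_contribution_heatmap(matrix: pd.DataFrame, path=None):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(matrix.to_numpy(), cmap="viridis")
    fig.colorbar(im, ax=ax, label="% of gene pool")
    ax.set_xlabel("contributing chromosome")
    ax.set_ylabel("chromosome")
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
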