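"""Readers and writers for the formats shared by all stages.

GFF3 is 1-based inclusive on disk and converted to 0-based half-open
internally; the conversion is exact and involutive. Tabular inputs (hit
tables, taxonomic hits, read profiles, chromosome lengths) are plain TSV.
"""
from __future__ import annotations

import io
import warnings
from pathlib import Path
from typing import Iterable, Optional, Union

import gffutils
import pandas as pd

from .core import (
    AnnotationSet,
    AssemblyLayout,
    GeneModel,
    Transcript,
    TranscriptCluster,
)

PathLike = Union[str, Path]

#: Column names of the 13-column all-vs-all alignment table (outfmt-6-like,
#: plus query length): query id, target id, fraction of identical matches,
#: alignment length, mismatches, gap opens, query start/end, target
#: start/end, e-value, bit score, query length.
HIT_COLUMNS = [
    "qseqid",
    "tseqid",
    "fident",
    "alnlen",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "tstart",
    "tend",
    "evalue",
    "bits",
    "qlen",
]

_HIT_DTYPES = {
    "qseqid": str,
    "tseqid": str,
    "fident": float,
    "alnlen": int,
    "mismatch": int,
    "gapopen": int,
    "qstart": int,
    "qend": int,
    "tstart": int,
    "tend": int,
    "evalue": float,
    "bits": float,
    "qlen": int,
}


class FormatError(ValueError):
    """Raised for malformed input files; the message names the offending line."""


# ---------------------------------------------------------------------------
# chromosome layout (faidx-style name/length TSV)
# ---------------------------------------------------------------------------

def read_layout_tsv(path: PathLike) -> AssemblyLayout:
    pairs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected 'name<TAB>length'")
            try:
                pairs.append((parts[0], int(parts[1])))
            except ValueError as e:
                raise FormatError(f"{path}:{lineno}: bad length {parts[1]!r}") from e
    return AssemblyLayout(pairs)


def write_layout_tsv(layout: AssemblyLayout, path: PathLike) -> None:
    with open(path, "w") as fh:
        for name, length in layout.items():
            fh.write(f"{name}\t{length}\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def _validate_gff_lines(path: PathLike) -> int:
    """Pre-scan a GFF3 file; returns the number of feature lines.

    gffutils silently skips unparseable lines, so malformed rows are
    rejected here with their line number instead.
    """
    n_features = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise FormatError(
                    f"{path}: line {lineno}: expected 9 tab-separated GFF3 "
                    f"columns, found {len(parts)}"
                )
            try:
                int(parts[3]), int(parts[4])
            except ValueError:
                raise FormatError(
                    f"{path}: line {lineno}: non-integer coordinates "
                    f"({parts[3]!r}, {parts[4]!r})"
                ) from None
            n_features += 1
    return n_features


def _gff_db(path: PathLike) -> gffutils.FeatureDB:
    try:
        return gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as e:  # gffutils raises assorted exceptions for bad input
        raise FormatError(f"{path}: not parseable as GFF3 ({e})") from e


def read_gff3(path: PathLike, layout: Optional[AssemblyLayout] = None) -> AnnotationSet:
    """Read a gene/exon GFF3 file into an :class:`AnnotationSet`.

    If no layout is given, one is built from the ``##sequence-region``
    pragmas, or failing that from the maximal feature coordinates.
    """
    if _validate_gff_lines(path) == 0:
        if layout is None:
            regions = _sequence_regions(path)
            if not regions:
                raise FormatError(f"{path}: no features and no sequence-region pragmas")
            layout = AssemblyLayout(regions)
        return AnnotationSet(layout)
    db = _gff_db(path)
    genes: list[GeneModel] = []
    seq_extent: dict[str, int] = {}
    for f in db.features_of_type("gene", order_by=("seqid", "start")):
        exons = []
        for ex in db.children(f, featuretype="exon", order_by="start"):
            exons.append((ex.start - 1, ex.end))
        source = f.attributes.get("source_class", [f.source])[0]
        genes.append(
            GeneModel(
                id=f.id,
                chromosome=f.seqid,
                start=f.start - 1,
                end=f.end,
                strand=f.strand,
                source=source,
                exons=exons or None or [],
            )
        )
        seq_extent[f.seqid] = max(seq_extent.get(f.seqid, 0), f.end)
    if layout is None:
        regions = _sequence_regions(path)
        if regions:
            layout = AssemblyLayout(regions)
        else:
            layout = AssemblyLayout(sorted(seq_extent.items()))
    return AnnotationSet(layout, genes)


def _sequence_regions(path: PathLike) -> list[tuple[str, int]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    out.append((parts[1], int(parts[3])))
            elif not line.startswith("#"):
                break
    return out


def write_gff3(annotation: AnnotationSet, path: PathLike) -> None:
    """Write genes and their exons as GFF3 (1-based inclusive on disk)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for name, length in annotation.layout.items():
            fh.write(f"##sequence-region {name} 1 {length}\n")
        for g in annotation.sorted_genes():
            attrs = f"ID={g.id};source_class={g.source}"
            fh.write(
                f"{g.chromosome}\t{g.source}\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )
            for i, (a, b) in enumerate(g.exons, 1):
                fh.write(
                    f"{g.chromosome}\t{g.source}\texon\t{a + 1}\t{b}\t.\t"
                    f"{g.strand}\t.\tID={g.id}.exon{i};Parent={g.id}\n"
                )


def read_clusters_gff3(path: PathLike) -> list[TranscriptCluster]:
    """Read transcript clusters from GFF3 (gene -> mRNA -> exon hierarchy)."""
    if _validate_gff_lines(path) == 0:
        return []
    db = _gff_db(path)
    clusters = []
    for f in db.features_of_type("gene", order_by=("seqid", "start")):
        transcripts = []
        for t in db.children(f, featuretype=("mRNA", "transcript"), order_by="start"):
            exons = [(ex.start - 1, ex.end) for ex in db.children(t, featuretype="exon", order_by="start")]
            transcripts.append(Transcript(t.id, t.start - 1, t.end, exons or None))
        if not transcripts:
            transcripts = [Transcript(f.id + ".t1", f.start - 1, f.end)]
        clusters.append(TranscriptCluster(f.id, f.seqid, f.strand, transcripts))
    return clusters


def write_clusters_gff3(clusters: Iterable[TranscriptCluster], layout: AssemblyLayout, path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for name, length in layout.items():
            fh.write(f"##sequence-region {name} 1 {length}\n")
        for c in clusters:
            a, b = c.span
            fh.write(f"{c.chromosome}\tiso\tgene\t{a + 1}\t{b}\t.\t{c.strand}\t.\tID={c.id}\n")
            for t in c.transcripts:
                fh.write(
                    f"{c.chromosome}\tiso\tmRNA\t{t.start + 1}\t{t.end}\t.\t{c.strand}\t.\t"
                    f"ID={t.id};Parent={c.id}\n"
                )
                for i, (ea, eb) in enumerate(t.exons or [(t.start, t.end)], 1):
                    fh.write(
                        f"{c.chromosome}\tiso\texon\t{ea + 1}\t{eb}\t.\t{c.strand}\t.\t"
                        f"ID={t.id}.exon{i};Parent={t.id}\n"
                    )


# ---------------------------------------------------------------------------
# tabular inputs
# ---------------------------------------------------------------------------

def read_hits_table(source: Union[PathLike, io.TextIOBase], n_columns: int = 13) -> pd.DataFrame:
    """Read the 13-column tab-separated all-vs-all alignment table.

    Every row must have exactly ``n_columns`` fields; a malformed row is
    reported with its line number. Scientific-notation e-values parse
    exactly via float.
    """
    name = getattr(source, "name", None) or str(source)
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            lines = fh.readlines()
    else:
        lines = source.readlines()
    rows = []
    for lineno, line in enumerate(lines, 1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != n_columns:
            raise FormatError(
                f"{name}: line {lineno}: expected {n_columns} tab-separated "
                f"columns, found {len(parts)}"
            )
        rows.append(parts)
    df = pd.DataFrame(rows, columns=HIT_COLUMNS[:n_columns])
    try:
        df = df.astype({k: v for k, v in _HIT_DTYPES.items() if k in df.columns})
    except ValueError as e:
        raise FormatError(f"{name}: unparseable numeric field ({e})") from e
    if (df["evalue"] < 0).any():
        bad = df.index[df["evalue"] < 0][0]
        raise FormatError(f"{name}: negative e-value in data row {bad + 1}")
    return df


def write_hits_table(hits: pd.DataFrame, path: PathLike) -> None:
    hits.to_csv(path, sep="\t", header=False, index=False)


def read_tax_hits(path: PathLike, strict: bool = True) -> pd.DataFrame:
    """Read taxonomic hits as TSV: scaffold, hit id, lineage (or 0/1), score.

    Malformed rows are fatal when ``strict``; otherwise they are skipped
    with a warning that names the line.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4 or not parts[0]:
                msg = f"{path}: line {lineno}: expected 'scaffold<TAB>hit<TAB>lineage<TAB>score'"
                if strict:
                    raise FormatError(msg)
                warnings.warn(msg + " (skipped)")
                continue
            try:
                score = float(parts[3])
            except ValueError:
                msg = f"{path}: line {lineno}: bad score {parts[3]!r}"
                if strict:
                    raise FormatError(msg)
                warnings.warn(msg + " (skipped)")
                continue
            rows.append((parts[0], parts[1], parts[2], score))
    return pd.DataFrame(rows, columns=["scaffold_id", "hit_id", "lineage", "score"])


def write_tax_hits(hits: pd.DataFrame, path: PathLike) -> None:
    hits.to_csv(path, sep="\t", header=False, index=False)


def read_read_profiles(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        names=["read_id", "read_length", "repeat_bases"],
        dtype={"read_id": str, "read_length": int, "repeat_bases": int},
    )
    df["repeat_fraction"] = df["repeat_bases"] / df["read_length"]
    return df


def write_read_profiles(profiles: pd.DataFrame, path: PathLike) -> None:
    profiles[["read_id", "read_length", "repeat_bases"]].to_csv(
        path, sep="\t", header=False, index=False
    )


# ---------------------------------------------------------------------------
# FASTA (optional sequence support)
# ---------------------------------------------------------------------------

def rename_fasta(src: PathLike, dst: PathLike, mapping: dict[str, str], keep: Optional[set] = None) -> None:
    """Copy a FASTA applying a scaffold renaming map, optionally dropping records."""
    from Bio import SeqIO

    records = []
    for rec in SeqIO.parse(str(src), "fasta"):
        if keep is not None and rec.id not in keep:
            continue
        new_id = mapping.get(rec.id, rec.id)
        rec.id = new_id
        rec.description = new_id
        records.append(rec)
    SeqIO.write(records, str(dst), "fasta")


def rename_annotation(annotation: AnnotationSet, mapping: dict[str, str]) -> AnnotationSet:
    """Apply a scaffold renaming map to a whole annotation (layout + genes)."""
    new_layout = annotation.layout.renamed(mapping)
    genes = []
    for g in annotation:
        genes.append(
            GeneModel(
                id=g.id,
                chromosome=mapping.get(g.chromosome, g.chromosome),
                start=g.start,
                end=g.end,
                strand=g.strand,
                source=g.source,
                exons=list(g.exons),
                attrs=dict(g.attrs),
            )
        )
    return AnnotationSet(new_layout, genes)
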