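"""Scaffold decontamination by taxonomic majority vote and repeat-read triage.

A scaffold is flagged as a contaminant when fewer than 90% of its protein
hits are of metazoan origin (strict inequality at the threshold); scaffolds
with no hits are kept, since absence of evidence is not treated as
contamination. Surviving numbered pseudochromosomes are renumbered
consecutively in assembly order. Suspicious long reads are triaged into
repeat classes by their repeat-masked fraction (> 50% highly repetitive,
> 25% mildly repetitive).
"""
from __future__ import annotations

import re
from typing import Iterable, Optional, Sequence

import pandas as pd

#: Taxonomic clade whose presence anywhere in a hit's lineage string marks
#: the hit as metazoan. Unresolved or unclassified lineages count as
#: non-metazoan (the conservative reading of the majority-vote rule).
METAZOAN_LABEL = "Metazoa"

DEFAULT_MIN_METAZOAN = 0.90
HIGH_REPEAT_CUTOFF = 0.50
MILD_REPEAT_CUTOFF = 0.25


def _is_metazoan(value, metazoan_label: str = METAZOAN_LABEL) -> bool:
    if isinstance(value, bool):
        return value
    if isinstance(value, (int, float)):
        return bool(value)
    parts = str(value).split(";")
    return metazoan_label in parts or str(value) == metazoan_label


def summarize_scaffold_taxonomy(
    hits: pd.DataFrame, metazoan_label: str = METAZOAN_LABEL
) -> pd.DataFrame:
    """Aggregate hits per scaffold into metazoan fractions.

    ``hits`` needs columns ``scaffold_id`` and either ``is_metazoan``
    (boolean) or ``lineage`` (semicolon-separated path; a hit is metazoan
    when the path contains the metazoan clade label). Returns one row per
    scaffold with ``n_hits`` and ``metazoan_fraction``.
    """
    if "scaffold_id" not in hits.columns:
        raise ValueError("hits table needs a 'scaffold_id' column")
    if "is_metazoan" in hits.columns:
        flags = hits["is_metazoan"].astype(bool)
    elif "lineage" in hits.columns:
        flags = hits["lineage"].map(lambda v: _is_metazoan(v, metazoan_label))
    else:
        raise ValueError("hits table needs an 'is_metazoan' or 'lineage' column")
    df = pd.DataFrame({"scaffold_id": hits["scaffold_id"], "metazoan": flags})
    grouped = df.groupby("scaffold_id", sort=True)["metazoan"].agg(["size", "sum"])
    out = pd.DataFrame(
        {
            "scaffold_id": grouped.index,
            "n_hits": grouped["size"].astype(int).to_numpy(),
            "metazoan_fraction": (grouped["sum"] / grouped["size"]).to_numpy(),
        }
    ).reset_index(drop=True)
    return out


def flag_contaminant_scaffolds(
    summaries: pd.DataFrame,
    all_scaffolds: Sequence[str],
    min_metazoan: float = DEFAULT_MIN_METAZOAN,
) -> tuple[list[str], list[str]]:
    """Partition scaffolds into (keep, remove) by the majority-vote rule.

    A scaffold is removed iff it has hits and its metazoan fraction is
    strictly below ``min_metazoan``; zero-hit scaffolds are kept. The two
    lists partition ``all_scaffolds`` and preserve its (assembly) order.
    """
    if not 0.0 <= min_metazoan <= 1.0:
        raise ValueError(f"min_metazoan must be in [0, 1], got {min_metazoan}")
    known = set(all_scaffolds)
    unknown = sorted(set(summaries["scaffold_id"]) - known)
    if unknown:
        raise ValueError(
            f"summaries mention scaffolds absent from the assembly: {unknown} "
            "(annotation/assembly mismatch)"
        )
    frac = dict(zip(summaries["scaffold_id"], summaries["metazoan_fraction"]))
    n_hits = dict(zip(summaries["scaffold_id"], summaries["n_hits"]))
    keep, remove = [], []
    for s in all_scaffolds:
        if n_hits.get(s, 0) > 0 and frac[s] < min_metazoan:
            remove.append(s)
        else:
            keep.append(s)
    return keep, remove


_NUM_RE = re.compile(r"^(?P<prefix>.*?)(?P<num>\d+)$")


def renumber_scaffolds(kept: Sequence[str], removed: Sequence[str]) -> dict[str, str]:
    """Renumber surviving numbered scaffolds consecutively in assembly order.

    Scaffold names carrying a trailing numeric component are renumbered
    1..n in their original order (width-preserving if zero-padded);
    non-numbered scaffolds map to themselves. The result is injective.
    """
    mapping: dict[str, str] = {}
    counter = 0
    for name in kept:
        m = _NUM_RE.match(name)
        if m is None:
            mapping[name] = name
            continue
        counter += 1
        num = m.group("num")
        new_num = str(counter).zfill(len(num)) if num.startswith("0") else str(counter)
        mapping[name] = f"{m.group('prefix')}{new_num}"
    if len(set(mapping.values())) != len(mapping):
        seen: dict[str, str] = {}
        for old, new in mapping.items():
            if new in seen:
                raise ValueError(f"renumbering collision: {old!r} and {seen[new]!r} both map to {new!r}")
            seen[new] = old
    overlap = set(mapping.values()) & set(removed)
    # reusing a removed scaffold's name is fine (that is the point of the
    # renumbering); only duplicates among survivors are fatal, checked above
    _ = overlap
    return mapping


def classify_repeat_reads(
    profiles: pd.DataFrame,
    high_cutoff: float = HIGH_REPEAT_CUTOFF,
    mild_cutoff: float = MILD_REPEAT_CUTOFF,
) -> dict[str, int]:
    """Count reads per repeat class.

    high: fraction > high_cutoff; mild: mild_cutoff < fraction <=
    high_cutoff; low: otherwise. Both boundaries are strict "greater than",
    so a read at exactly 25% repeat content is low and one at exactly 50%
    is mild.
    """
    if "repeat_fraction" in profiles.columns:
        frac = profiles["repeat_fraction"].astype(float)
    else:
        frac = profiles["repeat_bases"] / profiles["read_length"]
    if ((frac < 0) | (frac > 1)).any():
        bad = frac[(frac < 0) | (frac > 1)].index[0]
        raise ValueError(f"repeat fraction outside [0, 1] at row {bad}")
    high = int((frac > high_cutoff).sum())
    mild = int(((frac > mild_cutoff) & (frac <= high_cutoff)).sum())
    low = int(len(frac) - high - mild)
    return {"high": high, "mild": mild, "low": low}


def decontaminate(
    hits: pd.DataFrame,
    all_scaffolds: Sequence[str],
    min_metazoan: float = DEFAULT_MIN_METAZOAN,
    metazoan_label: str = METAZOAN_LABEL,
) -> tuple[list[str], list[str], dict[str, str]]:
    """One-call pipeline: summarize, flag, renumber. Returns (keep, remove, renaming)."""
    summaries = summarize_scaffold_taxonomy(hits, metazoan_label=metazoan_label)
    keep, remove = flag_contaminant_scaffolds(summaries, all_scaffolds, min_metazoan)
    return keep, remove, renumber_scaffolds(keep, remove)
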