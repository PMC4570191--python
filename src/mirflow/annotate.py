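"""Tag annotation: reference mapping, ncRNA removal, known-miRNA calling.

Cleaned tags are mapped to a reference transcript set (exact, full-length,
both strands), matched against a structural ncRNA catalog (rRNA / tRNA /
snoRNA / snRNA fragments are removed), and compared to a mature-miRNA
catalog with miRBase-style identifiers.  A tag is called a known miRNA
when its best ungapped distance to a catalog mature sequence is at most
two mismatches; calls are grouped into families by identifier (species
prefix and arm/variant suffixes stripped, with a configurable merge map
uniting families such as miR156/157 that are indistinguishable at the
mature level).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from ._seq import revcomp
from .preprocess import SRNATag

__all__ = [
    "KnownAssignment",
    "CountTable",
    "Locus",
    "map_reference",
    "filter_ncrna",
    "identify_known",
    "build_count_table",
    "family_name",
    "read_fasta",
    "DEFAULT_FAMILY_MERGE",
]

NCRNA_CLASSES = ("rRNA", "tRNA", "snoRNA", "snRNA")

# Families whose mature sequences are near-identical are reported jointly.
DEFAULT_FAMILY_MERGE: dict[str, str] = {
    "miR156": "miR156/157",
    "miR157": "miR156/157",
    "miR165": "miR165/166",
    "miR166": "miR165/166",
}


@dataclass(frozen=True)
class Locus:
    transcript_id: str
    start: int  # 0-based half-open
    end: int
    strand: str  # "+" | "-"


@dataclass(frozen=True)
class KnownAssignment:
    tag: SRNATag
    mirna_id: str
    family: str
    n_mismatches: int


def read_fasta(path) -> list[tuple[str, str]]:
    """Read FASTA as ``[(header_id, SEQUENCE), ...]`` preserving file order."""
    return [(rec.id, str(rec.seq).upper().replace("U", "T")) for rec in SeqIO.parse(str(path), "fasta")]


def map_reference(
    tags: Sequence[SRNATag],
    reference: Sequence[tuple[str, str]],
) -> dict[str, list[Locus]]:
    """Map each tag to all exact full-length loci on the reference.

    Both strands are searched; reverse-complement hits are reported with
    strand ``-`` and coordinates on the forward reference.  Unmapped tags
    get an empty locus list (they are retained, not dropped).
    """
    if not reference:
        raise ValueError("reference must be non-empty")
    out: dict[str, list[Locus]] = {}
    for tag in tags:
        seq = tag.sequence
        rc = revcomp(seq)
        loci: list[Locus] = []
        for tid, tseq in reference:
            for query, strand in ((seq, "+"), (rc, "-")):
                if strand == "-" and rc == seq:
                    continue  # palindromic tag: avoid double-reporting
                start = tseq.find(query)
                while start >= 0:
                    loci.append(Locus(tid, start, start + len(query), strand))
                    start = tseq.find(query, start + 1)
        out[seq] = loci
    return out


def filter_ncrna(
    tags: Sequence[SRNATag],
    ncrna_catalog: Sequence[tuple[str, str]],
) -> tuple[list[SRNATag], list[tuple[SRNATag, str]]]:
    """Remove tags matching a structural-ncRNA catalog record.

    A tag is removed iff it (or its reverse complement) is an exact
    substring of a catalog sequence; the removed tag is labeled with the
    class token (rRNA|tRNA|snoRNA|snRNA) of the first matching record in
    catalog order.  Catalog headers must carry a class token.
    """
    classes = []
    for header, _ in ncrna_catalog:
        tok = next((c for c in NCRNA_CLASSES if c.lower() in header.lower()), None)
        if tok is None:
            raise ValueError(f"ncRNA catalog header lacks a class token: {header!r}")
        classes.append(tok)

    retained: list[SRNATag] = []
    removed: list[tuple[SRNATag, str]] = []
    for tag in tags:
        rc = revcomp(tag.sequence)
        label = None
        for (header, seq), cls in zip(ncrna_catalog, classes):
            if tag.sequence in seq or rc in seq:
                label = cls
                break
        if label is None:
            retained.append(tag)
        else:
            removed.append((tag, label))
    return retained, removed


def family_name(mirna_id: str, merge: Mapping[str, str] | None = DEFAULT_FAMILY_MERGE) -> str:
    """Derive the family from a miRBase-style identifier.

    ``ath-miR156a-5p`` -> ``miR156`` (then through the merge map ->
    ``miR156/157``).  Identifiers without a recognizable ``miR``/``miRn``
    core are returned with only the species prefix stripped.
    """
    name = re.sub(r"^[a-z]{3,4}-", "", mirna_id, flags=re.IGNORECASE)
    m = re.match(r"(miRn?\d+)", name, flags=re.IGNORECASE)
    fam = m.group(1) if m else name
    if merge:
        fam = merge.get(fam, fam)
    return fam


def _ungapped_distance(a: str, b: str) -> int:
    """Best ungapped end-to-end distance between sequences of length diff <= 2.

    Equal lengths: Hamming distance.  Unequal: the shorter is slid along
    the longer; overhanging positions of the longer count as mismatches.
    Length difference > 2 is treated as no alignment (returns a large value).
    """
    if len(a) > len(b):
        a, b = b, a
    diff = len(b) - len(a)
    if diff > 2:
        return 10**9
    best = 10**9
    for off in range(diff + 1):
        mm = diff + sum(1 for x, y in zip(a, b[off : off + len(a)]) if x != y)
        best = min(best, mm)
    return best


def identify_known(
    tags: Sequence[SRNATag],
    mature_catalog: Sequence[tuple[str, str]],
    max_mm: int = 2,
    family_merge: Mapping[str, str] | None = DEFAULT_FAMILY_MERGE,
) -> list[KnownAssignment]:
    """Assign tags to known mature miRNAs at <= ``max_mm`` mismatches.

    Each tag goes to the catalog entry with the fewest ungapped mismatches
    (ties broken by catalog order); best distance above ``max_mm`` leaves
    the tag unassigned.
    """
    if not mature_catalog:
        raise ValueError("mature catalog is empty")
    out: list[KnownAssignment] = []
    for tag in tags:
        best_mm = 10**9
        best_id = None
        for mid, mseq in mature_catalog:
            mm = _ungapped_distance(tag.sequence, mseq)
            if mm < best_mm:
                best_mm, best_id = mm, mid
        if best_id is not None and best_mm <= max_mm:
            out.append(
                KnownAssignment(
                    tag=tag,
                    mirna_id=best_id,
                    family=family_name(best_id, family_merge),
                    n_mismatches=best_mm,
                )
            )
    return out


def format_ratio(count_vs: int, count_rs: int) -> str:
    """RS/VS ratio formatted to 2 decimals; VS=0 -> "–", RS=0 -> "0"."""
    if count_vs == 0:
        return "–"
    if count_rs == 0:
        return "0"
    return f"{count_rs / count_vs:.2f}"


@dataclass
class CountTable:
    """Per-miRNA and per-family count table for the two libraries."""

    mirnas: pd.DataFrame  # mirna_id, family, count_vs, count_rs, total, ratio
    families: pd.DataFrame  # family, members, count_vs, count_rs, total, ratio
    n1: int
    n2: int


def build_count_table(
    rows: Iterable[tuple[str, str, int, int]],
    n1: int,
    n2: int,
) -> CountTable:
    """Aggregate per-miRNA count rows into the two-library count table.

    Parameters
    ----------
    rows: iterable of ``(mirna_id, family, count_vs, count_rs)``; multiple
        rows per miRNA id (e.g. one per assigned tag) are summed.
    n1, n2: library clean-read totals (must be > 0).
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library totals must be > 0")
    df = pd.DataFrame(rows, columns=["mirna_id", "family", "count_vs", "count_rs"])
    if df.empty:
        empty = df.assign(total=[], ratio=[])
        fam = pd.DataFrame(columns=["family", "members", "count_vs", "count_rs", "total", "ratio"])
        return CountTable(empty, fam, n1, n2)
    per_mirna = (
        df.groupby(["mirna_id", "family"], as_index=False)[["count_vs", "count_rs"]]
        .sum()
        .sort_values(["family", "mirna_id"], kind="stable")
        .reset_index(drop=True)
    )
    per_mirna["total"] = per_mirna["count_vs"] + per_mirna["count_rs"]
    per_mirna["ratio"] = [
        format_ratio(v, r) for v, r in zip(per_mirna["count_vs"], per_mirna["count_rs"])
    ]
    fam = (
        per_mirna.groupby("family", as_index=False)
        .agg(
            members=("mirna_id", "nunique"),
            count_vs=("count_vs", "sum"),
            count_rs=("count_rs", "sum"),
        )
        .sort_values("family", kind="stable")
        .reset_index(drop=True)
    )
    fam["total"] = fam["count_vs"] + fam["count_rs"]
    fam["ratio"] = [format_ratio(v, r) for v, r in zip(fam["count_vs"], fam["count_rs"])]
    return CountTable(per_mirna, fam, n1, n2)


def assignments_to_rows(
    assignments: Sequence[KnownAssignment],
    novel_calls: Sequence[tuple[str, str, int, int]] = (),
) -> list[tuple[str, str, int, int]]:
    """Convert known assignments (plus optional novel calls) to count rows."""
    rows = [
        (a.mirna_id, a.family, a.tag.count_vs, a.tag.count_rs) for a in assignments
    ]
    rows.extend(novel_calls)
    return rows
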