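"""Raw small-RNA read cleaning, tag collapsing and length profiling.

Raw reads from a small-RNA library carry ligated adapters and several
well-known artifact classes.  :func:`clean_reads` trims the adapters and
sorts every read into exactly one accounting category, mirroring the
read-statistics table such studies publish (clean reads, 3'-adapter-null,
insert-null, 5'-adapter contaminants, short inserts, poly-A).  Clean
inserts are then collapsed to unique tags with per-library counts.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio import SeqIO

from ._seq import is_nucleotide

__all__ = [
    "CleanStats",
    "SRNATag",
    "clean_reads",
    "collapse",
    "length_distribution",
    "read_sequences",
    "write_tags_fasta",
]

MIN_TAG_LEN = 18
MAX_TAG_LEN = 30


@dataclass
class CleanStats:
    """Per-library read accounting over the fixed filter categories.

    The partition invariant is
    ``high_quality == clean_reads + adapter3_null + insert_null +
    adapter5_contaminant + shorter_than_18nt + polyA + longer_than_max``;
    ``longer_than_max`` is kept as a separate bucket because published
    accounting tables print no over-length category.
    """

    raw_reads: int = 0
    high_quality: int = 0
    clean_reads: int = 0
    adapter3_null: int = 0
    insert_null: int = 0
    adapter5_contaminant: int = 0
    shorter_than_18nt: int = 0
    polyA: int = 0
    longer_than_max: int = 0

    def check(self) -> None:
        parts = (
            self.clean_reads
            + self.adapter3_null
            + self.insert_null
            + self.adapter5_contaminant
            + self.shorter_than_18nt
            + self.polyA
            + self.longer_than_max
        )
        if parts != self.high_quality:
            raise ValueError(
                f"category partition violated: {parts} != {self.high_quality}"
            )

    def as_rows(self) -> list[tuple[str, int]]:
        rows = [
            ("raw_reads", self.raw_reads),
            ("high_quality", self.high_quality),
            ("clean_reads", self.clean_reads),
            ("adapter3_null", self.adapter3_null),
            ("insert_null", self.insert_null),
            ("adapter5_contaminant", self.adapter5_contaminant),
            ("shorter_than_18nt", self.shorter_than_18nt),
            ("polyA", self.polyA),
        ]
        if self.longer_than_max:
            rows.append(("longer_than_max", self.longer_than_max))
        return rows


@dataclass(frozen=True)
class SRNATag:
    """A unique 18-30 nt small-RNA sequence with per-library counts."""

    sequence: str
    count_vs: int = 0
    count_rs: int = 0

    def __post_init__(self) -> None:
        n = len(self.sequence)
        if not MIN_TAG_LEN <= n <= MAX_TAG_LEN:
            raise ValueError(f"tag length {n} outside [{MIN_TAG_LEN}, {MAX_TAG_LEN}]")
        if self.count_vs < 0 or self.count_rs < 0 or self.count_vs + self.count_rs < 1:
            raise ValueError("tag counts must be non-negative and sum to >= 1")

    @property
    def total(self) -> int:
        return self.count_vs + self.count_rs


def read_sequences(path) -> Iterator[tuple[str, str | None]]:
    """Yield ``(sequence, quality-or-None)`` records from FASTA/FASTQ."""
    path = str(path)
    fmt = "fastq" if path.endswith(("fastq", "fq")) else "fasta"
    for rec in SeqIO.parse(path, fmt):
        if fmt == "fastq":
            quals = rec.letter_annotations["phred_quality"]
            yield str(rec.seq).upper(), quals
        else:
            yield str(rec.seq).upper(), None


def clean_reads(
    raw: Iterable[tuple[str, Sequence[int] | None] | str],
    adapter5: str,
    adapter3: str,
    min_len: int = MIN_TAG_LEN,
    max_len: int = MAX_TAG_LEN,
    polya_threshold: float = 0.9,
    adapter3_seed_len: int = 8,
    min_mean_quality: float = 20.0,
) -> tuple[list[str], CleanStats]:
    """Trim adapters and filter reads into the fixed accounting categories.

    Parameters
    ----------
    raw:
        Iterable of reads; each item is either a sequence string or a
        ``(sequence, qualities)`` pair where qualities may be ``None``.
    adapter5, adapter3:
        Ligated adapter sequences (ACGT).  Passing both as empty strings
        enables bypass mode: inputs are assumed to be already-trimmed
        inserts and only the length/poly-A filters apply (and those are
        skipped too when the insert already satisfies the bounds, making
        the operation idempotent on clean inserts).
    polya_threshold:
        Minimum A fraction of the trimmed insert to call a poly-A artifact.
    adapter3_seed_len:
        The 3' adapter is located by the leftmost exact match of its first
        ``adapter3_seed_len`` bases; no match puts the read in
        ``adapter3_null``.

    Returns
    -------
    (inserts, stats):
        The retained clean inserts, in input order, and the
        :class:`CleanStats` accounting with the partition invariant checked.

    The filter order is fixed: low-quality -> 5'-adapter contaminant ->
    3'-adapter location -> empty insert -> poly-A -> length bounds.  Each
    discarded read lands in exactly one category.
    """
    bypass = adapter5 == "" and adapter3 == ""
    if not bypass:
        for name, a in (("adapter5", adapter5), ("adapter3", adapter3)):
            if not is_nucleotide(a):
                raise ValueError(f"{name} must be non-empty ACGT, got {a!r}")
    seed3 = adapter3[:adapter3_seed_len]

    stats = CleanStats()
    clean: list[str] = []
    for idx, item in enumerate(raw):
        if isinstance(item, str):
            seq, quals = item, None
        else:
            try:
                seq, quals = item
            except (TypeError, ValueError) as exc:
                raise ValueError(f"malformed record at index {idx}") from exc
        if not isinstance(seq, str) or not is_nucleotide(seq, "ACGTN"):
            raise ValueError(f"malformed record at index {idx}: {seq!r}")
        stats.raw_reads += 1

        low_quality = "N" in seq or (
            quals is not None and len(quals) > 0 and float(np.mean(quals)) < min_mean_quality
        )
        if low_quality:
            continue
        stats.high_quality += 1

        if bypass:
            insert = seq
        else:
            # 5' adapter appearing anywhere past the read start marks a
            # ligation contaminant.
            if adapter5 in seq[1:]:
                stats.adapter5_contaminant += 1
                continue
            pos = seq.find(seed3)
            if pos < 0:
                stats.adapter3_null += 1
                continue
            insert = seq[:pos]
            if not insert:
                stats.insert_null += 1
                continue
        if insert and insert.count("A") / len(insert) >= polya_threshold:
            stats.polyA += 1
            continue
        if len(insert) < min_len:
            stats.shorter_than_18nt += 1
            continue
        if len(insert) > max_len:
            stats.longer_than_max += 1
            continue
        stats.clean_reads += 1
        clean.append(insert)

    stats.check()
    return clean, stats


def collapse(inserts_vs: Iterable[str], inserts_rs: Iterable[str]) -> list[SRNATag]:
    """Collapse clean inserts from the two libraries into unique tags.

    Output is sorted by descending total count, ties broken lexicographically
    by sequence.
    """
    c_vs = Counter(inserts_vs)
    c_rs = Counter(inserts_rs)
    tags = [
        SRNATag(seq, c_vs.get(seq, 0), c_rs.get(seq, 0))
        for seq in set(c_vs) | set(c_rs)
    ]
    tags.sort(key=lambda t: (-t.total, t.sequence))
    return tags


def length_distribution(
    tags: Sequence[SRNATag],
    min_len: int = MIN_TAG_LEN,
    max_len: int = MAX_TAG_LEN,
) -> dict[str, dict[int, float]]:
    """Per-length read fractions for each library.

    Fractions are of reads (tag counts), not of unique tags, and sum to 1
    per library over lengths ``min_len..max_len``.
    """
    if not tags:
        raise ValueError("no tags")
    lengths = range(min_len, max_len + 1)
    out: dict[str, dict[int, float]] = {}
    for lib, attr in (("vs", "count_vs"), ("rs", "count_rs")):
        counts = {n: 0 for n in lengths}
        for t in tags:
            counts[len(t.sequence)] += getattr(t, attr)
        total = sum(counts.values())
        out[lib] = {n: (c / total if total else 0.0) for n, c in counts.items()}
    return out


def write_tags_fasta(tags: Sequence[SRNATag], path) -> None:
    """Write collapsed tags as FASTA with ``tag{i}_x{vs}_y{rs}`` headers."""
    with open(path, "w") as fh:
        for i, t in enumerate(tags, start=1):
            fh.write(f">tag{i}_x{t.count_vs}_y{t.count_rs}\n{t.sequence}\n")
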