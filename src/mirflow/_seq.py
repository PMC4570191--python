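"""Shared sequence helpers and reference-table access."""

from __future__ import annotations

from importlib import resources

import pandas as pd

_COMPLEMENT = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")

DNA = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement (DNA alphabet; U treated as T)."""
    return seq.translate(_COMPLEMENT)[::-1]


def is_nucleotide(seq: str, alphabet: str = "ACGT") -> bool:
    return bool(seq) and all(c in alphabet for c in seq)


def load_reference_table(name: str) -> pd.DataFrame:
    """Load one of the bundled study summary tables.

    Available names: ``radish_library_stats``, ``radish_known_family_counts``,
    ``radish_novel_mirnas``. These hold the published read-accounting,
    known-family count and novel-miRNA summary rows for the two radish leaf
    libraries (NAU-VS, vegetative stage; NAU-RS, reproductive stage) and are
    used as worked-example inputs.
    """
    ref = resources.files("mirflow.data").joinpath(f"{name}.tsv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")
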