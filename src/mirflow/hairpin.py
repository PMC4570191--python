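"""Hairpin precursor folding and novel-miRNA candidate evaluation.

A candidate novel miRNA must sit on one arm of a stem-loop precursor whose
miRNA/miRNA* duplex satisfies the classical plant criteria: mature length
18-25 nt, at least 16 paired positions in the duplex, precursor minimum
folding free energy at most -18 kcal/mol, and no more than 4 unpaired
(bulged/asymmetric) nucleotides inside the duplex.  Observing the star
strand among the sequenced tags upgrades an accepted candidate to
high confidence.

Folding uses a declared base-pair-wise energy model (GC -3, AU -2, GU -1
kcal/mol, minimum hairpin loop 3) optimized exactly by dynamic programming
with a deterministic traceback.  It is not a nearest-neighbour
thermodynamic model; its energy scale is calibrated so realistic stems
clear the -18 kcal/mol gate, and :func:`import_structure` accepts
dot-bracket output from an external thermodynamic folder when exact MFE
values matter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from numba import njit

from ._seq import revcomp
from .preprocess import SRNATag
from .annotate import Locus, map_reference

__all__ = [
    "SecondaryStructure",
    "PrecursorRecord",
    "NovelCriteriaReport",
    "fold",
    "import_structure",
    "extract_candidates",
    "evaluate_candidate",
    "call_novel",
    "PAIR_ENERGIES",
    "MIN_LOOP",
]

# kcal/mol per closed pair; GU wobble allowed.
PAIR_ENERGIES = {("G", "C"): -3.0, ("A", "T"): -2.0, ("G", "T"): -1.0}
MIN_LOOP = 3

MFE_MAX = -18.0  # kcal/mol, inclusive
MIN_DUPLEX_PAIRS = 16
MAX_BULGE_NT = 4
MATURE_LEN_RANGE = (18, 25)
PRECURSOR_LEN_BAND = (69, 700)  # warning band only
_DUPLEX_GAP = 6  # max unpaired nt (either strand) bridged within one duplex

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}

# energy[a, b] == 0.0 means the pair is disallowed
_EMAT = np.zeros((4, 4))
for (a, b), e in PAIR_ENERGIES.items():
    _EMAT[_CODE[a], _CODE[b]] = e
    _EMAT[_CODE[b], _CODE[a]] = e


@njit(cache=True)
def _fill_dp(codes, emat, min_loop):  # pragma: no cover - numba kernel
    n = codes.shape[0]
    w = np.zeros((n, n))
    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = w[i + 1, j]
            for k in range(i + min_loop + 1, j + 1):
                e = emat[codes[i], codes[k]]
                if e < 0.0:
                    cand = e + w[i + 1, k - 1]
                    if k < j:
                        cand += w[k + 1, j]
                    if cand < best:
                        best = cand
            w[i, j] = best
    return w


@dataclass(frozen=True)
class SecondaryStructure:
    """Non-crossing secondary structure with its folding free energy."""

    dotbracket: str
    mfe: float
    pair_map: Mapping[int, int]

    def __post_init__(self) -> None:
        _validate_dotbracket(self.dotbracket)
        if self.mfe > 0:
            raise ValueError("mfe must be <= 0")


def _validate_dotbracket(db: str) -> dict[int, int]:
    stack: list[int] = []
    pairs: dict[int, int] = {}
    for i, c in enumerate(db):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError(f"unbalanced bracket at position {i}")
            j = stack.pop()
            if i - j - 1 < MIN_LOOP:
                raise ValueError(f"hairpin loop shorter than {MIN_LOOP} at pair ({j},{i})")
            pairs[i] = j
            pairs[j] = i
        elif c != ".":
            raise ValueError(f"invalid dot-bracket character {c!r}")
    if stack:
        raise ValueError("unbalanced bracket: unclosed '('")
    return pairs


def _encode(sequence: str) -> np.ndarray:
    try:
        return np.array([_CODE[c] for c in sequence.upper()], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"non-nucleotide character in sequence: {exc.args[0]!r}") from None


def fold(sequence: str) -> SecondaryStructure:
    """Fold a sequence under the base-pair energy model.

    Returns the minimum-energy non-crossing structure; ties are resolved by
    a deterministic traceback that prefers pairing position ``i`` over
    leaving it unpaired, and among partners prefers the smallest index.
    """
    if not sequence:
        raise ValueError("empty sequence")
    codes = _encode(sequence)
    n = len(codes)
    w = _fill_dp(codes, _EMAT, MIN_LOOP)

    pairs: dict[int, int] = {}
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j - i <= MIN_LOOP:
            continue
        target = w[i, j]
        paired = False
        for k in range(i + MIN_LOOP + 1, j + 1):
            e = _EMAT[codes[i], codes[k]]
            if e < 0.0:
                cand = e + w[i + 1, k - 1] + (w[k + 1, j] if k < j else 0.0)
                if cand == target:
                    pairs[i] = k
                    pairs[k] = i
                    stack.append((k + 1, j))
                    stack.append((i + 1, k - 1))
                    paired = True
                    break
        if not paired:
            stack.append((i + 1, j))

    db = "".join(
        "(" if i in pairs and pairs[i] > i else (")" if i in pairs else ".")
        for i in range(n)
    )
    return SecondaryStructure(dotbracket=db, mfe=float(w[0, n - 1]), pair_map=pairs)


def import_structure(sequence: str, dotbracket: str, mfe: float) -> SecondaryStructure:
    """Adopt an externally computed structure (e.g. from Mfold/ViennaRNA)."""
    if len(dotbracket) != len(sequence):
        raise ValueError(
            f"dot-bracket length {len(dotbracket)} != sequence length {len(sequence)}"
        )
    _encode(sequence)
    pairs = _validate_dotbracket(dotbracket)
    if mfe > 0:
        raise ValueError("mfe must be <= 0")
    return SecondaryStructure(dotbracket=dotbracket, mfe=float(mfe), pair_map=pairs)


@dataclass
class PrecursorRecord:
    """Candidate hairpin precursor with the mature span annotated."""

    precursor_id: str
    sequence: str
    mature_span: tuple[int, int]  # 0-based half-open
    arm: str = "5p"  # which arm the mature is expected on
    structure: SecondaryStructure | None = None
    star_span: tuple[int, int] | None = None
    source: Locus | None = None
    true_duplex_pairs: int | None = None  # set by the synthetic generator
    true_bulge_nt: int | None = None

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def mature(self) -> str:
        return self.sequence[self.mature_span[0] : self.mature_span[1]]

    @property
    def star(self) -> str | None:
        if self.star_span is None:
            return None
        return self.sequence[self.star_span[0] : self.star_span[1]]

    def folded(self) -> "PrecursorRecord":
        if self.structure is not None:
            return self
        return replace(self, structure=fold(self.sequence))


@dataclass(frozen=True)
class NovelCriteriaReport:
    mature_len_ok: bool
    duplex_pairs: int
    pairs_ok: bool
    mfe_ok: bool
    bulge_nt: int
    bulge_ok: bool
    star_observed: bool
    accepted: bool
    high_confidence: bool
    reason: str | None = None


def extract_candidates(
    tag: SRNATag,
    locus: Locus,
    reference: Mapping[str, str],
    window: int = 250,
) -> list[PrecursorRecord]:
    """Cut candidate precursor windows around a mapped tag locus.

    Two windows are produced, placing the tag near the 5' end
    (``[start-20, end+window]``) and near the 3' end
    (``[start-window, end+20]``), clipped to the transcript.  Minus-strand
    loci are handled by orienting the transcript to the tag's strand first.
    """
    tseq = reference[locus.transcript_id]
    if locus.strand == "-":
        tseq = revcomp(tseq)
        start = len(tseq) - locus.end
        end = len(tseq) - locus.start
    else:
        start, end = locus.start, locus.end
    if window < end - start:
        return []
    out = []
    for arm, (a, b) in (
        ("5p", (start - 20, end + window)),
        ("3p", (start - window, end + 20)),
    ):
        a = max(0, a)
        b = min(len(tseq), b)
        if b - a < end - start:
            continue
        out.append(
            PrecursorRecord(
                precursor_id=f"{locus.transcript_id}:{a}-{b}:{locus.strand}:{arm}",
                sequence=tseq[a:b],
                mature_span=(start - a, end - a),
                arm=arm,
                source=locus,
            )
        )
    return out


def _structure_duplex(prec: PrecursorRecord) -> tuple[int, int, int, int] | None:
    """Duplex statistics read off the precursor's own structure.

    Returns ``(pairs, bulge_nt, star_lo, star_hi)`` for the dominant
    contiguous helix formed between the mature and the opposite arm, or
    None when the mature pairs to no single arm.  Pairs separated by more
    than ``_DUPLEX_GAP`` unpaired nt on either strand belong to a
    different structural element (e.g. a hairpin inside the loop), not to
    the miRNA/miRNA* duplex.
    """
    s, e = prec.mature_span
    pm = prec.structure.pair_map
    outside = {i: pm[i] for i in range(s, e) if i in pm and (pm[i] < s or pm[i] >= e)}
    if not outside:
        return None
    items = sorted(outside.items())
    runs: list[list[tuple[int, int]]] = []
    for i, p in items:
        if (
            runs
            and (p < s) == (runs[-1][-1][1] < s)
            and i - runs[-1][-1][0] - 1 <= _DUPLEX_GAP
            and runs[-1][-1][1] - p - 1 <= _DUPLEX_GAP
        ):
            runs[-1].append((i, p))
        else:
            runs.append([(i, p)])
    run = max(runs, key=len)
    partners = [p for _, p in run]
    lo, hi = min(partners), max(partners)
    m_lo, m_hi = run[0][0], run[-1][0]
    bulge = sum(1 for i in range(m_lo, m_hi + 1) if i not in pm)
    bulge += sum(1 for i in range(lo, hi + 1) if i not in pm)
    return len(run), bulge, lo, hi


# Duplex alignment scoring: a pair gains 1000; every internal unpaired
# nucleotide costs 150 (a mismatch consumes one nt on each strand).  The
# ratio makes bridging more than `_DUPLEX_GAP` unpaired nt for a single
# extra pair unprofitable, matching the duplex-gap rule above.
_PAIR_SCORE = 1000
_UNPAIRED_COST = 150


def _align_duplex(seq: str, mature_span: tuple[int, int], region: tuple[int, int]) -> tuple[int, int, int, int] | None:
    """Best antiparallel miRNA/miRNA* duplex by direct alignment.

    Locally aligns the mature against ``region`` of the precursor (the
    putative star arm), antiparallel, maximizing pair count first and
    minimizing internal unpaired nucleotides second.  Returns
    ``(pairs, bulge_nt, star_lo, star_hi)`` or None when nothing pairs.
    """
    s, e = mature_span
    a, b = region
    if b - a < 4:
        return None
    mature = seq[s:e]
    rr = seq[a:b][::-1]  # walk the star arm 3'->5'
    L, R = len(mature), len(rr)
    codes_m = _encode(mature)
    codes_r = _encode(rr)
    H = np.zeros((L + 1, R + 1), dtype=np.int64)
    for i in range(1, L + 1):
        hi_prev = H[i - 1]
        hi_row = H[i]
        for j in range(1, R + 1):
            pair = _EMAT[codes_m[i - 1], codes_r[j - 1]] < 0.0
            diag = hi_prev[j - 1] + (_PAIR_SCORE if pair else -2 * _UNPAIRED_COST)
            best = diag
            up = hi_prev[j] - _UNPAIRED_COST
            if up > best:
                best = up
            left = hi_row[j - 1] - _UNPAIRED_COST
            if left > best:
                best = left
            hi_row[j] = best if best > 0 else 0
    score = int(H.max())
    if score < _PAIR_SCORE:
        return None
    i, j = np.unravel_index(int(H.argmax()), H.shape)
    i, j = int(i), int(j)
    je = j - 1  # last consumed rr index (local alignment ends on a pair)
    pairs = 0
    unpaired = 0
    while H[i, j] > 0:
        h = H[i, j]
        if i > 0 and j > 0:
            p = _EMAT[codes_m[i - 1], codes_r[j - 1]] < 0.0
            if h == H[i - 1, j - 1] + (_PAIR_SCORE if p else -2 * _UNPAIRED_COST):
                pairs += int(p)
                unpaired += 0 if p else 2
                i, j = i - 1, j - 1
                continue
        if i > 0 and h == H[i - 1, j] - _UNPAIRED_COST:
            unpaired += 1
            i -= 1
        else:
            unpaired += 1
            j -= 1
    js = j  # first consumed rr index
    lo = b - 1 - je
    hi = b - 1 - js
    return pairs, unpaired, lo, hi


def evaluate_candidate(
    prec: PrecursorRecord,
    tags: Sequence[SRNATag] = (),
    mfe_max: float = MFE_MAX,
    min_pairs: int = MIN_DUPLEX_PAIRS,
    max_bulge: int = MAX_BULGE_NT,
) -> NovelCriteriaReport:
    """Score a folded precursor against the novel-miRNA duplex criteria.

    ``duplex_pairs`` counts mature positions paired to the opposite arm;
    ``bulge_nt`` counts unpaired nucleotides inside the duplex region on
    both strands (each asymmetric nucleotide counted once).  The duplex is
    taken from the precursor's structure when that yields the stronger
    helix, and otherwise from a direct antiparallel alignment of the
    mature against the opposite arm — the global minimum-energy structure
    of a long window need not thread the mature through its true duplex,
    while the alignment search always finds it.  The star span is the
    duplex region on the opposite arm, shifted 2 nt toward its own 3' end
    to give the canonical 2-nt 3' overhangs.
    """
    if prec.structure is None:
        raise ValueError("precursor must be folded first")
    s, e = prec.mature_span
    if not (0 <= s < e <= len(prec.sequence)):
        raise ValueError("mature span outside precursor")
    mature_len = e - s
    mature_len_ok = MATURE_LEN_RANGE[0] <= mature_len <= MATURE_LEN_RANGE[1]
    mfe_ok = prec.structure.mfe <= mfe_max

    duplex = _structure_duplex(prec)
    if prec.arm == "5p":
        region = (e + MIN_LOOP, len(prec.sequence))
    else:
        region = (0, max(0, s - MIN_LOOP))
    aligned = _align_duplex(prec.sequence, prec.mature_span, region)
    for cand in (aligned,):
        if cand is not None and (duplex is None or (cand[0], -cand[1]) > (duplex[0], -duplex[1])):
            duplex = cand

    if duplex is None:
        pm = prec.structure.pair_map
        left = any(i in pm and pm[i] < s for i in range(s, e))
        right = any(i in pm and pm[i] >= e for i in range(s, e))
        return NovelCriteriaReport(
            mature_len_ok=mature_len_ok,
            duplex_pairs=0,
            pairs_ok=False,
            mfe_ok=mfe_ok,
            bulge_nt=0,
            bulge_ok=False,
            star_observed=False,
            accepted=False,
            high_confidence=False,
            reason="loop-spanning" if left and right else "no-duplex",
        )

    duplex_pairs, bulge_nt, lo, hi = duplex
    pairs_ok = duplex_pairs >= min_pairs
    bulge_ok = bulge_nt <= max_bulge
    # star interval shifted +2 toward higher coordinates: within either
    # arm the 3' end lies at the higher coordinate.
    star_span = (max(0, lo + 2), min(len(prec.sequence), hi + 3))
    prec.star_span = star_span
    star_seq = prec.sequence[star_span[0] : star_span[1]]
    star_observed = any(t.sequence == star_seq for t in tags)

    accepted = mature_len_ok and pairs_ok and mfe_ok and bulge_ok
    return NovelCriteriaReport(
        mature_len_ok=mature_len_ok,
        duplex_pairs=duplex_pairs,
        pairs_ok=pairs_ok,
        mfe_ok=mfe_ok,
        bulge_nt=bulge_nt,
        bulge_ok=bulge_ok,
        star_observed=star_observed,
        accepted=accepted,
        high_confidence=accepted and star_observed,
    )


def call_novel(
    tags: Sequence[SRNATag],
    reference: Sequence[tuple[str, str]],
    window: int = 250,
    min_total_count: int = 5,
    max_loci_per_tag: int = 10,
    mfe_max: float = MFE_MAX,
    min_pairs: int = MIN_DUPLEX_PAIRS,
    max_bulge: int = MAX_BULGE_NT,
    id_prefix: str = "rsa-miRn",
):
    """Call novel miRNAs from unannotated mapped tags.

    For each tag (total count >= ``min_total_count``) every mapped locus is
    expanded into candidate precursor windows, folded and evaluated; the
    best accepted precursor per locus is kept (lowest MFE, then shortest
    precursor, then leftmost).  Tags sharing an identical mature sequence
    across loci form one novel family, whose ``loci`` column counts the
    accepted loci.  Returns a pandas DataFrame in the novel-table layout
    (mature, size, LP, MFE, per-library reads, total, star reads, loci).
    """
    import pandas as pd

    ref_map = dict(reference)
    candidates = [t for t in tags if t.total >= min_total_count]
    loci_by_tag = map_reference(candidates, reference)

    rows = []
    for tag in candidates:
        loci = loci_by_tag[tag.sequence][:max_loci_per_tag]
        accepted: list[tuple[PrecursorRecord, NovelCriteriaReport, Locus]] = []
        for locus in loci:
            best: tuple[float, int, int, PrecursorRecord, NovelCriteriaReport] | None = None
            for prec in extract_candidates(tag, locus, ref_map, window=window):
                prec = prec.folded()
                rep = evaluate_candidate(
                    prec, tags, mfe_max=mfe_max, min_pairs=min_pairs, max_bulge=max_bulge
                )
                if not rep.accepted:
                    continue
                key = (prec.structure.mfe, prec.length, prec.mature_span[0])
                if best is None or key < best[:3]:
                    best = (*key, prec, rep)
            if best is not None:
                accepted.append((best[3], best[4], locus))
        if not accepted:
            continue
        prec, rep, _ = min(
            accepted, key=lambda t: (t[0].structure.mfe, t[0].length, t[0].mature_span[0])
        )
        star_seq = prec.star
        star_reads = sum(t.total for t in tags if star_seq and t.sequence == star_seq)
        rows.append(
            {
                "mature": tag.sequence,
                "size": len(tag.sequence),
                "lp": prec.length,
                "mfe": prec.structure.mfe,
                "count_vs": tag.count_vs,
                "count_rs": tag.count_rs,
                "total": tag.total,
                "star_reads": star_reads,
                "loci": len(accepted),
                "high_confidence": any(r.star_observed for _, r, _ in accepted),
            }
        )

    df = pd.DataFrame(
        rows,
        columns=[
            "mature", "size", "lp", "mfe", "count_vs", "count_rs",
            "total", "star_reads", "loci", "high_confidence",
        ],
    )
    if not df.empty:
        df = df.sort_values(["total", "mature"], ascending=[False, True], kind="stable")
        df.insert(0, "mirna", [f"{id_prefix}{i}" for i in range(1, len(df) + 1)])
        df = df.reset_index(drop=True)
    else:
        df.insert(0, "mirna", [])
    return df
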