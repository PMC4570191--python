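"""Plant miRNA target prediction by complementarity (expectation) scoring.

Emulates the scoring rule of the standard plant small-RNA target servers:
the miRNA is aligned, antiparallel, against each transcript window and
accumulates penalties — 1.0 per mismatch, 0.5 per G:U wobble, 2.0 per gap
— with every penalty doubled inside the 5' seed region (miRNA positions
2-13, counted 1-based from the 5' end).  The total penalty is the
"expectation"; sites at or below the cutoff (default 3.0) are reported.
A site whose miRNA positions 9-11 are all paired is annotated as cleavage,
otherwise as translational inhibition.  Target-accessibility (UPE) energy
is not computed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._seq import revcomp

__all__ = ["TargetSite", "score_site", "predict_targets"]

MISMATCH = 1.0
WOBBLE = 0.5
GAP = 2.0
SEED_RANGE = (2, 13)  # 1-based, inclusive, from the miRNA 5' end
DEFAULT_CUTOFF = 3.0
CENTRAL_RANGE = (9, 11)  # unpaired here -> translational inhibition

_COMP = {"A": "T", "T": "A", "G": "C", "C": "G"}


def _pair_penalty(mirna_base: str, target_base: str) -> float:
    """Penalty for aligning one miRNA base against one target base.

    The miRNA binds the target transcript, so a "match" means the bases are
    complementary; G:U wobble (miRNA G on target T, or miRNA T on target G)
    costs half a mismatch.
    """
    if _COMP[mirna_base] == target_base:
        return 0.0
    if (mirna_base, target_base) in (("G", "T"), ("T", "G")):
        return WOBBLE
    return MISMATCH


def _seed_factor(pos_1based: int) -> float:
    return 2.0 if SEED_RANGE[0] <= pos_1based <= SEED_RANGE[1] else 1.0


def score_site(mirna: str, window: str) -> tuple[float, tuple[str, str, str]]:
    """Optimal gapped complementarity score of a miRNA against a window.

    Parameters
    ----------
    mirna: miRNA sequence, 5'->3' (ACGT/U).
    window: transcript subsequence, 5'->3', with
        ``len(mirna) <= len(window) <= len(mirna) + 2``.

    Returns
    -------
    (expectation, alignment): the minimum total penalty and the alignment
    triple (miRNA 3'->5', match line, transcript 5'->3').  In the match
    line ``|`` marks a Watson-Crick pair, ``o`` a G:U wobble, ``.`` a
    mismatch and a space a gap.

    The alignment is global in both sequences; because the miRNA pairs its
    target antiparallel, the miRNA is traversed 3'->5' along the window's
    5'->3' direction.  Gap and substitution penalties are doubled at miRNA
    seed positions 2-13 (1-based from the miRNA 5' end); a gap in the
    miRNA (an unpaired target base) takes the seed factor of the next
    miRNA position toward the 5' end.
    """
    mirna = mirna.upper().replace("U", "T")
    window = window.upper().replace("U", "T")
    m, w = len(mirna), len(window)
    if w < m:
        raise ValueError("window shorter than miRNA")
    if w > m + 2:
        raise ValueError("window longer than miRNA + 2")

    # q[i] = i-th base of the miRNA walked 3'->5'
    q = mirna[::-1]
    # 1-based miRNA position (from 5' end) of q[i]
    pos = [m - i for i in range(m)]

    INF = float("inf")
    # dp[i][j]: best penalty aligning q[:i] with window[:j]
    dp = [[INF] * (w + 1) for _ in range(m + 1)]
    dp[0][0] = 0.0
    for j in range(1, w + 1):
        # leading target bases unpaired: gap in miRNA before its 3' end
        dp[0][j] = dp[0][j - 1] + GAP * _seed_factor(pos[0])
    for i in range(1, m + 1):
        for j in range(0, w + 1):
            best = INF
            if j >= 1:
                sub = dp[i - 1][j - 1]
                if sub < INF:
                    best = sub + _pair_penalty(q[i - 1], window[j - 1]) * _seed_factor(pos[i - 1])
            # gap in target (miRNA base unpaired)
            sub = dp[i - 1][j]
            if sub < INF:
                best = min(best, sub + GAP * _seed_factor(pos[i - 1]))
            # gap in miRNA (target base unpaired)
            if j >= 1 and dp[i][j - 1] < INF:
                f = _seed_factor(pos[i]) if i < m else _seed_factor(pos[m - 1])
                best = min(best, dp[i][j - 1] + GAP * f)
            dp[i][j] = best

    # traceback (prefer diagonal, then miRNA gap, then target gap)
    i, j = m, w
    a_mir: list[str] = []
    a_mid: list[str] = []
    a_tgt: list[str] = []
    while i > 0 or j > 0:
        here = dp[i][j]
        if i > 0 and j > 0 and dp[i - 1][j - 1] < INF and here == dp[i - 1][j - 1] + _pair_penalty(q[i - 1], window[j - 1]) * _seed_factor(pos[i - 1]):
            p = _pair_penalty(q[i - 1], window[j - 1])
            a_mir.append(q[i - 1])
            a_mid.append("|" if p == 0 else ("o" if p == WOBBLE else "."))
            a_tgt.append(window[j - 1])
            i, j = i - 1, j - 1
        elif j > 0 and dp[i][j - 1] < INF and (
            (i == 0 and here == dp[i][j - 1] + GAP * _seed_factor(pos[0]))
            or (i > 0 and here == dp[i][j - 1] + GAP * (_seed_factor(pos[i]) if i < m else _seed_factor(pos[m - 1])))
        ):
            a_mir.append("-")
            a_mid.append(" ")
            a_tgt.append(window[j - 1])
            j -= 1
        else:
            a_mir.append(q[i - 1])
            a_mid.append(" ")
            a_tgt.append("-")
            i -= 1
    aln = ("".join(reversed(a_mir)), "".join(reversed(a_mid)), "".join(reversed(a_tgt)))
    return dp[m][w], aln


@dataclass(frozen=True)
class TargetSite:
    mirna_id: str
    transcript_id: str
    start: int  # 0-based half-open on the transcript
    end: int
    expectation: float
    inhibition: str  # "cleavage" | "translation"
    alignment: tuple[str, str, str]


def _inhibition_mode(mirna: str, alignment: tuple[str, str, str]) -> str:
    """Cleavage unless any miRNA position 9-11 is unpaired or mismatched."""
    a_mir, a_mid, _ = alignment
    m = len(mirna)
    # walk the alignment 3'->5' over the miRNA; recover 1-based 5' positions
    seen = 0
    for c_mir, c_mid in zip(a_mir, a_mid):
        if c_mir == "-":
            continue
        seen += 1
        pos = m - seen + 1
        if CENTRAL_RANGE[0] <= pos <= CENTRAL_RANGE[1] and c_mid not in ("|", "o"):
            return "translation"
    return "cleavage"


_B2I = {"A": 0, "C": 1, "G": 2, "T": 3}


def _ungapped_profile(mirna: str) -> np.ndarray:
    """Per-alignment-position penalty lookup (position x target base)."""
    m = len(mirna)
    q = mirna[::-1]
    prof = np.empty((m, 4))
    for i in range(m):
        f = _seed_factor(m - i)
        for b, bi in _B2I.items():
            prof[i, bi] = _pair_penalty(q[i], b) * f
    return prof


def predict_targets(
    mirnas: Sequence[tuple[str, str]],
    transcripts: Sequence[tuple[str, str]],
    cutoff: float = DEFAULT_CUTOFF,
    max_gaps: int = 2,
    dp_margin: float = 8.0,
) -> list[TargetSite]:
    """Scan every transcript window for sites of every miRNA.

    Windows of length ``len(mirna)`` .. ``len(mirna) + max_gaps`` are scored
    at every position; sites with expectation <= ``cutoff`` are kept and
    sites of the same (miRNA, transcript) pair whose spans overlap by at
    least 50% of the shorter span are merged, keeping the lowest
    expectation (ties: leftmost, then shortest).

    For speed, a vectorized ungapped scan runs first and the exact gapped
    alignment is evaluated only at offsets whose ungapped penalty is within
    ``dp_margin`` of the cutoff; a gapped site whose ungapped counterpart
    exceeds that margin would be skipped, which at the default margin is
    vanishingly rare.
    """
    if not mirnas or not transcripts:
        raise ValueError("mirnas and transcripts must be non-empty")
    hits: list[TargetSite] = []
    enc_cache: dict[str, np.ndarray] = {}
    for mid, mseq in mirnas:
        mseq = mseq.upper().replace("U", "T")
        m = len(mseq)
        prof = _ungapped_profile(mseq)
        for tid, tseq in transcripts:
            tseq = tseq.upper().replace("U", "T")
            if len(tseq) < m:
                continue
            codes = enc_cache.get(tid)
            if codes is None:
                codes = np.array([_B2I.get(c, 0) for c in tseq], dtype=np.int8)
                enc_cache[tid] = codes
            win = np.lib.stride_tricks.sliding_window_view(codes, m)
            ungapped = prof[np.arange(m)[None, :], win].sum(axis=1)
            cand = np.flatnonzero(ungapped <= cutoff + dp_margin)
            found: list[TargetSite] = []
            for start in cand:
                start = int(start)
                for wlen in range(m, m + max_gaps + 1):
                    if start + wlen > len(tseq):
                        continue
                    window = tseq[start : start + wlen]
                    exp, aln = score_site(mseq, window)
                    if exp <= cutoff:
                        found.append(
                            TargetSite(
                                mirna_id=mid,
                                transcript_id=tid,
                                start=start,
                                end=start + wlen,
                                expectation=exp,
                                inhibition=_inhibition_mode(mseq, aln),
                                alignment=aln,
                            )
                        )
            hits.extend(_merge_overlapping(found))
    hits.sort(key=lambda s: (s.mirna_id, s.transcript_id, s.start, s.end))
    return hits


def _merge_overlapping(sites: list[TargetSite]) -> list[TargetSite]:
    sites = sorted(sites, key=lambda s: (s.expectation, s.start, s.end - s.start))
    kept: list[TargetSite] = []
    for s in sites:
        clash = False
        for k in kept:
            ov = min(s.end, k.end) - max(s.start, k.start)
            shorter = min(s.end - s.start, k.end - k.start)
            if ov > 0 and ov / shorter >= 0.5:
                clash = True
                break
        if not clash:
            kept.append(s)
    return kept
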