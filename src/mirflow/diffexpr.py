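"""Two-library differential expression of miRNA counts.

The comparison is between exactly two un-replicated sequencing libraries
(here a vegetative-stage, VS, and a reproductive-stage, RS, radish leaf
library).  Counts are normalized to reads per million (RPM) of each
library's clean-read total; zero normalized values are floored at 0.01 so
library-specific miRNAs yield finite log2 fold-changes.  Significance uses
the classical exact count statistic for two libraries of known depths
(Audic & Claverie): conditional on the count ``x`` in library 1, the count
in library 2 follows

    p(y | x) = (N2/N1)^y * (x+y)! / (x! y! (1+N2/N1)^(x+y+1)),

a negative-binomial law NB(x+1, N1/(N1+N2)); the two-sided P-value doubles
the smaller tail and is capped at 1.  A miRNA is called up (down) when
log2FC >= 1 (<= -1) and P <= 0.05, boundaries inclusive; no
multiple-testing correction is applied by default, matching the printed
decision rule (Benjamini-Hochberg is available but off).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as _st

__all__ = [
    "DETestResult",
    "DdctInput",
    "normalize_rpm",
    "log2_fold_change",
    "exact_count_test",
    "classify",
    "ddct",
]

DEFAULT_FLOOR = 0.01
LOG2FC_THRESHOLD = 1.0
ALPHA = 0.05


@dataclass(frozen=True)
class DETestResult:
    mirna_id: str
    count_vs: int
    count_rs: int
    n1: int
    n2: int
    rpm_vs: float
    rpm_rs: float
    log2fc: float
    pvalue: float
    call: str  # "up" | "down" | "unchanged"


@dataclass(frozen=True)
class DdctInput:
    """Ct quadruple for relative qPCR quantification.

    ``target`` is the assayed gene/miRNA, ``ref`` the endogenous reference
    (e.g. 5.8S rRNA); ``sample`` the condition of interest and
    ``calibrator`` the baseline condition.
    """

    ct_target_sample: float
    ct_ref_sample: float
    ct_target_calibrator: float
    ct_ref_calibrator: float

    def __post_init__(self) -> None:
        for v in (
            self.ct_target_sample,
            self.ct_ref_sample,
            self.ct_target_calibrator,
            self.ct_ref_calibrator,
        ):
            if not v > 0:
                raise ValueError("Ct values must be positive")


def normalize_rpm(count: float, library_total: int) -> float:
    """Reads-per-million normalization, unfloored: count / total * 1e6."""
    if library_total <= 0:
        raise ZeroDivisionError("library_total must be > 0")
    return count / library_total * 1e6


def log2_fold_change(rpm_vs: float, rpm_rs: float, floor: float = DEFAULT_FLOOR) -> float:
    """log2(RS/VS) with both RPM values floored at `floor` first."""
    if rpm_vs < 0 or rpm_rs < 0:
        raise ValueError("rpm values must be >= 0")
    return float(np.log2(max(rpm_rs, floor) / max(rpm_vs, floor)))


def exact_count_test(
    x: int | np.ndarray,
    y: int | np.ndarray,
    n1: int,
    n2: int,
) -> float | np.ndarray:
    """Two-sided exact count test P-value for counts (x, y) at depths (N1, N2).

    Computed in log-space through the negative-binomial tail functions, so
    it is stable for counts up to millions.  Accepts scalars or equal-shaped
    integer arrays.  P is in (0, 1].
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library totals must be > 0")
    x_a = np.asarray(x)
    y_a = np.asarray(y)
    if np.any(x_a < 0) or np.any(y_a < 0):
        raise ValueError("counts must be >= 0")
    # y | x ~ NB(r = x+1, p = N1/(N1+N2)), pmf matching p(y|x) above.
    p = n1 / (n1 + n2)
    log_lower = _st.nbinom.logcdf(y_a, x_a + 1, p)
    log_upper = _st.nbinom.logsf(y_a - 1, x_a + 1, p)
    log_p = np.log(2.0) + np.minimum(log_lower, log_upper)
    # clamp at a representable positive floor: P is in (0, 1] by contract
    # but can underflow double precision for extreme count imbalances
    pval = np.clip(np.exp(log_p), 1e-300, 1.0)
    if np.isscalar(x) or x_a.ndim == 0:
        return float(pval)
    return pval


def classify(
    rows: Iterable[tuple[str, int, int]],
    n1: int,
    n2: int,
    floor: float = DEFAULT_FLOOR,
    lfc_threshold: float = LOG2FC_THRESHOLD,
    alpha: float = ALPHA,
    bh_correct: bool = False,
) -> list[DETestResult]:
    """Run normalization, fold-change, exact test and the up/down call.

    Parameters
    ----------
    rows: iterable of ``(mirna_id, count_vs, count_rs)``.
    n1, n2: clean-read totals of the VS and RS libraries.
    bh_correct: apply Benjamini-Hochberg to the P-values before calling
        (off by default; the printed decision rule uses raw P).

    Call rule (boundaries inclusive): up iff log2FC >= `lfc_threshold` and
    P <= `alpha`; down iff log2FC <= -`lfc_threshold` and P <= `alpha`.
    """
    rows = list(rows)
    if not rows:
        return []
    ids = [r[0] for r in rows]
    xs = np.array([r[1] for r in rows], dtype=np.int64)
    ys = np.array([r[2] for r in rows], dtype=np.int64)
    pvals = np.atleast_1d(exact_count_test(xs, ys, n1, n2))
    p_eff = _bh(pvals) if bh_correct else pvals
    out = []
    for mid, x, y, p_raw, p in zip(ids, xs, ys, pvals, p_eff):
        rpm_vs = normalize_rpm(int(x), n1)
        rpm_rs = normalize_rpm(int(y), n2)
        lfc = log2_fold_change(rpm_vs, rpm_rs, floor=floor)
        if lfc >= lfc_threshold and p <= alpha:
            call = "up"
        elif lfc <= -lfc_threshold and p <= alpha:
            call = "down"
        else:
            call = "unchanged"
        out.append(
            DETestResult(
                mirna_id=mid,
                count_vs=int(x),
                count_rs=int(y),
                n1=n1,
                n2=n2,
                rpm_vs=max(rpm_vs, floor),
                rpm_rs=max(rpm_rs, floor),
                log2fc=lfc,
                pvalue=float(p_raw),
                call=call,
            )
        )
    return out


def _bh(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted P-values."""
    m = len(pvals)
    order = np.argsort(pvals)
    adj = pvals[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def ddct(inp: DdctInput) -> float:
    """Relative expression by the 2^-ddCt method."""
    dct_sample = inp.ct_target_sample - inp.ct_ref_sample
    dct_cal = inp.ct_target_calibrator - inp.ct_ref_calibrator
    return float(2.0 ** -(dct_sample - dct_cal))
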