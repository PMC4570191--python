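"""Synthetic small-RNA-seq data with a ground-truth ledger.

Generates everything the pipeline consumes: a reference transcript set, a
mature-miRNA catalog (miRBase-style headers), a structural ncRNA catalog,
planted hairpin precursors carrying miRNA/miRNA* duplexes, and two raw
FASTQ libraries (vegetative-stage "VS" and reproductive-stage "RS") with
adapters, contaminants and the Table-1-style artifact classes.  A
:class:`TruthLedger` records, per miRNA, the true sequence, precursor and
expected per-library counts, and per read its origin class, so downstream
stages can be scored against ground truth.

The statistical structure mirrors what deep plant sRNA libraries show:
heavy-tailed (log-normal) family abundances with conserved families far
above novel ones, a dominant 21-nt length mode, a star:mature read ratio
well below 1, and between-library log2 fold-changes planted on the
normalized (reads-per-million) scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from ._seq import DNA, is_nucleotide, revcomp
from .hairpin import PAIR_ENERGIES, PrecursorRecord, _align_duplex

__all__ = [
    "SimulationConfig",
    "TruthLedger",
    "SimulatedDataset",
    "make_hairpin",
    "simulate_libraries",
]

READ_CLASSES = (
    "known-miRNA",
    "novel-miRNA",
    "star",
    "ncRNA",
    "degradation",
    "adapter-artifact",
)

_PAIRABLE = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}


@dataclass
class SimulationConfig:
    """Study conditions for the two-library simulation.

    Defaults emulate a desk-scale version of a deep two-library radish leaf
    experiment: a 21-nt dominated length profile (the two real libraries
    showed 33.33% and 52.97% 21-nt reads; the default is their midpoint),
    log-normal family abundances so conserved families dwarf novel ones,
    and a small contaminant/artifact fraction matching the shape (not the
    scale) of published read-accounting tables.
    """

    seed: int = 0
    n_transcripts: int = 40
    transcript_len_range: tuple[int, int] = (400, 900)
    n_known_families: int = 12
    members_per_family: tuple[int, int] = (1, 4)
    n_novel_hairpins: int = 6
    depth_per_library: int = 100_000
    contaminant_fraction: float = 0.12
    adapter5: str = "GTTCAGAGTTCTACAGTCCGACGATC"
    adapter3: str = "TCGTATGCCGTCTTCTGCTTG"
    length_mode_fraction_21nt: float = 0.43
    planted_log2fc: tuple[tuple[str, float], ...] = ()
    star_to_mature_ratio: float = 0.1
    abundance_dispersion: float = 1.5

    # class mix within the non-contaminant mass
    known_fraction: float = 0.55
    novel_fraction: float = 0.06

    def validate(self) -> None:
        for name in ("contaminant_fraction", "length_mode_fraction_21nt",
                     "star_to_mature_ratio", "known_fraction", "novel_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.depth_per_library < 1:
            raise ValueError("depth_per_library must be >= 1")
        if self.abundance_dispersion <= 0:
            raise ValueError("abundance_dispersion must be > 0")
        for name in ("adapter5", "adapter3"):
            if not is_nucleotide(getattr(self, name)):
                raise ValueError(f"{name} must be non-empty ACGT")

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["transcript_len_range"] = list(self.transcript_len_range)
        d["members_per_family"] = list(self.members_per_family)
        d["planted_log2fc"] = [list(t) for t in self.planted_log2fc]
        return d


@dataclass
class TruthLedger:
    """Ground truth: per-miRNA expectations and per-read origins."""

    mirnas: pd.DataFrame
    # per-read (class, origin id) aligned with the emitted read order
    origins_vs: list[tuple[str, str]]
    origins_rs: list[tuple[str, str]]
    precursors: list[PrecursorRecord] = field(default_factory=list)

    def class_counts(self, library: str) -> dict[str, int]:
        origins = self.origins_vs if library == "vs" else self.origins_rs
        out: dict[str, int] = {c: 0 for c in READ_CLASSES}
        for cls, _ in origins:
            out[cls] += 1
        return out

    def observed_counts(self, origin_id: str, library: str) -> int:
        origins = self.origins_vs if library == "vs" else self.origins_rs
        return sum(1 for _, oid in origins if oid == origin_id)


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    reads_vs: list[str]
    reads_rs: list[str]
    reference: list[tuple[str, str]]
    mature_catalog: list[tuple[str, str]]
    ncrna_catalog: list[tuple[str, str]]
    ledger: TruthLedger

    def write(self, outdir) -> dict[str, Path]:
        """Write FASTQ x2, FASTA x3, ledger TSVs and the config YAML."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}

        for lib, reads in (("vs", self.reads_vs), ("rs", self.reads_rs)):
            p = outdir / f"reads_{lib}.fastq"
            with open(p, "w") as fh:
                for i, seq in enumerate(reads, start=1):
                    fh.write(f"@{lib}_read{i}\n{seq}\n+\n{'I' * len(seq)}\n")
            paths[f"reads_{lib}"] = p
        for name, records in (
            ("reference", self.reference),
            ("mature_catalog", self.mature_catalog),
            ("ncrna_catalog", self.ncrna_catalog),
        ):
            p = outdir / f"{name}.fasta"
            with open(p, "w") as fh:
                for rid, seq in records:
                    fh.write(f">{rid}\n{seq}\n")
            paths[name] = p

        p = outdir / "truth_mirnas.tsv"
        self.ledger.mirnas.to_csv(p, sep="\t", index=False)
        paths["truth_mirnas"] = p
        p = outdir / "truth_reads.tsv"
        with open(p, "w") as fh:
            fh.write("library\tread\tclass\torigin\n")
            for lib, origins in (("vs", self.ledger.origins_vs), ("rs", self.ledger.origins_rs)):
                for i, (cls, oid) in enumerate(origins, start=1):
                    fh.write(f"{lib}\t{lib}_read{i}\t{cls}\t{oid}\n")
        paths["truth_reads"] = p

        p = outdir / "config.yaml"
        with open(p, "w") as fh:
            yaml.safe_dump(self.config.to_dict(), fh, sort_keys=True)
        paths["config"] = p
        return paths


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(DNA[i] for i in rng.integers(0, 4, size=n))


def _safe_base(rng: np.random.Generator, context: str) -> str:
    """A base that cannot pair (Watson-Crick or wobble) with any base in
    ``context``; falls back to a random base if none exists."""
    options = [b for b in DNA if all((b, c) not in _PAIRABLE for c in context)]
    if not options:
        options = list(DNA)
    return options[int(rng.integers(0, len(options)))]


def make_hairpin(
    mature: str,
    loop_len: int,
    n_mismatches: int,
    n_bulges: int,
    seed: int,
    precursor_id: str = "hairpin",
) -> PrecursorRecord:
    """Construct a stem-loop precursor with the mature on the 5' arm.

    The 3' arm carries the star: the reverse complement of the mature with
    ``n_mismatches`` substitutions and ``n_bulges`` single-nucleotide
    insertions, followed by a 2-nt 3' overhang.  Substituted bases are set
    equal to the opposing mature base (which can never pair with itself)
    and inserted/loop bases are chosen not to pair with nearby stem bases.
    Each construction is checked against the duplex-alignment search and
    re-drawn (deterministically, bounded retries) if an alignment beats
    the planted duplex, so evaluation recovers the ground truth exactly:
    ``true_duplex_pairs = len(mature) - n_mismatches`` and
    ``true_bulge_nt = n_bulges + 2 * n_mismatches``.
    """
    mature = mature.upper().replace("U", "T")
    if not 18 <= len(mature) <= 25:
        raise ValueError(f"mature length {len(mature)} outside 18-25 nt")
    if loop_len < 3:
        raise ValueError("loop_len must be >= 3")
    if n_mismatches < 0 or n_bulges < 0:
        raise ValueError("n_mismatches and n_bulges must be >= 0")
    if not is_nucleotide(mature):
        raise ValueError("mature must be ACGT/U")
    rng = np.random.default_rng(seed)
    truth = (len(mature) - n_mismatches, -(n_bulges + 2 * n_mismatches))
    prec = None
    for _ in range(200):
        prec = _build_hairpin(mature, loop_len, n_mismatches, n_bulges, rng, precursor_id)
        found = _align_duplex(
            prec.sequence, prec.mature_span, (prec.mature_span[1] + 3, len(prec.sequence))
        )
        if found is None or (found[0], -found[1]) <= truth:
            break
    return prec


def _build_hairpin(
    mature: str,
    loop_len: int,
    n_mismatches: int,
    n_bulges: int,
    rng: np.random.Generator,
    precursor_id: str,
) -> PrecursorRecord:
    L = len(mature)

    # star as (base, mature partner index or None); star[k] pairs mature[L-1-k]
    star: list[tuple[str, int | None]] = [
        (b, L - 1 - k) for k, b in enumerate(revcomp(mature))
    ]
    interior = np.arange(2, L - 2)
    if n_mismatches > len(interior):
        raise ValueError("too many mismatches for this mature length")
    mm_pos = sorted(rng.choice(interior, size=n_mismatches, replace=False))
    for k in mm_pos:
        star[k] = (mature[L - 1 - k], None)  # x opposite x never pairs

    for _ in range(n_bulges):
        k = int(rng.integers(2, len(star) - 2))
        m_idx = L - 1 - k
        context = mature[max(0, m_idx - 2) : m_idx + 3]
        star.insert(k, (_safe_base(rng, context), None))

    # loop bases must not pair with the stem ends flanking the loop
    flank = mature[-3:] + "".join(b for b, _ in star[:3])
    loop = "".join(_safe_base(rng, flank) for _ in range(loop_len))
    overhang = "".join(_safe_base(rng, mature[:3]) for _ in range(2))

    star_seq = "".join(b for b, _ in star)
    seq = mature + loop + star_seq + overhang
    star_start = L + loop_len

    # the constructed duplex is attached as the precursor's structure, with
    # its energy summed over the planted pairs; downstream refolding (from a
    # reference window) may of course find an equally good or better one
    pair_map: dict[int, int] = {}
    mfe = 0.0
    for k, (b, m_idx) in enumerate(star):
        if m_idx is None:
            continue
        pair_map[star_start + k] = m_idx
        pair_map[m_idx] = star_start + k
        key = tuple(sorted((b, mature[m_idx])))
        mfe += PAIR_ENERGIES.get((key[1], key[0]), PAIR_ENERGIES.get((key[0], key[1]), 0.0))
    db = "".join(
        "(" if i in pair_map and pair_map[i] > i else (")" if i in pair_map else ".")
        for i in range(len(seq))
    )
    from .hairpin import SecondaryStructure

    structure = SecondaryStructure(dotbracket=db, mfe=mfe, pair_map=pair_map)
    return PrecursorRecord(
        precursor_id=precursor_id,
        sequence=seq,
        mature_span=(0, L),
        arm="5p",
        structure=structure,
        # canonical 2-nt 3' overhang convention: the star read is the
        # paired block shifted +2 toward its own 3' end (the appended
        # overhang supplies the final two bases)
        star_span=(star_start + 2, star_start + 2 + len(star)),
        true_duplex_pairs=L - n_mismatches,
        true_bulge_nt=n_bulges + 2 * n_mismatches,
    )


# length profile away from the 21-nt mode (weights over 18..30 nt, 21 excluded)
_OTHER_LENGTHS = np.array([18, 19, 20, 22, 23, 24, 25, 26, 27, 28, 29, 30])
_OTHER_WEIGHTS = np.array([2.0, 4.0, 12.0, 10.0, 6.0, 8.0, 2.0, 1.0, 0.7, 0.5, 0.4, 0.4])
_OTHER_WEIGHTS = _OTHER_WEIGHTS / _OTHER_WEIGHTS.sum()


def _draw_length(rng: np.random.Generator, p21: float) -> int:
    if rng.random() < p21:
        return 21
    return int(rng.choice(_OTHER_LENGTHS, p=_OTHER_WEIGHTS))


def simulate_libraries(cfg: SimulationConfig) -> SimulatedDataset:
    """Simulate the two raw libraries plus every catalog the pipeline needs.

    Reads are drawn per library by a single multinomial over atomic
    sources (each miRNA member, each novel star, and pooled degradation /
    ncRNA / artifact buckets), so zero counts for rare sources arise
    naturally.  Planted log2 fold-changes reweight the RS library, with the
    difference absorbed by the degradation bucket so the clean-read totals
    (the normalization denominators) stay comparable and the planted
    effects land on the reads-per-million scale.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    f21 = cfg.length_mode_fraction_21nt

    # --- reference transcripts ------------------------------------------------
    lens = rng.integers(cfg.transcript_len_range[0], cfg.transcript_len_range[1] + 1,
                        size=cfg.n_transcripts)
    reference = [(f"transcript{i+1}", _random_seq(rng, int(n))) for i, n in enumerate(lens)]

    # --- known miRNA catalog --------------------------------------------------
    mature_catalog: list[tuple[str, str]] = []
    known: list[dict] = []
    seen: set[str] = set()
    for fi in range(cfg.n_known_families):
        fam_num = 150 + fi
        n_members = int(rng.integers(cfg.members_per_family[0], cfg.members_per_family[1] + 1))
        consensus = _random_seq(rng, _draw_length(rng, f21))
        for mi in range(n_members):
            seq = list(consensus)
            for _ in range(mi):  # members differ from the consensus
                pos = int(rng.integers(0, len(seq)))
                seq[pos] = DNA[(DNA.index(seq[pos]) + 1 + int(rng.integers(0, 3))) % 4]
            s = "".join(seq)
            while s in seen:
                pos = int(rng.integers(0, len(s)))
                s = s[:pos] + DNA[(DNA.index(s[pos]) + 1) % 4] + s[pos + 1:]
            seen.add(s)
            mid = f"ath-miR{fam_num}{'abcdefgh'[mi]}"
            mature_catalog.append((mid, s))
            known.append({"id": mid, "family": f"miR{fam_num}", "mature": s})

    # --- novel hairpins planted into transcripts ------------------------------
    occupied: dict[int, list[tuple[int, int]]] = {i: [] for i in range(len(reference))}

    def _plant(seq: str) -> tuple[int, str, int]:
        """Overwrite a random non-occupied slice of a transcript with `seq`."""
        for _ in range(200):
            ti = int(rng.integers(0, len(reference)))
            tid, tseq = reference[ti]
            if len(tseq) <= len(seq):
                continue
            pos = int(rng.integers(0, len(tseq) - len(seq)))
            if any(pos < b and a < pos + len(seq) for a, b in occupied[ti]):
                continue
            reference[ti] = (tid, tseq[:pos] + seq + tseq[pos + len(seq):])
            occupied[ti].append((pos, pos + len(seq)))
            return ti, tid, pos
        raise RuntimeError("could not place planted sequence without overlap")

    novel: list[dict] = []
    precursors: list[PrecursorRecord] = []
    for ni in range(cfg.n_novel_hairpins):
        mature = _random_seq(rng, max(18, min(25, _draw_length(rng, f21))))
        while mature in seen:
            mature = _random_seq(rng, len(mature))
        seen.add(mature)
        prec = make_hairpin(
            mature,
            loop_len=int(rng.integers(6, 16)),
            n_mismatches=int(rng.integers(0, 2)),
            n_bulges=0,
            seed=int(rng.integers(0, 2**31)),
            precursor_id=f"novel_prec{ni+1}",
        )
        _, tid, pos = _plant(prec.sequence)
        precursors.append(prec)
        novel.append({
            "id": f"novel{ni+1}", "family": f"novel{ni+1}", "mature": mature,
            "star": prec.star, "precursor_id": prec.precursor_id,
            "transcript": tid, "position": pos,
        })
    # make sure known matures also map to the reference
    for rec in known:
        _plant(rec["mature"])

    # --- ncRNA catalog --------------------------------------------------------
    ncrna_catalog = []
    for i, cls in enumerate(("rRNA", "tRNA", "snoRNA", "snRNA") * 2):
        ncrna_catalog.append((f"{cls}_{i+1}", _random_seq(rng, int(rng.integers(80, 200)))))

    # --- abundance weights ----------------------------------------------------
    sigma = cfg.abundance_dispersion
    fam_w = {f"miR{150+fi}": float(rng.lognormal(0.0, sigma)) for fi in range(cfg.n_known_families)}
    for rec in known:
        rec["w"] = fam_w[rec["family"]] * float(rng.lognormal(0.0, sigma / 2))
    for rec in novel:
        rec["w"] = float(rng.lognormal(0.0, sigma))

    kw = sum(r["w"] for r in known) or 1.0
    nw = sum(r["w"] for r in novel) or 1.0
    clean_mass = 1.0 - cfg.contaminant_fraction
    ncrna_mass = 0.5 * cfg.contaminant_fraction
    artifact_mass = cfg.contaminant_fraction - ncrna_mass
    known_mass = cfg.known_fraction * clean_mass
    novel_mass = cfg.novel_fraction * clean_mass
    star_mass = cfg.star_to_mature_ratio * novel_mass
    deg_mass = clean_mass - known_mass - novel_mass - star_mass
    if deg_mass < 0:
        raise ValueError("class fractions exceed available clean mass")

    for rec in known:
        rec["w_vs"] = rec["w"] / kw * known_mass
    for rec in novel:
        rec["w_vs"] = rec["w"] / nw * novel_mass
        rec["w_star_vs"] = rec["w_vs"] * cfg.star_to_mature_ratio

    planted = dict(cfg.planted_log2fc)
    all_mirnas = known + novel
    known_ids = {r["id"] for r in all_mirnas}
    for mid in planted:
        if mid not in known_ids:
            raise ValueError(f"planted_log2fc id {mid!r} not in simulated catalog")
    # planted effects are absorbed by the degradation bucket in the RS
    # library; a planted miRNA's base abundance is capped so the shift can
    # never exhaust that bucket (at most half of it across all planted ids)
    n_planted_up = sum(1 for lfc in planted.values() if lfc > 0) or 1
    budget = 0.5 * deg_mass / n_planted_up
    for rec in all_mirnas:
        lfc = planted.get(rec["id"], 0.0)
        if lfc > 0:
            factor = (2.0 ** lfc - 1.0) * (1.0 + (cfg.star_to_mature_ratio if "w_star_vs" in rec else 0.0))
            if rec["w_vs"] * factor > budget:
                scale = budget / (rec["w_vs"] * factor)
                rec["w_vs"] *= scale
                if "w_star_vs" in rec:
                    rec["w_star_vs"] *= scale
    shift = 0.0
    for rec in all_mirnas:
        lfc = rec["lfc"] = planted.get(rec["id"], 0.0)
        rec["w_rs"] = rec["w_vs"] * (2.0 ** lfc)
        shift += rec["w_rs"] - rec["w_vs"]
        if "w_star_vs" in rec:
            rec["w_star_rs"] = rec["w_star_vs"] * (2.0 ** lfc)
            shift += rec["w_star_rs"] - rec["w_star_vs"]
    deg_mass_rs = deg_mass - shift
    if deg_mass_rs <= 0:
        raise ValueError("planted fold-changes too large for the degradation mass to absorb")

    # the fixed-length sources (matures, stars) contribute their own 21-nt
    # mass; per-read length draws for degradation/ncRNA compensate so the
    # overall clean 21-nt fraction targets length_mode_fraction_21nt.
    def _p21(deg_m: float) -> float:
        fixed21 = sum(r["w_vs"] for r in all_mirnas if len(r["mature"]) == 21)
        fixed21 += sum(r.get("w_star_vs", 0.0) for r in novel if len(r["star"]) == 21)
        cm = known_mass + novel_mass + star_mass + deg_m + ncrna_mass
        free = deg_m + ncrna_mass
        return min(1.0, max(0.0, (f21 * cm - fixed21) / free)) if free > 0 else 0.0

    # --- per-library sampling -------------------------------------------------
    artifact_classes = ("low_quality", "polyA", "insert_null", "adapter3_null",
                       "adapter5_contaminant", "short_insert")
    art_w = artifact_mass / len(artifact_classes)

    def _sample_library(lib: str) -> tuple[list[str], list[tuple[str, str]]]:
        sources: list[tuple[str, str, float]] = []  # (class, origin, weight)
        key = "w_vs" if lib == "vs" else "w_rs"
        for rec in known:
            sources.append(("known-miRNA", rec["id"], rec[key]))
        for rec in novel:
            sources.append(("novel-miRNA", rec["id"], rec[key]))
            sources.append(("star", rec["id"] + "*", rec["w_star_vs" if lib == "vs" else "w_star_rs"]))
        sources.append(("degradation", "degradation", deg_mass if lib == "vs" else deg_mass_rs))
        sources.append(("ncRNA", "ncRNA", ncrna_mass))
        for cls in artifact_classes:
            sources.append(("adapter-artifact", cls, art_w))

        w = np.array([s[2] for s in sources])
        counts = rng.multinomial(cfg.depth_per_library, w / w.sum())
        p21 = _p21(deg_mass if lib == "vs" else deg_mass_rs)

        mature_by_id = {r["id"]: r["mature"] for r in all_mirnas}
        star_by_id = {r["id"] + "*": r["star"] for r in novel}
        a3 = cfg.adapter3
        reads: list[str] = []
        origins: list[tuple[str, str]] = []
        for (cls, oid, _), c in zip(sources, counts):
            for _ in range(int(c)):
                if cls in ("known-miRNA", "novel-miRNA"):
                    insert = mature_by_id[oid]
                    read = insert + a3
                elif cls == "star":
                    insert = star_by_id[oid]
                    read = insert + a3
                elif cls == "degradation":
                    tid, tseq = reference[int(rng.integers(0, len(reference)))]
                    n = _draw_length(rng, p21)
                    start = int(rng.integers(0, max(1, len(tseq) - n)))
                    read = tseq[start:start + n] + a3
                elif cls == "ncRNA":
                    _, nseq = ncrna_catalog[int(rng.integers(0, len(ncrna_catalog)))]
                    n = _draw_length(rng, p21)
                    start = int(rng.integers(0, max(1, len(nseq) - n)))
                    read = nseq[start:start + n] + a3
                elif oid == "low_quality":
                    read = _random_seq(rng, 20) + "N" + a3
                elif oid == "polyA":
                    read = "A" * int(rng.integers(18, 26)) + a3
                elif oid == "insert_null":
                    read = a3 + _random_seq(rng, 10)
                elif oid == "adapter3_null":
                    while True:
                        read = _random_seq(rng, 40)
                        if a3[:8] not in read:
                            break
                elif oid == "adapter5_contaminant":
                    read = _random_seq(rng, 12) + cfg.adapter5 + a3
                else:  # short_insert
                    read = _random_seq(rng, int(rng.integers(8, 18))) + a3
                reads.append(read)
                origins.append((cls, oid))
        perm = rng.permutation(len(reads))
        return [reads[i] for i in perm], [origins[i] for i in perm]

    reads_vs, origins_vs = _sample_library("vs")
    reads_rs, origins_rs = _sample_library("rs")

    depth = cfg.depth_per_library
    rows = []
    for rec in all_mirnas:
        rows.append({
            "mirna_id": rec["id"],
            "mature": rec["mature"],
            "arm": "5p",
            "precursor_id": rec.get("precursor_id", ""),
            "family": rec["family"],
            "novel": "precursor_id" in rec,
            "expected_count_vs": depth * rec["w_vs"],
            "expected_count_rs": depth * rec["w_rs"],
            "true_log2fc": rec["lfc"],
        })
    ledger = TruthLedger(
        mirnas=pd.DataFrame(rows),
        origins_vs=origins_vs,
        origins_rs=origins_rs,
        precursors=precursors,
    )
    return SimulatedDataset(
        config=cfg,
        reads_vs=reads_vs,
        reads_rs=reads_rs,
        reference=reference,
        mature_catalog=mature_catalog,
        ncrna_catalog=ncrna_catalog,
        ledger=ledger,
    )
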