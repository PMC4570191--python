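"""Configured end-to-end pipeline and summary-report rendering.

Stages run in a fixed order — simulate (optional) -> clean -> annotate ->
novel -> diffexpr -> targets -> report — each writing a TSV artifact plus
a JSON sidecar with the stage parameters and a SHA-256 checksum, so a
rerun under the same configuration is byte-identical and verifiable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import annotate as _ann
from . import diffexpr as _de
from . import hairpin as _hp
from . import preprocess as _pp
from . import simulate as _sim
from . import targets as _tp

__all__ = ["PipelineConfig", "StageError", "run_pipeline", "render_report"]

log = logging.getLogger("mirflow")

STAGES = ("simulate", "clean", "annotate", "novel", "diffexpr", "targets", "report")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    outdir: str = "mirflow_out"
    # inputs (filled automatically when the simulate stage runs)
    reads_vs: str | None = None
    reads_rs: str | None = None
    reference: str | None = None
    mature_catalog: str | None = None
    ncrna_catalog: str | None = None
    target_transcripts: str | None = None  # defaults to `reference`
    # parameters
    seed: int = 0
    adapter5: str = "GTTCAGAGTTCTACAGTCCGACGATC"
    adapter3: str = "TCGTATGCCGTCTTCTGCTTG"
    max_mismatches: int = 2
    hairpin_window: int = 250
    min_novel_count: int = 5
    target_cutoff: float = 3.0
    rpm_floor: float = 0.01
    depth_per_library: int = 20_000
    # stage toggles
    stages: tuple[str, ...] = STAGES

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        if isinstance(cfg.stages, list):
            cfg.stages = tuple(cfg.stages)
        return cfg

    def validate(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if "simulate" not in self.stages:
            for name in ("reads_vs", "reads_rs", "reference", "mature_catalog", "ncrna_catalog"):
                p = getattr(self, name)
                if p is None:
                    raise ValueError(f"input {name!r} is required when not simulating")
                if not Path(p).exists():
                    raise FileNotFoundError(f"input {name!r} not found: {p}")
        if not 0 <= self.max_mismatches <= 3:
            raise ValueError("max_mismatches must be in 0..3")
        if self.hairpin_window < 30:
            raise ValueError("hairpin_window must be >= 30")
        if self.rpm_floor <= 0:
            raise ValueError("rpm_floor must be > 0")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_artifact(df: pd.DataFrame, path: Path, params: dict) -> None:
    tmp = path.with_suffix(path.suffix + ".partial")
    df.to_csv(tmp, sep="\t", index=False)
    tmp.rename(path)
    sidecar = {"params": params, "sha256": _sha256(path), "rows": int(len(df))}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1, sort_keys=True))


def run_pipeline(cfg: PipelineConfig) -> dict[str, Path]:
    """Run the configured stages in order; returns the artifact paths."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    state: dict = {}

    runners = {
        "simulate": _stage_simulate,
        "clean": _stage_clean,
        "annotate": _stage_annotate,
        "novel": _stage_novel,
        "diffexpr": _stage_diffexpr,
        "targets": _stage_targets,
        "report": _stage_report,
    }
    for stage in STAGES:
        if stage not in cfg.stages:
            continue
        log.info("stage %s: starting", stage)
        try:
            runners[stage](cfg, outdir, state, artifacts)
        except Exception as exc:  # noqa: BLE001 - abort with a named stage
            raise StageError(stage, exc) from exc
        log.info("stage %s: done", stage)
    return artifacts


def _stage_simulate(cfg, outdir, state, artifacts):
    sim_cfg = _sim.SimulationConfig(
        seed=cfg.seed,
        depth_per_library=cfg.depth_per_library,
        adapter5=cfg.adapter5,
        adapter3=cfg.adapter3,
    )
    ds = _sim.simulate_libraries(sim_cfg)
    paths = ds.write(outdir / "simulated")
    cfg.reads_vs = str(paths["reads_vs"])
    cfg.reads_rs = str(paths["reads_rs"])
    cfg.reference = str(paths["reference"])
    cfg.mature_catalog = str(paths["mature_catalog"])
    cfg.ncrna_catalog = str(paths["ncrna_catalog"])
    state["dataset"] = ds
    artifacts.update({f"sim_{k}": v for k, v in paths.items()})


def _stage_clean(cfg, outdir, state, artifacts):
    stats_rows = []
    inserts = {}
    for lib, path in (("vs", cfg.reads_vs), ("rs", cfg.reads_rs)):
        clean, stats = _pp.clean_reads(
            _pp.read_sequences(path), cfg.adapter5, cfg.adapter3
        )
        inserts[lib] = clean
        for cat, n in stats.as_rows():
            stats_rows.append({"library": lib, "category": cat, "count": n})
        log.info("clean %s: %s", lib, dict(stats.as_rows()))
    tags = _pp.collapse(inserts["vs"], inserts["rs"])
    state["tags"] = tags
    state["totals"] = {
        "vs": sum(t.count_vs for t in tags),
        "rs": sum(t.count_rs for t in tags),
    }
    stats_df = pd.DataFrame(stats_rows)
    _write_artifact(stats_df, outdir / "clean_stats.tsv", {"adapter5": cfg.adapter5, "adapter3": cfg.adapter3})
    artifacts["clean_stats"] = outdir / "clean_stats.tsv"

    _pp.write_tags_fasta(tags, outdir / "tags.fasta")
    artifacts["tags"] = outdir / "tags.fasta"

    dist = _pp.length_distribution(tags)
    dist_df = pd.DataFrame(
        [
            {"length": n, "fraction_vs": dist["vs"][n], "fraction_rs": dist["rs"][n]}
            for n in sorted(dist["vs"])
        ]
    )
    _write_artifact(dist_df, outdir / "length_distribution.tsv", {})
    artifacts["length_distribution"] = outdir / "length_distribution.tsv"


def _stage_annotate(cfg, outdir, state, artifacts):
    tags = state["tags"]
    reference = _ann.read_fasta(cfg.reference)
    ncrna = _ann.read_fasta(cfg.ncrna_catalog)
    mature = _ann.read_fasta(cfg.mature_catalog)

    retained, removed = _ann.filter_ncrna(tags, ncrna)
    assignments = _ann.identify_known(retained, mature, max_mm=cfg.max_mismatches)
    assigned_seqs = {a.tag.sequence for a in assignments}
    unannotated = [t for t in retained if t.sequence not in assigned_seqs]
    loci = _ann.map_reference(unannotated, reference)

    state.update(
        reference=reference,
        assignments=assignments,
        unannotated=unannotated,
        loci=loci,
        removed_ncrna=removed,
    )
    table = _ann.build_count_table(
        _ann.assignments_to_rows(assignments), state["totals"]["vs"], state["totals"]["rs"]
    )
    state["count_table"] = table
    _write_artifact(table.mirnas, outdir / "known_mirnas.tsv", {"max_mismatches": cfg.max_mismatches})
    _write_artifact(table.families, outdir / "known_families.tsv", {"max_mismatches": cfg.max_mismatches})
    artifacts["known_mirnas"] = outdir / "known_mirnas.tsv"
    artifacts["known_families"] = outdir / "known_families.tsv"
    removed_df = pd.DataFrame(
        [{"sequence": t.sequence, "class": c, "count_vs": t.count_vs, "count_rs": t.count_rs} for t, c in removed]
    )
    _write_artifact(removed_df, outdir / "ncrna_removed.tsv", {})
    artifacts["ncrna_removed"] = outdir / "ncrna_removed.tsv"

    gff = outdir / "tag_loci.gff3"
    with open(gff, "w") as fh:
        fh.write("##gff-version 3\n")
        for seq, ll in loci.items():
            for lo in ll:
                fh.write(
                    f"{lo.transcript_id}\tmirflow\tsRNA_tag\t{lo.start + 1}\t{lo.end}\t.\t{lo.strand}\t.\tID=tag:{seq}\n"
                )
    artifacts["tag_loci"] = gff


def _stage_novel(cfg, outdir, state, artifacts):
    novel = _hp.call_novel(
        state["unannotated"],
        state["reference"],
        window=cfg.hairpin_window,
        min_total_count=cfg.min_novel_count,
    )
    state["novel"] = novel
    _write_artifact(
        novel,
        outdir / "novel_mirnas.tsv",
        {"window": cfg.hairpin_window, "min_total_count": cfg.min_novel_count},
    )
    artifacts["novel_mirnas"] = outdir / "novel_mirnas.tsv"


def _stage_diffexpr(cfg, outdir, state, artifacts):
    table = state["count_table"]
    rows = [
        (r.mirna_id, int(r.count_vs), int(r.count_rs))
        for r in table.mirnas.itertuples()
    ]
    novel = state.get("novel")
    if novel is not None:
        rows.extend(
            (r.mirna, int(r.count_vs), int(r.count_rs)) for r in novel.itertuples()
        )
    results = _de.classify(rows, state["totals"]["vs"], state["totals"]["rs"], floor=cfg.rpm_floor)
    df = pd.DataFrame(
        [
            {
                "mirna_id": r.mirna_id,
                "count_vs": r.count_vs,
                "count_rs": r.count_rs,
                "rpm_vs": round(r.rpm_vs, 4),
                "rpm_rs": round(r.rpm_rs, 4),
                "log2fc": round(r.log2fc, 2),
                "pvalue": f"{r.pvalue:.3e}",
                "call": r.call,
            }
            for r in results
        ]
    )
    state["diffexpr"] = df
    _write_artifact(df, outdir / "diffexpr.tsv", {"floor": cfg.rpm_floor})
    artifacts["diffexpr"] = outdir / "diffexpr.tsv"


def _stage_targets(cfg, outdir, state, artifacts):
    mirnas = [(a.mirna_id, dict(_ann.read_fasta(cfg.mature_catalog))[a.mirna_id]) for a in state["assignments"]]
    # deduplicate while preserving order
    seen = set()
    uniq = []
    for mid, seq in mirnas:
        if mid not in seen:
            seen.add(mid)
            uniq.append((mid, seq))
    novel = state.get("novel")
    if novel is not None and not novel.empty:
        uniq.extend((r.mirna, r.mature) for r in novel.itertuples())
    transcripts = _ann.read_fasta(cfg.target_transcripts or cfg.reference)
    sites = _tp.predict_targets(uniq, transcripts, cutoff=cfg.target_cutoff) if uniq else []
    df = pd.DataFrame(
        [
            {
                "mirna_id": s.mirna_id,
                "transcript_id": s.transcript_id,
                "start": s.start,
                "end": s.end,
                "expectation": s.expectation,
                "inhibition": s.inhibition,
                "alignment_mirna_3to5": s.alignment[0],
                "alignment_match": s.alignment[1],
                "alignment_target_5to3": s.alignment[2],
            }
            for s in sites
        ],
        columns=[
            "mirna_id", "transcript_id", "start", "end", "expectation",
            "inhibition", "alignment_mirna_3to5", "alignment_match",
            "alignment_target_5to3",
        ],
    )
    state["targets"] = df
    _write_artifact(df, outdir / "target_sites.tsv", {"cutoff": cfg.target_cutoff})
    artifacts["target_sites"] = outdir / "target_sites.tsv"


def _stage_report(cfg, outdir, state, artifacts):
    md, payload = render_report(outdir)
    (outdir / "report.md").write_text(md)
    (outdir / "report.json").write_text(json.dumps(payload, indent=1, sort_keys=True))
    artifacts["report_md"] = outdir / "report.md"
    artifacts["report_json"] = outdir / "report.json"


def render_report(outdir) -> tuple[str, dict]:
    """Render the summary document from the stage TSVs already on disk.

    Numbers are read back from the artifacts, never recomputed, so the
    report always equals the underlying TSVs.  Missing artifacts are
    listed as "not run".
    """
    outdir = Path(outdir)
    sections = {
        "Read accounting": "clean_stats.tsv",
        "Length distribution": "length_distribution.tsv",
        "Known miRNA families": "known_families.tsv",
        "Novel miRNAs": "novel_mirnas.tsv",
        "Differential expression": "diffexpr.tsv",
        "Target sites": "target_sites.tsv",
    }
    lines = ["# mirflow pipeline report", ""]
    payload: dict = {}
    for title, fname in sections.items():
        lines.append(f"## {title}")
        path = outdir / fname
        if not path.exists():
            lines.append("")
            lines.append("not run")
            lines.append("")
            payload[fname.removesuffix(".tsv")] = None
            continue
        df = pd.read_csv(path, sep="\t")
        payload[fname.removesuffix(".tsv")] = df.to_dict(orient="records")
        lines.append("")
        lines.append("```\n" + df.to_string(index=False) + "\n```")
        lines.append("")
    return "\n".join(lines), payload
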