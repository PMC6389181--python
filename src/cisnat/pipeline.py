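"""End-to-end orchestration: annotation -> catalog -> counts -> RPKM -> DE -> classification.

``run_pipeline`` executes every stage on real inputs (GFF3 annotation, a
design table pointing at per-sample SAM/BAM files, optionally a GO mapping)
and writes plain-TSV outputs with stable names into one directory; rerunning
with identical inputs and config is bit-identical apart from the timestamp
line in run.log.  ``report`` re-derives a human-readable summary from the
TSVs alone, never from cached state.
"""

from __future__ import annotations

import hashlib
import json
import os
import time as _time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .catalog import build_catalog, parse_gff
from .diffexpr import (
    DEFAULT_ALPHA,
    DEFAULT_FC_FLOOR,
    DEFAULT_PSEUDOCOUNT,
    replicate_qc,
    run_contrasts,
    summarize_calls,
)
from .nat import classify_nat_loci, go_distribution, overlap_stats
from .quantify import compute_rpkm, count_reads

__all__ = ["PipelineConfig", "run_pipeline", "report"]

STAGE_FILES = {
    "catalog": "catalog.tsv",
    "counts": "counts.tsv",
    "library_sizes": "library_sizes.tsv",
    "rpkm": "rpkm.tsv",
    "replicate_qc": "replicate_qc.tsv",
    "diffcalls": "diffcalls.tsv",
    "summary": "summary_counts.tsv",
    "classification": "classification.tsv",
    "overlaps": "overlap_regions.tsv",
    "go": "go_distribution.tsv",
}


@dataclass
class PipelineConfig:
    """Paths and thresholds for one pipeline run; serialised into the output."""

    annotation: str
    design: str
    go_mapping: str | None = None
    strandedness: str = "forward"
    min_reads: int = 1
    alpha: float = DEFAULT_ALPHA
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    fc_floor: float = DEFAULT_FC_FLOOR
    exclude_same_strand: bool = True
    min_mapq: int | None = None
    classify_time: int | None = None  # default: latest timepoint
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.strandedness not in {"forward", "reverse"}:
            raise ValueError("strandedness must be 'forward' or 'reverse'")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.pseudocount < 0 or self.fc_floor < 1 or self.min_reads < 0:
            raise ValueError("thresholds out of range")

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "PipelineConfig":
        return cls(**json.loads(Path(path).read_text()))

    def to_json(self, path: str | os.PathLike) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def run_pipeline(config: PipelineConfig, out_dir: str | os.PathLike) -> Path:
    """Run every stage and write outputs under ``out_dir``.

    The design TSV must have columns sample_id, tissue, condition, time,
    replicate, path (SAM/BAM per sample).  Stage failures abort with the
    stage name in the exception message.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = [
        f"# cisnat {__version__} run",
        f"timestamp: {_time.strftime('%Y-%m-%dT%H:%M:%S')}",
        f"config_hash: {_config_hash(config)}",
    ]
    config.to_json(out / "config.json")

    def stage(name):
        log_lines.append(f"stage: {name}")

    try:
        stage("catalog")
        genes = parse_gff(config.annotation)
        catalog = build_catalog(genes, exclude_same_strand=config.exclude_same_strand)
        catalog.to_tsv(out / STAGE_FILES["catalog"])
        log_lines.append(
            f"  genes={len(genes)} eligible={len(catalog.eligible)} "
            f"excluded={len(catalog.excluded)}"
        )

        stage("quantify")
        design = pd.read_csv(config.design, sep="\t")
        design_dir = Path(config.design).parent
        sample_paths = {
            s: p if Path(p).is_absolute() else str(design_dir / p)
            for s, p in zip(design["sample_id"], design["path"])
        }
        table = count_reads(
            sample_paths, catalog, strandedness=config.strandedness, min_mapq=config.min_mapq
        )
        table.to_tsv(out / STAGE_FILES["counts"])
        table.library_sizes_to_tsv(out / STAGE_FILES["library_sizes"])
        log_lines.append(f"  samples={len(sample_paths)} count_rows={len(table.counts)}")

        stage("rpkm")
        expr = compute_rpkm(table, catalog.exon_lengths())
        expr.sort_values(["transcript_id", "strand_class", "sample_id"]).to_csv(
            out / STAGE_FILES["rpkm"], sep="\t", index=False
        )

        stage("replicate_qc")
        qc = replicate_qc(expr, design)
        qc.to_csv(out / STAGE_FILES["replicate_qc"], sep="\t", index=False)
        log_lines.append(f"  groups={len(qc)} passing={int(qc['pass'].sum())}")

        stage("diffexp")
        calls = run_contrasts(
            table, expr, design,
            alpha=config.alpha, pseudocount=config.pseudocount, fc_floor=config.fc_floor,
        )
        calls.sort_values(
            ["tissue", "condition", "time", "strand_class", "transcript_id"]
        ).to_csv(out / STAGE_FILES["diffcalls"], sep="\t", index=False)
        summarize_calls(calls).to_csv(out / STAGE_FILES["summary"], sep="\t", index=False)
        log_lines.append(f"  tests={len(calls)}")

        stage("classify")
        t_cls = config.classify_time if config.classify_time is not None else calls["time"].max()
        cls_frames = []
        antisense_up_sets: dict[str, set[str]] = {}
        for (tissue, cond), grp in calls[calls["time"] == t_cls].groupby(["tissue", "condition"]):
            anti = grp[grp["strand_class"] == "antisense"]
            sense = grp[grp["strand_class"] == "sense"]
            classification = classify_nat_loci(anti, sense)
            frame = classification.table.copy()
            frame.insert(0, "condition", cond)
            frame.insert(0, "tissue", tissue)
            cls_frames.append(frame)
            antisense_up_sets[f"{tissue}:{cond}"] = set(frame["transcript_id"])
        classification_table = (
            pd.concat(cls_frames, ignore_index=True)
            if cls_frames
            else pd.DataFrame(columns=["tissue", "condition", "transcript_id", "sense_call", "group"])
        )
        classification_table.to_csv(out / STAGE_FILES["classification"], sep="\t", index=False)
        log_lines.append(f"  classified={len(classification_table)} at time={t_cls}")

        stage("overlap")
        if len(antisense_up_sets) >= 2:
            summary = overlap_stats(antisense_up_sets)
            summary.to_tsv(out / STAGE_FILES["overlaps"])
            log_lines.append(f"  sets={len(antisense_up_sets)}")
        else:
            log_lines.append("  skipped (needs >=2 condition sets)")

        stage("go")
        if config.go_mapping:
            mapping = pd.read_csv(config.go_mapping, sep="\t")
            all_up = set(classification_table["transcript_id"])
            go = go_distribution(all_up, mapping)
            go.to_csv(out / STAGE_FILES["go"], sep="\t", index=False)
            log_lines.append(f"  categories={len(go)}")
        else:
            log_lines.append("  skipped (no mapping)")
    except Exception as exc:
        log_lines.append(f"ABORTED: {exc}")
        (out / "run.log").write_text("\n".join(log_lines) + "\n")
        raise

    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return out


def report(output_dir: str | os.PathLike) -> str:
    """Re-derive a markdown summary from a completed run's TSVs."""
    out = Path(output_dir)
    for key in ("diffcalls", "classification"):
        if not (out / STAGE_FILES[key]).exists():
            raise FileNotFoundError(f"missing stage output: {STAGE_FILES[key]}")
    calls = pd.read_csv(out / STAGE_FILES["diffcalls"], sep="\t")
    classification = pd.read_csv(out / STAGE_FILES["classification"], sep="\t")

    lines = ["# cisnat run summary", "", "## Responsive transcripts per contrast", ""]
    lines.append("| tissue | condition | time | class | up | down |")
    lines.append("|---|---|---|---|---|---|")
    for (tissue, cond, t, cls), grp in calls.groupby(
        ["tissue", "condition", "time", "strand_class"]
    ):
        n_up = int((grp["call"] == "up").sum())
        n_down = int((grp["call"] == "down").sum())
        lines.append(f"| {tissue} | {cond} | {t} | {cls} | {n_up} | {n_down} |")

    lines += ["", "## Sense response at antisense-up loci", ""]
    if classification.empty:
        lines.append("no antisense-upregulated loci")
    else:
        for (tissue, cond), grp in classification.groupby(["tissue", "condition"]):
            sizes = grp["group"].value_counts()
            lines.append(
                f"- {tissue} / {cond}: {len(grp)} antisense-up loci — "
                f"{int(sizes.get('upregulated', 0))} sense-up, "
                f"{int(sizes.get('invariable', 0))} invariable, "
                f"{int(sizes.get('downregulated', 0))} sense-down"
            )

    overlaps_path = out / STAGE_FILES["overlaps"]
    if overlaps_path.exists():
        regions = pd.read_csv(overlaps_path, sep="\t")
        lines += ["", "## Antisense-up overlap regions", ""]
        for row in regions.itertuples(index=False):
            lines.append(f"- {row.region}: {row.count}")
    return "\n".join(lines) + "\n"
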