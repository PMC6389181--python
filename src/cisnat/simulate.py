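"""Synthetic strand-specific RNA-seq experiment with known ground truth.

Generates everything the downstream stages consume — a GFF3 annotation with
isolated single-gene loci plus planted overlapping gene pairs, a sample
design table (tissue x condition x time x replicate), per-sample stranded
SAM alignments, and FASTQ for the trimmer — so the whole pipeline is testable
without any external data.

The count model is deliberately minimal: per (locus, strand class, sample)
reads are drawn negative-binomially with mean = baseline x effect multiplier
and a single NB2 overdispersion parameter (variance = m + dispersion * m^2;
dispersion 0 collapses to Poisson).  Reads are single-end, placed uniformly
within the locus span, with no splicing, sequencing error or adapters.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import pysam

from .catalog import GeneModel

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "make_annotation",
    "write_gff",
    "simulate_counts",
    "emit_alignments",
    "emit_fastq",
    "write_experiment",
]

SENSE = "sense"
ANTISENSE = "antisense"
STRAND_CLASSES = (SENSE, ANTISENSE)

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class SimulationConfig:
    """Design of the synthetic stranded experiment.

    ``effect_table`` maps ``(transcript_id, strand_class, condition, time)``
    to a fold-effect multiplier applied to the class baseline mean; absent
    keys mean 1 (null).  Differential truth for a contrast against time 0 is
    the ratio of the multiplier at time t to the multiplier at time 0.
    ``library_size`` is a nominal per-sample target; the realised library
    size (the NB draw total) is what gets recorded and used downstream.
    """

    n_single_loci: int = 20
    n_opposite_overlap_pairs: int = 2
    n_same_strand_overlap_pairs: int = 1
    locus_length_range: tuple[int, int] = (800, 2000)
    conditions: tuple[str, ...] = ("Cd_50uM",)
    timepoints: tuple[int, ...] = (0, 1, 12, 24)
    tissue: str = "root"
    replicates_per_sample: int = 2
    baseline_sense_mean: float = 100.0
    baseline_antisense_mean: float = 20.0
    dispersion: float = 0.1
    effect_table: Mapping[tuple[str, str, str, int], float] = field(default_factory=dict)
    library_size: int | None = None
    read_length: int = 75
    multimapper_fraction: float = 0.0
    intergenic_gap: int = 500
    chrom: str = "chrS1"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_single_loci, self.n_opposite_overlap_pairs, self.n_same_strand_overlap_pairs) < 0:
            raise ValueError("locus counts must be >= 0")
        lo, hi = self.locus_length_range
        if lo < 2 or hi < lo:
            raise ValueError(f"invalid locus_length_range {self.locus_length_range}")
        if self.replicates_per_sample < 1:
            raise ValueError("replicates_per_sample must be >= 1")
        if self.dispersion < 0:
            raise ValueError(f"dispersion must be >= 0, got {self.dispersion}")
        if self.baseline_sense_mean < 0 or self.baseline_antisense_mean < 0:
            raise ValueError("baseline means must be >= 0")
        if not 0 <= self.multimapper_fraction <= 1:
            raise ValueError("multimapper_fraction must be in [0, 1]")
        for key, eff in self.effect_table.items():
            if eff < 0:
                raise ValueError(f"effect multiplier for {key} must be >= 0")

    @property
    def n_genes(self) -> int:
        return (
            self.n_single_loci
            + 2 * self.n_opposite_overlap_pairs
            + 2 * self.n_same_strand_overlap_pairs
        )

    def sample_ids(self) -> list[str]:
        return [
            f"{self.tissue}_{cond}_t{t}_r{r}"
            for cond in self.conditions
            for t in self.timepoints
            for r in range(1, self.replicates_per_sample + 1)
        ]

    def design(self) -> pd.DataFrame:
        rows = [
            {
                "sample_id": f"{self.tissue}_{cond}_t{t}_r{r}",
                "tissue": self.tissue,
                "condition": cond,
                "time": t,
                "replicate": r,
            }
            for cond in self.conditions
            for t in self.timepoints
            for r in range(1, self.replicates_per_sample + 1)
        ]
        return pd.DataFrame(rows)

    def effect(self, transcript_id: str, strand_class: str, condition: str, time: int) -> float:
        return float(self.effect_table.get((transcript_id, strand_class, condition, time), 1.0))

    def to_json(self, path: str | os.PathLike) -> None:
        data = asdict(self)
        data["effect_table"] = [
            list(k) + [v] for k, v in sorted(self.effect_table.items())
        ]
        Path(path).write_text(json.dumps(data, indent=2, default=str) + "\n")


@dataclass
class GroundTruth:
    """Planted truth of the simulation.

    ``expected``: per (transcript_id, strand_class, sample_id) the NB mean.
    ``status``: per (transcript_id, strand_class, condition, time>0) the true
    differential status vs. time 0 in {up, null, down}.
    ``library_sizes``: realised total reads per sample.
    """

    expected: pd.DataFrame
    status: pd.DataFrame
    library_sizes: dict[str, int]

    def true_set(self, strand_class: str, condition: str, time: int, direction: str) -> set[str]:
        s = self.status
        mask = (
            (s["strand_class"] == strand_class)
            & (s["condition"] == condition)
            & (s["time"] == time)
            & (s["status"] == direction)
        )
        return set(s.loc[mask, "transcript_id"])

    def write(self, out_dir: str | os.PathLike) -> None:
        out = Path(out_dir)
        self.expected.to_csv(out / "truth_expected.tsv", sep="\t", index=False)
        self.status.to_csv(out / "truth_status.tsv", sep="\t", index=False)
        pd.Series(self.library_sizes, name="library_size").rename_axis("sample_id").to_csv(
            out / "truth_library_sizes.tsv", sep="\t"
        )


def make_annotation(config: SimulationConfig) -> tuple[list[GeneModel], dict[str, int]]:
    """Lay out the synthetic genes on one chromosome.

    Emits ``n_single_loci`` isolated genes, then the opposite-strand
    overlapping pairs, then the same-strand pairs, separated by
    ``intergenic_gap`` so no unplanned overlap can occur.  Each gene has a
    single transcript with one exon covering its span.  Deterministic for a
    given config (seeded layout).
    """
    rng = np.random.default_rng([config.seed, 0])
    lo, hi = config.locus_length_range
    genes: list[GeneModel] = []
    pos = config.intergenic_gap
    idx = 0

    def add_gene(start: int, length: int, strand: str) -> GeneModel:
        nonlocal idx
        idx += 1
        gid = f"SYNG{idx:05d}"
        g = GeneModel(
            gene_id=gid,
            transcript_id=f"{gid}-01",
            chrom=config.chrom,
            strand=strand,
            start=start,
            end=start + length,
            exon_length=length,
        )
        genes.append(g)
        return g

    for _ in range(config.n_single_loci):
        length = int(rng.integers(lo, hi + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        add_gene(pos, length, strand)
        pos += length + config.intergenic_gap
    for _ in range(config.n_opposite_overlap_pairs):
        l1 = int(rng.integers(lo, hi + 1))
        l2 = int(rng.integers(lo, hi + 1))
        a = add_gene(pos, l1, "+")
        add_gene(a.start + l1 // 2, l2, "-")  # overlaps a by construction
        pos = max(a.end, a.start + l1 // 2 + l2) + config.intergenic_gap
    for _ in range(config.n_same_strand_overlap_pairs):
        l1 = int(rng.integers(lo, hi + 1))
        l2 = int(rng.integers(lo, hi + 1))
        a = add_gene(pos, l1, "+")
        add_gene(a.start + l1 // 2, l2, "+")
        pos = max(a.end, a.start + l1 // 2 + l2) + config.intergenic_gap

    chrom_lengths = {config.chrom: pos + config.intergenic_gap}
    return genes, chrom_lengths


def write_gff(
    genes: list[GeneModel],
    chrom_lengths: Mapping[str, int],
    path: str | os.PathLike,
) -> None:
    """Write gene/mRNA/exon features as GFF3 (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom in sorted(chrom_lengths):
            fh.write(f"##sequence-region {chrom} 1 {chrom_lengths[chrom]}\n")
        for g in genes:
            start1, end1 = g.start + 1, g.end
            common = f"{g.chrom}\tcisnat_sim"
            fh.write(f"{common}\tgene\t{start1}\t{end1}\t.\t{g.strand}\t.\tID={g.gene_id}\n")
            fh.write(
                f"{common}\tmRNA\t{start1}\t{end1}\t.\t{g.strand}\t.\t"
                f"ID={g.transcript_id};Parent={g.gene_id}\n"
            )
            fh.write(
                f"{common}\texon\t{start1}\t{end1}\t.\t{g.strand}\t.\t"
                f"ID={g.transcript_id}.exon1;Parent={g.transcript_id}\n"
            )


def _nb_draw(rng: np.random.Generator, mean: float, dispersion: float, size: int) -> np.ndarray:
    """NB2 draw: variance = mean + dispersion * mean^2; dispersion 0 => Poisson."""
    if mean <= 0:
        return np.zeros(size, dtype=int)
    if dispersion == 0:
        return rng.poisson(mean, size)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p, size)


def simulate_counts(
    config: SimulationConfig, genes: list[GeneModel] | None = None
) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw per-sample sense and antisense counts for every locus.

    Returns a long-format count table (transcript_id, strand_class,
    sample_id, count) and the :class:`GroundTruth`.  Realised library sizes
    are the per-sample count totals.
    """
    if genes is None:
        genes, _ = make_annotation(config)
    rng = np.random.default_rng([config.seed, 1])
    baselines = {SENSE: config.baseline_sense_mean, ANTISENSE: config.baseline_antisense_mean}

    rows = []
    expected_rows = []
    for cond in config.conditions:
        for t in config.timepoints:
            for g in genes:
                for cls in STRAND_CLASSES:
                    mean = baselines[cls] * config.effect(g.transcript_id, cls, cond, t)
                    draws = _nb_draw(rng, mean, config.dispersion, config.replicates_per_sample)
                    for r in range(1, config.replicates_per_sample + 1):
                        sample = f"{config.tissue}_{cond}_t{t}_r{r}"
                        rows.append((g.transcript_id, cls, sample, int(draws[r - 1])))
                        expected_rows.append((g.transcript_id, cls, sample, mean))

    counts = pd.DataFrame(rows, columns=["transcript_id", "strand_class", "sample_id", "count"])
    expected = pd.DataFrame(
        expected_rows, columns=["transcript_id", "strand_class", "sample_id", "mean"]
    )

    status_rows = []
    for cond in config.conditions:
        t0 = min(config.timepoints)
        for t in config.timepoints:
            if t == t0:
                continue
            for g in genes:
                for cls in STRAND_CLASSES:
                    ratio = config.effect(g.transcript_id, cls, cond, t) / max(
                        config.effect(g.transcript_id, cls, cond, t0), 1e-300
                    )
                    status = "up" if ratio > 1 else ("down" if ratio < 1 else "null")
                    status_rows.append((g.transcript_id, cls, cond, t, status))
    status = pd.DataFrame(
        status_rows, columns=["transcript_id", "strand_class", "condition", "time", "status"]
    )

    library_sizes = counts.groupby("sample_id")["count"].sum().astype(int).to_dict()
    return counts, GroundTruth(expected=expected, status=status, library_sizes=library_sizes)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def emit_alignments(
    counts: pd.DataFrame,
    genes: list[GeneModel],
    chrom_lengths: Mapping[str, int],
    out_dir: str | os.PathLike,
    strandedness: str = "forward",
    read_length: int = 75,
    multimapper_fraction: float = 0.0,
    seed: int = 0,
) -> dict[str, Path]:
    """Write one SAM file per sample realising the simulated counts.

    Each simulated read becomes one aligned single-end record placed
    uniformly within its locus span, oriented so that under the declared
    ``strandedness`` convention it quantifies back to its strand class.
    Uniqueness is encoded in the ``NH`` tag (1 = unique); a
    ``multimapper_fraction`` > 0 marks that fraction of reads NH=2.
    """
    if strandedness not in {"forward", "reverse"}:
        raise ValueError(f"strandedness must be 'forward' or 'reverse', got {strandedness!r}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    by_id = {g.transcript_id: g for g in genes}
    chroms = sorted(chrom_lengths)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": int(chrom_lengths[c])} for c in chroms],
    }
    tid = {c: i for i, c in enumerate(chroms)}

    paths: dict[str, Path] = {}
    samples = sorted(counts["sample_id"].unique())
    for si, sample in enumerate(samples):
        rng = np.random.default_rng([seed, 2, si])
        path = out / f"{sample}.sam"
        sub = counts[counts["sample_id"] == sample]
        with pysam.AlignmentFile(str(path), "w", header=header) as sam:
            for row in sub.itertuples(index=False):
                g = by_id[row.transcript_id]
                n = int(row.count)
                if n == 0:
                    continue
                rlen = min(read_length, g.length)
                starts = rng.integers(g.start, g.end - rlen + 1, size=n)
                multi = (
                    rng.random(n) < multimapper_fraction
                    if multimapper_fraction > 0
                    else np.zeros(n, dtype=bool)
                )
                transcript_orientation = (
                    g.strand if row.strand_class == SENSE else ("-" if g.strand == "+" else "+")
                )
                if strandedness == "forward":
                    read_orientation = transcript_orientation
                else:
                    read_orientation = "-" if transcript_orientation == "+" else "+"
                for i in range(n):
                    a = pysam.AlignedSegment()
                    a.query_name = f"{sample}:{row.transcript_id}:{row.strand_class}:{i}"
                    a.query_sequence = _random_seq(rng, rlen)
                    a.flag = 16 if read_orientation == "-" else 0
                    a.reference_id = tid[g.chrom]
                    a.reference_start = int(starts[i])
                    a.mapping_quality = 3 if multi[i] else 50
                    a.cigarstring = f"{rlen}M"
                    a.query_qualities = pysam.qualitystring_to_array("I" * rlen)
                    a.set_tag("NH", 2 if multi[i] else 1)
                    sam.write(a)
        paths[sample] = path
    return paths


def emit_fastq(
    path: str | os.PathLike,
    n_reads: int,
    quality_profile: np.ndarray | list[int],
    seed: int = 0,
) -> None:
    """Write ``n_reads`` FASTQ records with the given per-base Phred profile.

    All reads share ``quality_profile`` (one Phred score per base, Phred+33
    encoded); sequences are random nucleotides.  Deterministic for a given
    seed.
    """
    profile = np.asarray(quality_profile, dtype=int)
    if profile.ndim != 1 or profile.size == 0:
        raise ValueError("quality_profile must be a non-empty 1-D array of Phred scores")
    if profile.min() < 0 or profile.max() > 93:
        raise ValueError("Phred scores must be in [0, 93] for Phred+33 encoding")
    rng = np.random.default_rng([seed, 3])
    qual = "".join(chr(q + 33) for q in profile)
    with open(path, "w") as fh:
        for i in range(n_reads):
            seq = _random_seq(rng, profile.size)
            fh.write(f"@synthetic_read_{i}\n{seq}\n+\n{qual}\n")


def write_experiment(
    config: SimulationConfig, out_dir: str | os.PathLike
) -> dict[str, object]:
    """Materialise the full synthetic experiment in ``out_dir``.

    Writes annotation.gff3, genome.tsv, design.tsv, per-sample SAM files
    under sam/, ground-truth TSVs and the config as JSON.  Returns the
    in-memory objects (genes, counts, truth, sam paths, design).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genes, chrom_lengths = make_annotation(config)
    write_gff(genes, chrom_lengths, out / "annotation.gff3")
    with open(out / "genome.tsv", "w") as fh:
        fh.write("chrom\tlength\n")
        for c in sorted(chrom_lengths):
            fh.write(f"{c}\t{chrom_lengths[c]}\n")
    counts, truth = simulate_counts(config, genes)
    truth.write(out)
    sam_paths = emit_alignments(
        counts,
        genes,
        chrom_lengths,
        out / "sam",
        read_length=config.read_length,
        multimapper_fraction=config.multimapper_fraction,
        seed=config.seed,
    )
    design = config.design()
    # paths relative to the experiment directory keep reruns byte-identical
    design["path"] = [f"sam/{s}.sam" for s in design["sample_id"]]
    design.to_csv(out / "design.tsv", sep="\t", index=False)
    config.to_json(out / "config.json")
    return {
        "genes": genes,
        "chrom_lengths": chrom_lengths,
        "counts": counts,
        "truth": truth,
        "sam_paths": sam_paths,
        "design": design,
    }
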