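"""Strand-aware read counting and RPKM for single-gene loci.

Uniquely mapped reads are assigned to the sense or antisense class of the
eligible locus they overlap: a read whose transcriptional orientation (its
mapped orientation under a forward-stranded library, the complement under a
reverse-stranded one) matches the gene's strand is sense, otherwise
antisense.  Any ≥1 bp overlap of the read interval with the locus span
counts; reads touching two eligible loci are ambiguous and dropped, and
multimappers are never counted.  Expression is reported as RPKM =
10^9 * C / (N * L) with N the sample's total unique alignments and L the
transcript's exon length.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd
import pysam
from intervaltree import IntervalTree

from .catalog import GeneModel, LocusCatalog

__all__ = [
    "StrandedAlignment",
    "StrandedCountTable",
    "iter_alignments",
    "assign_read",
    "count_sample",
    "count_reads",
    "compute_rpkm",
    "detect_expressed",
]

SENSE = "sense"
ANTISENSE = "antisense"


@dataclass(frozen=True)
class StrandedAlignment:
    """A single-end read placement: 0-based half-open interval plus orientation."""

    read_id: str
    chrom: str
    start: int
    end: int
    orientation: str
    is_unique: bool

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"{self.read_id}: empty alignment interval")
        if self.orientation not in {"+", "-"}:
            raise ValueError(f"{self.read_id}: orientation must be '+' or '-'")


@dataclass
class StrandedCountTable:
    """Per (transcript, strand class, sample) read counts plus library sizes.

    ``counts`` is long-format with columns transcript_id, strand_class,
    sample_id, count; ``library_sizes`` maps sample_id to the total number of
    unique alignments in that sample.
    """

    counts: pd.DataFrame
    library_sizes: dict[str, int] = field(default_factory=dict)

    def get(self, transcript_id: str, strand_class: str, sample_id: str) -> int:
        df = self.counts
        mask = (
            (df["transcript_id"] == transcript_id)
            & (df["strand_class"] == strand_class)
            & (df["sample_id"] == sample_id)
        )
        sub = df.loc[mask, "count"]
        return int(sub.iloc[0]) if len(sub) else 0

    def to_tsv(self, path: str | os.PathLike) -> None:
        self.counts.sort_values(["transcript_id", "strand_class", "sample_id"]).to_csv(
            path, sep="\t", index=False
        )

    def library_sizes_to_tsv(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write("sample_id\tlibrary_size\n")
            for s in sorted(self.library_sizes):
                fh.write(f"{s}\t{self.library_sizes[s]}\n")


def iter_alignments(
    path: str | os.PathLike, min_mapq: int | None = None
) -> Iterator[StrandedAlignment]:
    """Stream primary mapped records from SAM/BAM as :class:`StrandedAlignment`.

    Uniqueness comes from the ``NH`` tag when present (NH == 1); otherwise a
    read is unique iff its MAPQ is >= ``min_mapq`` (default: any MAPQ).
    """
    with pysam.AlignmentFile(str(path), check_sq=False) as sam:
        for a in sam:
            if a.is_unmapped or a.is_secondary or a.is_supplementary:
                continue
            if a.has_tag("NH"):
                unique = a.get_tag("NH") == 1
            elif min_mapq is not None:
                unique = a.mapping_quality >= min_mapq
            else:
                unique = True
            yield StrandedAlignment(
                read_id=a.query_name,
                chrom=a.reference_name,
                start=a.reference_start,
                end=a.reference_end,
                orientation="-" if a.is_reverse else "+",
                is_unique=unique,
            )


def _transcription_orientation(aln_orientation: str, strandedness: str) -> str:
    if strandedness == "forward":
        return aln_orientation
    if strandedness == "reverse":
        return "-" if aln_orientation == "+" else "+"
    raise ValueError(f"strandedness must be 'forward' or 'reverse', got {strandedness!r}")


def assign_read(
    aln: StrandedAlignment, locus: GeneModel, strandedness: str = "forward"
) -> str | None:
    """Classify one alignment against one locus: 'sense', 'antisense' or None.

    None for non-unique reads, different chromosomes, or no span overlap.
    """
    tx_orientation = _transcription_orientation(aln.orientation, strandedness)
    if not aln.is_unique or aln.chrom != locus.chrom:
        return None
    if aln.end <= locus.start or aln.start >= locus.end:
        return None
    return SENSE if tx_orientation == locus.strand else ANTISENSE


def _locus_trees(catalog: LocusCatalog) -> dict[str, IntervalTree]:
    """Interval trees over union gene spans of eligible loci, keyed by chromosome."""
    spans: dict[str, tuple[str, str, int, int]] = {}
    for g in catalog.eligible:
        if g.gene_id in spans:
            chrom, strand, s, e = spans[g.gene_id]
            spans[g.gene_id] = (chrom, strand, min(s, g.start), max(e, g.end))
        else:
            spans[g.gene_id] = (g.chrom, g.strand, g.start, g.end)
    trees: dict[str, IntervalTree] = {}
    for gid, (chrom, strand, s, e) in spans.items():
        trees.setdefault(chrom, IntervalTree()).addi(s, e, (gid, strand))
    return trees


def count_sample(
    alignments: Iterable[StrandedAlignment] | str | os.PathLike,
    catalog: LocusCatalog,
    strandedness: str = "forward",
    min_mapq: int | None = None,
    known_chroms: set[str] | None = None,
) -> tuple[dict[tuple[str, str], int], int]:
    """Count sense/antisense reads per eligible gene for one sample.

    Returns ``({(gene_id, strand_class): count}, library_size)`` where
    library_size is the number of unique alignments seen.  A unique read
    overlapping exactly one eligible locus increments that locus; reads
    overlapping two or more eligible loci are discarded as ambiguous.
    Raises :class:`ValueError` for an alignment on a chromosome absent from
    ``known_chroms`` (when provided).
    """
    if isinstance(alignments, (str, os.PathLike)):
        alignments = iter_alignments(alignments, min_mapq=min_mapq)
    trees = _locus_trees(catalog)
    counts: dict[tuple[str, str], int] = {}
    library_size = 0
    for aln in alignments:
        if known_chroms is not None and aln.chrom not in known_chroms:
            raise ValueError(f"alignment {aln.read_id} references unknown chromosome {aln.chrom}")
        if not aln.is_unique:
            continue
        library_size += 1
        tree = trees.get(aln.chrom)
        if tree is None:
            continue
        hits = tree.overlap(aln.start, aln.end)
        if len(hits) != 1:
            continue  # no locus, or ambiguous between two eligible loci
        gid, gene_strand = next(iter(hits)).data
        tx_orientation = _transcription_orientation(aln.orientation, strandedness)
        cls = SENSE if tx_orientation == gene_strand else ANTISENSE
        counts[(gid, cls)] = counts.get((gid, cls), 0) + 1
    return counts, library_size


def count_reads(
    sample_paths: Mapping[str, str | os.PathLike],
    catalog: LocusCatalog,
    strandedness: str = "forward",
    min_mapq: int | None = None,
    known_chroms: set[str] | None = None,
) -> StrandedCountTable:
    """Build the full count table over all samples.

    ``sample_paths`` maps sample_id to a SAM/BAM path.  Locus-level counts
    are reported per transcript of the gene (one row per transcript and
    strand class), with zero-filled cells for unexpressed loci.
    """
    transcripts_by_gene: dict[str, list[str]] = {}
    for g in catalog.eligible:
        transcripts_by_gene.setdefault(g.gene_id, []).append(g.transcript_id)

    rows = []
    library_sizes: dict[str, int] = {}
    for sample in sorted(sample_paths):
        gene_counts, n = count_sample(
            sample_paths[sample],
            catalog,
            strandedness=strandedness,
            min_mapq=min_mapq,
            known_chroms=known_chroms,
        )
        library_sizes[sample] = n
        for gid in sorted(transcripts_by_gene):
            for cls in (SENSE, ANTISENSE):
                c = gene_counts.get((gid, cls), 0)
                for tx in transcripts_by_gene[gid]:
                    rows.append((tx, cls, sample, c))
    counts = pd.DataFrame(rows, columns=["transcript_id", "strand_class", "sample_id", "count"])
    return StrandedCountTable(counts=counts, library_sizes=library_sizes)


def compute_rpkm(
    table: StrandedCountTable, exon_lengths: Mapping[str, int]
) -> pd.DataFrame:
    """RPKM = 10^9 * C / (N * L) per (transcript, strand class, sample).

    L is the transcript's exon length, used for both strand classes.  Raises
    for L == 0 or for a sample with reads at a locus but library size 0.
    """
    df = table.counts.copy()
    lengths = df["transcript_id"].map(exon_lengths)
    if lengths.isna().any():
        missing = sorted(df.loc[lengths.isna(), "transcript_id"].unique())
        raise KeyError(f"no exon length for transcripts: {missing[:5]}")
    if (lengths <= 0).any():
        raise ValueError("exon length must be positive for RPKM")
    n = df["sample_id"].map(table.library_sizes).astype(float)
    bad = (n == 0) & (df["count"] > 0)
    if bad.any():
        raise ValueError("library size 0 with nonzero counts in sample(s): "
                         f"{sorted(df.loc[bad, 'sample_id'].unique())}")
    with np.errstate(invalid="ignore", divide="ignore"):
        rpkm = 1e9 * df["count"].to_numpy(float) / (n.to_numpy() * lengths.to_numpy(float))
    df["rpkm"] = np.where(df["count"].to_numpy() == 0, 0.0, rpkm)
    return df


def detect_expressed(table: StrandedCountTable, min_reads: int = 1) -> pd.DataFrame:
    """Flag each (transcript, strand class) expressed if C >= min_reads in any sample."""
    grouped = (
        table.counts.groupby(["transcript_id", "strand_class"])["count"]
        .max()
        .reset_index()
    )
    grouped["expressed"] = grouped["count"] >= min_reads
    return grouped.drop(columns="count")
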