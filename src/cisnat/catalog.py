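"""Gene-locus catalog construction for cis-NAT analysis.

A cis-natural antisense transcript (cis-NAT) can only be called unambiguously
at a locus occupied by a single annotated gene: if two genes overlap on
opposite strands, antisense reads of one are sense reads of the other.  This
module parses a GFF3 annotation into transcript-level gene models and
partitions them into loci *eligible* for sense/antisense quantification and
loci *excluded* because of overlap with another gene.

Coordinates are converted from GFF3 (1-based, inclusive) to the internal
0-based half-open convention at parse time.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass, field

import gffutils
from intervaltree import IntervalTree

__all__ = [
    "GeneModel",
    "LocusCatalog",
    "parse_gff",
    "build_catalog",
    "OPPOSITE_STRAND_OVERLAP",
    "SAME_STRAND_OVERLAP",
]

OPPOSITE_STRAND_OVERLAP = "opposite_strand_overlap"
SAME_STRAND_OVERLAP = "same_strand_overlap"


@dataclass(frozen=True)
class GeneModel:
    """One annotated transcript.

    ``start``/``end`` are 0-based half-open genomic coordinates of the
    transcript span.  ``exon_length`` is the summed exon length in bp and is
    the RPKM length denominator for both the sense transcript and its
    antisense counterpart (antisense signal is reported relative to the
    annotated transcript it overlaps).
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exon_length: int

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.transcript_id}: strand must be '+' or '-', got {self.strand!r}")
        if not self.start < self.end:
            raise ValueError(f"{self.transcript_id}: empty or inverted span [{self.start}, {self.end})")
        if self.exon_length <= 0 or self.exon_length > self.end - self.start:
            raise ValueError(
                f"{self.transcript_id}: exon_length {self.exon_length} outside (0, span length]"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class LocusCatalog:
    """Partition of annotated genes into cis-NAT-eligible and excluded loci.

    ``eligible`` holds transcript-level models of genes with no overlapping
    neighbour; ``excluded`` pairs each excluded transcript with the reason
    (:data:`OPPOSITE_STRAND_OVERLAP` or :data:`SAME_STRAND_OVERLAP`).
    """

    eligible: list[GeneModel] = field(default_factory=list)
    excluded: list[tuple[GeneModel, str]] = field(default_factory=list)

    @property
    def eligible_gene_ids(self) -> set[str]:
        return {g.gene_id for g in self.eligible}

    @property
    def eligible_transcript_ids(self) -> set[str]:
        return {g.transcript_id for g in self.eligible}

    @property
    def excluded_gene_ids(self) -> set[str]:
        return {g.gene_id for g, _ in self.excluded}

    def exon_lengths(self) -> dict[str, int]:
        return {g.transcript_id: g.exon_length for g in self.eligible}

    def to_tsv(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write("gene_id\ttranscript_id\tchrom\tstart\tend\tstrand\tstatus\treason\n")
            rows = [(g, "eligible", ".") for g in self.eligible] + [
                (g, "excluded", reason) for g, reason in self.excluded
            ]
            rows.sort(key=lambda r: (r[0].chrom, r[0].start, r[0].transcript_id))
            for g, status, reason in rows:
                fh.write(
                    f"{g.gene_id}\t{g.transcript_id}\t{g.chrom}\t{g.start}\t{g.end}\t"
                    f"{g.strand}\t{status}\t{reason}\n"
                )


def parse_gff(path: str | os.PathLike) -> list[GeneModel]:
    """Parse a GFF3 annotation into one :class:`GeneModel` per transcript.

    Expects standard gene → mRNA → exon feature nesting.  ``exon_length`` is
    the sum of exon lengths; an mRNA without exon children spans its full
    length.  Raises :class:`ValueError` for a missing strand or an exon
    outside its parent's span.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    models: list[GeneModel] = []
    for mrna in db.features_of_type(("mRNA", "transcript")):
        parents = list(db.parents(mrna, featuretype="gene"))
        gene_id = parents[0].id if parents else mrna.id
        if mrna.strand not in {"+", "-"}:
            raise ValueError(f"{mrna.id}: missing or undefined strand")
        exon_length = 0
        for exon in db.children(mrna, featuretype="exon"):
            if exon.start < mrna.start or exon.end > mrna.end:
                raise ValueError(
                    f"{mrna.id}: exon {exon.start}..{exon.end} outside parent span "
                    f"{mrna.start}..{mrna.end}"
                )
            exon_length += exon.end - exon.start + 1
        if exon_length == 0:
            exon_length = mrna.end - mrna.start + 1
        models.append(
            GeneModel(
                gene_id=gene_id,
                transcript_id=mrna.id,
                chrom=mrna.seqid,
                strand=mrna.strand,
                start=mrna.start - 1,  # 1-based inclusive -> 0-based half-open
                end=mrna.end,
                exon_length=exon_length,
            )
        )
    models.sort(key=lambda g: (g.chrom, g.start, g.transcript_id))
    return models


def _gene_spans(genes: list[GeneModel]) -> dict[str, tuple[str, str, int, int]]:
    """Collapse transcripts to the union span per gene: gene_id -> (chrom, strand, start, end)."""
    spans: dict[str, tuple[str, str, int, int]] = {}
    for g in genes:
        if g.gene_id in spans:
            chrom, strand, start, end = spans[g.gene_id]
            if chrom != g.chrom or strand != g.strand:
                raise ValueError(f"{g.gene_id}: transcripts on different chromosomes or strands")
            spans[g.gene_id] = (chrom, strand, min(start, g.start), max(end, g.end))
        else:
            spans[g.gene_id] = (g.chrom, g.strand, g.start, g.end)
    return spans


def build_catalog(genes: list[GeneModel], exclude_same_strand: bool = True) -> LocusCatalog:
    """Build the catalog of single-gene loci eligible for cis-NAT calling.

    A gene whose union span intersects (≥1 bp) a gene on the opposite strand
    is excluded with reason :data:`OPPOSITE_STRAND_OVERLAP`; with
    ``exclude_same_strand`` (the default) same-strand intersections are also
    excluded, since they make sense-count attribution ambiguous.  Setting the
    flag to False restores the strict opposite-orientation-only criterion.
    Overlap is decided on full gene spans, not exons.
    """
    spans = _gene_spans(genes)
    trees: dict[str, IntervalTree] = {}
    for gid, (chrom, _strand, start, end) in spans.items():
        trees.setdefault(chrom, IntervalTree()).addi(start, end, gid)

    reasons: dict[str, str] = {}
    for gid, (chrom, strand, start, end) in spans.items():
        for hit in trees[chrom].overlap(start, end):
            other = hit.data
            if other == gid:
                continue
            other_strand = spans[other][1]
            if other_strand != strand:
                reasons[gid] = OPPOSITE_STRAND_OVERLAP
                break  # opposite-strand overlap takes precedence
            if exclude_same_strand:
                reasons.setdefault(gid, SAME_STRAND_OVERLAP)

    catalog = LocusCatalog()
    for g in sorted(genes, key=lambda g: (g.chrom, g.start, g.transcript_id)):
        reason = reasons.get(g.gene_id)
        if reason is None:
            catalog.eligible.append(g)
        else:
            catalog.excluded.append((g, reason))
    return catalog
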