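"""Co-regulation classification of loci with upregulated antisense transcripts.

Loci whose antisense transcript is called up in a contrast are partitioned by
the response of the sense transcript at the same locus into three groups:
``upregulated`` (sense also up), ``invariable`` (sense not significant in
either direction at the configured FDR) and ``downregulated`` (sense down).
Cross-condition behaviour of the antisense-up sets is summarised with Venn
region counts and shared-fraction percentages; optional GO tabulation counts
set members per user-supplied category.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "NatClassification",
    "OverlapSummary",
    "classify_nat_loci",
    "overlap_stats",
    "go_distribution",
    "round_half_up",
]

GROUP_OF_SENSE_CALL = {"up": "upregulated", "ns": "invariable", "down": "downregulated"}
GROUPS = ("upregulated", "invariable", "downregulated")


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (the reporting convention for percentages)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class NatClassification:
    """Three-group partition of the antisense-up transcript set."""

    table: pd.DataFrame  # columns: transcript_id, sense_call, group

    @property
    def group_sizes(self) -> dict[str, int]:
        counts = self.table["group"].value_counts()
        return {g: int(counts.get(g, 0)) for g in GROUPS}

    @property
    def total(self) -> int:
        return len(self.table)

    def to_tsv(self, path: str | os.PathLike) -> None:
        self.table.sort_values("transcript_id").to_csv(path, sep="\t", index=False)


def classify_nat_loci(
    antisense_calls: pd.DataFrame, sense_calls: pd.DataFrame
) -> NatClassification:
    """Classify sense partners of upregulated antisense transcripts.

    Both inputs are DiffCall-style frames with at least ``transcript_id`` and
    ``call`` columns, computed on the same contrast over the same loci.  For
    every transcript whose antisense call is 'up', the sense call maps to the
    group (up -> upregulated, ns -> invariable, down -> downregulated).  A
    transcript in the antisense-up set missing from the sense results is an
    error.
    """
    sense_by_tx = sense_calls.set_index("transcript_id")["call"]
    if sense_by_tx.index.has_duplicates:
        raise ValueError("sense_calls contains duplicate transcript_ids")
    up = antisense_calls.loc[antisense_calls["call"] == "up", "transcript_id"]
    rows = []
    for tx in sorted(up):
        if tx not in sense_by_tx.index:
            raise KeyError(f"transcript {tx} in antisense-up set but absent from sense results")
        sense_call = sense_by_tx[tx]
        rows.append((tx, sense_call, GROUP_OF_SENSE_CALL[sense_call]))
    return NatClassification(
        table=pd.DataFrame(rows, columns=["transcript_id", "sense_call", "group"])
    )


@dataclass
class OverlapSummary:
    """Venn-style decomposition of k named transcript-id sets.

    ``regions`` maps each non-empty subset of set names (a frozenset) to the
    number of elements belonging to exactly those sets; region counts
    therefore sum to the size of the union, and per-set sums reproduce each
    set's cardinality (inclusion-exclusion consistency).
    """

    sets: dict[str, set[str]]
    regions: dict[frozenset, int] = field(init=False)

    def __post_init__(self) -> None:
        names = list(self.sets)
        self.regions = {}
        for k in range(1, len(names) + 1):
            for combo in combinations(names, k):
                self.regions[frozenset(combo)] = 0
        for element in set().union(*self.sets.values()):
            membership = frozenset(n for n in names if element in self.sets[n])
            self.regions[membership] += 1

    def region(self, *names: str) -> int:
        """Elements in exactly the given sets and no others."""
        return self.regions[frozenset(names)]

    def intersection_size(self, *names: str) -> int:
        """|intersection of the given sets| (regardless of membership elsewhere)."""
        return len(set.intersection(*(self.sets[n] for n in names)))

    def shared_fraction(self, name: str, others: Iterable[str] | None = None) -> float:
        """Percentage of set ``name`` also found in the union of ``others``.

        100 * |A ∩ (B ∪ C ∪ ...)| / |A|, rounded half-up to one decimal.
        """
        if others is None:
            others = [n for n in self.sets if n != name]
        a = self.sets[name]
        if not a:
            raise ValueError(f"set {name!r} is empty; shared fraction undefined")
        union_others = set().union(*(self.sets[n] for n in others))
        return round_half_up(100.0 * len(a & union_others) / len(a), 1)

    def to_tsv(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write("region\tcount\n")
            for combo in sorted(self.regions, key=lambda c: (len(c), sorted(c))):
                fh.write(f"{'&'.join(sorted(combo))}\t{self.regions[combo]}\n")


def overlap_stats(sets: Mapping[str, Iterable[str]]) -> OverlapSummary:
    """Compute all Venn region counts for >= 2 named transcript-id sets."""
    if len(sets) < 2:
        raise ValueError("need at least two named sets")
    if any(not str(name) for name in sets):
        raise ValueError("set names must be non-empty strings")
    return OverlapSummary(sets={str(n): set(v) for n, v in sets.items()})


def go_distribution(
    transcript_ids: Iterable[str], mapping: pd.DataFrame
) -> pd.DataFrame:
    """Tabulate set members per GO category.

    ``mapping`` has columns ``transcript_id`` and ``category``; a transcript
    annotated with k categories contributes to all k.  Percentages are
    relative to the number of annotated set members; transcripts without any
    category are tallied as 'unannotated' (percentage relative to the whole
    set).  Returns a frame with columns category, count, percentage sorted by
    descending count.
    """
    ids = set(transcript_ids)
    if not ids:
        return pd.DataFrame(columns=["category", "count", "percentage"])
    sub = mapping[mapping["transcript_id"].isin(ids)]
    annotated = set(sub["transcript_id"])
    n_annotated = len(annotated)
    counts = sub.groupby("category")["transcript_id"].nunique().sort_values(ascending=False)
    rows = [
        {"category": cat, "count": int(c),
         "percentage": round_half_up(100.0 * c / n_annotated, 1)}
        for cat, c in counts.items()
    ]
    n_unannotated = len(ids - annotated)
    if n_unannotated:
        rows.append(
            {"category": "unannotated", "count": n_unannotated,
             "percentage": round_half_up(100.0 * n_unannotated / len(ids), 1)}
        )
    return pd.DataFrame(rows, columns=["category", "count", "percentage"])
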