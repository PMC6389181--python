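"""End-trimming of single reads by base quality.

The rule: low-quality bases (Phred < 15 by default) are removed from both the
5' and the 3' end of a read until a stretch of three or more consecutive
high-quality bases appears at each end.  Concretely, the trimmed read runs
from the start of the first run of ``stretch`` consecutive bases with quality
>= ``q_threshold`` through the end of the last such run; interior low-quality
bases are kept.  A read containing no qualifying run is discarded.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = ["QualityRead", "TrimReport", "trim_read", "trim_fastq"]

DEFAULT_Q = 15
DEFAULT_STRETCH = 3
DEFAULT_MIN_LENGTH = 20


@dataclass(frozen=True)
class QualityRead:
    """A read with per-base Phred qualities."""

    id: str
    sequence: str
    qualities: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(f"{self.id}: sequence and qualities differ in length")
        if any(q < 0 for q in self.qualities):
            raise ValueError(f"{self.id}: negative Phred score")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def is_empty(self) -> bool:
        return len(self.sequence) == 0


@dataclass
class TrimReport:
    """Totals from trimming one FASTQ file; reads_in == reads_out + reads_discarded."""

    reads_in: int = 0
    reads_out: int = 0
    reads_discarded: int = 0
    bases_in: int = 0
    bases_out: int = 0

    @property
    def bases_removed(self) -> int:
        return self.bases_in - self.bases_out


def _run_starts(good: np.ndarray, stretch: int) -> np.ndarray:
    """Indices i such that good[i:i+stretch] are all True."""
    if good.size < stretch:
        return np.empty(0, dtype=int)
    windows = np.lib.stride_tricks.sliding_window_view(good, stretch)
    return np.flatnonzero(windows.all(axis=1))


def trim_read(
    read: QualityRead,
    q_threshold: int = DEFAULT_Q,
    stretch: int = DEFAULT_STRETCH,
) -> QualityRead:
    """Trim both ends of ``read`` back to the outermost high-quality stretches.

    Returns the contiguous subread from the start of the first run of
    ``stretch`` consecutive bases with quality >= ``q_threshold`` through the
    end of the last such run, or an empty read if no such run exists.
    """
    if stretch < 1:
        raise ValueError(f"stretch must be >= 1, got {stretch}")
    good = np.asarray(read.qualities) >= q_threshold
    starts = _run_starts(good, stretch)
    if starts.size == 0:
        return QualityRead(read.id, "", ())
    lo = int(starts[0])
    hi = int(starts[-1]) + stretch  # end (exclusive) of the last qualifying run
    return QualityRead(read.id, read.sequence[lo:hi], read.qualities[lo:hi])


def trim_fastq(
    path_in: str | os.PathLike,
    path_out: str | os.PathLike,
    q_threshold: int = DEFAULT_Q,
    stretch: int = DEFAULT_STRETCH,
    min_length: int = DEFAULT_MIN_LENGTH,
) -> TrimReport:
    """Trim every read in a FASTQ file, dropping reads shorter than ``min_length``.

    Discarded reads contribute their full length to ``bases_removed``.
    Raises :class:`ValueError` naming the (0-based) record index of a
    malformed record.
    """
    report = TrimReport()
    with open(path_in) as fin, open(path_out, "w") as fout:
        parser = SeqIO.parse(fin, "fastq")
        index = 0
        while True:
            try:
                rec = next(parser)
            except StopIteration:
                break
            except ValueError as exc:
                raise ValueError(f"malformed FASTQ record at index {index}: {exc}") from exc
            report.reads_in += 1
            report.bases_in += len(rec)
            read = QualityRead(
                rec.id, str(rec.seq), tuple(rec.letter_annotations["phred_quality"])
            )
            trimmed = trim_read(read, q_threshold=q_threshold, stretch=stretch)
            if len(trimmed) < min_length:
                report.reads_discarded += 1
            else:
                report.reads_out += 1
                report.bases_out += len(trimmed)
                out = SeqRecord(Seq(trimmed.sequence), id=trimmed.id, description="")
                out.letter_annotations["phred_quality"] = list(trimmed.qualities)
                SeqIO.write(out, fout, "fastq")
            index += 1
    return report
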