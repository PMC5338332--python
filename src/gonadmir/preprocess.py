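"""Adapter trimming, quality filtering and read-length profiling.

Raw small-RNA reads carry the 3' ligation adapter because the biological
insert (~18-35 nt) is shorter than the instrument read.  Processing is the
classic two-step rule: remove the best-scoring 3' adapter occurrence, then
quality-trim the 3' end at Phred 20 and discard reads whose mean quality
or length falls below threshold.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .core import ReadRecord, ValidationError, as_dna

__all__ = [
    "TrimReport",
    "trim_adapter",
    "quality_filter",
    "length_histogram",
    "process_reads",
    "read_fastq",
    "write_fastq",
]


@dataclass
class TrimReport:
    """Per-library bookkeeping for the trim/filter pass."""

    n_input: int = 0
    n_adapter_trimmed: int = 0
    n_quality_discarded: int = 0
    n_too_short: int = 0
    n_kept: int = 0
    length_histogram: dict[int, int] = field(default_factory=dict)

    def validate(self) -> None:
        if self.n_kept != self.n_input - self.n_quality_discarded - self.n_too_short:
            raise ValidationError("TrimReport tallies do not conserve reads")
        if sum(self.length_histogram.values()) != self.n_kept:
            raise ValidationError("length histogram does not total kept reads")

    def to_json(self) -> str:
        d = self.__dict__.copy()
        d["length_histogram"] = {str(k): v for k, v in sorted(self.length_histogram.items())}
        return json.dumps(d, indent=2)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("metric\tvalue\n")
            for key in ("n_input", "n_adapter_trimmed", "n_quality_discarded",
                        "n_too_short", "n_kept"):
                fh.write(f"{key}\t{getattr(self, key)}\n")
            for length in sorted(self.length_histogram):
                fh.write(f"length_{length}\t{self.length_histogram[length]}\n")


def _adapter_match_start(
    seq: str, adapter: str, min_overlap: int, max_error_rate: float
) -> int | None:
    """Start of the best-scoring 3' adapter occurrence, or None.

    Candidates are full internal matches or a read-suffix/adapter-prefix
    overlap of at least ``min_overlap`` bases; a candidate qualifies when
    its mismatch fraction is <= ``max_error_rate`` (N counts as mismatch).
    Best = maximal (matches - mismatches), ties to the leftmost start, so
    the longest trim wins among equals.
    """
    la = len(adapter)
    n = len(seq)
    # Fast path: a leftmost exact full occurrence always attains the top
    # score (= adapter length), which no mismatched or shorter overlap
    # candidate can reach.
    pos = seq.find(adapter)
    if pos != -1:
        return pos
    best: tuple[int, int] | None = None  # (score, -start)
    for start in range(0, n):
        overlap = min(la, n - start)
        if overlap < la and overlap < min_overlap:
            break  # overlaps only shrink from here on
        mism = 0
        limit = int(max_error_rate * overlap)
        for x, y in zip(seq[start : start + overlap], adapter):
            if x != y:
                mism += 1
                if mism > limit:
                    break
        if mism > limit:
            continue
        score = (overlap - mism) - mism
        cand = (score, -start)
        if best is None or cand > best:
            best = cand
    if best is None:
        return None
    return -best[1]


def trim_adapter(
    read: ReadRecord,
    adapter: str,
    min_overlap: int = 3,
    max_error_rate: float = 0.1,
) -> ReadRecord:
    """Remove the 3' adapter (and everything after it) from a read.

    Returns the read unchanged when no qualifying occurrence exists.
    Sequence and qualities are truncated together.
    """
    adapter = as_dna(adapter)
    if len(adapter) < 5:
        raise ValidationError("adapter must be at least 5 nt")
    start = _adapter_match_start(read.seq, adapter, min_overlap, max_error_rate)
    if start is None:
        return read
    return ReadRecord(read.id, read.seq[:start], read.qual[:start])


def quality_filter(
    read: ReadRecord, q_threshold: int = 20, min_len: int = 16
) -> tuple[ReadRecord | None, str | None]:
    """Quality-trim the 3' end, then keep or discard the read.

    Terminal bases with quality below ``q_threshold`` are trimmed; the
    read is then discarded as ``"too_short"`` if shorter than ``min_len``
    or as ``"quality"`` if its mean quality is still below threshold.
    Returns ``(read, None)`` when kept, ``(None, reason)`` otherwise.
    """
    end = len(read)
    while end > 0 and read.qual[end - 1] < q_threshold:
        end -= 1
    if end < min_len:
        return None, "too_short"
    qual = read.qual[:end]
    if sum(qual) / end < q_threshold:
        return None, "quality"
    if end == len(read):
        return read, None
    return ReadRecord(read.id, read.seq[:end], qual), None


def length_histogram(reads: Iterable[ReadRecord]) -> dict[int, int]:
    """Exact integer histogram of read lengths (bins are nt lengths)."""
    return dict(Counter(len(r) for r in reads))


def process_reads(
    reads: Iterable[ReadRecord],
    adapter: str,
    q_threshold: int = 20,
    min_len: int = 16,
    min_overlap: int = 3,
    max_error_rate: float = 0.1,
) -> tuple[list[ReadRecord], TrimReport]:
    """Full trim + filter pass over one library; returns kept reads and report."""
    report = TrimReport()
    kept: list[ReadRecord] = []
    for read in reads:
        report.n_input += 1
        trimmed = trim_adapter(read, adapter, min_overlap, max_error_rate)
        if len(trimmed) < len(read):
            report.n_adapter_trimmed += 1
        final, reason = quality_filter(trimmed, q_threshold, min_len)
        if final is None:
            if reason == "quality":
                report.n_quality_discarded += 1
            else:
                report.n_too_short += 1
            continue
        report.n_kept += 1
        kept.append(final)
    report.length_histogram = length_histogram(kept)
    report.validate()
    return kept, report


def read_fastq(path) -> Iterator[ReadRecord]:
    """Stream a Phred+33 FASTQ file as ReadRecords (U converted to T)."""
    with open(path) as fh:
        for title, seq, qual in FastqGeneralIterator(fh):
            yield ReadRecord(
                title.split()[0],
                as_dna(seq),
                tuple(ord(c) - 33 for c in qual),
            )


def write_fastq(reads: Iterable[ReadRecord], path) -> None:
    """Write Phred+33 FASTQ."""
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.seq}\n+\n{''.join(chr(q + 33) for q in r.qual)}\n")
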