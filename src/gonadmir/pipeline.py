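"""End-to-end convenience layer: FASTQ -> counts, class fractions, isomiR calls.

Chains preprocessing, class annotation, mature-miRNA quantification and
isomiR calling for a set of libraries sharing one reference.  Each module
remains usable on its own; this layer only wires them together and keeps
the per-sample bookkeeping tidy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .annotate import ClassIndex, MatureIndex, build_count_matrix, map_to_mature
from .core import CountMatrix, ReadRecord
from .isomir import call_isomir
from .preprocess import TrimReport, process_reads, read_fastq
from .simdata import ReferenceBundle

__all__ = ["PipelineResult", "quantify_samples", "quantify_fastq_dir"]


@dataclass
class PipelineResult:
    """Everything the quantification pass produces for a set of libraries."""

    count_matrix: CountMatrix
    #: classes x samples read counts of kept reads (hierarchical assignment)
    class_counts: pd.DataFrame
    #: one row per miRNA-mapped read: sample_id, read_id, mature_id, variant_key
    isomir_calls: pd.DataFrame
    trim_reports: dict[str, TrimReport] = field(default_factory=dict)

    def class_fractions(self) -> pd.DataFrame:
        tot = self.class_counts.sum(axis=0)
        return self.class_counts / tot


def quantify_samples(
    reads_by_sample: Mapping[str, Iterable[ReadRecord]],
    bundle: ReferenceBundle,
    sample_sheet: pd.DataFrame,
    adapter: str,
    q_threshold: int = 20,
    min_len: int = 16,
    max_mismatch: int = 1,
) -> PipelineResult:
    """Trim, classify, map and call isomiRs for each library.

    Reads are assigned hierarchically to ncRNA classes; miRNA membership
    is decided by the single-mismatch mature index.  Each miRNA read
    contributes once to the count matrix (ties split equally); its isomiR
    call uses the best hit (ties broken to the lexicographically first
    mature id, deterministically).
    """
    index = MatureIndex(bundle.matures, max_mismatch=max_mismatch)
    class_index = ClassIndex(bundle.class_refs, mature_index=index)
    mature = bundle.mature_by_id
    hits_per_sample: dict[str, list] = {}
    class_rows: dict[str, dict[str, int]] = {}
    call_rows: list[dict] = []
    trim_reports: dict[str, TrimReport] = {}
    for sid, raw in reads_by_sample.items():
        kept, report = process_reads(
            raw, adapter, q_threshold=q_threshold, min_len=min_len
        )
        trim_reports[sid] = report
        tallies: dict[str, int] = {}
        hitlists = []
        for read in kept:
            label = class_index.classify(read.seq)
            tallies[label] = tallies.get(label, 0) + 1
            if label != "miRNA":
                continue
            hits = map_to_mature(read, index)
            hitlists.append(hits)
            best = hits[0]
            call = call_isomir(best, mature[best.mature_id])
            call_rows.append(
                {
                    "sample_id": sid,
                    "read_id": read.id,
                    "mature_id": call.mature_id,
                    "variant_key": call.variant_key,
                }
            )
        hits_per_sample[sid] = hitlists
        class_rows[sid] = tallies
    count_matrix = build_count_matrix(
        hits_per_sample, sample_sheet, feature_ids=bundle.feature_ids
    )
    class_counts = pd.DataFrame(class_rows).fillna(0).astype(int)
    class_counts = class_counts.reindex(
        sorted(class_counts.index), columns=list(reads_by_sample)
    ).fillna(0).astype(int)
    calls = pd.DataFrame(
        call_rows, columns=["sample_id", "read_id", "mature_id", "variant_key"]
    )
    return PipelineResult(count_matrix, class_counts, calls, trim_reports)


def quantify_fastq_dir(
    fastq_dir,
    bundle: ReferenceBundle,
    sample_sheet: pd.DataFrame,
    adapter: str,
    **kwargs,
) -> PipelineResult:
    """Run :func:`quantify_samples` over ``<sample_id>.fastq`` files."""
    fastq_dir = Path(fastq_dir)
    reads = {
        sid: read_fastq(fastq_dir / f"{sid}.fastq")
        for sid in sample_sheet.index
        if (fastq_dir / f"{sid}.fastq").exists()
    }
    return quantify_samples(reads, bundle, sample_sheet, adapter, **kwargs)
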