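"""Read annotation: ncRNA class assignment and mature-miRNA mapping.

Mapping follows the known-miRNA quantification convention: a read is
assigned to a mature miRNA when it aligns to the precursor-anchored
mature window with at most one mismatch, allowing bounded 5'/3' end
shifts and a short untemplated 3' tail.  The alignment is anchored in
precursor coordinates, so every decision about templated 3' additions
and 5' extensions is made by direct comparison to the precursor (which
carries genomic flanks).

For a read ``r`` and a candidate 5' offset ``o5`` the decomposition is
fully determined: bases opposite precursor positions before the
canonical 3' end form the aligned core (<= ``max_mismatch`` mismatches
allowed), bases at or beyond the canonical end are 3' additions, each
templated iff it equals the precursor base at that position.  The only
search dimension is ``o5``; the best offset per mature minimizes
(edit count, untemplated additions, |o5|) where the edit count is
``mismatches + |o5| + |o3|``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .core import CountMatrix, MatureMiRNARecord, ReadRecord, ValidationError

__all__ = [
    "AlignmentHit",
    "MatureIndex",
    "ClassIndex",
    "CLASS_PRIORITY",
    "map_to_mature",
    "classify_read",
    "build_count_matrix",
]

#: Hierarchical assignment order when a read matches several references.
CLASS_PRIORITY: tuple[str, ...] = ("miRNA", "tRNA", "rRNA", "piRNA", "lincRNA")


@dataclass(frozen=True)
class AlignmentHit:
    """One read-to-mature alignment within the isomiR search bounds.

    ``offset_5p`` > 0 means the read starts downstream of the canonical
    5' end (truncation); < 0 is a templated 5' extension into the
    precursor.  ``offset_3p`` > 0 means the read extends past the
    canonical 3' end.  ``tail_seq`` holds the unaligned 3' tail: the
    added bases from the first untemplated one onward (empty when every
    addition matches the precursor).
    """

    read_id: str
    mature_id: str
    n_mismatches: int
    offset_5p: int
    offset_3p: int
    tail_seq: str
    read_seq: str

    @property
    def end_shift(self) -> int:
        return abs(self.offset_5p) + abs(self.offset_3p)


class MatureIndex:
    """Mature-miRNA reference index with memoised read lookup.

    Small-RNA libraries are dominated by duplicate sequences, so results
    are cached per distinct read sequence.
    """

    def __init__(
        self,
        matures: Sequence[MatureMiRNARecord],
        max_mismatch: int = 1,
        max_offset_5p: int = 3,
        offset_3p_bounds: tuple[int, int] = (-3, 4),
        min_read_len: int = 16,
    ):
        ids = [m.mature_id for m in matures]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate mature ids in index")
        self.matures: dict[str, MatureMiRNARecord] = {m.mature_id: m for m in matures}
        self.max_mismatch = max_mismatch
        self.max_offset_5p = max_offset_5p
        self.offset_3p_bounds = offset_3p_bounds
        self.min_read_len = min_read_len
        self._cache: dict[str, tuple[tuple[str, int, int, int, str], ...]] = {}

    @property
    def feature_ids(self) -> list[str]:
        return sorted(self.matures)

    def _best_offset(
        self, seq: str, ref: MatureMiRNARecord
    ) -> tuple[int, int, int, str] | None:
        """Best (n_mismatch, o5, o3, tail) for one mature, or None."""
        P = ref.precursor_seq
        L = len(ref)
        lo3, hi3 = self.offset_3p_bounds
        best_rank: tuple[int, int, int, int] | None = None
        best: tuple[int, int, int, str] | None = None
        for o5 in range(-self.max_offset_5p, self.max_offset_5p + 1):
            p0 = ref.start + o5
            if p0 < 0 or p0 + len(seq) > len(P):
                continue
            o3 = o5 + len(seq) - L
            if not (lo3 <= o3 <= hi3):
                continue
            core_len = len(seq) - max(o3, 0)
            if core_len < 1:
                continue
            mism = 0
            for i in range(core_len):
                if seq[i] != P[p0 + i]:
                    mism += 1
                    if mism > self.max_mismatch:
                        break
            if mism > self.max_mismatch:
                continue
            n_untemplated = 0
            first_untemplated = -1
            for j in range(core_len, len(seq)):
                if seq[j] != P[p0 + j]:
                    n_untemplated += 1
                    if first_untemplated < 0:
                        first_untemplated = j
            edits = mism + abs(o5) + abs(o3)
            rank = (edits, n_untemplated, abs(o5), o5)
            if best_rank is None or rank < best_rank:
                tail = seq[first_untemplated:] if first_untemplated >= 0 else ""
                best_rank = rank
                best = (mism, o5, o3, tail)
        return best

    def map(self, seq: str) -> tuple[tuple[str, int, int, int, str], ...]:
        """All matures hit by ``seq``: tuples (mature_id, mism, o5, o3, tail).

        Sorted by (mismatches, |o5| + |o3|, mature_id); empty when unmapped
        or when the read is shorter than ``min_read_len``.
        """
        if len(seq) < self.min_read_len:
            return ()
        cached = self._cache.get(seq)
        if cached is not None:
            return cached
        hits = []
        for mid in self.feature_ids:
            found = self._best_offset(seq, self.matures[mid])
            if found is not None:
                mism, o5, o3, tail = found
                hits.append((mid, mism, o5, o3, tail))
        hits.sort(key=lambda h: (h[1], abs(h[2]) + abs(h[3]), h[0]))
        out = tuple(hits)
        self._cache[seq] = out
        return out


def map_to_mature(
    read: ReadRecord | str, index: MatureIndex
) -> list[AlignmentHit]:
    """Map one read against the mature index; empty list when unmapped."""
    if isinstance(read, ReadRecord):
        read_id, seq = read.id, read.seq
    else:
        read_id, seq = "", read
    return [
        AlignmentHit(read_id, mid, mism, o5, o3, tail, seq)
        for mid, mism, o5, o3, tail in index.map(seq)
    ]


class ClassIndex:
    """ncRNA class references with exact-substring / 1-mismatch lookup.

    A read matches a class when it is an exact substring of any class
    reference sequence, or a full-length match with at most one mismatch
    against a same-length reference.  Classes are tried in the fixed
    priority order miRNA > tRNA > rRNA > piRNA > lincRNA; unmatched
    reads fall through to ``"other"``.  When a :class:`MatureIndex` is
    supplied the miRNA decision is delegated to it, so isomiR-bearing
    reads (end shifts, tails, one substitution) stay in the miRNA class
    with the same tolerance the quantification uses.
    """

    def __init__(
        self,
        class_refs: Mapping[str, Iterable[str]],
        mature_index: MatureIndex | None = None,
    ):
        self.mature_index = mature_index
        self._blobs: dict[str, str] = {}
        self._by_length: dict[str, dict[int, list[str]]] = {}
        for label, refs in class_refs.items():
            seqs = sorted(set(refs))
            self._blobs[label] = "#" + "#".join(seqs) + "#"
            by_len: dict[int, list[str]] = {}
            for s in seqs:
                by_len.setdefault(len(s), []).append(s)
            self._by_length[label] = by_len
        self._cache: dict[str, str] = {}

    def _matches_class(self, seq: str, label: str) -> bool:
        blob = self._blobs.get(label)
        if blob is not None and seq in blob:
            return True
        for ref in self._by_length.get(label, {}).get(len(seq), ()):
            mism = 0
            for x, y in zip(seq, ref):
                if x != y:
                    mism += 1
                    if mism > 1:
                        break
            if mism <= 1:
                return True
        return False

    def classify(self, seq: str) -> str:
        cached = self._cache.get(seq)
        if cached is not None:
            return cached
        label_out = "other"
        for label in CLASS_PRIORITY:
            if label == "miRNA" and self.mature_index is not None:
                if self.mature_index.map(seq):
                    label_out = "miRNA"
                    break
                continue
            if self._matches_class(seq, label):
                label_out = label
                break
        self._cache[seq] = label_out
        return label_out


def classify_read(
    read: ReadRecord | str,
    class_refs: Mapping[str, Iterable[str]] | ClassIndex,
    mature_index: MatureIndex | None = None,
) -> str:
    """Assign one read to an ncRNA class (see :class:`ClassIndex`)."""
    seq = read.seq if isinstance(read, ReadRecord) else read
    if not isinstance(class_refs, ClassIndex):
        class_refs = ClassIndex(class_refs, mature_index)
    return class_refs.classify(seq)


def build_count_matrix(
    hits_per_sample: Mapping[str, Iterable[Sequence[AlignmentHit]]],
    sample_sheet: pd.DataFrame,
    feature_ids: Sequence[str] | None = None,
) -> CountMatrix:
    """Aggregate per-read alignment hits into a features x samples matrix.

    Each read contributes exactly once: fully to its unique best hit, or
    split equally among hits tied at the best (mismatches, end-shift)
    rank, so column sums equal the number of miRNA-mapped reads.
    """
    unknown = set(hits_per_sample) - set(sample_sheet.index)
    if unknown:
        raise ValidationError(f"sample ids not in sample sheet: {sorted(unknown)}")
    features = list(feature_ids) if feature_ids is not None else None
    seen: dict[str, dict[str, float]] = {}
    for sample_id, read_hitlists in hits_per_sample.items():
        col = seen.setdefault(sample_id, {})
        for hits in read_hitlists:
            if not hits:
                continue
            best = min((h.n_mismatches, h.end_shift) for h in hits)
            tied = [h for h in hits if (h.n_mismatches, h.end_shift) == best]
            w = 1.0 / len(tied)
            for h in tied:
                col[h.mature_id] = col.get(h.mature_id, 0.0) + w
    if features is None:
        features = sorted({f for col in seen.values() for f in col})
    counts = pd.DataFrame(
        {sid: [seen.get(sid, {}).get(f, 0.0) for f in features]
         for sid in hits_per_sample},
        index=features,
    )
    return CountMatrix(counts, sample_sheet)
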