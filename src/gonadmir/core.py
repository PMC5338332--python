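"""Core containers shared across the pipeline.

The internal sequence alphabet is DNA (``A/C/G/T``, plus ``N`` in reads);
RNA input (``U``) is converted at ingest and re-emitted as ``U`` only in
RNA-facing reports such as isomiR variant keys.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

DNA = frozenset("ACGT")
READ_ALPHABET = frozenset("ACGTN")


class ValidationError(ValueError):
    """Raised when an input violates a documented contract."""


def as_dna(seq: str) -> str:
    """Uppercase and convert RNA ``U`` to the internal DNA alphabet."""
    return seq.upper().replace("U", "T")


def as_rna(seq: str) -> str:
    """Convert an internal DNA string back to the RNA alphabet for reports."""
    return seq.upper().replace("T", "U")


@dataclass(frozen=True)
class ReadRecord:
    """One sequencing read: identifier, bases and per-base Phred scores."""

    id: str
    seq: str
    qual: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.qual):
            raise ValidationError(
                f"read {self.id!r}: sequence length {len(self.seq)} != "
                f"quality length {len(self.qual)}"
            )
        if any(q < 0 or q > 60 for q in self.qual):
            raise ValidationError(f"read {self.id!r}: Phred score outside [0, 60]")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class MatureMiRNARecord:
    """A mature miRNA anchored within its precursor hairpin.

    The precursor sequence carries genomic flanks on both sides of the
    hairpin, so every templated-addition and 5'-extension decision can be
    made by direct lookup in ``precursor_seq``.
    """

    mature_id: str
    precursor_id: str
    arm: str  # "5p" or "3p"
    mature_seq: str
    start: int  # 0-based offset of the mature 5' end within precursor_seq
    end: int  # exclusive end
    precursor_seq: str

    def __post_init__(self) -> None:
        if self.arm not in ("5p", "3p"):
            raise ValidationError(f"{self.mature_id}: arm must be 5p or 3p")
        if not (18 <= len(self.mature_seq) <= 26):
            raise ValidationError(
                f"{self.mature_id}: mature length {len(self.mature_seq)} outside 18..26"
            )
        if self.precursor_seq[self.start : self.end] != self.mature_seq:
            raise ValidationError(
                f"{self.mature_id}: mature_seq does not match precursor window"
            )
        if set(self.precursor_seq) - DNA:
            raise ValidationError(f"{self.precursor_id}: non-ACGT characters")

    def __len__(self) -> int:
        return len(self.mature_seq)


class CountMatrix:
    """Integer (or tie-split fractional) read counts, features x samples.

    Wraps a pandas DataFrame plus a sample sheet indexed by sample id with
    at least ``stage_wpf``, ``tissue`` and ``replicate`` columns.  The
    ``group`` of a sample is ``"{tissue}_{stage_wpf}"``, the unit at which
    replicate pooling and contrasts operate.
    """

    def __init__(self, counts: pd.DataFrame, samples: pd.DataFrame):
        counts = counts.astype(float)
        if (counts.values < 0).any():
            raise ValidationError("counts must be non-negative")
        missing = set(counts.columns) - set(samples.index)
        if missing:
            raise ValidationError(f"samples missing from sample sheet: {sorted(missing)}")
        self.counts = counts
        self.samples = samples.loc[list(counts.columns)].copy()
        if "group" not in self.samples.columns:
            self.samples["group"] = sample_groups(self.samples)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def group_of(self, sample_id: str) -> str:
        return str(self.samples.loc[sample_id, "group"])

    def groups(self) -> dict[str, list[str]]:
        """Map group label -> ordered list of member sample ids."""
        out: dict[str, list[str]] = {}
        for sid in self.sample_ids:
            out.setdefault(self.group_of(sid), []).append(sid)
        return out

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"CountMatrix({self.counts.shape[0]} features x "
            f"{self.counts.shape[1]} samples)"
        )


def sample_groups(samples: pd.DataFrame) -> pd.Series:
    """Group label per sample: ``tissue_stage`` (e.g. ``testis_24``)."""
    return samples.apply(
        lambda r: f"{r['tissue']}_{int(r['stage_wpf'])}", axis=1
    ).astype(str)


def read_sample_sheet(path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "stage_wpf", "tissue", "replicate"}
    missing = required - set(sheet.columns)
    if missing:
        raise ValidationError(f"sample sheet missing columns: {sorted(missing)}")
    sheet = sheet.set_index("sample_id")
    sheet["group"] = sample_groups(sheet)
    return sheet


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    sheet.reset_index().rename(columns={"index": "sample_id"}).to_csv(
        path, sep="\t", index=False
    )


def geometric_mean(values: np.ndarray) -> float:
    """Geometric mean of strictly positive values."""
    return float(np.exp(np.mean(np.log(values))))


def hamming(a: str, b: str, limit: int | None = None) -> int:
    """Mismatch count between equal-length strings, early-exiting past limit."""
    if len(a) != len(b):
        raise ValidationError("hamming requires equal-length strings")
    n = 0
    for x, y in zip(a, b):
        if x != y:
            n += 1
            if limit is not None and n > limit:
                return n
    return n
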