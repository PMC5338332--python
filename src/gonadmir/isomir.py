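"""isomiR classification and per-group variant composition.

Every mature-mapped read is decomposed, relative to its precursor-anchored
canonical window, into: a signed 5' offset (truncation or templated
extension), a signed 3' offset (trimming or additions), per-base template
status for each 3' added base, and internal/terminal substitutions within
the aligned core.  A 3' added base is *templated* iff it equals the
precursor base at the corresponding extended position — decidable from the
precursor alone, which carries genomic flanks.

Variant keys are a canonical text grammar (RNA alphabet), segments joined
by ``|`` in fixed order::

    canonical                 unmodified read
    5p+2 / 5p-1               5' truncation by 2 / templated 5' extension by 1
    3p-2                      3' trimming by 2
    3p+AU*                    3' additions, '*' marks an untemplated base
    s12:U>G  /  s22:U>G!      substitution at read position 12 (1-based);
                              '!' flags the 3'-terminal aligned base

``generate_variant_read`` inverts the grammar, so calling a generated read
returns its key (round-trip identity inside the search bounds).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .annotate import AlignmentHit
from .core import MatureMiRNARecord, ValidationError, as_dna, as_rna

__all__ = [
    "IsomiRCall",
    "IsomiRTable",
    "CANONICAL",
    "call_isomir",
    "variant_key",
    "parse_variant_key",
    "generate_variant_read",
    "summarize_isomirs",
    "substitution_dynamics",
]

CANONICAL = "canonical"

_SUB_RE = re.compile(r"^s(\d+):([ACGU])>([ACGU])(!?)$")
_ADD_RE = re.compile(r"^3p\+((?:[ACGU]\*?)+)$")
_OFF_RE = re.compile(r"^(5p|3p)([+-]\d+)$")


@dataclass(frozen=True)
class IsomiRCall:
    """One read's deviation from the canonical mature sequence."""

    mature_id: str
    variant_key: str
    offset_5p: int
    offset_3p: int
    #: (base, templated) per 3' added base, 5'->3' (DNA alphabet)
    additions: tuple[tuple[str, bool], ...]
    #: (0-based read position, canonical base, observed base), DNA alphabet
    substitutions: tuple[tuple[int, str, str], ...]
    terminal_3p_substitution: bool

    @property
    def is_canonical(self) -> bool:
        return self.variant_key == CANONICAL

    @property
    def has_untemplated_addition(self) -> bool:
        return any(not t for _, t in self.additions)


def variant_key(
    offset_5p: int,
    offset_3p: int,
    additions: Sequence[tuple[str, bool]],
    substitutions: Sequence[tuple[int, str, str]],
    terminal: bool,
) -> str:
    """Render call components as the canonical key string."""
    parts: list[str] = []
    if offset_5p:
        parts.append(f"5p{offset_5p:+d}")
    if offset_3p < 0:
        parts.append(f"3p{offset_3p:+d}")
    if additions:
        body = "".join(as_rna(b) + ("" if t else "*") for b, t in additions)
        parts.append(f"3p+{body}")
    for i, (pos, canon, obs) in enumerate(substitutions):
        mark = "!" if terminal and i == len(substitutions) - 1 else ""
        parts.append(f"s{pos + 1}:{as_rna(canon)}>{as_rna(obs)}{mark}")
    return "|".join(parts) if parts else CANONICAL


def call_isomir(hit: AlignmentHit, ref: MatureMiRNARecord) -> IsomiRCall:
    """Classify one aligned read against its mature reference."""
    if hit.mature_id != ref.mature_id:
        raise ValidationError(
            f"hit refers to {hit.mature_id}, reference is {ref.mature_id}"
        )
    seq = hit.read_seq
    o5 = hit.offset_5p
    p0 = ref.start + o5
    if p0 < 0 or p0 + len(seq) > len(ref.precursor_seq):
        raise ValidationError("alignment outside precursor bounds")
    o3 = o5 + len(seq) - len(ref)
    if o3 != hit.offset_3p:
        raise ValidationError("hit offsets inconsistent with read length")
    core_len = len(seq) - max(o3, 0)
    P = ref.precursor_seq
    substitutions = tuple(
        (i, P[p0 + i], seq[i]) for i in range(core_len) if seq[i] != P[p0 + i]
    )
    additions = tuple(
        (seq[i], seq[i] == P[p0 + i]) for i in range(core_len, len(seq))
    )
    terminal = bool(
        substitutions
        and not additions
        and substitutions[-1][0] == len(seq) - 1
    )
    key = variant_key(o5, o3, additions, substitutions, terminal)
    return IsomiRCall(
        mature_id=ref.mature_id,
        variant_key=key,
        offset_5p=o5,
        offset_3p=o3,
        additions=additions,
        substitutions=substitutions,
        terminal_3p_substitution=terminal,
    )


def parse_variant_key(key: str) -> dict:
    """Parse a key into components (DNA alphabet internally).

    Returns dict with ``offset_5p``, ``trim_3p`` (>= 0), ``additions``
    (list of (base, templated)), ``substitutions`` (list of
    (0-based pos, canonical, observed, terminal_flag)).
    """
    out = {"offset_5p": 0, "trim_3p": 0, "additions": [], "substitutions": []}
    if key == CANONICAL:
        return out
    for part in key.split("|"):
        m = _OFF_RE.match(part)
        if m:
            which, val = m.group(1), int(m.group(2))
            if which == "5p":
                out["offset_5p"] = val
            else:
                if val >= 0:
                    raise ValidationError(f"bad 3' offset segment {part!r}")
                out["trim_3p"] = -val
            continue
        m = _ADD_RE.match(part)
        if m:
            body = m.group(1)
            adds = []
            i = 0
            while i < len(body):
                base = as_dna(body[i])
                templated = True
                if i + 1 < len(body) and body[i + 1] == "*":
                    templated = False
                    i += 1
                adds.append((base, templated))
                i += 1
            out["additions"] = adds
            continue
        m = _SUB_RE.match(part)
        if m:
            if int(m.group(1)) < 1:
                raise ValidationError(f"substitution position must be >= 1: {part!r}")
            out["substitutions"].append(
                (int(m.group(1)) - 1, as_dna(m.group(2)), as_dna(m.group(3)),
                 m.group(4) == "!")
            )
            continue
        raise ValidationError(f"unparseable variant-key segment {part!r}")
    if out["trim_3p"] and out["additions"]:
        raise ValidationError("a key cannot both trim and extend the 3' end")
    return out


def generate_variant_read(ref: MatureMiRNARecord, key: str) -> str:
    """Build the read sequence a variant key describes (DNA alphabet).

    Raises :class:`ValidationError` when the key is not realizable on this
    precursor (e.g. a templated addition whose base does not match the
    template, or an untemplated one whose base does).
    """
    parts = parse_variant_key(key)
    o5, trim = parts["offset_5p"], parts["trim_3p"]
    p0 = ref.start + o5
    core_end = ref.end - trim
    if p0 < 0 or p0 >= core_end:
        raise ValidationError(f"key {key!r} leaves no aligned core")
    read = list(ref.precursor_seq[p0:core_end])
    core_len = len(read)
    for pos, canon, obs, terminal in parts["substitutions"]:
        if pos < 0 or pos >= core_len:
            raise ValidationError(f"substitution position {pos + 1} outside core")
        if read[pos] != canon:
            raise ValidationError(
                f"key {key!r}: canonical base at position {pos + 1} is "
                f"{as_rna(read[pos])}, not {as_rna(canon)}"
            )
        if obs == canon:
            raise ValidationError(f"key {key!r}: substitution to the same base")
        if terminal and (pos != core_len - 1 or parts["additions"]):
            raise ValidationError(f"key {key!r}: '!' on a non-terminal position")
        read[pos] = obs
    for j, (base, templated) in enumerate(parts["additions"]):
        tpos = core_end + j
        if tpos >= len(ref.precursor_seq):
            raise ValidationError("addition runs past the precursor flank")
        template = ref.precursor_seq[tpos]
        if templated and base != template:
            raise ValidationError(
                f"key {key!r}: templated addition {as_rna(base)} but template "
                f"base is {as_rna(template)}"
            )
        if not templated and base == template:
            raise ValidationError(
                f"key {key!r}: untemplated addition {as_rna(base)} equals the "
                "template base"
            )
        read.append(base)
    return "".join(read)


@dataclass
class IsomiRTable:
    """Variant composition per (group, mature); replicate-pooled counts.

    ``full`` has columns group, mature_id, variant_key, count, fraction;
    fractions sum to 1 over the variant keys of each (group, mature).
    """

    full: pd.DataFrame
    min_fraction: float = 0.05

    @property
    def filtered(self) -> pd.DataFrame:
        """Reporting view: rows at or above ``min_fraction``."""
        return self.full[self.full["fraction"] >= self.min_fraction].reset_index(
            drop=True
        )

    def validate(self) -> None:
        sums = self.full.groupby(["group", "mature_id"])["fraction"].sum()
        if not ((sums - 1.0).abs() < 1e-9).all():
            raise ValidationError("isomiR fractions do not sum to 1 per group/mature")


def summarize_isomirs(
    calls: pd.DataFrame | Iterable[tuple[str, IsomiRCall]],
    sample_to_group: Mapping[str, str],
    min_fraction: float = 0.05,
) -> IsomiRTable:
    """Pool per-read calls across replicates within groups.

    ``calls`` is either an iterable of ``(sample_id, IsomiRCall)`` or a
    DataFrame with columns sample_id, mature_id, variant_key and an
    optional ``count`` column (default 1 per row).
    """
    if not isinstance(calls, pd.DataFrame):
        rows = [
            {"sample_id": sid, "mature_id": c.mature_id, "variant_key": c.variant_key}
            for sid, c in calls
        ]
        calls = pd.DataFrame(rows, columns=["sample_id", "mature_id", "variant_key"])
    df = calls.copy()
    if "count" not in df.columns:
        df["count"] = 1.0
    unknown = set(df["sample_id"]) - set(sample_to_group)
    if unknown:
        raise ValidationError(f"samples without a group: {sorted(unknown)}")
    df["group"] = df["sample_id"].map(sample_to_group)
    pooled = (
        df.groupby(["group", "mature_id", "variant_key"], as_index=False)["count"]
        .sum()
    )
    totals = pooled.groupby(["group", "mature_id"])["count"].transform("sum")
    pooled["fraction"] = pooled["count"] / totals
    pooled = pooled.sort_values(
        ["group", "mature_id", "fraction", "variant_key"],
        ascending=[True, True, False, True],
    ).reset_index(drop=True)
    table = IsomiRTable(pooled, min_fraction)
    table.validate()
    return table


def substitution_dynamics(
    table: IsomiRTable,
    from_base: str,
    to_base: str,
    mature_ids: Sequence[str] | None = None,
    terminal_only: bool = True,
) -> pd.DataFrame:
    """Per-group fraction of reads carrying a 3' (from -> to) substitution.

    The fraction is (reads of the queried miRNAs carrying the
    substitution) / (all reads of the queried miRNAs) within each group.
    By default only substitutions at the 3'-terminal aligned base count,
    matching the 3'-end substitution taxonomy.
    """
    from_base, to_base = from_base.upper(), to_base.upper()
    for b in (from_base, to_base):
        if b not in set("ACGU"):
            raise ValidationError(f"unknown base symbol {b!r} (use A/C/G/U)")
    if table.full.groupby("group").ngroups < 1:
        raise ValidationError("empty isomiR table")

    def carries(key: str) -> bool:
        if key == CANONICAL:
            return False
        for pos, canon, obs, terminal in parse_variant_key(key)["substitutions"]:
            if terminal_only and not terminal:
                continue
            if as_rna(canon) == from_base and as_rna(obs) == to_base:
                return True
        return False

    df = table.full
    if mature_ids is not None:
        df = df[df["mature_id"].isin(set(mature_ids))]
    out = []
    for group, sub in df.groupby("group"):
        total = sub["count"].sum()
        hit = sub.loc[sub["variant_key"].map(carries), "count"].sum()
        out.append({"group": group, "fraction": hit / total if total else 0.0})
    return pd.DataFrame(out, columns=["group", "fraction"])
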