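"""Synthetic small-RNA study generator.

Emulates the statistical structure of a developmental gonad small-RNA
experiment: libraries dominated by 26-31 nt piRNA-length reads with a
~22 nt miRNA peak, 3'-adapter read-through at a fixed instrument read
length, negative-binomial miRNA counts across stage x tissue groups with
five biological replicates (single pooled libraries where the design has
no replication), planted group fold changes, and planted isomiR variant
proportions.  Everything is seeded; ground truth sufficient to score
every downstream recovery test is returned alongside the data.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import (
    CountMatrix,
    MatureMiRNARecord,
    ReadRecord,
    ValidationError,
    sample_groups,
)
from .isomir import CANONICAL, generate_variant_read

__all__ = [
    "SimulationConfig",
    "ReferenceBundle",
    "SimulationTruth",
    "build_reference",
    "simulate_counts",
    "simulate_reads",
    "simulate_study",
    "make_sample_sheet",
    "study_design",
    "default_config",
    "abundance_profile",
    "write_reference",
    "load_reference",
]

#: Illumina TruSeq small-RNA 3' adapter.
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"

#: Default per-class read proportions (piRNA-dominated gonad library).
DEFAULT_CLASS_MIX = {
    "piRNA": 0.55,
    "miRNA": 0.25,
    "tRNA": 0.08,
    "rRNA": 0.04,
    "lincRNA": 0.06,
    "other": 0.02,
}

#: Class-typical fragment length ranges (inclusive), nt.
CLASS_LENGTHS = {
    "piRNA": (26, 31),
    "tRNA": (30, 36),
    "rRNA": (34, 45),
    "lincRNA": (22, 40),
    "other": (18, 40),
}

_BASES = np.array(list("ACGT"))


def _child_rng(seed: int, *tags: int | str) -> np.random.Generator:
    """Deterministic child stream; string tags are stably hashed (CRC32)."""
    words = [int(seed) & 0x7FFFFFFF]
    for t in tags:
        words.append(zlib.crc32(str(t).encode()) & 0x7FFFFFFF)
    return np.random.default_rng(words)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults are the study conditions."""

    n_mirna: int = 50
    class_mix: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_MIX)
    )
    #: per-feature NB mean at baseline (feature id -> mean miRNA-mapped reads)
    nb_mean: dict[str, float] = field(default_factory=dict)
    #: per-feature NB dispersion (scalar applied to all when a float)
    nb_dispersion: float | Mapping[str, float] = 0.05
    #: feature id -> {group -> log2 fold change vs baseline mean}
    planted_lfc: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    #: mature id -> {variant key -> proportion}; remainder is canonical
    isomir_profile: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    adapter: str = DEFAULT_ADAPTER
    read_length: int = 50
    #: per-position Phred mean (scalar broadcast over the read length)
    quality_mean: float | Sequence[float] = 35.0
    quality_sd: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mirna < 1:
            raise ValidationError("n_mirna must be >= 1")
        total = sum(self.class_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"class_mix sums to {total}, not 1")
        for mid, prof in self.isomir_profile.items():
            s = sum(prof.values())
            if s > 1 + 1e-9 or any(p < 0 for p in prof.values()):
                raise ValidationError(
                    f"isomir_profile for {mid} must be non-negative and sum to <= 1"
                )
        disp = self.nb_dispersion
        if isinstance(disp, (int, float)):
            if disp <= 0:
                raise ValidationError("nb_dispersion must be > 0")
        elif any(a <= 0 for a in disp.values()):
            raise ValidationError("nb_dispersion must be > 0")

    def dispersion_of(self, feature: str) -> float:
        if isinstance(self.nb_dispersion, (int, float)):
            return float(self.nb_dispersion)
        return float(self.nb_dispersion[feature])

    def quality_means(self) -> np.ndarray:
        if np.isscalar(self.quality_mean):
            return np.full(self.read_length, float(self.quality_mean))
        arr = np.asarray(self.quality_mean, dtype=float)
        if len(arr) != self.read_length:
            raise ValidationError("quality_mean length must equal read_length")
        return arr


@dataclass
class ReferenceBundle:
    """Precursors (with flanks), mature annotations, class reference sets."""

    precursors: list[tuple[str, str]]
    matures: list[MatureMiRNARecord]
    class_refs: dict[str, list[str]]

    def __post_init__(self) -> None:
        ids = [m.mature_id for m in self.matures]
        if len(set(ids)) != len(ids):
            raise ValidationError("mature ids are not unique")
        prec = dict(self.precursors)
        for m in self.matures:
            if m.precursor_id not in prec:
                raise ValidationError(f"{m.mature_id}: unknown precursor")
            if prec[m.precursor_id][m.start : m.end] != m.mature_seq:
                raise ValidationError(f"{m.mature_id}: offset mismatch in precursor")

    @property
    def mature_by_id(self) -> dict[str, MatureMiRNARecord]:
        return {m.mature_id: m for m in self.matures}

    @property
    def feature_ids(self) -> list[str]:
        return sorted(m.mature_id for m in self.matures)


@dataclass
class SimulationTruth:
    """Planted ground truth, sufficient to score every recovery test."""

    #: expected (mean) miRNA-mapped reads, features x samples
    expected_counts: pd.DataFrame
    #: feature -> {group -> planted log2 fold change}
    planted_lfc: dict[str, dict[str, float]]
    #: mature -> {variant key -> planted proportion (canonical included)}
    isomir_proportions: dict[str, dict[str, float]]
    #: planted reads per class, classes x samples
    class_read_counts: pd.DataFrame
    #: per-read provenance, sample -> DataFrame(read_id, class, feature,
    #: variant_key, bio_length); filled by simulate_reads
    read_details: dict[str, pd.DataFrame] = field(default_factory=dict)
    seed: int = 0

    def class_fractions(self) -> pd.DataFrame:
        tot = self.class_read_counts.sum(axis=0)
        return self.class_read_counts / tot

    def to_dir(self, outdir, include_read_details: bool = False) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.expected_counts.rename_axis("feature").to_csv(
            outdir / "truth_expected_counts.tsv", sep="\t"
        )
        self.class_read_counts.rename_axis("class").to_csv(
            outdir / "truth_class_counts.tsv", sep="\t"
        )
        rows = [
            {"feature": f, "group": g, "log2fc": v}
            for f, d in self.planted_lfc.items()
            for g, v in d.items()
        ]
        pd.DataFrame(rows, columns=["feature", "group", "log2fc"]).to_csv(
            outdir / "truth_planted_lfc.tsv", sep="\t", index=False
        )
        rows = [
            {"mature_id": m, "variant_key": k, "proportion": p}
            for m, d in self.isomir_proportions.items()
            for k, p in d.items()
        ]
        pd.DataFrame(
            rows, columns=["mature_id", "variant_key", "proportion"]
        ).to_csv(outdir / "truth_isomir_proportions.tsv", sep="\t", index=False)
        if include_read_details:
            for sid, df in self.read_details.items():
                df.to_csv(outdir / f"truth_reads_{sid}.tsv", sep="\t", index=False)


def build_reference(config: SimulationConfig) -> ReferenceBundle:
    """Seeded reference: hairpin precursors with >= 10 nt flanks, one
    mature (20-24 nt) per precursor, and per-class background pools."""
    rng = _child_rng(config.seed, "reference")
    precursors: list[tuple[str, str]] = []
    matures: list[MatureMiRNARecord] = []
    seen: set[str] = set()
    flank = 12
    for i in range(config.n_mirna):
        while True:
            mlen = int(rng.integers(20, 25))
            left = int(rng.integers(5, 16))
            right = int(rng.integers(5, 16))
            seq = _random_seq(rng, flank + left + mlen + right + flank)
            start = flank + left
            mature_seq = seq[start : start + mlen]
            if mature_seq not in seen:
                seen.add(mature_seq)
                break
        arm = "5p" if i % 2 == 0 else "3p"
        pid = f"dre-mir-sim{i + 1}"
        mid = f"dre-miR-sim{i + 1}-{arm}"
        precursors.append((pid, seq))
        matures.append(
            MatureMiRNARecord(mid, pid, arm, mature_seq, start, start + mlen, seq)
        )
    pool_sizes = {"piRNA": 100, "tRNA": 60, "rRNA": 40, "lincRNA": 80}
    class_refs: dict[str, list[str]] = {"miRNA": [m.mature_seq for m in matures]}
    for label, n in pool_sizes.items():
        lo, hi = CLASS_LENGTHS[label]
        pool = set()
        while len(pool) < n:
            pool.add(_random_seq(rng, int(rng.integers(lo, hi + 1))))
        class_refs[label] = sorted(pool)
    return ReferenceBundle(precursors, matures, class_refs)


def abundance_profile(
    feature_ids: Sequence[str], total_mean: float, decay: float = 0.85
) -> dict[str, float]:
    """Geometric abundance ladder: feature i gets total * decay^i / norm.

    A skewed profile with clearly separated top ranks, as observed in
    real small-RNA libraries where a handful of miRNAs dominate.
    """
    weights = np.array([decay**i for i in range(len(feature_ids))])
    weights /= weights.sum()
    return {f: float(total_mean * w) for f, w in zip(feature_ids, weights)}


def default_config(n_mirna: int = 50, seed: int = 0, **overrides) -> SimulationConfig:
    """Study-condition defaults with a geometric abundance profile.

    Baseline means put ~2500 miRNA-mapped reads in a 10k-read library
    (miRNA class fraction 0.25).
    """
    cfg = SimulationConfig(n_mirna=n_mirna, seed=seed, **overrides)
    if not cfg.nb_mean:
        ids = [
            f"dre-miR-sim{i + 1}-{'5p' if i % 2 == 0 else '3p'}"
            for i in range(n_mirna)
        ]
        cfg.nb_mean = abundance_profile(ids, total_mean=2500.0)
    return cfg


def make_sample_sheet(
    stages: Sequence[int],
    tissues: Sequence[str] = ("testis", "ovary"),
    n_replicates: int = 5,
    pooled: Mapping[tuple[str, int], int] | None = None,
) -> pd.DataFrame:
    """Sample sheet for a stages x tissues design with biological replicates.

    ``pooled`` overrides the replicate count for specific (tissue, stage)
    combinations (e.g. single pooled libraries).
    """
    pooled = dict(pooled or {})
    rows = []
    for tissue in tissues:
        for stage in stages:
            n = pooled.get((tissue, stage), n_replicates)
            for r in range(1, n + 1):
                rows.append(
                    {
                        "sample_id": f"{tissue}_{stage}_r{r}",
                        "stage_wpf": stage,
                        "tissue": tissue,
                        "replicate": r,
                    }
                )
    sheet = pd.DataFrame(rows).set_index("sample_id")
    sheet["group"] = sample_groups(sheet)
    return sheet


def study_design() -> pd.DataFrame:
    """The full developmental design: undifferentiated 3 wpf pool, five
    replicates per stage x sex from 6 to 24 wpf, egg replicates and a
    pooled spermatozoa library."""
    parts = [
        make_sample_sheet([3], ["undifferentiated"], n_replicates=1),
        make_sample_sheet([6, 9, 12, 24], ["testis", "ovary"], n_replicates=5),
        make_sample_sheet([24], ["egg"], n_replicates=5),
        make_sample_sheet([24], ["spermatozoa"], n_replicates=1),
    ]
    return pd.concat(parts)


def simulate_counts(
    config: SimulationConfig, sample_sheet: pd.DataFrame
) -> tuple[CountMatrix, SimulationTruth]:
    """Draw per-sample miRNA counts: NB(mean scaled by planted fold
    changes per group, dispersion)."""
    if sample_sheet.empty:
        raise ValidationError("sample sheet lists no samples")
    if "group" not in sample_sheet.columns:
        sample_sheet = sample_sheet.copy()
        sample_sheet["group"] = sample_groups(sample_sheet)
    groups = set(sample_sheet["group"])
    if not config.nb_mean:
        raise ValidationError("config.nb_mean is empty; use default_config()")
    for f, per_group in config.planted_lfc.items():
        if f not in config.nb_mean:
            raise ValidationError(f"planted_lfc names unknown feature {f}")
        for g in per_group:
            if g not in groups:
                raise ValidationError(
                    f"planted_lfc for {f} names group {g!r} absent from sample sheet"
                )
    features = list(config.nb_mean)
    counts = {}
    expected = {}
    for sid, row in sample_sheet.iterrows():
        rng = _child_rng(config.seed, sid, "counts")
        group = row["group"]
        mu = np.array(
            [
                config.nb_mean[f]
                * 2.0 ** config.planted_lfc.get(f, {}).get(group, 0.0)
                for f in features
            ]
        )
        alpha = np.array([config.dispersion_of(f) for f in features])
        draw = np.zeros(len(features), dtype=np.int64)
        pos = mu > 0
        nb = pos & (alpha >= 1e-12)
        po = pos & ~nb
        if nb.any():
            size = 1.0 / alpha[nb]
            p = size / (size + mu[nb])
            draw[nb] = rng.negative_binomial(size, p)
        if po.any():
            draw[po] = rng.poisson(mu[po])
        counts[sid] = draw
        expected[sid] = mu
    counts_df = pd.DataFrame(counts, index=features, dtype=float)
    matrix = CountMatrix(counts_df, sample_sheet)
    truth = SimulationTruth(
        expected_counts=pd.DataFrame(expected, index=features),
        planted_lfc={f: dict(d) for f, d in config.planted_lfc.items()},
        isomir_proportions=_full_isomir_truth(config),
        class_read_counts=pd.DataFrame(),
        seed=config.seed,
    )
    return matrix, truth


def _full_isomir_truth(config: SimulationConfig) -> dict[str, dict[str, float]]:
    out = {}
    for mid, prof in config.isomir_profile.items():
        d = dict(prof)
        d[CANONICAL] = 1.0 - sum(prof.values())
        out[mid] = d
    return out


def _phred33(qual: np.ndarray) -> tuple[int, ...]:
    return tuple(int(q) for q in qual)


def simulate_reads(
    bundle: ReferenceBundle,
    counts: CountMatrix,
    config: SimulationConfig,
    truth: SimulationTruth | None = None,
) -> dict[str, list[ReadRecord]]:
    """Emit adapter-ligated reads for each sample.

    Each biological sequence (miRNA variant or class background) is
    followed by the 3' adapter and random carrier bases, truncated to the
    instrument read length.  miRNA variants are drawn multinomially from
    the configured isomiR profile; background classes are drawn from the
    class reference pools at the configured class mix.  When ``truth`` is
    given, planted per-class read counts and per-read provenance are
    recorded on it.
    """
    adapter = config.adapter.upper().replace("U", "T")
    if len(adapter) < 5:
        raise ValidationError("adapter shorter than 5 nt is untrimmable")
    unknown = set(counts.feature_ids) - set(bundle.mature_by_id)
    if unknown:
        raise ValidationError(f"count features absent from reference: {sorted(unknown)}")
    mature = bundle.mature_by_id
    mix = dict(config.class_mix)
    mirna_frac = mix.get("miRNA", 0.0)
    qmeans = config.quality_means()
    out: dict[str, list[ReadRecord]] = {}
    class_counts: dict[str, dict[str, int]] = {}
    for sid in counts.sample_ids:
        rng = _child_rng(config.seed, sid, "reads")
        entries: list[tuple[str, str, str, str]] = []  # (class, feature, key, bioseq)
        n_mirna = 0
        for f in counts.feature_ids:
            n = int(counts.counts.loc[f, sid])
            if n == 0:
                continue
            n_mirna += n
            prof = config.isomir_profile.get(f, {})
            keys = list(prof) + [CANONICAL]
            probs = list(prof.values())
            probs.append(1.0 - sum(probs))
            alloc = rng.multinomial(n, probs)
            ref = mature[f]
            for key, k in zip(keys, alloc):
                if k == 0:
                    continue
                seq = (
                    ref.mature_seq
                    if key == CANONICAL
                    else generate_variant_read(ref, key)
                )
                entries.extend(("miRNA", f, key, seq) for _ in range(k))
        per_class = {"miRNA": n_mirna}
        if n_mirna and mirna_frac > 0:
            total = n_mirna / mirna_frac
            for label, frac in mix.items():
                if label == "miRNA":
                    continue
                n_c = int(round(total * frac))
                per_class[label] = n_c
                if n_c == 0:
                    continue
                if label == "other":
                    lo, hi = CLASS_LENGTHS["other"]
                    for _ in range(n_c):
                        entries.append(
                            ("other", "", "", _random_seq(rng, int(rng.integers(lo, hi + 1))))
                        )
                else:
                    pool = bundle.class_refs[label]
                    picks = rng.integers(0, len(pool), size=n_c)
                    entries.extend((label, "", "", pool[j]) for j in picks)
        class_counts[sid] = per_class
        order = rng.permutation(len(entries))
        reads: list[ReadRecord] = []
        details = []
        for serial, idx in enumerate(order):
            label, feature, key, bio = entries[idx]
            construct = bio + adapter
            if len(construct) < config.read_length:
                construct += _random_seq(rng, config.read_length - len(construct))
            seq = construct[: config.read_length]
            qual = np.clip(
                np.rint(rng.normal(qmeans[: len(seq)], config.quality_sd)), 2, 40
            ).astype(int)
            rid = f"{sid}.{serial + 1}"
            reads.append(ReadRecord(rid, seq, _phred33(qual)))
            if truth is not None:
                details.append(
                    {
                        "read_id": rid,
                        "class": label,
                        "feature": feature,
                        "variant_key": key or (CANONICAL if label == "miRNA" else ""),
                        "bio_length": len(bio),
                    }
                )
        out[sid] = reads
        if truth is not None:
            truth.read_details[sid] = pd.DataFrame(
                details,
                columns=["read_id", "class", "feature", "variant_key", "bio_length"],
            )
    if truth is not None:
        truth.class_read_counts = (
            pd.DataFrame(class_counts).fillna(0).astype(int)
        )
    return out


def example_study(seed: int = 0):
    """A ready-made two-stage, two-sex benchmark study.

    50 miRNAs on a geometric abundance ladder, the default piRNA-dominated
    class mix, 2 stages (6 and 9 wpf) x testis/ovary x 5 biological
    replicates at ~10k reads per library.  Planted structure: isomiR
    profiles on the three most abundant matures (templated +1 at 0.30;
    untemplated +1U at 0.20 plus a 5' truncation at 0.10; a terminal
    substitution to G at 0.25) and log2 fold changes of +3 for two
    ovary-enriched and two testis-enriched features at both stages.

    Returns ``(config, bundle, sample_sheet)``.
    """
    cfg = default_config(n_mirna=50, seed=seed)
    bundle = build_reference(cfg)
    by_id = bundle.mature_by_id
    ranked = sorted(cfg.nb_mean, key=cfg.nb_mean.get, reverse=True)
    cfg.isomir_profile = {
        ranked[0]: {templated_addition_key(by_id[ranked[0]], 1): 0.30},
        ranked[1]: {
            untemplated_addition_key(by_id[ranked[1]], "U", 1): 0.20,
            "5p+1": 0.10,
        },
        ranked[2]: {terminal_substitution_key(by_id[ranked[2]], "G"): 0.25},
    }
    cfg.planted_lfc = {
        ranked[7]: {"ovary_6": 3.0, "ovary_9": 3.0},
        ranked[9]: {"ovary_6": 3.0, "ovary_9": 3.0},
        ranked[8]: {"testis_6": 3.0, "testis_9": 3.0},
        ranked[10]: {"testis_6": 3.0, "testis_9": 3.0},
    }
    sheet = make_sample_sheet([6, 9], ["testis", "ovary"], n_replicates=5)
    return cfg, bundle, sheet


def templated_addition_key(ref: MatureMiRNARecord, n: int = 1) -> str:
    """Key for n templated 3' additions (bases read off the precursor)."""
    if n < 1 or ref.end + n > len(ref.precursor_seq):
        raise ValidationError("templated addition runs past the precursor")
    body = "".join(
        ref.precursor_seq[ref.end + j].replace("T", "U") for j in range(n)
    )
    return f"3p+{body}"


def untemplated_addition_key(
    ref: MatureMiRNARecord, base: str = "U", n: int = 1
) -> str:
    """Key for n untemplated 3' additions of ``base`` (RNA alphabet).

    Falls back to the alphabetically first non-template base at any
    position where ``base`` happens to match the template.
    """
    base_dna = base.upper().replace("U", "T")
    parts = []
    for j in range(n):
        template = ref.precursor_seq[ref.end + j]
        b = base_dna if base_dna != template else next(
            c for c in "ACGT" if c != template
        )
        parts.append(b.replace("T", "U") + "*")
    return "3p+" + "".join(parts)


def terminal_substitution_key(ref: MatureMiRNARecord, to_base: str = "G") -> str:
    """Key for a substitution at the 3'-terminal base of the mature."""
    pos = len(ref) - 1
    canon = ref.mature_seq[pos]
    to_dna = to_base.upper().replace("U", "T")
    if to_dna == canon:
        to_dna = next(c for c in "GACT" if c != canon)
    return (
        f"s{pos + 1}:{canon.replace('T', 'U')}>{to_dna.replace('T', 'U')}!"
    )


def write_reference(bundle: ReferenceBundle, outdir) -> None:
    """Serialize precursors (FASTA), mature table (TSV) and class FASTA."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    SeqIO.write(
        (SeqRecord(Seq(seq), id=pid, description="") for pid, seq in bundle.precursors),
        str(outdir / "precursors.fasta"),
        "fasta",
    )
    pd.DataFrame(
        [
            {
                "mature_id": m.mature_id,
                "precursor_id": m.precursor_id,
                "arm": m.arm,
                "start_0based": m.start,
                "end_exclusive": m.end,
                "mature_seq": m.mature_seq,
            }
            for m in bundle.matures
        ]
    ).to_csv(outdir / "matures.tsv", sep="\t", index=False)
    records = []
    for label, seqs in bundle.class_refs.items():
        records.extend(
            SeqRecord(Seq(s), id=f"{label}|{i + 1}", description="")
            for i, s in enumerate(seqs)
        )
    SeqIO.write(records, str(outdir / "class_refs.fasta"), "fasta")


def load_reference(precursor_fasta, mature_tsv, class_fasta=None) -> ReferenceBundle:
    """Load a reference bundle from the on-disk formats."""
    precursors = [
        (rec.id, str(rec.seq).upper().replace("U", "T"))
        for rec in SeqIO.parse(str(precursor_fasta), "fasta")
    ]
    prec = dict(precursors)
    table = pd.read_csv(mature_tsv, sep="\t")
    matures = [
        MatureMiRNARecord(
            row["mature_id"],
            row["precursor_id"],
            row["arm"],
            str(row["mature_seq"]).upper().replace("U", "T"),
            int(row["start_0based"]),
            int(row["end_exclusive"]),
            prec[row["precursor_id"]],
        )
        for _, row in table.iterrows()
    ]
    class_refs: dict[str, list[str]] = {}
    if class_fasta is not None:
        for rec in SeqIO.parse(str(class_fasta), "fasta"):
            label = rec.id.split("|")[0]
            class_refs.setdefault(label, []).append(str(rec.seq).upper().replace("U", "T"))
    return ReferenceBundle(precursors, matures, class_refs)


def simulate_study(
    config: SimulationConfig, sample_sheet: pd.DataFrame, outdir
) -> tuple[ReferenceBundle, CountMatrix, SimulationTruth]:
    """One-call generator: reference, counts, FASTQ and truth, all on disk."""
    from .preprocess import write_fastq

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = build_reference(config)
    matrix, truth = simulate_counts(config, sample_sheet)
    reads = simulate_reads(bundle, matrix, config, truth)
    write_reference(bundle, outdir / "reference")
    sample_sheet.reset_index().to_csv(outdir / "samples.tsv", sep="\t", index=False)
    matrix.counts.rename_axis("feature").to_csv(outdir / "true_counts.tsv", sep="\t")
    fastq_dir = outdir / "fastq"
    fastq_dir.mkdir(exist_ok=True)
    for sid, recs in reads.items():
        write_fastq(recs, fastq_dir / f"{sid}.fastq")
    truth.to_dir(outdir / "truth")
    return bundle, matrix, truth
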