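"""Descriptive analytics: abundance rankings, ordination, titration
correlation and empirical-resampling GO enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import ValidationError
from .diffabund import bh_adjust

__all__ = [
    "AbundanceRanking",
    "OrdinationResult",
    "TitrationResult",
    "top_k_abundance",
    "ordination",
    "titration_correlation",
    "go_empirical_enrichment",
]


@dataclass
class AbundanceRanking:
    """Per-group ordered abundance lists and cross-group top-k frequency."""

    k: int
    rankings: dict[str, list[tuple[str, float]]]
    frequency: pd.Series

    def top(self, group: str) -> list[str]:
        return [f for f, _ in self.rankings[group][: self.k]]


def top_k_abundance(
    normalized: pd.DataFrame,
    group_labels: Mapping[str, str] | pd.Series,
    k: int = 10,
) -> AbundanceRanking:
    """Rank features by replicate-mean normalized abundance per group.

    Ties break lexicographically on the feature id, so the output is
    invariant to sample and feature ordering.  The frequency table
    counts, per feature, the groups in whose top-k it appears.
    """
    if k > normalized.shape[0]:
        raise ValidationError(f"k={k} exceeds feature count {normalized.shape[0]}")
    labels = pd.Series(group_labels).loc[list(normalized.columns)]
    rankings: dict[str, list[tuple[str, float]]] = {}
    freq: dict[str, int] = {}
    for group in sorted(labels.unique()):
        cols = list(labels.index[labels == group])
        means = normalized[cols].mean(axis=1)
        order = sorted(means.items(), key=lambda kv: (-kv[1], kv[0]))
        rankings[group] = [(f, float(v)) for f, v in order]
        for f, _ in order[:k]:
            freq[f] = freq.get(f, 0) + 1
    frequency = pd.Series(freq, name="n_groups").sort_values(
        ascending=False, kind="stable"
    )
    frequency = frequency.loc[
        sorted(frequency.index, key=lambda f: (-frequency[f], f))
    ]
    return AbundanceRanking(k, rankings, frequency)


@dataclass
class OrdinationResult:
    """Principal-component sample coordinates on log2(normalized + 1)."""

    coordinates: pd.DataFrame  # samples x components
    variance_explained: np.ndarray  # fraction per retained component


def ordination(normalized: pd.DataFrame, n_components: int = 2) -> OrdinationResult:
    """PCA of samples from log2(normalized + 1), feature-centered.

    Exact decomposition by SVD; the sign of each component is fixed so
    that its largest-magnitude feature loading is positive, making the
    output deterministic and invariant to sample order.
    """
    if normalized.shape[1] < 3:
        raise ValidationError("ordination requires at least 3 samples")
    X = np.log2(normalized.to_numpy(dtype=float) + 1.0)  # features x samples
    Xc = X - X.mean(axis=1, keepdims=True)
    if not np.any(np.abs(Xc) > 1e-12):
        raise ValidationError("constant matrix: no variance to decompose")
    # samples x features
    U, S, Vt = np.linalg.svd(Xc.T, full_matrices=False)
    total = float((S**2).sum())
    n_components = min(n_components, len(S))
    coords = U[:, :n_components] * S[:n_components]
    for j in range(n_components):
        loading = Vt[j]
        i = int(np.argmax(np.abs(loading)))
        if loading[i] < 0:
            coords[:, j] *= -1.0
    var = (S[:n_components] ** 2) / total
    frame = pd.DataFrame(
        coords,
        index=normalized.columns,
        columns=[f"PC{j + 1}" for j in range(n_components)],
    )
    return OrdinationResult(frame, var)


@dataclass
class TitrationResult:
    """Library-vs-library agreement at a reads-per-million threshold."""

    r_log: float
    r_raw: float
    n_retained: int
    table: pd.DataFrame  # feature, rpm_a, rpm_b, retained, dropout
    dropouts: list[str] = field(default_factory=list)

    @property
    def r(self) -> float:
        return self.r_log


def titration_correlation(
    lib_a: pd.Series, lib_b: pd.Series, min_rpm: float = 100.0
) -> TitrationResult:
    """Pearson correlation between two libraries above an RPM threshold.

    Both vectors are scaled to reads per million; features with
    RPM > ``min_rpm`` in the reference library A are retained.  The
    correlation is computed on log2 RPM over retained features detected
    in both libraries (the raw-scale r is reported alongside); retained
    features absent from B are listed as dropouts.
    """
    a, b = lib_a.align(lib_b, join="inner")
    if a.sum() <= 0 or b.sum() <= 0:
        raise ValidationError("libraries must contain reads")
    rpm_a = a / a.sum() * 1e6
    rpm_b = b / b.sum() * 1e6
    retained = rpm_a > min_rpm
    dropout = retained & (b <= 0)
    both = retained & (b > 0)
    if int(both.sum()) < 3:
        raise ValidationError("fewer than 3 features retained for correlation")
    la = np.log2(rpm_a[both].to_numpy())
    lb = np.log2(rpm_b[both].to_numpy())
    if np.ptp(la) == 0 or np.ptp(lb) == 0:
        r_log = 1.0 if np.allclose(la - la.mean(), lb - lb.mean()) else 0.0
    else:
        r_log = float(np.corrcoef(la, lb)[0, 1])
    r_raw = float(np.corrcoef(rpm_a[both], rpm_b[both])[0, 1])
    table = pd.DataFrame(
        {
            "rpm_a": rpm_a,
            "rpm_b": rpm_b,
            "retained": retained,
            "dropout": dropout,
        }
    ).rename_axis("feature")
    return TitrationResult(
        r_log=r_log,
        r_raw=r_raw,
        n_retained=int(retained.sum()),
        table=table,
        dropouts=sorted(table.index[dropout]),
    )


def go_empirical_enrichment(
    target_genes: Iterable[str],
    go_annotation: Mapping[str, Iterable[str]],
    universe: Iterable[str],
    n_samples: int = 10_000,
    seed: int | None = None,
    batch_size: int = 20_000,
) -> pd.DataFrame:
    """Empirical-resampling GO term enrichment.

    For each term, ``n_samples`` random gene sets of the target size are
    drawn from the universe without replacement (one shared set of draws
    across terms); the empirical p-value is (b + 1) / (N + 1) where b is
    the number of draws whose overlap with the term meets or exceeds the
    observed overlap.  BH adjustment across terms.  Fully seeded.

    Returns a DataFrame: term, term_size, observed_overlap,
    expected_overlap, p_value, adj_p, sorted by p then term.
    """
    universe_list = sorted(set(universe))
    if not universe_list:
        raise ValidationError("empty gene universe")
    targets = set(target_genes)
    outside = targets - set(universe_list)
    if outside:
        raise ValidationError(f"target genes outside universe: {sorted(outside)[:5]}")
    if not targets:
        raise ValidationError("empty target gene set")
    terms = {t: set(g) & set(universe_list) for t, g in go_annotation.items()}
    if not terms or any(len(g) == 0 for g in terms.values()):
        raise ValidationError("every GO term needs at least one universe gene")
    idx = {g: i for i, g in enumerate(universe_list)}
    U = len(universe_list)
    k = len(targets)
    if k > U:
        raise ValidationError("target set larger than universe")
    term_names = sorted(terms)
    indicators = np.zeros((len(term_names), U), dtype=np.int8)
    observed = np.zeros(len(term_names), dtype=int)
    for ti, t in enumerate(term_names):
        for g in terms[t]:
            indicators[ti, idx[g]] = 1
        observed[ti] = len(terms[t] & targets)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(term_names), dtype=np.int64)
    overlap_sum = np.zeros(len(term_names), dtype=np.float64)
    remaining = n_samples
    while remaining > 0:
        b = min(batch_size, remaining, max(1, 2_000_000 // max(U, 1)))
        keys = rng.random((b, U))
        sampled = np.argpartition(keys, k - 1, axis=1)[:, :k]  # b x k indices
        member = np.zeros((b, U), dtype=np.int8)
        np.put_along_axis(member, sampled, 1, axis=1)
        overlaps = member @ indicators.T  # b x terms
        exceed += (overlaps >= observed[None, :]).sum(axis=0)
        overlap_sum += overlaps.sum(axis=0)
        remaining -= b
    p = (exceed + 1.0) / (n_samples + 1.0)
    out = pd.DataFrame(
        {
            "term": term_names,
            "term_size": [len(terms[t]) for t in term_names],
            "observed_overlap": observed,
            "expected_overlap": overlap_sum / n_samples,
            "p_value": p,
            "adj_p": bh_adjust(p),
        }
    )
    return out.sort_values(["p_value", "term"], kind="stable").reset_index(drop=True)
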