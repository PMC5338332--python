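"""Median-of-ratios normalization and negative-binomial differential abundance.

Size factors are the classic median-of-ratios estimator: for sample j,
s_j = median over reference features f of count[f, j] / geomean_k count[f, k],
where reference features have no zero across samples.  Differential
abundance is a simplified NB Wald test on normalized counts: fold change
log2((mean_B + c0) / (mean_A + c0)) with pseudo-count c0 = 0.5, a
method-of-moments dispersion per feature shrunk 50/50 toward a fitted
mean-dispersion trend, a delta-method standard error, and
Benjamini-Hochberg adjustment.  A feature is called under the study
filters when the larger group mean of normalized reads passes the
abundance threshold (100 by default; 1000 for gonad-vs-gamete
contrasts), |log2FC| >= 2, and adjusted p <= 0.01.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import nnls
from statsmodels.stats.multitest import multipletests

from .core import CountMatrix, ValidationError

__all__ = [
    "Contrast",
    "DifferentialResult",
    "size_factors",
    "normalize",
    "estimate_dispersion",
    "test_differential",
    "contrast_matrix",
    "bh_adjust",
]

ALPHA_FLOOR = 1e-8


@dataclass(frozen=True)
class Contrast:
    """A two-group comparison; fold changes are alt over ref."""

    name: str
    ref_group: str
    alt_group: str
    min_norm: float = 100.0


@dataclass(frozen=True)
class DifferentialResult:
    """One feature's test outcome under the study filters."""

    feature: str
    base_mean: float
    log2fc: float
    se_log2fc: float
    p_value: float
    adj_p: float
    passes_filters: bool


def _counts_frame(counts: CountMatrix | pd.DataFrame) -> pd.DataFrame:
    return counts.counts if isinstance(counts, CountMatrix) else counts


def size_factors(
    counts: CountMatrix | pd.DataFrame, pseudo_reference: bool = False
) -> pd.Series:
    """Median-of-ratios size factor per sample.

    Reference features are those with no zero in any sample.  When none
    exists the estimator is undefined; pass ``pseudo_reference=True`` to
    fall back to geometric means over the positive counts of each
    feature (ratios taken only where the count is positive).
    """
    mat = _counts_frame(counts)
    values = mat.to_numpy(dtype=float)
    all_pos = (values > 0).all(axis=1)
    if all_pos.any():
        ref = values[all_pos]
        geo = np.exp(np.mean(np.log(ref), axis=1, keepdims=True))
        ratios = ref / geo
        s = np.median(ratios, axis=0)
    elif pseudo_reference:
        with np.errstate(divide="ignore"):
            logs = np.where(values > 0, np.log(values), np.nan)
        geo = np.exp(np.nanmean(logs, axis=1, keepdims=True))
        any_pos = (values > 0).any(axis=1)
        if not any_pos.any():
            raise ValidationError("all counts are zero; size factors undefined")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            ratios = np.where(values > 0, values / geo, np.nan)
            s = np.nanmedian(ratios[any_pos], axis=0)
    else:
        raise ValidationError(
            "no feature is nonzero in every sample; median-of-ratios is "
            "undefined — re-run with pseudo_reference=True to use the "
            "positive-count fallback"
        )
    if np.any(~np.isfinite(s)) or np.any(s <= 0):
        raise ValidationError("size factors are not strictly positive")
    return pd.Series(s, index=mat.columns, name="size_factor")


def normalize(
    counts: CountMatrix | pd.DataFrame, s: pd.Series | None = None, **kwargs
) -> pd.DataFrame:
    """Normalized counts: raw counts divided column-wise by size factors."""
    mat = _counts_frame(counts)
    if s is None:
        s = size_factors(counts, **kwargs)
    return mat.div(s.loc[mat.columns], axis=1)


def _fit_trend(means: np.ndarray, alphas: np.ndarray) -> tuple[float, float]:
    """Non-negative least-squares fit of alpha ~ a0 + a1 / mean."""
    use = (means > 0) & np.isfinite(alphas)
    if use.sum() < 2:
        med = float(np.median(alphas[np.isfinite(alphas)])) if np.isfinite(alphas).any() else ALPHA_FLOOR
        return max(med, ALPHA_FLOOR), 0.0
    X = np.column_stack([np.ones(use.sum()), 1.0 / means[use]])
    coef, _ = nnls(X, alphas[use])
    return float(coef[0]), float(coef[1])


def estimate_dispersion(
    normalized: pd.DataFrame,
    group_labels: Mapping[str, str] | pd.Series,
    alpha_floor: float = ALPHA_FLOOR,
    shrink: float = 0.5,
) -> pd.Series:
    """Per-feature NB dispersion from normalized counts.

    Method-of-moments alpha = max((var - mean) / mean^2, floor) using the
    within-group pooled variance, then shrunk ``shrink``/(1-shrink)
    toward a fitted a0 + a1/mean trend.  Requires at least one group
    with >= 2 samples; single-replicate-only designs must borrow a
    pooled trend explicitly (see :func:`test_differential`).
    """
    labels = pd.Series(group_labels).loc[list(normalized.columns)]
    members = {g: list(idx) for g, idx in labels.groupby(labels).groups.items()}
    replicated = {g: cols for g, cols in members.items() if len(cols) >= 2}
    if not replicated:
        raise ValidationError(
            "no group has >= 2 replicates; dispersion cannot be estimated "
            "(use the pooled-dispersion fallback)"
        )
    values = normalized.to_numpy(dtype=float)
    col_index = {c: i for i, c in enumerate(normalized.columns)}
    ss = np.zeros(values.shape[0])
    df_total = 0
    rep_cols: list[int] = []
    for cols in replicated.values():
        idx = [col_index[c] for c in cols]
        rep_cols.extend(idx)
        sub = values[:, idx]
        ss += sub.var(axis=1, ddof=1) * (len(idx) - 1)
        df_total += len(idx) - 1
    var = ss / df_total
    mean = values[:, rep_cols].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        mom = np.where(mean > 0, (var - mean) / mean**2, alpha_floor)
    mom = np.maximum(mom, alpha_floor)
    a0, a1 = _fit_trend(mean, mom)
    with np.errstate(divide="ignore"):
        trend = np.where(mean > 0, a0 + a1 / mean, a0)
    alpha = np.maximum(shrink * mom + (1.0 - shrink) * trend, alpha_floor)
    out = pd.Series(alpha, index=normalized.index, name="dispersion")
    out.attrs["trend"] = (a0, a1)
    return out


def bh_adjust(p: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        return arr
    return multipletests(arr, method="fdr_bh")[1]


def test_differential(
    counts: CountMatrix,
    contrast: Contrast,
    lfc_threshold: float = 2.0,
    alpha: float = 0.01,
    min_norm: float | None = None,
    pseudo_count: float = 0.5,
    pooled_dispersion: bool = True,
) -> pd.DataFrame:
    """NB Wald test of ``contrast.alt_group`` vs ``contrast.ref_group``.

    Size factors and the dispersion trend are estimated on the full
    matrix; the test uses the contrast samples only.  Groups with a
    single library (pooled designs) borrow the fitted trend dispersion
    when ``pooled_dispersion`` is true (a warning is emitted), otherwise
    they are an error.  Returns a DataFrame with one row per feature:
    feature, base_mean, mean_ref, mean_alt, log2fc, se_log2fc, p_value,
    adj_p, passes_filters.
    """
    groups = counts.groups()
    for g in (contrast.ref_group, contrast.alt_group):
        if g not in groups:
            raise ValidationError(f"contrast group {g!r} absent from sample sheet")
    ref_cols = groups[contrast.ref_group]
    alt_cols = groups[contrast.alt_group]
    if not ref_cols or not alt_cols:
        raise ValidationError("empty contrast group")
    threshold = contrast.min_norm if min_norm is None else min_norm

    s = size_factors(counts, pseudo_reference=True)
    norm = normalize(counts, s)
    labels = counts.samples["group"]
    replicated_any = (labels.value_counts() >= 2).any()
    unreplicated = [g for g, c in ((contrast.ref_group, ref_cols),
                                   (contrast.alt_group, alt_cols)) if len(c) == 1]
    if unreplicated:
        if not pooled_dispersion:
            raise ValidationError(
                f"group(s) {unreplicated} have a single library; enable "
                "pooled_dispersion to borrow the trend dispersion"
            )
        warnings.warn(
            f"group(s) {unreplicated} are unreplicated; borrowing the pooled "
            "dispersion trend",
            stacklevel=2,
        )
    if replicated_any:
        disp = estimate_dispersion(norm, labels)
    else:
        if not pooled_dispersion:
            raise ValidationError("no replicated group anywhere in the design")
        warnings.warn(
            "no replicated group in the design; using the dispersion floor",
            stacklevel=2,
        )
        disp = pd.Series(ALPHA_FLOOR, index=norm.index, name="dispersion")

    nA, nB = len(ref_cols), len(alt_cols)
    mA = norm[ref_cols].mean(axis=1).to_numpy()
    mB = norm[alt_cols].mean(axis=1).to_numpy()
    a = disp.to_numpy()
    c0 = pseudo_count
    lfc = np.log2((mB + c0) / (mA + c0))
    varA = (mA + a * mA**2) / nA
    varB = (mB + a * mB**2) / nB
    ln2 = np.log(2.0)
    se = np.sqrt(varA / (mA + c0) ** 2 + varB / (mB + c0) ** 2) / ln2
    tested = (mA + mB) > 0
    z = np.zeros_like(lfc)
    nz = tested & (se > 0)
    z[nz] = lfc[nz] / se[nz]
    df = (nA - 1) + (nB - 1)
    if df >= 2:
        p = 2.0 * stats.t.sf(np.abs(z), df)
    else:
        p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.where(nz, p, 1.0)
    adj = np.ones_like(p)
    adj[tested] = bh_adjust(p[tested])
    base_mean = norm[ref_cols + alt_cols].mean(axis=1).to_numpy()
    passes = (
        (np.maximum(mA, mB) >= threshold)
        & (np.abs(lfc) >= lfc_threshold)
        & (adj <= alpha)
    )
    out = pd.DataFrame(
        {
            "feature": list(norm.index),
            "base_mean": base_mean,
            "mean_ref": mA,
            "mean_alt": mB,
            "log2fc": lfc,
            "se_log2fc": se,
            "p_value": p,
            "adj_p": adj,
            "passes_filters": passes,
        }
    )
    out.attrs["contrast"] = contrast
    out.attrs["n_ref"] = nA
    out.attrs["n_alt"] = nB
    return out


def results_as_records(table: pd.DataFrame) -> list[DifferentialResult]:
    """View a result table as typed records."""
    return [
        DifferentialResult(
            r.feature, r.base_mean, r.log2fc, r.se_log2fc, r.p_value, r.adj_p,
            bool(r.passes_filters),
        )
        for r in table.itertuples(index=False)
    ]


GAMETE_OF = {"testis": "spermatozoa", "ovary": "egg"}


def contrast_matrix(
    sample_sheet: pd.DataFrame,
    baseline_tissue: str = "undifferentiated",
    min_norm: float = 100.0,
    gamete_min_norm: float = 1000.0,
) -> list[Contrast]:
    """Enumerate the study's contrast families from a sample sheet.

    Families: each stage x sex vs the undifferentiated baseline (when
    present), consecutive stages within sex, ovary vs testis per stage,
    and gonad vs gamete at the final stage with the abundance filter
    raised to ``gamete_min_norm``.
    """
    sheet = sample_sheet.copy()
    if "group" not in sheet.columns:
        from .core import sample_groups

        sheet["group"] = sample_groups(sheet)
    stages_of: dict[str, list[int]] = {}
    for _, row in sheet.iterrows():
        stages_of.setdefault(row["tissue"], [])
        st = int(row["stage_wpf"])
        if st not in stages_of[row["tissue"]]:
            stages_of[row["tissue"]].append(st)
    for v in stages_of.values():
        v.sort()
    contrasts: list[Contrast] = []
    baseline = None
    if baseline_tissue in stages_of:
        b_stage = stages_of[baseline_tissue][0]
        baseline = f"{baseline_tissue}_{b_stage}"
    gonads = [t for t in ("testis", "ovary") if t in stages_of]
    if baseline:
        for tissue in gonads:
            for st in stages_of[tissue]:
                contrasts.append(
                    Contrast(
                        f"{tissue}_{st}_vs_baseline", baseline,
                        f"{tissue}_{st}", min_norm,
                    )
                )
    for tissue in gonads:
        st = stages_of[tissue]
        for a, b in zip(st, st[1:]):
            contrasts.append(
                Contrast(
                    f"{tissue}_{b}_vs_{a}", f"{tissue}_{a}", f"{tissue}_{b}",
                    min_norm,
                )
            )
    if "testis" in stages_of and "ovary" in stages_of:
        for st in sorted(set(stages_of["testis"]) & set(stages_of["ovary"])):
            contrasts.append(
                Contrast(
                    f"ovary_vs_testis_{st}", f"testis_{st}", f"ovary_{st}",
                    min_norm,
                )
            )
    for tissue in gonads:
        gamete = GAMETE_OF[tissue]
        if gamete in stages_of:
            st = stages_of[tissue][-1]
            contrasts.append(
                Contrast(
                    f"{tissue}_{st}_vs_{gamete}",
                    f"{gamete}_{stages_of[gamete][-1]}",
                    f"{tissue}_{st}",
                    gamete_min_norm,
                )
            )
    return contrasts
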