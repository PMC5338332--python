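"""Independent brute-force oracles used only by the test suite.

Each oracle re-derives an expected result by a different procedure than
the implementation under test (exhaustive enumeration, literal formula
transcription, or a closed form), so agreement is evidence rather than
tautology.
"""

from __future__ import annotations

import numpy as np

from gonadmir.core import MatureMiRNARecord
from gonadmir.isomir import variant_key


def adapter_start_bruteforce(seq, adapter, min_overlap, max_error_rate):
    """Best 3'-adapter start by scoring every alignment offset directly."""
    candidates = []
    for start in range(len(seq)):
        overlap = min(len(adapter), len(seq) - start)
        if overlap < len(adapter) and overlap < min_overlap:
            continue
        mism = sum(
            1 for a, b in zip(seq[start : start + overlap], adapter[:overlap])
            if a != b
        )
        if mism <= max_error_rate * overlap + 1e-12:
            score = (overlap - mism) - mism
            candidates.append((score, -start))
    if not candidates:
        return None
    return -max(candidates)[1]


def enumerate_alignments(seq, ref: MatureMiRNARecord, max_mismatch=1,
                         max_offset_5p=3, offset_3p_bounds=(-3, 4)):
    """All feasible read placements found by sliding the read along the
    *entire* precursor, then filtering by the mature-relative bounds.

    Returns a list of dicts with the positional call components and the
    tie-break rank; independent of the anchored search in the package.
    """
    P, s, e = ref.precursor_seq, ref.start, ref.end
    out = []
    for p0 in range(0, len(P) - len(seq) + 1):
        o5 = p0 - s
        if abs(o5) > max_offset_5p:
            continue
        o3 = (p0 + len(seq)) - e
        if not (offset_3p_bounds[0] <= o3 <= offset_3p_bounds[1]):
            continue
        core_len = len(seq) - max(o3, 0)
        if core_len < 1:
            continue
        subs = [
            (i, P[p0 + i], seq[i])
            for i in range(core_len)
            if seq[i] != P[p0 + i]
        ]
        if len(subs) > max_mismatch:
            continue
        additions = [
            (seq[i], seq[i] == P[p0 + i]) for i in range(core_len, len(seq))
        ]
        n_untemplated = sum(1 for _, t in additions if not t)
        edits = len(subs) + abs(o5) + abs(o3)
        out.append(
            {
                "o5": o5,
                "o3": o3,
                "subs": subs,
                "additions": additions,
                "rank": (edits, n_untemplated, abs(o5), o5),
                "n_mismatches": len(subs),
            }
        )
    return out


def best_call_key(seq, ref, **bounds):
    """Oracle isomiR key: minimal-edit placement, canonical key rendering."""
    placements = enumerate_alignments(seq, ref, **bounds)
    if not placements:
        return None
    best = min(placements, key=lambda d: d["rank"])
    terminal = bool(
        best["subs"]
        and not best["additions"]
        and best["subs"][-1][0] == len(seq) - 1
    )
    return variant_key(best["o5"], best["o3"], best["additions"], best["subs"],
                       terminal)


def size_factors_literal(counts: np.ndarray) -> np.ndarray:
    """Median of (count / geometric mean across samples) over features
    with no zero anywhere — a literal loop transcription."""
    n_feat, n_samp = counts.shape
    reference = [
        f for f in range(n_feat) if all(counts[f, j] > 0 for j in range(n_samp))
    ]
    factors = []
    for j in range(n_samp):
        ratios = []
        for f in reference:
            geo = 1.0
            for jj in range(n_samp):
                geo *= counts[f, jj]
            geo = geo ** (1.0 / n_samp)
            ratios.append(counts[f, j] / geo)
        factors.append(float(np.median(ratios)))
    return np.array(factors)
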