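"""isomiR calling: variant taxonomy, key grammar, round trip and oracle."""

import numpy as np
import pandas as pd
import pytest

from gonadmir.annotate import MatureIndex, map_to_mature
from gonadmir.core import ValidationError
from gonadmir.isomir import (
    CANONICAL,
    IsomiRTable,
    call_isomir,
    generate_variant_read,
    parse_variant_key,
    substitution_dynamics,
    summarize_isomirs,
)

from _oracles import best_call_key


def _call_seq(seq, ref):
    """Map a sequence against its single-mature index and call it."""
    index = MatureIndex([ref])
    hits = [h for h in map_to_mature(seq, index) if h.mature_id == ref.mature_id]
    assert hits, f"read did not map: {seq}"
    return call_isomir(hits[0], ref)


class TestCallIsomir:
    def test_canonical_read(self, handmade_mature):
        call = _call_seq(handmade_mature.mature_seq, handmade_mature)
        assert call.is_canonical
        assert call.variant_key == CANONICAL
        assert call.offset_5p == call.offset_3p == 0
        assert call.additions == () and call.substitutions == ()

    def test_templated_vs_untemplated_single_addition(self, handmade_mature):
        """The same +1 base is templated iff it equals the precursor base
        just past the canonical 3' end."""
        ref = handmade_mature
        template = ref.precursor_seq[ref.end]
        call = _call_seq(ref.mature_seq + template, ref)
        assert call.additions == ((template, True),)
        assert not call.has_untemplated_addition
        other = next(b for b in "ACGT" if b != template)
        call2 = _call_seq(ref.mature_seq + other, ref)
        assert call2.additions == ((other, False),)
        assert call2.has_untemplated_addition
        assert call2.variant_key.endswith("*")

    def test_terminal_substitution_flagged(self, handmade_mature):
        ref = handmade_mature
        last = ref.mature_seq[-1]
        obs = next(b for b in "ACGT" if b != last)
        call = _call_seq(ref.mature_seq[:-1] + obs, ref)
        assert call.terminal_3p_substitution
        assert call.variant_key.endswith("!")

    def test_mismatched_reference_rejected(self, handmade_mature, small_bundle):
        index = MatureIndex([handmade_mature])
        hit = map_to_mature(handmade_mature.mature_seq, index)[0]
        with pytest.raises(ValidationError):
            call_isomir(hit, small_bundle.matures[0])


def _enumerate_key_space(ref):
    """All single-axis keys plus representative combinations realizable on
    this precursor, inside the search bounds."""
    P, e = ref.precursor_seq, ref.end
    L = len(ref)
    keys = []
    for o5 in range(-3, 4):
        if o5:
            keys.append(f"5p{o5:+d}")
    for trim in (1, 2, 3):
        keys.append(f"3p-{trim}")

    def addition_body(n, untemplated_at):
        parts = []
        for j in range(n):
            template = P[e + j]
            if j in untemplated_at:
                b = next(c for c in "ACGT" if c != template)
                parts.append(b.replace("T", "U") + "*")
            else:
                parts.append(template.replace("T", "U"))
        return "3p+" + "".join(parts)

    for n in (1, 2, 3, 4):
        for mask in range(2**n):
            keys.append(addition_body(n, {j for j in range(n) if mask >> j & 1}))
    for pos in range(L):
        canon = ref.mature_seq[pos]
        for obs in "ACGT":
            if obs == canon:
                continue
            mark = "!" if pos == L - 1 else ""
            keys.append(
                f"s{pos + 1}:{canon.replace('T', 'U')}>{obs.replace('T', 'U')}{mark}"
            )
    # combinations across axes
    for o5 in (-2, 1, 3):
        keys.append(f"5p{o5:+d}|{addition_body(1, set())}")
        keys.append(f"5p{o5:+d}|{addition_body(2, {1})}")
        keys.append(f"5p{o5:+d}|3p-1")
        core_len = L - o5  # no trim, no additions
        canon = P[ref.start + o5 + 5]
        obs = next(c for c in "ACGT" if c != canon)
        keys.append(
            f"5p{o5:+d}|s6:{canon.replace('T', 'U')}>{obs.replace('T', 'U')}"
        )
    for trim in (1, 2):
        core_len = L - trim
        canon = ref.mature_seq[core_len - 1]
        obs = next(c for c in "ACGT" if c != canon)
        keys.append(
            f"3p-{trim}|s{core_len}:{canon.replace('T', 'U')}>"
            f"{obs.replace('T', 'U')}!"
        )
    return keys


class TestRoundTrip:
    def test_generate_then_call_is_identity(self, handmade_mature):
        """Every enumerated key in the search space survives the
        generate -> map -> call round trip unchanged."""
        ref = handmade_mature
        keys = _enumerate_key_space(ref)
        assert len(keys) > 100
        for key in keys:
            seq = generate_variant_read(ref, key)
            call = _call_seq(seq, ref)
            assert call.variant_key == key, f"{key} -> {call.variant_key}"

    def test_parse_rejects_garbage(self):
        for bad in ("3p+2", "5p", "s0:U>G", "sX:U>G", "3p+AB", "3p-1|3p+A"):
            with pytest.raises(ValidationError):
                parse_variant_key(bad)

    def test_generate_validates_template_status(self, handmade_mature):
        ref = handmade_mature
        template = ref.precursor_seq[ref.end].replace("T", "U")
        with pytest.raises(ValidationError):
            generate_variant_read(ref, f"3p+{template}*")  # claims untemplated
        other = next(b for b in "ACGU" if b != template and b != "T")
        if other.replace("U", "T") != ref.precursor_seq[ref.end]:
            with pytest.raises(ValidationError):
                generate_variant_read(ref, f"3p+{other}")  # claims templated


class TestOracleEquivalence:
    def test_random_variants_match_minimal_edit_oracle(self, small_bundle):
        """1000 randomly perturbed reads across all variant classes call
        identically to the exhaustive sliding-window minimal-edit oracle."""
        rng = np.random.default_rng(17)
        matures = small_bundle.matures
        index = MatureIndex(matures)
        n_checked = 0
        while n_checked < 1000:
            ref = matures[int(rng.integers(len(matures)))]
            P, s, e = ref.precursor_seq, ref.start, ref.end
            o5 = int(rng.integers(-3, 4))
            o3 = int(rng.integers(-3, 5))
            p0, p1 = s + o5, e + o3
            if p0 < 0 or p1 > len(P) or p1 - p0 < 16:
                continue
            seq = list(P[p0:p1])
            if o3 > 0:  # randomize template status of extensions
                for j in range(len(seq) - o3, len(seq)):
                    if rng.random() < 0.5:
                        seq[j] = "ACGT"[int(rng.integers(4))]
            if rng.random() < 0.6:  # one core substitution
                core_len = len(seq) - max(o3, 0)
                i = int(rng.integers(core_len))
                seq[i] = next(
                    b for b in np.random.default_rng(n_checked).permutation(
                        list("ACGT")
                    ) if b != seq[i]
                )
            read = "".join(seq)
            hits = [h for h in map_to_mature(read, index)
                    if h.mature_id == ref.mature_id]
            oracle_key = best_call_key(read, ref)
            if not hits:
                assert oracle_key is None
                n_checked += 1
                continue
            call = call_isomir(hits[0], ref)
            assert call.variant_key == oracle_key, read
            n_checked += 1


class TestSummarize:
    @staticmethod
    def _calls(rows):
        return pd.DataFrame(rows, columns=["sample_id", "mature_id",
                                           "variant_key", "count"])

    def test_single_canonical_read(self):
        calls = self._calls([("s1", "mirA", CANONICAL, 1)])
        table = summarize_isomirs(calls, {"s1": "g1"})
        assert len(table.full) == 1
        assert table.full.loc[0, "fraction"] == 1.0

    def test_threshold_splits_report_from_full_table(self):
        calls = self._calls(
            [("s1", "mirA", CANONICAL, 951), ("s1", "mirA", "3p+A", 49)]
        )
        table = summarize_isomirs(calls, {"s1": "g1"}, min_fraction=0.05)
        assert set(table.full["variant_key"]) == {CANONICAL, "3p+A"}
        assert set(table.filtered["variant_key"]) == {CANONICAL}

    def test_fractions_sum_to_one_per_group_and_mature(self):
        rng = np.random.default_rng(3)
        rows = []
        for s, g in (("s1", "g1"), ("s2", "g1"), ("s3", "g2")):
            for m in ("mirA", "mirB"):
                for key in (CANONICAL, "3p+A", "5p+1"):
                    rows.append((s, m, key, int(rng.integers(1, 100))))
        table = summarize_isomirs(self._calls(rows), {"s1": "g1", "s2": "g1",
                                                      "s3": "g2"})
        sums = table.full.groupby(["group", "mature_id"])["fraction"].sum()
        assert np.allclose(sums, 1.0)

    def test_replicates_pool_within_group(self):
        calls = self._calls(
            [("s1", "mirA", CANONICAL, 30), ("s2", "mirA", "3p+A", 10)]
        )
        table = summarize_isomirs(calls, {"s1": "g1", "s2": "g1"})
        frac = table.full.set_index("variant_key")["fraction"]
        assert frac["3p+A"] == pytest.approx(0.25)


class TestSubstitutionDynamics:
    def test_no_substitutions_gives_zero_series(self):
        calls = pd.DataFrame(
            [("s1", "mirA", CANONICAL, 10), ("s2", "mirA", "3p+A", 5)],
            columns=["sample_id", "mature_id", "variant_key", "count"],
        )
        table = summarize_isomirs(calls, {"s1": "g1", "s2": "g2"})
        series = substitution_dynamics(table, "U", "G")
        assert (series["fraction"] == 0.0).all()
        assert set(series["group"]) == {"g1", "g2"}

    def test_quarter_of_reads_with_terminal_u_to_g(self):
        """A group where 25% of a miRNA's reads carry the U>G terminal
        substitution reports 0.25, the scale seen for the most affected
        miRNA in mid-development ovaries."""
        calls = pd.DataFrame(
            [("s1", "mirA", CANONICAL, 75), ("s1", "mirA", "s22:U>G!", 25),
             ("s2", "mirA", CANONICAL, 100)],
            columns=["sample_id", "mature_id", "variant_key", "count"],
        )
        table = summarize_isomirs(calls, {"s1": "g1", "s2": "g2"})
        series = substitution_dynamics(table, "U", "G").set_index("group")
        assert series.loc["g1", "fraction"] == pytest.approx(0.25)
        assert series.loc["g2", "fraction"] == 0.0

    def test_monotone_planted_gradient_recovered(self):
        fracs = {"g1": 0.05, "g2": 0.15, "g3": 0.30}
        rows = []
        for i, (g, f) in enumerate(fracs.items()):
            rows.append((f"s{i}", "mirA", CANONICAL, int(1000 * (1 - f))))
            rows.append((f"s{i}", "mirA", "s20:A>G!", int(1000 * f)))
        calls = pd.DataFrame(
            rows, columns=["sample_id", "mature_id", "variant_key", "count"]
        )
        table = summarize_isomirs(calls, {f"s{i}": g for i, g in
                                          enumerate(fracs)})
        series = substitution_dynamics(table, "A", "G").set_index("group")
        values = [series.loc[g, "fraction"] for g in ("g1", "g2", "g3")]
        assert values == sorted(values)
        assert values == pytest.approx(list(fracs.values()), abs=1e-9)

    def test_unknown_base_rejected(self):
        calls = pd.DataFrame(
            [("s1", "mirA", CANONICAL, 1)],
            columns=["sample_id", "mature_id", "variant_key", "count"],
        )
        table = summarize_isomirs(calls, {"s1": "g1"})
        with pytest.raises(ValidationError):
            substitution_dynamics(table, "X", "G")
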