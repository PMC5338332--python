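"""Rankings, ordination, titration correlation and empirical enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gonadmir.core import ValidationError
from gonadmir.report import (
    go_empirical_enrichment,
    ordination,
    titration_correlation,
    top_k_abundance,
)


def _norm(arr, samples):
    arr = np.asarray(arr, dtype=float)
    return pd.DataFrame(
        arr, index=[f"f{i}" for i in range(arr.shape[0])], columns=samples
    )


class TestTopK:
    def test_dominant_feature_tops_every_group(self):
        rng = np.random.default_rng(0)
        mat = rng.random((20, 6)) * 10
        mat[7] = 1000.0
        norm = _norm(mat, [f"s{j}" for j in range(6)])
        labels = pd.Series(["a"] * 3 + ["b"] * 3, index=norm.columns)
        ranking = top_k_abundance(norm, labels, k=1)
        assert ranking.top("a") == ["f7"] and ranking.top("b") == ["f7"]
        assert ranking.frequency["f7"] == 2

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(1)
        mat = rng.random((30, 8)) * 100
        samples = [f"s{j}" for j in range(8)]
        norm = _norm(mat, samples)
        labels = pd.Series(["a"] * 4 + ["b"] * 4, index=samples)
        shuffled = norm[list(np.array(samples)[rng.permutation(8)])]
        r1 = top_k_abundance(norm, labels)
        r2 = top_k_abundance(shuffled, labels)
        for g in r1.rankings:
            assert [f for f, _ in r1.rankings[g]] == [f for f, _ in r2.rankings[g]]
            assert np.allclose(
                [v for _, v in r1.rankings[g]], [v for _, v in r2.rankings[g]]
            )
        assert r1.frequency.equals(r2.frequency)

    def test_ties_break_lexicographically(self):
        norm = _norm([[5.0], [5.0], [1.0]], ["s0"])
        labels = pd.Series(["g"], index=["s0"])
        ranking = top_k_abundance(norm, labels, k=2)
        assert ranking.top("g") == ["f0", "f1"]

    def test_k_beyond_features_rejected(self):
        norm = _norm([[1.0], [2.0]], ["s0"])
        with pytest.raises(ValidationError):
            top_k_abundance(norm, pd.Series(["g"], index=["s0"]), k=3)


class TestOrdination:
    def test_identical_samples_identical_coordinates(self):
        rng = np.random.default_rng(2)
        col = rng.random(40) * 50
        norm = _norm(np.column_stack([col, col, col * 3]), ["a", "b", "c"])
        result = ordination(norm)
        assert np.allclose(
            result.coordinates.loc["a"], result.coordinates.loc["b"]
        )

    def test_variance_explained_is_a_partition(self):
        rng = np.random.default_rng(3)
        norm = _norm(rng.random((50, 8)) * 100, [f"s{j}" for j in range(8)])
        result = ordination(norm)
        assert result.variance_explained.sum() <= 1.0 + 1e-12
        assert (result.variance_explained >= 0).all()
        assert result.variance_explained[0] >= result.variance_explained[1]

    def test_group_shift_separates_on_first_component(self):
        rng = np.random.default_rng(4)
        base = rng.lognormal(4, 1, size=(100, 1))
        a = base * rng.lognormal(0, 0.1, size=(100, 5))
        b = base * rng.lognormal(0, 0.1, size=(100, 5))
        b[:30] *= 8.0  # planted mean shift in group b
        norm = _norm(np.hstack([a, b]), [f"s{j}" for j in range(10)])
        coords = ordination(norm).coordinates["PC1"]
        ga, gb = coords.iloc[:5], coords.iloc[5:]
        gap = abs(ga.mean() - gb.mean())
        spread = max(ga.std(ddof=1), gb.std(ddof=1))
        assert gap > 2 * spread

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValidationError):
            ordination(_norm(np.ones((5, 4)), list("abcd")))
        with pytest.raises(ValidationError):
            ordination(_norm(np.ones((5, 2)), list("ab")))

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(5)
        samples = [f"s{j}" for j in range(6)]
        norm = _norm(rng.random((30, 6)) * 10, samples)
        perm = list(np.array(samples)[rng.permutation(6)])
        c1 = ordination(norm).coordinates
        c2 = ordination(norm[perm]).coordinates
        assert np.allclose(c1.loc[samples], c2.loc[samples])


class TestTitration:
    def test_identical_libraries_correlate_perfectly(self):
        rng = np.random.default_rng(6)
        a = pd.Series(rng.integers(1, 5000, 50).astype(float),
                      index=[f"f{i}" for i in range(50)])
        res = titration_correlation(a, a.copy())
        assert res.r == pytest.approx(1.0)
        assert res.dropouts == []

    def test_scale_free(self):
        rng = np.random.default_rng(7)
        a = pd.Series(rng.integers(1, 5000, 50).astype(float),
                      index=[f"f{i}" for i in range(50)])
        res = titration_correlation(a, 0.5 * a)
        assert res.r == pytest.approx(1.0)

    def test_matches_direct_formula(self):
        """r on a 10% subsample equals a literal Pearson transcription."""
        rng = np.random.default_rng(8)
        a = pd.Series(rng.lognormal(6, 1.5, 80),
                      index=[f"f{i}" for i in range(80)]).round()
        b = pd.Series(rng.binomial(a.astype(int), 0.1).astype(float),
                      index=a.index)
        res = titration_correlation(a, b)
        rpm_a, rpm_b = a / a.sum() * 1e6, b / b.sum() * 1e6
        mask = (rpm_a > 100) & (b > 0)
        x, y = np.log2(rpm_a[mask]), np.log2(rpm_b[mask])
        n = len(x)
        r_literal = (
            (n * (x * y).sum() - x.sum() * y.sum())
            / np.sqrt(n * (x**2).sum() - x.sum() ** 2)
            / np.sqrt(n * (y**2).sum() - y.sum() ** 2)
        )
        assert res.r == pytest.approx(float(r_literal), abs=1e-9)

    def test_dropouts_reported(self):
        a = pd.Series([4000.0, 3000.0, 2000.0, 900.0, 100.0],
                      index=list("abcde"))
        b = pd.Series([4100.0, 0.0, 1900.0, 850.0, 150.0], index=list("abcde"))
        res = titration_correlation(a, b)
        assert res.dropouts == ["b"]

    def test_too_few_features_rejected(self):
        a = pd.Series([100.0, 100.0], index=["a", "b"])
        with pytest.raises(ValidationError):
            titration_correlation(a, a)


class TestEnrichment:
    UNIVERSE = [f"g{i}" for i in range(50)]

    def test_disjoint_term_has_p_one(self):
        targets = self.UNIVERSE[:10]
        go = {"GO:far": set(self.UNIVERSE[40:45])}
        res = go_empirical_enrichment(targets, go, self.UNIVERSE,
                                      n_samples=500, seed=1)
        # observed overlap 0 can never be exceeded downward: p must be 1
        assert res.loc[0, "observed_overlap"] == 0
        assert res.loc[0, "p_value"] == pytest.approx(1.0)

    def test_perfect_term_attains_minimum_p(self):
        targets = self.UNIVERSE[:10]
        go = {"GO:self": set(targets)}
        n = 2000
        res = go_empirical_enrichment(targets, go, self.UNIVERSE,
                                      n_samples=n, seed=2)
        assert res.loc[0, "p_value"] == pytest.approx(1.0 / (n + 1))

    def test_seeded_reproducibility(self):
        targets = self.UNIVERSE[:8]
        go = {"GO:a": set(self.UNIVERSE[4:20]), "GO:b": set(self.UNIVERSE[30:40])}
        r1 = go_empirical_enrichment(targets, go, self.UNIVERSE,
                                     n_samples=3000, seed=42)
        r2 = go_empirical_enrichment(targets, go, self.UNIVERSE,
                                     n_samples=3000, seed=42)
        pd.testing.assert_frame_equal(r1, r2)

    def test_converges_to_hypergeometric_tail(self):
        """Empirical p within 3 sigma of the exact hypergeometric tail."""
        targets = self.UNIVERSE[:10]
        go = {
            "GO:mid": set(self.UNIVERSE[5:25]),
            "GO:small": set(self.UNIVERSE[8:14]),
        }
        n = 20_000
        res = go_empirical_enrichment(targets, go, self.UNIVERSE,
                                      n_samples=n, seed=3).set_index("term")
        for term, genes in go.items():
            obs = len(set(targets) & genes)
            exact = float(stats.hypergeom.sf(obs - 1, 50, len(genes), 10))
            sigma = np.sqrt(exact * (1 - exact) / n)
            assert abs(res.loc[term, "p_value"] - exact) <= 3 * sigma + 2 / n

    def test_validation_errors(self):
        with pytest.raises(ValidationError):
            go_empirical_enrichment(["gX"], {"GO:a": {"g1"}}, self.UNIVERSE,
                                    n_samples=10, seed=0)
        with pytest.raises(ValidationError):
            go_empirical_enrichment(self.UNIVERSE[:5], {"GO:a": set()},
                                    self.UNIVERSE, n_samples=10, seed=0)
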