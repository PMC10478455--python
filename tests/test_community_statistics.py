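import math

import numpy as np
import pandas as pd
import pytest

from snowassembly.community_data import CommunityMatrix
from snowassembly.community_statistics import (
    chao1,
    correlation_matrix,
    diversity_table,
    hellinger_transform,
    mantel_rm,
    permutation_anova,
    rarefaction_curve,
    rda,
    rda_with_tests,
    shannon,
)


class TestShannon:
    def test_uniform_four(self):
        assert shannon([10, 10, 10, 10]) == pytest.approx(math.log(4))

    def test_single_taxon(self):
        assert shannon([42]) == 0.0

    def test_arithmetic(self):
        assert shannon([2, 1, 1]) == pytest.approx(1.0397, abs=1e-4)

    def test_base_option(self):
        assert shannon([1, 1], base=2) == pytest.approx(1.0)

    def test_bounded_by_log_richness(self, rng):
        for _ in range(50):
            c = rng.integers(0, 20, size=8)
            if c.sum() == 0:
                continue
            s = int((c > 0).sum())
            assert -1e-12 <= shannon(c) <= math.log(max(s, 1)) + 1e-12


class TestChao1:
    def test_no_singletons_gives_observed(self):
        assert chao1([5, 3, 2, 0]) == 3.0

    def test_formula_arithmetic(self):
        # 10 observed taxa, 4 singletons, 2 doubletons
        counts = [1, 1, 1, 1, 2, 2, 5, 5, 5, 5]
        assert chao1(counts) == pytest.approx(10 + 4 * 3 / (2 * 3))

    def test_at_least_observed(self, rng):
        for _ in range(50):
            c = rng.integers(0, 10, size=12)
            if c.sum() == 0:
                continue
            assert chao1(c) >= (np.asarray(c) > 0).sum()

    def test_non_integer_rejected(self):
        with pytest.raises(ValueError):
            chao1([1.5, 2.0])


class TestRarefaction:
    def test_full_depth_gives_observed(self):
        c = [5, 3, 0, 2]
        assert rarefaction_curve(c, [10])[0] == pytest.approx(3.0)

    def test_depth_one(self):
        assert rarefaction_curve([4, 4, 4], [1])[0] == pytest.approx(1.0)

    def test_depth_beyond_total_rejected(self):
        with pytest.raises(ValueError):
            rarefaction_curve([2, 2], [5])

    def test_matches_subsampling_oracle(self, rng):
        counts = np.array([12, 7, 3, 1, 1, 0, 25])
        n = 20
        expected = rarefaction_curve(counts, [n])[0]
        pool = np.repeat(np.arange(len(counts)), counts)
        reps = 8000
        richness = np.empty(reps)
        for r in range(reps):
            sub = rng.choice(pool, size=n, replace=False)
            richness[r] = len(np.unique(sub))
        mc_err = richness.std(ddof=1) / math.sqrt(reps)
        assert expected == pytest.approx(richness.mean(), abs=4 * mc_err)

    def test_monotone_in_depth(self):
        c = [9, 4, 2, 1]
        vals = rarefaction_curve(c, [1, 4, 8, 16])
        assert np.all(np.diff(vals) >= -1e-12)


class TestHellinger:
    def test_unit_sum_of_squares(self, small_counts):
        h = hellinger_transform(small_counts)
        assert np.allclose((h**2).sum(axis=1), 1.0, atol=1e-12)

    def test_examples(self):
        cm = CommunityMatrix(pd.DataFrame({"a": [1, 1, 1, 1], "b": [4, 0, 0, 0]}, index=list("wxyz")))
        h = hellinger_transform(cm)
        assert np.allclose(h.loc["a"], 0.5)
        assert h.loc["b", "w"] == 1.0 and h.loc["b", "x"] == 0.0

    def test_orthogonal_extremes_distance(self):
        cm = CommunityMatrix(pd.DataFrame({"a": [3, 0], "b": [0, 7]}, index=["t1", "t2"]))
        h = hellinger_transform(cm).to_numpy()
        assert np.linalg.norm(h[0] - h[1]) == pytest.approx(math.sqrt(2))


class TestRda:
    def test_orthogonal_constraints_explain_nothing(self, rng):
        n = 30
        Y = pd.DataFrame(rng.standard_normal((n, 5)))
        x = np.repeat([1.0, -1.0], n // 2)
        Y.iloc[:, 0] = x + 0.01 * rng.standard_normal(n)
        X = pd.DataFrame({"v": rng.standard_normal(n)})
        res = rda(Y, X)
        assert res.constrained_variance_fraction < 0.2

    def test_perfect_linear_response(self, rng):
        n = 20
        X = pd.DataFrame({"a": rng.standard_normal(n), "b": rng.standard_normal(n)})
        B = rng.standard_normal((2, 6))
        Y = pd.DataFrame(X.to_numpy() @ B)
        res = rda(Y, X)
        assert res.constrained_variance_fraction == pytest.approx(1.0, abs=1e-10)

    def test_single_variable_matches_ols_r2(self, rng):
        n = 25
        x = rng.standard_normal(n)
        Y = pd.DataFrame(
            np.outer(x, rng.standard_normal(4)) + rng.standard_normal((n, 4))
        )
        res = rda(Y, pd.DataFrame({"x": x}))
        # oracle: per-column simple-regression explained SS over total SS
        xc = x - x.mean()
        Yc = Y.to_numpy() - Y.to_numpy().mean(axis=0)
        ss_fit = sum(
            (np.dot(xc, Yc[:, j]) / np.dot(xc, xc)) ** 2 * np.dot(xc, xc)
            for j in range(Yc.shape[1])
        )
        assert res.constrained_variance_fraction == pytest.approx(
            ss_fit / (Yc**2).sum(), abs=1e-10
        )

    def test_collinear_column_dropped_with_warning(self, rng):
        n = 20
        a = rng.standard_normal(n)
        X = pd.DataFrame({"a": a, "b": 2 * a})
        Y = pd.DataFrame(rng.standard_normal((n, 3)))
        with pytest.warns(UserWarning, match="rank-deficient"):
            res = rda(Y, X)
        assert list(res.variable_scores.index) == ["a"]

    def test_matches_vegan_reference(self, tmp_path, rng):
        """Cross-check constrained variance and marginal F against R vegan."""
        import shutil
        import subprocess

        if shutil.which("Rscript") is None:
            pytest.skip("Rscript unavailable")
        n = 16
        X = pd.DataFrame(
            {"a": rng.standard_normal(n), "b": rng.standard_normal(n)}
        )
        Y = pd.DataFrame(
            np.outer(X["a"], rng.standard_normal(5)) * 0.8 + rng.standard_normal((n, 5))
        )
        Y.to_csv(tmp_path / "Y.csv", index=False)
        X.to_csv(tmp_path / "X.csv", index=False)
        script = tmp_path / "rda.R"
        script.write_text(
            "suppressMessages(library(vegan))\n"
            f"Y <- read.csv('{tmp_path}/Y.csv'); X <- read.csv('{tmp_path}/X.csv')\n"
            "m <- rda(Y ~ a + b, data = X)\n"
            "cat(summary(m)$constr.chi / summary(m)$tot.chi, '\\n')\n"
            "an <- anova(m, by = 'margin', permutations = 99)\n"
            "cat(an$F[1], an$F[2], '\\n')\n"
        )
        out = subprocess.run(
            ["Rscript", "--vanilla", str(script)], capture_output=True, text=True, timeout=120
        )
        if out.returncode != 0:
            pytest.skip(f"vegan unavailable: {out.stderr[:200]}")
        lines = out.stdout.strip().splitlines()
        frac_ref = float(lines[0].split()[0])
        f_ref = [float(v) for v in lines[1].split()]
        res = rda(Y, X)
        assert res.constrained_variance_fraction == pytest.approx(frac_ref, abs=1e-6)
        fa, _ = permutation_anova(Y, X, "a", n_perm=9, seed=0)
        fb, _ = permutation_anova(Y, X, "b", n_perm=9, seed=0)
        assert fa == pytest.approx(f_ref[0], rel=1e-6)
        assert fb == pytest.approx(f_ref[1], rel=1e-6)


class TestPermutationAnova:
    def test_perfect_association_floor_p(self, rng):
        n = 24
        X = pd.DataFrame({"a": rng.standard_normal(n)})
        Y = pd.DataFrame(np.outer(X["a"], np.ones(4)))
        f, p = permutation_anova(Y, X, "a", n_perm=999, seed=0)
        assert p == pytest.approx(1 / 1000)

    def test_invariant_to_consistent_relabeling(self, rng):
        n = 20
        X = pd.DataFrame({"a": rng.standard_normal(n), "b": rng.standard_normal(n)})
        Y = pd.DataFrame(rng.standard_normal((n, 5)))
        f1, _ = permutation_anova(Y, X, "a", n_perm=49, seed=1)
        perm = rng.permutation(n)
        f2, _ = permutation_anova(Y.iloc[perm].reset_index(drop=True), X.iloc[perm].reset_index(drop=True), "a", n_perm=49, seed=1)
        assert f1 == pytest.approx(f2)

    def test_bad_nperm_rejected(self, rng):
        Y = pd.DataFrame(rng.standard_normal((10, 2)))
        X = pd.DataFrame({"a": rng.standard_normal(10)})
        with pytest.raises(ValueError):
            permutation_anova(Y, X, "a", n_perm=0)


class TestMantel:
    def test_proportional_distances(self, rng):
        d = rng.random(10)
        assert mantel_rm(d, 3.0 * d) == pytest.approx(1.0)

    def test_independent_distances_small(self, rng):
        a, b = rng.random(500), rng.random(500)
        assert abs(mantel_rm(a, b)) < 0.15

    def test_matches_manual_pearson(self, rng):
        a, b = rng.random(15), rng.random(15)
        am, bm = a - a.mean(), b - b.mean()
        manual = (am @ bm) / math.sqrt((am @ am) * (bm @ bm))
        assert mantel_rm(a, b) == pytest.approx(manual, abs=1e-12)

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            mantel_rm([1.0, 2.0], [1.0, 2.0])


class TestCorrelationMatrix:
    def test_scaled_profile(self, rng):
        base = rng.random(10)
        profiles = pd.DataFrame([base, 2 * base, -base], index=["p", "q", "r"])
        out = correlation_matrix(profiles)
        assert out.r.loc["p", "q"] == pytest.approx(1.0)
        assert out.r.loc["p", "r"] == pytest.approx(-1.0)
        assert bool(out.mask.loc["p", "q"])

    def test_zero_variance_masked(self, rng):
        profiles = pd.DataFrame(
            [rng.random(8), np.full(8, 3.0)], index=["p", "flat"]
        )
        with pytest.warns(UserWarning, match="zero-variance"):
            out = correlation_matrix(profiles)
        assert np.isnan(out.r.loc["p", "flat"])
        assert not bool(out.mask.loc["p", "flat"])

    def test_needs_three_samples(self):
        with pytest.raises(ValueError):
            correlation_matrix(pd.DataFrame([[1, 2], [3, 4]]))


def test_diversity_table_and_rda_with_tests(rng):
    counts = pd.DataFrame(
        rng.integers(0, 30, size=(12, 10)),
        index=[f"t{i}" for i in range(12)],
        columns=[f"s{i}" for i in range(10)],
    )
    counts.iloc[0] += 1
    cm = CommunityMatrix(counts)
    div = diversity_table(cm)
    assert set(div.columns) == {"shannon", "chao1", "observed"}
    assert (div["chao1"] >= div["observed"]).all()

    Y = hellinger_transform(cm)
    X = pd.DataFrame(
        rng.standard_normal((10, 2)), index=Y.index, columns=["nh4", "doc"]
    )
    res = rda_with_tests(Y, X, n_perm=49, seed=1)
    assert set(res.terms["term"]) == {"nh4", "doc"}
    assert ((res.terms["p"] > 0) & (res.terms["p"] <= 1)).all()
    assert -1.0 <= res.rm <= 1.0
    assert 0.0 <= res.constrained_variance_fraction <= 1.0
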