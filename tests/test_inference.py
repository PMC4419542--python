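"""Welch t, label-permutation disparity test, and PERMANOVA."""

import itertools
import subprocess
import textwrap

import numpy as np
import pytest
from scipy import stats

from morphdiv.disparity import family_disparity
from morphdiv.inference import np_manova, permutation_disparity_test, welch_t


def welch_oracle(a, b):
    """Independent implementation of the Welch formulas."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return t, df, p


class TestWelch:
    def test_identical_samples_give_t_zero_p_one(self):
        t, df, p = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0
        assert p == pytest.approx(1.0)

    def test_matches_formula_oracle(self):
        a, b = [10.0, 12.0, 14.0, 16.0], [11.0, 13.0, 15.0]
        t, df, p = welch_t(a, b)
        to, dfo, po = welch_oracle(a, b)
        assert t == pytest.approx(to, abs=1e-10)
        assert df == pytest.approx(dfo, abs=1e-10)
        assert p == pytest.approx(po, abs=1e-10)
        assert df != int(df)  # Satterthwaite df is fractional here

    def test_random_samples_match_oracle(self, rng):
        for _ in range(20):
            a = rng.normal(size=rng.integers(3, 12))
            b = rng.normal(loc=0.5, size=rng.integers(3, 12))
            got = welch_t(a, b)
            want = welch_oracle(a, b)
            np.testing.assert_allclose(got, want, atol=1e-10)

    def test_errors(self):
        with pytest.raises(ValueError, match="at least 2"):
            welch_t([1.0], [1.0, 2.0])
        with pytest.raises(ValueError, match="zero variance"):
            welch_t([2.0, 2.0], [3.0, 3.0])


class TestPermutationDisparity:
    def test_identical_scores_give_p_one(self):
        scores = np.ones((7, 3))
        res = permutation_disparity_test(scores, ["A"] * 4 + ["B"] * 3,
                                         n_perm=99, seed=0)
        assert res.observed_difference == 0.0
        assert res.p_value == 1.0
        assert res.null_min == res.null_max == 0.0

    def test_matches_exhaustive_enumeration(self, rng):
        scores = rng.normal(size=(5, 2))
        labels = np.array(["A", "A", "A", "B", "B"])
        res = permutation_disparity_test(scores, labels, n_perm=10_000, seed=3)

        def diff(mask):
            da = family_disparity(scores, mask).mean
            db = family_disparity(scores, ~mask).mean
            return da - db

        obs = diff(labels == "A")
        diffs = []
        for combo in itertools.combinations(range(5), 3):
            mask = np.zeros(5, dtype=bool)
            mask[list(combo)] = True
            diffs.append(diff(mask))
        p_exact = np.mean(np.abs(diffs) >= abs(obs) - 1e-15)
        se = np.sqrt(p_exact * (1 - p_exact) / 10_000)
        assert res.observed_difference == pytest.approx(obs, abs=1e-12)
        assert abs(res.p_value - p_exact) <= 3 * se + 2e-4

    def test_p_invariant_to_family_relabelling(self, rng):
        scores = rng.normal(size=(12, 3))
        labels = ["A"] * 7 + ["B"] * 5
        r1 = permutation_disparity_test(scores, labels, n_perm=499, seed=11,
                                        family_order=["A", "B"])
        r2 = permutation_disparity_test(scores, labels, n_perm=499, seed=11,
                                        family_order=["B", "A"])
        assert r1.observed_difference == pytest.approx(-r2.observed_difference)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_reproducible_given_seed(self, rng):
        scores = rng.normal(size=(10, 2))
        labels = ["A"] * 6 + ["B"] * 4
        r1 = permutation_disparity_test(scores, labels, n_perm=200, seed=5)
        r2 = permutation_disparity_test(scores, labels, n_perm=200, seed=5)
        np.testing.assert_array_equal(r1.null_differences, r2.null_differences)

    def test_detects_strong_dispersion_difference(self, rng):
        scores = np.vstack([rng.normal(scale=3.0, size=(15, 4)),
                            rng.normal(scale=1.0, size=(12, 4))])
        labels = ["wide"] * 15 + ["narrow"] * 12
        res = permutation_disparity_test(scores, labels, n_perm=999, seed=1)
        assert res.p_value <= 0.05
        assert res.observed_difference > 0

    def test_group_size_guard(self, rng):
        with pytest.raises(ValueError, match="at least 2"):
            permutation_disparity_test(rng.normal(size=(3, 2)),
                                       ["A", "A", "B"], n_perm=10, seed=0)


class TestNpManova:
    def test_univariate_two_groups_equals_classical_anova(self, rng):
        for _ in range(20):
            a = rng.normal(size=rng.integers(4, 10))
            b = rng.normal(loc=1.0, size=rng.integers(4, 10))
            scores = np.concatenate([a, b])[:, None]
            labels = ["A"] * len(a) + ["B"] * len(b)
            res = np_manova(scores, labels, n_perm=9, seed=0)
            f_ref = stats.f_oneway(a, b).statistic
            assert res.pseudo_F == pytest.approx(f_ref, abs=1e-10)

    def test_three_group_univariate_equals_classical_anova(self, rng):
        groups = [rng.normal(loc=i, size=6) for i in range(3)]
        scores = np.concatenate(groups)[:, None]
        labels = sum(([f"g{i}"] * 6 for i in range(3)), [])
        res = np_manova(scores, labels, n_perm=9, seed=0)
        assert res.pseudo_F == pytest.approx(stats.f_oneway(*groups).statistic,
                                             abs=1e-10)
        assert (res.df_between, res.df_within) == (2, 15)

    def test_minimal_p_is_one_over_nperm_plus_one(self, rng):
        scores = np.vstack([rng.normal(size=(10, 3)),
                            rng.normal(loc=50.0, size=(10, 3))])
        labels = ["A"] * 10 + ["B"] * 10
        res = np_manova(scores, labels, n_perm=999, seed=2)
        assert res.p_value == pytest.approx(1.0 / 1000)

    def test_r_squared_bounds_and_rotation_invariance(self, rng):
        scores = rng.normal(size=(14, 4))
        labels = ["A"] * 8 + ["B"] * 6
        res = np_manova(scores, labels, n_perm=99, seed=0)
        assert 0.0 <= res.r_squared <= 1.0
        from scipy.stats import ortho_group
        Q = ortho_group.rvs(4, random_state=0)
        res_rot = np_manova(scores @ Q, labels, n_perm=99, seed=0)
        assert res_rot.pseudo_F == pytest.approx(res.pseudo_F, abs=1e-10)
        assert res_rot.p_value == res.p_value

    def test_degenerate_data_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            np_manova(np.ones((6, 2)), ["A"] * 3 + ["B"] * 3, n_perm=9, seed=0)

    def test_small_group_guard(self, rng):
        with pytest.raises(ValueError, match="fewer than 2"):
            np_manova(rng.normal(size=(4, 2)), ["A", "A", "A", "B"],
                      n_perm=9, seed=0)

    def test_matches_vegan_adonis2_pseudo_f(self, rng, tmp_path):
        """Cross-check pseudo-F against the R vegan reference on a fixture."""
        scores = np.round(rng.normal(size=(9, 3)), 6)
        labels = ["A"] * 5 + ["B"] * 4
        res = np_manova(scores, labels, n_perm=9, seed=0)
        csv = tmp_path / "scores.csv"
        np.savetxt(csv, scores, delimiter=",")
        script = tmp_path / "permanova.R"
        script.write_text(textwrap.dedent(f"""
            suppressMessages(library(vegan))
            x <- as.matrix(read.csv("{csv}", header=FALSE))
            g <- factor(c(rep("A", 5), rep("B", 4)))
            fit <- adonis2(dist(x) ~ g, permutations=9)
            cat(sprintf("%.12f %.12f\\n", fit$F[1], fit$R2[1]))
        """))
        try:
            out = subprocess.run(["Rscript", "--vanilla", str(script)],
                                 capture_output=True, text=True, timeout=120)
        except (FileNotFoundError, subprocess.TimeoutExpired):
            pytest.skip("Rscript unavailable")
        assert out.returncode == 0, out.stderr
        f_ref, r2_ref = map(float, out.stdout.split())
        assert res.pseudo_F == pytest.approx(f_ref, abs=1e-6)
        assert res.r_squared == pytest.approx(r2_ref, abs=1e-6)
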