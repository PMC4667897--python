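"""Bray-Curtis, PERMANOVA and SIMPER against independent oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from trophicoverlap import community
from trophicoverlap.schemas import ValidationError


def _factors(levels, name="g"):
    return pd.DataFrame({name: list(levels)}, index=[f"s{i}" for i in range(len(levels))])


class TestTransformAndDistance:
    def test_sqrt_transform_basics(self):
        assert community.sqrt_transform(np.zeros((2, 3))).sum() == 0.0
        assert community.sqrt_transform(np.array([[4.0]]))[0, 0] == 2.0
        with pytest.raises(ValidationError):
            community.sqrt_transform(np.array([[-1.0]]))

    def test_sqrt_transform_not_idempotent(self):
        x = np.array([[4.0, 9.0]])
        once = community.sqrt_transform(x)
        assert not np.allclose(community.sqrt_transform(once), once)

    def test_identical_samples_zero_dissimilarity(self):
        d = community.zero_adjusted_bray_curtis(np.array([[1.0, 2.0], [1.0, 2.0]]))
        assert d[0, 1] == 0.0

    def test_two_empty_samples_similar_by_adjustment(self):
        d = community.zero_adjusted_bray_curtis(np.zeros((2, 2)), dummy_value=1.0)
        assert d[0, 1] == 0.0

    def test_hand_computed_value(self):
        # [1,0] vs [0,1] with dummy 1: 100*(1+1+0)/(1+1+2) = 50
        d = community.zero_adjusted_bray_curtis(np.array([[1.0, 0.0], [0.0, 1.0]]), 1.0)
        assert d[0, 1] == pytest.approx(50.0)

    def test_symmetry_zero_diagonal_and_range(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 5, size=(10, 6))
        d = community.zero_adjusted_bray_curtis(x)
        assert np.allclose(d, d.T)
        assert np.all(np.diag(d) == 0)
        assert d.min() >= 0 and d.max() <= 100

    def test_matches_scikit_bio_on_augmented_matrix(self):
        """Independent oracle: our zero-adjusted BC equals scikit-bio's
        plain Bray-Curtis on the dummy-augmented matrix (x100)."""
        skbio_distance = pytest.importorskip("skbio.diversity").beta_diversity
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 3, size=(8, 5))
        ours = community.zero_adjusted_bray_curtis(x, dummy_value=1.0)
        aug = np.column_stack([x, np.ones(8)])
        theirs = 100.0 * skbio_distance("braycurtis", aug).data
        assert np.allclose(ours, theirs, atol=1e-10)

    def test_nonpositive_dummy_rejected(self):
        with pytest.raises(ValidationError):
            community.zero_adjusted_bray_curtis(np.ones((2, 2)), dummy_value=0.0)


def _euclidean(x):
    x = np.asarray(x, dtype=float)[:, None] if np.ndim(x) == 1 else np.asarray(x)
    return np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2))


class TestPermanova:
    def test_pseudo_f_equals_classical_anova_f(self):
        """On univariate data with Euclidean distance the PERMANOVA
        pseudo-F is exactly the one-way ANOVA F."""
        rng = np.random.default_rng(4)
        y = np.concatenate([rng.normal(0, 1, 10), rng.normal(1.2, 1, 10)])
        g = ["a"] * 10 + ["b"] * 10
        res = community.permanova(_euclidean(y), _factors(g), ["g"], perms=9, seed=0)
        f_cls = stats.f_oneway(y[:10], y[10:]).statistic
        assert res.terms[0].pseudo_f == pytest.approx(f_cls, rel=1e-8)

    def test_permutation_p_matches_complete_enumeration(self):
        """n=6, 3 vs 3: exact p from all 20 label assignments."""
        y = np.array([0.1, 0.5, 0.9, 2.0, 2.6, 3.1])
        g = np.array(["a"] * 3 + ["b"] * 3)
        d = _euclidean(y)

        def f_stat(labels):
            r = community.permanova(d, _factors(labels), ["g"], perms=1, seed=0)
            return r.terms[0].pseudo_f

        f_obs = f_stat(g)
        fs = [f_stat(np.array(["a" if i in comb else "b" for i in range(6)]))
              for comb in itertools.combinations(range(6), 3)]
        p_exact = np.mean([f >= f_obs - 1e-12 for f in fs])
        reps = 20_000
        res = community.permanova(d, _factors(g), ["g"], perms=reps, seed=3)
        se = np.sqrt(p_exact * (1 - p_exact) / reps)
        assert abs(res.terms[0].p_perm - p_exact) < 3 * se + 1 / (reps + 1)

    def test_all_identical_samples_zero_f(self):
        d = np.zeros((8, 8))
        res = community.permanova(d, _factors(["a", "b"] * 4), ["g"], perms=19, seed=0)
        assert res.terms[0].ss == pytest.approx(0.0, abs=1e-10)
        assert res.terms[0].pseudo_f == 0.0

    def test_sequential_ss_partition_sums_to_total(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(0, 4, size=(24, 5))
        fac = pd.DataFrame({
            "a": rng.choice(["u", "v"], 24),
            "b": rng.choice(["x", "y", "z"], 24),
        }, index=[f"s{i}" for i in range(24)])
        d = community.zero_adjusted_bray_curtis(x)
        res = community.permanova(d, fac, ["a", "b", "a:b"], perms=9, seed=1)
        parts = sum(t.ss for t in res.terms) + res.residual_ss
        assert parts == pytest.approx(res.total_ss, rel=1e-8)
        assert sum(t.df for t in res.terms) + res.residual_df == res.total_df

    def test_matches_scikit_bio_one_way_statistic(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(9)
        x = rng.uniform(0, 3, size=(15, 4))
        g = list(rng.choice(["a", "b", "c"], 15))
        d = community.zero_adjusted_bray_curtis(x)
        ours = community.permanova(d, _factors(g), ["g"], perms=9, seed=0)
        dm = skbio.DistanceMatrix(d, ids=[f"s{i}" for i in range(15)])
        theirs = skbio.stats.distance.permanova(dm, grouping=g, permutations=9)
        assert ours.terms[0].pseudo_f == pytest.approx(theirs["test statistic"], rel=1e-8)

    def test_single_level_factor_rejected(self):
        with pytest.raises(ValidationError, match="single level"):
            community.permanova(np.zeros((4, 4)), _factors(["a"] * 4), ["g"],
                                perms=9, seed=0)

    def test_null_uniformity_of_p_values(self):
        """Rejection rate at alpha=0.05 under an exchangeable null stays in
        the binomial 99% band (light version of the calibration check)."""
        rng = np.random.default_rng(12)
        rejections = 0
        n_sim = 400
        for i in range(n_sim):
            x = rng.uniform(0, 2, size=(12, 3))
            g = ["a"] * 6 + ["b"] * 6
            d = community.zero_adjusted_bray_curtis(x)
            res = community.permanova(d, _factors(g), ["g"], perms=99, seed=1000 + i)
            rejections += res.terms[0].p_perm <= 0.05
        half = 2.576 * np.sqrt(0.05 * 0.95 / n_sim)
        assert abs(rejections / n_sim - 0.05) < half + 0.01  # p-grid coarseness at 99 perms


class TestPairwise:
    def test_identical_groups_large_p(self):
        x = np.tile(np.array([[1.0, 2.0, 3.0]]), (8, 1))
        d = community.zero_adjusted_bray_curtis(x)
        res = community.pairwise_permanova(d, _factors(["a"] * 4 + ["b"] * 4), "g",
                                           ("a", "b"), perms=99, seed=0)
        assert res.terms[0].p_perm > 0.5

    def test_third_level_is_ignored(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 2, size=(12, 4))
        fac = _factors(["a"] * 4 + ["b"] * 4 + ["c"] * 4)
        d1 = community.zero_adjusted_bray_curtis(x)
        x2 = x.copy()
        x2[8:] = rng.uniform(5, 9, size=(4, 4))  # perturb only level c
        d2 = community.zero_adjusted_bray_curtis(x2)
        r1 = community.pairwise_permanova(d1, fac, "g", ("a", "b"), perms=49, seed=7)
        r2 = community.pairwise_permanova(d2, fac, "g", ("a", "b"), perms=49, seed=7)
        assert r1.terms[0].pseudo_f == pytest.approx(r2.terms[0].pseudo_f)
        assert r1.terms[0].p_perm == r2.terms[0].p_perm

    def test_power_on_separated_groups(self):
        """A >=2 SD multivariate location shift is detected (p <= 0.01)
        in at least 95% of simulated datasets."""
        rng = np.random.default_rng(21)
        hits = 0
        n_sim = 200
        for i in range(n_sim):
            a = rng.normal(2.0, 0.5, size=(10, 4)).clip(0)
            b = rng.normal(4.0, 0.5, size=(10, 4)).clip(0)  # 4 SD shift
            d = community.zero_adjusted_bray_curtis(np.vstack([a, b]))
            res = community.pairwise_permanova(
                d, _factors(["a"] * 10 + ["b"] * 10), "g", ("a", "b"),
                perms=999, seed=5000 + i)
            hits += res.terms[0].p_perm <= 0.01
        assert hits >= 0.95 * n_sim

    def test_small_level_rejected(self):
        with pytest.raises(ValidationError, match="fewer than 2"):
            community.pairwise_permanova(np.zeros((3, 3)),
                                         _factors(["a", "a", "b"]), "g",
                                         ("a", "b"), perms=9, seed=0)


class TestSimper:
    def test_one_vs_one_hand_example(self):
        res = community.simper(np.array([[1.0, 0.0], [0.0, 1.0]]), ["x", "y"],
                               ["a", "b"], ("a", "b"), dummy_value=1.0)
        assert res.contributions["x"] == pytest.approx(25.0)
        assert res.contributions["y"] == pytest.approx(25.0)
        assert res.contributions[community.DUMMY_VARIABLE] == 0.0
        assert res.average_dissimilarity == pytest.approx(50.0)

    def test_shared_constant_variable_contributes_zero(self):
        x = np.array([[3.0, 0.0], [3.0, 0.0], [3.0, 0.0], [3.0, 0.0]])
        res = community.simper(x, ["v", "w"], ["a", "a", "b", "b"], ("a", "b"),
                               dummy_value=1.0)
        assert res.contributions["v"] == 0.0

    def test_contributions_sum_to_mean_between_group_dissimilarity(self):
        rng = np.random.default_rng(2)
        for trial in range(10):
            x = rng.uniform(0, 3, size=(9, 4))
            g = np.array(["a"] * 4 + ["b"] * 5)
            res = community.simper(x, list("wxyz"), g, ("a", "b"), dummy_value=1.0)
            d = community.zero_adjusted_bray_curtis(x, dummy_value=1.0)
            between = d[np.ix_(g == "a", g == "b")].mean()
            assert res.contributions.sum() == pytest.approx(between, abs=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError, match="empty group"):
            community.simper(np.ones((2, 2)), ["x", "y"], ["a", "a"], ("a", "b"))
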