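import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mgwaskit import association

from conftest import make_cohort


def spearman_enumeration_p(x, y):
    """Oracle: exact two-sided p by enumerating all rank permutations."""
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    rho = np.corrcoef(rx, ry)[0, 1]
    null = [np.corrcoef(rx, np.array(perm))[0, 1]
            for perm in itertools.permutations(ry)]
    return np.mean([abs(v) >= abs(rho) - 1e-12 for v in null])


def permanova_coordinate_oracle(points, labels):
    """Pseudo-F via the centroid identity on Euclidean coordinates."""
    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    grand = points.mean(axis=0)
    sst = ((points - grand) ** 2).sum()
    ssw = 0.0
    for g in np.unique(labels):
        sub = points[labels == g]
        ssw += ((sub - sub.mean(axis=0)) ** 2).sum()
    ssa = sst - ssw
    a, n = len(np.unique(labels)), len(labels)
    return (ssa / (a - 1)) / (ssw / (n - a))


class TestSpearman:
    def test_exact_matches_enumeration(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=6), rng.normal(size=6)
        rho, p = association.spearman_rho_p(x, y)
        assert rho == pytest.approx(stats.spearmanr(x, y).statistic)
        assert p == pytest.approx(spearman_enumeration_p(x, y))

    def test_large_n_t_approximation(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=40), rng.normal(size=40)
        rho, p = association.spearman_rho_p(x, y)
        ref = stats.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)


class TestMlgNetwork:
    def _mat(self, rows, ids=None):
        ids = ids or [f"m{i}" for i in range(len(rows))]
        return pd.DataFrame(rows, index=ids, columns=[f"s{i}" for i in range(len(rows[0]))])

    def test_identical_profiles_edge(self):
        mat = self._mat([[1, 2, 3, 4], [1, 2, 3, 4], [4, 1, 3, 2]])
        edges = association.mlg_network(mat, rho_cut=0.9)
        assert len(edges) == 1
        assert edges.iloc[0]["rho"] == pytest.approx(1.0)
        assert edges.iloc[0]["sign"] == "positive"

    def test_hand_negative_edge(self):
        mat = self._mat([[1, 2, 3, 4], [4, 3, 2, 1]])
        edges = association.mlg_network(mat)
        assert edges.iloc[0]["rho"] == pytest.approx(-1.0)
        assert edges.iloc[0]["sign"] == "negative"

    def test_rho_cut_one_no_edges(self):
        mat = self._mat([[1, 2, 3, 4], [1, 2, 3, 4]])
        assert association.mlg_network(mat, rho_cut=1.0).empty

    def test_strict_inequality_at_cut(self):
        # ranks (1..5) vs (4,1,2,3,5): sum d^2 = 12 -> rho = 1 - 72/120 = 0.4 exactly
        mat = self._mat([[1, 2, 3, 4, 5], [4, 1, 2, 3, 5]])
        rho = stats.spearmanr(mat.iloc[0], mat.iloc[1]).statistic
        assert rho == pytest.approx(0.4)
        assert association.mlg_network(mat, rho_cut=0.4).empty

    def test_constant_profile_skipped(self):
        mat = self._mat([[1, 1, 1, 1], [1, 2, 3, 4], [2, 3, 4, 5]])
        edges = association.mlg_network(mat, rho_cut=0.5)
        assert len(edges) == 1
        assert set(edges.iloc[0][["mlg_a", "mlg_b"]]) == {"m1", "m2"}

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        mat = self._mat(list(rng.random((5, 10))))
        e1 = association.mlg_network(mat)
        e2 = association.mlg_network(np.exp(mat * 3))
        pd.testing.assert_frame_equal(e1, e2)

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            association.mlg_network(self._mat([[1, 2], [2, 1]]))


class TestGrossAbundanceRatio:
    def test_equal_gross_abundance_ratio_one(self):
        mat = pd.DataFrame([[0.2, 0.3], [0.2, 0.3]], index=["a", "b"], columns=["s1", "s2"])
        directions = pd.Series({"a": "case-enriched", "b": "control-enriched"})
        np.testing.assert_allclose(
            association.gross_abundance_ratio(mat, directions).to_numpy(), 1.0
        )

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        mat = pd.DataFrame(rng.random((4, 6)), index=list("abcd"))
        directions = pd.Series(
            {"a": "case-enriched", "b": "case-enriched",
             "c": "control-enriched", "d": "none"}
        )
        r1 = association.gross_abundance_ratio(mat, directions)
        r2 = association.gross_abundance_ratio(mat * 7.3, directions)
        np.testing.assert_allclose(r1.to_numpy(), r2.to_numpy())

    def test_missing_direction_error(self):
        mat = pd.DataFrame([[1.0, 2.0]], index=["a"], columns=["s1", "s2"])
        with pytest.raises(ValueError):
            association.gross_abundance_ratio(mat, pd.Series({"a": "case-enriched"}))

    def test_zero_denominator_missing(self):
        mat = pd.DataFrame([[1.0, 1.0], [0.0, 2.0]], index=["a", "b"], columns=["s1", "s2"])
        directions = pd.Series({"a": "case-enriched", "b": "control-enriched"})
        out = association.gross_abundance_ratio(mat, directions)
        assert np.isnan(out["s1"]) and out["s2"] == pytest.approx(0.5)


class TestFeaturePhenotypeCorrelation:
    def test_self_correlation_marked(self):
        n = 12
        cohort = make_cohort([f"s{i}" for i in range(n)], ["case"] * 6 + ["control"] * 6,
                             glucose_0=np.arange(n, dtype=float) + 4)
        abund = pd.DataFrame([np.arange(n, dtype=float) + 1], index=["f1"],
                             columns=cohort.index)
        out = association.feature_phenotype_correlation(abund, cohort, min_mean_abund=0)
        row = out[(out["feature_id"] == "f1") & (out["phenotype"] == "glucose_0")].iloc[0]
        assert row["rho"] == pytest.approx(1.0)
        assert row["mark"] == "++"

    def test_filter_exhausts_input(self):
        cohort = make_cohort([f"s{i}" for i in range(6)], ["case"] * 3 + ["control"] * 3)
        abund = pd.DataFrame([np.full(6, 1e-8)], index=["f1"], columns=cohort.index)
        out = association.feature_phenotype_correlation(abund, cohort, min_mean_abund=1e-5)
        assert out.empty

    def test_null_mostly_unmarked(self):
        rng = np.random.default_rng(8)
        n, n_feat = 30, 200
        cohort = make_cohort([f"s{i}" for i in range(n)], ["case"] * 15 + ["control"] * 15,
                             glucose_0=rng.normal(5, 0.5, n))
        abund = pd.DataFrame(rng.random((n_feat, n)),
                             index=[f"f{i}" for i in range(n_feat)], columns=cohort.index)
        out = association.feature_phenotype_correlation(
            abund, cohort, min_mean_abund=0, phenotypes=["glucose_0"]
        )
        marked = out["feature_id"].nunique()
        assert marked / n_feat <= 0.05  # >= 95% of features unmarked


class TestBrayCurtis:
    def test_identity(self):
        ab = pd.DataFrame({"s1": [0.5, 0.5], "s2": [0.5, 0.5]})
        assert association.bray_curtis(ab).loc["s1", "s2"] == 0.0

    def test_disjoint_supports(self):
        ab = pd.DataFrame({"s1": [1.0, 0.0], "s2": [0.0, 1.0]})
        assert association.bray_curtis(ab).loc["s1", "s2"] == pytest.approx(1.0)

    def test_hand_value(self):
        ab = pd.DataFrame({"s1": [0.5, 0.5], "s2": [1.0, 0.0]})
        assert association.bray_curtis(ab).loc["s1", "s2"] == pytest.approx(0.5)

    def test_symmetry_and_range(self, rng):
        ab = pd.DataFrame(rng.random((6, 5)))
        d = association.bray_curtis(ab).to_numpy()
        np.testing.assert_allclose(d, d.T)
        assert (d >= 0).all() and (d <= 1).all()
        np.testing.assert_allclose(np.diag(d), 0)

    def test_two_zero_samples_error(self):
        ab = pd.DataFrame({"s1": [0.0, 0.0], "s2": [0.0, 0.0], "s3": [1.0, 0.0]})
        with pytest.raises(ValueError):
            association.bray_curtis(ab)


class TestPermanova:
    def _setup(self, sep=0.0, n=8, seed=0):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(n, 3))
        pts[: n // 2] += sep
        labels = ["case"] * (n // 2) + ["control"] * (n // 2)
        ids = [f"s{i}" for i in range(n)]
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        dist = pd.DataFrame(d, index=ids, columns=ids)
        cohort = make_cohort(ids, labels)
        return pts, labels, dist, cohort

    def test_pseudo_f_matches_coordinate_oracle(self):
        pts, labels, dist, cohort = self._setup(sep=1.0, n=8, seed=2)
        f_obs = association.permanova_pseudo_f(dist, np.array(labels))
        assert f_obs == pytest.approx(permanova_coordinate_oracle(pts, labels))

    def test_exhaustive_enumeration_p(self):
        # p from random permutations approaches the exhaustive label-assignment p
        pts, labels, dist, cohort = self._setup(sep=1.2, n=8, seed=3)
        f_obs = association.permanova_pseudo_f(dist, np.array(labels))
        fs = []
        for idx in itertools.combinations(range(8), 4):
            lab = np.array(["control"] * 8, dtype=object)
            lab[list(idx)] = "case"
            fs.append(association.permanova_pseudo_f(dist, lab))
        exact_p = np.mean([f >= f_obs - 1e-12 for f in fs])
        _, p = association.permanova(dist, cohort, n_perm=20000, seed=0)
        assert abs(p - exact_p) < 0.02

    def test_maximal_separation_floor(self):
        _, _, dist, cohort = self._setup(sep=50.0, n=20, seed=1)
        _, p = association.permanova(dist, cohort, n_perm=999, seed=1)
        assert p == pytest.approx(1 / 1000)

    def test_p_lower_bound_exact(self):
        _, _, dist, cohort = self._setup(sep=100.0, n=10, seed=5)
        for n_perm in (99, 499):
            _, p = association.permanova(dist, cohort, n_perm=n_perm, seed=0)
            assert p >= 1 / (n_perm + 1) - 1e-12

    def test_single_group_error(self):
        _, _, dist, cohort = self._setup()
        cohort["group"] = "case"
        with pytest.raises(ValueError):
            association.permanova(dist, cohort, n_perm=9, seed=0)


class TestDbRda:
    def _abund(self, sep, n=20, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.lognormal(size=(8, n))
        x[:4, : n // 2] *= np.exp(sep)
        x /= x.sum(axis=0, keepdims=True)
        ids = [f"s{i}" for i in range(n)]
        ab = pd.DataFrame(x, index=[f"f{i}" for i in range(8)], columns=ids)
        cohort = make_cohort(ids, ["case"] * (n // 2) + ["control"] * (n // 2))
        return ab, cohort

    def test_separated_groups(self):
        ab, cohort = self._abund(sep=2.0)
        res = association.dbrda(association.bray_curtis(ab), cohort, features=ab)
        y = (cohort["group"] == "case").to_numpy(dtype=float)
        r = np.corrcoef(res.scores.to_numpy(), y)[0, 1]
        assert abs(r) > 0.8
        assert res.loadings is not None and len(res.loadings) == 8

    def test_randomized_labels_chance_variance(self):
        rng = np.random.default_rng(7)
        ab, cohort = self._abund(sep=0.0, seed=7)
        dist = association.bray_curtis(ab)
        obs = association.dbrda(dist, cohort).axis_variance[0]
        null = []
        for _ in range(60):
            shuffled = cohort.copy()
            shuffled["group"] = rng.permutation(cohort["group"].to_numpy())
            null.append(association.dbrda(dist, shuffled).axis_variance[0])
        assert obs <= np.percentile(null, 95)

    def test_duplicate_samples_identical_geometry(self):
        ab, cohort = self._abund(sep=1.0, n=10, seed=2)
        dup = pd.concat([ab, ab.add_suffix("_dup", axis=1)], axis=1)
        dup_cohort = pd.concat([
            cohort,
            cohort.assign(sample_id=cohort["sample_id"] + "_dup").set_index("sample_id", drop=False),
        ])
        res = association.dbrda(association.bray_curtis(dup), dup_cohort)
        orig = res.scores[: len(cohort)].to_numpy()
        copy = res.scores[len(cohort):].to_numpy()
        np.testing.assert_allclose(orig, copy, atol=1e-8)
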