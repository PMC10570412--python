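"""ANOVA, Tukey HSD, PCA and general features vs. hand math and reference libs."""

import numpy as np
import pytest
import scipy.stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from epistage.complexity import FeatureMatrix
from epistage.preprocess import Epoch
from epistage.signal_io import Stage
from epistage.stats import (
    GeneralFeatures,
    StageGroups,
    general_features,
    one_way_anova,
    pca_scores,
    stage_separation_report,
    tukey_hsd,
)


class TestAnova:
    def test_hand_computed_example(self):
        # groups {1,2}, {4,5}, {8,9}: grand mean 29/6,
        # SSB = 2[(1.5-29/6)^2 + (4.5-29/6)^2 + (8.5-29/6)^2], SSW = 4*0.25 + 2*0.25
        groups = [[1, 2], [4, 5], [8, 9]]
        means = np.array([1.5, 4.5, 8.5])
        grand = 29 / 6
        ssb = 2 * ((means - grand) ** 2).sum()
        ssw = 6 * 0.25
        expected_f = (ssb / 2) / (ssw / 3)
        F, p = one_way_anova(groups)
        assert abs(F - expected_f) < 1e-10
        assert abs(p - sps.f.sf(expected_f, 2, 3)) < 1e-12

    def test_matches_scipy_f_oneway(self, rng):
        groups = [rng.normal(loc=i, size=30) for i in range(3)]
        F, p = one_way_anova(groups)
        ref = sps.f_oneway(*groups)
        assert abs(F - ref.statistic) < 1e-10
        assert abs(p - ref.pvalue) < 1e-12

    def test_two_groups_f_equals_t_squared(self, rng):
        a, b = rng.normal(size=25), rng.normal(loc=0.4, size=25)
        F, p = one_way_anova([a, b])
        t = sps.ttest_ind(a, b)
        assert abs(F - t.statistic**2) < 1e-10
        assert abs(p - t.pvalue) < 1e-12

    def test_identical_groups_degenerate_cases(self):
        assert one_way_anova([[3, 3], [3, 3]]) == (0.0, 1.0)
        with pytest.raises(ValueError):
            one_way_anova([[1, 1], [2, 2]])  # SSB > 0, SSW = 0
        with pytest.raises(ValueError):
            one_way_anova([[1, 2]])
        with pytest.raises(ValueError):
            one_way_anova([[1], [2, 3]])

    def test_stage_groups_container(self):
        sg = StageGroups(
            {Stage.ACUTE: [1, 2], Stage.NORMAL: [3, 4], Stage.CHRONIC: [5, 6]}
        )
        assert [s for s, _ in sg.in_order()] == [
            Stage.NORMAL,
            Stage.ACUTE,
            Stage.CHRONIC,
        ]
        with pytest.raises(ValueError):
            StageGroups({Stage.NORMAL: [1, 2]})


class TestTukey:
    def test_matches_statsmodels(self, rng):
        groups = [rng.normal(loc=0.3 * i, size=20 + 5 * i) for i in range(3)]
        ours = tukey_hsd(groups)
        data = np.concatenate(groups)
        labels = np.concatenate([[i] * len(g) for i, g in enumerate(groups)])
        ref = pairwise_tukeyhsd(data, labels)
        # statsmodels reports group2 - group1; ours is first - second
        np.testing.assert_allclose(
            [-r["mean_difference"] for r in ours], ref.meandiffs, atol=1e-10
        )
        np.testing.assert_allclose(
            [r["p_adjusted"] for r in ours], ref.pvalues, atol=1e-8
        )

    def test_signed_differences_in_stage_order(self):
        sg = StageGroups(
            {
                Stage.NORMAL: np.array([10.0, 10.0, 10.1]),
                Stage.ACUTE: np.array([1.0, 1.1, 0.9]),
                Stage.CHRONIC: np.array([5.0, 5.1, 4.9]),
            }
        )
        res = {r["pair"]: r for r in tukey_hsd(sg)}
        assert res[("normal", "acute")]["mean_difference"] > 0
        assert res[("normal", "chronic")]["mean_difference"] > 0
        assert res[("acute", "chronic")]["mean_difference"] < 0

    def test_identical_groups_p_one(self):
        res = tukey_hsd([[2.0, 2.0], [2.0, 2.0]])
        assert res[0]["mean_difference"] == 0.0
        assert res[0]["p_adjusted"] == 1.0


class TestPCA:
    def test_matches_sklearn_on_standardized_data(self, rng):
        from sklearn.decomposition import PCA

        X = rng.normal(size=(100, 5)) @ rng.normal(size=(5, 5))
        ours = pca_scores(X, 2)
        Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
        ref = PCA(n_components=2).fit_transform(Z)
        # components agree up to sign
        for c in range(2):
            s = np.sign(np.dot(ours[:, c], ref[:, c]))
            np.testing.assert_allclose(ours[:, c], s * ref[:, c], atol=1e-8)

    def test_scores_centered_and_orthogonal(self, rng):
        X = rng.normal(size=(60, 5))
        s = pca_scores(X, 2)
        np.testing.assert_allclose(s.mean(axis=0), 0.0, atol=1e-10)
        assert abs(np.dot(s[:, 0], s[:, 1])) < 1e-8
        # PC1 captures at least as much variance as PC2
        assert s[:, 0].var() >= s[:, 1].var()

    def test_collinear_features_one_dominant_component(self, rng):
        base = rng.normal(size=100)
        X = np.column_stack([base, 2 * base, -base, 3 * base + 1e-9, base])
        s = pca_scores(X, 2)
        assert s[:, 0].var() > 1e6 * max(s[:, 1].var(), 1e-30)

    def test_validation(self, rng):
        with pytest.raises(ValueError):
            pca_scores(np.zeros((1, 5)), 2)
        with pytest.raises(ValueError):
            pca_scores(rng.normal(size=(10, 3)), 4)


class TestGeneralFeatures:
    def test_hand_example(self):
        ep = Epoch(np.array([[1.0, 2.0, 3.0]]), 0, "normal", "s")
        gf = general_features(ep)
        # mean 2, population variance 2/3, max 3, min 1, skewness 0 (symmetric)
        np.testing.assert_allclose(gf.values[0], [2.0, 2 / 3, 3.0, 1.0, 0.0])
        assert gf.feature_names == ["mean", "variance", "maximum", "minimum", "skewness"]

    def test_skewness_matches_scipy(self, rng):
        x = rng.exponential(size=(3, 500))
        ep = Epoch(x, 0, "acute", "s")
        gf = general_features(ep)
        np.testing.assert_allclose(gf.values[:, 4], sps.skew(x, axis=1), atol=1e-10)

    def test_constant_channel_warns(self):
        ep = Epoch(np.ones((2, 10)), 0, "normal", "s")
        with pytest.warns(RuntimeWarning):
            gf = general_features(ep)
        assert (gf.values[:, 4] == 0.0).all()

    def test_too_short_epoch_rejected(self):
        with pytest.raises(ValueError):
            general_features(Epoch(np.ones((1, 2)), 0, "normal", "s"))

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            GeneralFeatures(np.full((2, 5), np.nan))


def _fms_for_stages(n_per_stage=30, gap=1.0, seed=0):
    rng = np.random.default_rng(seed)
    fms = []
    for k, stage in enumerate(("normal", "acute", "chronic")):
        for i in range(n_per_stage):
            vals = rng.normal(loc=k * gap, scale=0.3, size=(8, 5))
            fms.append(
                FeatureMatrix(vals, stage=stage, subject_id="s", epoch_index=i)
            )
    return fms


class TestStageSeparationReport:
    def test_table_shape_and_significance(self):
        rep = stage_separation_report(_fms_for_stages())
        assert list(rep.table["measure"]) == ["ApEn", "SampEn", "PE", "FuzzEn", "KC"]
        assert (rep.table["p"] < 1e-6).all()
        assert (rep.table["p_normal_acute"] < 1e-6).all()
        # normal (loc 0) minus acute (loc 1) is negative
        assert (rep.table["diff_normal_acute"] < 0).all()
        assert rep.scores.shape == (3 * 30 * 8, 2)
        assert set(rep.score_labels) == {"normal", "acute", "chronic"}

    def test_missing_stage_rejected(self):
        fms = [fm for fm in _fms_for_stages(5) if fm.stage is not Stage.CHRONIC]
        with pytest.raises(ValueError):
            stage_separation_report(fms)

    def test_csv_round_trip(self, tmp_path):
        import pandas as pd

        rep = stage_separation_report(_fms_for_stages(5))
        t = tmp_path / "table.csv"
        s = tmp_path / "scores.csv"
        rep.table_to_csv(t)
        rep.scores_to_csv(s)
        assert len(pd.read_csv(t)) == 5
        back = pd.read_csv(s)
        assert list(back.columns) == ["PC1", "PC2", "stage"]
        assert len(back) == len(rep.scores)


def test_permutation_null_p_values_are_uniform(rng):
    # under the null (labels shuffled), the ANOVA p-value should be roughly
    # uniform: the rejection rate at alpha = 0.05 stays near 0.05
    x = rng.normal(size=300)
    rejections = 0
    n_perm = 200
    for _ in range(n_perm):
        perm = rng.permutation(x)
        _, p = one_way_anova([perm[:100], perm[100:200], perm[200:]])
        rejections += p < 0.05
    assert abs(rejections / n_perm - 0.05) < 0.05
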