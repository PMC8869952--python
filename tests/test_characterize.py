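import numpy as np
import pandas as pd
import pytest
from scipy import stats
from statsmodels.stats.multitest import multipletests

from admoe import (
    PhenotypeConfig,
    abnormal_proportions,
    compare_qualitative,
    compare_quantitative,
    csf_abnormality,
    generate_cohort,
    generate_phenotypes,
    roi_atrophy_map,
)
from admoe.io import PHENOTYPE_COLUMNS, PhenotypeTable
from admoe.residualize import ResidualTable


def residuals_table(X_cn, X_sub, p=None):
    n_cn, n_sub = len(X_cn), len(X_sub)
    df = pd.DataFrame(
        {
            "subject_id": [f"c{i}" for i in range(n_cn)]
            + [f"a{i}" for i in range(n_sub)],
            "diagnosis": ["CN"] * n_cn + ["AD"] * n_sub,
        }
    )
    X = np.vstack([X_cn, X_sub])
    roi = pd.DataFrame(X, columns=[f"r{j}" for j in range(X.shape[1])])
    return ResidualTable(pd.concat([df, roi], axis=1), "density")


def phenotype_frame(values: dict, n: int):
    df = pd.DataFrame({c: [np.nan] * n for c in PHENOTYPE_COLUMNS})
    df["subject_id"] = [f"a{i}" for i in range(n)]
    for col, vals in values.items():
        df[col] = vals
    return PhenotypeTable(df[PHENOTYPE_COLUMNS])


class TestRoiAtrophyMap:
    def test_null_subtype_flags_almost_nothing(self):
        rng = np.random.default_rng(0)
        res = residuals_table(rng.normal(size=(60, 116)), rng.normal(size=(40, 116)))
        cn = {f"c{i}" for i in range(60)}
        sub = {f"a{i}" for i in range(40)}
        amap = roi_atrophy_map(sub, cn, res)
        assert amap["significant"].sum() <= 1

    def test_shifted_rois_exactly_detected(self):
        rng = np.random.default_rng(1)
        X_cn = rng.normal(size=(60, 30))
        X_sub = rng.normal(size=(60, 30))
        X_sub[:, :10] -= 1.5  # 1.5 SD shift, power ~ 1 at n=60
        res = residuals_table(X_cn, X_sub)
        amap = roi_atrophy_map(
            {f"a{i}" for i in range(60)}, {f"c{i}" for i in range(60)}, res
        )
        assert amap["significant"][:10].all()
        assert not amap["significant"][10:].any()

    def test_bh_step_up_hand_example(self):
        # classical step-up: p=(.01,.02,.03,.04) with m=4 -> all q=.04
        _, q, _, _ = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")
        assert np.allclose(q, 0.04)

    def test_q_at_least_p_and_monotone(self):
        rng = np.random.default_rng(2)
        res = residuals_table(rng.normal(size=(30, 20)), rng.normal(size=(30, 20)))
        amap = roi_atrophy_map(
            {f"a{i}" for i in range(30)}, {f"c{i}" for i in range(30)}, res
        )
        assert (amap["q"] >= amap["p"] - 1e-12).all()
        ordered = amap.sort_values("p")
        assert ordered["q"].is_monotonic_increasing

    def test_zero_variance_roi_excluded_with_warning(self):
        rng = np.random.default_rng(3)
        X_cn = rng.normal(size=(20, 4))
        X_sub = rng.normal(size=(20, 4))
        X_cn[:, 2] = 0.0
        X_sub[:, 2] = 0.0
        res = residuals_table(X_cn, X_sub)
        with pytest.warns(UserWarning, match="zero variance"):
            amap = roi_atrophy_map(
                {f"a{i}" for i in range(20)}, {f"c{i}" for i in range(20)}, res
            )
        assert np.isnan(amap.loc[2, "q"])
        assert not amap.loc[2, "significant"]

    def test_uncorrected_variant_uses_raw_p(self):
        rng = np.random.default_rng(4)
        res = residuals_table(rng.normal(size=(20, 6)), rng.normal(size=(20, 6)))
        amap = roi_atrophy_map(
            {f"a{i}" for i in range(20)}, {f"c{i}" for i in range(20)}, res,
            correction="none",
        )
        assert np.allclose(amap["q"], amap["p"])


class TestCompareQualitative:
    def test_chi_square_hand_case(self):
        # [[10,20],[20,10]]: chi2 = 6.6667, df 1 (no continuity correction)
        phen = phenotype_frame(
            {"apoe_e4": [0] * 10 + [1] * 20 + [0] * 20 + [1] * 10}, 60
        )
        group_a = {f"a{i}" for i in range(30)}
        group_b = {f"a{i}" for i in range(30, 60)}
        result = compare_qualitative(group_a, group_b, "apoe_e4", phen)
        assert np.isclose(result.statistic, 20 / 3, atol=1e-4)
        assert result.detail["dof"] == 1

    def test_transpose_symmetry(self):
        table = np.array([[12, 30], [25, 14]])
        a, _, _, _ = stats.chi2_contingency(table, correction=False)
        b, _, _, _ = stats.chi2_contingency(table.T, correction=False)
        flags = [0] * 12 + [1] * 30 + [0] * 25 + [1] * 14
        phen = phenotype_frame({"apoe_e2": flags}, 81)
        res = compare_qualitative(
            {f"a{i}" for i in range(42)}, {f"a{i}" for i in range(42, 81)},
            "apoe_e2", phen,
        )
        assert np.isclose(a, b)
        assert np.isclose(res.statistic, a)

    def test_null_proportions_not_significant(self):
        rng = np.random.default_rng(5)
        flags = rng.integers(0, 2, size=400)
        phen = phenotype_frame({"apoe_e4": flags}, 400)
        res = compare_qualitative(
            {f"a{i}" for i in range(200)}, {f"a{i}" for i in range(200, 400)},
            "apoe_e4", phen,
        )
        assert res.p > 0.05

    def test_zero_margin_untestable(self):
        phen = phenotype_frame({"apoe_e2": [1] * 20}, 20)
        res = compare_qualitative(
            {f"a{i}" for i in range(10)}, {f"a{i}" for i in range(10, 20)},
            "apoe_e2", phen,
        )
        assert res.status == "untestable"
        assert res.statistic is None

    def test_missing_rows_dropped_and_counted(self):
        flags = [0, 1, np.nan, 1, 0, np.nan, 1, 0]
        phen = phenotype_frame({"apoe_e4": flags}, 8)
        with pytest.warns(UserWarning, match="expected count"):
            res = compare_qualitative(
                {f"a{i}" for i in range(4)}, {f"a{i}" for i in range(4, 8)},
                "apoe_e4", phen,
            )
        assert res.detail["n_missing"] == 2


class TestCompareQuantitative:
    def test_null_groups_not_significant(self):
        rng = np.random.default_rng(6)
        phen = phenotype_frame({"mmse": rng.normal(24, 2, size=300)}, 300)
        groups = [{f"a{i}" for i in range(j, 300, 3)} for j in range(3)]
        results = compare_quantitative(groups, "mmse", phen, reference_index=0)
        assert results[0].test == "anova"
        assert results[0].p > 0.05

    def test_shifted_group_detected_others_not(self):
        rng = np.random.default_rng(7)
        vals = rng.normal(0, 1, size=150)
        vals[50:100] += 2.0  # group 1 shifted by 2 SD
        phen = phenotype_frame({"adni_mem": vals}, 150)
        groups = [
            {f"a{i}" for i in range(50)},
            {f"a{i}" for i in range(50, 100)},
            {f"a{i}" for i in range(100, 150)},
        ]
        results = compare_quantitative(groups, "adni_mem", phen, reference_index=0)
        pairwise = {r.detail["group"]: r for r in results[1:]}
        assert pairwise[1].p < 0.05
        assert pairwise[2].p > 0.05

    def test_two_group_anova_equals_squared_pooled_t(self):
        rng = np.random.default_rng(8)
        vals = np.concatenate([rng.normal(0, 1, 40), rng.normal(0.5, 1, 40)])
        phen = phenotype_frame({"cdrsb": vals}, 80)
        groups = [{f"a{i}" for i in range(40)}, {f"a{i}" for i in range(40, 80)}]
        results = compare_quantitative(groups, "cdrsb", phen, reference_index=0)
        t_pooled, _ = stats.ttest_ind(vals[:40], vals[40:], equal_var=True)
        assert np.isclose(results[0].statistic, t_pooled**2, rtol=1e-10)

    def test_insufficient_groups_rejected(self):
        phen = phenotype_frame({"mmse": [20.0, 21.0, np.nan, np.nan]}, 4)
        groups = [{"a0", "a1"}, {"a2", "a3"}]
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="2 usable groups"):
                compare_quantitative(groups, "mmse", phen, reference_index=0)


class TestCsfAbnormality:
    def test_cutoff_boundaries(self):
        phen = phenotype_frame(
            {
                "abeta": [191.9, 192.0, 300.0],
                "ttau": [94.0, 93.0, 10.0],
                "ptau": [23.0, 23.1, 5.0],
            },
            3,
        )
        flags = csf_abnormality(phen)
        assert list(flags["abnormal_abeta"]) == [True, False, False]
        assert list(flags["abnormal_ttau"]) == [True, False, False]
        assert list(flags["abnormal_ptau"]) == [False, True, False]

    def test_missing_values_excluded_from_denominator(self):
        phen = phenotype_frame({"abeta": [100.0, np.nan, 250.0]}, 3)
        flags = csf_abnormality(phen)
        assert pd.isna(flags.loc[1, "abnormal_abeta"])
        props = abnormal_proportions(flags)
        abeta_row = props[props["biomarker"] == "abeta"].iloc[0]
        assert abeta_row["n_usable"] == 2
        assert np.isclose(abeta_row["proportion_abnormal"], 0.5)

    def test_negative_concentration_rejected(self):
        phen = phenotype_frame({"ttau": [-1.0, 50.0]}, 2)
        with pytest.raises(ValueError, match="negative"):
            csf_abnormality(phen)

    def test_generated_phenotypes_respect_subtype_fractions(self):
        _, _, truth, _ = generate_cohort(8, 400, seed=30)
        phen = generate_phenotypes(
            truth,
            PhenotypeConfig(abnormal_abeta={"DAD": 1.0, "MAD": 0.0, "LTAD": 0.5, "OSAD": 0.5}),
            seed=3,
        )
        flags = csf_abnormality(phen).merge(
            truth.df[["subject_id", "z"]], on="subject_id"
        )
        assert flags.loc[flags["z"] == 1, "abnormal_abeta"].all()
        assert not flags.loc[flags["z"] == 2, "abnormal_abeta"].any()
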