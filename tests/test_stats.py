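"""EBS handling, transforms, mixed MANOVA and the nonparametric suite."""

import itertools

import numpy as np
import pandas as pd
import pytest

import lumovar as lv
from lumovar.stats import (
    AMPLITUDE_DVS,
    VARIABILITY_DVS,
    StatsError,
    ebs_split,
    mixed_manova,
    nonparametric_suite,
    partial_eta_squared,
    transform_skewed,
    univariate_followup,
    _participant_frame,
    _design_matrix,
)
from lumovar.synthetic import CONDITION_THREAT


@pytest.fixture(scope="module")
def cohort():
    return lv.generate_cohort(lv.CohortConfig(seed=17))


@pytest.fixture(scope="module")
def transformed(cohort):
    return transform_skewed(cohort)


class TestEbsSplit:
    @pytest.mark.parametrize("value,expected", [(0, "low"), (3, "low"), (4, "high"), (10, "high")])
    def test_threshold(self, value, expected):
        assert ebs_split(value) == expected

    @pytest.mark.parametrize("value", [-1, 11, 3.5])
    def test_out_of_range_rejected(self, value):
        with pytest.raises(StatsError):
            ebs_split(value)


class TestTransformSkewed:
    def test_unit_value_maps_to_zero(self):
        df = pd.DataFrame({"meansd_fe": [1.0], "lde": [3.9]})
        out = transform_skewed(df)
        assert out["meansd_fe"].iloc[0] == 0.0

    def test_lde_untouched(self, cohort, transformed):
        assert np.array_equal(cohort["lde"], transformed["lde"])

    def test_exp_inverts(self, cohort, transformed):
        for col in ("meansd_fe", "cyclsd", "velocity"):
            assert np.allclose(np.exp(transformed[col]), cohort[col], atol=1e-12)

    def test_nonpositive_value_named(self):
        df = pd.DataFrame({"cyclsd": [0.1, 0.0]})
        with pytest.raises(StatsError, match="cyclsd"):
            transform_skewed(df)


class TestMixedManova:
    def test_design_dfs(self, transformed):
        res = {r.effect: r for r in mixed_manova(transformed, VARIABILITY_DVS)}
        assert (res["threat"].df_num, res["threat"].df_den) == (5, 52)
        res4 = {r.effect: r for r in mixed_manova(transformed, AMPLITUDE_DVS)}
        assert (res4["threat"].df_num, res4["threat"].df_den) == (4, 53)

    def test_wilks_in_unit_interval(self, transformed):
        for r in mixed_manova(transformed, VARIABILITY_DVS):
            assert 0 < r.wilks_lambda <= 1
            assert r.p <= 1

    def test_missing_condition_rejected(self, transformed):
        broken = transformed.drop(transformed[
            (transformed["participant"] == "P001")
            & (transformed["condition"] == CONDITION_THREAT)
        ].index)
        with pytest.raises(StatsError, match="P001"):
            mixed_manova(broken, VARIABILITY_DVS)

    def test_matches_statsmodels_oracle(self):
        from statsmodels.multivariate.manova import MANOVA

        for seed in range(10):
            table = transform_skewed(lv.generate_cohort(lv.CohortConfig(seed=seed)))
            mine = {r.effect: r for r in mixed_manova(table, VARIABILITY_DVS)}
            meta, D, M = _participant_frame(table, VARIABILITY_DVS)
            frame = pd.DataFrame(D, columns=list(VARIABILITY_DVS))
            frame["g"] = np.where(meta["group"].to_numpy() == "LBP", 1.0, -1.0)
            frame["e"] = np.where(np.asarray(ebs_split(meta["ebs_threat"].to_numpy())) == "high", 1.0, -1.0)
            dvs = " + ".join(VARIABILITY_DVS)
            mv = MANOVA.from_formula(f"{dvs} ~ g * e", data=frame).mv_test()
            pairs = [("threat", "Intercept"), ("threat x group", "g"),
                     ("threat x EBS", "e"), ("threat x group x EBS", "g:e")]
            for mine_name, sm_name in pairs:
                lam = mv.results[sm_name]["stat"].loc["Wilks' lambda", "Value"]
                F = mv.results[sm_name]["stat"].loc["Wilks' lambda", "F Value"]
                assert mine[mine_name].wilks_lambda == pytest.approx(float(lam), abs=1e-6)
                assert mine[mine_name].F == pytest.approx(float(F), rel=1e-6)

    def test_null_cohort_pvalues_uniform(self):
        pvals = []
        for seed in range(200):
            table = transform_skewed(lv.generate_cohort(lv.CohortConfig(
                seed=seed, threat_effect=1.0, interaction_effect=1.0,
                threat_lde_shift=0.0, threat_amplitude_factor=1.0,
                threat_velocity_factor=1.0)))
            res = {r.effect: r for r in mixed_manova(table, VARIABILITY_DVS)}
            pvals.append(res["threat"].p)
        from scipy.stats import kstest
        assert kstest(pvals, "uniform").pvalue > 0.01


class TestUnivariateFollowup:
    def test_eta_squared_identity_for_1df_effect(self, transformed):
        effects = univariate_followup(transformed, "meansd_fe")
        for eff in effects:
            assert eff.partial_eta_sq == pytest.approx(
                eff.F / (eff.F + 56), abs=1e-10)

    def test_eta_squared_from_ss_decomposition(self, transformed):
        # identity eta2 = SS_h / (SS_h + SS_e) against an explicit OLS decomposition
        meta, D, _ = _participant_frame(transformed, ["cyclsd"])
        X = _design_matrix(meta)
        y = D[:, 0]
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        ss_err = resid @ resid
        full = univariate_followup(transformed, "cyclsd")
        threat = next(e for e in full if e.effect == "threat")
        # drop-column SS for the intercept (Type III with effect coding)
        Xr = X[:, 1:]
        br, *_ = np.linalg.lstsq(Xr, y, rcond=None)
        ss_eff = (y - Xr @ br) @ (y - Xr @ br) - ss_err
        assert threat.partial_eta_sq == pytest.approx(ss_eff / (ss_eff + ss_err), abs=1e-10)

    def test_zero_F_zero_eta(self):
        assert partial_eta_squared(0.0, 10.0) == 0.0

    def test_reported_effect_size_consistency(self):
        # a 1-df F of 19.565 with 56 error df corresponds to eta2 ~ 0.259
        F = 19.565
        assert F / (F + 56) == pytest.approx(0.259, abs=5e-4)


class TestNonparametricSuite:
    def test_identical_paired_samples_p_one(self, cohort):
        table = cohort.copy()
        table["ebs_reference"] = table["ebs_threat"]
        out = nonparametric_suite(table)
        assert out["wilcoxon_ebs"]["p"] == pytest.approx(1.0)
        assert out["wilcoxon_ebs"]["mean_difference"] == 0.0

    def test_u_statistic_matches_rank_count_oracle(self):
        x, y = [1.2, 3.4, 5.1], [0.7, 2.2, 4.0]
        # brute force: number of (x_i, y_j) pairs with x_i > y_j (+0.5 for ties)
        u_oracle = sum(
            1.0 if a > b else (0.5 if a == b else 0.0)
            for a, b in itertools.product(x, y)
        )
        from scipy.stats import mannwhitneyu
        u, _ = mannwhitneyu(x, y, alternative="two-sided")
        assert u == u_oracle

    def test_monotone_scores_rho_one(self, cohort):
        table = cohort.copy()
        first = table.drop_duplicates("participant")
        rank = np.arange(len(first))
        table = table.merge(
            pd.DataFrame({"participant": first["participant"], "_r": rank}),
            on="participant")
        table["ebs_threat"] = table["_r"]
        table["ebs_reference"] = table["_r"] * 2 + 1
        out = nonparametric_suite(table)
        assert out["spearman_ebs"]["rho"] == pytest.approx(1.0)

    def test_single_group_rejected(self, cohort):
        with pytest.raises(StatsError):
            nonparametric_suite(cohort[cohort["group"] == "LBP"])
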