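"""Group-level inference: rm-ANOVA against hand-computed sums of squares
and pingouin, t-tests against textbook formulas, and the random-intercept
mixed model against a dense-covariance likelihood oracle and statsmodels."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from hippopred import stats
from hippopred.stats import (LINEAR_CONTRAST, MATCH_MISMATCH_CONTRAST,
                             ContrastSpec, across_participant_correlation,
                             compare_models, contrast_score, fit_mixed_model,
                             group_contrast_test, one_sample_t, paired_t,
                             rm_anova, univariate_trend)


def long_table(arr, factors):
    """subjects x levels... ndarray -> long DataFrame."""
    rows = []
    it = np.ndindex(*arr.shape)
    for idx in it:
        row = {"participant": idx[0], "value": arr[idx]}
        for name, lev in zip(factors, idx[1:]):
            row[name] = lev
        rows.append(row)
    return pd.DataFrame(rows)


class TestRmAnova:
    def test_two_level_factor_equals_paired_t(self):
        rng = np.random.default_rng(0)
        arr = rng.standard_normal((10, 2))
        res = rm_anova(long_table(arr, ["cond"]), "value", "participant",
                       ["cond"])
        t = paired_t(arr[:, 0], arr[:, 1])
        assert res["cond"].F == pytest.approx(t.t ** 2, abs=1e-8)
        assert res["cond"].p == pytest.approx(t.p, abs=1e-10)

    def test_matches_hand_computed_sums_of_squares(self):
        # printed toy table: 3 participants x 2 x 2, fixed values
        arr = np.array([
            [[4.0, 6.0], [5.0, 9.0]],
            [[3.0, 5.0], [4.0, 6.0]],
            [[5.0, 8.0], [7.0, 12.0]],
        ])
        res = rm_anova(long_table(arr, ["A", "B"]), "value", "participant",
                       ["A", "B"])
        # independent textbook decomposition, explicit loops
        M = arr.mean()
        ms = arr.mean(axis=(1, 2))       # per subject
        ma = arr.mean(axis=(0, 2))       # per A level
        mb = arr.mean(axis=(0, 1))
        msa = arr.mean(axis=2)
        msb = arr.mean(axis=1)
        mab = arr.mean(axis=0)
        ss_a = 3 * 2 * sum((ma - M) ** 2)
        ss_a_err = 2 * sum((msa[s, a] - ms[s] - ma[a] + M) ** 2
                           for s in range(3) for a in range(2))
        ss_ab = 3 * sum((mab[a, b] - ma[a] - mb[b] + M) ** 2
                        for a in range(2) for b in range(2))
        ss_ab_err = sum(
            (arr[s, a, b] - msa[s, a] - msb[s, b] - mab[a, b]
             + ms[s] + ma[a] + mb[b] - M) ** 2
            for s in range(3) for a in range(2) for b in range(2))
        assert res["A"].ss_effect == pytest.approx(ss_a, abs=1e-10)
        assert res["A"].ss_error == pytest.approx(ss_a_err, abs=1e-10)
        assert res["A:B"].ss_effect == pytest.approx(ss_ab, abs=1e-10)
        assert res["A:B"].ss_error == pytest.approx(ss_ab_err, abs=1e-10)
        assert res["A"].eta_p_sq == pytest.approx(
            ss_a / (ss_a + ss_a_err), abs=1e-10)

    def test_matches_pingouin_two_way(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(1)
        arr = rng.standard_normal((8, 3, 2)) + \
            np.arange(3)[None, :, None] * 0.5
        df = long_table(arr, ["A", "B"])
        res = rm_anova(df, "value", "participant", ["A", "B"])
        pg = pingouin.rm_anova(data=df, dv="value", subject="participant",
                               within=["A", "B"], detailed=True)
        for effect, pg_name in (("A", "A"), ("B", "B"), ("A:B", "A * B")):
            row = pg[pg["Source"] == pg_name].iloc[0]
            assert res[effect].F == pytest.approx(row["F"], rel=1e-6)
            assert res[effect].p == pytest.approx(row["p_unc"], rel=1e-6)

    def test_identical_values_give_zero_F(self):
        arr = np.full((4, 3), 2.5)
        res = rm_anova(long_table(arr, ["cond"]), "value", "participant",
                       ["cond"])
        assert res["cond"].F == 0.0

    def test_location_shift_leaves_F_unchanged(self):
        rng = np.random.default_rng(2)
        arr = rng.standard_normal((6, 4))
        f1 = rm_anova(long_table(arr, ["c"]), "value", "participant",
                      ["c"])["c"].F
        f2 = rm_anova(long_table(arr + 100.0, ["c"]), "value", "participant",
                      ["c"])["c"].F
        assert f1 == pytest.approx(f2, rel=1e-9)

    def test_three_way_design_df_structure(self):
        # 19 participants x 5 changes x 2 ROIs: the interaction stratum
        # is forced to df (4, 72) by the design
        rng = np.random.default_rng(3)
        arr = rng.standard_normal((19, 5, 2))
        res = rm_anova(long_table(arr, ["changes", "roi"]), "value",
                       "participant", ["changes", "roi"])
        eff = res["changes:roi"]
        assert (eff.df_num, eff.df_den) == (4, 72)

    def test_missing_cell_raises_naming_subject(self):
        df = long_table(np.zeros((3, 2)), ["c"])
        df = df.drop(index=3)
        with pytest.raises(ValueError, match="not balanced"):
            rm_anova(df, "value", "participant", ["c"])

    def test_single_participant_rejected(self):
        df = long_table(np.zeros((1, 3)), ["c"])
        with pytest.raises(ValueError, match="at least 2"):
            rm_anova(df, "value", "participant", ["c"])


class TestContrasts:
    def test_weights_must_sum_to_zero(self):
        with pytest.raises(ValueError, match="sum to 0"):
            ContrastSpec("bad", {0: 1.0, 1: 1.0})
        assert sum(LINEAR_CONTRAST.weights.values()) == 0
        assert sum(MATCH_MISMATCH_CONTRAST.weights.values()) == 0

    def test_equal_values_score_zero(self):
        values = {c: 3.7 for c in range(5)}
        assert contrast_score(values, LINEAR_CONTRAST) == pytest.approx(0.0)
        assert contrast_score(values, MATCH_MISMATCH_CONTRAST) == \
            pytest.approx(0.0)

    def test_linear_contrast_arithmetic(self):
        values = dict(enumerate([0.0, 1.0, 2.0, 3.0, 4.0]))
        assert contrast_score(values, LINEAR_CONTRAST) == 10.0

    def test_match_mismatch_weight_definition(self):
        values = {0: 1.0, 1: 0.0, 2: 0.0, 3: 0.0, 4: 0.0}
        assert contrast_score(values, MATCH_MISMATCH_CONTRAST) == -1.0

    def test_missing_level_raises(self):
        with pytest.raises(ValueError, match="missing level"):
            contrast_score({0: 1.0, 1: 2.0}, LINEAR_CONTRAST)


class TestGroupTests:
    def test_constant_nonzero_scores_hit_zero_variance_error(self):
        with pytest.raises(ValueError, match="zero variance"):
            group_contrast_test([0.3] * 5)

    def test_zero_mean_scores_give_zero_t(self):
        res = group_contrast_test([1.0, -1.0, 2.0, -2.0])
        assert res.t == pytest.approx(0.0)

    def test_hand_formula_oracle(self):
        x = [0.2, 0.1, 0.3, 0.0, 0.4]
        res = group_contrast_test(x)
        n = 5
        mean = sum(x) / n
        sd = math.sqrt(sum((v - mean) ** 2 for v in x) / (n - 1))
        t = mean / (sd / math.sqrt(n))
        assert res.t == pytest.approx(t, abs=1e-12)
        assert res.cohens_d == pytest.approx(mean / sd, abs=1e-12)
        assert res.df == 4
        assert res.ci95[0] < mean < res.ci95[1]

    def test_matches_scipy_paired_test(self):
        rng = np.random.default_rng(4)
        a, b = rng.standard_normal((2, 12))
        res = paired_t(a, b)
        ref = sps.ttest_rel(a, b)
        assert res.t == pytest.approx(ref.statistic, abs=1e-10)
        assert res.p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_univariate_trend_detects_graded_activation(self):
        rng = np.random.default_rng(5)
        rows = []
        for p in range(19):
            for c in range(5):
                rows.append(dict(participant=p, total_changes=c,
                                 value=0.3 * c + rng.standard_normal() * 0.4))
        res = univariate_trend(pd.DataFrame(rows))
        assert res.t > 0 and res.p < 0.05

    def test_univariate_trend_single_participant_rejected(self):
        df = pd.DataFrame(dict(participant=[0] * 5, total_changes=range(5),
                               value=np.arange(5.0)))
        with pytest.raises(ValueError, match="at least 2"):
            univariate_trend(df)

    def test_univariate_trend_null_calibration(self):
        rng = np.random.default_rng(6)
        hits = 0
        for _ in range(100):
            rows = [dict(participant=p, total_changes=c,
                         value=rng.standard_normal())
                    for p in range(19) for c in range(5)]
            hits += univariate_trend(pd.DataFrame(rows)).p < 0.05
        assert 0.0 <= hits / 100 <= 0.12


def mixed_table(rng, n_subj=12, intercept_sd=0.5, lin_effect=0.0,
                match_effect=0.0, noise=0.3):
    rows = []
    for p in range(n_subj):
        offset = intercept_sd * rng.standard_normal()
        for c in range(5):
            lin = LINEAR_CONTRAST.weights[c]
            match = 1.0 if c > 0 else 0.0
            rows.append(dict(participant=p, total_changes=c,
                             z=offset + lin_effect * lin
                             + match_effect * match
                             + noise * rng.standard_normal()))
    return pd.DataFrame(rows)


class TestMixedModel:
    def test_intercept_only_estimates_grand_mean(self):
        rng = np.random.default_rng(7)
        df = mixed_table(rng)
        fit = fit_mixed_model(df, "z", [])
        assert fit.params["intercept"] == pytest.approx(df["z"].mean(),
                                                        abs=1e-8)

    def test_zero_between_subject_variance_estimated_near_zero(self):
        # with no true participant offsets the ML variance estimate sits
        # at the zero boundary for typical draws; single draws can land
        # slightly positive, so check the median over replicates
        rng = np.random.default_rng(8)
        ratios = []
        for _ in range(11):
            df = mixed_table(rng, n_subj=40, intercept_sd=0.0,
                             lin_effect=0.2)
            fit = fit_mixed_model(df, "z", [LINEAR_CONTRAST])
            ratios.append(fit.random_intercept_var / fit.residual_var)
        assert sum(r <= 1e-4 for r in ratios) >= 4  # boundary reached
        assert np.mean(ratios) < 0.05               # all shrink toward 0

    def test_loglik_matches_dense_covariance_oracle(self):
        # brute force: evaluate the marginal Gaussian likelihood at the
        # fitted parameters with an explicitly assembled covariance
        rng = np.random.default_rng(9)
        df = mixed_table(rng, n_subj=6)
        fit = fit_mixed_model(df, "z", [LINEAR_CONTRAST,
                                        MATCH_MISMATCH_CONTRAST])
        X = np.column_stack([
            np.ones(len(df)),
            df["total_changes"].map(LINEAR_CONTRAST.weights),
            (df["total_changes"] > 0).astype(float)])
        beta = np.array([fit.params["intercept"], fit.params["linear"],
                         fit.params["match_lt_mismatch"]])
        Z = pd.get_dummies(df["participant"]).to_numpy(dtype=float)
        cov = fit.residual_var * np.eye(len(df)) \
            + fit.random_intercept_var * (Z @ Z.T)
        ll = sps.multivariate_normal.logpdf(df["z"], mean=X @ beta, cov=cov)
        assert fit.loglik == pytest.approx(ll, abs=1e-6)

    def test_matches_statsmodels_mixedlm(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(10)
        df = mixed_table(rng, n_subj=15, intercept_sd=0.8, lin_effect=0.15)
        fit = fit_mixed_model(df, "z", [LINEAR_CONTRAST])
        X = np.column_stack([np.ones(len(df)),
                             df["total_changes"].map(LINEAR_CONTRAST.weights)])
        res = sm.MixedLM(df["z"].to_numpy(), X,
                         groups=df["participant"].to_numpy()).fit(reml=False)
        assert fit.loglik == pytest.approx(res.llf, abs=1e-4)
        assert fit.params["intercept"] == pytest.approx(res.fe_params[0],
                                                        abs=1e-4)
        assert fit.params["linear"] == pytest.approx(res.fe_params[1],
                                                     abs=1e-4)

    def test_aic_bic_identities(self):
        rng = np.random.default_rng(11)
        df = mixed_table(rng)
        for fixed in ([], [LINEAR_CONTRAST],
                      [LINEAR_CONTRAST, MATCH_MISMATCH_CONTRAST]):
            fit = fit_mixed_model(df, "z", fixed)
            assert fit.aic == pytest.approx(2 * fit.n_params - 2 * fit.loglik)
            assert fit.bic == pytest.approx(
                fit.n_params * math.log(fit.n_obs) - 2 * fit.loglik)

    def test_confounded_terms_raise_rank_error(self):
        rng = np.random.default_rng(12)
        df = mixed_table(rng)
        df["copy"] = df["total_changes"].map(LINEAR_CONTRAST.weights)
        with pytest.raises(ValueError, match="not full rank"):
            fit_mixed_model(df, "z", [LINEAR_CONTRAST, "copy"])


class TestModelComparison:
    def test_identical_models_give_zero_chi2_p_one(self):
        rng = np.random.default_rng(13)
        df = mixed_table(rng)
        fit = fit_mixed_model(df, "z", [LINEAR_CONTRAST])
        cmp = compare_models(fit, fit)
        assert cmp.chi2 == 0.0
        assert cmp.p == 1.0

    def test_chi2_equals_twice_loglik_difference(self):
        rng = np.random.default_rng(14)
        df = mixed_table(rng, lin_effect=0.2)
        full = fit_mixed_model(df, "z", [LINEAR_CONTRAST,
                                         MATCH_MISMATCH_CONTRAST])
        red = fit_mixed_model(df, "z", [MATCH_MISMATCH_CONTRAST])
        cmp = compare_models(full, red)
        assert cmp.chi2 == pytest.approx(
            2 * (full.loglik - red.loglik), abs=1e-8)
        assert cmp.df == 1
        assert full.loglik >= red.loglik  # nested ML fits

    def test_non_nested_or_different_data_rejected(self):
        rng = np.random.default_rng(15)
        df = mixed_table(rng)
        lin = fit_mixed_model(df, "z", [LINEAR_CONTRAST])
        match = fit_mixed_model(df, "z", [MATCH_MISMATCH_CONTRAST])
        with pytest.raises(ValueError, match="not nested"):
            compare_models(lin, match)
        other = fit_mixed_model(mixed_table(rng), "z", [])
        with pytest.raises(ValueError, match="different data"):
            compare_models(lin, other)

    def test_nested_loglik_ordering_over_replicates(self):
        rng = np.random.default_rng(16)
        for _ in range(10):
            df = mixed_table(rng, lin_effect=0.1 * rng.standard_normal())
            full = fit_mixed_model(df, "z", [LINEAR_CONTRAST,
                                             MATCH_MISMATCH_CONTRAST])
            red = fit_mixed_model(df, "z", [LINEAR_CONTRAST])
            assert full.loglik >= red.loglik - 1e-8

    def test_lrt_calibration_linear_only_world(self):
        # data carry only a linear effect: the match term should add
        # nothing (nominal rejection rate), the linear term should be
        # needed nearly always
        rng = np.random.default_rng(17)
        match_hits = lin_hits = 0
        n_rep = 50
        for _ in range(n_rep):
            df = mixed_table(rng, n_subj=19, lin_effect=0.12, noise=0.2)
            full = fit_mixed_model(df, "z", [LINEAR_CONTRAST,
                                             MATCH_MISMATCH_CONTRAST])
            lin_only = fit_mixed_model(df, "z", [LINEAR_CONTRAST])
            match_only = fit_mixed_model(df, "z", [MATCH_MISMATCH_CONTRAST])
            match_hits += compare_models(full, lin_only).p < 0.05
            lin_hits += compare_models(full, match_only).p < 0.05
        assert lin_hits / n_rep >= 0.8
        assert match_hits / n_rep <= 0.15


class TestAcrossParticipantCorrelation:
    def test_identity_gives_r_one(self):
        x = np.arange(5.0)
        r, p = across_participant_correlation(x, x)
        assert r == pytest.approx(1.0)

    def test_five_point_toy_matches_hand_formula(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0])
        r, p = across_participant_correlation(x, y)
        num = np.sum((x - x.mean()) * (y - y.mean()))
        den = math.sqrt(np.sum((x - x.mean()) ** 2)
                        * np.sum((y - y.mean()) ** 2))
        assert r == pytest.approx(num / den, abs=1e-12)

    def test_null_calibration(self):
        rng = np.random.default_rng(18)
        hits = sum(across_participant_correlation(
            rng.standard_normal(19), rng.standard_normal(19))[1] < 0.05
            for _ in range(100))
        assert 0.0 <= hits / 100 <= 0.12

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            across_participant_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="size >= 3"):
            across_participant_correlation([1.0, 2.0], [1.0, 2.0])
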