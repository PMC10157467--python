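"""Inferential battery: dfs, identities, null behavior, and cross-checks."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from avsync import stats as avstats


class TestMixedAnova:
    def test_printed_degrees_of_freedom(self, profiles):
        # 141 SJ participants in 3 groups, 8 ISIs per order
        for order in ("AV", "VA"):
            aov = avstats.mixed_anova_synchrony(profiles, order).set_index("effect")
            assert (aov.loc["group", "df1"], aov.loc["group", "df2"]) == (2, 138)
            assert (aov.loc["isi", "df1"], aov.loc["isi", "df2"]) == (7, 966)
            assert (aov.loc["group x isi", "df1"], aov.loc["group x isi", "df2"]) == (14, 966)
            assert ((aov["np2"] >= 0) & (aov["np2"] <= 1)).all()

    def test_duplicated_groups_give_near_zero_group_f(self):
        rng = np.random.default_rng(0)
        isis = [25.0, 100.0, 251.0]
        rows = []
        base = rng.normal(size=(30, 3))
        for g, label in enumerate(["CD", "TD"]):
            for i in range(30):
                for j, isi in enumerate(isis):
                    rows.append(
                        {
                            "participant_id": f"{label}{i}",
                            "group": label,
                            "soa_ms": isi,
                            "order": "VA",
                            "proportion": base[i, j],  # identical data per group
                        }
                    )
        aov = avstats.mixed_anova_synchrony(pd.DataFrame(rows), "VA").set_index("effect")
        assert aov.loc["group", "F"] == pytest.approx(0.0, abs=1e-10)

    def test_requires_two_groups(self):
        df = pd.DataFrame(
            {
                "participant_id": ["P1"] * 2 + ["P2"] * 2,
                "group": "CD",
                "soa_ms": [25.0, 100.0] * 2,
                "order": "VA",
                "proportion": [0.9, 0.5, 0.8, 0.4],
            }
        )
        with pytest.raises(ValueError, match="2 groups"):
            avstats.mixed_anova_synchrony(df, "VA")


class TestSimpleEffectsAndLsd:
    def test_identical_groups_have_zero_lsd_difference(self):
        y = np.tile(np.arange(10.0), 2)
        g = np.repeat(["CD", "TD"], 10)
        lsd = avstats.lsd_pairwise(y, g)
        assert lsd["mean_diff"].iloc[0] == pytest.approx(0.0)

    def test_lsd_antisymmetric_means(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=30)
        g = np.repeat(["AD", "CD", "TD"], 10)
        lsd = avstats.lsd_pairwise(y, g).set_index(["A", "B"])
        means = {lbl: y[g == lbl].mean() for lbl in ("AD", "CD", "TD")}
        assert lsd.loc[("AD", "CD"), "mean_diff"] == pytest.approx(means["AD"] - means["CD"])
        assert lsd.loc[("CD", "TD"), "mean_diff"] == pytest.approx(means["CD"] - means["TD"])

    def test_large_shift_at_one_isi_is_detected(self):
        # A +0.3 proportion shift for one group at a single ISI, n=50/group,
        # should be flagged at alpha = 0.001 in essentially every replicate.
        rng = np.random.default_rng(1)
        hits = 0
        n_sims = 30
        for _ in range(n_sims):
            rows = []
            for label, shift in (("CD", 0.3), ("TD", 0.0), ("AD", 0.0)):
                for i in range(50):
                    for isi, s in ((100.0, shift), (251.0, 0.0)):
                        rows.append(
                            {
                                "participant_id": f"{label}{i}",
                                "group": label,
                                "soa_ms": isi,
                                "order": "VA",
                                "proportion": np.clip(0.5 + s + rng.normal(0, 0.1), 0, 1),
                            }
                        )
            res = avstats.simple_effects_by_isi(pd.DataFrame(rows), "VA")
            if res[100.0]["anova"]["p"].iloc[0] < 0.001:
                hits += 1
        assert hits >= n_sims - 1

    def test_simple_effects_cover_every_isi(self, profiles):
        res = avstats.simple_effects_by_isi(profiles, "AV")
        assert sorted(res) == [25.0, 40.0, 63.0, 100.0, 158.0, 251.0, 398.0, 500.0]
        for isi, tables in res.items():
            assert tables["anova"]["df1"].iloc[0] == 2
            assert len(tables["lsd"]) == 3


class TestWindowAnova:
    def test_printed_degrees_of_freedom(self, windows):
        # 126 fitted participants, 3 groups
        res = avstats.window_anova(windows, "tbw")
        assert res["anova"]["df1"].iloc[0] == 2
        assert res["anova"]["df2"].iloc[0] == 123

    def test_excluded_participants_do_not_enter(self, windows):
        res = avstats.window_anova(windows, "va_tbw")
        n = res["anova"]["df2"].iloc[0] + 3
        assert n == (windows["status"] == "ok").sum()


class TestPairedContrast:
    def test_cd_degrees_of_freedom(self, windows):
        table = avstats.within_va_av_contrast(windows, "CD")
        assert (table["df1"].iloc[0], table["df2"].iloc[0]) == (1, 44)

    def test_equal_halves_give_zero_f(self):
        w = pd.DataFrame(
            {
                "participant_id": [f"P{i}" for i in range(10)],
                "group": "CD",
                "va_tbw": np.linspace(100, 300, 10),
                "av_tbw": np.linspace(100, 300, 10),
                "status": "ok",
            }
        )
        assert avstats.within_va_av_contrast(w, "CD")["F"].iloc[0] == pytest.approx(0.0, abs=1e-10)

    def test_paired_f_equals_squared_paired_t(self):
        rng = np.random.default_rng(5)
        w = pd.DataFrame(
            {
                "participant_id": [f"P{i}" for i in range(25)],
                "group": "TD",
                "va_tbw": rng.normal(220, 60, 25),
                "av_tbw": rng.normal(150, 50, 25),
                "status": "ok",
            }
        )
        F = avstats.within_va_av_contrast(w, "TD")["F"].iloc[0]
        t = sps.ttest_rel(w["va_tbw"], w["av_tbw"]).statistic
        assert F == pytest.approx(t**2, rel=1e-9)


class TestAncova:
    def test_printed_degrees_of_freedom(self, order_errors, profiles):
        res = avstats.ancova_toj_errors(order_errors, profiles, "VA")
        assert (res.table["df1"].iloc[0], res.table["df2"].iloc[0]) == (2, 137)

    def test_covariate_absorbs_all_group_variance(self):
        # identical covariate/residual patterns in every group: nothing is
        # left for the group factor once the covariate is controlled
        rng = np.random.default_rng(2)
        cov = np.tile(rng.normal(size=20), 3)
        noise = np.tile(rng.normal(size=20), 3)
        data = pd.DataFrame(
            {
                "group": np.repeat(["CD", "TD", "AD"], 20),
                "toj_error_pct": 3.0 * cov + 10.0 + noise,
                "sj_sync_pct": cov,
            }
        )
        res = avstats.ancova(data, dv="toj_error_pct", covar="sj_sync_pct")
        assert res.table["F"].iloc[0] == pytest.approx(0.0, abs=1e-9)
        assert abs(res.covariate_coef - 3.0) < 0.5

    def test_constant_covariate_is_degenerate(self):
        data = pd.DataFrame(
            {
                "group": np.repeat(["CD", "TD"], 5),
                "toj_error_pct": np.arange(10.0),
                "sj_sync_pct": 1.0,
            }
        )
        with pytest.raises(ValueError, match="covariate"):
            avstats.ancova(data, dv="toj_error_pct", covar="sj_sync_pct")

    def test_group_error_ordering_in_default_cohort(self, order_errors, profiles):
        res = avstats.ancova_toj_errors(order_errors, profiles, "VA")
        adj = res.adjusted_means.set_index("group")["adjusted_mean"]
        assert adj["CD"] > adj["TD"] > adj["AD"]


class TestHierarchicalRegression:
    @staticmethod
    def _orthogonal_scores(n=48, seed=0):
        rng = np.random.default_rng(seed)
        raw = np.column_stack([np.ones(n), rng.normal(size=(n, 6))])
        q, _ = np.linalg.qr(raw)
        cols = ["gender", "age_years", "raven", "phonological_awareness",
                "rapid_naming", "va_tbw"]
        df = pd.DataFrame(q[:, 1:], columns=cols)
        df["group"] = "CD"
        return df

    def test_block_structure(self, scores, windows):
        merged = scores.merge(
            windows[windows["status"] == "ok"][["participant_id", "va_tbw"]],
            on="participant_id",
        )
        res = avstats.hierarchical_regression(merged, "va_tbw")
        assert [b.predictors for b in res.blocks] == [
            ["gender", "age_years", "raven"],
            ["phonological_awareness", "rapid_naming"],
            ["va_tbw"],
        ]
        r2 = [b.r2 for b in res.blocks]
        assert r2 == sorted(r2)
        assert res.blocks[1].delta_r2 == pytest.approx(r2[1] - r2[0])

    def test_noiseless_dv_reaches_r2_one(self):
        df = self._orthogonal_scores()
        df["reading_fluency"] = (
            0.3 * df["gender"] + 0.2 * df["age_years"] - 0.1 * df["raven"]
            + 0.5 * df["phonological_awareness"] - 0.4 * df["rapid_naming"]
            - 0.2 * df["va_tbw"]
        )
        res = avstats.hierarchical_regression(df, "va_tbw")
        assert res.blocks[-1].r2 == pytest.approx(1.0, abs=1e-10)

    def test_orthogonal_delta_r2_equals_sum_of_squared_correlations(self):
        df = self._orthogonal_scores(seed=7)
        rng = np.random.default_rng(8)
        df["reading_fluency"] = rng.normal(size=len(df))
        res = avstats.hierarchical_regression(df, "va_tbw")
        z = (df - df.mean(numeric_only=True)) / df.std(numeric_only=True, ddof=1)
        for blk in res.blocks:
            expect = sum(
                float(np.corrcoef(z[c], z["reading_fluency"])[0, 1]) ** 2
                for c in blk.predictors
            )
            assert blk.delta_r2 == pytest.approx(expect, abs=1e-10)

    def test_r2_invariant_to_within_block_order(self):
        df = self._orthogonal_scores(seed=9)
        rng = np.random.default_rng(10)
        df["reading_fluency"] = rng.normal(size=len(df))
        a = avstats.hierarchical_regression(df, "va_tbw")
        blocks = [["raven", "gender", "age_years"], ["rapid_naming", "phonological_awareness"], ["va_tbw"]]
        b = avstats.hierarchical_regression(df, "va_tbw", blocks=blocks)
        for ba, bb in zip(a.blocks, b.blocks):
            assert ba.r2 == pytest.approx(bb.r2, abs=1e-12)

    def test_collinear_block_raises_naming_block(self):
        df = self._orthogonal_scores(seed=11)
        df["va_tbw"] = df["raven"]  # duplicate of an earlier predictor
        df["reading_fluency"] = np.arange(len(df), dtype=float)
        with pytest.raises(ValueError, match="va_tbw"):
            avstats.hierarchical_regression(df, "va_tbw")


class TestDemographics:
    def test_child_t_df_is_104(self, scores):
        res = avstats.demographic_tests(scores).set_index("variable")
        assert res.loc["age_years", "df"] == 104
        assert res.loc["raven", "test"] == "t"

    def test_identical_vectors_give_t_zero(self):
        df = pd.DataFrame(
            {
                "group": np.repeat(["CD", "TD"], 20),
                "gender": ["M", "F"] * 20,
                "grade": ["3", "4"] * 20,
                "age_years": np.tile(np.linspace(9, 11, 20), 2),
                "raven": np.tile(np.linspace(90, 110, 20), 2),
                "character_recognition": 1000.0,
                "reading_fluency": np.tile(np.linspace(100, 200, 20), 2),
                "phonological_awareness": 30.0,
                "orthographic_knowledge": 70.0,
                "rapid_naming": 40.0,
            }
        )
        res = avstats.demographic_tests(df).set_index("variable")
        assert res.loc["age_years", "stat"] == pytest.approx(0.0, abs=1e-12)

    def test_gender_chi_square_matches_hand_formula(self):
        # 2x2 Pearson chi-square without continuity correction on the
        # counts 32/21 vs 33/20.
        rows = []
        for label, males, females in (("CD", 32, 21), ("TD", 33, 20)):
            rows += [{"group": label, "gender": "M"}] * males
            rows += [{"group": label, "gender": "F"}] * females
        df = pd.DataFrame(rows)
        for col in ("grade", "age_years", "raven", "character_recognition",
                    "reading_fluency", "phonological_awareness",
                    "orthographic_knowledge", "rapid_naming"):
            df[col] = np.arange(len(df), dtype=float) if col != "grade" else "3"
        res = avstats.demographic_tests(df).set_index("variable")
        a, b, c, d = 21, 32, 20, 33  # crosstab order: F, M rows sorted
        n = a + b + c + d
        expect = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        assert res.loc["gender", "stat"] == pytest.approx(expect, abs=1e-9)
        assert round(res.loc["gender", "stat"], 2) == 0.04
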