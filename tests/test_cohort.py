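"""Observer models, session simulation, cohort sampling and score generation."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import binom

import statsmodels.api as sm

from avsync.cohort import (
    CohortConfig,
    ConfigurationError,
    GroupParamSpec,
    ObserverParams,
    ParamDist,
    ScoreDist,
    ScoreModel,
    default_cohort_config,
    generate_behavioral_scores,
    sample_cohort,
    simulate_session,
    sj_response_probability,
    toj_visual_first_probability,
    true_half_windows,
)
from avsync.design import StudyDesign
from avsync.io import trials_to_frame


class TestResponseProbabilities:
    def test_peak_equals_amplitude_without_lapse(self):
        obs = ObserverParams(A=0.87, pss_mu=35.0, sigma=120.0, lapse=0.0)
        assert sj_response_probability(obs, 35.0) == pytest.approx(0.87)

    def test_far_asymptote_is_half_lapse(self):
        obs = ObserverParams(A=0.9, pss_mu=0.0, sigma=100.0, lapse=0.1)
        assert sj_response_probability(obs, 1e7) == pytest.approx(0.05)

    def test_known_value(self):
        # (1-0.02)*0.9*exp(-100^2/(2*100^2)) + 0.01 = 0.5450 to 4 dp
        obs = ObserverParams(A=0.9, pss_mu=0.0, sigma=100.0, lapse=0.02)
        assert sj_response_probability(obs, 100.0) == pytest.approx(0.5450, abs=5e-5)

    def test_toj_midpoint_and_slope_point(self):
        obs = ObserverParams(A=0.9, pss_mu=0.0, sigma=100.0, lapse=0.0,
                             toj_mu=20.0, toj_sigma=80.0, toj_lapse=0.0)
        assert toj_visual_first_probability(obs, 20.0) == pytest.approx(0.5)
        assert toj_visual_first_probability(obs, 100.0) == pytest.approx(0.8413, abs=5e-5)
        obs2 = ObserverParams(A=0.9, pss_mu=0.0, sigma=100.0, lapse=0.0,
                              toj_mu=0.0, toj_sigma=80.0, toj_lapse=0.1)
        assert toj_visual_first_probability(obs2, 1e7) == pytest.approx(0.95)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        A=st.floats(0.05, 1.0),
        mu=st.floats(-300, 300),
        sigma=st.floats(5, 1000),
        lapse=st.floats(0, 1),
        soa=st.floats(-600, 600),
    )
    def test_probability_bounds_and_symmetry(self, A, mu, sigma, lapse, soa):
        obs = ObserverParams(A=A, pss_mu=mu, sigma=sigma, lapse=lapse)
        p = sj_response_probability(obs, soa)
        assert 0.0 <= p <= 1.0
        mirrored = sj_response_probability(obs, 2 * mu - soa)
        assert p == pytest.approx(mirrored, abs=1e-12)


class TestSimulateSession:
    def test_design_counts(self, design):
        obs = ObserverParams(A=0.95, pss_mu=0.0, sigma=150.0, lapse=0.02)
        trials = simulate_session(obs, design, "SJ", 0)
        assert len(trials) == 320
        counts = pd.Series([t.soa_ms for t in trials]).value_counts()
        assert len(counts) == 16
        assert (counts == 20).all()

    def test_certain_observer_always_synchronous(self, design):
        obs = ObserverParams(A=1.0, pss_mu=0.0, sigma=1e9, lapse=0.0)
        trials = simulate_session(obs, design, "SJ", 1)
        assert all(t.response == "synchronous" for t in trials)

    def test_guesser_within_binomial_band(self, design):
        obs = ObserverParams(A=0.95, pss_mu=0.0, sigma=150.0, lapse=1.0)
        trials = simulate_session(obs, design, "SJ", 9)
        k = sum(t.response == "synchronous" for t in trials)
        lo, hi = binom.ppf(0.005, 320, 0.5), binom.ppf(0.995, 320, 0.5)
        assert lo <= k <= hi

    def test_seed_determinism(self, design):
        obs = ObserverParams(A=0.9, pss_mu=10.0, sigma=200.0, lapse=0.05)
        assert simulate_session(obs, design, "SJ", 7) == simulate_session(obs, design, "SJ", 7)

    def test_empirical_proportions_converge_to_model(self):
        # 2,000 trials per cell pins every cell proportion to the response
        # probability within 0.02.
        design = StudyDesign(trials_per_cell=2000)
        obs = ObserverParams(A=0.92, pss_mu=25.0, sigma=180.0, lapse=0.04)
        trials = simulate_session(obs, design, "SJ", 123)
        df = trials_to_frame(trials)
        props = df.groupby("soa_ms")["response"].apply(lambda s: (s == "synchronous").mean())
        for soa, prop in props.items():
            assert prop == pytest.approx(sj_response_probability(obs, soa), abs=0.02)


class TestSampleCohort:
    def test_default_counts(self, cohort):
        truth = cohort["truth"]
        assert len(truth) == 143
        assert truth.groupby("group").size().to_dict() == {"AD": 37, "CD": 53, "TD": 53}

    def test_two_adults_are_toj_only(self, cohort):
        truth, trials = cohort["truth"], cohort["trials"]
        toj_only = truth[truth["toj_only"]]
        assert len(toj_only) == 2
        assert (toj_only["group"] == "AD").all()
        sj_ids = {t.participant_id for t in trials if t.task == "SJ"}
        assert sj_ids.isdisjoint(toj_only["participant_id"])
        assert len(sj_ids) == 141

    def test_zero_variance_group_shares_parameters(self):
        dists = {
            "A": ParamDist(0.9, 0.0), "pss_mu": ParamDist(30.0, 0.0),
            "sigma": ParamDist(200.0, 0.0), "lapse": ParamDist(0.02, 0.0),
            "toj_mu": ParamDist(0.0, 0.0), "toj_sigma": ParamDist(100.0, 0.0),
            "toj_lapse": ParamDist(0.05, 0.0),
        }
        spec = GroupParamSpec(label="TD", n_participants=5, dists=dists)
        config = CohortConfig(
            design=StudyDesign(), groups=(spec,),
            score_model=default_cohort_config(0).score_model, seed=0,
        )
        observers, _, _ = sample_cohort(config, tasks=())
        assert len({o for o in observers.values()}) == 1

    def test_determinism_byte_identical(self, tmp_path):
        frames = []
        for _ in range(2):
            config = default_cohort_config(11)
            _, trials, _ = sample_cohort(config)
            path = tmp_path / "t.csv"
            trials_to_frame(trials).to_csv(path, index=False)
            frames.append(path.read_bytes())
        assert frames[0] == frames[1]

    def test_impossible_truncation_bounds_raise(self):
        with pytest.raises(ConfigurationError):
            ParamDist(0.5, 0.1, lo=1.0, hi=0.0)

    def test_true_windows_match_targets_on_average(self, cohort):
        # The generator is parameterized so clean observers' true group mean
        # windows sit near the configured targets.
        truth = cohort["truth"]
        clean = truth[truth["role"] == "clean"]
        cd = clean[clean["group"] == "CD"]["true_tbw"].mean()
        td = clean[clean["group"] == "TD"]["true_tbw"].mean()
        assert cd == pytest.approx(394.29, abs=60.0)
        assert td == pytest.approx(316.34, abs=60.0)
        assert cd > td


class TestBehavioralScores:
    def test_noiseless_fluency_has_r2_one(self):
        # Weights with squared sum 1 leave zero residual variance; a
        # within-group regression on the generative predictors is exact.
        w = {"phonological_awareness": 0.6, "rapid_naming": -0.6, "va_tbw": math.sqrt(1 - 0.72)}
        model = default_cohort_config(0).score_model
        model = ScoreModel(
            score_dists=model.score_dists, p_male=model.p_male, age=model.age,
            fluency_weights=w,
        )
        truth = pd.DataFrame(
            {
                "participant_id": [f"CD{i:02d}" for i in range(40)],
                "group": "CD",
                "true_va_tbw": np.random.default_rng(0).normal(220, 60, 40),
                "true_pss": 40.0,
            }
        )
        recs = generate_behavioral_scores(truth, model, seed=4)
        df = pd.DataFrame(
            {
                "pa": [r.phonological_awareness for r in recs],
                "ran": [r.rapid_naming for r in recs],
                "va": truth["true_va_tbw"].to_numpy(),
                "fluency": [r.reading_fluency for r in recs],
            }
        )
        # exclude rows touched by instrument-range clipping
        df = df[(df.pa > 0) & (df.pa < 40)]
        fit = sm.OLS(df["fluency"], sm.add_constant(df[["pa", "ran", "va"]])).fit()
        assert fit.rsquared == pytest.approx(1.0, abs=1e-9)

    def test_group_mean_matches_configuration_at_large_n(self):
        model = default_cohort_config(0).score_model
        n = 5000
        truth = pd.DataFrame(
            {
                "participant_id": [f"CD{i:05d}" for i in range(n)],
                "group": "CD",
                "true_va_tbw": np.random.default_rng(1).normal(240, 90, n),
                "true_pss": 40.0,
            }
        )
        recs = generate_behavioral_scores(truth, model, seed=2)
        fluency = np.array([r.reading_fluency for r in recs])
        target = model.score_dists["CD"]["reading_fluency"]
        sem = target.sd / math.sqrt(n)
        assert abs(fluency.mean() - target.mean) < 2 * sem + 0.5

    def test_rapid_naming_anticorrelates_with_fluency(self, scores):
        kids = scores[scores["group"].isin(["CD", "TD"])]
        assert kids["rapid_naming"].corr(kids["reading_fluency"]) < 0

    def test_adults_have_no_child_scores(self, scores):
        adults = scores[scores["group"] == "AD"]
        assert adults["reading_fluency"].isna().all()
        assert adults["raven"].isna().all()


def test_true_half_windows_closed_form():
    obs = ObserverParams(A=0.95, pss_mu=30.0, sigma=150.0, lapse=0.02)
    av, va = true_half_windows(obs, criterion=0.70)
    d = 150.0 * math.sqrt(2 * math.log((0.98 * 0.95) / (0.70 - 0.01)))
    assert av == pytest.approx(d - 30.0)
    assert va == pytest.approx(d + 30.0)
    flat = ObserverParams(A=0.6, pss_mu=0.0, sigma=150.0, lapse=0.0)
    assert all(math.isnan(v) for v in true_half_windows(flat))
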