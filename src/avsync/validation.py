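"""Monte-Carlo validation utilities: oracle agreement, parameter recovery,
type-I-error calibration of every inferential test, and a replicate-cohort
power check on the group window contrast.

These routines exist so the package can audit itself end to end: they drive
the public simulation, fitting and statistics APIs on seeded synthetic data
and return summary numbers (agreement errors, recovery errors, rejection
rates). Null-calibration problem sizes are deliberately modest (noted per
function) — under the null the rejection rate does not depend on sample size,
so small cells keep the 1,000-rep loops quick.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from avsync import stats as avstats
from avsync.cohort import (
    CohortConfig,
    ObserverParams,
    default_cohort_config,
    sample_cohort,
    simulate_session,
    true_half_windows,
)
from avsync.design import StudyDesign
from avsync.io import aggregate_synchrony
from avsync.psychometric import (
    DETECTED,
    FitConfig,
    GaussianFit,
    extract_window,
    fit_cohort,
    fit_gaussian,
    gaussian,
)


def crossing_agreement(n_draws: int = 1000, seed: int = 0) -> float:
    """Max |analytic - bisection| criterion crossing over random parameters.

    The analytic crossings mu +/- sigma*sqrt(2 ln(A/c)) from window
    extraction are compared against numeric root-finding (Brent) on the
    Gaussian itself; returns the worst absolute disagreement in ms.
    """
    rng = np.random.default_rng(seed)
    config = FitConfig(max_abs_soa=math.inf)
    worst = 0.0
    for _ in range(n_draws):
        c = config.criterion
        A = rng.uniform(c + 0.02, 1.0)
        sigma = rng.uniform(30.0, 400.0)
        # keep the window straddling zero so both half-windows are crossings
        d = sigma * math.sqrt(2.0 * math.log(A / c))
        mu = rng.uniform(-0.9 * d, 0.9 * d)
        fit = GaussianFit(A, mu, sigma, 0.0, 1.0, True)
        w = extract_window(fit, config)
        assert w.status_av == DETECTED and w.status_va == DETECTED and not w.av_clamped
        span = 12.0 * sigma
        left = brentq(lambda x: gaussian(x, A, mu, sigma) - c, mu - span, mu, xtol=1e-12)
        right = brentq(lambda x: gaussian(x, A, mu, sigma) - c, mu, mu + span, xtol=1e-12)
        worst = max(worst, abs(-left - w.av_tbw), abs(right - w.va_tbw))
    return worst


@dataclass
class RecoveryResult:
    mean_pss_error: float  # |mean fitted PSS - true PSS|, ms
    mean_tbw_error: float  # |mean fitted TBW - true TBW|, ms
    n_observers: int


def parameter_recovery(
    n_observers: int = 200,
    seed: int = 0,
    obs: ObserverParams | None = None,
) -> RecoveryResult:
    """Fit simulated sessions at study scale (20 trials per signed SOA) from a
    single known observer and report the absolute error of the mean recovered
    PSS and total window."""
    obs = obs or ObserverParams(A=0.95, pss_mu=30.0, sigma=150.0, lapse=0.02)
    design = StudyDesign()
    config = FitConfig()
    true_av, true_va = true_half_windows(obs, config.criterion, config.max_abs_soa)
    rng = np.random.default_rng(seed)
    pss, tbw = [], []
    for _ in range(n_observers):
        trials = simulate_session(obs, design, "SJ", rng)
        profile = aggregate_synchrony(trials)[0]
        w = extract_window(fit_gaussian(profile, config), config)
        if w.detected:
            pss.append(w.pss)
            tbw.append(w.tbw)
    return RecoveryResult(
        mean_pss_error=abs(float(np.mean(pss)) - obs.pss_mu),
        mean_tbw_error=abs(float(np.mean(tbw)) - (true_av + true_va)),
        n_observers=n_observers,
    )


def noiseless_recovery(
    A: float = 0.9, mu: float = 20.0, sigma: float = 120.0
) -> float:
    """Max absolute parameter error when fitting an exact Gaussian profile."""
    from avsync.design import SynchronyProfile

    design = StudyDesign()
    n = design.trials_per_cell
    points = {}
    for soa in design.signed_soas():
        p = gaussian(np.array(soa), A, mu, sigma)
        points[soa] = (10**6, int(round(float(p) * 10**6)))
    profile = SynchronyProfile("noiseless", "TD", points)
    fit = fit_gaussian(profile, FitConfig())
    return max(abs(fit.A - A), abs(fit.mu - mu), abs(fit.sigma - sigma))


# ---------------------------------------------------------------------------
# Type-I-error calibration (null simulations). Each function simulates data
# with NO true effect and returns the fraction of replicates with p < alpha.


def _rate(ps: list[float], alpha: float) -> float:
    return float(np.mean(np.asarray(ps) < alpha))


def typeI_mixed_anova(
    n_reps: int = 1000, seed: int = 0, alpha: float = 0.05,
    n_per_group: int = 20, n_levels: int = 4,
) -> float:
    """Null rejection rate of the mixed-ANOVA group effect (3 groups,
    ``n_levels`` within-cells of iid normal noise)."""
    rng = np.random.default_rng(seed)
    isis = [25.0, 100.0, 251.0, 500.0][:n_levels]
    n = 3 * n_per_group
    base = pd.DataFrame(
        {
            "participant_id": np.repeat([f"P{i:03d}" for i in range(n)], n_levels),
            "group": np.repeat(["CD", "TD", "AD"], n_per_group * n_levels),
            "soa_ms": np.tile(isis, n),
            "order": "VA",
        }
    )
    ps = []
    for _ in range(n_reps):
        df = base.copy()
        df["proportion"] = rng.normal(size=len(df))
        aov = avstats.mixed_anova_synchrony(df, "VA")
        ps.append(float(aov.loc[aov["effect"] == "group", "p"].iloc[0]))
    return _rate(ps, alpha)


def typeI_window_anova(
    n_reps: int = 1000, seed: int = 0, alpha: float = 0.05, n_per_group: int = 20
) -> float:
    """Null rejection rate of the one-way window ANOVA (3 identical groups)."""
    rng = np.random.default_rng(seed)
    groups = np.repeat(["CD", "TD", "AD"], n_per_group)
    ps = []
    for _ in range(n_reps):
        windows = pd.DataFrame(
            {
                "participant_id": [f"P{i}" for i in range(len(groups))],
                "group": groups,
                "tbw": rng.normal(300.0, 100.0, len(groups)),
                "status": "ok",
            }
        )
        res = avstats.window_anova(windows, "tbw")
        ps.append(float(res["anova"]["p"].iloc[0]))
    return _rate(ps, alpha)


def typeI_lsd(
    n_reps: int = 1000, seed: int = 0, alpha: float = 0.05, n_per_group: int = 20
) -> float:
    """Null rejection rate of one LSD pairwise comparison (first pair)."""
    rng = np.random.default_rng(seed)
    groups = np.repeat(["CD", "TD", "AD"], n_per_group)
    ps = []
    for _ in range(n_reps):
        y = rng.normal(size=len(groups))
        ps.append(float(avstats.lsd_pairwise(y, groups)["p"].iloc[0]))
    return _rate(ps, alpha)


def typeI_paired_contrast(
    n_reps: int = 1000, seed: int = 0, alpha: float = 0.05, n: int = 20
) -> float:
    """Null rejection rate of the paired VA-vs-AV window contrast."""
    rng = np.random.default_rng(seed)
    ps = []
    for _ in range(n_reps):
        windows = pd.DataFrame(
            {
                "participant_id": [f"P{i}" for i in range(n)],
                "group": "CD",
                "va_tbw": rng.normal(200.0, 60.0, n),
                "av_tbw": rng.normal(200.0, 60.0, n),
                "status": "ok",
            }
        )
        table = avstats.within_va_av_contrast(windows, "CD")
        ps.append(float(table["p"].iloc[0]))
    return _rate(ps, alpha)


def typeI_ancova(
    n_reps: int = 1000, seed: int = 0, alpha: float = 0.05, n_per_group: int = 20
) -> float:
    """Null rejection rate of the ANCOVA group effect: the DV depends on the
    covariate but not on group."""
    rng = np.random.default_rng(seed)
    groups = np.repeat(["CD", "TD", "AD"], n_per_group)
    ps = []
    for _ in range(n_reps):
        cov = rng.normal(size=len(groups))
        dv = 0.5 * cov + rng.normal(size=len(groups))
        data = pd.DataFrame({"group": groups, "toj_error_pct": dv, "sj_sync_pct": cov})
        res = avstats.ancova(data, dv="toj_error_pct", covar="sj_sync_pct")
        ps.append(float(res.table["p"].iloc[0]))
    return _rate(ps, alpha)


def typeI_regression_block3(
    n_reps: int = 1000, seed: int = 0, alpha: float = 0.05, n: int = 60
) -> float:
    """Null rejection rate of the block-3 F-change: the window measure is
    independent of the DV given blocks 1-2."""
    rng = np.random.default_rng(seed)
    ps = []
    for _ in range(n_reps):
        df = pd.DataFrame(
            {
                "group": "CD",
                "gender": rng.choice(["M", "F"], n),
                "age_years": rng.normal(10.0, 1.0, n),
                "raven": rng.normal(100.0, 10.0, n),
                "phonological_awareness": rng.normal(30.0, 6.0, n),
                "rapid_naming": rng.normal(40.0, 10.0, n),
                "va_tbw": rng.normal(200.0, 80.0, n),
            }
        )
        df["reading_fluency"] = (
            150.0
            + 2.0 * df["phonological_awareness"]
            - 1.5 * df["rapid_naming"]
            + rng.normal(0.0, 30.0, n)
        )
        res = avstats.hierarchical_regression(df, "va_tbw")
        ps.append(res.blocks[2].p_change)
    return _rate(ps, alpha)


ALL_TYPEI = {
    "mixed_anova_group": typeI_mixed_anova,
    "window_anova": typeI_window_anova,
    "lsd_pairwise": typeI_lsd,
    "paired_contrast": typeI_paired_contrast,
    "ancova_group": typeI_ancova,
    "regression_block3": typeI_regression_block3,
}


def children_config(seed: int) -> CohortConfig:
    """Default cohort restricted to the two child groups."""
    cfg = default_cohort_config(seed)
    return CohortConfig(
        design=cfg.design, groups=cfg.groups[:2], score_model=cfg.score_model, seed=seed
    )


def cd_td_sign_rate(n_cohorts: int = 200, seed: int = 0) -> float:
    """Fraction of replicate child cohorts (full pipeline: simulate ->
    aggregate -> fit -> group means) whose fitted mean total window is larger
    in the dyslexic group than in the control group."""
    config = FitConfig()
    hits = 0
    for k in range(n_cohorts):
        cohort = children_config(seed * 100_000 + k)
        _, trials, _ = sample_cohort(cohort, tasks=("SJ",))
        windows = fit_cohort(aggregate_synchrony(trials), config)
        ok = windows[windows["status"] == "ok"]
        means = ok.groupby("group")["tbw"].mean()
        if means["CD"] > means["TD"]:
            hits += 1
    return hits / n_cohorts
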