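"""Seeded synthetic observers, SJ/TOJ sessions, and correlated behavioral scores.

The generative observer answers "synchronous" on an SJ trial with probability

    p(soa) = (1 - lapse) * A * exp(-(soa - pss_mu)^2 / (2 sigma^2)) + lapse / 2

(a Gaussian synchrony curve with a stimulus-independent lapse split evenly
across the two responses), and "visual first" on a TOJ trial with probability

    p(soa) = (1 - toj_lapse) * Phi((soa - toj_mu) / toj_sigma) + toj_lapse / 2.

Group defaults are parameterized by target mean/SD of the temporal binding
window (TBW) and point of subjective simultaneity (PSS), from which the
Gaussian width distribution is derived analytically, so the cohort's true
group-level windows match the configured targets. Each group additionally
contains a fixed number of deliberately degenerate observers (ceiling
responders on the visual-leading side, chance-level responders, and
flat responders) that exercise the downstream fit-failure taxonomy.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, truncnorm

from avsync.design import (
    CHILD_SCORE_FIELDS,
    SCORE_RANGES,
    ParticipantScores,
    StudyDesign,
    TrialRecord,
)


class ConfigurationError(ValueError):
    """Raised for impossible generator configurations (e.g. lo > hi bounds)."""


@dataclass(frozen=True)
class ObserverParams:
    """Generative parameters of one synthetic observer."""

    A: float  # peak synchrony probability, (0, 1]
    pss_mu: float  # center of the synchrony Gaussian, ms (signed)
    sigma: float  # width of the synchrony Gaussian, ms
    lapse: float  # SJ lapse probability, [0, 1]
    toj_mu: float = 0.0  # TOJ psychometric center, ms
    toj_sigma: float = 100.0  # TOJ slope, ms
    toj_lapse: float = 0.05  # TOJ lapse probability, [0, 1]

    def __post_init__(self) -> None:
        if not 0 < self.A <= 1:
            raise ValueError("A must be in (0, 1]")
        if self.sigma <= 0 or self.toj_sigma <= 0:
            raise ValueError("sigma and toj_sigma must be positive")
        if not 0 <= self.lapse <= 1 or not 0 <= self.toj_lapse <= 1:
            raise ValueError("lapse rates must be in [0, 1]")


def sj_response_probability(obs: ObserverParams, soa_ms) -> np.ndarray | float:
    """Probability of a 'synchronous' SJ response at a signed SOA."""
    soa = np.asarray(soa_ms, dtype=float)
    core = obs.A * np.exp(-((soa - obs.pss_mu) ** 2) / (2.0 * obs.sigma**2))
    p = (1.0 - obs.lapse) * core + obs.lapse / 2.0
    return p if p.ndim else float(p)


def toj_visual_first_probability(obs: ObserverParams, soa_ms) -> np.ndarray | float:
    """Probability of a 'visual first' TOJ response at a signed SOA."""
    soa = np.asarray(soa_ms, dtype=float)
    p = (1.0 - obs.toj_lapse) * norm.cdf((soa - obs.toj_mu) / obs.toj_sigma) + obs.toj_lapse / 2.0
    return p if p.ndim else float(p)


def true_half_windows(
    obs: ObserverParams, criterion: float = 0.70, max_abs_soa: float = 500.0
) -> tuple[float, float]:
    """Criterion crossings of the generative response curve (AV, VA half-windows).

    Solves (1-lapse)*A*exp(...) + lapse/2 = criterion. Returns NaN for a side
    whose crossing does not exist or lies beyond ``max_abs_soa``; a left
    crossing on the positive side gives an AV half-window of 0.
    """
    peak = (1.0 - obs.lapse) * obs.A
    target = criterion - obs.lapse / 2.0
    if target <= 0 or peak <= target:
        return math.nan, math.nan
    d = obs.sigma * math.sqrt(2.0 * math.log(peak / target))
    left, right = obs.pss_mu - d, obs.pss_mu + d
    av = max(0.0, -left)
    va = right
    if left < -max_abs_soa:
        av = math.nan
    if right > max_abs_soa or right < 0:
        va = math.nan
    return av, va


# ---------------------------------------------------------------------------
# Cohort configuration


@dataclass(frozen=True)
class ParamDist:
    """Truncated-normal distribution for one observer parameter."""

    mean: float
    sd: float
    lo: float = -math.inf
    hi: float = math.inf

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ConfigurationError("sd must be >= 0")
        if self.lo > self.hi:
            raise ConfigurationError(f"impossible truncation bounds [{self.lo}, {self.hi}]")

    def draw(self, rng: np.random.Generator) -> float:
        if self.sd == 0:
            if not self.lo <= self.mean <= self.hi:
                raise ConfigurationError("zero-sd mean outside truncation bounds")
            return self.mean
        a = (self.lo - self.mean) / self.sd
        b = (self.hi - self.mean) / self.sd
        # Inverse-CDF truncated-normal draw (much faster than truncnorm.rvs).
        lo_u, hi_u = norm.cdf(a), norm.cdf(b)
        u = rng.uniform(lo_u, hi_u)
        return float(self.mean + self.sd * norm.ppf(u))


@dataclass(frozen=True)
class GroupParamSpec:
    """Generative description of one cohort group."""

    label: str
    n_participants: int
    dists: dict[str, ParamDist]
    n_ceiling_va: int = 0
    n_chance: int = 0
    n_flat: int = 0
    n_toj_only: int = 0

    def __post_init__(self) -> None:
        if self.n_participants <= 0:
            raise ConfigurationError("n_participants must be positive")
        n_degen = self.n_ceiling_va + self.n_chance + self.n_flat
        if n_degen + self.n_toj_only > self.n_participants:
            raise ConfigurationError("degenerate + TOJ-only counts exceed group size")


# Fixed parameter sets for the degenerate observer roles. The chance responder
# guesses on every trial; the flat responder's curve spans only a few
# percentage points; the ceiling responder stays near ceiling at every
# visual-leading SOA with no criterion crossing inside the tested range.
DEGENERATE_PARAMS = {
    "chance": dict(A=0.9, pss_mu=0.0, sigma=200.0, lapse=1.0),
    "flat": dict(A=0.62, pss_mu=0.0, sigma=1600.0, lapse=0.15),
    "ceiling_va": dict(A=0.99, pss_mu=320.0, sigma=1300.0, lapse=0.02),
}

# Conversion between a target total window and the Gaussian width: the
# generative curve crosses the criterion at pss_mu +/- d with
# d = sigma * sqrt(2 ln((1-lapse)*A / (criterion - lapse/2))).
_DEFAULT_A, _DEFAULT_LAPSE, _DEFAULT_CRITERION = 0.95, 0.02, 0.70


def _width_factor(A: float = _DEFAULT_A, lapse: float = _DEFAULT_LAPSE,
                  criterion: float = _DEFAULT_CRITERION) -> float:
    return math.sqrt(2.0 * math.log((1.0 - lapse) * A / (criterion - lapse / 2.0)))


def _calibrate_truncnorm_mean(target: float, sd: float, lo: float, hi: float) -> float:
    """Raw mean whose [lo, hi]-truncated normal has mean ``target``."""
    if sd == 0:
        return target
    from scipy.optimize import brentq

    def gap(m: float) -> float:
        a, b = (lo - m) / sd, (hi - m) / sd
        return float(truncnorm.mean(a, b, loc=m, scale=sd)) - target

    return float(brentq(gap, lo - 5 * sd, hi + 5 * sd, xtol=1e-6))


def group_spec_from_window_targets(
    label: str,
    n_participants: int,
    pss_mean: float,
    pss_sd: float,
    tbw_mean: float,
    tbw_sd: float,
    toj_mu: ParamDist,
    toj_sigma: ParamDist,
    toj_lapse: ParamDist,
    *,
    n_ceiling_va: int = 0,
    n_chance: int = 0,
    n_flat: int = 0,
    n_toj_only: int = 0,
) -> GroupParamSpec:
    """Build a group spec whose true mean window/PSS equal the given targets.

    pss maps directly onto the Gaussian center; the width distribution is the
    window distribution divided by 2*width_factor. Truncation corners are set
    so that mu_hi + d(sigma_hi) stays ~40 ms inside the 500 ms tested range:
    a clean observer's true crossings never leave the range, and fitting
    noise rarely pushes the estimated crossing past it. Raw truncated-normal
    means are calibrated numerically so the post-truncation means equal the
    targets.
    """
    f = _width_factor()
    sigma_lo, sigma_hi = 60.0, 400.0
    mu_lo, mu_hi = -120.0, 150.0
    sigma_sd = tbw_sd / 2.0 / f
    sigma_mean = _calibrate_truncnorm_mean(tbw_mean / 2.0 / f, sigma_sd, sigma_lo, sigma_hi)
    mu_mean = _calibrate_truncnorm_mean(pss_mean, pss_sd, mu_lo, mu_hi)
    dists = {
        "A": ParamDist(_DEFAULT_A, 0.03, 0.80, 1.0),
        "pss_mu": ParamDist(mu_mean, pss_sd, mu_lo, mu_hi),
        "sigma": ParamDist(sigma_mean, sigma_sd, sigma_lo, sigma_hi),
        "lapse": ParamDist(_DEFAULT_LAPSE, 0.01, 0.0, 0.06),
        "toj_mu": toj_mu,
        "toj_sigma": toj_sigma,
        "toj_lapse": toj_lapse,
    }
    return GroupParamSpec(
        label=label,
        n_participants=n_participants,
        dists=dists,
        n_ceiling_va=n_ceiling_va,
        n_chance=n_chance,
        n_flat=n_flat,
        n_toj_only=n_toj_only,
    )


@dataclass(frozen=True)
class ScoreDist:
    mean: float
    sd: float


@dataclass(frozen=True)
class ScoreModel:
    """Per-group behavioral-score distributions plus the reading-fluency model.

    Children's reading fluency is built as
    group_mean + group_sd * (w_pa * z_PA + w_ran * z_RAN + w_vatbw * z_VATBW
    + residual_frac * eps), with predictors standardized against their
    configured population moments; the default weights give phonological
    awareness a positive, rapid naming a negative and the visual-leading
    half-window a small negative standardized effect.
    """

    score_dists: dict[str, dict[str, ScoreDist]]
    p_male: dict[str, float]
    age: dict[str, ScoreDist]
    fluency_weights: dict[str, float] = field(
        default_factory=lambda: {
            "phonological_awareness": 0.29,
            "rapid_naming": -0.43,
            "va_tbw": -0.17,
        }
    )
    char_weights: dict[str, float] = field(
        default_factory=lambda: {
            "phonological_awareness": 0.30,
            "rapid_naming": -0.35,
            "va_tbw": 0.0,
        }
    )

    def residual_frac(self, weights: dict[str, float]) -> float:
        s = sum(w * w for w in weights.values())
        if s > 1:
            raise ConfigurationError("squared weights exceed 1; residual sd undefined")
        return math.sqrt(1.0 - s)


def default_score_model() -> ScoreModel:
    dists = {
        "CD": {
            "raven": ScoreDist(104.13, 10.08),
            "character_recognition": ScoreDist(947.56, 240.58),
            "reading_fluency": ScoreDist(144.47, 39.55),
            "phonological_awareness": ScoreDist(28.31, 7.30),
            "orthographic_knowledge": ScoreDist(72.62, 3.63),
            "rapid_naming": ScoreDist(45.67, 12.63),
        },
        "TD": {
            "raven": ScoreDist(103.17, 10.23),
            "character_recognition": ScoreDist(1794.58, 209.35),
            "reading_fluency": ScoreDist(206.94, 43.29),
            "phonological_awareness": ScoreDist(33.42, 5.60),
            "orthographic_knowledge": ScoreDist(73.74, 3.23),
            "rapid_naming": ScoreDist(36.47, 6.46),
        },
    }
    return ScoreModel(
        score_dists=dists,
        p_male={"CD": 32 / 53, "TD": 33 / 53, "AD": 8 / 37},
        age={"CD": ScoreDist(9.99, 0.91), "TD": ScoreDist(9.97, 1.02), "AD": ScoreDist(23.05, 3.87)},
    )


@dataclass(frozen=True)
class CohortConfig:
    design: StudyDesign
    groups: tuple[GroupParamSpec, ...]
    score_model: ScoreModel
    seed: int = 0

    def __post_init__(self) -> None:
        labels = [g.label for g in self.groups]
        if len(set(labels)) != len(labels):
            raise ConfigurationError("group labels must be unique")


def default_cohort_config(seed: int = 0) -> CohortConfig:
    """The default three-group study: 53 CD, 53 TD, 37 AD (2 TOJ-only adults).

    Window/PSS targets per group (mean, SD): CD (44.13, 57.02) PSS with
    394.29 (181.31) TBW; TD (28.43, 58.11) / 316.34 (169.97); AD (4.78,
    47.73) / 318.12 (138.12). Degenerate observers: 1 ceiling + 4 chance +
    3 flat in CD, 3 ceiling + 1 chance in TD, 3 ceiling in AD.
    """
    groups = (
        group_spec_from_window_targets(
            "CD", 53, 44.13, 57.02, 394.29, 181.31,
            toj_mu=ParamDist(40.0, 40.0, -150.0, 200.0),
            toj_sigma=ParamDist(190.0, 60.0, 40.0, 400.0),
            toj_lapse=ParamDist(0.28, 0.10, 0.0, 0.6),
            n_ceiling_va=1, n_chance=4, n_flat=3,
        ),
        group_spec_from_window_targets(
            "TD", 53, 28.43, 58.11, 316.34, 169.97,
            toj_mu=ParamDist(30.0, 40.0, -150.0, 200.0),
            toj_sigma=ParamDist(150.0, 50.0, 40.0, 400.0),
            toj_lapse=ParamDist(0.18, 0.08, 0.0, 0.5),
            n_ceiling_va=3, n_chance=1,
        ),
        group_spec_from_window_targets(
            "AD", 37, 4.78, 47.73, 318.12, 138.12,
            toj_mu=ParamDist(5.0, 25.0, -120.0, 120.0),
            toj_sigma=ParamDist(80.0, 30.0, 30.0, 250.0),
            toj_lapse=ParamDist(0.06, 0.04, 0.0, 0.3),
            n_ceiling_va=3, n_toj_only=2,
        ),
    )
    return CohortConfig(
        design=StudyDesign(), groups=groups, score_model=default_score_model(), seed=seed
    )


# ---------------------------------------------------------------------------
# Simulation


def _participant_seed(master_seed: int, participant_id: str, stream: int) -> np.random.Generator:
    """Stable per-participant child stream: adding a participant never
    perturbs another participant's draws."""
    key = zlib.crc32(participant_id.encode())
    return np.random.default_rng(np.random.SeedSequence([master_seed, key, stream]))


def simulate_session(
    obs: ObserverParams,
    design: StudyDesign,
    task: str,
    seed: int | np.random.Generator,
    participant_id: str = "P01",
    group: str = "TD",
    timeout_rate: float = 0.0,
) -> list[TrialRecord]:
    """Simulate one full session: one Bernoulli draw per trial.

    Trial order is a seeded random permutation of the design cells. Reaction
    times are uniform placeholders in [400, 1500] ms; with ``timeout_rate`` > 0
    a trial times out (no response, valid=False) with that probability.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if task not in ("SJ", "TOJ"):
        raise ValueError(f"unknown task {task!r}")
    soas = []
    for isi in design.isi_levels_ms:
        for order in design.orders:
            signed = -isi if order == "AV" else isi
            soas.extend([signed] * design.trials_per_cell)
    soas = np.array(soas, dtype=float)
    soas = soas[rng.permutation(len(soas))]

    if task == "SJ":
        p = np.array([sj_response_probability(obs, s) for s in soas])
        pos_label, neg_label = "synchronous", "asynchronous"
    else:
        p = np.array([toj_visual_first_probability(obs, s) for s in soas])
        pos_label, neg_label = "visual_first", "auditory_first"

    hits = rng.random(len(soas)) < p
    timeouts = rng.random(len(soas)) < timeout_rate
    rts = rng.uniform(400.0, 1500.0, len(soas))

    records = []
    for soa, hit, to, rt in zip(soas, hits, timeouts, rts):
        if to:
            records.append(
                TrialRecord(participant_id, group, task, float(soa), None, valid=False)
            )
        else:
            records.append(
                TrialRecord(
                    participant_id,
                    group,
                    task,
                    float(soa),
                    pos_label if hit else neg_label,
                    valid=True,
                    rt_ms=float(rt),
                )
            )
    return records


def _draw_observer(spec: GroupParamSpec, role: str, rng: np.random.Generator) -> ObserverParams:
    draws = {name: dist.draw(rng) for name, dist in spec.dists.items()}
    if role != "clean":
        draws.update(DEGENERATE_PARAMS[role])
    return ObserverParams(**draws)


def sample_cohort(
    config: CohortConfig,
    criterion: float = _DEFAULT_CRITERION,
    tasks: tuple[str, ...] = ("SJ", "TOJ"),
) -> tuple[dict[str, ObserverParams], list[TrialRecord], pd.DataFrame]:
    """Draw observers, simulate sessions for ``tasks``, and keep the truth table.

    Returns (observers by participant id, all trial records, truth DataFrame
    with the generative parameters and true half-windows at ``criterion``).
    TOJ-only participants get no SJ trials.
    """
    observers: dict[str, ObserverParams] = {}
    trials: list[TrialRecord] = []
    truth_rows = []
    for spec in config.groups:
        # Degenerate roles are shuffled among SJ-taking participants only;
        # TOJ-only participants (the last indices) are always clean draws.
        n_sj = spec.n_participants - spec.n_toj_only
        roles = (
            ["ceiling_va"] * spec.n_ceiling_va
            + ["chance"] * spec.n_chance
            + ["flat"] * spec.n_flat
            + ["clean"] * (n_sj - spec.n_ceiling_va - spec.n_chance - spec.n_flat)
        )
        role_rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, zlib.crc32(spec.label.encode()), 7])
        )
        roles = [roles[i] for i in role_rng.permutation(len(roles))]
        roles += ["clean"] * spec.n_toj_only
        for i, role in enumerate(roles, start=1):
            pid = f"{spec.label}{i:02d}"
            toj_only = i > spec.n_participants - spec.n_toj_only
            obs = _draw_observer(spec, role, _participant_seed(config.seed, pid, 0))
            observers[pid] = obs
            if "SJ" in tasks and not toj_only:
                trials.extend(
                    simulate_session(
                        obs, config.design, "SJ", _participant_seed(config.seed, pid, 1),
                        participant_id=pid, group=spec.label,
                    )
                )
            if "TOJ" in tasks:
                trials.extend(
                    simulate_session(
                        obs, config.design, "TOJ", _participant_seed(config.seed, pid, 2),
                        participant_id=pid, group=spec.label,
                    )
                )
            av, va = true_half_windows(obs, criterion, max(config.design.isi_levels_ms))
            truth_rows.append(
                {
                    "participant_id": pid,
                    "group": spec.label,
                    "role": role,
                    "toj_only": toj_only,
                    "A": obs.A,
                    "pss_mu": obs.pss_mu,
                    "sigma": obs.sigma,
                    "lapse": obs.lapse,
                    "toj_mu": obs.toj_mu,
                    "toj_sigma": obs.toj_sigma,
                    "toj_lapse": obs.toj_lapse,
                    "true_av_tbw": av,
                    "true_va_tbw": va,
                    "true_tbw": av + va if not (math.isnan(av) or math.isnan(va)) else math.nan,
                    "true_pss": obs.pss_mu,
                }
            )
    return observers, trials, pd.DataFrame(truth_rows)


def generate_behavioral_scores(
    truth: pd.DataFrame,
    model: ScoreModel,
    seed: int,
) -> list[ParticipantScores]:
    """Draw demographics for everyone and behavioral scores for the children.

    Reading fluency (and character recognition) are linear in standardized
    phonological awareness, rapid naming and the true visual-leading
    half-window, plus Gaussian residual noise; degenerate observers without a
    defined half-window contribute 0 to that term. Scores are clipped to their
    instrument ranges. Adults receive demographics only.
    """
    scores: list[ParticipantScores] = []
    for row in truth.itertuples(index=False):
        rng = _participant_seed(seed, row.participant_id, 3)
        group = row.group
        gender = "M" if rng.random() < model.p_male[group] else "F"
        age = rng.normal(model.age[group].mean, model.age[group].sd)
        if group == "AD":
            scores.append(
                ParticipantScores(
                    participant_id=row.participant_id,
                    group=group, gender=gender, age_years=max(18.0, age), grade=None,
                )
            )
            continue
        grade = str(rng.choice(["3", "4", "5"]))
        dists = model.score_dists[group]
        raw = {name: rng.normal(d.mean, d.sd) for name, d in dists.items()}

        # Standardized predictor values against configured population moments.
        z = {}
        for name in ("phonological_awareness", "rapid_naming"):
            z[name] = (raw[name] - dists[name].mean) / dists[name].sd
        z["va_tbw"] = _standardize_va(row, truth)

        for dv, weights in (
            ("reading_fluency", model.fluency_weights),
            ("character_recognition", model.char_weights),
        ):
            d = dists[dv]
            signal = sum(w * z[k] for k, w in weights.items())
            eps = rng.normal()
            raw[dv] = d.mean + d.sd * (signal + model.residual_frac(weights) * eps)

        for name, (lo, hi) in SCORE_RANGES.items():
            raw[name] = min(hi, max(lo, raw[name]))
        raw["rapid_naming"] = max(5.0, raw["rapid_naming"])
        raw["reading_fluency"] = max(1.0, raw["reading_fluency"])
        raw["character_recognition"] = max(0.0, raw["character_recognition"])
        scores.append(
            ParticipantScores(
                participant_id=row.participant_id,
                group=group, gender=gender,
                age_years=min(12.9, max(8.0, age)),
                grade=grade,
                **{k: raw[k] for k in CHILD_SCORE_FIELDS},
            )
        )
    return scores


def _standardize_va(row, truth: pd.DataFrame) -> float:
    """Z-score of the true VA half-window within the participant's group."""
    if math.isnan(row.true_va_tbw):
        return 0.0
    vals = truth.loc[(truth.group == row.group), "true_va_tbw"].dropna()
    sd = float(vals.std(ddof=1))
    if not np.isfinite(sd) or sd == 0:
        return 0.0
    return float((row.true_va_tbw - vals.mean()) / sd)
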