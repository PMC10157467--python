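"""Gaussian synchrony fitting and temporal-binding-window extraction.

Each participant's proportion of "synchronous" responses as a function of the
signed SOA is fitted with a three-parameter Gaussian

    f(x) = A * exp(-(x - mu)^2 / (2 sigma^2)).

The window edges are where the fitted curve crosses an absolute criterion
line (default 70%): the left crossing magnitude is the auditory-leading (AV)
half-window, the right crossing the visual-leading (VA) half-window; the
total temporal binding window (TBW) is their sum and the point of subjective
simultaneity (PSS) is the window midpoint, which coincides with the fitted
``mu`` whenever both crossings exist. Crossings are available in closed form:

    x = mu +/- sigma * sqrt(2 ln(A / c)).

Participants whose curve never reaches the criterion, whose crossing falls
beyond the tested SOA range, or whose data are at chance / near-constant are
classified as unfittable and excluded from window-level analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping

import numpy as np
from scipy.optimize import curve_fit

from avsync.design import SynchronyProfile

OK = "ok"
CEILING_VA = "ceiling_va"
CHANCE_LEVEL = "chance_level"
FLAT_RESPONSE = "flat_response"
BEYOND_RANGE = "beyond_range"
NO_FIT = "no_fit"

DETECTED = "detected"
BELOW_CRITERION = "below_criterion"


@dataclass(frozen=True)
class FitConfig:
    """Fitting and window-extraction settings.

    ``criterion`` is an absolute synchrony-proportion line by default;
    ``criterion_mode='relative_to_peak'`` instead places the line at
    ``criterion * A`` (a convention used by part of the precedent literature).
    """

    criterion: float = 0.70
    criterion_mode: str = "absolute"  # or "relative_to_peak"
    max_abs_soa: float = 500.0
    amp_bounds: tuple[float, float] = (1e-3, 1.0)
    sigma_bounds: tuple[float, float] = (5.0, 2000.0)
    mu_bounds: tuple[float, float] = (-600.0, 600.0)
    tol: float = 1e-12
    min_points: int = 16
    chance_band: float = 0.55  # max observed proportion at or below -> chance
    flat_span: float = 0.45  # observed max-min below -> flat responder
    ceiling_level: float = 0.90  # all VA proportions at/above -> ceiling check
    censor_beyond_range: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.criterion < 1:
            raise ValueError("criterion must be in (0, 1)")
        if self.max_abs_soa <= 0:
            raise ValueError("max_abs_soa must be positive")
        if self.criterion_mode not in ("absolute", "relative_to_peak"):
            raise ValueError(f"unknown criterion_mode {self.criterion_mode!r}")


@dataclass(frozen=True)
class GaussianFit:
    A: float
    mu: float
    sigma: float
    sse: float
    r2: float
    converged: bool

    @classmethod
    def failed(cls) -> "GaussianFit":
        return cls(math.nan, math.nan, math.nan, math.nan, math.nan, False)


@dataclass(frozen=True)
class WindowEstimate:
    """AV/VA half-windows (ms, magnitudes), total window, and PSS.

    ``tbw`` and ``pss`` are populated only when both sides are detected; then
    tbw = av_tbw + va_tbw, pss = (va_tbw - av_tbw)/2 = fitted mu.
    ``av_clamped`` flags the rare case of a left crossing on the positive
    side, where the AV half-window is reported as 0.
    """

    av_tbw: float
    va_tbw: float
    tbw: float
    pss: float
    status_av: str
    status_va: str
    av_clamped: bool = False

    @property
    def detected(self) -> bool:
        return self.status_av == DETECTED and self.status_va == DETECTED

    @classmethod
    def undetected(cls, status: str) -> "WindowEstimate":
        return cls(math.nan, math.nan, math.nan, math.nan, status, status)


def gaussian(x, A, mu, sigma):
    return A * np.exp(-((x - mu) ** 2) / (2.0 * sigma**2))


def total_window(av_tbw: float, va_tbw: float) -> float:
    """Total binding window: sum of the two half-windows."""
    return av_tbw + va_tbw


def midpoint_pss(av_tbw: float, va_tbw: float) -> float:
    """PSS as the window midpoint: positive = visual-leading direction."""
    return (va_tbw - av_tbw) / 2.0


def _moment_start(x: np.ndarray, y: np.ndarray, config: FitConfig) -> tuple[float, float, float]:
    w = np.clip(y, 1e-9, None)
    mu0 = float(np.sum(w * x) / np.sum(w))
    sigma0 = float(math.sqrt(np.sum(w * (x - mu0) ** 2) / np.sum(w)))
    A0 = float(np.max(y))
    lo_a, hi_a = config.amp_bounds
    lo_s, hi_s = config.sigma_bounds
    lo_m, hi_m = config.mu_bounds
    return (
        min(max(A0, lo_a + 1e-6), hi_a),
        min(max(mu0, lo_m), hi_m),
        min(max(sigma0, lo_s + 1e-6), hi_s),
    )


def fit_gaussian(profile: SynchronyProfile, config: FitConfig | None = None) -> GaussianFit:
    """Least-squares Gaussian fit of one synchrony profile.

    Multi-start: a moment-based initialization plus two deterministic
    perturbations of it; the best (lowest SSE) solution is kept. Residuals are
    unweighted (trial counts are equal across points by design). Returns a
    non-converged fit for profiles with too few points, optimizer failure
    from every start, or a non-identifiable width (fitted sigma pinned at its
    upper bound, as happens when every proportion is at ceiling).
    """
    config = config or FitConfig()
    props = profile.proportions()
    if len(props) < config.min_points:
        return GaussianFit.failed()
    x = np.array(sorted(props), dtype=float)
    y = np.array([props[v] for v in sorted(props)], dtype=float)

    A0, mu0, sigma0 = _moment_start(x, y, config)
    starts = [
        (A0, mu0, sigma0),
        (A0, mu0 + 50.0, sigma0 * 0.6),
        (A0, mu0 - 50.0, min(sigma0 * 1.8, config.sigma_bounds[1])),
    ]
    bounds = (
        [config.amp_bounds[0], config.mu_bounds[0], config.sigma_bounds[0]],
        [config.amp_bounds[1], config.mu_bounds[1], config.sigma_bounds[1]],
    )
    best = None
    for p0 in starts:
        p0 = tuple(min(max(v, lo), hi) for v, lo, hi in zip(p0, bounds[0], bounds[1]))
        try:
            popt, _ = curve_fit(
                gaussian, x, y, p0=p0, bounds=bounds, maxfev=5000, ftol=config.tol
            )
        except RuntimeError:
            continue
        sse = float(np.sum((y - gaussian(x, *popt)) ** 2))
        if best is None or sse < best[1]:
            best = (popt, sse)
    if best is None:
        return GaussianFit.failed()
    (A, mu, sigma), sse = best
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else math.nan
    # Width pinned at its upper bound means the curve is effectively flat over
    # the data: non-identifiable (e.g. all proportions at ceiling).
    converged = sigma < 0.999 * config.sigma_bounds[1]
    return GaussianFit(float(A), float(mu), float(sigma), sse, r2, converged)


def criterion_line(fit: GaussianFit, config: FitConfig) -> float:
    if config.criterion_mode == "relative_to_peak":
        return config.criterion * fit.A
    return config.criterion


def extract_window(fit: GaussianFit, config: FitConfig | None = None) -> WindowEstimate:
    """Solve the fitted curve's criterion crossings for the window estimate."""
    config = config or FitConfig()
    if not fit.converged:
        return WindowEstimate.undetected(NO_FIT)
    c = criterion_line(fit, config)
    if fit.A <= c:
        return WindowEstimate.undetected(BELOW_CRITERION)
    d = fit.sigma * math.sqrt(2.0 * math.log(fit.A / c))
    left, right = fit.mu - d, fit.mu + d

    av_clamped = False
    status_av = status_va = DETECTED
    av = -left
    if av < 0:  # window entirely on the visual-leading side
        av, av_clamped = 0.0, True
    va = right
    if left < -config.max_abs_soa:
        if config.censor_beyond_range:
            av = config.max_abs_soa
        else:
            status_av, av = BEYOND_RANGE, math.nan
    if right > config.max_abs_soa:
        if config.censor_beyond_range:
            va = config.max_abs_soa
        else:
            status_va, va = BEYOND_RANGE, math.nan
    if right < 0:  # entirely auditory-leading; mirror of the clamp case
        va = 0.0
    if status_av == DETECTED and status_va == DETECTED:
        tbw = total_window(av, va)
        pss = midpoint_pss(av, va)
    else:
        tbw = pss = math.nan
    return WindowEstimate(av, va, tbw, pss, status_av, status_va, av_clamped)


def classify_participant(
    profile: SynchronyProfile,
    fit: GaussianFit,
    window: WindowEstimate,
    config: FitConfig | None = None,
) -> str:
    """Assign a fit-status code; anything other than ``ok`` means excluded.

    Checks, in order: chance-level data (max observed proportion within the
    chance band), near-constant data (observed span below ``flat_span``),
    optimizer failure, ceiling on the visual-leading side without a crossing
    in range, any crossing beyond the tested range, and a fitted curve that
    never reaches the criterion (counted as a flat responder: its variation
    range is too small to cross the line).
    """
    config = config or FitConfig()
    props = profile.proportions()
    vals = np.array(list(props.values()))
    if vals.size and float(vals.max()) <= config.chance_band:
        return CHANCE_LEVEL
    va_props = [p for soa, p in props.items() if soa > 0]
    no_va_crossing = (not fit.converged) or window.status_va != DETECTED
    if va_props and min(va_props) >= config.ceiling_level and no_va_crossing:
        return CEILING_VA
    if vals.size and float(vals.max() - vals.min()) < config.flat_span:
        return FLAT_RESPONSE
    if not fit.converged:
        return NO_FIT
    if BEYOND_RANGE in (window.status_av, window.status_va):
        return BEYOND_RANGE
    if window.status_av == BELOW_CRITERION:
        return FLAT_RESPONSE
    return OK


@dataclass(frozen=True)
class GroupExclusion:
    group: str
    n_enrolled: int
    n_excluded: int
    exclusion_percent: float
    n_fitted: int


@dataclass(frozen=True)
class ExclusionSummary:
    groups: tuple[GroupExclusion, ...]
    statuses: Mapping[str, str]  # participant -> status code


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (the convention of reported percentages)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def summarize_exclusions(
    statuses: Mapping[str, tuple[str, str]]
) -> ExclusionSummary:
    """Per-group exclusion counts and percentages.

    ``statuses`` maps participant id -> (group, status code). Percentages are
    100 * excluded / enrolled, rounded half-up to 2 decimal places. An empty
    group raises.
    """
    groups: dict[str, list[str]] = {}
    for pid, (group, status) in statuses.items():
        groups.setdefault(group, []).append(status)
    rows = []
    for group in sorted(groups):
        codes = groups[group]
        n = len(codes)
        if n == 0:
            raise ValueError(f"group {group} has no participants")
        n_exc = sum(c != OK for c in codes)
        rows.append(
            GroupExclusion(
                group=group,
                n_enrolled=n,
                n_excluded=n_exc,
                exclusion_percent=round_half_up(100.0 * n_exc / n),
                n_fitted=n - n_exc,
            )
        )
    return ExclusionSummary(
        groups=tuple(rows),
        statuses={pid: status for pid, (_, status) in statuses.items()},
    )


def fit_cohort(
    profiles: Iterable[SynchronyProfile], config: FitConfig | None = None
):
    """Fit every profile; returns a DataFrame of fits, windows and statuses."""
    import pandas as pd

    config = config or FitConfig()
    rows = []
    for p in profiles:
        fit = fit_gaussian(p, config)
        window = extract_window(fit, config)
        status = classify_participant(p, fit, window, config)
        rows.append(
            {
                "participant_id": p.participant_id,
                "group": p.group,
                "A": fit.A,
                "mu": fit.mu,
                "sigma": fit.sigma,
                "r2": fit.r2,
                "converged": fit.converged,
                "av_tbw": window.av_tbw,
                "va_tbw": window.va_tbw,
                "tbw": window.tbw,
                "pss": window.pss,
                "status_av": window.status_av,
                "status_va": window.status_va,
                "status": status,
            }
        )
    return pd.DataFrame(rows)


def plot_fit(profile: SynchronyProfile, fit: GaussianFit, config: FitConfig | None = None, ax=None):
    """Diagnostic plot: observed proportions, fitted curve, criterion line."""
    import matplotlib.pyplot as plt

    config = config or FitConfig()
    if ax is None:
        _, ax = plt.subplots()
    props = profile.proportions()
    x = sorted(props)
    ax.plot(x, [props[v] for v in x], "ko", label="observed")
    if fit.converged:
        grid = np.linspace(min(x), max(x), 400)
        ax.plot(grid, gaussian(grid, fit.A, fit.mu, fit.sigma), "b-", label="Gaussian fit")
        ax.axhline(criterion_line(fit, config), color="r", ls="--", label="criterion")
    ax.set_xlabel("SOA (ms, negative = auditory first)")
    ax.set_ylabel("proportion synchronous")
    ax.set_ylim(0, 1.05)
    ax.legend(frameon=False)
    return ax
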