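"""Domain types for audiovisual simultaneity (SJ) and temporal-order (TOJ) sessions.

Sign convention for stimulus onset asynchrony (SOA): negative values are
auditory-leading (AV) trials, positive values are visual-leading (VA) trials.
The magnitude of the SOA is one of the design's inter-stimulus intervals (ISIs).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

GROUPS = ("CD", "TD", "AD")
TASKS = ("SJ", "TOJ")
ORDERS = ("AV", "VA")

SJ_RESPONSES = ("synchronous", "asynchronous")
TOJ_RESPONSES = ("visual_first", "auditory_first")

#: ISI levels (ms) of the default study design.
DEFAULT_ISI_LEVELS = (25.0, 40.0, 63.0, 100.0, 158.0, 251.0, 398.0, 500.0)


@dataclass(frozen=True)
class StudyDesign:
    """Factorial layout of one SJ or TOJ session.

    The default design crosses 8 ISIs with 2 stimulus orders at 20 trials per
    cell, i.e. 320 trials per session.
    """

    isi_levels_ms: tuple[float, ...] = DEFAULT_ISI_LEVELS
    trials_per_cell: int = 20
    orders: tuple[str, ...] = ORDERS
    response_timeout_ms: float = 5000.0
    stimulus_duration_ms: float = 16.7

    def __post_init__(self) -> None:
        levels = tuple(float(v) for v in self.isi_levels_ms)
        if not levels or any(v <= 0 for v in levels):
            raise ValueError("isi_levels_ms must be positive")
        if any(b <= a for a, b in zip(levels, levels[1:])):
            raise ValueError("isi_levels_ms must be strictly increasing")
        if self.trials_per_cell <= 0:
            raise ValueError("trials_per_cell must be positive")
        unknown = set(self.orders) - set(ORDERS)
        if unknown:
            raise ValueError(f"unknown orders: {sorted(unknown)}")
        object.__setattr__(self, "isi_levels_ms", levels)

    @property
    def n_trials(self) -> int:
        return len(self.isi_levels_ms) * len(self.orders) * self.trials_per_cell

    def signed_soas(self) -> tuple[float, ...]:
        """All signed SOA levels, ascending (negative = auditory-first)."""
        neg = tuple(-v for v in reversed(self.isi_levels_ms)) if "AV" in self.orders else ()
        pos = tuple(self.isi_levels_ms) if "VA" in self.orders else ()
        return neg + pos

    def contains_soa(self, soa_ms: float) -> bool:
        return any(math.isclose(abs(soa_ms), v) for v in self.isi_levels_ms)


def order_of_soa(soa_ms: float) -> str:
    """Stimulus order implied by a signed SOA (negative → AV, positive → VA)."""
    if soa_ms == 0:
        raise ValueError("SOA of 0 has no stimulus order")
    return "AV" if soa_ms < 0 else "VA"


@dataclass(frozen=True)
class TrialRecord:
    """A single SJ or TOJ trial.

    ``response`` is ``None`` iff the trial timed out (``valid`` is False).
    """

    participant_id: str
    group: str
    task: str
    soa_ms: float
    response: str | None
    valid: bool = True
    rt_ms: float | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}")
        if (self.response is None) != (not self.valid):
            raise ValueError("response must be missing iff valid is False")
        if self.response is not None:
            allowed = SJ_RESPONSES if self.task == "SJ" else TOJ_RESPONSES
            if self.response not in allowed:
                raise ValueError(
                    f"response {self.response!r} invalid for task {self.task}"
                )

    @property
    def order(self) -> str:
        return order_of_soa(self.soa_ms)


@dataclass
class SynchronyProfile:
    """Per-participant proportion of 'synchronous' SJ responses at each signed SOA."""

    participant_id: str
    group: str
    #: signed soa_ms -> (n_valid, n_synchronous)
    points: Mapping[float, tuple[int, int]] = field(default_factory=dict)

    def proportion(self, soa_ms: float) -> float:
        n_valid, n_sync = self.points[soa_ms]
        return n_sync / n_valid

    def proportions(self) -> dict[float, float]:
        return {
            soa: n_sync / n_valid
            for soa, (n_valid, n_sync) in sorted(self.points.items())
            if n_valid > 0
        }

    @property
    def is_empty(self) -> bool:
        return not any(n_valid > 0 for n_valid, _ in self.points.values())


@dataclass
class OrderErrorProfile:
    """Per-order TOJ error fractions (reporting the non-leading modality).

    ``errors[order]`` is NaN when the order has no valid trials.
    """

    participant_id: str
    group: str
    errors: dict[str, float] = field(default_factory=dict)
    #: optional diagnostic breakdown: signed soa -> error fraction
    per_isi: dict[float, float] = field(default_factory=dict)


# Instrument ranges for bounded behavioral scores.
SCORE_RANGES = {
    "phonological_awareness": (0.0, 40.0),
    "orthographic_knowledge": (0.0, 80.0),
}

CHILD_SCORE_FIELDS = (
    "raven",
    "character_recognition",
    "reading_fluency",
    "phonological_awareness",
    "orthographic_knowledge",
    "rapid_naming",
)


@dataclass
class ParticipantScores:
    """Demographics and behavioral screening scores for one participant.

    Adults carry demographics only; child test scores are NaN for them.
    """

    participant_id: str
    group: str
    gender: str
    age_years: float
    grade: str | None = None
    raven: float = math.nan
    character_recognition: float = math.nan
    reading_fluency: float = math.nan
    phonological_awareness: float = math.nan
    orthographic_knowledge: float = math.nan
    rapid_naming: float = math.nan

    def __post_init__(self) -> None:
        for name, (lo, hi) in SCORE_RANGES.items():
            v = getattr(self, name)
            if not math.isnan(v) and not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside instrument range [{lo}, {hi}]")
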