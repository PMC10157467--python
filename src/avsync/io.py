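"""CSV readers/writers and trial aggregation.

Trial CSV schema (UTF-8, header required)::

    participant_id,group,task,order,isi_ms,soa_ms,response,rt_ms,valid

``soa_ms`` is authoritative (negative = auditory-first AV, positive =
visual-first VA); ``order`` and ``isi_ms`` are redundant and checked for
consistency, which catches sign errors at load time. A missing response is an
empty field with ``valid`` false.
"""

from __future__ import annotations

import math
from collections import defaultdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from avsync.design import (
    GROUPS,
    TASKS,
    OrderErrorProfile,
    StudyDesign,
    SynchronyProfile,
    TrialRecord,
    order_of_soa,
)

TRIAL_COLUMNS = (
    "participant_id",
    "group",
    "task",
    "order",
    "isi_ms",
    "soa_ms",
    "response",
    "rt_ms",
    "valid",
)

SCORE_COLUMNS = (
    "participant_id",
    "group",
    "gender",
    "age_years",
    "grade",
    "raven",
    "character_recognition",
    "reading_fluency",
    "phonological_awareness",
    "orthographic_knowledge",
    "rapid_naming",
)


class SchemaError(ValueError):
    """Raised when a CSV does not match the documented schema."""


def load_trials(path: str | Path, design: StudyDesign | None = None) -> list[TrialRecord]:
    """Read a trial CSV and validate every row against ``design``.

    Rows whose |soa_ms| is not one of the design's ISI levels, whose group or
    task token is unknown, or whose redundant order/isi_ms fields contradict
    soa_ms are rejected with a descriptive error.
    """
    design = design or StudyDesign()
    df = pd.read_csv(
        path, dtype={"participant_id": str, "response": str}, float_precision="round_trip"
    )
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"trial CSV missing column(s): {sorted(missing)}")

    records: list[TrialRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        soa = float(row.soa_ms)
        if not design.contains_soa(soa):
            raise ValueError(f"line {i}: |soa_ms|={abs(soa)} not an ISI of the design")
        if not math.isclose(float(row.isi_ms), abs(soa)):
            raise ValueError(f"line {i}: isi_ms={row.isi_ms} inconsistent with soa_ms={soa}")
        if row.order != order_of_soa(soa):
            raise ValueError(f"line {i}: order={row.order!r} inconsistent with soa_ms={soa}")
        if row.group not in GROUPS:
            raise ValueError(f"line {i}: unknown group token {row.group!r}")
        if row.task not in TASKS:
            raise ValueError(f"line {i}: unknown task token {row.task!r}")
        valid = _parse_bool(row.valid)
        response = None if (isinstance(row.response, float) and math.isnan(row.response)) else row.response
        if response is not None and response == "":
            response = None
        rt = None if (row.rt_ms is None or (isinstance(row.rt_ms, float) and math.isnan(row.rt_ms))) else float(row.rt_ms)
        records.append(
            TrialRecord(
                participant_id=str(row.participant_id),
                group=row.group,
                task=row.task,
                soa_ms=soa,
                response=response,
                valid=valid,
                rt_ms=rt,
            )
        )
    return records


def _parse_bool(v) -> bool:
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    s = str(v).strip().lower()
    if s in ("true", "1"):
        return True
    if s in ("false", "0"):
        return False
    raise ValueError(f"cannot parse valid flag {v!r}")


def trials_to_frame(trials: Iterable[TrialRecord]) -> pd.DataFrame:
    rows = [
        {
            "participant_id": t.participant_id,
            "group": t.group,
            "task": t.task,
            "order": t.order,
            "isi_ms": abs(t.soa_ms),
            "soa_ms": t.soa_ms,
            "response": "" if t.response is None else t.response,
            "rt_ms": "" if t.rt_ms is None else repr(t.rt_ms),
            "valid": t.valid,
        }
        for t in trials
    ]
    return pd.DataFrame(rows, columns=list(TRIAL_COLUMNS))


def write_trials(trials: Iterable[TrialRecord], path: str | Path) -> None:
    """Write trials as CSV with deterministic column order and formatting."""
    trials_to_frame(trials).to_csv(path, index=False)


def aggregate_synchrony(trials: Sequence[TrialRecord]) -> list[SynchronyProfile]:
    """Collapse SJ trials into per-participant synchrony profiles.

    Timed-out (invalid) trials are excluded from denominators. One profile per
    participant, points keyed by signed SOA; a participant with zero valid
    trials everywhere yields an empty profile (``is_empty``).
    """
    if any(t.task != "SJ" for t in trials):
        raise ValueError("aggregate_synchrony expects SJ trials only")
    counts: dict[tuple[str, str], dict[float, list[int]]] = defaultdict(
        lambda: defaultdict(lambda: [0, 0])
    )
    for t in trials:
        cell = counts[(t.participant_id, t.group)][t.soa_ms]
        if t.valid:
            cell[0] += 1
            if t.response == "synchronous":
                cell[1] += 1
    profiles = []
    for (pid, group), pts in sorted(counts.items()):
        profiles.append(
            SynchronyProfile(
                participant_id=pid,
                group=group,
                points={soa: (nv, ns) for soa, (nv, ns) in sorted(pts.items())},
            )
        )
    return profiles


def aggregate_order_errors(trials: Sequence[TrialRecord]) -> list[OrderErrorProfile]:
    """Collapse TOJ trials into per-order error fractions.

    An error is a response naming the non-leading modality (e.g. answering
    "auditory_first" on a visual-leading trial). Orders with zero valid trials
    get NaN.
    """
    if any(t.task != "TOJ" for t in trials):
        raise ValueError("aggregate_order_errors expects TOJ trials only")
    by_participant: dict[tuple[str, str], list[TrialRecord]] = defaultdict(list)
    for t in trials:
        by_participant[(t.participant_id, t.group)].append(t)

    profiles = []
    for (pid, group), ts in sorted(by_participant.items()):
        errors: dict[str, float] = {}
        per_isi: dict[float, float] = {}
        for order in ("AV", "VA"):
            sub = [t for t in ts if t.order == order and t.valid]
            if not sub:
                errors[order] = math.nan
                continue
            wrong = "visual_first" if order == "AV" else "auditory_first"
            errors[order] = sum(t.response == wrong for t in sub) / len(sub)
        for soa in sorted({t.soa_ms for t in ts}):
            sub = [t for t in ts if t.soa_ms == soa and t.valid]
            if sub:
                wrong = "visual_first" if soa < 0 else "auditory_first"
                per_isi[soa] = sum(t.response == wrong for t in sub) / len(sub)
        profiles.append(
            OrderErrorProfile(participant_id=pid, group=group, errors=errors, per_isi=per_isi)
        )
    return profiles


def profiles_to_frame(profiles: Iterable[SynchronyProfile]) -> pd.DataFrame:
    """Long-format table: one row per (participant, signed soa)."""
    rows = []
    for p in profiles:
        for soa, (nv, ns) in sorted(p.points.items()):
            rows.append(
                {
                    "participant_id": p.participant_id,
                    "group": p.group,
                    "soa_ms": soa,
                    "order": order_of_soa(soa),
                    "n_valid": nv,
                    "n_synchronous": ns,
                    "proportion": ns / nv if nv else math.nan,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "participant_id",
            "group",
            "soa_ms",
            "order",
            "n_valid",
            "n_synchronous",
            "proportion",
        ],
    )


def scores_to_frame(scores: Iterable) -> pd.DataFrame:
    rows = [{c: getattr(s, c if c != "grade" else "grade") for c in SCORE_COLUMNS} for s in scores]
    df = pd.DataFrame(rows, columns=list(SCORE_COLUMNS))
    return df


def write_scores(scores: Iterable, path: str | Path) -> None:
    scores_to_frame(scores).to_csv(path, index=False)


def load_scores(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"participant_id": str})
    missing = set(SCORE_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"scores CSV missing column(s): {sorted(missing)}")
    return df
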