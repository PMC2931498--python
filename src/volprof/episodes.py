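"""Episode-of-care reconstruction and register-based effectiveness indicators.

Administrative discharge registers record institutional care as admission /
discharge intervals.  This module expands those intervals into a daily
ordinal *level of care* trajectory and derives two patient-level outcome
indicators from it:

* four-month mortality — death observed within the follow-up window;
* maintainability — satisfactory when the daily level-of-care sequence
  shows no *backward step* (an increase in care intensity) within the
  window.  The first backward step is classified as a death, a readmission
  (community back to inpatient care), or a referral to a higher-level
  provider (health-center ward to hospital).

Levels of care are ordered by intensity::

    1 = home (incl. home care and outpatient services)
    2 = nursing home
    3 = health center inpatient ward
    4 = hospital
    5 = death (absorbing)
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CARE_LEVELS",
    "DEATH_LEVEL",
    "HOME_LEVEL",
    "CareIntervalRecord",
    "CareTrajectory",
    "MaintainabilityResult",
    "TrajectoryError",
    "build_trajectory",
    "four_month_mortality",
    "classify_event",
    "maintainability",
    "event_breakdown",
    "read_intervals_csv",
    "intervals_to_frame",
    "results_to_frame",
]

#: Ordinal care levels, ordered by intensity of care.
CARE_LEVELS: Mapping[int, str] = {
    1: "home",
    2: "nursing home",
    3: "health center",
    4: "hospital",
    5: "death",
}

HOME_LEVEL = 1
DEATH_LEVEL = 5

#: Default window operationalizing "four months" (4 x 30 days).
DEFAULT_WINDOW_DAYS = 120


class TrajectoryError(ValueError):
    """Structured validation error for malformed interval records."""


@dataclass(frozen=True)
class CareIntervalRecord:
    """One register interval: patient at `level` during [start_day, end_day).

    Days are counted since the index fracture admission (day 0).  Death is
    encoded as a level-5 interval of length >= 1.
    """

    patient_id: str
    start_day: int
    end_day: int
    level: int

    def __post_init__(self) -> None:
        if self.level not in CARE_LEVELS:
            raise TrajectoryError(
                f"patient {self.patient_id}: level {self.level} not in 1..5"
            )
        if self.start_day < 0:
            raise TrajectoryError(
                f"patient {self.patient_id}: negative start_day {self.start_day}"
            )
        if self.start_day >= self.end_day:
            raise TrajectoryError(
                f"patient {self.patient_id}: empty interval "
                f"[{self.start_day}, {self.end_day})"
            )


@dataclass(frozen=True)
class CareTrajectory:
    """Daily level-of-care sequence for one patient, day 0 = fracture admission."""

    patient_id: str
    levels: np.ndarray  # int8, length horizon_days
    horizon_days: int

    def __post_init__(self) -> None:
        if len(self.levels) != self.horizon_days:
            raise TrajectoryError(
                f"patient {self.patient_id}: levels length {len(self.levels)} "
                f"!= horizon {self.horizon_days}"
            )


@dataclass(frozen=True)
class MaintainabilityResult:
    patient_id: str
    unsuccessful: int
    first_event_type: str  # death | readmission | referral | none
    first_event_day: int | None


def build_trajectory(
    records: Iterable[CareIntervalRecord],
    horizon_days: int,
    fill_level: int = HOME_LEVEL,
) -> CareTrajectory:
    """Expand interval records into a daily trajectory of length `horizon_days`.

    Uncovered days get `fill_level` (default home: registers record only
    institutional care, so absence means community dwelling).  Death is
    absorbing: every day at or after the first level-5 interval is level 5.

    Raises
    ------
    TrajectoryError
        On overlapping intervals (naming the patient and days) or invalid
        records.
    """
    records = sorted(records, key=lambda r: r.start_day)
    if not records:
        raise TrajectoryError("no interval records supplied")
    if horizon_days < 1:
        raise TrajectoryError(f"horizon_days must be >= 1, got {horizon_days}")
    pid = records[0].patient_id
    levels = np.full(horizon_days, fill_level, dtype=np.int8)
    prev_end = -1
    prev = None
    death_day: int | None = None
    for rec in records:
        if rec.patient_id != pid:
            raise TrajectoryError(
                f"records mix patients {pid!r} and {rec.patient_id!r}"
            )
        if prev is not None and rec.start_day < prev_end:
            raise TrajectoryError(
                f"patient {pid}: intervals [{prev.start_day}, {prev.end_day}) "
                f"and [{rec.start_day}, {rec.end_day}) overlap"
            )
        lo = min(rec.start_day, horizon_days)
        hi = min(rec.end_day, horizon_days)
        levels[lo:hi] = rec.level
        if rec.level == DEATH_LEVEL and (death_day is None or rec.start_day < death_day):
            death_day = rec.start_day
        prev_end = rec.end_day
        prev = rec
    if death_day is not None and death_day < horizon_days:
        levels[death_day:] = DEATH_LEVEL
    return CareTrajectory(patient_id=pid, levels=levels, horizon_days=horizon_days)


def four_month_mortality(
    trajectory: CareTrajectory, window_days: int = DEFAULT_WINDOW_DAYS
) -> int:
    """1 iff death (level 5) occurs on any day in [0, window_days]."""
    if trajectory.horizon_days < window_days + 1:
        raise TrajectoryError(
            f"patient {trajectory.patient_id}: horizon {trajectory.horizon_days} "
            f"days does not cover day {window_days}; extend the trajectory"
        )
    return int(np.any(trajectory.levels[: window_days + 1] == DEATH_LEVEL))


def classify_event(prev_level: int, new_level: int) -> str:
    """Classify a backward step (level increase) as death, referral or readmission.

    Rules: any step into level 5 is a death; the inpatient escalation 3 -> 4
    is a referral to a higher-level provider; every other increase (community
    levels 1-2 back into institutional care, or 1 -> 2) is a readmission.
    """
    if new_level <= prev_level:
        raise ValueError(
            f"not a backward step: {prev_level} -> {new_level} (level must increase)"
        )
    if new_level == DEATH_LEVEL:
        return "death"
    if prev_level == 3 and new_level == 4:
        return "referral"
    return "readmission"


def maintainability(
    trajectory: CareTrajectory,
    window_days: int = DEFAULT_WINDOW_DAYS,
    classifier=classify_event,
) -> MaintainabilityResult:
    """First backward step within the window; none means satisfactory.

    Scans day-to-day transitions on days 1..window_days and records the
    first day whose level exceeds the previous day's level.  Only the first
    event counts; later steps are ignored.
    """
    if trajectory.horizon_days < window_days + 1:
        raise TrajectoryError(
            f"patient {trajectory.patient_id}: horizon {trajectory.horizon_days} "
            f"days does not cover day {window_days}"
        )
    lv = trajectory.levels[: window_days + 1].astype(np.int16)
    steps = np.flatnonzero(np.diff(lv) > 0)
    if steps.size == 0:
        return MaintainabilityResult(trajectory.patient_id, 0, "none", None)
    day = int(steps[0]) + 1
    etype = classifier(int(lv[day - 1]), int(lv[day]))
    return MaintainabilityResult(trajectory.patient_id, 1, etype, day)


def event_breakdown(
    results: Sequence[MaintainabilityResult] | Mapping[str, int],
) -> dict[str, dict[str, float]]:
    """Count and percentage share of each first-event type among unsuccessful results.

    Accepts either a list of :class:`MaintainabilityResult` or a precomputed
    ``{event_type: count}`` mapping (e.g. published register counts).
    Percentages are rounded to one decimal and sum to 100 within rounding.
    """
    if isinstance(results, Mapping):
        counts = Counter({k: int(v) for k, v in results.items() if v})
    else:
        counts = Counter(
            r.first_event_type for r in results if r.unsuccessful
        )
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no unsuccessful results: event breakdown undefined")
    return {
        etype: {"count": n, "percent": round(100.0 * n / total, 1)}
        for etype, n in sorted(counts.items())
    }


# ---------------------------------------------------------------------------
# I/O helpers (CSV dialects shared with the synthetic registry)

def intervals_to_frame(records: Iterable[CareIntervalRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.patient_id, r.start_day, r.end_day, r.level) for r in records],
        columns=["patient_id", "start_day", "end_day", "level"],
    )


def read_intervals_csv(path) -> dict[str, list[CareIntervalRecord]]:
    """Read interval records grouped by patient from a CSV with the documented header."""
    df = pd.read_csv(path, dtype={"patient_id": str})
    out: dict[str, list[CareIntervalRecord]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.patient_id, []).append(
            CareIntervalRecord(
                patient_id=row.patient_id,
                start_day=int(row.start_day),
                end_day=int(row.end_day),
                level=int(row.level),
            )
        )
    return out


def results_to_frame(
    results: Sequence[MaintainabilityResult],
    mortality: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Tabulate maintainability results (and optional mortality flags) for CSV output."""
    df = pd.DataFrame(
        [
            (r.patient_id, r.unsuccessful, r.first_event_type, r.first_event_day)
            for r in results
        ],
        columns=["patient_id", "unsuccessful", "first_event_type", "first_event_day"],
    )
    if mortality is not None:
        df["mortality"] = df["patient_id"].map(mortality)
    return df
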