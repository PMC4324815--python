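"""Training and performance quantification for ladder-climbing sessions.

A training session is quantified by the potential mechanical work of the
combined centre of mass (rat + tail load) over all climbs,

    TW = (m_load + m_rat) * g * dh * N   [J],

and performance by the mean power output over the climbing time,

    P = TW / t_total   [W].

Daily training amounts are laid out on a 1-day grid (``TrainingSeries``):
zero on rest days, the session's work on training days. Observed
performance is attached to the day it was measured.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Standard gravity, m s^-2. Configurable in the work/power functions for
#: sensitivity analyses.
GRAVITY = 9.81

SESSION_CSV_COLUMNS = [
    "rat_id",
    "day",
    "body_mass_g",
    "load_mass_g",
    "height_m",
    "reps",
    "total_time_s",
]


class ValidationError(ValueError):
    """A domain object violated one of its invariants."""


@dataclass(frozen=True)
class ClimbSession:
    """One rat's one ladder-climbing session.

    Parameters
    ----------
    rat_id : str
        Animal identifier.
    day : int
        1-based day index; day 1 is the first training day.
    body_mass : float
        Rat body mass in kg.
    load_mass : float
        Additional load in the tail bag, kg.
    climb_height : float
        Vertical distance per climb, m.
    repetitions : int
        Number of climbs in the session.
    total_time : float
        Summed climbing time for the session in seconds (rests excluded).
    """

    rat_id: str
    day: int
    body_mass: float
    load_mass: float
    climb_height: float = 1.0
    repetitions: int = 10
    total_time: float = 1.0

    def __post_init__(self) -> None:
        checks = [
            ("day", self.day >= 1),
            ("body_mass", self.body_mass > 0),
            ("load_mass", self.load_mass >= 0),
            ("climb_height", self.climb_height > 0),
            ("repetitions", self.repetitions >= 1),
            ("total_time", self.total_time > 0),
        ]
        for name, ok in checks:
            if not ok:
                raise ValidationError(
                    f"ClimbSession field {name!r} violates its invariant "
                    f"(got {getattr(self, name)!r})"
                )


def training_work(session: ClimbSession, g: float = GRAVITY) -> float:
    """Potential work of the session in joules.

    ``(load_mass + body_mass) * g * climb_height * repetitions``.
    """
    return (
        (session.load_mass + session.body_mass)
        * g
        * session.climb_height
        * session.repetitions
    )


def session_performance(session: ClimbSession, g: float = GRAVITY) -> float:
    """Mean power output of the session in watts (work / climbing time)."""
    if session.total_time <= 0:
        raise ValidationError("total_time must be positive")
    return training_work(session, g=g) / session.total_time


@dataclass
class TrainingSeries:
    """Daily training impulses and measured performances for one rat.

    ``w[i-1]`` is the training amount (J) on day ``i``; rest days are zero.
    ``measured_days`` lists the days with an observed performance and
    ``p_obs`` the corresponding values (W).
    """

    rat_id: str
    w: np.ndarray
    measured_days: np.ndarray
    p_obs: np.ndarray

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        self.measured_days = np.asarray(self.measured_days, dtype=int)
        self.p_obs = np.asarray(self.p_obs, dtype=float)
        if np.any(self.w < 0):
            raise ValidationError("training amounts w must be non-negative")
        if self.measured_days.size != self.p_obs.size:
            raise ValidationError("measured_days and p_obs lengths differ")
        if self.measured_days.size and (
            self.measured_days.min() < 1
            or self.measured_days.max() > self.n_days
        ):
            raise ValidationError("measured day outside the series span")
        if np.any(self.p_obs <= 0):
            raise ValidationError("observed performances must be positive")

    @property
    def n_days(self) -> int:
        return len(self.w)


def ladder_calendar(
    n_sessions: int, days_on: int = 5, days_off: int = 2
) -> np.ndarray:
    """Day indices of consecutive sessions on a train/rest weekly cycle.

    With the default 5-on/2-off cycle, session ``s`` falls on day
    ``s + days_off * ((s - 1) // days_on)``; 19 sessions end on day 25.
    """
    s = np.arange(1, n_sessions + 1)
    return s + days_off * ((s - 1) // days_on)


def build_training_series(
    sessions: Sequence[ClimbSession],
    n_days: int | None = None,
    g: float = GRAVITY,
    input_scale: float = 1.0,
) -> TrainingSeries:
    """Assemble one rat's daily impulse series from its session log.

    Sessions must be sorted by day with at most one session per day.
    ``input_scale`` optionally rescales the work values (defaults to raw
    joules).
    """
    if not sessions:
        raise ValidationError("empty session list")
    rat_ids = {s.rat_id for s in sessions}
    if len(rat_ids) != 1:
        raise ValidationError(f"sessions from multiple rats: {sorted(rat_ids)}")
    days = [s.day for s in sessions]
    if any(b <= a for a, b in zip(days, days[1:])):
        raise ValidationError("session days must be strictly increasing")
    span = max(days) if n_days is None else int(n_days)
    if span < max(days):
        raise ValidationError("n_days smaller than the last session day")
    w = np.zeros(span)
    p_obs = np.empty(len(sessions))
    for j, s in enumerate(sessions):
        w[s.day - 1] = training_work(s, g=g) * input_scale
        p_obs[j] = session_performance(s, g=g)
    return TrainingSeries(
        rat_id=sessions[0].rat_id,
        w=w,
        measured_days=np.array(days),
        p_obs=p_obs,
    )


# ---------------------------------------------------------------------------
# File round-tripping

def sessions_to_frame(sessions: Iterable[ClimbSession]) -> pd.DataFrame:
    """Tidy session-log frame (masses in grams, as in the file format)."""
    rows = [
        {
            "rat_id": s.rat_id,
            "day": s.day,
            "body_mass_g": s.body_mass * 1000.0,
            "load_mass_g": s.load_mass * 1000.0,
            "height_m": s.climb_height,
            "reps": s.repetitions,
            "total_time_s": s.total_time,
        }
        for s in sessions
    ]
    return pd.DataFrame(rows, columns=SESSION_CSV_COLUMNS)


def frame_to_sessions(df: pd.DataFrame) -> list[ClimbSession]:
    missing = set(SESSION_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"session log missing columns: {sorted(missing)}")
    return [
        ClimbSession(
            rat_id=str(r.rat_id),
            day=int(r.day),
            body_mass=float(r.body_mass_g) / 1000.0,
            load_mass=float(r.load_mass_g) / 1000.0,
            climb_height=float(r.height_m),
            repetitions=int(r.reps),
            total_time=float(r.total_time_s),
        )
        for r in df.itertuples(index=False)
    ]


def write_sessions_csv(sessions: Iterable[ClimbSession], path) -> None:
    sessions_to_frame(sessions).to_csv(path, index=False)


def read_sessions_csv(path) -> list[ClimbSession]:
    return frame_to_sessions(pd.read_csv(path))


def series_to_frame(series: TrainingSeries) -> pd.DataFrame:
    """Tidy per-day frame: rat_id, day, w_joules, p_obs_watts (NaN off days)."""
    p = np.full(series.n_days, np.nan)
    p[series.measured_days - 1] = series.p_obs
    return pd.DataFrame(
        {
            "rat_id": series.rat_id,
            "day": np.arange(1, series.n_days + 1),
            "w_joules": series.w,
            "p_obs_watts": p,
        }
    )


def write_series_csv(series_list: Iterable[TrainingSeries], path) -> None:
    pd.concat([series_to_frame(s) for s in series_list]).to_csv(
        path, index=False
    )


def sessions_by_rat(sessions: Sequence[ClimbSession]) -> dict[str, list[ClimbSession]]:
    """Group a mixed session log by rat, each group sorted by day."""
    groups: dict[str, list[ClimbSession]] = {}
    for s in sessions:
        groups.setdefault(s.rat_id, []).append(s)
    for rid, group in groups.items():
        group.sort(key=lambda s: s.day)
        days = [s.day for s in group]
        if len(set(days)) != len(days):
            raise ValidationError(f"duplicate (rat, day) for rat {rid!r}")
    return groups
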