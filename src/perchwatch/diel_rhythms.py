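"""Diel (24-hour) activity profiles, circular uniformity testing, and
nocturnal-activity flagging.

Clock times are mapped to angles on the 24-h circle (``theta = 2*pi*t/86400``)
and tested for uniformity with the Rayleigh test.  The test is applied to
individual visit start times by default; a weighted (binned) variant is
available through the ``weights`` argument for sensitivity analysis.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from datetime import date, datetime, time
from typing import Callable, Sequence

import numpy as np

from .visits_metrics import Visit

SECONDS_PER_DAY = 86400


class Season(str, enum.Enum):
    WINTER = "WINTER"
    SPRING = "SPRING"
    SUMMER = "SUMMER"
    FALL = "FALL"


_SEASON_BY_MONTH = {
    12: Season.WINTER, 1: Season.WINTER, 2: Season.WINTER,
    3: Season.SPRING, 4: Season.SPRING, 5: Season.SPRING,
    6: Season.SUMMER, 7: Season.SUMMER, 8: Season.SUMMER,
    9: Season.FALL, 10: Season.FALL, 11: Season.FALL,
}


def assign_season(d: date | datetime) -> Season:
    """Meteorological seasons: WINTER = Dec-Feb, SPRING = Mar-May,
    SUMMER = Jun-Aug, FALL = Sep-Nov."""
    return _SEASON_BY_MONTH[d.month]


@dataclass
class DielProfile:
    season: Season
    hourly_mean: np.ndarray  # 24 values: mean visits per hour across days
    hourly_se: np.ndarray
    n_visits: int
    n_days: int
    first_visit_clock: time | None  # mean of daily first-visit clock times
    last_visit_clock: time | None   # mean of daily last-visit clock times
    earliest_visit_clock: time | None  # extreme over the whole season
    latest_visit_clock: time | None

    @property
    def peak_hour(self) -> int | None:
        if self.n_visits == 0:
            return None
        return int(np.argmax(self.hourly_mean))  # argmax takes earliest on ties


@dataclass
class RayleighResult:
    n: float
    Rbar: float
    Z: float
    p: float


def _clock_seconds(ts: datetime) -> float:
    return ts.hour * 3600 + ts.minute * 60 + ts.second + ts.microsecond / 1e6


def _mean_time(seconds: Sequence[float]) -> time:
    s = int(round(float(np.mean(seconds)))) % SECONDS_PER_DAY
    return time(s // 3600, (s % 3600) // 60, s % 60)


def diel_profile(
    visits: Sequence[Visit],
    season: Season,
    group_filter: Callable[[Visit], bool] | None = None,
) -> DielProfile:
    """Seasonal hourly activity profile.

    Per-day hour-of-day visit counts are averaged across the days observed in
    the season (days with at least one qualifying visit); the SE is the
    between-day standard error.  Activity span is reported both as the mean
    of daily first/last visit clock times and as the seasonal extremes.
    """
    sel = [
        v for v in visits
        if assign_season(v.start) is season
        and (group_filter is None or group_filter(v))
    ]
    if not sel:
        return DielProfile(
            season=season,
            hourly_mean=np.zeros(24),
            hourly_se=np.zeros(24),
            n_visits=0,
            n_days=0,
            first_visit_clock=None,
            last_visit_clock=None,
            earliest_visit_clock=None,
            latest_visit_clock=None,
        )
    days = sorted({v.start.date() for v in sel})
    day_index = {d: i for i, d in enumerate(days)}
    counts = np.zeros((len(days), 24))
    firsts = np.full(len(days), np.inf)
    lasts = np.full(len(days), -np.inf)
    for v in sel:
        i = day_index[v.start.date()]
        counts[i, v.start.hour] += 1
        cs = _clock_seconds(v.start)
        firsts[i] = min(firsts[i], cs)
        lasts[i] = max(lasts[i], cs)
    mean = counts.mean(axis=0)
    if len(days) > 1:
        se = counts.std(axis=0, ddof=1) / np.sqrt(len(days))
    else:
        se = np.zeros(24)
    return DielProfile(
        season=season,
        hourly_mean=mean,
        hourly_se=se,
        n_visits=len(sel),
        n_days=len(days),
        first_visit_clock=_mean_time(firsts),
        last_visit_clock=_mean_time(lasts),
        earliest_visit_clock=_mean_time([firsts.min()]),
        latest_visit_clock=_mean_time([lasts.max()]),
    )


def clock_to_angle(ts: datetime) -> float:
    """Map a timestamp's clock time to an angle in radians on the 24-h circle."""
    return 2.0 * np.pi * _clock_seconds(ts) / SECONDS_PER_DAY


def rayleigh_test(
    angles_radians: Sequence[float], weights: Sequence[float] | None = None
) -> RayleighResult:
    """Rayleigh test of circular uniformity.

    Rbar is the mean resultant length, Z = n * Rbar**2, and the p-value uses
    the standard series correction

        p = exp(-Z) * [1 + (2Z - Z^2)/(4n)
                         - (24Z - 132Z^2 + 76Z^3 - 9Z^4)/(288 n^2)]

    clamped to (0, 1].  With ``weights`` the resultant is weight-averaged and
    n is the total weight (binned variant).
    """
    theta = np.asarray(angles_radians, dtype=float)
    if weights is None:
        w = np.ones_like(theta)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != theta.shape:
            raise ValueError("weights must match angles in shape")
    n = float(w.sum())
    if (weights is None and theta.size < 2) or n <= 0:
        raise ValueError("need at least 2 angles")
    C = float(np.sum(w * np.cos(theta)))
    S = float(np.sum(w * np.sin(theta)))
    Rbar = np.sqrt(C * C + S * S) / n
    Rbar = min(Rbar, 1.0)
    Z = n * Rbar * Rbar
    correction = (
        1.0
        + (2.0 * Z - Z * Z) / (4.0 * n)
        - (24.0 * Z - 132.0 * Z**2 + 76.0 * Z**3 - 9.0 * Z**4) / (288.0 * n * n)
    )
    p = float(np.exp(-Z) * correction)
    p = min(max(p, np.finfo(float).tiny), 1.0)
    return RayleighResult(n=n, Rbar=float(Rbar), Z=float(Z), p=p)


NIGHT_WINDOW = (time(22, 0), time(4, 0))


def is_nocturnal(ts: datetime, window: tuple[time, time] = NIGHT_WINDOW) -> bool:
    """True if the clock time falls in the midnight-wrapping night window
    [22:00, 24:00) u [00:00, 04:00] (both window edges inclusive)."""
    t = ts.time()
    start, end = window
    return t >= start or t <= end


def night_activity(
    visits: Sequence[Visit], window: tuple[time, time] = NIGHT_WINDOW
) -> list[dict]:
    """Birds with visits starting inside the night window, with their
    nocturnal visit counts, stations, and dates."""
    per_bird: dict[str, list[Visit]] = {}
    for v in visits:
        if is_nocturnal(v.start, window):
            per_bird.setdefault(v.tag_id, []).append(v)
    out = []
    for tag in sorted(per_bird):
        vs = per_bird[tag]
        out.append(
            {
                "tag_id": tag,
                "n_night_visits": len(vs),
                "stations": sorted({v.station_id for v in vs}),
                "dates": sorted({v.start.date() for v in vs}),
            }
        )
    return out
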