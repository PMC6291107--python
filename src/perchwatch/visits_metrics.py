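"""Visit segmentation and visitation metrics.

A *visit* is a maximal run of one bird's detections at one station in which
every consecutive inter-read gap is at most ``gap_max_s`` seconds (default 11,
one second more than the 10-s reader duty cycle; a gap of exactly 11 s still
merges).  Visit duration is last read minus first read, so a single-read
visit has duration 0 and is *transient* (duration < 10 s).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from datetime import datetime
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .detections_io import BirdRecord, Detection

TRANSIENT_MAX_S = 10  # visits shorter than this are transient
DEFAULT_GAP_MAX_S = 11


@dataclass(frozen=True)
class Visit:
    tag_id: str
    station_id: str
    site_id: str
    start: datetime
    end: datetime
    n_detections: int

    @property
    def duration_s(self) -> int:
        return int((self.end - self.start).total_seconds())

    @property
    def transient(self) -> bool:
        return self.duration_s < TRANSIENT_MAX_S


@dataclass
class BirdVisitSummary:
    tag_id: str
    n_visits: int
    n_transient: int
    mean_duration_s: float
    total_time_s: int
    observation_span_s: int
    proportion_time: float
    days_detected: int
    latency_days: int | None
    observation_period_days: int | None
    span_zero_flag: bool = False


@dataclass
class FeederRanking:
    """Per-bird feeders ordered by visit count; ranks 1-3 are the primary,
    secondary, and tertiary feeders."""

    tag_id: str
    ranking: list[tuple[str, int, float]]  # (station_id, n_visits, pct_visits)

    def role(self, rank: int) -> tuple[str, int, float] | None:
        return self.ranking[rank - 1] if len(self.ranking) >= rank else None

    @property
    def primary(self):
        return self.role(1)

    @property
    def secondary(self):
        return self.role(2)

    @property
    def tertiary(self):
        return self.role(3)


def segment_visits(
    detections: Sequence[Detection], gap_max_s: int = DEFAULT_GAP_MAX_S
) -> list[Visit]:
    """Segment detections into visits per (tag, station).

    Input need not be sorted; duplicate timestamps within a group collapse to
    a single read.  Detections at different stations never merge.
    """
    if gap_max_s < 0:
        raise ValueError("gap_max_s must be >= 0")
    groups: dict[tuple[str, str], list[Detection]] = {}
    for d in detections:
        groups.setdefault((d.tag_id, d.station_id), []).append(d)

    visits: list[Visit] = []
    for (tag, station), reads in groups.items():
        reads.sort(key=lambda d: d.timestamp)
        # collapse exact duplicate timestamps
        uniq: list[Detection] = []
        for d in reads:
            if uniq and d.timestamp == uniq[-1].timestamp:
                continue
            uniq.append(d)
        run_start = 0
        for i in range(1, len(uniq) + 1):
            if i == len(uniq) or (
                (uniq[i].timestamp - uniq[i - 1].timestamp).total_seconds() > gap_max_s
            ):
                run = uniq[run_start:i]
                visits.append(
                    Visit(
                        tag_id=tag,
                        station_id=station,
                        site_id=run[0].site_id,
                        start=run[0].timestamp,
                        end=run[-1].timestamp,
                        n_detections=len(run),
                    )
                )
                run_start = i
    visits.sort(key=lambda v: (v.start, v.tag_id, v.station_id))
    return visits


def summarize_birds(
    visits: Sequence[Visit], roster: Sequence[BirdRecord]
) -> list[BirdVisitSummary]:
    """One visitation summary per detected bird.

    Birds never detected are simply absent from the result (report them from
    the roster separately).  ``proportion_time`` is total visit time over the
    first-to-last-detection span; a single-detection bird has span 0 and gets
    proportion 0 with ``span_zero_flag`` set.
    """
    by_tag = {b.tag_id: b for b in roster}
    grouped: dict[str, list[Visit]] = {}
    for v in visits:
        if v.tag_id not in by_tag:
            raise ValueError(f"visit tag {v.tag_id!r} not in roster")
        grouped.setdefault(v.tag_id, []).append(v)

    out = []
    for tag in sorted(grouped):
        vs = sorted(grouped[tag], key=lambda v: v.start)
        total = sum(v.duration_s for v in vs)
        span = int((max(v.end for v in vs) - min(v.start for v in vs)).total_seconds())
        days = set()
        for v in vs:
            days.add(v.start.date())
            days.add(v.end.date())
        bird = by_tag[tag]
        first = min(v.start for v in vs)
        last = max(v.end for v in vs)
        out.append(
            BirdVisitSummary(
                tag_id=tag,
                n_visits=len(vs),
                n_transient=sum(v.transient for v in vs),
                mean_duration_s=total / len(vs),
                total_time_s=total,
                observation_span_s=span,
                proportion_time=(total / span) if span > 0 else 0.0,
                days_detected=len(days),
                latency_days=(first.date() - bird.tag_date).days,
                observation_period_days=(last.date() - bird.tag_date).days,
                span_zero_flag=span == 0,
            )
        )
    return out


def rank_feeders(visits: Sequence[Visit]) -> list[FeederRanking]:
    """Per-bird descending feeder ranking by visit count.

    Ties break lexicographically by station_id, so the ranking is
    deterministic.  Percentages are of that bird's total visits and sum
    to 100 over all stations it used.
    """
    counts: dict[str, dict[str, int]] = {}
    for v in visits:
        counts.setdefault(v.tag_id, {}).setdefault(v.station_id, 0)
        counts[v.tag_id][v.station_id] += 1
    out = []
    for tag in sorted(counts):
        per_station = counts[tag]
        total = sum(per_station.values())
        ordered = sorted(per_station.items(), key=lambda kv: (-kv[1], kv[0]))
        out.append(
            FeederRanking(
                tag_id=tag,
                ranking=[(s, n, 100.0 * n / total) for s, n in ordered],
            )
        )
    return out


def primary_feeder_tally(rankings: Sequence[FeederRanking]) -> dict[str, int]:
    """How many birds hold each station as their primary feeder."""
    tally: dict[str, int] = {}
    for r in rankings:
        if r.primary is not None:
            tally[r.primary[0]] = tally.get(r.primary[0], 0) + 1
    return dict(sorted(tally.items(), key=lambda kv: (-kv[1], kv[0])))


def site_movement(
    visits: Sequence[Visit], roster: Sequence[BirdRecord]
) -> tuple[dict[str, dict[str, float]], list[str]]:
    """Per-bird percentage of visits by site, plus the list of movers.

    A mover is any bird with > 0% of its visits at a site other than its
    tagging site.
    """
    tag_site = {b.tag_id: b.tag_site for b in roster}
    counts: dict[str, dict[str, int]] = {}
    for v in visits:
        counts.setdefault(v.tag_id, {}).setdefault(v.site_id, 0)
        counts[v.tag_id][v.site_id] += 1
    pct: dict[str, dict[str, float]] = {}
    movers: list[str] = []
    for tag in sorted(counts):
        total = sum(counts[tag].values())
        pct[tag] = {s: 100.0 * n / total for s, n in sorted(counts[tag].items())}
        home = tag_site.get(tag)
        if any(s != home for s in counts[tag]):
            movers.append(tag)
    return pct, movers


def kruskal_wallis(values_by_group: Mapping[str, Sequence[float]]) -> dict:
    """Kruskal-Wallis rank test across >= 2 non-empty groups.

    Returns ``{"H", "df", "p"}`` with the tie-corrected statistic and the
    chi-square p-value on k-1 degrees of freedom.
    """
    if len(values_by_group) < 2:
        raise ValueError("need at least 2 groups")
    for name, vals in values_by_group.items():
        if len(vals) == 0:
            raise ValueError(f"group {name!r} is empty")
    groups = [np.asarray(v, dtype=float) for v in values_by_group.values()]
    if all(np.array_equal(g, groups[0]) for g in groups[1:]):
        # identical groups: H is exactly 0 (scipy raises when all values tie)
        return {"H": 0.0, "df": len(groups) - 1, "p": 1.0}
    H, p = stats.kruskal(*groups)
    return {"H": float(H), "df": len(groups) - 1, "p": float(p)}


def fisher_exact_2x2(table) -> dict:
    """Two-sided Fisher's exact test on a 2x2 count table.

    p sums the hypergeometric probabilities of all tables (fixed margins)
    no more probable than the observed one.
    """
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (arr < 0).any():
        raise ValueError("table entries must be nonnegative")
    odds, p = stats.fisher_exact(arr, alternative="two-sided")
    return {"odds_ratio": float(odds), "p_two_sided": float(p)}


def flag_cross_station_overlaps(visits: Sequence[Visit]) -> list[tuple[Visit, Visit]]:
    """Pairs of same-bird visits at different stations that overlap in time
    (physically impossible; both are kept, callers decide how to report)."""
    by_tag: dict[str, list[Visit]] = {}
    for v in visits:
        by_tag.setdefault(v.tag_id, []).append(v)
    flagged = []
    for vs in by_tag.values():
        vs.sort(key=lambda v: (v.start, v.station_id))
        for a, b in zip(vs, vs[1:]):
            if b.start <= a.end and a.station_id != b.station_id:
                flagged.append((a, b))
    return flagged


def write_visits_csv(visits: Sequence[Visit], target) -> None:
    def _write(fh):
        w = csv.writer(fh)
        w.writerow(
            ["tag_id", "station_id", "site_id", "start", "end",
             "duration_s", "n_detections", "transient"]
        )
        for v in visits:
            w.writerow(
                [v.tag_id, v.station_id, v.site_id,
                 v.start.strftime("%Y-%m-%d %H:%M:%S"),
                 v.end.strftime("%Y-%m-%d %H:%M:%S"),
                 v.duration_s, v.n_detections, int(v.transient)]
            )

    if isinstance(target, (str, Path)):
        with open(target, "w", newline="", encoding="utf-8") as fh:
            _write(fh)
    else:
        _write(target)


def read_visits_csv(source) -> list[Visit]:
    from .detections_io import _open_rows

    out = []
    for row in _open_rows(source):
        out.append(
            Visit(
                tag_id=row["tag_id"],
                station_id=row["station_id"],
                site_id=row["site_id"],
                start=datetime.strptime(row["start"], "%Y-%m-%d %H:%M:%S"),
                end=datetime.strptime(row["end"], "%Y-%m-%d %H:%M:%S"),
                n_detections=int(row["n_detections"]),
            )
        )
    return out
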