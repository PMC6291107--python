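"""Reading, validation, and normalization of tag-detection logs and rosters.

Detection logs are tabular text (CSV with a header row).  The column layout
and timestamp format are configurable through a :class:`Dialect`; the default
expects columns ``datetime, tag_id, antenna_id, station_id, site_id``.
Timestamps are kept timezone-naive: downstream diel analyses work on local
wall-clock hours.
"""

from __future__ import annotations

import csv
import enum
import io
from dataclasses import dataclass, field
from datetime import date, datetime
from pathlib import Path
from typing import Iterable, Mapping, Sequence


class Species(str, enum.Enum):
    ANNA = "ANNA"
    ALLEN = "ALLEN"


class Sex(str, enum.Enum):
    F = "F"
    M = "M"
    UNKNOWN = "UNKNOWN"


class Age(str, enum.Enum):
    AHY = "AHY"
    HY = "HY"
    UNKNOWN = "UNKNOWN"


@dataclass(frozen=True)
class Detection:
    """One timestamped read of one tag at one antenna."""

    tag_id: str
    timestamp: datetime
    antenna_id: str
    station_id: str
    site_id: str

    def __post_init__(self) -> None:
        if not self.tag_id:
            raise ValueError("tag_id must be non-empty")


@dataclass(frozen=True)
class BirdRecord:
    tag_id: str
    band_id: str
    species: Species
    sex: Sex
    age: Age
    tag_date: date
    tag_site: str


@dataclass
class ValidationReport:
    unknown_tags: list[str]
    pre_tagging_detections: int
    duplicate_rows: int
    per_site_counts: dict[str, int]
    antenna_station_conflicts: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "unknown_tags": list(self.unknown_tags),
            "pre_tagging_detections": self.pre_tagging_detections,
            "duplicate_rows": self.duplicate_rows,
            "per_site_counts": dict(self.per_site_counts),
            "antenna_station_conflicts": list(self.antenna_station_conflicts),
        }


@dataclass(frozen=True)
class Dialect:
    """Column map and timestamp format for a detection-log export."""

    timestamp_col: str = "datetime"
    tag_col: str = "tag_id"
    antenna_col: str = "antenna_id"
    station_col: str = "station_id"
    site_col: str = "site_id"
    timestamp_format: str = "%Y-%m-%d %H:%M:%S"


DEFAULT_DIALECT = Dialect()


class DetectionLogError(ValueError):
    """Raised for malformed detection-log input, citing the offending row."""


def _open_rows(source) -> Iterable[dict]:
    if isinstance(source, (str, Path)):
        with open(source, newline="", encoding="utf-8") as fh:
            yield from csv.DictReader(fh)
    elif isinstance(source, io.IOBase) or hasattr(source, "read"):
        yield from csv.DictReader(source)
    else:  # already an iterable of rows
        yield from source


def read_detection_log(source, dialect: Dialect = DEFAULT_DIALECT) -> list[Detection]:
    """Parse a detection log into :class:`Detection` records in input order.

    ``station_id`` defaults to ``antenna_id`` and ``site_id`` to ``"SITE"``
    when those columns are absent (single-station deployments).  Unparseable
    timestamps or missing mandatory columns raise :class:`DetectionLogError`
    naming the 1-based data-row number.
    """
    out: list[Detection] = []
    for i, row in enumerate(_open_rows(source), start=1):
        for col in (dialect.timestamp_col, dialect.tag_col, dialect.antenna_col):
            if row.get(col) is None:
                raise DetectionLogError(
                    f"row {i}: missing mandatory column {col!r}"
                )
        raw_ts = row[dialect.timestamp_col]
        try:
            ts = datetime.strptime(raw_ts, dialect.timestamp_format)
        except (ValueError, TypeError) as exc:
            raise DetectionLogError(
                f"row {i}: cannot parse timestamp {raw_ts!r}: {exc}"
            ) from exc
        antenna = row[dialect.antenna_col]
        out.append(
            Detection(
                tag_id=row[dialect.tag_col],
                timestamp=ts,
                antenna_id=antenna,
                station_id=row.get(dialect.station_col) or antenna,
                site_id=row.get(dialect.site_col) or "SITE",
            )
        )
    _check_antenna_station_map(out)
    return out


def _check_antenna_station_map(detections: Sequence[Detection]) -> None:
    seen: dict[str, str] = {}
    for d in detections:
        prior = seen.setdefault(d.antenna_id, d.station_id)
        if prior != d.station_id:
            raise DetectionLogError(
                f"antenna {d.antenna_id!r} mapped to two stations: "
                f"{prior!r} and {d.station_id!r}"
            )


def write_detection_log(
    detections: Sequence[Detection], target, dialect: Dialect = DEFAULT_DIALECT
) -> None:
    """Write detections as CSV; inverse of :func:`read_detection_log`."""

    def _write(fh) -> None:
        cols = [
            dialect.timestamp_col,
            dialect.tag_col,
            dialect.antenna_col,
            dialect.station_col,
            dialect.site_col,
        ]
        w = csv.writer(fh)
        w.writerow(cols)
        for d in detections:
            w.writerow(
                [
                    d.timestamp.strftime(dialect.timestamp_format),
                    d.tag_id,
                    d.antenna_id,
                    d.station_id,
                    d.site_id,
                ]
            )

    if isinstance(target, (str, Path)):
        with open(target, "w", newline="", encoding="utf-8") as fh:
            _write(fh)
    else:
        _write(target)


_SPECIES_ALIASES = {
    "anna": Species.ANNA,
    "annas": Species.ANNA,
    "anna's hummingbird": Species.ANNA,
    "annas hummingbird": Species.ANNA,
    "calypte anna": Species.ANNA,
    "allen": Species.ALLEN,
    "allens": Species.ALLEN,
    "allen's hummingbird": Species.ALLEN,
    "allens hummingbird": Species.ALLEN,
    "selasphorus sasin": Species.ALLEN,
}
_SEX_ALIASES = {
    "f": Sex.F,
    "female": Sex.F,
    "m": Sex.M,
    "male": Sex.M,
    "u": Sex.UNKNOWN,
    "unknown": Sex.UNKNOWN,
    "": Sex.UNKNOWN,
}
_AGE_ALIASES = {
    "ahy": Age.AHY,
    "after-hatch year": Age.AHY,
    "after hatch year": Age.AHY,
    "after-hatch-year": Age.AHY,
    "adult": Age.AHY,
    "hy": Age.HY,
    "hatch year": Age.HY,
    "hatch-year": Age.HY,
    "u": Age.UNKNOWN,
    "unknown": Age.UNKNOWN,
    "": Age.UNKNOWN,
}


def _norm(value: str, aliases: Mapping, what: str, enum_cls):
    key = (value or "").strip().lower()
    if key in aliases:
        return aliases[key]
    try:
        return enum_cls(value.strip().upper())
    except ValueError:
        raise ValueError(f"unrecognized {what}: {value!r}") from None


def read_roster(source, date_format: str = "%Y-%m-%d") -> list[BirdRecord]:
    """Parse a bird roster CSV with columns tag, band, species, sex, age, date, site.

    Enum-like fields are normalized (``"Female"`` -> ``F``, ``"after-hatch
    year"`` -> ``AHY``); unknowns are preserved as UNKNOWN, never imputed.
    A duplicated ``tag_id`` is a hard error.
    """
    out: list[BirdRecord] = []
    seen: set[str] = set()
    for i, row in enumerate(_open_rows(source), start=1):
        tag = (row.get("tag_id") or row.get("tag") or "").strip()
        if not tag:
            raise ValueError(f"roster row {i}: empty tag_id")
        if tag in seen:
            raise ValueError(f"roster row {i}: duplicate tag_id {tag!r}")
        seen.add(tag)
        raw_date = (row.get("tag_date") or row.get("date") or "").strip()
        try:
            tag_date = datetime.strptime(raw_date, date_format).date()
        except ValueError as exc:
            raise ValueError(f"roster row {i}: bad tag_date {raw_date!r}") from exc
        out.append(
            BirdRecord(
                tag_id=tag,
                band_id=(row.get("band_id") or row.get("band") or "").strip(),
                species=_norm(row.get("species", ""), _SPECIES_ALIASES, "species", Species),
                sex=_norm(row.get("sex", ""), _SEX_ALIASES, "sex", Sex),
                age=_norm(row.get("age", ""), _AGE_ALIASES, "age", Age),
                tag_date=tag_date,
                tag_site=(row.get("tag_site") or row.get("site") or "").strip(),
            )
        )
    return out


def write_roster(roster: Sequence[BirdRecord], target) -> None:
    def _write(fh) -> None:
        w = csv.writer(fh)
        w.writerow(["tag_id", "band_id", "species", "sex", "age", "tag_date", "tag_site"])
        for b in roster:
            w.writerow(
                [b.tag_id, b.band_id, b.species.value, b.sex.value, b.age.value,
                 b.tag_date.isoformat(), b.tag_site]
            )

    if isinstance(target, (str, Path)):
        with open(target, "w", newline="", encoding="utf-8") as fh:
            _write(fh)
    else:
        _write(target)


def validate(
    detections: Sequence[Detection], roster: Sequence[BirdRecord]
) -> ValidationReport:
    """Report-only consistency checks between a log and a roster.

    Unknown-tag detections are flagged but retained (they still inform
    antenna diagnostics); callers exclude them from per-bird analyses.
    """
    by_tag = {b.tag_id: b for b in roster}
    unknown = sorted({d.tag_id for d in detections} - by_tag.keys())
    pre_tag = sum(
        1
        for d in detections
        if d.tag_id in by_tag and d.timestamp.date() < by_tag[d.tag_id].tag_date
    )
    rows = [
        (d.tag_id, d.timestamp, d.antenna_id, d.station_id, d.site_id)
        for d in detections
    ]
    duplicate_rows = len(rows) - len(set(rows))
    per_site: dict[str, int] = {}
    for d in detections:
        per_site[d.site_id] = per_site.get(d.site_id, 0) + 1
    return ValidationReport(
        unknown_tags=unknown,
        pre_tagging_detections=pre_tag,
        duplicate_rows=duplicate_rows,
        per_site_counts=per_site,
    )


def known_tag_detections(
    detections: Sequence[Detection], roster: Sequence[BirdRecord]
) -> list[Detection]:
    """Subset of detections whose tag appears in the roster."""
    known = {b.tag_id for b in roster}
    return [d for d in detections if d.tag_id in known]


def select_antenna(
    detections: Sequence[Detection],
    policy: str,
    antenna_roles: Mapping[str, str] | None = None,
    dedup_window_s: int = 1,
) -> list[Detection]:
    """Resolve multi-antenna stations to a single stream.

    ``side_only`` keeps only the side antenna of two-antenna stations;
    ``merge_dedup`` pools both antennas and collapses same-tag reads within
    ``dedup_window_s`` seconds to one.  Single-antenna stations pass through
    unchanged under either policy.
    """
    if policy not in {"side_only", "merge_dedup"}:
        raise ValueError(f"unknown antenna policy {policy!r}")
    antenna_roles = antenna_roles or {}
    antennas_by_station: dict[str, set[str]] = {}
    for d in detections:
        antennas_by_station.setdefault(d.station_id, set()).add(d.antenna_id)
    multi = {s for s, ants in antennas_by_station.items() if len(ants) > 1}

    if policy == "side_only":
        out = []
        for d in detections:
            if d.station_id not in multi:
                out.append(d)
                continue
            role = antenna_roles.get(d.antenna_id)
            if role is None:
                raise ValueError(f"no role declared for antenna {d.antenna_id!r}")
            if role == "side":
                out.append(d)
        return out

    # merge_dedup: pool antennas per station, drop same-tag reads closer than
    # the window to the previously kept read at that station.
    out = []
    last_kept: dict[tuple[str, str], datetime] = {}
    for d in sorted(
        detections, key=lambda d: (d.station_id, d.tag_id, d.timestamp, d.antenna_id)
    ):
        key = (d.station_id, d.tag_id)
        prev = last_kept.get(key)
        if prev is not None and (d.timestamp - prev).total_seconds() <= dedup_window_s:
            continue
        last_kept[key] = d.timestamp
        out.append(d)
    out.sort(key=lambda d: (d.timestamp, d.tag_id, d.antenna_id))
    return out


def compare_antennas(
    detections: Sequence[Detection], station_id: str, gap_max_s: int = 11
) -> dict[str, dict]:
    """Per-antenna summaries (reads, visits, unique tags, daily series) for a
    two-antenna station."""
    from . import visits_metrics  # local import; visits depends on this module

    at_station = [d for d in detections if d.station_id == station_id]
    antennas = sorted({d.antenna_id for d in at_station})
    if len(antennas) != 2:
        raise ValueError(
            f"station {station_id!r} has {len(antennas)} antenna(s); need exactly 2"
        )
    out: dict[str, dict] = {}
    for ant in antennas:
        reads = [d for d in at_station if d.antenna_id == ant]
        visits = visits_metrics.segment_visits(reads, gap_max_s=gap_max_s)
        daily: dict[date, int] = {}
        for d in reads:
            daily[d.timestamp.date()] = daily.get(d.timestamp.date(), 0) + 1
        out[ant] = {
            "n_detections": len(reads),
            "n_visits": len(visits),
            "unique_tags": sorted({d.tag_id for d in reads}),
            "daily_series": dict(sorted(daily.items())),
        }
    return out
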