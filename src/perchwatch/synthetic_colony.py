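"""Synthetic-colony generator with full ground truth.

Generates rosters, true visit intervals, and rendered detection logs with the
statistical structure the downstream analyses assume: strong per-bird feeder
preference, a bimodal dawn/dusk diel mixture with a dominant dawn peak,
transient-dominated visit durations, monthly survival, and a 10-s reader duty
cycle.  Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date, datetime, time, timedelta
from typing import Mapping, Sequence

import numpy as np

from . import datasets
from .detections_io import Age, BirdRecord, Detection, Sex, Species
from .cjs_survival import EncounterHistory

TWO_PI = 2.0 * np.pi

DEFAULT_SITES: dict[str, list[str]] = {
    "Site1": ["F1"],
    "Site2": ["A4", "A5", "A8"],
    "Site3": ["A9", "B1", "B2"],
}


@dataclass(frozen=True)
class ColonyConfig:
    """Generator parameters; the defaults emulate a ~230-bird two-species
    colony at 3 sites / 7 stations."""

    n_birds: Mapping[tuple[str, str, str], int] = field(
        default_factory=lambda: dict(datasets.TAGGED)
    )
    sites: Mapping[str, Sequence[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_SITES.items()}
    )
    start_date: date = date(2017, 6, 1)
    n_days: int = 28
    # Dirichlet concentration over a bird's site stations; the mean targets
    # roughly 87/11/2 % primary/secondary/tertiary visit shares.
    pref_alpha: tuple[float, ...] = (6.94, 0.9, 0.16)
    diel_peaks_h: tuple[float, ...] = (5.5, 17.5)
    diel_kappas: tuple[float, ...] = (8.0, 8.0)
    diel_weights: tuple[float, ...] = (0.65, 0.35)  # dominant dawn peak
    visit_rate_per_day: float = 8.0
    p_transient: float = 0.74
    long_visit_extra_mean_s: float = 14.0  # duration = 11 + Exp(mean), so mean ~ 25
    duration_cap_s: int = 615
    phi_monthly: float = 0.9
    night_active_fraction: float = 0.05
    night_visit_fraction: float = 0.15
    duty_interval_s: int = 10
    dropout: float = 0.0
    follower_pairs: int = 0
    follower_visit_prob: float = 0.5

    def __post_init__(self) -> None:
        for p in (self.p_transient, self.phi_monthly, self.night_active_fraction,
                  self.night_visit_fraction, self.dropout):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.visit_rate_per_day <= 0 or self.duty_interval_s <= 0:
            raise ValueError("rates and intervals must be positive")
        if abs(sum(self.diel_weights) - 1.0) > 1e-9:
            raise ValueError("diel_weights must sum to 1")


@dataclass(frozen=True)
class TrueVisit:
    tag_id: str
    station_id: str
    site_id: str
    start: datetime
    duration_s: int

    @property
    def end(self) -> datetime:
        return self.start + timedelta(seconds=self.duration_s)


@dataclass
class BirdTruth:
    tag_id: str
    site_id: str
    alive_until: date
    night_prone: bool          # generator intent
    nocturnal: bool            # realized: has >= 1 true night-window visit
    preference: dict[str, float]
    true_primary: str | None
    n_visits: int


@dataclass
class GroundTruth:
    birds: dict[str, BirdTruth]
    visits: list[TrueVisit]
    config: ColonyConfig
    seed: int


def simulate_roster(config: ColonyConfig, seed: int) -> list[BirdRecord]:
    """Deterministic roster with unique tag ids; birds are assigned to sites
    with probability proportional to each site's station count."""
    rng = np.random.default_rng(seed)
    site_ids = sorted(config.sites)
    weights = np.array([len(config.sites[s]) for s in site_ids], dtype=float)
    weights /= weights.sum()
    roster: list[BirdRecord] = []
    i = 0
    for (species, sex, age) in sorted(config.n_birds):
        for _ in range(config.n_birds[(species, sex, age)]):
            i += 1
            roster.append(
                BirdRecord(
                    tag_id=f"T{i:04d}",
                    band_id=f"B{i:04d}",
                    species=Species(species),
                    sex=Sex(sex),
                    age=Age(age),
                    tag_date=config.start_date,
                    tag_site=site_ids[rng.choice(len(site_ids), p=weights)],
                )
            )
    return roster


def _month_boundaries(start: date, end: date) -> list[date]:
    out = []
    y, m = start.year, start.month + 1
    if m == 13:
        y, m = y + 1, 1
    d = date(y, m, 1)
    while d < end:
        out.append(d)
        m += 1
        if m == 13:
            y, m = y + 1, 1
        d = date(y, m, 1)
    return out


def _draw_clock_seconds(rng: np.random.Generator, config: ColonyConfig,
                        night: bool) -> int:
    if night:
        h = (22.0 + rng.uniform(0.0, 6.0)) % 24.0
    else:
        comp = rng.choice(len(config.diel_weights), p=np.asarray(config.diel_weights))
        mu = TWO_PI * config.diel_peaks_h[comp] / 24.0
        theta = rng.vonmises(mu, config.diel_kappas[comp])
        h = (theta % TWO_PI) / TWO_PI * 24.0
    return int(h * 3600.0) % 86400


def _separate(visits: list[TrueVisit], min_gap_s: int = 12) -> list[TrueVisit]:
    """Drop same-bird visits that start within min_gap_s of the previous
    kept visit's end (a bird cannot be in two places; keeps segmentation
    round-trips exact)."""
    visits = sorted(visits, key=lambda v: v.start)
    kept: list[TrueVisit] = []
    for v in visits:
        if kept and (v.start - kept[-1].end).total_seconds() < min_gap_s:
            continue
        kept.append(v)
    return kept


def simulate_visits(
    roster: Sequence[BirdRecord], config: ColonyConfig, seed: int
) -> tuple[list[TrueVisit], GroundTruth]:
    """True visit intervals for every bird, plus the generating ground truth.

    Per alive bird-day the visit count is Poisson; start clock times come
    from the seasonal circular mixture (or the night window for night-prone
    birds); the station follows the bird's Dirichlet feeder preference;
    durations are 0 with the transient probability, otherwise shifted
    exponential capped at the configured maximum.  Visits are truncated at
    the bird's death month (monthly Bernoulli survival).
    """
    rng = np.random.default_rng(seed)
    end_date = config.start_date + timedelta(days=config.n_days)
    boundaries = _month_boundaries(config.start_date, end_date)

    truth_birds: dict[str, BirdTruth] = {}
    all_visits: list[TrueVisit] = []

    for bird in roster:
        alive_until = end_date
        for b in boundaries:
            if rng.random() > config.phi_monthly:
                alive_until = b
                break
        night_prone = bool(rng.random() < config.night_active_fraction)
        stations = sorted(config.sites[bird.tag_site])
        if len(stations) == 1:
            pref = {stations[0]: 1.0}
        else:
            alpha = [
                config.pref_alpha[k] if k < len(config.pref_alpha) else 0.02
                for k in range(len(stations))
            ]
            order = rng.permutation(len(stations))
            weights = rng.dirichlet(alpha)
            pref = {stations[order[k]]: float(weights[k]) for k in range(len(stations))}
        st_names = list(pref)
        st_probs = np.array([pref[s] for s in st_names])

        visits: list[TrueVisit] = []
        day = config.start_date
        while day < alive_until:
            n = rng.poisson(config.visit_rate_per_day)
            for _ in range(n):
                night = night_prone and rng.random() < config.night_visit_fraction
                sec = _draw_clock_seconds(rng, config, night)
                if rng.random() < config.p_transient:
                    dur = 0
                else:
                    dur = min(
                        11 + int(round(rng.exponential(config.long_visit_extra_mean_s))),
                        config.duration_cap_s,
                    )
                visits.append(
                    TrueVisit(
                        tag_id=bird.tag_id,
                        station_id=st_names[rng.choice(len(st_names), p=st_probs)],
                        site_id=bird.tag_site,
                        start=datetime.combine(day, time()) + timedelta(seconds=sec),
                        duration_s=dur,
                    )
                )
            day += timedelta(days=1)
        visits = _separate(visits)
        truth_birds[bird.tag_id] = BirdTruth(
            tag_id=bird.tag_id,
            site_id=bird.tag_site,
            alive_until=alive_until,
            night_prone=night_prone,
            nocturnal=False,  # set below from realized visits
            preference=pref,
            true_primary=max(pref, key=lambda s: (pref[s], s)) if pref else None,
            n_visits=len(visits),
        )
        all_visits.extend(visits)

    if config.follower_pairs > 0:
        all_visits = _inject_followers(all_visits, roster, config, rng)
        for tag in truth_birds:
            truth_birds[tag].n_visits = sum(
                1 for v in all_visits if v.tag_id == tag
            )

    for v in all_visits:
        t = v.start.time()
        if t >= time(22, 0) or t <= time(4, 0):
            truth_birds[v.tag_id].nocturnal = True

    all_visits.sort(key=lambda v: (v.start, v.tag_id, v.station_id))
    return all_visits, GroundTruth(
        birds=truth_birds, visits=all_visits, config=config, seed=seed
    )


def _inject_followers(
    visits: list[TrueVisit],
    roster: Sequence[BirdRecord],
    config: ColonyConfig,
    rng: np.random.Generator,
) -> list[TrueVisit]:
    """Clone some long visits onto a paired 'follower' bird with a 2-s lag,
    guaranteeing LONG interactions with known membership."""
    by_site: dict[str, list[str]] = {}
    for b in roster:
        by_site.setdefault(b.tag_site, []).append(b.tag_id)
    pairs: list[tuple[str, str]] = []
    for site in sorted(by_site):
        tags = sorted(by_site[site])
        for i in range(0, len(tags) - 1, 2):
            pairs.append((tags[i], tags[i + 1]))
            if len(pairs) >= config.follower_pairs:
                break
        if len(pairs) >= config.follower_pairs:
            break

    extra: list[TrueVisit] = []
    followers = {leader: follower for leader, follower in pairs}
    for v in visits:
        follower = followers.get(v.tag_id)
        if follower is None or v.duration_s < 20:
            continue
        if rng.random() < config.follower_visit_prob:
            extra.append(
                TrueVisit(
                    tag_id=follower,
                    station_id=v.station_id,
                    site_id=v.site_id,
                    start=v.start + timedelta(seconds=2),
                    duration_s=v.duration_s - 4,
                )
            )
    if not extra:
        return visits
    merged: list[TrueVisit] = []
    by_tag: dict[str, list[TrueVisit]] = {}
    for v in visits + extra:
        by_tag.setdefault(v.tag_id, []).append(v)
    for tag in sorted(by_tag):
        merged.extend(_separate(by_tag[tag]))
    return merged


def render_detections(
    true_visits: Sequence[TrueVisit], config: ColonyConfig, seed: int
) -> list[Detection]:
    """Emit duty-cycled reads for each visit: offsets {0, 10, 20, ...} up to
    the duration (a 0-s visit gives one read).  Optional per-read dropout
    models imperfect antennas."""
    rng = np.random.default_rng(seed)
    out: list[Detection] = []
    for v in true_visits:
        for off in range(0, v.duration_s + 1, config.duty_interval_s):
            if config.dropout > 0 and rng.random() < config.dropout:
                continue
            out.append(
                Detection(
                    tag_id=v.tag_id,
                    timestamp=v.start + timedelta(seconds=off),
                    antenna_id=f"{v.station_id}:side",
                    station_id=v.station_id,
                    site_id=v.site_id,
                )
            )
    out.sort(key=lambda d: (d.timestamp, d.tag_id, d.station_id))
    return out


def simulate_colony(
    config: ColonyConfig, seed: int
) -> tuple[list[BirdRecord], list[Detection], GroundTruth]:
    """Roster + rendered detection log + ground truth from one seed.

    Sub-stages draw from independent seeded substreams so adding one stage
    never perturbs another's randomness.
    """
    children = np.random.SeedSequence(seed).spawn(3)
    s_roster, s_visits, s_render = (int(c.generate_state(1)[0]) for c in children)
    roster = simulate_roster(config, s_roster)
    visits, truth = simulate_visits(roster, config, s_visits)
    detections = render_detections(visits, config, s_render)
    return roster, detections, truth


def simulate_encounter_histories(
    n_by_group: Mapping[tuple[str, str], int],
    T: int,
    phi: float,
    p_by_age: Mapping[str, float],
    seed: int,
    winter: tuple[int, ...] | None = None,
) -> list[EncounterHistory]:
    """Direct CJS-process simulation conditioned on release at occasion 1.

    ``n_by_group`` maps (sex, age) to cohort sizes; alive states follow a
    Bernoulli(phi) chain and detections are Bernoulli(p given alive) with p
    set by age class.  The release occasion is always encountered.
    """
    if T < 2:
        raise ValueError("need at least 2 occasions")
    rng = np.random.default_rng(seed)
    w = winter if winter is not None else tuple([0] * T)
    out: list[EncounterHistory] = []
    i = 0
    for (sex, age) in sorted(n_by_group):
        p = p_by_age[age]
        for _ in range(n_by_group[(sex, age)]):
            i += 1
            h = [1] + [0] * (T - 1)
            alive = True
            for t in range(1, T):
                alive = alive and (rng.random() < phi)
                if alive and rng.random() < p:
                    h[t] = 1
            out.append(
                EncounterHistory(
                    tag_id=f"S{i:04d}", h=tuple(h), sex=Sex(sex), age=Age(age),
                    winter=w,
                )
            )
    return out
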