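from __future__ import annotations

from datetime import date, datetime, timedelta

import pytest

from perchwatch.detections_io import Age, BirdRecord, Detection, Sex, Species
from perchwatch.visits_metrics import Visit

T0 = datetime(2017, 6, 15, 8, 0, 0)


def det(tag: str, offset_s: float, station: str = "S1", antenna: str | None = None,
        site: str = "Site1", base: datetime = T0) -> Detection:
    """Detection at base + offset seconds."""
    return Detection(
        tag_id=tag,
        timestamp=base + timedelta(seconds=offset_s),
        antenna_id=antenna or f"{station}:side",
        station_id=station,
        site_id=site,
    )


def visit(tag: str, start_s: float, end_s: float, station: str = "S1",
          site: str = "Site1", n: int | None = None,
          base: datetime = T0) -> Visit:
    """Visit spanning [start_s, end_s] seconds after base."""
    return Visit(
        tag_id=tag,
        station_id=station,
        site_id=site,
        start=base + timedelta(seconds=start_s),
        end=base + timedelta(seconds=end_s),
        n_detections=n if n is not None else max(1, int(end_s - start_s) // 10 + 1),
    )


def bird(tag: str, species: Species = Species.ANNA, sex: Sex = Sex.F,
         age: Age = Age.AHY, tag_date: date = date(2017, 6, 1),
         site: str = "Site1") -> BirdRecord:
    return BirdRecord(
        tag_id=tag, band_id=f"B-{tag}", species=species, sex=sex, age=age,
        tag_date=tag_date, tag_site=site,
    )


@pytest.fixture
def small_roster():
    return [
        bird("A", sex=Sex.F, age=Age.AHY),
        bird("B", sex=Sex.M, age=Age.HY),
        bird("C", sex=Sex.M, age=Age.AHY, species=Species.ALLEN),
    ]
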