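"""Sentinel-2 acquisition calendars: 5-day cadence with cloudy scenes removed.

Two reference calendars ship with the package.  The 2019 training-cycle
calendar has 27 usable scenes between 2 April and 4 September (June and July
lose several scenes to clouds, September all but one).  The 2020 test-cycle
calendar retains a usable scene roughly every 15 days from late April, which
is what makes the lag combinations progressively available within the season:
on 6 May only the 15-day pair can be formed, by 20 June all four combinations.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class AcquisitionCalendar:
    """Ordered acquisition dates with a per-date cloud flag."""

    dates: tuple[dt.date, ...]
    cloudy: tuple[bool, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.cloudy is None:
            object.__setattr__(self, "cloudy", tuple(False for _ in self.dates))
        if len(self.dates) != len(self.cloudy):
            raise ValueError("dates and cloudy flags must have equal length")
        if any(b >= a for a, b in zip(self.dates[1:], self.dates[:-1])):
            raise ValueError("acquisition dates must be strictly increasing")

    @property
    def cloud_free(self) -> tuple[dt.date, ...]:
        return tuple(d for d, c in zip(self.dates, self.cloudy) if not c)

    def __len__(self) -> int:
        return len(self.dates)


def build_calendar(start: dt.date, end: dt.date, cadence: int = 5,
                   cloud_probability: float = 0.0,
                   rng: np.random.Generator | None = None) -> AcquisitionCalendar:
    """Regular revisit calendar with scenes lost to clouds at random.

    ``cloud_probability`` is the chance that a whole scene is unusable
    (scene-wide loss; no per-plot partial clouds).
    """
    if not 0.0 <= cloud_probability <= 1.0:
        raise ValueError("cloud probability must lie in [0, 1]")
    dates = []
    d = start
    while d <= end:
        dates.append(d)
        d += dt.timedelta(days=cadence)
    if cloud_probability > 0.0:
        if rng is None:
            raise ValueError("a random generator is required for cloudy calendars")
        cloudy = tuple(bool(x) for x in rng.random(len(dates)) < cloud_probability)
    else:
        cloudy = tuple(False for _ in dates)
    return AcquisitionCalendar(dates=tuple(dates), cloudy=cloudy)


def _calendar_from_cloud_free(year: int, cloud_free: dict[int, list[int]],
                              start: dt.date, end: dt.date,
                              cadence: int = 5) -> AcquisitionCalendar:
    dates, cloudy = [], []
    d = start
    usable = {dt.date(year, m, day) for m, days in cloud_free.items() for day in days}
    while d <= end:
        dates.append(d)
        cloudy.append(d not in usable)
        d += dt.timedelta(days=cadence)
    return AcquisitionCalendar(dates=tuple(dates), cloudy=tuple(cloudy))


def calendar_2019() -> AcquisitionCalendar:
    """Training-cycle calendar: 5-day cadence 2 Apr - 29 Sep, 27 usable scenes.

    April, May and August kept every scene; June and July each kept four;
    only 4 September survived in September.
    """
    return _calendar_from_cloud_free(
        2019,
        {
            4: [2, 7, 12, 17, 22, 27],
            5: [2, 7, 12, 17, 22, 27],
            6: [1, 6, 21, 26],
            7: [6, 16, 26, 31],
            8: [5, 10, 15, 20, 25, 30],
            9: [4],
        },
        start=dt.date(2019, 4, 2), end=dt.date(2019, 9, 29),
    )


def calendar_2020() -> AcquisitionCalendar:
    """Test-cycle calendar: usable scenes every ~15 days from 21 April.

    Early in the cycle only the short-lag combination can be assembled from
    these scenes; all four combinations become available by 20 June.
    """
    return _calendar_from_cloud_free(
        2020,
        {
            4: [21],
            5: [6, 21],
            6: [5, 20],
            7: [5, 20],
            8: [4, 19],
            9: [3],
        },
        start=dt.date(2020, 4, 1), end=dt.date(2020, 9, 28),
    )
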