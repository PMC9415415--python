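"""Crop calendars and fractional-cover trajectories for the simulated module.

The Spring-Summer cycle runs April-September.  Corn dominates the module and
is sown through April into May and harvested at the end of September; beans
are sown in April and harvested in early July at grain filling; alfalfa is a
perennial cut roughly every eight weeks, so its canopy follows a sawtooth.

Cover is modelled as a logistic rise to a crop-specific peak, an exponential
senescence for annuals, a hard drop to zero at harvest, and (for perennials)
an exponential regrowth that is periodic in the cut interval.  The trajectory
is a deterministic function of (crop, sowing/anchor date, query date); all
stochasticity lives in the sampling of sowing dates and in reflectance noise.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Optional

import numpy as np


@dataclass(frozen=True)
class CropCalendarEntry:
    """Phenological parameters of one crop class.

    Day-of-year fields refer to the cycle year.  For perennials (alfalfa) the
    "sowing" window instead staggers the cutting anchor between plots, and
    ``cut_interval`` must be set; for annuals it must be ``None``.
    """

    crop_name: str
    sowing_window: tuple[int, int]          # (earliest, latest) day-of-year
    season_length: int                      # days of active growth
    peak_cover: float                       # asymptotic fractional cover
    rise_rate: float                        # logistic growth rate, 1/day
    senescence_rate: float = 0.0            # exponential decay rate, 1/day
    harvest_day: Optional[int] = None       # day-of-year; cover = 0 after
    cut_interval: Optional[int] = None      # days between cuts (perennials)
    emergence_lag: int = 7                  # days from sowing to emergence
    half_time: int = 35                     # days from sowing to half peak
    senescence_start: int = 120             # days from sowing to onset of decay
    residual_cover: float = 0.15            # post-cut cover (perennials)

    def __post_init__(self) -> None:
        lo, hi = self.sowing_window
        if lo > hi:
            raise ValueError("sowing_window earliest must not exceed latest")
        if not 0.0 < self.peak_cover <= 1.0:
            raise ValueError("peak_cover must lie in (0, 1]")
        if self.cut_interval is not None and self.cut_interval <= 0:
            raise ValueError("cut_interval must be positive")

    @property
    def is_perennial(self) -> bool:
        return self.cut_interval is not None


def _doy(date: dt.date) -> int:
    return date.timetuple().tm_yday


def simulate_cover(entry: CropCalendarEntry, sowing_date: dt.date,
                   query_date: dt.date) -> float:
    """Fractional green cover of one plot on one date, in [0, 1].

    Annuals: zero before emergence, logistic rise to ``peak_cover``,
    exponential senescence from ``senescence_start`` days after sowing, and
    zero after ``harvest_day``.  Perennials: periodic regrowth from
    ``residual_cover`` toward ``peak_cover`` with period ``cut_interval``,
    anchored at the plot's (staggered) anchor date.
    """
    if entry.is_perennial:
        # Established stand: cover depends only on the phase in the cut cycle.
        phase = (query_date - sowing_date).days % entry.cut_interval
        span = entry.peak_cover - entry.residual_cover
        cover = entry.residual_cover + span * (1.0 - np.exp(-entry.rise_rate * phase))
        return float(min(max(cover, 0.0), 1.0))

    days = (query_date - sowing_date).days
    if days < entry.emergence_lag:
        return 0.0
    if entry.harvest_day is not None and _doy(query_date) > entry.harvest_day \
            and query_date.year == sowing_date.year:
        return 0.0
    cover = entry.peak_cover / (1.0 + np.exp(-entry.rise_rate * (days - entry.half_time)))
    if days > entry.senescence_start:
        cover *= np.exp(-entry.senescence_rate * (days - entry.senescence_start))
    return float(min(max(cover, 0.0), 1.0))


# Default crop calendar for the simulated irrigation module.  Windows and
# harvest dates follow the module's cropping pattern (cycle April-September,
# bean harvested in early July, alfalfa cut about every eight weeks); rates
# and peaks are realistic canopy-development choices, see docs/methods.md.
CROP_CALENDAR: dict[str, CropCalendarEntry] = {
    "corn": CropCalendarEntry(
        crop_name="corn", sowing_window=(91, 135), season_length=170,
        peak_cover=0.92, rise_rate=0.12, senescence_rate=0.03,
        harvest_day=270, emergence_lag=8, half_time=45, senescence_start=140,
    ),
    "bean": CropCalendarEntry(
        crop_name="bean", sowing_window=(91, 120), season_length=95,
        peak_cover=0.85, rise_rate=0.15, senescence_rate=0.05,
        harvest_day=188, emergence_lag=6, half_time=30, senescence_start=75,
    ),
    "alfalfa": CropCalendarEntry(
        crop_name="alfalfa", sowing_window=(60, 116), season_length=365,
        peak_cover=0.88, rise_rate=0.08, cut_interval=56, residual_cover=0.15,
    ),
    "other": CropCalendarEntry(
        crop_name="other", sowing_window=(105, 150), season_length=130,
        peak_cover=0.70, rise_rate=0.12, senescence_rate=0.04,
        harvest_day=250, emergence_lag=7, half_time=35, senescence_start=90,
    ),
}

#: 2019 module-wide crop priors (fractions of all plots).
CROP_PRIORS_2019: dict[str, float] = {
    "corn": 0.672, "alfalfa": 0.225, "bean": 0.059, "other": 0.044,
}
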