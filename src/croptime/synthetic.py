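"""Seeded synthetic irrigation-module datasets.

Emulates the plot-level observation process of the Tepatepec-like study
system: a few hundred surveyed plots with a known crop-class mix (corn,
alfalfa, bean plus a small "other" remainder), staggered sowing, alfalfa cut
cycles, a 5-day optical revisit with whole scenes lost to cloud, sampling
units of 8-10 pixels, and reflectance formed as a linear soil/vegetation
mixture along a fixed soil line with per-pixel Gaussian noise.

The generator is deliberately simple where the real world is not (no
radiative transfer, no within-plot heterogeneity beyond iid pixel noise, no
partial cloud); docs/methods.md spells out what that implies for tests.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .calendars import AcquisitionCalendar, build_calendar, calendar_2019, calendar_2020
from .phenology import CROP_CALENDAR, CROP_PRIORS_2019, CropCalendarEntry, simulate_cover
from .spectral import BANDS, SoilLine, as_band_vector

__all__ = [
    "EndmemberSpectra", "SyntheticPlot", "ScenarioConfig", "SyntheticDataset",
    "sample_crop_pattern", "mix_reflectance", "generate_dataset",
    "SOIL_SPECTRUM", "VEGETATION_SPECTRA", "write_plots_geojson",
]

#: Bare-soil endmember; satisfies B8A = 1.62 * B4 (the module's soil line).
SOIL_SPECTRUM: dict[str, float] = {
    "B2": 0.11, "B3": 0.15, "B4": 0.20, "B5": 0.24, "B6": 0.28, "B7": 0.30,
    "B8A": 0.324, "B11": 0.40, "B12": 0.35,
}

#: Full-canopy endmembers per crop.  Differences between crops are modest and
#: realistic (legume canopies greener and brighter in SWIR than corn; alfalfa
#: densest in the red edge); the dominant class signal is temporal.
VEGETATION_SPECTRA: dict[str, dict[str, float]] = {
    "corn": {"B2": 0.025, "B3": 0.055, "B4": 0.035, "B5": 0.11, "B6": 0.32,
             "B7": 0.42, "B8A": 0.46, "B11": 0.19, "B12": 0.09},
    "bean": {"B2": 0.030, "B3": 0.070, "B4": 0.045, "B5": 0.13, "B6": 0.33,
             "B7": 0.41, "B8A": 0.44, "B11": 0.22, "B12": 0.11},
    "alfalfa": {"B2": 0.028, "B3": 0.065, "B4": 0.040, "B5": 0.12, "B6": 0.35,
                "B7": 0.45, "B8A": 0.48, "B11": 0.16, "B12": 0.075},
    "other": {"B2": 0.035, "B3": 0.070, "B4": 0.055, "B5": 0.13, "B6": 0.30,
              "B7": 0.38, "B8A": 0.42, "B11": 0.24, "B12": 0.13},
}


@dataclass(frozen=True)
class EndmemberSpectra:
    """Soil and full-canopy endmembers plus per-pixel noise level."""

    soil: np.ndarray
    vegetation: np.ndarray
    noise_sd: float = 0.01

    def __post_init__(self) -> None:
        object.__setattr__(self, "soil", as_band_vector(self.soil))
        object.__setattr__(self, "vegetation", as_band_vector(self.vegetation))
        for name, vec in (("soil", self.soil), ("vegetation", self.vegetation)):
            if np.any(vec < 0) or np.any(vec > 1):
                raise ValueError(f"{name} reflectance must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass(frozen=True)
class SyntheticPlot:
    plot_id: str
    crop_label: str
    sowing_date: dt.date
    pixel_count: int
    cover_params: Optional[CropCalendarEntry]

    def __post_init__(self) -> None:
        if self.pixel_count not in (8, 9, 10):
            raise ValueError("sampling units hold 8, 9 or 10 pixels")


@dataclass(frozen=True)
class ScenarioConfig:
    """Full parameter set for one simulated crop cycle.

    Either ``class_counts`` (exact plots per class) or ``n_plots`` + ``priors``
    (multinomial draw) fixes the crop pattern.  ``n_bare_plots`` adds permanent
    bare-soil plots (label "bare") used to calibrate the soil line; they are
    not part of the surveyed crop plots.
    """

    year: int = 2019
    class_counts: Optional[dict[str, int]] = None
    n_plots: Optional[int] = None
    priors: dict[str, float] = field(default_factory=lambda: dict(CROP_PRIORS_2019))
    n_bare_plots: int = 20
    calendar: Optional[AcquisitionCalendar] = None
    cadence: int = 5
    cloud_probability: float = 0.0
    noise_sd: float = 0.01
    soil_spectrum: dict[str, float] = field(default_factory=lambda: dict(SOIL_SPECTRUM))
    vegetation_spectra: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in VEGETATION_SPECTRA.items()})
    crop_calendar: dict[str, CropCalendarEntry] = field(
        default_factory=lambda: dict(CROP_CALENDAR))
    include_other: bool = True
    train_fraction: float = 0.5
    analysis_dates: tuple[dt.date, ...] = ()

    @property
    def soil_line(self) -> SoilLine:
        s = self.soil_spectrum
        return SoilLine(slope_a=s["B8A"] / s["B4"])


#: Training-cycle survey preset: 280 monitored crop plots (154 corn, 72
#: alfalfa, 54 bean) on the 2019 calendar, analysed on a 30-day schedule.
_ANALYSIS_2019 = (dt.date(2019, 4, 7), dt.date(2019, 5, 7), dt.date(2019, 6, 6),
                  dt.date(2019, 7, 6), dt.date(2019, 8, 5), dt.date(2019, 9, 4))
#: Test-cycle preset: 895 whole-plot units (590 corn, 264 alfalfa, 41 bean)
#: on the 2020 calendar, evaluated on the cloud-free dates of that cycle.
_ANALYSIS_2020 = (dt.date(2020, 5, 6), dt.date(2020, 5, 21),
                  dt.date(2020, 6, 5), dt.date(2020, 6, 20))


def scenario_preset(name: str) -> ScenarioConfig:
    """Named scenario presets: ``survey2019`` (training) and ``cycle2020`` (test)."""
    if name == "survey2019":
        return ScenarioConfig(
            year=2019,
            class_counts={"corn": 154, "alfalfa": 72, "bean": 54},
            calendar=calendar_2019(),
            analysis_dates=_ANALYSIS_2019,
        )
    if name == "cycle2020":
        return ScenarioConfig(
            year=2020,
            class_counts={"corn": 590, "alfalfa": 264, "bean": 41},
            calendar=calendar_2020(),
            analysis_dates=_ANALYSIS_2020,
        )
    raise ValueError(f"unknown scenario preset {name!r}")


@dataclass
class SyntheticDataset:
    """One generated crop cycle: long reflectance table plus metadata."""

    table: pd.DataFrame                     # plot_id, date, bands, label, cover
    calendar: AcquisitionCalendar
    plots: list[SyntheticPlot]              # surveyed crop plots
    bare_plots: list[SyntheticPlot]         # permanent bare-soil plots
    train_plot_ids: list[str]
    validation_plot_ids: list[str]
    config: ScenarioConfig

    @property
    def soil_line(self) -> SoilLine:
        return self.config.soil_line

    def bare_records(self) -> pd.DataFrame:
        return self.table[self.table["crop_label"] == "bare"]


def sample_crop_pattern(n_plots: int, priors: dict[str, float],
                        seed: "int | np.random.Generator") -> list[str]:
    """Draw plot crop labels independently from the module's class priors."""
    if n_plots < 1:
        raise ValueError("n_plots must be at least 1")
    total = sum(priors.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"priors must sum to 1, got {total}")
    if any(p < 0 for p in priors.values()):
        raise ValueError("priors must be non-negative")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    labels = list(priors)
    return [labels[i] for i in rng.choice(len(labels), size=n_plots,
                                          p=list(priors.values()))]


def mix_reflectance(cover: float, spectra: EndmemberSpectra,
                    seed: "int | np.random.Generator") -> np.ndarray:
    """Linear soil/vegetation mixture for one pixel, with Gaussian noise.

    reflectance = (1 - cover) * soil + cover * vegetation + N(0, noise_sd),
    clipped to [0, 1].
    """
    if not 0.0 <= cover <= 1.0:
        raise ValueError(f"cover must lie in [0, 1], got {cover}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    base = (1.0 - cover) * spectra.soil + cover * spectra.vegetation
    if spectra.noise_sd > 0:
        base = base + rng.normal(0.0, spectra.noise_sd, size=base.shape)
    return np.clip(base, 0.0, 1.0)


def _draw_plots(cfg: ScenarioConfig, rng: np.random.Generator) -> list[SyntheticPlot]:
    if cfg.class_counts is not None:
        labels = [c for c, n in cfg.class_counts.items() for _ in range(n)]
    else:
        if cfg.n_plots is None:
            raise ValueError("config must set class_counts or n_plots")
        priors = dict(cfg.priors)
        if not cfg.include_other:
            priors.pop("other", None)
            s = sum(priors.values())
            priors = {k: v / s for k, v in priors.items()}
        labels = sample_crop_pattern(cfg.n_plots, priors, rng)
    plots = []
    for i, label in enumerate(labels):
        entry = cfg.crop_calendar[label]
        lo, hi = entry.sowing_window
        doy = int(rng.integers(lo, hi + 1))
        sowing = dt.date(cfg.year, 1, 1) + dt.timedelta(days=doy - 1)
        plots.append(SyntheticPlot(
            plot_id=f"P{i + 1:04d}", crop_label=label, sowing_date=sowing,
            pixel_count=int(rng.integers(8, 11)), cover_params=entry))
    return plots


def _bare_plots(cfg: ScenarioConfig, rng: np.random.Generator) -> list[SyntheticPlot]:
    return [SyntheticPlot(plot_id=f"BARE{i + 1:03d}", crop_label="bare",
                          sowing_date=dt.date(cfg.year, 1, 1),
                          pixel_count=int(rng.integers(8, 11)), cover_params=None)
            for i in range(cfg.n_bare_plots)]


def _stratified_split(plots: Sequence[SyntheticPlot], train_fraction: float,
                      rng: np.random.Generator) -> tuple[list[str], list[str]]:
    """Per-class random split of plot ids (training first)."""
    train, valid = [], []
    by_class: dict[str, list[str]] = {}
    for p in plots:
        by_class.setdefault(p.crop_label, []).append(p.plot_id)
    for label in sorted(by_class):
        ids = sorted(by_class[label])
        perm = rng.permutation(len(ids))
        n_train = int(round(train_fraction * len(ids)))
        train.extend(ids[i] for i in perm[:n_train])
        valid.extend(ids[i] for i in perm[n_train:])
    return sorted(train), sorted(valid)


def generate_dataset(config: "str | ScenarioConfig", seed: int) -> SyntheticDataset:
    """Simulate one full crop cycle of plot-level zonal-mean reflectance.

    For every plot and every cloud-free acquisition the per-pixel
    soil/vegetation mixture is drawn and averaged over the plot's 8-10 pixels,
    reproducing the zonal-mean observation process.  Two calls with equal seed
    and config return identical datasets.
    """
    cfg = scenario_preset(config) if isinstance(config, str) else config
    root = np.random.default_rng(seed)
    rng_plots, rng_split, rng_noise, rng_cal = root.spawn(4)

    calendar = cfg.calendar
    if calendar is None:
        calendar = build_calendar(
            dt.date(cfg.year, 4, 1), dt.date(cfg.year, 9, 28), cadence=cfg.cadence,
            cloud_probability=cfg.cloud_probability, rng=rng_cal)

    plots = _draw_plots(cfg, rng_plots)
    bare = _bare_plots(cfg, rng_plots)
    dates = calendar.cloud_free

    soil = as_band_vector(cfg.soil_spectrum)
    veg = {c: as_band_vector(v) for c, v in cfg.vegetation_spectra.items()}

    rows: list[tuple] = []
    band_rows: list[np.ndarray] = []
    for plot in plots + bare:
        spectrum_v = veg.get(plot.crop_label, soil)
        for date in dates:
            if plot.cover_params is None:
                cover = 0.0
            else:
                cover = simulate_cover(plot.cover_params, plot.sowing_date, date)
            base = (1.0 - cover) * soil + cover * spectrum_v
            pix = base + rng_noise.normal(0.0, cfg.noise_sd,
                                          size=(plot.pixel_count, len(BANDS)))
            band_rows.append(np.clip(pix, 0.0, 1.0).mean(axis=0))
            rows.append((plot.plot_id, date, plot.crop_label, cover))

    table = pd.DataFrame(rows, columns=["plot_id", "date", "crop_label", "true_cover"])
    table[list(BANDS)] = np.asarray(band_rows)
    table = table[["plot_id", "date", *BANDS, "crop_label", "true_cover"]]

    train_ids, valid_ids = _stratified_split(plots, cfg.train_fraction, rng_split)
    return SyntheticDataset(table=table, calendar=calendar, plots=plots,
                            bare_plots=bare, train_plot_ids=train_ids,
                            validation_plot_ids=valid_ids, config=cfg)


def write_plots_geojson(plots: Sequence[SyntheticPlot], path,
                        origin: tuple[float, float] = (-99.10, 20.42),
                        cell_deg: float = 0.002, per_row: int = 20) -> None:
    """Write plots as rectangles on a synthetic lon/lat grid (EPSG:4326)."""
    features = []
    for i, p in enumerate(plots):
        r, c = divmod(i, per_row)
        x0 = origin[0] + c * cell_deg
        y0 = origin[1] - r * cell_deg
        ring = [[x0, y0], [x0 + cell_deg * 0.9, y0],
                [x0 + cell_deg * 0.9, y0 - cell_deg * 0.9],
                [x0, y0 - cell_deg * 0.9], [x0, y0]]
        features.append({
            "type": "Feature",
            "properties": {"plot_id": p.plot_id, "crop_label": p.crop_label,
                           "pixel_count": p.pixel_count},
            "geometry": {"type": "Polygon", "coordinates": [ring]},
        })
    payload = {"type": "FeatureCollection",
               "crs": {"type": "name",
                       "properties": {"name": "urn:ogc:def:crs:OGC:1.3:CRS84"}},
               "features": features}
    with open(path, "w") as fh:
        json.dump(payload, fh)


def dataset_to_csv(ds: SyntheticDataset, table_path, calendar_path) -> None:
    """Persist the long reflectance table and the acquisition calendar."""
    out = ds.table.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(table_path, index=False)
    cal = pd.DataFrame({
        "date": [d.isoformat() for d in ds.calendar.dates],
        "cloudy": [int(c) for c in ds.calendar.cloudy],
    })
    cal.to_csv(calendar_path, index=False)
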