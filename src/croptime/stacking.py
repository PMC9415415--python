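"""Lagged scene matching and multitemporal feature-record assembly.

Cloud outages make a fixed-cadence time series impossible, so each analysis
date is paired with earlier scenes at nominal lags of 15/30/60 days, taking
the nearest cloud-free scene within a tolerance.  Four lag schemes are used:

====  ===============  ===========
id    lags (days)      descriptors
====  ===============  ===========
C1    0, 30, 60        33
C2    0, 30            22
C3    0, 15, 30        33
C4    0, 15            22
====  ===============  ===========

Each matched scene contributes 11 descriptors (nine band means + NDVI +
WDVI); records are scene-major, current scene first.  Records in which any
constituent scene has WDVI below the emergence threshold are dropped — they
describe bare, not-yet-sown or already-harvested ground, not a standing crop.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from sklearn.base import BaseEstimator, TransformerMixin

from .calendars import AcquisitionCalendar
from .spectral import (DESCRIPTORS_PER_SCENE, EMERGENCE_THRESHOLD, SoilLine,
                       attach_indices, estimate_soil_line)

__all__ = [
    "CombinationSpec", "SceneSelection", "COMBINATIONS", "combination",
    "match_scenes", "build_record", "apply_emergence_filter",
    "assemble_training_table", "descriptor_columns", "TemporalStacker",
    "META_COLUMNS",
]

#: Non-descriptor columns of an assembled training table.
META_COLUMNS: tuple[str, ...] = ("plot_id", "crop_label", "analysis_date")


@dataclass(frozen=True)
class CombinationSpec:
    """A lag scheme: ordered day offsets back from the analysis date."""

    id: str
    lags: tuple[int, ...]
    tolerance: int = 5

    def __post_init__(self) -> None:
        if not self.lags or self.lags[0] != 0:
            raise ValueError("lag 0 (the current scene) must come first")
        if any(b <= a for a, b in zip(self.lags, self.lags[1:])):
            raise ValueError("lags must be strictly increasing")
        if self.tolerance < 0:
            raise ValueError("tolerance must be non-negative")

    @property
    def n_scenes(self) -> int:
        return len(self.lags)

    @property
    def n_descriptors(self) -> int:
        return len(DESCRIPTORS_PER_SCENE) * self.n_scenes


COMBINATIONS: dict[str, CombinationSpec] = {
    "C1": CombinationSpec("C1", (0, 30, 60)),
    "C2": CombinationSpec("C2", (0, 30)),
    "C3": CombinationSpec("C3", (0, 15, 30)),
    "C4": CombinationSpec("C4", (0, 15)),
}


def combination(spec: "str | CombinationSpec", tolerance: Optional[int] = None
                ) -> CombinationSpec:
    """Resolve a combination id (or pass through a spec), optionally re-toleranced."""
    if isinstance(spec, str):
        try:
            spec = COMBINATIONS[spec]
        except KeyError:
            raise ValueError(f"unknown combination {spec!r}; choose from "
                             f"{sorted(COMBINATIONS)}") from None
    if tolerance is not None and tolerance != spec.tolerance:
        spec = CombinationSpec(spec.id, spec.lags, tolerance)
    return spec


@dataclass(frozen=True)
class SceneSelection:
    """One calendar date per lag; the lag-0 date is the analysis date itself."""

    analysis_date: dt.date
    matched_dates: tuple[dt.date, ...]


def match_scenes(cloudfree_dates: Iterable[dt.date], analysis_date: dt.date,
                 spec: "str | CombinationSpec") -> Optional[SceneSelection]:
    """Match each lag to the nearest cloud-free scene within the tolerance.

    Ties between two equidistant scenes break toward the earlier one.
    Returns ``None`` if any lag cannot be matched.  The analysis date must
    itself be a cloud-free scene: classification happens on scene dates only.
    """
    spec = combination(spec)
    dates = sorted(set(cloudfree_dates))
    if analysis_date not in dates:
        raise ValueError(f"analysis date {analysis_date} is not a cloud-free scene")
    matched = []
    for lag in spec.lags:
        target = analysis_date - dt.timedelta(days=lag)
        best = min(dates, key=lambda d: (abs((d - target).days), d))
        if abs((best - target).days) > spec.tolerance:
            return None
        matched.append(best)
    return SceneSelection(analysis_date=analysis_date, matched_dates=tuple(matched))


def descriptor_columns(spec: "str | CombinationSpec") -> list[str]:
    """Scene-major descriptor names, e.g. ``B2_0 ... WDVI_0 B2_30 ... WDVI_60``."""
    spec = combination(spec)
    return [f"{name}_{lag}" for lag in spec.lags for name in DESCRIPTORS_PER_SCENE]


def build_record(plot_id: str, selection: SceneSelection,
                 features: Mapping[dt.date, "pd.Series | Sequence[float]"],
                 label: Optional[str] = None) -> dict:
    """Assemble one labelled feature record from per-date 11-descriptor vectors.

    ``features`` maps each matched date to that plot's descriptors for the
    scene (band means, NDVI, WDVI, in that order).  The record is scene-major:
    the current scene's 11 descriptors first, then each older scene's.
    """
    record: dict = {"plot_id": plot_id, "crop_label": label,
                    "analysis_date": selection.analysis_date}
    lag0 = selection.analysis_date
    for date in selection.matched_dates:
        if date not in features:
            raise KeyError(f"no features available for matched scene {date}")
        lag = (lag0 - date).days
        vec = features[date]
        if isinstance(vec, pd.Series):
            vec = vec.reindex(list(DESCRIPTORS_PER_SCENE)).to_numpy(dtype=float)
        else:
            vec = np.asarray(vec, dtype=float)
        if vec.shape != (len(DESCRIPTORS_PER_SCENE),):
            raise ValueError("each scene must contribute exactly "
                             f"{len(DESCRIPTORS_PER_SCENE)} descriptors")
        if np.any(~np.isfinite(vec)):
            raise ValueError(f"missing descriptor values for scene {date}")
        for name, value in zip(DESCRIPTORS_PER_SCENE, vec):
            record[f"{name}_{lag}"] = float(value)
    return record


def _wdvi_columns(columns: Iterable[str], scope: str) -> list[str]:
    cols = [c for c in columns if c.startswith("WDVI_")]
    if scope == "lagged":
        cols = [c for c in cols if c != "WDVI_0"]
    elif scope != "all":
        raise ValueError("filter scope must be 'all' or 'lagged'")
    return cols


def apply_emergence_filter(records: pd.DataFrame,
                           threshold: float = EMERGENCE_THRESHOLD,
                           scope: str = "all") -> pd.DataFrame:
    """Drop records with sub-threshold WDVI on any constituent scene.

    ``scope='all'`` (default) tests every scene in the record; ``'lagged'``
    tests only the pre-analysis scenes, the strict reading of a filter meant
    to prove the crop already existed before the analysis date.
    """
    cols = _wdvi_columns(records.columns, scope)
    if not cols:
        raise ValueError("records carry no WDVI descriptors to filter on")
    keep = (records[cols] >= threshold).all(axis=1)
    return records.loc[keep].reset_index(drop=True)


def assemble_training_table(dataset: pd.DataFrame, calendar: AcquisitionCalendar,
                            spec: "str | CombinationSpec",
                            soil_line: SoilLine,
                            analysis_dates: Optional[Sequence[dt.date]] = None,
                            emergence_threshold: float = EMERGENCE_THRESHOLD,
                            filter_scope: str = "all",
                            apply_filter: bool = True) -> pd.DataFrame:
    """Build the per-(plot, analysis date) multitemporal database.

    ``dataset`` is the long reflectance table (plot_id, date, nine bands,
    crop_label).  Every requested analysis date for which the lag scheme can
    be matched yields one candidate record per plot; the emergence filter
    then removes records without a standing crop.  Returns a wide table with
    ``plot_id, crop_label, analysis_date`` plus the 11 x k descriptors.
    """
    spec = combination(spec)
    feats = attach_indices(dataset, soil_line, emergence_threshold)
    feats = feats[feats["crop_label"] != "bare"]
    dates = calendar.cloud_free
    if analysis_dates is None:
        candidates = list(dates)
    else:
        candidates = [d for d in analysis_dates if d in set(dates)]

    pieces = []
    value_cols = list(DESCRIPTORS_PER_SCENE)
    for adate in candidates:
        sel = match_scenes(dates, adate, spec)
        if sel is None:
            continue
        base = feats.loc[feats["date"] == adate, ["plot_id", "crop_label"]].copy()
        base["analysis_date"] = adate
        ok = True
        for date in sel.matched_dates:
            lag = (adate - date).days
            scene = feats.loc[feats["date"] == date,
                              ["plot_id", *value_cols]].copy()
            scene.columns = ["plot_id"] + [f"{n}_{lag}" for n in value_cols]
            before = len(base)
            base = base.merge(scene, on="plot_id", how="inner")
            if len(base) < before:
                # plots without a record on a matched scene cannot form rows
                pass
            if base.empty:
                ok = False
                break
        if ok and not base.empty:
            pieces.append(base)

    cols = [*META_COLUMNS, *descriptor_columns(spec)]
    if not pieces:
        import warnings
        warnings.warn(f"no feasible analysis dates for combination {spec.id}; "
                      "returning an empty table", stacklevel=2)
        return pd.DataFrame(columns=cols)
    out = pd.concat(pieces, ignore_index=True)[cols]
    if apply_filter:
        out = apply_emergence_filter(out, emergence_threshold, filter_scope)
    return out.sort_values(["plot_id", "analysis_date"]).reset_index(drop=True)


class TemporalStacker(TransformerMixin, BaseEstimator):
    """Transformer from a long reflectance table to multitemporal records.

    Parameters
    ----------
    calendar : AcquisitionCalendar
        Acquisition dates with cloud flags for the cycle being stacked.
    combination : str or CombinationSpec, default "C1"
        Lag scheme (C1-C4).
    tolerance : int or None
        Override of the scene-matching tolerance in days.
    soil_line : SoilLine or None
        Fixed soil line; if ``None``, :meth:`fit` estimates it from the rows
        labelled ``"bare"`` by the ratio-of-sums estimator.
    emergence_threshold : float
        WDVI below which a scene is considered void of standing crop.
    filter_scope : {"all", "lagged"}
        Which scenes of a record the emergence filter inspects.
    analysis_dates : sequence of dates or None
        Restrict stacking to these analysis dates (``None``: every cloud-free
        scene date that the lag scheme can serve).

    After :meth:`fit`, ``soil_line_`` holds the soil line in use and
    ``feature_names_out_`` the descriptor column names.
    """

    def __init__(self, calendar: AcquisitionCalendar, combination: str = "C1",
                 tolerance: Optional[int] = None,
                 soil_line: Optional[SoilLine] = None,
                 emergence_threshold: float = EMERGENCE_THRESHOLD,
                 filter_scope: str = "all",
                 analysis_dates: Optional[Sequence[dt.date]] = None):
        self.calendar = calendar
        self.combination = combination
        self.tolerance = tolerance
        self.soil_line = soil_line
        self.emergence_threshold = emergence_threshold
        self.filter_scope = filter_scope
        self.analysis_dates = analysis_dates

    def fit(self, X: pd.DataFrame, y=None) -> "TemporalStacker":
        if self.soil_line is not None:
            self.soil_line_ = self.soil_line
        else:
            bare = X[X.get("crop_label", pd.Series(index=X.index, dtype=object))
                     == "bare"]
            if bare.empty:
                raise ValueError("no bare-soil rows to estimate the soil line "
                                 "from; pass soil_line explicitly")
            from .spectral import BANDS
            self.soil_line_ = estimate_soil_line(bare[list(BANDS)].to_numpy())
        self.spec_ = combination(self.combination, self.tolerance)
        self.feature_names_out_ = descriptor_columns(self.spec_)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "soil_line_"):
            raise RuntimeError("TemporalStacker must be fitted before transform")
        return assemble_training_table(
            X, self.calendar, self.spec_, self.soil_line_,
            analysis_dates=self.analysis_dates,
            emergence_threshold=self.emergence_threshold,
            filter_scope=self.filter_scope)
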