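"""Per-plot spectral features: zonal band means, NDVI, WDVI and the soil line.

All reflectances are Sentinel-2 L2A surface reflectance on unit scale
(digital numbers divided by 1e4), so every band value lies in [0, 1] and the
vegetation-emergence threshold on WDVI (0.005 by default) is meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: The nine 20 m bands used throughout, in fixed order: visible (B2-B4),
#: red edge (B5-B7), narrow NIR (B8A) and shortwave infrared (B11, B12).
BANDS: tuple[str, ...] = ("B2", "B3", "B4", "B5", "B6", "B7", "B8A", "B11", "B12")

#: Per-scene descriptor order: the nine band means plus the two indices.
DESCRIPTORS_PER_SCENE: tuple[str, ...] = BANDS + ("NDVI", "WDVI")

#: Default WDVI threshold separating bare/unemerged plots from standing crop.
EMERGENCE_THRESHOLD: float = 0.005


@dataclass(frozen=True)
class SoilLine:
    """Linear bare-soil relation between narrow NIR and red: B8A = slope_a * B4.

    The slope calibrates WDVI so that bare soil scores ~0 regardless of soil
    brightness.  The intercept is fixed at 0 in this formulation.
    """

    slope_a: float
    intercept: float = 0.0

    def __post_init__(self) -> None:
        if not self.slope_a > 0:
            raise ValueError(f"soil-line slope must be positive, got {self.slope_a}")


def as_band_vector(values: "Sequence[float] | dict | pd.Series") -> np.ndarray:
    """Coerce a 9-band reflectance record to a float array in BANDS order."""
    if isinstance(values, dict):
        vec = np.array([values[b] for b in BANDS], dtype=float)
    elif isinstance(values, pd.Series):
        vec = values.reindex(list(BANDS)).to_numpy(dtype=float)
    else:
        vec = np.asarray(values, dtype=float)
    if vec.shape != (len(BANDS),):
        raise ValueError(f"expected {len(BANDS)} band values, got shape {vec.shape}")
    return vec


def zonal_mean(pixel_vectors: Iterable[Sequence[float]]) -> np.ndarray:
    """Arithmetic per-band mean over the pixels of one sampling unit.

    Sampling units are clusters of typically 8-10 pixels (or a whole plot
    polygon); the unit's feature is the mean reflectance per band.
    """
    arr = np.asarray([as_band_vector(v) for v in pixel_vectors], dtype=float)
    if arr.size == 0:
        raise ValueError("empty sampling unit: no pixels to average")
    return arr.mean(axis=0)


def compute_ndvi(b8a, b4):
    """NDVI = (B8A - B4) / (B8A + B4), bounded in [-1, 1].

    A zero denominator is physically impossible for surface reflectance and is
    treated as corrupt input rather than silently returned as 0.
    """
    b8a = np.asarray(b8a, dtype=float)
    b4 = np.asarray(b4, dtype=float)
    denom = b8a + b4
    if np.any(denom <= 0):
        raise ValueError("NDVI undefined: B8A + B4 must be positive")
    return (b8a - b4) / denom


def compute_wdvi(b8a, b4, line: SoilLine):
    """WDVI = B8A - a * B4 with *a* the soil-line slope; ~0 for bare soil."""
    b8a = np.asarray(b8a, dtype=float)
    b4 = np.asarray(b4, dtype=float)
    return b8a - line.slope_a * b4


def estimate_soil_line(bare_vectors: Iterable[Sequence[float]]) -> SoilLine:
    """Estimate the soil-line slope from bare-land plots as a ratio of sums.

    slope_a = sum_i B8A_i / sum_i B4_i over the n bare plots.  This is the
    ratio-of-sums estimator (not a per-plot average of ratios, and not a
    least-squares slope); it is scale invariant and robust to zero-variance
    inputs.
    """
    arr = np.asarray([as_band_vector(v) for v in bare_vectors], dtype=float)
    if arr.size == 0:
        raise ValueError("cannot estimate a soil line from zero bare plots")
    i8a, i4 = BANDS.index("B8A"), BANDS.index("B4")
    sum_b4 = arr[:, i4].sum()
    if sum_b4 <= 0:
        raise ValueError("soil line undefined: bare-plot red reflectance sums to 0")
    return SoilLine(slope_a=float(arr[:, i8a].sum() / sum_b4))


def emergence_status(wdvi, threshold: float = EMERGENCE_THRESHOLD):
    """True where the plot carries standing vegetation (WDVI >= threshold).

    Strictly sub-threshold WDVI marks bare, not-yet-emerged or already
    harvested plots; the boundary value itself counts as emerged.
    """
    wdvi = np.asarray(wdvi, dtype=float)
    if not np.all(np.isfinite(wdvi)):
        raise ValueError("WDVI must be finite")
    out = wdvi >= threshold
    return bool(out) if out.ndim == 0 else out


def attach_indices(table: pd.DataFrame, line: SoilLine,
                   threshold: float = EMERGENCE_THRESHOLD) -> pd.DataFrame:
    """Append NDVI, WDVI and the emergence flag to a long reflectance table.

    ``table`` must carry the nine band columns; the result adds ``NDVI``,
    ``WDVI`` and boolean ``emerged`` columns and leaves the input untouched.
    """
    missing = [b for b in BANDS if b not in table.columns]
    if missing:
        raise ValueError(f"reflectance table is missing band columns: {missing}")
    out = table.copy()
    out["NDVI"] = compute_ndvi(out["B8A"].to_numpy(), out["B4"].to_numpy())
    out["WDVI"] = compute_wdvi(out["B8A"].to_numpy(), out["B4"].to_numpy(), line)
    out["emerged"] = emergence_status(out["WDVI"].to_numpy(), threshold)
    return out
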