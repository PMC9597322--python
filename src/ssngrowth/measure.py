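"""Diameter, volume and mass quantification of segmented nodules.

The three growth measurements are:

* **diameter** (mm): the longest side of the minimum-area rotated
  rectangle circumscribing the mask foreground on the axial slice with
  the largest foreground area (ties broken toward the lowest slice
  index).  The rectangle is fitted to the outer *corners* of the
  foreground voxels mapped to mm, so an axis-aligned n-voxel row has
  diameter n times the in-plane spacing and a single voxel has
  diameter one spacing.
* **volume** (mm^3): foreground voxel count times the voxel volume.
* **mass** (mg): ``M = V * (A + 1000) / 1000`` where A is the mean HU
  of the volume under the mask.

Doubling times follow the exponential-growth closed form
``DT = dt * ln 2 / ln(X2 / X1)`` and are left undefined (flagged, not
infinite) for non-increasing metrics; cohort summaries only use
doubling times inside [1, 1000] days.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from shapely.geometry import MultiPoint

from .grids import NoduleMask, VoxelGrid
from .phantom import DAYS_PER_YEAR, mass_mg

__all__ = [
    "NoduleMeasurement",
    "GrowthRecord",
    "measure",
    "increase_rate",
    "doubling_time",
    "summarize_cohort",
    "DOUBLING_TIME_WINDOW",
]

METRICS = ("diameter", "volume", "mass")

#: doubling times outside this window (days) are excluded from summaries
DOUBLING_TIME_WINDOW = (1.0, 1000.0)


@dataclass(frozen=True)
class NoduleMeasurement:
    """Measurements of one nodule at one time point."""

    diameter: float  # mm
    volume: float  # mm^3
    mean_hu: float  # HU
    mass: float  # mg

    def metric(self, name: str) -> float:
        if name not in METRICS:
            raise ValueError(f"unknown metric {name!r}; expected one of {METRICS}")
        return getattr(self, name)


@dataclass
class GrowthRecord:
    """Per-trajectory growth statistics between two consecutive exams."""

    rate_diameter: float
    rate_volume: float
    rate_mass: float
    dt_days: float
    doubling_time_diameter: float | None
    doubling_time_volume: float | None
    doubling_time_mass: float | None
    annualized_mass_rate: float
    growth_label: bool

    def rate(self, name: str) -> float:
        return getattr(self, f"rate_{name}")

    def doubling_time(self, name: str) -> float | None:
        return getattr(self, f"doubling_time_{name}")


def _axial_diameter(mask: NoduleMask) -> float:
    fg = mask.values
    areas = fg.sum(axis=(1, 2))
    z = int(np.argmax(areas))  # argmax takes the lowest index on ties
    sl = fg[z]
    ys, xs = np.nonzero(sl)
    sy, sx = mask.spacing[1], mask.spacing[2]
    # outer corners of each foreground voxel, in mm
    corners = np.empty((ys.size * 4, 2))
    for i, (dy, dx) in enumerate(((0, 0), (0, 1), (1, 0), (1, 1))):
        corners[i::4, 0] = (xs + dx) * sx
        corners[i::4, 1] = (ys + dy) * sy
    rect = MultiPoint(corners).minimum_rotated_rectangle
    if rect.geom_type == "Point":
        return 0.0
    coords = np.asarray(rect.exterior.coords) if rect.geom_type == "Polygon" \
        else np.asarray(rect.coords)
    sides = np.linalg.norm(np.diff(coords, axis=0), axis=1)
    return float(sides.max())


def measure(voi: VoxelGrid, mask: NoduleMask) -> NoduleMeasurement:
    """Measure diameter, volume, mean HU and mass of a masked nodule."""
    if voi.shape != mask.shape:
        raise ValueError(f"VOI shape {voi.shape} != mask shape {mask.shape}")
    if voi.spacing != mask.spacing:
        raise ValueError("VOI and mask spacing differ")
    if mask.num_foreground == 0:
        raise ValueError("cannot measure an empty mask")
    volume = mask.num_foreground * voi.voxel_volume
    mean_hu = float(voi.values[mask.values].mean())
    return NoduleMeasurement(
        diameter=_axial_diameter(mask),
        volume=volume,
        mean_hu=mean_hu,
        mass=mass_mg(volume, mean_hu),
    )


def increase_rate(prev: NoduleMeasurement, curr: NoduleMeasurement,
                  metric: str = "mass") -> float:
    """Relative increase ``(X_t - X_{t-1}) / X_{t-1}`` of one metric."""
    x0, x1 = prev.metric(metric), curr.metric(metric)
    if x0 <= 0:
        raise ValueError(f"previous {metric} must be positive, got {x0}")
    return (x1 - x0) / x0


def doubling_time(prev: NoduleMeasurement, curr: NoduleMeasurement,
                  dt_days: float, metric: str = "mass") -> float | None:
    """Exponential doubling time in days, or ``None`` when not growing."""
    if dt_days <= 0:
        raise ValueError("dt_days must be positive")
    x0, x1 = prev.metric(metric), curr.metric(metric)
    if x0 <= 0 or x1 <= 0:
        raise ValueError("doubling time requires positive measurements")
    if x1 <= x0:
        return None
    return dt_days * np.log(2.0) / np.log(x1 / x0)


def growth_record(prev: NoduleMeasurement, curr: NoduleMeasurement,
                  dt_days: float, threshold: float = 0.25) -> GrowthRecord:
    """Assemble the full growth record for one consecutive exam pair."""
    from .labels import annualized_mass_rate, growth_label  # cycle-free import

    y = annualized_mass_rate(prev.mass, curr.mass, dt_days)
    return GrowthRecord(
        rate_diameter=increase_rate(prev, curr, "diameter"),
        rate_volume=increase_rate(prev, curr, "volume"),
        rate_mass=increase_rate(prev, curr, "mass"),
        dt_days=dt_days,
        doubling_time_diameter=doubling_time(prev, curr, dt_days, "diameter"),
        doubling_time_volume=doubling_time(prev, curr, dt_days, "volume"),
        doubling_time_mass=doubling_time(prev, curr, dt_days, "mass"),
        annualized_mass_rate=y,
        growth_label=growth_label(y, threshold),
    )


def _clipped_dts(records, metric):
    lo, hi = DOUBLING_TIME_WINDOW
    vals = [r.doubling_time(metric) for r in records]
    return np.array([v for v in vals if v is not None and lo <= v <= hi])


def summarize_cohort(records, groups) -> pd.DataFrame:
    """Per-group rate and doubling-time summary with Welch t-tests.

    For each metric the table reports mean +/- SD of the relative
    increase rates per group, and median (Q1, Q3) of doubling times
    restricted to [1, 1000] days; two-sided Welch t-test P-values
    compare the two groups.  Exactly two groups are required for the
    P-value columns.
    """
    records = list(records)
    groups = np.asarray(groups)
    if len(records) != len(groups):
        raise ValueError("records and groups must have equal length")
    names = list(pd.unique(groups))
    by = {g: [r for r, gg in zip(records, groups) if gg == g] for g in names}
    for g, rs in by.items():
        if len(rs) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 records")
    rows = []
    for metric in METRICS:
        row_rate = {"metric": metric, "statistic": "rate"}
        row_dt = {"metric": metric, "statistic": "doubling_time"}
        for g in names:
            rates = np.array([r.rate(metric) for r in by[g]])
            row_rate[f"{g}_mean"] = rates.mean()
            row_rate[f"{g}_sd"] = rates.std(ddof=1)
            dts = _clipped_dts(by[g], metric)
            if dts.size:
                q1, med, q3 = np.percentile(dts, [25, 50, 75])
            else:
                q1 = med = q3 = np.nan
            row_dt[f"{g}_median"] = med
            row_dt[f"{g}_q1"] = q1
            row_dt[f"{g}_q3"] = q3
            row_dt[f"{g}_n"] = dts.size
        if len(names) == 2:
            a = np.array([r.rate(metric) for r in by[names[0]]])
            b = np.array([r.rate(metric) for r in by[names[1]]])
            row_rate["p_value"] = _welch_p(a, b)
            da, db = _clipped_dts(by[names[0]], metric), _clipped_dts(by[names[1]], metric)
            row_dt["p_value"] = _welch_p(da, db) if min(da.size, db.size) >= 2 else np.nan
        rows.extend([row_rate, row_dt])
    return pd.DataFrame(rows)


def _welch_p(a, b) -> float:
    if np.allclose(a.std(), 0) and np.allclose(b.std(), 0) and np.isclose(a.mean(), b.mean()):
        return 1.0  # identical degenerate groups
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)
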