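"""Growth-curve kinetics: sliding-R² linear-range detection and doubling time.

OD600 time series are log2-transformed; during balanced exponential growth
log2(OD) is linear in time with slope = growth rate (doublings/min) and
doubling time T_D = 1/slope.  The linear range is detected by assigning
each interior time point the R² of the least-squares line through the 11
points centered on it (the point plus the five before and after), averaging
these R² values across replicates on the shared time grid, and taking the
longest contiguous stretch with mean R² >= 0.99.  Using one shared window
for all replicates lowers the variance of the fitted slopes.

``GrowthRateModel`` wraps the procedure in a fit()/results API::

    fit = GrowthRateModel(curves).fit()
    print(fit.summary())
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

HALF_WINDOW = 5  # five points before and after -> 11-point window
R2_THRESHOLD = 0.99


class GrowthError(ValueError):
    """Raised for malformed growth curves or undetectable linear ranges."""


@dataclass(frozen=True)
class GrowthCurve:
    """One replicate OD600 time series (times strictly increasing, OD > 0)."""

    replicate_id: str
    times: np.ndarray
    od600: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        od = np.asarray(self.od600, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "od600", od)
        if t.shape != od.shape or t.ndim != 1:
            raise GrowthError(f"{self.replicate_id}: times/od600 shape mismatch")
        if np.any(np.diff(t) <= 0):
            raise GrowthError(f"{self.replicate_id}: times must strictly increase")
        if np.any(od <= 0):
            raise GrowthError(f"{self.replicate_id}: OD600 must be positive")

    @property
    def log2_od(self) -> np.ndarray:
        return np.log2(self.od600)


def read_growth_csv(path: str | Path) -> list[GrowthCurve]:
    """Load replicate growth curves from CSV (time_min, od600, replicate)."""
    df = pd.read_csv(path)
    required = {"time_min", "od600", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise GrowthError(f"{path}: missing columns {sorted(missing)}")
    curves = []
    for rid, grp in df.groupby("replicate", sort=False):
        grp = grp.sort_values("time_min")
        curves.append(
            GrowthCurve(str(rid), grp.time_min.to_numpy(), grp.od600.to_numpy())
        )
    return curves


def pointwise_window_r2(curve: GrowthCurve, half_window: int = HALF_WINDOW) -> np.ndarray:
    """Centered-window R² of log2(OD) vs time for each point.

    Each interior point gets the R² of the least-squares line through the
    ``2*half_window + 1`` points centered on it; the first and last
    ``half_window`` points are undefined (NaN).
    """
    n = curve.times.size
    w = 2 * half_window + 1
    if n < w:
        raise GrowthError(f"need at least {w} points, got {n}")
    t = curve.times
    y = curve.log2_od
    r2 = np.full(n, np.nan)
    for i in range(half_window, n - half_window):
        ts = t[i - half_window : i + half_window + 1]
        ys = y[i - half_window : i + half_window + 1]
        res = stats.linregress(ts, ys)
        r2[i] = res.rvalue**2
    return r2


def averaged_linear_range(
    r2_per_replicate: Sequence[np.ndarray], threshold: float = R2_THRESHOLD
) -> tuple[int, int]:
    """Longest contiguous index run with replicate-mean R² >= threshold.

    Replicates must share the time grid.  Returns (start_index, end_index)
    inclusive; ties between equal-length runs go to the earliest.
    """
    arrays = [np.asarray(a, dtype=float) for a in r2_per_replicate]
    if not arrays:
        raise GrowthError("no replicates supplied")
    n = arrays[0].size
    if any(a.size != n for a in arrays):
        raise GrowthError("replicates must share the time grid")
    stack = np.vstack(arrays)
    defined = ~np.isnan(stack)
    counts = defined.sum(axis=0)
    mean_r2 = np.where(
        counts > 0, np.nansum(np.where(defined, stack, 0.0), axis=0) / np.maximum(counts, 1), np.nan
    )
    ok = ~np.isnan(mean_r2) & (mean_r2 >= threshold)
    best: Optional[tuple[int, int]] = None
    i = 0
    while i < n:
        if ok[i]:
            j = i
            while j + 1 < n and ok[j + 1]:
                j += 1
            if best is None or (j - i) > (best[1] - best[0]):
                best = (i, j)
            i = j + 1
        else:
            i += 1
    if best is None:
        raise GrowthError(f"no linear range: no point reaches mean R² >= {threshold}")
    return best


@dataclass
class GrowthFit:
    """Fitted growth kinetics over a shared linear range.

    ``growth_rate`` is the mean of per-replicate log2(OD) slopes
    (doublings per minute); ``doubling_time`` = 1/growth_rate minutes;
    ``standard_error`` is the SE of the per-replicate doubling times.
    """

    linear_range: tuple[float, float]  # start/end time, minutes
    range_indices: tuple[int, int]
    replicate_ids: list[str]
    slopes: np.ndarray  # log2-OD per minute, one per replicate
    growth_rate: float
    doubling_time: float
    standard_error: float
    r2_threshold: float = R2_THRESHOLD

    @property
    def per_replicate_doubling_times(self) -> np.ndarray:
        return 1.0 / self.slopes

    def summary(self) -> str:
        lines = [
            "Growth-rate fit (log2 OD600 vs time)",
            "=" * 44,
            f"linear range        {self.linear_range[0]:.0f} - {self.linear_range[1]:.0f} min"
            f"  (indices {self.range_indices[0]}..{self.range_indices[1]})",
            f"R² threshold        {self.r2_threshold}",
            f"replicates          {len(self.replicate_ids)}",
            f"growth rate         {self.growth_rate:.5f} log2-OD/min",
            f"doubling time T_D   {self.doubling_time:.1f} min (SE {self.standard_error:.1f})",
            "-" * 44,
        ]
        for rid, s, td in zip(
            self.replicate_ids, self.slopes, self.per_replicate_doubling_times
        ):
            lines.append(f"  {rid:<12} slope {s:.5f}  T_D {td:.1f} min")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "linear_range_min": list(self.linear_range),
            "growth_rate_per_min": self.growth_rate,
            "doubling_time_min": self.doubling_time,
            "standard_error_min": self.standard_error,
            "replicates": self.replicate_ids,
            "slopes": [float(s) for s in self.slopes],
        }


def doubling_time(
    curves: Sequence[GrowthCurve],
    index_range: tuple[int, int],
    r2_threshold: float = R2_THRESHOLD,
) -> GrowthFit:
    """Per-replicate slopes over a shared index range -> doubling time.

    The slope of the least-squares fit of log2(OD600) over the range is
    each replicate's growth rate; the reported rate is their mean and
    T_D = 1/rate.  SE is the standard error of the per-replicate T_D.
    """
    curves = list(curves)
    if not curves:
        raise GrowthError("no growth curves supplied")
    i0, i1 = index_range
    n = curves[0].times.size
    if not (0 <= i0 <= i1 < n):
        raise GrowthError(f"index range {index_range} outside data (n={n})")
    slopes = []
    for c in curves:
        if c.times.size != n or not np.allclose(c.times, curves[0].times):
            raise GrowthError("replicates must share the time grid (no interpolation)")
        res = stats.linregress(c.times[i0 : i1 + 1], c.log2_od[i0 : i1 + 1])
        slopes.append(res.slope)
    slopes = np.asarray(slopes)
    rate = float(slopes.mean())
    if rate <= 0:
        raise GrowthError("mean growth rate is non-positive over the chosen range")
    tds = 1.0 / slopes
    se = float(tds.std(ddof=1) / math.sqrt(len(tds))) if len(tds) > 1 else 0.0
    return GrowthFit(
        linear_range=(float(curves[0].times[i0]), float(curves[0].times[i1])),
        range_indices=(i0, i1),
        replicate_ids=[c.replicate_id for c in curves],
        slopes=slopes,
        growth_rate=rate,
        doubling_time=1.0 / rate,
        standard_error=se,
        r2_threshold=r2_threshold,
    )


class GrowthRateModel:
    """Doubling-time estimation from replicate OD600 curves.

    Parameters
    ----------
    curves:
        Replicate growth curves on a shared time grid.
    half_window:
        Points on either side of a point in its R² window (default 5).
    r2_threshold:
        Minimum replicate-averaged window R² for the linear range.

    ``fit()`` auto-detects the linear range; ``fit(time_range=(a, b))``
    fixes it to a user-chosen window in minutes instead.
    """

    def __init__(
        self,
        curves: Sequence[GrowthCurve],
        half_window: int = HALF_WINDOW,
        r2_threshold: float = R2_THRESHOLD,
    ) -> None:
        self.curves = list(curves)
        if not self.curves:
            raise GrowthError("no growth curves supplied")
        self.half_window = half_window
        self.r2_threshold = r2_threshold

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kw) -> "GrowthRateModel":
        curves = []
        for rid, grp in df.groupby("replicate", sort=False):
            grp = grp.sort_values("time_min")
            curves.append(
                GrowthCurve(str(rid), grp.time_min.to_numpy(), grp.od600.to_numpy())
            )
        return cls(curves, **kw)

    @classmethod
    def from_csv(cls, path: str | Path, **kw) -> "GrowthRateModel":
        return cls(read_growth_csv(path), **kw)

    def fit(self, time_range: Optional[tuple[float, float]] = None) -> GrowthFit:
        t = self.curves[0].times
        if time_range is None:
            r2s = [pointwise_window_r2(c, self.half_window) for c in self.curves]
            idx = averaged_linear_range(r2s, self.r2_threshold)
        else:
            mask = (t >= time_range[0]) & (t <= time_range[1])
            sel = np.nonzero(mask)[0]
            if sel.size < 2:
                raise GrowthError(f"time range {time_range} covers < 2 points")
            idx = (int(sel[0]), int(sel[-1]))
        return doubling_time(self.curves, idx, self.r2_threshold)
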