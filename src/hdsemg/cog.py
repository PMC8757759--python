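"""Centre of gravity (barycentre) of activation maps.

The CoG of a map is the amplitude-weighted mean electrode coordinate,

    CoG = Σ_ij HM_ij · (i, j) / Σ_ij HM_ij,

in 1-based electrode-index units: ``x`` along the fiber (row) axis, ``y``
across columns.  Two estimators are provided: the classical *point* method,
which reduces a contraction to the CoG of one reference map (the peak-
intensity map for dynamic contractions, or the midpoint epoch), and the
*trajectory* method, which tracks the CoG over every analysis window from
the beginning to the end of the contraction and summarises each axis by its
mean, variance/SD and min-max range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sst

from .grid import ActivationMap

__all__ = [
    "CoGPoint",
    "CoGTrajectory",
    "cog_point",
    "cog_reference",
    "cog_trajectory",
    "compare_cog_methods",
]


@dataclass(frozen=True)
class CoGPoint:
    """Barycentre of one activation map, in electrode-index units."""

    x: float  # along-fiber (row) axis
    y: float  # across (column) axis
    reference_window: str = "midpoint"

    def to_mm(self, ied_mm: float) -> tuple[float, float]:
        """Convert to millimetres from the grid origin (electrode 1 at 0)."""
        return ((self.x - 1) * ied_mm, (self.y - 1) * ied_mm)


@dataclass
class CoGTrajectory:
    """Time series of CoG positions over one contraction, with summaries."""

    times_s: np.ndarray
    xs: np.ndarray
    ys: np.ndarray

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.xs = np.asarray(self.xs, dtype=float)
        self.ys = np.asarray(self.ys, dtype=float)
        if not (len(self.times_s) == len(self.xs) == len(self.ys)):
            raise ValueError("trajectory series lengths differ")
        if len(self.xs) == 0:
            raise ValueError("empty trajectory")

    @property
    def mean_x(self) -> float:
        return float(self.xs.mean())

    @property
    def mean_y(self) -> float:
        return float(self.ys.mean())

    @property
    def var_x(self) -> float:
        return float(self.xs.var())

    @property
    def var_y(self) -> float:
        return float(self.ys.var())

    @property
    def sd_x(self) -> float:
        return float(self.xs.std())

    @property
    def sd_y(self) -> float:
        return float(self.ys.std())

    @property
    def range_x(self) -> float:
        return float(self.xs.max() - self.xs.min())

    @property
    def range_y(self) -> float:
        return float(self.ys.max() - self.ys.min())

    def summary_dict(self) -> dict:
        return {
            "cogx_mean": self.mean_x,
            "cogy_mean": self.mean_y,
            "cogx_var": self.var_x,
            "cogy_var": self.var_y,
            "cogx_sd": self.sd_x,
            "cogy_sd": self.sd_y,
            "cogx_range": self.range_x,
            "cogy_range": self.range_y,
        }


def cog_point(amap: ActivationMap, reference_window: str = "midpoint") -> CoGPoint:
    """Amplitude-weighted mean grid coordinate of one map.

    Weighting is linear in the map amplitude; masked positions are excluded.
    Invariant under positive rescaling of the map.
    """
    rows, cols = np.nonzero(amap.valid_mask)
    w = amap.values[rows, cols]
    total = w.sum()
    if total <= 0:
        raise ValueError("cannot locate the CoG of an all-zero map")
    x = float(np.sum(w * (rows + 1)) / total)
    y = float(np.sum(w * (cols + 1)) / total)
    return CoGPoint(x=x, y=y, reference_window=reference_window)


def cog_reference(
    maps: Sequence[ActivationMap],
    rule: str = "peak_intensity",
    torque: Optional[np.ndarray] = None,
    torque_fs_hz: float = 100.0,
) -> CoGPoint:
    """Point-method CoG: pick one reference map per ``rule``, return its CoG.

    ``midpoint`` takes the middle window (isometric convention);
    ``peak_intensity`` the window with the largest mean map amplitude (the
    single point at peak intensity used for dynamic contractions);
    ``peak_torque`` the window whose span contains the torque maximum.
    """
    maps = list(maps)
    if not maps:
        raise ValueError("no maps given")
    if rule == "midpoint":
        k = len(maps) // 2
    elif rule == "peak_intensity":
        k = int(np.argmax([m.valid_values.mean() for m in maps]))
    elif rule == "peak_torque":
        if torque is None:
            raise ValueError("peak_torque rule requires a torque trace")
        t_peak = float(np.argmax(np.abs(torque))) / torque_fs_hz
        centers = np.array([m.center_time_s for m in maps])
        k = int(np.argmin(np.abs(centers - t_peak)))
    else:
        raise ValueError(f"unknown reference rule {rule!r}")
    return cog_point(maps[k], reference_window=rule)


def cog_trajectory(maps: Sequence[ActivationMap]) -> CoGTrajectory:
    """CoG series over consecutive windows of a contraction.

    All-zero windows are skipped with a warning; the trajectory fails only
    if every window is empty.
    """
    maps = list(maps)
    if len(maps) < 2:
        raise ValueError("trajectory needs at least two maps")
    times, xs, ys = [], [], []
    for m in maps:
        try:
            p = cog_point(m)
        except ValueError:
            warnings.warn(
                f"skipping all-zero window at t={m.center_time_s:.3f} s",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        times.append(m.center_time_s)
        xs.append(p.x)
        ys.append(p.y)
    if not xs:
        raise ValueError("every window was all-zero; no trajectory")
    return CoGTrajectory(times_s=np.array(times), xs=np.array(xs), ys=np.array(ys))


def compare_cog_methods(
    points: Sequence[CoGPoint],
    trajectories: Sequence[CoGTrajectory],
    speeds: Optional[Sequence] = None,
) -> pd.DataFrame:
    """Pearson agreement of the point and trajectory-mean CoG estimates.

    One row per axis (and per speed group when ``speeds`` is given, plus a
    pooled row) with r, r², the two-sided p-value and n.  Groups in which
    either series has zero variance yield an undefined (NaN) correlation.
    """
    points = list(points)
    trajectories = list(trajectories)
    if len(points) != len(trajectories):
        raise ValueError("points and trajectories are not matched")
    if len(points) < 3:
        raise ValueError("need at least 3 matched trials")
    px = np.array([p.x for p in points])
    py = np.array([p.y for p in points])
    tx = np.array([t.mean_x for t in trajectories])
    ty = np.array([t.mean_y for t in trajectories])
    speeds_arr = None if speeds is None else np.asarray(list(speeds))

    def one(axis: str, a: np.ndarray, b: np.ndarray, label) -> dict:
        row = {"axis": axis, "speed": label, "n": len(a)}
        if len(a) < 3 or a.std() == 0 or b.std() == 0:
            row.update(r=np.nan, r2=np.nan, p=np.nan, note="undefined (zero variance)")
        else:
            r, p = sst.pearsonr(a, b)
            row.update(r=float(r), r2=float(r) ** 2, p=float(p), note="")
        return row

    rows = []
    for axis, a, b in (("x", px, tx), ("y", py, ty)):
        rows.append(one(axis, a, b, "all"))
        if speeds_arr is not None:
            for s in sorted(set(speeds_arr.tolist())):
                sel = speeds_arr == s
                rows.append(one(axis, a[sel], b[sel], s))
    return pd.DataFrame(rows, columns=["axis", "speed", "n", "r", "r2", "p", "note"])
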