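"""Model/results interface over the spatial-analysis pipeline.

Three model classes follow the statsmodels convention of a model object
built from data whose ``fit()`` returns a results object with a
``summary()``:

* :class:`ContractionAnalysis` — one contraction trial: filtering,
  segmentation, activation maps, the six map features, and both CoG
  estimators.
* :class:`SpeedComparison` — a cohort feature table: per-speed normality
  checks and Bonferroni-corrected paired t-tests of every feature across
  speeds.
* :class:`CoGMethodAgreement` — Pearson agreement of the point and
  trajectory CoG estimators across trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cog import CoGPoint, CoGTrajectory, cog_reference, cog_trajectory, compare_cog_methods
from .features import FeatureSet, feature_set
from .grid import ActivationMap, ContractionSegment, GridRecording
from .io import load_recording
from .preprocess import bandpass_filter, midpoint_epoch, segment_contraction, to_single_differential, windowed_maps
from .stats import pairwise_t_bonferroni, shapiro_wilk

__all__ = ["ContractionAnalysis", "ContractionResults", "SpeedComparison", "CoGMethodAgreement"]

FEATURE_COLUMNS = [
    "entropy",
    "cov",
    "intensity",
    "differential_intensity",
    "mean_rms",
    "median_frequency",
]


class ContractionAnalysis:
    """Spatial analysis of one contraction trial.

    Parameters
    ----------
    recording
        A monopolar :class:`~hdsemg.grid.GridRecording`.
    low_hz, high_hz, filter_order
        Band-pass settings (20-400 Hz, 4th-order zero-phase Butterworth).
    window_s, overlap_frac
        Trajectory analysis window (250 ms, non-overlapping by default;
        ``window_s=1.0`` gives the per-second amplitude tiling).
    epoch_s
        Feature epoch centred at the contraction midpoint (250 ms).
    segment_source, threshold_frac
        Contraction detection: torque when present else the grid EMG
        envelope, at 10% of peak.
    cog_rule
        Reference-map rule for the point CoG estimator
        (``peak_intensity`` | ``midpoint`` | ``peak_torque``).
    prefiltered
        Skip band-pass filtering (signals already conditioned).
    """

    def __init__(
        self,
        recording: GridRecording,
        *,
        low_hz: float = 20.0,
        high_hz: float = 400.0,
        filter_order: int = 4,
        window_s: float = 0.25,
        overlap_frac: float = 0.0,
        epoch_s: float = 0.25,
        segment_source: str = "auto",
        threshold_frac: float = 0.1,
        cog_rule: str = "peak_intensity",
        prefiltered: bool = False,
    ) -> None:
        if recording.mode != "monopolar":
            raise ValueError("ContractionAnalysis expects a monopolar recording")
        self.recording = recording
        self.low_hz = low_hz
        self.high_hz = high_hz
        self.filter_order = filter_order
        self.window_s = window_s
        self.overlap_frac = overlap_frac
        self.epoch_s = epoch_s
        self.segment_source = segment_source
        self.threshold_frac = threshold_frac
        self.cog_rule = cog_rule
        self.prefiltered = prefiltered

    @classmethod
    def from_files(cls, signal_path, sidecar_path, **kwargs) -> "ContractionAnalysis":
        """Build from a signal TSV + JSON sidecar pair."""
        return cls(load_recording(signal_path, sidecar_path), **kwargs)

    def fit(self) -> "ContractionResults":
        rec = self.recording
        if not self.prefiltered:
            rec = bandpass_filter(rec, self.low_hz, self.high_hz, self.filter_order)
        seg = segment_contraction(
            rec,
            source=self.segment_source,
            threshold_frac=self.threshold_frac,
            min_duration_s=max(self.epoch_s, self.window_s),
        )
        maps = windowed_maps(rec, seg, window_s=self.window_s, overlap_frac=self.overlap_frac)
        feats = feature_set(rec, seg, epoch_s=self.epoch_s)
        point = cog_reference(
            maps, rule=self.cog_rule, torque=rec.torque, torque_fs_hz=rec.torque_fs_hz
        )
        traj = cog_trajectory(maps) if len(maps) >= 2 else None
        mid_map = midpoint_epoch(rec, seg, epoch_s=self.epoch_s)
        return ContractionResults(
            model=self,
            filtered=rec,
            segment=seg,
            maps=maps,
            midpoint_map=mid_map,
            features=feats,
            cog=point,
            trajectory=traj,
        )


@dataclass
class ContractionResults:
    """Per-trial estimates: features, CoG point, CoG trajectory."""

    model: ContractionAnalysis
    filtered: GridRecording
    segment: ContractionSegment
    maps: list[ActivationMap]
    midpoint_map: ActivationMap
    features: FeatureSet
    cog: CoGPoint
    trajectory: Optional[CoGTrajectory]

    def to_row(self) -> dict:
        """One feature-table row (the per-trial report layout)."""
        rec = self.model.recording
        row = {"side": rec.side, "speed": rec.speed_label}
        row.update(self.features.as_dict())
        row.update({"cog_x": self.cog.x, "cog_y": self.cog.y})
        if self.trajectory is not None:
            row.update(self.trajectory.summary_dict())
        return row

    def summary(self) -> str:
        rec = self.model.recording
        fs = rec.fs_hz
        lines = [
            "Contraction spatial analysis",
            "=" * 60,
            f"grid                 {rec.geometry.n_rows}x{rec.geometry.n_cols}"
            f" ({rec.n_channels} electrodes, IED {rec.geometry.ied_mm:g} mm)",
            f"speed / side         {rec.speed_label} deg/s / {rec.side or '-'}",
            f"segment              {self.segment.start_sample / fs:.3f}-"
            f"{self.segment.end_sample / fs:.3f} s ({self.segment.method})",
            f"windows              {len(self.maps)} x {self.model.window_s:g} s",
            "-" * 60,
            f"entropy              {self.features.entropy:8.4f} bits",
            f"CoV                  {self.features.cov:8.2f} %",
            f"intensity            {self.features.intensity:8.4f} log10-mV",
            f"diff. intensity      {self.features.differential_intensity:8.4f} log10-mV",
            f"mean RMS             {self.features.mean_rms:8.4f} mV",
            f"median frequency     {self.features.median_frequency:8.2f} Hz",
            "-" * 60,
            f"CoG (point, {self.cog.reference_window:>14s})  x={self.cog.x:.3f}  y={self.cog.y:.3f}",
        ]
        if self.trajectory is not None:
            t = self.trajectory
            lines += [
                f"CoG (trajectory mean)      x={t.mean_x:.3f}  y={t.mean_y:.3f}",
                f"CoG trajectory var         x={t.var_x:.4f}  y={t.var_y:.4f}",
                f"CoG trajectory range       x={t.range_x:.3f}  y={t.range_y:.3f}",
            ]
        return "\n".join(lines)

    def plot_map(self, which: str = "midpoint", ax=None, **kwargs):
        from .plotting import plot_activation_map

        amap = self.midpoint_map if which == "midpoint" else self.maps[int(which)]
        return plot_activation_map(amap, ax=ax, **kwargs)

    def plot_trajectory(self, ax=None, **kwargs):
        from .plotting import plot_cog_trajectory

        if self.trajectory is None:
            raise ValueError("no trajectory (single-window contraction)")
        return plot_cog_trajectory(
            self.trajectory, geometry=self.model.recording.geometry, ax=ax, **kwargs
        )


class SpeedComparison:
    """Speed-effect statistics on a long-format cohort feature table.

    ``table`` needs ``subject`` and ``speed`` columns plus one column per
    feature (any subset of the six standard features, or other scalars).
    """

    def __init__(self, table: pd.DataFrame, features: Optional[Sequence[str]] = None):
        required = {"subject", "speed"}
        if not required.issubset(table.columns):
            raise ValueError(f"table must have columns {sorted(required)}")
        if features is None:
            features = [c for c in FEATURE_COLUMNS if c in table.columns]
        if not features:
            raise ValueError("no feature columns found")
        self.table = table
        self.features = list(features)

    def fit(self, alpha: float = 0.05) -> "SpeedComparisonResults":
        # average replicate trials within subject x speed before pairing
        agg = (
            self.table.groupby(["subject", "speed"])[self.features]
            .mean()
            .reset_index()
        )
        normality_rows = []
        test_frames = []
        for feat in self.features:
            wide = agg.pivot(index="subject", columns="speed", values=feat).dropna()
            for speed in wide.columns:
                try:
                    w, p = shapiro_wilk(wide[speed])
                except ValueError:
                    w, p = np.nan, np.nan
                normality_rows.append(
                    {"feature": feat, "speed": speed, "W": w, "p": p, "n": len(wide)}
                )
            tests = pairwise_t_bonferroni(wide, alpha=alpha)
            tests.insert(0, "feature", feat)
            test_frames.append(tests)
        return SpeedComparisonResults(
            model=self,
            alpha=alpha,
            normality=pd.DataFrame(normality_rows),
            tests=pd.concat(test_frames, ignore_index=True),
            by_speed=self.table.groupby("speed")[self.features].agg(["mean", "std"]),
        )


@dataclass
class SpeedComparisonResults:
    model: SpeedComparison
    alpha: float
    normality: pd.DataFrame
    tests: pd.DataFrame
    by_speed: pd.DataFrame

    @property
    def any_significant(self) -> bool:
        return bool(self.tests["significant"].any())

    def summary(self) -> str:
        n_sig = int(self.tests["significant"].sum())
        lines = [
            "Speed-effect comparison (paired t, Bonferroni)",
            "=" * 60,
            f"features: {', '.join(self.model.features)}",
            f"alpha = {self.alpha}; comparisons per feature = "
            f"{self.tests.groupby('feature').size().iloc[0]}",
            "",
            self.tests.to_string(index=False, float_format=lambda v: f"{v:.4g}"),
            "",
            f"{n_sig} significant speed difference(s) after correction"
            + ("" if n_sig else " — no effect of speed detected"),
        ]
        return "\n".join(lines)


class CoGMethodAgreement:
    """Agreement of the point and trajectory-mean CoG estimates.

    Built either from matched :class:`CoGPoint` / :class:`CoGTrajectory`
    lists or from a table with columns ``cog_x, cog_y, cogx_mean, cogy_mean``
    (and optionally ``speed``).
    """

    def __init__(
        self,
        points: Optional[Sequence[CoGPoint]] = None,
        trajectories: Optional[Sequence[CoGTrajectory]] = None,
        speeds: Optional[Sequence] = None,
        table: Optional[pd.DataFrame] = None,
    ) -> None:
        if table is not None:
            points = [
                CoGPoint(x, y) for x, y in zip(table["cog_x"], table["cog_y"])
            ]
            # the table carries only the trajectory means; hold them as
            # degenerate one-sample trajectories
            trajectories = [
                CoGTrajectory(times_s=[0.0], xs=[x], ys=[y])
                for x, y in zip(table["cogx_mean"], table["cogy_mean"])
            ]
            speeds = table["speed"] if "speed" in table.columns else None
        if points is None or trajectories is None:
            raise ValueError("give matched points and trajectories, or a table")
        self.points = list(points)
        self.trajectories = list(trajectories)
        self.speeds = None if speeds is None else list(speeds)

    def fit(self) -> "CoGMethodAgreementResults":
        corr = compare_cog_methods(self.points, self.trajectories, speeds=self.speeds)
        return CoGMethodAgreementResults(model=self, correlations=corr)


@dataclass
class CoGMethodAgreementResults:
    model: CoGMethodAgreement
    correlations: pd.DataFrame

    def summary(self) -> str:
        return (
            "CoG point vs. trajectory-mean agreement (Pearson)\n"
            + "=" * 60
            + "\n"
            + self.correlations.to_string(index=False, float_format=lambda v: f"{v:.4g}")
        )
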