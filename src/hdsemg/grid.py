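"""Data model for grid EMG recordings.

High-density surface EMG (HDsEMG) is recorded from a 2D electrode grid placed
over one muscle.  The study layout is a 13-row x 5-column semi-disposable
array with one corner position unpopulated, giving 64 active electrodes at an
8 mm inter-electrode distance.  Grid positions are 1-based ``(row, col)``
pairs; the row axis runs along the muscle-fiber direction (the long,
13-electrode axis) and the column axis across it.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "GridGeometry",
    "GridRecording",
    "ContractionSegment",
    "ActivationMap",
    "default_channel_map",
    "to_grid_view",
    "scatter_to_grid",
]

#: Recognised recording modes.
MODES = ("monopolar", "single_differential")


@dataclass(frozen=True)
class GridGeometry:
    """Electrode grid layout.

    Parameters
    ----------
    n_rows, n_cols
        Grid extent.  Default 13 x 5 (the study array).
    missing
        Grid positions (1-based ``(row, col)``) with no electrode.  The
        default leaves one corner unpopulated, for 64 electrodes on the
        13 x 5 grid.  Which corner the physical array omits is not fixed by
        the hardware documentation available to us; ``(1, 1)`` is this
        package's documented convention and is configurable.
    ied_mm
        Inter-electrode distance in millimetres.
    """

    n_rows: int = 13
    n_cols: int = 5
    missing: tuple[tuple[int, int], ...] = ((1, 1),)
    ied_mm: float = 8.0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")
        if self.ied_mm <= 0:
            raise ValueError(f"ied_mm must be positive, got {self.ied_mm}")
        miss = tuple((int(r), int(c)) for r, c in self.missing)
        object.__setattr__(self, "missing", miss)
        for r, c in miss:
            if not (1 <= r <= self.n_rows and 1 <= c <= self.n_cols):
                raise ValueError(f"missing position {(r, c)} outside {self.n_rows}x{self.n_cols} grid")
        if len(set(miss)) != len(miss):
            raise ValueError("duplicate missing positions")

    @property
    def n_electrodes(self) -> int:
        return self.n_rows * self.n_cols - len(self.missing)

    def is_missing(self, row: int, col: int) -> bool:
        return (row, col) in set(self.missing)

    def valid_mask(self) -> np.ndarray:
        """Boolean (n_rows, n_cols) array, True where an electrode exists."""
        mask = np.ones((self.n_rows, self.n_cols), dtype=bool)
        for r, c in self.missing:
            mask[r - 1, c - 1] = False
        return mask

    def positions(self) -> list[tuple[int, int]]:
        """All populated positions in row-major order (1-based)."""
        return [
            (r, c)
            for r in range(1, self.n_rows + 1)
            for c in range(1, self.n_cols + 1)
            if not self.is_missing(r, c)
        ]


def default_channel_map(geometry: GridGeometry) -> list[tuple[int, int]]:
    """Row-major electrode-index -> (row, col) assignment."""
    return geometry.positions()


@dataclass
class ContractionSegment:
    """A contiguous stretch of samples containing one contraction."""

    start_sample: int
    end_sample: int
    method: str = "manual"  # torque-threshold | envelope-threshold | manual

    def __post_init__(self) -> None:
        if not (0 <= self.start_sample < self.end_sample):
            raise ValueError(
                f"invalid segment [{self.start_sample}, {self.end_sample})"
            )

    @property
    def n_samples(self) -> int:
        return self.end_sample - self.start_sample

    def duration_s(self, fs_hz: float) -> float:
        return self.n_samples / fs_hz

    def midpoint_s(self, fs_hz: float) -> float:
        return 0.5 * (self.start_sample + self.end_sample) / fs_hz


@dataclass
class ActivationMap:
    """Per-position RMS amplitudes for one time window (the map ``HM``).

    ``values[i-1, j-1]`` is the RMS amplitude (mV) of the channel at grid
    position ``(i, j)``; positions with no electrode are masked invalid and
    excluded from every downstream channel count.
    """

    values: np.ndarray
    valid_mask: np.ndarray
    window: tuple[float, float]
    mode: str = "monopolar"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.values.shape != self.valid_mask.shape:
            raise ValueError("values and valid_mask shapes differ")
        if self.window[0] >= self.window[1]:
            raise ValueError(f"window start >= end: {self.window}")
        if self.mode not in MODES:
            raise ValueError(f"unknown map mode {self.mode!r}")
        vv = self.values[self.valid_mask]
        if vv.size and not np.all(np.isfinite(vv)):
            raise ValueError("non-finite map values at valid positions")
        if vv.size and np.any(vv < 0):
            raise ValueError("RMS map values must be non-negative")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def n_valid(self) -> int:
        return int(self.valid_mask.sum())

    @property
    def valid_values(self) -> np.ndarray:
        """Flat array of the RMS values at populated positions."""
        return self.values[self.valid_mask]

    @property
    def center_time_s(self) -> float:
        return 0.5 * (self.window[0] + self.window[1])


class GridRecording:
    """A multichannel grid EMG recording.

    Parameters
    ----------
    signals
        ``(n_channels, n_samples)`` array in mV.
    fs_hz
        EMG sampling rate (1024 Hz for the study hardware).
    geometry
        The electrode layout.
    channel_positions
        ``channel_positions[k]`` is the 1-based ``(row, col)`` grid position
        of channel ``k``; must be a bijection onto the populated positions.
    mode
        ``"monopolar"`` or ``"single_differential"``.
    torque
        Optional dynamometer torque trace in Nm, sampled at ``torque_fs_hz``
        (100 Hz on the study dynamometer); kept at its native rate.
    speed_label
        Isokinetic speed condition in deg/s (0 = isometric MVC), or None.
    side
        Optional limb tag, e.g. ``"affected"`` / ``"intact"``.
    """

    def __init__(
        self,
        signals: np.ndarray,
        fs_hz: float,
        geometry: GridGeometry,
        channel_positions: Optional[Sequence[tuple[int, int]]] = None,
        mode: str = "monopolar",
        torque: Optional[np.ndarray] = None,
        torque_fs_hz: float = 100.0,
        speed_label: Optional[int] = None,
        side: Optional[str] = None,
    ) -> None:
        signals = np.asarray(signals, dtype=float)
        if signals.ndim != 2:
            raise ValueError("signals must be a 2D (channels x samples) array")
        if mode not in MODES:
            raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
        if fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if channel_positions is None:
            channel_positions = default_channel_map(geometry)
        channel_positions = [(int(r), int(c)) for r, c in channel_positions]
        if len(channel_positions) != signals.shape[0]:
            raise ValueError(
                f"channel map has {len(channel_positions)} entries but the "
                f"signal matrix has {signals.shape[0]} channels"
            )
        expected = set(geometry.positions())
        got = set(channel_positions)
        if len(got) != len(channel_positions):
            raise ValueError("channel map assigns one position to several channels")
        if got != expected:
            raise ValueError(
                "channel map is not a bijection onto the populated grid "
                f"positions ({len(got)} mapped vs {len(expected)} populated)"
            )
        if not np.all(np.isfinite(signals)):
            bad = np.unique(np.nonzero(~np.isfinite(signals))[0]).tolist()
            raise ValueError(f"non-finite samples in channels {bad}")
        self.signals = signals
        self.fs_hz = float(fs_hz)
        self.geometry = geometry
        self.channel_positions = channel_positions
        self.mode = mode
        self.torque = None if torque is None else np.asarray(torque, dtype=float)
        self.torque_fs_hz = float(torque_fs_hz)
        self.speed_label = speed_label
        self.side = side
        self._pos_to_channel = {p: k for k, p in enumerate(channel_positions)}

    # -- basic properties ---------------------------------------------------

    @property
    def n_channels(self) -> int:
        return self.signals.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs_hz

    def channel_at(self, row: int, col: int) -> int:
        """Channel index recording grid position (row, col)."""
        try:
            return self._pos_to_channel[(row, col)]
        except KeyError:
            raise KeyError(f"no electrode at position {(row, col)}") from None

    def replace(self, **kwargs) -> "GridRecording":
        """Copy with selected attributes replaced."""
        init = dict(
            signals=self.signals,
            fs_hz=self.fs_hz,
            geometry=self.geometry,
            channel_positions=self.channel_positions,
            mode=self.mode,
            torque=self.torque,
            torque_fs_hz=self.torque_fs_hz,
            speed_label=self.speed_label,
            side=self.side,
        )
        init.update(kwargs)
        return GridRecording(**init)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"GridRecording({self.n_channels} ch x {self.n_samples} samples @ "
            f"{self.fs_hz:g} Hz, {self.mode}, "
            f"{self.geometry.n_rows}x{self.geometry.n_cols} grid)"
        )


def scatter_to_grid(
    rec: GridRecording, channel_values: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Place one scalar per channel at its grid position.

    Returns a ``(n_rows, n_cols)`` array (zero at missing positions) and the
    validity mask.  Scattering then gathering with the channel map returns
    the original channel-ordered vector.
    """
    channel_values = np.asarray(channel_values, dtype=float)
    if channel_values.shape != (rec.n_channels,):
        raise ValueError(
            f"expected {rec.n_channels} channel values, got {channel_values.shape}"
        )
    g = rec.geometry
    grid = np.zeros((g.n_rows, g.n_cols))
    for k, (r, c) in enumerate(rec.channel_positions):
        grid[r - 1, c - 1] = channel_values[k]
    return grid, g.valid_mask()


def to_grid_view(
    rec: GridRecording, sample_window: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Arrange a window of the recording on the grid.

    Returns a ``(n_rows, n_cols, n_window_samples)`` stack with each
    electrode's samples placed at its ``(row, col)``, and the validity mask
    flagging missing positions (excluded from all downstream channel counts).
    """
    start, end = int(sample_window[0]), int(sample_window[1])
    if not (0 <= start < end <= rec.n_samples):
        raise ValueError(
            f"empty or out-of-range window [{start}, {end}) for "
            f"{rec.n_samples} samples"
        )
    g = rec.geometry
    stack = np.zeros((g.n_rows, g.n_cols, end - start))
    for k, (r, c) in enumerate(rec.channel_positions):
        stack[r - 1, c - 1] = rec.signals[k, start:end]
    return stack, g.valid_mask()
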