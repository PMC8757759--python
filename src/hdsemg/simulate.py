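"""Synthetic grid EMG with known ground truth.

The generator emulates the study's recordings — a 64-channel 13x5 grid at
1024 Hz over a muscle performing an isokinetic effort — at the level the
spatial analysis actually sees: per-channel amplitude topography and
spectrum.  Each channel carries an independent band-limited, unit-RMS
Gaussian carrier (spectrally flat inside the band), amplitude-modulated by

* an anisotropic Gaussian spatial envelope over the grid whose centre may
  follow a configurable path (drift ground truth for CoG trajectories), and
* a trapezoidal force profile (ramp - plateau - ramp) standing in for the
  dynamometer effort, also emitted as a 100 Hz torque channel;

plus white hardware noise at the amplifier's noise floor (< 2 uV RMS).
This is not a motor-unit train simulator: every downstream feature depends
only on the RMS topography and the spectrum, which this model controls
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .grid import GridGeometry, GridRecording

__all__ = [
    "SimulationConfig",
    "spatial_envelope",
    "force_profile",
    "simulate_recording",
]


@dataclass
class SimulationConfig:
    """Ground-truth description of one simulated contraction trial.

    ``center_path`` is a sequence of ``(time_s, x, y)`` waypoints for the
    envelope barycentre (grid-index units, x along the 13-row fiber axis);
    a single waypoint means a stationary source.  ``amplitude_mv`` is the
    peak envelope RMS at full force; ``noise_floor_mv`` the additive
    hardware noise RMS.  The default sigmas give a broad, near-uniform
    activation like an able-bodied rectus femoris map; localized sources
    are modelled by narrowing them.
    """

    geometry: GridGeometry = field(default_factory=GridGeometry)
    fs_hz: float = 1024.0
    duration_s: float = 3.0
    center_path: tuple = ((0.0, 7.0, 3.0),)
    sigma_rows: float = 4.0
    sigma_cols: float = 2.5
    amplitude_mv: float = 0.2
    noise_floor_mv: float = 0.002
    onset_s: float = 0.5
    ramp_s: float = 0.5
    plateau_s: float = 1.0
    peak_torque_nm: float = 150.0
    band: tuple[float, float] = (20.0, 400.0)
    common_drive: float = 0.0
    speed_label: Optional[int] = 90
    side: Optional[str] = None
    torque_fs_hz: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_rows <= 0 or self.sigma_cols <= 0:
            raise ValueError("envelope sigmas must be positive")
        if self.amplitude_mv < 0 or self.noise_floor_mv < 0:
            raise ValueError("amplitudes must be non-negative")
        if not (0 <= self.common_drive <= 1):
            raise ValueError("common_drive must be in [0, 1]")
        if not (0 < self.band[0] < self.band[1] < self.fs_hz / 2):
            raise ValueError(f"band {self.band} invalid for fs={self.fs_hz}")
        if self.onset_s + 2 * self.ramp_s + self.plateau_s > self.duration_s + 1e-9:
            raise ValueError("force profile does not fit inside duration_s")
        path = tuple((float(t), float(x), float(y)) for t, x, y in self.center_path)
        if not path:
            raise ValueError("center_path needs at least one waypoint")
        for t, x, y in path:
            if not (1 <= x <= self.geometry.n_rows and 1 <= y <= self.geometry.n_cols):
                raise ValueError(f"waypoint ({x}, {y}) outside the grid")
        if any(b[0] > a[0] for a, b in zip(path[1:], path)):
            raise ValueError("center_path times must be non-decreasing")
        self.center_path = path


def spatial_envelope(
    geometry: GridGeometry,
    center: tuple[float, float],
    sigma_rows: float,
    sigma_cols: float,
) -> np.ndarray:
    """Anisotropic Gaussian weight over the grid, peak 1 at ``center``.

    Returns a ``(n_rows, n_cols)`` array, zeroed at missing positions.
    """
    if sigma_rows <= 0 or sigma_cols <= 0:
        raise ValueError("sigma must be positive")
    cx, cy = center
    if not (1 <= cx <= geometry.n_rows and 1 <= cy <= geometry.n_cols):
        raise ValueError(f"center {center} outside the grid")
    rows = np.arange(1, geometry.n_rows + 1)[:, None]
    cols = np.arange(1, geometry.n_cols + 1)[None, :]
    w = np.exp(
        -((rows - cx) ** 2) / (2 * sigma_rows**2)
        - ((cols - cy) ** 2) / (2 * sigma_cols**2)
    )
    return w * geometry.valid_mask()


def force_profile(
    duration_s: float,
    ramp_s: float,
    plateau_s: float,
    onset_s: float = 0.0,
    fs_hz: float = 1024.0,
) -> np.ndarray:
    """Trapezoidal normalised effort in [0, 1]: rest, ramp up, hold, ramp down."""
    if onset_s < 0 or ramp_s < 0 or plateau_s < 0:
        raise ValueError("durations must be non-negative")
    if onset_s + 2 * ramp_s + plateau_s > duration_s + 1e-9:
        raise ValueError(
            f"profile (onset {onset_s} + 2x ramp {ramp_s} + plateau {plateau_s} s) "
            f"exceeds duration {duration_s} s"
        )
    t = np.arange(int(round(duration_s * fs_hz))) / fs_hz
    t1, t2 = onset_s, onset_s + ramp_s
    t3, t4 = t2 + plateau_s, t2 + plateau_s + ramp_s
    up = np.clip((t - t1) / max(ramp_s, 1e-12), 0.0, 1.0)
    down = np.clip((t4 - t) / max(ramp_s, 1e-12), 0.0, 1.0)
    return np.minimum(up, np.where(t <= t3, 1.0, down))


def _band_limited_carriers(
    rng: np.random.Generator,
    n_series: int,
    n_samples: int,
    fs_hz: float,
    band: tuple[float, float],
) -> np.ndarray:
    """Unit-RMS Gaussian carriers with a flat (brick-wall) in-band spectrum."""
    white = rng.standard_normal((n_series, n_samples))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs_hz)
    spec[:, (freqs < band[0]) | (freqs > band[1])] = 0.0
    x = np.fft.irfft(spec, n=n_samples, axis=1)
    rms = np.sqrt(np.mean(x**2, axis=1, keepdims=True))
    return x / np.where(rms > 0, rms, 1.0)


def _interp_center(cfg: SimulationConfig, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    path = np.asarray(cfg.center_path)
    if path.shape[0] == 1:
        return (np.full_like(t, path[0, 1]), np.full_like(t, path[0, 2]))
    return (
        np.interp(t, path[:, 0], path[:, 1]),
        np.interp(t, path[:, 0], path[:, 2]),
    )


def simulate_recording(cfg: SimulationConfig) -> tuple[GridRecording, dict]:
    """Generate one trial and its ground truth.

    Per channel: ``signal = amplitude_mv * envelope_weight(t) * force(t) *
    carrier(t) + noise``, with the envelope weight following the (possibly
    moving) centre path.  Identical seeds give bit-identical output.

    Returns the recording (with its synthetic 100 Hz torque channel) and a
    ground-truth dict holding the config, the centre path sampled at the
    EMG rate, and the expected plateau RMS per channel.
    """
    rng = np.random.default_rng(cfg.seed)
    g = cfg.geometry
    n = int(round(cfg.duration_s * cfg.fs_hz))
    t = np.arange(n) / cfg.fs_hz
    positions = g.positions()
    n_ch = len(positions)

    carriers = _band_limited_carriers(rng, n_ch + 1, n, cfg.fs_hz, cfg.band)
    common = carriers[-1]
    m = cfg.common_drive
    mix = np.sqrt(max(1 - m**2, 0.0)) * carriers[:-1] + m * common

    cx, cy = _interp_center(cfg, t)
    rows = np.array([p[0] for p in positions], dtype=float)[:, None]
    cols = np.array([p[1] for p in positions], dtype=float)[:, None]
    weights = np.exp(
        -((rows - cx[None, :]) ** 2) / (2 * cfg.sigma_rows**2)
        - ((cols - cy[None, :]) ** 2) / (2 * cfg.sigma_cols**2)
    )

    force = force_profile(
        cfg.duration_s, cfg.ramp_s, cfg.plateau_s, onset_s=cfg.onset_s, fs_hz=cfg.fs_hz
    )
    signals = cfg.amplitude_mv * weights * force[None, :] * mix
    signals = signals + cfg.noise_floor_mv * rng.standard_normal((n_ch, n))

    n_torque = int(round(cfg.duration_s * cfg.torque_fs_hz))
    torque = cfg.peak_torque_nm * force_profile(
        cfg.duration_s, cfg.ramp_s, cfg.plateau_s, onset_s=cfg.onset_s,
        fs_hz=cfg.torque_fs_hz,
    )[:n_torque]

    rec = GridRecording(
        signals=signals,
        fs_hz=cfg.fs_hz,
        geometry=g,
        channel_positions=positions,
        mode="monopolar",
        torque=torque,
        torque_fs_hz=cfg.torque_fs_hz,
        speed_label=cfg.speed_label,
        side=cfg.side,
    )

    plateau_mid = cfg.onset_s + cfg.ramp_s + 0.5 * cfg.plateau_s
    k_mid = min(int(round(plateau_mid * cfg.fs_hz)), n - 1)
    expected_rms = np.sqrt(
        (cfg.amplitude_mv * weights[:, k_mid]) ** 2 + cfg.noise_floor_mv**2
    )
    truth = {
        "config": cfg,
        "times_s": t,
        "center_x": cx,
        "center_y": cy,
        "plateau_window_s": (cfg.onset_s + cfg.ramp_s, cfg.onset_s + cfg.ramp_s + cfg.plateau_s),
        "expected_plateau_rms_mv": expected_rms,
        "channel_positions": positions,
    }
    return rec, truth
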