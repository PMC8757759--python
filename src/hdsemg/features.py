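"""Scalar features of an activation map.

Six features summarise one contraction epoch:

* **intensity** ``I = log10(mean of the map RMS values)`` — log amplitude of
  the monopolar map, used because EMG amplitude grows nonlinearly with force;
* **differential intensity** ``DI`` — the same log-mean aggregation applied
  to the single-differential map;
* **modified entropy** ``E = −Σ q_i log2 q_i`` with
  ``q_i = RMS_i² / Σ_k RMS_k²`` — maximal (``log2 N``) when all channels are
  equally active, zero when one channel carries everything;
* **CoV** — percent coefficient of variation of the channel RMS values, a
  heterogeneity index opposite in sense to entropy;
* **mean RMS** in mV;
* **median frequency** — the frequency splitting the epoch's power spectrum
  into equal halves, averaged over channels.

Entropy, CoV and DI are computed from the single-differential map (59
channels on the default grid); intensity, mean RMS and median frequency from
the monopolar signals.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import signal as sps

from .grid import ActivationMap, ContractionSegment, GridRecording
from .preprocess import midpoint_epoch, to_single_differential

__all__ = [
    "FeatureSet",
    "intensity",
    "differential_intensity",
    "modified_entropy",
    "coefficient_of_variation",
    "mean_rms",
    "median_frequency",
    "feature_set",
]


@dataclass
class FeatureSet:
    """The six scalar features of one contraction epoch."""

    entropy: float  # bits
    cov: float  # percent
    intensity: float  # log10-mV
    differential_intensity: float  # log10-mV
    mean_rms: float  # mV
    median_frequency: float  # Hz

    def as_dict(self) -> dict:
        return asdict(self)


def _valid_positive(amap: ActivationMap) -> np.ndarray:
    v = amap.valid_values
    if v.size == 0:
        raise ValueError("map has no valid positions")
    return v


def mean_rms(amap: ActivationMap) -> float:
    """Arithmetic mean of the valid map values, in mV."""
    return float(_valid_positive(amap).mean())


def intensity(amap: ActivationMap) -> float:
    """Common logarithm of the mean map amplitude: ``I = log10(mean RMS)``."""
    m = mean_rms(amap)
    if m <= 0:
        raise ValueError("cannot take log of an all-zero map")
    return float(np.log10(m))


def differential_intensity(diff_map: ActivationMap) -> float:
    """Log amplitude of the single-differential map.

    The per-pair definition ``log10(RMS(s_ij − s_{i+1,j}))`` yields one value
    per channel pair; a trial-level scalar is obtained by the same
    aggregation as ``intensity`` — the common log of the mean differential
    RMS — keeping DI and I commensurable.
    """
    if diff_map.mode != "single_differential":
        raise ValueError("differential intensity requires a single-differential map")
    m = mean_rms(diff_map)
    if m <= 0:
        raise ValueError("no differential activity (common-mode-only recording?)")
    return float(np.log10(m))


def modified_entropy(amap: ActivationMap) -> float:
    """Shannon entropy (bits) of the normalised squared-RMS distribution.

    ``q_i = RMS_i² / Σ_k RMS_k²`` over the valid channels; zero-power
    channels contribute nothing.  Bounded by ``log2(n_valid)``, attained for
    a spatially uniform map.
    """
    v = _valid_positive(amap)
    power = v**2
    total = power.sum()
    if total <= 0:
        raise ValueError("cannot compute entropy of an all-zero map")
    q = power / total
    nz = q[q > 0]
    return float(-(nz * np.log2(nz)).sum())


def coefficient_of_variation(amap: ActivationMap) -> float:
    """Percent CoV of the valid channel RMS values (population SD / mean)."""
    v = _valid_positive(amap)
    m = v.mean()
    if m <= 0:
        raise ValueError("cannot compute CoV with zero mean")
    return float(100.0 * v.std() / m)


def median_frequency(
    signals: np.ndarray,
    fs_hz: float,
    silent_rms_mv: float = 1e-9,
) -> float:
    """Mean over channels of the per-channel spectral median frequency.

    Per channel the power spectrum of the epoch is estimated with a
    Hann-windowed periodogram; the median frequency is the smallest frequency
    at which cumulative power reaches half the total in [0, fs/2].  Channels
    with RMS below ``silent_rms_mv`` are excluded.
    """
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    if signals.shape[1] < 128:
        raise ValueError("epoch too short for a spectral estimate (< 128 samples)")
    rms = np.sqrt(np.mean(signals**2, axis=1))
    keep = rms > silent_rms_mv
    if not np.any(keep):
        raise ValueError("all channels silent; no median frequency")
    freqs, pxx = sps.periodogram(signals[keep], fs=fs_hz, window="hann", axis=1)
    cum = np.cumsum(pxx, axis=1)
    total = cum[:, -1]
    half_idx = np.argmax(cum >= 0.5 * total[:, None], axis=1)
    return float(freqs[half_idx].mean())


def feature_set(
    rec: GridRecording,
    seg: ContractionSegment,
    epoch_s: float = 0.25,
) -> FeatureSet:
    """All six features from the midpoint epoch of one contraction.

    ``rec`` is a band-pass-filtered monopolar recording; the
    single-differential montage is derived internally for entropy, CoV and
    differential intensity.
    """
    if rec.mode != "monopolar":
        raise ValueError("feature_set expects a monopolar recording")
    diff = to_single_differential(rec)
    mono_map = midpoint_epoch(rec, seg, epoch_s=epoch_s)
    diff_map = midpoint_epoch(diff, seg, epoch_s=epoch_s)
    s0 = int(round(mono_map.window[0] * rec.fs_hz))
    s1 = int(round(mono_map.window[1] * rec.fs_hz))
    return FeatureSet(
        entropy=modified_entropy(diff_map),
        cov=coefficient_of_variation(diff_map),
        intensity=intensity(mono_map),
        differential_intensity=differential_intensity(diff_map),
        mean_rms=mean_rms(mono_map),
        median_frequency=median_frequency(rec.signals[:, s0:s1], rec.fs_hz),
    )
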