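"""Filtering, squat-cycle segmentation, resampling and amplitude scaling.

The pipeline applies, in order: a 20-400 Hz fourth-order Butterworth
band-pass to the sEMG, a 6 Hz fourth-order Butterworth low-pass to the
kinematics, segmentation of both signals at qualifying local minima of the
knee angle, cubic-spline resampling of every cycle to a fixed number of
points (1000 by default), and per-channel min-max normalization

    x_norm = (x - x_min) / (x_max - x_min)

with the exact algebraic inverse used to return network outputs to degrees
before scoring.  Both filters are run forward-backward (zero phase): a
causal filter would add a frequency-dependent group delay that the
downstream cross-correlation stage would mistake for electromechanical
delay.  The effective attenuation is therefore that of an eighth-order
magnitude response.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import butter, find_peaks, sosfiltfilt

from .synthetic import Recording

__all__ = [
    "SamplingRateError",
    "SegmentationError",
    "DegenerateScaleError",
    "CycleSet",
    "ScalerParams",
    "bandpass_emg",
    "lowpass_kinematics",
    "segment_cycles",
    "resample_cycle",
    "fit_scaler",
    "normalize",
    "denormalize",
    "build_cycle_set",
]


class SamplingRateError(ValueError):
    """Sampling rate too low for the requested filter band."""


class SegmentationError(RuntimeError):
    """Fewer than two qualifying local minima found."""


class DegenerateScaleError(ValueError):
    """A channel has zero amplitude range; min-max scaling is undefined."""


def bandpass_emg(signal: np.ndarray, rate: float) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band-pass, 20-400 Hz."""
    if rate <= 800.0:
        raise SamplingRateError(
            f"rate {rate} Hz too low: Nyquist must exceed the 400 Hz band edge"
        )
    sos = butter(4, (20.0, 400.0), btype="bandpass", fs=rate, output="sos")
    return sosfiltfilt(sos, np.asarray(signal, dtype=float), axis=-1)


def lowpass_kinematics(signal: np.ndarray, rate: float) -> np.ndarray:
    """Zero-phase 4th-order Butterworth low-pass, 6 Hz cutoff."""
    if rate <= 12.0:
        raise SamplingRateError(
            f"rate {rate} Hz too low: Nyquist must exceed the 6 Hz cutoff"
        )
    sos = butter(4, 6.0, btype="lowpass", fs=rate, output="sos")
    return sosfiltfilt(sos, np.asarray(signal, dtype=float), axis=-1)


def segment_cycles(
    angle: np.ndarray,
    rate: float,
    min_prominence: float = 0.1,
    min_separation_s: float = 0.5,
) -> list[tuple[int, int]]:
    """Find squat cycles as intervals between qualifying local minima.

    Candidate minima are interior local minima of ``angle`` (plus the series
    endpoints when they are locally minimal).  A pair of consecutive minima
    delimits a cycle when the interior maximum exceeds both endpoints by at
    least ``min_prominence`` times the global signal range and the minima
    are at least ``min_separation_s`` apart.  Returns half-open index pairs
    ``(min_i, min_{i+1})``.
    """
    angle = np.asarray(angle, dtype=float)
    if angle.size < 3:
        raise SegmentationError("series too short to segment")
    if not 0.0 < min_prominence < 1.0:
        raise ValueError("min_prominence must lie in (0, 1)")
    full_range = float(angle.max() - angle.min())
    if full_range == 0.0:
        raise SegmentationError("constant series has no cycles")
    prom = min_prominence * full_range
    dist = max(1, int(round(min_separation_s * rate)))
    idx, _ = find_peaks(-angle, prominence=prom, distance=dist)
    cand = list(idx)
    # find_peaks cannot flag endpoints; a squat trial starts and ends standing
    if angle[0] <= angle[1] and (not cand or cand[0] >= dist):
        cand.insert(0, 0)
    if angle[-1] <= angle[-2] and (not cand or angle.size - 1 - cand[-1] >= dist):
        cand.append(angle.size - 1)
    bounds: list[tuple[int, int]] = []
    for a, b in zip(cand, cand[1:]):
        interior_max = float(angle[a : b + 1].max())
        if interior_max - max(angle[a], angle[b]) >= prom:
            bounds.append((int(a), int(b)))
    if not bounds:
        raise SegmentationError(
            f"found {len(cand)} candidate minima but no qualifying cycle "
            f"(prominence threshold {prom:.3g}, separation {dist} samples)"
        )
    return bounds


def resample_cycle(segment: np.ndarray, n_points: int = 1000) -> np.ndarray:
    """Cubic-spline resample one cycle onto ``n_points`` uniform abscissae."""
    segment = np.asarray(segment, dtype=float)
    if segment.size < 4:
        raise ValueError("segment too short for cubic-spline resampling (need >= 4)")
    if segment.size == n_points:
        return segment.copy()
    x = np.arange(segment.size, dtype=float)
    spline = CubicSpline(x, segment)
    out = spline(np.linspace(0.0, segment.size - 1.0, n_points))
    out[0], out[-1] = segment[0], segment[-1]
    return out


@dataclass(frozen=True)
class ScalerParams:
    """Per-channel min-max extrema, fitted on training data only."""

    x_min: np.ndarray
    x_max: np.ndarray


def fit_scaler(train_matrix: np.ndarray) -> ScalerParams:
    """Per-channel extrema of a (channels x samples) training matrix."""
    m = np.atleast_2d(np.asarray(train_matrix, dtype=float))
    x_min = m.min(axis=1)
    x_max = m.max(axis=1)
    if np.any(x_max <= x_min):
        bad = np.nonzero(x_max <= x_min)[0]
        raise DegenerateScaleError(f"constant channel(s) {bad.tolist()}: x_max <= x_min")
    return ScalerParams(x_min=x_min, x_max=x_max)


def normalize(x: np.ndarray, s: ScalerParams) -> np.ndarray:
    """Map each channel through (x - x_min) / (x_max - x_min).

    Training data lands in [0, 1]; held-out data may exceed the interval and
    is deliberately not clipped.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    return (x - s.x_min[:, None]) / (s.x_max - s.x_min)[:, None]


def denormalize(x_norm: np.ndarray, s: ScalerParams) -> np.ndarray:
    """Exact inverse of :func:`normalize` under the same parameters."""
    x_norm = np.atleast_2d(np.asarray(x_norm, dtype=float))
    return x_norm * (s.x_max - s.x_min)[:, None] + s.x_min[:, None]


@dataclass
class CycleSet:
    """Segmented, per-cycle resampled signals for one subject x load.

    ``features_raw`` holds the band-passed, rectified sEMG resampled to
    ``n_points`` per cycle; ``targets`` the low-passed joint angles in
    degrees.  Cycles are concatenated along the column axis;
    ``cycle_boundaries`` lists the start column of each cycle.
    """

    subject_id: str
    load: str
    features_raw: np.ndarray  # (5, n_cycles * n_points)
    targets: np.ndarray  # (2, n_cycles * n_points)
    cycle_boundaries: list[int]
    n_points: int = 1000

    @property
    def n_cycles(self) -> int:
        return len(self.cycle_boundaries)

    def __post_init__(self) -> None:
        if self.features_raw.shape[1] != self.targets.shape[1]:
            raise ValueError("feature and target matrices must share column count")
        if self.features_raw.shape[1] != self.n_cycles * self.n_points:
            raise ValueError("column count must equal n_cycles * n_points")


def build_cycle_set(
    recording: Recording,
    n_points: int = 1000,
    min_prominence: float = 0.1,
    min_separation_s: float = 0.5,
    segment_joint: int = 0,
    rectify: bool = True,
) -> CycleSet:
    """Filter, segment and resample one recording into a :class:`CycleSet`.

    Segmentation minima are located on the low-passed angle of
    ``segment_joint`` (knee by default) and mapped to sEMG sample indices by
    time.  The sEMG is band-passed and, by default, full-wave rectified
    before per-cycle spline resampling, so the stored feature rows are
    nonnegative activity traces whose smooth envelope the wavelet stage
    extracts.
    """
    kin = lowpass_kinematics(recording.angles, recording.kin_rate)
    emg = bandpass_emg(recording.emg, recording.emg_rate)
    if rectify:
        emg = np.abs(emg)
    bounds = segment_cycles(
        kin[segment_joint], recording.kin_rate, min_prominence, min_separation_s
    )
    ratio = recording.emg_rate / recording.kin_rate
    feat_cycles, targ_cycles, starts = [], [], []
    col = 0
    for a, b in bounds:
        ea, eb = int(round(a * ratio)), int(round(b * ratio))
        eb = min(eb, emg.shape[1] - 1)
        feat_cycles.append(
            np.vstack([resample_cycle(ch, n_points) for ch in emg[:, ea : eb + 1]])
        )
        targ_cycles.append(
            np.vstack([resample_cycle(ch, n_points) for ch in kin[:, a : b + 1]])
        )
        starts.append(col)
        col += n_points
    return CycleSet(
        subject_id=recording.subject_id,
        load=recording.load,
        features_raw=np.hstack(feat_cycles),
        targets=np.hstack(targ_cycles),
        cycle_boundaries=starts,
        n_points=n_points,
    )
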