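"""Wavelet envelope extraction and cross-correlation lag alignment.

Features fed to the regressors are the level-8 ``sym8`` discrete-wavelet
approximation of each (rectified, resampled) sEMG channel: the multilevel
decomposition is taken, every detail band is zeroed, and the inverse
transform returns a smooth envelope of the original length.  At level 8 the
approximation band is roughly [0, rate / 2**9], i.e. only the slow
activation envelope survives.

Because muscle activity leads the motion it produces by an
electromechanical delay of tens to hundreds of milliseconds, each envelope
channel is additionally aligned to its kinematic target by the lag that
maximizes the normalized cross-covariance

    C(k)  = (1/T) * sum_{t=1..T-k} (y1_t - mean(y1)) (y2_{t+k} - mean(y2))
    CC(k) = C(k) / (sqrt(C_11(0)) * sqrt(C_22(0)))

searched over k in [0, k_max].  The chosen lag is the number of working-rate
samples by which the EMG-side series leads the target; alignment shifts the
EMG-side series later in time by that amount under a finite-support
convention (vacated leading positions are zero-filled, length preserved).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pywt
from scipy.signal import correlate

from .preprocessing import CycleSet

__all__ = [
    "LagRangeError",
    "DegenerateSignalError",
    "LagProfile",
    "DEFAULT_CHANNEL_JOINT_MAP",
    "dwt_approximation",
    "cross_covariance",
    "cross_correlation",
    "estimate_lag",
    "apply_lag",
    "estimate_lag_profile",
    "apply_lag_profile",
    "assemble_design_matrix",
]

#: which joint each muscle's lag is estimated against: knee extensors /
#: flexors and the biarticular gastrocnemius against the knee, tibialis
#: anterior against the ankle
DEFAULT_CHANNEL_JOINT_MAP = {
    "VM": "knee",
    "RF": "knee",
    "BF": "knee",
    "TA": "ankle",
    "MG": "knee",
}


class LagRangeError(ValueError):
    """Requested lag is outside the admissible range."""


class DegenerateSignalError(ValueError):
    """Constant series: correlation normalization is undefined."""


def dwt_approximation(
    signal: np.ndarray, wavelet_name: str = "sym8", level: int = 8
) -> np.ndarray:
    """Level-``level`` wavelet approximation, reconstructed at full length.

    All detail coefficients are zeroed and the inverse transform taken, so
    the output has the same length as the input (trimmed if the transform
    padded to an even length).  Periodized signal extension is used at the
    boundaries: it keeps the decomposition orthogonal, so the operation is
    an exact projection onto the approximation space (applying it twice
    equals applying it once to machine precision).
    """
    signal = np.asarray(signal, dtype=float)
    if wavelet_name not in pywt.wavelist(kind="discrete"):
        raise ValueError(f"unsupported wavelet {wavelet_name!r}")
    if signal.size < 2**level:
        warnings.warn(
            f"signal length {signal.size} < 2**{level}; boundary effects dominate",
            stacklevel=2,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        coeffs = pywt.wavedec(signal, wavelet_name, mode="periodization", level=level)
    coeffs = [coeffs[0]] + [np.zeros_like(c) for c in coeffs[1:]]
    rec = pywt.waverec(coeffs, wavelet_name, mode="periodization")
    return rec[: signal.size]


def _validate_lag(k: int, T: int) -> None:
    if abs(int(k)) >= T:
        raise LagRangeError(f"|k|={abs(k)} must be < series length {T}")


def cross_covariance(y1: np.ndarray, y2: np.ndarray, k: int) -> float:
    """Lagged cross-covariance with divisor T (not T - k).

    For k >= 0 pairs ``y1[t]`` with ``y2[t+k]``; negative k mirrors the
    definition.  Means are taken over the full series.
    """
    y1 = np.asarray(y1, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    if y1.shape != y2.shape or y1.ndim != 1:
        raise ValueError("y1 and y2 must be 1-D series of equal length")
    T = y1.size
    k = int(k)
    _validate_lag(k, T)
    y1c = y1 - y1.mean()
    y2c = y2 - y2.mean()
    if k >= 0:
        return float(np.dot(y1c[: T - k], y2c[k:]) / T)
    return float(np.dot(y2c[: T + k], y1c[-k:]) / T)


def cross_correlation(y1: np.ndarray, y2: np.ndarray, k: int) -> float:
    """Normalized cross-covariance; CC(y, y, 0) == 1 exactly."""
    v1 = cross_covariance(y1, y1, 0)
    v2 = cross_covariance(y2, y2, 0)
    if v1 <= 0.0 or v2 <= 0.0:
        raise DegenerateSignalError("constant series: zero variance")
    if int(k) == 0 and np.array_equal(y1, y2):
        return 1.0
    return cross_covariance(y1, y2, k) / (np.sqrt(v1) * np.sqrt(v2))


def _cc_profile(feature: np.ndarray, target: np.ndarray, k_max: int) -> np.ndarray:
    """CC(feature, target, k) for all k in [0, k_max], FFT-accelerated."""
    f = np.asarray(feature, dtype=float)
    g = np.asarray(target, dtype=float)
    T = f.size
    fc = f - f.mean()
    gc = g - g.mean()
    v1 = float(np.dot(fc, fc) / T)
    v2 = float(np.dot(gc, gc) / T)
    if v1 <= 0.0 or v2 <= 0.0:
        raise DegenerateSignalError("constant series: zero variance")
    # sum_t fc[t] gc[t+k] = correlate(gc, fc)[T-1+k]
    full = correlate(gc, fc, mode="full", method="fft")
    cov = full[T - 1 : T + k_max] / T
    return cov / (np.sqrt(v1) * np.sqrt(v2))


def estimate_lag(
    feature: np.ndarray, target: np.ndarray, k_max: int
) -> tuple[int, float]:
    """Lag in [0, k_max] maximizing CC(feature, target, k).

    Returns ``(lag, cc_at_lag)``.  The lag is the number of samples by which
    the EMG-side series leads the target; ties break toward the smallest
    lag.
    """
    feature = np.asarray(feature, dtype=float)
    target = np.asarray(target, dtype=float)
    if k_max < 0 or k_max >= feature.size // 2:
        raise LagRangeError(f"k_max={k_max} must lie in [0, length/2)")
    cc = _cc_profile(feature, target, k_max)
    lag = int(np.argmax(cc))
    return lag, float(cc[lag])


def apply_lag(feature: np.ndarray, lag: int) -> np.ndarray:
    """Shift the EMG-side series ``lag`` samples later in time.

    The series is treated as finite-support: the vacated leading positions
    are zero-filled and the length is unchanged, so feature and target
    vectors stay the same length.  After shifting by the lag returned by
    :func:`estimate_lag`, re-estimating against the original target yields a
    residual lag of 0.
    """
    feature = np.asarray(feature, dtype=float)
    lag = int(lag)
    if not 0 <= lag < feature.shape[-1]:
        raise LagRangeError(f"lag {lag} out of range [0, {feature.shape[-1]})")
    if lag == 0:
        return feature.copy()
    out = np.zeros_like(feature)
    out[..., lag:] = feature[..., :-lag]
    return out


@dataclass
class LagProfile:
    """Per-channel alignment lags (working-rate samples) with their CCs."""

    channels: tuple[str, ...]
    lags: np.ndarray  # int samples, one per channel
    cc_at_lag: np.ndarray
    cc_at_zero: np.ndarray

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=int)
        self.cc_at_lag = np.asarray(self.cc_at_lag, dtype=float)
        self.cc_at_zero = np.asarray(self.cc_at_zero, dtype=float)
        if np.any(self.cc_at_lag + 1e-12 < self.cc_at_zero):
            raise ValueError("cc_at_lag must be >= cc_at_zero (argmax property)")
        if np.any(self.lags < 0):
            raise ValueError("lags must be >= 0")

    def to_json(self) -> str:
        return json.dumps(
            {
                ch: {
                    "lag": int(self.lags[i]),
                    "cc_at_lag": float(self.cc_at_lag[i]),
                    "cc_at_zero": float(self.cc_at_zero[i]),
                }
                for i, ch in enumerate(self.channels)
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "LagProfile":
        d = json.loads(text)
        chans = tuple(d)
        return cls(
            channels=chans,
            lags=np.array([d[c]["lag"] for c in chans]),
            cc_at_lag=np.array([d[c]["cc_at_lag"] for c in chans]),
            cc_at_zero=np.array([d[c]["cc_at_zero"] for c in chans]),
        )


def estimate_lag_profile(
    features: np.ndarray,
    targets: np.ndarray,
    channels: tuple[str, ...],
    joints: tuple[str, ...],
    k_max: int = 300,
    channel_joint_map: dict[str, str] | None = None,
) -> LagProfile:
    """Estimate one alignment lag per channel on pooled training data.

    Each feature channel is correlated against the kinematic target of the
    joint it acts on (``channel_joint_map``); estimation must only ever see
    training-fold data.
    """
    mapping = channel_joint_map or DEFAULT_CHANNEL_JOINT_MAP
    lags = np.empty(len(channels), dtype=int)
    cc_best = np.empty(len(channels))
    cc_zero = np.empty(len(channels))
    for i, ch in enumerate(channels):
        j = joints.index(mapping.get(ch, joints[0]))
        cc = _cc_profile(features[i], targets[j], k_max)
        lags[i] = int(np.argmax(cc))
        cc_best[i] = cc[lags[i]]
        cc_zero[i] = cc[0]
    return LagProfile(
        channels=tuple(channels), lags=lags, cc_at_lag=cc_best, cc_at_zero=cc_zero
    )


def apply_lag_profile(features: np.ndarray, profile: LagProfile) -> np.ndarray:
    """Apply per-channel alignment shifts to a (channels x samples) block."""
    out = np.empty_like(np.asarray(features, dtype=float))
    for i in range(features.shape[0]):
        out[i] = apply_lag(features[i], int(profile.lags[i]))
    return out


def assemble_design_matrix(
    cycle_sets: list[CycleSet],
) -> tuple[np.ndarray, np.ndarray]:
    """Concatenate cycle sets into (features 5 x M, targets 2 x M) matrices.

    Columns follow deterministic (subject, load, cycle) order: cycle sets
    are stably sorted by subject, preserving the given load order within
    each subject.  With 19 subjects x 20 cycles x 1000 points, M = 380,000.
    """
    if not cycle_sets:
        raise ValueError("no cycle sets to assemble")
    n_pts = cycle_sets[0].n_points
    n_ch = cycle_sets[0].features_raw.shape[0]
    ordered = sorted(cycle_sets, key=lambda cs: cs.subject_id)
    for cs in ordered:
        if cs.n_points != n_pts or cs.features_raw.shape[0] != n_ch:
            raise ValueError(
                f"inconsistent cycle set {cs.subject_id}/{cs.load}: "
                f"n_points {cs.n_points}, channels {cs.features_raw.shape[0]}"
            )
    features = np.hstack([cs.features_raw for cs in ordered])
    targets = np.hstack([cs.targets for cs in ordered])
    return features, targets
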