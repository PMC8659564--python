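"""Synthetic paired sEMG / joint-angle recordings for loaded squats.

Emulates the structure of a squat-training data set: each subject performs
five squat cycles at four loading conditions (no load, 60, 80 and 100 % of
the five-repetition maximum), while five lower-limb muscles (VM, RF, BF, TA,
MG) are recorded at 1500 Hz and the sagittal knee and ankle angles at 100 Hz.

Three structural features of the real data are reproduced with known ground
truth so every downstream stage is testable:

* quasi-periodic squat cycles whose range of motion shrinks as load grows;
* sEMG modelled as band-limited (20-400 Hz) carrier noise, amplitude
  modulated by a muscle-activation envelope derived from the kinematics;
* the activation envelope leads the kinematics by a per-subject, per-channel
  electromechanical delay in the physiological 20-200 ms range, stored on
  the recording as ``truth_lags_ms``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import butter, sosfiltfilt

__all__ = [
    "SynthConfig",
    "Recording",
    "ConfigurationError",
    "generate_angle_trajectory",
    "generate_emg_channel",
    "generate_dataset",
]

CHANNELS = ("VM", "RF", "BF", "TA", "MG")
JOINTS = ("knee", "ankle")

# Mixture weights of each muscle's activation drive:
# (knee deviation, knee |velocity|, ankle deviation, ankle |velocity|).
# VM/RF/BF act on the knee, TA on the ankle, MG is biarticular.
_ENVELOPE_WEIGHTS = {
    "VM": (1.0, 0.4, 0.0, 0.0),
    "RF": (0.8, 0.6, 0.0, 0.0),
    "BF": (0.5, 0.8, 0.0, 0.0),
    "TA": (0.0, 0.0, 0.9, 0.5),
    "MG": (0.4, 0.0, 0.6, 0.5),
}


class ConfigurationError(ValueError):
    """Raised for invalid generator configurations or unknown labels."""


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic squat data set.

    Defaults reproduce the nominal study design: 19 subjects x 4 loading
    conditions x 5 cycles, sEMG at 1500 Hz, kinematics at 100 Hz, knee range
    of motion ~100 deg shrinking multiplicatively with load, and
    electromechanical leads drawn uniformly from a sub-interval of the
    physiological 20-200 ms range.
    """

    n_subjects: int = 19
    loads: tuple[str, ...] = ("none", "60", "80", "100")
    cycles_per_load: int = 5
    emg_rate: float = 1500.0
    kin_rate: float = 100.0
    channels: tuple[str, ...] = CHANNELS
    joints: tuple[str, ...] = JOINTS
    #: uniform sampling interval for per-subject, per-channel leads (ms)
    lag_range_ms: tuple[float, float] = (60.0, 180.0)
    rom_base_deg: dict[str, float] = field(
        default_factory=lambda: {"knee": 100.0, "ankle": 35.0}
    )
    angle_min_deg: dict[str, float] = field(
        default_factory=lambda: {"knee": 5.0, "ankle": -5.0}
    )
    rom_load_scale: tuple[float, ...] = (1.0, 0.9, 0.8, 0.7)
    cycle_period_s: float = 2.5
    period_jitter: float = 0.04
    amp_jitter: float = 0.04
    #: SD of additive band-limited measurement noise, relative to the
    #: unit-scale activation envelope
    noise_sd: float = 0.02
    #: per-subject lognormal-ish scatter of envelope mixture weights
    subject_weight_jitter: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.emg_rate <= 0 or self.kin_rate <= 0:
            raise ConfigurationError("sampling rates must be positive")
        if self.cycles_per_load < 1:
            raise ConfigurationError("cycles_per_load must be >= 1")
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")
        lo, hi = self.lag_range_ms
        # physiological leads span [20, 200] ms; 0 is allowed so that
        # lag-free null-control data sets can be generated
        if not (0.0 <= lo <= hi <= 200.0):
            raise ConfigurationError(
                f"lag_range_ms {self.lag_range_ms} must lie inside [0, 200] ms"
            )
        if len(self.rom_load_scale) != len(self.loads):
            raise ConfigurationError("rom_load_scale must match loads")
        scales = np.asarray(self.rom_load_scale, dtype=float)
        if not np.all(np.diff(scales) < 0):
            raise ConfigurationError(
                "rom_load_scale must be strictly decreasing across loads"
            )
        for joint in self.joints:
            if joint not in self.rom_base_deg:
                raise ConfigurationError(f"missing rom_base_deg for joint {joint!r}")

    def load_scale(self, load: str) -> float:
        try:
            return self.rom_load_scale[self.loads.index(load)]
        except ValueError:
            raise ConfigurationError(f"unknown load label {load!r}") from None


@dataclass
class Recording:
    """One trial: raw 5-channel sEMG plus knee/ankle angle time series."""

    subject_id: str
    load: str
    emg: np.ndarray  # (5, N_e) at emg_rate
    angles: np.ndarray  # (2, N_k) degrees at kin_rate
    emg_rate: float
    kin_rate: float
    channels: tuple[str, ...] = CHANNELS
    joints: tuple[str, ...] = JOINTS
    #: per-channel ground-truth lead of the EMG envelope over the
    #: kinematics, milliseconds (only known for synthetic data)
    truth_lags_ms: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.emg = np.asarray(self.emg, dtype=float)
        self.angles = np.asarray(self.angles, dtype=float)
        if self.emg.shape[0] != len(self.channels):
            raise ValueError("emg must have one row per channel")
        if self.angles.shape[0] != len(self.joints):
            raise ValueError("angles must have one row per joint")
        if not (np.all(np.isfinite(self.emg)) and np.all(np.isfinite(self.angles))):
            raise ValueError("signals must be finite")
        span_e = self.emg.shape[1] / self.emg_rate
        span_k = self.angles.shape[1] / self.kin_rate
        if abs(span_e - span_k) > 1.0 / self.kin_rate:
            raise ValueError(
                f"EMG span {span_e:.4f}s and kinematic span {span_k:.4f}s disagree"
            )


def _cycle_durations_amplitudes(
    joint: str,
    load: str,
    n_cycles: int,
    config: SynthConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    if joint not in config.joints:
        raise ConfigurationError(f"unknown joint label {joint!r}")
    scale = config.load_scale(load)
    base = config.rom_base_deg[joint]
    durations = config.cycle_period_s * (
        1.0 + config.period_jitter * rng.uniform(-1.0, 1.0, size=n_cycles)
    )
    amplitudes = base * scale * (
        1.0 + config.amp_jitter * rng.uniform(-1.0, 1.0, size=n_cycles)
    )
    return durations, amplitudes


def _trajectory_from_cycles(
    baseline: float,
    durations: np.ndarray,
    amplitudes: np.ndarray,
    rate: float,
) -> np.ndarray:
    """Raised-cosine min-to-peak-to-min cycles sampled at ``rate``."""
    edges = np.concatenate([[0.0], np.cumsum(durations)])
    n = int(round(edges[-1] * rate)) + 1
    t = np.arange(n) / rate
    t = np.minimum(t, edges[-1])
    cyc = np.clip(np.searchsorted(edges, t, side="right") - 1, 0, len(durations) - 1)
    phase = (t - edges[cyc]) / durations[cyc]
    return baseline + amplitudes[cyc] * 0.5 * (1.0 - np.cos(2.0 * np.pi * phase))


def generate_angle_trajectory(
    joint: str,
    load: str,
    n_cycles: int,
    config: SynthConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Generate one joint-angle series (degrees, at ``config.kin_rate``).

    The series consists of ``n_cycles`` raised-cosine flexion cycles with
    local minima at the cycle boundaries; peak-to-trough amplitude is
    ``rom_base_deg[joint] * rom_load_scale[load]`` up to per-cycle jitter.
    """
    if n_cycles < 1:
        raise ConfigurationError("n_cycles must be >= 1")
    durations, amplitudes = _cycle_durations_amplitudes(
        joint, load, n_cycles, config, rng
    )
    return _trajectory_from_cycles(
        config.angle_min_deg[joint], durations, amplitudes, config.kin_rate
    )


def _bandlimited_noise(
    n: int, rate: float, rng: np.random.Generator, band: tuple[float, float] = (20.0, 400.0)
) -> np.ndarray:
    """Zero-mean, unit-variance Gaussian noise band-limited to ``band``."""
    w = rng.standard_normal(n)
    sos = butter(4, band, btype="bandpass", fs=rate, output="sos")
    w = sosfiltfilt(sos, w)
    sd = w.std()
    return w / sd if sd > 0 else w


def generate_emg_channel(
    activation_envelope: np.ndarray,
    lag_ms: float,
    config: SynthConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Synthesize one raw sEMG channel from a nonnegative activation envelope.

    The envelope (sampled at ``config.emg_rate``) is advanced by
    ``lag_ms`` so the resulting EMG activity *leads* the kinematics that
    defined it, then multiplied by unit-variance carrier noise band-limited
    to 20-400 Hz; band-limited measurement noise of scale ``noise_sd`` is
    added.
    """
    env = np.asarray(activation_envelope, dtype=float)
    if np.any(env < 0) or not np.all(np.isfinite(env)):
        raise ValueError("activation envelope must be nonnegative and finite")
    if lag_ms < 0:
        raise ValueError("lag_ms must be >= 0")
    shift = int(round(lag_ms / 1000.0 * config.emg_rate))
    shifted = np.zeros_like(env)
    if shift < env.size:
        shifted[: env.size - shift] = env[shift:]
    carrier = _bandlimited_noise(env.size, config.emg_rate, rng)
    noise = _bandlimited_noise(env.size, config.emg_rate, rng)
    return shifted * carrier + config.noise_sd * noise


def _subject_envelopes(
    angles: np.ndarray,
    config: SynthConfig,
    weights: dict[str, np.ndarray],
) -> np.ndarray:
    """Per-channel activation envelopes at kin_rate from both joint angles."""
    n_k = angles.shape[1]
    drives = []
    for j, joint in enumerate(config.joints):
        theta = angles[j]
        dev = (theta - theta.min()) / config.rom_base_deg[joint]
        vel = np.gradient(theta, 1.0 / config.kin_rate)
        vel = np.abs(vel) / (config.rom_base_deg[joint] / config.cycle_period_s)
        drives.extend([dev, vel])
    drives = np.asarray(drives)  # (4, N_k)
    env = np.empty((len(config.channels), n_k))
    for c, name in enumerate(config.channels):
        env[c] = weights[name] @ drives
    return env


def generate_dataset(config: SynthConfig) -> list[Recording]:
    """Generate the full data set: one ``Recording`` per subject x load.

    All randomness derives from ``config.seed``; identical configs give
    element-wise identical data sets, including the injected lead times.
    """
    rng = np.random.default_rng(config.seed)
    recordings: list[Recording] = []
    for s in range(config.n_subjects):
        subject = f"S{s + 1:02d}"
        lags_ms = rng.uniform(*config.lag_range_ms, size=len(config.channels))
        weights = {
            name: np.asarray(_ENVELOPE_WEIGHTS[name])
            * (1.0 + config.subject_weight_jitter * rng.uniform(-1, 1, size=4))
            for name in config.channels
        }
        subj_rom = 1.0 + 0.05 * rng.uniform(-1, 1)
        subj_period = 1.0 + 0.05 * rng.uniform(-1, 1)
        for load in config.loads:
            durations, _ = _cycle_durations_amplitudes(
                "knee", load, config.cycles_per_load, config, rng
            )
            durations = durations * subj_period
            angles = []
            for joint in config.joints:
                amp = (
                    config.rom_base_deg[joint]
                    * config.load_scale(load)
                    * subj_rom
                    * (1.0 + config.amp_jitter * rng.uniform(-1, 1, config.cycles_per_load))
                )
                angles.append(
                    _trajectory_from_cycles(
                        config.angle_min_deg[joint], durations, amp, config.kin_rate
                    )
                )
            n_k = min(a.size for a in angles)
            angles = np.vstack([a[:n_k] for a in angles])
            env_kin = _subject_envelopes(angles, config, weights)
            n_e = int(round(n_k / config.kin_rate * config.emg_rate))
            t_e = np.arange(n_e) / config.emg_rate
            t_k = np.arange(n_k) / config.kin_rate
            emg = np.empty((len(config.channels), n_e))
            for c in range(len(config.channels)):
                env_e = np.interp(t_e, t_k, env_kin[c])
                emg[c] = generate_emg_channel(env_e, lags_ms[c], config, rng)
            recordings.append(
                Recording(
                    subject_id=subject,
                    load=load,
                    emg=emg,
                    angles=angles,
                    emg_rate=config.emg_rate,
                    kin_rate=config.kin_rate,
                    channels=config.channels,
                    joints=config.joints,
                    truth_lags_ms=lags_ms.copy(),
                )
            )
    return recordings


def desk_config(n_subjects: int = 8, seed: int = 0, **overrides) -> SynthConfig:
    """A reduced-size configuration for laptop-scale experiments."""
    return replace(SynthConfig(), n_subjects=n_subjects, seed=seed, **overrides)
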