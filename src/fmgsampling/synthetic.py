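"""Synthetic force-myography (FMG) trial generator.

Emulates the study design of a sampling-frequency investigation of upper-limb
FMG: 12 participants each perform 7 rapid hand actions (3 isometric, 4
dynamic) for 5 s, three trials per action, with an 8-sensor force strap on the
forearm and another at the wrist, sampled at 1 kHz.

The per-channel signal model is

    s_c(t) = o_c + g_c * [ d_c(t) + sum_k a_k cos(2*pi*k*f0*t + phi_ck)
                           + artifact_c(t) + eps_c(t) ]   shifted so s >= 0

where ``d_c`` is a slow baseline drift (strap pressure / posture variation,
dominating the lowest PSD bins), the harmonic train encodes the voluntary
action at rate ``f0`` (drawn near the maximum voluntary speed of ~6.5 Hz)
with power-law amplitude decay ``a_k = A1 * k**(-beta)``, ``artifact_c`` is a
band-limited motion-artifact component added only for dynamic actions, and
``eps_c`` is a small white sensor-noise floor.  Per-channel multiplicative
gain and additive offset emulate unequal strap tightness; they carry no
information and are removed by the normalization stage.

All randomness flows from hierarchical ``numpy.random.SeedSequence`` streams
keyed by (seed, participant, action, trial, placement), so any single trial
can be regenerated in isolation and a fixed config yields a bit-identical
dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

ISOMETRIC = "isometric"
DYNAMIC = "dynamic"
ACTION_TYPES = (ISOMETRIC, DYNAMIC)
PLACEMENTS = ("forearm", "wrist")

# Sub-stream namespaces for the hierarchical RNG.
_PARTICIPANT_STREAM = 101
_TRIAL_STREAM = 202


@dataclass(frozen=True)
class ActionSpec:
    """One hand action and its spectral parameterization.

    Parameters
    ----------
    name : str
        Action label (e.g. ``"squeeze"``).
    action_type : {"isometric", "dynamic"}
        Whether the action produces limb displacement (dynamic) or not.
    fundamental_range : (float, float)
        Interval in Hz from which the per-trial voluntary action rate ``f0``
        is drawn, before the per-participant speed offset is applied.
    n_harmonics : int
        Number of harmonics ``K`` of the action rate.
    decay_exponent : float
        beta > 0; harmonic amplitudes fall off as ``k**(-beta)``.
    harmonic_level : float
        Amplitude of the fundamental relative to the unit drift level.
    artifact_bandwidth : float
        Upper edge (Hz) of the band-limited motion-artifact noise added for
        dynamic actions; ignored when ``artifact_level`` is 0.
    artifact_level : float
        Standard deviation of the artifact component relative to the unit
        drift level (0 for isometric actions).
    """

    name: str
    action_type: str
    fundamental_range: tuple[float, float]
    n_harmonics: int = 6
    decay_exponent: float = 3.4
    harmonic_level: float = 0.12
    artifact_bandwidth: float = 0.0
    artifact_level: float = 0.0

    def validate(self, fs: float) -> None:
        if self.action_type not in ACTION_TYPES:
            raise ValueError(
                f"ActionSpec.action_type must be one of {ACTION_TYPES}, "
                f"got {self.action_type!r}"
            )
        lo, hi = self.fundamental_range
        if not (0.0 < lo <= hi < fs / 2):
            raise ValueError(
                "ActionSpec.fundamental_range must lie within (0, fs/2), "
                f"got {self.fundamental_range}"
            )
        if self.n_harmonics < 1:
            raise ValueError("ActionSpec.n_harmonics must be >= 1")
        if self.decay_exponent <= 0:
            raise ValueError("ActionSpec.decay_exponent must be > 0")
        if self.harmonic_level <= 0:
            raise ValueError("ActionSpec.harmonic_level must be > 0")
        if self.artifact_level < 0:
            raise ValueError("ActionSpec.artifact_level must be >= 0")
        if self.artifact_level > 0 and not (0 < self.artifact_bandwidth < fs / 2):
            raise ValueError(
                "ActionSpec.artifact_bandwidth must lie within (0, fs/2) "
                f"when artifact_level > 0, got {self.artifact_bandwidth}"
            )


def default_actions() -> tuple[ActionSpec, ...]:
    """The seven study actions with calibrated spectral defaults.

    Voluntary rates cluster just below the ~6.5 Hz maximum hand speed, with
    dynamic actions slightly faster and spectrally richer (lower harmonic
    decay, added motion artifact) than isometric ones.
    """
    iso = dict(
        action_type=ISOMETRIC,
        fundamental_range=(5.3, 6.1),
        n_harmonics=6,
        decay_exponent=3.4,
        harmonic_level=0.12,
    )
    dyn = dict(
        action_type=DYNAMIC,
        fundamental_range=(5.8, 6.5),
        n_harmonics=8,
        decay_exponent=3.0,
        harmonic_level=0.14,
        artifact_bandwidth=25.0,
        artifact_level=0.006,
    )
    return (
        ActionSpec(name="squeeze", **iso),
        ActionSpec(name="palm_press", **iso),
        ActionSpec(name="finger_press", **iso),
        ActionSpec(name="finger_tap", **dyn),
        ActionSpec(name="pad", **dyn),
        ActionSpec(name="shake", **dyn),
        ActionSpec(name="drum", **dyn),
    )


@dataclass(frozen=True)
class SyntheticConfig:
    """Full parameterization of the simulated study."""

    n_participants: int = 12
    n_trials: int = 3
    actions: tuple[ActionSpec, ...] = field(default_factory=default_actions)
    fs: float = 1000.0
    duration: float = 5.0
    n_channels: int = 8
    seed: int = 0
    noise_floor: float = 0.001
    channel_gain_range: tuple[float, float] = (0.75, 1.25)
    channel_offset_range: tuple[float, float] = (0.0, 0.3)
    # Slow baseline drift: a primary tone below the second PSD bin plus a
    # weaker secondary tone, per channel.  Unit drift level sets the amplitude
    # scale of the whole model.
    drift_freq_range: tuple[float, float] = (0.08, 0.22)
    secondary_drift_level: float = 0.3
    secondary_drift_freq_range: tuple[float, float] = (0.25, 0.8)
    # Per-participant effects: action-rate offset (Hz) and amplitude
    # multiplier (physique / strap coupling).
    participant_rate_shift: float = 0.25
    participant_gain_range: tuple[float, float] = (0.8, 1.2)
    placements: tuple[str, ...] = PLACEMENTS
    # The wrist strap sits closer to the moving hand and picks up slightly
    # stronger action content and artifacts.
    wrist_gain: float = 1.12

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ValueError("SyntheticConfig.n_participants must be >= 1")
        if self.n_trials < 1:
            raise ValueError("SyntheticConfig.n_trials must be >= 1")
        if self.fs <= 0:
            raise ValueError("SyntheticConfig.fs must be > 0")
        if self.duration <= 0:
            raise ValueError("SyntheticConfig.duration must be > 0")
        if self.n_channels < 1:
            raise ValueError("SyntheticConfig.n_channels must be >= 1")
        if self.noise_floor < 0:
            raise ValueError("SyntheticConfig.noise_floor must be >= 0")
        glo, ghi = self.channel_gain_range
        if not (0 < glo <= ghi):
            raise ValueError(
                "SyntheticConfig.channel_gain_range must be strictly positive"
            )
        olo, ohi = self.channel_offset_range
        if not (0 <= olo <= ohi):
            raise ValueError(
                "SyntheticConfig.channel_offset_range must be nonnegative"
            )
        if not self.actions:
            raise ValueError("SyntheticConfig.actions must be non-empty")
        names = [a.name for a in self.actions]
        if len(set(names)) != len(names):
            raise ValueError("SyntheticConfig.actions must have unique names")
        for a in self.actions:
            a.validate(self.fs)
        if not self.placements:
            raise ValueError("SyntheticConfig.placements must be non-empty")
        for p in self.placements:
            if p not in PLACEMENTS:
                raise ValueError(
                    f"SyntheticConfig.placements entries must be in {PLACEMENTS}"
                )

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration))

    def with_seed(self, seed: int) -> "SyntheticConfig":
        return replace(self, seed=int(seed))


@dataclass(frozen=True)
class FMGRecording:
    """One trial: an [n_samples x n_channels] nonnegative signal matrix plus labels."""

    signal: np.ndarray
    fs: float
    participant: int
    action: str
    action_type: str
    placement: str
    trial: int

    @property
    def n_samples(self) -> int:
        return self.signal.shape[0]

    @property
    def n_channels(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


def _participant_effects(config: SyntheticConfig, participant: int) -> tuple[float, float]:
    """Per-participant (rate_shift_hz, amplitude_multiplier), stable across trials."""
    rng = np.random.Generator(
        np.random.PCG64(
            np.random.SeedSequence([config.seed, _PARTICIPANT_STREAM, participant])
        )
    )
    shift = rng.uniform(-config.participant_rate_shift, config.participant_rate_shift)
    amp = rng.uniform(*config.participant_gain_range)
    return shift, amp


def _trial_generator(
    config: SyntheticConfig, participant: int, action_index: int, trial: int, placement: str
) -> np.random.Generator:
    placement_index = PLACEMENTS.index(placement)
    seq = np.random.SeedSequence(
        [config.seed, _TRIAL_STREAM, participant, action_index, trial, placement_index]
    )
    return np.random.Generator(np.random.PCG64(seq))


def _bandlimited_noise(
    rng: np.random.Generator, n: int, n_channels: int, fs: float, bandwidth: float, level: float
) -> np.ndarray:
    """White noise sharply band-limited to [0, bandwidth] Hz, std = level per channel."""
    white = rng.standard_normal((n, n_channels))
    spec = np.fft.rfft(white, axis=0)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spec[freqs > bandwidth, :] = 0.0
    band = np.fft.irfft(spec, n=n, axis=0)
    std = band.std(axis=0)
    std[std == 0] = 1.0
    return level * band / std


def generate_trial(
    config: SyntheticConfig,
    action: ActionSpec,
    participant: int,
    trial: int,
    placement: str,
    rng: np.random.Generator | None = None,
) -> FMGRecording:
    """Generate one labelled FMG trial.

    The RNG stream is derived deterministically from
    (config.seed, participant, action, trial, placement); passing ``rng``
    overrides it (used for ad-hoc experiments, not the study design).
    """
    config.validate()
    action.validate(config.fs)
    if placement not in PLACEMENTS:
        raise ValueError(f"placement must be one of {PLACEMENTS}, got {placement!r}")

    try:
        action_index = [a.name for a in config.actions].index(action.name)
    except ValueError:
        action_index = len(config.actions)  # ad-hoc action outside the design
    if rng is None:
        rng = _trial_generator(config, participant, action_index, trial, placement)

    n = config.n_samples
    c = config.n_channels
    t = np.arange(n) / config.fs
    rate_shift, amp_mult = _participant_effects(config, participant)
    place_gain = config.wrist_gain if placement == "wrist" else 1.0

    # Voluntary action rate for this trial.
    f0 = rng.uniform(*action.fundamental_range) + rate_shift

    # Slow baseline drift, per channel (primary tone + weaker secondary tone).
    f_d1 = rng.uniform(*config.drift_freq_range, size=c)
    f_d2 = rng.uniform(*config.secondary_drift_freq_range, size=c)
    a_d1 = rng.uniform(0.9, 1.1, size=c)
    a_d2 = config.secondary_drift_level * rng.uniform(0.8, 1.2, size=c)
    ph_d1 = rng.uniform(0, 2 * np.pi, size=c)
    ph_d2 = rng.uniform(0, 2 * np.pi, size=c)
    base = a_d1 * np.cos(2 * np.pi * np.outer(t, f_d1) + ph_d1)
    base += a_d2 * np.cos(2 * np.pi * np.outer(t, f_d2) + ph_d2)

    # Harmonic train of the action rate with power-law amplitude decay.
    k = np.arange(1, action.n_harmonics + 1)
    a_k = place_gain * action.harmonic_level * k ** (-action.decay_exponent)
    phases = rng.uniform(0, 2 * np.pi, size=(c, action.n_harmonics))
    for ki, ak in zip(k, a_k):
        base += ak * np.cos(2 * np.pi * ki * f0 * t[:, None] + phases[:, ki - 1])

    # Band-limited motion artifact (dynamic actions only).
    if action.artifact_level > 0:
        base += _bandlimited_noise(
            rng, n, c, config.fs, action.artifact_bandwidth,
            place_gain * action.artifact_level,
        )

    # White sensor-noise floor.
    if config.noise_floor > 0:
        base += rng.normal(0.0, config.noise_floor, size=(n, c))

    # Channel model: shift each channel to be nonnegative, then apply strap
    # gain and offset (the bias the normalization stage must remove).
    base *= amp_mult
    base -= base.min(axis=0)
    gains = rng.uniform(*config.channel_gain_range, size=c)
    offsets = rng.uniform(*config.channel_offset_range, size=c)
    signal = offsets + gains * base
    np.maximum(signal, 0.0, out=signal)

    return FMGRecording(
        signal=signal,
        fs=config.fs,
        participant=participant,
        action=action.name,
        action_type=action.action_type,
        placement=placement,
        trial=trial,
    )


def generate_dataset(
    config: SyntheticConfig,
) -> tuple[list[FMGRecording], pd.DataFrame]:
    """Generate one recording per (participant, action, trial, placement).

    Returns the recordings plus a metadata table with one row per recording.
    With the default design this is 12 x 7 x 3 x 2 = 504 recordings.
    """
    config.validate()
    recordings: list[FMGRecording] = []
    rows = []
    for participant in range(1, config.n_participants + 1):
        for action in config.actions:
            for trial in range(1, config.n_trials + 1):
                for placement in config.placements:
                    rec = generate_trial(config, action, participant, trial, placement)
                    recordings.append(rec)
                    rows.append(
                        {
                            "participant": participant,
                            "action": action.name,
                            "action_type": action.action_type,
                            "placement": placement,
                            "trial": trial,
                            "fs": config.fs,
                        }
                    )
    metadata = pd.DataFrame(rows)
    return recordings, metadata
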