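"""Synthetic labelled sEMG with the statistical structure the pipeline assumes.

Each trial follows the acquisition protocol: 4 s rest, 1 s motion to the
rotation limit, 3 s hold, 4 s rest, sampled at 1,000 Hz on four shank
muscles (TA, LG, MG, SOL). A movement is encoded as a distinct pattern of
per-channel amplitude gains; the load level scales every gain by a common
factor (defaults 1/3/9, mirroring the roughly 3x spring-stiffness steps
between load levels). The carrier is Gaussian noise shaped by the same
4th-order 20-450 Hz Butterworth band-pass the preprocessing stage uses,
plus optional 50 Hz power-line interference so the notch filter is
exercised end to end. Amplitudes are in microvolts: baseline noise sigma
10, active gains 30-150 before load scaling.

This is a statistical emulator for testing the decoding pipeline, not a
biophysical motor-unit model: no recruitment, fatigue or kinematics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .preprocessing import DEFAULT_CHANNELS, EmgRecording

__all__ = [
    "MOVEMENTS",
    "LOADS",
    "ActivationProfile",
    "ProtocolSpec",
    "Trial",
    "generate_trial",
    "generate_dataset",
]

#: Movement label order, fixed throughout the package (class indices 0-5).
MOVEMENTS = ("PF", "DF", "IV", "EV", "IR", "ER")
#: Load label order (class indices 0-2).
LOADS = ("low", "medium", "high")

# Per-movement x per-channel amplitude gains (uV), loosely reflecting which
# muscles drive each rotation (TA in dorsiflexion/inversion, the triceps
# surae in plantarflexion); chosen so no two rows are proportional.
_DEFAULT_GAINS = np.array(
    [
        #  TA    LG    MG   SOL
        [30.0, 120.0, 130.0, 150.0],  # PF
        [150.0, 35.0, 30.0, 40.0],  # DF
        [120.0, 40.0, 90.0, 70.0],  # IV
        [60.0, 130.0, 50.0, 100.0],  # EV
        [100.0, 90.0, 45.0, 120.0],  # IR
        [50.0, 70.0, 140.0, 60.0],  # ER
    ]
)


@dataclass(frozen=True)
class ActivationProfile:
    """Amplitude model of the generator.

    ``gains[m, c]`` is the active-phase signal standard deviation (uV) of
    channel ``c`` during movement ``m`` under unit load scale;
    ``load_scales`` multiplies all gains per load level and must increase
    from low to high. ``interference_uv`` is the peak amplitude of the
    50 Hz power-line component; ``baseline_uv`` the rest-phase noise sigma.
    """

    gains: np.ndarray = field(default_factory=lambda: _DEFAULT_GAINS.copy())
    load_scales: tuple = (1.0, 3.0, 9.0)
    interference_uv: float = 20.0
    interference_hz: float = 50.0
    baseline_uv: float = 10.0
    band: tuple = (20.0, 450.0)
    filter_order: int = 4

    def __post_init__(self):
        gains = np.asarray(self.gains, dtype=float)
        object.__setattr__(self, "gains", gains)
        if gains.shape != (len(MOVEMENTS), len(DEFAULT_CHANNELS)):
            raise ValueError(f"gains must be {len(MOVEMENTS)}x{len(DEFAULT_CHANNELS)}")
        if np.any(gains < 0):
            raise ValueError("gains must be non-negative")
        for i in range(len(MOVEMENTS)):
            for j in range(i + 1, len(MOVEMENTS)):
                if np.array_equal(gains[i], gains[j]):
                    raise ValueError(
                        f"movements {MOVEMENTS[i]} and {MOVEMENTS[j]} have identical gain rows"
                    )
        scales = tuple(float(s) for s in self.load_scales)
        object.__setattr__(self, "load_scales", scales)
        if len(scales) != len(LOADS) or not all(
            a < b for a, b in zip(scales, scales[1:])
        ):
            raise ValueError("load_scales must be 3 strictly increasing values")
        if self.baseline_uv < 0 or self.interference_uv < 0:
            raise ValueError("amplitudes must be non-negative")

    def load_scale(self, load: str) -> float:
        return self.load_scales[LOADS.index(load)]

    def with_jitter(self, rng: np.random.Generator, sigma: float) -> "ActivationProfile":
        """Per-subject variant: multiplicative log-normal jitter on the gains."""
        jitter = np.exp(rng.normal(0.0, sigma, size=self.gains.shape))
        return ActivationProfile(
            gains=self.gains * jitter,
            load_scales=self.load_scales,
            interference_uv=self.interference_uv,
            interference_hz=self.interference_hz,
            baseline_uv=self.baseline_uv,
            band=self.band,
            filter_order=self.filter_order,
        )


@dataclass(frozen=True)
class ProtocolSpec:
    """Trial timing of the acquisition protocol."""

    rest_s: float = 4.0
    motion_s: float = 1.0
    hold_s: float = 3.0
    trim_ms: float = 200.0
    repetitions: int = 12
    fs: float = 1000.0

    def __post_init__(self):
        if min(self.rest_s, self.motion_s, self.hold_s) < 0 or self.trim_ms < 0:
            raise ValueError("durations must be non-negative")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def active_s(self) -> float:
        """Motion plus hold duration, before trimming."""
        return self.motion_s + self.hold_s

    @property
    def effective_s(self) -> float:
        """Active duration after removing the trim from both ends (default 3.6 s)."""
        return self.active_s - 2 * self.trim_ms / 1000.0

    @property
    def total_s(self) -> float:
        return self.rest_s + self.active_s + self.rest_s

    def active_slice(self) -> tuple[int, int]:
        """(start, stop) sample indices of the motion+hold phase."""
        start = int(round(self.rest_s * self.fs))
        stop = start + int(round(self.active_s * self.fs))
        return start, stop


@dataclass
class Trial:
    """A generated trial with its labels."""

    recording: EmgRecording
    movement: str
    load: str
    subject: int
    repetition: int
    trial_id: int
    protocol: ProtocolSpec


from functools import lru_cache


@lru_cache(maxsize=32)
def _shaping_filter(order: int, low: float, high: float, fs: float):
    """Cached band-pass design plus its white-noise std attenuation."""
    sos = signal.butter(order, (low, high), btype="bandpass", fs=fs, output="sos")
    w, h = signal.sosfreqz(sos, worN=4096, fs=fs)
    # white noise has flat PSD; output variance is the mean squared magnitude
    gain = float(np.sqrt(np.mean(np.abs(h) ** 2)))
    return sos, gain


def _band_power_gain(profile: ActivationProfile, fs: float) -> float:
    """Std attenuation of unit white noise through the shaping band-pass."""
    return _shaping_filter(profile.filter_order, *profile.band, fs)[1]


def generate_trial(
    movement: str,
    load: str,
    profile: ActivationProfile = ActivationProfile(),
    protocol: ProtocolSpec = ProtocolSpec(),
    seed: int | np.random.Generator = 0,
) -> EmgRecording:
    """Generate one full-timeline 4-channel trial.

    The active (motion+hold) phase of channel ``c`` is band-limited noise
    with standard deviation ``gains[movement, c] * load_scale(load)``; the
    rest phases carry baseline noise only; 50 Hz interference (if enabled)
    runs through the whole trial. Identical seeds give identical output.
    """
    if movement not in MOVEMENTS:
        raise KeyError(f"unknown movement {movement!r}; expected one of {MOVEMENTS}")
    if load not in LOADS:
        raise KeyError(f"unknown load {load!r}; expected one of {LOADS}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    fs = protocol.fs
    n_total = int(round(protocol.total_s * fs))
    start, stop = protocol.active_slice()
    n_ch = len(DEFAULT_CHANNELS)

    # target per-sample sigma envelope, then band-shape white noise to match
    sigma = np.full((n_ch, n_total), profile.baseline_uv)
    active = profile.gains[MOVEMENTS.index(movement)] * profile.load_scale(load)
    sigma[:, start:stop] = active[:, None]

    white = rng.standard_normal((n_ch, n_total))
    if np.any(sigma > 0):
        sos, gain = _shaping_filter(profile.filter_order, *profile.band, fs)
        data = signal.sosfilt(sos, white * sigma, axis=1) / gain
    else:
        data = np.zeros_like(white)

    if profile.interference_uv > 0:
        t = np.arange(n_total) / fs
        phase = rng.uniform(0, 2 * np.pi, size=n_ch)
        data = data + profile.interference_uv * np.sin(
            2 * np.pi * profile.interference_hz * t[None, :] + phase[:, None]
        )

    return EmgRecording(data=data, fs=fs, channel_names=DEFAULT_CHANNELS)


def generate_dataset(
    n_subjects: int = 6,
    profile: ActivationProfile = ActivationProfile(),
    protocol: ProtocolSpec = ProtocolSpec(),
    seed: int = 0,
    subject_jitter: float = 0.1,
) -> list[Trial]:
    """Generate a balanced labelled dataset.

    Produces ``n_subjects x 3 loads x 6 movements x repetitions`` trials
    (defaults: 6 x 216 = 1,296). Each subject gets its own log-normally
    jittered copy of the gain matrix so subject-wise experiments are
    possible; the same seed reproduces signals and label order bitwise.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    root = np.random.SeedSequence(seed)
    trials: list[Trial] = []
    trial_id = 0
    subject_seqs = root.spawn(n_subjects)
    for subj, subj_seq in enumerate(subject_seqs, start=1):
        subj_rng = np.random.default_rng(subj_seq)
        subj_profile = (
            profile.with_jitter(subj_rng, subject_jitter)
            if subject_jitter > 0
            else profile
        )
        for load in LOADS:
            for movement in MOVEMENTS:
                for rep in range(1, protocol.repetitions + 1):
                    rec = generate_trial(
                        movement, load, subj_profile, protocol, seed=subj_rng
                    )
                    trials.append(
                        Trial(
                            recording=rec,
                            movement=movement,
                            load=load,
                            subject=subj,
                            repetition=rep,
                            trial_id=trial_id,
                            protocol=protocol,
                        )
                    )
                    trial_id += 1
    return trials
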