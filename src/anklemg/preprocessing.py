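"""Filtering, normalization, trial trimming and two-level sliding-window segmentation.

The processing chain for a raw recording is fixed as
``notch_filter`` (50 Hz power line) -> ``bandpass_filter`` (20-450 Hz,
4th-order Butterworth) -> optional ``normalize`` (per-channel z-score).
Analysis windows come in two levels: a "large" 210 ms window slid by
120 ms over each trial, and "small" 20 ms sub-windows slid by 10 ms
inside every large window (20 sub-windows per large window with the
defaults).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

__all__ = [
    "EmgRecording",
    "WindowingSpec",
    "LargeWindow",
    "notch_filter",
    "bandpass_filter",
    "normalize",
    "trim_trial",
    "segment_large",
    "segment_small",
    "eq3_sample_count",
    "DEFAULT_CHANNELS",
]

#: Recorded shank muscles, in electrode order.
DEFAULT_CHANNELS = ("TA", "LG", "MG", "SOL")


@dataclass
class EmgRecording:
    """A multi-channel sEMG signal block.

    Parameters
    ----------
    data : ndarray of shape (n_channels, n_samples)
        Signal values in microvolts (arbitrary units once normalized).
    fs : float
        Sampling rate in Hz.
    channel_names : tuple of str
        One name per channel.
    filtered, normalized : bool
        Provenance flags set by the filtering/normalization stages.
    channel_scale : ndarray or None
        Per-channel population standard deviation recorded *before*
        normalization; needed to express microvolt amplitude thresholds
        on the normalized scale.
    """

    data: np.ndarray
    fs: float = 1000.0
    channel_names: tuple = DEFAULT_CHANNELS
    filtered: bool = False
    normalized: bool = False
    channel_scale: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("channel_names length must match channel count")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_ms(self) -> float:
        return 1000.0 * self.n_samples / self.fs

    def slice_samples(self, start: int, stop: int) -> "EmgRecording":
        """Return a new recording restricted to ``[start, stop)`` samples."""
        return replace(self, data=self.data[:, start:stop].copy())


@dataclass(frozen=True)
class WindowingSpec:
    """Two-level sliding-window geometry, all lengths in milliseconds."""

    large_ms: float = 210.0
    large_slide_ms: float = 120.0
    small_ms: float = 20.0
    small_slide_ms: float = 10.0

    def __post_init__(self):
        if not (self.large_ms >= self.large_slide_ms > 0):
            raise ValueError("large window length must be >= slide > 0")
        if not (self.small_ms >= self.small_slide_ms > 0):
            raise ValueError("small window length must be >= slide > 0")
        if self.large_ms < self.small_ms:
            raise ValueError("large window must not be shorter than small window")

    def n_small_windows(self) -> int:
        """Sub-windows per large window: (large - small)/small_slide + 1."""
        n, rem = divmod(self.large_ms - self.small_ms, self.small_slide_ms)
        if rem:
            raise ValueError(
                "small windows do not tile the large window: "
                f"({self.large_ms} - {self.small_ms}) not a multiple of {self.small_slide_ms}"
            )
        return int(n) + 1

    def large_samples(self, fs: float) -> int:
        return int(round(self.large_ms * fs / 1000.0))

    def large_slide_samples(self, fs: float) -> int:
        return int(round(self.large_slide_ms * fs / 1000.0))

    def small_samples(self, fs: float) -> int:
        return int(round(self.small_ms * fs / 1000.0))

    def small_slide_samples(self, fs: float) -> int:
        return int(round(self.small_slide_ms * fs / 1000.0))


@dataclass
class LargeWindow:
    """One analysis window (channels x samples) with its trial labels."""

    data: np.ndarray
    fs: float
    movement: str | None = None
    load: str | None = None
    subject: int | None = None
    trial_id: int | None = None
    start_sample: int = 0
    channel_scale: np.ndarray | None = None
    channel_names: tuple = DEFAULT_CHANNELS

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("window data must be 2-D (channels x samples)")


def _apply_sos(rec: EmgRecording, sos: np.ndarray, zero_phase: bool) -> np.ndarray:
    if zero_phase:
        return signal.sosfiltfilt(sos, rec.data, axis=1)
    return signal.sosfilt(sos, rec.data, axis=1)


def notch_filter(
    rec: EmgRecording, center: float = 50.0, q: float = 30.0, zero_phase: bool = False
) -> EmgRecording:
    """Remove narrowband power-line interference with a 2nd-order IIR notch.

    ``zero_phase`` applies the filter forward and backward (offline use);
    the default is causal, compatible with streaming control loops.
    """
    if rec.fs <= 2 * center:
        raise ValueError("sampling rate must exceed twice the notch frequency")
    b, a = signal.iirnotch(center, q, fs=rec.fs)
    sos = signal.tf2sos(b, a)
    out = _apply_sos(rec, sos, zero_phase)
    return replace(rec, data=out, filtered=True)


def bandpass_filter(
    rec: EmgRecording,
    low: float = 20.0,
    high: float = 450.0,
    order: int = 4,
    zero_phase: bool = False,
) -> EmgRecording:
    """4th-order Butterworth band-pass confining the signal to the sEMG band."""
    if not (0 < low < high < rec.fs / 2):
        raise ValueError(
            f"invalid band [{low}, {high}] Hz for sampling rate {rec.fs} Hz"
        )
    sos = signal.butter(order, [low, high], btype="bandpass", fs=rec.fs, output="sos")
    out = _apply_sos(rec, sos, zero_phase)
    return replace(rec, data=out, filtered=True)


def normalize(rec: EmgRecording) -> EmgRecording:
    """Z-score every channel to zero mean, unit population variance.

    The pre-normalization standard deviation of each channel is kept on
    the result (``channel_scale``) so microvolt thresholds can be mapped
    onto the normalized scale downstream.
    """
    mean = rec.data.mean(axis=1, keepdims=True)
    std = rec.data.std(axis=1, keepdims=True)  # population sigma (ddof=0)
    if np.any(std <= 0) or not np.all(np.isfinite(std)):
        bad = [rec.channel_names[i] for i in np.nonzero(std.ravel() <= 0)[0]]
        raise ValueError(f"zero-variance channel(s), cannot normalize: {bad}")
    out = (rec.data - mean) / std
    scale = std.ravel().copy()
    if rec.channel_scale is not None:  # compose with an earlier normalization
        scale = scale * rec.channel_scale
    return replace(rec, data=out, normalized=True, channel_scale=scale)


def trim_trial(active_segment: EmgRecording, trim_ms: float = 200.0) -> EmgRecording:
    """Drop ``trim_ms`` from each end of an active segment.

    Removes the movement-transition edges; the default turns the 4 s
    motion-plus-hold phase into a 3.6 s steady segment.
    """
    n_trim = int(round(trim_ms * active_segment.fs / 1000.0))
    if active_segment.n_samples <= 2 * n_trim:
        raise ValueError(
            f"segment of {active_segment.n_samples} samples too short to trim "
            f"{n_trim} samples from each end"
        )
    if n_trim == 0:
        return replace(active_segment, data=active_segment.data.copy())
    return active_segment.slice_samples(n_trim, active_segment.n_samples - n_trim)


def segment_large(
    rec: EmgRecording,
    spec: WindowingSpec = WindowingSpec(),
    movement: str | None = None,
    load: str | None = None,
    subject: int | None = None,
    trial_id: int | None = None,
) -> list[LargeWindow]:
    """Cut a trial into overlapping large windows (inclusive enumeration).

    Start offsets run 0, slide, 2*slide, ... while a full window fits, so a
    recording exactly one window long yields one window and a shorter one
    yields none. Windows never span beyond the recording.
    """
    win = spec.large_samples(rec.fs)
    slide = spec.large_slide_samples(rec.fs)
    out: list[LargeWindow] = []
    for start in range(0, rec.n_samples - win + 1, slide):
        out.append(
            LargeWindow(
                data=rec.data[:, start : start + win].copy(),
                fs=rec.fs,
                movement=movement,
                load=load,
                subject=subject,
                trial_id=trial_id,
                start_sample=start,
                channel_scale=None
                if rec.channel_scale is None
                else rec.channel_scale.copy(),
                channel_names=rec.channel_names,
            )
        )
    return out


def eq3_sample_count(total_ms: float, spec: WindowingSpec = WindowingSpec()) -> int:
    """Window count by the bookkeeping rule floor((T - window) / slide).

    This is the sample-accounting arithmetic applied to the concatenated
    effective recording duration; note it has no "+1", so for a duration
    where (T - window) is an exact multiple of the slide it is one less
    than the number of windows ``segment_large`` enumerates.
    """
    if total_ms < spec.large_ms:
        raise ValueError("total duration shorter than one window")
    return int((total_ms - spec.large_ms) // spec.large_slide_ms)


def segment_small(win: LargeWindow, spec: WindowingSpec = WindowingSpec()) -> np.ndarray:
    """Split a large window into its small sub-windows.

    Returns an array of shape (n_sub, n_channels, small_samples), ordered
    by start time.
    """
    small = spec.small_samples(win.fs)
    slide = spec.small_slide_samples(win.fs)
    n_samples = win.data.shape[1]
    expected = spec.large_samples(win.fs)
    if n_samples != expected:
        raise ValueError(
            f"window has {n_samples} samples, spec expects {expected}"
        )
    n_sub = spec.n_small_windows()
    out = np.empty((n_sub, win.data.shape[0], small))
    for k in range(n_sub):
        start = k * slide
        out[k] = win.data[:, start : start + small]
    return out
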