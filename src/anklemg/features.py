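"""The eight time-domain sEMG features and feature-tensor assembly.

For a sub-window ``x`` of length ``M`` (with amplitude threshold ``t``
where one applies):

====  =========================================================
RMS   sqrt(mean(x_i^2))
MAV   mean(|x_i|)
WL    sum |x_{i+1} - x_i|
ZC    # sign changes with |x_i - x_{i+1}| >= t
SSC   # i with (x_i - x_{i-1})(x_i - x_{i+1}) >= t
VAR   unbiased sample variance (divisor M - 1)
LogD  exp(mean(log(|x_i| + eps)))
WA    # i with |x_i - x_{i+1}| >= t
====  =========================================================

The threshold default of 50 uV suppresses baseline-noise counts; it is
interpreted on the raw microvolt scale, so when features are computed on
a z-normalized window the threshold is divided by the channel's stored
pre-normalization sigma.

``extract_tensor`` evaluates a feature list on every 20 ms sub-window of
every channel of a 210 ms analysis window, yielding the (20, N, 4)
feature tensor the movement classifier consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocessing import LargeWindow, WindowingSpec, segment_small

__all__ = [
    "ALL_FEATURES",
    "FeatureSpec",
    "FeatureTensor",
    "rms",
    "mav",
    "wl",
    "zc",
    "ssc",
    "var",
    "logd",
    "wa",
    "extract_tensor",
]

#: Canonical feature order; every FeatureSpec preserves it.
ALL_FEATURES = ("RMS", "MAV", "WL", "ZC", "SSC", "VAR", "LogD", "WA")


def _as_window(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim == 0 or x.shape[-1] == 0:
        raise ValueError("empty sub-window")
    return x


def rms(x) -> float:
    """Root mean square."""
    x = _as_window(x)
    return np.sqrt(np.mean(np.square(x), axis=-1))


def mav(x) -> float:
    """Mean absolute value."""
    x = _as_window(x)
    return np.mean(np.abs(x), axis=-1)


def wl(x) -> float:
    """Waveform length: total variation of the sample sequence."""
    x = _as_window(x)
    if x.shape[-1] < 2:
        raise ValueError("waveform length needs at least 2 samples")
    return np.sum(np.abs(np.diff(x, axis=-1)), axis=-1)


def zc(x, threshold: float = 50.0):
    """Zero crossings: sign changes whose amplitude jump reaches the threshold."""
    x = _as_window(x)
    if x.shape[-1] < 2:
        raise ValueError("zero crossing needs at least 2 samples")
    a, b = x[..., :-1], x[..., 1:]
    cross = np.sign(a) * np.sign(b) < 0
    big = np.abs(a - b) >= threshold
    return np.sum(cross & big, axis=-1)


def ssc(x, threshold: float = 50.0):
    """Slope sign changes: local extrema whose slope product reaches the threshold."""
    x = _as_window(x)
    if x.shape[-1] < 3:
        raise ValueError("slope sign change needs at least 3 samples")
    prev, cur, nxt = x[..., :-2], x[..., 1:-1], x[..., 2:]
    return np.sum((cur - prev) * (cur - nxt) >= threshold, axis=-1)


def var(x) -> float:
    """Unbiased sample variance (divisor M - 1)."""
    x = _as_window(x)
    if x.shape[-1] < 2:
        raise ValueError("variance needs at least 2 samples")
    return np.var(x, axis=-1, ddof=1)


def logd(x, eps: float = 1e-12) -> float:
    """Log detector: geometric mean of |x_i|, guarded against zeros by eps."""
    x = _as_window(x)
    return np.exp(np.mean(np.log(np.abs(x) + eps), axis=-1))


def wa(x, threshold: float = 50.0):
    """Willison amplitude: consecutive differences reaching the threshold."""
    x = _as_window(x)
    if x.shape[-1] < 2:
        raise ValueError("Willison amplitude needs at least 2 samples")
    return np.sum(np.abs(np.diff(x, axis=-1)) >= threshold, axis=-1)


@dataclass(frozen=True)
class FeatureSpec:
    """Which features to compute, with the shared amplitude threshold (uV)."""

    names: tuple = ALL_FEATURES
    threshold_uv: float = 50.0
    log_eps: float = 1e-12

    def __post_init__(self):
        names = tuple(self.names)
        unknown = [n for n in names if n not in ALL_FEATURES]
        if unknown:
            raise ValueError(f"unknown feature names {unknown}; choose from {ALL_FEATURES}")
        if len(set(names)) != len(names):
            raise ValueError("feature names must be unique")
        if not names:
            raise ValueError("feature list must not be empty")
        # keep the canonical order regardless of how the caller listed them
        object.__setattr__(
            self, "names", tuple(n for n in ALL_FEATURES if n in names)
        )
        if self.threshold_uv < 0:
            raise ValueError("threshold must be non-negative")

    @property
    def n_features(self) -> int:
        return len(self.names)


@dataclass
class FeatureTensor:
    """Per-window feature values, shape (n_sub_windows, n_features, n_channels)."""

    values: np.ndarray
    feature_names: tuple
    movement: str | None = None
    load: str | None = None
    subject: int | None = None
    trial_id: int | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("feature tensor must be 3-D (sub-windows x features x channels)")
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError("feature axis does not match feature_names")


def _feature_matrix(sub: np.ndarray, spec: FeatureSpec, thresholds: np.ndarray) -> np.ndarray:
    """Features for stacked sub-windows.

    ``sub`` has shape (n_sub, n_channels, M); ``thresholds`` one value per
    channel. Returns (n_sub, n_features, n_channels).
    """
    n_sub, n_ch, _ = sub.shape
    out = np.empty((n_sub, len(spec.names), n_ch))
    t = thresholds[None, :, None]  # broadcast over sub-windows and samples
    for j, name in enumerate(spec.names):
        if name == "RMS":
            vals = rms(sub)
        elif name == "MAV":
            vals = mav(sub)
        elif name == "WL":
            vals = wl(sub)
        elif name == "ZC":
            vals = zc(sub, threshold=t)
        elif name == "SSC":
            vals = ssc(sub, threshold=t)
        elif name == "VAR":
            vals = var(sub)
        elif name == "LogD":
            vals = logd(sub, eps=spec.log_eps)
        elif name == "WA":
            vals = wa(sub, threshold=t)
        out[:, j, :] = vals
    return out


def effective_thresholds(win: LargeWindow, spec: FeatureSpec) -> np.ndarray:
    """Per-channel threshold on the window's own scale.

    Raw/filtered windows use the microvolt threshold directly; windows cut
    from a normalized recording divide it by the stored pre-normalization
    sigma so the gate corresponds to the same physical amplitude.
    """
    n_ch = win.data.shape[0]
    if win.channel_scale is None:
        return np.full(n_ch, spec.threshold_uv)
    scale = np.asarray(win.channel_scale, dtype=float)
    if scale.shape != (n_ch,):
        raise ValueError("channel_scale length must match channel count")
    return spec.threshold_uv / scale


def extract_tensor(
    win: LargeWindow,
    wspec: WindowingSpec = WindowingSpec(),
    fspec: FeatureSpec = FeatureSpec(),
) -> FeatureTensor:
    """Compute the (n_sub, N, n_channels) feature tensor of one analysis window."""
    sub = segment_small(win, wspec)  # (n_sub, n_ch, M)
    values = _feature_matrix(sub, fspec, effective_thresholds(win, fspec))
    if not np.all(np.isfinite(values)):
        bad = np.argwhere(~np.isfinite(values))
        j = int(bad[0, 1])
        raise FloatingPointError(
            f"non-finite value for feature {fspec.names[j]} "
            f"(sub-window {int(bad[0, 0])}, channel {int(bad[0, 2])})"
        )
    return FeatureTensor(
        values=values,
        feature_names=fspec.names,
        movement=win.movement,
        load=win.load,
        subject=win.subject,
        trial_id=win.trial_id,
    )
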