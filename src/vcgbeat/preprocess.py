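"""Per-buffer conditioning: uniform resampling and brick-wall high-pass.

Each buffered channel is interpolated onto a uniform grid with shape-
preserving cubic (pchip) interpolation, then stripped of baseline wander with
an ideal high-pass realized in the frequency domain.  The grid is aligned to
absolute multiples of ``1/fs``, so overlapping buffers of the same recording
sample the identical grid points — beat timestamps therefore agree exactly
across buffers.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.interpolate import PchipInterpolator

from .errors import InsufficientDataError, ParameterError
from .signal_io import BufferSegment


@dataclass
class UniformSignal:
    """A single uniformly sampled channel.

    Sample ``k`` sits at absolute time ``t0 + k / fs``.
    """

    values: np.ndarray
    fs: float
    t0: float
    channel_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.fs <= 0:
            raise ParameterError("fs must be > 0")
        if self.values.size < 2:
            raise InsufficientDataError("a uniform signal needs at least 2 samples")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.size) / self.fs

    @property
    def duration(self) -> float:
        return (self.values.size - 1) / self.fs


def resample_uniform(
    seg: BufferSegment, channel: str, target_fs: float = 200.0
) -> UniformSignal:
    """Resample one buffered channel onto the uniform ``target_fs`` grid.

    The grid runs from ``ceil(first * fs) / fs`` to ``floor(last * fs) / fs``
    (both ends inclusive); no extrapolation beyond the sampled span occurs.
    Monotone cubic interpolation is shape-preserving, so output values never
    overshoot the local data envelope.
    """
    if not seg.has_channel(channel):
        raise KeyError(channel)
    t = seg.timestamps
    x = seg.channel(channel)
    if t.size < 4:
        raise InsufficientDataError("pchip resampling needs at least 4 samples")
    if target_fs <= 0:
        raise ParameterError("target_fs must be > 0")
    k0 = int(np.ceil(t[0] * target_fs - 1e-9))
    k1 = int(np.floor(t[-1] * target_fs + 1e-9))
    if k1 - k0 + 1 < 2:
        raise InsufficientDataError("segment too short for the target grid")
    grid = np.arange(k0, k1 + 1) / target_fs
    values = PchipInterpolator(t, x)(grid)
    return UniformSignal(values=values, fs=float(target_fs), t0=k0 / target_fs,
                         channel_id=channel)


def highpass_brickwall(sig: UniformSignal, cutoff: float = 0.4) -> UniformSignal:
    """Remove all frequency content strictly below ``cutoff`` Hz.

    The ideal response is realized per buffer: real FFT of the window, bins
    with ``|f| < cutoff`` zeroed (DC always included), inverse transform.
    This is a projection, hence idempotent; edge ringing from the implicit
    periodic extension is accepted.
    """
    if cutoff >= sig.fs / 2:
        raise ParameterError(
            f"cutoff {cutoff} Hz is not below Nyquist {sig.fs / 2} Hz"
        )
    spectrum = np.fft.rfft(sig.values)
    freqs = np.fft.rfftfreq(sig.values.size, d=1.0 / sig.fs)
    spectrum[freqs < cutoff] = 0.0
    filtered = np.fft.irfft(spectrum, n=sig.values.size)
    return replace(sig, values=filtered)
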