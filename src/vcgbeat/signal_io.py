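"""CSV input/output for multi-axis cardiomechanical recordings.

A recording couples a strictly increasing, possibly jittered timestamp vector
with up to seven channels: three accelerometer axes in g (aX longitudinal-down,
aY frontal-right, aZ dorsoventral-out), three gyroscope axes in deg/s (gX, gY,
gZ, right-hand rule) and an optional single-lead ECG in millivolts.  This
module also provides the rolling-buffer replay that emulates a real-time
acquisition loop: a sliding window of ``buffer_span`` seconds advanced by
``step`` seconds per refresh.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterator, Optional

import numpy as np
import pandas as pd

from .errors import FormatError, InsufficientDataError, ParameterError

log = logging.getLogger(__name__)

#: Canonical channel names, in serialization order.
CHANNELS = ("aX", "aY", "aZ", "gX", "gY", "gZ", "ecg")

#: Shortest recording accepted for streaming: the smallest analysis window.
MIN_RECORDING_S = 2.0


@dataclass
class CsvDialect:
    """Column mapping for the recording CSV format.

    ``channel_cols`` maps canonical channel names to the column names used in
    the file; channels missing from the mapping (or from the file) are simply
    absent from the parsed recording.
    """

    time_col: str = "t"
    channel_cols: Dict[str, str] = field(
        default_factory=lambda: {name: name for name in CHANNELS}
    )


@dataclass
class RawRecording:
    """Irregularly sampled multi-axis sensor record on one absolute clock.

    Timestamps are seconds, zero-based at acquisition start and strictly
    increasing; every beat timestamp produced downstream uses this clock.
    """

    timestamps: np.ndarray
    channels: Dict[str, np.ndarray]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.timestamps.ndim != 1 or self.timestamps.size < 2:
            raise InsufficientDataError("a recording needs at least 2 samples")
        if not np.all(np.diff(self.timestamps) > 0):
            raise FormatError("timestamps must be strictly increasing")
        for name, values in self.channels.items():
            values = np.asarray(values, dtype=float)
            if values.shape != self.timestamps.shape:
                raise FormatError(
                    f"channel {name!r} has length {values.size}, "
                    f"expected {self.timestamps.size}"
                )
            self.channels[name] = values
        if self.nominal_fs <= 0:
            raise ParameterError("nominal rate must be > 0")

    @property
    def duration(self) -> float:
        return float(self.timestamps[-1] - self.timestamps[0])

    @property
    def nominal_fs(self) -> float:
        """Nominal acquisition rate in Hz (from metadata, else median spacing)."""
        fs = self.meta.get("fs")
        if fs is None:
            fs = 1.0 / float(np.median(np.diff(self.timestamps)))
        return float(fs)

    def has_channel(self, name: str) -> bool:
        return name in self.channels


@dataclass
class BufferSegment:
    """One rolling-buffer snapshot: samples with timestamp in
    ``(window_end - buffer_span, window_end]``."""

    recording: RawRecording
    start: int
    stop: int
    window_end: float
    buffer_span: float
    step: float

    @property
    def timestamps(self) -> np.ndarray:
        return self.recording.timestamps[self.start : self.stop]

    def channel(self, name: str) -> np.ndarray:
        return self.recording.channels[name][self.start : self.stop]

    def has_channel(self, name: str) -> bool:
        return self.recording.has_channel(name)

    def __len__(self) -> int:
        return self.stop - self.start


def read_recording(path, dialect: Optional[CsvDialect] = None) -> RawRecording:
    """Parse a recording CSV.

    Rows whose timestamp does not strictly exceed the previous retained
    timestamp (serial-acquisition duplicates or reordering artifacts) are
    dropped with a logged warning.
    """
    dialect = dialect or CsvDialect()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path)
    if dialect.time_col not in frame.columns:
        raise FormatError(f"no timestamp column {dialect.time_col!r} in {path}")
    t = frame[dialect.time_col].to_numpy(dtype=float)
    keep = np.ones(t.size, dtype=bool)
    last = -np.inf
    for i, ti in enumerate(t):
        if ti > last:
            last = ti
        else:
            keep[i] = False
    n_drop = int((~keep).sum())
    if n_drop:
        log.warning("dropped %d non-monotone timestamp row(s) from %s", n_drop, path)
    channels = {
        name: frame[col].to_numpy(dtype=float)[keep]
        for name, col in dialect.channel_cols.items()
        if col in frame.columns
    }
    if t[keep].size < 2:
        raise InsufficientDataError(f"{path} holds fewer than 2 usable samples")
    return RawRecording(timestamps=t[keep], channels=channels, meta={"path": str(path)})


def write_recording(rec: RawRecording, path, dialect: Optional[CsvDialect] = None) -> None:
    """Serialize a recording as CSV (header row, full float precision)."""
    dialect = dialect or CsvDialect()
    data = {dialect.time_col: rec.timestamps}
    for name in CHANNELS:
        if name in rec.channels:
            data[dialect.channel_cols.get(name, name)] = rec.channels[name]
    pd.DataFrame(data).to_csv(path, index=False)


def stream_buffers(
    rec: RawRecording, buffer_span: float = 10.0, step: float = 1.0
) -> Iterator[BufferSegment]:
    """Replay a recording as a sequence of rolling-buffer segments.

    No segment is emitted before one full ``buffer_span`` has accrued
    (warm-up); thereafter ``window_end`` advances by ``step`` until the end of
    the recording is covered.  A final shortened step is emitted if the
    recording does not end on the step grid.  Acquisition dropouts that leave
    a buffer empty are reported with a warning and skipped.
    """
    if buffer_span <= 0 or step <= 0:
        raise ParameterError("buffer_span and step must be > 0")
    if rec.duration < MIN_RECORDING_S:
        raise InsufficientDataError(
            f"recording spans {rec.duration:.3f} s < minimum {MIN_RECORDING_S} s"
        )
    t = rec.timestamps
    first, last = float(t[0]), float(t[-1])
    end = first + buffer_span
    eps = 1e-9
    while end <= last + eps:
        yield from _emit(rec, t, end, buffer_span, step)
        if abs(end - last) <= eps:
            break
        nxt = end + step
        if nxt > last + eps:  # cover the tail with one shortened step
            nxt = last
        end = nxt


def _emit(rec, t, end, buffer_span, step) -> Iterator[BufferSegment]:
    start = int(np.searchsorted(t, end - buffer_span, side="right"))
    stop = int(np.searchsorted(t, end, side="right"))
    if stop <= start:
        log.warning("empty buffer at window_end=%.3f s (acquisition gap?)", end)
        return
    yield BufferSegment(
        recording=rec,
        start=start,
        stop=stop,
        window_end=float(end),
        buffer_span=float(buffer_span),
        step=float(step),
    )
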