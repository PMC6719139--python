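"""Pan-Tompkins QRS detection for the ECG reference channel.

Canonical stages: 5-15 Hz band-pass, differentiation, squaring, 150 ms
moving-window integration, then dual adaptive thresholds with search-back.
The band-pass is realized as a zero-phase Butterworth filter, which keeps the
timing of the integrator output aligned with the raw waveform at any sampling
rate; detections are refined to the raw-signal local maximum within +/-50 ms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt, find_peaks

from .errors import InsufficientDataError
from .preprocess import UniformSignal

BAND_HZ = (5.0, 15.0)
INTEGRATION_MS = 150.0
REFRACTORY_S = 0.2
LEARNING_S = 2.0
REFINE_S = 0.05
SEARCHBACK_FACTOR = 1.66


@dataclass
class RPeakList:
    """Strictly increasing ECG R-peak timestamps in seconds."""

    timestamps: np.ndarray

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)

    @property
    def rr_s(self) -> np.ndarray:
        return np.diff(self.timestamps)

    def __len__(self) -> int:
        return self.timestamps.size


def pan_tompkins(ecg: UniformSignal) -> RPeakList:
    """Detect R-peaks; a flat or empty signal yields an empty list."""
    fs = ecg.fs
    x = np.asarray(ecg.values, dtype=float)
    if x.size < int(LEARNING_S * fs):
        raise InsufficientDataError("ECG shorter than the 2 s learning phase")
    if np.ptp(x) == 0:
        return RPeakList(timestamps=np.empty(0))
    x = x - x.mean()

    nyq = fs / 2.0
    b, a = butter(3, [BAND_HZ[0] / nyq, min(BAND_HZ[1], 0.9 * nyq) / nyq],
                  btype="bandpass")
    bp = filtfilt(b, a, x)
    deriv = np.gradient(bp) * fs
    sq = deriv * deriv
    w = max(1, int(round(INTEGRATION_MS / 1000.0 * fs)))
    integ = np.convolve(sq, np.ones(w) / w, mode="same")

    cand, _ = find_peaks(integ, distance=max(1, int(REFRACTORY_S * fs)))
    if cand.size == 0:
        return RPeakList(timestamps=np.empty(0))

    learn = integ[: int(LEARNING_S * fs)]
    spki = 0.25 * learn.max()
    npki = 0.5 * learn.mean()
    detections: list[int] = []
    rr_history: list[float] = []

    def threshold() -> float:
        return npki + 0.25 * (spki - npki)

    for p in cand:
        if integ[p] > threshold():
            _accept(p, detections, rr_history, fs)
            spki = 0.125 * integ[p] + 0.875 * spki
        else:
            npki = 0.125 * integ[p] + 0.875 * npki
            # search-back: revisit sub-threshold candidates when a beat is
            # overdue relative to the running RR average
            if detections and rr_history:
                rr_avg = float(np.mean(rr_history[-8:]))
                overdue = (p - detections[-1]) / fs > SEARCHBACK_FACTOR * rr_avg
                if overdue and integ[p] > 0.5 * threshold():
                    _accept(p, detections, rr_history, fs)
                    spki = 0.25 * integ[p] + 0.75 * spki

    if not detections:
        return RPeakList(timestamps=np.empty(0))

    refined = _refine_to_raw(np.asarray(detections), x, fs)
    refined = _apply_refractory(refined, fs)
    return RPeakList(timestamps=ecg.t0 + refined / fs)


def _accept(p: int, detections: list, rr_history: list, fs: float) -> None:
    if detections and (p - detections[-1]) / fs < REFRACTORY_S:
        return
    if detections:
        rr_history.append((p - detections[-1]) / fs)
    detections.append(p)


def _refine_to_raw(det: np.ndarray, raw: np.ndarray, fs: float) -> np.ndarray:
    """Snap each integrator detection to the raw local maximum within 50 ms."""
    half = max(1, int(round(REFINE_S * fs)))
    out = []
    for p in det:
        lo = max(0, p - half)
        hi = min(raw.size, p + half + 1)
        out.append(lo + int(np.argmax(raw[lo:hi])))
    return np.asarray(sorted(set(out)), dtype=float)


def _apply_refractory(idx: np.ndarray, fs: float) -> np.ndarray:
    out: list[float] = []
    for p in idx:
        if not out or (p - out[-1]) / fs >= REFRACTORY_S:
            out.append(p)
    return np.asarray(out)


def write_annotations(peaks, path) -> None:
    """One timestamp per line, shared dialect with the beat annotations."""
    ts = getattr(peaks, "timestamps", peaks)
    with open(path, "w") as fh:
        for t in np.asarray(ts, dtype=float):
            fh.write(f"{t:.6f}\n")


def read_annotations(path) -> np.ndarray:
    with open(path) as fh:
        return np.asarray([float(line) for line in fh if line.strip()], dtype=float)
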