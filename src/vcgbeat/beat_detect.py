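"""Individual aortic-opening (AO) beat identification.

The averaged heart rate acts as a spacing prior: local maxima of the
forward-looking VarWin output are admitted greedily in descending amplitude
order subject to a minimum spacing of 75% of the average BTB interval.
Candidates from overlapping windows are merged at a deduplication tolerance,
and SCG candidates are finally cross-verified against the gyration axis: an
SCG timestamp survives only if a GCG peak lies within 25 ms of it — the
gyroscope never injects beats, it only vetoes them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.signal import find_peaks

from .varwin import EnhancedSignal


@dataclass
class BeatList:
    """Strictly increasing AO (or R-peak surrogate) timestamps in seconds."""

    timestamps: np.ndarray
    axis_of_origin: str = "fused"

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.timestamps.size > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("beat timestamps must be strictly increasing")

    @property
    def btb_s(self) -> np.ndarray:
        return np.diff(self.timestamps)

    def __len__(self) -> int:
        return self.timestamps.size


@dataclass
class InstantHRSeries:
    """Instantaneous heart rate, one value per retained beat after the first."""

    times: np.ndarray
    hr_bpm: np.ndarray

    def __len__(self) -> int:
        return self.times.size


def detect_ao_candidates(
    enh: EnhancedSignal,
    hr_bpm: Optional[float],
    min_frac: float = 0.75,
    height_frac: float = 0.3,
) -> np.ndarray:
    """AO candidate timestamps from one beat-variant enhanced window.

    Local maxima are admitted greedily in descending amplitude order (ties to
    the earlier sample) subject to a pairwise spacing of at least
    ``min_frac * 60 / hr_bpm`` seconds.  An adaptive floor rejects peaks below
    ``height_frac`` of the window's strongest peak, which suppresses residual
    edge ringing and aortic-closing echoes.  Without a heart-rate prior the
    beat stage cannot run and an empty list is returned.
    """
    if hr_bpm is None or hr_bpm <= 0:
        return np.empty(0)
    v = enh.values
    peaks, _ = find_peaks(v)
    peaks = peaks[v[peaks] > 0]
    if peaks.size == 0:
        return np.empty(0)
    floor = height_frac * v[peaks].max()
    peaks = peaks[v[peaks] >= floor]
    order = peaks[np.lexsort((peaks, -v[peaks]))]  # amplitude desc, earlier first
    min_gap = min_frac * 60.0 / hr_bpm * enh.fs
    accepted: list[int] = []
    for p in order:
        if all(abs(p - q) >= min_gap for q in accepted):
            accepted.append(p)
    accepted.sort()
    return enh.t0 + np.asarray(accepted, dtype=float) / enh.fs


def consolidate_candidates(
    per_window: Iterable[Sequence[float]], dedupe_tol: float = 0.1
) -> np.ndarray:
    """Merge candidate timestamps reported by multiple windows.

    Sorted timestamps are clustered by single linkage at ``dedupe_tol`` and
    each cluster collapses to its centroid.
    """
    pool = np.concatenate([np.asarray(ts, dtype=float) for ts in per_window]) \
        if per_window else np.empty(0)
    if pool.size == 0:
        return np.empty(0)
    pool.sort()
    out = []
    start = 0
    for i in range(1, pool.size + 1):
        if i == pool.size or pool[i] - pool[i - 1] > dedupe_tol:
            out.append(pool[start:i].mean())
            start = i
    return np.asarray(out)


def cross_verify(
    scg_ts: Sequence[float],
    gcg_ts: Sequence[float],
    tol: float = 0.025,
    permissive: bool = False,
) -> BeatList:
    """Retain SCG timestamps confirmed by a GCG peak within ``tol`` seconds.

    Matching is nearest-first and one-to-one (each GCG peak vouches for at
    most one SCG beat); SCG timing is authoritative for the retained beats.
    In permissive mode an empty GCG list passes every SCG candidate through,
    for recordings without a usable gyroscope channel.
    """
    scg = np.asarray(scg_ts, dtype=float)
    gcg = np.asarray(gcg_ts, dtype=float)
    if gcg.size == 0:
        kept = scg if permissive else np.empty(0)
        return BeatList(timestamps=np.sort(kept), axis_of_origin="aZ")
    pairs = []
    for i, t in enumerate(scg):
        j0 = int(np.searchsorted(gcg, t))
        for j in (j0 - 1, j0):
            if 0 <= j < gcg.size and abs(gcg[j] - t) <= tol:
                pairs.append((abs(gcg[j] - t), i, j))
    pairs.sort()
    used_s: set[int] = set()
    used_g: set[int] = set()
    kept_idx = []
    for _, i, j in pairs:
        if i not in used_s and j not in used_g:
            used_s.add(i)
            used_g.add(j)
            kept_idx.append(i)
    kept_idx.sort()
    return BeatList(timestamps=scg[kept_idx], axis_of_origin="fused")


def enforce_min_spacing(ts: np.ndarray, min_spacing: float) -> np.ndarray:
    """Greedy keep-first pass dropping beats closer than ``min_spacing``."""
    out: list[float] = []
    for t in np.sort(np.asarray(ts, dtype=float)):
        if not out or t - out[-1] >= min_spacing:
            out.append(t)
    return np.asarray(out)


def instantaneous_hr(beats: BeatList) -> InstantHRSeries:
    """Inverse BTB interval, aligned to the later beat of each pair."""
    ts = beats.timestamps
    if ts.size < 2:
        return InstantHRSeries(times=np.empty(0), hr_bpm=np.empty(0))
    btb = np.diff(ts)
    return InstantHRSeries(times=ts[1:], hr_bpm=60.0 / btb)
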