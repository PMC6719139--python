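"""Offline replay of the real-time detection workflow.

``process_recording`` walks the rolling buffers of a recording and, per
refresh cycle, runs the heart-rate stage (resample, high-pass, centered
VarWin, windowed autocorrelation, axis consolidation) followed by the beat
stage (forward-looking VarWin, spacing-constrained peak admission over all
window sizes).  Candidates accumulated across buffers are deduplicated,
cross-verified between the aZ and gX axes and reduced to the final beat list
with its instantaneous heart-rate series.  Replay is fully deterministic:
identical recording and configuration give identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
import pandas as pd

from .beat_detect import (BeatList, InstantHRSeries, consolidate_candidates,
                          cross_verify, detect_ao_candidates,
                          enforce_min_spacing, instantaneous_hr)
from .config import RunConfig
from .errors import InsufficientDataError, VcgError
from .hr_autocorr import HRMeasurement, consolidate_axes, estimate_axis_hr
from .preprocess import UniformSignal, highpass_brickwall, resample_uniform
from .signal_io import RawRecording, stream_buffers
from .varwin import varwin_beat, varwin_hr

log = logging.getLogger(__name__)


@dataclass
class DetectionResult:
    """Everything one replay produces."""

    measurements: List[HRMeasurement]
    beats: BeatList
    instant: InstantHRSeries
    scg_candidates: np.ndarray
    gcg_candidates: np.ndarray
    mode: str = "vcg"

    def hr_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": [m.time for m in self.measurements],
                "hr_bpm": [m.hr_bpm for m in self.measurements],
                "hr_scg": [m.hr_scg for m in self.measurements],
                "hr_gcg": [m.hr_gcg for m in self.measurements],
                "source": [m.source for m in self.measurements],
            }
        )

    def beat_frame(self) -> pd.DataFrame:
        ts = self.beats.timestamps
        hr = np.full(ts.size, np.nan)
        if ts.size >= 2:
            hr[1:] = 60.0 / np.diff(ts)
        return pd.DataFrame({"timestamp_s": ts, "instantaneous_hr_bpm": hr})


def prepare_axis(seg, channel: str, cfg: RunConfig, negate: bool = False
                 ) -> Optional[UniformSignal]:
    """Resample and high-pass one buffered channel; None when unusable."""
    if not seg.has_channel(channel):
        return None
    try:
        sig = resample_uniform(seg, channel, cfg.target_fs)
    except (InsufficientDataError, VcgError) as exc:
        log.warning("buffer at %.1f s: %s unusable (%s)", seg.window_end, channel, exc)
        return None
    if negate:
        sig.values = -sig.values
    return highpass_brickwall(sig, cfg.highpass_hz)


def _beat_candidates(enh, hr_bpm, cfg: RunConfig) -> list[np.ndarray]:
    """AO candidates from each trailing window of one enhanced buffer."""
    out = []
    n = enh.values.size
    for w_s in cfg.window_sizes:
        m = min(n, int(round(w_s * enh.fs)))
        from .varwin import EnhancedSignal

        sliced = EnhancedSignal(values=enh.values[n - m :], fs=enh.fs,
                                t0=enh.t0 + (n - m) / enh.fs,
                                variant=enh.variant, span_ms=enh.span_ms)
        out.append(detect_ao_candidates(sliced, hr_bpm, cfg.min_frac,
                                        cfg.beat_height_frac))
    return out


def process_recording(
    rec: RawRecording, cfg: Optional[RunConfig] = None, mode: str = "vcg"
) -> DetectionResult:
    """Replay the full detection workflow over one recording.

    ``mode`` selects the axes in play: ``vcg`` (both, with cross-
    verification), ``scg`` (aZ only, beats pass unverified) or ``gcg``
    (-gX only).
    """
    cfg = cfg or RunConfig()
    if mode not in ("vcg", "scg", "gcg"):
        raise ValueError(f"unknown mode {mode!r}")
    use_scg = mode in ("vcg", "scg")
    use_gcg = mode in ("vcg", "gcg")

    measurements: List[HRMeasurement] = []
    scg_lists: list[np.ndarray] = []
    gcg_lists: list[np.ndarray] = []
    prev_hr: Optional[float] = None
    locked = False  # prev-HR feedback engages after the first dual agreement

    for seg in stream_buffers(rec, cfg.buffer_span, cfg.step):
        axis_hr = {"aZ": None, "gX": None}
        axis_sig = {}
        for axis, negate, wanted in (("aZ", False, use_scg), ("gX", True, use_gcg)):
            if not wanted:
                continue
            sig = prepare_axis(seg, axis, cfg, negate=negate)
            if sig is None:
                continue
            axis_sig[axis] = sig
            enh = varwin_hr(sig, cfg.varwin_span_ms)
            axis_hr[axis], _ = estimate_axis_hr(
                enh, cfg.window_sizes, cfg.hr_bounds, axis=axis,
                prom_floor=cfg.prom_floor, amp_ratio=cfg.amp_ratio,
                harmonic_tol=cfg.harmonic_tol,
            )
        m = consolidate_axes(axis_hr["aZ"], axis_hr["gX"], prev_hr,
                             cfg.hr_tolerance, time=seg.window_end)
        measurements.append(m)
        if m.source == "both-agree":
            locked = True
        if m.present and (locked or mode != "vcg"):
            prev_hr = m.hr_bpm

        if m.present:
            for axis, pool in (("aZ", scg_lists), ("gX", gcg_lists)):
                if axis in axis_sig:
                    enh_b = varwin_beat(axis_sig[axis], cfg.varwin_span_ms,
                                        cfg.suppress_ms, cfg.suppress_prom_frac)
                    pool.extend(_beat_candidates(enh_b, m.hr_bpm, cfg))
        else:
            log.info("no heart rate at %.1f s; beat stage skipped", seg.window_end)

    scg_cand = consolidate_candidates(scg_lists, cfg.dedupe_tol)
    gcg_cand = consolidate_candidates(gcg_lists, cfg.dedupe_tol)

    floor_spacing = cfg.min_frac * 60.0 / cfg.hr_bounds[1]
    if mode == "gcg":
        beats = BeatList(timestamps=enforce_min_spacing(gcg_cand, floor_spacing),
                         axis_of_origin="gX")
    elif mode == "scg":
        beats = BeatList(timestamps=enforce_min_spacing(scg_cand, floor_spacing),
                         axis_of_origin="aZ")
    else:
        permissive = cfg.permissive_gcg and gcg_cand.size == 0
        verified = cross_verify(scg_cand, gcg_cand, cfg.cross_tol,
                                permissive=permissive)
        beats = BeatList(
            timestamps=enforce_min_spacing(verified.timestamps, floor_spacing),
            axis_of_origin=verified.axis_of_origin,
        )
    return DetectionResult(measurements=measurements, beats=beats,
                           instant=instantaneous_hr(beats),
                           scg_candidates=scg_cand, gcg_candidates=gcg_cand,
                           mode=mode)


def reference_rpeaks(rec: RawRecording, cfg: Optional[RunConfig] = None):
    """Pan-Tompkins R-peaks from the whole ECG channel (reference path)."""
    from .ecg_ref import pan_tompkins
    from .signal_io import BufferSegment

    cfg = cfg or RunConfig()
    if not rec.has_channel("ecg"):
        raise KeyError("recording has no ECG channel")
    whole = BufferSegment(recording=rec, start=0, stop=rec.timestamps.size,
                          window_end=float(rec.timestamps[-1]),
                          buffer_span=rec.duration, step=rec.duration)
    sig = resample_uniform(whole, "ecg", cfg.target_fs)
    return pan_tompkins(sig)
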