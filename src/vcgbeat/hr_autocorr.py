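"""Averaged heart rate from windowed autocorrelation of the enhanced waveform.

One buffer yields, per vibration axis (dorsoventral acceleration aZ and the
negated longitudinal gyration -gX), up to nine window estimates: the most
recent n seconds (n = 2..10) of the VarWin-enhanced waveform are
autocorrelated and the dominant beat-to-beat (BTB) lag is extracted.  The
window estimates are fused by a weighted mean with weights inversely
proportional to the window size, prioritizing the freshest data, and finally
the two axes are consolidated with a previous-measurement feedback rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
from scipy.signal import correlate, find_peaks

from .errors import ParameterError
from .varwin import EnhancedSignal

#: Physiological heart-rate bounds in bpm (configurable; generous around the
#: 36-140 bpm range the detector is designed for).
DEFAULT_BOUNDS = (30.0, 200.0)

#: Candidate peaks must reach this prominence, relative to the zero-lag
#: autocorrelation, to count as a BTB hypothesis.
DEFAULT_PROM_FLOOR = 0.3

#: Candidate peaks whose amplitude falls below this fraction of the strongest
#: candidate are rejected — this is what filters aortic-closing (AC) echoes,
#: whose autocorrelation peaks are systematically weaker than the true BTB
#: peak, out of the shortest-lag preference.
DEFAULT_AMP_RATIO = 0.9

#: Relative tolerance when checking that integer multiples of a candidate lag
#: also carry autocorrelation peaks (harmonic disambiguation).
DEFAULT_HARMONIC_TOL = 0.05

#: Axis-consolidation tolerance in bpm.
DEFAULT_TOLERANCE_BPM = 10.0

#: Window sizes in seconds.
DEFAULT_WINDOWS = tuple(range(2, 11))


@dataclass
class WindowEstimate:
    """Heart-rate estimate from one (axis, window-size) pair.

    ``hr_bpm``/``btb_s`` are ``None`` when no autocorrelation peak passes the
    acceptance rules (an absent estimate, not an error).
    """

    window_s: float
    axis: str
    hr_bpm: Optional[float]
    btb_s: Optional[float]
    confidence: float = 0.0

    @property
    def present(self) -> bool:
        return self.hr_bpm is not None


@dataclass
class HRMeasurement:
    """One refresh-cycle heart-rate output with per-axis provenance.

    ``source`` is one of ``both-agree``, ``scg-selected``, ``gcg-selected``,
    ``carry-forward`` or ``none``.
    """

    time: float
    hr_bpm: Optional[float]
    hr_scg: Optional[float]
    hr_gcg: Optional[float]
    source: str
    prev_hr: Optional[float] = None

    @property
    def present(self) -> bool:
        return self.hr_bpm is not None


def hr_from_window(
    enh: EnhancedSignal,
    bounds: Tuple[float, float] = DEFAULT_BOUNDS,
    *,
    window_s: Optional[float] = None,
    axis: str = "",
    prom_floor: float = DEFAULT_PROM_FLOOR,
    amp_ratio: float = DEFAULT_AMP_RATIO,
    harmonic_tol: float = DEFAULT_HARMONIC_TOL,
) -> WindowEstimate:
    """Estimate the BTB interval of one enhanced window by autocorrelation.

    The mean-removed waveform is autocorrelated with unbiased normalization
    and peaks are sought for lags between ``60/bounds[1]`` seconds and
    ``min(60/bounds[0], half the window)``.  Candidate selection: peaks below
    ``prom_floor`` of the zero-lag value or below ``amp_ratio`` of the
    strongest candidate are discarded; among the survivors the shortest lag
    whose integer multiples (within ``harmonic_tol`` relative tolerance) also
    carry peaks wins, which resists half- and double-rate errors.  The chosen
    lag is refined by parabolic interpolation.
    """
    lo, hi = bounds
    if lo <= 0 or hi <= lo:
        raise ParameterError(f"inverted or non-positive bounds {bounds}")
    x = np.asarray(enh.values, dtype=float)
    n = x.size
    fs = enh.fs
    if window_s is None:
        window_s = n / fs
    absent = WindowEstimate(window_s=window_s, axis=axis, hr_bpm=None, btb_s=None)
    if n < 4 or not np.any(x != 0):
        return absent
    x = x - x.mean()
    r = correlate(x, x, mode="full", method="fft")[n - 1 :]
    r = r / (n - np.arange(n))  # unbiased normalization
    r0 = r[0]
    if r0 <= 0:
        return absent
    lag_min = int(math.ceil(60.0 / hi * fs))
    lag_cap_s = min(60.0 / lo, 0.5 * n / fs)
    lag_max = int(math.floor(lag_cap_s * fs))
    if lag_max - lag_min < 2:
        return absent
    search = r[: lag_max + 1]
    cand_idx, _ = find_peaks(search, prominence=prom_floor * r0)
    cand_idx = cand_idx[cand_idx >= lag_min]
    if cand_idx.size == 0:
        return absent
    support_idx, _ = find_peaks(search, prominence=0.05 * r0)
    support_idx = support_idx[support_idx >= lag_min]
    amp_max = r[cand_idx].max()
    eligible = [k for k in cand_idx if r[k] >= amp_ratio * amp_max]
    best = None
    for k in sorted(eligible):
        if _harmonics_supported(k, support_idx, lag_max, harmonic_tol):
            best = k
            break
    if best is None:
        return absent
    lag = _parabolic_refine(r, best) / fs
    hr = 60.0 / lag
    if not (lo <= hr <= hi):
        return absent
    prominences, _, _ = _peak_prominence(search, best)
    return WindowEstimate(window_s=window_s, axis=axis, hr_bpm=hr, btb_s=60.0 / hr,
                          confidence=float(prominences / r0))


def _harmonics_supported(lag, support_idx, lag_max, tol) -> bool:
    """All integer multiples of ``lag`` up to 0.9 * lag_max must carry a
    support peak; multiples beyond the search range pass vacuously."""
    limit = 0.9 * lag_max
    m = 2
    while m * lag <= limit:
        target = m * lag
        if not np.any(np.abs(support_idx - target) <= tol * target):
            return False
        m += 1
    return True


def _parabolic_refine(r: np.ndarray, k: int) -> float:
    if k <= 0 or k >= r.size - 1:
        return float(k)
    denom = r[k - 1] - 2.0 * r[k] + r[k + 1]
    if denom == 0:
        return float(k)
    delta = 0.5 * (r[k - 1] - r[k + 1]) / denom
    return float(k + np.clip(delta, -0.5, 0.5))


def _peak_prominence(x: np.ndarray, k: int) -> tuple[float, int, int]:
    from scipy.signal import peak_prominences

    prom, lb, rb = peak_prominences(x, [k])
    return float(prom[0]), int(lb[0]), int(rb[0])


def fuse_windows(estimates: Sequence[WindowEstimate]) -> Optional[float]:
    """Weighted mean of the present window estimates, weights 1/window_size.

    Returns ``None`` when every estimate is absent.  All estimates must come
    from one axis.
    """
    axes = {e.axis for e in estimates}
    if len(axes) > 1:
        raise ParameterError(f"mixed axes in fuse_windows: {sorted(axes)}")
    num = den = 0.0
    for e in estimates:
        if e.present:
            w = 1.0 / e.window_s
            num += w * e.hr_bpm
            den += w
    return num / den if den > 0 else None


def consolidate_axes(
    hr_scg: Optional[float],
    hr_gcg: Optional[float],
    prev_hr: Optional[float],
    tolerance: float = DEFAULT_TOLERANCE_BPM,
    time: float = float("nan"),
) -> HRMeasurement:
    """Fuse the per-axis heart rates with the previous-measurement feedback.

    Decision table: both present and within ``tolerance`` bpm -> average
    (``both-agree``); both present but discordant -> the one closer to
    ``prev_hr`` (ties and a missing ``prev_hr`` resolve to the SCG value);
    one present -> that one; neither present -> carry the previous value
    forward, or an absent measurement when there is none.
    """
    if tolerance <= 0:
        raise ParameterError("tolerance must be > 0")
    if hr_scg is not None and hr_gcg is not None:
        if abs(hr_scg - hr_gcg) <= tolerance:
            return HRMeasurement(time, (hr_scg + hr_gcg) / 2.0, hr_scg, hr_gcg,
                                 "both-agree", prev_hr)
        if prev_hr is None or abs(hr_scg - prev_hr) <= abs(hr_gcg - prev_hr):
            return HRMeasurement(time, hr_scg, hr_scg, hr_gcg, "scg-selected", prev_hr)
        return HRMeasurement(time, hr_gcg, hr_scg, hr_gcg, "gcg-selected", prev_hr)
    if hr_scg is not None:
        return HRMeasurement(time, hr_scg, hr_scg, None, "scg-selected", prev_hr)
    if hr_gcg is not None:
        return HRMeasurement(time, hr_gcg, None, hr_gcg, "gcg-selected", prev_hr)
    if prev_hr is not None:
        return HRMeasurement(time, prev_hr, None, None, "carry-forward", prev_hr)
    return HRMeasurement(time, None, None, None, "none", prev_hr)


def run_hr_pipeline(seg, prev_hr: Optional[float], cfg=None) -> HRMeasurement:
    """One refresh cycle of the heart-rate stage on a buffer segment.

    Orchestrates resampling, high-pass filtering, centered VarWin enhancement
    and windowed autocorrelation for the aZ and -gX axes, fuses the window
    estimates per axis and consolidates the two axes against ``prev_hr``.
    Axes with missing channels or insufficient data yield absent estimates
    rather than errors, so SCG-only (or GCG-only) recordings degrade
    gracefully.
    """
    from .config import RunConfig
    from .pipeline import prepare_axis

    cfg = cfg or RunConfig()
    hr_axis = {}
    for axis, negate in (("aZ", False), ("gX", True)):
        sig = prepare_axis(seg, axis, cfg, negate=negate)
        if sig is None:
            hr_axis[axis] = None
            continue
        from .varwin import varwin_hr

        enh = varwin_hr(sig, cfg.varwin_span_ms)
        hr_axis[axis], _ = estimate_axis_hr(
            enh, cfg.window_sizes, cfg.hr_bounds, axis=axis,
            prom_floor=cfg.prom_floor, amp_ratio=cfg.amp_ratio,
            harmonic_tol=cfg.harmonic_tol,
        )
    return consolidate_axes(hr_axis["aZ"], hr_axis["gX"], prev_hr,
                            cfg.hr_tolerance, time=seg.window_end)


def estimate_axis_hr(
    enh: EnhancedSignal,
    windows: Iterable[float] = DEFAULT_WINDOWS,
    bounds: Tuple[float, float] = DEFAULT_BOUNDS,
    axis: str = "",
    **kwargs,
) -> tuple[Optional[float], list[WindowEstimate]]:
    """Run ``hr_from_window`` over trailing windows of ``enh`` and fuse them."""
    estimates = []
    n = enh.values.size
    for w_s in windows:
        m = min(n, int(round(w_s * enh.fs)))
        sliced = EnhancedSignal(values=enh.values[n - m :], fs=enh.fs,
                                t0=enh.t0 + (n - m) / enh.fs,
                                variant=enh.variant, span_ms=enh.span_ms,
                                channel_id=enh.channel_id)
        estimates.append(
            hr_from_window(sliced, bounds, window_s=float(w_s), axis=axis, **kwargs)
        )
    return fuse_windows(estimates), estimates
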