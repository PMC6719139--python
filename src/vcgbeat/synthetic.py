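"""Ground-truth-annotated synthetic ECG + SCG + GCG recordings.

The generator emulates the statistical structure the detector relies on:
quasi-periodic beat trains with Gaussian heart-rate variability and
respiratory sinus arrhythmia, an optional exponentially decaying recovery
profile, ECG PQRST complexes, sternal vibration packets with S1 (AO-IC) and
S2 (AC-MO) structure on the aZ and gX axes, sub-0.4 Hz baseline wander,
broadband noise at a configurable SNR and acquisition timestamp jitter.
Every draw is fixed by the seed, so identical configurations reproduce
bit-identical recordings.

The S2 complex is placed 0.3 s after the aortic opening with a relative
amplitude of 0.5 on aZ but only 0.2 on gX: the gyration axis carries far less
second-heart-sound crosstalk, which is the asymmetry the SCG/GCG fusion
logic exploits.  The aortic opening itself is modeled as the R-peak time plus
a fixed 100 ms pre-ejection delay.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Tuple

import numpy as np

from .errors import ParameterError
from .signal_io import RawRecording


@dataclass
class SimConfig:
    duration: float = 60.0        # s
    fs: float = 250.0             # Hz, nominal acquisition rate
    mean_hr: float = 70.0         # bpm (ignored when hr_trend is set)
    hrv_sd: float = 0.03          # Gaussian RR jitter, fraction of RR
    resp_rate: float = 0.25       # Hz, respiration frequency
    resp_mod: float = 0.05        # fractional RR modulation depth
    #: optional recovery profile (start bpm, end bpm, time constant s)
    hr_trend: Optional[Tuple[float, float, float]] = None
    pep_delay: float = 0.10       # s, R-peak to aortic opening
    s2_offset: float = 0.30       # s, AO to AC complex
    # per-axis template amplitudes (physiological orders of magnitude)
    scg_amp: float = 0.02         # g, aZ S1 packet peak
    gcg_amp: float = 3.0          # deg/s, gX S1 packet peak
    ecg_amp: float = 1.0          # mV, R-peak
    s2_rel_scg: float = 0.5       # S2 amplitude relative to S1 on aZ
    s2_rel_gcg: float = 0.2       # ... on gX (deliberately smaller)
    s1_freq: float = 18.0         # Hz, packet oscillation frequency
    s1_sigma_pre: float = 0.012   # s, envelope width before the AO maximum
    s1_sigma_post: float = 0.05   # s, envelope width after it
    wander_frac: float = 0.5      # baseline wander amplitude / packet amplitude
    noise_snr_db: float = 15.0    # broadband noise level vs cardiac signal RMS
    jitter_sd: float = 0.0005     # s, timestamp jitter
    seed: int = 0

    def validate(self) -> None:
        if self.duration <= 0 or self.fs <= 0 or self.mean_hr <= 0:
            raise ParameterError("duration, fs and mean_hr must be > 0")
        if self.hrv_sd < 0 or self.resp_mod < 0:
            raise ParameterError("hrv_sd and resp_mod must be >= 0")


@dataclass
class GroundTruth:
    """True beat times: R-peaks and the derived aortic openings."""

    r_times: np.ndarray
    ao_times: np.ndarray
    rr_s: np.ndarray = field(init=False)
    instantaneous_hr: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.r_times = np.asarray(self.r_times, dtype=float)
        self.ao_times = np.asarray(self.ao_times, dtype=float)
        self.rr_s = np.diff(self.r_times)
        self.instantaneous_hr = 60.0 / self.rr_s if self.rr_s.size else np.empty(0)


def generate_beat_times(cfg: SimConfig) -> GroundTruth:
    """Draw the beat schedule.

    ``RR_k = base_RR(t_k) * (1 + hrv_sd * eps_k)
    * (1 + resp_mod * sin(2 pi resp_rate t_k))`` with standard-normal
    ``eps_k`` under the seed; ``base_RR`` comes from ``mean_hr`` or the
    exponential recovery profile.  The first beat falls at t = 0.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    times = []
    t = 0.0
    while t < cfg.duration:
        times.append(t)
        rr = _base_rr(cfg, t)
        rr *= 1.0 + cfg.hrv_sd * rng.standard_normal()
        rr *= 1.0 + cfg.resp_mod * np.sin(2.0 * np.pi * cfg.resp_rate * t)
        if rr <= 0:
            raise ParameterError("parameters imply a non-positive RR interval")
        t += rr
    r = np.asarray(times)
    # every annotated aortic opening must be fully rendered: drop trailing
    # beats whose S1 complex would spill past the end of the recording
    r = r[r + cfg.pep_delay + 2.0 * cfg.s1_sigma_post <= cfg.duration]
    return GroundTruth(r_times=r, ao_times=r + cfg.pep_delay)


def _base_rr(cfg: SimConfig, t: float) -> float:
    if cfg.hr_trend is None:
        return 60.0 / cfg.mean_hr
    start, end, tau = cfg.hr_trend
    hr = end + (start - end) * np.exp(-t / tau)
    return 60.0 / hr


def _packet(tau: np.ndarray, freq: float, s_pre: float, s_post: float) -> np.ndarray:
    """Asymmetric Gabor packet: cosine carrier with a sharp leading and slow
    trailing Gaussian envelope, so the first extremum is the dominant maximum."""
    sigma = np.where(tau < 0, s_pre, s_post)
    return np.exp(-(tau * tau) / (2.0 * sigma * sigma)) * np.cos(2.0 * np.pi * freq * tau)


#: ECG bump library: (center offset s, width s, amplitude) for P Q R S T.
_ECG_BUMPS = ((-0.20, 0.025, 0.12), (-0.030, 0.010, -0.15), (0.0, 0.012, 1.0),
              (0.030, 0.010, -0.20), (0.25, 0.045, 0.30))


def _add_events(out: np.ndarray, t: np.ndarray, centers: np.ndarray,
                shape, half_width: float) -> None:
    for c in centers:
        lo = int(np.searchsorted(t, c - half_width))
        hi = int(np.searchsorted(t, c + half_width))
        if hi > lo:
            out[lo:hi] += shape(t[lo:hi] - c)


def synthesize_recording(
    cfg: SimConfig, gt: Optional[GroundTruth] = None
) -> tuple[RawRecording, GroundTruth]:
    """Render a recording (all seven channels) for a beat schedule."""
    cfg.validate()
    if gt is None:
        gt = generate_beat_times(cfg)
    rng = np.random.default_rng(cfg.seed + 1)
    n = int(round(cfg.duration * cfg.fs))
    t = np.arange(n) / cfg.fs
    jitter = np.clip(rng.normal(0.0, cfg.jitter_sd, n),
                     -0.45 / cfg.fs, 0.45 / cfg.fs)
    timestamps = t + jitter  # strictly increasing: |jitter| < half the spacing

    def s1s2(tau: np.ndarray, s2_rel: float) -> np.ndarray:
        return _packet(tau, cfg.s1_freq, cfg.s1_sigma_pre, cfg.s1_sigma_post)

    half = 4.0 * cfg.s1_sigma_post + 0.1

    ecg = np.zeros(n)
    for off, width, amp in _ECG_BUMPS:
        _add_events(ecg, timestamps, gt.r_times + off,
                    lambda d, w=width, a=amp: a * np.exp(-(d * d) / (2 * w * w)),
                    4.0 * width)
    ecg *= cfg.ecg_amp

    az = np.zeros(n)
    _add_events(az, timestamps, gt.ao_times, lambda d: s1s2(d, 0.0), half)
    _add_events(az, timestamps, gt.ao_times + cfg.s2_offset,
                lambda d: cfg.s2_rel_scg * s1s2(d, 0.0), half)
    az *= cfg.scg_amp

    gx = np.zeros(n)
    _add_events(gx, timestamps, gt.ao_times, lambda d: s1s2(d, 0.0), half)
    _add_events(gx, timestamps, gt.ao_times + cfg.s2_offset,
                lambda d: cfg.s2_rel_gcg * s1s2(d, 0.0), half)
    gx *= -cfg.gcg_amp  # the beat signature rides on -gX

    channels = {"ecg": ecg, "aZ": az, "gX": gx}
    # secondary axes: attenuated, slightly delayed copies of the main packets
    for name, source, scale, delay in (("aX", az, 0.35, 0.012), ("aY", az, 0.25, 0.02),
                                       ("gY", gx, 0.4, 0.01), ("gZ", gx, 0.3, 0.015)):
        shift = int(round(delay * cfg.fs))
        channels[name] = scale * np.roll(source, shift)

    for name, x in channels.items():
        rms = float(np.sqrt(np.mean(x * x)))
        if rms > 0:
            amp = float(np.max(np.abs(x)))
            x = x + _baseline_wander(timestamps, cfg.wander_frac * amp, rng)
            x = x + rng.normal(0.0, rms * 10 ** (-cfg.noise_snr_db / 20.0), n)
        channels[name] = x

    meta = {"subject": "synthetic", "condition": "recovery" if cfg.hr_trend else "rest",
            "fs": cfg.fs, "sim_config": asdict(cfg)}
    return RawRecording(timestamps=timestamps, channels=channels, meta=meta), gt


def _baseline_wander(t: np.ndarray, amp: float, rng) -> np.ndarray:
    """Slow drift strictly below the 0.4 Hz high-pass cutoff."""
    phases = rng.uniform(0.0, 2.0 * np.pi, 3)
    return amp * (0.6 * np.sin(2 * np.pi * 0.15 * t + phases[0])
                  + 0.3 * np.sin(2 * np.pi * 0.09 * t + phases[1])
                  + 0.3 * np.sin(2 * np.pi * 0.33 * t + phases[2]))


def write_ground_truth(gt: GroundTruth, path) -> None:
    """Two-column CSV of true R and AO times."""
    import pandas as pd

    pd.DataFrame({"r_time_s": gt.r_times, "ao_time_s": gt.ao_times}).to_csv(
        path, index=False
    )


def read_ground_truth(path) -> GroundTruth:
    import pandas as pd

    frame = pd.read_csv(path)
    return GroundTruth(r_times=frame["r_time_s"].to_numpy(),
                       ao_times=frame["ao_time_s"].to_numpy())
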