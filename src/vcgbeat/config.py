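"""Run configuration: every tunable parameter of the detection workflow.

Defaults reproduce the published operating point of the algorithm: a 10 s
rolling buffer refreshed at 1 Hz, resampling to 200 Hz, a 0.4 Hz brick-wall
high-pass, a 250 ms VarWin span, analysis windows of 2-10 s, a 10 bpm
axis-consolidation tolerance, beat spacing at 75% of the BTB interval, a
25 ms SCG/GCG cross-verification tolerance and a 250 ms reference-matching
tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, fields
from typing import Optional, Tuple

import yaml


@dataclass
class RunConfig:
    # rolling buffer
    buffer_span: float = 10.0        # s of signal per measurement
    step: float = 1.0                # s between refreshes
    # preprocessing
    target_fs: float = 200.0         # Hz, uniform resampling rate
    highpass_hz: float = 0.4         # Hz, brick-wall cutoff
    # VarWin
    varwin_span_ms: float = 250.0
    suppress_ms: Optional[float] = None   # None -> varwin_span_ms
    suppress_prom_frac: float = 0.6
    # heart-rate estimation
    window_sizes: Tuple[float, ...] = tuple(float(n) for n in range(2, 11))
    hr_bounds: Tuple[float, float] = (30.0, 200.0)
    hr_tolerance: float = 10.0       # bpm, axis-consolidation tolerance
    prom_floor: float = 0.3
    amp_ratio: float = 0.9
    harmonic_tol: float = 0.05
    # beat detection
    min_frac: float = 0.75           # of the BTB interval, minimum peak spacing
    beat_height_frac: float = 0.3    # adaptive floor: fraction of the window max
    dedupe_tol: float = 0.1          # s, cross-window duplicate merging
    cross_tol: float = 0.025         # s, SCG/GCG cross-verification
    permissive_gcg: bool = False     # pass SCG beats unverified if gyro absent
    # evaluation
    ref_match_tol: float = 0.25      # s, detection-vs-reference matching

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        for name in ("window_sizes", "hr_bounds"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg
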