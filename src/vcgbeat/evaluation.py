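"""Scoring of detected beats against a reference annotation.

Detections and reference beats are matched one-to-one within a tolerance
window (250 ms by default) by an optimal assignment: maximum number of
matches, minimum total time offset among maximum matchings.  Matched pairs
are true positives, unmatched detections false positives, unmatched
references false negatives — true negatives are meaningless for event
detection and are not defined.  From the counts follow the true positive
rate TPR = TP / (TP + FN) and the positive predictive value
PPV = TP / (TP + FP); agreement of paired heart-rate values is summarized by
the squared Pearson correlation and Bland-Altman 95% limits of agreement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.stats import pearsonr

from .errors import UndefinedStatisticError

_BIG = 1e9  # cost of an infeasible pairing; dwarfs any sum of feasible costs


def _times(obj) -> np.ndarray:
    ts = getattr(obj, "timestamps", obj)
    return np.asarray(ts, dtype=float)


@dataclass
class EvalCounts:
    """TP/FP/FN tallies from tolerance-window matching."""

    n_ref: int
    tp: int
    fp: int
    fn: int
    tol: float
    #: matched (detection index, reference index) pairs, sorted by detection
    pairs: list = field(default_factory=list, repr=False)


@dataclass
class AgreementSummary:
    """Correlation and Bland-Altman statistics for paired bpm values."""

    r2: float
    mean_diff: float
    loa_low: float
    loa_high: float
    n_pairs: int


def match_beats(detected, reference, tol: float = 0.25) -> EvalCounts:
    """Optimal one-to-one matching of detections to reference beats.

    A pairing is feasible when the absolute time offset is at most ``tol``
    seconds.  The assignment maximizes the number of matched pairs and,
    among such assignments, minimizes the total offset, which makes the
    result identical to an exhaustive search on small instances.
    """
    det = _times(detected)
    ref = _times(reference)
    if tol <= 0:
        raise UndefinedStatisticError("matching tolerance must be > 0")
    if det.size == 0 or ref.size == 0:
        return EvalCounts(n_ref=ref.size, tp=0, fp=det.size, fn=ref.size, tol=tol)
    cost = np.abs(det[:, None] - ref[None, :])
    cost[cost > tol] = _BIG
    rows, cols = linear_sum_assignment(cost)
    pairs = sorted(
        (int(i), int(j)) for i, j in zip(rows, cols) if cost[i, j] < _BIG
    )
    tp = len(pairs)
    return EvalCounts(n_ref=ref.size, tp=tp, fp=det.size - tp, fn=ref.size - tp,
                      tol=tol, pairs=pairs)


def tpr(c: EvalCounts) -> float:
    """Sensitivity: the proportion of reference beats that were detected."""
    if c.tp + c.fn == 0:
        raise UndefinedStatisticError("TPR undefined: no reference beats")
    return c.tp / (c.tp + c.fn)


def ppv(c: EvalCounts) -> float:
    """Precision: the likelihood that a detected beat is correct."""
    if c.tp + c.fp == 0:
        raise UndefinedStatisticError("PPV undefined: no detections")
    return c.tp / (c.tp + c.fp)


def paired_hr_series(
    detected, reference, counts: EvalCounts
) -> Tuple[np.ndarray, np.ndarray]:
    """Instantaneous heart-rate pairs from runs of consecutive true positives.

    For every adjacent pair of detections matched to an adjacent pair of
    references, the inverse AO-AO interval is paired with the inverse R-R
    interval; intervals broken by an intervening FP or FN are dropped.
    Returns ``(detected_bpm, reference_bpm)``.
    """
    det = _times(detected)
    ref = _times(reference)
    x, y = [], []
    for (i0, j0), (i1, j1) in zip(counts.pairs, counts.pairs[1:]):
        if i1 == i0 + 1 and j1 == j0 + 1:
            x.append(60.0 / (det[i1] - det[i0]))
            y.append(60.0 / (ref[j1] - ref[j0]))
    return np.asarray(x), np.asarray(y)


def agreement(x: Sequence[float], y: Sequence[float]) -> AgreementSummary:
    """Squared Pearson correlation plus Bland-Altman limits of agreement.

    ``mean_diff`` is the mean of ``x - y``; the limits are
    ``mean_diff +/- 1.96 * sd(x - y)`` with the sample (n-1) standard
    deviation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise UndefinedStatisticError("agreement needs >= 3 paired values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError("agreement undefined for constant input")
    r = pearsonr(x, y).statistic
    diff = x - y
    mean_diff = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return AgreementSummary(r2=float(r * r), mean_diff=mean_diff,
                            loa_low=mean_diff - 1.96 * sd,
                            loa_high=mean_diff + 1.96 * sd, n_pairs=x.size)


def averaged_hr_reference(
    rpeak_times: Sequence[float], refresh_times: Sequence[float], span: float = 10.0
) -> np.ndarray:
    """Reference averaged heart rate at each refresh instant.

    The mean inverse R-R interval over the trailing ``span`` seconds, NaN
    when fewer than two R-peaks fall inside the window.  This mirrors how the
    detector's own averaged output summarizes its buffer.
    """
    rp = np.asarray(rpeak_times, dtype=float)
    out = np.full(len(refresh_times), np.nan)
    for k, t in enumerate(refresh_times):
        inside = rp[(rp > t - span) & (rp <= t)]
        if inside.size >= 2:
            out[k] = float(np.mean(60.0 / np.diff(inside)))
    return out
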