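"""Beat segmentation and per-beat peak velocities.

The cardiac cycle length is estimated from the autocorrelation of the traced
velocity curve (a standard trick from ECG analysis); that estimate then sets
the minimum distance between detected peaks so noise spikes are not mistaken
for s', e' or a'. Each positive (systolic) peak anchors one beat; the early-
and late-diastolic peaks are the first and last negative peaks of the beat
interval.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .calibration import Calibration
from .envelope import FilterParams, VelocityTrace, trace_strip
from .errors import BeatError

# Plausible adult heart-rate band used to bound the autocorrelation search.
MIN_BPM = 30.0
MAX_BPM = 180.0


@dataclass(frozen=True)
class CycleEstimate:
    period_s: float
    period_px: int
    confidence: float               # autocorrelation peak / lag-0 value, in [0, 1]


@dataclass(frozen=True)
class PeakCandidate:
    column: int
    velocity_cm_s: float
    sign: int                       # +1 systolic, -1 diastolic


@dataclass(frozen=True)
class BeatMeasurement:
    """One beat's peak annular velocities.

    e' and a' are stored signed (negative, below-baseline deflections);
    ``a_prime_cm_s``/``t_a`` are None when the beat shows a single fused
    diastolic peak.
    """

    beat_index: int
    s_prime_cm_s: float
    e_prime_cm_s: float
    a_prime_cm_s: float | None
    t_s: float
    t_e: float
    t_a: float | None
    convention: str
    confident: bool = True


def estimate_cycle_length(trace: VelocityTrace, cal: Calibration) -> CycleEstimate:
    """Cardiac cycle length from the mean-removed, biased autocorrelation.

    The highest autocorrelation maximum whose lag lies in the 30-180 beats/min
    band gives the period; confidence is that maximum normalized by the lag-0
    value. Raises when the trace is flat or no maximum falls in the band.
    """
    x = trace.velocity_cm_s - trace.velocity_cm_s.mean()
    n = x.size
    min_lag = int(np.ceil(60.0 / MAX_BPM / cal.sec_per_px))
    max_lag = int(np.floor(60.0 / MIN_BPM / cal.sec_per_px))
    if n < 2 * min_lag:
        raise BeatError("trace too short for cycle estimation")
    r = signal.correlate(x, x, mode="full")[n - 1:] / n   # biased estimator
    if r[0] <= 0:
        raise BeatError("cycle length not found")
    max_lag = min(max_lag, n - 1)
    peaks, _ = signal.find_peaks(r)
    peaks = peaks[(peaks >= min_lag) & (peaks <= max_lag)]
    if peaks.size == 0:
        raise BeatError("cycle length not found")
    best = peaks[np.argmax(r[peaks])]         # ties -> smallest lag via argmax
    return CycleEstimate(period_s=float(best * cal.sec_per_px),
                         period_px=int(best),
                         confidence=float(np.clip(r[best] / r[0], 0.0, 1.0)))


def _prune(cands: list[PeakCandidate], min_dist_px: float) -> list[PeakCandidate]:
    """Greedy minimum-distance pruning, keeping the larger |velocity|
    (ties: the earlier column)."""
    order = sorted(cands, key=lambda p: (-abs(p.velocity_cm_s), p.column))
    kept: list[PeakCandidate] = []
    for p in order:
        if all(abs(p.column - q.column) >= min_dist_px for q in kept):
            kept.append(p)
    return sorted(kept, key=lambda p: p.column)


def detect_peaks(trace: VelocityTrace, cycle: CycleEstimate,
                 min_distance_frac: float = 0.6,
                 min_height_frac: float = 0.1) -> list[PeakCandidate]:
    """Candidate s' and e'/a' peaks with cycle-aware distance pruning.

    Positive peaks (local maxima above baseline) must be at least
    ``min_distance_frac x period`` apart; negative peaks use half that
    fraction, since two diastolic peaks share each cycle. Peaks smaller than
    ``min_height_frac`` of the trace's largest |velocity| are discarded as
    noise ripples (e.g. residual wiggle where the blanked zero-axis line
    crosses the trace).
    """
    v = trace.velocity_cm_s
    floor = min_height_frac * np.abs(v).max()
    pos_idx, _ = signal.find_peaks(v)
    neg_idx, _ = signal.find_peaks(-v)
    pos = [PeakCandidate(int(i), float(v[i]), +1) for i in pos_idx if v[i] > floor]
    neg = [PeakCandidate(int(i), float(v[i]), -1) for i in neg_idx if v[i] < -floor]
    pos = _prune(pos, min_distance_frac * cycle.period_px)
    neg = _prune(neg, 0.5 * min_distance_frac * cycle.period_px)
    return sorted(pos + neg, key=lambda p: p.column)


def classify_peaks(candidates: list[PeakCandidate], cycle: CycleEstimate,
                   cal: Calibration, convention: str = "middle",
                   confident: np.ndarray | None = None,
                   trace_len: int | None = None) -> list[BeatMeasurement]:
    """Assign candidates to beats as s', e', a'.

    Each positive candidate anchors a beat spanning the half-open interval to
    the next positive candidate (the last beat extends one period). Within the
    interval the first negative candidate is e' and the last distinct one a';
    a single negative candidate is a fused e' (a' absent). Beats with no e'
    are dropped, as are beats whose interval is truncated by the strip edge.
    """
    pos = [p for p in candidates if p.sign > 0]
    neg = [p for p in candidates if p.sign < 0]
    if not pos:
        raise BeatError("no beats detected")
    beats: list[BeatMeasurement] = []
    for i, anchor in enumerate(pos):
        start = anchor.column
        if i + 1 < len(pos):
            end = pos[i + 1].column
        else:
            end = start + cycle.period_px
            if trace_len is not None and end > trace_len:
                break                            # truncated final beat: drop
        inside = [q for q in neg if start <= q.column < end]
        if not inside:
            continue
        e = inside[0]
        a = inside[-1] if len(inside) > 1 else None
        ok = True
        if confident is not None:
            cols = [anchor.column, e.column] + ([a.column] if a else [])
            ok = all(bool(confident[c]) for c in cols)
        beats.append(BeatMeasurement(
            beat_index=len(beats),
            s_prime_cm_s=anchor.velocity_cm_s,
            e_prime_cm_s=e.velocity_cm_s,
            a_prime_cm_s=a.velocity_cm_s if a else None,
            t_s=anchor.column * cal.sec_per_px,
            t_e=e.column * cal.sec_per_px,
            t_a=a.column * cal.sec_per_px if a else None,
            convention=convention,
            confident=ok))
    if not beats:
        raise BeatError("no beats detected")
    return beats


def _peak_confidence(valid: np.ndarray, window: int) -> np.ndarray:
    """Per-column flag: False where more than half the surrounding window was
    interpolated rather than traced."""
    kernel = np.ones(window) / window
    frac_valid = np.convolve(valid.astype(float), kernel, mode="same")
    return frac_valid >= 0.5


def measure_strip(strip: np.ndarray, cal: Calibration, convention: str = "middle",
                  params: FilterParams = FilterParams(),
                  min_distance_frac: float = 0.6,
                  min_height_frac: float = 0.1) -> list[BeatMeasurement]:
    """The full pipeline for one strip and one tracing convention:
    threshold -> clean -> extract -> smooth -> cycle -> peaks -> beats.

    Deterministic: identical inputs give identical output.
    """
    trace = trace_strip(strip, cal, convention, params)
    cycle = estimate_cycle_length(trace, cal)
    cands = detect_peaks(trace, cycle, min_distance_frac, min_height_frac)
    conf = _peak_confidence(trace.valid, params.sg_window_px)
    return classify_peaks(cands, cycle, cal, convention, conf,
                          trace_len=trace.velocity_cm_s.size)


def beats_to_frame(beats: list[BeatMeasurement]) -> pd.DataFrame:
    """Long-format table of beat measurements (one row per beat)."""
    return pd.DataFrame([{
        "beat_index": b.beat_index,
        "convention": b.convention,
        "s_prime_cm_s": b.s_prime_cm_s,
        "e_prime_cm_s": b.e_prime_cm_s,
        "a_prime_cm_s": b.a_prime_cm_s if b.a_prime_cm_s is not None else np.nan,
        "t_s": b.t_s,
        "t_e": b.t_e,
        "t_a": b.t_a if b.t_a is not None else np.nan,
        "confident": b.confident,
    } for b in beats])
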