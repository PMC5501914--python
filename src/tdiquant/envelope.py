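"""Envelope extraction: from a calibrated Doppler strip to per-column velocity
traces at the middle and outer edge of the spectral band.

The middle of the envelope is the modal (brightest) velocity of each column
after low-pass filtering; the outer edge is the sharpest drop in filtered
intensity moving outward from the middle, i.e. the boundary of the spectral
band farthest from the baseline.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .calibration import Calibration, rows_to_velocity
from .errors import EnvelopeError


@dataclass(frozen=True)
class FilterParams:
    """Tunables for the column filter and trace smoother.

    The column low-pass is a zero-phase Butterworth applied along the row
    (velocity) axis of each column; cutoff is a fraction of the column
    Nyquist. Trace smoothing is Savitzky-Golay over columns.
    """

    butterworth_order: int = 2
    butterworth_cutoff: float = 0.1
    sg_window_px: int = 15
    sg_poly_order: int = 3
    axis_halfwidth_px: int = 2

    def __post_init__(self) -> None:
        if self.butterworth_order < 1:
            raise ValueError("butterworth_order must be >= 1")
        if not 0 < self.butterworth_cutoff < 1:
            raise ValueError("butterworth_cutoff must be in (0, 1) x Nyquist")
        if self.sg_window_px % 2 == 0 or self.sg_window_px <= self.sg_poly_order:
            raise ValueError("sg_window_px must be odd and > sg_poly_order")
        if self.axis_halfwidth_px < 0:
            raise ValueError("axis_halfwidth_px must be >= 0")


@dataclass(frozen=True)
class BinarizedStrip:
    mask: np.ndarray                # boolean, True = trace foreground
    threshold_used: int
    axis_halfwidth_px: int


@dataclass(frozen=True)
class VelocityTrace:
    """Per-column velocity in cm/s for one tracing convention.

    ``valid`` is False where the column held no foreground pixels; such
    columns carry values linearly interpolated from the nearest valid
    neighbours.
    """

    velocity_cm_s: np.ndarray
    valid: np.ndarray
    convention: str                 # "middle" | "outer"
    smoothed: bool = False

    def __post_init__(self) -> None:
        if self.velocity_cm_s.shape != self.valid.shape:
            raise ValueError("velocity and validity lengths differ")
        if self.convention not in ("middle", "outer"):
            raise ValueError(f"unknown convention {self.convention!r}")


def otsu_threshold(strip: np.ndarray) -> int:
    """Otsu's threshold on the 256-bin histogram of an 8-bit image.

    Returns the integer t in [0, 255] maximizing the between-class variance
    of the split {<= t} / {> t}; ties broken by the smallest t. Pixels are
    binned at their integer intensity.
    """
    strip = np.asarray(strip)
    hist = np.bincount(strip.astype(np.uint8).ravel(), minlength=256).astype(float)
    total = hist.sum()
    if np.count_nonzero(hist) < 2:
        raise EnvelopeError("degenerate histogram")
    levels = np.arange(256, dtype=float)
    w0 = np.cumsum(hist)                      # class {<= t}
    m0 = np.cumsum(hist * levels)
    w1 = total - w0
    mu_total = m0[-1] / total
    with np.errstate(divide="ignore", invalid="ignore"):
        mean0 = m0 / w0
        mean1 = (m0[-1] - m0) / w1
        between = w0 * w1 * (mean0 - mean1) ** 2
    between = np.where((w0 > 0) & (w1 > 0), between, -np.inf)
    return int(np.argmax(between))            # argmax takes the smallest index on ties


def binarize_and_clean(strip: np.ndarray, threshold: int, cal: Calibration,
                       axis_halfwidth_px: int = 2) -> BinarizedStrip:
    """Foreground mask ``intensity > threshold`` with the zero-axis line
    blanked: rows within ``axis_halfwidth_px`` of the baseline are forced to
    background so the bright axis cannot masquerade as signal."""
    if not 0 <= threshold <= 255:
        raise EnvelopeError("threshold must be in 0-255")
    strip = np.asarray(strip)
    mask = strip > threshold
    lo = max(0, cal.zero_row - axis_halfwidth_px)
    hi = min(strip.shape[0], cal.zero_row + axis_halfwidth_px + 1)
    mask[lo:hi, :] = False
    return BinarizedStrip(mask=mask, threshold_used=int(threshold),
                          axis_halfwidth_px=axis_halfwidth_px)


def filter_column(column: np.ndarray, order: int = 2, cutoff: float = 0.1) -> np.ndarray:
    """Zero-phase low-pass Butterworth filter of one column's intensities.

    Applied forward-backward (filtfilt) so the response has no phase lag and
    unit DC gain: a constant column passes through unchanged.
    """
    column = np.asarray(column, dtype=float)
    padlen = 3 * (order + 1)
    if column.shape[-1] <= padlen:
        raise EnvelopeError("column too short to filter")
    b, a = signal.butter(order, cutoff)
    return signal.filtfilt(b, a, column, axis=-1)


def _interp_invalid(values: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Fill invalid entries by linear interpolation from the nearest valid
    neighbours (edge invalid runs take the nearest valid value)."""
    if valid.all():
        return values
    if not valid.any():
        return np.zeros_like(values)
    idx = np.arange(values.size)
    out = values.astype(float).copy()
    out[~valid] = np.interp(idx[~valid], idx[valid], values[valid])
    return out


def _filtered_columns(bin_strip: BinarizedStrip, raw_strip: np.ndarray,
                      params: FilterParams) -> np.ndarray:
    """Mask the raw intensities (background -> 0) and low-pass each column
    along the row axis."""
    masked = np.where(bin_strip.mask, np.asarray(raw_strip, dtype=float), 0.0)
    b, a = signal.butter(params.butterworth_order, params.butterworth_cutoff)
    padlen = 3 * (params.butterworth_order + 1)
    if masked.shape[0] <= padlen:
        raise EnvelopeError("column too short to filter")
    return signal.filtfilt(b, a, masked, axis=0)


def extract_middle(bin_strip: BinarizedStrip, raw_strip: np.ndarray,
                   cal: Calibration,
                   params: FilterParams = FilterParams()) -> tuple[np.ndarray, np.ndarray]:
    """Per-column row index of the envelope middle (modal velocity).

    Each column's masked intensities are low-pass filtered and the argmax row
    taken. Exact ties go to the row nearest the previous column's middle (or
    the baseline for the first valid column). Columns with an all-background
    mask are invalid and filled by linear interpolation.

    Returns ``(rows, valid)`` with float rows.
    """
    if bin_strip.mask.shape != np.asarray(raw_strip).shape:
        raise EnvelopeError("mask and strip shapes differ")
    filtered = _filtered_columns(bin_strip, raw_strip, params)
    n_rows, n_cols = filtered.shape
    rows = np.zeros(n_cols)
    valid = bin_strip.mask.any(axis=0)
    prev: float | None = None
    for c in range(n_cols):
        if not valid[c]:
            continue
        col = filtered[:, c]
        peak = col.max()
        ties = np.flatnonzero(col == peak)
        if ties.size == 1:
            r = ties[0]
        else:
            anchor = prev if prev is not None else cal.zero_row
            r = ties[np.argmin(np.abs(ties - anchor))]
        rows[c] = r
        prev = float(r)
    rows = _interp_invalid(rows, valid)
    return rows, valid


def extract_outer(bin_strip: BinarizedStrip, raw_strip: np.ndarray,
                  middle_rows: np.ndarray, middle_valid: np.ndarray,
                  cal: Calibration,
                  params: FilterParams = FilterParams()) -> tuple[np.ndarray, np.ndarray]:
    """Per-column row index of the envelope's outer edge.

    From the middle row, step away from the zero axis (increasing |velocity|)
    through the contiguous foreground run containing the middle, plus one
    pixel beyond it; the edge is the inner pixel of the steepest consecutive
    intensity drop along that path (ties: nearest the middle). Columns where
    the middle is invalid stay invalid.
    """
    filtered = _filtered_columns(bin_strip, raw_strip, params)
    n_rows, n_cols = filtered.shape
    rows = np.zeros(n_cols)
    valid = middle_valid.copy()
    for c in range(n_cols):
        if not valid[c]:
            continue
        m = int(round(middle_rows[c]))
        m = min(max(m, 0), n_rows - 1)
        step = -1 if m < cal.zero_row else 1   # away from the baseline
        path = [m]
        r = m
        while True:
            nxt = r + step
            if nxt < 0 or nxt >= n_rows:
                break
            path.append(nxt)                    # include one pixel past the run
            if not bin_strip.mask[nxt, c]:
                break
            r = nxt
        if len(path) < 2:
            rows[c] = m
            continue
        prof = filtered[path, c]
        drops = prof[:-1] - prof[1:]
        i = int(np.argmax(drops))               # ties -> smallest i = nearest middle
        rows[c] = path[i]
    rows = _interp_invalid(rows, valid)
    return rows, valid


def smooth_trace(trace: VelocityTrace, window_px: int = 15,
                 poly_order: int = 3) -> VelocityTrace:
    """Savitzky-Golay smoothing of a velocity trace.

    Least-squares polynomial convolution: polynomials of degree <= poly_order
    pass through unchanged. Validity flags are preserved.
    """
    if window_px % 2 == 0 or window_px <= poly_order:
        raise EnvelopeError("window must be odd and exceed poly_order")
    if trace.velocity_cm_s.size < window_px:
        raise EnvelopeError("trace too short")
    smoothed = signal.savgol_filter(trace.velocity_cm_s, window_px, poly_order,
                                    mode="interp")
    return replace(trace, velocity_cm_s=smoothed, smoothed=True)


def trace_strip(strip: np.ndarray, cal: Calibration, convention: str,
                params: FilterParams = FilterParams(),
                smooth: bool = True) -> VelocityTrace:
    """Full envelope stage: threshold, clean, extract (per convention),
    convert to velocity, smooth. Returns a :class:`VelocityTrace`."""
    thr = otsu_threshold(strip)
    bin_strip = binarize_and_clean(strip, thr, cal, params.axis_halfwidth_px)
    mid_rows, mid_valid = extract_middle(bin_strip, strip, cal, params)
    if convention == "middle":
        rows, valid = mid_rows, mid_valid
    elif convention == "outer":
        rows, valid = extract_outer(bin_strip, strip, mid_rows, mid_valid, cal, params)
    else:
        raise EnvelopeError(f"unknown convention {convention!r}")
    trace = VelocityTrace(velocity_cm_s=rows_to_velocity(rows, cal),
                          valid=valid, convention=convention)
    if smooth and trace.velocity_cm_s.size >= params.sg_window_px:
        trace = smooth_trace(trace, params.sg_window_px, params.sg_poly_order)
    return trace
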