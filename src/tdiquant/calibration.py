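"""Locating the Doppler trace inside a captured frame and mapping pixels to
physical units.

A pulsed-wave tissue-Doppler screen capture contains the spectrogram itself
plus text, ECG preview and menu areas. This module scores candidate crop
regions to find the spectrogram, finds the bright zero-velocity baseline
(the brightest horizontal line), reads the axis scales either by
template-matching OCR of tick labels or from a plain-text sidecar, and
converts row indices to velocities.

Conventions: 0-based indices, row 0 at the top, half-open crop regions,
velocities above the baseline (smaller row index) are positive.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import CalibrationError


@dataclass(frozen=True)
class CropRegion:
    """Half-open pixel bounds ``[top_row, bottom_row) x [left_col, right_col)``."""

    top_row: int
    left_col: int
    bottom_row: int
    right_col: int

    def __post_init__(self) -> None:
        if not (self.bottom_row > self.top_row and self.right_col > self.left_col):
            raise ValueError("degenerate crop region")
        if min(self.top_row, self.left_col) < 0:
            raise ValueError("crop region outside frame")

    @property
    def height(self) -> int:
        return self.bottom_row - self.top_row

    @property
    def width(self) -> int:
        return self.right_col - self.left_col

    def extract(self, frame: np.ndarray) -> np.ndarray:
        if self.bottom_row > frame.shape[0] or self.right_col > frame.shape[1]:
            raise ValueError("crop region outside frame")
        return frame[self.top_row:self.bottom_row, self.left_col:self.right_col]


@dataclass(frozen=True)
class Calibration:
    """Pixel-to-physical mapping for a cropped Doppler strip.

    Attributes
    ----------
    zero_row:
        0-based row index of the zero-velocity baseline within the strip.
    cm_per_px:
        Velocity scale, cm/s per pixel (row direction), strictly positive.
    sec_per_px:
        Time scale, seconds per pixel (column direction), strictly positive.
    """

    zero_row: int
    cm_per_px: float
    sec_per_px: float

    def __post_init__(self) -> None:
        if self.zero_row < 0:
            raise ValueError("zero_row must be non-negative")
        if not (self.cm_per_px > 0 and self.sec_per_px > 0):
            raise ValueError("scales must be strictly positive")


@dataclass(frozen=True)
class TickLabel:
    """One labelled axis tick: where its text sits and where the tick is.

    ``text_row``/``text_col`` give the top-left pixel of the rendered label;
    ``tick_px`` is the tick's pixel coordinate along its axis (a row index for
    velocity labels, a column index for time labels); ``value`` is the labelled
    physical value (cm/s or seconds).
    """

    text_row: int
    text_col: int
    tick_px: int
    value: float


def detect_layout_and_crop(frame: np.ndarray,
                           layout_templates: list[CropRegion],
                           min_score: float = 0.002) -> CropRegion:
    """Pick the candidate region most likely to contain the Doppler trace.

    Each candidate is scored by the fraction of its rows whose mean intensity
    exceeds the frame's global Otsu threshold — spectrogram rows are bright
    where the envelope passes, text/preview areas mostly are not. The highest
    scorer wins (ties: earliest candidate). A score floor guards against
    frames with no trace at all; the default demands only a baseline-like
    bright row or two, since row means in a mostly-dark spectrogram sit far
    below the pixel-level threshold.
    """
    from .envelope import otsu_threshold  # local import; envelope depends on this module

    frame = np.asarray(frame)
    if not layout_templates:
        raise CalibrationError("no candidate layouts provided")
    try:
        thr = otsu_threshold(frame)
    except Exception as exc:
        raise CalibrationError("no Doppler region found") from exc
    best: CropRegion | None = None
    best_score = -1.0
    for region in layout_templates:
        inner = region.extract(frame)
        score = float(np.mean(inner.mean(axis=1) > thr))
        if score > best_score:
            best, best_score = region, score
    if best is None or best_score < min_score:
        raise CalibrationError("no Doppler region found")
    return best


def detect_zero_axis(strip: np.ndarray) -> int:
    """Row index of the zero-velocity baseline: the row with the highest mean
    intensity (ties broken by the smallest row index)."""
    strip = np.asarray(strip)
    if strip.size == 0:
        raise CalibrationError("empty strip")
    return int(np.argmax(strip.mean(axis=1)))


def _ncc(patch: np.ndarray, template: np.ndarray) -> float:
    """Zero-mean normalized cross-correlation; 0 when either side is flat."""
    a = patch.astype(float) - patch.mean()
    b = template.astype(float) - template.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        return 0.0
    return float(np.dot(a.ravel(), b.ravel()) / denom)


def _read_label(frame: np.ndarray, row: int, col: int,
                glyphs: dict[str, np.ndarray],
                min_corr: float, max_chars: int = 8) -> str:
    """Greedy left-to-right glyph recognition starting at (row, col)."""
    from .glyphs import GLYPH_SPACING

    chars: list[str] = []
    c = col
    for _ in range(max_chars):
        best_ch, best_corr, best_w = None, min_corr, 0
        for ch, g in glyphs.items():
            h, w = g.shape
            if row + h > frame.shape[0] or c + w > frame.shape[1]:
                continue
            corr = _ncc(frame[row:row + h, c:c + w], g)
            if corr > best_corr:
                best_ch, best_corr, best_w = ch, corr, w
        if best_ch is None:
            break
        chars.append(best_ch)
        c += best_w + GLYPH_SPACING
    return "".join(chars)


def read_scale(frame: np.ndarray,
               glyph_templates: dict[str, np.ndarray],
               vel_ticks: list[TickLabel],
               time_ticks: list[TickLabel],
               min_corr: float = 0.7) -> tuple[float, float]:
    """Read the velocity and time axis scales from labelled ticks.

    For each tick the label text is recognized by maximizing normalized
    cross-correlation of the supplied glyph bitmaps at the expected position;
    the scale is the labelled-value span divided by the tick pixel span.
    Returns ``(cm_per_px, sec_per_px)``.
    """
    frame = np.asarray(frame)

    def axis_scale(ticks: list[TickLabel], axis_name: str) -> float:
        if len(ticks) < 2:
            raise CalibrationError("unreadable scale; supply calibration sidecar")
        values = []
        for t in ticks:
            text = _read_label(frame, t.text_row, t.text_col, glyph_templates, min_corr)
            try:
                read_value = float(text)
            except ValueError:
                raise CalibrationError(
                    "unreadable scale; supply calibration sidecar") from None
            if abs(read_value - t.value) > 1e-9:
                raise CalibrationError("unreadable scale; supply calibration sidecar")
            values.append(read_value)
        lo, hi = ticks[0], ticks[-1]
        if hi.tick_px == lo.tick_px:
            raise CalibrationError("unreadable scale; supply calibration sidecar")
        scale = abs(values[-1] - values[0]) / abs(hi.tick_px - lo.tick_px)
        if scale <= 0:
            raise CalibrationError("unreadable scale; supply calibration sidecar")
        return scale

    return axis_scale(vel_ticks, "velocity"), axis_scale(time_ticks, "time")


def rows_to_velocity(row_indices: np.ndarray, cal: Calibration) -> np.ndarray:
    """Map per-column row positions to velocities in cm/s.

    ``v = (zero_row - row) * cm_per_px``: rows above the baseline map to
    positive velocities.
    """
    return (cal.zero_row - np.asarray(row_indices, dtype=float)) * cal.cm_per_px


def velocity_to_row(velocity_cm_s: np.ndarray, cal: Calibration) -> np.ndarray:
    """Inverse of :func:`rows_to_velocity` (float rows; round to draw)."""
    return cal.zero_row - np.asarray(velocity_cm_s, dtype=float) / cal.cm_per_px


def load_sidecar(path: str | Path) -> Calibration:
    """Read a plain-text ``key=value`` calibration sidecar.

    Required keys: ``zero_row`` (int), ``cm_per_px``, ``sec_per_px`` (floats).
    Blank lines and ``#`` comments are ignored.
    """
    values: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise CalibrationError(f"malformed sidecar line: {line!r}")
        key, _, val = line.partition("=")
        values[key.strip()] = val.strip()
    try:
        return Calibration(zero_row=int(values["zero_row"]),
                           cm_per_px=float(values["cm_per_px"]),
                           sec_per_px=float(values["sec_per_px"]))
    except KeyError as exc:
        raise CalibrationError(f"sidecar missing key {exc.args[0]!r}") from None


def save_sidecar(cal: Calibration, path: str | Path) -> None:
    Path(path).write_text(
        f"zero_row={cal.zero_row}\n"
        f"cm_per_px={cal.cm_per_px!r}\n"
        f"sec_per_px={cal.sec_per_px!r}\n")
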