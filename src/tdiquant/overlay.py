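"""Overlay rendering: traced envelopes and peak markers drawn back onto the
Doppler strip, for visual QC of the automated tracing."""
from __future__ import annotations

from pathlib import Path

import numpy as np

from .beats import BeatMeasurement
from .calibration import Calibration, velocity_to_row
from .envelope import VelocityTrace
from .io import write_image

TRACE_COLORS = {"middle": (60, 120, 255), "outer": (255, 60, 60)}
PEAK_COLORS = {"s": (60, 220, 60), "e": (60, 220, 220), "a": (220, 60, 220)}
MARKER_HALF = 2                     # 5x5 hollow square markers


def _draw_square(rgb: np.ndarray, row: int, col: int, color: tuple[int, int, int]) -> None:
    h, w = rgb.shape[:2]
    r0, r1 = row - MARKER_HALF, row + MARKER_HALF
    c0, c1 = col - MARKER_HALF, col + MARKER_HALF
    for r in range(max(r0, 0), min(r1 + 1, h)):
        for c in range(max(c0, 0), min(c1 + 1, w)):
            if r in (r0, r1) or c in (c0, c1):
                rgb[r, c] = color


def render_overlay(strip: np.ndarray, traces: list[VelocityTrace],
                   beats: list[BeatMeasurement], cal: Calibration,
                   out_path: str | Path) -> np.ndarray:
    """Write (and return) an RGB image: the strip in gray, the middle trace
    in blue, the outer trace in red, and per-peak square markers (s' green,
    e' cyan, a' magenta) at their reported (time, velocity) positions."""
    gray = np.asarray(strip, dtype=np.uint8)
    rgb = np.stack([gray] * 3, axis=-1)
    h, w = gray.shape
    for trace in traces:
        rows = np.rint(velocity_to_row(trace.velocity_cm_s, cal)).astype(int)
        cols = np.arange(rows.size)
        ok = (rows >= 0) & (rows < h) & (cols < w)
        rgb[rows[ok], cols[ok]] = TRACE_COLORS[trace.convention]
    for b in beats:
        marks = [("s", b.t_s, b.s_prime_cm_s), ("e", b.t_e, b.e_prime_cm_s)]
        if b.a_prime_cm_s is not None:
            marks.append(("a", b.t_a, b.a_prime_cm_s))
        for kind, t, v in marks:
            col = int(round(t / cal.sec_per_px))
            row = int(round(float(velocity_to_row(np.array([v]), cal)[0])))
            if 0 <= row < h and 0 <= col < w:
                _draw_square(rgb, row, col, PEAK_COLORS[kind])
    write_image(rgb, out_path)
    return rgb
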