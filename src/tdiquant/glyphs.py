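"""A small 5x7 bitmap font for axis-label rendering and template-matching OCR.

Real vendor fonts are proprietary; scale read-out works against *user-supplied*
glyph bitmaps. This module provides a synthetic font covering the characters
axis labels need (digits, minus sign, decimal point) so that the render → OCR
round trip is fully testable. Glyphs are uint8 arrays with ink = 255.
"""
from __future__ import annotations

import numpy as np

_GLYPH_ROWS: dict[str, tuple[str, ...]] = {
    "0": ("01110", "10001", "10011", "10101", "11001", "10001", "01110"),
    "1": ("00100", "01100", "00100", "00100", "00100", "00100", "01110"),
    "2": ("01110", "10001", "00001", "00010", "00100", "01000", "11111"),
    "3": ("11111", "00010", "00100", "00010", "00001", "10001", "01110"),
    "4": ("00010", "00110", "01010", "10010", "11111", "00010", "00010"),
    "5": ("11111", "10000", "11110", "00001", "00001", "10001", "01110"),
    "6": ("00110", "01000", "10000", "11110", "10001", "10001", "01110"),
    "7": ("11111", "00001", "00010", "00100", "01000", "01000", "01000"),
    "8": ("01110", "10001", "10001", "01110", "10001", "10001", "01110"),
    "9": ("01110", "10001", "10001", "01111", "00001", "00010", "01100"),
    "-": ("00000", "00000", "00000", "11111", "00000", "00000", "00000"),
    ".": ("00000", "00000", "00000", "00000", "00000", "01100", "01100"),
}

GLYPH_HEIGHT = 7
GLYPH_WIDTH = 5
GLYPH_SPACING = 1  # blank columns between glyphs when rendering


def default_glyphs() -> dict[str, np.ndarray]:
    """Return the built-in glyph set as ``{char: uint8 bitmap}``."""
    return {
        ch: (np.array([[int(c) for c in row] for row in rows], dtype=np.uint8) * 255)
        for ch, rows in _GLYPH_ROWS.items()
    }


def render_text(canvas: np.ndarray, row: int, col: int, text: str,
                glyphs: dict[str, np.ndarray] | None = None,
                intensity: int = 255) -> None:
    """Stamp ``text`` onto ``canvas`` (in place) with its top-left at (row, col)."""
    if glyphs is None:
        glyphs = default_glyphs()
    c = col
    for ch in text:
        g = glyphs[ch]
        h, w = g.shape
        patch = canvas[row:row + h, c:c + w]
        if patch.shape != g.shape:
            raise ValueError(f"text {text!r} does not fit on canvas at ({row}, {col})")
        np.maximum(patch, (g > 0) * np.uint8(intensity), out=patch)
        c += w + GLYPH_SPACING


def text_width(text: str) -> int:
    n = len(text)
    return n * GLYPH_WIDTH + (n - 1) * GLYPH_SPACING if n else 0
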