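"""Axis-scale read-out by template-matching OCR.

Renders a frame whose velocity and time axes carry tick labels from the
built-in glyph set, then recovers the cm/s-per-pixel and s-per-pixel scales
by normalized cross-correlation against those glyphs — the fallback when no
calibration sidecar is supplied.
"""
import numpy as np

import tdiquant as tq
from tdiquant.glyphs import default_glyphs, render_text

frame = np.zeros((300, 500), dtype=np.uint8)
vel_ticks, time_ticks = [], []
for value, row in [(5, 60), (-5, 160)]:          # +/-5 cm/s, 100 px apart
    render_text(frame, row - 3, 10, f"{value:g}")
    vel_ticks.append(tq.TickLabel(text_row=row - 3, text_col=10,
                                  tick_px=row, value=value))
for value, col in [(0, 50), (1, 300)]:           # 0 s and 1 s, 250 px apart
    render_text(frame, 280, col, f"{value:g}")
    time_ticks.append(tq.TickLabel(text_row=280, text_col=col,
                                   tick_px=col, value=value))

cm_per_px, sec_per_px = tq.read_scale(frame, default_glyphs(),
                                      vel_ticks, time_ticks)
print(f"velocity scale: {cm_per_px:.3f} cm/s per pixel  (10 cm/s over 100 px)")
print(f"time scale:     {sec_per_px:.4f} s per pixel     (1 s over 250 px)")
print("a 4 cm/s peak 40 px above the baseline maps back to "
      f"{40 * cm_per_px:.1f} cm/s")
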