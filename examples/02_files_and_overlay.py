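"""The file-based workflow: strip image + calibration sidecar + overlay.

Writes a synthetic strip to PNG with its plain-text calibration sidecar,
reads both back (as one would with a real screen-capture strip), measures
the beats and renders a QC overlay with the traces and peak markers.
"""
import tempfile
from pathlib import Path

import tdiquant as tq

work = Path(tempfile.mkdtemp())
strip, cal, _ = tq.simulate(seed=8)
tq.write_image(strip.pixels, work / "strip.png")
tq.save_sidecar(cal, work / "strip.cal")

loaded = tq.read_image(work / "strip.png")
cal2 = tq.load_sidecar(work / "strip.cal")
beats = tq.measure_strip(loaded.pixels, cal2, "middle")
traces = [tq.trace_strip(loaded.pixels, cal2, c) for c in ("middle", "outer")]
tq.render_overlay(loaded.pixels, traces, beats, cal2, work / "overlay.png")

print(f"analyzed {loaded.meta['path']}: {len(beats)} beats")
print(f"first beat: s'={beats[0].s_prime_cm_s:.2f} cm/s at t={beats[0].t_s:.2f} s, "
      f"e'={beats[0].e_prime_cm_s:.2f}, a'={beats[0].a_prime_cm_s:.2f} cm/s")
print(f"overlay written to {work / 'overlay.png'} "
      "(blue = middle trace, red = outer edge, squares = detected peaks)")
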