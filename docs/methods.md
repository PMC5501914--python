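# Methods

## Problem and scope

A pulsed-wave tissue-Doppler spectrogram is a 2-D grayscale raster: rows are
velocity (row 0 at the top, a bright horizontal line at zero velocity),
columns are time. The package recovers, per cardiac beat, the peak systolic
(s′, positive) and early/late diastolic (e′, a′, negative) annular
velocities, traced at two conventions — the *middle* of the spectral band
(its modal, brightest velocity) and its *outer edge* (the band boundary
farthest from the baseline). In-scope inputs are single-frame DICOM
secondary captures and pre-reconstructed PNG/TIFF strips; live video
capture, color/multi-gate Doppler, aliasing unwrapping and atrial
fibrillation (irregular-rhythm) segmentation are out of scope.

## Coordinate and sign conventions

0-based indices, half-open crop regions, velocities above the baseline
(smaller row index) positive: `v = (zero_row − row) · cm_per_px`. e′ and a′
are carried as signed (negative) values; CSV output keeps the sign so
magnitude and direction are both recoverable. All stages are deterministic —
identical input, identical output, bit for bit.

## Calibration

- **Layout detection**: candidate crop regions (user-supplied; a vendor
  template library is deliberately not shipped) are scored by the fraction
  of region rows whose mean intensity exceeds the frame's global Otsu
  threshold; the best-scoring region wins. The acceptance floor defaults to
  0.002 — in a mostly-dark spectrogram only baseline-like rows exceed a
  pixel-level threshold, so the floor demands little more than one bright
  row while an empty or trace-free frame still fails.
- **Zero axis**: the row with the greatest mean intensity; ties go to the
  smallest row index.
- **Scale read-out**: tick labels are recognized by greedy left-to-right
  template matching (zero-mean normalized cross-correlation, so uniform
  brightness changes are irrelevant) against user-supplied glyph bitmaps;
  the scale is the labelled-value span over the tick pixel span. A small
  synthetic 5×7 font (digits, minus, point) ships for rendering and testing;
  real vendor fonts can be supplied as bitmaps. A plain-text sidecar
  (`zero_row`, `cm_per_px`, `sec_per_px`) always overrides OCR and is the
  recommended path for images with unknown fonts.

## Envelope extraction

- **Otsu threshold**: implemented directly on the 256-bin histogram
  (between-class variance, smallest threshold on ties) so the tie-break is
  explicit and testable against a brute-force search. Foreground is
  `intensity > t`; rows within `axis_halfwidth_px` (default 2) of the zero
  axis are forced to background, removing the baseline.
- **Column filter**: order-2 Butterworth, cutoff 0.1 × the column's Nyquist,
  run forward–backward (zero phase, unit DC gain) over the masked
  intensities of each column. Both parameters are exposed in the config; the
  defaults trade noise suppression against peak flattening and were fixed
  once against the synthetic generator's defaults.
- **Middle**: per-column argmax of the filtered masked intensity. Exact ties
  resolve to the row nearest the previous column's middle (first column: the
  baseline) for temporal continuity. Columns whose mask is empty are flagged
  invalid and filled by linear interpolation between valid neighbours.
- **Outer edge**: from the middle row, stepping away from the baseline
  through the contiguous foreground run (plus one pixel beyond it), the edge
  is the inner pixel of the largest drop between consecutive filtered
  intensities; equal drops resolve nearest the middle. Confining the search
  to the contiguous run keeps speckle islands beyond the band from
  attracting the edge.
- **Smoothing**: Savitzky–Golay, window 15 columns, order 3 (exposed in
  config), applied to the velocity trace; polynomial sections up to cubic
  pass through unchanged. Smoothing acts on velocities rather than row
  indices — the two differ only by an affine map.

## Beat segmentation

The mean-removed, biased autocorrelation of the trace is searched for its
highest local maximum at lags corresponding to 30–180 beats/min; the lag is
the cycle length and the peak's height relative to lag 0 is a confidence in
[0, 1]. Peak candidates are local maxima of the trace (and of its negation)
taller than `min_height_frac` (default 0.1) of the trace's largest |v| —
residual ripple where the blanked axis crosses the trace is otherwise
detected as a peak, which is precisely the noise-spike failure mode the
minimum-distance rule exists to prevent. Same-sign candidates closer than
`min_distance_frac` × period (default 0.6; halved for negative peaks, since
e′ and a′ share a cycle) are pruned keeping the larger |v|, earlier column
on ties. Each positive candidate anchors a beat spanning the half-open
interval to the next positive candidate (the last beat extends one estimated
period; if that interval runs past the strip the beat is dropped as
truncated). The first negative candidate inside the interval is e′, the last
distinct one a′; a single negative candidate is reported as a fused e′ with
a′ absent, and beats with no negative candidate are dropped. A beat is
flagged low-confidence when more than half of the columns in a
smoothing-window neighbourhood of any of its peaks were interpolated rather
than traced.

## Synthetic generator

The waveform is a sum of Gaussian pulses per beat — s′ positive, e′ and a′
negative — with per-beat period drawn as `period·(1 + N(0, jitter))`
(clipped to ±50%). Defaults: period 0.8 s (75 beats/min), jitter 5%,
amplitudes 8/10/8 cm/s, pulse σ 50/45/45 ms, phases 0.18/0.48/0.80 of the
cycle — mid-range normal adult septal annular velocities, and amplitude
parameters span the full observed physiological ranges used by the recovery
studies (s′ 1.3–11.5 cm/s). A quiet span of 0.25 period follows the final
beat, as recordings do not end on a cycle boundary. Truth (peak values =
amplitudes, peak times = pulse centres) is analytic; parameter sets whose
overlapping pulses would shift any apex by more than 5% are rejected as
ambiguous.

Rendering: per column at its time stamp, band intensity over rows is a
Gaussian centred on the true velocity (σ = the band half-width, 1 cm/s
default, modelling spectral broadening) times a sigmoidal cutoff at ±the
half-width (softness 2 px), times multiplicative lognormal speckle (unit
mean, σ 0.3 — the standard ultrasound speckle approximation), plus additive
Gaussian background noise (σ 8 of 255), plus the bright baseline row.
Intensities clip to 0–255. One global seed spawns independent sub-seeds for
waveform jitter and rendering noise, so the waveform can be held fixed while
noise is re-rolled. Ground truth carries the per-column band-centre
velocity, the outer-edge velocity (centre + signed half-width, the rendered
cutoff), and a band mask defined at the full-width-half-maximum of the
noiseless profile — the pixels that are genuinely signal-bright; the soft
cutoff's outermost pixels are dim by construction and not part of the
nominal band.

What the generator does *not* emulate: aliasing wrap-around, FFT-derived
spectral texture (speckle is i.i.d. lognormal, real spectra are correlated),
ECG traces and on-screen annotation clutter, drop-out, arrhythmia. Passing
recovery tests therefore demonstrates correctness of the tracing logic under
a controlled, physiologically scaled image model — not clinical performance.

## Agreement statistics

Bland–Altman bias is `mean(a − b)`; the 95% limits of agreement are
bias ± 1.96 × sample SD (n−1 denominator) of the differences. R² comes from
ordinary least-squares regression of series a on series b (direction fixed
and documented; it matters only in pathological cases). Consensus across
raters is the per-beat mean; each rater is compared against the leave-one-
out consensus of the others, beats missing any of those raters excluded.
Beats are matched across raters by strip identity and nearest peak time
within 0.15 s (greedy, closest pairs first — equivalent to the optimal
assignment whenever time jitter is below half the tolerance, which holds for
plausible annotation error at physiological heart rates).

Variance decomposition assumes `y = beat + rater-by-beat effect (inter) +
reading noise (intra)`: the intra-operator SD is the RMS of within-rater
first-vs-repeat differences divided by √2 (each difference carries two
readings' noise); the inter-operator SD is the pooled across-rater SD of
per-beat rater means with the residual intra contribution (intra²/readings)
subtracted, floored at zero. Strata (wall × peak × convention) are estimated
separately and averaged unweighted. The intra share of variance is
intra²/(intra² + inter²). The Monte-Carlo recovery study simulates six
raters × two readings × 1000 beats: with only three raters the across-rater
variance carries two degrees of freedom per beat and a ±10% check on the
recovered inter-SD would be a 2σ coin-flip; six raters make it well-powered.

## Validation metrics and problem sizes

The acceptance script and test suite validate by parameter recovery at desk
scale: 100 images for threshold-oracle equivalence; 20 noiseless strips
(jitter and render noise off, amplitudes swept 4–11 cm/s) for exact
recovery; 50 default-noise strips sweeping s′ over 1.3–11.5 cm/s for
detection rate and measured-vs-true regression; 5 heart rates × 10 seeds for
cycle recovery; 1000 beats for variance recovery. Trace-MAE metrics score
only *traceable* columns — those whose true velocity lies outside the
blanked zero-axis band, since the axis-replacement step removes the signal
there by construction (the tracer then sits on a band shoulder a few pixels
away during diastasis; peak measurements are unaffected and are checked on
every beat without exclusions).

## Known limitations

- Irregular rhythms break the single-period assumption of both the
  autocorrelation estimate and the distance pruning.
- The outer-edge trace carries a small inward bias (~0.3 cm/s at defaults):
  the steepest filtered gradient sits just inside the rendered cutoff. The
  middle trace has no such bias.
- Near-zero velocities (within the blanked axis band) are untraceable by
  design; affected columns are interpolated and flagged through the
  confidence mechanism.
- OCR handles only fonts for which glyph bitmaps are supplied; the sidecar
  path is the robust alternative.
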