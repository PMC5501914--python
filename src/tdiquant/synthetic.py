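"""Synthetic tissue-Doppler strips with analytic ground truth.

Every stage of the pipeline is testable without patient data: a Gaussian-pulse
annular-velocity waveform (one positive systolic peak s', two negative
diastolic peaks e' and a' per beat, with beat-to-beat period jitter) is
rendered into a speckled spectrogram image with a bright zero-velocity
baseline, a soft-edged spectral band and additive background noise. The truth
(per-column band-centre and outer-edge velocities, per-beat peak values and
times, the band mask) is computed analytically before rendering.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .beats import BeatMeasurement
from .calibration import Calibration
from .errors import SyntheticError
from .io import DopplerStrip


@dataclass(frozen=True)
class WaveformParams:
    """Shape of the annular-velocity waveform.

    Amplitudes in cm/s (all positive; e'/a' are rendered as negative
    deflections), pulse widths in seconds (Gaussian sigma), phases as
    fractions of the cycle, ordered s < e < a. Defaults sit mid-range of
    normal adult septal annular velocities at a resting heart rate of 75
    beats/min.
    """

    period_s: float = 0.8
    jitter_frac: float = 0.05
    s_amp: float = 8.0
    e_amp: float = 10.0
    a_amp: float = 8.0
    s_width_s: float = 0.050
    e_width_s: float = 0.045
    a_width_s: float = 0.045
    s_phase: float = 0.18
    e_phase: float = 0.48
    a_phase: float = 0.80
    n_beats: int = 10
    # quiet span appended after the final beat, as a fraction of the period,
    # so the final cycle is fully on the strip (recordings do not stop on a
    # beat boundary)
    tail_frac: float = 0.25

    @classmethod
    def for_heart_rate(cls, bpm: float, **overrides) -> "WaveformParams":
        """Params for a given heart rate; pulse widths shrink proportionally
        below the default 75 beats/min so fast rhythms keep distinct peaks
        (systolic/diastolic durations shorten less than the cycle, so the
        scaling is clamped at half)."""
        period = 60.0 / bpm
        scale = float(np.clip(period / 0.8, 0.5, 1.0))
        base = cls()
        return cls(period_s=period,
                   s_width_s=base.s_width_s * scale,
                   e_width_s=base.e_width_s * scale,
                   a_width_s=base.a_width_s * scale,
                   **overrides)

    def __post_init__(self) -> None:
        if min(self.s_amp, self.e_amp, self.a_amp) <= 0:
            raise ValueError("amplitudes must be positive")
        if not (0 <= self.s_phase < self.e_phase < self.a_phase < 1):
            raise ValueError("phases must be ordered s < e < a within the cycle")
        if not 0 <= self.jitter_frac <= 0.2:
            raise ValueError("jitter_frac must lie in [0, 0.2]")
        if self.n_beats < 1:
            raise ValueError("need at least one beat")


@dataclass(frozen=True)
class RenderParams:
    """How the waveform is painted into a spectrogram image.

    ``band_halfwidth_cm_s`` models spectral broadening: the band extends that
    far either side of the true velocity, with a sigmoidal outer cutoff of
    width ``edge_softness_px``. Speckle is multiplicative lognormal (the
    standard ultrasound approximation); background noise additive Gaussian.
    """

    cm_per_px: float = 0.1
    sec_per_px: float = 0.004
    strip_height_px: int = 320
    baseline_row: int = 130
    band_halfwidth_cm_s: float = 1.0
    band_peak_intensity: float = 200.0
    edge_softness_px: float = 2.0
    speckle_sd: float = 0.3
    background_noise_sd: float = 8.0
    baseline_intensity: int = 255
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.cm_per_px, self.sec_per_px) <= 0:
            raise ValueError("scales must be positive")
        if min(self.band_halfwidth_cm_s, self.edge_softness_px, self.speckle_sd,
               self.background_noise_sd, self.band_peak_intensity) < 0:
            raise ValueError("widths and intensities must be non-negative")


@dataclass(frozen=True)
class BeatTruth:
    beat_index: int
    s_cm_s: float                   # positive
    e_cm_s: float                   # negative
    a_cm_s: float                   # negative
    t_s: float
    t_e: float
    t_a: float
    period_s: float = 0.8           # this beat's own (jittered) cycle length


@dataclass(frozen=True)
class Waveform:
    velocity: Callable[[np.ndarray], np.ndarray]
    duration_s: float
    beats: tuple[BeatTruth, ...]
    params: WaveformParams


@dataclass(frozen=True)
class GroundTruth:
    mid_velocity_cm_s: np.ndarray   # per column
    outer_velocity_cm_s: np.ndarray
    band_mask: np.ndarray           # boolean, rows x cols; FWHM of the clean band
    beats: tuple[BeatTruth, ...]


def make_waveform(params: WaveformParams = WaveformParams(),
                  seed: int | np.random.SeedSequence = 0) -> Waveform:
    """Build the continuous velocity waveform and its per-beat truth.

    v(t) is a sum over beats of three Gaussian pulses (s' positive, e'/a'
    negative); each beat's period is drawn as period_s * (1 + N(0, jitter)).
    The analytic apex of each pulse is its amplitude; if neighbouring pulses
    overlap enough to shift any apex by more than 5% the truth is ambiguous
    and an error is raised.
    """
    rng = np.random.default_rng(seed)
    periods = params.period_s * (1.0 + rng.normal(0.0, params.jitter_frac,
                                                  size=params.n_beats))
    periods = np.clip(periods, 0.5 * params.period_s, 1.5 * params.period_s)
    starts = np.concatenate([[0.0], np.cumsum(periods[:-1])])
    duration = float(np.sum(periods) + params.tail_frac * params.period_s)

    centers, amps, widths = [], [], []
    beats: list[BeatTruth] = []
    for i, (t0, p) in enumerate(zip(starts, periods)):
        t_s = t0 + params.s_phase * p
        t_e = t0 + params.e_phase * p
        t_a = t0 + params.a_phase * p
        centers += [t_s, t_e, t_a]
        amps += [params.s_amp, -params.e_amp, -params.a_amp]
        widths += [params.s_width_s, params.e_width_s, params.a_width_s]
        beats.append(BeatTruth(i, params.s_amp, -params.e_amp, -params.a_amp,
                               t_s, t_e, t_a, period_s=float(p)))
    centers_a = np.array(centers)
    amps_a = np.array(amps)
    widths_a = np.array(widths)

    def velocity(t: np.ndarray) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        pulses = amps_a * np.exp(-((t[:, None] - centers_a) ** 2)
                                 / (2.0 * widths_a ** 2))
        return pulses.sum(axis=1)

    for b in beats:
        for t_peak, truth in ((b.t_s, b.s_cm_s), (b.t_e, b.e_cm_s), (b.t_a, b.a_cm_s)):
            if abs(float(velocity(np.array([t_peak]))[0]) - truth) > 0.05 * abs(truth):
                raise SyntheticError("pulses too wide for unambiguous truth")

    return Waveform(velocity=velocity, duration_s=duration,
                    beats=tuple(beats), params=params)


def render_strip(wave: Waveform,
                 render: RenderParams = RenderParams()
                 ) -> tuple[DopplerStrip, Calibration, GroundTruth]:
    """Rasterize a waveform into a spectrogram strip.

    Column c samples the waveform at t = c * sec_per_px. The band intensity
    over rows is a Gaussian centred on the true velocity (sigma = the band
    half-width) times a sigmoidal cutoff at +/- the half-width, times
    lognormal speckle, plus Gaussian background noise and the bright baseline
    row. Fully seeded and reproducible.
    """
    rng = np.random.default_rng(render.seed)
    n_cols = int(np.floor(wave.duration_s / render.sec_per_px))
    n_rows = render.strip_height_px
    t = np.arange(n_cols) * render.sec_per_px
    v_true = wave.velocity(t)

    v_rows = (render.baseline_row - np.arange(n_rows)) * render.cm_per_px
    pos_span = max(float(v_true.max()), 0.0) + render.band_halfwidth_cm_s
    neg_span = max(float(-v_true.min()), 0.0) + render.band_halfwidth_cm_s
    if pos_span > (render.baseline_row * render.cm_per_px) or \
       neg_span > ((n_rows - 1 - render.baseline_row) * render.cm_per_px):
        raise SyntheticError("increase strip height")

    d = v_rows[:, None] - v_true[None, :]          # rows x cols, cm/s from centre
    sigma_b = render.band_halfwidth_cm_s
    profile = render.band_peak_intensity * np.exp(-d ** 2 / (2.0 * sigma_b ** 2))
    softness = max(render.edge_softness_px * render.cm_per_px, 1e-6)
    cutoff = 1.0 / (1.0 + np.exp((np.abs(d) - render.band_halfwidth_cm_s) / softness))
    clean = profile * cutoff
    img = clean.copy()
    if render.speckle_sd > 0:
        s = render.speckle_sd
        img *= rng.lognormal(mean=-0.5 * s * s, sigma=s, size=img.shape)
    if render.background_noise_sd > 0:
        img += rng.normal(0.0, render.background_noise_sd, size=img.shape)
    img[render.baseline_row, :] = np.maximum(img[render.baseline_row, :],
                                             render.baseline_intensity)
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    cal = Calibration(zero_row=render.baseline_row,
                      cm_per_px=render.cm_per_px, sec_per_px=render.sec_per_px)
    outer = v_true + np.sign(v_true) * render.band_halfwidth_cm_s
    # band mask at full-width-half-maximum of the noiseless profile: the
    # pixels that are genuinely signal-bright (the soft cutoff's outermost
    # pixels are dim by construction and not part of the nominal band)
    band_mask = clean >= 0.5 * clean.max(axis=0, keepdims=True)
    truth = GroundTruth(mid_velocity_cm_s=v_true, outer_velocity_cm_s=outer,
                        band_mask=band_mask, beats=wave.beats)
    strip = DopplerStrip(pixels=pixels, source="synthetic",
                         meta={"seed": render.seed})
    return strip, cal, truth


def simulate(wave_params: WaveformParams = WaveformParams(),
             render_params: RenderParams = RenderParams(),
             seed: int = 0) -> tuple[DopplerStrip, Calibration, GroundTruth]:
    """One-call generator: a single seed deterministically drives two
    independent streams (waveform jitter, rendering noise), so the waveform
    can be held fixed while the noise is re-rolled."""
    wave_ss, render_ss = np.random.SeedSequence(seed).spawn(2)
    wave = make_waveform(wave_params, seed=wave_ss)
    render_seed = int(render_ss.generate_state(1)[0] % (2 ** 31))
    return render_strip(wave, RenderParams(**{**render_params.__dict__,
                                              "seed": render_seed}))


@dataclass(frozen=True)
class MatchResult:
    errors: pd.DataFrame            # one row per matched beat
    n_matched: int
    n_missed: int                   # truth beats with no measured partner
    n_false: int                    # measured beats with no truth partner


def match_beats(measured: list[BeatMeasurement], truth: GroundTruth | tuple,
                tol_s: float = 0.15) -> MatchResult:
    """Greedy nearest-time pairing of measured and true beats.

    Measured s' times are matched to true s' times, closest pairs first,
    each beat used at most once, pairs farther apart than ``tol_s``
    rejected. Returns per-peak signed errors (measured - truth) plus
    miss/false-detection counts.
    """
    truth_beats = truth.beats if isinstance(truth, GroundTruth) else tuple(truth)
    pairs = sorted(
        ((abs(m.t_s - tb.t_s), i, j)
         for i, m in enumerate(measured)
         for j, tb in enumerate(truth_beats)
         if abs(m.t_s - tb.t_s) <= tol_s),
        key=lambda x: (x[0], x[1], x[2]))
    used_m: set[int] = set()
    used_t: set[int] = set()
    rows = []
    for dt, i, j in pairs:
        if i in used_m or j in used_t:
            continue
        used_m.add(i)
        used_t.add(j)
        m, tb = measured[i], truth_beats[j]
        rows.append({
            "measured_index": i, "truth_index": j, "dt_s": m.t_s - tb.t_s,
            "s_err_cm_s": m.s_prime_cm_s - tb.s_cm_s,
            "e_err_cm_s": m.e_prime_cm_s - tb.e_cm_s,
            "a_err_cm_s": (m.a_prime_cm_s - tb.a_cm_s
                           if m.a_prime_cm_s is not None else np.nan),
            "s_true_cm_s": tb.s_cm_s, "s_meas_cm_s": m.s_prime_cm_s,
        })
    errors = pd.DataFrame(rows, columns=["measured_index", "truth_index", "dt_s",
                                         "s_err_cm_s", "e_err_cm_s", "a_err_cm_s",
                                         "s_true_cm_s", "s_meas_cm_s"])
    return MatchResult(errors=errors, n_matched=len(rows),
                       n_missed=len(truth_beats) - len(used_t),
                       n_false=len(measured) - len(used_m))


def truth_to_frame(truth: GroundTruth) -> pd.DataFrame:
    """Per-beat truth as a table (for the CLI's truth file)."""
    return pd.DataFrame([{
        "beat_index": b.beat_index, "s_cm_s": b.s_cm_s, "e_cm_s": b.e_cm_s,
        "a_cm_s": b.a_cm_s, "t_s": b.t_s, "t_e": b.t_e, "t_a": b.t_a,
    } for b in truth.beats])
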