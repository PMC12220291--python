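"""The three singing-accuracy scores and the full scoring pipeline.

Given an aligned (contour, template) pair, the pipeline computes:

* **pitch error** (semitones) — after a single 2.5-SD outlier pass and a
  final mean re-shift of the template, the template is cut into inter-onset
  segments at its pitch discontinuities; the score is the mean absolute
  difference between each segment's median sung pitch and its template
  pitch.
* **melody contour error** — the L1 distance between the Parsons codes
  (up / repeat / down between successive segments) of the sung segment
  medians and of the template segment pitches.
* **rhythm error** (eighth-note units) — the mean absolute rate of change
  of the warping path's shift series; a metronomic rendition warps along
  the diagonal and scores 0.

All three are invariant to global transposition (removed by mean-pitch
registration), global gain (the tracker and envelope are scale-free), and
uniform tempo (absorbed by stretching the template to the contour length).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .align import WarpPath, dtw_euclidean, shift_series
from .errors import InputError, ScoringError
from .pitchtrack import (
    PitchContour,
    Waveform,
    YinConfig,
    fill_unvoiced,
    trim_silence,
    yin_pitch,
)
from .template import (
    MelodyTemplate,
    PianoRollCurve,
    expand_template,
    stretch_previous_neighbor,
)

__all__ = [
    "ScoreConfig",
    "Segment",
    "AccuracyScores",
    "remove_outliers",
    "derive_segments",
    "pitch_error",
    "parsons_code",
    "contour_error",
    "rhythm_error",
    "score_contour",
    "score_recording",
]


@dataclass(frozen=True)
class ScoreConfig:
    """Every pipeline constant in one place, with the frozen defaults.

    The tracker constants (threshold 0.1, f0 range 30–1000 Hz, hop 32) and
    the scoring constants (10% envelope median for trimming, 2.5-SD outlier
    cut) are the method's fixed operating point; ``deadband_semitones`` is
    the repeat/step boundary used when Parsons-coding the continuous sung
    medians (0.5 = the integer rounding boundary).
    """

    yin_threshold: float = 0.1
    minf0_hz: float = 30.0
    maxf0_hz: float = 1000.0
    hop: int = 32
    trim_frac: float = 0.10
    max_gap_s: float = 0.25
    outlier_sd: float = 2.5
    deadband_semitones: float = 0.5
    merge_equal_pitch_segments: bool = True
    max_align_len: int = 4000
    steps_per_eighth: int = 1

    def yin_config(self) -> YinConfig:
        return YinConfig(
            threshold=self.yin_threshold,
            minf0_hz=self.minf0_hz,
            maxf0_hz=self.maxf0_hz,
            hop=self.hop,
        )

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class Segment:
    """One inter-onset segment on the warped time axis (half-open frame span)."""

    start: int
    end: int
    template_pitch: float
    median_pitch: float
    n_voiced: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise InputError("segment must satisfy start < end")


@dataclass(frozen=True)
class AccuracyScores:
    """The scoring triple plus diagnostics.  Higher scores denote more errors."""

    pitch_error: float
    melody_error: float
    rhythm_error: float
    n_segments: int
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("pitch_error", "melody_error", "rhythm_error"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ScoringError(f"{name} must be finite and non-negative, got {v}")


def remove_outliers(contour, template, k: float = 2.5) -> tuple[np.ndarray, np.ndarray]:
    """Single-pass outlier mask on an aligned pair, then a final re-shift.

    Frames where the mean-centred |contour - template| difference exceeds
    ``k`` standard deviations are masked out (the centring keeps a residual
    global transposition from inflating the SD).  The template is then
    shifted once more so the *median* retained difference is zero: the
    median is used because the frames inside a note-to-note pitch glide
    pull the mean away from the note plateaus that the segment medians
    measure, which would otherwise leak a registration-dependent constant
    into every segment deviation.
    Returns ``(mask, shifted_template)``.
    """
    c = np.asarray(contour, dtype=np.float64)
    t = np.asarray(template, dtype=np.float64)
    if c.shape != t.shape or c.ndim != 1:
        raise InputError("aligned sequences must be equal-length 1-D arrays")
    diff = c - t
    centred = diff - diff.mean()
    sd = centred.std()
    mask = np.abs(centred) <= k * sd if sd > 0 else np.ones_like(c, dtype=bool)
    if not mask.any():
        raise ScoringError("outlier mask removed every frame", stage="remove_outliers")
    shifted = t + float(np.median(diff[mask]))
    return mask, shifted


def derive_segments(
    template_curve: np.ndarray,
    contour: np.ndarray,
    mask: np.ndarray | None = None,
    note_ids: np.ndarray | None = None,
    merge_equal_pitch: bool = True,
) -> tuple[list[Segment], int]:
    """Cut the warped time axis at the template's pitch discontinuities.

    With ``merge_equal_pitch`` (the default) boundaries fall only where the
    template *value* changes, so consecutive equal-pitch notes merge into one
    segment; passing ``merge_equal_pitch=False`` (requires ``note_ids``)
    keeps every note separate.  Each segment's sung pitch is the median of
    the retained contour frames inside it; segments whose frames are all
    masked are dropped and counted.

    Returns ``(segments, n_dropped)``.
    """
    t = np.asarray(template_curve, dtype=np.float64)
    c = np.asarray(contour, dtype=np.float64)
    if t.shape != c.shape or t.ndim != 1:
        raise InputError("template and contour must be equal-length 1-D arrays")
    if mask is None:
        mask = np.ones_like(t, dtype=bool)
    if merge_equal_pitch:
        change = np.flatnonzero(np.diff(t) != 0) + 1
    else:
        if note_ids is None:
            raise InputError("note_ids required when merge_equal_pitch=False")
        change = np.flatnonzero(np.diff(np.asarray(note_ids)) != 0) + 1
    bounds = np.concatenate(([0], change, [len(t)]))
    segments: list[Segment] = []
    dropped = 0
    for a, b in zip(bounds[:-1], bounds[1:]):
        seg_mask = mask[a:b]
        if not seg_mask.any():
            dropped += 1
            continue
        segments.append(
            Segment(
                start=int(a),
                end=int(b),
                template_pitch=float(t[a]),
                median_pitch=float(np.median(c[a:b][seg_mask])),
                n_voiced=int(seg_mask.sum()),
            )
        )
    return segments, dropped


def pitch_error(segments: list[Segment]) -> float:
    """Mean absolute difference (semitones) between each segment's median sung
    pitch and its template pitch."""
    if not segments:
        raise ScoringError("no voiced segments to score", stage="pitch_error")
    devs = [abs(s.median_pitch - s.template_pitch) for s in segments]
    return float(np.mean(devs))


def parsons_code(values, deadband: float = 0.0) -> np.ndarray:
    """Directional (Parsons) code of a pitch sequence: +1 up, 0 repeat, -1 down.

    ``deadband`` treats steps smaller than this as repeats — used for the
    continuous sung medians, where 0.5 semitone is the integer rounding
    boundary of the template's pitch grid.
    """
    v = np.asarray(values, dtype=np.float64)
    if v.ndim != 1 or v.size < 2:
        raise InputError("Parsons code needs at least two pitch values")
    steps = np.diff(v)
    codes = np.sign(steps)
    codes[np.abs(steps) < deadband] = 0.0
    return codes.astype(int)


def contour_error(sung_codes, template_codes) -> float:
    """L1 distance between two equal-length Parsons code sequences."""
    s = np.asarray(sung_codes, dtype=np.int64)
    t = np.asarray(template_codes, dtype=np.int64)
    if s.shape != t.shape:
        raise ScoringError("code sequences differ in length", stage="contour_error")
    return float(np.abs(s - t).sum())


def rhythm_error(shifts: np.ndarray, eighth_len: float) -> float:
    """Mean absolute slope of the warp-path shift series, in eighth units.

    ``shifts`` holds one shift per contour frame (already in eighths);
    consecutive frames are 1/``eighth_len`` eighths apart, so the slope at
    each step is ``diff(shifts) * eighth_len``.
    """
    s = np.asarray(shifts, dtype=np.float64)
    if s.size < 2:
        raise ScoringError("shift series shorter than 2 frames", stage="rhythm_error")
    return float(np.mean(np.abs(np.diff(s))) * eighth_len)


# --------------------------------------------------------------------------
# Pipeline
# --------------------------------------------------------------------------

def score_contour(
    contour, template: MelodyTemplate, cfg: ScoreConfig | None = None
) -> AccuracyScores:
    """Score a gap-free pitch contour (MIDI note numbers) against a template.

    This is the geometric half of the pipeline: expand the template, stretch
    and mean-shift it onto the contour, warp with DTW, mask outliers, segment
    at the template's discontinuities, then compute the three scores.
    """
    cfg = cfg or ScoreConfig()
    full = np.asarray(getattr(contour, "midi", contour), dtype=np.float64)
    if full.ndim != 1 or full.size < 2:
        raise InputError("contour must hold at least two frames")
    if np.isnan(full).any():
        raise InputError("contour must be gap-free; run fill_unvoiced first")

    # stretch the template to the FULL contour length, then co-decimate both
    # with one stride: the curves keep a shared frame-boundary convention,
    # so decimation does not introduce spurious one-frame warp excursions
    stride = max(1, int(math.ceil(len(full) / cfg.max_align_len)))
    vals = full[::stride]
    roll = expand_template(template, cfg.steps_per_eighth)
    stretched = stretch_previous_neighbor(roll, len(full))
    registered = PianoRollCurve(
        values=stretched.values[::stride] + (vals.mean() - stretched.values[::stride].mean()),
        eighth_len=stretched.eighth_len / stride,
        note_ids=stretched.note_ids[::stride],
    )
    path, _cost = dtw_euclidean(vals, registered.values)

    warped_contour = vals[path.contour_indices]
    warped_template = registered.values[path.template_indices]
    warped_ids = registered.note_ids[path.template_indices]

    mask, shifted_template = remove_outliers(warped_contour, warped_template, cfg.outlier_sd)
    segments, n_dropped = derive_segments(
        shifted_template,
        warped_contour,
        mask=mask,
        note_ids=warped_ids,
        merge_equal_pitch=cfg.merge_equal_pitch_segments,
    )
    pe = pitch_error(segments)
    medians = np.array([s.median_pitch for s in segments])
    targets = np.array([s.template_pitch for s in segments])
    if len(segments) >= 2:
        me = contour_error(
            parsons_code(medians, deadband=cfg.deadband_semitones),
            parsons_code(targets, deadband=cfg.deadband_semitones),
        )
    else:
        me = 0.0
    eighth_len = len(vals) / template.total_eighths
    shifts = shift_series(path, eighth_len)
    re = rhythm_error(shifts, eighth_len)
    return AccuracyScores(
        pitch_error=pe,
        melody_error=me,
        rhythm_error=re,
        n_segments=len(segments),
        flags={
            "outlier_fraction": float(1.0 - mask.mean()),
            "dropped_segments": n_dropped,
            "aligned_frames": int(len(vals)),
            "dtw_path_len": int(len(path)),
        },
    )


def score_recording(
    w: Waveform, template: MelodyTemplate, cfg: ScoreConfig | None = None
) -> AccuracyScores:
    """Score a sung recording end to end.

    Stages: YIN pitch tracking -> RMS envelope -> silent head/tail trimming
    -> unvoiced-gap filling -> geometric scoring (:func:`score_contour`).
    Raises :class:`SilentRecordingError` / :class:`ScoringError` with stage
    provenance on degenerate input.
    """
    cfg = cfg or ScoreConfig()
    contour, env = yin_pitch(w, cfg.yin_config())
    trimmed_start = len(contour)
    contour = trim_silence(contour, env, frac=cfg.trim_frac)
    contour = fill_unvoiced(contour, max_gap_s=cfg.max_gap_s)
    voiced_fraction = len(contour) / trimmed_start if trimmed_start else 0.0
    scores = score_contour(contour.midi, template, cfg)
    scores.flags["voiced_fraction"] = float(voiced_fraction)
    scores.flags["duration_s"] = float(w.duration_s)
    return scores
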