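"""Synthetic sung renditions with known ground truth.

The simulator realises a melody template as a performance with controlled
imperfections — global transposition, per-note pitch offsets, contour
inversions, per-note timing jitter, linear tempo drift, dropped syllables,
vibrato, additive noise, and leading/trailing silence — and reports, from
the same random draws, the ground-truth quantities the estimator tries to
recover.  Audio is a four-partial harmonic complex: periodic enough for the
tracker, cheap to generate, and deliberately unlike a real voice (no
formants, no lyrics, no breath).

Ground-truth pitch deviation is defined after removing the rendition's own
mean offset, matching the estimator's transposition invariance, and is
measured on the same merged-segment structure the estimator scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InputError
from .pitchtrack import Waveform, hz_to_midi, midi_to_hz
from .score import parsons_code
from .template import MelodyTemplate, canonical_template

__all__ = ["SynthConfig", "GroundTruth", "render_contour", "render_audio", "make_cohort", "PROFILES"]

_HARMONIC_AMPS = (1.0, 0.5, 0.25, 0.125)
_MIN_NOTE_S = 0.03


@dataclass(frozen=True)
class SynthConfig:
    """One rendition's performance parameters.

    Units: pitch in semitones, timing in eighth-note slots, tempo in eighth
    notes per second (4.0 = 120 quarter-note bpm, an ordinary pace for the
    song), noise as signal-to-noise ratio in dB (None = noiseless).
    ``seed`` fixes every random draw.
    """

    tonic_hz: float = 261.6256  # middle C
    tempo_eighths_per_s: float = 4.0
    transpose_semitones: float = 0.0
    note_offset_sd: float = 0.0
    note_offsets: tuple[float, ...] | None = None  # explicit per-note, overrides sd
    contour_inversions: frozenset[int] = frozenset()
    timing_jitter_sd_eighths: float = 0.0
    tempo_drift_pct: float = 0.0
    dropped_notes: frozenset[int] = frozenset()
    snr_db: float | None = None
    vibrato_cents: float = 0.0
    vibrato_hz: float = 5.0
    lead_silence_s: float = 0.0
    tail_silence_s: float = 0.0
    rate_hz: float = 48000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tempo_eighths_per_s <= 0:
            raise InputError("tempo must be positive")
        if self.tonic_hz <= 0 or self.rate_hz <= 0:
            raise InputError("tonic_hz and rate_hz must be positive")
        object.__setattr__(self, "contour_inversions", frozenset(self.contour_inversions))
        object.__setattr__(self, "dropped_notes", frozenset(self.dropped_notes))


@dataclass(frozen=True)
class GroundTruth:
    """Analytically known properties of one rendition."""

    true_mean_abs_pitch_dev: float
    true_contour_code_flips: int
    true_contour_l1: float
    true_note_onsets_s: np.ndarray
    nominal_note_onsets_s: np.ndarray
    note_pitches_midi: np.ndarray
    dropped_notes: tuple[int, ...]

    def as_dict(self) -> dict:
        return {
            "true_mean_abs_pitch_dev": self.true_mean_abs_pitch_dev,
            "true_contour_code_flips": self.true_contour_code_flips,
            "true_contour_l1": self.true_contour_l1,
            "true_note_onsets_s": list(map(float, self.true_note_onsets_s)),
            "nominal_note_onsets_s": list(map(float, self.nominal_note_onsets_s)),
            "note_pitches_midi": list(map(float, self.note_pitches_midi)),
            "dropped_notes": list(self.dropped_notes),
        }


@dataclass(frozen=True)
class _Realization:
    kept: np.ndarray            # original note indices retained
    template_rel: np.ndarray    # template pitch (semitones rel. tonic) of kept notes
    sung_midi: np.ndarray       # realised pitch of each kept note
    onsets_s: np.ndarray        # realised onsets (len kept + 1, incl. final offset)
    nominal_onsets_s: np.ndarray


def _realize(template: MelodyTemplate, cfg: SynthConfig, rng: np.random.Generator) -> _Realization:
    kept = np.array([n.index for n in template.notes if n.index not in cfg.dropped_notes])
    if kept.size == 0:
        raise InputError("configuration drops every note of the template")
    rel = template.pitches[kept]
    durs = template.durations[kept].astype(float)

    # pitch: transpose + per-note offsets (+ contour inversions about the previous note)
    if cfg.note_offsets is not None:
        offsets = np.asarray(cfg.note_offsets, dtype=float)[kept]
    else:
        offsets = rng.normal(0.0, cfg.note_offset_sd, size=kept.size) if cfg.note_offset_sd > 0 else np.zeros(kept.size)
    rel_eff = rel.copy()
    for pos, orig in enumerate(kept):
        if orig in cfg.contour_inversions and pos > 0:
            rel_eff[pos] = 2.0 * rel[pos - 1] - rel[pos]
    tonic_midi = hz_to_midi(cfg.tonic_hz)
    sung = tonic_midi + rel_eff + cfg.transpose_semitones + offsets

    # timing: nominal grid, linear tempo drift, per-boundary jitter
    base = durs / cfg.tempo_eighths_per_s
    nominal = np.concatenate(([0.0], np.cumsum(base)))
    if cfg.tempo_drift_pct != 0.0:
        mid = (nominal[:-1] + nominal[1:]) / (2.0 * nominal[-1])
        base = base * (1.0 + cfg.tempo_drift_pct / 100.0 * (mid - 0.5))
    onsets = np.concatenate(([0.0], np.cumsum(base)))
    if cfg.timing_jitter_sd_eighths > 0 and kept.size > 1:
        jit = rng.normal(0.0, cfg.timing_jitter_sd_eighths / cfg.tempo_eighths_per_s, size=kept.size - 1)
        onsets[1:-1] += jit
        for k in range(1, len(onsets)):  # keep boundaries ordered
            onsets[k] = max(onsets[k], onsets[k - 1] + _MIN_NOTE_S)
        for k in range(len(onsets) - 2, -1, -1):
            onsets[k] = min(onsets[k], onsets[k + 1] - _MIN_NOTE_S)
    return _Realization(
        kept=kept, template_rel=rel, sung_midi=sung, onsets_s=onsets, nominal_onsets_s=nominal
    )


def _ground_truth(real: _Realization, cfg: SynthConfig, deadband: float = 0.5) -> GroundTruth:
    """Recompute what an ideal, perfectly aligned estimator would measure."""
    # per-frame deviation on a fine grid (frame-weighted, like the estimator)
    fr = 1000.0
    n = max(2, int(round(real.onsets_s[-1] * fr)))
    t = (np.arange(n) + 0.5) * real.onsets_s[-1] / n
    idx = np.clip(np.searchsorted(real.onsets_s[1:], t, side="right"), 0, len(real.kept) - 1)
    tonic_midi = hz_to_midi(cfg.tonic_hz)
    dev = real.sung_midi[idx] - (tonic_midi + real.template_rel[idx])
    dev = dev - dev.mean()
    # merged-segment structure: consecutive kept notes with equal template pitch
    seg_id_per_note = np.concatenate(([0], np.cumsum(np.diff(real.template_rel) != 0)))
    seg_id = seg_id_per_note[idx]
    n_segs = seg_id_per_note[-1] + 1
    medians = np.array([np.median(dev[seg_id == s]) for s in range(n_segs)])
    seg_template = np.array(
        [real.template_rel[np.argmax(seg_id_per_note == s)] for s in range(n_segs)]
    )
    true_dev = float(np.mean(np.abs(medians)))
    if n_segs >= 2:
        sung_codes = parsons_code(seg_template + medians, deadband=deadband)
        tmpl_codes = parsons_code(seg_template, deadband=deadband)
        flips = int(np.sum(sung_codes != tmpl_codes))
        l1 = float(np.abs(sung_codes - tmpl_codes).sum())
    else:
        flips, l1 = 0, 0.0
    return GroundTruth(
        true_mean_abs_pitch_dev=true_dev,
        true_contour_code_flips=flips,
        true_contour_l1=l1,
        true_note_onsets_s=real.onsets_s[:-1].copy(),
        nominal_note_onsets_s=real.nominal_onsets_s[:-1].copy(),
        note_pitches_midi=real.sung_midi.copy(),
        dropped_notes=tuple(sorted(int(i) for i in cfg.dropped_notes)),
    )


def render_contour(
    template: MelodyTemplate, cfg: SynthConfig, frame_rate_hz: float = 1500.0
) -> tuple[np.ndarray, GroundTruth]:
    """Realise a rendition directly as a gap-free pitch contour (MIDI numbers).

    The grid default of 1500 frames/s matches the tracker's grid at 48 kHz
    with hop 32.  Use this to exercise the geometric scoring stages without
    audio synthesis.
    """
    ss = np.random.SeedSequence(cfg.seed)
    draw_ss, _noise_ss = ss.spawn(2)
    real = _realize(template, cfg, np.random.default_rng(draw_ss))
    n = max(2, int(round(real.onsets_s[-1] * frame_rate_hz)))
    # note boundaries quantised by normalised position with the same ceil
    # convention previous-neighbour stretching uses, so a clean rendition is
    # frame-for-frame identical to the stretched template at any tempo
    # the 1e-6-frame guard keeps float round-off from flipping boundaries
    # that land exactly on a frame (integer-slot onsets)
    bounds = np.ceil(real.onsets_s / real.onsets_s[-1] * n - 1e-6).astype(np.int64)
    frames = np.arange(n)
    idx = np.clip(np.searchsorted(bounds[1:], frames, side="right"), 0, len(real.kept) - 1)
    return real.sung_midi[idx], _ground_truth(real, cfg)


def render_audio(template: MelodyTemplate, cfg: SynthConfig) -> tuple[Waveform, GroundTruth]:
    """Synthesise a rendition as audio: a four-partial harmonic complex with
    soft onset/offset ramps, optional vibrato and additive white noise, padded
    with the configured leading/trailing silence."""
    ss = np.random.SeedSequence(cfg.seed)
    draw_ss, noise_ss = ss.spawn(2)
    real = _realize(template, cfg, np.random.default_rng(draw_ss))
    rate = cfg.rate_hz
    n = int(round(real.onsets_s[-1] * rate))
    t = np.arange(n) / rate
    idx = np.clip(np.searchsorted(real.onsets_s[1:], t, side="right"), 0, len(real.kept) - 1)
    midi = real.sung_midi[idx].astype(float)
    if cfg.vibrato_cents > 0:
        midi = midi + (cfg.vibrato_cents / 100.0) * np.sin(2 * np.pi * cfg.vibrato_hz * t)
    f0 = midi_to_hz(midi)
    phase = 2 * np.pi * np.cumsum(f0) / rate
    tone = np.zeros(n)
    for h, amp in enumerate(_HARMONIC_AMPS, start=1):
        tone += amp * np.sin(h * phase)
    tone *= 0.35 / sum(_HARMONIC_AMPS)
    ramp = min(int(0.03 * rate), n // 4)
    if ramp > 0:
        win = 0.5 * (1 - np.cos(np.pi * np.arange(ramp) / ramp))
        tone[:ramp] *= win
        tone[-ramp:] *= win[::-1]
    lead = np.zeros(int(round(cfg.lead_silence_s * rate)))
    tail = np.zeros(int(round(cfg.tail_silence_s * rate)))
    samples = np.concatenate([lead, tone, tail])
    if cfg.snr_db is not None:
        sig_rms = float(np.sqrt(np.mean(tone**2)))
        noise_sd = sig_rms / (10.0 ** (cfg.snr_db / 20.0))
        samples = samples + np.random.default_rng(noise_ss).normal(0.0, noise_sd, size=samples.size)
    return Waveform(samples=samples, rate_hz=rate), _ground_truth(real, cfg)


# --------------------------------------------------------------------------
# Cohorts
# --------------------------------------------------------------------------

#: Severity presets.  "control" and "patient" bracket mild vs. strongly
#: impaired singing: per-note pitch scatter (semitones), timing jitter
#: (eighths), tempo drift (%), and recording noise floor (dB SNR).
PROFILES: dict[str, dict] = {
    "clean": dict(),
    "control": dict(note_offset_sd=0.3, timing_jitter_sd_eighths=0.05, tempo_drift_pct=2.0, snr_db=35.0),
    "patient": dict(note_offset_sd=1.5, timing_jitter_sd_eighths=0.3, tempo_drift_pct=5.0, snr_db=25.0),
}


def make_cohort(
    n: int,
    profile: str,
    seed: int,
    template: MelodyTemplate | None = None,
    **overrides,
) -> list[tuple[Waveform, GroundTruth]]:
    """A reproducible batch of ``n`` renditions from a named severity preset.

    Per-item seeds are derived from the master ``seed``; the same call
    returns byte-identical waveforms.  Keyword overrides are applied on top
    of the preset (e.g. ``transpose_semitones=3``).
    """
    if n < 1:
        raise InputError("cohort size must be >= 1")
    if profile not in PROFILES:
        raise InputError(f"unknown profile {profile!r}; available: {sorted(PROFILES)}")
    template = template or canonical_template()
    item_seeds = np.random.SeedSequence(seed).generate_state(n) & 0x7FFFFFFF
    out = []
    for s in item_seeds:
        cfg = SynthConfig(seed=int(s), **{**PROFILES[profile], **overrides})
        out.append(render_audio(template, cfg))
    return out
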