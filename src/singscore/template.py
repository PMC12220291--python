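"""Geometric melody templates.

A song is described as an ordered list of notes, each encoded in semitones
relative to the tonic and in multiples of the song's smallest time unit
(the eighth note).  Expanding a template onto a uniform time grid yields a
piecewise-constant piano-roll curve — the geometric benchmark that sung
renditions are scored against.

The built-in song is the two-verse "Brother John" (*Frère Jacques*; Finnish
*Jaakko-kulta*): 32 syllables per verse, 64 in total, 128 eighth-note slots.
The opening bar ("Are you sleep-ing?") expands on the eighth grid to
``0 0 2 2 4 4 0 0``.
"""

from __future__ import annotations

import math
import re
import struct
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import AnnotationMismatchError, FormatError, InputError

__all__ = [
    "NoteEvent",
    "MelodyTemplate",
    "SyllableAnnotation",
    "PianoRollCurve",
    "canonical_template",
    "subject_template",
    "expand_template",
    "stretch_previous_neighbor",
    "read_textgrid",
    "write_textgrid",
    "read_template",
    "write_template",
    "write_midi",
]


@dataclass(frozen=True)
class NoteEvent:
    """One sung syllable: pitch relative to the tonic, length in eighth slots."""

    pitch_rel: int
    duration: int
    syllable: str
    index: int

    def __post_init__(self) -> None:
        if self.duration < 1:
            raise InputError(f"note duration must be >= 1 eighth, got {self.duration}")
        if self.index < 0:
            raise InputError("note index must be non-negative")


@dataclass(frozen=True)
class MelodyTemplate:
    """Ordered note list describing a song's melody.

    Invariants: non-empty; note indices are 0..n-1 in order.
    """

    notes: tuple[NoteEvent, ...]
    name: str = "untitled"

    def __post_init__(self) -> None:
        if not self.notes:
            raise InputError("a melody template must contain at least one note")
        object.__setattr__(self, "notes", tuple(self.notes))
        for pos, note in enumerate(self.notes):
            if note.index != pos:
                raise InputError(
                    f"note indices must be contiguous from 0; position {pos} has index {note.index}"
                )

    def __len__(self) -> int:
        return len(self.notes)

    @property
    def total_eighths(self) -> int:
        return sum(n.duration for n in self.notes)

    @property
    def pitches(self) -> np.ndarray:
        return np.array([n.pitch_rel for n in self.notes], dtype=float)

    @property
    def durations(self) -> np.ndarray:
        return np.array([n.duration for n in self.notes], dtype=int)

    @property
    def syllables(self) -> list[str]:
        return [n.syllable for n in self.notes]

    def subset(self, indices: Iterable[int], name: str | None = None) -> "MelodyTemplate":
        """Template restricted to the given original note indices (order preserved)."""
        idx = sorted(set(int(i) for i in indices))
        if not idx:
            raise AnnotationMismatchError("subset would produce an empty template")
        if idx[0] < 0 or idx[-1] >= len(self.notes):
            raise InputError(f"note index out of range: {idx}")
        notes = tuple(
            replace(self.notes[i], index=pos) for pos, i in enumerate(idx)
        )
        return MelodyTemplate(notes=notes, name=name or self.name)


@dataclass(frozen=True)
class SyllableAnnotation:
    """Ordered, validated syllable intervals (seconds) from a manual annotation."""

    intervals: tuple[tuple[float, float, str], ...]

    def __post_init__(self) -> None:
        prev_end = -math.inf
        for start, end, label in self.intervals:
            if start < 0 or not start < end:
                raise FormatError(f"invalid interval ({start}, {end}, {label!r})")
            if start < prev_end - 1e-9:
                raise FormatError(f"overlapping interval at t={start:.3f}s ({label!r})")
            prev_end = end

    @property
    def labels(self) -> list[str]:
        return [lab for _, _, lab in self.intervals]


@dataclass(frozen=True)
class PianoRollCurve:
    """A template expanded on a uniform grid: piecewise-constant pitch values.

    ``eighth_len`` is the (possibly fractional) number of grid steps per
    eighth-note slot.  ``note_ids`` tracks which source note each step came
    from, so segmentation can optionally keep repeated-pitch notes apart.
    """

    values: np.ndarray
    eighth_len: float
    note_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size == 0:
            raise InputError("piano-roll curve must be a non-empty 1-D sequence")
        if self.eighth_len <= 0:
            raise InputError("eighth_len must be positive")
        object.__setattr__(self, "values", values)
        if self.note_ids is None:
            object.__setattr__(self, "note_ids", np.zeros(values.size, dtype=int))
        else:
            ids = np.asarray(self.note_ids, dtype=int)
            if ids.shape != values.shape:
                raise InputError("note_ids must match values in length")
            object.__setattr__(self, "note_ids", ids)

    def __len__(self) -> int:
        return len(self.values)


# --------------------------------------------------------------------------
# Built-in song
# --------------------------------------------------------------------------

# One verse of the standard "Brother John" / "Jaakko-kulta" tune in
# (semitones above tonic, eighth slots, syllable).  Four phrases, each sung
# twice: 4+4, 3+3, 6+6, 3+3 syllables; 32 notes and 64 eighth slots per verse.
_VERSE: tuple[tuple[int, int, str], ...] = (
    # "Jaakko kulta, Jaakko kulta"  (Are you sleeping? x2)
    (0, 2, "jaak"), (2, 2, "ko"), (4, 2, "kul"), (0, 2, "ta"),
    (0, 2, "jaak"), (2, 2, "ko"), (4, 2, "kul"), (0, 2, "ta"),
    # "herää jo, herää jo"  (Brother John x2)
    (4, 2, "he"), (5, 2, "rää"), (7, 4, "jo"),
    (4, 2, "he"), (5, 2, "rää"), (7, 4, "jo"),
    # "kellojasi soita, kellojasi soita"  (Morning bells are ringing x2)
    (7, 1, "kel"), (9, 1, "lo"), (7, 1, "ja"), (5, 1, "si"), (4, 2, "soi"), (0, 2, "ta"),
    (7, 1, "kel"), (9, 1, "lo"), (7, 1, "ja"), (5, 1, "si"), (4, 2, "soi"), (0, 2, "ta"),
    # "pium paum poum, pium paum poum"  (Ding dang dong x2)
    (0, 2, "pium"), (-5, 2, "paum"), (0, 4, "poum"),
    (0, 2, "pium"), (-5, 2, "paum"), (0, 4, "poum"),
)


def canonical_template(verses: int = 2) -> MelodyTemplate:
    """The built-in "Brother John" template.

    With the default two successive verses the template has 64 notes and 128
    eighth-note slots; its first eight slots expand to ``0 0 2 2 4 4 0 0``.
    """
    if verses < 1:
        raise InputError("verses must be >= 1")
    events = []
    pos = 0
    for _ in range(verses):
        for pitch, dur, syl in _VERSE:
            events.append(NoteEvent(pitch_rel=pitch, duration=dur, syllable=syl, index=pos))
            pos += 1
    name = "brother-john" if verses == 2 else f"brother-john-{verses}v"
    return MelodyTemplate(notes=tuple(events), name=name)


def subject_template(
    template: MelodyTemplate, produced_labels: Sequence[str]
) -> MelodyTemplate:
    """Restrict a template to the syllables a subject actually produced.

    ``produced_labels`` must be an ordered subsequence of the template's
    syllables (greedy leftmost matching disambiguates the song's many
    repeated labels).  When every syllable is present the original template
    is returned unchanged.
    """
    labels = [str(lab).strip().lower() for lab in produced_labels]
    if not labels:
        raise AnnotationMismatchError("no produced syllables: template would be empty")
    tmpl_labels = [s.strip().lower() for s in template.syllables]
    kept: list[int] = []
    j = 0
    for lab in labels:
        while j < len(tmpl_labels) and tmpl_labels[j] != lab:
            j += 1
        if j == len(tmpl_labels):
            raise AnnotationMismatchError(
                f"label {lab!r} does not fit as an in-order subsequence of template "
                f"{template.name!r} (matched {len(kept)}/{len(labels)})"
            )
        kept.append(j)
        j += 1
    if len(kept) == len(template):
        return template
    return template.subset(kept, name=f"{template.name}-subject")


def expand_template(template: MelodyTemplate, steps_per_eighth: int = 1) -> PianoRollCurve:
    """Expand a note list onto a uniform grid of ``steps_per_eighth`` per slot."""
    if steps_per_eighth < 1:
        raise InputError("steps_per_eighth must be >= 1")
    reps = template.durations * steps_per_eighth
    values = np.repeat(template.pitches, reps)
    ids = np.repeat(np.arange(len(template)), reps)
    return PianoRollCurve(values=values, eighth_len=float(steps_per_eighth), note_ids=ids)


def stretch_previous_neighbor(curve: PianoRollCurve, target_len: int) -> PianoRollCurve:
    """Time-stretch a piano-roll curve with previous-neighbor interpolation.

    Output sample ``i`` takes the input value at index ``floor(i * n / target_len)``;
    stretching to the same length is the identity.
    """
    if target_len < 1:
        raise InputError("target_len must be >= 1")
    n = len(curve)
    src = (np.arange(target_len, dtype=np.int64) * n) // target_len
    return PianoRollCurve(
        values=curve.values[src],
        eighth_len=curve.eighth_len * target_len / n,
        note_ids=curve.note_ids[src],
    )


# --------------------------------------------------------------------------
# Praat TextGrid I/O (long and short text dialects)
# --------------------------------------------------------------------------

def _read_text(path) -> str:
    raw = Path(path).read_bytes()
    if raw.startswith(b"\xfe\xff") or raw.startswith(b"\xff\xfe"):
        return raw.decode("utf-16")
    return raw.decode("utf-8", errors="replace")


_NUM = re.compile(r"^-?\d+(?:\.\d+)?(?:[eE][+-]?\d+)?$")


def _tokenize_textgrid(text: str) -> list[str]:
    """Reduce a TextGrid (either dialect) to a flat stream of values.

    Long-format decoration (``xmin = ``, ``intervals [k]:`` ...) is stripped;
    what remains is the same value stream the short format stores directly.
    """
    tokens: list[str] = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("File type") or line.startswith("Object class"):
            if '"TextGrid"' in line:
                tokens.append('"TextGrid"')
            continue
        if "=" in line and not line.startswith('"'):
            line = line.split("=", 1)[1].strip()
        if line.endswith("?") or line.endswith(":") or line.endswith("]"):
            # decoration like `tiers? <exists>` or `item [1]:`
            if "<exists>" in line:
                tokens.append("<exists>")
            continue
        if line.startswith('"'):
            tokens.append(line)
        elif _NUM.match(line):
            tokens.append(line)
        elif "<exists>" in line:
            tokens.append("<exists>")
    return tokens


def read_textgrid(path, tier: str | None = None) -> SyllableAnnotation:
    """Read syllable intervals from a Praat TextGrid (long or short format).

    Returns the intervals of the requested interval tier (by name), or the
    first interval tier when ``tier`` is None.  Empty-label intervals
    (silence) are skipped.
    """
    tokens = _tokenize_textgrid(_read_text(path))
    if '"TextGrid"' not in tokens:
        raise FormatError(f"{path}: not a Praat TextGrid")
    i = tokens.index('"TextGrid"') + 1
    try:
        i += 2  # global xmin, xmax
        if tokens[i] == "<exists>":
            i += 1
        n_tiers = int(float(tokens[i])); i += 1
    except (IndexError, ValueError) as exc:
        raise FormatError(f"{path}: malformed TextGrid header") from exc
    for _ in range(n_tiers):
        try:
            klass = tokens[i].strip('"'); i += 1
            tname = tokens[i].strip('"'); i += 1
            i += 2  # tier xmin, xmax
            n_items = int(float(tokens[i])); i += 1
        except (IndexError, ValueError) as exc:
            raise FormatError(f"{path}: malformed tier header") from exc
        if klass == "IntervalTier":
            intervals = []
            for _ in range(n_items):
                start = float(tokens[i]); end = float(tokens[i + 1])
                label = tokens[i + 2].strip('"')
                i += 3
                if label.strip():
                    intervals.append((start, end, label.strip()))
            if tier is None or tname == tier:
                if not intervals and tier is not None:
                    raise FormatError(f"{path}: tier {tier!r} has no labeled intervals")
                return SyllableAnnotation(intervals=tuple(intervals))
        elif klass == "TextTier":
            i += 2 * n_items  # points: time, mark
        else:
            raise FormatError(f"{path}: unknown tier class {klass!r}")
    raise FormatError(f"{path}: no interval tier" + (f" named {tier!r}" if tier else ""))


def write_textgrid(annotation: SyllableAnnotation, path, tier: str = "syllables") -> None:
    """Write intervals as a long-format TextGrid (gaps become empty intervals)."""
    ivs = annotation.intervals
    xmax = ivs[-1][1] if ivs else 1.0
    # fill gaps with empty intervals so the tier tiles [0, xmax]
    full: list[tuple[float, float, str]] = []
    t = 0.0
    for start, end, label in ivs:
        if start > t + 1e-9:
            full.append((t, start, ""))
        full.append((start, end, label))
        t = end
    lines = [
        'File type = "ooTextFile"',
        'Object class = "TextGrid"',
        "",
        "xmin = 0",
        f"xmax = {xmax:.6f}",
        "tiers? <exists>",
        "size = 1",
        "item []:",
        "    item [1]:",
        '        class = "IntervalTier"',
        f'        name = "{tier}"',
        "        xmin = 0",
        f"        xmax = {xmax:.6f}",
        f"        intervals: size = {len(full)}",
    ]
    for k, (start, end, label) in enumerate(full, start=1):
        lines += [
            f"        intervals [{k}]:",
            f"            xmin = {start:.6f}",
            f"            xmax = {end:.6f}",
            f'            text = "{label}"',
        ]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# --------------------------------------------------------------------------
# Note-list text format and Standard MIDI File export
# --------------------------------------------------------------------------

def write_template(template: MelodyTemplate, path) -> None:
    """Write a template as delimited text: one `pitch_rel<TAB>eighths<TAB>syllable` per line."""
    lines = [f"# template: {template.name}", "# pitch_rel\teighths\tsyllable"]
    lines += [f"{n.pitch_rel}\t{n.duration}\t{n.syllable}" for n in template.notes]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_template(path) -> MelodyTemplate:
    """Read a note-list template written by :func:`write_template`."""
    name = Path(path).stem
    notes = []
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if line.startswith("# template:"):
                name = line.split(":", 1)[1].strip()
            continue
        parts = re.split(r"[\t,]\s*|\s+", line)
        if len(parts) < 3:
            raise FormatError(f"{path}:{lineno}: expected `pitch_rel eighths syllable`")
        try:
            pitch, dur = int(parts[0]), int(parts[1])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-integer pitch/duration") from exc
        notes.append(NoteEvent(pitch_rel=pitch, duration=dur, syllable=parts[2], index=len(notes)))
    if not notes:
        raise FormatError(f"{path}: no notes found")
    return MelodyTemplate(notes=tuple(notes), name=name)


def _vlq(value: int) -> bytes:
    """MIDI variable-length quantity."""
    out = [value & 0x7F]
    value >>= 7
    while value:
        out.append(0x80 | (value & 0x7F))
        value >>= 7
    return bytes(reversed(out))


def write_midi(template: MelodyTemplate, path, tonic_midi: int = 60, bpm: float = 120.0) -> None:
    """Export a template as a format-0 Standard MIDI File (eighth = 240 ticks)."""
    ticks_per_eighth = 240
    tempo_us = int(round(60_000_000 / bpm))
    track = bytearray()
    track += b"\x00\xff\x51\x03" + struct.pack(">I", tempo_us)[1:]
    for note in template.notes:
        key = tonic_midi + note.pitch_rel
        if not 0 <= key <= 127:
            raise InputError(f"note {note.index} maps outside MIDI range: {key}")
        track += b"\x00" + bytes([0x90, key, 0x60])
        track += _vlq(note.duration * ticks_per_eighth) + bytes([0x80, key, 0x40])
    track += b"\x00\xff\x2f\x00"
    header = b"MThd" + struct.pack(">IHHH", 6, 0, 1, 2 * ticks_per_eighth)
    with open(path, "wb") as fh:
        fh.write(header + b"MTrk" + struct.pack(">I", len(track)) + bytes(track))
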