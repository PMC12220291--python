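# singscore

Automated scoring of singing accuracy from monophonic recordings of a known
song, against a geometric melody template.

Clinicians and researchers who study vocal production — for example singing
in people with post-stroke aphasia, where melodic production can be spared
or impaired independently of speech — need objective, reproducible accuracy
measures in musically meaningful units. Hand-scoring sung renditions is slow
and rater-dependent; string-matching measures return edit costs with no
physical unit. `singscore` instead treats the song as a geometric shape in
the time–pitch plane and measures how far a rendition departs from it, in
semitones and eighth notes.

## Method

The song is encoded as a note list: pitch in semitones relative to the
tonic, duration in eighth notes (the built-in song is the two-verse
"Brother John" / *Jaakko-kulta*, 64 syllables, 128 eighth slots; its first
bar expands on the eighth grid to `0 0 2 2 4 4 0 0`). A recording is scored
as follows:

1. **Pitch tracking.** The YIN algorithm (cumulative-mean-normalised
   difference with absolute threshold 0.1, f0 range 30–1000 Hz, hop 32
   samples, parabolic lag refinement) yields a framewise contour in MIDI
   note numbers, `m = 69 + 12·log2(f/440)`.
2. **Trimming.** A normalised RMS envelope on the same frame grid removes
   the silent head and tail (frames below 10% of the envelope maximum);
   short unvoiced gaps are bridged so the contour is gap-free.
3. **Registration.** The template is expanded to a piano-roll curve,
   time-stretched to the contour length by previous-neighbour
   interpolation, and shifted so its mean pitch matches the contour's —
   removing key and overall tempo from the comparison.
4. **Warping.** Unconstrained dynamic time warping with local cost
   `|c_i − t_j|` aligns contour and template.
5. **Scores.** After a single 2.5-SD outlier pass and a final re-shift,
   the template is segmented at its pitch discontinuities, and

   * **pitch error** = mean over segments of |median sung pitch − template
     pitch| (semitones);
   * **melody contour error** = L1 distance between the Parsons codes
     (up / repeat / down) of sung segment medians and template segment
     pitches;
   * **rhythm error** = mean absolute rate of change of the warping path's
     temporal shift, in eighth notes (a metronomic rendition scores 0).

Higher scores denote more errors. All three are invariant to
transposition, gain, leading/trailing silence, and uniform tempo change.

A synthetic-singer simulator (`singscore.synth`) renders the template as a
harmonic tone complex with controllable transposition, per-note pitch
offsets, contour inversions, timing jitter, tempo drift, dropped
syllables, vibrato and noise — with analytic ground truth, so every stage
of the pipeline is testable without human recordings.

## Worked example

```python
import singscore as ss

song = ss.canonical_template()                     # 64 notes, 128 eighths
cfg = ss.SynthConfig(seed=42, note_offset_sd=1.0,  # a shaky singer:
                     timing_jitter_sd_eighths=0.2, # 1 st pitch scatter,
                     snr_db=30.0)                  # 0.2-eighth timing jitter
wave, truth = ss.render_audio(song, cfg)
scores = ss.score_recording(wave, song)
print(f"pitch  error: {scores.pitch_error:.3f} semitones")
print(f"melody error: {scores.melody_error:.0f}")
print(f"rhythm error: {scores.rhythm_error:.3f} eighth notes")
```

prints

```
pitch  error: 0.685 semitones
melody error: 12
rhythm error: 0.228 eighth notes
```

i.e. the sung notes sit on average ~0.7 semitones off the template after
the best key match, twelve contour-direction codes disagree, and the
rendition needed on average ~0.23 eighth notes of local time-warp change
per eighth to line up with the metronomic template. The simulator's own
ground truth for this rendition (`truth.true_mean_abs_pitch_dev`) is 0.786
semitones, recovered by the estimator within the tracker's tolerance.

From the shell, the same pipeline is available as:

```
singscore simulate --profile patient --n 5 --seed 1 --outdir renditions/
singscore score renditions/*.wav --out scores.csv
singscore template-export --format midi --out brother-john.mid
```

`score` accepts a directory of Praat TextGrid syllable annotations
(`--annotations`) to restrict the template to the syllables a subject
actually produced.

## Layout

- `singscore.template` — note-list templates, piano-roll expansion,
  TextGrid/MIDI/text I/O
- `singscore.pitchtrack` — YIN tracker, envelope, trimming, gap filling
- `singscore.align` — registration, dynamic time warping, shift series
- `singscore.score` — the three scores and the end-to-end pipeline
- `singscore.synth` — synthetic renditions with ground truth
- `singscore.cli` — `singscore` command-line interface
- `docs/methods.md` — modelling choices, parameters, limitations
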