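# Methods

This note records how the scoring pipeline works, the choices made where
the design was genuinely open, what the synthetic singer does and does not
emulate, and the package's known limitations. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## The geometric model

A song is a piecewise-constant function of time in the time–pitch plane:
pitch in semitones relative to the tonic, time in eighth notes (the song's
smallest rhythmic unit). Scoring a rendition means registering this shape
to the recording's pitch contour — removing the nuisance parameters a
singer legitimately chooses (key, overall tempo, loudness, when to start)
— and measuring what remains: local pitch deviation, contour-direction
mistakes, and local timing deformation.

The built-in template is the standard two-verse "Brother John" tune, 32
notes per verse in four twice-sung phrases (4+4, 3+3, 6+6, 3+3 syllables),
64 notes and 128 eighth slots in total, compass −5 to +9 semitones around
the tonic. The first bar expands on the eighth grid to `0 0 2 2 4 4 0 0`.
Only the first bar of the transcription has a printed anchor; the
remainder is the universally standard tune, shipped as a versioned
built-in plus a plain-text note-list format (and a format-0 MIDI export)
so alternative transcriptions can be loaded. Subject-specific templates
are built by deleting the notes of unproduced syllables, identified from
a Praat TextGrid interval tier by ordered-subsequence matching of labels
(greedy leftmost match; the song is highly repetitive, so positional
order, not label identity, disambiguates).

## Pitch tracking

`yin_pitch` implements YIN: squared difference function over an
integration window, cumulative-mean-normalised difference (CMNDF),
absolute-threshold lag selection descended to the local minimum, and
parabolic interpolation of the raw difference function around the chosen
lag. Fixed operating point: threshold 0.1, f0 ∈ [30, 1000] Hz, hop 32
samples. Choices the parameter tuple does not fix:

* **Integration window** — `ceil(2·rate/minf0)` samples (two periods at
  the lowest searched f0; 3200 samples = 67 ms at 48 kHz). With the
  maximum lag this makes each analysis frame 100 ms.
* **Voicing** — a frame is unvoiced when its CMNDF minimum exceeds twice
  the threshold or its RMS is below 1% of the loudest frame; estimates
  outside the f0 search range are discarded. This keeps noise-floor
  frames out of scoring.
* **Framing** — the signal is zero-padded by a whole number of hops on
  both sides so every sample is covered by some frame. Framing therefore
  commutes with hop-aligned time shifts, which is what makes the scores
  exactly invariant to added head/tail silence; it also means a recording
  gains ~150 low-energy frames at each edge, which trimming removes.

On the simulator's four-partial tones the tracker is sub-cent accurate
(the oracle tests bound it at 10 cents on ≥ 95% of voiced frames over
f0 ∈ [80, 800] Hz, with no octave errors observed); real voices with
breath, formant structure and irregular phonation will sit closer to the
bound than to the typical case.

## Trimming and gap filling

A normalised RMS envelope is computed on the pitch frame grid, over a
short (10 ms) window centred in each analysis frame — short enough to
localise the singing's edges to a few frames, long enough to average over
glottal cycles. Head and tail frames below 10% of the envelope maximum
are dropped, and the retained window must have median envelope above that
fraction (otherwise the recording is reported silent). The window-based
greedy-median selection rule was considered and rejected: the median of a
half-silent recording already exceeds the criterion, so a rule that stops
when the median is satisfied does not actually remove silence.

Interior unvoiced gaps up to 0.25 s are bridged linearly; longer gaps
hold the nearest voiced value from each side. Leading/trailing unvoiced
frames are dropped. Alignment and scoring then see a gap-free curve.

## Registration, warping, and the three scores

The template is expanded at one step per eighth, stretched to the full
contour length by previous-neighbour interpolation, and mean-shifted onto
the contour. For alignment the contour is decimated by the smallest
integer stride that brings it to at most `max_align_len` frames (default
4000, chosen to keep the quadratic DTW under ~130 MB and ~0.2 s); the
stretched template is decimated *with the same stride* rather than
re-stretched to the shorter length, so both curves keep one shared
boundary convention and decimation cannot manufacture one-frame warp
excursions. DTW is the classical unconstrained formulation: local cost
`|c_i − t_j|`, steps (1,1), (1,0), (0,1), full boundary conditions,
deterministic backtracking preference diagonal → contour-advance →
template-advance.

After warping, a single outlier pass masks frames whose mean-centred
difference from the template exceeds 2.5 SD (centring keeps a residual
transposition from inflating the SD; the pass is not iterated). The
template is then shifted once more so the **median** retained difference
is zero. The median, not the mean, is deliberate: the tracker's 100 ms
window smears every note transition into a glide, and which glide frames
survive the outlier mask depends on absolute frequency; a mean-based
re-shift therefore leaks a key-dependent constant (up to ~0.04 st) into
every segment deviation, while the median sits on the note plateaus that
the segment statistic actually measures. With the median re-shift the
pitch score of a clean rendition is ~1e-5 st at any transposition.

Segments are the template's inter-onset intervals on the warped axis:
boundaries wherever the template value changes. Consecutive equal-pitch
notes (e.g. the repeated tonic across the phrase seam) therefore merge —
a known coarsening of the inter-onset idea; `merge_equal_pitch_segments
= False` keeps every note separate via the curve's note ids. Segments
whose frames are all masked are dropped from pitch/contour scoring and
counted in the diagnostics.

* **Pitch error**: mean over segments of |median sung pitch − template
  pitch|, in semitones. Segments are weighted equally regardless of
  duration.
* **Melody contour error**: Parsons codes (+1/0/−1) between successive
  segment pitches, for the sung medians with a 0.5-semitone deadband
  (the rounding boundary of the integer-valued template; segment medians
  are continuous) and for the template; the score is the L1 distance. A
  single up sung as down contributes 2.
* **Rhythm error**: the warp path is reduced to one temporal shift per
  contour frame (many-to-one matches averaged; positive shift = sung
  event earlier than its template position), expressed in eighths via
  the frames-per-eighth of the aligned pair; the score is the mean
  absolute first difference of that series per eighth of time. Uniform
  tempo error is absorbed by the length-matching stretch and scores 0.

## The synthetic singer

`singscore.synth` renders a template as a performance with known
imperfections: global transposition; per-note pitch offsets (explicit or
i.i.d. normal); contour inversions (a note reflected about its
predecessor); per-boundary timing jitter (normal, in eighths, with a
30 ms minimum note length enforced); linear tempo drift across the song;
dropped syllables (their time is skipped, matching the subject-template
convention); vibrato; additive white noise at a set SNR; and silence
padding. Audio is a four-partial harmonic complex (amplitudes 1, ½, ¼,
⅛) with 30 ms raised-cosine edge ramps — periodic enough for YIN, cheap
to generate, and deliberately not voice-like. Defaults: tonic middle C
(261.6256 Hz), tempo 4 eighths/s (120 quarter-note bpm, an ordinary pace
for this song), 48 kHz, all perturbations zero. Severity presets:
"control" (pitch scatter SD 0.3 st, jitter SD 0.05 eighths, 2% drift,
35 dB SNR) and "patient" (1.5 st, 0.3 eighths, 5% drift, 25 dB SNR),
bracketing mild vs. strongly impaired singing qualitatively.

Ground truth is computed analytically from the same random draws: the
ideal per-frame deviation curve is centred by its own mean (matching the
estimator's transposition invariance) and reduced on the same
merged-segment structure the estimator scores, giving the mean absolute
per-segment deviation a perfect, perfectly aligned estimator would
report. The contour-level renderer quantises note boundaries with the
same normalised-position `ceil` convention as previous-neighbour
stretching (with a 1e-6-frame guard against float round-off), so a clean
rendition is frame-for-frame identical to the registered template at any
tempo — which is what makes the transposition/tempo invariance of the
scoring geometry exact rather than approximate.

What the simulator does **not** emulate: formants, consonants and lyrics,
breath noise, irregular phonation, room acoustics, or the cued auditory
model bleeding into the recording. Passing tests therefore demonstrate
the correctness and invariances of the *scoring geometry* and the
tracker's behaviour on clean periodic signals; they do not certify
tracker robustness on real voices.

## Numerical choices and degenerate inputs

* Decimation stride `ceil(n/max_align_len)`, taken relative to the first
  retained frame, so it commutes with trimming.
* DTW ties broken diagonally first; identical inputs return the exact
  diagonal with cost 0.
* All-zero audio → silent-recording error; an outlier mask that empties
  the signal, or a contour with no voiced segment → scoring errors with
  stage provenance.
* Gains that are powers of two, and silence paddings that are whole
  numbers of hops, reproduce bit-identical scores; other gains are
  invariant up to float rounding in the normalisations.
* Problem sizes in the shipped tests and acceptance script: full
  two-verse renditions for the clean-pipeline checks, one-verse
  renditions for grids and cohorts (5×5 severity grid × 20 seeds at
  contour level; 12–20 audio cohort pairs), sizes chosen to exercise
  every stage at realistic length while keeping a full validation run in
  minutes on one CPU.

## Known limitations

* Notes shorter than ~3 analysis windows (~0.3 s, i.e. tempi much above
  ~6 eighths/s for this song's one-slot notes) blur into their
  neighbours: the tracker's glide frames dominate the segments and all
  three scores degrade. The study-like tempo regime (2–5 eighths/s) is
  safe.
* Through real audio, the warp path's fine structure at note boundaries
  depends on absolute frequency (how the tracker traverses each glide),
  so rhythm scores are stable only to ~0.03 eighths under large
  transpositions — far below any behaviourally meaningful difference,
  but not exact.
* The rhythm score has a frame-quantisation noise floor of roughly
  (number of boundary excursions)/(aligned frames) ≈ 0.01 for clean
  audio renditions; it vanishes at contour level.
* Melody contour error counts direction mistakes on the merged-segment
  partition; it cannot see an inversion inside a merged pair of
  equal-pitch notes.
* Polyphony, duets with the cueing model, and automatic syllable
  segmentation are out of scope; syllable annotations, where used, are
  manual (TextGrid).
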