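"""Framewise fundamental-frequency estimation and silence handling.

The tracker implements the YIN algorithm: squared difference function,
cumulative-mean-normalised difference (CMNDF), absolute aperiodicity
threshold, and parabolic refinement of the selected lag.  Estimates are
returned in MIDI note numbers (A4 = 440 Hz = 69); unvoiced frames are NaN.

A framewise RMS envelope on the same hop grid drives the trimming of the
silent head and tail of a recording, and short unvoiced gaps are filled so
downstream alignment sees a gap-free curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit
from scipy.fft import irfft, next_fast_len, rfft
from scipy.io import wavfile

from .errors import InputError, SilentRecordingError

__all__ = [
    "Waveform",
    "YinConfig",
    "PitchContour",
    "EnvelopeCurve",
    "load_wav",
    "save_wav",
    "hz_to_midi",
    "midi_to_hz",
    "yin_pitch",
    "amplitude_envelope",
    "trim_silence",
    "fill_unvoiced",
]


@dataclass(frozen=True)
class Waveform:
    """Mono audio: float samples in [-1, 1] at ``rate_hz``."""

    samples: np.ndarray
    rate_hz: float

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise InputError("Waveform requires a mono (1-D) sample array")
        if self.rate_hz <= 0:
            raise InputError("sampling rate must be positive")
        object.__setattr__(self, "samples", samples)

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.rate_hz


@dataclass(frozen=True)
class YinConfig:
    """YIN parameters.  Defaults follow the scoring pipeline's frozen values:
    aperiodicity threshold 0.1, f0 search range 30–1000 Hz, hop 32 samples.

    ``window`` (the difference-function integration window, in samples) is
    derived from the rate when left as None: the smallest window spanning two
    periods at ``minf0_hz``.
    """

    threshold: float = 0.1
    minf0_hz: float = 30.0
    maxf0_hz: float = 1000.0
    hop: int = 32
    window: int | None = None
    env_window_s: float = 0.01

    def __post_init__(self) -> None:
        if not 0 < self.threshold < 1:
            raise InputError("threshold must lie in (0, 1)")
        if not 0 < self.minf0_hz < self.maxf0_hz:
            raise InputError("need 0 < minf0_hz < maxf0_hz")
        if self.hop < 1:
            raise InputError("hop must be >= 1 sample")

    def window_for(self, rate_hz: float) -> int:
        if self.window is not None:
            return int(self.window)
        return int(math.ceil(2.0 * rate_hz / self.minf0_hz))


@dataclass(frozen=True)
class PitchContour:
    """Framewise pitch in MIDI note numbers; unvoiced frames are NaN."""

    midi: np.ndarray
    times_s: np.ndarray
    rate_hz: float
    hop: int

    def __post_init__(self) -> None:
        midi = np.asarray(self.midi, dtype=np.float64)
        times = np.asarray(self.times_s, dtype=np.float64)
        if midi.shape != times.shape or midi.ndim != 1:
            raise InputError("midi and times_s must be equal-length 1-D arrays")
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise InputError("frame times must be strictly increasing")
        object.__setattr__(self, "midi", midi)
        object.__setattr__(self, "times_s", times)

    def __len__(self) -> int:
        return len(self.midi)

    @property
    def voiced(self) -> np.ndarray:
        return ~np.isnan(self.midi)

    @property
    def voiced_fraction(self) -> float:
        return float(np.mean(self.voiced)) if len(self.midi) else 0.0

    def slice(self, start: int, stop: int) -> "PitchContour":
        return replace(self, midi=self.midi[start:stop], times_s=self.times_s[start:stop])


@dataclass(frozen=True)
class EnvelopeCurve:
    """Per-frame RMS amplitude normalised to [0, 1]; ``silent`` marks all-zero input."""

    values: np.ndarray
    silent: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=np.float64))

    def __len__(self) -> int:
        return len(self.values)


# --------------------------------------------------------------------------
# WAV I/O
# --------------------------------------------------------------------------

def load_wav(path) -> Waveform:
    """Read a WAV file; stereo is averaged to mono, sample rate preserved."""
    rate, data = wavfile.read(path)
    data = np.asarray(data)
    if data.dtype.kind == "i":
        data = data.astype(np.float64) / float(2 ** (8 * data.dtype.itemsize - 1))
    elif data.dtype.kind == "u":  # 8-bit unsigned PCM
        data = (data.astype(np.float64) - 128.0) / 128.0
    else:
        data = data.astype(np.float64)
    if data.ndim == 2:
        data = data.mean(axis=1)
    return Waveform(samples=data, rate_hz=float(rate))


def save_wav(w: Waveform, path) -> None:
    """Write 16-bit PCM."""
    clipped = np.clip(w.samples, -1.0, 1.0)
    wavfile.write(path, int(round(w.rate_hz)), (clipped * 32767.0).astype(np.int16))


# --------------------------------------------------------------------------
# Pitch scale conversions
# --------------------------------------------------------------------------

def hz_to_midi(f_hz):
    """Frequency (Hz) to MIDI note number: 69 + 12*log2(f/440)."""
    f = np.asarray(f_hz, dtype=np.float64)
    if np.any(f <= 0):
        raise InputError("frequency must be positive")
    out = 69.0 + 12.0 * np.log2(f / 440.0)
    return float(out) if np.isscalar(f_hz) else out


def midi_to_hz(m):
    """MIDI note number to frequency (Hz)."""
    m = np.asarray(m, dtype=np.float64)
    out = 440.0 * np.power(2.0, (m - 69.0) / 12.0)
    return float(out) if out.ndim == 0 else out


# --------------------------------------------------------------------------
# YIN
# --------------------------------------------------------------------------

@njit(cache=False)
def _select_lags(cmndf: np.ndarray, tau_min: int, threshold: float):
    """Per frame: first lag whose CMNDF dips below the threshold, descended to
    its local minimum; if no dip, the global CMNDF minimum in range.  Returns
    integer lags and the CMNDF value (aperiodicity) at each."""
    n_frames, n_lags = cmndf.shape
    taus = np.empty(n_frames, dtype=np.int64)
    aper = np.empty(n_frames)
    for f in range(n_frames):
        row = cmndf[f]
        tau = -1
        for t in range(tau_min, n_lags):
            if row[t] < threshold:
                while t + 1 < n_lags and row[t + 1] < row[t]:
                    t += 1
                tau = t
                break
        if tau < 0:
            best = tau_min
            for t in range(tau_min + 1, n_lags):
                if row[t] < row[best]:
                    best = t
            tau = best
        taus[f] = tau
        aper[f] = row[tau]
    return taus, aper


def yin_pitch(w: Waveform, cfg: YinConfig | None = None) -> tuple[PitchContour, EnvelopeCurve]:
    """Estimate the framewise pitch contour of a mono waveform with YIN.

    Returns the contour (MIDI note numbers, NaN where unvoiced) together with
    the RMS envelope on the identical frame grid.  A frame is unvoiced when
    its CMNDF minimum exceeds twice the threshold or its RMS falls below 1%
    of the loudest frame.
    """
    cfg = cfg or YinConfig()
    x = w.samples
    rate = w.rate_hz
    W = cfg.window_for(rate)
    tau_min = max(2, int(math.floor(rate / cfg.maxf0_hz)))
    tau_max = int(math.ceil(rate / cfg.minf0_hz))
    if tau_max <= tau_min:
        raise InputError("f0 search range collapses at this sampling rate")
    frame_len = W + tau_max
    if len(x) < frame_len:
        raise InputError(
            f"audio too short: need {frame_len} samples for minf0={cfg.minf0_hz} Hz, got {len(x)}"
        )
    hop = cfg.hop
    # pad by a whole number of hops on both sides so every input sample is
    # covered by some frame; framing then commutes with hop-aligned shifts
    pad = int(math.ceil((frame_len - hop) / hop)) * hop
    x = np.concatenate([np.zeros(pad), x, np.zeros(pad)])
    n_frames = (len(x) - frame_len) // hop + 1
    starts = np.arange(n_frames, dtype=np.int64) * hop

    energy = np.concatenate(([0.0], np.cumsum(x * x)))
    taus_axis = np.arange(tau_max + 1, dtype=np.int64)
    nfft = next_fast_len(frame_len)

    midi = np.full(n_frames, np.nan)
    rms = np.empty(n_frames)
    chunk = max(1, int(64_000_000 // (nfft * 16)))  # ~64 MB of spectra per chunk
    frames_view = np.lib.stride_tricks.sliding_window_view(x, frame_len)[::hop]
    for lo in range(0, n_frames, chunk):
        hi = min(lo + chunk, n_frames)
        fr = frames_view[lo:hi]
        s = starts[lo:hi]
        # cross-correlation C[t, tau] = sum_j x[t+j] x[t+j+tau], j < W, via FFT
        spec_full = rfft(fr, n=nfft, axis=1)
        spec_head = rfft(fr[:, :W], n=nfft, axis=1)
        corr = irfft(spec_full * np.conj(spec_head), n=nfft, axis=1)[:, : tau_max + 1]
        head_e = energy[s + W] - energy[s]
        idx = s[:, None] + taus_axis[None, :]
        tail_e = energy[idx + W] - energy[idx]
        diff = head_e[:, None] + tail_e - 2.0 * corr
        np.maximum(diff, 0.0, out=diff)  # guard tiny negative round-off
        # cumulative-mean normalisation
        csum = np.cumsum(diff[:, 1:], axis=1)
        cmndf = np.empty_like(diff)
        cmndf[:, 0] = 1.0
        with np.errstate(divide="ignore", invalid="ignore"):
            cmndf[:, 1:] = diff[:, 1:] * taus_axis[1:] / np.where(csum > 0, csum, np.inf)
        taus, aper = _select_lags(cmndf, tau_min, cfg.threshold)
        # parabolic refinement on the raw difference function
        t0 = np.clip(taus, 1, tau_max - 1)
        rows = np.arange(hi - lo)
        d_m, d_0, d_p = diff[rows, t0 - 1], diff[rows, t0], diff[rows, t0 + 1]
        denom = d_m - 2.0 * d_0 + d_p
        delta = np.where(np.abs(denom) > 0, 0.5 * (d_m - d_p) / np.where(denom != 0, denom, 1.0), 0.0)
        delta = np.clip(delta, -1.0, 1.0)
        lag = taus.astype(np.float64)
        refine = t0 == taus  # only refine where neighbours exist
        lag[refine] += delta[refine]
        f0 = rate / lag
        rms[lo:hi] = np.sqrt(head_e / W)
        voiced = (aper <= 2.0 * cfg.threshold) & (f0 > 0)
        vals = np.full(hi - lo, np.nan)
        vals[voiced] = 69.0 + 12.0 * np.log2(f0[voiced] / 440.0)
        midi[lo:hi] = vals

    max_rms = rms.max() if n_frames else 0.0
    silent = max_rms == 0
    if silent:
        midi[:] = np.nan
    else:
        midi[rms < 0.01 * max_rms] = np.nan
    # trimming envelope: RMS over a short window centred in each analysis
    # frame — sharp enough to localise the singing's edges, long enough to
    # ride over individual glottal cycles
    w_env = max(1, int(round(cfg.env_window_s * rate)))
    centres = starts + frame_len // 2
    lo_e = np.clip(centres - w_env // 2, 0, len(x))
    hi_e = np.clip(lo_e + w_env, 0, len(x))
    env_vals = np.sqrt((energy[hi_e] - energy[lo_e]) / w_env)
    peak = env_vals.max()
    if peak > 0:
        env_vals = env_vals / peak
    # clamp out-of-range estimates to unvoiced
    lo_midi = hz_to_midi(cfg.minf0_hz)
    hi_midi = hz_to_midi(cfg.maxf0_hz)
    with np.errstate(invalid="ignore"):
        midi[(midi < lo_midi) | (midi > hi_midi)] = np.nan
    times = (starts - pad + 0.5 * W) / rate
    contour = PitchContour(midi=midi, times_s=times, rate_hz=rate, hop=hop)
    return contour, EnvelopeCurve(values=env_vals, silent=silent)


def amplitude_envelope(w: Waveform, hop: int, window: int) -> EnvelopeCurve:
    """Framewise RMS envelope, max-normalised, on the same padded (hop, window)
    frame grid as :func:`yin_pitch` uses for that window length."""
    x = w.samples
    if len(x) < window:
        raise InputError("audio shorter than one analysis window")
    pad = int(math.ceil((window - hop) / hop)) * hop
    x = np.concatenate([np.zeros(pad), x, np.zeros(pad)])
    energy = np.concatenate(([0.0], np.cumsum(x * x)))
    n_frames = (len(x) - window) // hop + 1
    s = np.arange(n_frames, dtype=np.int64) * hop
    rms = np.sqrt((energy[s + window] - energy[s]) / window)
    peak = rms.max()
    if peak == 0:
        return EnvelopeCurve(values=rms, silent=True)
    return EnvelopeCurve(values=rms / peak, silent=False)


# --------------------------------------------------------------------------
# Trimming and gap filling
# --------------------------------------------------------------------------

def trim_silence(
    contour: PitchContour,
    env: EnvelopeCurve,
    frac: float = 0.10,
    min_frames: int = 10,
) -> PitchContour:
    """Remove the silent head and tail of a recording.

    Drops leading and trailing frames whose envelope falls below ``frac`` of
    the maximum, then checks that the retained central window's *median*
    envelope exceeds ``frac``.  Interior frames are never reordered or
    removed; the output is always a contiguous slice of the input.
    """
    if len(contour) != len(env):
        raise InputError("contour and envelope must share one frame grid")
    if env.silent:
        raise SilentRecordingError("recording is silent (all-zero envelope)")
    v = env.values
    loud = np.flatnonzero(v >= frac)
    if loud.size == 0 or loud[-1] - loud[0] + 1 < min_frames:
        raise SilentRecordingError(
            f"fewer than {min_frames} frames reach {frac} of the envelope maximum"
        )
    lo, hi = int(loud[0]), int(loud[-1]) + 1
    if np.median(v[lo:hi]) <= frac:
        raise SilentRecordingError(
            f"median envelope of the non-silent window does not exceed {frac}"
        )
    return contour.slice(lo, hi)


def fill_unvoiced(contour: PitchContour, max_gap_s: float = 0.25) -> PitchContour:
    """Produce a gap-free contour for alignment.

    Leading/trailing unvoiced frames are dropped.  Interior gaps no longer
    than ``max_gap_s`` are bridged linearly; longer gaps hold the nearest
    voiced value from each side (split at the gap midpoint).
    """
    voiced = contour.voiced
    if not voiced.any():
        raise SilentRecordingError("no voiced frames in contour")
    idx = np.flatnonzero(voiced)
    sub = contour.slice(int(idx[0]), int(idx[-1]) + 1)
    midi = sub.midi.copy()
    frame_dt = contour.hop / contour.rate_hz
    max_gap = max(1, int(round(max_gap_s / frame_dt)))
    nan = np.isnan(midi)
    if nan.any():
        i = 0
        n = len(midi)
        while i < n:
            if not nan[i]:
                i += 1
                continue
            j = i
            while j < n and nan[j]:
                j += 1
            left, right = midi[i - 1], midi[j]  # interior: both exist
            gap = j - i
            if gap <= max_gap:
                midi[i:j] = left + (right - left) * np.arange(1, gap + 1) / (gap + 1)
            else:
                half = (gap + 1) // 2
                midi[i : i + half] = left
                midi[i + half : j] = right
            i = j
    return replace(sub, midi=midi)
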