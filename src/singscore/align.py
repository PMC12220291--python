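"""Geometric registration of a melody template to a sung pitch contour.

The template is time-stretched (previous-neighbour) to the contour length,
vertically translated so its mean pitch matches the contour's, and then
time-aligned with classical unconstrained dynamic time warping using the
1-D Euclidean local cost |a_i - b_j| and the symmetric step set
(1,0), (0,1), (1,1) with full boundary conditions.

The warping path's departure from the diagonal, reduced to one shift value
per contour frame and expressed in eighth-note units, is the raw material
of the rhythm score.  Sign convention: a positive shift means the sung
event occurs earlier than its template position (the contour must be pushed
forward to align).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .errors import InputError
from .template import PianoRollCurve, stretch_previous_neighbor

__all__ = ["WarpPath", "AlignedPair", "register_template", "dtw_euclidean", "shift_series"]


@dataclass(frozen=True)
class WarpPath:
    """Monotone index correspondence between contour frames and template frames."""

    pairs: np.ndarray  # (L, 2) int array of (contour index, template index)

    def __post_init__(self) -> None:
        pairs = np.asarray(self.pairs, dtype=np.int64)
        if pairs.ndim != 2 or pairs.shape[1] != 2 or len(pairs) == 0:
            raise InputError("warp path must be a non-empty (L, 2) index array")
        steps = np.diff(pairs, axis=0)
        if pairs[0, 0] != 0 or pairs[0, 1] != 0:
            raise InputError("warp path must start at (0, 0)")
        if len(steps) and not (
            (steps >= 0).all() and (steps <= 1).all() and (steps.sum(axis=1) >= 1).all()
        ):
            raise InputError("warp path steps must advance each index by 0 or 1, not both 0")
        object.__setattr__(self, "pairs", pairs)

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def contour_indices(self) -> np.ndarray:
        return self.pairs[:, 0]

    @property
    def template_indices(self) -> np.ndarray:
        return self.pairs[:, 1]


@dataclass(frozen=True)
class AlignedPair:
    """A contour and an equal-length registered template with their warp path."""

    contour: np.ndarray
    template: PianoRollCurve
    path: WarpPath
    eighth_len: float

    def __post_init__(self) -> None:
        if len(self.contour) != len(self.template):
            raise InputError("aligned contour and template must have equal length")


def register_template(curve: PianoRollCurve, contour) -> PianoRollCurve:
    """Stretch a piano-roll curve to the contour length and shift its mean pitch
    onto the contour mean."""
    contour = np.asarray(contour, dtype=np.float64)
    if contour.ndim != 1 or contour.size == 0:
        raise InputError("contour must be a non-empty 1-D sequence")
    stretched = stretch_previous_neighbor(curve, len(contour))
    shift = contour.mean() - stretched.values.mean()
    return PianoRollCurve(
        values=stretched.values + shift,
        eighth_len=stretched.eighth_len,
        note_ids=stretched.note_ids,
    )


@njit(cache=False)
def _dtw_fill(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    n, m = len(a), len(b)
    D = np.empty((n, m))
    D[0, 0] = abs(a[0] - b[0])
    for j in range(1, m):
        D[0, j] = D[0, j - 1] + abs(a[0] - b[j])
    for i in range(1, n):
        D[i, 0] = D[i - 1, 0] + abs(a[i] - b[0])
        for j in range(1, m):
            best = D[i - 1, j - 1]
            if D[i - 1, j] < best:
                best = D[i - 1, j]
            if D[i, j - 1] < best:
                best = D[i, j - 1]
            D[i, j] = abs(a[i] - b[j]) + best
    return D


@njit(cache=False)
def _dtw_backtrack(D: np.ndarray) -> np.ndarray:
    n, m = D.shape
    path = np.empty((n + m - 1, 2), dtype=np.int64)
    k = n + m - 2
    i, j = n - 1, m - 1
    path[k, 0], path[k, 1] = i, j
    while i > 0 or j > 0:
        if i == 0:
            j -= 1
        elif j == 0:
            i -= 1
        else:
            # tie-break preference: diagonal, then contour-advance, then template-advance
            diag, up, left = D[i - 1, j - 1], D[i - 1, j], D[i, j - 1]
            if diag <= up and diag <= left:
                i -= 1
                j -= 1
            elif up <= left:
                i -= 1
            else:
                j -= 1
        k -= 1
        path[k, 0], path[k, 1] = i, j
    return path[k:]


def dtw_euclidean(a, b) -> tuple[WarpPath, float]:
    """Unconstrained DTW of two 1-D sequences under the |a_i - b_j| local cost.

    Returns one optimal warp path (deterministic tie-breaking: diagonal,
    then first-sequence advance, then second-sequence advance) and the
    optimal cumulative cost.
    """
    a = np.ascontiguousarray(a, dtype=np.float64)
    b = np.ascontiguousarray(b, dtype=np.float64)
    if a.ndim != 1 or b.ndim != 1 or a.size == 0 or b.size == 0:
        raise InputError("DTW inputs must be non-empty 1-D sequences")
    if np.isnan(a).any() or np.isnan(b).any():
        raise InputError("DTW inputs must be gap-free (no NaN)")
    D = _dtw_fill(a, b)
    path = _dtw_backtrack(D)
    return WarpPath(pairs=path), float(D[-1, -1])


def shift_series(path: WarpPath, eighth_len: float) -> np.ndarray:
    """Reduce a warp path to one temporal shift per contour frame, in eighths.

    For contour frame ``i`` the shift is ``(mean matched template index - i) /
    eighth_len``; many-to-one matches are averaged.
    """
    if eighth_len <= 0:
        raise InputError("eighth_len must be positive")
    ci = path.contour_indices
    tj = path.template_indices
    n = int(ci[-1]) + 1
    sums = np.zeros(n)
    counts = np.zeros(n)
    np.add.at(sums, ci, tj)
    np.add.at(counts, ci, 1.0)
    mean_j = sums / counts
    return (mean_j - np.arange(n)) / eighth_len
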