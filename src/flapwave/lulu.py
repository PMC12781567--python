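"""LULU nonlinear smoothers.

LULU operators are rank-based smoothers built from running minima and
maxima. The floor operator ``L_n`` removes upward impulses no wider than
``n`` samples; its dual ``U_n`` removes downward impulses. Compositions
``L_n(U_n(x))`` and ``U_n(L_n(x))`` are idempotent smoothers that strip
impulsive noise while preserving edges, which makes the residual
``x - smooth(x)`` a clean carrier for spike (wingbeat) detection.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import maximum_filter1d, minimum_filter1d

__all__ = ["lulu_floor", "lulu_ceil", "lulu_smooth"]


def _check(x: np.ndarray, n: int) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("input must be a 1-D sequence")
    if n < 1:
        raise ValueError("operator width n must be >= 1")
    if x.size <= 2 * n:
        raise ValueError(f"sequence length {x.size} must exceed 2*n = {2 * n}")
    return x


def _running(filt, x: np.ndarray, n: int, anchor: str) -> np.ndarray:
    """Running min/max over a width-(n+1) window anchored left or right.

    'right' covers [i-n, i], 'left' covers [i, i+n]. scipy's origin
    shifts the window toward lower indices when positive:
    window = [i - size//2 - origin, i + size-1-size//2 - origin].
    """
    s = n + 1
    if anchor == "right":
        return filt(x, s, mode="nearest", origin=n - s // 2)
    return filt(x, s, mode="nearest", origin=-(s // 2))


def lulu_floor(x: np.ndarray, n: int) -> np.ndarray:
    """Floor operator ``L_n``: running max (width n+1) of running min (width n+1).

    ``L_n(x)_i = max_{j in [i-n, i]} min_{k in [j, j+n]} x_k``, with the
    sequence extended constantly beyond its ends (the infinite-extension
    definition, under which every monotone sequence is a fixed point).
    Removes upward impulses of width <= n.
    """
    x = _check(x, n)
    xp = np.pad(x, n, mode="edge")
    inner = _running(minimum_filter1d, xp, n, "left")
    return _running(maximum_filter1d, inner, n, "right")[n:-n]


def lulu_ceil(x: np.ndarray, n: int) -> np.ndarray:
    """Ceiling operator ``U_n``: running min of running max (dual of ``L_n``)."""
    x = _check(x, n)
    xp = np.pad(x, n, mode="edge")
    inner = _running(maximum_filter1d, xp, n, "left")
    return _running(minimum_filter1d, inner, n, "right")[n:-n]


def lulu_smooth(x: np.ndarray, n: int, composition: str = "LU") -> np.ndarray:
    """Apply a LULU composition.

    Parameters
    ----------
    x : array
        Input sequence.
    n : int
        Operator width in samples; impulses up to this width are removed.
    composition : {"LU", "UL"}
        Application order: ``"LU"`` applies ``L_n`` first and smooths the
        result with ``U_n`` (the order that strips upward spike trains —
        ``U_n`` first would bridge the short gaps inside a wingbeat burst
        into a plateau too wide for ``L_n`` to remove); ``"UL"`` is the
        reverse. Both compositions are idempotent.
    """
    if composition == "LU":
        return lulu_ceil(lulu_floor(x, n), n)
    if composition == "UL":
        return lulu_floor(lulu_ceil(x, n), n)
    raise ValueError(f"composition must be 'LU' or 'UL', got {composition!r}")
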