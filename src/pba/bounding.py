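"""Bounding functions: the CDF-like curves a p-box is made of.

Every bounding function is a non-decreasing, right-continuous map from the
real line to [0, 1] that is 0 far enough left and 1 at or beyond the support
maximum.  Three concrete representations are provided:

* :class:`PiecewiseBF` — an ordered sequence of breakpoints with closed-form
  segment expressions (constants, Markov-type ratios, Cantelli-type ratios);
  all the analytic p-box formulas are built from this.
* :class:`EnvelopeBF` — pointwise max/min over other bounding functions,
  used for intersections of p-boxes.
* :class:`StepBF` — a staircase through sample points, used when importing
  a p-box from a delimited-text export or when wrapping weighted ECDFs.

The convention at a breakpoint is right-continuity: the breakpoint itself
belongs to the segment on its right.
"""

from __future__ import annotations

from typing import Callable, Sequence, Union

import numpy as np

Piece = Union[float, Callable[[np.ndarray], np.ndarray]]


class BoundingFunction:
    """Abstract non-decreasing right-continuous map R -> [0, 1]."""

    #: sorted breakpoints where the expression changes (finite values only)
    breakpoints: tuple
    #: breakpoints at which the function is known to be continuous
    continuous_breaks: tuple = ()

    def __call__(self, theta):
        raise NotImplementedError

    def _eval_scalar(self, theta: float) -> float:
        return float(self(np.asarray([theta]))[0])


class PiecewiseBF(BoundingFunction):
    """Closed-form piecewise function.

    ``pieces[i]`` applies on ``[breaks[i-1], breaks[i])`` (with implied
    ``breaks[-1] = -inf`` and ``breaks[len] = +inf``); a piece may be a float
    or a vectorized callable.  ``breaks`` must be non-decreasing; a repeated
    break yields an empty segment, which is convenient for degenerate
    parameter values (e.g. xi1 == a).
    """

    def __init__(self, breaks: Sequence[float], pieces: Sequence[Piece],
                 continuous_breaks: Sequence[float] = ()):
        breaks = tuple(float(x) for x in breaks)
        if list(breaks) != sorted(breaks):
            raise ValueError("breakpoints must be sorted")
        if len(pieces) != len(breaks) + 1:
            raise ValueError("need len(breaks)+1 pieces")
        self.breakpoints = breaks
        self.pieces = tuple(pieces)
        self.continuous_breaks = tuple(continuous_breaks)
        self._breaks_arr = np.asarray(breaks, dtype=float)

    def __call__(self, theta):
        t = np.asarray(theta, dtype=float)
        scalar = t.ndim == 0
        t = np.atleast_1d(t)
        idx = np.searchsorted(self._breaks_arr, t, side="right")
        out = np.empty(t.shape, dtype=float)
        for i, piece in enumerate(self.pieces):
            mask = idx == i
            if not mask.any():
                continue
            if callable(piece):
                out[mask] = piece(t[mask])
            else:
                out[mask] = piece
        np.clip(out, 0.0, 1.0, out=out)
        return float(out[0]) if scalar else out


class EnvelopeBF(BoundingFunction):
    """Pointwise max or min over member bounding functions."""

    def __init__(self, members: Sequence[BoundingFunction], mode: str):
        if mode not in ("max", "min"):
            raise ValueError("mode must be 'max' or 'min'")
        if not members:
            raise ValueError("empty envelope")
        self.members = tuple(members)
        self.mode = mode
        self.breakpoints = tuple(
            sorted({bp for m in members for bp in m.breakpoints})
        )

    def __call__(self, theta):
        vals = [m(theta) for m in self.members]
        stacked = np.stack([np.atleast_1d(np.asarray(v, float)) for v in vals])
        out = stacked.max(axis=0) if self.mode == "max" else stacked.min(axis=0)
        if np.ndim(theta) == 0:
            return float(out[0])
        return out


class StepBF(BoundingFunction):
    """Right-continuous staircase through ``(thetas, values)``.

    ``side='right'`` (default) gives the value of the last point at or
    before theta — exact for staircases sampled from a right-continuous
    non-decreasing function, and a conservative *under*-estimate between
    sample points.  ``side='left'`` gives the value of the next point at or
    after theta — a conservative *over*-estimate between sample points.
    The two sides are used for imported lower and upper bounds respectively
    so that a re-imported p-box still encloses everything the original did.
    """

    def __init__(self, thetas: Sequence[float], values: Sequence[float],
                 side: str = "right", fill_left: float = 0.0,
                 fill_right: float = 1.0):
        thetas = np.asarray(thetas, dtype=float)
        values = np.asarray(values, dtype=float)
        if thetas.ndim != 1 or thetas.shape != values.shape:
            raise ValueError("thetas and values must be 1-D and equal length")
        if thetas.size == 0:
            raise ValueError("empty staircase")
        order = np.argsort(thetas, kind="stable")
        self.thetas = thetas[order]
        self.values = np.maximum.accumulate(values[order])
        if side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")
        self.side = side
        self.fill_left = float(fill_left)
        self.fill_right = float(fill_right)
        self.breakpoints = tuple(self.thetas)

    def __call__(self, theta):
        t = np.asarray(theta, dtype=float)
        scalar = t.ndim == 0
        t = np.atleast_1d(t)
        if self.side == "right":
            idx = np.searchsorted(self.thetas, t, side="right") - 1
            out = np.where(idx >= 0, self.values[np.clip(idx, 0, None)],
                           self.fill_left)
        else:
            idx = np.searchsorted(self.thetas, t, side="left")
            inside = idx < self.thetas.size
            out = np.where(inside,
                           self.values[np.clip(idx, None, self.thetas.size - 1)],
                           self.fill_right)
        out = np.clip(out, 0.0, 1.0)
        return float(out[0]) if scalar else out


def step_function(at: float, low: float = 0.0, high: float = 1.0) -> PiecewiseBF:
    """Unit step: ``low`` strictly below ``at``, ``high`` at and above it."""
    return PiecewiseBF([at], [low, high])


def weighted_ecdf(points: Sequence[float], masses: Sequence[float]) -> StepBF:
    """Right-continuous weighted empirical CDF of ``points``."""
    points = np.asarray(points, dtype=float)
    masses = np.asarray(masses, dtype=float)
    order = np.argsort(points, kind="stable")
    pts = points[order]
    cum = np.cumsum(masses[order])
    cum /= cum[-1]
    # merge duplicate atoms so the staircase has one riser per location
    uniq, last_idx = np.unique(pts[::-1], return_index=True)
    cum_at = cum[::-1][last_idx]
    return StepBF(uniq, cum_at, side="right")
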