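"""Slicing p-boxes into interval-mass structures and joint hyperrectangles.

A p-box is discretized by partitioning the probability axis [0, 1] into
sub-intervals (equiprobable by default) and, for each sub-interval
``(c_j, d_j]``, taking the widest parameter interval consistent with the
bounds: the lower endpoint comes from the upper bound's quasi-inverse at
``c_j`` and the upper endpoint from the lower bound's quasi-inverse at
``d_j`` (outer discretization — conservative, never under-covers).  The
result is a small Dempster–Shafer-style structure of focal intervals with
masses.  Joint structures over several parameters are full-factorial
Cartesian products with product masses (random set independence).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence, Union

import numpy as np

from .errors import InvalidInputError
from .pbox import PBox, quasi_inverse

__all__ = ["DiscretizedPBox", "Hyperrectangle", "slice_pbox",
           "enumerate_hyperrectangles"]

MASS_TOL = 1e-12


@dataclass(frozen=True)
class DiscretizedPBox:
    """Interval-mass representation of one p-box.

    Per slice ``j``: probability sub-interval ``(c[j], d[j]]``, mass
    ``mass[j]``, and parameter interval ``[lo[j], hi[j]]``.
    """

    c: np.ndarray
    d: np.ndarray
    mass: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    source: Optional[PBox] = field(default=None, compare=False)

    def __post_init__(self):
        n = len(self.mass)
        if not (len(self.c) == len(self.d) == len(self.lo) == len(self.hi) == n):
            raise InvalidInputError("slice arrays must have equal length")
        if abs(float(np.sum(self.mass)) - 1.0) > MASS_TOL:
            raise InvalidInputError("slice masses must sum to 1")
        if np.any(self.lo > self.hi + 1e-15):
            raise InvalidInputError("slice intervals must satisfy lo <= hi")

    def __len__(self) -> int:
        return len(self.mass)

    def intervals(self) -> np.ndarray:
        return np.column_stack([self.lo, self.hi])


@dataclass(frozen=True)
class Hyperrectangle:
    """One joint focal element: a box in parameter space with a mass."""

    index: tuple
    intervals: tuple  # of (lo, hi) pairs
    mass: float


def slice_pbox(p: PBox, n: int, partition: Union[str, Sequence[float]] = "equal",
               scheme: str = "outer") -> DiscretizedPBox:
    """Discretize a p-box into ``n`` probability slices.

    ``partition`` is either ``"equal"`` (masses 1/n) or an explicit mass
    vector summing to 1 (then ``n`` must match its length).  Only the
    ``"outer"`` discretization scheme is implemented; it is the
    conservative choice and the only one that never under-covers.
    """
    if scheme != "outer":
        raise InvalidInputError(
            f"discretization scheme {scheme!r} is recognized but not "
            "implemented; only 'outer' is supported"
        )
    if n < 1:
        raise InvalidInputError(f"need n >= 1 slices, got {n}")
    if isinstance(partition, str):
        if partition != "equal":
            raise InvalidInputError(f"unknown partition scheme {partition!r}")
        masses = np.full(n, 1.0 / n)
    else:
        masses = np.asarray(partition, dtype=float)
        if masses.ndim != 1 or len(masses) != n:
            raise InvalidInputError("partition mass vector must have length n")
        if np.any(masses <= 0) or abs(masses.sum() - 1.0) > MASS_TOL:
            raise InvalidInputError("partition masses must be positive and sum to 1")
    edges = np.concatenate([[0.0], np.cumsum(masses)])
    edges[-1] = 1.0
    c, d = edges[:-1], edges[1:]
    lo = np.array([quasi_inverse(p, cj).left for cj in c])
    hi = np.array([quasi_inverse(p, dj).right for dj in d])
    # outer endpoints are monotone in j by construction; enforce against
    # bisection rounding so downstream code can rely on it
    lo = np.maximum.accumulate(lo)
    hi = np.maximum.accumulate(hi)
    hi = np.maximum(hi, lo)
    return DiscretizedPBox(c=c, d=d, mass=masses, lo=lo, hi=hi, source=p)


def enumerate_hyperrectangles(
    ds: Sequence[DiscretizedPBox],
) -> Iterator[Hyperrectangle]:
    """Lazily yield the full factorial product of slices across parameters.

    Iteration order is lexicographic in the multi-index; the mass of each
    hyperrectangle is the product of its member slice masses.
    """
    ds = list(ds)
    if not ds:
        raise InvalidInputError("need at least one discretized p-box")
    index_ranges = [range(len(d)) for d in ds]
    for multi in itertools.product(*index_ranges):
        mass = 1.0
        ivs = []
        for d, j in zip(ds, multi):
            mass *= float(d.mass[j])
            ivs.append((float(d.lo[j]), float(d.hi[j])))
        yield Hyperrectangle(index=multi, intervals=tuple(ivs), mass=mass)
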