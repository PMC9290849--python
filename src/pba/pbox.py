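"""Probability boxes from minimal data.

A p-box is a pair of bounding CDFs (a lower-bounding function ``lower`` and
an upper-bounding function ``upper``) on a finite support ``[a, b]``; every
distribution consistent with the summary statistics has its CDF pointwise
between them.  This module provides the closed-form constructions for the
four primitive data combinations

* ``{a, b}``                 — vacuous box (unit steps at the endpoints),
* ``{a, b, median}``         — half steps at the median,
* ``{a, b, mean}``           — Markov-type ratio bounds,
* ``{a, b, mean, sd}``       — Cantelli-type four-segment bounds with
  internal breakpoints ``xi1 = mean - sd^2/(b - mean)`` and
  ``xi2 = mean + sd^2/(mean - a)``,

plus their intersection (pointwise max of lower bounds / min of upper
bounds) for richer data combinations, evaluation, quasi-inverses, and
validity/enclosure diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, NamedTuple, Optional, Sequence, Union

import numpy as np

from .bounding import BoundingFunction, EnvelopeBF, PiecewiseBF, step_function
from .errors import InconsistentDataError, InvalidInputError
from .minimal import MinimalData

__all__ = [
    "PBox", "make_pbox", "make_pbox_minmax", "make_pbox_median",
    "make_pbox_mean", "make_pbox_mean_sd", "eval_bounds", "quasi_inverse",
    "verify_pbox", "encloses", "VerifyReport",
]

#: absolute tolerance on probabilities for closed-form comparisons
PROB_TOL = 1e-9


@dataclass(frozen=True)
class PBox:
    """A pair of bounding CDFs over a bounded support.

    ``lower`` is the lower-bounding function (reaches 1 last); ``upper`` the
    upper-bounding function (reaches 1 first).  ``data`` records the
    summary statistics the box was built from, when applicable.
    """

    lower: BoundingFunction
    upper: BoundingFunction
    a: float
    b: float
    data: Optional[MinimalData] = None
    label: str = field(default="", compare=False)

    @property
    def support(self) -> tuple:
        return (self.a, self.b)

    def __call__(self, theta):
        return eval_bounds(self, theta)

    def quasi_inverse(self, prob: float) -> "QuasiInverse":
        return quasi_inverse(self, prob)

    def grid(self, n: int = 512) -> np.ndarray:
        """Evaluation grid: ``n`` equispaced points plus all breakpoints."""
        pts = np.linspace(self.a, self.b, n)
        bps = [bp for f in (self.lower, self.upper) for bp in f.breakpoints
               if self.a <= bp <= self.b]
        return np.unique(np.concatenate([pts, np.asarray(bps, float)]))


class QuasiInverse(NamedTuple):
    left: float
    right: float


# ---------------------------------------------------------------------------
# primitive constructors
# ---------------------------------------------------------------------------

def make_pbox_minmax(d: MinimalData) -> PBox:
    """Vacuous p-box from support bounds only.

    The lower bound is the unit step at ``b`` (all mass as late as
    possible), the upper bound the unit step at ``a``.
    """
    _require(d, set())
    return PBox(lower=step_function(d.b), upper=step_function(d.a),
                a=d.a, b=d.b, data=d, label=d.name)


def make_pbox_median(d: MinimalData) -> PBox:
    """P-box from support bounds and the median: half steps at ``median``."""
    _require(d, {"median"})
    m = d.median
    lower = PiecewiseBF([m, d.b], [0.0, 0.5, 1.0])
    upper = PiecewiseBF([d.a, m], [0.0, 0.5, 1.0])
    return PBox(lower=lower, upper=upper, a=d.a, b=d.b, data=d, label=d.name)


def make_pbox_mean(d: MinimalData) -> PBox:
    """P-box from support bounds and the mean (Markov-type ratio bounds)."""
    _require(d, {"mean"})
    a, b, mu = d.a, d.b, d.mean
    if mu == a or mu == b:
        # the mean pinned at an endpoint forces a point mass there
        step = step_function(mu)
        return PBox(lower=step, upper=step, a=a, b=b, data=d, label=d.name)
    lower = PiecewiseBF([mu, b], [0.0, lambda t: (t - mu) / (t - a), 1.0],
                        continuous_breaks=[mu])
    upper = PiecewiseBF([a, mu], [0.0, lambda t: (b - mu) / (b - t), 1.0],
                        continuous_breaks=[mu])
    return PBox(lower=lower, upper=upper, a=a, b=b, data=d, label=d.name)


def make_pbox_mean_sd(d: MinimalData) -> PBox:
    """P-box from support bounds, mean and SD (Cantelli-type bounds).

    Both bounds have four segments joined continuously at the internal
    breakpoints ``xi1`` and ``xi2``; as ``sd -> 0`` they collapse to the
    unit step at the mean.
    """
    _require(d, {"mean", "sd"})
    a, b, mu, sd = d.a, d.b, d.mean, d.sd
    if sd == 0.0 or mu == a or mu == b:
        step = step_function(mu)
        return PBox(lower=step, upper=step, a=a, b=b, data=d, label=d.name)
    var = sd * sd
    xi1 = mu - var / (b - mu)
    xi2 = mu + var / (mu - a)
    # rounding can push the xis a hair outside [a, b]; feasibility was checked
    xi1 = min(max(xi1, a), b)
    xi2 = min(max(xi2, a), b)
    lower = PiecewiseBF(
        [xi1, xi2, b],
        [0.0,
         lambda t: (var + (b - mu) * (t - mu)) / ((b - a) * (t - a)),
         lambda t: (t - mu) ** 2 / ((t - mu) ** 2 + var),
         1.0],
        continuous_breaks=[xi1, xi2],
    )
    upper = PiecewiseBF(
        [a, xi1, xi2],
        [0.0,
         lambda t: var / ((mu - t) ** 2 + var),
         lambda t: ((b - mu) * (b - a + mu - t) - var) / ((b - a) * (b - t)),
         1.0],
        continuous_breaks=[xi1, xi2],
    )
    return PBox(lower=lower, upper=upper, a=a, b=b, data=d, label=d.name)


_PRIMITIVES = {
    frozenset(): make_pbox_minmax,
    frozenset({"median"}): make_pbox_median,
    frozenset({"mean"}): make_pbox_mean,
    frozenset({"mean", "sd"}): make_pbox_mean_sd,
}


def make_pbox(d: Union[MinimalData, dict], label: str = "") -> PBox:
    """Build the p-box for an arbitrary minimal-data record.

    Records matching one of the four primitive combinations use the
    closed-form constructor directly.  Richer combinations (median and
    mean together, with or without SD) take the intersection of all
    applicable primitive boxes: the pointwise maximum of the lower bounds
    and minimum of the upper bounds.  If the intersected bounds cross, the
    statistics are jointly infeasible and an
    :class:`~pba.errors.InconsistentDataError` is raised.
    """
    if isinstance(d, dict):
        d = MinimalData.from_dict(d)
    stats = d.stats()
    ctor = _PRIMITIVES.get(stats)
    if ctor is not None:
        p = ctor(d)
        return replace(p, label=label or p.label)

    members = [make_pbox_minmax(MinimalData(d.a, d.b))]
    if d.median is not None:
        members.append(make_pbox_median(MinimalData(d.a, d.b, median=d.median)))
    if d.mean is not None and d.sd is not None:
        members.append(
            make_pbox_mean_sd(MinimalData(d.a, d.b, mean=d.mean, sd=d.sd)))
    elif d.mean is not None:
        members.append(make_pbox_mean(MinimalData(d.a, d.b, mean=d.mean)))
    lower = EnvelopeBF([m.lower for m in members], "max")
    upper = EnvelopeBF([m.upper for m in members], "min")
    p = PBox(lower=lower, upper=upper, a=d.a, b=d.b, data=d,
             label=label or d.name)
    grid = p.grid(2001)
    lo, up = eval_bounds(p, grid)
    if np.any(lo > up + PROB_TOL):
        t = float(grid[np.argmax(lo - up)])
        raise InconsistentDataError(
            f"summary statistics are jointly infeasible: intersected bounds "
            f"cross near theta={t:.6g}"
        )
    return p


def _require(d: MinimalData, stats: set):
    if not isinstance(d, MinimalData):
        raise InvalidInputError("expected a MinimalData record")
    if d.stats() != frozenset(stats):
        want = sorted(stats) if stats else "none"
        raise InvalidInputError(
            f"constructor expects optional statistics {want}, "
            f"record has {sorted(d.stats()) or 'none'}"
        )


# ---------------------------------------------------------------------------
# evaluation and inversion
# ---------------------------------------------------------------------------

def eval_bounds(p: PBox, theta):
    """Evaluate ``(lower(theta), upper(theta))``, vectorized over theta."""
    return p.lower(theta), p.upper(theta)


def quasi_inverse(p: PBox, prob: float, tol: Optional[float] = None) -> QuasiInverse:
    """Quasi-inverse of a p-box at probability level ``prob``.

    Returns ``left = inf{theta : upper(theta) >= prob}`` and
    ``right = sup{theta : lower(theta) <= prob}``, both clamped to the
    support.  Computed by bisection on the monotone bounding functions
    (tolerance ``1e-10 * (b - a)`` by default), with results snapped to
    nearby breakpoints so that step-function inverses come out exact.
    """
    if not 0.0 <= prob <= 1.0 or not np.isfinite(prob):
        raise InvalidInputError(f"prob must be in [0, 1], got {prob}")
    a, b = p.a, p.b
    if tol is None:
        tol = 1e-10 * (b - a)

    if p.upper(a) >= prob:
        left = a
    else:
        lo, hi = a, b          # invariant: upper(lo) < prob <= upper(hi)
        while hi - lo > tol:
            mid = 0.5 * (lo + hi)
            if p.upper(mid) >= prob:
                hi = mid
            else:
                lo = mid
        left = _snap(hi, p.upper.breakpoints, 10 * tol, a, b)

    if prob >= 1.0 or p.lower(b) <= prob:
        right = b
    elif p.lower(a) > prob:
        right = a
    else:
        lo, hi = a, b          # invariant: lower(lo) <= prob < lower(hi)
        while hi - lo > tol:
            mid = 0.5 * (lo + hi)
            if p.lower(mid) <= prob:
                lo = mid
            else:
                hi = mid
        right = _snap(hi, p.lower.breakpoints, 10 * tol, a, b)

    left = min(max(left, a), b)
    right = min(max(right, a), b)
    if left > right:
        left = right = 0.5 * (left + right)
    return QuasiInverse(left, right)


def _snap(x: float, breakpoints: Sequence[float], atol: float,
          a: float, b: float) -> float:
    for bp in list(breakpoints) + [a, b]:
        if abs(x - bp) <= atol:
            return bp
    return x


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

class VerifyReport(NamedTuple):
    passed: bool
    failures: tuple  # of (check_name, theta)

    @property
    def first_violation(self):
        return self.failures[0] if self.failures else None


def verify_pbox(p: PBox, grid_size: int = 1001, tol: float = PROB_TOL) -> VerifyReport:
    """Check p-box validity on a grid.

    Verifies monotonicity of both bounds, range within [0, 1], the ordering
    ``lower <= upper``, the tail values (0 strictly below ``a``, 1 at and
    above ``b``), and continuity at breakpoints declared continuous.
    """
    if grid_size < 2:
        raise InvalidInputError("grid_size must be >= 2")
    failures = []
    pad = 1e-6 * (p.b - p.a) + 1e-12
    grid = p.grid(grid_size)
    lo, up = eval_bounds(p, grid)
    for name, vals in (("lower", lo), ("upper", up)):
        dv = np.diff(vals)
        bad = np.nonzero(dv < -tol)[0]
        if bad.size:
            failures.append((f"{name} non-decreasing", float(grid[bad[0] + 1])))
        bad = np.nonzero((vals < -tol) | (vals > 1 + tol))[0]
        if bad.size:
            failures.append((f"{name} in [0,1]", float(grid[bad[0]])))
    bad = np.nonzero(lo > up + tol)[0]
    if bad.size:
        failures.append(("lower <= upper", float(grid[bad[0]])))
    below = p.a - pad
    if abs(p.lower(below)) > tol or abs(p.upper(below)) > tol:
        failures.append(("zero below support", below))
    if abs(p.lower(p.b) - 1) > tol or abs(p.upper(p.b) - 1) > tol:
        failures.append(("one at support max", p.b))
    eps = 1e-9 * (p.b - p.a)
    for f in (p.lower, p.upper):
        for bp in getattr(f, "continuous_breaks", ()):
            if p.a < bp < p.b and abs(f(bp) - f(bp - eps)) > max(tol, 1e-7):
                failures.append(("continuity at breakpoint", float(bp)))
    return VerifyReport(passed=not failures, failures=tuple(failures))


def encloses(p: PBox, cdf, eps: Optional[float] = None,
             confidence: float = 0.999, grid_size: int = 512) -> bool:
    """Does the p-box enclose a CDF (callable) or an empirical sample?

    For a callable CDF the comparison is pointwise on a grid with absolute
    tolerance ``1e-9``.  For a sample (array of draws) the empirical CDF is
    compared with a two-sided Dvoretzky–Kiefer–Wolfowitz band at the given
    confidence added to the tolerance.  ``eps`` adds extra slack on top
    (used e.g. for discretized outcome boxes, where one slice mass of
    slack is inherent to the outer approximation).
    """
    extra = 0.0 if eps is None else float(eps)
    if callable(cdf):
        grid = p.grid(grid_size)
        vals = np.asarray(cdf(grid), dtype=float)
        lo, up = eval_bounds(p, grid)
        tol = PROB_TOL + extra
        return bool(np.all(vals >= lo - tol) and np.all(vals <= up + tol))

    sample = np.sort(np.asarray(cdf, dtype=float))
    n = sample.size
    if n == 0:
        raise InvalidInputError("empty sample")
    alpha = 1.0 - confidence
    dkw = np.sqrt(np.log(2.0 / alpha) / (2.0 * n))
    tol = dkw + extra + PROB_TOL
    ecdf_hi = np.arange(1, n + 1) / n        # value at each sample point
    ecdf_lo = np.arange(0, n) / n            # value just below it
    lo_at, up_at = eval_bounds(p, sample)
    tiny = 1e-12 * (p.b - p.a) + 1e-300
    lo_before = p.lower(sample - tiny)
    ok_upper = np.all(ecdf_hi <= up_at + tol)
    ok_lower = np.all(ecdf_lo >= lo_before - tol)
    # also the flat stretch from the largest sample point to b
    ok_tail = 1.0 >= p.lower(p.b) - tol
    return bool(ok_upper and ok_lower and ok_tail)
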