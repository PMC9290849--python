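"""Randomized test inputs and brute-force oracles.

This module is first-class, tested code: it generates distributions that
are provably consistent with a given minimal-data record (for enclosure
checks), randomized feasible records, toy black-box models, and a linear
programming oracle that bounds ``P(X <= t)`` over grid-supported
distributions subject to the same summary-statistic constraints — an
independent check on the closed-form bound formulas.

Median constraints are encoded as ``P(X <= m) >= 0.5`` and
``P(X >= m) >= 0.5`` (the standard definition, valid with an atom at m).
All randomness flows through explicit seeds or generators.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from scipy.optimize import linprog

from .errors import InconsistentDataError, InvalidInputError
from .minimal import MinimalData
from .propagation import BlackBoxModel, Parameter

__all__ = [
    "ConsistentDistribution", "sample_consistent_distribution",
    "lp_bound_oracle", "random_minimal_data", "make_toy_models",
    "gamma_from_moments", "beta_from_moments", "uniform_on",
]

DEFAULT_GRID = 201


@dataclass(frozen=True)
class ConsistentDistribution:
    """A discrete distribution on [a, b] matching a minimal-data record."""

    points: np.ndarray
    weights: np.ndarray
    data: MinimalData
    descriptor: str = ""
    seed: Optional[int] = None

    def cdf(self, x):
        x = np.asarray(x, dtype=float)
        idx = np.searchsorted(self.points, np.atleast_1d(x), side="right")
        cum = np.concatenate([[0.0], np.cumsum(self.weights)])
        out = np.clip(cum[idx], 0.0, 1.0)
        return float(out[0]) if x.ndim == 0 else out

    def rvs(self, size: int, rng: np.random.Generator) -> np.ndarray:
        return rng.choice(self.points, size=size, p=self.weights)

    def mean(self) -> float:
        return float(self.points @ self.weights)

    def sd(self) -> float:
        m = self.mean()
        return float(np.sqrt(self.weights @ (self.points - m) ** 2))

    def median(self) -> float:
        cum = np.cumsum(self.weights)
        return float(self.points[np.searchsorted(cum, 0.5)])


def _constraints(d: MinimalData, grid: np.ndarray):
    """Equality/inequality matrices for the LP on ``grid`` weights."""
    A_eq = [np.ones_like(grid)]
    b_eq = [1.0]
    if d.mean is not None:
        A_eq.append(grid)
        b_eq.append(d.mean)
    if d.sd is not None:
        A_eq.append(grid**2)
        b_eq.append(d.sd**2 + d.mean**2)
    A_ub, b_ub = [], []
    if d.median is not None:
        at_or_below = (grid <= d.median).astype(float)
        at_or_above = (grid >= d.median).astype(float)
        A_ub.append(-at_or_below)   # P(X <= m) >= 0.5
        b_ub.append(-0.5)
        A_ub.append(-at_or_above)   # P(X >= m) >= 0.5
        b_ub.append(-0.5)
    return (np.array(A_eq), np.array(b_eq),
            np.array(A_ub) if A_ub else None,
            np.array(b_ub) if b_ub else None)


def _solve(c, d, grid):
    A_eq, b_eq, A_ub, b_ub = _constraints(d, grid)
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                  bounds=(0, None), method="highs")
    if not res.success:
        raise InconsistentDataError(
            f"no distribution on the grid satisfies {d.to_dict()}: "
            f"{res.message}")
    return res


def sample_consistent_distribution(d: MinimalData, seed: Optional[int] = None,
                                   grid_points: int = DEFAULT_GRID
                                   ) -> ConsistentDistribution:
    """A randomized discrete distribution satisfying every statistic in ``d``.

    Solves the moment/median constraint system over weights on an
    equispaced grid of ``[a, b]`` (the median, if present, is inserted
    into the grid) with a random linear objective, so different seeds give
    different vertices of the feasible polytope.
    """
    rng = np.random.default_rng(seed)
    grid = np.linspace(d.a, d.b, grid_points)
    if d.median is not None:
        grid = np.unique(np.append(grid, d.median))
    c = rng.standard_normal(grid.size)
    res = _solve(c, d, grid)
    w = np.clip(res.x, 0.0, None)
    w /= w.sum()
    return ConsistentDistribution(
        points=grid, weights=w, data=d,
        descriptor=f"lp-vertex(grid={grid.size})", seed=seed)


def lp_bound_oracle(d: MinimalData, t: float, sense: str = "min",
                    grid_points: int = DEFAULT_GRID) -> float:
    """Optimize ``P(X <= t)`` over grid distributions consistent with ``d``.

    A brute-force check of the closed-form CDF bounds: as the grid
    refines, the minimum approaches the lower bound and the maximum the
    upper bound.
    """
    if sense not in ("min", "max"):
        raise InvalidInputError("sense must be 'min' or 'max'")
    if not d.a <= t <= d.b:
        raise InvalidInputError(f"t={t} outside support [{d.a}, {d.b}]")
    grid = np.linspace(d.a, d.b, grid_points)
    # extremal distributions place atoms at the threshold or just beyond
    # it, so the grid must offer support points there
    delta = 1e-9 * (d.b - d.a)
    grid = np.append(grid, [t, min(t + delta, d.b), max(t - delta, d.a)])
    if d.median is not None:
        grid = np.unique(np.append(grid, d.median))
    grid = np.unique(grid)
    indicator = (grid <= t).astype(float)
    c = indicator if sense == "min" else -indicator
    res = _solve(c, d, grid)
    value = float(indicator @ res.x)
    return min(max(value, 0.0), 1.0)


# ---------------------------------------------------------------------------
# randomized minimal-data records
# ---------------------------------------------------------------------------

def random_minimal_data(rng: np.random.Generator, kind: str = "mean_sd",
                        a: Optional[float] = None, b: Optional[float] = None
                        ) -> MinimalData:
    """A random feasible record of the requested kind.

    Kinds: ``minmax``, ``median``, ``mean``, ``mean_sd``, ``median_mean``,
    ``median_mean_sd``.  Supports are drawn with width in [0.5, 10]; means
    stay 5% away from the endpoints and SDs between 10% and 90% of the
    feasibility cap, which keeps the records representative without
    hugging degenerate corners.
    """
    if kind not in ("minmax", "median", "mean", "mean_sd", "median_mean",
                    "median_mean_sd"):
        raise InvalidInputError(f"unknown record kind {kind!r}")
    if a is None:
        a = float(rng.uniform(-5, 5))
    if b is None:
        b = a + float(rng.uniform(0.5, 10.0))
    w = b - a
    for _ in range(100):
        mu = float(rng.uniform(a + 0.05 * w, b - 0.05 * w))
        fields = {}
        sd = None
        if kind in ("mean_sd", "median_mean_sd"):
            cap = np.sqrt((mu - a) * (b - mu))
            sd = float(rng.uniform(0.1, 0.9)) * float(cap)
            fields["sd"] = sd
        if kind in ("median", "median_mean", "median_mean_sd"):
            if sd is not None:
                # a distribution's median lies within one SD of its mean;
                # staying inside that band is necessary but, on a bounded
                # support, not sufficient — certified by the LP below
                lo_m = max(a, mu - 0.7 * sd)
                hi_m = min(b, mu + 0.7 * sd)
                fields["median"] = float(rng.uniform(lo_m, hi_m))
            elif "mean" in kind:
                # keep the median on the mean's side of the support
                lo_m = max(a, mu - 0.4 * min(mu - a, b - mu))
                hi_m = min(b, mu + 0.4 * min(mu - a, b - mu))
                fields["median"] = float(rng.uniform(lo_m, hi_m))
            else:
                fields["median"] = float(rng.uniform(a, b))
        if kind in ("mean", "mean_sd", "median_mean", "median_mean_sd"):
            fields["mean"] = mu
        d = MinimalData(a=a, b=b, **fields)
        if len(d.stats()) < 2 or _is_feasible(d):
            return d
    raise InconsistentDataError(
        f"could not draw a feasible {kind!r} record on [{a}, {b}]")


def _is_feasible(d: MinimalData, grid_points: int = 101) -> bool:
    grid = np.linspace(d.a, d.b, grid_points)
    if d.median is not None:
        grid = np.unique(np.append(grid, d.median))
    try:
        _solve(np.zeros(grid.size), d, grid)
    except InconsistentDataError:
        return False
    return True


# ---------------------------------------------------------------------------
# moment-matched parametric families (for PSA comparisons)
# ---------------------------------------------------------------------------

def gamma_from_moments(mean: float, sd: float):
    """Gamma distribution with the given mean and SD (shape/scale form)."""
    if mean <= 0 or sd <= 0:
        raise InvalidInputError("gamma moments must be positive")
    shape = (mean / sd) ** 2
    scale = sd**2 / mean
    return stats.gamma(a=shape, scale=scale)


def beta_from_moments(mean: float, sd: float, a: float = 0.0, b: float = 1.0):
    """Beta distribution on [a, b] matched to the given mean and SD."""
    if not a < mean < b:
        raise InvalidInputError("mean must lie strictly inside [a, b]")
    m = (mean - a) / (b - a)
    v = (sd / (b - a)) ** 2
    if v >= m * (1 - m):
        raise InvalidInputError("sd too large for a beta on this support")
    nu = m * (1 - m) / v - 1.0
    return stats.beta(a=m * nu, b=(1 - m) * nu, loc=a, scale=b - a)


def uniform_on(a: float, b: float):
    return stats.uniform(loc=a, scale=b - a)


# ---------------------------------------------------------------------------
# toy black-box models
# ---------------------------------------------------------------------------

def make_toy_models() -> dict:
    """Catalog of small documented models for propagation tests."""
    from .cohort import residence_black_box  # local import avoids a cycle

    unit = MinimalData(0.0, 1.0)

    def _pbox(name, data=None, mono=None):
        return Parameter(name=name, role="pbox", data=data or unit,
                         monotone=mono)

    identity = BlackBoxModel(
        evaluator=lambda v: np.atleast_2d(v)[:, 0],
        parameters=(_pbox("theta", mono="increasing"),),
        name="identity", vectorized=True)
    affine = BlackBoxModel(
        evaluator=lambda v: 2.0 * np.atleast_2d(v)[:, 0] - np.atleast_2d(v)[:, 1],
        parameters=(_pbox("theta1", mono="increasing"),
                    _pbox("theta2", mono="decreasing")),
        name="affine", vectorized=True)
    product = BlackBoxModel(
        evaluator=lambda v: np.atleast_2d(v)[:, 0] * np.atleast_2d(v)[:, 1],
        parameters=(_pbox("theta1", MinimalData(-1.0, 1.0)),
                    _pbox("theta2", MinimalData(-1.0, 1.0))),
        name="product", vectorized=True)
    bowl = BlackBoxModel(
        evaluator=lambda v: (np.atleast_2d(v)[:, 0] - 0.5) ** 2,
        parameters=(_pbox("theta"),),
        name="bowl", vectorized=True)
    residence = residence_black_box(
        c1_data=MinimalData(0.0, 10.0, mean=0.05, sd=0.00033),
        c6_data=MinimalData(0.0, 10.0, mean=1.0, sd=0.0167),
        fixed={"c2": 0.01, "c3": 0.001, "c4": 0.1, "c5": 0.05})
    return {m.name: m for m in (identity, affine, product, bowl, residence)}
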