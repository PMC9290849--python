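"""Propagating p-boxes through black-box deterministic models.

Each parameter of a model plays one of three roles: ``fixed`` (a known
value), ``cdf`` (a precisely specified distribution, handled by Monte
Carlo), or ``pbox`` (known only through summary statistics, handled by
interval slicing).  Propagation slices every p-box parameter, forms the
full-factorial product of slices (hyperrectangles with product masses),
and finds the minimum and maximum of the model over each hyperrectangle.
Cumulating the masses of the minima gives the upper bound on the outcome
CDF; cumulating the maxima gives the lower bound.

The per-box optimizers:

``grid``
    full factorial grid of ``g`` points per varying dimension (endpoints
    included, so all vertices are evaluated); the test oracle for low
    dimension.
``direct``
    deterministic DIRECT (dividing rectangles) global search via
    :func:`scipy.optimize.direct`, with an evaluation budget per bound;
    box vertices are also evaluated so the incumbent is never worse than
    the vertex heuristic.  DIRECT samples rectangle centres only, so it
    never evaluates on the box boundary.
``vertex``
    exact for models declared monotone in every p-box parameter; two
    evaluations per box.

Infinite model outputs are legitimate extremes (some functionals, e.g.
mean time to absorption, are genuinely unbounded on boxes touching a
degenerate rate) and are carried through the records; NaN outputs raise
:class:`~pba.errors.EvaluationError`.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np

from .bounding import weighted_ecdf
from .errors import EvaluationError, InvalidInputError, PBAError
from .minimal import MinimalData
from .pbox import PBox, make_pbox
from .slicing import (DiscretizedPBox, Hyperrectangle,
                      enumerate_hyperrectangles, slice_pbox)

__all__ = [
    "Parameter", "BlackBoxModel", "OutcomePBox", "optimize_on_box",
    "propagate_pba", "propagate_mixed", "empirical_outcome_pbox",
]

ROLES = ("fixed", "cdf", "pbox")
MASS_TOL = 1e-9


@dataclass(frozen=True)
class Parameter:
    """One model input and what is known about it."""

    name: str
    role: str
    value: Optional[float] = None          # fixed
    dist: object = None                    # cdf: scipy frozen distribution
    data: Optional[MinimalData] = None     # pbox: summary statistics
    monotone: Optional[str] = None         # 'increasing' | 'decreasing' | None

    def __post_init__(self):
        if self.role not in ROLES:
            raise InvalidInputError(f"unknown role {self.role!r} for {self.name!r}")
        if self.role == "fixed" and self.value is None:
            raise InvalidInputError(f"fixed parameter {self.name!r} needs a value")
        if self.role == "cdf" and self.dist is None:
            raise InvalidInputError(
                f"cdf parameter {self.name!r} needs a distribution")
        if self.role == "pbox" and self.data is None:
            raise InvalidInputError(
                f"pbox parameter {self.name!r} needs minimal data")
        if self.monotone not in (None, "increasing", "decreasing"):
            raise InvalidInputError(
                f"monotone must be 'increasing' or 'decreasing', "
                f"got {self.monotone!r}")


@dataclass(frozen=True)
class BlackBoxModel:
    """A deterministic model plus the role manifest of its parameters.

    ``evaluator`` maps a full parameter vector (in manifest order) to one
    real outcome.  If ``vectorized`` is true the evaluator also accepts an
    ``(n, k)`` array and returns ``n`` outcomes; the grid and vertex
    optimizers exploit this.
    """

    evaluator: Callable
    parameters: tuple
    name: str = ""
    vectorized: bool = False

    def __post_init__(self):
        names = [p.name for p in self.parameters]
        if len(set(names)) != len(names):
            raise InvalidInputError("duplicate parameter names in manifest")

    @property
    def pbox_parameters(self):
        return [p for p in self.parameters if p.role == "pbox"]

    @property
    def cdf_parameters(self):
        return [p for p in self.parameters if p.role == "cdf"]

    @property
    def fixed_parameters(self):
        return [p for p in self.parameters if p.role == "fixed"]

    def template(self, fixed_values: Optional[dict] = None) -> np.ndarray:
        """Full parameter vector with p-box entries left as NaN placeholders."""
        fixed_values = fixed_values or {}
        vec = np.empty(len(self.parameters))
        for i, p in enumerate(self.parameters):
            if p.role == "pbox":
                vec[i] = np.nan
            elif p.name in fixed_values:
                vec[i] = fixed_values[p.name]
            elif p.role == "fixed":
                vec[i] = p.value
            else:
                raise InvalidInputError(
                    f"no value supplied for cdf parameter {p.name!r}")
        return vec

    def eval_one(self, vector: np.ndarray) -> float:
        y = self.evaluator(vector)
        y = float(np.asarray(y).reshape(()))
        if math.isnan(y):
            raise EvaluationError(
                f"model {self.name or '<anonymous>'} returned NaN",
                vector=np.array(vector))
        return y

    def eval_many(self, vectors: np.ndarray) -> np.ndarray:
        if self.vectorized:
            ys = np.asarray(self.evaluator(vectors), dtype=float).reshape(-1)
        else:
            ys = np.array([self.evaluator(v) for v in vectors], dtype=float)
        if np.isnan(ys).any():
            bad = vectors[int(np.argmax(np.isnan(ys)))]
            raise EvaluationError("model returned NaN", vector=np.array(bad))
        return ys


# ---------------------------------------------------------------------------
# per-hyperrectangle optimization
# ---------------------------------------------------------------------------

def optimize_on_box(model: BlackBoxModel, box: Hyperrectangle,
                    fixed_values: Optional[dict] = None,
                    method: str = "direct", g: int = 21,
                    budget: Optional[int] = None) -> tuple:
    """Bounds of the model over one hyperrectangle of p-box parameters.

    Returns ``(ymin, ymax)``.  See the module docstring for the methods.
    """
    pbox_idx = [i for i, p in enumerate(model.parameters) if p.role == "pbox"]
    if len(box.intervals) != len(pbox_idx):
        raise InvalidInputError(
            f"box has {len(box.intervals)} intervals for "
            f"{len(pbox_idx)} p-box parameters")
    template = model.template(fixed_values)
    lows = np.array([iv[0] for iv in box.intervals], dtype=float)
    highs = np.array([iv[1] for iv in box.intervals], dtype=float)

    if method == "vertex":
        return _vertex_bounds(model, template, pbox_idx, lows, highs)
    if method == "grid":
        return _grid_bounds(model, template, pbox_idx, lows, highs, g)
    if method == "direct":
        return _direct_bounds(model, template, pbox_idx, lows, highs, budget)
    raise InvalidInputError(f"unknown optimizer method {method!r}")


def _fill(template, pbox_idx, values):
    vec = template.copy()
    vec[pbox_idx] = values
    return vec


def _vertex_bounds(model, template, pbox_idx, lows, highs):
    directions = []
    for i in pbox_idx:
        mono = model.parameters[i].monotone
        if mono is None:
            raise InvalidInputError(
                f"vertex method needs declared monotonicity for "
                f"{model.parameters[i].name!r}")
        directions.append(1 if mono == "increasing" else -1)
    at_min = np.where(np.asarray(directions) > 0, lows, highs)
    at_max = np.where(np.asarray(directions) > 0, highs, lows)
    ymin = model.eval_one(_fill(template, pbox_idx, at_min))
    ymax = model.eval_one(_fill(template, pbox_idx, at_max))
    if ymin > ymax:  # guards against a wrong monotonicity declaration
        raise EvaluationError(
            "vertex bounds inverted; monotonicity declaration is wrong",
            vector=_fill(template, pbox_idx, at_min))
    return ymin, ymax


def _grid_bounds(model, template, pbox_idx, lows, highs, g):
    if g < 2:
        raise InvalidInputError("grid oracle needs g >= 2")
    axes = [np.linspace(lo, hi, 1 if hi == lo else g)
            for lo, hi in zip(lows, highs)]
    mesh = np.meshgrid(*axes, indexing="ij") if axes else []
    if axes:
        pts = np.column_stack([m.ravel() for m in mesh])
    else:
        pts = np.empty((1, 0))
    vectors = np.tile(template, (len(pts), 1))
    vectors[:, pbox_idx] = pts
    ys = model.eval_many(vectors)
    return float(np.min(ys)), float(np.max(ys))


def _direct_bounds(model, template, pbox_idx, lows, highs, budget):
    from scipy.optimize import direct as _direct

    varying = np.nonzero(highs > lows)[0]
    fixed_at = lows.copy()  # degenerate dims pinned at their single value
    base = _fill(template, pbox_idx, fixed_at)

    # vertices first: cheap, and makes the incumbent at least vertex-tight
    vert_axes = [(lo, hi) for lo, hi in zip(lows[varying], highs[varying])]
    best_min, best_max = np.inf, -np.inf
    if len(varying) <= 16:
        for corner in itertools.product(*vert_axes) if vert_axes else [()]:
            vals = fixed_at.copy()
            vals[varying] = corner
            y = model.eval_one(_fill(template, pbox_idx, vals))
            best_min = min(best_min, y)
            best_max = max(best_max, y)
    else:  # pragma: no cover - very high dimension
        y = model.eval_one(base)
        best_min = best_max = y

    if varying.size == 0:
        return best_min, best_max

    dim = varying.size
    maxfun = budget if budget is not None else 500 * dim
    bounds = list(zip(lows[varying], highs[varying]))

    seen = [best_min, best_max]  # true incumbents, inf allowed

    def objective(x, sign):
        vals = fixed_at.copy()
        vals[varying] = x
        y = model.eval_one(_fill(template, pbox_idx, vals))
        seen[0] = min(seen[0], y)
        seen[1] = max(seen[1], y)
        if math.isinf(y):
            # DIRECT cannot digest inf; an overwhelming finite stand-in
            # keeps the search going while the true extreme is recorded
            return sign * math.copysign(1e300, y)
        return sign * y

    for sign in (1.0, -1.0):
        _direct(lambda x: objective(x, sign), bounds,
                maxfun=maxfun, maxiter=maxfun,
                locally_biased=False, vol_tol=1e-30, len_tol=1e-9)
    return float(seen[0]), float(seen[1])


# ---------------------------------------------------------------------------
# outcome assembly
# ---------------------------------------------------------------------------

def empirical_outcome_pbox(records, grid: Union[int, np.ndarray] = 512):
    """Weighted ECDF staircases of the per-box minima and maxima.

    ``records`` is a sequence of ``(y_min, y_max, mass)``; masses must sum
    to 1.  Returns ``(ys, lower_cdf, upper_cdf)`` where the lower bound is
    the ECDF of the maxima and the upper bound the ECDF of the minima.
    """
    records = list(records)
    if not records:
        raise InvalidInputError("no records")
    y_min = np.array([r[0] for r in records], dtype=float)
    y_max = np.array([r[1] for r in records], dtype=float)
    mass = np.array([r[2] for r in records], dtype=float)
    if np.any(y_min > y_max):
        raise InvalidInputError("records must satisfy y_min <= y_max")
    if abs(mass.sum() - 1.0) > MASS_TOL:
        raise PBAError(f"record masses sum to {mass.sum()}, expected 1")
    ys = _outcome_grid(y_min, y_max, grid)
    lower = _wecdf_eval(y_max, mass, ys)
    upper = _wecdf_eval(y_min, mass, ys)
    return ys, lower, upper


def _outcome_grid(y_min, y_max, grid):
    if not isinstance(grid, (int, np.integer)):
        return np.asarray(grid, dtype=float)
    finite = np.concatenate([y_min[np.isfinite(y_min)],
                             y_max[np.isfinite(y_max)]])
    if finite.size == 0:
        raise InvalidInputError("all record endpoints are infinite")
    lo, hi = float(finite.min()), float(finite.max())
    if lo == hi:
        return np.array([lo])
    return np.linspace(lo, hi, int(grid))


def _wecdf_eval(points, mass, ys):
    order = np.argsort(points, kind="stable")
    pts = points[order]
    cum = np.cumsum(mass[order])
    idx = np.searchsorted(pts, ys, side="right")
    out = np.where(idx > 0, cum[np.clip(idx - 1, 0, None)], 0.0)
    return np.clip(out, 0.0, 1.0)


@dataclass(frozen=True)
class OutcomePBox:
    """Propagation result: per-box extremes with masses plus staircases."""

    y_min: np.ndarray
    y_max: np.ndarray
    mass: np.ndarray
    ys: np.ndarray
    lower_cdf: np.ndarray
    upper_cdf: np.ndarray
    provenance: dict = field(default_factory=dict, compare=False)

    @classmethod
    def from_records(cls, records, grid: Union[int, np.ndarray] = 512,
                     provenance: Optional[dict] = None) -> "OutcomePBox":
        ys, lower, upper = empirical_outcome_pbox(records, grid)
        records = list(records)
        return cls(
            y_min=np.array([r[0] for r in records], dtype=float),
            y_max=np.array([r[1] for r in records], dtype=float),
            mass=np.array([r[2] for r in records], dtype=float),
            ys=ys, lower_cdf=lower, upper_cdf=upper,
            provenance=provenance or {},
        )

    def cdf_bounds(self, y):
        """(lower, upper) bounds on the outcome CDF at ``y`` (vectorized)."""
        y = np.asarray(y, dtype=float)
        scalar = y.ndim == 0
        yv = np.atleast_1d(y)
        lower = _wecdf_eval(self.y_max, self.mass, yv)
        upper = _wecdf_eval(self.y_min, self.mass, yv)
        if scalar:
            return float(lower[0]), float(upper[0])
        return lower, upper

    def as_pbox(self) -> PBox:
        """The outcome staircase as a :class:`~pba.pbox.PBox` (exact ECDFs)."""
        finite = np.concatenate([self.y_min[np.isfinite(self.y_min)],
                                 self.y_max[np.isfinite(self.y_max)]])
        a = float(finite.min()) if finite.size else float(self.y_min.min())
        b = float(finite.max()) if finite.size else float(self.y_max.max())
        return PBox(lower=weighted_ecdf(self.y_max, self.mass),
                    upper=weighted_ecdf(self.y_min, self.mass),
                    a=a, b=b, label=self.provenance.get("model", "outcome"))

    def expectation_interval(self) -> tuple:
        """Mass-weighted sums of the minima and maxima: [mu_lo, mu_hi]."""
        return (float(np.sum(self.mass * self.y_min)),
                float(np.sum(self.mass * self.y_max)))

    def area(self) -> float:
        """Area between the staircase bounds over the outcome grid."""
        if self.ys.size < 2:
            return 0.0
        return float(np.trapezoid(self.upper_cdf - self.lower_cdf, self.ys))

    @property
    def support(self) -> tuple:
        """Range of plausible outcome values: [min y_min, max y_max]."""
        return float(self.y_min.min()), float(self.y_max.max())


# ---------------------------------------------------------------------------
# drivers
# ---------------------------------------------------------------------------

def _slice_all(model: BlackBoxModel, n_slices) -> list:
    params = model.pbox_parameters
    if not params:
        return []
    if isinstance(n_slices, (int, np.integer)):
        counts = [int(n_slices)] * len(params)
    else:
        counts = [int(n) for n in n_slices]
        if len(counts) != len(params):
            raise InvalidInputError(
                f"{len(counts)} slice counts for {len(params)} p-box parameters")
    out = []
    for p, n in zip(params, counts):
        out.append(slice_pbox(make_pbox(p.data, label=p.name), n))
    return out


def _boxes(ds):
    if ds:
        yield from enumerate_hyperrectangles(ds)
    else:
        yield Hyperrectangle(index=(), intervals=(), mass=1.0)


def propagate_pba(model: BlackBoxModel, n_slices: Union[int, Sequence[int]],
                  method: str = "direct", outcome_grid: Union[int, np.ndarray] = 512,
                  fixed_values: Optional[dict] = None, g: int = 21,
                  budget: Optional[int] = None) -> OutcomePBox:
    """Pure p-box propagation (no precise-CDF parameters).

    Slices every p-box parameter, optimizes the model over every
    hyperrectangle, and assembles the outcome p-box.
    """
    if model.cdf_parameters and not fixed_values:
        raise InvalidInputError(
            "model has cdf parameters; use propagate_mixed or supply "
            "fixed_values for them")
    ds = _slice_all(model, n_slices)
    records = []
    for box in _boxes(ds):
        ymin, ymax = optimize_on_box(model, box, fixed_values, method,
                                     g=g, budget=budget)
        records.append((ymin, ymax, box.mass))
    total = sum(r[2] for r in records)
    if abs(total - 1.0) > MASS_TOL:
        raise PBAError(f"hyperrectangle masses sum to {total}, expected 1")
    prov = {"model": model.name, "method": method,
            "n_slices": [len(d) for d in ds] or None,
            "n_hyperrectangles": len(records), "g": g, "budget": budget}
    return OutcomePBox.from_records(records, grid=outcome_grid, provenance=prov)


def propagate_mixed(model: BlackBoxModel, n_slices: Union[int, Sequence[int]],
                    N: int = 100, seed: Optional[int] = None,
                    method: str = "direct", mode: str = "sample",
                    outcome_grid: Union[int, np.ndarray] = 512, g: int = 21,
                    budget: Optional[int] = None,
                    rng: Optional[np.random.Generator] = None) -> OutcomePBox:
    """Propagation with both p-box and precise-CDF parameters.

    ``mode='sample'`` draws ``N`` independent joint samples of the
    precise-CDF parameters and averages the per-sample staircases — which
    is exactly the weighted ECDF of the pooled per-sample records, so the
    records are pooled with masses divided by ``N``.  ``mode='fix_at_mean'``
    does a single pass at the distribution means (a shortcut that is exact
    for models linear in those parameters).
    """
    if mode not in ("sample", "fix_at_mean"):
        raise InvalidInputError(f"unknown mode {mode!r}")
    cdf_params = model.cdf_parameters

    if mode == "fix_at_mean" or not cdf_params:
        fixed = {p.name: float(p.dist.mean()) for p in cdf_params}
        out = propagate_pba(model, n_slices, method=method,
                            outcome_grid=outcome_grid, fixed_values=fixed,
                            g=g, budget=budget)
        out.provenance.update(mode="fix_at_mean" if cdf_params else "pure-pbox",
                              N=None, seed=None)
        return out

    if N < 1:
        raise InvalidInputError(f"need N >= 1 Monte Carlo samples, got {N}")
    if rng is None:
        rng = np.random.default_rng(seed)
    draws = {p.name: np.atleast_1d(p.dist.rvs(size=N, random_state=rng))
             for p in cdf_params}
    ds = _slice_all(model, n_slices)
    records = []
    for l in range(N):
        fixed = {name: float(vals[l]) for name, vals in draws.items()}
        for box in _boxes(ds):
            ymin, ymax = optimize_on_box(model, box, fixed, method,
                                         g=g, budget=budget)
            records.append((ymin, ymax, box.mass / N))
    total = sum(r[2] for r in records)
    if abs(total - 1.0) > MASS_TOL:
        raise PBAError(f"pooled masses sum to {total}, expected 1")
    prov = {"model": model.name, "method": method,
            "n_slices": [len(d) for d in ds] or None, "N": N, "seed": seed,
            "mode": "sample", "g": g, "budget": budget}
    return OutcomePBox.from_records(records, grid=outcome_grid, provenance=prov)
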