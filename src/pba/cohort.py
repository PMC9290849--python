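"""Built-in cohort models: a four-state rate model and a discrete-cycle
cost-effectiveness Markov engine.

The four-state model is a continuous-time feed-forward chain over health
states S1..S4 with S4 absorbing.  Six nonnegative transition rates govern
it: c1 (S1->S2), c2 (S1->S3), c3 (S1->S4), c4 (S2->S3), c5 (S2->S4) and
c6 (S3->S4).  Its outcome of interest is the expected residence time in
the non-absorbing states, obtained in closed form from the transient
sub-generator.

The cost-effectiveness engine iterates a cohort trace over named states
with per-cycle transition probability matrices, accrues per-state costs
and QALY contributions each cycle, discounts them at a per-cycle factor
derived from an annual rate, and summarizes two interventions by the
incremental net monetary benefit at a willingness-to-pay threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .errors import InvalidInputError, ModelError
from .minimal import MinimalData
from .propagation import BlackBoxModel, Parameter

__all__ = [
    "RateModel4State", "expected_residence", "residence_rates_vectorized",
    "CEAMarkovModel", "run_cea", "inmb", "residence_black_box",
]

STATES_4 = ("S1", "S2", "S3", "S4")
ROW_TOL = 1e-12


@dataclass(frozen=True)
class RateModel4State:
    """Transition rates (per unit time) of the four-state chain."""

    c1: float  # S1 -> S2
    c2: float  # S1 -> S3
    c3: float  # S1 -> S4
    c4: float  # S2 -> S3
    c5: float  # S2 -> S4
    c6: float  # S3 -> S4
    initial: tuple = (1.0, 0.0, 0.0, 0.0)

    def __post_init__(self):
        rates = (self.c1, self.c2, self.c3, self.c4, self.c5, self.c6)
        if any(r < 0 for r in rates):
            raise InvalidInputError(f"rates must be nonnegative, got {rates}")
        init = np.asarray(self.initial, dtype=float)
        if init.shape != (4,) or np.any(init < 0) or abs(init.sum() - 1) > ROW_TOL:
            raise InvalidInputError("initial distribution must be a length-4 "
                                    "probability vector")

    def generator(self) -> np.ndarray:
        """4x4 continuous-time generator; rows sum to zero, S4 absorbing."""
        c1, c2, c3, c4, c5, c6 = (self.c1, self.c2, self.c3,
                                  self.c4, self.c5, self.c6)
        return np.array([
            [-(c1 + c2 + c3), c1, c2, c3],
            [0.0, -(c4 + c5), c4, c5],
            [0.0, 0.0, -c6, c6],
            [0.0, 0.0, 0.0, 0.0],
        ])

    @classmethod
    def from_rates(cls, rates: Sequence[float], **kw) -> "RateModel4State":
        return cls(*[float(r) for r in rates], **kw)


def expected_residence(m: RateModel4State) -> float:
    """Expected total time in S1..S3 before absorption in S4.

    Closed form: with Q_T the transient sub-generator and pi0 the initial
    distribution over transient states, the expectation is
    ``pi0 @ (-Q_T)^{-1} @ 1``.  Only states reachable from the initial
    support enter the system; if absorption is not almost sure from there
    (singular sub-generator) a :class:`~pba.errors.ModelError` is raised.
    """
    Q = m.generator()
    init = np.asarray(m.initial, dtype=float)
    reachable = _reachable_transient(Q, init)
    if not reachable:
        return 0.0  # all mass starts absorbed
    idx = sorted(reachable)
    QT = Q[np.ix_(idx, idx)]
    ones = np.ones(len(idx))
    try:
        t = np.linalg.solve(-QT, ones)
    except np.linalg.LinAlgError:
        raise ModelError(
            "absorption is unreachable from the initial distribution: "
            "transient sub-generator is singular") from None
    if np.any(t < -1e-9) or not np.all(np.isfinite(t)):
        raise ModelError("invalid residence times; check the rates")
    return float(init[idx] @ t)


def _reachable_transient(Q: np.ndarray, init: np.ndarray) -> set:
    """Transient states reachable from the support of ``init``."""
    n = Q.shape[0]
    frontier = [i for i in range(n - 1) if init[i] > 0]
    seen = set(frontier)
    while frontier:
        i = frontier.pop()
        for j in range(n - 1):
            if j != i and j not in seen and Q[i, j] > 0:
                seen.add(j)
                frontier.append(j)
    return seen


def residence_rates_vectorized(rates: np.ndarray) -> np.ndarray:
    """Expected residence for an ``(n, 6)`` array of rate vectors.

    Solves the same transient linear system by forward substitution (the
    generator is upper triangular), starting from all mass in S1.  Rates
    that make absorption unreachable yield ``+inf`` — the true value of
    the functional in that limit — rather than an error, so optimizers can
    probe the closed boxes that arise in propagation.
    """
    r = np.asarray(rates, dtype=float)
    squeeze = r.ndim == 1
    r = np.atleast_2d(r)
    if r.shape[1] != 6:
        raise InvalidInputError("expected 6 rates per row")
    if np.any(r < 0):
        raise InvalidInputError("rates must be nonnegative")
    c1, c2, c3, c4, c5, c6 = (r[:, i] for i in range(6))
    with np.errstate(divide="ignore", invalid="ignore"):
        t3 = np.where(c6 > 0, 1.0 / np.where(c6 > 0, c6, 1.0), np.inf)
        r2 = c4 + c5
        t2 = np.where(r2 > 0,
                      (1.0 + c4 * np.where(np.isfinite(t3), t3, 0.0)) / np.where(r2 > 0, r2, 1.0),
                      np.inf)
        # an infinite downstream sojourn only matters if the arc is used
        t2 = np.where((c4 > 0) & np.isinf(t3), np.inf, t2)
        r1 = c1 + c2 + c3
        t2_used = np.where(np.isfinite(t2), t2, 0.0)
        t3_used = np.where(np.isfinite(t3), t3, 0.0)
        t1 = np.where(r1 > 0,
                      (1.0 + c1 * t2_used + c2 * t3_used) / np.where(r1 > 0, r1, 1.0),
                      np.inf)
        t1 = np.where(((c1 > 0) & np.isinf(t2)) | ((c2 > 0) & np.isinf(t3)),
                      np.inf, t1)
    return t1[0] if squeeze else t1


def residence_black_box(c1_data: Optional[MinimalData] = None,
                        c6_data: Optional[MinimalData] = None,
                        fixed: Optional[dict] = None,
                        cdf_dists: Optional[dict] = None) -> BlackBoxModel:
    """Four-state residence time as a :class:`BlackBoxModel`.

    By default ``c1`` and ``c6`` are p-box parameters and the remaining
    rates are fixed; any rate can instead be fixed, given a precise
    distribution (``cdf_dists``) or given minimal data (``fixed`` and
    ``cdf_dists`` are keyed by rate name).
    """
    fixed = dict(fixed or {})
    cdf_dists = dict(cdf_dists or {})
    data = {"c1": c1_data, "c6": c6_data}
    params = []
    for name in ("c1", "c2", "c3", "c4", "c5", "c6"):
        if data.get(name) is not None:
            params.append(Parameter(name=name, role="pbox", data=data[name]))
        elif name in cdf_dists:
            params.append(Parameter(name=name, role="cdf", dist=cdf_dists[name]))
        elif name in fixed:
            params.append(Parameter(name=name, role="fixed",
                                    value=float(fixed[name])))
        else:
            raise InvalidInputError(f"rate {name!r} has no role assigned")
    return BlackBoxModel(evaluator=residence_rates_vectorized,
                         parameters=tuple(params),
                         name="residence4", vectorized=True)


# ---------------------------------------------------------------------------
# discrete-cycle cost-effectiveness engine
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CEAMarkovModel:
    """Discrete-cycle Markov cost-effectiveness model.

    ``matrix_builder(params, intervention)`` returns the per-cycle
    transition probability matrix for the given parameter vector; ``costs``
    and ``utilities`` are per-state per-cycle accruals (the utility entry
    is the QALY contribution of spending one cycle in the state, i.e. the
    annual weight already scaled by the cycle length).  Discounting uses
    the per-cycle factor ``(1 + annual_discount) ** (-cycle * months / 12)``
    with rewards credited at cycle end; ``half_cycle`` switches to
    averaging adjacent cycle occupancies.
    """

    states: tuple
    matrix_builder: Callable
    costs: tuple
    utilities: tuple
    cycle_months: float
    n_cycles: int
    annual_discount: float
    wtp: float
    initial: tuple
    half_cycle: bool = False

    def __post_init__(self):
        k = len(self.states)
        for name in ("costs", "utilities", "initial"):
            if len(getattr(self, name)) != k:
                raise InvalidInputError(f"{name} must have one entry per state")
        init = np.asarray(self.initial, dtype=float)
        if np.any(init < 0) or abs(init.sum() - 1.0) > ROW_TOL:
            raise InvalidInputError("initial must be a probability vector")
        if self.n_cycles < 1 or self.cycle_months <= 0:
            raise InvalidInputError("need n_cycles >= 1 and cycle_months > 0")
        if self.annual_discount < 0:
            raise InvalidInputError("discount rate must be nonnegative")

    def transition_matrix(self, params, intervention: str) -> np.ndarray:
        P = np.asarray(self.matrix_builder(params, intervention), dtype=float)
        k = len(self.states)
        if P.shape != (k, k):
            raise ModelError(f"transition matrix must be {k}x{k}, got {P.shape}")
        if np.any(P < -ROW_TOL) or np.any(P > 1 + ROW_TOL):
            i = int(np.argmax((P < -ROW_TOL) | (P > 1 + ROW_TOL)) // k)
            raise ModelError(
                f"transition probabilities outside [0, 1] in row "
                f"{self.states[i]!r} for intervention {intervention!r}")
        rows = P.sum(axis=1)
        bad = np.nonzero(np.abs(rows - 1.0) > 1e-9)[0]
        if bad.size:
            i = int(bad[0])
            raise ModelError(
                f"row {self.states[i]!r} sums to {rows[i]:.12g} (expected 1) "
                f"for intervention {intervention!r}")
        return np.clip(P, 0.0, 1.0)


def run_cea(m: CEAMarkovModel, params, intervention: str) -> tuple:
    """Discounted (cost, QALY) totals of one intervention.

    Iterates the cohort trace for ``n_cycles`` cycles and accrues the
    per-state rewards with per-cycle discounting.
    """
    P = m.transition_matrix(params, intervention)
    pi = np.asarray(m.initial, dtype=float)
    costs = np.asarray(m.costs, dtype=float)
    utils = np.asarray(m.utilities, dtype=float)
    years_per_cycle = m.cycle_months / 12.0
    disc = (1.0 + m.annual_discount) ** (-years_per_cycle)
    total_cost = 0.0
    total_qaly = 0.0
    for cycle in range(1, m.n_cycles + 1):
        pi_next = pi @ P
        occupancy = 0.5 * (pi + pi_next) if m.half_cycle else pi_next
        w = disc ** cycle
        total_cost += w * float(occupancy @ costs)
        total_qaly += w * float(occupancy @ utils)
        pi = pi_next
    return total_cost, total_qaly


def inmb(cost_new: float, qaly_new: float, cost_cmp: float, qaly_cmp: float,
         wtp: float) -> float:
    """Incremental net monetary benefit: wtp * dQALY - dCost."""
    return wtp * (qaly_new - qaly_cmp) - (cost_new - cost_cmp)
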