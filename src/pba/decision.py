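"""Interval decision rules for comparing interventions under p-box uncertainty.

The expected value of an outcome over a p-box is an interval
``[mu_lo, mu_hi]`` — the range of expectations attainable by CDFs inside
the box.  In the discrete record form the endpoints are the mass-weighted
sums of the per-box minima and maxima.  Four rules compare such intervals:

* **dominance** — one interval beats another iff both endpoints are
  strictly greater; with no single winner, the non-dominated set is
  returned;
* **pessimist** — maximize the lower endpoint (worst-case expectation);
* **optimist** — maximize the upper endpoint;
* **hurwicz** — maximize ``alpha * lo + (1 - alpha) * hi``; ``alpha=1``
  reduces to the pessimist rule and ``alpha=0`` to the optimist rule.

The outcome must already be on the utility scale (compose any utility
function into the model before propagation); comparisons use strict
inequalities, so exact ties are reported as tie sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import InvalidInputError
from .propagation import OutcomePBox

__all__ = ["ExpectedInterval", "DecisionProblem", "DecisionReport",
           "expected_interval", "decide", "RULES"]

RULES = ("dominance", "pessimist", "optimist", "hurwicz")


@dataclass(frozen=True)
class ExpectedInterval:
    """Range of expected outcomes for one intervention."""

    lo: float
    hi: float
    label: str = ""

    def __post_init__(self):
        if not self.lo <= self.hi:
            raise InvalidInputError(
                f"interval for {self.label!r} has lo={self.lo} > hi={self.hi}")

    def hurwicz_score(self, alpha: float) -> float:
        return alpha * self.lo + (1.0 - alpha) * self.hi

    def shifted(self, c: float) -> "ExpectedInterval":
        return ExpectedInterval(self.lo + c, self.hi + c, self.label)


@dataclass(frozen=True)
class DecisionProblem:
    intervals: tuple
    rule: str
    alpha: Optional[float] = None

    def __post_init__(self):
        if len(self.intervals) < 2:
            raise InvalidInputError("need at least two interventions")
        if self.rule not in RULES:
            raise InvalidInputError(f"unknown rule {self.rule!r}; one of {RULES}")
        if self.rule == "hurwicz":
            if self.alpha is None or not 0.0 <= self.alpha <= 1.0:
                raise InvalidInputError("hurwicz rule needs alpha in [0, 1]")
        elif self.alpha is not None:
            raise InvalidInputError(f"alpha only applies to the hurwicz rule")
        labels = [iv.label for iv in self.intervals]
        if len(set(labels)) != len(labels):
            raise InvalidInputError("intervention labels must be unique")


@dataclass(frozen=True)
class DecisionReport:
    preferred: tuple          # labels of the chosen / non-dominated set
    rule: str
    alpha: Optional[float]
    scores: dict = field(compare=False, default_factory=dict)
    rationale: str = ""

    @property
    def is_tie(self) -> bool:
        return len(self.preferred) > 1


def expected_interval(outcome: OutcomePBox, label: str = "") -> ExpectedInterval:
    """Expected-value interval of an outcome p-box (record form)."""
    if outcome.mass.size == 0:
        raise InvalidInputError("outcome p-box has no records")
    lo, hi = outcome.expectation_interval()
    return ExpectedInterval(lo=lo, hi=hi, label=label)


def decide(problem: DecisionProblem) -> DecisionReport:
    """Apply an interval decision rule; ties return every tied intervention."""
    ivs = problem.intervals
    labels = [iv.label or f"a{r + 1}" for r, iv in enumerate(ivs)]

    if problem.rule == "dominance":
        dominated = set()
        for i, x in enumerate(ivs):
            for j, y in enumerate(ivs):
                if i != j and y.lo > x.lo and y.hi > x.hi:
                    dominated.add(i)
                    break
        keep = tuple(labels[i] for i in range(len(ivs)) if i not in dominated)
        rationale = ("single dominant intervention" if len(keep) == 1
                     else "non-dominated set (no single winner)")
        scores = {lab: (iv.lo, iv.hi) for lab, iv in zip(labels, ivs)}
        return DecisionReport(preferred=keep, rule="dominance", alpha=None,
                              scores=scores, rationale=rationale)

    if problem.rule == "pessimist":
        vals = np.array([iv.lo for iv in ivs])
    elif problem.rule == "optimist":
        vals = np.array([iv.hi for iv in ivs])
    else:
        vals = np.array([iv.hurwicz_score(problem.alpha) for iv in ivs])
    best = vals.max()
    keep = tuple(lab for lab, v in zip(labels, vals) if v == best)
    scores = {lab: float(v) for lab, v in zip(labels, vals)}
    rationale = f"argmax of {problem.rule} score" + (
        f" (alpha={problem.alpha})" if problem.rule == "hurwicz" else "")
    return DecisionReport(preferred=keep, rule=problem.rule,
                          alpha=problem.alpha, scores=scores,
                          rationale=rationale)
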