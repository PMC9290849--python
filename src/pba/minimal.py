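"""Minimal data records: the summary statistics available for one parameter.

A record always carries a finite support ``[a, b]``; the median, mean and
standard deviation are optional.  Feasibility is checked at construction:
a record that no distribution on ``[a, b]`` can satisfy is rejected
immediately (pairs of median and mean that conflict only through the
bound intersection are caught later, when the p-box is assembled).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .errors import InvalidInputError


@dataclass(frozen=True)
class MinimalData:
    """Summary statistics for a single uncertain parameter.

    Parameters
    ----------
    a, b
        Lower and upper bound of the support (required, ``a < b``).
    median
        Median of the unknown distribution, if known.
    mean
        Mean, if known.
    sd
        Standard deviation, if known.  Requires ``mean`` and must satisfy
        the bounded-support moment condition ``sd**2 <= (mean - a) * (b - mean)``.
    """

    a: float
    b: float
    median: Optional[float] = None
    mean: Optional[float] = None
    sd: Optional[float] = None
    name: str = field(default="", compare=False)

    def __post_init__(self):
        for key in ("a", "b"):
            v = getattr(self, key)
            if v is None or not _finite(v):
                raise InvalidInputError(f"{key} is required and must be finite")
        if not self.a < self.b:
            raise InvalidInputError(f"need a < b, got a={self.a}, b={self.b}")
        if self.median is not None and not self.a <= self.median <= self.b:
            raise InvalidInputError(
                f"median {self.median} outside support [{self.a}, {self.b}]"
            )
        if self.mean is not None and not self.a <= self.mean <= self.b:
            raise InvalidInputError(
                f"mean {self.mean} outside support [{self.a}, {self.b}]"
            )
        if self.sd is not None:
            if self.mean is None:
                raise InvalidInputError("sd given without mean")
            if self.sd < 0:
                raise InvalidInputError(f"sd must be nonnegative, got {self.sd}")
            cap = (self.mean - self.a) * (self.b - self.mean)
            if self.sd**2 > cap * (1 + 1e-12) + 1e-300:
                raise InvalidInputError(
                    f"sd={self.sd} infeasible on [{self.a}, {self.b}] with "
                    f"mean={self.mean}: sd^2 must be <= {cap:.6g}"
                )

    @property
    def width(self) -> float:
        return self.b - self.a

    def stats(self) -> frozenset:
        """The set of optional statistics present, e.g. ``{'mean', 'sd'}``."""
        return frozenset(
            k for k in ("median", "mean", "sd") if getattr(self, k) is not None
        )

    @classmethod
    def from_dict(cls, record: dict, name: str = "") -> "MinimalData":
        """Build from a config-style mapping with keys a, b, median, mean, sd."""
        known = {"a", "b", "median", "mean", "sd", "name"}
        extra = set(record) - known
        if extra:
            raise InvalidInputError(f"unknown minimal-data keys: {sorted(extra)}")
        if "a" not in record or "b" not in record:
            raise InvalidInputError("minimal data requires both 'a' and 'b'")
        return cls(
            a=float(record["a"]),
            b=float(record["b"]),
            median=_opt(record.get("median")),
            mean=_opt(record.get("mean")),
            sd=_opt(record.get("sd")),
            name=record.get("name", name),
        )

    def to_dict(self) -> dict:
        out = {"a": self.a, "b": self.b}
        for k in ("median", "mean", "sd"):
            v = getattr(self, k)
            if v is not None:
                out[k] = v
        if self.name:
            out["name"] = self.name
        return out


def _opt(v):
    return None if v is None else float(v)


def _finite(v) -> bool:
    try:
        return abs(float(v)) < float("inf")
    except (TypeError, ValueError):
        return False
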