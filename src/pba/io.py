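"""Reading and writing the package's text formats.

All outputs are comma-separated text with '.' as the decimal mark and a
documented header row, plus JSON sidecars for provenance — formats that
round-trip through spreadsheets, which is how health-economics teams
usually consume them.  Config files are YAML.
"""

from __future__ import annotations

import json
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from .bounding import StepBF
from .errors import InvalidInputError
from .minimal import MinimalData
from .pbox import PBox, eval_bounds
from .slicing import DiscretizedPBox
from .propagation import OutcomePBox
from .decision import DecisionReport, ExpectedInterval

__all__ = [
    "write_staircase", "read_staircase", "write_slices", "read_slices",
    "write_outcome", "read_records", "write_intervals", "read_intervals",
    "write_decision_report", "load_config", "dump_config",
]


# -- p-box staircases -------------------------------------------------------

def write_staircase(path, p: PBox, grid: Union[int, np.ndarray] = 512) -> pd.DataFrame:
    """Export a p-box as a theta/lower_cdf/upper_cdf staircase."""
    if isinstance(grid, (int, np.integer)):
        if grid < 1:
            raise InvalidInputError("grid must have at least one point")
        thetas = np.linspace(p.a, p.b, int(grid)) if grid > 1 else np.array([p.a])
    else:
        thetas = np.asarray(grid, dtype=float)
    lo, up = eval_bounds(p, thetas)
    df = pd.DataFrame({"theta": thetas,
                       "lower_cdf": np.atleast_1d(lo),
                       "upper_cdf": np.atleast_1d(up)})
    df.to_csv(path, index=False, float_format="%.17g")
    return df


def read_staircase(path) -> PBox:
    """Re-import a staircase as an envelope p-box.

    Step interpolation keeps the import conservative: the lower bound
    steps up *at* each exported point (under-estimating between points)
    and the upper bound holds the next exported value (over-estimating),
    so the imported box encloses everything the original did and
    reproduces the exported values exactly at the grid points.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("theta", "lower_cdf", "upper_cdf"):
        if col not in df.columns:
            raise InvalidInputError(f"staircase file missing column {col!r}")
    thetas = df["theta"].to_numpy(dtype=float)
    lower = StepBF(thetas, df["lower_cdf"].to_numpy(dtype=float), side="right")
    upper = StepBF(thetas, df["upper_cdf"].to_numpy(dtype=float), side="left")
    return PBox(lower=lower, upper=upper,
                a=float(thetas.min()), b=float(thetas.max()),
                label="imported")


# -- slices -----------------------------------------------------------------

def write_slices(path, d: DiscretizedPBox) -> pd.DataFrame:
    df = pd.DataFrame({
        "slice_index": np.arange(len(d)),
        "prob_lo": d.c, "prob_hi": d.d, "mass": d.mass,
        "theta_lo": d.lo, "theta_hi": d.hi,
    })
    df.to_csv(path, index=False, float_format="%.17g")
    return df


def read_slices(path) -> DiscretizedPBox:
    df = pd.read_csv(path, float_precision="round_trip")
    return DiscretizedPBox(
        c=df["prob_lo"].to_numpy(float), d=df["prob_hi"].to_numpy(float),
        mass=df["mass"].to_numpy(float),
        lo=df["theta_lo"].to_numpy(float), hi=df["theta_hi"].to_numpy(float))


# -- outcomes ---------------------------------------------------------------

def write_outcome(outcome: OutcomePBox, records_path=None, staircase_path=None,
                  provenance_path=None) -> None:
    """Write the records, staircase and provenance files of an outcome."""
    if records_path is not None:
        pd.DataFrame({
            "k": np.arange(outcome.mass.size),
            "y_min": outcome.y_min, "y_max": outcome.y_max,
            "mass": outcome.mass,
        }).to_csv(records_path, index=False, float_format="%.17g")
    if staircase_path is not None:
        pd.DataFrame({
            "y": outcome.ys,
            "lower_cdf": outcome.lower_cdf,
            "upper_cdf": outcome.upper_cdf,
        }).to_csv(staircase_path, index=False, float_format="%.17g")
    if provenance_path is not None:
        with open(provenance_path, "w") as fh:
            json.dump(_jsonable(outcome.provenance), fh, indent=2)
            fh.write("\n")


def read_records(path) -> OutcomePBox:
    df = pd.read_csv(path, float_precision="round_trip")
    records = list(zip(df["y_min"], df["y_max"], df["mass"]))
    return OutcomePBox.from_records(records)


# -- expected intervals and decisions ---------------------------------------

def write_intervals(path, intervals) -> pd.DataFrame:
    df = pd.DataFrame({
        "label": [iv.label for iv in intervals],
        "mu_lo": [iv.lo for iv in intervals],
        "mu_hi": [iv.hi for iv in intervals],
    })
    df.to_csv(path, index=False, float_format="%.17g")
    return df


def read_intervals(path) -> list:
    df = pd.read_csv(path, float_precision="round_trip")
    return [ExpectedInterval(lo=row.mu_lo, hi=row.mu_hi, label=str(row.label))
            for row in df.itertuples()]


def write_decision_report(path, report: DecisionReport, intervals=None) -> None:
    payload = {
        "rule": report.rule,
        "alpha": report.alpha,
        "preferred": list(report.preferred),
        "tie": report.is_tie,
        "rationale": report.rationale,
        "scores": _jsonable(report.scores),
    }
    if intervals:
        payload["intervals"] = {
            iv.label: {"mu_lo": iv.lo, "mu_hi": iv.hi} for iv in intervals}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


# -- config -----------------------------------------------------------------

def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise InvalidInputError(f"config {path} is not a mapping")
    return cfg


def dump_config(path, cfg: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and not np.isfinite(obj):
        return str(obj)
    return obj
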