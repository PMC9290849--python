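"""Analysis configs: validation and model construction.

A config is a YAML mapping with up to four blocks::

    parameters:                      # role manifest, one entry per model input
      - {name: c1, role: pbox, data: {a: 0, b: 10, mean: 0.05, sd: 0.00033}}
      - {name: c2, role: fixed, value: 0.01}
      - {name: c4, role: cdf, dist: {family: gamma, mean: 0.1, sd: 0.02}}
    model:
      builtin: residence4            # or cea: {...}, or plugin: "pkg.mod:func"
    propagation:
      n_slices: 50
      method: direct                 # direct | grid | vertex
      N: 100                         # Monte Carlo samples (mixed mode)
      mode: sample                   # sample | fix_at_mean
      seed: 1
      grid: 512
    decision:
      rule: hurwicz
      alpha: 0.5

Validation reports field-level messages; unknown keys are rejected so
typos fail loudly instead of being silently ignored.
"""

from __future__ import annotations

import importlib
from typing import Optional

import numpy as np
from scipy import stats

from .cohort import CEAMarkovModel, inmb, run_cea
from .errors import InvalidInputError
from .minimal import MinimalData
from .propagation import BlackBoxModel, Parameter

__all__ = ["validate_config", "build_model", "dist_from_spec",
           "build_cea_model", "propagation_settings"]

_DIST_FAMILIES = {
    "gamma": stats.gamma, "beta": stats.beta, "uniform": stats.uniform,
    "normal": stats.norm, "lognormal": stats.lognorm,
}

_PROP_DEFAULTS = {"n_slices": 10, "method": "direct", "N": 100,
                  "mode": "sample", "seed": None, "grid": 512,
                  "g": 21, "budget": None}


def dist_from_spec(spec: dict, where: str = "dist"):
    """Frozen scipy distribution from a config spec.

    Either explicit family parameters (``{family: gamma, a: 2, scale: 3}``)
    or moment form (``{family: gamma, mean: .., sd: ..}``) for the gamma,
    beta (with optional a/b support) and uniform (``{a: .., b: ..}``)
    families.
    """
    if not isinstance(spec, dict) or "family" not in spec:
        raise InvalidInputError(f"{where}: needs a mapping with a 'family' key")
    spec = dict(spec)
    family = spec.pop("family")
    if family not in _DIST_FAMILIES:
        raise InvalidInputError(
            f"{where}: unknown family {family!r}; known: "
            f"{sorted(_DIST_FAMILIES)}")
    if "mean" in spec or "sd" in spec:
        from .fixtures import beta_from_moments, gamma_from_moments
        mean, sd = spec.pop("mean", None), spec.pop("sd", None)
        if mean is None or sd is None:
            raise InvalidInputError(f"{where}: moment form needs mean and sd")
        if family == "gamma":
            dist = gamma_from_moments(mean, sd)
        elif family == "beta":
            dist = beta_from_moments(mean, sd, spec.pop("a", 0.0),
                                     spec.pop("b", 1.0))
        else:
            raise InvalidInputError(
                f"{where}: moment form supported for gamma and beta only")
        if spec:
            raise InvalidInputError(f"{where}: stray keys {sorted(spec)}")
        return dist
    if family == "uniform" and "a" in spec and "b" in spec:
        a, b = spec.pop("a"), spec.pop("b")
        if spec:
            raise InvalidInputError(f"{where}: stray keys {sorted(spec)}")
        return stats.uniform(loc=a, scale=b - a)
    try:
        return _DIST_FAMILIES[family](**spec)
    except TypeError as exc:
        raise InvalidInputError(f"{where}: bad parameters for {family}: {exc}")


def _parse_parameter(entry: dict, pos: int) -> Parameter:
    where = f"parameters[{pos}]"
    if not isinstance(entry, dict):
        raise InvalidInputError(f"{where}: must be a mapping")
    known = {"name", "role", "value", "dist", "data", "monotone"}
    extra = set(entry) - known
    if extra:
        raise InvalidInputError(f"{where}: unknown keys {sorted(extra)}")
    name = entry.get("name")
    role = entry.get("role")
    if not name or not role:
        raise InvalidInputError(f"{where}: 'name' and 'role' are required")
    kwargs = {"name": str(name), "role": str(role),
              "monotone": entry.get("monotone")}
    if role == "fixed":
        if "value" not in entry:
            raise InvalidInputError(f"{where} ({name}): fixed role needs 'value'")
        kwargs["value"] = float(entry["value"])
    elif role == "cdf":
        kwargs["dist"] = dist_from_spec(entry.get("dist"),
                                        where=f"{where} ({name}).dist")
    elif role == "pbox":
        data = entry.get("data")
        if not isinstance(data, dict):
            raise InvalidInputError(
                f"{where} ({name}): pbox role needs a 'data' mapping")
        kwargs["data"] = MinimalData.from_dict(data, name=str(name))
    return Parameter(**kwargs)


def validate_config(cfg: dict) -> dict:
    """Validate the config structure; returns a normalized copy."""
    if not isinstance(cfg, dict):
        raise InvalidInputError("config must be a mapping")
    known = {"parameters", "model", "propagation", "decision"}
    extra = set(cfg) - known
    if extra:
        raise InvalidInputError(f"unknown top-level config keys {sorted(extra)}")
    out = dict(cfg)
    entries = cfg.get("parameters", [])
    if not isinstance(entries, list):
        raise InvalidInputError("'parameters' must be a list")
    params = [_parse_parameter(e, i) for i, e in enumerate(entries)]
    names = [p.name for p in params]
    if len(set(names)) != len(names):
        raise InvalidInputError("parameter names must be unique")
    out["_parameters"] = tuple(params)
    out["propagation"] = propagation_settings(cfg.get("propagation", {}))
    return out


def propagation_settings(block: dict) -> dict:
    if not isinstance(block, dict):
        raise InvalidInputError("'propagation' must be a mapping")
    extra = set(block) - set(_PROP_DEFAULTS)
    if extra:
        raise InvalidInputError(f"unknown propagation keys {sorted(extra)}")
    settings = {**_PROP_DEFAULTS, **block}
    if settings["method"] not in ("direct", "grid", "vertex"):
        raise InvalidInputError(f"unknown method {settings['method']!r}")
    if settings["mode"] not in ("sample", "fix_at_mean"):
        raise InvalidInputError(f"unknown mode {settings['mode']!r}")
    if int(settings["N"]) < 1:
        raise InvalidInputError("N must be >= 1")
    return settings


def build_model(cfg: dict) -> BlackBoxModel:
    """Construct the black-box model a validated config describes."""
    params = cfg.get("_parameters")
    if params is None:
        cfg = validate_config(cfg)
        params = cfg["_parameters"]
    block = cfg.get("model")
    if not isinstance(block, dict):
        raise InvalidInputError("config needs a 'model' mapping")
    if "plugin" in block:
        target = block["plugin"]
        mod_name, _, attr = target.partition(":")
        if not attr:
            raise InvalidInputError(
                f"plugin must be 'module:callable', got {target!r}")
        evaluator = getattr(importlib.import_module(mod_name), attr)
        return BlackBoxModel(evaluator=evaluator, parameters=params,
                             name=target, vectorized=bool(block.get("vectorized")))
    builtin = block.get("builtin")
    if builtin == "residence4":
        from .cohort import residence_rates_vectorized
        order = [p.name for p in params]
        if sorted(order) != ["c1", "c2", "c3", "c4", "c5", "c6"]:
            raise InvalidInputError(
                "residence4 expects exactly the parameters c1..c6")
        def evaluator(v, _names=tuple(order)):
            arr = np.atleast_2d(np.asarray(v, dtype=float))
            cols = [arr[:, _names.index(f"c{i}")] for i in range(1, 7)]
            return residence_rates_vectorized(np.column_stack(cols))

        return BlackBoxModel(evaluator=evaluator, parameters=params,
                             name="residence4", vectorized=True)
    if builtin == "cea":
        return build_cea_model(block.get("cea"), params)
    raise InvalidInputError(
        f"model must declare 'plugin' or builtin in {{'residence4', 'cea'}}, "
        f"got {block}")


def build_cea_model(cea_cfg: dict, params) -> BlackBoxModel:
    """INMB model from a structured cost-effectiveness config.

    The config carries per-intervention base transition matrices; each
    model parameter overrides one matrix entry (``uncertain`` mapping
    entries) and the row's designated ``complement`` column absorbs the
    remainder so rows keep summing to one.
    """
    if not isinstance(cea_cfg, dict):
        raise InvalidInputError("builtin 'cea' needs a 'cea' config mapping")
    required = {"states", "transitions", "costs", "utilities", "initial",
                "cycle_months", "n_cycles", "annual_discount", "wtp",
                "intervention", "comparator"}
    missing = required - set(cea_cfg)
    if missing:
        raise InvalidInputError(f"cea config missing keys {sorted(missing)}")
    states = tuple(cea_cfg["states"])
    s_index = {s: i for i, s in enumerate(states)}
    base = {name: np.asarray(mat, dtype=float)
            for name, mat in cea_cfg["transitions"].items()}
    for arm in (cea_cfg["intervention"], cea_cfg["comparator"]):
        if arm not in base:
            raise InvalidInputError(f"no transition matrix for arm {arm!r}")
    uncertain = cea_cfg.get("uncertain", [])
    complement = cea_cfg.get("complement", {})
    names = [p.name for p in params]
    for entry in uncertain:
        for key in ("param", "intervention", "from", "to"):
            if key not in entry:
                raise InvalidInputError(f"uncertain entry missing {key!r}: {entry}")
        if entry["param"] not in names:
            raise InvalidInputError(
                f"uncertain entry refers to unknown parameter {entry['param']!r}")
        for s in (entry["from"], entry["to"]):
            if s not in s_index:
                raise InvalidInputError(f"unknown state {s!r} in uncertain entry")

    def builder(vector, arm):
        P = base[arm].copy()
        touched_rows = set()
        values = dict(zip(names, np.asarray(vector, dtype=float)))
        for entry in uncertain:
            arms = entry["intervention"]
            if arms not in ("both", arm):
                continue
            i, j = s_index[entry["from"]], s_index[entry["to"]]
            P[i, j] = values[entry["param"]]
            touched_rows.add(i)
        for i in touched_rows:
            comp_state = complement.get(states[i])
            if comp_state is None:
                raise InvalidInputError(
                    f"row {states[i]!r} modified but has no complement column")
            j = s_index[comp_state]
            others = P[i].sum() - P[i, j]
            P[i, j] = 1.0 - others
        return P

    cea = CEAMarkovModel(
        states=states, matrix_builder=builder,
        costs=tuple(float(c) for c in cea_cfg["costs"]),
        utilities=tuple(float(u) for u in cea_cfg["utilities"]),
        cycle_months=float(cea_cfg["cycle_months"]),
        n_cycles=int(cea_cfg["n_cycles"]),
        annual_discount=float(cea_cfg["annual_discount"]),
        wtp=float(cea_cfg["wtp"]),
        initial=tuple(float(x) for x in cea_cfg["initial"]),
        half_cycle=bool(cea_cfg.get("half_cycle", False)),
    )
    arm_new, arm_cmp = cea_cfg["intervention"], cea_cfg["comparator"]

    def evaluator(vector):
        cost_n, qaly_n = run_cea(cea, vector, arm_new)
        cost_c, qaly_c = run_cea(cea, vector, arm_cmp)
        return inmb(cost_n, qaly_n, cost_c, qaly_c, cea.wtp)

    model = BlackBoxModel(evaluator=evaluator, parameters=tuple(params),
                          name="cea-inmb", vectorized=False)
    return model
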