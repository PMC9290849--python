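"""Shipped example configurations.

``case_study_1_config`` is the four-state rate model with two p-box
rates (c1, c6) and the remaining rates fixed at their means.

``synthetic_cea_config`` is a nine-state knee-replacement-shaped
cost-effectiveness model comparing a computer-assisted against a
conventional procedure over a 10-year monthly-cycle horizon at a 3.5%
annual discount rate and a £30,000/QALY threshold.  Its numbers are
synthetic placeholders chosen to be clinically plausible; it exercises
the pipeline and is NOT a replication of any published parameter table.
"""

from __future__ import annotations

__all__ = ["case_study_1_config", "synthetic_cea_config"]


def case_study_1_config() -> dict:
    return {
        "parameters": [
            {"name": "c1", "role": "pbox",
             "data": {"a": 0.0, "b": 10.0, "mean": 0.05, "sd": 0.00033}},
            {"name": "c2", "role": "fixed", "value": 0.01},
            {"name": "c3", "role": "fixed", "value": 0.001},
            {"name": "c4", "role": "fixed", "value": 0.1},
            {"name": "c5", "role": "fixed", "value": 0.05},
            {"name": "c6", "role": "pbox",
             "data": {"a": 0.0, "b": 10.0, "mean": 1.0, "sd": 0.0167}},
        ],
        "model": {"builtin": "residence4"},
        "propagation": {"n_slices": 50, "method": "direct", "seed": 1,
                        "grid": 512},
    }


# state order: operation, normal-primary, minor-comp, serious-comp,
# simple-revision, complex-revision, other-treatment, normal-revision, dead
_STATES = ["tkr_op", "normal_primary", "minor_comp", "serious_comp",
           "simple_rev", "complex_rev", "other_treat", "normal_rev", "dead"]


def _base_matrix(p_minor, p_serious):
    """Monthly transition matrix of the synthetic nine-state model."""
    rows = {
        "tkr_op":        {"normal_primary": None, "minor_comp": p_minor,
                          "serious_comp": p_serious, "dead": 0.002},
        "normal_primary": {"normal_primary": None, "minor_comp": 0.004,
                           "serious_comp": 0.001, "dead": 0.002},
        "minor_comp":    {"minor_comp": None, "normal_primary": 0.25,
                          "serious_comp": 0.02, "other_treat": 0.10,
                          "dead": 0.002},
        "serious_comp":  {"serious_comp": None, "simple_rev": 0.15,
                          "complex_rev": 0.08, "other_treat": 0.05,
                          "dead": 0.005},
        "simple_rev":    {"simple_rev": None, "normal_rev": 0.30,
                          "serious_comp": 0.01, "dead": 0.004},
        "complex_rev":   {"complex_rev": None, "normal_rev": 0.20,
                          "serious_comp": 0.02, "dead": 0.008},
        "other_treat":   {"other_treat": None, "normal_primary": 0.15,
                          "minor_comp": 0.03, "serious_comp": 0.01,
                          "dead": 0.003},
        "normal_rev":    {"normal_rev": None, "minor_comp": 0.003,
                          "serious_comp": 0.001, "dead": 0.002},
        "dead":          {"dead": 1.0},
    }
    mat = []
    for s in _STATES:
        row = [0.0] * len(_STATES)
        spec = rows[s]
        stay_state = next(k for k, v in spec.items() if v is None) \
            if None in spec.values() else None
        total = sum(v for v in spec.values() if v is not None)
        for target, v in spec.items():
            row[_STATES.index(target)] = (1.0 - total) if v is None else v
        assert stay_state is None or row[_STATES.index(stay_state)] >= 0
        mat.append(row)
    return mat


def synthetic_cea_config() -> dict:
    # the computer-assisted arm has fewer complications after the operation
    conventional = _base_matrix(p_minor=0.05, p_serious=0.015)
    assisted = _base_matrix(p_minor=0.035, p_serious=0.010)
    monthly_utility = [u / 12.0 for u in
                       [0.60, 0.78, 0.62, 0.45, 0.55, 0.50, 0.58, 0.74, 0.0]]
    return {
        "parameters": [
            {"name": "p_minor_ca", "role": "pbox",
             "data": {"a": 0.005, "b": 0.08, "mean": 0.035}},
            {"name": "p_serious_ca", "role": "pbox",
             "data": {"a": 0.002, "b": 0.03, "mean": 0.010}},
        ],
        "model": {
            "builtin": "cea",
            "cea": {
                "states": list(_STATES),
                "transitions": {"conventional": conventional,
                                "assisted": assisted},
                "uncertain": [
                    {"param": "p_minor_ca", "intervention": "assisted",
                     "from": "tkr_op", "to": "minor_comp"},
                    {"param": "p_serious_ca", "intervention": "assisted",
                     "from": "tkr_op", "to": "serious_comp"},
                ],
                "complement": {"tkr_op": "normal_primary"},
                "costs": [4500.0, 15.0, 250.0, 900.0, 5200.0, 7800.0,
                          400.0, 20.0, 0.0],
                "utilities": monthly_utility,
                "initial": [1.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0],
                "cycle_months": 1,
                "n_cycles": 120,
                "annual_discount": 0.035,
                "wtp": 30000.0,
                "intervention": "assisted",
                "comparator": "conventional",
            },
        },
        "propagation": {"n_slices": 10, "method": "direct", "seed": 1},
    }
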