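"""Canonical experiment presets.

These are the representative scenarios of the study: three (or two)
patches with qualities in (0,1], a slow constant leak a = 1e-3, average
recruitment strength r = 100 (social recruitment much faster than
independent discovery), stop-signal strength z = 3.1, and a finite
population of S = 200 for the stochastic ensembles.  Ensemble sizes
default to 200 runs, a scale at which the orderings and confidence
intervals of interest are already resolved; all entries can be overridden
from a config file or CLI flags.
"""

from __future__ import annotations

import copy

FIG1: dict = {
    "qualities": [0.75, 0.5, 0.25],
    "a": 1e-3,
    "r": 100.0,
    "z": 3.1,
    "S": 200,
    "t_end": 400.0,
    "eval_time": 400.0,
    "n_runs": 200,
    # small perturbation of the initial population: x1 = x2 = 0, x3 = 0.05
    "perturbed_init": [0.0, 0.0, 0.05],
    "convergence_tol": 1e-4,
}

FIG2: dict = {
    "qualities": [0.75, 0.5],
    "a": 1e-3,
    "r": 100.0,
    "z": 3.1,
    "S": 200,
    "t_end": 1000.0,
    "eval_time": 1000.0,
    "n_runs": 200,
}

FIG3: dict = {
    "qualities": [0.75, 0.5, 0.25],
    "a": 1e-3,
    "r": 100.0,
    "z": 3.1,
    "z_grid": [0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0],
    "rho_grid": [50.0, 100.0, 200.0, 400.0, 800.0],
    "convergence_tol": 1e-4,
}

SWEEP: dict = {
    "S_values": [100, 200],
    "r_values": [50.0, 100.0],
    "quality_sets": [[0.75, 0.5, 0.25], [0.9, 0.3]],
    "a": 1e-3,
    "z": 3.1,
    "t_end": 400.0,
    "eval_time": 400.0,
    "n_runs": 100,
    "a_values": None,  # set for the abandonment sub-sweep
}

ADAPTATION: dict = {
    "qualities_before": [0.75, 0.5, 0.25],
    "qualities_after": [0.25, 0.5, 0.75],
    "a": 1e-3,
    "r": 100.0,
    "z": 3.1,
    "switch_time": 10.0,
    "n_inits": 10,
    "convergence_tol": 1e-4,
}

ASOCIAL: dict = {
    "qualities": [0.75, 0.5, 0.25],
    "a": 1e-3,
    "r": 100.0,
    "z": 3.1,
    "S": 200,
    "t_end": 400.0,
    "eval_time": 400.0,
    "n_runs": 100,
    "convergence_tol": 1e-4,
}

DEVIATION: dict = {
    "qualities": [0.75, 0.5, 0.25],
    "a": 1e-3,
    "r": 100.0,
    "z": 3.1,
    "S": 200,
    "t_end": 400.0,
    "eval_time": 400.0,
    "n_runs": 200,
    "delta": None,  # default: 95th percentile of the negative-feedback R^2
}


def merged(preset: dict, overrides: "dict | None") -> dict:
    out = copy.deepcopy(preset)
    if overrides:
        out.update({k: v for k, v in overrides.items() if v is not None})
    return out
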