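"""One-parameter sweeps: signal-response curves, folds, oscillation windows.

``sweep`` walks a grid of one external input (stress, or the total mTOR pool
to mimic rapamycin titration), tracking steady-state branches by Newton
continuation from the previous grid point plus fresh multi-starts, labelling
stability, and — where no stable state exists — measuring the limit-cycle
envelope (per-variable min/max of the post-transient orbit).  Fold
(saddle-node) inputs are localised by bisection on the steady-state count;
oscillation-window edges are the attractor-label transitions and should
coincide with Hopf loss of stability of the interior state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dynamics import (
    SteadyStateRecord,
    find_steady_states,
    physiological_state,
    simulate,
)
from .model import (
    STATE_NAMES,
    ConnectionMask,
    ParameterSet,
    SystemInputs,
    SystemState,
)

__all__ = ["BifurcationDiagram", "sweep", "signal_response",
           "reversibility_check", "ReversibilityReport"]


def _inputs_for(input_name: str, value: float, base: SystemInputs) -> SystemInputs:
    if input_name == "stress":
        return SystemInputs(stress=value, mtor_total=base.mtor_total)
    if input_name == "mtor_total":
        return SystemInputs(stress=base.stress, mtor_total=value)
    raise KeyError(f"unknown swept input {input_name!r}")


@dataclass
class BifurcationDiagram:
    input_name: str
    grid: np.ndarray
    #: per grid point: list of SteadyStateRecord
    states: list
    #: per grid point: dict var -> (min, max) when oscillatory, else None
    envelopes: list
    fold_inputs: list
    #: list of (lo, hi) input intervals with sustained oscillation
    oscillation_windows: list
    params: ParameterSet = None
    mask: ConnectionMask = None
    base_inputs: SystemInputs = None

    def n_states(self) -> np.ndarray:
        return np.array([len(s) for s in self.states])

    def n_stable(self) -> np.ndarray:
        return np.array([sum(r.is_stable for r in s) for s in self.states])

    def is_oscillatory(self) -> np.ndarray:
        return np.array([e is not None for e in self.envelopes])

    def to_table(self) -> pd.DataFrame:
        """Long-format export: input value, branch id, variable, value, flag."""
        rows = []
        for g, recs, env in zip(self.grid, self.states, self.envelopes):
            for b, rec in enumerate(recs):
                for var in STATE_NAMES:
                    rows.append({"input": g, "branch": b, "variable": var,
                                 "value": getattr(rec.state, var),
                                 "flag": rec.stability_label})
            if env is not None:
                for var, (lo, hi) in env.items():
                    rows.append({"input": g, "branch": -1, "variable": var,
                                 "value": lo, "flag": "cycle_min"})
                    rows.append({"input": g, "branch": -1, "variable": var,
                                 "value": hi, "flag": "cycle_max"})
        return pd.DataFrame(rows)


def _count_states(params, mask, inputs, seed, warm=()):
    recs = find_steady_states(params, mask, inputs, n_starts=30, seed=seed,
                              extra_starts=warm)
    return recs


def _envelope(params, mask, inputs, x0, t_end=400.0, transient=0.5,
              output_step=0.05):
    from ._fastsim import fast_timecourse

    t, y = fast_timecourse(params, mask, inputs, np.asarray(x0, float),
                           t_end, output_step, rtol=1e-6, atol=1e-9)
    i0 = int(transient * t.size)
    seg = y[i0:]
    env = {var: (float(seg[:, i].min()), float(seg[:, i].max()))
           for i, var in enumerate(STATE_NAMES)}
    return env, y[-1]


def sweep(params: ParameterSet, mask: ConnectionMask, input_name: str,
          input_grid, base_inputs: SystemInputs | None = None,
          seed: int = 0, amp_tol: float = 1e-3) -> BifurcationDiagram:
    """Sweep one input over a strictly increasing grid of >= 50 points."""
    grid = np.asarray(input_grid, dtype=float)
    if grid.size < 50 or np.any(np.diff(grid) <= 0):
        raise ValueError("input grid must be strictly increasing with >= 50 points")
    base = base_inputs or SystemInputs()

    states: list = []
    envelopes: list = []
    prev_states: list[np.ndarray] = []
    x_osc = None
    # the resting branch hugs the state-box faces where random multi-starts
    # rarely land; seed it explicitly at every grid point
    from .model import resting_state_array

    rest = np.asarray(resting_state_array(params), dtype=float)
    for k, g in enumerate(grid):
        inputs = _inputs_for(input_name, g, base)
        # continuation warm starts from the previous grid point
        warm = [np.clip(x, 0, None) for x in prev_states]
        warm.append(np.minimum(rest, [params.ulk1_total, params.ampk_total,
                                      inputs.mtor_total, np.inf]))
        recs = _count_states(params, mask, inputs, seed, warm)
        states.append(recs)
        prev_states = [r.state.as_array() for r in recs]
        if any(r.is_stable for r in recs):
            envelopes.append(None)
            x_osc = None
        else:
            if x_osc is None:
                if recs:
                    x0 = recs[0].state.as_array() * 1.02 + 1e-3
                    x0[2] = min(x0[2], inputs.mtor_total)
                else:
                    x0 = np.array([0.01, 0.01,
                                   0.5 * inputs.mtor_total, 0.05])
                x_osc = x0
            env, x_osc = _envelope(params, mask, inputs, x_osc)
            amp = max(hi - lo for lo, hi in env.values())
            envelopes.append(env if amp > amp_tol else None)

    # fold localisation: bisection on steady-state count changes
    fold_inputs = []
    counts = [len(s) for s in states]
    for k in range(len(grid) - 1):
        if counts[k] != counts[k + 1]:
            lo, hi = grid[k], grid[k + 1]
            n_lo = counts[k]
            warm = [r.state.as_array() for r in states[k] + states[k + 1]]
            while hi - lo > 1e-4:
                mid = 0.5 * (lo + hi)
                recs = _count_states(params, mask,
                                     _inputs_for(input_name, mid, base),
                                     seed, warm)
                if len(recs) == n_lo:
                    lo = mid
                else:
                    hi = mid
            fold_inputs.append(0.5 * (lo + hi))

    # oscillation windows from attractor-label transitions
    osc = [e is not None for e in envelopes]
    windows = []
    k = 0
    while k < len(grid):
        if osc[k]:
            j = k
            while j + 1 < len(grid) and osc[j + 1]:
                j += 1
            windows.append((float(grid[k]), float(grid[j])))
            k = j + 1
        else:
            k += 1

    return BifurcationDiagram(input_name, grid, states, envelopes,
                              fold_inputs, windows, params, mask, base)


def signal_response(diagram: BifurcationDiagram, variable: str) -> pd.DataFrame:
    """Stable/unstable branch segments of one variable vs the swept input.

    Branches are chained by continuity (nearest continuation within a step
    bound); the returned frame has columns input/branch/value/stability.
    """
    iv = STATE_NAMES.index(variable)
    rows = []
    open_branches: list = []   # (branch_id, last_value, last_stab)
    next_id = 0
    for g, recs in zip(diagram.grid, diagram.states):
        vals = [(getattr(r.state, variable), r.stability_label) for r in recs]
        assigned = {}
        used = set()
        for bid, last_v, last_s in open_branches:
            best, bestd = None, np.inf
            for i, (v, s) in enumerate(vals):
                if i in used or s != last_s:
                    continue
                d = abs(v - last_v)
                if d < bestd:
                    best, bestd = i, d
            if best is not None and bestd < 0.25:
                assigned[best] = bid
                used.add(best)
        new_open = []
        for i, (v, s) in enumerate(vals):
            bid = assigned.get(i)
            if bid is None:
                bid = next_id
                next_id += 1
            rows.append({"input": g, "branch": bid, "value": v,
                         "stability": s})
            new_open.append((bid, v, s))
        open_branches = new_open
    return pd.DataFrame(rows)


@dataclass
class ReversibilityReport:
    initial_state: SystemState
    final_state: SystemState
    max_abs_difference: float
    reversible: bool
    up_branch: np.ndarray      # swept-variable ULK1 value at each up step
    down_branch: np.ndarray


def reversibility_check(params: ParameterSet, mask: ConnectionMask,
                        up_grid, down_grid,
                        base_inputs: SystemInputs | None = None,
                        hold_time: float = 60.0, tol: float = 1e-3,
                        input_name: str = "stress") -> ReversibilityReport:
    """Quasi-static up-then-down sweep; checks return to the starting state.

    The system is equilibrated at each grid value from the previous end
    state (hold_time per step), emulating a slow signal ramp; hysteresis
    shows up as different branch occupancy between the two passes.
    """
    up = np.asarray(up_grid, dtype=float)
    down = np.asarray(down_grid, dtype=float)
    if not np.allclose(up, down[::-1]):
        raise ValueError("down grid must mirror the up grid")
    base = base_inputs or SystemInputs()

    x = physiological_state(params, mask,
                            mtor_total=base.mtor_total).as_array()
    x0 = x.copy()
    up_vals, down_vals = [], []
    for g in up:
        inputs = _inputs_for(input_name, g, base)
        x[2] = min(x[2], inputs.mtor_total)
        tc = simulate(params, mask, inputs, SystemState.from_array(x),
                      hold_time, output_step=hold_time / 50, rtol=1e-8,
                      atol=1e-11)
        x = tc.states[-1]
        up_vals.append(x[0])
    for g in down:
        inputs = _inputs_for(input_name, g, base)
        tc = simulate(params, mask, inputs, SystemState.from_array(x),
                      hold_time, output_step=hold_time / 50, rtol=1e-8,
                      atol=1e-11)
        x = tc.states[-1]
        down_vals.append(x[0])
    diff = float(np.max(np.abs(x - x0)))
    return ReversibilityReport(SystemState.from_array(x0),
                               SystemState.from_array(x), diff, diff < tol,
                               np.array(up_vals), np.array(down_vals))
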