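"""The qualitative regime table of the model and its automated checker.

Each row states a wiring variant, external inputs, an optional parameter
perturbation, and the expected long-run behaviour: a sustained limit cycle,
a damped oscillation, a single steady state with prescribed high/low levels,
or bistability with a given steady-state count.  ``run_regime_suite`` runs
every row through the dynamics machinery (steady-state analysis and/or
stress-onset simulation from the computed resting state) and reports
pass/fail per row.  The default parameter set is calibrated so that all rows
pass; the suite therefore doubles as the package's regression surface for
the model's qualitative biology.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dynamics import (
    AmbiguousAttractorError,
    classify_attractor,
    find_steady_states,
    physiological_state,
    simulate,
)
from .model import (
    ConnectionMask,
    ParameterSet,
    SystemInputs,
    apply_perturbation,
    default_parameters,
    effective_parameters,
)

__all__ = ["RegimeExpectation", "RegimeResult", "REGIME_TABLE",
           "run_regime_suite", "HIGH_FRAC", "LOW_FRAC"]

#: qualitative level thresholds, as fractions of the relevant pool
HIGH_FRAC = 0.6
LOW_FRAC = 0.2


@dataclass(frozen=True)
class RegimeExpectation:
    row_id: str
    variant: str
    stress: float
    mtor_total: float
    expected: str           # limit_cycle | damped_oscillation | steady_state | bistable
    perturbation: str | None = None
    n_states: int | None = None      # expected steady-state count (count rows)
    n_stable: int | None = None
    levels: dict = field(default_factory=dict)   # var -> "high" | "low"
    #: levels expected on the two stable branches of a bistable row
    branch_levels: tuple = ()
    anchor: str = ""
    # simulation settings
    t_end: float = 600.0
    transient_fraction: float = 0.5


REGIME_TABLE: tuple[RegimeExpectation, ...] = (
    RegimeExpectation("r1", "full", 0.5, 1.0, "limit_cycle",
                      anchor="stress onset drives sustained oscillation"),
    RegimeExpectation("r2", "full", 0.0, 0.5, "limit_cycle",
                      anchor="rapamycin (halved mTOR pool) drives sustained oscillation"),
    RegimeExpectation("r3", "toggle", 0.0, 1.0, "steady_state",
                      n_states=1, n_stable=1,
                      levels={"mtor": "high", "ulk1": "low"},
                      anchor="physiological resting state of the toggle"),
    RegimeExpectation("r4", "toggle", 0.5, 1.0, "bistable",
                      n_states=3, n_stable=2,
                      branch_levels=({"mtor": "high", "ulk1": "low"},
                                     {"ulk1": "high", "mtor": "low"}),
                      anchor="intermediate stress: bistable toggle"),
    RegimeExpectation("r5", "toggle", 1.0, 1.0, "steady_state",
                      n_states=1, n_stable=1,
                      levels={"ulk1": "high", "mtor": "low"},
                      anchor="high stress: switch committed to autophagy"),
    RegimeExpectation("r6", "toggle", 0.0, 0.1, "steady_state",
                      n_states=1, n_stable=1,
                      levels={"ulk1": "high"},
                      anchor="strong rapamycin: autophagy on without stress"),
    RegimeExpectation("r7", "direct_nfb", 5.0, 1.0, "damped_oscillation",
                      t_end=400.0, transient_fraction=0.0,
                      anchor="direct negative feedback rings but cannot sustain"),
    RegimeExpectation("r8", "direct_nfb", 5.0, 0.01, "steady_state",
                      levels={"ampk": "low", "ulk1": "low"},
                      t_end=600.0,
                      anchor="no mTOR: homeostatic low state of the AMPK-ULK1 loop"),
    RegimeExpectation("r9", "triangle", 3.0, 1.0, "limit_cycle",
                      anchor="amplified negative feedback oscillates under stress"),
    RegimeExpectation("r10", "triangle", 3.0, 0.01, "steady_state",
                      t_end=800.0, transient_fraction=0.6,
                      anchor="triangle without mTOR cannot oscillate"),
    RegimeExpectation("r11", "full", 0.5, 1.0, "steady_state",
                      perturbation="no_reg_to_ulk1",
                      levels={"ampk": "high", "ulk1": "low", "mtor": "low"},
                      t_end=600.0,
                      anchor="REG->ULK1 cut: AMPK on, autophagy cannot fire"),
    RegimeExpectation("r12", "full", 0.5, 1.0, "steady_state",
                      perturbation="no_reg_to_mtor",
                      levels={"mtor": "high", "ampk": "low", "ulk1": "low"},
                      t_end=600.0,
                      anchor="REG-|mTOR cut: mTOR stays high, system silent"),
)


@dataclass
class RegimeResult:
    expectation: RegimeExpectation
    observed_label: str
    observed_levels: dict
    n_states: int | None
    n_stable: int | None
    passed: bool
    detail: str = ""


def _pool(var: str, params: ParameterSet, inputs: SystemInputs) -> float:
    return {"ulk1": params.ulk1_total, "ampk": params.ampk_total,
            "mtor": inputs.mtor_total}[var]


def _levels_ok(levels: dict, state_dict: dict, params, inputs,
               high=HIGH_FRAC, low=LOW_FRAC) -> bool:
    for var, want in levels.items():
        frac = state_dict[var] / _pool(var, params, inputs)
        if want == "high" and frac < high:
            return False
        if want == "low" and frac > low:
            return False
    return True


def _state_dict(state) -> dict:
    return {"ulk1": state.ulk1, "ampk": state.ampk, "mtor": state.mtor,
            "reg": state.reg}


def run_regime_row(row: RegimeExpectation, params: ParameterSet,
                   seed: int = 0, high=HIGH_FRAC, low=LOW_FRAC) -> RegimeResult:
    mask = ConnectionMask.by_name(row.variant)
    p = params
    if row.perturbation is not None:
        p, mask, _ = apply_perturbation(p, mask, row.perturbation)
    p = effective_parameters(p, row.variant)
    inputs = SystemInputs(stress=row.stress, mtor_total=row.mtor_total)

    if row.expected in ("steady_state", "bistable") and row.n_states is not None:
        # steady-state-count row (toggle branch structure)
        recs = find_steady_states(p, mask, inputs, n_starts=40, seed=seed)
        stable = [r for r in recs if r.is_stable]
        n, ns = len(recs), len(stable)
        ok = (n == row.n_states and ns == row.n_stable)
        levels_obs = [_state_dict(r.state) for r in stable]
        if ok and row.levels:
            ok = any(_levels_ok(row.levels, d, p, inputs, high, low)
                     for d in levels_obs)
        if ok and row.branch_levels:
            for want in row.branch_levels:
                if not any(_levels_ok(want, d, p, inputs, high, low)
                           for d in levels_obs):
                    ok = False
        label = "bistable" if ns > 1 else "steady_state"
        return RegimeResult(row, label,
                            levels_obs[0] if levels_obs else {},
                            n, ns, ok and label == row.expected,
                            detail=f"{n} steady states ({ns} stable)")

    # attractor row: stress/rapamycin onset from the resting state
    x0 = physiological_state(p, mask, mtor_total=1.0, seed=seed)
    if inputs.mtor_total < 1.0:
        x0 = type(x0)(x0.ulk1, x0.ampk, min(x0.mtor, inputs.mtor_total), x0.reg)
    # fine output grid: the classifier needs many samples per cycle; an
    # ambiguous verdict triggers one refinement in case of aliasing
    label = report = None
    for step in (0.05, 0.01):
        tc = simulate(p, mask, inputs, x0, t_end=row.t_end, output_step=step)
        try:
            report = classify_attractor(tc,
                                        transient_fraction=row.transient_fraction)
            label = report.label
            break
        except AmbiguousAttractorError:
            label, report = "ambiguous", None
    final = _state_dict(tc.final_state())
    ok = label == row.expected
    if ok and row.levels:
        ok = _levels_ok(row.levels, final, p, inputs, high, low)

    # eigenvalue cross-check of the classifier's verdict
    detail = ""
    if ok:
        recs = find_steady_states(p, mask, inputs, n_starts=30, seed=seed,
                                  extra_starts=[tc.states[-1]])
        stable = [r for r in recs if r.is_stable]
        if label == "limit_cycle" and stable:
            ok, detail = False, "limit cycle but a stable steady state exists"
        if label in ("steady_state", "damped_oscillation") and not stable:
            ok, detail = False, f"{label} but no stable steady state found"
    return RegimeResult(row, label, final, None, None, ok, detail)


def run_regime_suite(params: ParameterSet | None = None, seed: int = 0,
                     high=HIGH_FRAC, low=LOW_FRAC) -> list[RegimeResult]:
    """Run every row of the regime table; deterministic given ``seed``."""
    params = params if params is not None else default_parameters()
    return [run_regime_row(r, params, seed=seed, high=high, low=low)
            for r in REGIME_TABLE]


def suite_report(results: list[RegimeResult]) -> pd.DataFrame:
    """Tabular pass/fail summary of a regime-suite run."""
    rows = []
    for r in results:
        e = r.expectation
        rows.append({
            "row": e.row_id, "variant": e.variant, "stress": e.stress,
            "mtor_total": e.mtor_total, "perturbation": e.perturbation or "",
            "expected": e.expected, "observed": r.observed_label,
            "passed": r.passed, "detail": r.detail,
        })
    return pd.DataFrame(rows)
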