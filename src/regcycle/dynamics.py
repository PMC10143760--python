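"""Time-course integration, steady states and attractor classification.

Three complementary views of the model's long-run behaviour live here:

- :func:`simulate` integrates the stiff ODE system on a requested output
  grid (LSODA, relative tolerance 1e-9 by default);
- :func:`find_steady_states` locates fixed points by Newton refinement from
  Latin-hypercube multi-starts and classifies their linear stability from
  the analytic Jacobian's eigenvalues;
- :func:`classify_attractor` labels a simulated trajectory as a steady
  state, a damped oscillation, or a sustained limit cycle from the
  post-transient peak structure of the ULK1 trace.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root
from scipy.signal import find_peaks
from scipy.stats import qmc

from .model import (
    STATE_NAMES,
    ConnectionMask,
    ParameterSet,
    SystemInputs,
    SystemState,
    jacobian,
    rhs_array,
)

__all__ = [
    "TimeCourse",
    "SteadyStateRecord",
    "AttractorReport",
    "AmbiguousAttractorError",
    "IntegrationError",
    "simulate",
    "find_steady_states",
    "classify_attractor",
    "physiological_state",
]

#: eigenvalue real-part margin separating stable from unstable
STABILITY_MARGIN = 1e-8


class IntegrationError(RuntimeError):
    """Raised when the ODE solver fails; carries the failing time."""

    def __init__(self, message: str, t_fail: float):
        super().__init__(f"{message} (t = {t_fail:g})")
        self.t_fail = t_fail


class AmbiguousAttractorError(ValueError):
    """Peaks are present but match neither the sustained nor the damped
    oscillation criteria."""


@dataclass
class TimeCourse:
    """A simulated trajectory plus the configuration that produced it."""

    t: np.ndarray
    states: np.ndarray  # shape (len(t), 4), columns ulk1/ampk/mtor/reg
    inputs: SystemInputs
    params: ParameterSet
    mask: ConnectionMask

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.states.shape != (self.t.size, 4):
            raise ValueError("states must have shape (len(t), 4)")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time grid must be strictly increasing")

    @property
    def ulk1(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def ampk(self) -> np.ndarray:
        return self.states[:, 1]

    @property
    def mtor(self) -> np.ndarray:
        return self.states[:, 2]

    @property
    def reg(self) -> np.ndarray:
        return self.states[:, 3]

    def column(self, name: str) -> np.ndarray:
        return self.states[:, STATE_NAMES.index(name)]

    def final_state(self) -> SystemState:
        return SystemState.from_array(self.states[-1])

    def to_table(self, path) -> None:
        """Write a tab-separated table with a provenance comment header."""
        from .io import write_timecourse

        write_timecourse(self, path)


@dataclass(frozen=True)
class SteadyStateRecord:
    state: SystemState
    residual_norm: float
    eigenvalues: np.ndarray
    stability_label: str  # "stable" | "unstable"

    @property
    def is_stable(self) -> bool:
        return self.stability_label == "stable"


@dataclass(frozen=True)
class AttractorReport:
    label: str  # "steady_state" | "damped_oscillation" | "limit_cycle"
    period: float | None
    amplitude: dict[str, float]
    decay_ratio: float | None
    n_peaks: int = 0


def simulate(params: ParameterSet, mask: ConnectionMask, inputs: SystemInputs,
             initial_state: SystemState, t_end: float, output_step: float = 0.1,
             rtol: float = 1e-9, atol: float = 1e-12) -> TimeCourse:
    """Integrate the model from ``initial_state`` until ``t_end``.

    Uses the stiff-capable LSODA solver with the analytic Jacobian.  Output
    is reported on the uniform grid ``0, output_step, ..., t_end``.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    x0 = initial_state.as_array()
    t_eval = np.arange(0.0, t_end + 0.5 * output_step, output_step)
    t_eval = t_eval[t_eval <= t_end]

    def f(t, x):
        return rhs_array(x, inputs, params, mask)

    def jac(t, x):
        return jacobian(x, inputs, params, mask)

    sol = solve_ivp(f, (0.0, t_end), x0, method="LSODA", jac=jac,
                    t_eval=t_eval, rtol=rtol, atol=atol)
    if not sol.success:
        raise IntegrationError(sol.message, sol.t[-1] if sol.t.size else 0.0)
    return TimeCourse(sol.t, sol.y.T, inputs, params, mask)


def _reg_upper_bound(params: ParameterSet) -> float:
    if params.k_d_reg > 0:
        return (params.k_s_reg_basal
                + params.k_s_reg_ampk * params.ampk_total) / params.k_d_reg
    return 10.0


def _classify_eigs(eigs: np.ndarray) -> str:
    return "stable" if np.all(eigs.real < -STABILITY_MARGIN) else "unstable"


def find_steady_states(params: ParameterSet, mask: ConnectionMask,
                       inputs: SystemInputs, n_starts: int = 40,
                       seed: int = 0,
                       extra_starts: Sequence[np.ndarray] = ()) -> list[SteadyStateRecord]:
    """Locate steady states by Newton refinement from Latin-hypercube starts.

    Duplicate solutions are merged at Euclidean distance < 1e-6.  Each
    surviving record carries the Jacobian eigenvalues and a stability label
    (stable iff every real part is below ``-STABILITY_MARGIN``).
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    from scipy.special import expit, logit

    lo = np.zeros(4)
    hi = np.array([params.ulk1_total, params.ampk_total,
                   max(inputs.mtor_total, 1e-12),
                   _reg_upper_bound(params) * (1.0 + 1e-3) + 1e-9])
    sampler = qmc.LatinHypercube(d=4, seed=seed)
    starts = [lo + (hi - lo) * row for row in sampler.random(n_starts)]
    # deterministic near-corner starts: ultrasensitive cycles park steady
    # states against the box faces, far from any interior random start
    fracs = (1e-4, 0.5, 1.0 - 1e-4)
    for fu in fracs:
        for fm in fracs:
            starts.append(hi * np.array([fu, 0.05, fm, 0.1]))
            starts.append(hi * np.array([fu, 1.0 - 1e-4, fm, 0.5]))
    starts.extend(np.asarray(s, dtype=float) for s in extra_starts)

    def f(x):
        return rhs_array(x, inputs, params, mask)

    # Newton in logit coordinates: steep Michaelis-Menten legs push steady
    # states extremely close to the box faces, where untransformed Newton
    # either stalls or escapes to spurious out-of-pool roots.
    eps = 1e-12

    def to_z(x):
        return logit(np.clip(x / hi, eps, 1.0 - eps))

    def g(z):
        return f(hi * expit(z))

    def g_jac(z):
        x = hi * expit(z)
        return jacobian(x, inputs, params, mask) * (hi * expit(z) * (1.0 - expit(z)))

    found: list[np.ndarray] = []
    for x0 in starts:
        sol = root(g, to_z(x0), jac=g_jac, method="hybr", tol=1e-13)
        # the residual is the acceptance criterion: near the box faces the
        # logit coordinates are so ill-conditioned that hybr can report
        # failure while sitting on a machine-precision root
        x = hi * expit(sol.x)
        if np.linalg.norm(f(x)) >= 1e-9:
            continue
        if any(np.linalg.norm(x - y) < 1e-6 for y in found):
            continue
        found.append(x)

    records = []
    for x in found:
        eigs = np.linalg.eigvals(jacobian(x, inputs, params, mask))
        records.append(SteadyStateRecord(
            state=SystemState.from_array(x),
            residual_norm=float(np.linalg.norm(f(x))),
            eigenvalues=eigs,
            stability_label=_classify_eigs(eigs),
        ))
    records.sort(key=lambda r: r.state.ulk1)
    return records


def physiological_state(params: ParameterSet, mask: ConnectionMask,
                        mtor_total: float = 1.0, seed: int = 0) -> SystemState:
    """The resting state at zero stress, computed (not hard-coded).

    Integrates from a low-activity initial guess at ``stress = 0`` and
    refines the endpoint by Newton; this is the default initial condition
    for stress-onset simulations.
    """
    inputs = SystemInputs(stress=0.0, mtor_total=mtor_total)
    x0 = SystemState(0.01, 0.01, 0.9 * mtor_total, 0.05)
    tc = simulate(params, mask, inputs, x0, t_end=500.0, output_step=1.0,
                  rtol=1e-8, atol=1e-10)
    xf = tc.states[-1]
    sol = root(lambda x: rhs_array(x, inputs, params, mask), xf,
               jac=lambda x: jacobian(x, inputs, params, mask),
               method="hybr", tol=1e-13)
    x = sol.x if sol.success else xf
    return SystemState.from_array(np.clip(x, 0.0, None))


def _peak_amplitudes(t: np.ndarray, x: np.ndarray):
    """Per-cycle amplitudes: peak height minus the mean of flanking troughs."""
    span = float(np.ptp(x))
    if span == 0.0:
        return np.array([]), np.array([])
    prom = 0.01 * span
    peaks, _ = find_peaks(x, prominence=prom)
    troughs, _ = find_peaks(-x, prominence=prom)
    amps = []
    times = []
    for p in peaks:
        left = troughs[troughs < p]
        right = troughs[troughs > p]
        base_candidates = []
        if left.size:
            base_candidates.append(x[left[-1]])
        if right.size:
            base_candidates.append(x[right[0]])
        if not base_candidates:
            base_candidates.append(float(np.min(x)))
        amps.append(x[p] - float(np.mean(base_candidates)))
        times.append(t[p])
    return np.asarray(times), np.asarray(amps)


def classify_attractor(timecourse: TimeCourse, transient_fraction: float = 0.5,
                       variable: str = "ulk1", flat_tol: float = 1e-4,
                       cycle_band: tuple[float, float] = (0.99, 1.01),
                       ) -> AttractorReport:
    """Label the long-run behaviour of a trajectory.

    The post-transient segment of the chosen variable (ULK1 by default) is
    inspected:

    - total variation below ``flat_tol`` of the pool -> ``steady_state``;
    - at least 5 peaks whose successive cycle amplitudes (over the final
      five) stay within ``cycle_band`` -> ``limit_cycle``;
    - at least 2 peaks with decreasing amplitude -> ``damped_oscillation``;
    - anything else with peaks present raises
      :class:`AmbiguousAttractorError` rather than silently coercing.

    ``decay_ratio`` is the last/first cycle-amplitude ratio over the window
    used for the decision; ``period`` (limit cycles only) is the mean
    inter-peak interval of the last three cycles.
    """
    if not 0.0 <= transient_fraction < 1.0:
        raise ValueError("transient_fraction must be in [0, 1)")
    i0 = int(np.floor(transient_fraction * timecourse.t.size))
    t = timecourse.t[i0:]
    x = timecourse.column(variable)[i0:]
    pool = {"ulk1": timecourse.params.ulk1_total,
            "ampk": timecourse.params.ampk_total,
            "mtor": max(timecourse.inputs.mtor_total, 1e-12),
            "reg": _reg_upper_bound(timecourse.params)}[variable]

    def amplitudes_all() -> dict[str, float]:
        return {name: float(np.ptp(timecourse.column(name)[i0:]))
                for name in STATE_NAMES}

    if np.ptp(x) < flat_tol * pool:
        return AttractorReport("steady_state", None, amplitudes_all(), None, 0)

    times, amps = _peak_amplitudes(t, x)
    n = amps.size
    lo, hi = cycle_band

    if n >= 5:
        last = amps[-5:]
        ratios = last[1:] / last[:-1]
        if np.all((ratios >= lo) & (ratios <= hi)):
            intervals = np.diff(times)[-3:]
            period = float(np.mean(intervals))
            return AttractorReport(
                "limit_cycle", period, amplitudes_all(),
                float(last[-1] / last[0]), int(n))

    if n >= 2:
        decay = float(amps[-1] / amps[0])
        ratios = amps[1:] / amps[:-1]
        if decay < lo and np.all(ratios < hi):
            return AttractorReport("damped_oscillation", None,
                                   amplitudes_all(), decay, int(n))
        raise AmbiguousAttractorError(
            f"{n} peaks found but amplitude trend matches neither a limit "
            f"cycle nor a damped oscillation (decay ratio {decay:.4f})")

    # A single peak with an otherwise settling trace: treat as damped if the
    # trajectory's variation collapses in the final stretch, else ambiguous.
    tail = x[int(0.8 * x.size):]
    if n == 1 and np.ptp(tail) < 0.1 * np.ptp(x):
        return AttractorReport("damped_oscillation", None, amplitudes_all(),
                               float(np.ptp(tail) / np.ptp(x)), 1)
    raise AmbiguousAttractorError(
        "trajectory is neither flat nor resolvably oscillatory")
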