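"""Sobol global sensitivity analysis of the oscillation.

Variance-based sensitivity ranks the 25 kinetic constants by how much of
the variance of an oscillation metric (ULK1 amplitude by default, measured
at stress 0.5 with a full mTOR pool) each one controls.  Sampling follows
the Saltelli scheme on a scrambled Sobol' sequence (matrices A, B and the
k column-swapped AB_i); first-order indices use the Saltelli-2010
estimator and total-order indices the Jansen estimator, with bootstrap
confidence half-widths.  The module carries the Ishigami function and its
closed-form indices as a self-test hook for the estimators.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.stats import qmc

from ._fastsim import fast_timecourse
from .model import (
    PARAM_NAMES,
    ConnectionMask,
    ParameterSet,
    SystemInputs,
)

__all__ = ["SobolResult", "define_metric", "sobol_analysis",
           "sobol_indices", "saltelli_sample", "ishigami",
    "ishigami_analytical_indices"]


# ---------------------------------------------------------------------------
# sampling + estimators
# ---------------------------------------------------------------------------

def saltelli_sample(bounds: np.ndarray, base_n: int, seed: int,
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """A, B and AB_i sample matrices for first/total-order estimation.

    ``bounds`` is (k, 2); returns A and B of shape (N, k) and AB of shape
    (k, N, k) where AB[i] equals A with column i taken from B.  ``base_n``
    must be a power of two (Sobol' sequence balance).
    """
    bounds = np.asarray(bounds, dtype=float)
    k = bounds.shape[0]
    if base_n < 2 or (base_n & (base_n - 1)) != 0:
        raise ValueError("base_n must be a power of 2")
    eng = qmc.Sobol(d=2 * k, scramble=True, seed=seed)
    u = eng.random(base_n)
    lo, hi = bounds[:, 0], bounds[:, 1]
    A = lo + (hi - lo) * u[:, :k]
    B = lo + (hi - lo) * u[:, k:]
    AB = np.empty((k, base_n, k))
    for i in range(k):
        AB[i] = A
        AB[i][:, i] = B[:, i]
    return A, B, AB


def sobol_indices(f_A: np.ndarray, f_B: np.ndarray, f_AB: np.ndarray,
                  n_boot: int = 100, seed: int = 0):
    """First-order (Saltelli 2010) and total-order (Jansen) estimators.

    ``f_AB`` has shape (k, N).  Returns (S1, ST, S1_conf, ST_conf).
    """
    f_A = np.asarray(f_A, float)
    f_B = np.asarray(f_B, float)
    f_AB = np.asarray(f_AB, float)
    k, N = f_AB.shape

    def estimate(idx):
        a, b, ab = f_A[idx], f_B[idx], f_AB[:, idx]
        var = np.var(np.concatenate([a, b]), ddof=0)
        if var <= 0:
            return np.zeros(k), np.zeros(k)
        s1 = np.mean(b * (ab - a), axis=1) / var
        st = 0.5 * np.mean((a - ab) ** 2, axis=1) / var
        return s1, st

    S1, ST = estimate(np.arange(N))
    rng = np.random.default_rng(seed)
    boots1, bootst = [], []
    for _ in range(n_boot):
        idx = rng.integers(0, N, N)
        s1, st = estimate(idx)
        boots1.append(s1)
        bootst.append(st)
    conf1 = 1.96 * np.std(boots1, axis=0, ddof=1)
    confT = 1.96 * np.std(bootst, axis=0, ddof=1)
    return S1, ST, conf1, confT


@dataclass
class SobolResult:
    names: list
    S1: np.ndarray
    ST: np.ndarray
    S1_conf: np.ndarray
    ST_conf: np.ndarray
    bounds: np.ndarray
    base_n: int
    seed: int
    metric: str
    n_failed: int = 0

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"parameter": self.names, "S1": self.S1,
                           "ST": self.ST, "S1_conf": self.S1_conf,
                           "ST_conf": self.ST_conf})
        df["negative_by_noise"] = (df["S1"] < 0) | (df["ST"] < 0)
        return df

    def ranking(self, order: str = "ST") -> list:
        idx = np.argsort(getattr(self, order))[::-1]
        return [self.names[i] for i in idx]


# ---------------------------------------------------------------------------
# model metric
# ---------------------------------------------------------------------------

_METRICS = ("ulk1_amplitude", "ulk1_period", "ulk1_mean")


def _simulate_fast(params: ParameterSet, inputs: SystemInputs,
                   mask: ConnectionMask, x0, t_end: float, step: float,
                   rtol: float = 1e-6, atol: float = 1e-9):
    return fast_timecourse(params, mask, inputs, x0, t_end, step,
                           rtol=rtol, atol=atol)


def define_metric(name: str, stress: float = 0.5, mtor_total: float = 1.0,
                  t_end: float = 160.0, transient_fraction: float = 0.5,
                  output_step: float | None = None,
                  rtol: float = 1e-4,
                  amp_tol: float = 1e-3) -> Callable[[ParameterSet], float]:
    """Scalar post-transient metric of a full-model stress simulation.

    Non-oscillating parameter draws give amplitude 0; the period of such a
    draw is recorded as NaN (excluded from period analyses).  All draws use
    a common low-activity initial state so the metric is a function of the
    parameters alone.
    """
    if name not in _METRICS:
        raise KeyError(f"unknown metric {name!r}; choose from {_METRICS}")
    inputs = SystemInputs(stress=stress, mtor_total=mtor_total)
    mask = ConnectionMask.full()
    x0 = np.array([0.01, 0.02, 0.8 * mtor_total, 0.05])
    if output_step is None:
        # period estimation needs many samples per cycle; range metrics
        # only need phase coverage
        output_step = 0.05 if name == "ulk1_period" else 0.25

    def metric(params: ParameterSet) -> float:
        # two-stage run: the transient leg doubles as an early exit for
        # draws that have already settled to a fixed point
        t_mid = transient_fraction * t_end
        t1, y1 = _simulate_fast(params, inputs, mask, x0, t_mid,
                                output_step, rtol=rtol, atol=rtol * 1e-3)
        tail = y1[int(0.7 * t1.size):, 0]
        settled = np.ptp(tail) < 0.25 * amp_tol
        if settled and name == "ulk1_amplitude":
            return 0.0
        if settled and name == "ulk1_period":
            return float("nan")
        t2, y2 = _simulate_fast(params, inputs, mask, y1[-1],
                                t_end - t_mid, output_step,
                                rtol=rtol, atol=rtol * 1e-3)
        t = t_mid + t2[1:]
        u = y2[1:, 0]
        i0 = 0
        if name == "ulk1_mean":
            return float(np.mean(u))
        amp = float(np.ptp(u))
        if name == "ulk1_amplitude":
            return amp if amp > amp_tol else 0.0
        peaks, _ = find_peaks(u, prominence=0.05 * amp if amp > 0 else 1.0)
        if amp <= amp_tol or peaks.size < 3:
            return float("nan")
        return float(np.mean(np.diff(t[i0:][peaks])[-3:]))

    metric.__name__ = name
    return metric


def default_bounds(params: ParameterSet, lower: float = 0.2,
                   upper: float = 5.0) -> np.ndarray:
    """Per-parameter interval [lower x, upper x] around the default value."""
    base = params.as_array()
    return np.column_stack([lower * base, upper * base])


def sobol_analysis(bounds=None, base_n: int = 512, seed: int = 0,
                   metric: str | Callable = "ulk1_amplitude",
                   params: ParameterSet | None = None,
                   names: Sequence[str] | None = None,
                   evaluator: Callable | None = None,
                   n_boot: int = 100) -> SobolResult:
    """Saltelli-scheme Sobol analysis of the model (or a test function).

    With the default evaluator each sample row is a full 25-parameter
    vector; failed simulations are discarded pairwise and counted in
    ``n_failed``.  Fully reproducible from ``seed``.
    """
    from .model import default_parameters

    params = params or default_parameters()
    names = list(names) if names is not None else list(PARAM_NAMES)
    if bounds is None:
        bounds = default_bounds(params)
    bounds = np.asarray(bounds, float)
    metric_name = metric if isinstance(metric, str) else metric.__name__
    if evaluator is None:
        mfun = define_metric(metric) if isinstance(metric, str) else metric

        def evaluator(row):
            return mfun(ParameterSet.from_array(row,
                                                ulk1_total=params.ulk1_total,
                                                ampk_total=params.ampk_total))

    A, B, AB = saltelli_sample(bounds, base_n, seed)
    k, N = AB.shape[0], A.shape[0]

    def run(rows):
        out = np.empty(rows.shape[0])
        for i, row in enumerate(rows):
            try:
                out[i] = evaluator(row)
            except Exception:
                out[i] = np.nan
        return out

    f_A = run(A)
    f_B = run(B)
    f_AB = np.vstack([run(AB[i])[None, :] for i in range(k)])

    ok = np.isfinite(f_A) & np.isfinite(f_B) & np.all(np.isfinite(f_AB), axis=0)
    n_failed = int(N - ok.sum())
    if ok.sum() < 8:
        raise RuntimeError("too many failed samples for index estimation")
    S1, ST, c1, cT = sobol_indices(f_A[ok], f_B[ok], f_AB[:, ok],
                                   n_boot=n_boot, seed=seed)
    return SobolResult(names, S1, ST, c1, cT, bounds, base_n, seed,
                       metric_name, n_failed)


# ---------------------------------------------------------------------------
# Ishigami self-test hook
# ---------------------------------------------------------------------------

def ishigami(x: np.ndarray, a: float = 7.0, b: float = 0.1) -> float:
    """The standard three-input test function on [-pi, pi]^3."""
    x1, x2, x3 = x
    return float(np.sin(x1) + a * np.sin(x2) ** 2
                 + b * x3 ** 4 * np.sin(x1))


def ishigami_analytical_indices(a: float = 7.0, b: float = 0.1):
    """Closed-form first- and total-order Sobol indices of the Ishigami
    function (uniform inputs on [-pi, pi])."""
    pi = np.pi
    V1 = 0.5 * (1 + b * pi ** 4 / 5) ** 2
    V2 = a ** 2 / 8
    V13 = b ** 2 * pi ** 8 * (1 / 18 - 1 / 50)
    V = V1 + V2 + V13
    S1 = np.array([V1 / V, V2 / V, 0.0])
    ST = np.array([(V1 + V13) / V, V2 / V, V13 / V])
    return S1, ST
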