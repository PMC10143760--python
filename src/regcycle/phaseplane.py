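"""Nullclines, planar reduction and phase portraits.

The model has four state variables but its behaviour is naturally read in a
plane (ULK1-AMPK for the oscillatory variants, ULK1-mTOR for the toggle).
``reduce_to_plane`` closes out the off-axis variables — by default at their
quasi-steady state given the axis values, alternatively frozen at supplied
values — producing a planar vector field whose nullclines and intersections
reproduce the full system's steady states.

Colour convention for plots: ULK1 green, AMPK blue, mTOR red.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, root

from .dynamics import STABILITY_MARGIN, SteadyStateRecord, _reg_upper_bound
from .model import (
    STATE_NAMES,
    ConnectionMask,
    ParameterSet,
    SystemInputs,
    SystemState,
    jacobian,
    rhs_array,
)

__all__ = ["PlanarField", "NullclineCurve", "PhasePortrait",
           "reduce_to_plane", "nullcline", "intersect_nullclines",
           "phase_portrait", "plot_portrait", "VARIABLE_COLORS"]

VARIABLE_COLORS = {"ulk1": "tab:green", "ampk": "tab:blue",
                   "mtor": "tab:red", "reg": "tab:purple"}


class ClosureError(RuntimeError):
    """Quasi-steady-state closure failed to converge at a plane point."""


@dataclass
class PlanarField:
    """A 2-D vector field obtained by closing out two of the four variables."""

    axis_pair: tuple[str, str]
    params: ParameterSet
    mask: ConnectionMask
    inputs: SystemInputs
    off_axis_rule: str = "qss"            # "qss" | "frozen"
    frozen_values: dict = field(default_factory=dict)

    def __post_init__(self):
        a, b = self.axis_pair
        if a == b or a not in STATE_NAMES or b not in STATE_NAMES:
            raise ValueError(f"invalid axis pair {self.axis_pair}")
        self._ia = STATE_NAMES.index(a)
        self._ib = STATE_NAMES.index(b)
        self._off = [i for i in range(4) if i not in (self._ia, self._ib)]
        if self.off_axis_rule not in ("qss", "frozen"):
            raise ValueError("off_axis_rule must be 'qss' or 'frozen'")
        if self.off_axis_rule == "frozen":
            missing = [STATE_NAMES[i] for i in self._off
                       if STATE_NAMES[i] not in self.frozen_values]
            if missing:
                raise ValueError(f"frozen_values missing {missing}")

    # -- bounds -----------------------------------------------------------
    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        hi_all = np.array([self.params.ulk1_total, self.params.ampk_total,
                           max(self.inputs.mtor_total, 1e-12),
                           _reg_upper_bound(self.params)])
        idx = [self._ia, self._ib]
        return np.zeros(2), hi_all[idx]

    # -- closure ----------------------------------------------------------
    def closure(self, x_axis: float, y_axis: float) -> np.ndarray:
        """Full 4-state consistent with the plane point."""
        x = np.empty(4)
        x[self._ia], x[self._ib] = x_axis, y_axis
        if self.off_axis_rule == "frozen":
            for i in self._off:
                x[i] = self.frozen_values[STATE_NAMES[i]]
            return x
        return self._qss_close(x)

    def _qss_close(self, x: np.ndarray) -> np.ndarray:
        p, mk, inp = self.params, self.mask, self.inputs
        x = x.copy()
        # REG has a closed form once AMPK is known
        i_reg, i_ampk, i_mtor, i_ulk = 3, 1, 2, 0

        def reg_qss():
            drive = p.k_s_reg_basal
            if mk.ampk_to_reg:
                drive += p.k_s_reg_ampk * x[i_ampk]
            return drive / p.k_d_reg if p.k_d_reg > 0 else 0.0

        def solve_1d(i, hi):
            def g(v):
                x[i] = v
                return rhs_array(x, inp, p, mk)[i]
            g0, g1 = g(0.0), g(hi)
            if g0 == 0.0:
                return 0.0
            if g1 == 0.0:
                return hi
            if g0 * g1 > 0:     # derivative one-signed on [0, hi]
                return 0.0 if g0 < 0 else hi
            return brentq(g, 0.0, hi, xtol=1e-14)

        hi_map = {i_ampk: p.ampk_total, i_mtor: max(inp.mtor_total, 1e-12),
                  i_ulk: p.ulk1_total}
        # dependency-ordered sequential closure; iterate to fixed point when
        # the off-axis pair is mutually coupled
        for _ in range(60):
            before = x[self._off].copy()
            for i in self._off:
                if i == i_reg:
                    x[i_reg] = reg_qss()
                else:
                    x[i] = solve_1d(i, hi_map[i])
            if np.max(np.abs(x[self._off] - before)) < 1e-12:
                break
        else:
            res = np.abs([rhs_array(x, inp, p, mk)[i] for i in self._off])
            if np.max(res) > 1e-8:
                raise ClosureError(
                    f"QSS closure did not converge at plane point "
                    f"({x[self._ia]:.4g}, {x[self._ib]:.4g})")
        return x

    # -- field ------------------------------------------------------------
    def __call__(self, x_axis: float, y_axis: float) -> np.ndarray:
        x = self.closure(x_axis, y_axis)
        d = rhs_array(x, self.inputs, self.params, self.mask)
        return np.array([d[self._ia], d[self._ib]])

    def derivative_of(self, variable: str, x_axis: float, y_axis: float) -> float:
        x = self.closure(x_axis, y_axis)
        return float(rhs_array(x, self.inputs, self.params,
                               self.mask)[STATE_NAMES.index(variable)])


def reduce_to_plane(params: ParameterSet, mask: ConnectionMask,
                    inputs: SystemInputs, axis_pair: tuple[str, str],
                    off_axis_rule: str = "qss",
                    frozen_values: dict | None = None) -> PlanarField:
    """Planar reduction of the 4-variable system (see :class:`PlanarField`)."""
    return PlanarField(tuple(axis_pair), params, mask, inputs,
                       off_axis_rule, frozen_values or {})


@dataclass
class NullclineCurve:
    """Zero set of one variable's time derivative in a plane."""

    axis_pair: tuple[str, str]
    variable: str
    segments: list  # list of (n, 2) arrays, ordered along the curve

    @property
    def points(self) -> np.ndarray:
        if not self.segments:
            return np.empty((0, 2))
        return np.vstack(self.segments)

    def __len__(self):
        return sum(len(s) for s in self.segments)


def _chain_points(pts: np.ndarray, link: float) -> list:
    """Greedy nearest-neighbour chaining into ordered polyline segments."""
    if pts.shape[0] == 0:
        return []
    remaining = list(range(pts.shape[0]))
    segments = []
    while remaining:
        chain = [remaining.pop(0)]
        # extend forward then backward
        for direction in (1, 0):
            while remaining:
                tip = pts[chain[-1 if direction else 0]]
                d = np.linalg.norm(pts[remaining] - tip, axis=1)
                j = int(np.argmin(d))
                if d[j] > link:
                    break
                idx = remaining.pop(j)
                chain.append(idx) if direction else chain.insert(0, idx)
        segments.append(pts[chain])
    return segments


def nullcline(planar_field: PlanarField, which_variable: str,
              grid_resolution: int = 100) -> NullclineCurve:
    """Zero-contour of ``d(which_variable)/dt`` under the planar field.

    Sign changes are bracketed on a uniform grid along both axes and then
    bisected to near machine precision; multi-branch (S-shaped) curves come back as separate
    ordered segments.
    """
    if grid_resolution < 50:
        raise ValueError("grid_resolution must be >= 50")
    lo, hi = planar_field.bounds()
    xs = np.linspace(lo[0], hi[0], grid_resolution)
    ys = np.linspace(lo[1], hi[1], grid_resolution)

    def f(x, y):
        return planar_field.derivative_of(which_variable, x, y)

    F = np.array([[f(x, y) for y in ys] for x in xs])

    pts = []
    # scan along y for each x
    for i, x in enumerate(xs):
        col = F[i]
        for j in range(len(ys) - 1):
            a, b = col[j], col[j + 1]
            if a == 0.0:
                pts.append((x, ys[j]))
            elif a * b < 0:
                y0 = brentq(lambda y: f(x, y), ys[j], ys[j + 1], xtol=1e-14)
                pts.append((x, y0))
    # scan along x for each y
    for j, y in enumerate(ys):
        row = F[:, j]
        for i in range(len(xs) - 1):
            a, b = row[i], row[i + 1]
            if a * b < 0:
                x0 = brentq(lambda x: f(x, y), xs[i], xs[i + 1], xtol=1e-14)
                pts.append((x0, y))
    if not pts:
        return NullclineCurve(planar_field.axis_pair, which_variable, [])
    pts = np.array(pts)
    # normalise per-axis before chaining so anisotropic boxes chain cleanly
    scale = np.where(hi - lo > 0, hi - lo, 1.0)
    link = 2.5 / grid_resolution
    segments_n = _chain_points(pts / scale, link)
    segments = [s * scale for s in segments_n]
    segments = [s for s in segments if len(s) >= 2]
    return NullclineCurve(planar_field.axis_pair, which_variable, segments)


def _segment_intersections(sa: np.ndarray, sb: np.ndarray) -> list:
    """Crossing points between two polylines (parametric segment test)."""
    out = []
    p = sa[:-1]
    r = sa[1:] - sa[:-1]
    for k in range(len(sb) - 1):
        q = sb[k]
        s = sb[k + 1] - q
        rxs = r[:, 0] * s[1] - r[:, 1] * s[0]
        qp = q - p
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (qp[:, 0] * s[1] - qp[:, 1] * s[0]) / rxs
            u = (qp[:, 0] * r[:, 1] - qp[:, 1] * r[:, 0]) / rxs
        hit = (np.abs(rxs) > 1e-15) & (t >= -1e-9) & (t <= 1 + 1e-9) \
            & (u >= -1e-9) & (u <= 1 + 1e-9)
        for i in np.where(hit)[0]:
            out.append(p[i] + t[i] * r[i])
    return out


def intersect_nullclines(curve_a: NullclineCurve, curve_b: NullclineCurve,
                         planar_field: PlanarField) -> list[SteadyStateRecord]:
    """Steady states at nullcline crossings, refined by planar Newton and
    lifted back to full :class:`SteadyStateRecord` via the closure."""
    if curve_a.axis_pair != curve_b.axis_pair:
        raise ValueError("curves must share an axis pair")
    cands = []
    for sa in curve_a.segments:
        for sb in curve_b.segments:
            cands.extend(_segment_intersections(sa, sb))
    lo, hi = planar_field.bounds()

    refined = []
    for c in cands:
        sol = root(lambda z: planar_field(z[0], z[1]), np.asarray(c),
                   method="hybr", tol=1e-13)
        z = sol.x
        if not sol.success and np.linalg.norm(planar_field(*z)) > 1e-9:
            continue
        if np.any(z < lo - 1e-7) or np.any(z > hi + 1e-7):
            continue
        if any(np.linalg.norm(z - y) < 1e-6 for y in refined):
            continue
        refined.append(z)

    records = []
    for z in refined:
        x = planar_field.closure(z[0], z[1])
        resid = rhs_array(x, planar_field.inputs, planar_field.params,
                          planar_field.mask)
        eigs = np.linalg.eigvals(jacobian(x, planar_field.inputs,
                                          planar_field.params,
                                          planar_field.mask))
        label = ("stable" if np.all(eigs.real < -STABILITY_MARGIN)
                 else "unstable")
        records.append(SteadyStateRecord(SystemState.from_array(x),
                                         float(np.linalg.norm(resid)),
                                         eigs, label))
    records.sort(key=lambda r: r.state.ulk1)
    return records


@dataclass
class PhasePortrait:
    field: PlanarField
    curve_x: NullclineCurve        # nullcline of the x-axis variable
    curve_y: NullclineCurve        # nullcline of the y-axis variable
    steady_states: list
    trajectories: list = None      # optional list of (n, 2) arrays


def phase_portrait(params: ParameterSet, mask: ConnectionMask,
                   inputs: SystemInputs, axis_pair: tuple[str, str],
                   grid_resolution: int = 100, off_axis_rule: str = "qss",
                   frozen_values: dict | None = None,
                   trajectories: list | None = None) -> PhasePortrait:
    """Assemble nullclines + steady states (+ projected trajectories)."""
    fld = reduce_to_plane(params, mask, inputs, axis_pair, off_axis_rule,
                          frozen_values)
    cx = nullcline(fld, axis_pair[0], grid_resolution)
    cy = nullcline(fld, axis_pair[1], grid_resolution)
    ss = intersect_nullclines(cx, cy, fld)
    proj = None
    if trajectories is not None:
        ix = STATE_NAMES.index(axis_pair[0])
        iy = STATE_NAMES.index(axis_pair[1])
        proj = [tc.states[:, [ix, iy]] for tc in trajectories]
    return PhasePortrait(fld, cx, cy, ss, proj)


def plot_portrait(portrait: PhasePortrait, ax=None):
    """Render a portrait with the package colour convention."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    xvar, yvar = portrait.field.axis_pair
    for seg in portrait.curve_x.segments:
        ax.plot(seg[:, 0], seg[:, 1], color=VARIABLE_COLORS[xvar], lw=1.5)
    for seg in portrait.curve_y.segments:
        ax.plot(seg[:, 0], seg[:, 1], color=VARIABLE_COLORS[yvar], lw=1.5)
    if portrait.trajectories:
        for tr in portrait.trajectories:
            ax.plot(tr[:, 0], tr[:, 1], color="grey", ls=":", lw=0.8)
    for rec in portrait.steady_states:
        x = getattr(rec.state, xvar)
        y = getattr(rec.state, yvar)
        filled = rec.is_stable
        ax.plot(x, y, marker="o", ms=7, mec="black",
                mfc="black" if filled else "white")
    ax.set_xlabel(xvar)
    ax.set_ylabel(yvar)
    return ax
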