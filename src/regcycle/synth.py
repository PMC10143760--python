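"""Seeded generators for every input the pipeline needs without downloads.

Three families of fixtures:

- signed interaction tables with planted REG candidates (satisfying exactly
  3, 2 or 1 of the screening criteria), decoy edges that can never create a
  criterion, and an upstream layer with known sign-consistency labels —
  mirroring the composition of a curated autophagy-interaction database so
  the screen's selection logic can be validated against exact ground truth;
- labelled synthetic trajectories (constant, damped, sustained) with known
  period and decay for validating the attractor classifier;
- Latin-hypercube parameter samples for sensitivity self-tests.

All generators are pure functions of their spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .dynamics import TimeCourse
from .model import (
    PARAM_NAMES,
    ConnectionMask,
    SystemInputs,
    default_parameters,
)

__all__ = ["FixtureSpec", "NetworkGroundTruth", "generate_network_fixture",
           "SignalFixture", "generate_signal_fixtures",
           "generate_parameter_samples", "HUB_IDS"]

HUB_IDS = {"ampk": "AMPK", "ulk1": "ULK1", "mtor": "MTOR"}

CRITERION_EDGES = {
    # criterion -> (source, target, sign) with X as the candidate
    "induced_by_ampk": ("AMPK", None, "activation"),
    "activates_ulk1": (None, "ULK1", "activation"),
    "inhibits_mtor": (None, "MTOR", "inhibition"),
}

#: hub-adjacent edge patterns that can never satisfy a criterion
_SAFE_HUB_PATTERNS = (
    ("AMPK", None, "inhibition"),
    (None, "ULK1", "inhibition"),
    (None, "MTOR", "activation"),
    (None, "AMPK", "activation"),
    (None, "AMPK", "inhibition"),
    ("ULK1", None, "activation"),
    ("MTOR", None, "inhibition"),
)


@dataclass(frozen=True)
class FixtureSpec:
    n_proteins: int = 300
    n_triple: int = 1
    n_double: int = 15
    n_single: int = 20
    decoy_edges: int = 250
    predicted_fraction: float = 0.3
    upstream_per_candidate: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.n_triple + self.n_double + self.n_single > self.n_proteins:
            raise ValueError("more planted candidates than proteins")
        if not 0 <= self.predicted_fraction <= 1:
            raise ValueError("predicted_fraction must be in [0, 1]")
        for f in ("n_proteins", "n_triple", "n_double", "n_single",
                  "decoy_edges", "upstream_per_candidate"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be non-negative")


@dataclass
class NetworkGroundTruth:
    triple: list
    double: list
    single: list
    upstream_kept: list      # (source, target) tuples that must survive
    upstream_dropped: list   # (source, target) tuples that must be removed

    def candidates(self, min_count: int) -> list:
        out = list(self.triple)
        if min_count <= 2:
            out += self.double
        if min_count <= 1:
            out += self.single
        return sorted(out)


def generate_network_fixture(spec: FixtureSpec
                             ) -> tuple[pd.DataFrame, NetworkGroundTruth]:
    """Edge table + exact ground truth for the screening pipeline.

    Planted candidates satisfy exactly their assigned number of criteria
    (criterion edges are always experimentally signed so decoys cannot
    overrule them); decoy edges use only hub-free pairs or hub-adjacent
    patterns with the wrong sign/direction, so no decoy can reach even one
    criterion by accident.  Deterministic: same spec -> identical table.
    """
    rng = np.random.default_rng(spec.seed)
    proteins = [f"P{i:04d}" for i in range(spec.n_proteins)]
    order = rng.permutation(spec.n_proteins)
    n_cand = spec.n_triple + spec.n_double + spec.n_single
    planted = [proteins[i] for i in order[:n_cand]]
    triple = planted[:spec.n_triple]
    double = planted[spec.n_triple:spec.n_triple + spec.n_double]
    single = planted[spec.n_triple + spec.n_double:]
    others = [proteins[i] for i in order[n_cand:]]

    rows = []
    used_pairs = set()

    def evidence():
        return ("predicted" if rng.random() < spec.predicted_fraction
                else "experimental")

    def add(src, dst, sign, layer="direct", ev=None):
        rows.append({"source": src, "target": dst, "sign": sign,
                     "layer": layer, "evidence": ev or evidence()})
        used_pairs.add((src, dst))

    crits = list(CRITERION_EDGES)
    for prot, k in [(p, 3) for p in triple] + [(p, 2) for p in double] \
            + [(p, 1) for p in single]:
        chosen = crits if k == 3 else list(rng.choice(crits, size=k,
                                                      replace=False))
        for c in chosen:
            src, dst, sign = CRITERION_EDGES[c]
            # criterion edges carry experimental sign so decoys cannot
            # overrule them under the evidence-priority rule
            add(src or prot, dst or prot, sign, ev="experimental")

    # decoys: hub-free pairs or wrong-sign hub-adjacent patterns
    n_added = 0
    max_tries = 50 * (spec.decoy_edges + 1)
    tries = 0
    while n_added < spec.decoy_edges and tries < max_tries:
        tries += 1
        if rng.random() < 0.7 and len(proteins) >= 2:
            a, b = rng.choice(spec.n_proteins, size=2, replace=False)
            src, dst = proteins[a], proteins[b]
            sign = "activation" if rng.random() < 0.5 else "inhibition"
        else:
            src, dst, sign = _SAFE_HUB_PATTERNS[
                rng.integers(len(_SAFE_HUB_PATTERNS))]
            prot = proteins[rng.integers(spec.n_proteins)]
            src, dst = src or prot, dst or prot
        if (src, dst) in used_pairs or src == dst:
            continue
        add(src, dst, sign)
        n_added += 1

    # upstream layer onto planted candidates with known keep/drop labels
    kept, dropped = [], []
    upstream_pool = others if others else proteins
    for prot in planted:
        for _ in range(spec.upstream_per_candidate):
            u = upstream_pool[rng.integers(len(upstream_pool))]
            if (u, prot) in used_pairs or u == prot:
                continue
            sign = "activation" if rng.random() < 0.5 else "inhibition"
            add(u, prot, sign, layer="additional")
            (kept if sign == "activation" else dropped).append((u, prot))

    df = pd.DataFrame(rows, columns=["source", "target", "sign", "layer",
                                     "evidence"])
    truth = NetworkGroundTruth(sorted(triple), sorted(double), sorted(single),
                               kept, dropped)
    return df, truth


# ---------------------------------------------------------------------------
# signal fixtures for the attractor classifier
# ---------------------------------------------------------------------------

@dataclass
class SignalFixture:
    label: str                  # steady_state | damped_oscillation | limit_cycle
    timecourse: TimeCourse
    period: float | None = None
    decay_per_cycle: float | None = None


_KIND_TO_LABEL = {"constant": "steady_state",
                  "damped": "damped_oscillation",
                  "sustained": "limit_cycle"}


def generate_signal_fixtures(kinds=("constant", "damped", "sustained"),
                             n_per_kind: int = 10, noise_sd: float = 0.0,
                             seed: int = 0, t_end: float = 400.0,
                             dt: float = 0.2) -> list[SignalFixture]:
    """Labelled synthetic ULK1 traces with known period/decay.

    Constant levels, exponentially damped sinusoids, and fixed-amplitude
    oscillations; optional additive Gaussian noise.  The trace is carried
    in the ULK1 column of a TimeCourse so it can be fed straight to the
    attractor classifier.
    """
    unknown = set(kinds) - set(_KIND_TO_LABEL)
    if unknown:
        raise KeyError(f"unknown signal kinds {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, t_end + 0.5 * dt, dt)
    params = default_parameters()
    mask = ConnectionMask.full()
    inputs = SystemInputs()
    out = []
    for kind in kinds:
        for _ in range(n_per_kind):
            level = rng.uniform(0.3, 0.6)
            period = float(rng.uniform(10.0, 40.0))
            amp = rng.uniform(0.1, 0.3)
            phase = rng.uniform(0, 2 * np.pi)
            if kind == "constant":
                u = np.full_like(t, level)
                per, decay = None, None
            elif kind == "damped":
                # amplitude shrinks by a fixed factor per cycle
                decay = float(rng.uniform(0.55, 0.85))
                tau = period / -np.log(decay)
                u = level + amp * np.exp(-t / tau) * np.sin(
                    2 * np.pi * t / period + phase)
                per = period
            else:
                u = level + amp * np.sin(2 * np.pi * t / period + phase)
                per, decay = period, 1.0
            if noise_sd > 0:
                u = u + rng.normal(0, noise_sd, t.size)
            states = np.column_stack([
                np.clip(u, 0, 1),
                np.full_like(t, 0.2),
                np.full_like(t, 0.5),
                np.full_like(t, 0.1),
            ])
            tc = TimeCourse(t, states, inputs, params, mask)
            out.append(SignalFixture(_KIND_TO_LABEL[kind], tc, per, decay))
    return out


def generate_parameter_samples(bounds, n: int, seed: int = 0,
                               names=None) -> pd.DataFrame:
    """Reproducible Latin-hypercube parameter samples within bounds."""
    names = list(names) if names is not None else list(PARAM_NAMES)
    bounds = np.asarray(bounds, dtype=float)
    if bounds.shape != (len(names), 2):
        raise ValueError("bounds must have shape (n_params, 2)")
    if np.any(bounds[:, 1] < bounds[:, 0]):
        raise ValueError("upper bounds below lower bounds")
    if n == 0:
        return pd.DataFrame(columns=names)
    sampler = qmc.LatinHypercube(d=len(names), seed=seed)
    u = sampler.random(n)
    vals = bounds[:, 0] + (bounds[:, 1] - bounds[:, 0]) * u
    return pd.DataFrame(vals, columns=names)
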