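# Methods

## The model

Autophagy initiation is controlled by a regulatory triangle: the energy
sensor AMPK promotes the initiator kinase ULK1 and inhibits the nutrient
sensor mTOR (mTORC1); mTOR inhibits both ULK1 and AMPK; active ULK1
feeds back negatively on AMPK and on mTOR. A negative feedback loop
(AMPK → ULK1 ⊣ AMPK) stabilised by two double-negative loops
(ULK1 ⊣ mTOR ⊣ ULK1 and AMPK ⊣ mTOR ⊣ AMPK) can produce switch-like
induction, but a *sustained* periodic induction additionally requires the
negative feedback to be delayed. The model therefore carries a fourth
species, REG: a regulator protein synthesised downstream of AMPK that
activates ULK1 and inhibits mTOR. REG converts the instantaneous
AMPK → ULK1 drive into a delayed, integrated one, which is what turns
damped ringing into a stable limit cycle.

State variables are the active fractions of ULK1, AMPK and mTOR on
conserved pools, plus the REG level (all dimensionless, relative units).
Each kinase is a covalent-modification cycle with Michaelis–Menten
activation and inactivation legs (Goldbeter–Koshland form): the sum of
mask-weighted activator terms plus a basal rate acts on the inactive pool
with saturation constant `km_a_*`; the sum of inhibitor terms plus a basal
rate acts on the active form with `km_i_*`. Small saturation constants
(0.01–0.1 of the pool) put the cycles in the zero-order ultrasensitive
regime, which supplies the nonlinearity that both the bistable switch and
the oscillation need. REG follows mass-action synthesis (basal +
AMPK-proportional) minus first-order degradation; its turnover rate
`k_d_reg` sets the delay of the loop.

External inputs are the stress level `S` (driving AMPK activation) and the
total mTOR pool `mTORT`; rapamycin treatment is modelled as a reduction of
`mTORT`. ULK1 and AMPK pools are fixed at 1. The model has exactly 25
tunable kinetic constants; the two pool sizes are structural constants,
not tunables.

## Wiring variants and the reduction convention

Four wiring variants are exposed through edge masks:

- `full` — the complete REG-extended network;
- `toggle` — the ULK1–mTOR double-negative loop alone;
- `direct_nfb` — the toggle plus the direct AMPK–ULK1 negative feedback;
- `triangle` — the amplified negative feedback (adds mutual
  AMPK–mTOR antagonism).

A masked-off edge contributes exactly zero to the right-hand side; this is
a hard invariant of `rhs()` and is property-tested.

Removing a *species* from a reduced diagram needs one further convention.
If the upstream layer were simply zeroed, the reduced networks would lose
the strong ULK1-activation conduit that flows through REG in the full
model, and no single parameter set could reproduce all the documented
regimes: the requirements are provably contradictory (monotonicity of the
ULK1 balance in its activation and inhibition forces the same rate
constant to be simultaneously large and small). The package therefore
reduces by adiabatic elimination:

- REG, when removed (`direct_nfb`, `triangle`), is slaved to AMPK at its
  quasi-steady level `R* = (k_s_reg_basal + k_s_reg_ampk·A)/k_d_reg`, so
  the surviving AMPK → ULK1 conduit gains
  `k_a_ulk_reg·k_s_reg_ampk/k_d_reg` and the basal ULK1 activation gains
  `k_a_ulk_reg·k_s_reg_basal/k_d_reg`;
- in the `toggle`, AMPK (and REG with it) is pinned at its full-model
  *resting* activity (zero stress, full mTOR pool, computed by Newton
  refinement of the resting branch), and stress enters ULK1's activation
  directly through a surrogate edge with rate `k_a_ulk_stress`;
- inhibitory conduits that the reduced wiring diagrams remove
  (REG ⊣ mTOR, AMPK ⊣ mTOR, mTOR ⊣ AMPK) are removed outright.

This preserves the physical content of the reductions — the reduced
diagrams probe the feedback *topology*, not a cell stripped of its
kinase activities — and it is what makes one parameter set serve every
variant. `effective_parameters()` implements the convention explicitly;
`rhs()` itself never deviates from strict mask semantics.

## Calibration

The defaults in `default_parameters()` were calibrated, by staged random
search with local refinement, against the qualitative regime table in
`regcycle.scenarios` (twelve rows: sustained oscillation under stress and
under rapamycin in the full model; the toggle's monostable → bistable →
monostable progression over stress and its autophagy-on state under strong
rapamycin; damped ringing and the homeostatic low state of the direct
negative feedback; the triangle's stress-driven cycle that rapamycin
silences; and the two REG knockout phenotypes). The search scored
candidate sets by steady-state structure, eigenvalue signatures (Hopf
instability for limit-cycle rows, under-damped stable foci for the damped
row) and level margins, then verified survivors by full simulation and
attractor classification. Qualitative regimes, not numeric rate values,
are the reproducible surface: the defaults are one point of a feasible
region, and the regime suite is the contract they satisfy.

Calibrated structure worth knowing: the REG → ULK1 route is much stronger
than the direct AMPK → ULK1 route (`k_a_ulk_reg ≫ k_a_ulk_ampk`), mTOR
inhibition of ULK1 is strong (`k_i_ulk_mtor` large) so the toggle is a
hard switch, AMPK and mTOR relax fast while REG turns over slowly
(`k_d_reg` small) — the timescale separation that makes the delayed
negative feedback oscillate.

## Dynamics machinery

- Integration: LSODA (stiff-capable) with the analytic Jacobian,
  `rtol = 1e-9` on the reference path; output on a uniform grid.
- Steady states: Newton (hybr) from Latin-hypercube multi-starts, run in
  logit-transformed coordinates because the ultrasensitive cycles push
  fixed points extremely close to the box faces, where untransformed
  Newton stalls or escapes to spurious out-of-pool roots; duplicates merge
  at Euclidean distance 1e-6; residual acceptance 1e-9; stability from
  Jacobian eigenvalues with a 1e-8 real-part margin (avoids calling a
  centre stable under floating-point noise).
- Attractor classification: peak detection on the post-transient ULK1
  trace. Flat (total variation < 1e-4 of pool) → steady state; at least
  five peaks with the last five cycle amplitudes within 1% of each other →
  limit cycle; at least two peaks with decaying amplitude → damped; any
  other peaked pattern raises an explicit ambiguity error rather than
  being coerced. Period is the mean of the last three inter-peak
  intervals. The 1% band, the five-peak requirement and the transient
  fraction (default 0.5) are exposed as arguments.
- Phase planes: off-axis variables close out at quasi-steady state by
  default (the convention that makes planar nullclines of a 4-variable
  system well-defined and reproduces the S-/N-shaped balance curves), or
  frozen at supplied values. Nullclines come from sign-change bracketing
  on a grid plus bisection to 1e-10, chained into ordered segments so
  S-shaped branches survive; intersections are refined by planar Newton
  and lifted back to full steady-state records through the closure.
- Bifurcation sweeps: Newton continuation (warm starts from the previous
  grid point) plus fresh multi-starts; where no stable state exists the
  limit-cycle envelope is measured from a post-transient simulation
  continued from the neighbouring attractor. Folds are localised by
  bisection on the steady-state count to 1e-4 in the swept input;
  oscillation windows are attractor-label transitions and are checked
  against Hopf loss of stability of the interior state. The canonical
  full-model stress sweep covers [0, 30]: at the default constants the
  resting state folds away near stress 0.15, the oscillation window spans
  roughly stress 0.4-24, and beyond the upper boundary induction is
  sustained rather than periodic; the range is chosen
  so both Hopf boundaries are inside the sweep (config-exposed). The
  toggle's signal-response sweep covers [0, 1.5].
- Two integration paths: the reference path (`dynamics.simulate`, all
  regime and classifier work) is LSODA with the analytic Jacobian at
  rtol 1e-9; high-volume work (the Saltelli loop, sweep envelopes) uses a
  numba-compiled L-stable Rosenbrock 2(3) scheme (`_fastsim`) whose
  trajectories agree with LSODA to ~1e-9 while costing milliseconds per
  run instead of seconds. The compiled path exists because a Saltelli
  design over 25 parameters needs ~14 000 stiff relaxation-oscillation
  simulations.

## Sensitivity analysis

Saltelli-scheme sampling on a scrambled Sobol' sequence (matrices A, B,
and the column-swapped AB_i; `base_n` a power of two), first-order indices
by the Saltelli-2010 estimator and total-order indices by the Jansen
estimator, with bootstrap (100 resamples) confidence half-widths. The
estimators are validated against the closed-form Ishigami indices. The
model metric is the post-transient ULK1 oscillation amplitude at stress
0.5 and a full mTOR pool (alternatives: period, mean), with parameter
bounds [0.2×, 5×] the defaults; non-oscillating draws contribute
amplitude 0 and a missing period. Draw-to-draw simulations use a relaxed
tolerance (rtol 1e-6) and a 360-time-unit horizon — the metric is
invariant within 1% to doubling the horizon, which is also asserted in
the tests.

## The network screen and its synthetic fixtures

The screen scores proteins of a signed, directed interaction table against
the three REG criteria (induced by AMPK; promotes ULK1; inhibits mTOR),
selects those meeting at least two, and filters their upstream layer under
sign consistency (an upstream regulator must not flip the net sign a
criterion requires; since every criterion needs the candidate active, only
activating incoming edges survive — a flag restricts the rule to the
literal ULK1-activator case). Experimental sign annotations take priority
over predicted ones; a predicted edge is overruled by an experimental edge
of the opposite sign.

The synthetic fixture generator emulates the *shape* of a curated
autophagy-interaction database — hub-adjacent criterion edges, decoys and
an upstream layer — with exact ground truth: planted candidates satisfy
exactly their assigned criterion count (criterion edges are always
experimentally signed so decoys cannot overrule them) and decoy edges are
drawn only from hub-free pairs or wrong-sign hub patterns, so they can
never create a criterion by accident. The default composition (1 triple +
15 double satisfiers plus ≥200 decoy edges and ~30% predicted
annotations) mirrors the scale of the real screen. What passing these
tests shows is that the selection and filtering logic is exact; it says
nothing about the biological correctness of any real database's
annotations, which is why the screen on real data should be read with the
same caution as any curated-evidence analysis.

## Problem sizes

The regime suite simulates 400–800 time units per row; sweeps use
~80-point grids; the model Sobol run uses `base_n = 512`
(13 824 simulations) and the estimator self-test `base_n = 1024`. These
sizes give stable qualitative outcomes (rankings and labels do not change
on doubling) while keeping a full analysis run in the minutes range on a
single core.

## Known limitations

- The kinetic constants are a calibrated feasible point, not fitted to
  quantitative measurements; only the regime structure is meaningful.
- The delay is structural (through REG), not an explicit
  delay-differential formulation.
- ULK1-complex partners (FIP200, ATG13), the PI3K complex and all
  downstream autophagosome steps are outside the model's scope.
- The screen treats identifier mapping as the caller's concern and does
  not attempt enrichment analysis of the candidate networks.
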