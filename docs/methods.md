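# Methods

## The social-learning model

The model tracks the proportion *p(t)* of a bird population that are
lanternfly eaters; the complement 1−*p* lumps undecided birds and
committed non-eaters together.  Birds and lanternfly interact at rate
*r_i* (interactions per bird per time step); each interaction is observed
by another bird with probability *r_o*; a proportion *q* of lanternfly is
toxic.  Four flows follow: observed good experiences recruit non-eaters at
rate r_i r_o p (1−q)(1−p); observed bad experiences and a bird's own toxic
meals remove eaters at rate (r_i r_o p q + r_i q) p.  Together,

    dp/dt = r_i p (r_o (1 − q − p) − q).

Assumptions worth making explicit:

- the population is well mixed (no spatial structure at this level);
- *q* and the prey pool are fixed — there is no prey-depletion term.  The
  agent-based simulator *does* deplete a finite pool, and the comparison
  between the two levels is made regardless; the residual mismatch this
  causes is discussed under limitations;
- *r_o* is treated as a probability in (0, 1] by default (an override flag
  admits larger rates; the analysis itself only requires r_o > 0);
- one ODE time unit is one simulation time step, so rates estimated from
  the simulator plug in without rescaling.

### Explicit solution, equilibria, thresholds

The equation is separable.  With α = r_o(1−q) − q the solution through
p(0) = p0 > 0 is

    p(t) = α / (r_o + (α/p0 − r_o) e^(−r_i α t)).

We write the denominator constant as K = α/p0 − r_o; sign conventions for
the integration constant differ between derivations, and this is the one
for which p(0) = p0 and the long-time limits (α/r_o for α > 0, 0 for
α < 0) hold.  At p0 = 0 the solution is identically the trivial
equilibrium and K is flagged undefined rather than dividing by zero.

Equilibria are p = 0 and p = 1 − (r_o+1)q/r_o, classified by the
first-derivative test: p = 0 is stable iff r_o < q/(1−q), the collective
control equilibrium iff r_o > q/(1−q); it lies inside [0, 1] exactly in
the latter case.  On the boundary r_o = q/(1−q) the test is indeterminate
and both equilibria are reported non-hyperbolic instead of being forced a
label.  At q = 1 the threshold observation rate q/(1−q) is reported as
+∞ (p = 0 is globally stable), not as an error.  The threshold in the
other direction, q\* = r_o/(r_o+1), is the toxic proportion above which no
collective control emerges.

### Numerical choices

- **Degenerate case α = 0** (q exactly at threshold): the closed form is
  0/0; the equation reduces to dp/dt = −r_i r_o p², solved by
  p(t) = p0/(1 + r_i r_o p0 t).  The branch is taken when
  |α| < 10⁻¹² · r_o (relative switch).
- **Overflow**: for α < 0 the exponential in the denominator diverges;
  exponents are capped at 700 and the overflowed entries set to the exact
  limit 0.
- **Numerical oracle**: `integrate_numeric` solves the ODE with LSODA at
  rtol 1e−10 / atol 1e−13.  It exists purely as an independent
  cross-check of the closed form (the tests require sup-norm agreement
  below 1e−6 over t ∈ [0, 10⁵]); integration failure raises, never
  returns silent NaN.
- Solutions are clipped to [0, 1] against last-ulp excursions.

## The agent-based simulator

*N* = 50 bird agents move in continuous 2-D space around a roost at the
origin; *N_l* lanternfly agents sit at fixed uniform-random positions in a
150 × 150 square centred on the roost, each toxic independently with
probability *q*.  Every step runs movement → foraging → observation:

- **Foraging.**  A bird with a living lanternfly within the encounter
  radius R_c = 1 (pecking range, deliberately small against the visual
  radius R_o = 6) tries it with probability π = 0.01 per step while
  undecided, always if a committed eater, never if a non-eater.  The
  trial is a fresh Bernoulli draw each step.  Eaten lanternfly die and
  never revive.  Birds are visited in a freshly randomized order each
  step and the first claimant consumes the fly, so simultaneous claims
  carry no index bias.
- **Observation.**  Every *other* bird within R_o of an eater — whatever
  its current state, so non-eaters can be re-converted — adopts the
  observed outcome: good → eater, bad → non-eater.  All state updates of
  one step (own outcomes included) are staged on pending flags and
  committed together, with a negative outcome dominating any positive one
  seen in the same step.  The commit is therefore invariant under
  permutation of same-step events; aversive dominance is the conservative
  tie rule for a toxicity model.
- **Termination.**  A run ends when all lanternfly are consumed, when all
  *N* birds are non-eaters (undecided birds keep a run alive), or at
  T_max; the eater proportion is recorded every `record_stride` steps and
  exactly at the final step.

### The stand-in flocking rule

The movement model is a standard zonal self-propelled-particle rule, built
here as a documented stand-in for roost-site flocking and exposed behind
`MovementParams` so another rule can be substituted: within the
interaction radius R = 6, neighbours closer than a repulsion radius of 3
contribute pure repulsion (repulsion has priority); other neighbours
contribute alignment (weight 0.4) and attraction (weight 0.25); beyond a
home radius of 85 a homing term (weight 0.5) turns the bird back toward
the roost; headings get uniform rotational noise of up to 0.3 rad per
step; speed is a constant 1 unit per step.  The weights were calibrated to
produce a loose, roost-bound swarm whose emergent observation rate
(fraction of eating events seen by at least one other bird) sits near the
reference operating point r_o ≈ 0.45; with them the pooled estimate from
the desk-scale sweep comes out just below 0.5.  All quantitative rate
estimates depend on this stand-in and should be re-derived if the
movement rule is replaced.

### Rate estimation and experiments

Rates are counted from event logs: r_i_hat = events / (N × live steps)
(per bird per time step, matching the ODE's units; alternative
normalizations can be formed from the logged counts), and r_o_hat =
events observed by ≥ 1 other bird / events, flagged undefined — never
silently 0 — when there are no events.

The long-term experiment runs replicate simulations per *q* (replicate
*k* of grid row *i* uses seed base + i·n_replicates + k, keeping streams
auditable) and aggregates the recorded final eater proportion into mean
and standard deviation (ddof = 1).  The trajectory experiment aggregates
the eater proportion per time step; replicates that terminate early carry
their final value forward so every replicate contributes to every time
point (a run that ate everything keeps its final eater fraction, a run
that went all-non-eater stays at 0); padding is exactly neutral for runs
that reach T_max.  A centred rolling average (default 10 recorded
samples, edges truncated) smooths the mean series.  Overlays place the
analytic equilibrium max(0, 1 − (r_o_hat+1)q/r_o_hat) over the per-q
means, and the explicit solution over the smoothed trajectories.  The ODE
needs p0 > 0 to leave the trivial equilibrium while simulated birds all
start undecided (ignition there comes from the spontaneous-trial channel
π, which the ODE lacks); trajectory overlays therefore default to
p0 = 1/N — a single first convert — and this choice is deliberate and
visible in the API.

### Problem sizes

The reference study conditions are N = 50, N_l = 500, T_max = 6×10⁶, with
2000 (long-term) or 5000 (trajectory) replicates per q — a cluster-sized
computation.  The package's desk-scale conditions, used by the test suite
and the `cbc` defaults, are q ∈ {0, 0.05, …, 0.6}, 50 replicates,
N_l = 200, T_max = 2×10⁵; `--paper-scale` restores the full settings.
Structural laws (purity at q = 0 and q = 1, determinism, conservation)
are scale-free; the quantitative ODE-vs-simulation comparison at desk
scale is noisier than at full scale.

## What the simulator does and does not emulate

It emulates: local, radius-limited social transmission of a foraging
behaviour through a moving flock; rare spontaneous trials; permanent
removal of consumed prey; the forced limits q = 0 (abandonment
impossible) and q = 1 (adoption impossible).

It does not emulate: prey movement, reproduction or replenishment; bird
energetics, mortality or seasonality; three-dimensional space; and the
specific published roost-site flocking rule (see the stand-in above).
Passing tests therefore support the *consistency of the two model levels*
under these idealizations, not field-level predictions for real birds.

## Known limitations

- **Observer multiplicity.**  One eating event can be observed by several
  birds at once, while the compartmental model's r_o is the probability
  that an event is observed at all.  The simulator's effective emergence
  threshold tracks the *mean* number of observers per event, k̄, as
  k̄/(1+k̄), whereas the counted estimate r_o_hat is P(k ≥ 1) ≤ k̄.  In
  any cohesive flock k is overdispersed, so the empirical collapse of the
  eater proportion occurs at slightly higher q than
  q\* = r_o_hat/(r_o_hat+1).  The calibration keeps the flock loose to
  hold this gap near one sweep grid step; it cannot be removed entirely
  without making observations single-recipient, which would change the
  stated observation rule.
- **Finite prey budget.**  With N_l = 200 prey and 50 birds, adoption at
  q = 0 can stall short of the analytic limit p = 1: once the reachable
  prey are consumed there are no further events to convert the last
  undecided birds.  At the reference scale (N_l = 500, T_max = 6×10⁶) the
  gap shrinks; at desk scale the long-term mean at q = 0 typically lands
  around 0.85–0.93.
- **Arena corners.**  The homing rule keeps birds within roughly the home
  radius plus a small overshoot, so prey in the extreme corners of the
  square (beyond ~90 units) are visited rarely; low-q runs usually end by
  time-out with a handful of corner prey alive rather than by consuming
  every last one.
- The ODE ignores prey depletion altogether; comparing it against a
  depleting simulator is part of the model design, and the std-band
  discrepancy report is the intended reading of that comparison — no
  hypothesis testing beyond it is attempted.
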