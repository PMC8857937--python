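# Methods

## Model

An organism develops over `T` discrete periods (default 20) in a patch
whose hidden state is `E0` or `E1` and never changes within a lifetime.
The prior probability of `E1` equals the patch distribution the lineage
adapted to; presets 0.5, 0.7 and 0.9 are exposed alongside a free
parameter, always strictly inside (0, 1).

Each period has three events, in order: the organism (1) receives a binary
cue whose reliability `r_t` is the probability that the cue matches the
true state (identical in both states, so mismatches have probability
`1 − r_t`); (2) updates its belief by Bayes' rule, using the previous
posterior as the prior; (3) chooses irreversibly to increment `y0`, to
increment `y1`, or to wait. Fitness is paid once, at maturity:

```
π = π0 + P(E0|D_T)·fR(y0) + P(E1|D_T)·fR(y1) − [P(E0|D_T)·fP(y1) + P(E1|D_T)·fP(y0)]
```

There is no constitutive cost of plasticity and no cost of switching
specialization targets; the only cost of waiting is the foregone
opportunity to specialize.

### Reliability schedules

`build_schedule(pattern, r_min, r_max, T)` produces the three standard
patterns plus a constant helper. Increasing is `linspace(r_min, r_max, T)`;
decreasing is its exact reverse; triangular (even `T` only) ramps up over
periods `1..T/2` and mirrors down over `T/2+1..T`, so the peak value is
attained twice. This discretization makes the equal-mean property exact by
construction — all three patterns average `(r_min + r_max)/2` — rather
than requiring a calibration search. A single-peak (odd-apex) triangle
would also satisfy an equal-mean constraint but not exactly on a uniform
grid; the mirrored version was chosen for that reason.

Reliabilities live in `[0.5, 1)`. The value 1 is excluded rather than
special-cased: a perfectly reliable cue makes the Bayesian update undefined
on a contradicting cue, and the twin treatments (reciprocal cues,
deprivation) generate exactly such contradictions.

### Fitness mappings

The reward and penalty mappings are drawn from the power family
`f(y) = max_payoff·(y/T)^γ` with γ = 1 (linear), 0.5 (diminishing) and
2 (accelerating). The family satisfies every property the model imposes —
`f(0) = 0`, `f(T) = max_payoff` for every shape (equal attainable payoff),
and constant / strictly decreasing / strictly increasing marginal effects —
and is deliberately replaceable: any monotone map with those properties
slots in without touching the solver. Reward and penalty shapes may differ.
`max_payoff` defaults to `T` (unit marginal effects for the linear shape);
the baseline `π0` defaults to `fP(T) = max_payoff`, which keeps total
fitness non-negative in the worst case. Policies are invariant to `π0`
(an additive constant); the test suite asserts this.

## Solver

Backward induction runs over decision states keyed `(t, log-odds, y0, y1)`,
where the belief has integrated the period-`t` cue and the counters cover
the `t − 1` completed decisions (`yw` is derived, never stored). The value
of a completed state is the expectation over the next cue — drawn from the
prior predictive `P(C1) = b·r + (1−b)·(1−r)` — of the best post-cue action
value; terminal states are initialized with `π`.

Two exact reductions keep `T = 20` tractable:

- **Belief merging.** Beliefs are exact signed log-odds sums
  `logit(prior) + Σ s_i·λ_i`, `λ_i = log(r_i/(1−r_i))`. States whose
  log-odds agree after rounding at 12 decimals are merged. Merging is
  dramatic whenever likelihood ratios repeat (triangular: every `λ`
  occurs twice, 6.2M states instead of 78M; constant schedules collapse
  to `t + 1` nodes per period) and is a no-op for generic ramps.
- **Linear-payoff collapse.** When both shapes are linear, terminal
  fitness depends on the phenotype only through `d = y0 − y1`, so the
  phenotype key collapses from `(y0, y1)` to `d`. The collapse is applied
  automatically and verified against the general representation at
  `T = 8` in the tests.

Actions tie when `|F_a − F_max| ≤ 1e-12·max(1, |F_max|)`; the relative
tolerance detects exact ties (uninformative cues, symmetric states)
despite floating-point noise. Tied actions are chosen uniformly at random
during simulation, so the tie rule is part of the model, not a numerical
detail. Probabilities are compared at absolute tolerance 1e-12 throughout;
there is no stochastic rounding. A state cap (default 5·10⁸) rejects
problems that would not fit, with guidance to lower `T` or rely on
merging; `T = 20` with two non-linear shapes (~4·10⁸ states) fits under
the cap but is a long, memory-hungry run compared to the collapsed
linear case (7.8·10⁷ states, seconds).

The forward pass (`state_probabilities`) propagates occupancy mass from
the root, splitting by cue probabilities and uniformly across tied
actions, and tracks full `(y0, y1)` phenotypes regardless of the solver's
internal collapse; per-period masses sum to one to 1e-9. States below the
display threshold (default 0.5%) are flagged, not dropped.

If numba is importable the decision kernel runs compiled; the pure-numpy
path is the reference implementation and produces identical output.

## Simulation and randomness

Populations are stepped in vectorized form. One master seed spawns an
independent `SeedSequence` per organism (cue stream, tie-break stream,
environment draw), so re-running any subset of organisms reproduces them
exactly, and twin designs can share cue streams while decoupling
tie-break streams. Trajectories store beliefs as `p1` at double
precision; the exact log-odds is recomputable from the cue history.

## Twin studies

"Separation in period `s`" means the clone's manipulated cues begin with
the period-`s` cue itself; the maximum post-separation divergence is
therefore `√2·(T − s + 1)`, which reproduces the overall maximum `20·√2`
at `s = 1`, `T = 20`. Twins share both the cue stream and the tie-break
stream strictly before `s` — sharing is the only convention that
guarantees identical phenotypes *and* posteriors at separation — and
tie-break streams decouple from `s` onwards. Clones apply the ordinary
Bayesian update to manipulated cues (they do not know about the
treatment). After a temporary window (default length 5 when a number is
not given) the clone resumes receiving the focal's cues; posteriors are
not reset. In the opposite-patch treatment the clone's cues are
independent draws from the opposite state's cue distribution, not
antithetic reuses of the focal's randomness. Measurement happens at the
end of ontogeny or the end of the window; the proportional normalizer
uses the measurement period `m` as its endpoint, `√2·(m − s + 1)`.

The posterior-only comparison reports the mean absolute posterior
difference of the *same* simulated twins rather than re-solving a
separate belief-only model: the comparison is between what phenotypes and
what beliefs retain of the manipulation, under one policy.

`exact_reciprocal_expectation` computes the permanent-reciprocal design
exactly by enumerating all cue sequences and all tie-break branches of
both twins (shared before `s`, independent after); it is feasible at
small `T` and anchors the Monte-Carlo implementation in the tests.

## Rank-order stability

Organisms are ranked on `y1` at each of the `T + 1` time points from
birth (all counters zero, one shared rank) through maturity; the
switch matrix is `(T+1)×(T+1)` and the consecutive series has one entry
per period. Including the natal time point matters: under a strictly
decreasing schedule the period-1→2 transition has structurally zero
switches (the second cue's likelihood ratio can never outweigh the
first, so first-period classes persist), and the measure's early decline
is visible only from birth onwards.

Ranking is dense (ties share a rank, ranks are consecutive) and, for
cross-period comparison, anchored at the top: rank 1 is the most
specialized class. Direction matters because the typical population
(environment fixed to `E1`) piles up at the maximum trait value;
top-anchored labels keep that stable majority's rank constant, whereas
bottom-anchored labels would relabel it whenever a new distinct value
appears below, flooding the measure with spurious switches. The
symmetric caveat — instability when the population piles at zero —
is the price of the convention. `rank_population` itself returns
conventional ascending dense ranks for within-period use.

## What the simulations do and do not show

All inputs are model-generated: cue sequences are exact draws from the
generative model the solver assumes, environments never change within a
lifetime, and every organism follows the optimal policy. Passing tests
therefore validate the solver, the estimators and their internal
consistency — not robustness to model misspecification, within-lifetime
environmental change, mortality before maturity, or organisms that must
learn cue reliabilities rather than inherit them. Those are limitations
of the model class, documented as such.

## Problem sizes and tolerances in the tests

Unit tests run at `T ≤ 8`; exhaustive checks (brute-force contingency
enumeration, one-step-deviation optimality, twin enumeration) at
`T ≤ 8`; the full `T = 20` scenarios run with 2,000 twin pairs per
separation period and 10,000 organisms for rank stability, with
Monte-Carlo agreement asserted at three standard errors. Exact
identities (martingale property of the posterior, counter conservation,
equal schedule means, baseline invariance) are asserted at 1e-12 or
1e-9 as stated above.
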