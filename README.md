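# ontosense

Optimal developmental policies — and the sensitive periods they imply — when
the reliability of environmental cues varies across ontogeny.

## The problem

Sensitive periods are life stages in which experience shapes the phenotype
more strongly than at other stages. Most formal models predict them only
early in life, yet adolescence-like sensitive periods are widespread. One
candidate explanation is that the *reliability of cues* changes across
development: relative body size predicts adult competitive ability better
late in the juvenile period; prenatal cues may summarize ancestral
conditions better than noisy postnatal ones.

`ontosense` implements a stochastic-dynamic-programming model for this
question, for behavioral ecologists and developmental modellers. An organism
lives `T` discrete periods in a patch whose hidden state `E ∈ {E0, E1}` is
fixed for life. Each period it receives a binary cue `x_t ∈ {C0, C1}` with
period-dependent reliability

```
r_t = P(C1,t | E1) = P(C0,t | E0),      0.5 ≤ r_t < 1,
```

updates its belief `b_t = P(E1 | D_t)` by Bayes' rule (the previous posterior
is the next prior), and then irreversibly allocates the period to one of
three actions: increment the specialization counter `y0` (towards the
`E0`-adapted phenotype), increment `y1`, or wait (`yw`). At maturity,
`y0 + y1 + yw = T` and fitness is

```
π = π0 + P(E0|D_T)·fR(y0) + P(E1|D_T)·fR(y1) − [P(E0|D_T)·fP(y1) + P(E1|D_T)·fP(y0)]
```

with reward/penalty mappings `f(y) = max_payoff·(y/T)^γ` (γ = 1 linear,
0.5 diminishing, 2 accelerating; all shapes share `f(T)`). Backward
induction over every reachable state `(t, b_t, y0, y1)` yields the policy
maximizing expected terminal fitness; ties among actions are broken
uniformly at random.

Reliability schedules come in the three standard patterns — linearly
*increasing*, *decreasing*, or *triangular* between `r_min` and `r_max` —
constructed so all three share the same mean reliability (equal total
information across ontogeny).

On top of the solver the package implements the simulated study designs
used to quantify plasticity:

- **twin studies** (`ontosense.twins`): clone each organism at a separation
  period `s`, manipulate the clone's cues (reciprocal-opposite cues,
  opposite-patch cues, cue deprivation, or a dose-response flip
  probability; permanent or temporary separation; measurement at the end of
  separation or of ontogeny), and measure the Euclidean distance between
  the twins' `(y0, y1)` phenotypes — *absolute* plasticity normalizes by
  the global maximum `T·√2`, *proportional* plasticity by the maximum
  attainable after separation, `√2·(T − s + 1)` — plus the mean absolute
  difference in posteriors (the "posterior-only" comparison);
- **rank-order stability** (`ontosense.ranks`): dense ranks on `y1` at
  every time point from birth to maturity, and the proportion of organisms
  switching rank between any two time points.

## Worked example

```python
import ontosense as ons
from ontosense.twins import TwinStudyConfig

schedule = ons.build_schedule("increasing", 0.55, 0.95, 20)
mapping = ons.FitnessMapping(max_payoff=20.0)   # linear rewards and penalties
policy = ons.solve_policy(0.5, schedule, mapping, store_values=False)
print(f"states: {policy.state_count:,}  root value: {policy.root_value:.3f}")

curve = ons.plasticity_curve(
    policy, ons.EnvironmentState.E1,
    TwinStudyConfig(separation_period=1, n_pairs=2000, seed=1),
)
for r in curve[:3] + curve[9:12] + curve[-2:]:
    print(f"s={r.separation_period:2d}  absolute={r.absolute:.3f}  "
          f"proportional={r.proportional:.3f}  posterior={r.posterior_distance:.3f}")
peak = max(curve, key=lambda r: r.proportional)
print(f"proportional plasticity peaks at separation period {peak.separation_period}")
```

prints

```
states: 77,594,630  root value: 33.120
s= 1  absolute=0.678  proportional=0.678  posterior=0.997
s= 2  absolute=0.662  proportional=0.696  posterior=0.998
s= 3  absolute=0.636  proportional=0.706  posterior=0.998
s=10  absolute=0.391  proportional=0.710  posterior=0.993
s=11  absolute=0.347  proportional=0.693  posterior=0.985
s=12  absolute=0.300  proportional=0.666  posterior=0.977
s=19  absolute=0.004  proportional=0.042  posterior=0.082
s=20  absolute=0.001  proportional=0.013  posterior=0.017
proportional plasticity peaks at separation period 7
```

The expected fitness of an optimal developer is 33.12 (baseline 20, i.e.
13.12 fitness units above an organism that waits out its whole ontogeny).
With *increasing* cue reliability, proportional plasticity rises from 0.678
at first-period separation to a **mid-ontogeny peak** (s = 7) before
collapsing late — a sensitive period in mid-ontogeny — while absolute
plasticity declines monotonically and posterior differences only shrink:
the mid-ontogeny peak is a joint property of phenotype and information
state, not of beliefs alone. A decreasing schedule instead confines
plasticity to the very start of ontogeny.

The same pipeline is scriptable from the shell:

```bash
ontosense fixtures -d configs/
ontosense solve configs/panel_prior05_increasing_T20.yaml -o policy.json
ontosense twin policy.json -o curve.csv
ontosense ranks policy.json -o ranks.csv
ontosense compare policy.json -o compare.csv
```

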