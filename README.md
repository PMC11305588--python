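# ismpop

Long-term human population dynamics under climate and innovation: a
delayed-logistic simulator with threshold-triggered infrastructure
regimes, plus the demographic diagnostics used to read such dynamics out
of archaeological density proxies.

The package is aimed at population ecologists and paleodemographers who
want to (a) explore how innovation ladders, delayed resource feedbacks,
and stochastic climate shape trajectories of growth, overshoot, recession
and cycling, and (b) apply the matching diagnostics — phase-plane paths,
demographic-transition and cycle detection, clustered-bootstrap mean
kernel density estimation of dated samples, logistic trend fits, and
counterfactual intervention analysis — to simulated or empirical density
series.

## The model

Population density p(t) follows a modified logistic,

    dp/dt = r p − S p² / K,        f ≡ (dp/dt)/p = r − S p / K,

with r the maximum per-capita gain (1/generation), S ∈ (0, 1] the cost of
social integration, and f the per-capita fitness (equivalently, the
per-capita growth rate).  The capacity constraint of the active
infrastructure regime i combines innovation, delayed density feedback and
climate:

    K_i(t) = A_i − B_i p(t − d) + C + Δ(t),

where A_i is the productivity augmentation of regime i, B_i its density
feedback applied at delay d, C the long-run mean climate suitability, and
Δ(t) stochastic climate variability (redrawn once per generation).  A
threshold rule drives innovation: while f_min < f the population keeps
its current footing; once fitness falls to the population-pressure
threshold f_min it adopts the next rung of a latent-innovation ladder.
Absence of a further rung is the innovation ceiling.  The closed-form
equilibrium of a rung is p* = r(A + C)/(S + rB).

One model generation maps to 30 calendar years when aligning simulations
with empirical 30-year bins.

## Worked example

`examples/02_innovation_ladder.py` runs a four-rung innovation ladder
(each rung doubles capacity: K = 1, 2, 4, 8; f_min = 0.1) and counts the
demographic transitions in the density–growth phase plane:

```
regime switches in the run:  3
terminal regime / density:   4 / 2.000
demographic transitions detected: 3
  bins  12- 17  peak growth 0.150  density 0.121 -> 0.242
  bins  17- 22  peak growth 0.150  density 0.242 -> 0.484
  bins  22-148  peak growth 0.150  density 0.484 -> 2.000
```

Each adoption lifts per-capita growth back above the pressure threshold
(the inverse-V excursions peaking near 0.15) and roughly doubles density
before pressure rebuilds; after the last rung the population settles at
the ceiling equilibrium p* = rK/S = 2.0.

The other example scripts cover the logistic baseline and its equilibrium
(`01`), delay-driven overshoot/recession sweeps (`03`), climate noise as
an innovation trigger when pressure is undetectable (`04`), recovery of a
known occupation curve by the clustered-bootstrap mean KDE (`05`), and
counterfactual estimation of an injected +50% intervention effect (`06`).
Each prints a few numbers and says what they mean.

A thin CLI wraps the same library calls
(`ismpop simulate|preset|phase|kde|impact|synth`); every artifact gets a
JSON sidecar with the resolved parameters and seed.

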