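# Methods

`polyethism` simulates how a colony of social-insect workers, split into a
*young* and an *old* age class, allocates itself between two tasks through
payoff-biased social learning, and analyses when this allocation becomes
age-based (age polyethism), when it splits the colony without regard to
age, and when it collapses onto a single task (regulation failure).

## The colony game

Each individual carries a trait `x ∈ [0, 1]`: its engagement with Task 1,
the in-nest *homeostatic* task (thermoregulation); `1 − x` is its
engagement with Task 0, the out-of-nest *maximising* task (foraging).
Workers interact in groups of `n` drawn from a colony of `N` (an n-player
public-goods game). The per-capita group benefit couples the two tasks
multiplicatively — both must be serviced for the colony to function:

    B = (1/n) · B0(Σ(1−x_j)) · B1(Σ x_j)

with, by default, a linear foraging benefit `B0(e) = b·e` and a concave
homeostatic benefit `B1(e) = 4(e/n)(1−e/n)` peaking at half the group
effort. Costs are borne individually and add across tasks:

    C(x, a) = (−(1−x)² + 2(1−x)) · exp(β(1−a)) + r·x

The foraging cost is marginally decreasing (practice makes it cheaper) and
scaled up by `exp(β)` for young workers (`a = 0`); the homeostatic cost is
linear with slope `r`. An individual's payoff is `Π = B − C(x, a)`.

Three environmental parameters matter: `b` (foraging benefit per unit of
effort — abundance), `r` (relative cost of the homeostatic task), and `β`
(the age differential of foraging cost). The exact benefit/cost shapes are
design choices of this package, constrained only by the qualitative
geometry above; all three are injectable through the configuration
(`benefit0`, `benefit1`, `cost1` accept registered names or callables), so
alternative shapes can be substituted without code changes.

Note one structural consequence of these shapes: expanding the foraging
cost gives `C0 = (1 − x²)·exp(β(1−a))`, which is *convex* in the trait —
intermediate generalists pay more than specialists at either extreme. This
is the built-in engine of disruptive selection that makes colonies split
into task groups.

## Social learning (SL engine)

Time is discrete. Each generation the colony is partitioned uniformly at
random into `K = N/n` games (redrawn every generation by default),
everyone earns a payoff, and then every individual synchronously picks a
"cultural parent" to imitate. The probability of picking parent `i` is

    p(j←i) ∝ exp(−ω·α·|a_i − a_j|) · exp(Π_i)

normalised over the whole colony, self included. `α ∈ [0, 1]` controls how
strongly recruitment is restricted to the own age class (`α = 0`: age is
ignored and the rule is exactly a softmax of payoffs; `α = 1` with
`ω = 10`: cross-age imitation is suppressed by `e^{−10}`). We read the
similarity kernel as `exp(−ω·α·|Δa|)`: for binary age classes the
alternative reading `|Δa|^α` is degenerate (any `α > 0` gives the same
kernel, and `α = 0` would not be similarity-blind). Finally, each trait
mutates with probability `μ` to a Gaussian perturbation of itself
(`σ` wide), clipped to `[0, 1]` — small autonomous behavioural
exploration.

Updates are synchronous: all parents are sampled against the previous
generation's traits and payoffs. Ages never change; the model describes
the fast behavioural dynamics induced by a fixed age structure, not
ageing itself.

## Stigmergy (SRT-SL engine)

The stimulus-coupled engine reinterprets the trait as a response
*threshold* and adds one colony-wide stimulus per task. The probability
that individual `i` performs Task 1 is

    p_i = 1 − 1/(1 + exp(−γ[(x_i − 0.5) + (S0 − S1)]))

so a high foraging stimulus `S0` pushes the whole colony toward foraging
and vice versa. Payoffs and costs are evaluated on the realised action
probabilities `p` (effort actually spent), not on the thresholds.
Stimuli follow deficit dynamics:

    ΔS0 = λ1 · max(0, B0min − Σ_k B0(task-0 effort of group k)) − λ2·S0
    ΔS1 = φ1 · (B1max − Σ_k B1(task-1 effort of group k)) − φ2·S1

`B0min` is the colony's foraging demand — half of every group foraging,
valued at a *calibration abundance* `reference_b = 20` — and `B1max` the
largest homeostatic benefit `K` groups can produce. The demand is a
property of the colony, not of the current weather: holding it fixed while
`b` varies is exactly what makes scarcity stressful (a hungry colony does
not need less food). With the default gains `λ1 = λ2/B0min`,
`φ1 = φ2/B1max` and decays `λ2 = φ2 = 0.1`, each stimulus is an
exponential smoother of the *fractional* unmet demand of its task (time
constant 10 generations). The update is then a convex combination of the
old level and a deficit fraction in `[0, 1]`, so stimuli are confined to
the unit interval by construction; a hard clip remains as a safety net for
custom gains. Keeping the stimulus equilibrium proportionate matters
dynamically: if the homeostatic stimulus were allowed to amplify its small
irreducible deficit (group-level `B1` is below `B1max` whenever groups are
not exactly balanced) into saturation, the `S0 − S1` offset would shift
the reachable action range so far that thresholds pin against the trait
boundary and the colony can no longer split into task groups at all.

One generation runs in a fixed order: payoffs from the previous step's
action probabilities → imitation of thresholds → mutation → stimulus
update → new action probabilities. Games are drawn once at the start and
held fixed (switchable to per-step redrawing, which is the SL engine's
default).

## Defaults and units

| parameter | default | meaning |
|---|---|---|
| `b` | 20 | foraging benefit per unit effort (abundance) |
| `r` | 1 | homeostatic cost slope relative to foraging |
| `β` | 0 | age differential of foraging cost (dimensionless exponent) |
| `n`, `N` | 10, 100 | game size, colony size (even young/old split) |
| `ω`, `α` | 10, 0.5 | similarity kernel scale, cross-age restriction |
| `μ`, `σ` | 0.01, 0.05 | mutation probability and step width |
| `γ` | 10 | threshold sigmoid slope |
| `λ2 = φ2` | 0.1 | stimulus decays (gains are decay/demand) |
| `S0⁰ = S1⁰` | 0.5 | initial stimuli |
| `x0` | 0.5 | common initial trait |
| `T` | 2000 | generations per run |
| tail window | last 20 % | steady-state summary window |

`T = 2000` is chosen because all regimes reported here reach their
steady-state statistics well before generation ~1000 at these population
sizes; the tail window then averages a stationary stretch. All defaults
are this package's own calibration of an under-determined model family
and are exposed in the YAML configuration.

## Analysis layer

Steady states are summarised by per-individual mean engagement over the
tail window (action probability `p` for the stimulus engine, trait `x`
for the SL engine) and classified:

* **regulation failure** — colony mean engagement beyond `lo = 0.2` or
  `hi = 0.8` with no two-cluster split;
* **branching (mixed)** — at least `min_frac = 10 %` of the colony at or
  below `lo` *and* at or above `hi`, with at least one branch of mixed
  age;
* **age polyethism** — such a split in which each branch's majority age
  class reaches `purity = 0.9`.

These thresholds quantify what the underlying study judged visually; they
are configurable (`RegimeThresholds`).

The *polyethism index* is the absolute young-minus-old difference of mean
tail engagement (0 = ages behave identically, 1 = perfect age-task
separation). Statistical null checks come in two forms, chosen by where
exchangeability actually holds: with `α = 0` individuals are exchangeable
across age labels and an individual-level permutation test applies; with
`α > 0` imitation couples individuals within a class, so only the two
class *labels* are exchangeable — the correct permutation null is then a
sign-flip test of the signed young/old gap across replicates (exact
enumeration of all `2^R` assignments).

*Relative colony efficiency* is the tail-average population mean payoff
divided by the best mean payoff any fixed workforce allocation can achieve
under the same game partition (partition noise is thereby excluded). The
benchmark optimum is found by simulated annealing over `[0, 1]^N`:
Metropolis acceptance, geometric cooling (×0.95 every 100 iterations from
temperature 1), single-coordinate Gaussian proposals mixing a coarse
(0.1) and a fine (0.005) width, 4×10⁴ iterations. The two-scale mixture
is what lets one run both find the basin and polish it (per-coordinate
error ~5×10⁻⁴ on a quadratic test objective); best-so-far is monotone by
construction. Efficiency is reported as undefined (NaN) when the optimum
is not strictly positive, which happens in severely scarce environments
where even the best allocation loses.

Parameter sweeps run replicate seeds (derived from a master seed by a
counter) over a `(b, β, α)` grid, record per-replicate regime, index,
efficiency and seed, and aggregate by modal label with ties flagged.
Failed cells are recorded with their error and do not abort the sweep.

## Adaptive-dynamics cross-check

To check the simulations against theory, the package computes invasion
fitness in the standard adaptive-dynamics limit (infinite population,
rare small mutations): the expected payoff of a rare mutant of one age
class in groups of `n − 1` residents — group age composition marginalised
exactly over the even binomial mix for `n ≤ 12`, Monte-Carlo beyond —
minus the same-age resident's expected payoff. The per-age-class selection
gradient is the mutant-trait derivative at the resident (central
differences, step 1e−5; one-sided with a warning at the trait boundary).
Singular strategies are located by sign-change scanning of the gradient
field on a coarse `(x_young, x_old)` grid followed by multivariate
root-finding, and classified by second-order conditions: negative
invasion-fitness curvature = evolutionarily stable; negative slope of the
conditional gradient through zero = convergence stable. Convergence-stable
but evolutionarily *unstable* points are **branching points** — the
analytical signature of the colony splitting into task specialists. A
boundary analysis reports whether the trait edges attract (the analytical
picture of regulation failure). We implement the per-age-class conditional
analysis; a joint two-trait stability analysis (Jacobian of both gradients)
is a possible refinement and would matter only for sets where the two
classes' dynamics interact degenerately.

The cross-check used in the tests: on parameter sets whose singular point
is classified branching, the within-age trait variance of an SL run grows
by more than 5× from the early transient (generations 1–50) to the tail;
on boundary-attracted (regulation-failure) sets it stays within 2× —
mutation–selection balance only. These bounds are test criteria of this
package, not claims of the underlying theory.

## What the simulations do and do not show

All experiments are self-generated: the model family *is* the object of
study and there is no external data. The phenomenology reproduced —
age polyethism under abundance with an age cost differential, mixed
branching when costs are age-symmetric or recruitment unrestricted,
age-pure branches under fully restricted recruitment, collapse of the
age-based division under scarcity (young workers forced into foraging),
regulation failure in extreme scarcity, and age polyethism *not*
maximising colony efficiency — is robust under the defaults above, at
these colony sizes, with binary age classes and two tasks. Passing tests
say nothing about continuous age structures, task repertoires beyond two,
mortality feedback (precocious-forager loss spirals), spatial nest
structure, or real insect parameter values.

## Numerical choices and degenerate inputs

* Payoff exponentials in the imitation rule subtract the maximum payoff
  before exponentiating; the distribution is exactly invariant to payoff
  shifts and immune to overflow.
* Parent sampling inverts the per-age-class cumulative distribution with
  a single uniform draw per individual; a guard clips the searchsorted
  index against round-off at the top of the CDF.
* The action-probability sigmoid uses the overflow-safe logistic.
* Traits outside `[0, 1]` are *rejected* at the payoff layer (clipping is
  the mutation operator's job); engagement-sum domains `[0, n]` likewise.
* The classic response-threshold update clips thresholds below at zero
  (a threshold is a stimulus comparator; negative values are meaningless).
* `T = 0` runs are legal and return only the initial condition.
* A trajectory stores `T + 1` state rows and `T` payoff rows: payoffs at
  row `t` were earned by the state of generation `t`.
* CSV trajectories are written at `%.17g` and parsed with round-trip
  float precision, so write→read is bit-exact and identical seeds yield
  identical checksums.

## Known limitations

* Branch *orientation* under fully restricted recruitment (`α = 1`) is
  not guaranteed: with the age classes dynamically isolated, an occasional
  replicate locks in the inverted assignment (young foraging). The
  expected orientation dominates (≥ 8/10 replicates under defaults).
* At `b = 20, β = 0` the SL engine with unrestricted recruitment often
  stays unimodal near the branching point instead of splitting: finite-
  population "herding" noise (group-luck amplified by the payoff softmax)
  competes with the weak disruptive curvature there. The stimulus-coupled
  engine, with fixed games, branches reliably at the same point.
* The annealing benchmark optimises a deterministic allocation under one
  fixed partition; it is a tight upper reference for the colony's mean
  payoff but not a game-theoretic equilibrium concept.
* Adaptive-dynamics classification ignores mutation size and finite-N
  noise; agreement with simulation is expected only in sign/regime, not
  in rates.
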