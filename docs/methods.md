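# Methods

## Model

A finite simple directed graph G = (V, E) carries a multitype branching
process.  A cell at vertex x divides at rate α(x), dies at rate β(x),
and — for each edge (x, y) — produces an additional cell at vertex y at
rate ν(x, y), leaving itself in place: (x) → (x), (y).  All cells act
independently; there is no interaction, resource limitation or carrying
capacity.  The process starts with z cells at the root vertex.  The root
must be a source and the target a sink; the root's growth rate
λ = α − β is assumed positive and strictly larger than every
intermediate vertex's growth rate λ(x) (validation flags violations of
the fitness assumption as warnings, because the simulator remains exact
there while the closed forms lose their justification).  The target's
fitness is deliberately unconstrained: the hitting time only concerns
the first arrival.

An alternative convention has transitions occur at division with
probability ν′, i.e. (x) → (y).  Only the (x) → (x), (y) form is
implemented; for small rates the two give very similar hitting times,
and the division-probability convention can be mapped onto ours by
ν = α′ν′.

## Closed forms and their regime

All analytic results are small-transition-rate asymptotics, exact in the
limit where the target-seeding rates tend to zero:

* survival of the hitting time
  P(T > t) ≈ ((λ/α)/(1 + e^{λt} φ_N α/λ²) + β/α)^z, identically equal to
  the limit law ((λ/α)/(1+e^{λs}) + β/α)^z at s = t − μ with
  μ = (1/λ) log(λ²/(α φ_N)) (the identity e^{λμ} = λ²/(αφ_N) is covered
  by a 1e-12-tolerance test over random parameter sets);
* seeding-path distribution w(p)/φ_N and the time-advantage law
  w(p)/(w(p) + e^{λt} Σ_{q≠p} w(q));
* long-run growth e^{−λt} Z_x(t) → W Φ_x with Φ_x = φ_x/(λ − λ(x)),
  Φ_root = 1, and W the binomial–Erlang mixture sampled by `sample_W`.

How fast the error vanishes matters in practice.  On the two-path
valley system at ν = 0.1 the exact process seeds the target via the
valley path with probability ≈ 0.51 (measured at 20 000 runs; an
independently written per-cell simulation agrees), while the asymptotic
w/φ value is 5/9 ≈ 0.556; scaling all rates down by 3× and 10× moves the
simulated frequency onto the asymptotic value within Monte-Carlo error.
Users working at rates of order 0.1 should expect absolute errors of a
few percentage points in path probabilities and survival curves; at the
mutation/migration rates typical of the applications (1e-9 .. 1e-2) the
approximation is excellent.

Numerical choices: weights are computed and accumulated in log space
(rates in the applications span 1e-8 to 1e-1, and 18-path products
underflow in linear arithmetic), with log-sum-exp totals; survival and
density evaluations clip the exponent λ(t − μ) to the double-precision
range and handle t = ±∞ by their limits.

### Approximations layered on the theorems

* **Conditional hitting law.**  Conditioning on root-population survival
  is implemented by removing the extinction atom lineage-wise:
  (S₁(t)^z − (β/α)^z)/(1 − (β/α)^z) with S₁ the per-lineage survival
  factor.  For z = 1 this is the logistic law with median exactly μ.
  For z > 1 it treats the z initial lineages as exchangeable rather than
  using the exact conditional law; it is validated against simulation,
  not against a printed formula.
* **Median for z > 1.**  The initial-size shift h(z) is implemented only
  in its large-z asymptotic form, so the median is μ for z = 1 and
  (1/λ) log(λ/(z φ_N)) otherwise; `MedianResult.regime` reports which
  branch produced the value.  For small z > 1 the large-z form is a
  documented approximation.
* **Cyclic graphs.**  The spectral condition (largest real eigenvalue of
  the rate matrix equal to λ and simple, tolerances 1e-9, configurable)
  is checked by `rate_matrix_and_eigencheck`; under it, φ_N can be
  approximated by truncated walk-weight sums over `enumerate_walks`,
  which is justified because cycle-containing walks carry weight of
  higher order in the transition rates.  The exact eigenvector summation
  that replaces φ_N in the cyclic hitting-time theorem is not
  implemented; the matrix and eigenvector are exposed for users who need
  it.

## Simulator

The SSA groups cells into lineage classes keyed by the vertex sequence
of their ancestry (consecutive duplicates collapsed).  Per event: one
exponential waiting time at the total rate, one uniform to pick the
class and event type.  Division and death change the class count by ±1;
a transition leaves the source class untouched and increments the child
class — so the event table is rebuilt in O(#classes) per event, and the
class structure *is* the path-tracking device: the first class ending at
the target gives both T and the seeding path.

Design choices:

* **Target cells are not propagated.**  Arrivals at the target are
  recorded (first arrival per lineage) but target cells neither divide
  nor die.  Every quantity the package estimates — hitting times,
  seeding paths, pre-target population growth — is unaffected, and runs
  stay cheap after the hit in `track_all_paths` mode.
* **Conditioning proxy.**  "Given the root population survives" is
  estimated by discarding runs whose entire population went extinct
  before a target hit.  Survival of the root population and the target
  ever being hit coincide in the small-rate limit; at moderate rates the
  proxy can differ from exact root-survival conditioning by runs in
  which the root lineage dies but a descendant lineage survives long
  enough to seed the target, which are rare under the fitness
  assumption.
* **Reproducibility.**  Run i of a campaign uses
  `default_rng(SeedSequence((seed, i)))`; identical configuration and
  seed reproduce the event sequence bit for bit, and campaigns are
  embarrassingly parallel.
* **Guards.**  `t_max` is mandatory; `pop_cap` (default 1e6 cells) and a
  class-count cap terminate runaway runs with an explicit `censored`
  status — censored runs restrict the valid domain of the empirical
  survival curve (reported as `t_valid`) rather than being dropped.

Estimators: the empirical survival curve uses all runs (never-hit runs
count as T > t for every t) with pointwise Clopper–Pearson intervals;
seeding-path frequencies are computed over target-hitting runs, with
requested-but-unobserved paths reported at frequency zero; scaled sizes
e^{−λt_f} Z_x(t_f) come from population snapshots taken at user-supplied
record times, and the per-run W estimate is the scaled root size.

## Test-problem sizes

The simulation-versus-theory checks run on the 4-vertex path graph
(α = 1 everywhere, β = 0.4/1.3/1.3/0.6, common ν): 1000 runs per ν for
the survival-curve comparison at ν ∈ {0.1, 0.05}; 300 runs to t_f = 14.5
for the Φ_x recovery, asserting agreement within 4 delta-method standard
errors of the ratio-of-means estimator; and 10 000 edgeless-graph runs
for the extinction frequency, where `pop_cap = 200` serves as an
almost-sure-survival barrier (the residual extinction probability from
200 cells is (β/α)^200 ≈ 1e-80), so each run ends quickly either way.
These sizes give standard errors comfortably below the effects being
tested.

## Scenario builders

The application graphs are ordinary `TransitionGraph`s; their printed
closed forms are the generic formulas specialised, and the tests verify
agreement with the generic pipeline to 1e-12 relative error.

* **Monotherapy**: 4 states (sanctuary/drug compartment × sensitive/
  resistant), resistance cost s and drug cost d added to the death rate;
  path weights νm/s (mutation–migration) and νm/d (migration–mutation);
  order probability d/(s+d); the drug-switch rule compares sanctuary
  sizes against (1 + s/d_B)/(1 + s/d_A).
* **Combination therapy**: 12 states (3 regions × 4 genotypes) with the
  drug-B region nested in drug A's — the only geometry modelled; other
  layouts are rejected explicitly.  Migration leaves a region at total
  rate m split in proportion to destination capacity; back migrations
  are omitted, following the applications' no-back-transition
  convention, which is also what makes the 18-path (6 direct + 12
  stepwise) structure finite.  Consequently only the sanctuary's
  out-migration rates sum to m.  Costs combine additively on death rates
  with no epistasis.  The stepwise-probability and acceleration limit
  forms (valid for s ≪ d, n_S + n_D ≪ n_Tot) are returned side by side
  with their exact-graph counterparts.
* **CML**: single-transition rate competition ν_pm/(ν_pm + ν_ga),
  optionally reweighted by founding-population survival probabilities
  via the successful-seeding rescaling ν ↦ νλ(N)/α(N); the
  two-amplification variant uses the two-step weight ν_ga²/s.  Two
  candidate thresholds for when point mutations dominate are reported
  (against 1/2 and against the single-event value) because they answer
  different comparisons; neither is privileged.
* **Bacterial MDR**: the diamond graph of the two acquisition orders;
  the order probability is the opposing cost fraction (mutation rates
  cancel), and the time law uses φ = 2ν₁ν₂/s.  The two-lineage relative
  probability is reported with a validity flag for its small-time limit
  (ν₁ν₂e^{λt} ≪ 1).

## Synthetic data

`evopaths.fixtures` generates every input used by the tests: the named
example systems with their published rate sets, and `random_dag` —
layered DAGs with a guaranteed root-to-target chain, log-uniform rates
in [1e-3, 1e-1], and intermediate death rates drawn above the root's so
the fitness assumption always holds.  These graphs exercise enumeration,
weighting and simulation, but they do not emulate features of real
systems such as rate heterogeneity over orders of magnitude within one
graph, near-critical intermediates, or state spaces too large to
enumerate; passing tests demonstrate correctness of the machinery, not
calibration to any particular biological system.

## Known limitations

* No size dependence, competition or carrying capacity; the branching
  assumption is an approximation to systems with large capacities.
* Hitting-time and median formulas are asymptotic; no error bounds are
  computed, only empirical convergence checks.
* The exact conditional law and exact h(z) for moderate z are not
  implemented (approximations above).
* Walk enumeration is truncated at a user-chosen length; for strongly
  cyclic graphs at large rates the truncated φ_N can be badly biased —
  the eigenvalue condition flag should be consulted first.
* Rare-event acceleration (importance sampling, tau-leaping) is out of
  scope; at application-scale rates (≤ 1e-6) direct simulation of
  seeding events is impractical and the closed forms are the intended
  tool.
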