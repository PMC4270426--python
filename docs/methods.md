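# Methods

## Model

An agent discriminates between two world states, *good* and *bad*, drawn
with prior probability 1/2 each, from a stream of conditionally i.i.d.
binary samples: green-husk probability ε_g under a good state, ε_b under a
bad one (0 < ε_b < ε_g < 1). Perception is a binary symmetric-erasure
channel parameterized by the effort level φ ∈ [0, 1): with probability φ a
sample is read correctly, otherwise it is replaced by a fair coin flip.
The effective sample distributions are therefore the φ-mixtures
ε'_s = φ ε_s + (1 − φ)/2. The agent is assumed self-aware (it knows φ) and
runs the sequential probability ratio test on the *adjusted* distributions:
per-sample log-likelihood weights w₊ = log(ε'_g/ε'_b) for a green reading
and w₋ = log((1−ε'_g)/(1−ε'_b)) for a pale one are summed into the decision
variable y_T, and sampling stops at the first exit from (−A, A) with
A = log(θ/(1−θ)), θ ∈ (0.5, 1). Time is counted in samples.

Costs and benefit: a correct decision earns B fitness units; each sample
costs C_t (baseline cost of time, set by the environment) plus C_e (cost of
effort per unit time, chosen by the agent). Effort buys reliability on the
saturating hyperbola φ = C_e/(k + C_e) — concave with diminishing returns,
φ(0) = 0, half-saturation at C_e = k — whose exact inverse C_e = k φ/(1−φ)
diverges as φ → 1, which is why φ = 1 is excluded everywhere. Strategy
fitness is W(θ, φ) = B·P_C − (C_t + C_e(φ))·DT. The hyperbola is isolated
behind `speedeffort.effort`, so an alternative saturating curve can be
swapped in without touching anything else.

## Evaluation routes

**Simulation** (`sprt.simulate_ensemble`) draws trials exactly as the model
states them: true state from the prior, husk from the state's distribution,
perception through the φ-channel, weight accumulation, threshold test.
Trials that reach the sample budget `t_max` undecided are *truncated*:
excluded from the accuracy denominator, counted at `t_max` in the mean
decision time, and reported. Any truncation invalidates a landscape cell
rather than being silently averaged.

**Absorption oracle** (`oracle.dp_absorption`) recasts the decision
variable as a bounded random walk on the two-step lattice and propagates
the state distribution forward in time, removing absorbed mass at every
step. States are indexed by integer up-step counts, never by rounded
decision-variable values, so there are no floating-point state collisions;
the alive band between the two boundaries has constant width
2A/(w₊ − w₋), which keeps the propagation O(band × t) and fast. The same
boundary comparison as the simulator is used, with a 1e-9 absolute slack:
lattice-aligned parameterizations (threshold an exact multiple of the step)
put states bit-exactly on the boundary, where a raw comparison is decided
by rounding noise. The slack is six orders of magnitude below any grid
step size used here, so it can only ever stabilize exact hits. Propagation
stops early once alive mass falls below 1e-14; the remainder is reported
as unabsorbed. A numba-jitted kernel is used when available, with an
equivalent pure-NumPy fallback that the tests exercise directly.

On symmetric environments (ε_b = 1 − ε_g) with the boundary an integer
number a of steps, the walk is a classic gambler's ruin started midway
between ±a, and `oracle.ruin_closed_form` gives the exact absorption
probability 1/(1 + (q/p)^a) and mean duration (a − 2aP)/(q − p) (a² when
p = 1/2). This closed form is used purely as an independent cross-check of
both the propagation and the simulator; it raises rather than approximate
on non-lattice walks.

Because P_C and DT depend only on (θ, φ) and not on the costs, the
landscape machinery computes one performance table per grid and re-prices
it at each C_t. This makes cost sweeps nearly free and — more importantly —
makes the Type 1 / Type 2 invariants exact: both agent types are scored
against the same table, so W(type1) ≥ W(type2) holds identically (Type 2
optimizes over a slice of Type 1's strategy set) and the two types select
the same cell at the baseline cost, giving a relative fitness advantage of
exactly zero there.

## Default scenario and parameters

| parameter | default | meaning |
|-----------|---------|---------|
| ε_g, ε_b | 0.75, 0.25 | green-husk probabilities (3:1 likelihood ratio per sample) |
| prior | 0.5 | probability the state is good |
| B | 100 | fitness benefit of a correct decision |
| k | 0.2 | half-saturation constant of the effort curve (cost units) |
| C_t | 0.2 | baseline cost of time per sample |
| θ grid | 0.55 … 0.99, step 0.01 | decision-threshold grid |
| φ grid | 0 … 0.98, step 0.02 | effort grid (φ = 1 excluded: infinite cost) |
| `t_max` | 10⁴ | sample budget per trial before truncation |
| `n_trials` | 10⁴ | ensemble size per cell in simulate mode |
| comparison costs | 0.1, 0.2, 0.4 | halved / baseline / doubled C_t |
| sweep | 20 points, geomspaced 0.02–2.0 | two orders of magnitude in C_t |

The default scenario was chosen once, by a coarse scan, to place the model
in the regime of scientific interest: an interior, single-peaked optimum on
the default grid whose θ* falls and φ* rises as time grows dearer, with
effort cheap enough relative to the benefit (k ≪ B) that modulating it
pays. With a much costlier effort curve (k of order 1 with B ≲ 50 here)
the optimum collapses to the θ-grid floor — agents decide on a single
sample and effort modulation is nearly worthless — which is a legitimate
but uninteresting corner of the parameter space.

Randomness: one master seed; each landscape cell in simulate mode draws its
generator from `SeedSequence([seed, theta_index, phi_index])`, so landscapes
are bit-reproducible and cells statistically independent. Oracle-mode
results involve no randomness at all.

## Peak counting on exact landscapes

Exact evaluation exposes structure that ensemble noise hides: the set of
absorbing lattice states is piecewise-constant in θ between boundary/lattice
crossings, so P_C and DT — hence W — are *terraced* in θ (runs of cells
with bitwise-equal fitness) and carry small jump ripples in φ. Counted
literally, a default landscape has on the order of a hundred 4-neighborhood
local maxima, all of topographic prominence below 0.05 against a fitness
relief of several hundred units; they are quantization artifacts of the
evidence lattice, not landscape structure. `is_single_peaked` therefore
counts maxima by prominence (H0 persistence: activate cells in decreasing
fitness order, union with active neighbors, record each dying component's
summit-minus-saddle), with plateaus merging at zero prominence. The default
threshold is 1% of the fitness relief over valid cells — several orders of
magnitude above the ripple scale and far below any genuine second mode —
and the raw local-maximum count is always reported in the diagnostics.
Passing `min_prominence=0` recovers the literal count.

The same discreteness means optimal cells tie exactly along θ-terraces;
ties are broken lexicographically (smallest θ, then smallest φ) and logged.

## What the tests do and do not show

The simulation route is validated against two independent oracles (the
ruin closed form on lattice cases, exact rational-arithmetic enumeration in
the tests, and forward propagation on asymmetric cases) within 3 binomial /
delta-method standard errors at n = 10⁵, and the qualitative claims —
monotone shifts of (θ*, φ*) with C_t, fitness dominance of adaptive effort,
monotone time-for-effort substitution, single-peakedness — are verified in
oracle mode, where no sampling noise can mask or fake them. One caution on
scope: accuracy dominance of Type 1 over Type 2 is asserted at the
halved/doubled comparison costs, not pointwise along the dense sweep; both
types' grid optima move in discrete jumps at different costs, so the
accuracy ordering genuinely flickers near Type 2's re-optimization points
while the fitness ordering remains exact everywhere.

The model itself idealizes aggressively: binary i.i.d. evidence, a
symmetric perception channel, a known and stationary φ, equal priors and
symmetric thresholds, and a fitness that is linear in P_C and DT. Passing
tests say nothing about decision-making with correlated or continuous
evidence, state-dependent misperception, unequal priors or asymmetric
payoffs — all deliberately out of scope.

## Known limitations

* Grid optimization only; optima are grid cells, and responses to C_t move
  in visible jumps at the default resolution (the refinement test doubles
  the resolution and checks the substitution ordering is preserved).
* Cells with θ high and φ low may not terminate within `t_max`; they are
  marked invalid and excluded rather than extrapolated. The φ = 0 column
  never terminates by construction.
* `expected_time` conventions couple truncation to `t_max`; comparisons
  between oracle and simulation are only meaningful at matching `t_max`.
* The closed-form ruin route requires exact step symmetry and lattice
  alignment and refuses everything else by design.
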