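# Methods

This note records the models, estimators, numerical choices and known
limitations behind the package, in enough detail to interpret what a green
test does and does not establish.

## Information measures

All quantities are in bits (log base 2), with `0·log 0 = 0` by continuity.
Exact entropies and mutual informations are computed from explicit joint
probability tables (`ProbabilityTable`); a table is valid when its masses
are non-negative and sum to 1 within 1e-12, and "zero information" on exact
tables means below 1e-10 bits.

Three estimators operate on finite samples:

* **plug-in** — empirical cell frequencies;
* **Bayesian (Dirichlet-smoothed)** — `prior_strength` pseudo-counts
  (default 1) added to every cell of the joint alphabet before normalising.
  The alphabet of a multi-column block is its *observed support* (the
  distinct patterns actually seen), not the full product alphabet: for a
  9-bit type vector a 512×512 prior table would contribute far more prior
  mass than 2000 trials of data. With skewed marginals, smoothing toward
  the uniform joint can *increase* the null bias of MI (the mixture of two
  different product distributions is not a product distribution), which is
  why criterion values are additionally reported shuffle-corrected (below).
* **Gaussian** — `I = ½·log2(det Σ_A · det Σ_B / det Σ_AB)` from sample
  covariances. A covariance is treated as singular when its smallest
  eigenvalue falls below 1e-12 of its largest (error names the offending
  group). This is the only continuous-data path; nonparametric estimators
  are out of scope.

## Emergence criteria and their surrogate null

`Psi`, `Delta`, `Gamma` follow the whole-minus-sum forms given in the
README. For orders k > 1 the single-part sums and maxima are replaced by
sums/maxima over all part groups of size exactly k — a generalisation that
reduces to the k = 1 forms and is labelled "generalised-k
(implementation-defined)" in reports; subset enumeration is guarded at 1e5
groups. Because mutual information is monotone in source sets, maxima over
groups of size exactly k equal maxima over size ≤ k.

**Surrogates.** The null hypothesis is "the feature carries no pairing
information": the feature series is re-paired at random — one global
permutation over the pooled trial × time axis for time-series data (a plain
time shuffle for a single trial), or independent per-time-slice trial
permutations for two-time-point ensembles. Within-trial time permutation
alone is too weak a null for strongly autocorrelated features (a trial's
feature composition survives any reordering inside the trial) and is not
used. The one-sided empirical p-value is
`(1 + #{surrogate ≥ observed}) / (1 + n_surrogates)`; default 100
surrogates at α = 0.05.

**Shuffle correction.** Each criterion is also reported as observed minus
surrogate mean. This is the classic shuffle-corrected MI estimate: the
surrogate mean measures the finite-sample estimator bias under the null,
and subtracting it calibrates every criterion to zero on unpaired data. The
correction matters most when many near-zero MI terms are summed — in the
collider experiment the 225-cell sum of `Psi` absorbs ≈ 2.8 bits of pure
estimator bias at 2000 trials, swamping the signal in the raw value.

**Verdicts.** Exact tables: emergent iff `psi > 1e-10`, downward iff
`delta > 1e-10`, decoupled iff emergent and `gamma ≤ 1e-10`. Sampled data
with surrogates: emergent iff the shuffle-corrected `psi` is positive *and*
p ≤ α (likewise `delta`); "Gamma ≈ 0" is operationalised as the observed
`gamma` lying below the 95th percentile of its own surrogate distribution,
since an exact zero is unattainable from samples. `psi ≤ 0` is always
inconclusive — redundancy between parts drives the criteria negative
without ruling out emergence — and every report says so. A report whose
`delta` verdict fires while the `psi` verdict does not carries a note that
downward causation is itself an emergent modality.

## Decomposition (MMI redundancy)

The redundancy lattice is the set of antichains of non-empty source
subsets, ordered by `α ≤ β` iff every member of β contains a member of α;
atoms are recovered by Möbius inversion of the cumulative redundancy. The
redundancy function is pluggable; the default is minimum mutual information
(MMI): `min_i I(X^{α_i}; Y)`, and for the two-time decomposition the
minimum of `I(X^a_t; X'^b)` over member pairs. MMI gives closed forms —
`Syn^(k) = I(X;Y) − max_{|α|=k} I(X^α;Y)` equals the lattice sum because
the antichains containing a member of size ≤ k form a down-set whose atom
total telescopes — and the package cross-checks closed form against lattice
on every tested table. Möbius inversion under MMI can yield negative atoms;
they are reported as-is with a flag (clipping would break the conservation
identity). Lattice generation is capped at 3 sources (18 antichains); the
two-time decomposition at 2 variables per side (16 atoms).

**Unique information: two instantiations.** `un_mmi` follows the
`I(V;X_t') − max_{|α|=k} I(X^α;X_t')` form (target: the whole future
state); it satisfies `un_mmi ≤ Syn^(k)` unconditionally but does **not**
upper-bound `Psi`: in a pure copy system (`X' = X`, independent bits) the
parity feature has `Psi = 1` bit while this form gives 0, because the
min-MI redundancy equates a part's self-prediction with the feature's
distinct content. The feature-target form `un_feature_mmi
= I(V;V') − max_{|α|=k} I(X^α;V')` does satisfy the chain
`Psi ≤ un_feature ≤ Syn^(k)` (verified on hundreds of random kernels and
in the copy-system worst case), and is the instantiation the bound-chain
tests use. The discrepancy is a known artifact of MMI with multivariate
targets, not of the decomposition framework.

## Parity testbeds

Three Markov dynamics on n uniform random bits, built around
`par(x) = 1` iff the bit-sum is even (note: this convention assigns 1 to
the all-zeros state). Closed forms used as oracles:
`I(par_t; par_{t+1}) = 1 − H_b(γ)`.

* **example1** — next state uniform over same-parity strings w.p. γ, else
  opposite: `Psi = 1 − H_b(γ)`, `Delta = Gamma = 0`; pure decoupling.
* **example2** — `x'_1 = par(x)`, other bits fair coins:
  `Delta = Gamma = 1` bit. `Psi = 0` exactly: the parity of the *next*
  state XORs the determined bit with fresh coins, so the feature does not
  predict itself. (Minimal downward causation.)
* **example3** — both mechanisms; `Psi = 1 − H_b(γ) > 0` and `Delta = 1`
  simultaneously. Its one-step marginal is *not* uniform: pinning
  `x'_1 = par(x)` gives states whose parity matches their first bit mass
  `2γ/2^n` (uniformity only at γ = ½). The uniform distribution is
  stationary for the first two dynamics only.

State indexing: part 1 is the least significant bit. Multi-step sampling
iterates the one-step kernel. Exact joints are refused above n = 12
(4^n cells).

## Game of Life collider

15×15 **toroidal** boards (wrap-around keeps drifting particles in
`{0,1}^225`; the boundary rule is recorded in reports), B3/S23 applied
synchronously, 1000 generations per trial, 2000 trials by default.

**Particle library.** Projectiles: glider, LWSS, blinker, block; detection
additionally knows the stable debris beehive, loaf, boat, tub, ship (L = 9
type bits). Every template is defined by one seed phase; the phase cycle,
period and velocity are derived by evolving the seed on an empty board, so
templates self-validate at load. Collider initialisation places one
particle uniformly in each board half with randomised type, phase, row and
column; spaceships are oriented toward the opposite particle; placements
within Chebyshev distance 2 of each other are rejected and redrawn.

**Detection** groups live cells into clusters at Chebyshev radius 2 (some
canonical spaceship phases are disconnected under plain 8-adjacency — the
LWSS corner spark sits at distance 2) and matches each cluster exactly
against every phase/rotation/reflection of every template, with seam
stitching on the torus. Unmatched clusters count as unrecognised mass
(reported, never typed); about 8% of final boards contain some.

**Statistics.** `V_t` is the 9-bit presence vector treated as one
variable over its observed patterns; criteria use the Bayesian estimator
(prior 1) with 100 surrogates, and the headline `Psi`, `Gamma`,
`I(V_t;V_t')` are shuffle-corrected (see above). With seed 1 the frozen
defaults give `Psi ≈ 0.52`, `Gamma ≈ 0.010`, `I(V;V') ≈ 1.23` bits, with
`Gamma` two orders of magnitude below the feature's self-information — the
decoupling signature. These values are sensitive to the projectile set: a
spaceships-only collider lowers `I(V;V')` to ≈ 0.3 because collisions
mostly destroy the incoming types, while still-life projectiles raise it
by surviving unchanged; results should be compared across libraries, which
is why the library is replaceable via a plain-text pattern file.

## Boids flock

N = 10 boids, each a 2-D position plus heading, on a **toroidal** arena of
side 60 (minimal-image interactions). An unbounded plane was rejected: the
flock performs an integrated random walk there, and Gaussian MI between raw
coordinates grows without bound as the window lengthens. The trade-off is
recorded as a limitation below.

Update rule (speed 1, timestep 1, perception radius arena/5 = 12, heading
noise sd 0.05 rad): steering = `a1·(unit vector to the centre of perceived
flockmates) + a2·(unit vector away from the nearest neighbour, active
within the radius) + a3·(mean neighbour heading unit vector − own heading
vector)`, added to the current heading vector and renormalised; position
advances along the new heading. All three rules are local — that is what
lets sub-flocks form and disintegrate, the regime where the emergence
criterion fires; avoidance is gated by the radius because an ungated
unit-vector repulsion disperses the flock without bound whenever
`a2 > a1`. Fixed weights `a1 = 0.5`, `a3 = 0.05` were chosen once so that
the zero-avoidance flock orbits a slowly-moving centre of mass rather than
collapsing into a ballistic cluster (which alignment-dominant weights
produce); all parameters are configurable and recorded in reports.

The feature is the centre of mass — on the torus, the per-coordinate
circular mean mapped back to the arena, which agrees with the arithmetic
mean whenever the flock does not straddle the seam. Criteria use the
Gaussian estimator on lag pairs after a 200-step burn-in and stride-5
subsampling (autocorrelation reduction). The default avoidance sweep is
`a2 ∈ {0, 0.3, 1, 3, 8}` at 6000 steps: `Psi` is negative at low avoidance
(every boid shadows the COM — redundancy), peaks at an interior value, and
the COM's self-information at the highest avoidance falls below its
zero-avoidance value.

Translation equivariance of the dynamics is exact (the update depends on
relative positions only): on the plane, trajectories and the COM shift
rigidly and Gaussian-estimated criteria are bit-identical; on the torus the
shift holds modulo the arena, but wrapped *coordinates* fed to a covariance
estimator are not shift-invariant, so Ψ-invariance under translation is a
plane-mode property only.

## What the synthetic testbeds do and do not establish

The parity systems are exactly solvable, so green tests there verify the
estimators and criteria against closed forms — no modelling risk. The
collider and flock are *models of* the phenomena, with defaults frozen
before comparison: green tests establish that the pipeline detects
emergence with the right qualitative structure (significant `Psi`,
`Gamma ≪ I(V;V')`, interior sweep maximum), not that the specific numeric
values transfer to other particle libraries, arena geometries or flocking
rule variants. Known limitations: whole-minus-sum criteria cannot rule out
emergence (false negatives under redundancy); MMI redundancy overestimates
microscopic redundancy and admits negative atoms; the Dirichlet estimator
needs the shuffle correction for many-term criteria; continuous features
with discrete systems (and vice versa) are rejected rather than mixed.
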