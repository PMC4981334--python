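# Methods

## Model

A population of `N` individuals occupies the vertices of a connected
k-regular graph.  Each individual plays a single symmetric (k+1)-player
game with its k immediate neighbors: an A-player with `j` A-co-players
receives `a_j`, a B-player `b_j`.  Evolution follows a Moran death-Birth
process: at each step a uniformly chosen individual dies, and its k
neighbors compete to place a copy of themselves on the vacant vertex with
probability proportional to `1 − w + w·payoff`.  The process has two
absorbing states (all-A, all-B); we compare the fixation probabilities
`ρ_A` and `ρ_B` of a single mutant of either type.

Under weak selection, `ρ_A > ρ_B` holds iff `Σ_j ς_j f_j > 0`, where
`f_j = a_j − b_{d−1−j}` are the gains from flipping and the normalized
structure coefficients `ς_j` depend only on the population structure and
the update rule.  Exact zero is reported as "not favored" with a boundary
flag, since the comparison is a strict inequality.

## Structure coefficients

**Well-mixed** (random group formation, Moran or Wright-Fisher):
`ς_j = N/(d(N−1))` for `j ≤ d−2`, `ς_{d−1} = (N−d)/(d(N−1))`; uniform
`1/d` in the large-population limit.

**Cycle** (`k = 2`): exact, `ς = (1/(2(N−2)), 1/2, (N−3)/(2(N−2)))`.
These feed the closed-form volunteer's-dilemma thresholds
`B/C > 2(N−2)/(N−3)` (plain) and `B/C > (5N−6)/(6(N−3))` (cost-sharing).

**Regular graphs of degree k ≥ 3**: no exact finite-N expression is
available; we use a pair approximation combined with a diffusion
approximation, valid for `N ≫ k` and `wk ≪ 1`, which treats the graph as a
Bethe lattice (no loops).  At the neutral quasi-equilibrium of local pair
frequencies, the probability that a neighbor of an A-player is itself A is
`q_{A|A} = p + r·x` and that a neighbor of a B-player is A is
`q_{A|B} = r·x`, with `p = 1/(k−1)`, `r = (k−2)/(k−1)` and global
A-frequency `x`.  Averaging the selective drift at A-B boundaries against
the diffusion measure and collecting the coefficient of each payoff entry
gives

```
ς_j ∝ ∫₀¹ [ C(k−1, j) (1 − r x) (p + r x)^j (r (1−x))^(k−1−j)
          + C(k−1, j−1) (p + r x)^j (r (1−x))^(k−j) ] dx .
```

The integrand is a polynomial in `x`; we put it over the common
denominator `(k−1)^k` (which cancels on normalization) and integrate
term-by-term in exact integer arithmetic, normalizing at the end.  The
implementation is pinned by three simultaneous, independent anchors, all
of which it satisfies *exactly* in rational arithmetic:

1. at `k = 3` the normalized vector is `(7, 31, 61, 45)/144`;
2. the mean identity `Σ_j ς_j·j = (k+1)/2` holds for every k (this is
   what collapses sums of pairwise games to the classical
   `(k+1)α + (k−1)β − (k−1)γ − (k+1)δ > 0` rule and the donation-game
   threshold `B/C = k`);
3. the top coefficient obeys the closed form
   `1/ς_k = k(k+1)(k−2) / ((k−1)² − (k−1)^{1−k})`.

Computation is cached per degree; a full scan of `k = 3..100` costs a few
seconds, dominated by big-integer arithmetic at large k.

**Cycle with overlapping games** (payoffs accumulated from the games
centered on the focal player and on each neighbor):
`ς = ((N+1)/(3(2N−3)), (2N−1)/(3(2N−3)), (N−3)/(2N−3))`.  This variant is
exposed analytically only; the simulator implements the single-game model.

**Containment order**: structure `a` promotes cooperation at least as much
as structure `b` — every cooperation game (payoffs nondecreasing in the
number of A-co-players) favored under `b` is favored under `a` — whenever
`ς_a − ς_b` has a single sign change from − to +.  Zeros are skipped when
counting sign changes, because `ς_0 = 0` occurs at the large-N cycle and a
zero entry neither creates nor breaks a run.  The test is sufficient, not
necessary, so everything else reports "incomparable by this test".  The
well-mixed baseline in degree scans is the large-population limit (uniform
`1/d`), matching the regular-graph coefficients, which are themselves a
large-N approximation; finite-N scans would be a straightforward
extension.

## Simulation

The Monte-Carlo estimator runs independent realizations from a single
mutant at a uniformly random vertex (placement is irrelevant on
vertex-transitive graphs but matters on random regular graphs) to
absorption, and reports the fixation fraction with its binomial standard
error `sqrt(ρ(1−ρ)/runs)`.

Numerical and design choices:

- **Payoff timing.** Competitors' payoffs are evaluated on the state just
  before the focal death, so the dying individual still counts in its
  neighbors' groups.  The vacancy exists only notionally within a single
  update; this matches the standard death-Birth formulation.  On the cycle
  the exact-chain threshold computed under this convention converges to
  the analytic `2(N−2)/(N−3)` as `w → 0`, which is the sensitivity check
  for the convention.
- **Fitness positivity.** `1 − w + w·payoff > 0` is enforced up front by
  scanning the payoff table; violation is a configuration error, never a
  runtime clamp.
- **Active-set acceleration.** A death at a vertex whose whole
  neighborhood shares its strategy cannot change the state.  The kernel
  maintains the set of vertices with at least one disagreeing neighbor and
  samples deaths uniformly *within* it; conditioning on the death landing
  in the active set leaves every absorption probability unchanged, so the
  acceleration is exact.  On a cycle this reduces the work per realization
  from O(N) to O(interface) per effective event.
- **Random numbers.** Each realization gets its own SplitMix64 stream
  whose state is derived by counter from the master seed
  (`numpy.random.SeedSequence`), so results are reproducible and
  independent of execution order.  The compiled (numba) kernel and its
  pure-Python twin are bit-for-bit identical, which is itself a test.
- **Run counts.** Defaults target desk-scale hardware: `10^5` runs resolve
  fixation-probability differences of order `10^-3` at `N = 100`
  (standard error of `ρ_A − ρ_B` ≈ `4·10^-4`).  Larger campaigns scale the
  standard error as `1/sqrt(runs)`.

**Exact chain.** For `N ≤ 14` the full `2^N`-state transition structure of
the process is assembled and the absorption system solved sparsely
(`ρ(all-A) = 1`, `ρ(all-B) = 0`); the single-mutant fixation probability
averages the N one-mutant states.  At `w = 0` it reproduces the neutral
`1/N` to solver tolerance (`10^-12`) on every tested graph, and it is the
oracle against which the Monte-Carlo kernel is validated.

## Graphs

Rings connect each vertex to its k/2 nearest neighbors on each side
(`k = 2` is the cycle).  Random regular graphs come from the configuration
model with rejection of self-loops, multi-edges and disconnected samples
(deterministically advancing the seed, capped at 10^4 attempts).  Lattices
are periodic (toroidal) — open boundaries would break the regularity the
theory requires: degree 4 (von Neumann), degree 6 (six-neighbor triangular
tiling, the "hexagonal" neighborhood), degree 8 (Moore).  The Moore
lattice requires side ≥ 4: on a 3×3 torus it degenerates to the complete
graph, where diagonal and orthogonal neighbors coincide.  All constructors
are validated for degree, symmetry, absence of self-loops and
connectivity.

## What the tests do and do not show

The analytical surface (coefficients, thresholds, reductions, containment)
is checked in exact rational arithmetic and is as strong as the pair
approximation behind it: exact for cycles and well-mixed populations,
asymptotically accurate for large random regular graphs, and known to
*overestimate* the ease of cooperation on graphs with many short loops
(rings with k ≥ 4, lattices), where clustering violates the Bethe-lattice
assumption — on such graphs the simulated critical ratio can even exceed
the well-mixed one.  Simulation validation here is desk-scale: cycles up
to `N = 100` with `10^5` runs per point and exact chains up to `N ≤ 14`.
These sizes resolve the cycle threshold crossing cleanly but are not a
substitute for cluster-scale sweeps (`10^7` runs, `N = 500`, all graph
families) when chasing differences much smaller than `10^-3`.

## Known limitations

- Two strategies, symmetric payoffs, no mutation; death-Birth updating
  only (structure coefficients differ for Birth-death or imitation).
- The k ≥ 3 coefficients are a large-N approximation; there is no finite-N
  formula in the package for k ≥ 3.
- The overlapping-games variant has coefficients for the cycle only, and
  no simulator counterpart.
- The exact chain is limited to `N ≤ 14` by the `2^N` state space.
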