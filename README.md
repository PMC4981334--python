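# graphgames

Evolutionary dynamics of **multiplayer games on regular graphs** under weak
selection: exact and approximate structure coefficients, the multiplayer
sigma rule with critical benefit-to-cost thresholds, and a Moran
death-Birth simulator for estimating fixation probabilities.

## The problem

Many social interactions — microbes secreting public goods, animals
mobbing a predator, people deciding whether to volunteer — are games among
*d* players, not pairs, and they unfold on a network: each individual sits
on a vertex of a graph and interacts only with its neighbors.  The package
answers the question *when does spatial structure favor a strategy?* for a
symmetric d-player game with two strategies A and B, payoffs `a_j` (to an
A-player with `j` A-co-players) and `b_j`, played on a connected k-regular
graph (`d = k + 1`) evolving by a Moran death-Birth process: a random
individual dies and its neighbors compete for the vacancy with probability
proportional to `1 − w + w·payoff`, with selection intensity `w`.

Under weak selection (`w ≪ 1`), strategy A fixes more readily than B
(`ρ_A > ρ_B`) exactly when the **sigma rule** holds:

```
Σ_j  ς_j f_j  =  E[f(J)]  >  0,        f_j = a_j − b_{d−1−j}
```

where `f` are the *gains from flipping* and the normalized structure
coefficients `ς_0 … ς_{d−1}` — payoff-independent constants determined by
the population structure and update rule — define the distribution of the
number `J` of A-co-players.  The package computes `ς` for

- **well-mixed populations** with random group formation (exact),
- the **cycle** (`k = 2`), where the coefficients are exact:
  `ς = (1/(2(N−2)), 1/2, (N−3)/(2(N−2)))`,
- **regular graphs of degree k ≥ 3**, via a pair-approximation +
  diffusion-approximation treatment of the graph as a Bethe lattice
  (accurate for random regular graphs, optimistic for loopy lattices),
- the cycle with **overlapping games** centered on neighbors,

plus the single pairwise-game coefficient of transitive graphs and its
scaled-relatedness transform `κ = (σ−1)/(σ+1)`.

From the coefficients follow closed-form critical benefit-to-cost ratios
for the volunteer's dilemma (`B/C > 1/ς_{d−1}`) and its cost-sharing
variant, reduced conditions for sums of pairwise games and linear games,
and containment-order comparisons between structures (single `−+` sign
change of the coefficient difference ⇒ one structure favors cooperation in
every cooperation game the other does).

The simulator estimates `ρ_A` and `ρ_B` directly by Monte Carlo on rings,
random regular graphs and periodic lattices (degree 4, 6, 8), and an exact
absorbing-Markov-chain solver on graphs with `N ≤ 14` vertices serves as
an oracle for validating both the simulator and the weak-selection theory.

## Worked example

Structure coefficients of a large random regular graph of degree 3, as
exact fractions:

```sh
$ graphgames coeffs --structure regular --k 3 --exact
j	sigma_j
0	7/144
1	31/144
2	61/144
3	5/16
```

The volunteer's dilemma threshold on a large cycle:

```sh
$ graphgames threshold --game vd --structure cycle --N inf
{ "threshold": 2.0, "structure": "cycle", ... }
```

Cooperation is favored on the large cycle once one volunteer's benefit
exceeds twice its cost — versus `B/C > k + 1 = 3` in a comparable
well-mixed population.  Checking the analytics by simulation on a cycle of
`N = 100` vertices just above its finite-size threshold
`2(N−2)/(N−3) ≈ 2.0206`:

```python
import graphgames as gg

g = gg.make_ring(100, 2)                      # cycle, N = 100
game = gg.volunteers_dilemma(2.2, 1, d=3)     # B/C = 2.2
cfg = gg.SimulationConfig(w=0.01, runs=100_000, seed=42)
est_A = gg.fixation_probability(g, game, cfg)
est_B = gg.fixation_probability(g, game,
        gg.SimulationConfig(w=0.01, runs=100_000, seed=42, mutant="B"))
print(f"rho_A = {est_A.rho:.5f} +- {est_A.stderr:.5f}")
print(f"rho_B = {est_B.rho:.5f} +- {est_B.stderr:.5f}")
```

prints

```
rho_A = 0.01000 +- 0.00031
rho_B = 0.00928 +- 0.00030
```

— the cooperator mutant fixes more often than the defector mutant
(`ρ_A > ρ_B`, both near the neutral value `1/N = 0.01`), as the sigma rule
predicts for `B/C = 2.2 > 2.0206`.

The CLI also exposes `containment` (sign-change scans across degrees),
`graph` (edge-list generation for rings, random regular graphs and
lattices), `simulate`, and `sweep` (tables of `ρ_A − ρ_B` over a grid of
benefit-to-cost ratios).

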