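# Model and methods

## The game

Each node of an undirected network hosts one player with a pure strategy
s_i ∈ {+1 (cooperate), −1 (defect)}. Every round, each player plays the
one-shot prisoner's dilemma with each neighbour and sums the pairwise
payoffs, f_i = Σ_{j∈N_i} f_ij. The payoff matrix follows the rescaled
("weak") convention R = 1, S = P = 0, leaving the temptation T as the only
game parameter; the constructor enforces T > R ≥ P ≥ S and 2R > T + S,
which for the rescaled matrix confines T to (1, 2). Payoffs are recomputed
from scratch each round — at N = 2500 an incremental scheme would buy
nothing.

## Visibility and strategy updating

Each player carries a heritable binary attribute, *visibility*,
initialised independently with probability β.

- **Visible players** observe all neighbours' payoffs. The player targets
  the neighbour j\* with the maximum current payoff (ties broken uniformly
  at random) and adopts s_{j\*} with the Fermi probability
  W = 1/(1 + exp(−κ(f_{j\*} − f_i))). κ multiplies the payoff gap, so
  large κ (default 10) makes imitation of better-paid models
  near-deterministic while retaining occasional learning from worse ones.
- **Invisible players** know only their own payoff history and apply
  win-stay/lose-shift to their two most recent payoffs: keep s_i if the
  newer payoff is strictly larger, switch to −s_i if strictly smaller, and
  choose uniformly at random on a tie or when fewer than two payoffs are
  on record (e.g. a freshly placed offspring).

## Resource and survival

After each round the fixed global budget G = rN is allocated in proportion
to payoff, D_i = G·f_i/Σf (equal split in the degenerate all-zero-payoff
round — proportionality is undefined there and the equal split is the only
strategy-neutral rule that conserves G). Net resource is L_i = D_i − 1;
resource does not carry over between rounds. Every player with L_i < δ
dies; the death mask is evaluated simultaneously before any replacement,
so within-round order cannot cascade. A dead player is overwritten by the
offspring of a parent drawn uniformly from its surviving neighbours
(`parent_rule="best_payoff"` selects the best-paid surviving neighbour
instead); a player whose neighbours all died draws its parent uniformly
from all survivors. Offspring inherit the parent's strategy and visibility
and start with a cleared payoff history.

Note that with δ = 0 the death condition is f_i < Σf/(rN), i.e. payoff
below roughly 1/r of the population mean — turnover is heavy by
construction (ρ_d ≈ 0.3–0.7 per round at the defaults).

## Round composition

A round executes synchronously: (1) payoffs; (2) record indices from the
strategies actually played; (3) allocation and survival; (4) all survivors
simultaneously select their next strategy (visible players use this
round's payoffs; replaced players keep their inherited strategy for this
transition); (5) payoff history shifts for survivors. Synchronous updating
is what gives the round-indexed payoff history of the invisible rule a
well-defined meaning; an asynchronous variant is out of scope.

## Networks

- **Lattice:** L×L von Neumann 4-neighbourhood. The boundary is a flag:
  simulations default to *periodic* (every degree 4); the printed
  diameter of 98 for L = 50 is the *open*-boundary value (the periodic
  50×50 lattice has diameter 50 = 2⌊L/2⌋), so diameter reproduction uses
  `boundary="open"`. Both are first-class.
- **Scale-free:** mechanistic Barabási–Albert growth. The seed is the
  complete graph on m nodes (the smallest seed admitting m distinct
  attachments); each arrival attaches to m distinct nodes drawn with
  probability proportional to degree. With m = 2, n = 2500 this yields
  exactly C(m,2) + m(n−m) = 4997 edges, mean degree 3.9976 ≈ 4. The graph
  is regenerated per run in ensembles.
- **Diameter** is computed by unweighted all-pairs shortest paths
  (scipy.sparse.csgraph); on an unweighted graph this equals the
  Floyd–Warshall result at far lower cost. Disconnected input raises an
  error rather than returning infinity.
- Custom graphs load from plain-text edge lists (0-based integer pairs,
  `#` comments; a `# nodes: N` header preserves isolated nodes).

## Parameters

| name | meaning | default |
|------|---------|---------|
| α | initial cooperator fraction | 0.1 |
| β | initial visible fraction | 0.5 |
| T | temptation (successful-defection payoff) | 1.1 |
| κ | Fermi selection intensity | 10 |
| r | environment parameter; budget G = rN | 1.1 |
| δ | survival threshold on L_i | 0 |
| N | population size (50×50 or BA n=2500, m=2) | 2500 |
| total_rounds / M | run length / averaging window | 1000 / 500 |
| n_runs | ensemble size | 100 |

Defaults are the canonical study conditions. Scaled-down experiment sizes
used by the test suite and the acceptance script (600–800 rounds,
M = 300–500, 5–20 runs per point) were fixed once as a practical ensemble
size for a single CPU; the methods and parameters are identical at any
scale.

## Seeding and determinism

Each run's generator derives from the master seed via
`SeedSequence(seed, spawn_key=(run_index,))`: runs are independent,
bit-reproducible, and extending an ensemble reproduces the earlier runs
unchanged. Trajectory CSVs are byte-identical across repeats of the same
seed.

## Behaviour of the model, and known limitations

- **Bistability.** At the defaults the lattice population has two
  attractors: visibility fixes (ρ_v → 1, ρ_c ≈ 0.83) or goes extinct
  (ρ_v → 0, ρ_c ≈ 0.30, sustained by the invisible rule's random branch).
  Fixation resolves within ~800 rounds; ensemble means over β are
  fixation-probability curves. Consequently the lattice-vs-BA comparison
  of E(ρ_c) at the default parameters is marginal at small ensemble sizes
  (lattice ≈ 0.51 on average vs BA ≈ 0.55, with run-to-run spread of
  ±0.27 on the lattice).
- **Trend directions.** Sweeping β at the defaults, lattice E(ρ_c)
  increases and E(ρ_d) decreases; on the BA network E(ρ_d) increases with
  β. BA E(ρ_c) also *increases* with β in this implementation — visible
  hubs amplify whichever strategy pays locally, and at T = 1.1 that is
  predominantly cooperation.
- **Cooperation floor.** Because invisible players randomise on tied
  payoffs and offspring enter with cleared histories, heavy death churn
  keeps ρ_c ≳ 0.29 even at T close to 2; the T × β spread of E(ρ_c) is
  therefore ≈ 0.71 on the lattice and ≈ 0.66 on the BA network at the
  scaled-down settings.
- The generator emulates idealised study conditions only: Bernoulli
  initial conditions, a closed population, noiseless payoffs, and exactly
  synchronous rounds. Passing tests show internal consistency of the
  mechanisms, not that real social or biological systems behave this way.
- Strategy and visibility change only by imitation and inheritance — there
  is no mutation; absorbing states (all-cooperator, all-visible, …) are
  permanent.
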