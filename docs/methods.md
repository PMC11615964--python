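# Methods

## Model

Agents occupy the nodes of an undirected, connected, simple graph. Each
agent's linguistic state is a Dempster–Shafer mass function over the frame
`Θ = {R1..Rn, I1..In}` — one regular and one irregular past-tense form per
verb. Mass on composite subsets encodes genuine indecision between forms;
the model never needs a discrete "mixed" state. Beliefs evolve through three
behaviours — social learning, self-learning, forgetting — scheduled in
synchronous rounds by random edge activation.

### Social learning (WER fold)

A source's communicated belief is discounted by `c = w/(1 + w − r)` before
combination: every subset mass is multiplied by `c` and the remainder sits
in a separate *unassigned* slot (bookkeeping, distinct from genuine
ignorance on `Θ`). The ego enters the fold first with full self-trust
(`w = r = 1`, so `c = 1`), then sources are folded pairwise: cross products
with the unassigned slot preserve each operand's masses, intersection
products implement agreement, conflicting products (empty intersection) are
dropped by renormalization, and the residual unassigned slot is finally
redistributed proportionally.

Two structural facts are worth recording:

* Because the ego enters undiscounted, the unassigned slot is identically
  zero throughout the fold, and each step is algebraically identical to
  Dempster's rule applied to the source's mass after classical Shafer
  discounting toward `Θ`. A corollary (verified by a test) is that for
  *fixed* per-source `(w, r)` the fold is order-invariant; sequence matters
  only because the in-group recursion assigns reliabilities by position.
* An agent with unit mass on a singleton is absorbing under social
  pressure: every product either lands on its singleton or on the empty set,
  so commitment is irreversible. This is the microscopic origin of both
  consensus lock-in and permanent polarization.

### Influence attributes

The weight `w_ij` is the partner's degree share within the ego's
neighbourhood — static, purely structural, and generally asymmetric. The
reliability starts from the cosine similarity of the two mass vectors; when
an ego hears `k > 1` sources in one round, the `k`-th source's raw
reliability halves the ego–source similarity and adds the mean pairwise
agreement among all sources heard so far, so an opposing view gains
credibility once it is corroborated. Raw reliability is then mapped
affinely from `[r_η, 1]` onto `[r_fair, r_max]` (identity below the
threshold): friends are trusted at least half-way once minimally similar,
but never fully (`r_max < 1` keeps `c < 1` and rules out degenerate total
conflict inside the simulator).

### Direction of interaction

On an activated social edge the two individuals exchange information and
*both* update, each as ego of its own fold. The two directions of the same
interaction generally produce different posteriors because the fold is
ego-anchored. This mirrors the symmetric treatment of self-learning edges
(both endpoints practise) and is the reading under which the simulated
small-world indices land on the reference behaviour; a one-way
speaker→hearer variant was evaluated during development and produced
markedly stronger fragmentation on clustered graphs.

### Self-learning and forgetting

Self-learning picks one verb uniformly at random and moves an `α`-fraction
of its irregular singleton mass to the regular singleton; an agent already
committed to that verb's irregular form is exempt. Forgetting applies to
agents that are uncommitted and participated in fewer than `η` learning
events in the round (each social fold and each self-learning event counts
once): with probability `p_f` a `β`-fraction of the largest non-`Θ` focal
mass moves to `Θ`. Forgetting is the only mechanism that creates mass on
`Θ`, and that mass is what later lets social learning import new singletons
into an agent's support — which is why moderate forgetting *helps*
consensus.

## Parameters

| name | meaning | default | notes |
|------|---------|---------|-------|
| `n_verbs` | verbs in the frame | 2 | frame has `2^(2n)` subsets |
| `phi` | Dirichlet concentration on irregular singletons | 1.0 | `<1` biases initial beliefs regular |
| `f` | per-edge activation probability / round | 0.10 | |
| `p_s` | social (vs self) learning share | 1.0 | self-learning off by default |
| `alpha` | self-learning rate | 0.0 | 0.05 in self-learning studies |
| `p_f`, `beta` | forgetting probability / rate | 0.05, 0.04 | |
| `eta` | learning-count threshold for forgetting | 2 | |
| `r_fair`, `r_eta`, `r_max` | reliability mapping | 0.5, 0.2, 0.95 | `r_max<1` forbids total conflict |
| `t_max`, `stall_window` | horizon / fixed-point window | 5000, 200 | see termination |
| `n_reps` | replicates in `replicate()` | 200 | tests/scripts use 20 (10 per grid cell) |

## Termination

"Stabilization" is operationalized as: every agent committed (unit mass
somewhere — a true fixed point given absorbency), or no belief in the
population changing bit-for-bit for `stall_window` consecutive rounds, or
`t_max` rounds (logged as a warning and treated as the terminal state). An
earlier candidate rule — stopping when each agent's *argmax* proposition is
unchanged for a window — was rejected after instrumentation showed argmaxes
freeze hundreds of rounds before masses finish converging, which biases
every stabilized observable downward.

## Synthetic networks

WS, ER and BA graphs come from networkx, regenerated until connected. The
BA generator grows from a complete core of `n_attach` nodes (485 edges at
`N=100, ne=5`), which makes it exactly the `κ = 0` limit of the GM
interpolation family — the GM construction also grows from a complete core,
placing each new link uniformly at random with probability `κ` and by
preferential attachment otherwise, at fixed node and edge counts. The seed
core is not a cosmetic choice: star-seeded BA graphs, though nearly
indistinguishable by degree statistics, polarize noticeably more often in
this model.

LFR benchmarks use networkx's generator, filtered to realizations with
exactly three communities and a connected graph. Note that at `N = 100`
networkx's LFR realizes roughly *twice* the nominal mixing fraction
(`μ = 0.1` yields ≈ 0.19 inter-community edges); the tests therefore assert
the guaranteed properties (zero mixing as `μ → 0`, monotone growth) rather
than the nominal value, and community-level consensus indices measured on
these graphs inherit the extra inter-community noise.

## What the generators do and do not emulate

The synthetic populations reproduce the study conditions: matched density
(≈ 0.1) across families, Dirichlet singleton initial beliefs, and known
community labels where defined. They do not emulate degree assortativity,
weighted or dynamic ties, heterogeneous per-agent learning rates, or
realistic verb-frequency distributions — so passing tests demonstrate the
network-structure effects under controlled conditions, not quantitative
predictions for any empirical speech community.

## Numerical choices

* Subsets are bitmask-encoded in the fixed element order `R1..Rn, I1..In`;
  all tie-breaks (forgetting target, adherence, dominant element, learning
  sequence at equal weight) resolve toward the lowest bitmask / node id, so
  a (graph, config, seed) triple fully determines a trajectory.
* Mass conservation and commitment use a `1e-9` tolerance; combination
  renormalizes every step, so committed states are exact up to rounding.
* Unit mass on `Θ` counts as "stable" (the criterion `max m = 1` is applied
  literally); such an agent is exempt from forgetting and has nothing to
  forget anyway.
* Total conflict (normalizer 0) requires two undiscounted disjoint operands;
  the library signals it as an error, and the simulator cannot reach it
  because `r ≤ r_max < 1` keeps every source's `c < 1`.
* The per-round social phase is compiled with numba for speed; the
  pure-numpy library operations remain the reference implementation and the
  test suite asserts the kernel reproduces them to `1e-12`.

## Desk-scale protocol

Tests and the acceptance script run 100-node networks with 20 replicates
per scenario (10 per cell of the 3×3 self-learning grid; 10 LFR
realizations with 2–5 runs each), reporting plain means of the stabilized
observables. A single run stabilizes in roughly 1500–3500 rounds
(~0.3–1 s); a full scenario batch takes well under two minutes.

## Known limitations

* Absolute levels of community-local consensus are sensitive to generator
  details (the LFR mixing overshoot above) and, for partition-based
  analyses of graphs without ground-truth communities, to the choice of
  partitioner; relative orderings (heterogeneity helps consensus, local
  `r` exceeds global `R`, self-learning regularizes) are robust across all
  conditions tested.
* Commitments are irreversible by construction; phenomena that require
  re-opening settled conventions (e.g. slow drift back toward irregulars)
  are outside the model.
* Interactions always use the full verb frame; restricting an exchange to a
  sub-frame of mentioned verbs is not implemented.
* The football benchmark is not redistributed; supply the GML file to
  `load_fixture("football", path)`.
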