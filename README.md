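# cnvphylo

Phylogenetics for single-cell gene copy-number profiles measured by FISH.

Tumors evolve by copy-number change, and interphase FISH counts a handful of
gene probes in hundreds of individual cells of one tumor. `cnvphylo`
reconstructs the progression tree of such a tumor under three event types:

* **SD** — duplication or loss of one copy of a single gene,
* **CD** — duplication or loss of one copy of every gene on one chromosome
  (unequal chromosome segregation),
* **GD** — whole-genome duplication: every probe count doubles (e.g. failed
  cytokinesis).

A cell's state is an integer vector `v ∈ [LB, UB]^G` over the `G` probes
(`[0, 9]` by default — FISH counting saturates at "9+"). The package
computes **provably minimal edit distances** between states for the SD,
SD+CD, SD+GD and SD+CD+GD models. On a single chromosome the SD+CD distance
is

    d(x, y) = min over integer shifts t of ( |t| + Σᵢ |xᵢ + t − yᵢ| ),

summed over chromosomes; with GD the directed distance satisfies

    D(a, v) = min( d_sdcd(a, v),
                   min over E ∈ N(v) of  D(a, E/2) + 1 + d_sdcd(E, v) ),

where `N(v)` is the set of nearest-even neighbors of `v` — the only states
a final doubling can land on. Every distance comes with a
*boundary-sensitive* witness sequence: an event ordering whose every
intermediate state stays within `[LB, UB]`.

On top of the distances sits a heuristic Steiner-tree (median-joining style)
algorithm: deduplicate the sampled cells, build a minimum spanning tree on
symmetrized distances, repeatedly propose unobserved intermediate states
from sampled node triplets, keep those that shrink the tree, then prune,
root at the diploid state and regraft subtrees that were attached in the
impossible "halving" direction of a GD edge. The package also contains the
branching-process tumor simulator, the bipartition-matching tree-comparison
metric (Hungarian matching; defined even when the two trees have different
node sets, unlike Robinson–Foulds), a neighbor-joining baseline, and
tree/cell feature extractors for downstream classification.

## Worked example (library)

The central estimator is scikit-learn shaped: `fit(X)` on an integer
cell-by-probe matrix produces a rooted tree.

```python
import numpy as np
from cnvphylo import CopyNumberPhylogeny

X = np.array([[2,2],[3,2],[3,3],[6,4],[6,5],[2,2],[3,3]])  # 7 cells, 2 probes
est = CopyNumberPhylogeny(model="sdcdgd",
                          chromosomes=["chr1", "chr1"],
                          random_state=0).fit(X)
print(est.weight_)      # 4
```

The fitted tree (`est.tree_`, a `networkx.DiGraph`) is:

```
(2, 2) -> (3, 2)  w=1 (obs, frac=0.14)
(2, 2) -> (3, 3)  w=1 (obs, frac=0.29)
(3, 2) -> (6, 4)  w=1 (obs, frac=0.14)
(6, 4) -> (6, 5)  w=1 (obs, frac=0.14)
```

Reading it: the tumor founder is the diploid `(2,2)`; one lineage gains one
copy of gene 1 to `(3,2)` and then **doubles its whole genome** to `(6,4)` —
a single GD event, where the SD-only model would need 5 steps. Edge weights
are directed minimal event counts, so `est.weight_ = 4` says the whole
history needs four mutations; node fractions are the share of sampled cells
with that profile.

## Worked example (command line)

```
$ cnvphylo fixtures --out fx --seed 7            # small simulated datasets
$ cnvphylo dist --model sdcdgd --probes fx/gd_rich.probes.tsv \
      --trace 2,2,2,2,2,2 5,4,4,4,5,4
3
gd              4,4,4,4,4,4
sd_gain 0       5,4,4,4,4,4
sd_gain 4       5,4,4,4,5,4
```

The distance from diploid to `(5,4,4,4,5,4)` is 3: one doubling and two
single-gene gains, with every intermediate inside `[0,9]`.

```
$ cnvphylo build --model sdcdgd --probes fx/gd_rich.probes.tsv \
      --cells fx/gd_rich.cells.tsv --seed 1 --out tree.tsv --dot tree.dot
tree weight 12, 13 nodes
$ cnvphylo evaluate --truth fx/gd_rich.truth.tsv --inferred tree.tsv \
      --cells fx/gd_rich.cells.tsv
W=32    |C|=10  |B_R|=4 |B_I|=4 E=20.00
```

`E` is the percentage reconstruction error: 100·(1 − 2W / (|C|·(|B_R|+|B_I|)))
for matching weight `W`, common taxa `C`, and nontrivial bipartition sets
`B_R`, `B_I` of the true and inferred trees. `E = 0` means isomorphic trees.

Other subcommands: `simulate` (branching-process ground truth), `bench`
(simulation → inference → evaluation sweeps, long-format TSV), `features`
(tree- and cell-derived feature vectors).

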