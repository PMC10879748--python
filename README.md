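# cfdiamond

Detection of four-node hybridization cycles in level-1 phylogenetic networks
from quartet concordance factors, using algebraic invariants.

## The problem

Hybridization, introgression and horizontal gene transfer leave reticulate
signatures that a strictly bifurcating species tree cannot represent.  The
simplest reticulation on a level-1 network is a *four-node hybridization
cycle* `h – v1 – v3 – v2 – h`: a hybrid node `h` with two parent edges.
The cycle partitions the taxa into four clades — the hybrid clade `n0`
below `h`, the parent-side clades `n1` and `n2`, and the clade `n3`
opposite the hybrid node.  Likelihood-based network inference must search
network space and optimize branch lengths, which is slow; this package
instead *evaluates polynomials*.

Under the multispecies coalescent, every four-taxon set has three
concordance factors (CFs): the fractions of gene trees displaying each of
its three splits, `CF(ab|cd) + CF(ac|bd) + CF(ad|bc) = 1`.  On a network
with a four-node cycle the expected CFs are polynomials in
`z_e = exp(-t_e)` (branch lengths `t_e` in coalescent units) and the
inheritance probability `γ`.  For the eight-taxon reference network with
two taxa per clade there are 19 informative quartet classes, hence
19 × 3 = 57 CF polynomials in 9 parameter variables; e.g. for the class
drawing two taxa from each of clades `n2` and `n3`,

    CF(major) = 1 − (2/3)·z2·z23·z3,   CF(minor) = (1/3)·z2·z23·z3  (twice).

Eliminating the parameters from this system yields *phylogenetic
invariants*: polynomials in the CF values alone that vanish whenever the
CFs come from the network, for **any** branch lengths and `γ`.  A candidate
placement of the cycle is scored by the L2 norm of its invariants evaluated
at the observed CFs (the *invariant score*); the candidate closest to
vanishing fits best.  For 5–8 taxa all ordered partitions of the taxa into
four clades of size 1–2 are ranked; for more taxa, all eight-taxon subsets
are ranked jointly and the remaining taxa are grafted onto the best subset
network.  The method identifies the partition of taxa among the four clades
(not the topology within clades) and cannot orient `n1` versus `n2` — the
clade-swapped "symmetric" network is reported alongside.

## Worked example

Simulate gene-tree sampling noise on the eight-taxon reference network
(all internal branches 1.0 coalescent units, `γ = 0.3`, 1000 gene trees
per quartet), then rank all 2520 candidate cycles:

```python
from cfdiamond import (make_partition, NetworkParameters,
                       sample_gene_tree_quartets, rank_partitions, to_enewick)

truth = make_partition(["A", "B"], ["C", "D"], ["E", "F"], ["G", "H"])
params = NetworkParameters(gamma=0.3)          # all branches 1.0 coalescent units
table = sample_gene_tree_quartets(truth, params, ngenes=1000, seed=7)
ranking = rank_partitions(table)
for rank, (p, score) in enumerate(ranking.top(3), start=1):
    print(f"{rank}. score {score:.4e}  {p.text()}")
print("best eNewick:", to_enewick(ranking.entries[0][0]))
```

prints

```
1. score 2.6768e-02  n0=A,B;n1=C,D;n2=E,F;n3=G,H
2. score 2.6768e-02  n0=A,B;n1=E,F;n2=C,D;n3=G,H
3. score 2.8235e-02  n0=A,B;n1=E,F;n2=G,H;n3=C,D
best eNewick: ((C,D,(A,B)#H1),(E,F,#H1),(G,H));
```

The true partition is recovered at rank 1; rank 2 is its symmetric partner
(clades `n1`/`n2` swapped), which always receives an identical score.  The
score gap to rank 3 — a genuinely different cycle placement — is what makes
the ranking informative.  With exact (infinite-gene) CFs the top score
drops to ~1e-16 and the gap is ~1.5e-2.

The same analysis from the shell:

```sh
cfdiamond simulate --net 2222 --ngenes 1000 --seed 7 --out sim
cfdiamond infer --cf-table sim/cf_table.csv -m 5 --out results
```

which writes `ranking_top.tsv`, `ranking_full.tsv` and `top1.enewick`.
Other subcommands: `cfdiamond cf` counts CFs from Newick gene trees and
`cfdiamond invariants` dumps or re-derives the invariant set of a clade-size
signature.  An optional example script, `examples/canis_reanalysis.py`,
shows the analysis on public canid gene trees (external download).

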