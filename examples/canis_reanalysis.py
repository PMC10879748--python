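#!/usr/bin/env python
"""Optional example: hybridization in the genus Canis from public gene trees.

The genus Canis carries a well-documented introgression event: gene flow
from the ancestor of dog and grey wolf into the ancestor of the golden
jackal.  This script reproduces that finding from gene trees alone, with
six taxa: one African hunting dog (outgroup), one coyote, one dhole, one
dog, one golden jackal and one grey wolf.

The gene trees are NOT bundled with this package.  Download the canid gene
trees published with the weighted-ASTRAL dataset collection

    https://github.com/chaoszhang/Weighted-ASTRAL_data

and pass a file of Newick trees (one per line) whose leaves are the six
individuals, together with a two-column CSV mapping each individual/allele
name to one of the six taxon names.  Expected outcome: the top-ranked
four-node cycle places dog and grey wolf in one parent clade of the hybrid
golden jackal.

Usage:
    python examples/canis_reanalysis.py GENE_TREES.nwk TAXON_MAP.csv
"""

import sys
from pathlib import Path

from cfdiamond import cfs_from_gene_trees, rank_partitions, read_gene_trees, to_enewick


def main() -> None:
    if len(sys.argv) != 3:
        sys.exit(__doc__)
    trees_path, map_path = sys.argv[1], sys.argv[2]
    taxon_map = {}
    for line in Path(map_path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            ind, taxon = [p.strip() for p in line.split(",")]
            taxon_map[ind] = taxon
    trees = read_gene_trees(trees_path)
    print(f"read {len(trees)} gene trees")
    table = cfs_from_gene_trees(trees, taxon_map=taxon_map or None)
    print(f"estimated CFs for {len(table)} quartets over taxa {table.taxa}")
    ranking = rank_partitions(table)
    print("top 5 candidate hybridization cycles:")
    for rank, (p, score) in enumerate(ranking.top(5), start=1):
        print(f"  {rank}. score {score:.4e}  {p.text()}")
    best = ranking.entries[0][0]
    print("best network (eNewick):", to_enewick(best))


if __name__ == "__main__":
    main()
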