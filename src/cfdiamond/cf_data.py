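"""Concordance-factor tables: I/O, estimation from gene trees, a-vector mapping.

A CF table has one row per four-taxon set with the frequencies of its three
splits among gene trees.  Rows are canonicalized to sorted taxon order with
the split columns permuted accordingly: for a sorted quadruple
``(t1, t2, t3, t4)`` the columns are ``CF12_34 = CF(t1 t2 | t3 t4)``,
``CF13_24`` and ``CF14_23``.
"""

from __future__ import annotations

import itertools
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .coalescent import cf_system, validate_signature
from .network import CladePartition

__all__ = [
    "CFTable",
    "CFTableError",
    "read_cf_table",
    "write_cf_table",
    "read_gene_trees",
    "cfs_from_gene_trees",
    "map_to_a_vector",
]

CF_COLUMNS = ("CF12_34", "CF13_24", "CF14_23")
TAXON_COLUMNS = ("taxon1", "taxon2", "taxon3", "taxon4")


class CFTableError(ValueError):
    """Raised for malformed CF tables or missing quartet rows."""


def _canonical_row(taxa: Sequence[str], cfs: Sequence[float]):
    """Sort the four taxa and permute the three CFs to match."""
    order = sorted(range(4), key=lambda i: taxa[i])
    sq = [taxa[i] for i in order]
    # original split k pairs taxa[0] with taxa[k]; find each original
    # split's canonical index after sorting
    out = [0.0, 0.0, 0.0]
    for k, val in zip((1, 2, 3), cfs):
        pair = {taxa[0], taxa[k]}
        lead_partner = next(t for t in pair if t != sq[0]) if sq[0] in pair \
            else next(t for t in {taxa[1], taxa[2], taxa[3]} - pair if t != sq[0])
        out[sq.index(lead_partner) - 1] = float(val)
    return tuple(sq), tuple(out)


def canonical_split_index(quad: Sequence[str], pair: Iterable[str]) -> int:
    """Canonical index (1..3) of the split grouping ``pair`` in sorted ``quad``.

    Index k means the split pairs ``quad[0]`` with ``quad[k]``.
    """
    pair = set(pair)
    if quad[0] in pair:
        partner = next(t for t in pair if t != quad[0])
    else:
        partner = next(t for t in quad[1:] if t not in pair)
    return list(quad).index(partner)


class CFTable:
    """Canonicalized table of quartet concordance factors.

    Wraps a :class:`pandas.DataFrame`; construction canonicalizes row order
    and taxon order.  ``sum_tolerance`` controls the row-sum check (set to
    ``None`` for tables with additive noise, which need not lie on the
    simplex).
    """

    def __init__(self, df: pd.DataFrame, sum_tolerance: float | None = 1e-6):
        missing = [c for c in TAXON_COLUMNS + CF_COLUMNS if c not in df.columns]
        if missing:
            raise CFTableError(f"missing columns: {missing}")
        rows = []
        seen: dict[tuple[str, ...], int] = {}
        for i, row in enumerate(df.itertuples(index=False)):
            taxa = [str(getattr(row, c)) for c in TAXON_COLUMNS]
            if len(set(taxa)) != 4:
                raise CFTableError(f"row {i}: duplicate taxon in quadruple {taxa}")
            try:
                cfs = [float(getattr(row, c)) for c in CF_COLUMNS]
            except (TypeError, ValueError):
                raise CFTableError(f"row {i}: non-numeric CF value")
            if any(not 0.0 <= v <= 1.0 for v in cfs):
                raise CFTableError(f"row {i}: CF outside [0, 1]: {cfs}")
            quad, canon = _canonical_row(taxa, cfs)
            if quad in seen:
                raise CFTableError(
                    f"row {i}: duplicate quadruple {quad} (first at row {seen[quad]})"
                )
            seen[quad] = i
            if sum_tolerance is not None and abs(sum(canon) - 1.0) > sum_tolerance:
                raise CFTableError(
                    f"row {i}: CFs sum to {sum(canon):.6g}, not 1"
                )
            rec = dict(zip(TAXON_COLUMNS, quad))
            rec.update(zip(CF_COLUMNS, canon))
            if "ngenes" in df.columns:
                rec["ngenes"] = getattr(row, "ngenes")
            rows.append(rec)
        out = pd.DataFrame(rows).sort_values(list(TAXON_COLUMNS))
        self.df = out.reset_index(drop=True)
        self._index: dict[frozenset, int] = {
            frozenset(q): i
            for i, q in enumerate(
                self.df[list(TAXON_COLUMNS)].itertuples(index=False)
            )
        }
        self._values = self.df[list(CF_COLUMNS)].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def taxa(self) -> tuple[str, ...]:
        labels: set[str] = set()
        for c in TAXON_COLUMNS:
            labels.update(self.df[c])
        return tuple(sorted(labels))

    def quad_row(self, quad: Iterable[str]) -> np.ndarray:
        """The canonical CF triple of a four-taxon set."""
        key = frozenset(quad)
        if key not in self._index:
            raise CFTableError(f"no CF row for quadruple {tuple(sorted(key))}")
        return self._values[self._index[key]]

    def has_quad(self, quad: Iterable[str]) -> bool:
        return frozenset(quad) in self._index

    def values_for(self, quads: Sequence[tuple[str, ...]]) -> np.ndarray:
        """Stacked canonical triples for a list of sorted quadruples."""
        idx = []
        for q in quads:
            key = frozenset(q)
            if key not in self._index:
                raise CFTableError(f"no CF row for quadruple {tuple(sorted(key))}")
            idx.append(self._index[key])
        return self._values[np.asarray(idx, dtype=int)]


def read_cf_table(path: str | Path, sum_tolerance: float | None = 1e-6) -> CFTable:
    """Read a CF table from CSV (columns taxon1..taxon4, CF12_34..CF14_23)."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise CFTableError(f"cannot read CF table {path}: {exc}")
    return CFTable(df, sum_tolerance=sum_tolerance)


def write_cf_table(table: CFTable, path: str | Path) -> None:
    """Write a canonical CF table to CSV, lossless to 12 significant digits."""
    table.df.to_csv(path, index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# gene trees


def read_gene_trees(path: str | Path) -> list[str]:
    """Read Newick gene trees, one per line; blank lines are skipped."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line:
            out.append(line)
    return out


def _tree_bipartitions(newick: str, taxon_map: dict[str, str] | None):
    """Leaf set and internal bipartitions (as frozensets) of one gene tree."""
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick")
    labels = []
    for leaf in tree.leaf_node_iter():
        lab = leaf.taxon.label if leaf.taxon else leaf.label
        if taxon_map is not None:
            lab = taxon_map.get(lab, lab)
        labels.append(lab)
        leaf.annotations["cf_label"] = lab
    if len(set(labels)) != len(labels):
        raise CFTableError(
            "gene tree has duplicate leaf labels after taxon mapping"
        )
    splits: list[frozenset] = []
    full = frozenset(labels)

    def collect(node) -> frozenset:
        if node.is_leaf():
            return frozenset([node.annotations["cf_label"].value])
        below = frozenset().union(*(collect(ch) for ch in node.child_nodes()))
        if 1 < len(below) < len(labels) - 1:
            splits.append(below)
        return below

    collect(tree.seed_node)
    return full, splits


def cfs_from_gene_trees(
    trees: Iterable[str],
    taxa: Iterable[str] | None = None,
    taxon_map: dict[str, str] | None = None,
) -> CFTable:
    """Estimate CFs as split frequencies over gene trees.

    For every four-taxon subset, counts each split among trees that contain
    all four leaves and resolve the quartet; unresolved quartets (polytomies)
    contribute to no denominator.  Quartets with zero informative trees are
    omitted with a warning.  ``taxon_map`` translates leaf labels (e.g.
    individual/allele names) to analysis taxon names before counting.
    """
    trees = list(trees)
    if not trees:
        raise CFTableError("no gene trees given")
    parsed = [_tree_bipartitions(t, taxon_map) for t in trees]
    if taxa is None:
        all_taxa: set[str] = set()
        for full, _ in parsed:
            all_taxa |= full
        taxa = sorted(all_taxa)
    else:
        taxa = sorted(taxa)
    counts: dict[tuple[str, ...], np.ndarray] = {}
    denom: dict[tuple[str, ...], int] = {}
    quads = [tuple(q) for q in itertools.combinations(taxa, 4)]
    for full, splits in parsed:
        for quad in quads:
            if not set(quad) <= full:
                continue
            for split in splits:
                inter = [t for t in quad if t in split]
                if len(inter) == 2:
                    k = canonical_split_index(quad, inter)
                    counts.setdefault(quad, np.zeros(3))[k - 1] += 1
                    denom[quad] = denom.get(quad, 0) + 1
                    break
    rows = []
    for quad in quads:
        if quad not in counts:
            warnings.warn(f"no informative gene tree for quartet {quad}; row omitted")
            continue
        freq = counts[quad] / denom[quad]
        rec = dict(zip(TAXON_COLUMNS, quad))
        rec.update(zip(CF_COLUMNS, freq))
        rec["ngenes"] = denom[quad]
        rows.append(rec)
    if not rows:
        raise CFTableError("no quartet had an informative gene tree")
    return CFTable(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# mapping observed CFs onto a candidate partition


def class_realizations(p: CladePartition, cls: Sequence[int]):
    """All ways of drawing the class's taxa from the partition's clades.

    Yields tuples of (taxon, clade) pairs in clade order.
    """
    pools = []
    for clade, count in enumerate(cls):
        pools.append(list(itertools.combinations(p.clades[clade], count)))
    for combo in itertools.product(*pools):
        chosen: list[tuple[str, int]] = []
        for clade, taxa in enumerate(combo):
            chosen.extend((t, clade) for t in taxa)
        yield chosen


def realization_slot_splits(chosen: list[tuple[str, int]]) -> tuple[tuple[str, ...], tuple[int, int, int]]:
    """Sorted quadruple and canonical split index of each CF slot.

    Slot 1 is the split predicted by the class (same-clade pairs grouped;
    for class (1,1,1,1), clade 0 with clade 1).  For classes with a
    same-clade pair the two remaining splits fill slots 2 and 3 in canonical
    (label) order; for class (1,1,1,1) slots 2 and 3 pair the hybrid-clade
    taxon with the clade-2 and clade-3 taxon respectively.
    """
    quad = tuple(sorted(t for t, _ in chosen))
    by_clade: dict[int, list[str]] = {}
    for t, c in chosen:
        by_clade.setdefault(c, []).append(t)
    pair_clades = [c for c, ts in by_clade.items() if len(ts) == 2]
    if pair_clades:
        k1 = canonical_split_index(quad, by_clade[pair_clades[0]])
        rest = [k for k in (1, 2, 3) if k != k1]
        return quad, (k1, rest[0], rest[1])
    clades = sorted(by_clade)  # four distinct clades drawn
    t0 = by_clade[clades[0]][0]
    slots = tuple(
        canonical_split_index(quad, (t0, by_clade[clades[s]][0]))
        for s in (1, 2, 3)
    )
    return quad, slots  # type: ignore[return-value]


def map_to_a_vector(table: CFTable, p: CladePartition) -> np.ndarray:
    """Observed a-vector of a candidate partition.

    For each informative class of the partition's signature, the three
    observed CFs of every realization are assigned to slots via the slot
    convention and averaged per slot across realizations.  Raises
    :class:`CFTableError` listing the quadruple if a required row is absent.
    """
    sig = validate_signature(p.signature)
    system = cf_system(sig)
    a = np.zeros(system.n_a)
    for ci, cls in enumerate(system.classes):
        acc = np.zeros(3)
        n = 0
        for chosen in class_realizations(p, cls):
            quad, slots = realization_slot_splits(chosen)
            row = table.quad_row(quad)
            acc += row[np.array(slots) - 1]
            n += 1
        a[3 * ci: 3 * ci + 3] = acc / n
    return a
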