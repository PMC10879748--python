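"""Synthetic data generation: the simulation study's inputs.

Generates every input the inference pipeline consumes: exact CF tables on a
given network, Gaussian-perturbed tables, multinomial gene-tree quartet
samples, and full coalescent gene trees in Newick.  Default conditions match
the simulation study design: every internal branch 1.0 coalescent unit and
inheritance probability 0.3; Gaussian noise levels 5e-4, 5e-5, 5e-6;
gene-tree counts 100, 1000, 10000; 30 replicates.

Within-clade topology for clades of three taxa (used by the >8-taxon
networks) is a caterpillar over the sorted taxon labels whose internal
branch is also 1.0 coalescent units.  Pendant edge lengths never enter any
CF formula and are irrelevant to quartet topology frequencies.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
import sympy as sp

from .cf_data import (
    CF_COLUMNS,
    TAXON_COLUMNS,
    CFTable,
    canonical_split_index,
    realization_slot_splits,
)
from .coalescent import (
    PARAM_SYMBOLS,
    NetworkParameters,
    cf_polynomials,
    tree_quartet_cf,
)
from .network import CladePartition

__all__ = [
    "SimulationConfig",
    "true_cf_table",
    "perturb_gaussian",
    "sample_gene_tree_quartets",
    "simulate_gene_trees",
]


@dataclass(frozen=True)
class SimulationConfig:
    """One simulation setting: network, parameters, noise and sample sizes."""

    partition: CladePartition
    parameters: NetworkParameters = field(default_factory=NetworkParameters)
    sigma: float = 0.0
    ngenes: int = 0
    replicates: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


_CLASS_FN_CACHE: dict[tuple[int, int, int, int], object] = {}


def _class_fn(cls: tuple[int, int, int, int]):
    if cls not in _CLASS_FN_CACHE:
        _CLASS_FN_CACHE[cls] = sp.lambdify(
            PARAM_SYMBOLS, list(cf_polynomials(cls)), modules="numpy"
        )
    return _CLASS_FN_CACHE[cls]


def _cherry_pair(clade: Sequence[str]) -> tuple[str, str]:
    """The cherry of a caterpillar clade: its two first sorted taxa."""
    ordered = sorted(clade)
    return ordered[0], ordered[1]


def _effective_stem(
    clade: Sequence[str], drawn: Sequence[str], stem: float, internal: float
) -> float:
    """Stem length from the drawn pair's junction to the cycle node.

    For one- and two-taxon clades this is the clade stem itself.  In a
    three-taxon caterpillar clade the cherry pair sits one internal branch
    deeper than the third taxon, so drawing the cherry adds that branch.
    """
    if len(clade) <= 2 or len(drawn) < 2:
        return stem
    if set(drawn) == set(_cherry_pair(clade)):
        return stem + internal
    return stem


def _quad_cfs(
    p: CladePartition,
    params: NetworkParameters,
    quad: Sequence[str],
    internal: float,
) -> np.ndarray:
    """Exact canonical CF triple of one four-taxon set on the network."""
    quad = tuple(sorted(quad))
    by_clade: dict[int, list[str]] = {}
    for t in quad:
        by_clade.setdefault(p.clade_of(t), []).append(t)
    counts = [len(by_clade.get(i, [])) for i in range(4)]
    if max(counts) >= 3:
        # three (or more) taxa from one clade: the cycle is pendant to this
        # quartet and only the within-clade caterpillar branch separates it
        clade_idx = counts.index(max(counts))
        members = by_clade[clade_idx]
        if max(counts) == 4:
            raise ValueError(
                "four taxa from a single clade need resolved within-clade "
                "topology beyond a three-taxon caterpillar"
            )
        cherry = _cherry_pair(p.clades[clade_idx])
        major, minor, _ = tree_quartet_cf(internal)
        out = np.full(3, minor)
        out[canonical_split_index(quad, cherry) - 1] = major
        return out
    cls = tuple(counts)
    stems = {
        0: params.t0, 1: params.t1, 2: params.t2, 3: params.t3,
    }
    eff = {
        i: _effective_stem(p.clades[i], by_clade.get(i, []), stems[i], internal)
        for i in range(4)
    }
    adj = replace(params, t0=eff[0], t1=eff[1], t2=eff[2], t3=eff[3])
    vals = np.asarray(_class_fn(cls)(*adj.z_values()), dtype=float)
    chosen = [(t, c) for c, ts in sorted(by_clade.items()) for t in ts]
    squad, slots = realization_slot_splits(chosen)
    assert squad == quad
    out = np.empty(3)
    for slot_val, k in zip(vals, slots):
        out[k - 1] = slot_val
    return out


def true_cf_table(
    p: CladePartition,
    params: NetworkParameters | None = None,
    internal: float = 1.0,
) -> CFTable:
    """Exact CF table of a network: one row per four-taxon subset.

    Quartets drawing at most two taxa per clade are evaluated with the
    class CF polynomials (with stems adjusted for the drawn pair's position
    inside three-taxon clades); quartets drawing three taxa from one clade
    see only the within-clade caterpillar branch and get tree CFs.  The
    resulting table is complete: feeding it to the ranking recovers the true
    partition (or its symmetric partner) at rank 1.
    """
    params = params or NetworkParameters()
    rows = []
    for quad in itertools.combinations(p.taxa, 4):
        cfs = _quad_cfs(p, params, quad, internal)
        rec = dict(zip(TAXON_COLUMNS, quad))
        rec.update(zip(CF_COLUMNS, cfs))
        rows.append(rec)
    return CFTable(pd.DataFrame(rows))


def perturb_gaussian(
    table: CFTable,
    sigma: float,
    seed: int,
    renormalize: bool = False,
) -> CFTable:
    """Add independent zero-mean Gaussian noise to every CF entry.

    Values are clipped to [0, 1]; triples are not renormalized by default
    (the study's noise levels are tiny, so perturbed triples stay near the
    simplex), and the row-sum check is relaxed on the result.  With
    ``renormalize=True`` each triple is rescaled to sum to one.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    df = table.df.copy()
    vals = df[list(CF_COLUMNS)].to_numpy(dtype=float)
    vals = np.clip(vals + rng.normal(0.0, sigma, size=vals.shape), 0.0, 1.0)
    if renormalize:
        vals = vals / vals.sum(axis=1, keepdims=True)
    df[list(CF_COLUMNS)] = vals
    return CFTable(df, sum_tolerance=None)


def sample_gene_tree_quartets(
    p: CladePartition,
    params: NetworkParameters | None = None,
    ngenes: int = 1000,
    seed: int = 0,
    internal: float = 1.0,
) -> CFTable:
    """CF table from multinomial gene-tree quartet counts.

    For every quartet, ``ngenes`` gene trees are drawn multinomially from
    the exact CF triple and converted to frequencies.  Quartets are sampled
    independently — a light-weight emulation of gene-tree sampling noise
    that matches its per-quartet marginal distribution (use
    :func:`simulate_gene_trees` when correlation of quartets within a gene
    matters).
    """
    if ngenes < 1:
        raise ValueError("ngenes must be >= 1")
    params = params or NetworkParameters()
    rng = np.random.default_rng(seed)
    exact = true_cf_table(p, params, internal=internal)
    df = exact.df.copy()
    vals = df[list(CF_COLUMNS)].to_numpy(dtype=float)
    sampled = np.stack([
        rng.multinomial(ngenes, row / row.sum()) / ngenes for row in vals
    ])
    df[list(CF_COLUMNS)] = sampled
    df["ngenes"] = ngenes
    return CFTable(df)


# ---------------------------------------------------------------------------
# full coalescent gene trees


def _coalesce_pop(
    lineages: list[str], length: float, rng: np.random.Generator
) -> list[str]:
    """Coalescent within one population edge; merges build Newick strings."""
    pool = list(lineages)
    t = 0.0
    while len(pool) >= 2:
        k = len(pool)
        t += rng.exponential(2.0 / (k * (k - 1)))
        if t > length:
            break
        i, j = sorted(rng.choice(k, size=2, replace=False))
        b = pool.pop(j)
        a = pool.pop(i)
        pool.append(f"({a},{b})")
    return pool


def simulate_gene_trees(
    p: CladePartition,
    params: NetworkParameters | None = None,
    ngenes: int = 1000,
    seed: int = 0,
    internal: float = 1.0,
) -> list[str]:
    """Simulate full coalescent gene trees on the rooted network.

    The network is rooted at the cycle node ``v3``.  Per gene, every lineage
    reaching the hybrid node independently follows the ``h-v1`` edge with
    probability ``gamma``; within each edge lineages coalesce pairwise at
    rate 1.  Clades of three taxa are caterpillars over sorted labels with
    an internal branch of ``internal`` coalescent units.  Returns topology
    Newick strings (one per gene); quartet frequencies counted from the
    output agree with the exact CF polynomials within sampling error, and
    quartets within one gene tree are correlated, unlike
    :func:`sample_gene_tree_quartets`.
    """
    if ngenes < 1:
        raise ValueError("ngenes must be >= 1")
    params = params or NetworkParameters()
    if max(p.signature) > 3:
        raise ValueError("clades of more than three taxa are not supported")
    rng = np.random.default_rng(seed)
    stems = (params.t0, params.t1, params.t2, params.t3)
    out = []
    for _ in range(ngenes):
        at_cycle: dict[int, list[str]] = {}
        for ci, clade in enumerate(p.clades):
            members = sorted(clade)
            if len(members) == 3:
                # cherry pair may coalesce on the caterpillar branch first
                pool = _coalesce_pop(members[:2], internal, rng) + [members[2]]
            else:
                pool = list(members)
            # clade root population: the stem edge
            at_cycle[ci] = _coalesce_pop(pool, stems[ci], rng)
        to_v1 = [l for l in at_cycle[0] if rng.random() < params.gamma]
        to_v2 = [l for l in at_cycle[0] if l not in to_v1]
        to_v1 = _coalesce_pop(to_v1, params.t01, rng)
        to_v2 = _coalesce_pop(to_v2, params.t02, rng)
        at_v1 = _coalesce_pop(at_cycle[1] + to_v1, params.t13, rng)
        at_v2 = _coalesce_pop(at_cycle[2] + to_v2, params.t23, rng)
        root_pool = at_v1 + at_v2 + at_cycle[3]
        while len(root_pool) > 1:
            i, j = sorted(rng.choice(len(root_pool), size=2, replace=False))
            b = root_pool.pop(j)
            a = root_pool.pop(i)
            root_pool.append(f"({a},{b})")
        out.append(root_pool[0] + ";")
    return out
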