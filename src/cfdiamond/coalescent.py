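"""Quartet concordance factors under the coalescent on the reference network.

The reference network has four clades hanging off a four-node hybridization
cycle ``h - v1 - v3 - v2 - h``.  Clade ``i`` is a two-leaf cherry whose stem
(cherry node to cycle node) has length ``t_i`` in coalescent units; the
hybrid clade (0) attaches below the hybrid node ``h``; ``t01``/``t02`` are
the hybrid-edge lengths ``h-v1``/``h-v2``; ``t13``/``t23`` the cycle edges
``v1-v3``/``v2-v3``.  A lineage entering ``h`` follows ``h-v1`` with the
inheritance probability ``gamma`` and ``h-v2`` otherwise.

A *quartet class* ``(i, j, k, l)`` records how many of the four sampled taxa
come from each clade.  Its three concordance factors are polynomials in
``z_e = exp(-t_e)`` and ``gamma``, obtained by scenario enumeration:

1. if both hybrid-clade lineages are sampled, they either coalesce on the
   clade-0 stem (probability ``1 - z0``, which fixes the quartet split) or
   survive (``z0``);
2. each surviving lineage entering ``h`` independently follows one hybrid
   edge;
3. conditional on a scenario the network resolves to a species tree, whose
   quartet split probabilities are ``1 - (2/3) e^{-T}`` for the split
   matching the tree and ``(1/3) e^{-T}`` for the other two, where ``T`` is
   the total length of internal edges separating the four lineages 2|2;
4. the class CF is the probability-weighted sum over scenarios.

Only internal branch lengths enter the formulas; pendant edges never appear.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import sympy as sp

__all__ = [
    "PARAM_SYMBOLS",
    "NetworkParameters",
    "QuartetClassError",
    "informative_classes",
    "class_slot_splits",
    "cf_polynomials",
    "CFSystem",
    "cf_system",
    "evaluate_cfs",
    "mc_quartet_cfs",
    "tree_quartet_cf",
]

#: The nine model parameters of the CF system, in canonical order.
z0, z1, z2, z3, z01, z02, z13, z23, g = sp.symbols(
    "z0 z1 z2 z3 z01 z02 z13 z23 g", positive=True
)
PARAM_SYMBOLS: tuple[sp.Symbol, ...] = (z0, z1, z2, z3, z01, z02, z13, z23, g)

_STEM = {1: z1, 2: z2, 3: z3}


class QuartetClassError(ValueError):
    """Raised for quartet-class vectors invalid on a signature."""


@dataclass(frozen=True)
class NetworkParameters:
    """Branch lengths (coalescent units) and inheritance probability.

    ``t0..t3`` are the clade stems, ``t01``/``t02`` the hybrid edges and
    ``t13``/``t23`` the cycle edges; ``gamma`` is the probability that a
    lineage entering the hybrid node follows the ``h-v1`` edge.
    """

    t0: float = 1.0
    t1: float = 1.0
    t2: float = 1.0
    t3: float = 1.0
    t01: float = 1.0
    t02: float = 1.0
    t13: float = 1.0
    t23: float = 1.0
    gamma: float = 0.3

    def __post_init__(self) -> None:
        for name in ("t0", "t1", "t2", "t3", "t01", "t02", "t13", "t23"):
            if getattr(self, name) < 0:
                raise ValueError(f"branch length {name} must be >= 0")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must lie in [0, 1]")

    def z_values(self) -> np.ndarray:
        """Values of (z0, z1, z2, z3, z01, z02, z13, z23, g)."""
        ts = (self.t0, self.t1, self.t2, self.t3,
              self.t01, self.t02, self.t13, self.t23)
        return np.array([*(np.exp(-t) for t in ts), self.gamma])


def validate_signature(sig: Sequence[int]) -> tuple[int, int, int, int]:
    sig = tuple(int(s) for s in sig)
    if len(sig) != 4 or any(s < 1 for s in sig):
        raise QuartetClassError(f"invalid signature {sig}")
    return sig  # type: ignore[return-value]


def informative_classes(sig: Sequence[int]) -> list[tuple[int, int, int, int]]:
    """Quartet classes carrying information about the hybridization cycle.

    All vectors ``(i, j, k, l)`` with entries in {0, 1, 2}, each entry at most
    the clade size, summing to 4 — quartets drawing three or more taxa from
    one clade only see pendant branches of the cycle.  Sorted
    lexicographically.  The reference signature (2,2,2,2) has 19 classes.
    """
    sig = validate_signature(sig)
    out = []
    for vec in itertools.product(range(3), repeat=4):
        if sum(vec) == 4 and all(v <= min(2, s) for v, s in zip(vec, sig)):
            out.append(vec)
    return sorted(out)


def _leaves_of_class(cls: Sequence[int]) -> list[int]:
    """Clade of origin for each of the four sampled lineages, in order."""
    leaves: list[int] = []
    for clade, count in enumerate(cls):
        leaves.extend([clade] * count)
    return leaves


def class_slot_splits(cls: Sequence[int]) -> tuple[int, int, int]:
    """Map CF slots to splits, as split indices ``k`` meaning ``{0,k}|rest``.

    Lineages are indexed 0..3 in clade order.  For classes containing a
    same-clade pair, slot 1 is the split grouping same-clade pairs; the two
    remaining splits fill slots 2 and 3 in index order (their CFs are equal
    by exchangeability of same-clade lineages).  For class (1,1,1,1), slot
    ``s`` pairs the clade-0 taxon with the clade-``s`` taxon.
    """
    cls = tuple(cls)
    leaves = _leaves_of_class(cls)
    if len(leaves) != 4:
        raise QuartetClassError(f"class {cls} does not draw four taxa")
    if max(cls) == 1:
        return (1, 2, 3)
    # find the split grouping every same-clade pair together
    for k in (1, 2, 3):
        sides = ({0, k}, {1, 2, 3} - {k})
        ok = all(
            any({a, b} <= side for side in sides)
            for a, b in itertools.combinations(range(4), 2)
            if leaves[a] == leaves[b]
        )
        if ok:
            rest = [j for j in (1, 2, 3) if j != k]
            return (k, rest[0], rest[1])
    raise QuartetClassError(f"no pair-grouping split for class {cls}")


# ---------------------------------------------------------------------------
# scenario trees


class _ScenarioTree:
    """Tiny weighted tree: the network resolved for one hybrid scenario."""

    def __init__(self) -> None:
        self.edges: list[tuple[str, str, sp.Expr]] = []
        self.leaf_at: dict[int, str] = {}

    def add_edge(self, a: str, b: str, weight: sp.Expr) -> None:
        self.edges.append((a, b, weight))

    def place(self, leaf: int, node: str) -> None:
        self.leaf_at[leaf] = node

    def split_weight(self, pair: tuple[int, int]) -> sp.Expr | None:
        """Product of ``exp(-t)`` over edges separating ``pair`` 2|2.

        Returns None if no edge induces the split (probability of that split
        is then a minor ``(1/3) e^{-T}`` of whichever split is induced).
        """
        others = tuple(l for l in self.leaf_at if l not in pair)
        sep: list[sp.Expr] = []
        for i, (a, b, w) in enumerate(self.edges):
            side = self._component_without(i, a)
            pair_in = [self.leaf_at[l] in side for l in pair]
            oth_in = [self.leaf_at[l] in side for l in others]
            if (all(pair_in) and not any(oth_in)) or (
                not any(pair_in) and all(oth_in)
            ):
                sep.append(w)
        if not sep:
            return None
        return sp.Mul(*sep)

    def _component_without(self, edge_idx: int, start: str) -> set[str]:
        adj: dict[str, list[str]] = {}
        for i, (a, b, _) in enumerate(self.edges):
            if i == edge_idx:
                continue
            adj.setdefault(a, []).append(b)
            adj.setdefault(b, []).append(a)
        seen = {start}
        stack = [start]
        while stack:
            for nb in adj.get(stack.pop(), []):
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        return seen

    def split_probs(self) -> dict[int, sp.Expr]:
        """Probability of each split ``k in {1,2,3}`` on this species tree."""
        probs: dict[int, sp.Expr] = {}
        induced = None
        weight = None
        for k in (1, 2, 3):
            w = self.split_weight((0, k))
            if w is not None:
                induced, weight = k, w
                break
        if induced is None:  # star tree
            return {1: sp.Rational(1, 3), 2: sp.Rational(1, 3), 3: sp.Rational(1, 3)}
        for k in (1, 2, 3):
            if k == induced:
                probs[k] = 1 - sp.Rational(2, 3) * weight
            else:
                probs[k] = sp.Rational(1, 3) * weight
        return probs


def _base_tree(cls: Sequence[int]) -> _ScenarioTree:
    """Scenario tree skeleton: cycle path v1-v3-v2 plus non-hybrid clades."""
    tree = _ScenarioTree()
    tree.add_edge("v1", "v3", z13)
    tree.add_edge("v3", "v2", z23)
    leaf = cls[0]  # clade-0 lineages occupy leaf indices 0..cls[0]-1
    for clade in (1, 2, 3):
        node = f"v{clade}"
        if cls[clade] == 2:
            junction = f"J{clade}"
            tree.add_edge(junction, node, _STEM[clade])
            tree.place(leaf, junction)
            tree.place(leaf + 1, junction)
            leaf += 2
        elif cls[clade] == 1:
            tree.place(leaf, node)
            leaf += 1
    return tree


def _hybrid_scenarios(cls: Sequence[int]):
    """Yield ``(probability, tree_or_none)`` over hybrid-lineage scenarios.

    ``None`` marks the scenario where the sampled clade-0 pair coalesces on
    its own stem, which fixes the quartet split outright.
    """
    c0 = cls[0]
    if c0 == 0:
        yield sp.Integer(1), _base_tree(cls)
        return
    if c0 == 1:
        for choice, prob in (("v1", g), ("v2", 1 - g)):
            tree = _base_tree(cls)
            tree.place(0, choice)
            yield prob, tree
        return
    # two hybrid-clade lineages: condition on coalescence on the stem
    yield 1 - z0, None
    for e1, e2 in itertools.product(("v1", "v2"), repeat=2):
        prob = z0 * (g if e1 == "v1" else 1 - g) * (g if e2 == "v1" else 1 - g)
        tree = _base_tree(cls)
        if e1 == e2:
            hz = z01 if e1 == "v1" else z02
            tree.add_edge("h", e1, hz)
            tree.place(0, "h")
            tree.place(1, "h")
        else:
            tree.place(0, e1)
            tree.place(1, e2)
        yield prob, tree


def cf_polynomials(cls: Sequence[int]) -> tuple[sp.Expr, sp.Expr, sp.Expr]:
    """The three CF polynomials of a quartet class, in slot order.

    Polynomials are in the nine parameter symbols and sum identically to 1.
    Example: class (0,0,2,2) gives ``1 - (2/3) z2 z23 z3`` in slot 1 and
    ``(1/3) z2 z23 z3`` in slots 2 and 3.
    """
    cls = tuple(int(c) for c in cls)
    if len(cls) != 4 or sum(cls) != 4 or any(not 0 <= c <= 2 for c in cls):
        raise QuartetClassError(f"invalid quartet class {cls}")
    slots = class_slot_splits(cls)
    acc = {1: sp.Integer(0), 2: sp.Integer(0), 3: sp.Integer(0)}
    for prob, tree in _hybrid_scenarios(cls):
        if tree is None:  # coalesced clade-0 pair: split fixed to slot 1
            acc[slots[0]] += prob
            continue
        for k, p in tree.split_probs().items():
            acc[k] += prob * p
    return tuple(sp.expand(acc[k]) for k in slots)  # type: ignore[return-value]


@dataclass(frozen=True)
class CFSystem:
    """The polynomial map ``a_i = f_i(z, gamma)`` for one signature.

    ``polys[3 * c + s]`` is the slot-``s+1`` CF of ``classes[c]``; classes
    are in lexicographic order, so the a-index map is canonical.
    """

    signature: tuple[int, int, int, int]
    classes: tuple[tuple[int, int, int, int], ...]
    polys: tuple[sp.Expr, ...]

    @property
    def n_a(self) -> int:
        return len(self.polys)

    def a_index(self, cls: Sequence[int], slot: int) -> int:
        """Flat a-index of ``(class, slot)`` with slot in {1, 2, 3}."""
        return 3 * self.classes.index(tuple(cls)) + (slot - 1)

    def parameter_symbols(self) -> set[sp.Symbol]:
        syms: set[sp.Symbol] = set()
        for p in self.polys:
            syms |= p.free_symbols
        return syms


_SYSTEM_CACHE: dict[tuple[int, int, int, int], CFSystem] = {}
_LAMBDA_CACHE: dict[tuple[int, int, int, int], object] = {}


def cf_system(sig: Sequence[int]) -> CFSystem:
    """Assemble the CF polynomial system for a signature (cached)."""
    sig = validate_signature(sig)
    if sig not in _SYSTEM_CACHE:
        classes = tuple(informative_classes(sig))
        polys: list[sp.Expr] = []
        for cls in classes:
            polys.extend(cf_polynomials(cls))
        _SYSTEM_CACHE[sig] = CFSystem(signature=sig, classes=classes,
                                      polys=tuple(polys))
    return _SYSTEM_CACHE[sig]


def _system_fn(sig: tuple[int, int, int, int]):
    if sig not in _LAMBDA_CACHE:
        system = cf_system(sig)
        _LAMBDA_CACHE[sig] = sp.lambdify(
            PARAM_SYMBOLS, list(system.polys), modules="numpy"
        )
    return _LAMBDA_CACHE[sig]


def evaluate_cfs(sig: Sequence[int], params: NetworkParameters) -> np.ndarray:
    """Numeric a-vector of the CF system at the given parameters."""
    sig = validate_signature(sig)
    fn = _system_fn(sig)
    return np.asarray(fn(*params.z_values()), dtype=float)


def evaluate_cfs_at(sig: Sequence[int], z_gamma: np.ndarray) -> np.ndarray:
    """Vectorized evaluation at raw ``(z..., gamma)`` rows.

    ``z_gamma`` has shape (9,) or (n, 9); returns shape (n_a,) or (n, n_a).
    """
    sig = validate_signature(sig)
    fn = _system_fn(sig)
    arr = np.asarray(z_gamma, dtype=float)
    out = np.asarray(fn(*(arr[..., i] for i in range(9))), dtype=float)
    return np.moveaxis(out, 0, -1)


def tree_quartet_cf(internal_length: float) -> tuple[float, float, float]:
    """Gene-quartet probabilities on a species tree: the displayed-tree limit.

    ``internal_length`` is the total internal path separating the quartet 2|2.
    """
    w = float(np.exp(-internal_length))
    return (1 - 2 * w / 3, w / 3, w / 3)


# ---------------------------------------------------------------------------
# Monte-Carlo coalescent oracle


def mc_quartet_cfs(
    cls: Sequence[int],
    params: NetworkParameters,
    nsim: int,
    seed: int,
) -> tuple[float, float, float]:
    """Empirical CF triple from coalescent simulation on the rooted network.

    The network is rooted at the cycle node ``v3`` (any admissible root gives
    identical unrooted quartet frequencies).  Each simulated gene draws the
    hybrid-edge choice of every clade-0 lineage independently with
    probability ``gamma``; lineages coalesce pairwise at rate 1 within each
    edge.  The returned triple is in the slot order of
    :func:`cf_polynomials`; reproducible given ``seed``.
    """
    cls = tuple(int(c) for c in cls)
    if nsim < 1:
        raise ValueError("nsim must be >= 1")
    slots = class_slot_splits(cls)
    slot_of_split = {split: slot for slot, split in enumerate(slots)}
    rng = np.random.default_rng(seed)
    counts = [0, 0, 0]
    leaves = _leaves_of_class(cls)
    clade_members = {
        c: [i for i, l in enumerate(leaves) if l == c] for c in range(4)
    }
    for _ in range(nsim):
        pair = _simulate_first_coalescence(cls, clade_members, params, rng)
        if 0 in pair:
            split = pair[0] if pair[0] != 0 else pair[1]
        else:
            split = next(k for k in (1, 2, 3) if k not in pair)
        counts[slot_of_split[split]] += 1
    return tuple(c / nsim for c in counts)  # type: ignore[return-value]


def _coalesce_on_edge(members: list[int], length: float, rng) -> tuple[int, int] | None:
    """First coalescing pair among co-located lineages on a finite edge."""
    k = len(members)
    t = 0.0
    while k >= 2:
        t += rng.exponential(1.0 / (k * (k - 1) / 2))
        if t > length:
            return None
        i, j = rng.choice(k, size=2, replace=False)
        return (members[min(i, j)], members[max(i, j)])
    return None


def _simulate_first_coalescence(cls, clade_members, params: NetworkParameters, rng):
    """Identity of the first-coalescing leaf pair (fixes the quartet split)."""
    # clade stems
    for clade, stem in ((1, params.t1), (2, params.t2), (3, params.t3)):
        if cls[clade] == 2:
            pair = _coalesce_on_edge(clade_members[clade], stem, rng)
            if pair is not None:
                return pair
    h_lineages = list(clade_members[0])
    if len(h_lineages) == 2:
        pair = _coalesce_on_edge(h_lineages, params.t0, rng)
        if pair is not None:
            return pair
    to_v1 = [l for l in h_lineages if rng.random() < params.gamma]
    to_v2 = [l for l in h_lineages if l not in to_v1]
    if len(to_v1) == 2:
        pair = _coalesce_on_edge(to_v1, params.t01, rng)
        if pair is not None:
            return pair
    if len(to_v2) == 2:
        pair = _coalesce_on_edge(to_v2, params.t02, rng)
        if pair is not None:
            return pair
    at_v1 = clade_members[1] + to_v1
    at_v2 = clade_members[2] + to_v2
    pair = _coalesce_on_edge(at_v1, params.t13, rng)
    if pair is not None:
        return pair
    pair = _coalesce_on_edge(at_v2, params.t23, rng)
    if pair is not None:
        return pair
    root = at_v1 + at_v2 + clade_members[3]
    i, j = rng.choice(len(root), size=2, replace=False)
    return (root[min(i, j)], root[max(i, j)])
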