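"""Candidate networks as ordered clade partitions.

A level-1 network with a single four-node hybridization cycle is determined,
up to topology within clades, by an ordered partition of the taxa into four
nonempty clades:

* clade 0 — the hybrid clade, attached below the hybrid node ``h``;
* clades 1 and 2 — attached to the two parents of ``h`` (``v1`` and ``v2``);
* clade 3 — attached to the cycle node opposite the hybrid (``v3``).

Swapping clades 1 and 2 yields the *symmetric* network, which is nearly
indistinguishable from the original because both parent clades feed the
hybrid node; candidate enumeration keeps both members of every symmetric
pair so downstream ranking can report them separately.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass
from typing import Iterable, Sequence


class PartitionError(ValueError):
    """Raised when a clade partition is structurally invalid."""


#: Signatures for which invariant sets exist: every clade holds 1 or 2 taxa
#: and the total number of taxa is between 5 and 8.
def is_supported_signature(sizes: Sequence[int]) -> bool:
    return (
        len(sizes) == 4
        and all(s in (1, 2) for s in sizes)
        and 5 <= sum(sizes) <= 8
    )


def supported_signatures() -> list[tuple[int, int, int, int]]:
    """All 15 clade-size signatures with entries in {1,2} and 5-8 taxa."""
    return [
        s
        for s in itertools.product((1, 2), repeat=4)
        if 5 <= sum(s) <= 8
    ]


@dataclass(frozen=True)
class CladePartition:
    """Ordered assignment of taxa to the four clades of the cycle.

    ``clades[0]`` is the hybrid clade, ``clades[1]``/``clades[2]`` the
    parent-side clades and ``clades[3]`` the clade opposite the hybrid node.
    Clades are stored as sorted tuples of labels.
    """

    clades: tuple[tuple[str, ...], tuple[str, ...], tuple[str, ...], tuple[str, ...]]

    @property
    def signature(self) -> tuple[int, int, int, int]:
        return tuple(len(c) for c in self.clades)  # type: ignore[return-value]

    @property
    def taxa(self) -> tuple[str, ...]:
        return tuple(sorted(itertools.chain.from_iterable(self.clades)))

    def clade_of(self, taxon: str) -> int:
        for i, c in enumerate(self.clades):
            if taxon in c:
                return i
        raise KeyError(taxon)

    def text(self) -> str:
        """Plain-text form ``n0=A,B;n1=C;n2=D;n3=E,F``."""
        return ";".join(
            f"n{i}=" + ",".join(c) for i, c in enumerate(self.clades)
        )

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.text()


def make_partition(
    clade0: Iterable[str],
    clade1: Iterable[str],
    clade2: Iterable[str],
    clade3: Iterable[str],
) -> CladePartition:
    """Validate and build a :class:`CladePartition`.

    Raises :class:`PartitionError` naming the offending clade or taxon on
    empty clades, duplicated taxa or overlapping clades.
    """
    raw = [tuple(sorted(c)) for c in (clade0, clade1, clade2, clade3)]
    for i, c in enumerate(raw):
        if len(c) == 0:
            raise PartitionError(f"clade n{i} is empty")
        for label in c:
            if not isinstance(label, str) or not label:
                raise PartitionError(f"clade n{i} contains an invalid taxon label {label!r}")
        if len(set(c)) != len(c):
            dup = next(t for t in c if c.count(t) > 1)
            raise PartitionError(f"taxon {dup!r} appears twice in clade n{i}")
    seen: dict[str, int] = {}
    for i, c in enumerate(raw):
        for t in c:
            if t in seen:
                raise PartitionError(
                    f"taxon {t!r} assigned to both clade n{seen[t]} and clade n{i}"
                )
            seen[t] = i
    return CladePartition(clades=tuple(raw))  # type: ignore[arg-type]


def parse_partition_text(text: str) -> CladePartition:
    """Parse the ``n0=A,B;n1=C;n2=D;n3=E,F`` plain-text form."""
    parts = text.strip().rstrip(";").split(";")
    if len(parts) != 4:
        raise PartitionError(f"expected four clades, got {len(parts)}: {text!r}")
    clades: list[list[str]] = [[], [], [], []]
    for part in parts:
        m = re.fullmatch(r"\s*n([0-3])\s*=\s*(.*?)\s*", part)
        if m is None:
            raise PartitionError(f"cannot parse clade field {part!r}")
        idx = int(m.group(1))
        labels = [t.strip() for t in m.group(2).split(",") if t.strip()]
        clades[idx] = labels
    return make_partition(*clades)


def symmetric_partner(p: CladePartition) -> CladePartition:
    """Swap the two parent-side clades (n1 and n2); an involution."""
    c = p.clades
    return CladePartition(clades=(c[0], c[2], c[1], c[3]))


def enumerate_candidates(taxa: Iterable[str]) -> list[CladePartition]:
    """All ordered partitions of ``taxa`` into four clades of size 1 or 2.

    These are the candidate placements of the four-node hybridization cycle
    for 5-8 taxa (larger clades are only reachable through the >8-taxon
    subset algorithm).  The result is deterministic: sorted by the canonical
    text form.  Counts: 240 (5 taxa), 1080 (6), 2520 (7), 2520 (8).
    """
    seq = list(taxa)
    if len(seq) != len(set(seq)):
        raise PartitionError("duplicate taxon labels in taxon set")
    labels = sorted(seq)
    n = len(labels)
    if not 5 <= n <= 8:
        raise PartitionError(
            f"candidate enumeration supports 5-8 taxa, got {n} "
            "(use the large-taxon subset procedure)"
        )
    out: list[CladePartition] = []
    sigs = [s for s in itertools.product((1, 2), repeat=4) if sum(s) == n]
    for sig in sigs:
        for assignment in _ordered_partitions(labels, sig):
            out.append(CladePartition(clades=assignment))
    out.sort(key=lambda p: p.text())
    return out


def _ordered_partitions(labels: Sequence[str], sizes: Sequence[int]):
    """Yield ordered set partitions of ``labels`` with the given block sizes."""
    if not sizes:
        yield ()
        return
    k = sizes[0]
    rest_sizes = sizes[1:]
    pool = list(labels)
    for block in itertools.combinations(pool, k):
        remaining = [t for t in pool if t not in block]
        for tail in _ordered_partitions(remaining, rest_sizes):
            yield (tuple(block),) + tail


# ---------------------------------------------------------------------------
# eNewick output and a minimal reader used to validate it


def _clade_newick(clade: Sequence[str]) -> str:
    if len(clade) == 1:
        return clade[0]
    return "(" + ",".join(sorted(clade)) + ")"


def to_enewick(p: CladePartition) -> str:
    """Extended-Newick form of the partition's semi-directed network.

    The hybrid node appears twice under the tag ``#H1``: once with the hybrid
    clade below it (child of the ``v1`` side) and once as a bare reference
    (child of the ``v2`` side).  Clades with two or more taxa are written as
    polytomies sorted by label — within-clade topology is not resolved by the
    method.  Branch lengths and inheritance probabilities are omitted.
    """
    c0, c1, c2, c3 = p.clades
    hybrid_first = "(" + ",".join(sorted(c0)) + ")#H1"
    v1 = "(" + ",".join(sorted(c1) + [hybrid_first]) + ")"
    v2 = "(" + ",".join(sorted(c2) + ["#H1"]) + ")"
    return f"({v1},{v2},{_clade_newick(c3)});"


def parse_enewick(text: str) -> "networkx.Graph":  # noqa: F821
    """Parse an eNewick string into an undirected ``networkx`` graph.

    Hybrid tags (``#H...``) occurring multiple times are merged into one
    node.  Only topology is read (branch lengths are ignored); used to check
    that :func:`to_enewick` output encodes exactly one cycle of four nodes.
    """
    import networkx as nx

    text = text.strip()
    if text.endswith(";"):
        text = text[:-1]
    g = nx.Graph()
    counter = itertools.count()
    hybrids: dict[str, str] = {}

    def node_for(label: str | None, tag: str | None) -> str:
        if tag is not None:
            if tag not in hybrids:
                hybrids[tag] = f"hybrid:{tag}"
                g.add_node(hybrids[tag])
            return hybrids[tag]
        if label:
            g.add_node(label)
            return label
        name = f"internal:{next(counter)}"
        g.add_node(name)
        return name

    pos = 0

    def parse_node() -> str:
        nonlocal pos
        children: list[str] = []
        if pos < len(text) and text[pos] == "(":
            pos += 1
            while True:
                children.append(parse_node())
                if pos >= len(text):
                    raise ValueError("unbalanced parentheses in eNewick")
                if text[pos] == ",":
                    pos += 1
                    continue
                if text[pos] == ")":
                    pos += 1
                    break
        m = re.match(r"[^(),;:#]*", text[pos:])
        label = m.group(0) if m else ""
        pos += len(label)
        tag = None
        if pos < len(text) and text[pos] == "#":
            m2 = re.match(r"#[^(),;:]+", text[pos:])
            assert m2 is not None
            tag = m2.group(0)
            pos += len(tag)
        if pos < len(text) and text[pos] == ":":
            m3 = re.match(r":[-0-9.eE+]+", text[pos:])
            assert m3 is not None
            pos += len(m3.group(0))
        node = node_for(label or None, tag)
        for ch in children:
            if ch != node:
                g.add_edge(node, ch)
        return node

    parse_node()
    if pos != len(text):
        raise ValueError(f"trailing characters in eNewick at offset {pos}")
    return g
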