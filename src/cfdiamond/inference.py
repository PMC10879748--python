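"""Ranking candidate hybridization cycles by invariant score.

The invariant score of a candidate partition is the L2 norm of its invariant
set evaluated at the observed a-vector; the candidate whose invariants are
closest to vanishing agrees best with the observed concordance factors.  For
5-8 taxa every ordered partition into four clades of size 1 or 2 is scored;
for more than eight taxa all eight-taxon subsets are scored jointly and the
remaining taxa are grafted onto the best subset network according to their
placement in the best compatible candidate.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .cf_data import CFTable, CFTableError, realization_slot_splits
from .coalescent import cf_system
from .invariants import (
    InvariantSet,
    get_invariants,
    reduced_coordinate_matrix,
)
from .network import (
    CladePartition,
    PartitionError,
    _ordered_partitions,
    symmetric_partner,
)

__all__ = [
    "invariant_score",
    "CandidateRanking",
    "rank_partitions",
    "infer_large",
    "TaxonPlacement",
]


def invariant_score(
    a: np.ndarray, inv: InvariantSet, normalized: bool = False
) -> float:
    """L2 norm of the invariant values at an observed a-vector.

    With ``normalized=True`` the norm is divided by the square root of the
    number of invariants, making scores comparable across signatures with
    invariant sets of different sizes (the raw norm is the default,
    matching the published ranking procedure).
    """
    a = np.asarray(a, dtype=float)
    if a.shape != (cf_system(inv.signature).n_a,):
        raise ValueError(
            f"a-vector of length {a.shape} does not match signature "
            f"{inv.signature} (need {cf_system(inv.signature).n_a})"
        )
    vals = inv.evaluate(a)
    score = float(np.sqrt(np.sum(vals**2)))
    if normalized:
        score /= np.sqrt(len(inv))
    return score


class _CompiledScore:
    """Vectorized invariant-score evaluator for one signature."""

    def __init__(self, inv: InvariantSet, normalized: bool = False):
        self.inv = inv
        system = cf_system(inv.signature)
        self.n_a = system.n_a
        self.sum_idx = np.arange(len(system.classes)) * 3
        self.minor_classes = np.array(
            [ci for ci, c in enumerate(system.classes) if max(c) == 2],
            dtype=int,
        )
        self.rmat = reduced_coordinate_matrix(inv.signature)
        self.norm = 1.0 / np.sqrt(len(inv)) if normalized else 1.0

    def scores(self, A: np.ndarray) -> np.ndarray:
        """Scores for a batch of a-vectors, shape (n_cand, n_a)."""
        trip = A.reshape(A.shape[0], -1, 3)
        total = np.sum((trip.sum(axis=2) - 1.0) ** 2, axis=1)
        if self.minor_classes.size:
            minors = trip[:, self.minor_classes, 1] - trip[:, self.minor_classes, 2]
            total += np.sum(minors**2, axis=1)
        r = A @ self.rmat.T
        for terms in self.inv.polys:
            val = np.zeros(A.shape[0])
            for coeff, idxs in terms:
                t = np.full(A.shape[0], float(coeff))
                for i in idxs:
                    t = t * r[:, i]
                val += t
            total += val**2
        return np.sqrt(total) * self.norm


@dataclass
class CandidateRanking:
    """Candidates with their invariant scores, best (smallest) first.

    Ties are broken by the canonical partition text, so symmetric pairs
    appear adjacently and deterministically.
    """

    entries: list[tuple[CladePartition, float]]

    def __post_init__(self) -> None:
        self.entries.sort(key=lambda e: (e[1], e[0].text()))
        self._scores = {p.text(): s for p, s in self.entries}

    def __len__(self) -> int:
        return len(self.entries)

    def top(self, m: int) -> list[tuple[CladePartition, float]]:
        return self.entries[: max(0, m)]

    #: scores closer than this are treated as tied.  Exactly-zero invariant
    #: evaluations land anywhere within ~1e-15 of zero depending on float
    #: summation order; certain candidate varieties provably contain each
    #: other's CF points, so such ties are real and must not be broken by
    #: floating-point noise.
    TIE_TOLERANCE = 1e-12

    def score_of(self, p: CladePartition) -> float:
        return self._scores[p.text()]

    def rank_of(self, p: CladePartition) -> int:
        """1-based rank, counting ties favorably.

        A candidate outranks ``p`` only if its score is smaller by more than
        :data:`TIE_TOLERANCE`.
        """
        s = self.score_of(p)
        return 1 + sum(1 for _, v in self.entries if v < s - self.TIE_TOLERANCE)

    def best_rank(self, p: CladePartition) -> int:
        """Best rank among the partition and its symmetric partner."""
        ranks = [self.rank_of(p)]
        partner = symmetric_partner(p)
        if partner.text() in self._scores:
            ranks.append(self.rank_of(partner))
        return min(ranks)


# ---------------------------------------------------------------------------
# position-based ranking plan, reusable across taxon relabelings


class _RankingPlan:
    """Precomputed realization indexing for all candidates on n positions.

    Candidates are ordered partitions of positions 0..n-1 into clades of
    size 1 or 2.  For each candidate and informative class, every
    realization is encoded as (candidate, a-offset, quad index, slot
    permutation); scoring any CF table then reduces to array indexing.
    """

    #: the 6 possible slot-to-canonical-split assignments
    PERMS = np.array(list(itertools.permutations((0, 1, 2))), dtype=int)

    def __init__(self, n: int):
        if not 5 <= n <= 8:
            raise PartitionError(f"ranking supports 5-8 taxa, got {n}")
        self.n = n
        positions = list(range(n))
        self.quads = list(itertools.combinations(positions, 4))
        quad_index = {q: i for i, q in enumerate(self.quads)}
        perm_index = {tuple(p): i for i, p in enumerate(map(tuple, self.PERMS))}
        sigs = [
            s for s in itertools.product((1, 2), repeat=4) if sum(s) == n
        ]
        self.groups: list[dict] = []
        for sig in sigs:
            system = cf_system(sig)
            cands = list(_ordered_partitions(positions, sig))
            real_cand: list[int] = []
            real_aoff: list[int] = []
            real_quad: list[int] = []
            real_perm: list[int] = []
            counts = np.zeros(system.n_a)
            for ci, cls in enumerate(system.classes):
                pools = [
                    list(itertools.combinations(range(s), c))
                    for s, c in zip(sig, cls)
                ]
                n_real = int(np.prod([len(p) for p in pools]))
                counts[3 * ci: 3 * ci + 3] = n_real
            for k, cand in enumerate(cands):
                for ci, cls in enumerate(system.classes):
                    pools = [
                        itertools.combinations(cand[clade], c)
                        for clade, c in enumerate(cls)
                    ]
                    for combo in itertools.product(*pools):
                        chosen = [
                            (t, clade)
                            for clade, ts in enumerate(combo)
                            for t in ts
                        ]
                        quad, slots = realization_slot_splits(chosen)
                        real_cand.append(k)
                        real_aoff.append(3 * ci)
                        real_quad.append(quad_index[quad])
                        real_perm.append(
                            perm_index[tuple(s - 1 for s in slots)]
                        )
            self.groups.append({
                "signature": sig,
                "candidates": cands,
                "n_a": system.n_a,
                "counts": counts,
                "cand": np.array(real_cand, dtype=int),
                "aoff": np.array(real_aoff, dtype=int)[:, None] + np.arange(3),
                "quad": np.array(real_quad, dtype=int),
                "perm": np.array(real_perm, dtype=int),
            })

    def score_all(
        self, quad_values: np.ndarray, normalized: bool = False
    ) -> list[tuple[tuple[tuple[int, ...], ...], float]]:
        """Score every candidate given canonical triples per position-quad."""
        out = []
        for grp in self.groups:
            n_cand = len(grp["candidates"])
            A = np.zeros((n_cand, grp["n_a"]))
            vals = quad_values[grp["quad"]]  # (R, 3) canonical order
            slotvals = np.take_along_axis(vals, self.PERMS[grp["perm"]], axis=1)
            np.add.at(A, (grp["cand"][:, None], grp["aoff"]), slotvals)
            A /= grp["counts"]
            engine = _compiled_score(grp["signature"], normalized)
            scores = engine.scores(A)
            out.extend(zip(grp["candidates"], scores.tolist()))
        return out


_PLAN_CACHE: dict[int, _RankingPlan] = {}
_SCORE_CACHE: dict[tuple[tuple[int, int, int, int], bool], _CompiledScore] = {}


def _compiled_score(sig, normalized: bool = False) -> _CompiledScore:
    key = (tuple(sig), normalized)
    if key not in _SCORE_CACHE:
        _SCORE_CACHE[key] = _CompiledScore(get_invariants(sig), normalized)
    return _SCORE_CACHE[key]


def _plan(n: int) -> _RankingPlan:
    if n not in _PLAN_CACHE:
        _PLAN_CACHE[n] = _RankingPlan(n)
    return _PLAN_CACHE[n]


def _quad_values(table: CFTable, labels: Sequence[str], plan: _RankingPlan):
    quads = [tuple(labels[i] for i in q) for q in plan.quads]
    return table.values_for(quads)


def rank_partitions(
    table: CFTable,
    taxa: Iterable[str] | None = None,
    m: int = 5,
    normalized: bool = False,
) -> CandidateRanking:
    """Score and rank every candidate four-clade partition of 5-8 taxa.

    Every ordered partition with clade sizes in {1, 2} is scored by mapping
    the observed CFs onto its a-vector and evaluating its signature's
    invariant set.  Returns the full ranking; ``ranking.top(m)`` gives the
    best ``m``.  The ranking is invariant to CF-table row order and to
    taxon renaming (up to relabeling of the output).
    """
    labels = sorted(set(taxa)) if taxa is not None else list(table.taxa)
    plan = _plan(len(labels))
    values = _quad_values(table, labels, plan)
    scored = plan.score_all(values, normalized=normalized)
    entries = [
        (
            CladePartition(
                clades=tuple(
                    tuple(sorted(labels[i] for i in clade)) for clade in cand
                )
            ),
            score,
        )
        for cand, score in scored
    ]
    return CandidateRanking(entries=entries)


# ---------------------------------------------------------------------------
# more than eight taxa


@dataclass
class TaxonPlacement:
    """Audit record for one grafted taxon in the >8-taxon procedure."""

    taxon: str
    clade: int | None
    via_rank: int | None
    note: str = ""


def infer_large(
    table: CFTable,
    taxa: Iterable[str],
    m: int = 5,
    normalized: bool = False,
) -> tuple[CladePartition | None, CandidateRanking, list[TaxonPlacement]]:
    """Infer the cycle partition for more than eight taxa by subset ranking.

    All candidates across all eight-taxon subsets are pooled into one global
    ranking.  The best candidate is the backbone ``N8*``; every taxon absent
    from it is assigned the clade it occupies in the highest-ranked
    candidate that contains it and whose clade assignment agrees with
    ``N8*`` on all shared taxa.  Taxa with no compatible candidate are
    reported unplaced rather than guessed.

    Returns ``(partition over all taxa or None if any taxon is unplaced,
    global ranking, per-taxon placement log)``.
    """
    labels = sorted(set(taxa))
    if len(labels) <= 8:
        raise PartitionError(
            f"infer_large requires more than eight taxa, got {len(labels)}"
        )
    plan = _plan(8)
    entries: list[tuple[CladePartition, float]] = []
    for subset in itertools.combinations(labels, 8):
        values = _quad_values(table, subset, plan)
        for cand, score in plan.score_all(values, normalized=normalized):
            p = CladePartition(
                clades=tuple(
                    tuple(sorted(subset[i] for i in clade)) for clade in cand
                )
            )
            entries.append((p, score))
    ranking = CandidateRanking(entries=entries)
    best = ranking.entries[0][0]
    best_taxa = set(best.taxa)
    placements: list[TaxonPlacement] = []
    clades = [list(c) for c in best.clades]
    unplaced = False
    for taxon in labels:
        if taxon in best_taxa:
            continue
        placed = False
        for rank, (cand, _) in enumerate(ranking.entries, start=1):
            if taxon not in cand.taxa:
                continue
            shared = set(cand.taxa) & best_taxa
            if all(
                best.clade_of(t) == cand.clade_of(t) for t in shared
            ):
                clade = cand.clade_of(taxon)
                clades[clade].append(taxon)
                placements.append(
                    TaxonPlacement(taxon=taxon, clade=clade, via_rank=rank)
                )
                placed = True
                break
        if not placed:
            placements.append(TaxonPlacement(
                taxon=taxon, clade=None, via_rank=None,
                note="no candidate compatible with the backbone contains it",
            ))
            unplaced = True
    if unplaced:
        return None, ranking, placements
    merged = CladePartition(
        clades=tuple(tuple(sorted(c)) for c in clades)  # type: ignore[arg-type]
    )
    return merged, ranking, placements
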