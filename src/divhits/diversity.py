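"""Diversity measures over molecule sets.

The central quantity is the circle count (sphere-exclusion packing number):
the size of the largest subset of a set of items whose pairwise distances
all *strictly exceed* a threshold D.  Geometrically this is the largest set
of circles of radius D centered on the items such that no center lies
inside another circle; graph-theoretically it is a maximum independent set
of the threshold graph with an edge wherever d(x, y) <= D.

Two solvers are provided:

* :func:`n_circles_exact` — branch-and-bound maximum independent set,
  exact but exponential; guarded to small inputs.
* :func:`n_circles_greedy` — sphere exclusion: scan items in a given order
  and keep an item iff it is farther than D from everything kept so far.
  Returns a maximal (not necessarily maximum) packing, never exceeding the
  exact count, and is the scalable estimator used on full run logs.

Classical measures with known pathologies (internal diversity, uniqueness,
Bemis–Murcko scaffold counts) and MaxMin diversity ordering round out the
module.  All set-level operations accept an abstract distance oracle — any
symmetric nonnegative pairwise function — so they work on hand-constructed
metric spaces as well as fingerprints.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence, TypeVar

import numpy as np
from rdkit import Chem
from rdkit.Chem.Scaffolds import MurckoScaffold

from .chem import MoleculeRecord, bulk_tanimoto_distance, pack_fingerprints

T = TypeVar("T")
DistFn = Callable[[T, T], float]

__all__ = [
    "DiverseHitResult",
    "n_circles_exact",
    "n_circles_greedy",
    "internal_diversity",
    "count_unique",
    "count_scaffolds",
    "maxmin_order",
    "maxmin_order_fingerprints",
]

#: default guard for the exact solver; beyond this the search is exponential
EXACT_MAX_N = 25


@dataclass(frozen=True)
class DiverseHitResult:
    """Result of a circle-count evaluation.

    ``selected`` indexes the chosen representatives in the input set; every
    pair of selected items is at distance strictly greater than
    ``threshold_D``, and no unselected item could be added without
    violating that constraint (maximality).
    """

    count: int
    selected: tuple[int, ...]
    threshold_D: float
    method: str  # "exact" or "greedy"

    def __post_init__(self) -> None:
        if self.count != len(self.selected):
            raise ValueError("count must equal len(selected)")


def _conflict_masks(items: Sequence[T], dist: DistFn, D: float) -> list[int]:
    """Bitmask adjacency of the threshold graph (edge iff d <= D)."""
    n = len(items)
    adj = [0] * n
    for i in range(n):
        for j in range(i + 1, n):
            if dist(items[i], items[j]) <= D:
                adj[i] |= 1 << j
                adj[j] |= 1 << i
    return adj


def _greedy_mask(adj: list[int], order: Sequence[int]) -> int:
    sel = 0
    for i in order:
        if adj[i] & sel == 0:
            sel |= 1 << i
    return sel


def n_circles_exact(
    items: Sequence[T],
    dist: DistFn,
    D: float,
    max_n: int = EXACT_MAX_N,
) -> DiverseHitResult:
    """Exact circle count: maximum subset with all pairwise distances > D.

    Branch-and-bound over the threshold graph: a greedy packing seeds the
    incumbent, branching picks the most-conflicted remaining vertex, and
    subtrees that cannot beat the incumbent by cardinality are pruned.
    Intended for ``len(items) <= max_n`` (default 25); larger inputs raise,
    directing the caller to :func:`n_circles_greedy`.
    """
    n = len(items)
    if n > max_n:
        raise ValueError(
            f"n_circles_exact is exponential and capped at n={max_n} "
            f"(got {n}); use n_circles_greedy for large sets"
        )
    if n == 0:
        return DiverseHitResult(0, (), D, "exact")

    adj = _conflict_masks(items, dist, D)
    best_mask = _greedy_mask(adj, range(n))
    best_size = bin(best_mask).count("1")
    full = (1 << n) - 1

    def search(cand: int, cur_mask: int, cur_size: int) -> None:
        nonlocal best_mask, best_size
        if cur_size + bin(cand).count("1") <= best_size:
            return
        if cand == 0:
            best_mask, best_size = cur_mask, cur_size
            return
        # branch on the vertex with most conflicts among the candidates
        v, v_deg = -1, -1
        m = cand
        while m:
            i = (m & -m).bit_length() - 1
            deg = bin(adj[i] & cand).count("1")
            if deg > v_deg:
                v, v_deg = i, deg
            m &= m - 1
        bit = 1 << v
        search(cand & ~(bit | adj[v]), cur_mask | bit, cur_size + 1)  # include v
        search(cand & ~bit, cur_mask, cur_size)  # exclude v

    search(full, 0, 0)
    selected = tuple(i for i in range(n) if best_mask >> i & 1)
    return DiverseHitResult(best_size, selected, D, "exact")


def n_circles_greedy(
    items: Sequence[T],
    dist: DistFn,
    D: float,
    order: Sequence[int] | None = None,
) -> DiverseHitResult:
    """Greedy sphere exclusion in ``order`` (default: input order).

    Scans items in the given order and keeps an item iff its distance to
    every kept item strictly exceeds D.  The result is a maximal packing
    whose size never exceeds the exact count.  Because the scan is online,
    running it on any prefix of the order yields a prefix of the same
    selection — the property the budget curves rely on.
    """
    n = len(items)
    if order is None:
        order = range(n)
    else:
        if sorted(order) != list(range(n)):
            raise ValueError("order must be a permutation of range(len(items))")
    selected: list[int] = []
    for i in order:
        if all(dist(items[i], items[j]) > D for j in selected):
            selected.append(i)
    return DiverseHitResult(len(selected), tuple(selected), D, "greedy")


def internal_diversity(items: Sequence[T], dist: DistFn) -> float:
    """Mean pairwise distance over unordered pairs (diagonal excluded)."""
    n = len(items)
    if n < 2:
        raise ValueError("internal_diversity requires at least 2 items")
    total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            total += dist(items[i], items[j])
    return total / (n * (n - 1) / 2)


def _valid_canonical(records: Sequence[MoleculeRecord]) -> list[str]:
    skipped = sum(1 for r in records if not r.valid)
    if skipped:
        warnings.warn(f"skipping {skipped} invalid molecule(s)", stacklevel=3)
    return [r.canonical_smiles for r in records if r.valid]


def count_unique(records: Sequence[MoleculeRecord]) -> int:
    """Number of distinct canonical SMILES among the valid records."""
    return len(set(_valid_canonical(records)))


def count_scaffolds(records: Sequence[MoleculeRecord]) -> int:
    """Number of distinct Bemis–Murcko scaffolds among the valid records.

    Acyclic molecules have an empty scaffold and share a single scaffold
    class.
    """
    scaffolds = set()
    for smi in set(_valid_canonical(records)):
        scaffolds.add(Chem.MolToSmiles(MurckoScaffold.GetScaffoldForMol(Chem.MolFromSmiles(smi))))
    return len(scaffolds)


def maxmin_order(items: Sequence[T], dist: DistFn, start: int = 0) -> list[int]:
    """MaxMin diversity ordering.

    Position 0 is ``start``; each subsequent position holds the item
    maximizing its minimum distance to all earlier picks, ties broken by
    smallest index.  O(n^2) distance evaluations.
    """
    n = len(items)
    if n < 1:
        raise ValueError("maxmin_order requires at least one item")
    if not 0 <= start < n:
        raise ValueError(f"start index {start} out of range")
    order = [start]
    min_d = [dist(items[start], items[i]) for i in range(n)]
    min_d[start] = -1.0  # picked
    for _ in range(n - 1):
        best = max(range(n), key=lambda i: (min_d[i], -i))
        order.append(best)
        for i in range(n):
            if min_d[i] >= 0:
                d = dist(items[best], items[i])
                if d < min_d[i]:
                    min_d[i] = d
        min_d[best] = -1.0
    return order


def maxmin_order_fingerprints(
    fps: Sequence[frozenset[int]], n_bits: int, start: int = 0
) -> list[int]:
    """Vectorized MaxMin over binary fingerprints (identical tie-breaks).

    Same contract as :func:`maxmin_order` with Tanimoto distance, using
    packed bit matrices so library-scale inputs stay fast.
    """
    n = len(fps)
    if n < 1:
        raise ValueError("maxmin_order requires at least one item")
    packed = pack_fingerprints(fps, n_bits)
    order = [start]
    min_d = bulk_tanimoto_distance(packed[start], packed)
    min_d[start] = -1.0
    for _ in range(n - 1):
        best = int(np.argmax(min_d))  # argmax takes the first (lowest-index) max
        order.append(best)
        d = bulk_tanimoto_distance(packed[best], packed)
        np.minimum(min_d, d, out=min_d)
        min_d[best] = -1.0
    return order
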