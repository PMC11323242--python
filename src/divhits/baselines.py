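"""Virtual-screening baselines and a minimal mutation GA.

Virtual screening scores a fixed library in some order without feedback:
``vs_random`` screens in a seeded uniform random order, ``vs_maxmin``
first sorts the library with the MaxMin algorithm so that the molecules
screened first have the largest possible pairwise distances, avoiding
redundant evaluations at small budgets.

``mutation_ga`` is a deliberately simple feedback-using reference
generator (select the top scorers, mutate, re-propose); it exercises the
harness's scoring callback and cache, and is not a reproduction of any
published molecular GA.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from rdkit import Chem

from .chem import DEFAULT_FP_CONFIG, FingerprintConfig, MoleculeRecord, canonicalize
from .diversity import maxmin_order_fingerprints
from .harness import BudgetView
from .io import read_smiles_file

__all__ = ["ScreeningLibrary", "vs_random", "vs_maxmin", "mutation_ga", "GENERATORS"]


@dataclass
class ScreeningLibrary:
    """A deduplicated, all-valid collection of molecules to screen."""

    records: list[MoleculeRecord]
    name: str = "library"

    def __post_init__(self) -> None:
        seen = set()
        kept = []
        for r in self.records:
            if r.valid and r.canonical_smiles not in seen:
                seen.add(r.canonical_smiles)
                kept.append(r)
        self.records = kept

    def __len__(self) -> int:
        return len(self.records)

    @property
    def smiles(self) -> list[str]:
        return [r.canonical_smiles for r in self.records]

    @classmethod
    def from_smiles(
        cls,
        smiles: Sequence[str],
        fp_config: FingerprintConfig = DEFAULT_FP_CONFIG,
        name: str = "library",
    ) -> "ScreeningLibrary":
        return cls([canonicalize(s, fp_config) for s in smiles], name=name)

    @classmethod
    def from_file(
        cls, path, fp_config: FingerprintConfig = DEFAULT_FP_CONFIG, name: str | None = None
    ) -> "ScreeningLibrary":
        return cls(read_smiles_file(path, fp_config), name=name or str(path))


def _screen_in_order(library: ScreeningLibrary, order: Sequence[int], batch_size: int):
    smiles = library.smiles

    def generator(score, budget: BudgetView, rng: np.random.Generator) -> None:
        for lo in range(0, len(order), batch_size):
            if budget.exhausted:
                return
            score([smiles[i] for i in order[lo : lo + batch_size]])

    return generator


def vs_random(library: ScreeningLibrary, batch_size: int = 64):
    """Screen the library once, in a seeded uniform random order."""
    if len(library) == 0:
        raise ValueError("screening library is empty")

    def generator(score, budget: BudgetView, rng: np.random.Generator) -> None:
        order = rng.permutation(len(library))
        _screen_in_order(library, order, batch_size)(score, budget, rng)

    return generator


def vs_maxmin(
    library: ScreeningLibrary,
    batch_size: int = 64,
    start: int = 0,
    fp_config: FingerprintConfig = DEFAULT_FP_CONFIG,
):
    """Screen the library once in MaxMin order (most-distant-first).

    The order is deterministic: it starts at ``start`` (index 0 by
    default) and is independent of the run seed.
    """
    if len(library) == 0:
        raise ValueError("screening library is empty")
    fps = [r.fingerprint for r in library.records]
    order = maxmin_order_fingerprints(fps, fp_config.n_bits, start=start)
    return _screen_in_order(library, order, batch_size)


# --- mutation GA -----------------------------------------------------------

_EDIT_ELEMENTS = [6, 7, 8, 9, 16, 17, 35]  # C N O F S Cl Br
_RETRY_CAP = 10


def _apply_atom_edit(rw: Chem.RWMol, rng: np.random.Generator) -> None:
    """One random atom-level edit: append an atom, delete a terminal atom,
    or swap an element."""
    op = int(rng.integers(3))
    if op == 0:
        idx = int(rng.integers(rw.GetNumAtoms()))
        new = rw.AddAtom(Chem.Atom(_EDIT_ELEMENTS[int(rng.integers(len(_EDIT_ELEMENTS)))]))
        rw.AddBond(idx, new, Chem.BondType.SINGLE)
    elif op == 1:
        terminal = [a.GetIdx() for a in rw.GetAtoms() if a.GetDegree() == 1]
        if terminal:
            rw.RemoveAtom(int(terminal[int(rng.integers(len(terminal)))]))
    else:
        idx = int(rng.integers(rw.GetNumAtoms()))
        rw.GetAtomWithIdx(idx).SetAtomicNum(_EDIT_ELEMENTS[int(rng.integers(len(_EDIT_ELEMENTS)))])


def _mutate_smiles(smiles: str, rng: np.random.Generator, mutation_rate: float) -> str:
    """Random atom-level edits with a validity retry.

    The number of edits is binomial(atom count, mutation_rate), so a rate
    of zero returns the parent unchanged.  Candidates failing sanitization
    are re-drawn up to a retry cap; after that a minimal parent
    perturbation (methyl extension) is proposed instead.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return smiles
    n_edits = int(rng.binomial(mol.GetNumAtoms(), mutation_rate))
    if n_edits == 0:
        return smiles
    for _ in range(_RETRY_CAP):
        rw = Chem.RWMol(mol)
        try:
            for _ in range(n_edits):
                _apply_atom_edit(rw, rng)
            cand = rw.GetMol()
            Chem.SanitizeMol(cand)
            return Chem.MolToSmiles(cand)
        except Exception:
            continue
    cand = smiles + "C"
    return cand if Chem.MolFromSmiles(cand) is not None else smiles


def mutation_ga(
    initial: Sequence[str],
    population_size: int = 20,
    batch_size: int = 20,
    mutation_rate: float = 0.1,
    max_stalled_generations: int = 50,
):
    """Minimal mutation-only genetic algorithm over molecules.

    Seeds the population with ``initial``, then repeats: keep the
    ``population_size`` best-scoring molecules seen so far, mutate random
    parents with atom-level edits, and propose the offspring batch for
    scoring.  All proposals flow through the harness scoring callback (so
    duplicates hit the cache and consume no budget); the loop stops when
    the budget view reports exhaustion, or after
    ``max_stalled_generations`` consecutive generations that consumed no
    budget (the degenerate regime, e.g. a zero mutation rate).
    """
    if not initial:
        raise ValueError("mutation_ga needs a nonempty initial population")

    def generator(score, budget: BudgetView, rng: np.random.Generator) -> None:
        pool: dict[str, float] = {}
        init = list(initial)[: max(population_size, len(initial))]
        scores = score(init)
        pool.update(zip(init, scores))
        stalled = 0
        while not budget.exhausted and stalled < max_stalled_generations:
            parents = sorted(pool.items(), key=lambda kv: (-kv[1], kv[0]))[:population_size]
            parent_smiles = [p for p, _ in parents]
            offspring = [
                _mutate_smiles(parent_smiles[int(rng.integers(len(parent_smiles)))], rng, mutation_rate)
                for _ in range(batch_size)
            ]
            before = budget.calls_used
            for smi, sc in zip(offspring, score(offspring)):
                if smi not in pool or sc > pool[smi]:
                    pool[smi] = sc
            stalled = stalled + 1 if budget.calls_used == before else 0

    return generator


#: generator factories registered under string keys for the CLI
GENERATORS: dict[str, Callable] = {
    "vs-random": vs_random,
    "vs-maxmin": vs_maxmin,
    "mutation-ga": mutation_ga,
}
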