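"""Deterministic synthetic libraries, toy oracles and abstract metric spaces.

Everything here is generated from code and a seed — no external data sets
are required.  The library enumerates decorated ring scaffolds spanning
roughly 100–600 Da, so the default property filter bites on some members;
the toy bioactivity oracle returns the maximum Tanimoto similarity to a
set of active seed molecules raised to a steepness power, mimicking the
contract of a probabilistic QSAR classifier: output in [0, 1], hits at
0.5, and a smooth activity landscape around each seed so that a diversity
filter demonstrably forces exploration.

Abstract metric-space builders (clustered points, evenly spread points)
make the pathologies of classical diversity measures constructible
without chemistry: a few tight clusters score high internal diversity but
cover little space, while a broad covering scores the opposite.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache
from typing import Callable, Sequence

import numpy as np

from .baselines import ScreeningLibrary
from .chem import (
    DEFAULT_FP_CONFIG,
    FingerprintConfig,
    MoleculeRecord,
    canonicalize,
    tanimoto_similarity,
)

__all__ = [
    "ToyOracleConfig",
    "make_library",
    "make_toy_oracle",
    "default_active_seeds",
    "EXTERNAL_ACTIVE_SEEDS",
    "make_clustered_task",
    "make_clustered_points",
    "make_uniform_points",
]

# Ring scaffolds as format templates: {0}/{1} are substituent attachment
# slots written so that plain concatenation yields valid SMILES.
_TEMPLATES: list[str] = [
    "{0}c1ccccc1",
    "{0}c1ccc({1})cc1",
    "{0}c1ccncc1",
    "{0}c1ccc({1})nc1",
    "{0}c1cccc2ccccc12",
    "{0}c1ccc2[nH]ccc2c1",
    "{0}c1ccoc1",
    "{0}c1ccsc1",
    "{0}c1ccc2ncccc2c1",
    "{0}c1ncccn1",
    "{0}C1CCCCC1",
    "{0}C1CCNCC1",
    "{0}c1ccc(-c2ccccc2{1})cc1",
    "{0}c1ccc2c(c1)oc1ccccc12",
    "{0}C1CCC(C(=O)N{1})CC1",
    "{0}c1ccc(-c2ccc({1})cc2)cc1",
]

_SUBSTITUENTS: list[str] = [
    "C",
    "CC",
    "CCC",
    "CCCC",
    "CCCCCCCC",
    "O",
    "OC",
    "OCC",
    "N",
    "NC",
    "F",
    "Cl",
    "Br",
    "C(F)(F)F",
    "C(=O)O",
    "C(=O)OC",
    "C(=O)N",
    "C#N",
    "CN(C)C",
    "S(=O)(=O)N",
    "CCCCCCCCCCCCCCCC",
    "C(c1ccccc1)(c1ccccc1)c1ccccc1",
    "Oc1ccccc1",
]


def _enumerate_smiles() -> list[str]:
    out = []
    for tpl in _TEMPLATES:
        slots = tpl.count("{")
        if slots == 1:
            for s in _SUBSTITUENTS:
                out.append(tpl.format(s))
        else:
            for s1, s2 in itertools.product(_SUBSTITUENTS, repeat=2):
                out.append(tpl.format(s1, s2))
    return out


@lru_cache(maxsize=2)
def _enumerated_records(fp_config: FingerprintConfig) -> tuple[MoleculeRecord, ...]:
    seen: set[str] = set()
    records: list[MoleculeRecord] = []
    for smi in _enumerate_smiles():
        rec = canonicalize(smi, fp_config)
        if rec.valid and rec.canonical_smiles not in seen:
            seen.add(rec.canonical_smiles)
            records.append(rec)
    return tuple(records)


def make_library(
    n: int,
    seed: int,
    fp_config: FingerprintConfig = DEFAULT_FP_CONFIG,
    name: str = "fixture-library",
) -> ScreeningLibrary:
    """Deterministic synthetic screening library of ``n`` unique molecules.

    Decorates a fixed list of ring scaffolds with substituents (halogens,
    alkyl chains, hydroxy/amino/carboxy groups, ...), canonicalizes,
    deduplicates, and takes a seed-shuffled sample of size ``n``.  Same
    (n, seed) always yields the same library, byte for byte.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    records = _enumerated_records(fp_config)
    if n > len(records):
        raise ValueError(
            f"requested {n} molecules but the enumerable space holds only {len(records)}"
        )
    rng = np.random.default_rng([seed, 0x11B])
    idx = rng.permutation(len(records))[:n]
    return ScreeningLibrary([records[i] for i in sorted(idx)], name=name)


@dataclass(frozen=True)
class ToyOracleConfig:
    """Configuration of the similarity-based pseudo-activity oracle.

    ``active_seeds`` are the canonical SMILES of the designated actives;
    ``steepness`` sharpens the landscape (score = max similarity to any
    seed, raised to this power — higher steepness, fewer hits).
    """

    active_seeds: tuple[str, ...]
    steepness: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not self.active_seeds:
            raise ValueError("active_seeds must be nonempty")
        if self.steepness <= 0:
            raise ValueError("steepness must be positive")


def default_active_seeds(
    library: ScreeningLibrary, k: int, seed: int
) -> tuple[str, ...]:
    """Pick ``k`` library members as the oracle's active seeds (seeded)."""
    rng = np.random.default_rng([seed, 0xACE])
    idx = rng.choice(len(library), size=min(k, len(library)), replace=False)
    return tuple(library.records[int(i)].canonical_smiles for i in sorted(idx))


def make_toy_oracle(
    cfg: ToyOracleConfig, fp_config: FingerprintConfig = DEFAULT_FP_CONFIG
) -> Callable[[MoleculeRecord], float]:
    """Pseudo-activity oracle: max Tanimoto similarity to the active seeds,
    raised to ``steepness``.  Deterministic; invalid molecules score 0."""
    seed_fps = []
    for smi in cfg.active_seeds:
        rec = canonicalize(smi, fp_config)
        if not rec.valid:
            raise ValueError(f"active seed {smi!r} is not a valid molecule")
        seed_fps.append(rec.fingerprint)

    def oracle(record: MoleculeRecord) -> float:
        if not record.valid or record.fingerprint is None:
            return 0.0
        sim = max(tanimoto_similarity(record.fingerprint, fp) for fp in seed_fps)
        return float(sim**cfg.steepness)

    return oracle


#: Drug-like actives deliberately outside the enumerated scaffold-decoration
#: space: screening a fixture library saturates at a low similarity ceiling,
#: so only generators that exploit scoring feedback can approach them.
EXTERNAL_ACTIVE_SEEDS: tuple[str, ...] = (
    "CN1CCN(CCCN2c3ccccc3Sc3ccc(Cl)cc32)CC1",  # phenothiazine + N-methylpiperazine
    "CC(=O)Nc1ccc(OCC(O)CNC(C)C)cc1",  # acetamidophenoxy-propanolamine
)


def make_clustered_task(
    n_library: int = 600,
    n_actives: int = 8,
    steepness: float = 0.25,
    library_seed: int = 1,
    oracle_seed: int = 0,
    fp_config: FingerprintConfig = DEFAULT_FP_CONFIG,
) -> tuple[ScreeningLibrary, Callable[[MoleculeRecord], float]]:
    """Screening task where diversity, not potency, is the bottleneck.

    The fixture library is clustered by construction (scaffold families
    decorated with substituents); the shallow activity landscape
    (steepness < 1) makes most of the library score above the hit
    threshold, so the limiting factor at small budgets is how many
    *distinct* regions a generator touches — the regime in which
    most-distant-first screening pays off over random order.
    """
    library = make_library(n_library, seed=library_seed, fp_config=fp_config)
    actives = default_active_seeds(library, n_actives, oracle_seed)
    oracle = make_toy_oracle(
        ToyOracleConfig(active_seeds=actives, steepness=steepness), fp_config
    )
    return library, oracle


# --- abstract metric spaces -------------------------------------------------

def make_clustered_points(
    k_clusters: int, per_cluster: int, intra_d: float, inter_d: float
) -> tuple[list[tuple[int, int]], Callable]:
    """Abstract point set: ``k_clusters`` clusters of ``per_cluster`` points,
    distance ``intra_d`` within a cluster and ``inter_d`` across clusters.

    With 0 < intra_d < inter_d this two-level distance always satisfies the
    triangle inequality (verified defensively).  Points are (cluster, member)
    pairs; the returned callable is the distance oracle.
    """
    if not 0 < intra_d < inter_d:
        # ordering guarantees the triangle inequality: the longest leg of any
        # triangle is at most inter_d <= min(intra_d, inter_d) + inter_d
        raise ValueError("need 0 < intra_d < inter_d")
    points = [(c, m) for c in range(k_clusters) for m in range(per_cluster)]

    def dist(x: tuple[int, int], y: tuple[int, int]) -> float:
        if x == y:
            return 0.0
        return intra_d if x[0] == y[0] else inter_d

    return points, dist


def make_uniform_points(n: int, d: float) -> tuple[list[int], Callable]:
    """``n`` points all at mutual distance ``d`` (a simplex metric)."""
    if n < 1 or not 0 < d:
        raise ValueError("need n >= 1 and d > 0")

    def dist(x: int, y: int) -> float:
        return 0.0 if x == y else d

    return list(range(n)), dist
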