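"""Molecule parsing, canonicalization, fingerprints, descriptors and distances.

Everything downstream (scoring, diversity metrics, the run harness) consumes
:class:`MoleculeRecord` objects produced by :func:`canonicalize`.  Malformed
SMILES are first-class values — they yield records with ``valid=False`` and
never raise, so generators that emit garbage are handled uniformly by the
benchmark loop.

Fingerprints are binary folded Morgan (extended-connectivity) fingerprints,
stored as frozen sets of on-bit indices; distances are Jaccard/Tanimoto
distances on those sets, which form a true metric.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, Descriptors, rdFingerprintGenerator

# RDKit is chatty about malformed SMILES; invalid input is an expected value
# here, not an event worth logging.
RDLogger.DisableLog("rdApp.*")

__all__ = [
    "FingerprintConfig",
    "MoleculeRecord",
    "DEFAULT_FP_CONFIG",
    "canonicalize",
    "tanimoto_similarity",
    "tanimoto_distance",
    "compute_descriptors",
    "pack_fingerprints",
    "bulk_tanimoto_distance",
]


@dataclass(frozen=True)
class FingerprintConfig:
    """Parameters of the folded circular (Morgan) fingerprint.

    radius
        Maximum bond radius of the atom-centered environments (default 2,
        i.e. ECFP4-like).
    n_bits
        Folded length; must be a power of two per the folding convention.
    use_counts
        Reserved; the default benchmark path is binary.
    """

    radius: int = 2
    n_bits: int = 2048
    use_counts: bool = False

    def __post_init__(self) -> None:
        if self.radius < 0:
            raise ValueError("radius must be non-negative")
        if self.n_bits <= 0 or (self.n_bits & (self.n_bits - 1)) != 0:
            raise ValueError(f"n_bits must be a positive power of two, got {self.n_bits}")


DEFAULT_FP_CONFIG = FingerprintConfig()


@dataclass(frozen=True)
class MoleculeRecord:
    """A parsed molecule: the unit every metric and filter consumes.

    ``valid`` is False iff canonicalization failed; in that case all derived
    fields (``canonical_smiles``, ``fingerprint``, descriptors) are ``None``.
    ``env_keys`` holds the unfolded atom-environment hash keys (radii
    0..radius) used by the idiosyncratic-substructure filter.
    """

    input_smiles: str
    canonical_smiles: str | None
    valid: bool
    fingerprint: frozenset[int] | None
    mw: float | None
    logp: float | None
    env_keys: frozenset[int] | None = None
    name: str | None = None


@lru_cache(maxsize=8)
def _morgan_generator(radius: int, n_bits: int):
    return rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)


def canonicalize(
    smiles: str,
    fp_config: FingerprintConfig = DEFAULT_FP_CONFIG,
    name: str | None = None,
) -> MoleculeRecord:
    """Parse ``smiles`` and return a fully populated :class:`MoleculeRecord`.

    Never raises on malformed input: unparsable text yields ``valid=False``.
    Canonicalization is idempotent — canonicalizing ``canonical_smiles``
    again returns the same string.
    """
    mol = Chem.MolFromSmiles(smiles) if isinstance(smiles, str) else None
    if mol is None:
        return MoleculeRecord(
            input_smiles=smiles,
            canonical_smiles=None,
            valid=False,
            fingerprint=None,
            mw=None,
            logp=None,
            env_keys=None,
            name=name,
        )
    gen = _morgan_generator(fp_config.radius, fp_config.n_bits)
    fp = frozenset(gen.GetFingerprint(mol).GetOnBits())
    env = frozenset(gen.GetSparseCountFingerprint(mol).GetNonzeroElements())
    return MoleculeRecord(
        input_smiles=smiles,
        canonical_smiles=Chem.MolToSmiles(mol),
        valid=True,
        fingerprint=fp,
        mw=float(Descriptors.MolWt(mol)),
        logp=float(Crippen.MolLogP(mol)),
        env_keys=env,
        name=name,
    )


def tanimoto_similarity(a: frozenset[int] | set[int], b: frozenset[int] | set[int]) -> float:
    """Jaccard similarity |a∩b| / |a∪b| of two on-bit sets.

    Two empty fingerprints are identical all-zero vectors: similarity 1.
    """
    if not a and not b:
        return 1.0
    inter = len(a & b)
    union = len(a) + len(b) - inter
    return inter / union


def tanimoto_distance(a: frozenset[int] | set[int], b: frozenset[int] | set[int]) -> float:
    """Jaccard (Tanimoto) distance 1 − |a∩b|/|a∪b|; a metric on bit sets."""
    return 1.0 - tanimoto_similarity(a, b)


def compute_descriptors(record: MoleculeRecord) -> tuple[float, float]:
    """Return (molecular weight in Daltons, Crippen logP) for a valid record."""
    if not record.valid:
        raise ValueError(f"cannot compute descriptors of invalid SMILES {record.input_smiles!r}")
    return record.mw, record.logp


# ---------------------------------------------------------------------------
# Packed-fingerprint fast path (used by the MaxMin library ordering, where
# the O(n^2) distance evaluations would dominate in pure Python).

def pack_fingerprints(fps: Sequence[Iterable[int]], n_bits: int) -> np.ndarray:
    """Pack on-bit index sets into a (n, n_bits/64) uint64 matrix."""
    n_words = (n_bits + 63) // 64
    out = np.zeros((len(fps), n_words), dtype=np.uint64)
    for i, fp in enumerate(fps):
        for b in fp:
            out[i, b >> 6] |= np.uint64(1) << np.uint64(b & 63)
    return out


def bulk_tanimoto_distance(query: np.ndarray, matrix: np.ndarray) -> np.ndarray:
    """Tanimoto distances from one packed fingerprint row to every matrix row."""
    inter = np.bitwise_count(matrix & query).sum(axis=1)
    pop_q = int(np.bitwise_count(query).sum())
    pop_m = np.bitwise_count(matrix).sum(axis=1)
    union = pop_q + pop_m - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / np.maximum(union, 1), 1.0)
    return 1.0 - sim
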