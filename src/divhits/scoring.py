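"""Composite filtered scoring for goal-directed molecule generation.

The score handed back to a generator is the product of three terms:

* a pluggable bioactivity oracle mapping a molecule to a probability in
  [0, 1] (in production a QSAR classifier's probabilistic output; in the
  tests a similarity-based stand-in),
* a binary property filter enforcing lenient drug-likeness ranges —
  molecular weight in [157, 761] Da, logP in [-2.0, 8.3], and a fraction
  of idiosyncratic (out-of-vocabulary) substructures in [0.00, 0.08] —
  molecules violating any range have their score set to zero,
* a binary diversity filter (DF) that zeroes the score of any molecule
  within Tanimoto distance 0.7 of a previously found hit, forcing the
  generator out of local optima.

A molecule is a *hit* when its raw oracle score is at least S = 0.5 and it
passes the property filter.  The DF is deliberately excluded from hit
determination: a genuine hit whose score was suppressed because a near
neighbor was found earlier still counts at evaluation time — the run log
keeps everything, and nothing valuable is discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, NamedTuple

from .chem import MoleculeRecord, tanimoto_distance

__all__ = [
    "PropertyFilterConfig",
    "DiversityFilterState",
    "HitThreshold",
    "ScoreParts",
    "ScoringContext",
    "property_filter",
    "idiosyncratic_fraction",
    "df_check",
    "df_register_hit",
    "composite_score",
    "is_hit",
    "vocabulary_from_records",
    "load_scoring_config",
]

Oracle = Callable[[MoleculeRecord], float]


@dataclass(frozen=True)
class PropertyFilterConfig:
    """Acceptable property ranges; violations zero the score.

    ``reference_vocabulary`` is the set of atom-environment keys considered
    familiar when judging idiosyncrasy.  It is an explicit input (build one
    from any reference collection via :func:`vocabulary_from_records`);
    when absent the idiosyncrasy term is skipped.
    """

    mw_range: tuple[float, float] = (157.0, 761.0)
    logp_range: tuple[float, float] = (-2.0, 8.3)
    idiosyncratic_range: tuple[float, float] = (0.0, 0.08)
    reference_vocabulary: frozenset[int] | None = None

    def __post_init__(self) -> None:
        for name in ("mw_range", "logp_range", "idiosyncratic_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} lower bound {lo} exceeds upper bound {hi}")


@dataclass
class DiversityFilterState:
    """Memory of previously found hits.

    Fingerprints are only ever appended (monotone memory); any molecule
    within ``distance_threshold`` of a stored hit scores zero.
    """

    hit_fingerprints: list[frozenset[int]] = field(default_factory=list)
    distance_threshold: float = 0.7
    hit_score_threshold: float = 0.5
    enabled: bool = True


@dataclass(frozen=True)
class HitThreshold:
    """Raw-score threshold S above which a molecule counts as a hit."""

    S: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.S < 1.0:
            raise ValueError(f"S must lie in (0, 1), got {self.S}")


class ScoreParts(NamedTuple):
    final: float
    raw: float
    property_pass: bool
    df_pass: bool


def vocabulary_from_records(records: Iterable[MoleculeRecord]) -> frozenset[int]:
    """Union of atom-environment keys over the valid records of a collection."""
    vocab: set[int] = set()
    for r in records:
        if r.valid and r.env_keys:
            vocab |= r.env_keys
    return frozenset(vocab)


def idiosyncratic_fraction(record: MoleculeRecord, reference_vocabulary: frozenset[int]) -> float:
    """Fraction of the molecule's circular substructure keys (radii 0..r)
    absent from the reference vocabulary."""
    if not reference_vocabulary:
        raise ValueError("reference vocabulary must be nonempty")
    if not record.valid:
        raise ValueError("idiosyncratic_fraction requires a valid molecule")
    keys = record.env_keys or frozenset()
    if not keys:
        return 0.0
    return len(keys - reference_vocabulary) / len(keys)


def property_filter(record: MoleculeRecord, cfg: PropertyFilterConfig) -> bool:
    """True iff every property lies in its acceptable range.

    Invalid molecules fail (treated as violating everything).
    """
    if not record.valid:
        return False
    lo, hi = cfg.mw_range
    if not lo <= record.mw <= hi:
        return False
    lo, hi = cfg.logp_range
    if not lo <= record.logp <= hi:
        return False
    if cfg.reference_vocabulary is not None:
        lo, hi = cfg.idiosyncratic_range
        if not lo <= idiosyncratic_fraction(record, cfg.reference_vocabulary) <= hi:
            return False
    return True


def df_check(fp: frozenset[int], state: DiversityFilterState) -> bool:
    """True iff ``fp`` is farther than the DF threshold from every stored hit.

    Empty memory passes everything; a disabled filter always passes.
    """
    if not state.enabled:
        return True
    return all(
        tanimoto_distance(fp, hit) > state.distance_threshold for hit in state.hit_fingerprints
    )


def df_register_hit(state: DiversityFilterState, fp: frozenset[int]) -> DiversityFilterState:
    """Append a hit fingerprint to the DF memory (mutates and returns state)."""
    state.hit_fingerprints.append(fp)
    return state


def is_hit(raw: float, property_pass: bool, S: float = 0.5) -> bool:
    """Hit determination: raw oracle score at least S and property filter passed.

    The diversity filter is deliberately not consulted, so hits suppressed
    by the DF during optimization still count in evaluation.
    """
    return property_pass and raw >= S


def composite_score(
    record: MoleculeRecord,
    oracle: Oracle,
    cfg: PropertyFilterConfig,
    state: DiversityFilterState | None = None,
) -> ScoreParts:
    """Score one molecule: final = raw × 1[property pass] × 1[DF pass].

    Invalid molecules get raw = final = 0.  When the raw score reaches the
    DF's hit registration threshold with both filters passing (so final
    equals raw), the molecule's fingerprint is registered in the DF memory
    and near neighbors are zeroed on subsequent calls.
    """
    if not record.valid:
        return ScoreParts(0.0, 0.0, False, True)
    raw = float(oracle(record))
    if not 0.0 <= raw <= 1.0:
        raise ValueError(f"oracle returned {raw!r}, outside [0, 1] — broken oracle")
    prop = property_filter(record, cfg)
    df = df_check(record.fingerprint, state) if state is not None else True
    final = raw if (prop and df) else 0.0
    if state is not None and state.enabled and prop and df and raw >= state.hit_score_threshold:
        df_register_hit(state, record.fingerprint)
    return ScoreParts(final, raw, prop, df)


@dataclass
class ScoringContext:
    """Bundle of oracle + filters + DF memory handed to the run harness."""

    oracle: Oracle
    property_config: PropertyFilterConfig = field(default_factory=PropertyFilterConfig)
    df_state: DiversityFilterState | None = field(default_factory=DiversityFilterState)
    hit_threshold: HitThreshold = field(default_factory=HitThreshold)

    def score(self, record: MoleculeRecord) -> ScoreParts:
        return composite_score(record, self.oracle, self.property_config, self.df_state)


def load_scoring_config(path) -> tuple[PropertyFilterConfig, DiversityFilterState, HitThreshold]:
    """Read an INI-style config with [filters], [df] and [hit] sections.

    Absent keys fall back to the benchmark defaults.
    """
    import configparser

    parser = configparser.ConfigParser()
    read = parser.read(path)
    if not read:
        raise FileNotFoundError(f"config file not found: {path}")
    f = parser["filters"] if parser.has_section("filters") else {}
    d = parser["df"] if parser.has_section("df") else {}
    h = parser["hit"] if parser.has_section("hit") else {}
    cfg = PropertyFilterConfig(
        mw_range=(float(f.get("mw_min", 157.0)), float(f.get("mw_max", 761.0))),
        logp_range=(float(f.get("logp_min", -2.0)), float(f.get("logp_max", 8.3))),
        idiosyncratic_range=(float(f.get("idio_min", 0.0)), float(f.get("idio_max", 0.08))),
    )
    state = DiversityFilterState(
        distance_threshold=float(d.get("threshold", 0.7)),
        enabled=str(d.get("enabled", "true")).lower() in ("1", "true", "yes"),
    )
    return cfg, state, HitThreshold(S=float(h.get("s", 0.5)))
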