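"""Budget-constrained run loop and post-hoc evaluation of run logs.

A *run* wraps an arbitrary generator in two kinds of computational budget:
a sample limit (default 10 000 scoring-function evaluations) or a time
limit (default 600 s of wall clock).  Every evaluation is appended to an
:class:`~divhits.io.EvaluationLog`; all results — diverse-hit counts,
budget curves, cross-generator rank tables — are recomputed from that log
after the fact, so a hit whose score the diversity filter zeroed during
optimization is never lost.

Budget accounting: proposals are canonicalized and cached, and a repeated
canonical SMILES is answered from the cache without consuming budget (the
budget counts *scoring function evaluations*, and re-scoring a known
molecule is free; strict counting is available via ``count_duplicates``).
Invalid proposals consume budget — invalid generation is penalized, not
hidden.  Time budgets are checked between scoring calls, so a batch may
overshoot the wall-clock limit; the log carries per-call timestamps and
:func:`evaluate_log` truncates at the cutoff post hoc, making reported
results overshoot-free.
"""

from __future__ import annotations

import time
import traceback
import warnings
import zlib
from dataclasses import dataclass, field
from typing import Callable, Protocol, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .chem import DEFAULT_FP_CONFIG, FingerprintConfig, canonicalize, tanimoto_distance
from .diversity import EXACT_MAX_N, DiverseHitResult, n_circles_exact, n_circles_greedy
from .io import EvaluationLog, ScoreRecord
from .scoring import ScoreParts, ScoringContext, is_hit

__all__ = [
    "BudgetConfig",
    "BudgetView",
    "BudgetExhausted",
    "RunResult",
    "named_rng",
    "run",
    "evaluate_log",
    "diverse_hits_curve",
    "aggregate",
    "RankReport",
]


@dataclass(frozen=True)
class BudgetConfig:
    """The two constraint regimes: max oracle calls and/or max wall seconds.

    At least one limit must be finite.  ``mode`` names the regime used for
    reporting: sample-limited when ``max_calls`` is finite, otherwise
    time-limited.
    """

    max_calls: int | None = 10_000
    max_seconds: float | None = 600.0

    def __post_init__(self) -> None:
        if self.max_calls is None and self.max_seconds is None:
            raise ValueError("at least one budget limit must be finite")
        if self.max_calls is not None and self.max_calls <= 0:
            raise ValueError("max_calls must be positive")
        if self.max_seconds is not None and self.max_seconds <= 0:
            raise ValueError("max_seconds must be positive")

    @property
    def mode(self) -> str:
        return "sample_limit" if self.max_calls is not None else "time_limit"


class BudgetExhausted(Exception):
    """Raised by the scoring callback once the budget is spent."""


class BudgetView:
    """Read-only budget state exposed to generators."""

    def __init__(self, budget: BudgetConfig, clock: Callable[[], float]) -> None:
        self._budget = budget
        self._clock = clock
        self._start = clock()
        self.calls_used = 0

    @property
    def max_calls(self) -> int | None:
        return self._budget.max_calls

    @property
    def max_seconds(self) -> float | None:
        return self._budget.max_seconds

    @property
    def elapsed_seconds(self) -> float:
        return self._clock() - self._start

    @property
    def exhausted(self) -> bool:
        if self._budget.max_calls is not None and self.calls_used >= self._budget.max_calls:
            return True
        if self._budget.max_seconds is not None and self.elapsed_seconds >= self._budget.max_seconds:
            return True
        return False


class Generator(Protocol):
    """Generator plug-in contract.

    A generator is a callable receiving a scoring callback, a budget view
    and a seeded random generator.  It proposes batches of SMILES through
    the callback, which returns one final score per proposal, and must
    return once ``budget.exhausted`` is true (the callback also raises
    :class:`BudgetExhausted` as a hard stop).
    """

    def __call__(
        self,
        score: Callable[[Sequence[str]], list[float]],
        budget: BudgetView,
        rng: np.random.Generator,
    ) -> None: ...


@dataclass
class RunResult:
    """A completed (or aborted) run: the log plus identifying metadata."""

    log: EvaluationLog
    seed: int
    generator_name: str = ""
    task_name: str = ""
    constraint_mode: str = "sample_limit"
    error: str | None = None


def named_rng(seed: int, name: str) -> np.random.Generator:
    """Independent named random stream fanned out from one master seed."""
    return np.random.default_rng([seed, zlib.crc32(name.encode())])


def run(
    generator: Generator,
    context: ScoringContext,
    budget: BudgetConfig,
    seed: int,
    generator_name: str = "",
    task_name: str = "",
    fp_config: FingerprintConfig = DEFAULT_FP_CONFIG,
    clock: Callable[[], float] | None = None,
    count_duplicates: bool = False,
) -> RunResult:
    """Drive ``generator`` against ``context`` until the budget is spent.

    Every proposal (cached or not) is logged with its timestamp.  Under a
    pure sample limit the default clock is a constant zero so that
    identical (generator, seed, oracle) runs produce byte-identical logs;
    pass ``clock=time.monotonic`` to record real timestamps, or any
    zero-argument callable (e.g. a fake clock in tests) for reproducible
    time-limited runs.
    """
    if clock is None:
        clock = (lambda: 0.0) if budget.max_seconds is None else time.monotonic
    view = BudgetView(budget, clock)
    log = EvaluationLog()
    cache: dict[str, ScoreParts] = {}
    rng = named_rng(seed, "generator")

    def score(batch: Sequence[str]) -> list[float]:
        if view.exhausted:
            raise BudgetExhausted
        out: list[float] = []
        for smi in batch:
            record = canonicalize(smi, fp_config)
            key = record.canonical_smiles if record.valid else record.input_smiles
            cached = not count_duplicates and key in cache
            if not cached:
                if view.max_calls is not None and view.calls_used >= view.max_calls:
                    raise BudgetExhausted  # proposals past the limit stay unanswered
                parts = context.score(record)
                cache[key] = parts
                view.calls_used += 1
            else:
                parts = cache[key]
            log.append(
                ScoreRecord(
                    call_index=len(log),
                    elapsed_seconds=view.elapsed_seconds,
                    canonical_smiles=key,
                    raw_oracle=parts.raw,
                    property_pass=parts.property_pass,
                    df_pass=parts.df_pass,
                    final_score=parts.final,
                )
            )
            out.append(parts.final)
        return out

    error: str | None = None
    try:
        generator(score, view, rng)
    except BudgetExhausted:
        pass
    except Exception:
        error = traceback.format_exc()
    return RunResult(
        log=log,
        seed=seed,
        generator_name=generator_name,
        task_name=task_name,
        constraint_mode=budget.mode,
        error=error,
    )


def _hit_entries(
    log: EvaluationLog, S: float, time_cutoff: float | None
) -> list[ScoreRecord]:
    """Hits of a log (property pass and raw >= S; DF ignored), optionally
    truncated in time, deduplicated by canonical SMILES keeping first."""
    seen: set[str] = set()
    hits: list[ScoreRecord] = []
    for rec in log:
        if time_cutoff is not None and rec.elapsed_seconds > time_cutoff:
            continue
        if not is_hit(rec.raw_oracle, rec.property_pass, S):
            continue
        if rec.canonical_smiles in seen:
            continue
        seen.add(rec.canonical_smiles)
        hits.append(rec)
    return hits


def _fingerprints_for(smiles: Sequence[str], fp_config: FingerprintConfig) -> list[frozenset[int]]:
    return [canonicalize(s, fp_config).fingerprint or frozenset() for s in smiles]


def evaluate_log(
    log: EvaluationLog,
    S: float = 0.5,
    D_eval: float = 0.7,
    dist: Callable | None = None,
    time_cutoff: float | None = None,
    fp_config: FingerprintConfig = DEFAULT_FP_CONFIG,
    method: str = "auto",
) -> DiverseHitResult:
    """Diverse-hit count of a run log.

    Filters to hits (property pass and raw score >= S — the diversity
    filter is ignored so suppressed duplicates of real hits still count),
    optionally truncates to ``elapsed_seconds <= time_cutoff``, removes
    duplicate canonical SMILES, then counts circles: exactly when the hit
    set is small (<= 25), by greedy sphere exclusion in log (discovery)
    order otherwise.  Distances default to Tanimoto on fingerprints
    recomputed from the logged canonical SMILES, so the computation is a
    pure function of the log.
    """
    hits = _hit_entries(log, S, time_cutoff)
    if dist is None:
        items: Sequence = _fingerprints_for([h.canonical_smiles for h in hits], fp_config)
        dist = tanimoto_distance
    else:
        items = [h.canonical_smiles for h in hits]
    if method == "auto":
        method = "exact" if len(hits) <= EXACT_MAX_N else "greedy"
    if method == "exact":
        return n_circles_exact(items, dist, D_eval)
    if method == "greedy":
        return n_circles_greedy(items, dist, D_eval)
    raise ValueError(f"unknown method {method!r}")


def diverse_hits_curve(
    log: EvaluationLog,
    S: float = 0.5,
    D_eval: float = 0.7,
    checkpoints: Sequence[float] = (),
    by: str = "calls",
    dist: Callable | None = None,
    fp_config: FingerprintConfig = DEFAULT_FP_CONFIG,
) -> list[tuple[float, int]]:
    """Diverse-hit count at increasing budget checkpoints.

    ``by="calls"`` reads checkpoints as numbers of evaluations (a record
    counts toward checkpoint c when ``call_index < c``); ``by="time"``
    reads them as seconds.  The greedy scan in log order is online, so a
    prefix of the log selects a prefix of the representatives and the
    curve is non-decreasing.
    """
    if list(checkpoints) != sorted(checkpoints):
        raise ValueError("checkpoints must be sorted ascending")
    if by not in ("calls", "time"):
        raise ValueError(f"unknown checkpoint axis {by!r}")
    hits = _hit_entries(log, S, None)
    if dist is None:
        items: Sequence = _fingerprints_for([h.canonical_smiles for h in hits], fp_config)
        dist = tanimoto_distance
    else:
        items = [h.canonical_smiles for h in hits]
    selected = n_circles_greedy(items, dist, D_eval).selected
    coords = [
        hits[i].call_index + 1 if by == "calls" else hits[i].elapsed_seconds for i in selected
    ]
    coords.sort()
    return [(c, int(np.searchsorted(coords, c, side="right"))) for c in checkpoints]


@dataclass
class RankReport:
    """Aggregated benchmark report.

    ``cells``: one row per (generator, task) with min/median/max diverse-hit
    counts over seeds.  ``ranking``: per generator, the rank within each
    task by median count (rank 1 = highest, ties share the mean rank) and
    the average rank across tasks; sorted best first.
    """

    cells: pd.DataFrame
    ranking: pd.DataFrame


def aggregate(
    results: Sequence[RunResult],
    S: float = 0.5,
    D_eval: float = 0.7,
    dist: Callable | None = None,
    fp_config: FingerprintConfig = DEFAULT_FP_CONFIG,
    time_cutoff: float | None = None,
) -> RankReport:
    """Turn a collection of runs into the cross-generator rank table."""
    if not results:
        raise ValueError("aggregate requires at least one run result")
    rows = []
    for res in results:
        count = evaluate_log(
            res.log, S=S, D_eval=D_eval, dist=dist, time_cutoff=time_cutoff, fp_config=fp_config
        ).count
        rows.append(
            {
                "generator": res.generator_name,
                "task": res.task_name,
                "seed": res.seed,
                "diverse_hits": count,
            }
        )
    per_run = pd.DataFrame(rows)
    cells = (
        per_run.groupby(["generator", "task"])["diverse_hits"]
        .agg(n_seeds="size", min="min", median="median", max="max")
        .reset_index()
    )
    tasks = sorted(cells["task"].unique())
    generators = sorted(cells["generator"].unique())
    rank_cols: dict[str, pd.Series] = {}
    for task in tasks:
        sub = cells[cells["task"] == task].set_index("generator")["median"]
        missing = [g for g in generators if g not in sub.index]
        if missing:
            warnings.warn(f"task {task!r}: no runs for {missing}; excluded from rank averaging")
        ranks = rankdata(-sub.values, method="average")
        rank_cols[task] = pd.Series(ranks, index=sub.index)
    ranking = pd.DataFrame({f"rank_{t}": rank_cols[t] for t in tasks}, index=pd.Index(generators, name="generator"))
    ranking["average_rank"] = ranking.mean(axis=1, skipna=True)
    ranking = ranking.sort_values("average_rank").reset_index()
    return RankReport(cells=cells, ranking=ranking)
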