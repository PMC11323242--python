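"""Run loop budget accounting, log determinism, and post-hoc evaluation."""

import itertools

import numpy as np
import pytest

from divhits.harness import (
    BudgetConfig,
    RunResult,
    aggregate,
    diverse_hits_curve,
    evaluate_log,
    run,
)
from divhits.io import EvaluationLog, ScoreRecord, read_log_csv, write_log_csv
from divhits.scoring import DiversityFilterState, PropertyFilterConfig, ScoringContext


def unique_stream_generator(batch_size=7):
    """Proposes an endless stream of distinct alkanes."""

    def generator(score, budget, rng):
        counter = itertools.count()
        while not budget.exhausted:
            score(["C" * (next(counter) + 1) for _ in range(batch_size)])

    return generator


def repeat_generator(smiles, times, batch_size=10):
    def generator(score, budget, rng):
        remaining = times
        while remaining > 0 and not budget.exhausted:
            k = min(batch_size, remaining)
            score([smiles] * k)
            remaining -= k

    return generator


def toy_context(raw=0.8, df=True):
    return ScoringContext(
        oracle=lambda record: raw,
        property_config=PropertyFilterConfig(),
        df_state=DiversityFilterState() if df else None,
    )


def fake_clock(step=1.0):
    """Deterministic clock advancing ``step`` seconds per reading."""
    t = itertools.count()
    return lambda: next(t) * step


class TestBudgetAccounting:
    def test_sample_budget_exactly_consumed(self):
        budget = BudgetConfig(max_calls=10, max_seconds=None)
        res = run(unique_stream_generator(), toy_context(), budget, seed=0)
        assert len(res.log) == 10
        assert res.error is None

    def test_duplicates_answered_from_cache_without_budget(self):
        budget = BudgetConfig(max_calls=10, max_seconds=None)
        res = run(repeat_generator("CCO", times=100), toy_context(), budget, seed=0)
        # all 100 proposals logged, but only the first consumed budget
        assert len(res.log) == 100
        distinct = {r.canonical_smiles for r in res.log}
        assert distinct == {"CCO"}

    def test_strict_counting_mode_charges_duplicates(self):
        budget = BudgetConfig(max_calls=10, max_seconds=None)
        res = run(
            repeat_generator("CCO", times=100),
            toy_context(),
            budget,
            seed=0,
            count_duplicates=True,
        )
        assert len(res.log) == 10

    def test_invalid_proposals_consume_budget(self):
        def garbage(score, budget, rng):
            score(["x%d!" % i for i in range(20)])

        budget = BudgetConfig(max_calls=5, max_seconds=None)
        res = run(garbage, toy_context(), budget, seed=0)
        assert len(res.log) == 5
        assert all(not r.property_pass and r.final_score == 0.0 for r in res.log)

    def test_time_budget_truncates_between_batches(self):
        budget = BudgetConfig(max_calls=None, max_seconds=5.0)
        res = run(
            unique_stream_generator(batch_size=3),
            toy_context(),
            budget,
            seed=0,
            clock=fake_clock(step=1.0),
        )
        # the clock passes 5 s mid-batch; the batch finishes, the next never starts
        assert res.error is None
        assert res.log[-1].elapsed_seconds >= 5.0
        assert len(res.log) <= 12

    def test_generator_exception_preserves_partial_log(self):
        def crashy(score, budget, rng):
            score(["CCO", "CCC"])
            raise RuntimeError("boom")

        res = run(crashy, toy_context(), BudgetConfig(max_calls=10, max_seconds=None), seed=0)
        assert len(res.log) == 2
        assert res.error is not None and "boom" in res.error

    def test_at_least_one_limit_required(self):
        with pytest.raises(ValueError):
            BudgetConfig(max_calls=None, max_seconds=None)


class TestDeterminism:
    def test_same_seed_gives_byte_identical_csv(self, tmp_path, library100):
        from divhits.baselines import vs_random

        budget = BudgetConfig(max_calls=50, max_seconds=None)
        paths = []
        for i in (1, 2):
            res = run(vs_random(library100), toy_context(), budget, seed=11)
            p = tmp_path / f"run{i}.csv"
            write_log_csv(res.log, p)
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_round_tripped_log_reproduces_count(self, tmp_path, library100):
        from divhits.baselines import vs_random

        budget = BudgetConfig(max_calls=60, max_seconds=None)
        res = run(vs_random(library100), toy_context(raw=0.7), budget, seed=5)
        p = tmp_path / "log.csv"
        write_log_csv(res.log, p)
        assert evaluate_log(read_log_csv(p)).count == evaluate_log(res.log).count


def synthetic_log(entries):
    """Build a log from (smiles_token, elapsed, raw, prop) tuples."""
    log = EvaluationLog()
    for i, (token, elapsed, raw, prop) in enumerate(entries):
        log.append(
            ScoreRecord(
                call_index=i,
                elapsed_seconds=elapsed,
                canonical_smiles=token,
                raw_oracle=raw,
                property_pass=prop,
                df_pass=True,
                final_score=raw if prop else 0.0,
            )
        )
    return log


def token_dist(a, b):
    """Abstract distance on string tokens: same first letter -> close."""
    if a == b:
        return 0.0
    return 0.2 if a[0] == b[0] else 0.9


class TestEvaluateLog:
    def test_no_hits_gives_zero(self):
        log = synthetic_log([("a1", 0.0, 0.2, True), ("b1", 1.0, 0.9, False)])
        assert evaluate_log(log, dist=token_dist).count == 0

    def test_distant_hits_all_counted(self):
        log = synthetic_log([("a1", 0.0, 0.9, True), ("b1", 1.0, 0.8, True), ("c1", 2.0, 0.7, True)])
        assert evaluate_log(log, dist=token_dist).count == 3

    def test_near_duplicate_hits_collapse(self):
        log = synthetic_log([("a1", 0.0, 0.9, True), ("a2", 1.0, 0.8, True), ("b1", 2.0, 0.7, True)])
        assert evaluate_log(log, D_eval=0.7, dist=token_dist).count == 2

    def test_exact_duplicates_deduplicated(self):
        log = synthetic_log([("a1", 0.0, 0.9, True), ("a1", 1.0, 0.9, True)])
        assert evaluate_log(log, dist=token_dist).count == 1

    def test_time_cutoff_truncates(self):
        log = synthetic_log([("a1", 100.0, 0.9, True), ("b1", 700.0, 0.9, True)])
        assert evaluate_log(log, dist=token_dist, time_cutoff=600.0).count == 1
        assert evaluate_log(log, dist=token_dist).count == 2

    def test_df_suppressed_hits_still_count(self):
        log = synthetic_log([("a1", 0.0, 0.9, True)])
        log.append(
            ScoreRecord(1, 1.0, "b1", 0.8, True, False, 0.0)  # DF zeroed this one
        )
        assert evaluate_log(log, dist=token_dist).count == 2

    def test_count_bounded_by_unique_hits(self):
        rng = np.random.default_rng(0)
        entries = [
            (f"{'abcde'[rng.integers(5)]}{rng.integers(3)}", float(i), float(rng.random()), True)
            for i in range(60)
        ]
        log = synthetic_log(entries)
        unique_hits = len({t for t, _, raw, _ in entries if raw >= 0.5})
        assert evaluate_log(log, dist=token_dist).count <= unique_hits <= len(entries)


class TestDiverseHitsCurve:
    def test_checkpoint_zero_and_past_end(self):
        log = synthetic_log([("a1", 0.0, 0.9, True), ("b1", 1.0, 0.9, True)])
        curve = diverse_hits_curve(log, checkpoints=[0, 1, 2, 1000], dist=token_dist)
        assert curve[0] == (0, 0)
        assert curve[-1] == (1000, 2)

    def test_prefix_monotone_over_random_logs(self):
        rng = np.random.default_rng(123)
        for _ in range(50):
            n = int(rng.integers(1, 40))
            entries = [
                (
                    f"{'abcdefg'[rng.integers(7)]}{rng.integers(4)}",
                    float(i),
                    float(rng.random()),
                    bool(rng.random() < 0.8),
                )
                for i in range(n)
            ]
            log = synthetic_log(entries)
            checkpoints = list(range(0, n + 5, 3))
            counts = [c for _, c in diverse_hits_curve(log, checkpoints=checkpoints, dist=token_dist)]
            assert all(x <= y for x, y in zip(counts, counts[1:]))
            # the final checkpoint agrees with greedy evaluation of the full log
            full = evaluate_log(log, dist=token_dist, method="greedy").count
            assert counts[-1] == full

    def test_unsorted_checkpoints_rejected(self):
        with pytest.raises(ValueError):
            diverse_hits_curve(synthetic_log([]), checkpoints=[5, 1], dist=token_dist)


def result_for(generator, task, seed, hit_tokens):
    log = synthetic_log([(t, float(i), 0.9, True) for i, t in enumerate(hit_tokens)])
    return RunResult(log=log, seed=seed, generator_name=generator, task_name=task)


class TestAggregate:
    def test_single_generator_stats(self):
        results = [
            result_for("g", "t", 0, ["a1", "b1", "c1", "d1", "e1"]),
            result_for("g", "t", 1, ["a1", "b1", "c1", "d1", "e1", "f1", "g1"]),
            result_for("g", "t", 2, ["a1", "b1", "c1", "d1", "e1", "f1"]),
        ]
        report = aggregate(results, dist=token_dist)
        row = report.cells.iloc[0]
        assert (row["min"], row["median"], row["max"]) == (5, 6, 7)
        assert report.ranking.iloc[0]["average_rank"] == 1.0

    def test_dominant_generator_ranks_first_everywhere(self):
        results = []
        for task in ("t1", "t2"):
            for seed in range(2):
                results.append(result_for("good", task, seed, [f"{c}1" for c in "abcdefghij"]))
                results.append(result_for("bad", task, seed, ["a1", "b1"]))
        report = aggregate(results, dist=token_dist)
        ranking = report.ranking.set_index("generator")
        assert ranking.loc["good", "average_rank"] == 1.0
        assert ranking.loc["bad", "average_rank"] == 2.0
        assert list(report.ranking["generator"]) == ["good", "bad"]

    def test_tie_shares_mean_rank(self):
        results = [
            # t1: tied medians; t2: g1 wins
            result_for("g1", "t1", 0, ["a1", "b1"]),
            result_for("g2", "t1", 0, ["c1", "d1"]),
            result_for("g1", "t2", 0, ["a1", "b1", "c1"]),
            result_for("g2", "t2", 0, ["a1"]),
        ]
        ranking = aggregate(results, dist=token_dist).ranking.set_index("generator")
        assert ranking.loc["g1", "rank_t1"] == 1.5
        assert ranking.loc["g2", "rank_t1"] == 1.5
        assert ranking.loc["g1", "average_rank"] == 1.25
        assert ranking.loc["g2", "average_rank"] == 1.75

    def test_missing_cell_warns_and_is_excluded(self):
        results = [
            result_for("g1", "t1", 0, ["a1", "b1"]),
            result_for("g1", "t2", 0, ["a1"]),
            result_for("g2", "t1", 0, ["a1"]),
        ]
        with pytest.warns(UserWarning, match="t2"):
            ranking = aggregate(results, dist=token_dist).ranking.set_index("generator")
        assert np.isnan(ranking.loc["g2", "rank_t2"])
        assert ranking.loc["g2", "average_rank"] == 2.0  # only t1 contributes
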