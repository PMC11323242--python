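# Methods

This note documents the models, conventions and numerical choices behind
`divhits`, in the order a user meets them: the diversity metric, the
composite scoring function, the budget harness, the baselines, and the
synthetic fixtures the tests and the acceptance script run on.

## The diverse-hit count

A molecule is a **hit** when its raw oracle score is at least S (default
0.5, the natural threshold for a probabilistic binary-activity classifier)
*and* it passes the property filters. The **diverse-hit count** of a run is

    #Circles(H, D) = max { |C| : C ⊆ H, d(x, y) > D for all x ≠ y in C },

the maximum number of hits that are pairwise farther apart than the distance
threshold D. Conventions:

* **Distance.** Jaccard/Tanimoto distance on binary folded Morgan
  fingerprints, radius 2, 2048 bits. These are the de-facto community
  defaults; both are configurable (`FingerprintConfig`). Binary Jaccard
  distance is a true metric, which the exact solver does not need but the
  tests verify because users reasonably assume it. Two all-zero
  fingerprints are identical vectors, so their distance is 0.
* **Strict inequality.** Pairs at exactly d = D are *excluded* (no circle
  center may lie within — or on the rim of — another circle). With D = 0
  the count therefore equals the number of distinct fingerprints, and with
  D ≥ the set diameter it is 1.
* **Exact solver.** Maximum independent set of the threshold graph (edge
  wherever d ≤ D), solved by branch-and-bound: a greedy packing seeds the
  incumbent, branching always picks the candidate vertex with most
  remaining conflicts, and any subtree whose candidate count cannot beat
  the incumbent is pruned. The search is exponential in the worst case and
  is capped at n = 25 by default; beyond the cap the call raises and
  directs the user to the greedy estimator.
* **Greedy estimator.** Sphere exclusion: scan in a given order, keep an
  item iff it is farther than D from everything kept. It yields a maximal
  packing, hence a lower bound on the exact count (equal whenever the
  threshold graph is empty or complete). The default scan order is the
  *log/discovery order*, which makes results reproducible from a log alone
  and means the selection over any prefix of a run is a prefix of the full
  selection — this is what makes budget curves non-decreasing by
  construction rather than by re-solving.
* **Evaluation.** `evaluate_log` ignores the diversity filter when deciding
  hits (raw ≥ S and property pass only): the DF is an *optimization*
  device, and a genuine hit that was zeroed because a near neighbor came
  first must still count. Deduplication is by canonical SMILES, keeping
  first occurrence. Hit sets of ≤ 25 are counted exactly, larger ones
  greedily.

Internal diversity (mean pairwise distance over unordered pairs, diagonal
excluded — some authors include it; we document the exclusion) and
unique/Bemis–Murcko-scaffold counts are provided as the classical
comparison metrics. The constructed-pathology tests demonstrate the known
failure: two tight, mutually distant clusters carry higher internal
diversity than fifteen evenly spread points, while the circle count orders
them the other way, and adding a molecule can strictly decrease internal
diversity.

## Composite scoring

The score a generator receives is the product

    final = raw_oracle × 1[property filters pass] × 1[diversity filter passes]

* **Property ranges** (lenient drug-likeness): MW ∈ [157, 761] Da,
  logP ∈ [−2.0, 8.3], idiosyncratic-substructure fraction ∈ [0.00, 0.08].
  Bounds are inclusive. Violating any range zeroes the final score; the raw
  oracle value is still logged.
* **Idiosyncratic fraction.** The fraction of a molecule's atom-centered
  circular environment keys (radii 0..2, unfolded hashes) that are absent
  from a reference vocabulary. The vocabulary is an explicit input — build
  one from any reference collection with `vocabulary_from_records`; when no
  vocabulary is supplied the term is skipped. This key-coverage definition
  is this package's own operationalization of "unusual substructures"; it
  has the intended range semantics (0 for in-distribution molecules,
  approaching 1 for alien chemistry) and is cheap enough for per-call use.
* **Diversity filter (DF).** A monotone, append-only memory of hit
  fingerprints. A molecule within Tanimoto distance ≤ 0.7 of any stored
  hit scores zero. A molecule registers into the memory when its raw score
  reaches the registration threshold (0.5) with both filters passing —
  per-hit memory, the simplest faithful policy; DF-suppressed
  near-duplicates are not re-registered. The DF can be disabled
  (`enabled=False`), which never changes hit determination, only the
  feedback a generator sees.
* **Hit threshold boundary.** "Score at least S" is implemented inclusively
  (raw ≥ S). For probabilistic oracles the boundary is measure-zero; the
  choice is documented and configurable.
* **Invalid SMILES** are values, not errors: they score raw = final = 0,
  fail the property filter by definition, never register in the DF — and
  *do* consume budget, so invalid generation is penalized rather than
  hidden.
* Oracles returning values outside [0, 1] raise immediately (broken-oracle
  guard).

## The budget harness

* **Budgets.** Sample limit (default 10 000 scoring-function evaluations)
  or wall-time limit (default 600 s); both limits may be combined, at least
  one must be finite.
* **Caching.** Proposals are canonicalized; a repeated canonical SMILES is
  answered from a cache, logged, and charged no budget — the budget counts
  *oracle evaluations*, and re-scoring a known molecule is free in any
  sane deployment. `count_duplicates=True` switches to strict counting for
  sensitivity analysis. Invalid proposals are cached under their raw text
  after consuming budget once.
* **Timestamps and determinism.** Every logged record carries
  `elapsed_seconds`. Under a pure sample limit the default clock is a
  constant zero so identical (generator, seed, oracle) runs produce
  byte-identical log CSVs; real or fake clocks are injectable. Under a time
  limit the budget check runs between scoring calls, so a batch may
  overshoot the limit; the log's timestamps let `evaluate_log` truncate at
  exactly the cutoff post hoc, making reported results overshoot-free.
* **Seeding.** One master seed fans out to independent named streams
  (`named_rng(seed, name)`, seed-sequence keyed by a CRC of the name) for
  generator randomness, oracle noise and library shuffling.
* **Aborts.** A generator exception preserves the partial log and flags the
  result rather than discarding the run.
* **Ranking.** Per (generator, task): min/median/max diverse-hit count over
  seeds. Per task, generators are ranked by median count (rank 1 best, ties
  share the mean of tied ranks); the report orders generators by the
  arithmetic mean of ranks across tasks. The median as central tendency is
  this package's choice; missing cells are excluded from the average with a
  warning.
* **Log CSV.** Columns `call_index, elapsed_seconds, canonical_smiles,
  raw_oracle, property_pass, df_pass, final_score`; floats are written with
  shortest round-trip `repr`, so write→read is bit-exact and every reported
  number is recomputable from the file alone.

## Baselines

* **VS random** screens a deduplicated library in a seeded uniform random
  order; **VS MaxMin** first sorts it with the MaxMin algorithm (start
  fixed at index 0 for reproducibility; ties broken by smallest index) so
  the earliest evaluations are the most mutually distant. MaxMin ordering
  runs on packed 64-bit fingerprint words (`np.bitwise_count`), with an
  O(n²) incremental update; the generic distance-oracle implementation is
  tested to agree with the vectorized one exactly.
* **Mutation GA** is a deliberately minimal feedback-using reference
  generator, not a reproduction of any published method: keep the
  best-scoring molecules seen, apply atom-level edits (append atom, delete
  terminal atom, swap element; binomial(atom count, mutation rate) edits
  per offspring, so rate 0 reproduces the parent), retry on sanitization
  failure up to 10 times, then fall back to a methyl extension of the
  parent. A stall guard terminates it after 50 consecutive generations that
  consumed no budget, which makes the degenerate zero-rate setting
  terminate cleanly.

## Synthetic fixtures and what they do (and do not) show

The fixture library deterministically enumerates ~2 500 molecules by
decorating 16 ring scaffolds with up to two of 23 substituents, spanning
MW ≈ 82–639 Da and logP ≈ −2 to 15, so the property filters genuinely bite
on both tails. The toy oracle scores a molecule as its maximum Tanimoto
similarity to a set of active seeds, raised to a steepness power — the
contract of a probabilistic activity model (output in [0, 1], hits at 0.5,
smooth landscape around actives) without any training data. Everything is
byte-reproducible from a seed.

Two standard task configurations are used by the tests and the acceptance
script:

* the **clustered task** (library of 600, 8 actives, steepness 0.25): the
  shallow landscape makes most of the library a hit, so at budget 100 the
  binding constraint is how many distinct regions a screen touches — the
  regime where MaxMin ordering beats random order;
* a **sharper variant** (library of 2 000, 12 actives, steepness 0.5,
  budget 500) where hits concentrate around the active clusters.

For the feedback-exploitation comparison, designated actives
(`EXTERNAL_ACTIVE_SEEDS`) lie deliberately *outside* the enumerable library
space: random screening saturates at the library's similarity ceiling
(≈ 0.3) while the GA's median best score climbs past it.

What these fixtures do **not** emulate: real QSAR landscapes (activity
cliffs, multi-pharmacophore SAR), assay noise, synthesizability, or the
scale and redundancy of real screening collections. Passing tests show the
*accounting* — metric correctness, filter semantics, budget conservation,
determinism — is right, and that the qualitative orderings the metric is
built to expose arise for the constructed reasons; they do not certify
generator performance on real targets.

## Problem sizes

Exhaustive-enumeration checks of the exact solver run at n ≤ 12 over ≥ 200
random instances (the 2ⁿ oracle is the bottleneck, not the solver, which
handles n = 25 routinely); monotonicity chains use n = 15. The acceptance
pipeline runs 2 tasks × 3 generators × 3 seeds at budgets of 100 and 500
calls — a desk-scale rendition of the 10 000-call / 600 s regimes, chosen so
the full pipeline (library enumeration, runs, post-hoc evaluation, ranking)
completes in well under a minute while every code path of the full-scale
configuration is exercised.

## Known limitations

* The exact circle count is exponential; beyond n = 25 only the greedy
  lower bound is practical. Greedy counts are order-dependent (documented,
  and the order is part of the result's provenance).
* Binary folded fingerprints can collide: homologous long-chain molecules
  may share identical bit sets and thus count as one circle at any D ≥ 0.
* The idiosyncrasy measure depends on the supplied vocabulary; a small
  vocabulary makes ordinary chemistry look idiosyncratic.
* Wall-time budgets measure the host's clock: cross-machine comparisons
  under time limits are only meaningful on matched hardware.
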