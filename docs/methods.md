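# Methods

## Effect measures and continuity correction

Each study is a 2×2 table (e1, n1, e0, n0), arm 1 = treatment. Effects
are analysed on the scale where the null is 0: log odds ratio, log
relative risk, or the risk difference itself. Standard errors are the
usual delta-method forms over the (possibly corrected) cells. If any of
the four cells {events, non-events} × {arms} is zero, 0.5 is added to
all four cells of that study — the corrected arm sizes are n + 1 — and
the correction is re-resolved on *every* fit: the fragility search
mutates counts, and a flip can create or remove a zero cell, so
correction status is a function of the current table, never cached.

Studies with zero events in both arms carry no information about a
relative effect. By default they are excluded from OR/RR fits
(`dz_policy="exclude"`) and retained, corrected, for RD; the
alternative (`"correct"`) keeps them for all measures. Both are
supported because usage in the field varies and neither choice is
canonical.

## Pooling, heterogeneity, intervals

Fixed-effect pooling uses weights 1/s_i²; the random-effects model uses
1/(s_i² + τ̂²). Cochran's Q is computed with fixed-effect weights;
I² = max(0, (Q − df)/Q), defined as 0 when Q = 0.

τ² estimators:

* **DL** — the moment estimator max(0, (Q − df)/(Σw − Σw²/Σw)),
  non-iterative.
* **REML** — fixed-point iteration on the restricted-likelihood score,

      τ² ← max(0, Σw*²[(y−θ̂)² − s²]/Σw*² + 1/Σw*),  w* = 1/(s² + τ²),

  started at the DL estimate, stopping when successive iterates change
  by < 1e−8, with a cap of 100 sweeps. In the equal-variance case the
  fixed point is max(0, sample variance − v), which the tests verify;
  the iterate also matches direct numerical maximisation of the
  explicit restricted log-likelihood to ~1e−6. Non-convergence within
  the cap is a reported state (`converged=False`), never an exception:
  analyses flag the meta-analysis as excluded for REML scenarios while
  retaining DL and fixed-effect results. The tolerance and cap are
  conventional defaults; regenerated corpora will not reproduce any
  particular published exclusion count, which depends on the original
  data and solver settings.

Intervals: the conventional normal (z) interval with se = (Σw*)^(−1/2),
or the HKSJ interval with variance Σw*(y − θ̂)²/((N−1)Σw*) and t(N−1)
quantiles. The HKSJ form is unmodified — no truncation guard — so it
can be narrower than the normal interval, and when all study effects
are identical its variance is exactly 0; that state is flagged
`degenerate` and judged by the (zero-width) interval as computed rather
than patched. Significance always means the 95% interval excludes 0 on
the analysis scale, equivalent to p < α = 0.05 for these symmetric
intervals.

The five scenario keys are FE, S1 (REML+HKSJ), S2 (REML, normal), S3
(DL+HKSJ), S4 (DL, normal).

## Fragility search

The FI is found by deterministic beam search over single-patient
flips. Every candidate state is re-fitted from scratch under the full
scenario; states are scored by how far the p-value moved toward the α
boundary, the `beam_width` best states survive each depth, visited
count configurations are never re-expanded, and the first depth
containing a verdict change is the FI. Tie-breaks are fixed (stable
sort; expansion order: lower study index first, treatment arm before
control, event-removal before event-addition), so results are
bit-reproducible.

Two design points deserve emphasis, both discovered by checking against
the exhaustive oracle:

* **All four flip types are candidates**, not only the two that move
  the pooled effect toward the target. A true minimum can spend a flip
  moving a study *away* from the null because doing so triggers the
  study's continuity correction and deflates its weight; and for an
  initially nonsignificant dataset under HKSJ, the cheapest route to
  significance is often to *homogenise* the study effects so the
  empirical variance collapses. A direction-restricted search misses
  both.
* **The default width is direction-dependent**: 32 when the dataset is
  initially significant (unwinding significance is a smooth descent
  that the p-score tracks well) and 256 when it is not (reaching
  significance can require coordinated flips that a narrow myopic beam
  prunes away). Width 1 recovers a plain greedy search.

The oracle, `fragility_index_ma_exact`, enumerates net event-count
change vectors over all (study, arm) cells in increasing total
magnitude 1, 2, …, cap, fitting states in vectorised chunks; a minimal
flip multiset never contains cancelling pairs, so net vectors cover all
minima, and the first magnitude with a verdict change is the exact FI —
which also certifies that no smaller flip set works. It is exponential
in the cap and intended for small instances, verification, and the
`--exact` CLI flag. On random small instances (2–4 studies, arms ≤ 25,
all five scenarios, three seeds, 440 instances) the beam search agreed
with the oracle in every case.

The search cap defaults to 2 × total events (at least 1); exhausting it
yields `fi = None` (not attainable) rather than a value. The FQ is the
exact ratio FI / Σ(n1 + n0).

Per-study FIs (used by the improvement metric) apply the same flip
semantics to a single table with the two-sided Fisher exact test as the
significance criterion — the individual-trial FI convention; the
p-value is computed from hypergeometric point probabilities and matches
`scipy.stats.fisher_exact`. The per-study search is exhaustive (the
state space is two cells).

## Improvement metric

For an MA with FI_MA and study FIs FI_1..FI_N, the improvement
proportion is 100 × N⁻¹ Σ I(FI_i < FI_MA). Categories: 0% → none;
(0, 50%] → slight; (50%, 100%) → considerable; 100% → complete. The
boundary at exactly 50% is assigned to "slight" so that "considerable"
is the open interval, matching the strict-inequality phrasing used for
that band; the source definitions are ambiguous at the edges, so the
choice is fixed here and tested. Studies whose FI is not attainable
within the per-study cap (default 20 in corpus runs) count as
infinitely robust — never more fragile than the MA — making the
proportion conservative.

## Subgroup conventions

All count bins are half-open [a, b): total sample size
{<50, 50–100, 100–200, 200–500, 500–1000, ≥1000}; total events
{<10, 10–50, 50–100, 100–500, 500–1000, ≥1000}. So 50 falls in
"50–100" and 1000 in "≥1000". Effect-magnitude bands invert ratios
below 1 first; OR cuts 1.68 / 3.47 / 6.71 and RR cuts 1.22 / 1.86 /
3.00 (half-open, so OR = 1.68 is "moderate" and RR = 3.00 is "large").
RD has no accepted magnitude bands and is omitted from magnitude
analyses. I² interpretive bands are closed and deliberately
overlapping ([0,0.4] not important, [0.3,0.6] moderate, [0.5,0.9]
substantial, [0.75,1] considerable); where a unique assignment is
needed (improvement-by-heterogeneity strata) the non-overlapping
partition [0,0.4), [0.4,0.6), [0.6,0.75), [0.75,1] is used and is
configurable. Corpus summaries (median/IQR of FI and FQ, proportions
FI=1, ≤5, ≥22, FQ<0.01, <0.05, per-bin distributions) are computed on
the statistically significant subset per scenario, the convention for
fragility reporting.

## Synthetic corpus generator

No public corpus of this kind is distributable, so the generator
emulates its statistical structure from published marginal summaries.
Per meta-analysis: k ~ 2 + NegBin(0.8, 0.16) studies; balanced arm
sizes round(LogNormal(4.0, 1.1)) clipped below at 5; control risks
p0 ~ Beta(1.6, 7.5); a true mean effect θ_m ~ N(0, 0.5²) on the log-OR
scale across meta-analyses; study effects θ_i ~ N(θ_m, τ²) with
τ² = 0.05; treatment risks by inverting the log OR; binomial event
counts. These defaults were calibrated once against the published
profile (median 4 studies per MA, IQR 3–8; median total sample size
723; median 130 events; ≈29% significant under REML+HKSJ/OR) and then
frozen; a seed-1 profile gives medians 4 (3–7), 741 (381–1510), 126,
and 29.8% significant. The between-MA spread θ_sd is what produces a
realistic mix of truly null and non-null meta-analyses; with a single
shared θ the significant fraction would be degenerate.

True effects are always generated on the log-OR scale; RR and RD
analyses run on the same count tables, as is standard in
meta-epidemiological comparisons of measures.

What the generator does **not** emulate: clinical topic structure,
publication bias and small-study effects, mega-trial weight
concentration, correlated arm sizes, or non-balanced designs. Passing
tests therefore demonstrate correctness of the estimators and searches
and qualitative corpus-level behaviour (e.g. the HKSJ fragility
ordering), not quantitative agreement with any particular empirical
corpus. Two further small-sample facts are deliberate: with θ = τ² = 0
the FE rejection rate is slightly below α (≈0.04) and mean Q is ≈0.89
× df, because the continuity correction inflates the estimated
variances of small-count tables; both effects vanish on the
normal-model simulator (`simulate_normal_effects`), where mean Q ≈ df
holds exactly.

Everything is a deterministic function of (seed, index) via
`numpy.random.SeedSequence`, so corpora, analyses and summary files are
byte-reproducible for a fixed seed and configuration.

## Problem sizes used in the checks

The shipped checks use sizes chosen to exercise the full pipeline at
meaningful scale on one CPU: 200 random small instances × 5 scenarios
for beam-vs-oracle equality (cap 5); 2,000 simulated meta-analyses
(k = 10, θ = 0.5, τ² = 0.1) for REML recovery and HKSJ coverage, and
2,000 at k = 3 for the coverage ordering; a 1,400-MA synthetic corpus
(yielding > 300 meta-analyses significant under all four random-effects
scenarios) for the paired HKSJ fragility comparison with cap 100. The
acceptance script uses a 1,200-MA corpus and reports each quantity with
the problem size it was computed from.

## Known limitations

* The beam search is exact on every instance checked against the
  oracle, but carries no optimality proof; `--exact` exists for
  certification on small inputs, and a mismatch would mean the beam
  width needs widening, not that the oracle is wrong.
* REML non-convergence handling (exclude from REML scenarios, keep
  DL/FE) matches common practice but makes corpus summaries depend
  mildly on the solver's tolerance and iteration cap.
* Fisher's exact test is the fixed per-study significance criterion;
  trials originally analysed with covariate adjustment or other tests
  would have different individual FIs.
* Continuous and time-to-event outcomes, network meta-analysis, Peto
  and arcsine effect measures, and alternative τ² estimators
  (Paule–Mandel, Sidik–Jonkman, Hartung–Makambi) are out of scope.
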