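# Methods

This note documents the models, statistics, and numerical choices behind
the package, and what the synthetic data can and cannot say about real
behavior.

## Design generation

Base pairs are split into five counterbalance groups of equal size;
subject *s* (0-based) assigns group *g* to the condition at position
`(g + s) mod 5` of the fixed order (NoChange, ΔTarget, ΔCue, ΔBoth,
Control).  This makes every pair serve every condition exactly once per
aligned block of five subjects, so that per-pair recall proportions in
different conditions come from disjoint but exchangeable subject sets.
Partial trailing blocks are allowed (the per-subject invariants still
hold; only the cross-subject rotation-completeness check is skipped for
them), because synthetic runs need arbitrary n while the human studies
re-ran subjects until reaching a multiple of the counterbalance.

The supplemental list is the non-Control four-fifths of the base list
(36 of 45 pairs), reflecting that Control pairs have no earlier
counterpart.  Synthetic word tokens are pronounceable 3–5 letter
consonant-vowel strings, unique by rejection sampling; they stand in for
the real three-to-five-letter English words, whose identity is irrelevant
to every statistic computed here.  Relatedness values are sampled
uniformly over the requested span — association strength 0.03–0.96 for
the narrower set, GloVe cosine −0.14–0.95 for the wider set.  Uniformity
is a modeling choice: the source norms give ranges, not distributions,
and a uniform spread maximizes regression leverage evenly across the
axis.  The secondary metric (each stimulus table carries both) is a noisy
monotone remapping of the primary, mimicking the loose coupling between
association norms and embedding cosines without claiming a calibrated
joint distribution.

Supplemental-list presentation order is shuffled uniformly per subject;
the source studies do not state how serial order interacted with the
counterbalance, and none of the computed statistics depend on it.

## The generative subject model

All quantities live on the logit scale.  For subject *s* and base pair
*i* with condition-specific relatedness *r* (target relatedness for
ΔTarget, cue relatedness for ΔCue, the cue/target mean for ΔBoth — the
mean keeps *r* on the metric's scale — and the metric maximum for
NoChange):

* ability `α_s ~ N(0, subject_sd²)`, default sd 0.8; item difficulties
  `δ_i ~ N(0, item_sd²)`, default sd 0.5, drawn once per *materials* set
  (see `item_seed` below) and separately for the base and supplemental
  member of a duo;
* reminding `R_i ~ Bernoulli(logistic(ρ₀ + ρ₁ r))` during second-list
  learning, defaults ρ₀ = −2, ρ₁ = 4 (reminding probability ≈ 0.12 at
  r = 0 rising to ≈ 0.88 at r = 1); forced for NoChange, impossible for
  Control;
* shared duo latent `c_i ~ N(0, coupling_sd²)` when reminded (default
  sd 1.5), zero otherwise;
* test recall succeeds when
  `logistic(μ_delay + α_s − δ_i + R_i β_F − (1−R_i) β_I 1[ΔTarget] + c_i
  + order_boost) > u`, with μ = +1.5 at 5 min and −0.5 at 48 hr
  (high-but-off-ceiling recall at the short delay, mid-scale at the long
  one), facilitation β_F = 1.0 and competitor interference β_I = 1.2
  (interference-dominant, producing the PI→PF crossover); an optional
  ΔCue penalty exists for sensitivity analyses and defaults to 0, since
  cue-change learning showed facilitation and only isolated interference;
* `order_boost = β_R R_i` (default 1.0) for the first-learned list's
  pairs, **excluding NoChange**: the reminding is a retrieval event for
  the earlier pair, and retrieval practice of testing-effect size is what
  makes retroactive benefits exceed proactive ones.  NoChange is excluded
  because an identical repeat's "reminding" coincides with ordinary
  restudy of the same association in both list orders, so it carries no
  differential order benefit; including it would also contaminate the
  NoChange-baselined between-experiment contrast that uses NoChange as
  the positive control;
* on a failed ΔTarget base test the supplemental target intrudes with
  probability `(1 − R_i) π` (default π = 0.4): successful remindings
  build contextually discriminable representations, so intrusions fall
  with relatedness even as interdependence rises.  Other failures emit
  junk tokens, occasionally (rate 0.05) another duo's supplemental target
  to exercise the intrusion scorer's negative cases;
* learning rounds to criterion follow a truncated geometric law with
  per-round success `logistic(λ₀ + λ₁ r 1[second list, non-Control] +
  α_s − δ_i)`, defaults λ₀ = −0.5, λ₁ = 1.0; first-list learning uses
  r = 0.  Pairs not learned within `max_rounds` (default 20) are counted
  at the cap and flagged rather than dropped.

List orders: *proactive* learns (supplemental, base) and tests (base,
supplemental); *retroactive* learns (base, supplemental) and still tests
(base, supplemental); *flipped_test* keeps the retroactive learning order
but tests (supplemental, base).  Only learning order enters the model —
test position carries no effect — so retroactive and flipped-test runs
are generatively identical for base-pair outcomes, which is exactly the
null the flipped-test control experiment was designed to approximate.

Seeding: item-level draws come from `default_rng([item_seed, 0])` and
each subject's draws from `default_rng([seed, 1, subject_index])`, so a
prefix of subjects is reproducible regardless of the total count.
`item_seed` defaults to `seed` but should be shared across experiments
that use the same materials: the human between-experiment comparisons
reused one stimulus set, and redrawing item difficulties per experiment
would add materials noise those comparisons never had.

### Parameter calibration

The design constants (pair counts, sample sizes, delays, relatedness
spans, the five-way counterbalance) are the study's.  The generative
effect sizes are not stated anywhere and were chosen once so that the
model reproduces the *reliability* of the reported phenomena at the
study's n = 200-per-experiment scale: crossover thirds t-statistics of
magnitude ≈ 3–8, ΔTarget memorability r² in the 0.3–0.7 range at 48 hr,
and retro-vs-pro contrasts significant in all three facilitated
conditions but not Control.  β_R = 1.0 in particular matches
testing-effect-sized retrieval-practice benefits; at half that size the
simulated order asymmetry is only marginal at these sample sizes, weaker
than the robust human effect.

### What the simulator does not emulate

Ceiling compression at 5 min is present (μ = 1.5) but real short-delay
data are closer to ceiling still; reaction times, forgetting between the
two delays, output interference across test positions, spell-checking
ambiguity, and subject drop-out are absent.  The raw
both-correct-or-both-incorrect dependence statistic is non-monotone in
relatedness for ΔTarget under interference-dominant parameters
(low-relatedness duos agree by jointly failing), so the simulator
reliably reproduces matched-above-null-threshold dependence at high
relatedness but not necessarily a positive dependence–relatedness slope
in that condition.  Passing tests therefore certify the pipeline's
arithmetic and the model's qualitative structure, not quantitative fits
to human data.

## Scoring and exclusions

Test responses are scored by normalized exact match (lowercase, trimmed);
an optional edit-distance-1 leniency (via `edlib`) is off by default — the
human procedure used no spell check during learning and left test scoring
unstated, so strict matching is the reproducible default.  An intrusion is
a base-test response matching the pair's supplemental target when that
target differs from the base target.  Subjects are excluded when their
pooled two-list test accuracy falls more than four standard deviations
below the sample mean; the z-score is computed once from the full sample,
with no re-iteration after removal.

## Statistics

* RM-ANOVA: `F = MS_condition / MS_(condition×subject)` with df
  `(k−1, (k−1)(n−1))`; no sphericity correction is applied, matching the
  plain degrees of freedom the field reports for this design.  Sums of
  squares below 1e−14 of the data scale are treated as zero so constant
  tables report F = 0 rather than rounding noise.
* Pairwise condition tests: within-subject t-tests over all 10 pairs,
  one Benjamini–Hochberg family per suite (and one per four-contrast
  order-comparison suite).
* Relatedness regressions: OLS with conventional n−2 degrees of freedom;
  the 95% band is the pointwise CI of the conditional mean on an evenly
  spaced grid.  Thirds splits rank pairs by relatedness and assign any
  remainder to the middle third, noted in the output.
* Between-experiment contrasts: each subject's condition means are
  re-expressed relative to their own NoChange mean, then compared across
  experiments with Welch t-tests (the safer default when samples were
  collected at different times).
* Dependence null: mismatched duos are restricted to the same
  counterbalance group so the null statistic uses exactly the same
  subjects and condition as the matched one; a flag lifts the
  restriction for sensitivity analysis.  The threshold is the linearly
  interpolated empirical 95th percentile, and the null is built within
  condition (pooling across conditions is possible by computing each
  condition and concatenating `null_values`).

## Surfaces

The ΔBoth summary uses a Nadaraya–Watson estimator with a Gaussian
product kernel, default bandwidth 0.15 × the spanned relatedness range on
a 41 × 41 grid.  Cells whose total kernel weight falls below that of a
single point 1.5 bandwidths away are masked rather than extrapolated.
Permutation bounds shuffle values against their (cue, target) coordinate
pairs — the exchangeability that holds when relatedness carries no
information — and take pointwise (α/2, 1−α/2) quantiles over the permuted
surfaces at α = 0.01, default 1000 shuffles (exhaustive enumeration for
tiny inputs).  Significance flags use a 1e−9 relative tolerance so that a
surface coinciding with a permuted one (e.g. constant values) is never
flagged by summation-order rounding.  No multiplicity correction is
applied across grid cells: the bounds are pointwise by construction, a
documented limitation.

## Problem sizes

The analysis drivers simulate 200 subjects per experiment (the study's
per-experiment sample) and the test suite's qualitative-replication
checks use 500; calibration suites run 200–500 replicates of small null
problems, evaluating permuted surfaces through a fixed weight-matrix
product so the whole suite completes in about half a minute.
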