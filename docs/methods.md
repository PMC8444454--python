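# Methods

## The unified scoring procedure

Each raw outcome measure is normalized to the unit interval within a
normalization stratum, by default animals of the same sex **and**
cohort: `X(i) = M(i) / M(m)` with `M(m)` the stratum maximum. The
within-sex split is essential because many behavioural readouts differ
systematically between male and female mice; the within-cohort split
reflects that separately run cohorts are not measured under identical
conditions. A switch (`stratum_cols=("sex",)`) pools cohorts for studies
run in one pass.

Rule order is fixed as: ratio to the maximum → clamp negative raw
values to 0 → force time-outs to the final score 1 → invert
(`x → 1 − x`) for measures negatively associated with their trait, with
the timeout override applied *after* inversion. Two consequences are
deliberate:

- `M(m)` is computed over non-missing, non-timeout values only, so a
  censoring placeholder (e.g. the 300 s session maximum) can never
  inflate the denominator and compress everyone else's scores.
- A time-out always yields the final score 1, even on an inverted
  measure. The alternative (`timeout_policy="literal"`), where the
  time-out sets the pre-inversion score so an inverted measure scores
  0, is available because the orderings are not equivalent and the
  intended semantics — failure to act is the maximal deficit — only
  holds for the default. Likewise `clamp_after_inversion=True` moves
  the negative clamp after inversion for users who prefer that reading.

Test scores are plain means of an animal's measure scores per (trait,
test); unified scores are means of test scores over tests. The
two-stage mean is what gives every behavioural test equal influence: a
test contributing five measures and a test contributing one each count
once at the second stage. Missing values are excluded from every mean
and never imputed; a trait score is missing only when every
contributing test is missing. A stratum whose measure has no positive
usable value cannot anchor the ratio scale and is flagged degenerate
(all its scores missing) rather than silently scored.

## Prevalence summary

Within each sex, the unified scores of all groups are pooled and their
median taken per trait; a group's prevalence is the fraction of its
animals *strictly* above that median (ties do not count, so a constant
trait yields prevalence 0, not 0.5). The heatmap cell is the relative
change `(p − p_WT) / p_WT`, anchored at 0 for "matches wildtype" — the
only reading on which increases and decreases are signed symmetrically;
`mode="ratio"` emits `p / p_WT` instead. A zero wildtype baseline with
a positive group prevalence makes the relative change undefined; the
absolute difference is reported with an `undefined_baseline` flag
rather than an arbitrary large number. The median is taken within sex
(consistent with within-sex normalization — pooling sexes would mix
normalization strata); `median_within_sex=False` provides the
whole-cohort alternative.

By construction the group prevalences, weighted by group size, average
exactly to the pooled prevalence, and for continuous scores the pooled
prevalence sits near 0.5 — both are exercised as invariants in tests.

## Group statistics

One-way and two-way fixed-effects ANOVA are computed from sums of
squares directly. Balanced two-way designs use the classical factorial
decomposition; unbalanced designs (the common case — cohort Ns of
12–20 per cell rarely stay equal after exclusions) use Type II sums of
squares via nested model comparisons on least-squares fits, the
conventional choice when the interaction is not the primary focus. Both
paths agree to machine precision on balanced data, which is itself a
test. Degenerate inputs (zero between- and within-group variance) are
flagged rather than producing a spurious F.

Post-hoc pairwise contrasts use the pooled ANOVA error term and its
residual degrees of freedom; Tukey adjustment evaluates the studentized
range at `q = |t|·√2` with the number of groups, Bonferroni multiplies
the raw two-sided p by the number of pairs capped at 1. With two groups
Tukey reduces exactly to the raw t test. A `welch=True` option computes
per-pair Welch statistics with Satterthwaite degrees of freedom for
heteroscedastic data. Whole-cohort two-way and sex-split one-way
analyses are both computed unconditionally for every trait; no gating
rule (e.g. "only split when the interaction is significant") is
imposed, interpretation stays with the analyst.

## DEG attribution

Benjamini-Hochberg adjustment is the textbook step-up, and the calling
threshold is strict (`adj_p < α`); α is an explicit parameter defaulting
to 0.05 because published analyses use both 0.05 and 0.01 for different
lists. Tables arriving with an `adj_pval` column use it verbatim
(adjustment belongs within each pairwise comparison); otherwise BH is
applied per table. Attribution intersects on gene identity only, with
direction taken from the Tg-vs-WT contrast, because the published count
structure splits up/down within that contrast; `strict_direction=True`
additionally requires sign agreement across the intersected contrasts.
The differential-expression model that produces the tables
(negative-binomial shrinkage etc.) is deliberately out of scope — the
attribution logic consumes its output.

## The synthetic-data generator

The generator emulates a three-group (WT, NTg, Tg) × two-sex design
with 12–20 animals per cell (default 20), a multi-test battery mapping
measures to nine traits, censorable latency measures, and
difference-type measures that may legitimately go negative. Reference
values are Gaussian on each measure's native scale; the published study
design states no distributions or variances, so the battery's means and
standard deviations (e.g. time in light 120 ± 40 s, latency to light
30 ± 15 s with a 300 s session maximum, 8 % time-out probability) are
this package's own choices of plausible apparatus scales, fixed once.
Effects are planted on the **raw** scales as mean shifts in sd units,
oriented along each measure's direction so the shift always increases
the trait deficit — this exercises normalization and inversion
non-trivially, which planting on scores would not. NTg effects default
to half the Tg effect, mirroring an environment that impacts carriers
hardest. Latency values are truncated at 0 and censored at the session
maximum; other non-negative measures are truncated at 0.

What the generator does *not* emulate: non-Gaussian and heavy-tailed
raw distributions, between-cohort batch effects, correlated measures
within an animal beyond the shared group shift, litter effects, or raw
per-session operant event streams. Passing recovery tests therefore
demonstrates that the pipeline's logic is correct under its stated
model, not that real cohorts of this size always yield these power
levels.

The DEG simulator plants adjusted-significance directly: planted genes
receive raw p-values around 1e-8 (hence BH-adjusted values orders of
magnitude below any threshold) in exactly the contrasts that define
their membership, with fold-change signs consistent across contrasts;
null genes draw uniform p-values. It validates the intersection logic
and its null behaviour, not the DE model.

## Monte-Carlo study sizes

Calibration and power studies run on an anxiety-only compact battery
(two tests, four measures). Scoring and testing of one trait depend
only on that trait's measures — other traits' measures are independent
noise that never enters the anxiety composite — so the compact battery
computes the identical statistic at a fraction of the cost. Study
sizes: 1000 replicates for type-I calibration of the GROUP term (Monte
Carlo s.e. ≈ 0.007 at α = 0.05), 100 replicates for power and
prevalence recovery of the planted 1.5 sd deficit, 200 seeds for the
null false-positive bound of DEG attribution, 50 random mini-cohorts
for brute-force oracle agreement.

## Numerical choices

- Scores are clipped to [0, 1] after the rule pipeline to absorb
  floating-point overshoot; tiny negative Type II sums of squares from
  round-off are clamped to 0.
- Medians use the standard midpoint-of-order-statistics definition.
- BH ties are handled by stable argsort; output order matches input.
- All simulation randomness flows from a single integer seed through
  one `numpy` generator per call; fixed seed ⇒ byte-identical outputs,
  which the pipeline manifest (config hash + version + record counts)
  makes checkable.

## Known limitations

- Repeated-measures ANOVA is not implemented; per-animal least-squares
  slopes across sessions act as the summary measure for acquisition
  data, which is the published summary for those figures anyway.
- Prevalence differences are summarized, not significance-tested (the
  testing scheme operates on the scores themselves).
- The Tukey p-value uses the pooled residual df for every pair; with
  strongly unequal group variances prefer `welch=True` plus Bonferroni.
- Heatmap image rendering is a convenience; the CSV matrix is the
  contract.
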