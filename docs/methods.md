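# Methods

## Design and data model

The pipeline targets subject-paired, multi-arm expression time courses: each
subject belongs to one group (by default a non-exercise Control plus
Endurance and Resistance exercise arms), and contributes one baseline (Pre)
sample and one sample per post time point (defaults 2.5 h and 5 h). Input
expression values must be on the log2 scale — the scale on which RMA-style
array summaries live and on which the pipeline's geometric-mean summaries
are defined. Missing values are not permitted in the matrix (array
summarization yields complete rows); missing *samples* are permitted, and
the engine handles the resulting unbalanced designs.

## Pre normalization

Every sample is replaced by its log2 difference from the same subject's Pre
sample (division of linear intensities). This is an exact operation: Pre
columns become identically zero, and any per-subject additive offset in the
raw matrix cancels without rounding whenever the offset itself entered the
matrix exactly (the subtraction of two nearby floats is exact by the
Sterbenz lemma). Re-normalizing a ratio matrix is a no-op.

A gate, not a filter: before normalization, a one-way fixed-effects ANOVA
across groups on Pre samples alone (vectorized `scipy.stats.f_oneway`)
checks for pre-existing group differences; the pipeline warns — it does not
abort — if any transcript clears BH-FDR < 0.05. Degenerate transcripts with
zero within-group variance use the convention p = 1 (F = 0) when the group
means also coincide, and p = 0 (F = ∞) when groups are exactly separated.

## The per-transcript mixed model

After normalization the Pre level has zero variance, so it cannot enter the
model as an observed factor level. The model is therefore fitted on the post
time points only, with a cell-means parameterization over group × time and a
subject random intercept:

    y_gts = μ_gt + b_s + ε,  b_s ~ N(0, σ²_subject),  ε ~ N(0, σ²_resid).

Every "versus Pre" hypothesis becomes a linear hypothesis on cell means:
μ_gt = 0 is exactly the paired contrast of group *g* at time *t* against its
own baseline. Note the subject intercept in *ratio* space is the shared
−ε(Pre) term of that subject, so σ²_subject here estimates the Pre-sample
noise, not the (cancelled) raw subject offset.

**REML.** The residual variance is profiled out, leaving a one-dimensional
problem in the variance ratio λ = σ²_subject/σ²_resid. A coarse grid on
log10 λ ∈ [−8, 8] brackets the optimum; bisection on the *analytic* REML
gradient (closed forms exist for a single ratio: d RSS/dλ = −‖Z′Py‖², etc.)
then solves the stationarity condition. Bisection on the gradient's sign is
used instead of direct likelihood comparison because near the optimum
likelihood differences fall below float precision while the gradient still
carries sign information; the achieved accuracy makes the balanced-case
Wald F agree with the classical sums-of-squares F to ~1e-12. If the
boundary fit λ = 0 has the better restricted likelihood, the subject
variance is truncated at zero and the transcript is refit as a fixed-effects
model (standard REML boundary behaviour); all its tests then use residual
df = n − p. Everything is vectorized across transcripts in chunks (default
2048), so a 28,869-transcript matrix fits in seconds on one core.

**Tests.**

* Omnibus Wald F: `Time` (equality of post-time profiles averaged over
  groups, df T−1), `Group` (df G−1) and `TimexGroup` (profile divergence
  across post times, df (G−1)(T−1)). For balanced complete data with an
  interior variance estimate these reproduce the classical repeated-measures
  ANOVA F statistics exactly, and the REML components equal the
  method-of-moments estimators.
* `TimexGroupVsPre` (df (G−1)·T): the factorial interaction when the
  implicit zero baseline level is counted — do the groups share the same
  change-from-Pre trajectory? A constant offset between group trajectories
  is invisible to the post-only profile interaction but is an interaction
  in the baseline-included factorial; both views are reported because the
  classification rules need the latter while the former is the textbook
  repeated-measures quantity.
* 1-df contrasts: each group × post-time cell versus Pre (`E2.5h`, `S5h`,
  …), each group pair per time (`EvC2.5h`, `SvE5h`, …; E = Endurance,
  S = Resistance/Strength, C = Control), and the across-group marginal
  change from Pre per time (`Time2.5h`, `Time5h`).

**Degrees of freedom.** Omnibus tests use containment df by default
(`Group` against subjects-minus-groups; `Time`/`TimexGroup` against the
within-subject residual df = n − rank([X Z])), matching the classical
strata for balanced data. Cell-mean contrasts mix the between- and
within-subject strata, where containment has no natural assignment, so
contrasts always use Satterthwaite df computed from the REML information
matrix (the lmerTest construction: df = 2g²/Var(g) with g = Var(L β̂) and
Var(θ̂) from the inverse expected information). `df_method="satterthwaite"`
switches the omnibus tests to the eigencontrast Satterthwaite method, the
recommended setting for clearly unbalanced data. `TimexGroupVsPre` uses the
Satterthwaite route under either setting, for the same strata-mixing reason.

**Degenerate rows.** A transcript whose ratios are identically zero has no
variance to test; its estimates are 0 with p = 1 by convention. Rows
yielding non-finite statistics are flagged non-converged, excluded from FDR
families (family size m reduced), left unlabelled by every rule set and
counted in the reports; the batch aborts only if more than half fail.

## Multiple testing

BH step-up adjustment (`statsmodels.stats.multitest.multipletests`,
`fdr_bh`) is applied per family, a family being one effect or one contrast
column across transcripts — never across contrasts. Missing p-values are
masked out before adjustment and restored as missing q-values.

## Classification rules

All clauses use q < 0.05 except where a rule explicitly works on the raw-p
scale. Thresholds (α = 0.05, interaction floor 0.1, per-group raw 0.05) are
configuration values recorded in every written report.

* **Changed versus Pre** per (group, time): q of the cell contrast < α.
* **Changed between groups** per (pair, time): q of the pair contrast < α.
* **Group-specific:** at some post time the transcript is changed versus
  Pre in group g *and* different from both other groups; and at no time is
  it changed versus Pre in any other group (exclusion clause, on the q
  scale). At most one group can qualify, so the label is single-valued, and
  it is mutually exclusive with the exercise-general labels by construction.
* **Exercise-general:** changed versus Pre in every exercise arm
  (≥1 time each). Split "dependent of exercise type" when any
  between-exercise contrast is significant at some time, else
  "independent". The split is one operationalization of a "responds to both,
  but differently" category; it is deliberately the only between-exercise
  statistic the model produces, and is configurable.
* **Time-regulated:** at a given post time, the across-group marginal
  change from Pre is significant (q of `Time2.5h`/`Time5h` < α), the
  `TimexGroupVsPre` interaction is quiet (raw p > 0.1), and all groups
  individually moved (raw p < 0.05). The marginal-per-time reading of the
  "Time effect at 2.5 h or 5 h" clause is used because an equal sustained
  shift in all groups has no post-profile Time signal at all; the
  per-time marginal contrast is the quantity the clause describes.

## The simulator

`generate_dataset` emulates the study design: log2 baselines per transcript
(N(7.0, 1.5²)), a subject random intercept (SD 0.5), homoscedastic Gaussian
log2 noise (SD 0.25), and planted shifts of 1.0 log2 units per affected
group × time cell. These defaults give high but not saturating power at
n = 6 per group, which is the regime the design targets; they are
conventions, not estimates from real arrays. Effect classes: null;
specific:<group>; general_independent (equal shift in both exercise arms);
general_dependent (opposite-sign shifts); time_all_groups (equal shift in
all arms including control, emulating circadian/dietary drift). Pre cells
are never shifted. Class assignment is deterministic (largest-remainder
apportionment over contiguous blocks); the only random draws are baselines,
subject intercepts, then noise, in that documented order from one seeded
generator — identical configs are byte-identical.

What the simulator does *not* model: probe-level effects, RMA/quantile
normalization artefacts, batch effects, heavy-tailed or
intensity-dependent noise, correlated transcripts. Passing tests therefore
demonstrate the statistical machinery under its own assumptions, not
robustness to real-array pathology.

## Problem sizes and runtime

The validation suite uses sizes chosen to make Monte-Carlo bounds sharp yet
keep a laptop run comfortable: 5,000 transcripts × 20 seeds for null
calibration, 200 transcripts per planted class (plus 1,000 nulls) × 3 seeds
for recovery, 100 transcripts for the classical-ANOVA equivalence, 1,000
transcripts for the byte-determinism round trip. The analysis scripts
default to an 8,000-transcript cohort; the full 28,869 × 54 scale runs in
well under a minute.

## Known limitations

* Contrast p-values rely on the Satterthwaite approximation; they are
  exactly calibrated only asymptotically (empirically, KS tests on 5,000
  null transcripts do not detect deviations).
* The λ = 0 boundary refit makes those transcripts' tests slightly
  conservative relative to a mixture-distribution treatment.
* One random intercept only: no subject-by-time random slopes, no
  moderated/empirical-Bayes variance sharing across transcripts.
* The dependent/independent split of the exercise-general class inherits
  the power of a single between-exercise contrast; a small opposite-sign
  response can be labelled "independent" at n = 6.
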