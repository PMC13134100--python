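# Methods

## The model

`modnet` estimates and compares **moderated network models (MNMs)** over a
fixed 20-item symptom panel: nine depression items and seven generalised
anxiety items scored 0–3, and four work/social functioning items scored 0–8
(the work-ability item is excluded because it is frequently not applicable).
Nodes are the items; an **edge** is the partial association between two items
given all other items and the covariates; a node's **intercept** for a group
is its adjusted mean level given the covariates and all other items. A
categorical group label (up to 11 levels) moderates both intercepts and
edges; age and gender enter as adjustment covariates only.

Estimation is nodewise (disjoint pseudolikelihood): each item `s` is
regressed on

* the 19 other items (main effects — the reference group's edges),
* `G − 1` group dummies (intercept differences from the reference),
* all `19·(G − 1)` item × dummy interactions (edge differences), and
* age and gender,

with an L1 (LASSO) penalty on every coefficient. All items are treated as
conditionally Gaussian. The penalty λ is selected per node by the extended
Bayesian information criterion

```
EBIC(λ) = n·log(RSS/n) + df·log(n) + 2γ·df·log(p)
```

with `df` the number of nonzero coefficients, `p` the number of candidate
predictors and `γ = 0.25` (the customary default for this estimator family;
`γ = 0` recovers plain BIC). The path has 50 log-spaced values from
`λ_max = max_j |⟨x_j, y⟩|/n` down to `λ_max/1000`; EBIC ties go to the larger
penalty. An exact `λ = 0` entry is permitted at the end of an explicit path
and is solved by least squares — this is what the oracle-equivalence tests
exercise.

**Scaling.** Items and age are z-scored on the full sample; dummies and
gender stay 0/1, and interaction columns are products of z-scored item and
raw dummy. The lasso itself runs on a fully standardized copy of this design
(so the penalty treats all columns symmetrically) and selected coefficients
are mapped back to the base scale before anything is derived from them. The
base scale matters: on it a dummy coefficient is directly a
standardized-units group difference, identical in magnitude across reference
rotations, which is what makes the rotation consistency below exact. The
zero/nonzero pattern is unaffected by the rescaling.

The two directed estimates of each edge (t's coefficient in s's regression
and vice versa) are combined by the **nodewise AND-rule**: the edge is
present only if both are nonzero, with value their mean (an OR variant is
available). Group-specific quantities are assembled by adding dummy /
interaction terms to the reference terms.

## All-pairs contrasts by reference rotation

A single fit only contrasts each group with the reference. The pipeline
refits the model once per group as reference (**rotation**), giving two
estimates of every pairwise difference: for pair (a, b), b's dummy
(interaction) coefficient under reference a, and a's sign-flipped coefficient
under reference b. A difference counts as **detected** only when both are
nonzero (the rotation-level AND-rule, `|coef| > 1e−10` to ignore float dust);
its combined value is the mean of the two estimates. At `λ = 0` the two
rotations are exact linear reparameterizations of each other, so the two
estimates agree to numerical precision — an invariant the test suite asserts.

Magnitudes are reported as symmetric percent differences
`200·(x − y)/(|x| + |y|) ∈ [−200, 200]`; ±200 means one group's estimate is
zero (or the signs disagree) — the presence-vs-absence case.

For G groups and p nodes the comparison universe is `G(G−1)/2` group pairs,
`p` symptoms per pair, and `p(p−1)` *ordered* co-occurrence slots (each of
`p` nodes with its `p − 1` possible connections; 380 at p = 20). The ordered
count is the default reporting denominator for edge proportions; the
unordered count `p(p−1)/2` is also emitted. At the study scale (G = 11,
p = 20) this gives 55 pairwise comparisons over 20 symptoms and 380 slots.

## Permutation inference

The null "no group differences" is simulated by shuffling group labels
across rows (items and covariates stay attached to their rows, so
covariate–group structure is broken while covariates remain adjusted for)
and refitting the entire rotation ensemble B times (default B = 100).
Empirical p-values use add-one smoothing,
`p = (1 + #{|null| ≥ |obs|})/(B + 1)`, valid at any finite B; the smallest
attainable p at B = 100 is 1/101 ≈ 0.0099. Ties count as extreme, so an
observed 0 always gets p = 1. Aggregate inference compares each pair's
*count* of AND-rule-detected differences with its permutation null
(one-sided); this is the primary inferential surface and no multiplicity
correction is applied to individual p-values. A parameter is reported
"significant" when it is both AND-detected and has p < α (default 0.05);
each criterion is also reported separately.

Per-group edge-count homogeneity is tested by a chi-square goodness-of-fit
of the G per-group estimated edge counts (each averaged over the G rotated
fits; single-fit counts are the obvious alternative) against a uniform
expectation, df = G − 1.

## The synthetic-cohort generator

Real service data of this kind are not publicly distributable, so all
testing runs on synthetic cohorts with known truth. Each group g has a
precision matrix `Ω_g = (1 + δ)I − P_g`, where `P_g` is the base partial
matrix (a fixed fraction — default 15% — of item pairs carrying positive
partials drawn U(0.1, 0.3)) plus that group's planted edge shifts. A single
diagonal repair δ, shared by all groups, is the smallest value bringing every
`Ω_g`'s minimum eigenvalue to 0.05; it shrinks all realized partials by
`1/(1 + δ)` uniformly, so planted *differences* remain differences.
Configurations needing `δ > 4` are rejected as infeasible.

Planted **intercept shifts** go to uniformly sampled (group, item) cells (a
fresh item per plant, magnitude in latent-SD units, random sign); planted
**edge shifts** go to (group, item-pair) cells whose base partial is zero —
presence-vs-absence differences, the kind the motivating analyses most often
report. A plant on one group implies a true difference against each of the
other G − 1 groups; `planted_differences` enumerates exactly that implied
set, which is the recovery oracle. Covariate effects are drawn N(0, 0.1) per
item and shared across groups; age is U(18, 75), gender Bernoulli(0.67).
Latent scores map to item scales (location 1.8/scale 1.0 for 0–3 items,
4.0/2.5 for 0–8 items); **ordinal mode** (the default for pipeline runs)
rounds and clips to the panel ranges. Default scenarios use unbalanced group
sizes scaled from the reference service cohort's composition (44.3% down to
1.87%).

What the generator does *not* emulate: ordinal marginals matched to any
published moment table, item-response measurement structure, copula-based
ordinal dependence, missing-data mechanisms, or covariate–group
confounding. Passing recovery tests therefore show the estimation pipeline
is correct under its own distributional assumptions, not that real symptom
data meet those assumptions.

## Calibration findings and known limitations

Problem sizes in the tests and the acceptance runs were chosen to exercise
each claim at the smallest scale that resolves it: oracle identities at
n ≈ 200–500; rotation consistency at G = 3, n = 500/group; recovery at
G = 4, n = 2,000/group; null calibration at G = 4, n = 1,000/group with
B = 50; the 11-group pipeline demonstration at a total n ≈ 4,000.

* **Intercept recovery.** Planted 0.4 SD intercept shifts at G = 4,
  n = 2,000/group are recovered with sensitivity ≈ 1.0 and specificity
  ≥ 0.96.
* **Edge-moderation conservatism.** One-group edge differences of 0.2
  partial are essentially never confirmed by the rotation-level AND-rule at
  that scale (sensitivity ≈ 0; ≈ 0.8–1.0 at 0.3; 1.0 at 0.4). The mechanism
  is structural: in the rotation where the affected group is the reference,
  expressing the difference requires G − 1 penalized interaction
  coefficients instead of one, and the EBIC prefers the pooled sparser
  model. The same mechanism makes differences involving *small* groups very
  hard to confirm at desk-scale n in unbalanced 11-group runs, because
  every pair is examined once with the small group as reference. This is a
  real property of the regularize-then-AND design — it trades sensitivity
  for a very low false-positive rate — and is consistent with
  co-occurrence differences being reported far more rarely than intercept
  differences in analyses of this kind at much larger n.
* **Ordinal attenuation.** Rounding/clipping to item ranges attenuates edge
  interaction signals unevenly (a 0.2 planted partial surfaced as 0.04–0.19
  across directions in one measured run). Recovery benchmarks therefore use
  continuous items; ordinal mode is kept for realism in pipeline
  demonstrations.
* **Null calibration.** On null cohorts the individual-parameter false
  positive rate at α = 0.05 is far below α (the LASSO + AND screen sends
  almost every null statistic to exactly 0, hence p = 1), and per-pair
  detected counts are almost all zero. Empirical p-values are conservative,
  not uniform, under the null.

Other numerical choices: coefficients below 1e−10 count as zero; constant
design columns are left at zero after standardization; permutation
sub-seeds derive from the master seed as `SeedSequence([master, b])`, and
pipeline stages use `SeedSequence([master, stage_counter])`, so any stage is
independently reproducible. Estimator non-convergence at a path point
surfaces as a warning from the coordinate-descent solver with the offending
node's diagnostics propagated.
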