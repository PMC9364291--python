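# Methods

## The measurement problem

In the schema-based source-monitoring paradigm, participants study items
paired with a schema-expected or schema-unexpected source (here: everyday
objects in a kitchen or bathroom scene) and later, in a three-alternative
forced-choice (3AFC) test, attribute old and new items to the expected
source, the unexpected source, or "new".  Raw attribution accuracy
confounds three processes: item recognition, source memory, and guessing —
and schema expectations push memory and guessing in opposite directions
(source *memory* is better for unexpected pairs, the inconsistency effect,
while *guessing* favors the expected source).  The package therefore
measures source memory with the two-high-threshold multinomial
processing-tree (MPT) model of source monitoring.

## The MPT model (`srcmon.mpt`)

Seven probabilities parameterize three processing trees, one per trial
type: `D_E`/`D_U` (recognizing an item from the expected/unexpected
source), `D_N` (knowing a new item is new), `d_E`/`d_U` (remembering the
expected/unexpected source given recognition), `b` (guessing "old"), and
`g` (guessing the expected source; `g > .5` is a schema-consistent bias).
Recognized items are never called "new" (the high-threshold assumption),
and source guessing is the same for recognized and unrecognized items.
One aggregate 3x3 table carries six degrees of freedom, so identification
requires tying `D_N` to `D_U` (default) or to `D_E`; both restrictions are
implemented and lead to the same orderings on the packaged reference data.

With six free parameters and six data degrees of freedom the restricted
aggregate model is exactly identified: `fit_ml` first inverts the observed
proportions in closed form (solve the tied `D` from the "new"-response
margin, then `b`, `g` from the new-item row, the other `D`, and finally
`d_E`, `d_U` from the correct-response cells).  If any solved value leaves
[0, 1], a Nelder-Mead maximization of the multinomial likelihood on
logit-transformed parameters takes over and the boundary flag is set.  An
interior closed-form solution reproduces the observed proportions exactly,
so `G^2 = 0` there; `G^2` is clamped at 0 against floating-point residue.

## Hierarchical latent-trait estimation (`srcmon.hierarchical`)

Aggregate fits ignore individual differences, so group-level inference
uses the latent-trait approach: each participant's free parameter vector
is `theta_i = Phi(eta_i)` with `eta_i ~ MVN(mu, Sigma)` on the probit
scale.  Priors are weakly informative: `mu_k ~ Normal(0, 1)` (covering
essentially the whole unit interval after the probit transform) and
`Sigma ~ Inverse-Wishart(K + 2, I)`.  The inverse-Wishart was chosen over
separate scale/correlation priors because it gives an exact conjugate
Gibbs update for `Sigma`, which both simplifies the sampler and makes the
replicated recovery studies cheap; at 40-72 participants the data dominate
this prior.

The sampler is Metropolis-within-Gibbs with four move types per iteration:

1. **Individual blocks.**  Two random-walk Metropolis sweeps over all
   `eta_i` (vectorized across participants and chains).  The proposal for
   participant i uses the Cholesky factor of the running covariance of
   `eta_i`, adapted during burn-in only, normalized to unit geometric-mean
   scale so a separately adapted scalar step controls magnitude (target
   acceptance .35).  Correlated proposals matter because weakly identified
   components (individual `d`, `g`) have wide, mutually correlated
   conditionals.
2. **Group translation.**  A joint shift of `mu` and every `eta_i` with
   proposal covariance adapted to the running covariance of `mu`.  This
   carries all chains across the group-level `d`-`g` likelihood ridge that
   single-participant moves cannot cross quickly.
3. **Funnel rescalings.**  Per-component rescaling of all deviations
   `eta_i - mu`, in both the centered form (`Sigma` fixed; Jacobian
   `n * sum(s)`) and the non-centered ASIS form (`Sigma` rescaled along
   with the deviations so standardized residuals stay fixed; the
   deviation-prior and Jacobian terms cancel, leaving likelihood and
   `Sigma`-prior terms).  Together these decouple the `Sigma` diagonal
   from the slow drift of individual deviations.
4. **Conjugate Gibbs updates** of `mu` (normal) and `Sigma`
   (inverse-Wishart via batched Bartlett sampling).

All adaptation freezes at the end of burn-in, so the retained chain is a
valid fixed-kernel Markov chain.  A single generator seeded by the master
seed drives all chains; chain c owns slice c of every vectorized draw,
which makes runs bit-reproducible given (seed, config).  Starting values
come from a smoothed closed-form inversion of each participant's table
(counts + 0.5), clipped to [0.02, 0.98] before the probit.

The default configuration (4 chains, 20,000 iterations, 10,000 burn-in,
thinning 5) is the desk-scale run used throughout the tests; a full-scale
preset (500,000 iterations, 250,000 burn-in, retain every tenth sample) is
available as `MCMCConfig.full_scale()`.  At the desk scale with 40
participants, the monitored split-Rhat values (components of `mu` and the
`Sigma` diagonal; individual parameters are not monitored) are typically
1.002-1.010 with effective sample sizes of roughly 400-900.

**Summaries and contrasts.**  `summarize_posterior` reports the posterior
median of `Phi(mu)` per parameter (means alongside) with central 95%
credibility intervals.  `parameter_contrast` evaluates arithmetic
expressions over the group-level draws; between-group contrasts pair draws
by index (independent groups) and subsample the longer chain with a seeded
generator if lengths differ.  A contrast is flagged significant exactly
when its 95% interval excludes zero.

**Fit statistics.**  The T1/T2 posterior-predictive checks are
implemented as: T1 = chi-square-type distance between the observed and
model-implied mean category-frequency table; T2 = Frobenius distance
between the observed across-participant covariance of the nine cell counts
and the model-implied covariance (between-participant covariance of
expected counts plus the mean within-participant multinomial covariance).
For each sampled posterior draw a replicate dataset is simulated from that
draw's individual parameters, and p is the fraction of draws whose
replicate discrepancy reaches the observed one.  This realization of the
named statistics is an interpretation: their original definitions are not
restated in the source material for this design.  Calibration was checked
by simulation: fitting data generated from the model and re-running the
check gives p-values concentrated in the central range, while a dataset
whose new-item row is deterministic (all "new") against a posterior
implying `b ~ .35` is rejected at p < .05.

**Convergence diagnostics.**  Split-Rhat follows the plain
between/within-variance ratio (rank normalization off); each chain is
split in half, the ratio is floored at 1 (finite-sample noise is the only
way below it), and exactly constant, identical chains report 1 by
convention.  Effective sample size uses Geyer's initial-positive-sequence
truncation of the FFT autocovariance.

## Behavioral statistics (`srcmon.behavioral`)

The 2x2 ANOVAs are direct least-squares decompositions for the balanced
designs this experiment produces (mixed: judgment-timing group between,
expectancy within; fully within: attribution accuracy x source
attribution).  The mixed design tests the between factor against subjects
within groups and the within factor and interaction against the
subject-by-within error; the fully-within design uses effect-specific
subject-by-effect error terms.  Partial eta squared is
`SS_effect / (SS_effect + SS_error-of-that-effect)`.  Unbalanced designs
are rejected rather than approximated; general-purpose ANOVA packages are
used as independent cross-checks in the test suite, not as the
implementation, because the balanced-only contract and the partial-eta
definition for the two-way repeated-measures case are pinned here.

Paired t tests report `d_z` = mean difference / SD of differences, which
satisfies `d_z = t / sqrt(n)` identically; independent t tests use pooled
variance with Cohen's d on the pooled SD; the one-sample test of gamma
correlations reports `|mean| / SD`.  All follow-up tests are two-sided;
the power analysis is one-sided, matching how each is used in this design.
No multiple-testing correction is applied anywhere.

Goodman-Kruskal gamma enumerates all pairs; pairs tied on either variable
drop out of both counts, and when no untied pairs remain (e.g. a
participant who declines every restudy offer) gamma is undefined and the
participant is excluded listwise from group-level tests — which is why a
group of 72 can yield a t test on 70 degrees of freedom.

The within-subject confidence interval (Loftus-Masson) removes participant
means and uses the subject-by-condition interaction error:
half-width = `t_{.975,(n-1)(k-1)} * sqrt(MS_err / n)`.

The power analysis searches n upward from 2, computing exact noncentral-t
power `P(T' > t_crit(n-1, alpha))` with noncentrality `d_z * sqrt(n)`; the
returned n is the boundary (power at n meets the target, at n-1 it does
not).

## The synthetic experiment (`srcmon.simulate`)

The generator emulates the full two-group study at its actual scale: 72
participants per group; 32 expected, 32 unexpected studied pairs and 32
distractors; a restudy cap of 32 with 50/50 expected/unexpected
substitution of unchosen pairs; and a delayed group that attempts a 2AFC
source attribution for every studied item before judging.

Defaults (units in parentheses) and their rationale:

- Group-level MPT means: immediate `D_E=.71, D_U=.73, d_E=.48, d_U=.83,
  b=.33, g=.75`; delayed `.78, .83, .31, .64, .39, .61` — the hierarchical
  point estimates reported for the two groups, so simulated test-phase
  data reproduce the inconsistency effect (`d_U > d_E`) and
  schema-consistent guessing (`g > .5`) in both groups.
- Heterogeneity SD 0.4 (probit scale), a typical latent-trait spread that
  yields realistic between-participant variation in 3AFC tables.
- 2AFC retrieval-plus-guessing parameters `a_E=.20, a_U=.4349,
  g2afc=.6897`: with `P(correct|expected) = a_E + (1-a_E) g2afc` and
  `P(correct|unexpected) = a_U + (1-a_U)(1-g2afc)`, the two free values
  were solved once from the reference attribution accuracies (75.17% and
  61.02%).  This one-high-threshold form is a simulator convention — no
  measurement model is fitted to the 2AFC task.
- JOS model (0-100 scale): intercept 50; expectancy effect +6.5 points
  (immediate) and -1.0 (delayed), chosen so the per-participant mean
  difference over 32 items with residual SD 18 gives `d_z ~ 1.44` and
  `~ -0.22` respectively; attribution-accuracy effect 15 points (delayed
  only); participant random-intercept SD 15.  JOSs are rounded and clamped
  to integers 0-100 (the keyboard scale granularity is taken as integers).
- Restudy choices: sequential Bernoulli with
  `P(choose) = logistic((50 - JOS) / 15)`, stopping once 32 pairs are
  chosen (the on-screen tracker).  The decreasing dependence on JOS
  produces the negative JOS-restudy gamma; the midpoint at the JOS
  intercept makes the median participant choose close to the cap, as
  observed.
- Restudy boost 0 (probit shift on `D` and `d` of restudied items at
  test), consistent with restudy differences having at most weak effects
  on source memory; it is configurable for power studies.

What the generator does **not** model: item-level effects (items are
exchangeable within expectancy class; counterbalanced lists are not
simulated), reaction times, within-participant correlation between JOS
accuracy and MPT parameters, and any direct dependence of test responses
on JOSs.  Passing tests therefore demonstrate that the analysis machinery
recovers the structure this generator encodes — not that real data share
that structure.

## Problem sizes used in the test suite

The replicated hierarchical studies run at a reduced scale chosen as the
package's standard desk configuration: 40 participants, 32 items per trial
type, 4 chains x 20,000 iterations (recovery and coverage, 40 replicates)
and 2 chains x 6,000 iterations (posterior-predictive calibration, 20
refits).  Aggregate-model saturation tests use multinomial tables of 10^6
observations; behavioral-statistics oracles run on hand-sized fixtures.

## Known limitations

- The aggregate ML fit is exactly identified, so `G^2` carries no
  goodness-of-fit information there; fit assessment belongs to the
  hierarchical T1/T2 checks.
- With 32 items per trial type, individual `d` and `g` are weakly
  identified; group means for those parameters shrink a few hundredths
  toward 0.5 at 40 participants (visible in the recovery study, within the
  documented bias bounds, and covered by the credibility intervals).
- The T1/T2 statistics are this package's interpretation of the named
  posterior-predictive checks (see above); absolute p-values from other
  implementations may differ even on identical data.
- `parameter_contrast` expressions are evaluated over group-level means
  only; contrasts of variance components are not implemented.
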