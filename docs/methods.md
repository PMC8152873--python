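# Methods

## Task structure and the triplet taxonomy

The stimulus stream interleaves a fixed-point-free 4-cycle over the
positions 1–4 (the pattern) with uniformly random positions. A block is
85 trials: 5 uniform warm-up trials, then ten repetitions of the
eight-element `P r P r P r P r` template, with the pattern phase
restarting at the cycle's first element in every block. Six distinct
cycles exist when written canonically starting at position 2; all are
structurally equivalent, and every analytic quantity in the package is
invariant to the choice.

Each trial from the third of a block onward is labeled by the triplet
it closes: *high-probability* when its position is the pattern
successor of the position two trials back, otherwise *low*. Structural
categories trill (a-b-a) and repetition (a-a-a) are tracked separately;
fixed-point-freeness of the cycle guarantees they are always
low-probability. Classification never crosses block boundaries: the
first two trials of each block are undefined, which matches the
per-block exclusion rule below.

The closed-form frequencies (62.5% high = 50% pattern-ending + 12.5%
random-ending; per-type ratio 5) describe the steady-state alternation.
Trials 3–7 of a block close triplets whose first element is still
warm-up context and sit at the 25% chance rate instead, so empirical
checks of the 62.5% value must apply the standard leading-7-trials
exclusion first; with it, the expectation is exact, not asymptotic.

## Filtering and scores

Both analysis sets drop, per block, trials 1–7, trills, repetitions and
unlabeled trials. The RT set additionally keeps only correct responses
(a config flag retains them, as a documented variant); the accuracy set
always keeps incorrect trials. RT is the latency of the first key
press; a response is correct when that first press matches the target.
Filtering is idempotent.

Blocks collapse into epochs of five (blocks 1–25 → epochs 1–5). Per
participant × epoch we take median RT and mean accuracy per triplet
label; `rt_score = median_low − median_high` (ms) and `acc_score =
acc_high − acc_low`, both signed so positive means learning. Cells with
no surviving trials become flagged missing values (NaN with a
`complete` flag); nothing is imputed.

Two standardized-score variants control for baseline differences
between regimes:

- `zdiff` (default): z-transform the RT-set trials within participant ×
  epoch and score mean z(low) − mean z(high); accuracy scores are
  divided by the participant-epoch mean accuracy. Chosen because it is
  invariant to affine rescaling of a participant's RTs, which is
  exactly the property needed to compare groups with different average
  speeds. Zero-variance cells are flagged missing.
- `ratio`: rt_score as a percentage of the participant-epoch overall
  median RT.

The cohort-level outlier screen excludes a participant whose per-epoch
overall performance (median RT and/or accuracy; both by default, either
alone by configuration) falls outside the group mean ± 2 SD in strictly
more than half of the epochs. It requires at least 3 participants per
group — below that a group SD is not meaningful.

## Generation (inclusion/exclusion) scoring

A run is exactly 24 presses — three rounds of the eight-element
alternation. Its 22 overlapping triplets are classified with the same
successor rule; the score is the percentage of high-probability
triplets. Because exactly one of the four continuations of any
two-press context is the successor, chance is 25% in every context
(verified by exhaustive enumeration, not sampling). Trills and
repetitions count toward the denominator by default — the trill/
repetition exclusion is an RT-analysis rule, not a generation-scoring
rule — with a flag for the excluding variant (it can only raise scores,
since those triplets are always low). Runs never pool across run
boundaries; with equal-length runs the mean of run percentages equals
the pooled percentage, which the tests assert. Participant scores
against chance use a one-sample t-test plus the JZS Bayes factor.

## The cohort simulator

The simulator emulates a two-group, two-phase design: epochs 1–4 under
group-specific speed/accuracy instructions, epoch 5 under a shared one.
Reaction times follow

    rt = (base − speedup[epoch] − effect[epoch]·1[high]) · exp(σZ)

with standard-normal Z. Multiplicative lognormal noise was chosen for
positive support and right skew; because the lognormal's median is the
deterministic term, per-cell median RTs are unbiased for it and the
median learning score recovers `effect[epoch]` directly — which is what
makes parameter-recovery testing clean. Errors are Bernoulli with rate
`base + drift[epoch] + increment·1[low]`, clamped to [0, 0.95]; wrong
responses land uniformly on the other three keys.

Default parameters are invented, configurable descriptions of a
plausible cohort, not empirical constants: accuracy group 450 ms base,
3% errors; speed group 350 ms base, 12% errors with a 5-point low-
triplet increment; triplet effect (0, 25, 25, 25, 25) ms in both groups
so that learning is absent in epoch 1 and stable afterwards; epoch-5
speed-ups chosen so the groups' RTs converge under the shared
instruction. Group sizes default to 31 + 30. σ = 0.18 puts the trial-SD
near 70–80 ms, in the range typical of choice-RT data.

Each participant draws an independent child stream of the master seed,
keyed by enrollment index, so per-participant data are reproducible and
independent of simulation order; the seed and a config hash are embedded
in the output.

Generation streams: after two uniform presses, each press is the
pattern successor of the press two back with probability p, otherwise
uniform over the other three positions — so the expected score is
exactly 100p, 0 at p = 0 and 100 at p = 1, and p = 0.25 sits at chance.
A `uniform` baseline variant draws from all four positions instead
(expected score 100·(p + (1−p)/4)). Defaults p = 0.32 (inclusion) and
0.30 (exclusion) mimic the above-chance-but-implicit regime typical of
trained cohorts.

What the simulator does **not** model: post-error slowing, fatigue and
time-on-task autocorrelation, the response-to-stimulus interval (120 ms,
carried as metadata only), individual differences in learning rate, and
any cognitive-process account of the speed–accuracy trade-off. Passing
recovery tests therefore show that the pipeline measures what the
generative model injects — not that real RT data satisfy these
assumptions.

## Statistics

**Split-plot ANOVA.** Designs with one or two within factors and an
optional between factor, requiring every subject in every within cell
exactly once (group sizes may differ). Sums of squares are computed per
error stratum: subject means for the between stratum; subject-centred
profiles for each within main effect; double-centred profiles for the
within×within interaction. Within each stratum, Type-III SS come from a
sum-to-zero OLS fit, so unbalanced group sizes are handled as in the
conventional (SPSS-style) analysis; error degrees of freedom are the
analytic split-plot values. Effect sizes are partial η² =
SS_effect/(SS_effect+SS_error) within the stratum. For a 2-level within
factor the F equals the squared paired t exactly (asserted in tests).

**Sphericity.** Greenhouse–Geisser ε is computed from the pooled
within-group covariance of orthonormal contrast scores (Kronecker
contrasts for interactions) and clamped to [1/q, 1]. Mauchly's test
uses the standard chi-square approximation on the same contrast
covariance. Correction policy: applied when the effect has ≥ 2 contrast
dimensions and Mauchly's p < .05; raw and corrected df/p are always
both reported. The correction multiplies both df by ε and re-evaluates
the F tail.

**LSD contrasts** use per-contrast error terms (paired or independent
t, uncorrected p), not the pooled ANOVA error: robust to sphericity
violations and indistinguishable at ordinary reporting precision.
Identical cells return t = 0, p = 1 rather than NaN.

**JZS Bayes factors.** The default-prior t-test Bayes factor places a
Cauchy(0, r) prior on standardized effect size (default r = 1),
equivalently g ~ InverseGamma(1/2, r²/2), and evaluates the resulting
one-dimensional integral over g with adaptive quadrature (relative
tolerance 1e-10; the integration error estimate is returned). Effective
sample size is n for one-sample and n₁n₂/(n₁+n₂) for two-sample tests;
the two-sample form assumes equal variances. Reported as BF₀₁ (support
for the null). Recomputing reference Bayes factors from t statistics
printed to two decimals reproduces them to ±0.02–0.03; the residual
slack exists because reference values are computed from unrounded t.

**Inclusion Bayes factors (approximate).** The model-averaged
inclusion BF per effect is approximated via BIC: each candidate model
(all effect subsets respecting marginality, uniform model prior) is a
random-intercept mixed model whose ML likelihood is computed in closed
form — exact for balanced designs, where OLS and GLS fixed-effect
estimates coincide and the compound-symmetry covariance diagonalizes
into a subject-mean and a within-contrast stratum. Posterior odds of
inclusion are formed from unnormalized model weights to avoid
cancellation when one model dominates. Every output row is labeled
`bic_anova_approx`; this is *not* a g-prior Bayesian ANOVA and its
numbers are not comparable to one at fine precision.

## Numerical and design choices

- Positions 1–4, blocks/trials/epochs 1-based throughout; data
  serialized as UTF-8 CSV with header.
- The pattern phase restarts per block, and triplet classification does
  not cross blocks: both follow from the per-block task structure and
  the per-block exclusion rule.
- Warm-up trials do serve as first/middle elements of later triplets;
  removing early trials is the scoring module's job, not the
  classifier's.
- Degenerate inputs fail loudly: non-permutation cycles, out-of-range
  blocks, unbalanced ANOVA cells (naming the offending subject),
  zero-variance score vectors. Missing summary cells propagate as NaN.
- Test problem sizes: frequency checks use ~10⁵ trials (1300 blocks),
  generation chance checks 10⁵ runs, parameter recovery a 30 + 30
  cohort, and the type-I calibration 500 reduced-size null cohorts
  (8 + 8 participants, one epoch); all stochastic assertions use
  3-standard-error bands around the analytic target.

## Known limitations

- The ANOVA requires complete within-subject data; there is no
  unbalanced-within or missing-cell estimation.
- Mauchly's test uses the large-sample chi-square approximation only.
- The inclusion-BF approximation inherits BIC's unit-information
  implicit prior; directionally reliable, not calibrated against
  g-prior implementations.
- The simulator's stationary, independent-trials RT model understates
  the autocorrelation of real RT series; recovered standard errors are
  accordingly optimistic relative to human data.
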