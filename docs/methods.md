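# Methods

This note documents the models implemented in `ranksat`, the numerical
choices behind them, what the synthetic-data generators do and do not
emulate, and the known limitations.

## Valuation primitives

The range value of x in a context spanning [min, max] is
(x − min)/(max − min); values outside the span clamp to the endpoints so the
output stays in [0, 1] (contexts are never evaluated outside their span in
the intended designs, so clamping only guards misuse). The frequency value
is (rank − 1)/(n − 1) with 1-based ascending ranks; tied values share the
average rank. The combined RFT value is w·range + (1 − w)·frequency with the
range weight w ∈ [0, 1]. The DbS sample relative rank counts binary
comparisons won against a sample, ties counting one half — an unbiased
reading of a tie as a coin-flip comparison. Orientation (whether larger
magnitudes mean worse provision) is **not** baked into these primitives;
they operate on raw magnitudes, and orientation enters only where
better/worse semantics matter (the DbS comparison direction, rater
screening, the complaint-threshold ordering). This keeps a single source of
truth and avoids double negation.

The closed forms referenced above are the standard textbook statements of
the range and frequency principles; the implementation treats them as given
rather than re-deriving them.

## Inferred-distribution ranks

Parametric fits: normal by sample mean and sample SD (n − 1 denominator);
log-normal by mean and *population* SD (n denominator) of the log values;
uniform by least-squares endpoints against the distinct sorted levels'
ranked positions (rank − 1)/(m − 1). The n − 1 normal convention reproduces
the conventional worked example SD of 9.3 on {138, 140, 155}; for the
log-normal both denominators give the same mean inferred ranks at two
decimals, so the simpler maximum-likelihood (population) form is used. The
fitting criterion for "best-fitting" parametric distributions is not uniquely
determined in the source literature; moment-matching on the log scale is
adopted because it is the log-normal MLE and reproduces the reference
values. The inferred rank of x is the fitted CDF at x; the mean inferred
rank of a stimulus set averages the fitted CDF over the set under a single
fit to all values.

## Latent-normal ordinal likelihood

A 1–5 dissatisfaction rating of stimulus x is a censored latent normal:
mean L + RFT(x; w)·(U − L), SD s, cut at fixed {1.5, 2.5, 3.5, 4.5} with
infinite outer tails. The cutpoints are fixed and the endpoints L, U free
(bounds [−5, 11]) — the minimal identifiable mapping when the literature
frees "scale endpoints" without stating a cutpoint scheme. For
higher-is-better domains (interestingness, contact ease) dissatisfaction
falls with provision; this is expressed by fitted U < L rather than by
transforming stimuli, preserving one formula across domains.

Per-rater maximum likelihood uses bounded L-BFGS-B with one data-informed
start (least-squares line of responses on frequency values) plus 7 random
restarts; s is bounded to [0.05, 5]. The likelihood is multimodal in
(L, U, s), hence the restarts. The full model is additionally warm-started
from each restricted optimum (w = 0 rank-only, w = 1 range-only), and each
restricted fit is re-polished from the full optimum's (s, L, U); this makes
LL_full ≥ LL_restricted hold by construction and keeps the two sides of the
nested comparison equally well optimized, which matters because an
under-optimized restricted fit would inflate the likelihood-ratio statistic.

Nested tests aggregate per-rater statistics: χ² = 2·Σᵢ(LL_full,i −
LL_restricted,i), df = number of raters (one constrained parameter each),
p from the upper χ² tail. Tiny negative per-rater differences (optimizer
tolerance) are clamped at zero. Two caveats are inherent to this test and
deliberately not corrected, matching the reporting convention the package
mirrors: (i) the restriction w = 0 or w = 1 lies on the parameter boundary,
so the asymptotic null is a chi-bar-square mixture and the standard χ²
reference is conservative; (ii) with 11 observations and 4 parameters per
rater the finite-sample LR is inflated relative to its asymptotic
distribution. Empirically these act in opposite directions: simulated at 8
raters per replicate the test's measured type-I rate at α = .05 is ≈ 7%,
statistically compatible with the nominal level at 200 replicates.

**Identifiability of w.** Within a single 11-point context, range and
frequency values are strongly correlated, so the per-rater ŵ is noisy
(at true w = 0.5 it is nearly uniform on [0, 1]) and, being bounded, shrinks
toward 0.5 on average at extreme true values. Recovery is therefore assessed
at the condition level: the mean ŵ over ~35 raters separates w = 0.2, 0.5
and 0.8 cleanly (median condition-level absolute error ≈ 0.07 across the
bimodal and positively skewed contexts), but individual-rater weights should
not be interpreted. The group-level LR tests do not suffer from this because
they aggregate likelihoods, not point estimates.

## Elicitation

Probe k ("better than k of 100") pins the (100 − k)th percentile of a
higher-is-worse magnitude and the kth of a higher-is-better one. Fitting
minimizes Σⱼ (F(valueⱼ) − pⱼ)² on the probability scale — bounded residuals,
robust to heavy right tails — over two families: log-normal (initialised by
regressing log values on normal scores, refined by least squares) and
uniform, i.e. a linear CDF with free endpoints (the only two-parameter
linear CDF). The family with the smaller SSE wins; the choice is
scale-invariant, and ties go to the log-normal. Records with more than four
missing probes are excluded; non-monotone probe sequences are repaired by
pool-adjacent-violators averaging, and sequences needing more than two
repairs are excluded — the screening mirrors exclusion practice for erratic
responders, for which no published repair rule exists.

The subjective mean is exp(μ + σ²/2) (log-normal) or the midpoint (uniform);
the subjective rank of one's own provision is the fitted CDF at the own
value, with no tail flip for higher-is-better domains — the orientation flag
fixes only the interpretation (proportion better vs worse off). This
convention makes the rank coefficient in the satisfaction regressions
positive for higher-is-worse domains and negative for higher-is-better ones.

## Inference

Proportional-odds (cumulative-logit) regression is fitted by statsmodels'
`OrderedModel`; per-coefficient Wald statistics are (β̂/SE)² on 1 df. The
intercept-only log-likelihood is the closed-form multinomial category
log-likelihood, which the threshold-only cumulative model attains exactly.
Nagelkerke pseudo-R² = [1 − exp(2(LL₀ − LL₁)/n)] / [1 − exp(2·LL₀/n)].
Kendall correlations use tau-b (tie-corrected; ordinal ratings always
contain ties). Two-sample comparisons use the pooled-variance t-test
(df = n₁ + n₂ − 2) and pooled-SD Cohen's d, the convention consistent with
the t/df pairs this literature reports.

## Pipelines

Rater screening for the rating experiment: exclude when the response range
is ≤ 2 or the appropriately signed Kendall coefficient between responses and
stimuli (positive for higher-is-worse domains, negative otherwise) falls
below .5. Screening decisions are per-rater, idempotent and
order-independent; every report carries retained/excluded counts with
per-reason tallies.

Complaint thresholds: responses are ordered from best to worst provision;
all-yes, all-no and non-monotone patterns (a complaint at better provision
than a tolerated level) are excluded, with no repair — a single inversion
excludes. The threshold is, by default, the midpoint between the worst
tolerated and the best complained-at value (the unbiased interval estimate);
the first complained-at value itself is available behind the
`threshold_convention` config switch, since summary statistics in the
literature do not disambiguate the two. The threshold rank is the frequency
value of the first complained-at level within its condition's context.

Reports are deterministic: the same input, configuration and seed produce
byte-identical JSON.

## Synthetic data

The generators produce datasets with the generative structure each analysis
assumes, at the scale of the original designs (four rating conditions of 38
raters; 170 elicitation respondents; 42 complaint raters per condition).
Defaults, chosen once: range weight w = 0.5 and latent noise s = 0.5 on the
1–5 scale (no published values exist; these give clearly context-driven yet
noisy raters whose screening failure rate is small); belief hyperpriors
log-normal over log-means (meanlog 1.046, sdlog 0.20) and half-normal
(scale 0.4, floor 0.1) over log-SDs, placing the 10th/90th percentiles of
believed median feedback times near 9 and 40 days, the qualitative spread
reported for real students; multiplicative probe noise with log-SD 0.025,
calibrated so the elicitation screening excludes ≈ 5% of simulated
respondents, matching the exclusion rates the original studies report;
own provision log-normal(log 12, 0.5), giving an SD near the reported 7.8
days; satisfaction from a proportional-odds model with rank coefficient 3.2
(the reported coefficient scale) and own-value coefficient 0 by default —
a misspecification toggle (own-value-driven satisfaction) supports contrast
tests; complaint rule mixing 0.7 contextual rank with 0.3 absolute position
against a Normal(0.55, 0.12) personal threshold, reproducing the observed
"relative with an absolute component" pattern.

Per-participant random substreams are spawned from the seed by counter, so
datasets are stable under changes in n and fully reproducible.

What the generators do **not** emulate: response-order (ascending vs
descending presentation) effects, anchoring or digit preferences in probe
answers, correlated probe errors, demographic structure beyond marginal
gender/year frequencies, and any dependence of beliefs on own experience.
Passing tests therefore show that the estimators recover the models they
assume at realistic scale and noise — not that real raters satisfy those
models.

## Problem sizes used in simulation-based tests

Parameter recovery runs 35 raters per (condition, w) cell over two contexts
and three w values; LR-test calibration runs 200 replicates of 8 raters
each; the elicitation regression recovery runs 50 replicates of the full
170-respondent design; noisy-probe recovery uses 200 respondents at 5%
noise. These sizes keep each check at or below a few minutes while leaving
the binomial/medians acceptance margins meaningful.

## Known limitations

- Per-rater range weights are not interpretable (see identifiability above).
- No boundary correction for the w = 0/1 LR tests; the standard χ² reference
  is used, with the conservatism/inflation trade-off quantified above.
- Only the three belief families (normal, log-normal, uniform) are
  supported; no nonparametric or kernel beliefs.
- No hierarchical/pooled estimation: all fits are per participant, and group
  inference aggregates per-participant statistics.
- The elicitation repair rule (PAVA, limit 2) and the missing-probe limit
  (4) are conventions; published analyses state exclusions but not rules.
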