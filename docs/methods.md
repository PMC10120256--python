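# Methods

## Design overview

`metaror` implements a two-stage meta-epidemiological procedure for
collections of systematic reviews of two-arm randomized trials with a
binary outcome.

**Stage 1 (within review).** One analysed binary outcome is chosen per
review by a deterministic hierarchical rule: among primary outcomes
whose trial set spans both publication languages, take the one with the
most trials, ties broken by total sample size, residual ties
lexicographically by outcome name; if no primary outcome qualifies, the
same rule is applied to secondary outcomes; otherwise the review is
excluded.  The review's trials are then split into two strata and each
stratum is pooled **with the model, method and zero-cell correction the
review itself reported**, so the replayed meta-analysis matches the
source analysis rather than imposing one convention.

**Stage 2 (across reviews).** Each review contributes the log ratio of
its two stratum odds ratios; the ratio-of-odds-ratios (ROR) variance is
the sum of the two stratum variances, which treats the strata as
independent — exact here because they are disjoint trial sets sharing no
trial-level data.  Review-level log RORs are pooled with random-effects
inverse variance (DerSimonian–Laird τ²), always, regardless of the
within-review models.  The pooled ROR is read off its 95% CI: entirely
below 1 ⇒ the first stratum shows the larger effect (under the
OR < 1 = benefit convention), entirely above 1 ⇒ the second does,
otherwise inconclusive.

Four stratification designs are packaged: language (Chinese vs other,
overall and split by outcome role with a between-role chi-square test),
risk-of-bias rating within each language stratum (high/unclear vs low,
per ROB domain), language within the high/unclear-risk trials of each
domain, and population (Chinese vs non-Chinese) restricted to the
low-risk trials of each domain.  The low-risk restriction in the
population design exists precisely to remove confounding by bias: any
effect inflation attached to high/unclear ratings cannot reach a
contrast computed only on low-risk trials.

## Estimators and numerical conventions

* Per-trial effect: `ln OR = ln(ad/bc)`, `Var = 1/a + 1/b + 1/c + 1/d`.
  Any zero cell ⇒ 0.5 added to **all four** cells (when the review's
  configuration says `constant_half`; with `none` a zero cell is an
  error rather than a silent repair).  Tables with zero events in both
  arms, or all events in both arms, carry no odds-ratio information and
  are excluded; their ids are reported on the result.
* Mantel–Haenszel: `OR_MH = Σ(a_i d_i/N_i) / Σ(b_i c_i/N_i)` with the
  Robins–Breslow–Greenland variance for `ln OR_MH`.  The same
  continuity-corrected cells feed the MH sums, the RBG variance and the
  Q weights, so the three statistics describe the same data.  Cochran's
  Q for MH pooling uses per-trial inverse-variance weights about
  `ln OR_MH` (standard practice; the MH weights have no per-trial
  variance interpretation).
* DerSimonian–Laird: `τ² = max(0, (Q − (k−1)) / (Σw − Σw²/Σw))` with
  fixed-effect weights.  With a single effect τ² is defined as 0 and a
  warning is logged; single-trial strata are allowed throughout because
  real review strata are often that small — their RORs simply carry wide
  intervals and little pooling weight.
* A configuration requesting a random-effects model is always pooled by
  inverse variance with DL τ², even if its method field says
  Mantel–Haenszel: "random-effects MH" is not a standard estimator, and
  the random-effects convention in the source tooling is IV.
* Heterogeneity: `I² = max(0, (Q − df)/Q)·100` (0 when Q = 0), with the
  conventional overlapping descriptive bands 0–40 (not necessarily
  important), 30–60 (possibly moderate), 50–90 (substantial), 75–100
  (considerable); a value can carry more than one label and the package
  reports all that apply.
* 95% intervals use the normal quantile 1.96 on the log scale — no
  small-sample t or Hartung–Knapp adjustment — matching the convention
  of the review tooling being replayed.
* Direction inversion (so OR < 1 favours the experimental arm) negates
  the pooled log OR and reciprocates/swaps the CI; it is applied to both
  stratum results **before** the ROR, so inverting is a pure relabelling
  that reciprocates the ROR exactly.
* Subgroup differences: `Q_between = Σ w_g (θ_g − θ̄)²` with
  `w_g = 1/se_g²`, chi-square with (groups − 1) df, significance at
  P < 0.05.

## Descriptive accounting

The contribution table counts reviews, trials and participants
cross-classified by whether the review searched Chinese-language
databases and by trial language.  Percentages are integers rounded
half-up; the "X times higher" figure is the relative increase
`(p_A − p_B)/p_B` computed **on the already-rounded integer
percentages** and rounded half-up to one decimal.  That convention is
deliberate: it is the arithmetic that reproduces published
contribution-table prose (54% vs 15% ⇒ 2.6 times higher), whereas
unrounded inputs do not.  Risk-of-bias profiles report, per domain and
language, the integer percentage of trials rated high or unclear; a
language stratum with no trials is omitted rather than shown as 0%.

## The synthetic generator

`metaror.simulate` draws review collections with the exact statistical
structure the analysis assumes, so every pipeline stage can be validated
against known truth without any external data.

* Review j: true mean log OR `θ_j ~ Normal(μ, τ²)`.
* Trial: true log OR
  `θ_j + δ_lang·1[language=chinese] + δ_pop·1[population=chinese]
  + δ_bias·1[driver ROB domain ∈ {high, unclear}]`.
* Events: control `~ Binomial(n, p₀)`, treatment
  `~ Binomial(n, expit(logit(p₀) + true log OR))` — a logistic link, so
  a trial's true OR is exactly `exp` of its true log OR and planted RORs
  are analytic.
* One designated driver domain carries δ_bias; the other five domains
  are rated with the same prevalence but are pure noise, mirroring
  domain-at-a-time analysis.
* Each review draws from its own substream
  (`SeedSequence(seed, spawn_key=(j,))`), so identical seeds give
  byte-identical CSVs and enlarging the collection never perturbs
  earlier reviews.
* Reviews alternate fixed-effect Mantel–Haenszel and random-effects
  inverse-variance configurations (both stage-1 paths exercised), and
  roughly 60% analyse a primary outcome, matching the typical mix in a
  quantitative review set.

Defaults describe a realistic acupuncture-like collection: 15 reviews
(a plausible quantitative set), 5 trials per language stratum, 100
participants per arm, control event probability 0.3, μ = ln 0.7 (a
moderate beneficial effect), τ = 0.2, all δ shifts 0 (a null
experiment), P(high/unclear on the driver domain) 0.97 for
Chinese-language vs 0.51 for other trials, and P(Chinese population)
0.95 vs 0.10 by language.  Packaged scenarios (`make_fixture`) plant a
pure language effect (δ_lang = ln 0.5), a bias-confounded collection
(δ_bias = ln 0.5 with the imbalanced ROB prevalences and no language
effect), and a pure population effect (δ_pop = ln 0.5, everything else
balanced).

What the generator does **not** emulate: correlated ROB domains,
unequal arm sizes, review-specific outcome definitions or disease areas,
non-binomial overdispersion, multi-arm trials (the data model is
two-arm by construction), and selective reporting of outcomes.  Passing
tests therefore demonstrate correctness of the estimators and the
two-stage logic under the stated sampling model, not robustness to
those real-data features.

## Monte-Carlo calibration

`metaror.experiments.run_replicates` repeats generate → analyse under a
fixed configuration, varying only the seed.  The calibration runs used
by the test suite and the acceptance script use 30 reviews × 10 trials
per stratum × 100 per arm, p₀ = 0.3, τ = 0.1: with δ_lang = ln 0.5 the
pooled ROR point estimate centres on 0.5 with 95% CI coverage near the
nominal level over 200 replicates, and with no planted effect the
CI-excludes-1 rate over 500 replicates sits at 3–4%.  The slight
conservatism is expected: the review effect θ_j cancels exactly in each
ROR, so the true between-review ROR heterogeneity is zero, and the
truncated DL estimator then over-covers — a well-documented property of
the estimator, not an artifact of the implementation.

## Known limitations

* ROB ratings are taken at face value (no re-assessment), and the
  high/unclear-vs-low dichotomy is fixed; no three-level analysis.
* Odds ratios only; no risk ratios, risk differences, Peto OR, or
  continuous outcomes.
* The τ² estimator is DerSimonian–Laird throughout; REML/Paule–Mandel
  alternatives are not implemented.
* One selected outcome per review: reviews contributing several
  outcomes are deliberately collapsed by the selection rule, trading
  information for independence of review-level RORs.
* No publication-bias diagnostics (funnel asymmetry, Egger) — out of
  scope for the design.
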