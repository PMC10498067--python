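# Methods

`ordif` implements the iterative hybrid ordinal-logistic / item-response-theory
procedure for detecting differential item functioning (DIF) in polytomous
questionnaires — the approach popularised by the lordif family of tools — as a
native Python library, together with the psychometric summary statistics and
group comparisons that usually accompany such an analysis, and a synthetic-data
generator with full ground truth.

## The DIF model

For item response `Y` with ordered categories `1..m`, latent trait `θ` and
binary group `g ∈ {0, 1}`, three nested proportional-odds models are fitted per
item:

    M1: logit P(Y ≤ k) = β0k + β1 θ
    M2: logit P(Y ≤ k) = β0k + β1 θ + β2 g
    M3: logit P(Y ≤ k) = β0k + β1 θ + β2 g + β3 θ g

Uniform DIF (a group shift that points the same way at every trait level) is
tested by the 1-df likelihood-ratio χ² between M1 and M2; nonuniform DIF
(a group difference that changes sign or size across the trait, i.e. crossing
item response curves) by the 1-df χ² between M2 and M3. The 2-df M1-vs-M3
statistic is computed and reported but not used for flagging.

Because statistical significance alone is misleading at large n, two effect
sizes accompany the tests:

* **ΔR** — the log-likelihood-ratio pseudo-R² change,
  `ΔR = 1 − ln L(full) / ln L(reduced)`, computed for the uniform (ΔR₁) and
  nonuniform (ΔR₂) comparisons. Values ≥ 0.070 count as large. The
  conventional McFadden *difference* form (which needs the intercept-only
  log-likelihood) is available as an option, because the ratio form printed in
  applied DIF tables and the McFadden label genuinely disagree; the ratio form
  is the default since it is the formula those tables define.
* **Δβ₁ (CVBL)** — the Crane–van Belle–Larson criterion,
  `|(β₁^{M1} − β₁^{M2}) / β₁^{M1}|`: the proportional change in the trait
  slope when the group term enters. Values > 0.01 count as large uniform DIF.

Flags are pure functions of the statistics: `flag_uniform_sig ⇔ p_u < α`,
`flag_nonuniform_sig ⇔ p_n < α`, `flag_large_r2 ⇔ max(ΔR₁, ΔR₂) ≥ 0.070`,
`flag_large_cvbl ⇔ Δβ₁ > 0.01`, with α = .05 by default and an optional (off
by default) Bonferroni correction.

## The matching trait and purification

The matching variable is not a sum score but an EAP (posterior-mean) trait
score from a graded response model (GRM): for item j,
`P(Y_j ≥ k+1 | θ) = expit(a_j (θ − b_{j,k}))` with discrimination `a_j > 0`
and ascending thresholds `b_{j,1} < … < b_{j,m−1}`. Item parameters are
estimated by marginal maximum likelihood EM over a fixed quadrature grid
(default 49 equally spaced nodes on [−4, 4] with renormalised standard-normal
weights; the prior fixes the latent scale). The M-step maximises the expected
complete-data log-likelihood by L-BFGS on an unconstrained parameterisation
(log a, first cutpoint, log threshold increments), which enforces the
parameter constraints by construction; partial maximisation is a generalised
EM step, so the marginal log-likelihood is non-decreasing across cycles — the
test suite asserts this path on every fit. EM stops when no item parameter
moves by more than 1e-4 (cap 500 cycles). An `equal_discrimination` variant
constrains a common slope for users who prefer a Rasch-like trait; the graded
default reflects what 5-category items support. Items with a single observed
category are excluded with a warning; empty categories are merged into the
adjacent lower category and the recode map is retained.

EAP scores are linearly standardised to sample mean 0, SD 1 (higher responses
map to higher θ since slopes are positive by construction). Purification:
iteration 0 scores θ from all items and tests every item; each later iteration
re-scores θ using only the currently unflagged (anchor) items — re-estimating
the anchor-item parameters by default, with a config switch to freeze the
iteration-0 parameters for speed — then re-tests every item. The loop stops
when the flagged set repeats (fixed point or cycle, recorded separately), when
every item is flagged (hard warning, last non-empty anchor set kept) or at the
iteration cap. Purification flags on the χ² tests alone (either DIF type); the
effect-size flags are reported but do not drive anchor selection, matching the
way applied analyses count their DIF items.

The cumulative-logit fits use Newton–Raphson with analytic gradient and
Hessian, step-halving (up to 20 halvings), empirical-cumulative-logit start
values, and a gradient max-norm criterion of 1e-8. Fitted slopes larger than
25 in absolute value are treated as quasi-complete separation and reported as
non-converged with a diagnostic. The lower-tail convention `P(Y ≤ k)` with a
positive linear predictor is modelled exactly as written above, so β₁ is
negative for positively discriminating items; all tests and effect sizes are
invariant to this sign convention, and Δβ₁ is defined as an absolute value.

## Synthetic data

The generator draws two-group graded-model responses with a normal trait per
group (common SD; a group mean difference expresses *impact*, a true trait
difference that is distinct from DIF). DIF is injected parametrically:
uniform DIF shifts all focal-group thresholds by +δ (lowering the focal
group's expected item score at every θ when δ > 0); nonuniform DIF multiplies
the focal-group discrimination by ρ, making the group item response curves
cross. These are the canonical generating mechanisms for the two behavioural
DIF definitions. The default desk-scale fixture has J = 20 items, m = 5
categories, 500 persons per group, two uniform-DIF items (δ = 0.5), two
nonuniform-DIF items (ρ = 2) and zero impact. The item bank spaces
discriminations over [0.9, 2.2] and centres threshold ladders near zero with
unit-ish spread — the usual regime for 5-point Likert items.

What the generator does *not* emulate: multidimensional traits, response
styles, non-normal trait distributions, informative missingness (only MCAR
masking is supported via the I/O layer) and 3+ groups. Passing recovery tests
therefore show the pipeline works when its own model assumptions hold, not
that real questionnaire data satisfy those assumptions.

A note on detection power: with shared cutpoints across groups, the
proportional-odds interaction test absorbs only part of a discrimination-ratio
distortion, so nonuniform DIF of ρ = 2 is detected in roughly half of
replicates at 500 per group, while uniform DIF of δ = 0.5–1.0 is detected
nearly always. The recovery criterion is therefore stated on medians: the
median flag rate over true-DIF items must exceed the median over clean items.

## Reliability and CFA

Cronbach's α uses the standard variance decomposition; Guttman's λ6 uses
squared multiple correlations computed on the covariance scale via the
inverse covariance matrix (a singular matrix raises, with a ridge option).
The one-factor CFA minimises the normal-theory ML discrepancy
`F = ln|Σ| + tr(SΣ⁻¹) − ln|S| − J` with `Σ = λλ' + diag(ψ)` (factor variance
1) by L-BFGS-B with the analytic gradient; uniquenesses are floored at a
small positive multiple of the item variances and an active floor is reported
as a Heywood case. Indices follow the standard definitions: χ² = (n−1)F̂ with
df = J(J+1)/2 − 2J, the independence baseline for CFI/TLI, RMSEA from the
noncentrality, SRMR over the standardised lower triangle including the
diagonal, and ω from the standardised loadings. CFI/TLI are reported
unclipped with clipped-to-[0,1] companions. Because published scale tables
label ω and λ6 inconsistently, both are always emitted side by side. Items
are treated as continuous (Pearson covariances); polychoric estimation is out
of scope.

## Group comparison

The person-level total score is the *mean* item response (1..m scale), so
removing items leaves the scale unchanged. Both the pooled-variance t-test
and the Mann–Whitney U-test are computed for the uncorrected score and for
the score after removing the uniform-DIF-flagged items. The Mann–Whitney
p-value is exact for n_x·n_y ≤ 400 via a dynamic-programming enumeration of
the permutation distribution of the rank-sum (valid under ties; equivalent to
exhaustively enumerating labelings), with the convention U = R_x − n_x(n_x+1)/2
and a two-sided p of twice the smaller point-inclusive tail, capped at 1;
larger samples use the normal approximation with tie and continuity
corrections.

## Reference statistics

Because the 950-respondent DAI-36 dataset behind the published analysis is
not deposited, the package bundles the *printed* per-item statistics of that
analysis (`ordif.reference`) and reproduces its item classification: 7/7/4
nonuniform and 2/5/4 uniform DIF items across gender/education/age at
α = .05, every ΔR below the 0.070 cutoff, and large Δβ₁ confined to the
uniform items highlighted there. Continuous statistics of that analysis
cannot be reproduced without the raw data; everything else is validated on
synthetic data with known truth.

## Numerical and design choices

* Group coding: reference = first level in sorted label order → 0, focal → 1.
* Missing data: listwise deletion by default (complete cases); a
  `pairwise_item` policy keeps persons and uses their observed items for both
  trait scoring (the EM and EAP handle missing cells natively) and per-item
  fits.
* Null calibration of the LR tests is assessed with the generating trait as
  the matching variable, which isolates the test calibration itself; EAP
  matching was observed to be very slightly conservative, never inflated, in
  the suite's pilot regime.
* DIF curves (per-group test characteristic curves over flagged items)
  re-estimate group-specific item parameters by cumulative-logit regression
  of each flagged item on the purified trait score, anchors held common
  through the shared θ; a group with no positive discrimination for an item
  is skipped with a warning.
* Problem sizes in the shipped tests and acceptance script (e.g. 200–500
  null replicates, 40–100 purification seeds, n = 2000 recovery samples) are
  desk-scale choices that keep each study to a few minutes while leaving
  Monte-Carlo error well inside the asserted margins.

## Known limitations

Two-group designs only; no partial proportional odds or adjacent-category
models; no Monte-Carlo-calibrated flagging thresholds; no polychoric CFA or
measurement-invariance CFA; no covariate-adjusted group comparisons. The
nonuniform χ² test has modest power against discrimination-ratio DIF at
typical questionnaire sample sizes — a property of the model family, worth
remembering when an analysis reports few nonuniform flags.
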