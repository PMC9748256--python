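# Methods

## Evidence model

Evidence strengths map to positive likelihood ratios through an exponential
model: a combination with `n_vs`, `n_st`, `n_mo`, `n_su` lines of very
strong/strong/moderate/supporting evidence carries

    LR+ = c^(n_vs + n_st/2 + n_mo/4 + n_su/8),

benign evidence the reciprocal.  Posteriors follow from Bayes' rule on the
odds scale at a configured prior probability of pathogenicity.  The prior
(default 0.0441, a population-reference estimate for rare missense variants
in disease genes) and the scaling constant (default c = 1124) are
configuration constants: the cutoff table is generated directly from them
and does not depend on the solver below.

`solve_c` finds the smallest grid value of c for which a set of
rule constraints (combination → posterior floor/ceiling) is satisfied.  The
shipped default constraint set is a reconstruction of the standard ACMG/AMP
combining rules — pathogenic combinations must reach posterior 0.99,
likely-pathogenic combinations 0.90 — with one deliberate placement: the
"two strong lines" combination is constrained at the likely-pathogenic
floor, the level the exponential model is known to assign it.  With these
defaults `solve_c(0.0441)` returns 1132, close to but not exactly the 1124
used as the default constant; the exact constraint set behind that constant
is not derivable from the combining tables alone, which is why c is treated
as configuration.  The points-based equivalents are the log2 of the LR+
weights: ±1/±2/±4/±8 per strength, with a recommended cap of 4 points on
combined computational + hot-spot evidence (`pp3_pm1_within_cap`).

## Local calibration

**Estimator.**  For each unique labeled score `s`, the posterior point
estimate is `P_w / (P_w + w·B_w)` with `P_w`, `B_w` the pathogenic/benign
counts in the closed window `[s − ε, s + ε]`, and the local LR+ follows by
inverting Bayes' rule at the configured prior.  No kernel or parametric
smoothing is applied; the window-count estimator is the method.

**Window widths.**  ε(s) is the smallest distance-to-a-data-point such that
the window holds at least `min_labeled_in_window` (default 100) labeled
scores and at least `min_unlabeled_fraction` (default 0.03) of the unlabeled
reference scores.  Near the ends of the observed score range both
requirements scale by the fraction of the window inside the range
(configurable to "none").  Restricting candidate widths to observed point
distances makes the definition exactly reproducible by an exhaustive scan
(the test oracle) while allowing a vectorized bisection in production;
window membership includes edge points up to a few ulps of float rounding,
which is what makes "a point at distance exactly ε" well defined after
floating-point arithmetic.  Satisfaction is monotone in ε (counts grow,
edge-scaled requirements shrink), so the bisection is exact.

**Prior-matching weight.**  `w = (n_pathogenic / n_benign) / prior_odds`,
computed over labeled variants with available scores (so it varies slightly
per tool under missingness).  A window whose composition matches the full
data set then posteriors to exactly the configured prior.  Tests that
exercise the closed-form Gaussian truth set `w = 1` with prior 0.5, under
which the estimated LR+ is the plain density ratio.

**Bootstrap bounds.**  Labeled variants are resampled with replacement
within each class (stratified — class sizes and w stay fixed), windows stay
at their original positions, and per score the empirical α-quantile
(default α = 0.05, 10,000 replicates; tests and the acceptance script use
300–1000) of the weighted posterior is taken: lower quantile for the
pathogenic side, upper for the benign side.  Quantiles are computed on the
posterior scale and converted to the LR+ scale (the two are monotonically
related at fixed prior; the posterior scale is numerically safer near 0
and 1).  Bounds are clipped to the conservative side of the point estimate,
which also guarantees the mediant property below.  A window with zero
weighted benign count yields posterior 1 and an `inf` LR+ sentinel, never
NaN; its bootstrap bound is also 1, since resampling cannot create benign
mass where none was observed — see Limitations.

**Orientation.**  Tools whose low scores mean pathogenic are negated (an
order-reversing monotone transform) before calibration; the flip is recorded
so thresholds can be reported on the native scale.  Missing scores are
excluded from estimation and later counted in the indeterminate bin.

## Threshold estimation

For each strength cutoff `x`, the pathogenic threshold is the smallest
observed score τ with the lower LR+ bound ≥ x at *every* observed score
≥ τ (suffix condition); the benign threshold mirrors it with the upper
bound and ≤ 1/x (prefix condition).  Candidates are the curve's observed
scores; between them the bound is undefined rather than interpolated.
Monotonicity of the conditions makes the nesting invariant (weaker
strengths reached first) automatic; a repair-and-warn path exists for
ragged bounds but is unreachable in practice.  Thresholds carve the line
into up to nine intervals: pathogenic intervals are closed on the left,
benign on the right, the indeterminate middle open on both sides; a variant
earns the strongest strength whose threshold it reaches, and missing scores
are indeterminate.  Because a score in both directions' qualifying regions
would need its lower bound above 2.406 and its upper bound below 0.4156
simultaneously, the benign-supporting threshold always lies strictly below
the pathogenic-supporting threshold.

## Validation

On an independent labeled set, each interval's likelihood ratio is the
ratio of raw class rates inside the interval (unweighted — the weighted
construction belongs to calibration, the held-out check to the test set;
both modes are exposed).  Zero benign rate with positive pathogenic rate
reports `inf`; an interval empty of both classes is undefined (NaN) and
treated as vacuous by the validation property tests.  On the calibration
sample itself a stronger, exact statement holds: summing the window counts
over the curve scores inside a selected pathogenic interval and forming the
weighted LR gives at least the interval's cutoff, by the mediant inequality
(each window's weighted posterior is at least the cutoff posterior because
the clipped bound is).  Population fractions assign every score of an
unlabeled set (missing included, as indeterminate) to the nine bins and sum
to one.

Fixed externally recommended thresholds are assessed by reading the curve
at the nearest observed score: LR+ point estimate, the two stored one-sided
bounds as the interval (set `one_sided_alpha = 0.025` for a 95% two-sided
interval), achieved strength decided on the point estimate, and the
inclusive population fraction at or beyond the threshold.  Multi-tool
consensus queries estimate a joint local LR+ by expanding an axis-aligned
hypercube in per-tool rank space (ranks remove scale differences between
tools) until the labeled-count requirement is met, then applying the same
weighted-posterior formula.

## Prior estimation

The class prior is estimated from a positive score sample and an unlabeled
reference sample by nearest-neighbor removal: positives are resampled with
replacement (sample size = positive-set size capped by the unlabeled-set
size), each query removes its nearest remaining unlabeled neighbor
(absolute difference on the 1-D score scale; ties broken toward the higher
score), and the removal distances are plotted against the fraction of the
unlabeled set removed.  Distances stay near zero while the positive-like
unlabeled component is being consumed and grow rapidly once it is
exhausted; the bend estimates the mixing proportion.  Averaging over
`n_reps` passes (default 10) stabilizes the curve.

The bend detector is the one genuinely open design choice.  The default is
a tangent-onset rule: smooth the averaged curve with a moving average
(window 5% of the grid), normalize by the interior maximum, prepend a
(0, 0) anchor, drop the final half-window (where the nearly exhausted
unlabeled pool makes distances diverge regardless of the mixture), find the
point of maximum slope, and project its tangent back to the pre-rise
baseline; the intersection's abscissa, clipped to [0, 1], is the estimate.
A maximum-second-difference detector (and a slope-threshold crossing) are
available as alternatives but are not the default: on removal curves the
second difference is dominated by the high-variance far-neighbor plateau,
and in benchmark mixtures it latched onto plateau noise rather than the
bend.  On 20,000-point samples the default recovers a 0.3 mixture to
±0.02 with seed-to-seed standard deviation ≈ 0.004, and the α = 0 / α = 1
edge cases to within 0.03.  A flat curve (all distances equal, e.g. all
scores identical) is reported as not estimable (NaN).

Scores fed to the estimator must already be univariate; any
class-prior-preserving 1-D transform of richer variant features can be used
upstream, and reproducing any particular published prevalence figure is out
of scope here.

## Variant filtering

Filters operate on pandas records with VCF-convention coordinates
(1-based, closed); BED exclusion regions are 0-based half-open and any
overlap excludes a record (a SNV at position p occupies [p−1, p)).
Labeled-set order: missense → allele frequency (exomes-first, genomes
fallback, absent-from-both treated as rare) → gene harbors a pathogenic
variant (supplied gene list, or derived from the records' P/LP labels) →
drop VUS/conflicting/zero-star → training-set exclusion → optional
prior-archive overlap removal (order swappable for follow-up releases).
Population-set order: AF → caller PASS → median GQ > 20 → depth ≥ 30 when
AC < 3, else ≥ 10 → missense in pathogenic gene → key dedup (exome/genome
union) → region exclusion (BED trees or boolean flags) → training and
archive-overlap removal.  All steps emit a non-increasing waterfall of
surviving counts, and the pipelines are idempotent.

## Synthetic data

The generator draws class-conditional scores from parametric families so
all downstream estimates have analytic truth: the exact local LR+ is the
density ratio, thresholds for any cutoff are obtained by monotone root
finding, and the unlabeled set is an α-mixture with known α.  Defaults
emulate a curated-archive labeled sample (4,000 pathogenic vs 7,834 benign,
Beta(7,2) vs Beta(2,7) on [0, 1], 5% missing scores) and a 100,000-variant
population sample at α = 0.0441.  Equal-variance Gaussian classes
(N(2,1) vs N(0,1), log LR+ linear in s) are used wherever a closed form is
wanted.  What the generator does *not* emulate: multimodal or discretized
empirical score distributions, score ties at tool-specific round values,
label noise in curated archives, and correlation between missingness and
score — so passing tests demonstrate estimator correctness under clean
conditions, not robustness to those artifacts.  Record fixtures for the
filter engine construct each record to violate exactly one named rule,
making the expected survivor set exact by construction.

## Problem sizes and numerical choices

The test suite and acceptance script use: 20,000 scores per labeled class
with 1,000 bootstrap replicates for Gaussian threshold recovery; an
8,000-per-class fixture with 300 replicates for interval-level properties;
50 fresh replicates of 3,000–5,000 per class for independent-set
validation; 20,000-point samples with 3 removal passes and 10 seeds for
prior recovery; 200 random instances of ≤ 50 variants for brute-force
oracle equivalence; and a 100-record fixture for the filter waterfall.
Bootstrap matrices are held in float32.  Comparisons against published
cutoff-table values are made at the values' printed precision (four
significant digits).

## Limitations

* **Deep-tail overconfidence.**  Where the labeled benign sample runs out,
  windows become purely pathogenic, the LR+ sentinel is `inf`, and the
  bootstrap bound cannot penalize benign mass it never observed; a
  very-strong threshold can therefore be granted on the strength of an
  absence.  On well-separated synthetic classes the resulting intervals
  still validate (the suffix condition pushes the threshold far beyond the
  last benign score), but on real data very-strong claims near the score
  maximum deserve independent scrutiny.
* **Designed conservatism of strong thresholds.**  Selection on the
  one-sided bound over an entire suffix biases thresholds toward stringency
  by construction.  At 20,000 per class the supporting threshold recovers
  the analytic value to ≈ +0.05–0.07 (score units, Gaussian model), while
  the strong threshold lands ≈ +0.1 to +0.5 above it depending on the draw
  — benign windows near the strong region hold only tens of variants, and
  their Poisson noise propagates through the bound and the suffix minimum.
  This is the intended trade-off (understate rather than overstate
  evidence), but users comparing recovered thresholds to analytic ones
  should expect one-sided deviations that grow with the strength level.
* **Bootstrap scope.**  The weight w and the window widths are held fixed
  across replicates; resampling uncertainty in ε(s) and w is not
  propagated.
* **Consensus estimator.**  The rank-space hypercube ignores the unlabeled
  window requirement unless an unlabeled matrix is supplied, and rank
  transforms are computed on the labeled complete-case sample only.
* **Prior estimator.**  The tangent-onset detector assumes the distance
  curve has a single dominant bend; heavily overlapping mixture components
  blur the bend and bias the estimate toward the onset of overlap.
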