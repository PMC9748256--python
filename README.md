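# varcalib

Calibration of continuous variant-effect predictor scores into ACMG/AMP
PP3/BP4 evidence strengths via local positive likelihood ratios.

## The problem

Computational pathogenicity predictors (REVEL, CADD, SIFT, ...) emit a
continuous score per variant, but clinical variant classification under the
ACMG/AMP guidelines consumes *evidence strengths*: supporting, moderate,
strong, or very strong, for pathogenicity (PP3) or benignity (BP4).
Developer-recommended score thresholds carry no quantitative guarantee about
the strength of evidence they provide.  `varcalib` implements a general
framework that converts any tool's scores into score intervals with a
defensible evidence strength, for clinical laboratories, tool developers,
and expert panels calibrating predictors on their own data.

## The model

In the Bayesian reading of the ACMG/AMP combining rules, evidence strengths
correspond to positive likelihood ratios rising exponentially with strength:
a single line of evidence must reach

    LR+ = c^(1/8), c^(1/4), c^(1/2), c

for supporting, moderate, strong, and very strong respectively (benign
evidence uses the exact reciprocals), where the scaling constant *c* is
fixed so the combining rules reach the likely-pathogenic (0.90) and
pathogenic (0.99) posterior levels.  At prior P(pathogenic) = 0.0441 this
gives c = 1124 and the supporting cutoff LR+ = 2.406.

For a continuous score *s* the binary-test LR+ is replaced by the **local
positive likelihood ratio**, the class-conditional density ratio

    lr+(s) = p(s | pathogenic) / p(s | benign),

equivalent at fixed prior to the local posterior probability (local
positive predictive value)

    P(pathogenic | s) = lr+(s) · π / ((lr+(s) − 1) · π + 1).

`varcalib` estimates lr+(s) with an adaptive sliding window over the sorted
scores of a labeled pathogenic/benign set: the half-width ε(s) is the
smallest value such that the window holds at least 100 labeled variants and
at least 3% of an unlabeled population reference set (requirements scale
down proportionally at the score-range edges).  Benign counts are weighted
so the labeled set's class balance matches the prior.  One-sided 95%
confidence bounds come from a stratified bootstrap, and the threshold for
each strength is the most permissive score such that the *bound* clears the
strength's LR+ cutoff at every observed score beyond it:

    τ_su^P = min{ τ : ∀ s ≥ τ,  lr̂+(s) − Δ ≥ 2.406 },

with the mirrored prefix condition for benign thresholds.  The resulting
thresholds partition the score line into up to nine intervals (four benign,
indeterminate, four pathogenic), which are then audited on an independent
labeled set via interval likelihood ratios and on a population set via
per-interval fractions.  A nonparametric positive–unlabeled estimator
(nearest-neighbor removal distance curve) recovers the prior probability of
pathogenicity from the data themselves, and a filter engine reproduces the
dataset-construction rules (rarity, review status, training-set exclusion,
sequencing-quality and region filters) with auditable per-step counts.

## Worked example

```python
import varcalib as vc

# 1. Evidence cutoff table at the study prior and scaling constant
cfg = vc.strength_cutoff_table(prior=0.0441, c=1124)
for s in ("supporting", "moderate", "strong", "very_strong"):
    print(f"PP3 {s:<12} LR+ >= {cfg.pathogenic_lr[s]:8.4g}   "
          f"posterior >= {cfg.pathogenic_posterior[s]:.4f}")

# 2. Calibrate a synthetic predictor with known truth:
#    N(2,1) vs N(0,1) classes, so lr+(s) = exp(2s - 2) exactly
model = vc.ScoreModel(
    pathogenic=vc.DistSpec("normal", (2.0, 1.0)),
    benign=vc.DistSpec("normal", (0.0, 1.0)),
    n_pathogenic=10_000, n_benign=10_000, n_unlabeled=20_000,
    alpha=0.5, missing_rate=0.0, seed=42,
)
sim = vc.simulate_scores(model)
settings = vc.CalibrationSettings(n_bootstrap=500, weight=1.0, random_seed=0)
curve = vc.local_posterior_curve(
    sim.pathogenic_scores, sim.benign_scores, sim.unlabeled_scores,
    settings, prior=0.5,
)
curve = vc.bootstrap_bounds(curve, sim.pathogenic_scores,
                            sim.benign_scores, settings)

# 3. Thresholds and intervals (prior 0.5 matches the w = 1 design)
cfg_half = vc.strength_cutoff_table(prior=0.5, c=1124)
tp, tb = vc.build_threshold_sets(curve, cfg_half)
for s in ("supporting", "moderate", "strong"):
    tau = tp.thresholds[s]
    analytic = sim.truth.threshold(cfg_half.pathogenic_lr[s])
    print(f"tau_P({s:<10}) = {tau:6.3f}   analytic {analytic:6.3f}")

intervals = vc.build_intervals(tp, tb)
print("score 2.5 =>", vc.assign_strength(2.5, intervals))
print("missing   =>", vc.assign_strength(None, intervals))
```

Output:

```
PP3 supporting   LR+ >=    2.406   posterior >= 0.0999
PP3 moderate     LR+ >=     5.79   posterior >= 0.2108
PP3 strong       LR+ >=    33.53   posterior >= 0.6073
PP3 very_strong  LR+ >=     1124   posterior >= 0.9811
tau_P(supporting) =  1.552   analytic  1.439
tau_P(moderate  ) =  2.014   analytic  1.878
tau_P(strong    ) =  3.087   analytic  2.756
score 2.5 => pathogenic_moderate
missing   => indeterminate
```

The cutoff table states what each evidence strength demands: e.g. a score
qualifies as supporting pathogenic evidence only where the local LR+ is at
least 2.406 (posterior ≥ 0.0999 at prior 0.0441).  The estimated thresholds
sit deliberately *above* the analytic LR+ crossings because selection uses
the lower bootstrap bound over the entire tail — the method prefers to
understate evidence rather than overstate it.  A score of 2.5 falls in the
moderate interval; a variant without a score contributes no evidence.

The same pipeline is available from the shell:

```
varcalib table1 --prior 0.0441 --c 1124
varcalib simulate --seed 1 --out data/
varcalib calibrate --scores data/scores.tsv --labels data/labels.tsv \
    --reference data/reference.tsv --prior 0.0441 --seed 1 --out-curve curve.tsv
varcalib thresholds --curve curve.tsv --prior 0.0441 --c 1124 --out-json th.json
varcalib validate --thresholds th.json --scores test_scores.tsv \
    --labels test_labels.tsv --population pop.tsv --out report.tsv
varcalib prior --positives pos.tsv --reference pop.tsv --reps 10 --seed 1 \
    --out-json prior.json
varcalib filter --mode population --records records.tsv --out kept.tsv
```

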