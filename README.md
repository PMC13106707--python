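# fitrx

BMI-category classification from physical-fitness test batteries and
personalized exercise prescription, for researchers in health informatics
and exercise science who want a fully testable, simulation-backed
implementation of the hybrid sequence-model + boosting + prescription
workflow.

## What it does

A subject's fitness battery is four tests: a 3,000 m run recorded as
fifteen 200 m lap splits, a maximal pull-up count, a 60 s sit-up count,
and a 30×2 shuttle-run time. The pipeline:

1. **Synthetic cohorts** (`fitrx.cohort`) — draws subjects with the WHO
   BMI-category mix of a male-student population (5.3 / 74.5 / 19.0 /
   1.2 % under/normal/over/obese by largest-remainder rounding), a
   monotone fitness–weight-status dependence, and a late-lap fatigue
   slope that grows with category. Also simulates two-arm randomized
   trials with permuted-block (size 4) allocation.
2. **Preprocessing** (`fitrx.preprocess`) — z-scoring, SMOTE (k = 5)
   rebalancing to the majority class, Gaussian noise injection
   (σ = 0.1), tensorization of the 18 compact features into the
   N×15×4 sequence (lap series + three scalar channels replicated over
   time), and stratified 5-fold plans in which augmentation is confined
   to training splits — validation folds contain only original subjects.
3. **Feature extractor** (`fitrx.extractor`) — a NumPy 1D-CNN
   (filters 64/128/256, kernel 5, stride 2: sequence length 15→8→4→2)
   with 8-head scaled dot-product attention (head dim 32, dropout 0.3),
   residual + LayerNorm, and global average pooling to a 256-dim
   embedding z. Trained with Adam (lr 0.001, β₁ 0.9, β₂ 0.999), an L2
   penalty (10⁻⁴) on all weights, hidden Gaussian noise (σ = 0.05), and
   early stopping (patience 10) on the loss
   `0.4·L_3000m + 0.2·L_pull + 0.2·L_sit + 0.2·L_shuttle + 0.1·H(attention)`,
   where each per-metric term is the cross-entropy of a shared auxiliary
   head on a channel-masked forward pass and H is the mean attention-row
   entropy (a sparsity regularizer). Backprop is hand-derived and
   verified against finite differences in the test suite.
4. **Classifier** (`fitrx.gbm`) — LightGBM on the embeddings with the
   regularized logistic objective (λ₁ = 1.2, λ₂ = 0.8; softmax
   multiclass, whose two-class restriction is the binary form).
5. **Prescription** (`fitrx.prescribe`) — exact Shapley attribution of a
   prediction over the four metric summaries (2⁴ coalitions, background-
   mean imputation), deficiency ranking (top 1–2 positive contributors),
   mapping onto the weekly template (HIIT 5×30 min, aerobic 3×30 min,
   strength 2×30 min, ≥ 300 min total) with emphasis rules, progressive
   overload (+7.5 % volume for stagnant domains), and a deload guard:
   if the fatigue-recovery balance index (acute 7-day : chronic 28-day
   mean load ratio) exceeds 1.2, all loads drop 17.5 % for 4 days.
6. **Evaluation & trial statistics** (`fitrx.trial`) — leakage-safe
   cross-validated accuracy / macro-F1 / one-vs-rest macro AUC /
   confusion matrices, and for trials: paired within-group changes with
   t-based CIs, baseline-adjusted ANCOVA group effects, Cohen's d on
   change scores, McNemar's test on the unhealthy-weight dichotomy, and
   category transition tables.

## Worked example

```python
import fitrx as fx
import numpy as np

# 1. simulate a cohort and analyze a 12-week two-arm trial
records = fx.generate_trial(n_per_arm=580, seed=7)
outcome = fx.analyze_trial(records)
row = outcome.metrics.query("metric=='pull_ups' and group=='intervention'").iloc[0]
print(f"pull-ups: {row.baseline_mean:.1f} -> {row.post_mean:.1f}, "
      f"within-group change {row.within_change:+.2f} "
      f"({row.within_ci_low:+.2f} to {row.within_ci_high:+.2f})")
print(f"ANCOVA effect {row.ancova_effect:+.2f}, p={row.ancova_p:.2g}, "
      f"Cohen's d {row.cohens_d:.2f}")
print(f"McNemar p = {outcome.mcnemar_p:.3g}; "
      f"overweight->normal rate {outcome.transitions[2,1]:.3f}")

# 2. prescribe for a deficient subject via exact Shapley attribution
plan = fx.map_prescription(["pull_ups"])
print(f"strength sessions/wk: {plan.session('strength').frequency}, "
      f"total {plan.total_weekly_minutes:.0f} min/wk")
```

prints (seed 7):

```
pull-ups: 9.0 -> 13.5, within-group change +4.52 (+4.39 to +4.65)
ANCOVA effect +3.04, p=1.6e-139, Cohen's d 1.88
McNemar p = 3.47e-28; overweight->normal rate 0.750
strength sessions/wk: 3, total 330 min/wk
```

The simulated intervention arm improves by ≈ +4.5 pull-ups (the effect
size the trial generator is parameterized with; the 0.750 transition
rate is one seed's draw around the generator's 0.69 expectation), and a
pull-up deficiency adds one weekly strength session (2 → 3) on top of
the 300-minute base template.

The command-line interface mirrors the library
(`fitrx simulate|preprocess|train-extractor|train-gbm|evaluate|prescribe|adjust|trial-analyze|run-all`);
`fitrx run-all` executes every stage and writes a manifest binding the
artifacts to the config hash and seed.

## Documentation

`docs/methods.md` describes the generative model behind the synthetic
cohorts, every tunable parameter with its default and rationale, the
numerical choices inside the extractor, and what the simulation-based
tests do and do not establish about real cohorts.
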