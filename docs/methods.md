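# Methods

## The problem and the model

The package classifies a subject's WHO BMI category (underweight < 18.5,
normal [18.5, 25), overweight [25, 30), obese ≥ 30 kg/m²; half-open
intervals so every positive BMI is covered) from a four-test fitness
battery, and converts the classifier's per-metric attributions into a
weekly exercise prescription that is then adapted over a trial. The
classifier is a two-stage hybrid: a sequence feature extractor (1D CNN +
multi-head self-attention) produces a 256-dimensional embedding of the
N×15×4 input tensor, and a gradient-boosted tree ensemble (LightGBM)
performs the 4-class decision on those embeddings.

### Input representation

The 3,000 m run contributes fifteen 200 m lap splits (a genuine time
series carrying pacing and fatigue information); pull-ups, sit-ups and
shuttle time are single measurements replicated across all 15 time steps
as constant channels, so one convolution stack can read all four metrics
jointly. The compact form of a subject is the 18-vector
(lap_01..lap_15, pull_ups, sit_ups, shuttle_s); all preprocessing and
augmentation act on this compact form, and tensorization happens last so
the replicated channels stay exactly constant.

### Feature extractor

Three strided 1D convolutions (filters 64/128/256, kernel 5, stride 2,
ReLU) shorten the lap axis 15→8→4→2 via ceil-mode "same" zero padding
(the only padding scheme that realizes the ⌈L/2⌉ chain). Eight scaled
dot-product attention heads (width 256, head dim 32, dropout 0.3 applied
to the attention probabilities) re-weight the two remaining positions;
head outputs are concatenated, projected, added residually and
layer-normalized; global average pooling over time gives z ∈ R²⁵⁶.

Training loss:

    L = 0.4·L_3000m + 0.2·L_pull + 0.2·L_sit + 0.2·L_shuttle
        + 0.1·H(attention) + 1e-4·Σ‖W‖²

Each per-metric term L_m is the cross-entropy of a shared auxiliary
4-class softmax head computed on a forward pass in which every input
channel except metric m's is zeroed (zero = the feature mean, since
inputs are standardized). H is the mean Shannon entropy of the attention
rows — one-hot rows give 0, uniform rows over T′ positions give ln T′ —
which is the natural differentiable sparsity penalty for row-stochastic
matrices (an L1 norm is constant on them). The entropy is averaged over
the four masked passes; the loss definition does not single out a pass.
The L2 term is a loss-side penalty on all trainable weights (not
decoupled weight decay). During training, Gaussian noise (σ = 0.05) is
added to the post-attention features immediately before pooling.

Optimization is Adam (lr 0.001, β₁ = 0.9, β₂ = 0.999) with minibatches
(default 128) and early stopping: training ends after 10 consecutive
epochs without strict validation-loss improvement and the best epoch's
weights are restored. One integer seed derives separate generator
states for initialization, shuffling, and dropout/noise, so runs are
bit-reproducible.

The network is implemented directly in NumPy with hand-derived
backpropagation (im2col convolutions, attention/softmax/LayerNorm
gradients, including the entropy-regularizer gradient through the
softmax); a finite-difference gradient check in the test suite guards
every parameter block. All computation is float64.

### Embedding protocol

Because the loss only ever presents channel-masked inputs, the trained
network's calibrated operating regime is the set of four masked views of
a subject, not the raw four-channel tensor — embeddings of the unmasked
tensor are an out-of-distribution extrapolation and carry measurably
less class information. The classification embedding is therefore
`embed_views`: the pooled feature vector averaged over the four masked
views (still a 256-dim GAP output). `embed` (raw tensor) remains
available for inspection.

### Boosted classifier

LightGBM with the regularized logistic objective: negative
log-likelihood plus λ₁‖θ‖₁ + λ₂‖θ‖₂² on the leaf weights, λ₁ = 1.2,
λ₂ = 0.8. Four classes use one softmax objective, whose two-class
restriction is the familiar binary form; one-vs-rest is available by
flag (scores are row-normalized to a distribution). Tree count (200),
learning rate (0.1) and leaf limit (31) have no canonical values and are
config-exposed. Probabilities are clipped at 1e-12 when the loss is
evaluated. `boost_from_average=False` keeps the constant init score out
of the first tree's leaves when one wants leaf values to be exactly the
penalized increments (used by the shrinkage tests).

## Synthetic cohorts

No subject-level data ship with the package; the generator is the
test bed. Per subject: BMI is drawn from a truncated normal inside the
category's window; lap t = (lognormal base pace) + slope·(t−1) +
N(0, 1.2 s), with the base pace centered at 55.5 s/200 m shifted by a
per-category effect; pull-ups / sit-ups / shuttle are shifted normals
(counts rounded, floored at zero). Defaults:

| parameter | default | why |
|---|---|---|
| class proportions | 5.3 / 74.5 / 19.0 / 1.2 % | the development cohort's prevalence; counts by largest-remainder rounding (deterministic, sums to n) |
| fatigue slope (s/lap) | 0.10 / 0.20 / 0.40 / 0.60 by category | late-lap slowdown grows with weight status; gives the attention stack a sequence signature to find |
| metric effect sizes | ≈ 0.4–2.2 SD shifts, counts down / times up from normal→obese; underweight slightly below normal | monotone fitness–weight-status dependence at plausible magnitudes |
| lap noise | 1.2 s per split | split-to-split variability of a steady runner |

The two-arm trial generator allocates by permuted blocks of 4, applies
arm-specific 12-week changes (+4.5 pull-ups, −84 s run, −3.3 s shuttle
for the intervention; +1.5 / −30 s / −1.3 s control) with subject-level
change noise, draws adherence from N(0.785, 0.123) clipped to [0,1], and
flags completion as missing-at-random Bernoulli draws (attrition 13.2% /
14.1%). The intervention BMI change is per baseline category
(+0.3 / −0.8 / −2.6 / −1.55), calibrated once so the expected transition
rates match the targeted-prescription outcomes the framework is designed
to produce (≈ 69% overweight→normal, ≈ 42% obese→overweight); repetition
counts round half-up so integer records stay integers.

What the generator does **not** emulate: sex/age heterogeneity, seasonal
or learning effects, correlated measurement error across tests,
non-Gaussian tails, informative dropout, or dietary covariates. Tests
passing on these cohorts demonstrate correctness of the machinery and
recoverability of planted effects — not clinical performance on real
students.

## Augmentation and leakage control

SMOTE runs on the standardized compact features (Euclidean neighbors,
k = 5, ties broken by lowest index): each synthetic row is
x_i + u·(x_j − x_i), u ~ U[0,1], x_j one of x_i's k nearest same-class
neighbors; every class is raised to the majority count. k is clipped to
class size − 1 with a warning (classes of 1 are an error). Zero-mean
Gaussian noise (σ = 0.1, standardized units) is then added to original
and synthetic training rows. Both steps run strictly inside each
training split of the stratified 5-fold plan; standardization statistics
come only from the fold's original training rows; validation folds are
original subjects, byte for byte. A manifest records fold, origin and
parents of every row.

## Prescription layer

Attribution is exact Shapley over the four metric summaries (run total,
pull-ups, sit-ups, shuttle): 2⁴ = 16 coalition evaluations with absent
features imputed by the background mean, coalition value = log-odds of
the predicted class. Exactness makes the additivity identity
(base + Σφ = model margin) hold to numerical precision, which the tests
assert at 1e-9; a repeated evaluation guards against non-deterministic
pipelines. Deficiencies are the top positive contributors toward a
non-normal prediction: the leader, plus the runner-up iff it reaches
50% of the leader (the "top 1–2" rule made precise); ties break by the
fixed metric order (3,000 m, pull-ups, sit-ups, shuttle).

The weekly template is HIIT 5×30 min (5 cycles of 20 s sprint + 40 s
rest), aerobic 3×30 min, strength 2×30 min — 10 sessions, 300 minutes.
Each deficiency adds one session of its mapped modality (pull-ups →
strength, 3,000 m → aerobic, sit-ups → core/strength, shuttle → HIIT)
and raises that modality's load multiplier to 1.2. Dietary and
mental-health guidance is carried as static plan text only.

Adaptation runs on a biweekly tick. The fatigue-recovery balance index
is the acute:chronic load ratio — mean daily session load (RPE ×
minutes) over the trailing 7 days divided by the trailing 28 days
(steady load ⇒ 1.0). FRBI > 1.2 forces a deload — all load multipliers
×(1 − 0.175) for 4 days — and overrides any intensification. Otherwise
a metric improving by < 2% since the last assessment has its modality's
volume raised by 7.5%. The 17.5% / 4-day / 7.5% values are the midpoints
of the 15–20%, 3–5-day and 5–10% bands; all are config-exposed, as are
the 1.2 threshold and the 2% improvement cut.

## Trial statistics

Within-group change: paired mean difference with a Student-t CI
(degenerate interval when differences have zero variance). Between-group
effect: ANCOVA, `post ~ arm + baseline` by OLS, Wald CI and p for the
arm coefficient — invariant to affine rescaling of the baseline and
equal to the change-score contrast when baselines are balanced. Effect
size: Cohen's d on change scores with the pooled-SD denominator.
Category shift: McNemar's test on the unhealthy-weight dichotomy
(overweight ∪ obese), continuity-corrected χ² = (|b−c|−1)²/(b+c) with an
exact two-sided binomial fallback below 25 discordant pairs (b+c = 0 ⇒
p = 1); the corrected form tracks the exact test within 10% for b+c ≥ 50,
which the uncorrected statistic does not. Transition tables are
row-normalized over non-empty origin categories. Analysis is
per-protocol (completers only) by default, intention-to-treat by flag;
category-shift statistics are computed on the intervention arm, where
the prescription acts. Percent changes are reported with decreases
positive for time metrics and increases positive for count metrics,
rounded to one decimal in reports only.

## Evaluation and the learning benchmark

Cross-validated metrics (accuracy, macro-F1, one-vs-rest macro AUC,
4×4 confusion matrix) are computed only on original validation rows;
a class absent from a fold's validation set is skipped in the AUC
average with a warning.

The end-to-end sanity benchmark asks whether extractor + boosting beats
a multinomial logistic baseline on the 18 compact features, macro-F1,
majority of 5 seeds. The benchmark cohort places the class signal in
the fatigue slope alone (scalar effect sizes zero, default slopes):
with level shifts present the signal is linear in the compact features
and a logistic model is near Bayes-optimal, so the comparison would be
uninformative about the sequence model. Both models train on fold 0 of
a 2,000-subject cohort (the pipeline on the augmented split, the
baseline on the original rows) and are scored on a 4,000-subject fresh
draw from the same population, because macro-F1 on a 400-row fold is
dominated by rare-class evaluation noise (± several points from a
handful of obese subjects). Extractor training uses max_epochs = 15 with
batch 256, the point at which embedding quality plateaus at this problem
size.

## Numerical choices and degenerate inputs

- Standardization refuses zero-variance columns by name; supplied stats
  are never refit.
- Softmax and entropy computations clamp at 1e-300 under logs; LayerNorm
  uses ε = 1e-5.
- SMOTE with two identical minority points yields that point (zero-length
  segment) — valid, tested.
- Attention over a single position is the identity weight 1.
- `randomize_blocks` truncates the final permuted block, bounding arm
  imbalance by block_size/2.
- Empty prediction input returns an empty 0×4 probability matrix.
- FRBI requires a history spanning the chronic window (explicit zero-load
  padding otherwise) and errors on zero chronic load.

## Known limitations

- The extractor is CPU NumPy: fine at cohort sizes of a few thousand,
  not meant for much larger corpora.
- The per-metric loss semantics (channel-masked passes with a shared
  auxiliary head) is one defensible operationalization of weighted
  per-metric losses; a reconstruction-based alternative would train the
  unmasked pass directly and is left as future work behind the config
  surface.
- The benchmark's margin over the linear baseline is modest by
  construction (the planted signal is low-dimensional); it establishes
  ordering, not a headline accuracy.
- Synthetic-cohort results do not transfer to real populations; see the
  generator's non-goals above.
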