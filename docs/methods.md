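# Methods

## Problem setting

Two linked tasks on a trained probabilistic classifier:

1. **Dataset-level membership auditing** — given a query dataset,
   report a p-value for the hypothesis that the query behaves like
   training data under the model. This is a *dataset-level* test: it
   aggregates weak per-sample membership signals over many samples,
   and makes no claim about any individual sample.
2. **Audit-guided forgetting (knowledge purification)** — given a
   forget set drawn from the training data, produce a (smaller) student
   model that retains the teacher's task knowledge while the audit no
   longer flags the forget set as member-like.

## Auditing

### Per-sample signals

For sample \((x, y)\) and model output row \(p = F(x)\) (post-softmax;
the three signals need values on the probability simplex):

| signal      | definition                          | member side | range        |
|-------------|-------------------------------------|-------------|--------------|
| correctness | \(\mathbb{1}\{\arg\max_i p_i = y\}\) | \(\ge 0.5\) (fixed) | {0, 1} |
| confidence  | \(p_y\)                              | \(\ge \tau_y\) | [0, 1]    |
| entropy     | \(-\sum_i p_i \ln p_i\)              | \(\le \hat\tau_y\) | [0, ln C] |

Entropy uses the natural log; the base only rescales the calibrated
threshold. Arg-max ties break to the lowest class index (ties are
measure-zero for trained models). Correctness is already binary and is
not calibrated.

### Threshold calibration

The calibration dataset must be disjoint from the target model's
training data. It is split 50/50; the first half trains a *calibration
(shadow) model* — by default the student architecture under the same
training protocol as the target — whose metric scores on the two halves
give known member and non-member populations. Per metric and per class,
the threshold maximises balanced accuracy \((TPR + TNR)/2\) over a
finite candidate grid: midpoints between consecutive sorted unique
pooled scores plus one sentinel below the minimum and one above the
maximum. This grid is complete with respect to achievable confusion
tables. The maximiser is selected on exact integer counts (no
floating-point ties) and the smallest maximising candidate wins, making
calibration deterministic. Classes with fewer than 5 calibration
samples on either side fall back to a pooled class-agnostic threshold —
with calibration sets of a few hundred samples and ~10 classes,
class-conditional score sets are otherwise too small.

### Aggregation and the p-value

A sample votes member iff at least one signal lands on its member side
(OR rule). The dataset p-value is a two-tailed pooled-variance
two-sample Student's t-test between the vote vector and an all-one
reference vector of equal length (df = 2N − 2). Degenerate cases are
fixed by convention: votes identical to the reference give p = 1;
zero pooled variance with unequal means gives p = 0. Because the
reference vector has zero variance, a Welch test is not meaningful
here; the pooled form is the one used throughout.

Queries with fewer than 20 samples carry a `low_power` flag: a
two-sample test on a handful of binary votes has essentially no
resolution, and results at such sizes should not be interpreted. In
particular this implementation intentionally reports p ∈ {0, 1} for
single-sample queries rather than any intermediate value.

The audit of n samples is a pure function of (model, samples,
thresholds); metric computation is batched, and per-epoch audits during
forgetting reuse frozen thresholds.

## Forgetting (knowledge purification)

The student minimises, over retain-set minibatches \(B\) and forget-set
minibatches \(B_f\) (cycled in step with the retain batches):

\( \mathcal{L} = (1-\alpha_{KD}) \cdot CE(p, y)
  + \alpha_{KD} \cdot T^2 KL(q_T \,\|\, p_T)
  + \beta \cdot (\ln C - \bar H(B_f)) \)

with \(p_T, q_T\) the temperature-softened student and teacher rows.
The gradient of the forget term with respect to the logits is
\(p \odot (\ln p + H(p))\), pushing outputs toward uniform.

**Why a surrogate forget loss.** The audit p-value is a step function
of the model parameters (votes are thresholded indicators), so it has
no useful gradient. The audit instead modulates a differentiable
surrogate: after each epoch the forget set is audited on the current
student with the frozen calibrated thresholds, and

- if p > `target_p`: β ← min(β·multiplier, cap) — forgetting pressure up;
- else: β ← max(β/multiplier, β_init) — relax toward the initial weight.

Training stops early once the audit has stayed at or below `target_p`
for `patience` consecutive epochs *and* held-out accuracy is within
`accuracy_budget` of the teacher's; otherwise it runs the full epoch
budget.

Thresholds are calibrated once per run (student architecture) and
frozen across epochs; per-epoch recalibration would retrain the shadow
model every epoch for no stated benefit.

### Defaults

| parameter | default | meaning |
|---|---|---|
| `kd_weight` (α_KD) | 0.5 | hard-label vs distillation balance |
| `temperature` (T) | 2.0 | soft-target temperature |
| `beta_init` / `beta_multiplier` / `beta_cap` | 1 / 2 / 64 | forget-weight feedback schedule |
| `target_p` | 0.05 | audit level at which QF counts as forgotten |
| `patience` | 3 epochs | consecutive sub-target epochs before stopping |
| `accuracy_budget` | 0.05 | tolerated held-out accuracy drop vs teacher |
| `retain_fraction` (k) | 0.5 | fraction of the retain set the student sees |
| epochs / lr / batch | 50 / 1e-5 / 8 | reference training protocol (Adam) |

With β = 0 and an empty forget set the procedure reduces exactly to
knowledge distillation, and with α_KD = 0 additionally to plain
supervised training (asserted in the test suite).

## Baselines

- **Independent teacher/student**: retrain from scratch on a seeded
  k-fraction of the training data, optionally excluding the forget set.
- **SISA**: the training ids are partitioned into 10 shards by seeded
  uniform hashing (persisted so the forget samples' shards can be
  located); one model per shard; prediction is majority vote over shard
  arg-maxes with vote shares as the probability output (ties to the
  lowest class index). Unlearning retrains only affected shards; the
  other shard models are reused object-identical.
- **CF-k / EU-k**: only the last k named parameter groups (registry
  order) are trained on the retain set — from current values (CF) or
  re-initialised from the seed (EU); the frozen prefix is bitwise
  unchanged. Because the frozen prefix is constant, its activations are
  precomputed once and the tail is trained on cached features; this is
  mathematically identical to masked full training and much cheaper.

## Synthetic data and the reference study

The generators emulate the three data shapes the tool ingests:
Gaussian-blob tabular data (class c centred at `separation · e_c`, unit
isotropic noise), procedurally generated images (class-specific
oriented bars plus pixel noise), and an EHR-like table (half Bernoulli,
half numeric features, logistic labels; its default 20-feature shape
matches a small clinical screening table). All are pure functions of
(parameters, seed).

The **reference blob study** fixes the conditions under which every
audit/forget experiment and the acceptance script run: a 5000-sample
pool, C = 5, d = 500, separation 3.0; splits 1000/500/1000
(train/test/calibration) with the remainder a held-out non-member pool;
teacher MLP 512×256, student MLP 256×128; 50 epochs, Adam, learning
rate 1e-5, batch size 8; five replicate seeds, with reported values
averaged over replicates. Queries default to N = 200 (N = 100 for the
forget set).

Two properties of these conditions matter:

- **Memorisation regime.** At this learning rate the networks sit in a
  lazy/interpolating regime: with 500 near-orthogonal input dimensions
  the teacher memorises its 1000 training points essentially perfectly
  (train accuracy ≥ 0.998 across seeds) while held-out accuracy stays
  modest (~0.6). This strong overfit gap is exactly the signal the
  audit exploits, and mirrors how over-parameterised clinical models
  leak membership.
- **What passing does not show.** Real medical datasets have correlated
  features, label noise, class imbalance and distribution shift between
  calibration and training pools; none of these are emulated. Results
  on the fixture demonstrate the mechanics and the qualitative
  orderings (member vs non-member p-values, purity monotonicity,
  purification beating its no-audit ablation), not clinical-scale
  effect sizes.

## Numerical choices

- Model parameters and training run in float32; metric and p-value
  computation in float64.
- Probabilities from logits via max-shifted softmax; metric rows are
  renormalised before scoring to guard float drift; 0·log 0 := 0.
- Purity rounding: `round(k·N)` half away from zero; the realised
  purity is stored, keeping the mixed-query invariant exact.
- Sampling is without replacement everywhere; non-members for
  QNO/mixed queries come from a dedicated held-out partition never used
  for training, testing or calibration, so no leakage through the
  calibration model is possible.
- The ResNet-18/34 registry entries follow the standard residual layer
  plan (7×7 stem, four stages of basic blocks, batch-norm affine
  parameters, fully connected head); their parameter counts are
  computed from the instantiated plan. They support seeded
  instantiation and forward inference (batch norm in inference mode);
  they are parameter-accounting references, not training targets, in
  this package.

## Known limitations

- Individual-sample (N = 1) membership guarantees are out of scope by
  construction; the test has no power there (see `low_power`).
- Classification only: the three audit signals presuppose a
  probability simplex over classes; regression is not supported.
- The forget term pushes toward uniform outputs on QF; under extreme β
  this can degrade nearby regions of input space. The feedback
  schedule and the accuracy budget are the guard rails, not a
  certificate — nothing here is certified removal or differential
  privacy.
- The shadow-model protocol assumes the calibration data distribution
  matches the training distribution; a mismatched calibration set
  shifts thresholds and biases the audit in either direction.

## Problem sizes

The test suite trains 5 replicate teachers (~12 s each on one core)
plus the purification/baseline runs per seed; the full suite completes
in about 3 minutes, and `scripts/acceptance.py` in about 2, on a single
CPU core. These sizes were chosen so a full reproduction is an
interactive-scale task.
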