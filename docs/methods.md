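# Methods

## Problem setting

The package predicts whether a patient with a first atrial-fibrillation (AF)
diagnosis will experience a transient ischemic attack or ischemic stroke
(TIA/IS) within one year, from electronic-health-record visits recorded over
the two years preceding the AF event. The defining difficulty of this data is
missingness: each visit records only a subset of ~40 demographic, laboratory
and echocardiographic variables, so after monthly summarization roughly 70%
of cells carry no observation.

## Model

### Architecture

Each feature *j* has its own branch: a GRU with scalar input and hidden size
*h* (default 8) consumes feature *j*'s 24-step summarized series; the final
hidden state feeds a one-hidden-layer tanh head (width 8) producing a scalar
branch output *uⱼ*. The prediction combines branches linearly before the
sigmoid,

    z = b + Σⱼ wⱼ uⱼ,    score = σ(z),    eⱼ = wⱼ uⱼ.

Because combination is affine, *eⱼ* is feature *j*'s exact additive
contribution to the logit, and branch *j*'s computation depends on no other
feature's input. Both properties are enforced by construction and tested
(additivity to <1e−5; isolation bit-exactly).

Three variants share one numpy kernel, a bank of *m* branches with *p* input
channels each: `independent` (m = 40, p = 1, per-branch heads), `shared_head`
(per-branch GRUs, one head parameter set), and `pooled_gru` (m = 1, p = 40),
the conventional GRU baseline. Gate equations use the standard GRU
formulation with the reset gate applied to the recurrent candidate term
including its bias; backpropagation-through-time is derived analytically and
checked against central finite differences (relative error <1e−5).

### Composite loss

The loss is binary cross-entropy on the combined logit plus a per-branch
term that treats each branch as a sub-classifier of the same label:

    L = BCE(σ(z), y) + λ · (1/m) Σⱼ BCE(σ(eⱼ), y).

The branch term is the only coupling between branches besides the shared
label; λ = 0 recovers plain BCE. The published description names this loss
but does not write it, so the form above is this package's interpretation
(configurable via `branch_loss_weight`). The default is λ = 1: with ~70%
sentinel cells, direct per-branch supervision is what makes individual
branches learn their feature's marginal signal; weak coupling (λ ≈ 0.1)
leaves non-dominant branches under-trained at the cohort sizes used here.

### Optimization and early stopping

Mini-batch Adam (batch 256), learning rate 0.02 with a cosine schedule to
zero over `max_epochs` (default 50), decoupled weight decay 1e−3 on weight
matrices, global gradient-norm clipping at 5. The combining bias starts at
the training-set log-odds so the loss is calibrated from the first epoch, and
the GRU update-gate bias starts at +2 — a persistence prior (analogous to
LSTM forget-bias initialization) that biases branches toward carrying hidden
state across months whose cell is the sentinel, i.e. toward accumulating the
few observed values rather than reacting to absence.

Early stopping watches the validation split and restores the best epoch.
The default monitor is validation AUROC (`monitor="auroc"`): the training set
is down-sampled to 4:1 negatives:positives while the validation set keeps
the natural ~8.6% prevalence, so validation cross-entropy mixes a calibration
offset with discrimination and, with only ~40 validation positives at the
default cohort size, is too noisy to select epochs reliably;
`monitor="loss"` (the composite loss itself) is available and tested.

## Preprocessing

The feature window is days −719…0 relative to the first AF event, tiled by
24 fixed 30-day intervals; interval 24 ([−29, 0]) contains the AF diagnosis
day. Numeric cells are interval means; binary/categorical cells are interval
modes with ties broken toward the smallest code (deterministic and
order-independent). Patients with no in-window observations keep an
all-missing sequence rather than being excluded.

Observed numeric cells are min–max scaled to [0, 1] using training-split
ranges (values outside the range are clipped); categorical codes are divided
by the maximum training code. Scaling statistics are fit on training
patients only — a leakage-guard test verifies that perturbing test values
changes nothing upstream. Missing cells then become either the scaled
training mean/mode or the sentinel −1, which is strictly outside the scaled
range, so a model can always distinguish absence from any measurement. The
original work does not state how features were normalized before the −1
substitution; min–max scaling is this package's choice precisely because it
guarantees the sentinel is out-of-range.

Splits: stratified 60/40 train/test, validation re-split as 20% of training
(both exact to one patient per label stratum), down-sampling keeps all
training positives and samples negatives without replacement to exactly 4:1
(the direction is forced: at 8.6% prevalence a 4:1 ratio is reachable only
by removing negatives). Validation and test sets are never down-sampled.

## Synthetic cohort generator

No study cohort is public, so the generator emulates the statistical
structure the pipeline assumes, with recorded ground truth:

- **Traits and visits.** Each patient has a latent per-feature trait
  (Gaussian for numeric features; patient-constant flags/codes otherwise).
  Visits follow a homogeneous Poisson process (default 1 visit/patient-month
  over 24 months) plus a guaranteed index visit at day 0; visit values add
  within-patient noise (0.3 × between-patient SD). Each value is independently
  missing at its feature's per-visit rate (0.05 for demographics up to 0.9
  for echo/NT-proBNP), matching the field's pattern that labs and echos are
  measured at dedicated encounters only. Missingness is MCAR by default; a
  MAR mode (sicker patients measured more often) exists but is off.
- **Outcome.** Logistic in standardized traits with nonzero weights only on
  five planted features: history of TIA/IS (+2.0 log-odds — the dominant
  predictor, consistent with prior thromboembolism being the strongest known
  stroke risk factor in AF), eGFR (−1.0 per SD), hsCRP (+0.9), hematocrit
  (−0.8), fasting glucose (+0.8). The intercept is calibrated by bisection so
  mean outcome probability hits the target prevalence 0.086 (tolerance
  0.002); with no planted weights the closed form logit(0.086) ≈ −2.364 is
  recovered.
- **Survival.** Positives receive an event day uniform on (0, 365];
  negatives are censored at 365 + Geometric(mean 180) days, giving every
  non-event patient a full outcome window and the KM/log-rank analyses a
  realistic censoring tail.

What the generator deliberately does **not** model: cross-feature
correlation (e.g. creatinine–eGFR coupling beyond the baseline table),
medication/anticoagulant dynamics, ICD-coded ascertainment, time-varying
hazards within the first year, and informative visit timing. Passing tests
therefore demonstrate that the pipeline recovers additive, patient-constant
signal under heavy missingness — not that it handles temporal trends or
confounded observation processes in real EHRs.

## Evaluation protocol

Discrimination: AUROC (equals pairwise concordance; verified against an
all-pairs oracle), AUPRC (step interpolation), Harrell's c-index (comparable
pairs are earlier-observed-event pairs; score ties score ½; verified against
a brute-force oracle and lifelines). Confidence intervals are percentile
bootstrap over 1,000 patient-level resamples (BCa was not used; the
percentile method is the simplest consistent with a plain bootstrap
protocol); resamples on which a metric is undefined are skipped and counted.

Decision thresholds come from the validation split only: fixed 0.5,
Youden-maximizing, or F1-maximizing, with candidates at midpoints of
consecutive sorted unique scores plus {0, 1} and ties toward the smaller
threshold (equivalent to exhaustive search over all cut-points).
Threshold-dependent metrics (Youden's J, F1, recall, precision, G-mean) are
reported on the test set at the validation-selected threshold.

Survival: Kaplan–Meier per predicted risk group (split at the same
validation threshold) with the two-group log-rank test, both backed by
lifelines and verified against hand product-limit/textbook computations;
follow-up is not truncated at 365 days. Decision-curve analysis reports net
benefit NB(p_t) = TP/n − (FP/n)·p_t/(1−p_t) against treat-all/treat-none.

## Benchmarks

Nonsequential learners (logistic regression, RBF-SVM with probability
outputs, random forest, XGBoost) consume either the 40 values of the last
summarization interval or the flattened 24 × 40 sequence, under either
missing policy; sequential models always consume the full sequence. Clinical
scores join the table with the integer score as the ranking statistic.
Hyperparameters are small fixed defaults (documented in
`benchmarks.default_specs`); the original tuning grids are not public, and
reproducing cohort-specific benchmark values is out of scope.

## Problem sizes and determinism

Default experiments use n = 4,000 patients (≈785 down-sampled training
patients, 480 validation, 1,600 test), chosen so the full 5-seed
planted-recovery and independence-benefit experiments and the test suite run
comfortably on a single CPU. Every stochastic step — cohort generation,
splitting, down-sampling, parameter initialization, batch order, bootstrap —
derives from explicit integer seeds; identical seeds reproduce outputs
byte-for-byte.

## Known limitations

- The composite-loss form and branch-head architecture are interpretations
  of a description whose exact specification is not public.
- The additive decomposition explains the model's logit, not causal feature
  effects; correlated features in real data would split credit arbitrarily.
- Scores are uncalibrated by design (down-sampled training shifts the
  intercept); no recalibration is applied.
- The pooled-GRU baseline uses the same budget and trainer as the
  independent model; its weakness under heavy sentinel missingness is the
  phenomenon under study, not a claim that pooled GRUs cannot be tuned
  further.
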