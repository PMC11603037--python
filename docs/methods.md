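# Methods

`trapod` implements an end-to-end framework for predicting postoperative
delirium (POD) from intraoperative multivariate time series, together with
the statistical machinery used to compare models and screen features. The
real perioperative cohorts such frameworks are developed on cannot be
shared, so the package ships a synthetic cohort generator that reproduces
the *structural* properties the methods depend on; every claim the test
suite makes is a claim about the methods under those simulated conditions,
not about clinical performance.

## Outcome and timing model

A surgery's POD label comes from Nu-DESC assessments in the recovery room:
each assessment scores five categories (disorientation, inappropriate
behavior/communication, hallucinations, psychomotor retardation) 0–2, and a
surgery is positive iff any assessment totals ≥ 1. Surgeries with no
assessment cannot be labeled and are excluded with a logged record rather
than treated as negatives — recovery-room assessment defines the cohort.

Intraoperative time is measured in minutes from anesthesia begin
(T_begin = 0) to anesthesia end (T_end). Observation windows W = [Tx, Ty]
have endpoints relative to T_begin (plain numbers) or T_end (negative
numbers), so `[0, 30]` is the first intraoperative half hour and
`[-30, T_end]` the last. Windows resolve to half-open intervals; bins are
left-closed, anchored at the window start.

## Preprocessing pipeline

Fixed order: valid-range cleaning → composite merging → grid resampling →
cumulative dose channels → missingness indicators → imputation → scaling.

* **Valid ranges** are inclusive on both bounds (a value exactly at the
  bound is physiologically possible); out-of-range values become missing,
  never deleted rows.
* **Composites** concatenate member event streams (e.g. invasive plus
  non-invasive mean blood pressure) before binning; members are kept so
  models can still tell the sources apart.
* **Resampling** mean-aggregates observations into 3- or 5-minute bins;
  an empty bin is missing with mask 1. The mask is computed here and never
  altered afterwards — it is the ground truth for the missingness
  indicators.
* **Cumulative doses** restart at 0 at the window start (no carry-in of
  medication given before the window) and are never missing.
* **Missingness indicators** copy the mask for the feature domains where
  absence is informative; domains where a missing entry means a negative
  finding (medical history) get none.
* **Imputation** is last-observation-carried-forward within the window;
  bins before the first observation, and all-missing series, take the
  training-set channel mean. LOCF deliberately does not carry values in
  from before the window, keeping windows self-contained (a `carry-in`
  variant would be a one-line change in `impute`).
* **Scaling** is a z-transform with mean/SD computed on the training split
  only, applied to indicator channels too; zero-variance channels map to 0.
  Imputation means use observed bins only (post-imputation statistics would
  be biased toward LOCF plateaus).

Tabular views for MLPs: `TAB_P` (10th/50th/90th percentiles, plus the
end-of-window total for medications), `TAB_F` (Hjorth activity/mobility/
complexity with population variance and first differences at the grid
interval, plus the full-depth orthonormal Haar transform after padding to
the next power of two by repeating the last value — padding choice makes
the transform energy-preserving and testable), and `TAB_T` (channel-major
vectorization of the raw grid).

## Models

All networks map a surgery to one score in [0, 1] and are implemented on a
small reverse-mode autodiff core (`trapod.nn`) written for this package.

* **MLP** — fully connected, logistic-sigmoid hidden activations.
* **LSTM** — stacked standard cells; last hidden state feeds the MLP head.
* **TRAPOD (encoder-only transformer)** — per-step linear projection of the
  k channels into a learnable d-dimensional space, additive positional
  encoding (fixed sinusoidal by default, learnable optional), a stack of
  post-norm encoder blocks (single-head self-attention by default, residual
  + layer norm, feed-forward), pooling over time (mean by default, flatten
  optional), MLP head.
* **Hybrids** — a sequence branch and a static-feature MLP branch each emit
  a pre-sigmoid logit; a 2-weight + bias linear combiner followed by a
  sigmoid fuses them.

Losses: class-weighted binary cross entropy (positive weight defaulting to
N_neg/N_pos of the training fold) and the focal loss
FL(p_t) = −α_t (1−p_t)^γ log(p_t), which reduces exactly to weighted cross
entropy at γ = 0 when α_t encodes the class weights. Probabilities are
clipped at machine epsilon with a logged warning. Training uses Adam with
seeded initialization and seeded batch shuffling; early stopping monitors
validation loss ("no improvement" read as no decrease) with patience 10 and
restores best-epoch weights.

Attention interpretation: the last encoder block's softmax weights (rows
sum to 1) are averaged over heads and surgeries; the per-time profile a_t
is the mean attention mass *received* by time index t, and the
feature × time saliency is S[f, t] = w_f · a_t with w_f the L1-normalized
magnitude of the input-projection weights of channel f.

## Model selection and comparison

Patient-grouped splits everywhere: all surgeries of a patient fall on one
side of every split, outer fold, and inner fold (3 × 3 nested CV).
Hyperparameter search is a full grid or successive halving (the rung logic
at the core of Hyperband; full bracket scheduling is out of scope because
it adds machinery without changing selection behaviour at this scale), with
configurations selected by mean validation AUPRC — the appropriate metric
at ~9% prevalence, where AUPRC chance level equals the prevalence.

Test metrics are summarized over bootstrap resamples of the test set
(percentile CIs; single-class resamples are redrawn and logged). Two
models' per-resample metric vectors P0, P1 are compared with the
train/test-size-corrected paired t-test:
D = |P0 − P1|, σ²_mod = Var(D)·(1/n + n_train/n_test), t = D̄/√σ²_mod, with
n−1 degrees of freedom. Two printed forms of this statistic in the source
material are internally inconsistent (a missing product with Var(D), and a
division by σ²_mod rather than its root); the implementation uses the only
form that is a t-statistic. The ratio orientation (the correction
literature scales by n_test/n_train) and the absolute value on D — which
makes the statistic one-sided by construction — are both flags, defaulting
to the printed convention.

Threshold scenarios: A maximizes sensitivity + specificity, B maximizes
precision + recall, C pins recall at ≥ 0.8 (implemented as the largest
threshold whose recall still meets the target — the literal "smallest
threshold" reading is degenerate, since every sufficiently small threshold
has recall 1). Confusion matrices are projected onto a daily caseload with
P = round(caseload·prevalence), TP = floor(recall·P), predicted positives
= round(TP/precision); these rounding conventions reproduce the standard
worked example (recall 0.8, precision 0.163, 100 surgeries at 9% →
TP 7, FP 36, TN 55).

## Univariate screening

Per feature and window, surgeries are summarized by the mean over observed
grid bins and the missingness rate over grid bins (the grid denominator
matches what the models see). Spearman rank correlations against the label
get t-statistic p-values and Benjamini–Hochberg FDR applied separately per
window; coefficients are reported as absolute values with the sign stored
separately. The mixed-effects screen fits, per feature,
`value ~ target + time + target:time` with a patient random intercept and a
surgery-within-patient variance component (statsmodels `MixedLM`), over
three consecutive begin-anchored 30-minute windows coded time = 1, 2, 3 —
a single numeric slope, since one time coefficient is reported per feature.
Non-converged fits are flagged and excluded. Min-max normalization of the
dependent variable is applied for comparability across features; parameter
recovery tests disable it so estimates are on the simulated scale.

## Synthetic cohort generator

Each time-dynamic feature is a stationary AR(1) latent path on a 1-minute
grid (tunable autocorrelation — the simplest process with one memory knob),
shifted by a patient-level random intercept shared across a patient's
surgeries, observed at Poisson-process times with i.i.d. Gaussian
measurement noise. Class effects on POD-positive surgeries: a mean shift, a
linear within-window trend, and a log-shift of the observation rate
(informative missingness). Nu-DESC assessments are drawn after anesthesia
end; positives are guaranteed a total ≥ 1, negatives are all-zero — the
label construction only needs the dichotomy. Every patient and surgery owns
a counter-based Philox stream keyed by the global seed, so growing the
cohort never perturbs existing surgeries.

Defaults emulate the structure of a large perioperative cohort: ~8.5%
prevalence, extra surgeries per patient ~ Poisson(0.15), surgery length
~ N(150, 50²) clipped to [100, 480] minutes, observation rate 1/3 per
minute (≈3-minute spacing), five vital-sign/medication/EEG-like channels.
What the generator does **not** emulate: real physiological waveform
shapes, pharmacokinetics, inter-feature correlation structure, documentation
artifacts, or the breadth of a 238-feature menu. Passing tests therefore
demonstrate that the pipeline recovers the kinds of signal it targets —
temporal trends, informative missingness, hierarchical mean shifts — not
that any particular clinical performance level is attainable.

### The mean-matched slope cohort

The central demonstration needs a cohort where classes differ *only* in the
within-window slope of one feature while the window mean is matched by
construction (trend centered on the window midpoint). For the slope to be
identifiable at all, the construction observes the signal feature densely
(1/min) and gives it weak autocorrelation (φ = 0.5): strong AR(1) memory
produces spurious within-window drift that mimics the signal, and sparse
observation leaves a third of the bins to imputation. The default effect
size is 1.25 latent-SD per 30-minute window with measurement noise at the
feature's own level; under these conditions the per-surgery least-squares
slope (the oracle upper reference) reaches AUROC ≈ 0.75 while the best
spread-based summary (p90 − p10) stays near 0.56 — exactly the gap the
experiment is meant to expose. Model configurations for this cohort scale
(transformer d = 16, flatten pooling, focal loss; LSTM hidden 16; both at
batch 32) were chosen by validation AUROC on the training side, mirroring
the grid-search protocol; the test set never entered selection.

### Parameter-recovery design

The mixed-effects recovery experiment simulates a c_target = 0.3 mean shift
with patient intercepts of SD 0.2 at 2,000 patients and a **balanced**
class design (prevalence 0.5): recovery measures estimator correctness, and
a balanced design maximizes information per simulated patient. At 9%
prevalence the estimator remains unbiased but its sampling SD (~0.06)
exceeds a ±0.05 band — a power property of the design, not an estimator
defect.

## Problem sizes and numerical choices

The reference experiments use ~3,000 surgeries (slope cohort), 1,500
patients (missingness cohort), 2,000 patients (recovery), and 20 × 100
features (null FDR); these sizes keep the full battery in the minutes
range on a single CPU while leaving clear margins on every tested
contrast. Other conventions: percentiles interpolate linearly between
order statistics; Hjorth uses population variance and first differences;
ties in model selection break by AUROC then config hash; degenerate inputs
(constant series, zero-variance channels, single-class resamples,
unreachable recall targets) are handled explicitly as documented in the
relevant docstrings.

## Known limitations

* The generator's feature menu is small and uncorrelated across features;
  attention patterns on it should not be over-interpreted.
* The autodiff core implements exactly the operations the model zoo needs;
  it is not a general-purpose deep-learning framework (no GPU, no dropout
  scheduling, no mixed precision).
* Successive halving replaces full Hyperband bracket scheduling.
* The mixed-effects screen delegates numerics to statsmodels `MixedLM`;
  occasional non-convergence on degenerate features is flagged rather than
  repaired.
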