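# Methods

This note documents the model, the training and evaluation procedures, the
synthetic-cohort simulator, and the numerical/design choices that were
genuinely open, in the package's own terms.

## Problem formulation

For a woman screened at a *target* exam we want the probability that she
will be diagnosed with breast cancer within each horizon `j = 1..15` years,
using the target mammograms, up to five *prior* (reference) exams with their
time intervals, classical risk factors, and — for women with a cancer
history — prognostic factors of the prior tumor.

Time is discretized into fifteen one-year bins plus a cancer-free class.
A diagnosis at `t` years after the target exam falls in class
`ceil(t)` (half-open bins `(i-1, i]`, so an event at exactly `j` years
belongs to year `j`, matching "within `j` years" cumulative semantics);
events beyond 15 years and event-free observations are class 0.  A 16-way
softmax head then yields

    Risk_j = sum_{i=1..j} softmax(logits)_i ,

which is monotone in `j` and satisfies `Risk_15 = 1 - P(cancer-free)` by
construction: a 5-year risk can never exceed the 10-year risk, an
inconsistency that separately trained per-horizon models do not rule out.

Exams qualify as targets if the outcome at one year is known: every exam of
a diagnosed patient, and exams with at least one year of negative follow-up
otherwise.  On the diagnosed side the breast-level label is the event class;
the contralateral breast is labelled cancer-free with its observation
truncated at the diagnosis date, which avoids leaking the ipsilateral event
into the contralateral label.

## Architecture

Five stages, all widths configurable (full-scale defaults in parentheses,
desk-scale test values in brackets):

1. **Shared image encoder.**  Every mammogram (4 views x up to 6 time
   points) passes through one weight-shared convolutional backbone into a
   local feature (512) [64].  The backbone is a constructor parameter; the
   default is a small stride-2 CNN whose global pooling concatenates the
   spatial *mean* (overall density/texture) with the spatial *max* (small
   high-contrast structures such as masses), followed by a linear projection
   and LayerNorm.  Max pooling matters here: a growing lesion is a local
   bright structure that plain average pooling dilutes.
2. **Side-specific module.**  Ipsilateral CC and MLO features are
   concatenated with a fixed-width encoding of that side's prior-tumor
   record (128, so the MLP input is 512+512+128 = 1152) [32 -> 160]; a
   two-layer MLP (dropout between the layers) produces the unilateral
   feature (512) and feeds side-level task heads.  Absent tumor records are
   minus-one-filled placeholders.
3. **Exam module.**  The (right, left) unilateral features are concatenated
   (order fixed) and reduced by an identical MLP to a per-exam global
   feature (512) with exam-level task heads.
4. **Multi-time-point fusion.**  Tokens = 4 local + 1 global feature per
   time point, each additively conditioned on a continuous sinusoidal
   embedding of the interval-to-target in months (64 geometric frequencies,
   periods 2..480 months, linearly projected) [8], plus one risk-factor
   token.  Exam order is carried *only* by the time embedding, which makes
   permutation invariance of prior slots a testable property.  Missing slots
   are zero-filled and excluded from attention and from the masked mean
   pooling, so padding is exactly inert.  A pre-norm transformer encoder
   (2 layers, 8 heads) [1 layer, 2 heads] runs over the tokens; the fused
   feature is the pooled output concatenated with a linear risk-factor skip
   (512 + 128 = 640) [64 + 16 = 80].  The skip decomposition of the fused
   width is this package's choice; only the total width is externally fixed.
5. **Heads.**  A 16-class patient risk head on the fused feature; one
   *shared* 16-class breast head applied to (fused feature, unilateral
   feature of that side); 16-class risk heads at the side and exam levels
   (deep supervision); and auxiliary classification heads per level
   (history, future/prior tumor location and type, receptor status, pCR,
   pT/pN stage at the side level; additionally age, density, BI-RADS,
   manufacturer, laterality at the exam level; a reduced set at the fused
   level).  Auxiliary heads are used only for training-time supervision.

Two details matter for *from-scratch* training, where no pretrained encoder
is available to hand the fusion stage well-conditioned features:

* the fused trunk output is pooled over the **target exam's tokens** (prior
  information reaches them through attention) with a residual from the
  target's global feature, so the single-exam pathway is exactly as fast to
  learn as in the STP ablation; and
* an explicit **longitudinal contrast channel**: the difference between the
  target exam's clean encoder features and the mean of its priors' features
  (computed before dropout, attention or time conditioning), standardised
  per feature over the batch (BatchNorm with running statistics), linearly
  projected, and added to the pooled trunk.  Within one patient the static
  anatomy cancels in this difference, so a slowly growing structure — tiny
  in absolute feature units — becomes an O(1) direction.  The channel is
  identically zero when no prior exists, which keeps the STP reduction
  bit-exact.  This is the architectural expression of the method's goal of
  disentangling risk-relevant change from static breast tissue; dropout is
  deliberately kept off this channel, since multiplicative noise on a
  within-patient difference dwarfs the growth signal it carries.

A single-time-point (STP) ablation is the identical network with every
prior slot masked (`use_multitimepoint=False`); further flags disable the
risk-factor token/skip, the auxiliary tasks, and the side/exam levels,
reproducing the standard ablation grid.

## Losses and training

Risk terms use binary cross entropy on the *cumulative* curve: for each
horizon `j`, `Risk_j` against the indicator "event within `j` years", with a
censoring mask — horizon `j` contributes only when the indicator is
observable (the event occurred, or follow-up reaches `j` years); the
per-sample loss is the mean over observable horizons.  This keeps the
monotone 16-class parametrisation while accommodating right-censored women,
and is unbiased under independent censoring.  Censored horizons are masked,
never imputed.  Rows with no observable horizon (e.g. the contralateral
breast of a woman diagnosed within a year) contribute nothing.

Within each level the risk term is weighted five times each auxiliary
cross-entropy (auxiliary labels of -1 mark "not applicable" and are
excluded).  The fused-level risk term is the mean of the patient head and
the two breast heads.  The total is

    L_total = 0.2 * L_side + 0.2 * L_exam + 1.0 * L_fusion .

Optimisation: Adam (optional decoupled weight decay), dropout 0.5 after
fully connected layers, default schedule 20 epochs, batch 8, lr 1e-4 decayed
x0.1 every 5 epochs.  Model selection keeps the epoch with the highest mean
validation AUC over the 1..10-year horizons.  Training augmentation:
per-image random horizontal flip (anatomically neutral for the labels),
brightness/contrast jitter (default +-10%, not stated by the protocol and
chosen mild enough not to mask the lesion contrast), and random dropping of
prior slots (default p=0.3 per slot, also a package choice) which doubles as
robustness training for missing history.  Patient-level split disjointness
is enforced with a hard error.

Desk-scale training runs (the experiment suite and acceptance script) use
the same code with the tiny widths above, a higher learning rate
(3e-3; 1e-4 is appropriate for fine-tuning a pretrained full-scale backbone,
not for a from-scratch tiny CNN), few epochs, and no prior-slot dropping
(with at most five priors available every prior is informative, and the
comparison trains a dedicated STP arm anyway, so the robustness augmentation
only dilutes the longitudinal signal at this scale); problem sizes were
chosen so a full multi-seed comparison completes in minutes on one CPU
core.

## Evaluation protocol

All statistics consume per-exam records (score, event, time, age, BI-RADS,
history and biopsy flags) and are invariant to record order.

* **Horizon AUC (j years).**  Positives: diagnosis within `j` years.
  Negatives: at least `j` event-free years.  Censored-before-`j` exams are
  excluded; ties count 1/2; undefined AUCs are reported as absent, never
  imputed as 0.5.
* **Windowed AUC (a, b].**  Exams diagnosed within `a` years are dropped
  first, isolating longer-term risk from short-term detection.
* **Uno's C-index.**  IPCW concordance truncated at 10 years with
  Kaplan-Meier censoring weights; with degenerate censoring the unweighted
  Harrell concordance is returned and flagged.
* **Age-adjusted AUC.**  Placement-value covariate-adjusted ROC: control
  scores are regressed on age (linear location model), the empirical
  residual distribution defines the age-conditional control law, and the
  aAUC is the mean case placement probability.  With constant age this is
  exactly the plain AUC.  The estimator choice (location model + empirical
  residuals) is this package's; fewer than 10 controls are refused.
* **DeLong's test** for paired AUCs (midrank structural components,
  two-sided normal p); identical score vectors return p = 1.
* **Bootstrap** 95% percentile intervals, resampling at patient level,
  1000 replicates, seeded; intervals are refused if the statistic is
  undefined on more than 20% of resamples.
* **KM percentile strata.**  Percentile groups 0-10 / 10-50 / 50-90 /
  90-100 of the evaluated population's own 10-year scores (rank-based cuts;
  ties broken deterministically by (score, patient, exam)), per-group
  Kaplan-Meier cancer-free curves and cancer-share columns that sum to 100%.
* **Cohort filters.**  screening1 (BI-RADS 1-2 or benign biopsy within 90
  days), screening2 (BI-RADS 0-2), recurrence (prior cancer history),
  bcsc_eligible (no history, age 35-74).

Exam-level pooling is the default unit; a seeded patient-level mode (one
exam per patient) supports patient-based sensitivity analyses.

## The simulator: what it emulates, what it does not

`simulate_cohort` generates per-patient risk factors with realistic marginal
frequencies, a discrete annual hazard `h = logistic(b0 + beta.x + gamma*u)`
with latent frailty `u ~ N(0,1)`, geometric event years (giving an analytic
goodness-of-fit target), ~annual exams with jitter, independent exponential
censoring after the last exam, a recurrence subgroup with prior-tumor
records, elevated hazard and ipsilateral bias, and four-view 16-bit images:
half-ellipse breast, per-patient static texture scaled with density, static
bright blobs (benign look-alikes), and a Gaussian lesion on the future event
side whose amplitude and radius grow linearly within `T_g = 4` years of the
diagnosis.  Defaults (600 patients, 64x32 pixels, 1-6 exams, hazard scale
giving roughly a fifth of patients an observed event) are deliberately
enriched relative to population screening so that desk-scale cohorts carry
enough events for stable rank statistics.

Design intent of the image model: benign blob brightness overlaps
early-lesion brightness, so a single exam is ambiguous by construction,
while blobs are static and lesions grow — the temporal contrast is the
reliable signal.  This is exactly the structure a multi-time-point model can
exploit and a single-time-point model cannot, and it is what the
MTP-vs-STP experiment measures.

What the simulator does *not* emulate: radiographic realism (vendor noise,
anatomy beyond ellipse+texture), reader variability beyond a crude BI-RADS
assignment rule, non-independent censoring, screening-interval policy
effects, or covariate shift between sites.  Passing tests on the simulator
therefore demonstrates that the pipeline recovers planted statistical
structure end to end — not clinical performance.

## Numerical choices and degenerate inputs

* All network arithmetic is float64; masking/permutation invariances hold to
  well below the 1e-6 assertion tolerance.
* Cumulative risks are clamped into `[eps, 1-eps]` (`eps = 1e-7`) by a
  linear squeeze before the log, keeping the BCE finite without breaking
  monotonicity or differentiability.
* Constant images preprocess to all-zeros (guarded min-max); the Otsu
  segmentation threshold is capped at 5% of the dynamic range so it cannot
  split inside dense tissue, holes are filled, and only *above-threshold*
  pixels outside the breast component are erased — which makes the
  preprocessing idempotent on its own output.
* Right/left orientation: left-side views are mirrored during preprocessing
  so every breast faces the same direction before the shared encoder.
* Dates are handled at day resolution; intervals in months use
  days / 30.4375.
* Prior selection at inference takes the `k` most recent priors
  (deterministic); random selection is a training-time behaviour.
* Grad-CAM with an all-zero gradient returns an all-zero map; otherwise maps
  are max-normalised per image.
* Percentile cuts are computed on the evaluated population itself (no
  external reference population is assumed).

## Known limitations

* The default backbone is a small CNN trained from scratch; no pretrained
  encoder is bundled, so absolute desk-scale metrics are far below what a
  pretrained full-scale encoder would reach on real data.
* The tumor-record and risk-factor encodings are fixed-width one-hot/ordinal
  blocks, not learned embeddings of free-text pathology.
* The aAUC location model is linear in age with homoscedastic residuals.
* The DICOM adapter reads pixel data and basic geometry only; no
  de-identification or vendor calibration.
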