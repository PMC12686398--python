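# Methods

## The model

`mammoage` estimates the biological age of breast tissue from a four-view
screening examination (right/left craniocaudal and mediolateral-oblique
projections, R-CC, R-MLO, L-CC, L-MLO). The estimate, *breast age* ŷ, is
compared with chronological age *x*; the bias-corrected difference
Δ = ŷ_corrected − x (the *breast-age gap*) is treated as a biomarker of
breast health and evaluated with standard survival methodology.

### Network

Each view passes through one weight-shared convolutional backbone; the
pre-pooling feature map of each view is flattened into a token sequence
("local features"). An **instance-bag transformer** fuses the exam: per
view, multi-head self-attention over the view's own tokens and
cross-attention in which the key/value sequence is the concatenation of
all four views' tokens ("global features"). Head count h = 8, block
repeats N = 1. The local, self-attention and cross-attention outputs are
concatenated channel-wise and projected back to the local size by a
two-layer feed-forward network, so fusion is shape-preserving. The self-
and cross-attention paths share projection weights — they differ only in
the key/value source, which makes the fusion exactly permutation-
equivariant over views when the optional learned view-type embedding is
disabled (the default).

Each fused view branch is mean-pooled and mapped to a **probabilistic
ordinal embedding**: a diagonal Gaussian N(μ, σ²) in a 16-dimensional
latent space. During training a reparameterized sample z = μ + σ⊙ε feeds
a 100-way softmax over integer age bins 1–100; at inference z = μ, so the
evaluation path is deterministic. The predicted age of a view is the
distribution mean m = Σₖ k·pₖ, and the exam prediction is the unweighted
mean of the four view predictions. An auxiliary density head consumes the
pooled concatenation of the four fused view vectors and predicts the
4-level ACR-style composition category.

### Losses

For a view distribution p over bins 1..100 with true age y:

* cross-entropy: −log p_y (ε = 1e-12 floor inside every log);
* mean loss: ½(m − y)², variance loss: Σₖ pₖ(k − m)²;
* ordinal embedding composite: mean hinge(margin + d(μᵢ,μⱼ) − d(μᵢ,μₖ))
  over triplets with |ageᵢ−ageⱼ| < |ageᵢ−ageₖ| (Euclidean distance on μ,
  margin 0.1), plus the per-dimension KL(N(μ,σ²) ‖ N(0,1)) =
  ½(σ² + μ² − 1 − ln σ²);
* density cross-entropy, with `unknown` labels contributing zero and
  excluded from the denominator.

The total is a weighted sum; every weight defaults to 1 and is
configurable. Per-view terms are averaged (not summed) across views.

### Training schedule

Adam; learning rate decayed by ×0.1 every 20 epochs; early stopping when
the validation **loss** has not decreased for 10 consecutive epochs; the
returned checkpoint is the epoch with the best validation **MAE**. These
are deliberately two separate criteria. All randomness (split, init,
augmentation, POE sampling, triplet sampling) flows from one run seed.
Full-scale defaults are initial LR 1e-4, dropout 0.5, 100 epochs.

Two numerical choices stabilize small-scale training and are always on:
the log-variance head bias is initialized to −2 (σ² ≈ 0.14, a
near-deterministic embedding at the start — unit variance would drown the
age signal in sampling noise), and gradients are clipped at global norm 5.

### Desk-scale preset

`desk_profile()` sizes everything for one CPU: a 60-patient cohort at
64×32 pixels, the `tiny_cnn` backbone, ≤ 30 epochs, batch 4, LR 1e-2,
dropout 0.2, and loss weights CE 1 / mean 0.2 / variance 0.05 / ordinal 1
/ KL 0.01 — the canonical weighting of the mean-variance formulation.
With the default unit weights the variance term makes a point mass at the
cohort mean age a strong attractor at this data scale, and the optimizer
frequently converges to a constant predictor; the canonical weighting
removes that failure mode. A desk training run takes roughly 20–30 s.

### Backbones

The registry ids follow the familiar ImageNet family names but resolve to
compact CPU-scale renditions of each architectural family, all with total
stride 32 and 32 output channels: `tiny_cnn` (plain stride-2 stack),
`resnet18` (residual), `resnet50` (bottleneck residual), `convnext_tiny`
(depthwise + pointwise MLP), `densenet121` (dense concatenation stages),
`efficientnet_b0` (inverted bottleneck). On a 256×128 input every
backbone produces an 8×4 token grid. These are not the ImageNet-scale
originals and ship no pretrained weights.

## Bias correction

Age-prediction models overestimate young and underestimate old subjects
(regression dilution), inducing a negative correlation between the raw
gap ŷ − x and x. The correction fits Δ̂ = a·x + b by ordinary least
squares **on a designated healthy reference population** and applies

    ŷ_corrected = ŷ − (a·x + b),    Δ_corrected = ŷ_corrected − x

unchanged to every other group. `fit_bias_model` requires an explicit
`fit_population_tag` so the reference cannot be silently refit on case
groups. On the fitting population the corrected gap is exactly orthogonal
to age (OLS residual property). Note the guarantee OLS gives is on
*squared* error: the corrected predictions never have a larger mean
squared error than the raw ones on the fitting set; mean absolute error
almost always improves too but is not guaranteed term-by-term.

The correction needs an adequately sized reference: fit on n exams, the
slope error alone induces a residual gap-age correlation of order 1/√n on
new data. The shipped analyses therefore fit on a ~750-exam healthy
reference cohort and evaluate on a disjoint held-out cohort of the same
size; a 20-exam reference cannot support the claim |r| < 0.1.

## Occlusion saliency

Region importance is ΔMAE = MAE_occluded − MAE_original: each window of a
square grid is blacked out in one view of every exam and the MAE over the
exam set recomputed. Grids at four mask sizes (32/64/128/256 px at the
1536×768 scale; scaled proportionally, e.g. 8/16/32/64 at 256-px frames)
are reconstructed to image resolution by bicubic spline interpolation of
the cell-centre values (edge cells replicated to the border), averaged
across scales, floored at zero, and divided by the maximum so the map
lies in [0, 1]. Normalization happens after cross-scale integration.
Negative ΔMAE (occlusion helps) is retained at the grid level; a config
flag can clamp it. A constant model yields an identically zero map, which
is returned as zeros rather than dividing by zero.

## Gap-risk statistics

* **Group difference**: OLS ANCOVA `gap ~ group + age + density`; the
  cancer coefficient is the adjusted mean difference, two-sided p.
* **Risk groups**: gap > cohort median → high; ties go to low.
* **Kaplan–Meier / log-rank**: product-limit curves with 95% CIs per
  group; two-sided log-rank test; groups without events are flagged.
* **Cox models**: model 1 unadjusted, model 2 adjusted for age and
  density, model 3 for a configurable risk-factor set; each fit for the
  continuous gap (HR per year) and the high/low split. Proportionality is
  checked per covariate with scaled Schoenfeld residuals against
  identity-transformed time; violating covariates (p < 0.05) are handled
  by stratification, quartile-binned first when continuous. Density
  `unknown` is a fifth categorical level, never dropped.

These routines are thin contracts over `statsmodels` and `lifelines`;
their tests are parameter-recovery and null-calibration simulations, not
re-derivations of the estimators.

## The synthetic cohort generator

Real screening mammograms are restricted; the generator reproduces the
*structure* the method consumes, not mammographic appearance.

Per patient: a latent trajectory apparent_age(t) = chronological_age(t) +
offset with offset ~ N(0, 3 y); cancer-subgroup patients (fraction
configurable) additionally appear `acceleration_delta` = 5 y older.
Per exam the rendered age adds appearance jitter ~ N(0, 8 y) —
between-woman variability of density at fixed age, with no hazard
consequence of its own. Each of the four views is a breast-shaped phantom
(half-disc CC, oblique half-ellipse MLO with a pectoral wedge; left views
exact mirrors): the fibroglandular fraction of the foreground follows the
closed curve f(a) = clip(0.85 − 0.0075·(a−1), 0.02, 0.98) exactly up to
pixel rounding, the skin line thickens with age (1 + ⌊a/25⌋ px), and
calcification-like speckles accumulate (⌊a/10⌋). Density categories come
from fixed quartile thresholds (0.25/0.5/0.75) on the fraction scale, so
labels correlate with age as ACR categories do. Follow-up is exponential
per exam with hazard 0.05·exp(log HR·true_gap) per year (default log HR =
ln 1.02 per gap-year), administratively censored at 10 years. Identical
config + seed gives byte-identical manifests and pixels.

Why the cues are multi-scale and multi-feature: a single global pixel
statistic should not solve the task outright, so occlusion saliency has
something to localize.

Why the appearance jitter matters: with a deterministic age→image map a
converged model fits it almost perfectly and regression dilution — the
phenomenon bias correction exists for — does not reliably appear. The 8-y
jitter makes the population-optimal predictor shrink toward the mean
(slope ≈ 0.89), so the negative gap-age correlation is a property of the
data-generating process rather than an accident of under-training. Real
ACR density at fixed age spans whole categories, so this is conservative
realism.

What the phantom does **not** emulate — and hence what passing tests do
not show about real data: mammographic texture, lesions, vendor/scanner
intensity differences, positioning variability, and any cancer signal
other than accelerated apparent aging. One consequence worth knowing: the
generator assigns the ACR label from the accelerated appearance itself,
so in end-to-end runs part of the cancer group's gap difference is
mediated by density and absorbed by the ANCOVA density adjustment; the
statistical layer's recovery is therefore calibrated on designs where
covariates are independent of the group.

## Problem sizes used in the shipped analyses

Training cohort 60 patients (~90 exams) at 64×32 px, ≤ 30 epochs;
bias reference and held-out cohorts 500 patients (~750 exams) each;
group-difference recovery n = 500 + 500; hazard-ratio recovery n = 20,000
exams with ~35% events; coverage checks 100 replicate seeds. These sizes
were chosen so the whole pipeline runs end-to-end on one CPU in minutes
while every estimate's sampling error stays well inside the margins being
tested.

## Known limitations

* Backbones are compact renditions; no pretrained weights, no GPU path.
* The POE composite is one concrete reading (hinge triplets on μ + unit
  KL); the literature contains richer variants.
* The exam-level prediction is the unweighted mean of view predictions;
  the full-scale alternative of learned view weighting is not
  implemented.
* Bias correction is linear only; no age-binned or spline variants.
* Survival analysis assumes exponential event times in the generator and
  proportional hazards in the default analysis; competing risks are out
  of scope.
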