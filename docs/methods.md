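# Methods

## Model

The classifier is two linear stages over a shared latent space. An encoder
maps an image `x` to one spatial feature map `g_f(x) ∈ R^{C×H'×W'}` per
finding `f`; global average pooling gives `z̄_f ∈ R^C`. A finding head
`(w_f, b_f)` scores `ŷ_f = σ(w_f·z̄_f + b_f)`; a disease head
`(v_d, c_d)` scores `ŷ_d = σ(Σ_f v_{d,f}·z̄_f + c_d)` over the
concatenation of all pooled finding features. Everything interpretable in
the package rests only on this contract, not on any particular encoder.

### Counterfactual attribution

`z̄_f` splits into a component along `w_f` and an orthogonal remainder:
`z̄_f = (ŵ_f·z̄_f)·ŵ_f + z̄_⊥`, with `ŵ_f = w_f/‖w_f‖`. The
counterfactual latent replaces the parallel coefficient by
`(σ⁻¹(ε) − b_f)/‖w_f‖`, so the finding score becomes exactly ε while
`z̄_⊥` — appearance unrelated to the head's decision axis — is untouched.
With disease odds `𝒪 = exp(Σ_f v_{d,f}·z̄_f + c_d)` and counterfactual
odds `𝒞` (same expression with `z̄_f` replaced), the ratio has the closed
form

    R_I-CAR = exp((σ⁻¹(ŷ_f) − σ⁻¹(ε)) · κ(f,d)),
    κ(f,d)  = v_{d,f}·w_f / ‖w_f‖².

`R_CAR` substitutes `ŷ_f → 1−ε`, removing the instance: it is a property of
the weights alone, and by logit antisymmetry equals `exp(−2σ⁻¹(ε)·κ)`.

**Norm convention.** The textbook form of the decomposition writes the
parallel coefficient as `σ⁻¹(ŷ_f) − b_f`, which is exact only for unit-norm
`w_f`. We implement the general projection (`parallel = ŵ_f·z̄_f`,
coupling `κ = v·w/‖w‖²`), under which every identity — counterfactual score
= ε, closed form = 𝒪/𝒞, attribution-map mean — holds exactly for raw
trained heads. `ModelBundle.normalized()` rescales heads to unit norm
(bias preserved) for the textbook convention; note this rescales finding
logits, so normalized heads need recalibration if their probabilities are
to be read directly. Raw heads are the default.

### ε policy

ε ∈ (0, 1/100) is the "confidently absent" score. Default 0.005 (midpoint
of the permitted interval). Alternatively the 5th-percentile
(nearest-rank, deterministic) of finding predictions on benign validation
cases, clipped into (0, 1/100) with a warning if outside. The same ε is
used for the suppression arm of I-CAR and both arms of CAR. Predictions
are clamped to [1e-12, 1−1e-12] before logits; clamping is logged.

### Attribution maps and interaction

`A(f,d;x) = (v_{d,f}·ŵ_f)·(w_f^T g_f(x))` is a class activation map scaled
by the finding–disease coupling; its spatial mean equals
`(v·ŵ)(σ⁻¹(ŷ_f) − b_f)` for any weight norm, since pooling commutes with
the linear head. For display the map is bilinearly upsampled and
normalized to [−1, 1] by its maximum absolute value; raw values are kept in
all data outputs. Findings are surfaced when their I-CAR exceeds the
natural constant *e*, top 3 by default. We apply the threshold to
instance-level I-CAR (not the instance-free CAR), since the display
accompanies a specific image. Overriding a finding score to p moves the
parallel coefficient to `(σ⁻¹(p) − b_f)/‖w_f‖` and re-evaluates the linear
disease heads — exactly equal to full recomputation, with no encoder pass.

## Encoder

A deliberately small fixed-filter CNN: shared 3×3-conv/ReLU/2×2-avg-pool
stages feeding one branch per finding (default one shared and one branch
stage, C = 8 channels, 64×64 inputs). Filters are seeded Gaussian except
that the first `min(C_in, C_out)` channels of each bank are identity
(delta) kernels, so low-level intensity structure survives pooling while
the remaining channels mix texture. Only the linear heads are trained.
This keeps the whole pipeline CPU-friendly while honoring the
`(g_f, w_f, b_f, v_d, c_d)` contract exactly; nothing in the CAR math
depends on encoder capacity. A freeze flag is moot here since filters are
fixed by construction; the branch-point question is instead covered by the
cosine-distance analysis (below).

## Head training

Heads are logistic regressions minimizing mean binary cross-entropy +
`l2·‖params‖²` (default l2 = 5e-4, the conventional weak ridge for linear
probes). Targets may be soft — EM posteriors are used directly as the
Bernoulli target distribution. Optimization is deterministic full-batch
gradient descent with Armijo backtracking line search: the recorded loss
history is provably non-increasing, convergence is declared at relative
loss change < 1e-9 or 5000 iterations. No randomness, so fits are
bit-reproducible. A balanced sampler (each batch slot picks the positive
class with probability 1/2, then uniformly within class) is provided for
mini-batch training on rare findings.

## Label fusion

Readers annotate independently, so conditional on the true label their
marks are independent Bernoullis with per-reader sensitivity/specificity —
a two-class Dawid–Skene model. The Naïve Bayes posterior over the marks is
the training target; profiles and prevalence are estimated by EM
(E-step: posteriors; M-step: posterior-weighted empirical rates),
initialized from majority-vote pseudo-labels. The initialization is
deterministic and anchors the labeling; if EM still lands in the mirrored
solution (mean sensitivity + specificity < 1), the latent class is flipped
and re-estimated, with a warning. Parameters are clipped to
[1e-6, 1−1e-6]; convergence at max parameter change < 1e-8 or 1000
iterations; the observed-data log-likelihood is asserted non-decreasing in
tests. EM runs per label (labels treated as independent), per reader id
across all images that reader read. Panels with any reader count are
supported; the conservative reference standard (majority positive /
unanimous negative / lone positive excluded) applies to evaluation splits
only, never to training targets.

Ordinal severity calls (e.g. non-referable DR < referable DR) are expanded
so a reader marking severity s is positive for every label at severity
≤ s — calls (DR, referable DR, none) give marks (1,1,0) for DR and (0,1,0)
for referable DR.

## Expert odds ratios

All (reader, image) readings are pooled into one 2×2 matrix per
finding–disease pair, laid out presence-first: the top-left cell counts
readings with finding = 1 and disease = 1. OR = N₁₁N₀₀/(N₁₀N₀₁) in
presence notation. The Haldane–Anscombe correction (+0.5 per cell) is the
default for grids so zero cells stay finite; uncorrected OR returns
infinity with a warning. Grid agreement between log-OR and log-CAR is
summarized per disease by Spearman rank correlation over findings — a
scalar stand-in for the visual heatmap comparison.

## Evaluation

AUROC is the Mann–Whitney statistic (ties ½), with a DeLong asymptotic CI
available; exact Clopper–Pearson (Beta-quantile) intervals are provided
for proportions such as sensitivity and specificity, which is where an
exact binomial interval is well-posed. Operating points: either maximize
the harmonic mean of sensitivity and specificity over thresholds at score
midpoints (ties broken toward higher specificity, the screening
convention), or take the largest threshold achieving a target sensitivity
(used when positives are scarce); an unreachable target falls back to the
minimum threshold with a warning. The branch-point analysis computes, per
encoder depth, the mean cosine distance between per-finding pooled feature
sets over all finding pairs, and suggests branching at the first layer
whose mean distance exceeds its predecessor's by a configurable margin
(default 0) — shallow layers share structure, deeper layers specialize.

## Synthetic data

The generator defines the study conditions: 2000 images of 64×64 pixels, 3
findings with prevalences 0.35/0.30/0.25 and distinct blob signatures (count,
radius, intensity, color channel), 2 diseases from a logistic link with
coefficients of magnitude 3 — including one zero and one negative coupling
so sign recovery is non-trivial — and 3 readers with sensitivities
(0.9, 0.8, 0.7) and specificities (0.95, 0.9, 0.85). Feature cohorts place
`z̄_f = presence·μ·u_f + noise` with μ = 3, isotropic Gaussian noise 0.3,
and fixed unit directions u_f. Pixel noise is Gaussian, σ = 0.02. All
generators are pure functions of (spec, seed); the random stream is
consumed in fixed-length blocks so that, e.g., zeroing a lesion's intensity
leaves images without that lesion bit-identical.

What the generator does *not* emulate: camera variation, illumination
gradients, anatomical structure (vessels, optic disc, fovea), reader
correlation, or label noise structure beyond conditional independence.
Passing tests therefore certify the algebra, the estimators, and the
pipeline plumbing — not clinical performance on real fundus photographs.

## Problem sizes

Tests and the acceptance script run the image pipeline at 2000 images
(1500 train / 500 held out), EM recovery at 5000 images, and identity
checks at 1000 random models (F = 15, C = 8) — sizes at which every
statistical check has comfortable margin while the whole suite stays in
the tens of seconds on one CPU.

## Known limitations

- CAR reads the *model's* couplings; on entangled features (the image
  branches share low-level channels) weak couplings can appear for pairs
  with zero generative effect. The feature-cohort route, where branches
  are independent by construction, shows the clean ordering.
- The EM anchor assumes readers are collectively better than chance.
- Clopper–Pearson is not applied to AUROC (an average of indicator pairs,
  not a binomial count); DeLong is the provided AUROC interval.
- The encoder is intentionally small; it is a vehicle for the head/CAR
  contract, not a competitive image classifier.
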