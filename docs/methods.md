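# Methods

This note documents the models, numerics, and design choices behind the
package, in the order a reader meets them: component CAM methods, the
consensus ensemble, ROAD evaluation, the experiment grid with its CRE
summary, the model adapter, and the synthetic fixtures the tests run on.

## Component CAM methods

All methods operate on activations `A_k` (K channels, layer resolution)
and, where applicable, gradients `G_k = ∂y_c/∂A_k` of the target-class
logit, captured at a named layer (default: the model's last convolutional
layer).  Gradients are taken with respect to the *logit*, not the softmax
probability — the standard convention, and numerically better behaved near
saturated probabilities.  Each method produces a raw map that is passed
through ReLU where the method prescribes it, bilinearly upsampled to image
resolution, and min-max normalized to [0, 1].

* **gradcam** — `α_k = mean_ij(G_k)`.
* **gradcampp** — `α_k = Σ_ij a_k^ij · ReLU(G_k^ij)` with
  `a_k^ij = G²/(2G² + Σ_ij A_k G³)`, the usual second/third-order-term
  formulation with the exponential-score gradient identity folded in and an
  ε-guard on the denominator.
* **xgradcam** — `α_k = Σ_ij(G_k ⊙ A_k) / (Σ_ij A_k + ε)`.
* **hirescam** — `ReLU(Σ_k G_k ⊙ A_k)` (sum before ReLU).
* **gradcam_elementwise** — `Σ_k ReLU(G_k ⊙ A_k)` (ReLU before sum).
* **layercam** — `ReLU(Σ_k ReLU(G_k) ⊙ A_k)` (positive gradients only).
* **scorecam** — channel weight = target logit on the input masked by the
  channel's normalized, upsampled activation; weights softmaxed over
  channels (config switch `score_softmax=False` for raw scores).
* **ablationcam** — channel weight = `(y_c − y_c^ablated)/y_c` with the
  channel zeroed at the layer (ε-guard when `y_c ≈ 0`).
* **eigencam / eigengradcam** — the K×(h·w) matrix of activations (or of
  `G ⊙ A`) is projected onto its first right singular vector (`σ₁·v₁`),
  reshaped to h×w.  The SVD sign is fixed so the entry of maximum magnitude
  is positive; without this the map can arbitrarily flip.  Only the first
  component is used; component rank selection is exposed nowhere because
  choosing it per image would itself be a form of leakage.
* **fullgrad** — `|∂y_c/∂x ⊙ x|` plus, per convolutional layer and
  channel, `|b_k · ∂y_c/∂z_k|` (gradient with respect to the
  pre-activation, times the bias), each term upsampled and min-max
  normalized before summation, then normalized again.  The final linear
  bias is spatially constant and is omitted.  Models that cannot expose
  bias gradients yield an invalid result, not an exception.
* **randomcam** — i.i.d. uniform[−1, 1] noise, normalized; a seeded control.

Every output is either a normalized image-resolution map or flagged
invalid (all-zero / constant, non-finite, or unsupported model) with a
reason — there is no third state.  ε = 1e-7 in all guarded denominators.

## Consensus ensemble and adaptive thresholding

Component maps are combined in one of three modes:

* **mean** — pixelwise average, renormalized.
* **weighted** — `Σ w_n L_n / Σ w_n` with nonnegative weights, typically
  per-map ROAD scores passed through a transform: `minmax` (affine to
  [0, 1]; equal scores degenerate to uniform weights), `softmax_amplified`
  (softmax of `s·v` with `s` the smallest power of 10 making
  `max|s·v| ≥ 10` — near-tied small scores are spread before the softmax),
  or `exponential` (`exp(v)/Σexp(v)`, i.e. a plain softmax of the raw
  values; implemented as such since exp-then-normalize *is* softmax).
  Weighting by scores computed on the same (image, class, model) is
  evaluation-driven; it is honest about that and mainly a comparison
  baseline for the consensus mode.
* **consensus** — pixelwise **sum**, then top-k% thresholding: pixels at
  or above the (100−k)-th percentile of the summed map survive verbatim,
  the rest are zeroed, and (by default) the result is renormalized to
  [0, 1] so downstream consumers never see the n-dependent sum scale.

Percentiles are linear-interpolation percentiles of the flattened pixel
values, so every rank-based operation is invariant to pixel traversal
order.  Ties at the threshold are all kept: deterministic and
order-independent, at the cost that the surviving set can exceed k% when
value ties are massive (see the ROAD caveat below).  Coordinates are
row-major, 0-based, `(row, col)` everywhere.

Invalid component maps are dropped before any combination; an ensemble
with no valid survivors is an error carrying the per-method reasons.

The adaptive threshold search evaluates the consensus (or a single map —
the same refinement the comparison baselines use) at every k in a grid,
scores each candidate with ROAD, and returns the argmax with the full
score table.  Ties break toward the smallest k: at equal faithfulness the
more selective map is preferred, and the rule is deterministic.  The
default grid is 5–95 in steps of 5 — wide enough to bracket the typically
useful 15–45 band while still catching very selective optima near k = 10;
narrow it via config when runtime matters.

## ROAD evaluation

A saliency map is scored by perturbing the most relevant pixels (MRP — the
map's highest values) and, separately, the least relevant pixels (LRP) and
measuring the model's softmax confidence for the target class on each
perturbed image:

    combined = mean over p of ( C_LRP(p) − C_MRP(p) ) / 2,  p ∈ {20, 40, 60, 80}

The mean over percentiles (rather than a sum) keeps the score in
[−0.5, 0.5] regardless of how many percentiles are configured; for a fixed
percentile set the two differ only by a constant factor and rank methods
identically.  Confidence is the softmax probability, not the logit:
bounded, hence scale-stable across models.

Masked pixels are replaced by *noisy linear imputation*: per channel, each
masked pixel is constrained to equal the weighted average of its
8-neighborhood (edge-adjacent 1/6, corner-adjacent 1/12 — so interior
weights sum to 1 — renormalized at image borders), with unmasked neighbors
entering as boundary data.  The sparse system is solved with an LU
factorization (`scipy.sparse.linalg.splu`), one solve per channel;
unmasked pixels are returned bit-identical.  Zero-mean Gaussian noise of
scale `noise_std` (default 0.01 on unit-scaled inputs) is added to imputed
pixels after solving, from a seeded generator; `noise_std=0` makes scoring
exactly deterministic and repeat calls bit-identical.  A fully masked
image has no boundary data anywhere — the system is then anchored at the
per-channel image mean.  For any connected unmasked set the system is
strictly diagonally dominant at pixels adjacent to boundary data and
irreducible, hence nonsingular.

Caveat on sparse maps: with the keep-ties rule, selecting the "least
relevant p%" of a heavily thresholded map (mostly exact zeros) selects
*all* zero pixels, which can be far more than p%.  That is the documented,
deterministic reading of the tie rule; it is harmless in practice because
perturbing pixels the map assigns zero relevance is precisely what LRP
perturbation is meant to survive.

## Experiment grid and CRE

Methods are partitioned into disjoint labelled groups; the shipped default
mirrors the methodological families:

    A: hirescam, gradcam_elementwise     B: gradcam, gradcampp
    C: xgradcam                          D: ablationcam, scorecam
    E: layercam                          F: fullgrad

The eigen methods are outside the default grid — they are the most
expensive per map on large models and are better studied by adding them
explicitly via custom groups.  All 2^n inclusion codes are enumerated in
binary counting order (leading bit = first group); n = 6 gives 64
experiments, each group included in exactly 32.  The all-zero code is
enumerated for count fidelity but is unscorable — an empty consensus is
undefined — and is excluded from the median.  Each scorable code runs
drop-invalid → consensus → adaptive search, with component maps computed
once and shared across codes; individual failures are recorded as
unscorable and never abort the grid.

CRE: with `r_i = road_i − median(road over scored experiments)`,
`CRE_g = Σ r_i` over experiments whose code includes group g.  The median
of an even count is the mean of the two middle values.  CRE is invariant
to adding a constant to all scores and equivariant under relabelling;
because it is residual-based, reports from different grids (images,
classes, models) aggregate by group-wise summation.

## Model adapter and the numpy CNN

CAMs and ROAD reach the classifier only through the `ModelAdapter`
protocol: `class_count`, `layer_names`, `input_shape`, `logits(image)`,
and `capture(image, layer, class) → ActivationBundle` (post-ReLU
activations of the named block plus gradients of the class logit with
respect to them — the usual "hook the layer output" convention).
AblationCAM and FullGrad need the extended surface
(`logits_with_ablation`, `full_gradients`); models lacking it degrade to
invalid results for those methods only.  Capture runs in evaluation mode
by contract: no dropout, no batch-statistics updates, deterministic.

`TinyConvNet` implements the protocol in pure numpy: three 3×3
convolutions (im2col) with ReLU, two 2× average pools, global average
pooling, and a linear head — about 3.6k parameters for the grayscale
4-class fixture.  The backward pass is hand-derived and is validated
against central finite differences (relative tolerance 1e-3 on an 8×8
toy).  The GAP head is deliberate: it makes channels class-selective, so
gradient-averaged weightings behave the way they do on large
classifiers — which constrains the fixture task to be channel-codable
(below).  When the caller names no class, the model's argmax on the
unperturbed image is explained.

## Synthetic fixtures

`gen_scene` plants one soft-edged disk glyph on a low-contrast smoothed-
noise background (intensity ≈ 0.25 ± 0.07).  The class label is the
glyph's interior texture — diagonal stripes, horizontal stripes, vertical
stripes, or a dot lattice, all period-4 patterns oscillating between dark
troughs and bright crests.  Three properties of this design carry the test
suite:

* the class signal is *local texture*, so a GAP-headed CNN learns
  texture-selective channels and gradient CAMs localize classically (a
  position-coded task would be unlearnable through spatial pooling);
* every class is positive evidence — a smooth patch supports none of
  them — so imputing the glyph away genuinely removes the class, which is
  what lets ROAD discriminate faithful from unfaithful maps (a "solid"
  class would be indistinguishable from imputed in-fill);
* the glyph support is recorded exactly, giving a ground-truth saliency
  mask by construction.

The low background contrast is a premise, not a convenience: if background
texture carried class evidence, the glyph support would not be the ground
truth.  With `with_decoy` a second glyph of a different class is planted
with 2 px clearance (masks provably disjoint) — the two-subject situation
in which a non-discriminative method highlights the wrong subject.

`gen_cam_stack` fabricates component maps as
`normalize(fidelity · blur(mask) + noise_level · noise)` with σ = 2
Gaussian blur of the target mask and a lightly smoothed (σ = 0.5) unit
noise field, independent per spec.  σ = 0.5 keeps fidelity-0 maps
empirically uncorrelated with the truth mask (max |Pearson r| = 0.064 over
100 seeds at 64×64) while retaining mild spatial coherence.
`targets_decoy` builds the "incorrect-subject" map from the decoy mask.

`train_tiny_model` trains on 400 decoy-free scenes (Adam, lr 3e-3, batch
8, ≤ 20 epochs with early stop at 98% held-out accuracy; 25% held out)
plus 100 glyph-free backgrounds carrying uniform soft targets.  The soft
targets calibrate the model to be *uncertain* on featureless input — a
four-class stand-in is otherwise free to dump all probability on one class
when the subject is removed, which would blind perturbation metrics;
thousand-class models get this behavior for free.  Held-out accuracy is
measured on glyph scenes only, reaches 0.98–1.00 across seeds, and
training takes 10–20 s on one CPU.  Everything is a pure function of its
seed.

What the fixtures do *not* emulate: natural-image statistics (textures
beyond the localized subject, occlusion, scale variation), deep-network
pathologies (gradient saturation across dozens of layers, batch-norm
interactions), and the 1000-class output geometry of large pre-trained
models.  Passing tests demonstrate the algorithms' correctness and the
consensus mechanism's behavior under controlled corruption — not
performance numbers on any natural-image benchmark, which require real
pre-trained weights and are out of scope here.

## Problem sizes and runtime choices

The default study conditions are 64×64 grayscale scenes, a 16-channel
final layer, ROAD percentiles {20, 40, 60, 80}, and a 4-point k-grid
{10, 20, 30, 40} for grid-scale runs (the full 5–95 default remains for
single searches).  One ROAD score is 8 sparse solves plus 8 forward
passes (~0.1 s); the full 64-experiment grid with adaptive search runs in
about half a minute.  These sizes were chosen so the complete pipeline —
training included — executes in about a minute on a single CPU while every
statistical property the suite asserts holds with margin.

## Known limitations

* The consensus dilutes fine-grained detail when components disagree
  sharply; it is a robustness device, not a super-resolution one.
* ROAD-derived ensemble weights (weighted mode) are computed on the same
  instance they are applied to; treat them as a diagnostic baseline.
* The grid is sequential; at 2^n experiments it is meant for small n
  (the practical bound is n ≤ 16, the default is 6).
* The tie-keeping percentile rule can select far more than p% of pixels on
  maps with massive value ties (exactly-zero regions of thresholded maps);
  see the ROAD caveat above.
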