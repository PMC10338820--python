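# Methods

## Problem and model

Cone-beam CT (CBCT) slices acquired during image-guided radiotherapy are
contaminated by scatter-driven grayscale nonuniformity — cupping (a radial
intensity depression), directional shading, and streaks — that planning CT
slices of the same region do not show. Because CBCT and CT are acquired at
different times with different geometry, pixel-aligned image pairs are not
available, so the correction must be learned from *unpaired* sets.

The toolkit trains a convolutional generator `G` that maps a degraded CBCT
slice `s` toward the CT domain. The objective is built entirely from the
contextual (CX) similarity between deep feature sets, which tolerates spatial
misalignment because it matches feature *sets*, not feature *positions*:

1. An extractor `phi` (VGG19 convolutional topology) turns an image into a set
   of feature vectors, one per spatial location of a chosen layer `l`.
2. For sets `S = {s_i}`, `T = {t_j}` with `|S| = |T| = N` (the larger set is
   uniformly subsampled first), centered cosine distances are
   `d_ij = 1 − ⟨s_i − η_t, t_j − η_t⟩ / (‖s_i − η_t‖ ‖t_j − η_t‖)` with
   `η_t = mean(T)` centering *both* sets — we follow the printed formula
   rather than centering `S` by its own mean.
3. `d̃_ij = d_ij / (min_k d_ik + ε)`, `w_ij = exp((1 − d̃_ij)/h)`,
   `CX_ij = w_ij / Σ_k w_ik` (rows sum to one; invariant to per-row positive
   rescaling), and `CX(S,T) = mean_j max_i CX_ij ∈ (0, 1]`, which equals 1
   when `T = S`.
4. The loss is `L_CX(s,t,l) = −log CX(φ_l(s), φ_l(t))`, and the training
   objective is `L(G) = λ · L_CX(G(s), t, l_style) + L_CX(G(s), s, l_content)`:
   the style term pulls `G(s)` toward the CT domain's feature statistics, the
   content term anchors it to the input's anatomy.

Defaults `h = 0.5`, `ε = 1e−5`, `λ = 5` are the protocol constants; multiple
style or content layers are averaged with equal weight (the aggregation rule
is our choice; nothing in the protocol fixes it).

### Index conventions and degenerate inputs

`CX_ij` normalizes over the second index (row-wise over `k` for fixed `i`);
the image similarity maximizes over the first index `i` per column `j`. The
chain is therefore asymmetric in `(S, T)`; tests pin this orientation. A
centered feature vector with exactly zero norm (only constant images produce
one) is rejected with an error naming the offending index rather than being
silently jittered. Negative cosine-distance round-off is clamped to zero. The
pipeline computes the `w`-row softmax with a per-row exponent shift, so no
bandwidth choice can overflow; in the standalone `w` operation, entries for
extremely dissimilar pairs may underflow to `0.0` in float64, which the row
normalization tolerates because each row keeps its O(1) entry.

When both feature sets must be subsampled and have equal original size, one
shared index draw is used, so comparing an image with itself remains an exact
identity comparison after sampling.

## Generator (FFRN)

The generator is a feature-fusion residual network: a front convolution +
ReLU produces `F_0,LF` (base width `C`); block `f` applies two 3×3
convolutions with ReLU after each (`F_f,2`), then a 1×1 local-feature-fusion
convolution over the concatenation `[F_0,LF, F_1,2, …, F_f,2]` — so block `f`
fuses `(f+1)·C` channels — and the fused map skips to the next block. A final
reconstruction convolution maps to one channel and a global residual adds the
input. The reconstruction convolution initializes to zero, so training starts
exactly at the identity map; all other convolutions use seeded He
initialization. `convs_per_block` is exposed (default 2, with the fusion
convolution as the third layer of each block) for the reading that places
fusion "behind three convolution layers". Defaults: 4 blocks of 32 channels;
the tiny profile uses 2 blocks of 8 channels.

Because no deep-learning framework is a dependency, the generator, extractor
and losses run on a purpose-built reverse-mode autodiff module
(`cbctcx.autodiff`) over numpy arrays; every operator's gradient is verified
against central finite differences in the test suite.

## Feature extractor

The extractor is the 16-convolution VGG19 topology (no fully connected
head). Grayscale inputs are replicated to three identical channels and
standardized with fixed constants (mean 0.449, std 0.226). Weights come
either from a local `.npz` file (pretrained use) or from seeded He
initialization — the random-weight mode is what all bundled experiments and
tests use, so nothing is downloaded; the CX mathematics is agnostic to the
weight values. `width_scale` shrinks channel widths proportionally (the tiny
profile uses 0.25) without changing the topology. Layer defaults for
full-resolution work are content `conv4_2`, style `{conv3_2, conv4_2}`; at
64×64 those layers' receptive fields span most of the slice, so the tiny
profile moves to style `{conv1_2, conv2_2}` and content `{conv2_2}`, whose
receptive fields match the scale of the grayscale nonuniformity there.

## Synthetic phantom and degradation

The phantom emulates an axial thorax slice as piecewise-constant tissue
classes on a 9-bit gray scale (512 levels): background air 0, lung ≈ 55,
skin ≈ 215, soft tissue ≈ 250, bone ≈ 308, with per-slice uniform intensity
jitter (±8 levels) and geometric jitter (±0.03 of the image extent) providing
anatomical variation. The HU map `HU = 4·I − 1000` puts air at −1000 HU, soft
tissue at 0 HU and bone near +230 HU, so ROI statistics land on a clinically
plausible scale. Optional nodules carry spiculation rays and vacuole holes,
the lesion morphologies a correction method must not erase.

Degradation is phenomenological: a multiplicative cup field
`1 − a·(1 − r^p)` (darkest at center, `a = 0.18`, `p = 2`), a directional
linear shading field (amplitude 0.10), additive streak rays with Gaussian
cross-profile (12 streaks, ±35 levels, σ = 1 px), and Gaussian noise
(σ = 6 levels), all clamped back into range. These magnitudes were fixed once
so the degraded-slice PSNR sits in the mid-20s dB, the fidelity scale real
degraded slices show. Unpairedness is manufactured: the two training domains
draw disjoint anatomy seeds and the CT-domain slices get a smooth elastic
warp (1.5 px RMS), so no aligned pair exists; the held-out test split keeps
its pairing for evaluation only.

What the phantom does **not** emulate: real scatter physics (no Monte-Carlo
transport, no beam hardening), anatomical texture inside tissue classes,
motion artifacts, and 3-D cone-beam geometry. Passing tests therefore
demonstrate that the optimization machinery behaves as designed under
controlled degradations — not clinical performance on patient data.

## Training protocol

Adam (β₁ = 0.9, β₂ = 0.999), learning rate 1e−4, 100 epochs, 3×3 kernels,
batch size 1 — the reference protocol — with the extractor frozen and
gradients flowing only through the generator. Each epoch pairs every
CBCT-domain slice once, in shuffled order, with a uniformly drawn CT-domain
slice. A `scheduler_step` interval is exposed for stepwise LR decay but
defaults to off, since the mechanism behind the protocol's "step size = 2" is
not defined. Target and content features are cached once per run. All
randomness derives from a single master seed; two runs with the same seed
produce bit-identical datasets, parameters, logs and reports.

The tiny profile — 64×64 phantoms, 8 + 8 unpaired training slices, 4 paired
test slices, 2 RSDBs of 8 channels, quarter-width extractor, 512-feature
sampling cap, 25 epochs (200 optimizer steps) at learning rate 1e−3 — is the
package's own scaled-down study condition: the reference rate of 1e−4 over
~240 k steps does not transfer to a 200-step run, so the tiny profile uses
the larger rate, chosen as the scaled-down analogue. On this profile the
combined loss falls across epochs and the corrected-vs-truth PSNR exceeds
the input-vs-truth PSNR on held-out pairs, the directional claim the
full-scale protocol makes; absolute dB gains at this scale are small
(a few tenths) and seed-dependent.

## Evaluation

PSNR uses the quantization peak `2^n − 1` (511 for 9-bit data, i.e. 512 gray
levels) — never 512: `PSNR = 10·log10((2^n−1)²/MSE)`. MSE and MAE are plain
pixel means in native intensity units (MAE is reported in gray levels, and
labelled so, since its unit convention is otherwise ambiguous). SSIM is the
standard Gaussian-window form (11-pixel window, σ = 1.5, stabilizers
`(0.01·R)²`, `(0.03·R)²` on dynamic range R), delegated to scikit-image and
cross-checked in tests against a from-the-formula implementation. ROI mean CT
numbers are mask means in HU; phantom ROI masks (vertebra, skin rim, lungs)
are regenerated from the anatomy seed, so they align with each test slice.
`evaluate_pairs` always reports the input-vs-truth column next to the
corrected-vs-truth column, because the degraded input is the baseline any
correction must beat.

## Numerical and design choices

- Raw dialect: headerless unsigned 16-bit little-endian, row-major, with a
  JSON sidecar for geometry/quantization/HU metadata; single-byte samples
  available for depths ≤ 8 bits. Lossless 16-bit PNG/TIFF supported; lossy
  formats rejected.
- Quantization: round-half-up, clamped to `[0, 2^n − 1]`.
- `learning_rate = 0` is accepted and is an exact parameter no-op, so the
  optimizer's null contract is testable.
- Checkpoints are `.npz` archives holding the config and all parameter
  arrays; save → load → forward is bit-identical.
- Problem sizes in the bundled tests (64×64 slices, ≤ 16×16 oracle fixtures,
  200-step training runs) are the package's desk-scale defaults; every piece
  scales to 512×512 through configuration alone.

## Known limitations

- The random-weight extractor makes the bundled experiments self-contained
  but weaker than pretrained perceptual features; with a pretrained VGG19
  weight file the same code path applies.
- Training is single-image (or small-batch) full-precision CPU numpy; it is
  deterministic but slow beyond desk scale.
- The phantom's piecewise-constant tissue model makes ROI ground truth exact
  but understates real anatomical texture, flattering SSIM for any method
  that smooths.
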