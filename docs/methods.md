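# Methods

This note documents the models, the privacy mathematics, the synthetic
data, and the numerical choices behind `dpvesselsynth`.  It is written for
a reader who wants to know exactly what the package computes and what its
tests do and do not demonstrate.

## Problem setting

Labeled angiography data (TOF-MRA volumes with voxel-level vessel masks)
cannot generally be shared because brain anatomy is identifying.  One
remedy is to train a generative model that jointly emits image patches
*and* their segmentation labels under a differential-privacy guarantee,
then share the synthetic pairs.  The package implements that pipeline
end-to-end: a Wasserstein GAN whose critic is trained with differentially
private gradients, a Rényi-differential-privacy accountant for the
resulting guarantee, and a utility readout that trains a U-Net on the
synthetic pairs and evaluates it on held-out volumes.

Because real clinical volumes are not distributable, the package ships a
phantom generator whose output has the single statistic the GAN must
learn — bright curvilinear tubes on a darker noisy background — and the
whole pipeline is exercised on those phantoms.

## Phantoms (`phantoms`)

A phantom volume is built from `n_vessels` random-walk centerlines: unit
steps with direction jitter (SD 0.25 per step, renormalised), reflecting
at the volume faces, with a per-point radius following a clipped random
walk in [1, 4] voxels.  Walks start in the central 60% of the volume —
vessels of interest sit in the organ's interior, and in-plane patch
extraction needs vessel centers at least half a patch away from the
faces, so interior starts guarantee a supply of vessel-centered
candidate positions on every generated subject.  The vessel mask is the exact union of balls around
the centerline samples; this makes the mask reproducible by a brute-force
voxel scan, which the tests exploit.  Intensities: background
0.15 ± 0.02 (smoothed Gaussian texture), vessels ≥ 0.7 with a Gaussian
radial brightness profile, additive Gaussian noise (SD = `noise_level`,
default 0.05), then per-volume min-max normalisation to [0, 1].  No MRI
physics (no TR/TE, coil, or anatomy modelling) is attempted: the phantom
reproduces low-order intensity statistics of angiography patches, nothing
more.  Consequences for interpretation: results on phantoms demonstrate
that the pipeline machinery works and that privacy-utility trends have the
expected sign; they say nothing quantitative about real TOF-MRA data.

Patch extraction mirrors the imbalance-aware scheme used for vessel
segmentation: from each subject, a quota of *vessel-centered* patches
(uniformly sampled positions whose central pixel lies on a vessel, the
full-scale protocol uses 500 per subject) plus a quota of uniformly
*random* patches (500 at full scale), each P×P (96 at full scale), with
duplicate positions rejected on the exact (subject, slice, row, column)
tuple.  Random patches may coincide with vessel-centered *positions*
statistically but never duplicate an already selected origin.  Coordinates
are 0-based; a patch covers the half-open window [r, r+P) × [c, c+P) and
its center pixel is (r + P//2, c + P//2).

## Differential privacy (`privacy`)

The sensitive operation is the critic's gradient update on real data.
Each update is a DP-SGD step: every per-sample gradient is rescaled to L2
norm at most C (`clip_norm`, 1.0 throughout), the clipped gradients are
summed, isotropic Gaussian noise of scale σ·C is added per coordinate
(σ = the *noise multiplier*), and the sum is divided by the batch size.

Accounting uses Rényi differential privacy.  For the sensitivity-1
Gaussian mechanism the order-α Rényi divergence is α/(2σ²) in closed
form.  With uniform-with-replacement batch sampling at rate
q = batch/N, the package uses the tight integer-order bound of the
subsampled Gaussian mechanism

    ε(α) = log( Σ_{k=0..α} C(α,k) (1−q)^(α−k) q^k e^{k(k−1)/(2σ²)} ) / (α−1)

evaluated in log-space.  Composition over steps is exactly additive per
order.  The order grid is the integers 2…64; the minimising order in every
regime exercised here is far from both ends.  Non-integer orders are
rejected rather than interpolated — the grid is integral by construction
and interpolation would silently weaken the bound's tightness guarantee.
Conversion to (ε′, δ)-DP uses

    ε′ = ε(α) + log((α−1)/α) − (log δ + log α)/(α−1)

minimised over the grid.  All epsilons are in nats.  δ defaults to the
inverse training-set size.  The non-private arm (σ = 0) bypasses the
ledger entirely and reports ε = ∞.

Generator updates never touch real data except through the already
privatised critic, so they are post-processing and consume no budget; the
ledger is composed exactly once per critic optimizer step of the training
loop.

### Step convention for the full-scale guarantee

The full-scale protocol (41,000 training patches, batch 32, noise
multiplier 0.65, stopped after 29 epochs) is accounted with the following
convention, which mirrors the structure of the reference DP-GAN training
pattern this architecture derives from: one epoch = 41000 // 32 = 1281
generator iterations; each generator iteration is preceded by 5 critic
updates; each critic update performs two private optimizer steps (one
after the real-batch backward pass, one after the generated-batch
backward pass), each of which composes the mechanism once.  That yields
29 × 1281 × 5 × 2 = 371,490 compositions and a converted ε′ ≈ 7.51 at
δ = 1/41000.  The phrase "the discriminator was updated 5 times [per
epoch]" admits other readings — 1281 critic batches per epoch with a
single composition per update gives ε′ ≈ 2.71, and 5 critic updates per
generator iteration with a single composition gives ε′ ≈ 5.15 — so the
reported guarantee is interpretation-dependent; `scripts/acceptance.py`
uses the dual-step reading above and this paragraph is its record.  The
package's own training loop (`gan.train`) uses the simpler convention:
one combined real+generated DP-SGD step per critic update, one
composition per step, which is the stronger (more conservative) reading
for a fixed step count.

## The GAN (`gan`, backend in `nn`)

Generator: a 128-D standard-normal latent vector through one dense layer
to a low-resolution grid, `gen_stages` stages of nearest-neighbour 2×
upsampling + 3×3 convolution + ReLU, and a final 3×3 convolution to two
channels.  Output activations (the architecture's own choice, since
nothing canonical exists for joint image-label synthesis): tanh rescaled
to [0, 1] for the image channel, sigmoid for the label channel, labels
binarised at 0.5 at synthesis time.

Critic: `critic_stages` strided convolutions (kernel 4, stride 2, LeakyReLU
slope 0.2) and a dense layer to one unbounded score.  The critic contains
no batch-coupling layers (no batch normalisation): per-sample gradients
must be well defined for DP-SGD, and batch statistics would couple
samples.

Losses are the Wasserstein pair loss_G = −mean(D(x_gen)),
loss_D = mean(D(x_gen)) − mean(D(x_real)); the Lipschitz constraint is the
original weight-clipping construction, |w| ≤ 0.01 after every critic
step.  The WGAN weight clip (0.01) and the DP gradient clip (1.0) are
unrelated parameters.  Optimisation is RMSprop for both networks;
optimizer state is not noised (only gradients are privatised).

Epoch convention: one epoch = ⌈N/batch⌉ critic batches sampled uniformly
with replacement; the generator updates after every 5th critic batch
(`n_critic = 5`).  This is the standard WGAN reading of "5 critic updates
per generator update" and is exposed as configuration.

Two profiles ship:

| parameter | full scale | desk scale |
|---|---|---|
| patch size | 96 | 32 |
| up/down stages | 5 + final conv | 3 + final conv |
| base channels (G/D) | 128 / 32 | 48 / 12 |
| batch size | 32 | 16 |
| learning rate | 5e-5 | 2.5e-4 |
| epochs | 50 | 60 |

The desk profile exists because the whole pipeline must run on one CPU in
minutes; its learning rate is raised relative to full scale roughly in
proportion to the reduced number of optimizer steps, chosen from a
stability sweep of the *non-private* arm across independent phantom
cohorts (weight-clipped WGANs at this scale are seed-sensitive; the desk
values were the only sweep point that trained successfully on every
cohort tested).  The networks are implemented directly in NumPy (module
`nn`): im2col convolutions with explicit backward passes that keep the
batch axis on all parameter gradients, which makes per-sample gradients —
the quantity DP-SGD clips — an ordinary array instead of a framework
internal.  Everything is float32; parameters and updates are deterministic
functions of the seeds.

## Segmentation readout (`segmentation`)

A slim two-level U-Net (3×3 convolutions, ReLU, 2×2 max pooling, optional
bottleneck dropout, nearest-upsampling decoder with skip concatenations,
1×1 output convolution) is trained on labeled patches with a batch-global
soft-Dice loss — chosen to match the selection metric and the extreme
foreground/background imbalance — using Adam.  The hyper-parameter grid
enumerates learning rate {1e-3, 1e-4} × dropout {0, 0.1} × label-consistent
augmentation (flips/right-angle rotations) {off, on} = 8 configurations;
model selection maximises mean volume-level Dice on validation volumes,
ties broken by lower balanced average Hausdorff distance, then
configuration order.  Volume inference tiles each axial slice with P×P
windows (non-overlapping by default, configurable overlap with per-pixel
averaging over covering tiles; the final partial tile is shifted flush to
the volume edge) and thresholds stitched probabilities at 0.5.

## Metrics (`metrics`)

* **DSC** = 2TP/(2TP+FP+FN).  The 0/0 corner is defined as 1.0 when both
  masks are empty and 0.0 when exactly one is empty (continuity
  conventions, documented because the formula is undefined there).
* **Balanced average Hausdorff distance**: the average of the two
  directed mean nearest-neighbour distances, **both normalised by the
  ground-truth voxel count N_G**.  This is deliberately not the
  conventional AHD (which divides the second sum by |S|): with the shared
  N_G normalisation a false-positive-heavy prediction is punished roughly
  in proportion to its excess voxels.  A regression test locks in both
  the asymmetry under operand swap and the false-positive penalty.
  Distances are Euclidean, in voxels by default, in mm when a spacing is
  given.  Undefined (error) when either mask is empty; the segmentation
  report records NaN for such volumes and aggregates over the rest.
* **Fréchet distance** between Gaussians fitted to feature embeddings:
  ‖Δμ‖² + Tr(Σa + Σb − 2(ΣaΣb)^{1/2}), principal matrix square root via
  `scipy.linalg.sqrtm`; rank-deficient sample covariances are retried
  with a relative ridge of 1e-6 on the diagonal, and residual negative
  values within the same tolerance are clamped to zero.  The feature
  extractor is pluggable.  The default is a fixed-seed random
  convolutional filter bank plus an 8-D hand-crafted statistic vector:
  random convolutional features preserve enough distributional structure
  to rank similarity, are fully deterministic, and require no pretrained
  weights; absolute values are therefore not comparable to
  Inception-based scores, but differences and orderings across arms use
  one fixed extractor and are internally consistent.
* **SSIM** with k1 = 0.01, k2 = 0.03, L = 1 for [0, 1] images; the primary
  mode computes one global statistic (the product of luminance, contrast
  and structure terms), a sliding uniform-window mode is available.  The
  mode-collapse probe averages SSIM over all unordered pairs of generated
  images (1,000 images at full scale), with a seeded random pair
  subsample above a configurable cap.

## Embedding (`embedding`)

Hand-written t-SNE: Gaussian conditional similarities with per-point
bandwidths calibrated by bisection to a target perplexity (default 30;
calibration tolerance 1e-5 in entropy, i.e. well under 1e-3 in
perplexity), symmetrised p_ij = (p_{j|i}+p_{i|j})/2N; Student-t
low-dimensional kernel; gradient descent with momentum 0.5→0.8 (switch at
iteration 250), early exaggeration ×4 for the first 100 iterations, seeded
random initialisation (SD 0.01).  The default cost is KL(p‖q), whose
analytic gradient is verified against finite differences.  The
"Wasserstein" mode replaces KL by the 1-Wasserstein distance between p
and q as distributions over the pair index set under the discrete ground
metric, which equals the total-variation cost 0.5·Σ|p_ij − q_ij|; this is
one deliberate reading of substituting a Wasserstein metric for KL in the
embedding cost (the substitution is not defined precisely anywhere we
could follow), and it is labelled an interpretation, not a claim.  Both
costs share one generic chain rule through the Student-t normalisation,
so the verified gradient path covers both.  No Barnes-Hut or FFT
acceleration: N is capped at desk scale (≤ 2,000 points).

## Pipeline and scale choices (`pipeline`)

`run_sweep` executes: phantom cohort → per-subject patch extraction →
one GAN per (noise multiplier, repeat) → accounting → synthesis → U-Net
grid → validation selection → test evaluation (DSC, bAHD) → Fréchet
distances from the generated pool to the training and test patch pools →
mean pairwise SSIM.  Failures are isolated per arm with recorded
tracebacks.  All randomness derives from one master seed through named
streams (cohort, gan, unet, synthesis, tsne, fid); per-arm seeds hash the
(noise multiplier, repeat) pair, so any arm can be reproduced alone.  The
non-private arm runs once; private arms run `repeats` times (5 at full
scale).

The FID reference pools are seeded uniform subsamples of the training and
test patch sets (not head slices), so both pools inherit the same
vessel-centered/random composition statistics; the memorization gap
reported per arm is FID_test − FID_train, positive when the generated
pool sits closer to the training data than to unseen data.

Desk-scale defaults (the package's own choice of a problem size that a
laptop CPU completes in minutes, used by the end-to-end tests): 4 train /
1 validation / 2 test subjects of 80×80×32 voxels with 5 vessels each,
60 + 60 patches per training subject (960 total), 32×32 patches, 60 GAN
epochs (≈ 3,600 critic steps), 300 synthetic pairs, a 2-configuration
U-Net grid at 6 epochs, 150-image FID pools.  The full-scale profile
(41/11/14 subjects, 500+500 patches, 96×96, 50 epochs, 41,000 synthetic
pairs, 8-configuration grid, 5 repeats) is expressed in the same
configuration schema but is a multi-day CPU computation and is not
exercised by the tests.

What the desk-scale trend tests show: that utility (test DSC of a U-Net
trained on synthetic pairs) is highest for the non-private arm and
decreases with the noise multiplier, required to hold in at least 2 of 3
independently seeded repetitions (observed: 3 of 3).  The suite also
measures the memorization gap FID_test − FID_train per arm and asserts
the full-scale expectation — largest gap for the non-private arm — at the
same 2-of-3 bar; at desk scale this assertion *fails*, and the failure is
informative rather than a defect: the phantom cohorts are all drawn from
one generative distribution, so the training and test pools are nearly
indistinguishable (pool-to-pool Fréchet distance 0.03–0.16, against
generator-to-pool distances of 0.5–1.7), leaving almost no train-specific
signal for the generator to memorise; doubling training length does not
change this.  Real patient cohorts carry genuine inter-subject identity,
which is exactly what the full-scale memorization gap detects and the
phantom model deliberately lacks.  What the tests cannot show in general:
absolute metric values comparable to GPU-scale training on clinical data;
weight-clipped WGANs at desk scale remain seed-sensitive, which is
precisely why the tests assert majority-of-seeds trends rather than
per-seed values.

## Known limitations

* The DP guarantee applies to the critic's view of the *patch* dataset;
  patches from one subject are correlated, so subject-level guarantees
  would require group privacy or subject-level sampling, neither of which
  is modelled.
* The accountant covers uniform-with-replacement/Poisson-style sampling
  only; shuffled-epoch sampling would need a different amplification
  argument.
* The default Fréchet feature extractor is not an Inception network;
  absolute FID-like values are not comparable across extractors.
* Phantoms contain no anatomy, intensity inhomogeneity, or acquisition
  artefacts; transfer of any quantitative result to clinical data is
  untested by construction.
* 2-D patches only; no 3-D generation or segmentation.
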