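# Methods

`ldmar` implements, end to end and at desk scale, a metal artifact reduction
(MAR) chain for fan-beam CT in which a conditional latent diffusion model
supplies the prior image for a normalized-MAR (NMAR) projection-domain
correction, a learned network segments the metal, and the same diffusion
model is reused to clean up the secondary artifacts that trace interpolation
introduces.  This note records the model, the numerical choices, and what
the synthetic study does and does not establish.

## Acquisition model and projector

The scan model is 2-D circular fan beam with a flat, equally spaced
detector; the learned parts of the chain all operate slice-wise, so nothing
scientific is lost relative to a cone-beam acquisition while everything
becomes testable on one CPU.  Geometry defaults: source-isocenter 500 mm,
source-detector 1000 mm, 128 detector elements of 1.6 mm, 180 views over
360 degrees.  A lateral detector offset parameter exists but the test
configurations are full-fan; short scans (arc < 360 degrees) are handled
with Parker weights.

The forward projector integrates along each source-to-element ray by
bilinear (Joseph-style) sampling at half-pixel steps; `backproject` scatters
with the identical weights and is therefore the exact adjoint (inner-product
agreement to float round-off, which the tests assert).  FBP follows the
standard equispaced fan-beam recipe: cosine pre-weighting on the virtual
detector through the isocenter, Ram-Lak ramp filtering via zero-padded FFT
(optional cosine/Hann apodization), distance-weighted backprojection.
Measured accuracy at the test geometry: 0.45% relative L2 against the
chord-length closed form of a centered disc, and a round-trip RMSE of about
1.4% of the phantom maximum at 370 detectors / 360 views (2.9% at the
coarser default detector).

## Synthetic study conditions

No public data exist for this problem, so the simulator defines the study
population: a soft-tissue (PMMA-like) body disc of radius 36 mm, a
200-degree horseshoe arch of nine bone-equivalent (Teflon-like) sockets at
radius 24 mm, an air throat, and two titanium inserts (cylinders by default,
screws available) of radius 3 mm seated in randomly chosen sockets.  Arch
orientation, insert placement and a low-frequency multiplicative soft-tissue
texture (4% amplitude, the "clay" variability of a physical phantom) are
drawn per seed.  Slices are 64 x 64 at 1.25 mm.

Attenuation follows a two-component model mu(E) = a (E/30)^-3 + b kn(E)
(photoelectric-like plus Compton-like, kn the normalized Klein-Nishina
energy factor), with per-material coefficients solved from two anchor
points; values are approximate by design — what matters for artifact
morphology is the ordering soft < bone << metal and the correct energy
dependence, not dosimetric accuracy.  The tube spectrum is a Kramers-law
shape up to 95 keV with light aluminium-like inherent filtration (0.5 mm),
discretized in 12 bins.

Corrupted sinograms are polychromatic Beer-Lambert sums with Poisson photon
noise at 500 photons per ray and a one-count floor (photon starvation);
reconstruction uses the plain ramp filter.  These conditions put the slices
in the severe-artifact regime the method targets: pronounced dark bands
between the inserts (beam hardening) and strong in-trace noise streaks
(photon statistics behind metal).  The clean member of each pair replaces
metal with bone-equivalent and is scanned noise-free at a single reference
energy chosen so that monoenergetic soft tissue matches the polychromatic
effective attenuation at a representative 60 mm body path — the moral
equivalent of a water-calibrated beam-hardening pre-correction, which keeps
the clean/corrupted difference map free of a global offset.

## Classical MAR

The metal trace is computed geometrically — a detector bin is flagged iff
its ray line intersects a metal pixel square (exact corner-straddle test,
verified against a brute-force sampling oracle) — then dilated by one
detector bin to absorb projector edge effects.  LIMAR fills traced runs by
linear interpolation along the detector axis (edge runs extend the single
neighbour; a fully traced view copies the nearest intact view with a
warning).  NMAR divides the sinogram by max(FP(prior), eps) with
eps = 1e-4 x median positive prior projection, inpaints the trace in the
normalized domain, and multiplies back; entries outside the trace are
returned bit-identical.  Trace inpainting defaults to harmonic (Laplace
solve over the 2-D view x detector grid with Dirichlet boundaries, via a
sparse direct solve), which couples neighbouring views; per-view linear
interpolation is available as a fallback mode.  The classical threshold
prior (air -> 0, soft tissue -> flat, bone kept, Gaussian-smoothed sigma 1)
is built from a LIMAR pre-correction rather than the raw corrupted image,
since dark bands below the air threshold would otherwise poison the prior.
Metal pixels are re-inserted from the uncorrected reconstruction by default.

## Learned components

All networks run on the package's own numpy layer library (`ldmar.nn`):
convolutions by im2col, GroupNorm, SiLU, pre-activation residual blocks
whose second convolution is small-initialized (the blocks start near the
identity, which keeps activation variance flat with depth — without this
the autoencoder cannot fit even a single slice in hundreds of Adam steps),
nearest-neighbour upsampling, and a three-scale U-Net with sinusoidal time
embedding injected per block.  Every backward pass is finite-difference
checked in the test suite.

**Codec.**  A vector-quantized autoencoder with downsample factor 4
(64 x 64 -> 16 x 16 latents), embedding dimension 4, 64 codebook vectors,
channels (16, 32).  Images enter through a fixed attenuation window
[-0.02, 0.10] mm^-1 mapped to [-1, 1]; metal saturates the window, which is
acceptable because the prior never needs to reproduce metal.  The loss is
the four-term composite: reconstruction MSE, codebook term
||sg[z_e] - z_q||^2, commitment term beta ||z_e - sg[z_q]||^2 (beta = 0.25),
and a perceptual feature distance with weight lambda_p = 0.01.  The
perceptual extractor is a fixed, seeded random three-scale conv stack with
unit layer weights; it preserves the loss's structure and identities
without downloaded weights, and a pretrained stack can be substituted
through the same interface.  Training: 400 Adam steps at lr 2e-3, batch 4,
with a 40% continuous warm-up before the bottleneck is enabled and the
codebook seeded from the warmed-up feature distribution; the VQ gradients
are mean-reduced inside the update (same minima, better-conditioned steps)
while the reported loss parts follow the norm-squared definitions.  Dead
codes (decayed usage below threshold) are re-anchored every 50 steps to
k-means centers of recently seen far-from-codebook features.  Measured:
held-out round-trip PSNR ~27 dB on the normalized window (the Poisson
noise in corrupted slices caps the attainable figure near 28 dB).

**Conditional latent diffusion.**  A fixed linear variance schedule
beta_t in [1e-4, 2e-2] over T = 200 steps (the schedule length is
configurable; 200 keeps desk-scale training well sampled), epsilon-prediction
U-Net (channels 16/32/48, 32-dim time embedding) with the corrupted slice's
latent concatenated to the input at every step.  Latents are normalized per
channel to unit scale using the clean-latent statistics.  Training: 1500
steps, batch 8, lr 2e-3 on 20 paired slices.  Sampling is deterministic
DDIM (eta = 0) over 5 uniformly spaced steps.  The condition fade-out
ablation Condition(t) = ((T - t) Corrupted - t)/T — full guidance at the
first generation step, a flat -1 grid at the last — is implemented with the
step index running forward from the start of generation; the indexing
direction is exposed through the policy should the opposite reading be
wanted.  An optional perceptual term on decoded x0 estimates is supported
in the training objective but off in the desk-scale recipe (the plain MSE
objective is what the moment/recovery tests pin down).

**Secondary artifact correction** reuses the trained model: the
NMAR-corrected image is encoded, noised to 20% of the trajectory
(start_fraction 0.2, i.e. one refinement segment), and the remaining DDIM
steps run with the image's own latent as condition.  start_fraction -> 0
degenerates to the codec round trip, which the tests assert.  A
full-trajectory mode (fresh generation conditioned on the corrected image)
is available through the same sampler arguments.

**Metal segmentation.**  Samples are synthesized by the artifact-transfer
procedure: difference maps (corrupted minus clean, carrying the metal and
its artifact pattern) are rotated uniformly at random and added to
metal-free slices, the rotated mask being the label; 1000 samples from the
20 training pairs.  A compact U-Net (channels 8/16/32) trains 400 steps
with the compound Dice + BCE loss on sigmoid outputs; inference thresholds
at 0.5 and drops components under 4 px.  An adaptive-threshold +
morphology pseudo-labeler covers the case where only unlabeled slices are
available; its parameters are config-exposed heuristics, and the suite only
requires Dice >= 0.7 agreement with ground truth for it (the network itself
reaches ~0.94 held-out).

## Evaluation

RMSE and PSNR exclude metal pixels (the clean reference replaces metal with
bone, so those pixels carry no correction information); PSNR uses the
window maximum as peak.  SSIM uses a Gaussian window (sigma 1.5) and is
mask-averaged over the same support.  Dark-band/streak severity is the
standard deviation over an automatically placed inter-arch ROI: a 3 px disc
at the centroid midpoint of the metal components, metal excluded.
`run_ablation` runs all methods over identical slices, masks and seeds, and
records per-method failures without aborting the suite.

## Problem sizes and what the tests show

The suite and the acceptance script use 24 simulated pairs (20 train, 4
held out), the training recipes above, and seeds fixed at collection time.
At this scale the package reproduces the directional structure of the
method: corrupted > LIMAR > oracle-prior NMAR in RMSE; the diffusion prior
roughly halves the corrupted RMSE; prior-quality monotonicity
(threshold < diffusion < oracle); NMAR with the diffusion prior is worse
than the prior alone until the secondary correction recovers the gap —
the full chain then matches or beats the prior alone while retaining
measured off-trace data; ROI standard deviation falls monotonically along
corrupted -> threshold NMAR -> full chain; and both eroded (-2 px) and
dilated (+8 px) masks degrade the final RMSE relative to the exact mask.
One interaction worth flagging: with a high-quality prior and very noisy
measurements, moderate over-dilation of the trace is not harmful for the
intermediate (pre-secondary) configuration — replacing noisy data with good
prior data can help — so the mask-sensitivity property is asserted for the
complete chain, where it holds in both directions.

One directional property does not survive the scale reduction: the full
chain's per-slice RMSE standard deviation is *not* lower than threshold
NMAR's here.  Threshold NMAR barely changes these noise-dominated slices
and is therefore near-uniformly mediocre, while the diffusion chain's RMSE
varies with its generated prior; consistency advantages of the learned
method are a property of settings where corrections are large relative to
the noise floor, and the suite does not assert it.

These are desk-scale, synthetic results.  The simulator produces the right
artifact morphology but not scanner realism: no scatter (assumed
pre-corrected), no detector lag or flat-field structure, no cone-angle
effects, two-material anatomy without fine texture, and a spectrum/material
model that is qualitative.  Absolute metric values therefore do not
transfer to clinical data; the orderings and identities are the claims
under test.

## Known limitations

* The projector's bilinear sampling slightly blurs at the half-pixel step;
  the metal trace is computed geometrically rather than by thresholding the
  projected mask for exactly this reason.
* The codec saturates metal at the window maximum; downstream stages that
  need metal values take them from the uncorrected reconstruction.
* Diffusion training at 20 pairs memorizes the phantom family by design;
  nothing here measures generalization across anatomies.
* The harmonic inpaint solves one sparse system per call; for much larger
  sinograms an iterative solver would be preferable.
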