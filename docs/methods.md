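# Methods

## Physical model and discretisation

All spectral quantities live on a `WavelengthGrid` of band centres in
nanometres.  The working default is 32 uniform bands spanning 400–700 nm —
the visible range over which tooth/ceramic colour is assessed; band count and
range are configurable, and `resample_spectrum` maps finer instrument grids
(e.g. a 204-band imager covering ~397–1004 nm) onto the working grid by
linear interpolation with edge-hold extrapolation.  How a real 204-band
instrument should be reduced to a 32-band training grid is genuinely
underdetermined (decimation, averaging and cropping are all defensible);
linear band interpolation was chosen because it is monotone,
nonnegativity-preserving and invertible in distribution, and the choice is
isolated behind one function.

The camera equation is evaluated as a discrete sum
`G[x,y,k] = Σ_λ cube[x,y,λ]·C_k(λ)` (`render_rgb`), radiance is the
elementwise product of reflectance and illuminant (`make_radiance`), and
reflectance recovery is the per-band ratio of the object cube to the light
cube (`compute_reflectance`).  The ratio uses a division floor of 10⁻⁶
(relative to an illuminant normalised to unit maximum): bands at or below the
floor are clamped and reported in a boolean mask rather than silently zeroed,
so downstream code can distinguish "dark illuminant" from "dark object".
Reflectance is required to be nonnegative but is *not* clipped at 1 — glossy
pixels can exceed a diffuse white reference in individual bands.  Images are
normalised to unit maximum (θ/max θ) before entering networks or metrics;
the all-zero image is rejected rather than mapped to NaN.

## The synthetic acquisition campaign

The generator emulates a light-box acquisition rig end to end.

**Illuminants.**  Sixteen LEDs, ids 1–16: warm whites (6, 11, 16), neutral
whites (7, 10, 13), cool whites (1, 4), and eight monochromatic hues with
centres spread over 420–665 nm.  White LEDs are modelled as a narrow blue
pump (450 nm, σ 12 nm) plus a broad phosphor band (σ 65–75 nm) whose centre
and relative amplitude encode the warm/neutral/cool class; only this
qualitative class structure is claimed, not measured spectral power
distributions.  The sixteen lighting conditions are 8 single whites, 5 binary
white–white mixes (7+6, 6+1, 7+1, 7+4, 6+4), 2 tricolor mixes (7-6-1, 7-6-4)
and one eleven-LED multicolor mix (1, 2, 3, 5, 6, 7, 8, 9, 12, 14, 15), with
equal mixing weights; because reasonable LED-id/class tables differ in the
binary-mix labelling, the condition list is configurable.
Condition spectra are normalised to unit maximum before broadcasting into a
spatially constant light cube — treating the light as scene-global, matching
a diffuser-homogenised box and the whiteboard reference being effectively one
spectrum.

**Scenes.**  A reflectance field is a dark background plus 3 soft-edged
elliptical "specimen" blobs.  Each blob's spectrum is a base level plus an
upward ramp toward long wavelengths (the characteristic tooth/ceramic slope)
plus a nonnegative combination of 4 broad Gaussian basis functions; values
are clipped to [0, 1.2].  The background is a dark *tinted* smooth spectrum
drawn per scene rather than a flat gray: a spectrally flat background would
put a perfect calibration reference into every image, letting a model infer
the illuminant from the object image alone and defeating the purpose of the
light input.  Spectra are smooth by construction (measured max |Δ²S| ≈ 0.03
across bands on the default grid).

**Imaging and noise.**  The default camera is three Gaussian sensitivities
centred at 610/540/460 nm with σ 35 nm — a generic RGB camera; tabulated
curves can be substituted.  Additive Gaussian sensor noise (default σ = 1% of
the light image's maximum) is applied to the two RGB images only; the
spectral cubes and the reflectance ground truth stay noise-free, because the
supervision targets in the emulated rig come from the spectral camera, and a
clean target keeps test oracles sharp.  Augmentation (rotation quantised to
90° multiples to avoid interpolating spectra, zero-padded shifts and crops)
applies one identical geometric transform to the object RGB, object cube and
reflectance ground truth, never to the light images.

**Datasets.**  `build_dataset` round-robins conditions, fans per-pair seeds
out of one `SeedSequence`, and assigns train/val/test splits in the
3000/300/100 proportion scaled to the requested size.  Generation is
bit-reproducible from (seed, params, conditions).

What the simulator does **not** emulate: translucency and subsurface
scattering of real ceramics, specular highlights, spatially nonuniform
illumination, cross-modal registration error, demosaicking artefacts, and
measured LED/camera curves.  Passing tests therefore demonstrate that the
pipeline recovers reflectance under the stated image-formation model — not
that it matches any particular accuracy on captured dental data, which is not
redistributable.

## Networks

All networks run on the package's numpy reverse-mode autograd core
(`specrec.nn`): broadcasting arithmetic, ReLU/sigmoid, reductions,
reshape/concat, strided conv2d (im2col + BLAS matmul, with the input gradient
computed as a full correlation with the rotated kernel), transposed conv2d,
and a separable valid-mode 1-D correlation used by the SSIM loss.  Gradients
are verified against central differences in the test suite.

**Sample branch** (`RadianceUNet`): 3×3 stem; N = 3 encoder stages of K = 2
local–global fusion (LGF) blocks followed by stride-2 convolution
(width doubling from a base of 32); an LGF bottleneck; a decoder of 2×2
transposed convolutions whose skip connections pass encoder features through
dual-stat attention (DSA) gates before 1×1 merge and K = 2 more LGF blocks; a
3×3 head.  The global residual adds the RGB input, lifted from 3 to B
channels by a fixed (untrained) 1×1 tiling projection — keeping the
input-to-output skip well-typed across the channel-count change and giving
the untrained network a physically sensible starting radiance.

An LGF block fuses a 3×3 convolutional local path with a global context path
(spatial average pool → 1×1 conv → broadcast) by concatenation and a 1×1
convolution, added residually.  A DSA gate computes each channel's spatial
mean and standard deviation and passes the pair through a shared two-layer
bottleneck with sigmoid output; sharing the bottleneck across channels makes
the gate equivariant under channel permutation (identical channels always
receive identical gates), which a cross-channel squeeze-excite bottleneck
would violate.  A small variance floor (10⁻⁸) keeps constant channels
finite.

**Light branch and fusion decoder** (`AttentionSpectralNet`): two distinctly
parameterised shallow 3×3 paths, each conv → ReLU → channel attention (CA) →
spatial attention (SA); 1×1 refinements of each; 4-way channel concatenation
(fused width = 4 × branch width, asserted at build); N = 3 residual L-blocks;
1×1 head.  CA gates each channel from its global average through a shared
per-channel bottleneck; SA gates each pixel from the channel-mean and
channel-max maps through a 3×3 convolution and sigmoid.  An L-block is
`shortcut₁ₓ₁(x) + SA(CA(conv₃ₓ₃(relu(conv₃ₓ₃(x)))))`.  The light-role
instance (3 → B channels) and the decoder-role instance (2B → B) share code
but never parameters — their input widths differ, so shared weights are not
type-sound.

**Initialisation.**  He-normal throughout, with two deliberate exceptions for
stability in these unnormalised nets: the final convolution of every residual
update (LGF fusion, L-block second conv) starts at zero, so each block begins
as the identity / its linear shortcut, and output heads are scaled by 0.1.
This puts the untrained model's loss at order 1 instead of 10⁴ and removes
any depth-dependent blow-up.

**Baseline** (`PlainUNet`): a classic U-Net shape (double-conv stages,
stride-2 downsampling, transposed-conv upsampling with skip concatenation, no
attention) mapping the object RGB alone directly to reflectance.

## Loss and metrics

The training loss is α·MSE + β·(1 − SSIM) with α = β = 1; auxiliary MSE terms
(weight 0.1 each) supervise the intermediate radiance and illuminant cubes
against their unit-max-normalised ground truths.  With three reconstructed
cubes the supervision target is genuinely open; supervising the final reflectance with weak
auxiliary anchors on the intermediates makes all three steps identifiable and
stabilises small-scale training, and either auxiliary weight can be set to 0.

SSIM uses the standard windowed statistics with C₁ = 10⁻⁴ and C₂ = 9·10⁻⁴
(exactly K₁ = 0.01, K₂ = 0.03 at unit data range), an 11×11 window —
Gaussian-weighted with σ = 1.5 by default, the de-facto standard; a uniform
window is provided for oracle comparisons — evaluated at fully interior
window positions only and averaged.  On cubes SSIM is computed per band and
averaged, matching per-band reporting; `evaluate_bands` returns the per-band
MSE/SSIM vectors plus their means, and per-image means are available by
averaging evaluations.  The implementation agrees with scikit-image's
`structural_similarity` (gaussian_weights, σ 1.5, population covariance) to
machine precision and with a brute-force per-window loop to < 10⁻⁸.
Evaluation compares predicted and true reflectance on their native scale
(reflectance is already an intrinsic ratio ≈ [0, 1.2]); the unit-range SSIM
constants are adequate at that scale.  SSIM's true range is (−1, 1]; the
upper bound is asserted, no lower bound is claimed.

## Training protocol

Adam with β₁ = 0.9, β₂ = 0.999, zero weight decay, constant learning rate
4·10⁻⁴, batch size 8; the full-scale protocol is 4000 pairs of 64×64×32
cubes, 3000/300/100 split, 54 epochs.  One global seed fans out through a
`SeedSequence` to data generation, parameter initialisation and batch order;
identical (seed, config, data) reproduce the loss history.  Training aborts
on a non-finite loss.  All three subnetworks are optimised jointly end to
end; the three-step presentation of the inversion does not force stagewise
training, and joint optimisation lets the decoder shape the intermediate
representations.

**Desk preset.**  For CPU-scale experiments the package uses 128 pairs of
32×32×16 cubes, widths 8 (sample branch base, attention branch — fused 32),
2 L-blocks, 12 epochs, batch 8, and the same optimiser and split proportions.
These sizes are the package's own desk-scale choice for the numpy backend;
the qualitative comparisons made at this scale (training reduces validation
loss; the two-branch model beats the plain U-Net; removing the DSA gates or
the illumination input does not help) are directional claims and are asserted
with a stochastic tolerance of 0.01 on 3-seed mean SSIM, not as absolute
accuracy figures.

## Ablation matrix

`run_ablation` builds, trains (identical config and seed) and scores on the
shared test split: `full`; `no_dsa` (skip gates → identity); `no_lgf` (LGF →
plain 3×3 convolutions); `p_only` (decoder consumes the radiance estimate
alone); `l_only` (decoder consumes the illuminant estimate alone);
`const_illumination` (light RGB replaced by constant 1 at train and test);
`baseline_unet`; `mse_loss_only` (β = 0).

## Numerical choices and degenerate inputs

Division floor 10⁻⁶ with clamp mask; variance floor 10⁻⁸ in statistic gates;
sigmoid inputs clipped to ±60 before exponentiation; ties in the channel-max
pooling split gradient equally among maxima; float64 is the default dtype
(used by all gradient checks), float32 is used for training throughput;
all-zero images are rejected by normalisation; spatial sizes must be
divisible by 2^N for the U-Nets, checked with an explicit error.

## Known limitations

The simulator's gap to captured data (above) is the main one.  The LGF, DSA,
CA and SA internals follow canonical readings of their names and the
surrounding architecture conventions, and the layer widths are this
package's own; parameter counts are therefore not comparable to other
implementations of similarly named blocks, and matching any particular
parameter count is explicitly not a goal.
The numpy backend is single-threaded and memory-bound, which caps practical
problem sizes well below GPU scale; the desk preset reflects that.  PNG I/O
is limited to the package's own 16-bit truecolour layout (unfiltered
scanlines), which external decoders read but which does not aim to be a
general PNG implementation.
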