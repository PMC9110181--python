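# Methods

## Problem and model

Sparse-view reconstruction is the linear inverse problem `z = F y` with far
fewer measurements than unknowns. For parallel-beam CT, `F` maps an image on
the `[-1,1]²` box to line integrals over `(angle, detector-offset)` pairs;
for Cartesian MRI it is the 2-D DFT restricted to a sampling mask. Both
operators here are exactly linear, and their adjoints are exact transposes
of the discretization (not merely approximate backprojections), so
gradient-based fitting and algebraic iterations behave as the theory
expects.

The image is represented by a coordinate network. With coordinates
`x ∈ [-1,1]^d`, latent `e ∈ R^16` and width `w`:

```
h_0    = sin(ω (x W_in + b_in))
c      = sin(ω (sin(ω (e W_c1 + b_c1)) W_c2 + b_c2))
h_k+1  = h_k + sin(ω (h_k W_k + b_k)) + c        k = 0 … n_blocks−1
f(x)   = h_L W_out + b_out
```

The conditioning feature `c` is computed once per patient and added to every
block's output; with zeroed conditioning weights the latent has no influence
(tested). Where the block structure was open, we add the conditioning
feature after the sine, reading "added to the block output" literally; the
skip connection joins adjacent blocks.

Reconstruction minimizes the mean squared measurement residual of the
rendered grid, `(1/M)‖F f(x) − z‖²/σ²`, where `σ` is the standard deviation
of the measurements over the training samples (measurements are centered
and scaled by training statistics; centering cancels in the residual and
the `1/σ²` makes the loss scale-free). The gradient with respect to the
rendered pixels is `(2/(Mσ²)) Fᵀ(F ŷ − z)`, and flows on through the
network by analytic reverse-mode differentiation. All parameters are plain
numpy arrays; Adam (β₁=0.9, β₂=0.999, ε=1e-8) is implemented directly.
Gradients with respect to weights, latent and coordinates are validated
against central finite differences to better than 1e-4 relative (measured:
~1e-9 on a width-8 config).

## Training protocol

**Pretraining (the interpatient prior).** Shared weights `θ` and one latent
per patient are optimized jointly (generative latent optimization — no
encoder), cycling round-robin through the cohort, one patient per step,
each step updating `θ` and that patient's latent. Pretraining uses the same
sparse measurement geometry as the test-time reconstruction by default.

**Reconstruction.** With a checkpoint, `θ` starts from the pretrained
weights and the latent is drawn `N(0, 0.01²)` and frozen; this follows the
protocol under which the experiments are run. A flag (`optimize_latent`)
enables joint latent optimization instead, since the method description
also admits that variant. Without a checkpoint (the no-prior ablation), `θ`
is freshly initialized and the latent is zero.

**Schedule.** The learning rate warms up linearly from 0 to the peak
(1e-4) over the first 100 iterations, then decays as the inverse square
root of the step count (Noam form `peak · min(t/w, √(w/t))`), continuous at
the changeover. "Decays proportional to the square root of the step count"
admits more than one reading; the Noam form is the standard one and is what
we test (`lr(400) = 5e-5`).

## Frequency scale ω

Sine networks are initialized SIREN-style: first layer uniform `±1/in_dim`,
later layers `±√(6/w)/ω`, biases zero. The default `ω = 30` is standard
practice and appropriate for fitting detail when data are dense (a
dense-view fit at 32² reaches ~27 dB with ω=30 but only ~19 dB with ω=8).
For the *sparse-view* experiments the desk-scale configuration uses
`ω = 8` at 64²: ω sets the network's spatial bandwidth, i.e. the strength
of the coherence prior, and a 10-view problem is solved by the prior, not
by bandwidth. Rendered total variation increases monotonically with ω at
fixed weights (tested), which is the quantitative face of this trade-off.

## Synthetic cohort

A patient is an additive list of ellipses in `[-1,1]²` (or ellipsoids in
3-D). The randomized generator draws, per patient, a jittered two-ellipse
"skull" shell (bright rim, moderate interior) shared across the cohort plus
3–7 interior ellipses with uniform centers (±0.45), axes (0.05–0.30),
rotations and intensities (−0.15–0.35), rejecting draws whose support
leaves the box. Every phantom is a pure function of `(seed, patient
index)`. The shell is what makes an *interpatient* prior meaningful at this
scale: cohort members share gross structure and differ in detail. The
generator does not emulate anatomy beyond that — no tissue textures, no
noise, no partial-volume effects — so passing experiments demonstrate the
mechanism (shared-weight pretraining transfers to held-out members of the
same population), not clinical performance.

Rasterization is a hard point-in-ellipse test at pixel centers (no
anti-aliasing), which makes the rasterizer exactly linear in the ellipse
list and lets a brute-force per-pixel oracle check it bit for bit. The
canonical Shepp-Logan head uses the modified (Toft/Kak–Slaney) intensity
table — skull 1.0, background 0 — the convention modern CT software
defaults to.

## Operators and discretization

Rays are sampled every half pixel along their full length across the box
diagonal; each sample deposits bilinear interpolation weights times the
step length into a sparse matrix, built once per (geometry, grid) and
cached. Apply and adjoint are the matrix and its transpose, so the
inner-product identity holds to machine precision. The default detector
array spans the grid diagonal with ~one-pixel spacing. A dense
`operator_matrix` (grids ≤ 32²) supports rank arguments and the
loss-oracle tests; the default 10-view geometry on 16² has rank 215 < 256,
the null-space fact that motivates priors in the first place. The Fourier
operator uses the unnormalized forward DFT; its adjoint is `N · ifft2`
zero-filled (real part), stated and tested.

## Baselines

**FBP.** Each sinogram row is filtered with the Ram-Lak ramp built from its
real-space kernel (which keeps the correct small DC response — dense-view
FBP preserves the image mean to ~5%, tested), optionally windowed by the
Hann raised cosine over the ramp's support, then backprojected with the
exact adjoint and scaled by `π/(2 n_angles)` times the factor
`detector_spacing / pixel_area` that converts the bilinear-weight adjoint
into the continuous backprojection integral. Our Hann FBP agrees with
skimage's `iradon` to within 0.05 dB on the 128² head-phantom round-trip.
Hann-windowed FBP at this resolution plateaus near 21.4 dB (both
implementations): the window's mid-band attenuation blurs the phantom's
hard edges; the unwindowed ramp reaches ~25.3 dB.

**SART.** The simultaneous update `x ← x + λ V⁻¹FᵀW⁻¹(z − Fx)` with
diagonal column/row-sum weights and zero-sum masking, all angles per
iteration, λ=1 by default; the weighted residual is nonincreasing (tested)
and falls to 2.3% of its initial value after 50 iterations on a dense-view
16² system (<1% by 200).

## Problem sizes and determinism

The packaged experiments run at desk scale by choice: cohorts of 20
patients at 64², 10 projection angles, width-64 four-block networks, 2000
pretraining steps and 300 reconstruction steps. At these sizes the full
ablation (one pretraining plus five held-out paired reconstructions and
baselines) completes in a few minutes on one CPU, and every qualitative
conclusion it supports — prior speeds up and improves held-out
reconstruction; neuRec-with-prior > SART > FBP at 10 views — is measured,
not assumed. Every entry point is deterministic given (seed, config,
inputs): rerunning the demo reproduces the metric table bit for bit.

## Limitations

- 2-D slices by default. The phantom generator and network support 3-D,
  but the measurement operators are 2-D parallel-beam/Cartesian; volumes
  are handled slice-wise.
- Parallel-beam CT only (no fan/cone beam), Cartesian k-space only, no
  physical noise model beyond what a user adds to the measurements.
- The latent is frozen at reconstruction by default; patient-specific
  appearance is absorbed by finetuning `θ`, so the latent mainly matters
  during pretraining (it is what lets one network fit many patients).
- Plain-numpy training is single-device and CPU-bound; it is sized for the
  experiments above, not for clinical volumes.
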