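# se3fod

Contextual PDE enhancement of fiber orientation distributions (FODs) and
fiber-to-bundle coherence filtering for diffusion MRI tractography.

## The problem

High angular resolution diffusion MRI (HARDI) estimates, in every voxel, a
fiber orientation distribution U : ℝ³ × S² → ℝ⁺ whose peaks indicate the
local white-matter fiber directions — typically by constrained spherical
deconvolution (CSD) of the measured signal with a single-fiber response.
At low SNR the per-voxel estimates are noisy and poorly aligned across
neighboring voxels, and streamline tractography run on them produces
dropouts and spurious fibers. This package implements two remedies that
share one mathematical core, for researchers working on diffusion-MRI
reconstruction and tractography pipelines:

1. **Contour enhancement** — before tracking, the FOD field is regularized
   by a linear diffusion on the coupled space of positions and orientations
   ℝ³⋊S²:

       ∂W/∂t = ( D₃₃ (n·∇_y)² + D₄₄ Δ_{S²} ) W,   W(·,·,0) = U,

   i.e. spatial diffusion only *along* the local orientation **n** plus
   isotropic angular diffusion. This hypo-elliptic flow propagates evidence
   along elongated structures while preserving crossings. It is applied
   either by an explicit finite-difference scheme or, equivalently, by a
   *shift-twist convolution* with an analytic approximation of the Green's
   function p_t (spatial offsets expressed in the moving frame of the
   source orientation).

2. **Fiber-to-bundle coherence (FBC)** — after tracking, each streamline
   point (y, n) is treated as a δ-distribution on ℝ³⋊S²; diffusing the
   whole tractogram's δ-density with the same kernel p_t and reading it
   back along each fiber gives the local FBC. Per fiber, the minimum
   windowed mean (FBC^α) relative to the bundle average (AFBC) yields the
   relative coherence RFBC ∈ [0, ∞); fibers with RFBC below a fraction ε of
   the maximum are classified as spurious and removed.

Around this core the package provides CSD (and a DTI-based FOD baseline),
deterministic and probabilistic tractography with the standard
parameterization (step = voxel/10, cutoff 0.1, initial cutoff 0.9, minimal
curvature radius 1 mm), local angular-error and global connection metrics
(VC/IC/NC, ABC, CSR, VCCR), and a synthetic phantom generator so every
stage is testable without external data.

## Worked example

```python
import numpy as np
from se3fod import *
from se3fod.enhance import enhance_fod
from se3fod.kernel import EnhancementParams
from se3fod.metrics import angular_error
from se3fod.sphere import cached_icosphere
from se3fod.synthetic import uniform_gradients

# 45-degree crossing phantom on a 13 mm cube
c, s = np.cos(np.radians(45)), np.sin(np.radians(45))
bundles = [
    BundleGeometry(kind="straight", radius=2.0, start=(0, 6, 6), end=(12, 6, 6)),
    BundleGeometry(kind="straight", radius=2.0,
                   start=(6 - 6*c, 6 - 6*s, 6), end=(6 + 6*c, 6 + 6*s, 6)),
]
truth = make_phantom(bundles, grid_shape=(13, 13, 13))

gradients = uniform_gradients(64)
response = default_response(b_value=3000.0)
dwi = simulate_dwi(truth, response, gradients, 3000.0, NoiseModel(snr=4.0, rng_seed=7))

fod = csd_fit_volume(dwi, response, CSDConfig(l_max=8), mask=truth.mask)
enhanced = enhance_fod(fod, EnhancementParams(d33=1.0, d44=0.02, t=2.0),
                       frequency=4, half_width=5, mass_tolerance=0.15)

tess = cached_icosphere(61)
print(f"angular error, CSD:            {angular_error(fod, truth, tess):.2f} deg")
print(f"angular error, CSD + enhanced: {angular_error(enhanced, truth, tess):.2f} deg")
```

prints

```
angular error, CSD:            11.58 deg
angular error, CSD + enhanced: 9.04 deg
```

— at SNR 4 (Rician noise with σ = 1/SNR of the unit b=0 intensity), the
mean angle between estimated FOD maxima and the ground-truth fiber
directions drops by about 2.5 degrees after enhancement. Coherence
filtering of a deliberately corrupted tractogram:

```python
geo = BundleGeometry(kind="straight", radius=1.0, start=(5, 10, 10), end=(45, 10, 10))
btruth = make_phantom([geo], (50, 20, 20))
bundle = sample_truth_fibers(btruth, 20, step_mm=1.0, rng_seed=1)
spiked = inject_spurious(bundle, 5, lateral_offset_mm=8.0, rng_seed=2)
scores = rfbc(spiked, alpha_mm=4.0)
kept = filter_bundle(spiked, scores, 0.1)
print(f"RFBC of bundle fibers:  {scores[:20].min():.2f} .. {scores[:20].max():.2f}")
print(f"RFBC of outliers:       {scores[20:].min():.3f} .. {scores[20:].max():.3f}")
print(f"fibers kept at eps=0.1: {kept.n_fibers} of {spiked.n_fibers}")
```

prints

```
RFBC of bundle fibers:  0.76 .. 1.07
RFBC of outliers:       0.029 .. 0.037
fibers kept at eps=0.1: 20 of 25
```

— the five injected outliers score an order of magnitude below the bundle
fibers and are removed exactly by the ε = 0.1·RFBC_max threshold.

A command-line interface exposes each stage
(`se3fod simulate|csd|enhance|track|fbc|metrics|pipeline`); see
`se3fod --help`.

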