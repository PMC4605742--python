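# Methods

## Model

The package treats an FOD field as a function U(y, n) on the coupled space
of positions and orientations ℝ³⋊S². Coupling means that an oriented
element (y, n) is identified with a rigid body motion (y, R_n) with
R_n e_z = n, so spatial displacement is expressed in the moving frame of
the orientation. Contour enhancement is the hypo-elliptic diffusion

    ∂W/∂t = ( D₃₃ (n·∇_y)² + D₄₄ Δ_{S²} ) W,

which lets probability mass move back and forth *along* its orientation
(D₃₃, voxel²/time) and change orientation isotropically (D₄₄, rad²/time),
but never step sideways. Both diffusivities must be strictly positive for a
smooth kernel (Hörmander's condition). A basic rescaling argument shows the
outcome depends only on t and the ratio D₃₃/D₄₄; we keep D₃₃ = 1 and vary
D₄₄ and t.

Two realizations of the evolution are implemented and cross-validated:

* **Finite differences** (`fd_evolve`): explicit Euler with the transport
  term (n·∇)² discretized by second-order central differences along ±n
  (trilinear interpolation at off-grid points) and Δ_{S²} by a
  cotangent-weight mesh Laplacian with lumped Voronoi masses on the
  icosphere. The step obeys the positivity bound
  dt ≤ 1 / (2 D₃₃/h² + D₄₄ max|L_ii|); violations raise with the maximal
  stable step. This path conserves mass to round-off and is the testing
  oracle.
* **Shift-twist convolution** (`shift_twist_convolve`): discrete group
  convolution with a lookup table of the analytic kernel approximation
  p_t(y, n) = k(z/2, x, β) · k(z/2, −y, γ), where k is the planar
  contour-enhancement kernel exp(−EN/4t) and (β, γ) chart the orientation.
  The factor θ/(2 tan(θ/2)) in EN is evaluated by its Taylor series for
  |θ| < π/10 (numerical stabilization) and by (θ/2)·cot(θ/2) elsewhere,
  which reaches the exact limit 0 at |θ| = π.

### Kernel discretization and normalization

The analytic prefactors of the kernel approximation are treated as
normalization constants: the diffusion semigroup conserves mass, so only
the normalized discrete shape matters. The LUT is built by evaluating the
kernel analytically for every (source orientation, integer spatial offset,
target orientation) triple — transport to each source orientation uses the
minimal rotation R_n; since the kernel is (approximately) axially
symmetric, the choice of R_n matters only at the level discussed below —
then projected onto two symmetries the exact semigroup kernel possesses:
the adjoint exchange (source, offset, target) → (target, −offset, source)
and antipodal flips. A symmetric Sinkhorn scaling finally makes the
quadrature mass of every source *and* target slice exactly one, so the
discrete convolution is simultaneously mass-preserving and exact on
constants.

Two properties of the *printed* kernel approximation matter for
interpreting tests:

* Its spatial marginal along the orientation axis is Gaussian with
  σ_z = 2√(D₃₃t), a factor √2 wider than the PDE's √(2D₃₃t) — a
  consequence of the z/2 coordinate split in the planar-product form.
  A δ-input therefore correlates only moderately with the FD solution,
  while smooth, bundle-shaped fields (the inputs the method actually
  processes) correlate above 0.95; the oracle-equivalence test uses such a
  field.
* It is axially symmetric about the source orientation only to ~6–10% of
  the peak value (median well below 1%); the symmetrization above averages
  this out of the LUT, but any computation that evaluates the raw kernel
  (notably the FBC sums) inherits a rotation-choice tolerance of the same
  order. Translation invariance is exact.

The window half-width defaults to ⌈2.3·σ_z⌉ with a 2% clipped-tail
tolerance; `build_kernel_lut` verifies the actual clipped mass and raises
with the required half-width when a stricter tolerance is requested.
A 1e-3 tail at t ≥ 1 needs half-width ≥ 7, i.e. tables approaching a
gigabyte — the 2% default trades a small shape truncation (removed anyway
by renormalization) for tractable memory and build time.

## CSD and the DTI baseline

CSD solves, per voxel, iterated least-squares problems: the data term
‖K ⋆_{S²} g − S‖² (response convolution realized as per-order Funk–Hecke
scaling in a real, orthonormal, even-order SH basis) plus λ² times the
squared amplitudes at constraint directions where the previous iterate
falls below τ times its mean (Heaviside reweighting). The initial iterate
is the data-driven solution; iteration stops when the constraint set
stabilizes (plus a 1e-6 coefficient-delta guard) or at i_max. Defaults
τ = 0.1, λ = 1, i_max = 50, constraint sampling = frequency-5 icosphere.
λ = 1 leaves negative lobes of at most a few percent of the peak (a
reasonable robustness/sharpness trade-off at low SNR); λ ≈ 10 suppresses
them almost completely at some cost in noise sensitivity — both behaviors
are pinned by tests. Super-resolution is disabled: l_max is capped so the
coefficient count never exceeds the number of gradient directions
(32 directions → l_max 6 → 28 coefficients; 64 → l_max 8 → 45).

The DTI baseline maps a log-linear tensor fit D(y) to
U_DTI(y, n) ∝ (nᵀD(y)⁻¹n)^{−3/2}, normalized by the single global constant
1/(4π ∫_Ω √det D); Ω is the analysis mask, and the integral is a
voxel-volume-weighted sum.

## Tractography

Directions live on a geodesic icosphere (frequency 16 by default, ~3.8°
spacing); SH coefficients are interpolated trilinearly. Deterministic
tracking follows the peak most aligned with the incoming direction
(antipodal sign resolved forward) and stops when that peak drops below
cutoff × the voxel's maximal angular response. Probabilistic tracking
samples the next direction proportionally to the positive FOD amplitudes
inside the curvature cone of half-angle 2·arcsin(step/(2·r_min)); it stops
when the cone-averaged positive amplitude falls below cutoff × the voxel
maximum (the cone average puts the mass criterion on the amplitude scale —
a raw solid-angle mass would compare a ~10⁻² sr integral against an O(1)
amplitude and stop immediately). The sampling frequency must satisfy
mesh spacing < cone half-angle for tracks to be able to turn; at the
defaults (step = 0.1 mm, r_min = 1 mm → 5.7° cone) frequency 16 provides
~7 candidate directions per step. Per-seed RNG streams are keyed by the
seed's coordinates, so seed-list order only permutes the output.

## Fiber-to-bundle coherence

LFBC at a fiber point is the kernel-diffused δ-density of the whole
tractogram (both ±tangent orientations per point, self term included — it
adds the same kernel-at-origin offset everywhere and cancels in RFBC),
normalized by 1/N_tot. Pairs farther apart than the radius where the
kernel falls below 10⁻⁶ of its maximum are skipped (KD-tree query); an
exact O(N²) mode is kept for tests. FBC^α is the minimum window mean with
the window in points, a ∈ [0, N_i − α]; α is configured in mm and
converted per fiber via its step. RFBC = FBC^α / AFBC. Default kernel
parameters for coherence scoring: D₃₃ = 1, D₄₄ = 0.04, t = 1.4 (spatial
units = streamline units, mm). Filtering retains fibers with
RFBC ≥ ε·max RFBC; the argmax fiber always survives.

## Metrics

Angular error: mean over all ground-truth peaks of the angle to the
nearest estimated FOD maximum (antipodally identified), with maxima
detected on the frequency-61 tessellation (18606 antipodally distinct
directions, covering radius 0.72°) above 0.1 × the voxel maximum. Voxels
with no detected peak contribute the worst case of 90° per truth peak —
a deliberate convention penalizing dropouts, exposed as a parameter.
Connections: a streamline is valid iff its endpoints fall in the two
distinct endpoint ROIs of one bundle (nearest-voxel ownership, half-open
at +0.5); invalid if both endpoints are in ROIs that are not a truth pair;
no-connection otherwise. CSR = 100 − NC, VCCR = 100·VC/(VC+IC), ABC = the
percentage of a bundle's tube voxels crossed by at least one of its valid
streamlines, averaged over bundles. Streamline–voxel intersection uses the
voxels of the streamline points; at step = voxel/10 consecutive points are
dense enough that no segment traversal is needed.

## Synthetic data

The generator emulates the conditions the package is evaluated under:
tube-shaped bundles (straight / circular-arc / cubic-spline centerlines,
radii ~1–2 mm) rasterized on 1 mm grids; per-voxel truth peaks from the
tangent at the nearest centerline point, merged below 5° separation;
endpoint ROIs as tube cross-sections. The DW signal is the response
convolution of the truth peaks — the same forward model CSD inverts —
with the single-fiber response the zonal SH fit of a prolate tensor signal
exp(−b·nᵀdiag(1.7, 0.2, 0.2)·10⁻³ n) at the configured b-value (typical
white-matter diffusivities), and Rician noise S = √((S+σX)² + (σY)²) with
σ = 1/SNR of the unit b=0 intensity. Study conditions used by the
end-to-end tests: 64 approximately uniform gradient directions at
b = 3000 s/mm², SNR ∞ and 4, a 45° two-bundle crossing for recovery, a
quarter-circle bundle (12 mm radius) for the stability experiment, 20-fiber
bundles with 5 injected outliers (8 mm lateral offset, far beyond the
kernel's √(D₃₃t) ≈ 1.2 mm spatial scale) for coherence filtering.

What this does *not* exercise: multi-compartment sub-voxel signal models
(the simulation is self-consistent with CSD's forward model, so CSD
recovery is easier here than on scanner data), partial-volume mixtures
with non-fiber tissue, susceptibility/eddy artifacts, and realistic
bundle-geometry complexity. Passing tests therefore demonstrate internal
correctness and the direction of the method's effects (noise robustness,
outlier removal, stability), not absolute error levels on real
acquisitions.

## Numerical choices and problem sizes

* Sphere quadrature: spherical-Voronoi cell areas (uniform fallback).
  The weighted Gram matrix of the order-8 basis deviates from identity by
  2×10⁻³ at frequency 16 and 1×10⁻³ at frequency 32.
* The (β, γ) chart is degenerate at n = ±e_x; γ is returned as 0 with a
  flag, and kernel values there are negligible for relevant parameters.
* Enhancement runs on a frequency-4 icosphere (162 directions) with an SH
  round-trip (evaluate → convolve → refit) at the field's own l_max; the
  refit is a weighted normal-equations projection. Enhanced FODs are not
  clipped to nonnegative by default (flag available, recorded in output
  metadata).
* End-to-end experiments use small grids (13³–22×22×17 voxels), 10
  tracking repetitions × ~24 seeds for the stability inequality, and a
  compact 8³ grid for the oracle-equivalence check — sizes chosen so the
  full suite runs on a single CPU in a few minutes while leaving every
  effect measurably above its noise floor.
* All randomness flows from explicit integer seeds (phantom noise,
  seeding, per-seed tracking streams); repeated runs are bit-identical.

## Known limitations

* The factored kernel's √2-wider spatial marginal and few-percent axial
  asymmetry (documented above) are inherited from the published analytic
  approximation; an exact Green's function evaluation would remove both at
  substantial cost.
* Probabilistic direction sampling is over tessellation vertices, not a
  continuous distribution: the sharpest representable (l_max = 8) lobe
  still yields ~8° per-step jitter inside the curvature cone.
* The connection classifier is a simplified ROI-pair rule; edge cases such
  as loops re-entering an ROI follow the documented rule and are not
  claimed identical to external benchmarking software.
* 90°-rotation equivariance of CSD and enhancement is approximate (a few
  percent): icosahedral tessellations have no 4-fold symmetry axis, so the
  rotated sampling is a different point set.
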