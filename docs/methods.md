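# Methods

## Problem

Quantitative susceptibility mapping (QSM) estimates tissue magnetic
susceptibility χ (ppm) from the phase of multi-echo gradient-echo MRI. The
phase accrues as φ(t_TE) = 2π·b·t_TE with the field shift b (Hz) related to
χ by a convolution with the unit dipole kernel, D(k) = 1/3 − k_z²/|k|² in
k-space. Because the inversion is a 3-D deconvolution, corrupted field
values anywhere on the support propagate into the whole map. Near the rim
of the brain support, strong background gradients (air cavities, bone)
routinely drive the per-voxel phase change beyond π — the Nyquist limit of
any unwrapper — so those voxels are either excluded (shrinking the usable
mask) or poison the map.

The package implements an iterative restoration of this "fringe" phase:
the background field estimated on the trustworthy interior is *parametric*
(harmonic polynomials, explicit external sources), so it can be evaluated
on the full support and subtracted from the raw wrapped phase *before*
unwrapping. Where the residual local gradients satisfy the Nyquist
criterion, previously unrecoverable voxels become recoverable; iterating
grows the evaluation area toward the full support.

## Pipeline

Let m_max be the maximum brain support and φ̂ the measured wrapped phase.
With an accumulated background estimate b̃_bg (initially 0), each iteration:

1. **Field mapping.** The corrected phase wrap(φ̂ − wrap(2π·t·b̃_bg)) is
   unwrapped per echo inside m_max (reliability-sorted region growing, the
   "best-path" family; exact whenever a Nyquist-compliant spanning path
   exists), echoes are aligned at a central reference voxel assuming
   φ(0)=0 (minimal-jump continuation with linear prediction), and the
   field is the per-voxel least-squares slope of phase vs 2π·t_TE
   (no intercept by default; an intercept and magnitude weighting are
   available for measured data). A σ=2 voxel Gaussian is applied to the
   complex first echo before mapping to tame its low phase contrast.
2. **Masking.** The local coherence Q_LC — the magnitude of the mean
   phasor over each 3×3×3 neighbourhood — is computed on the corrected
   second-echo phase within m_max (neighbourhood renormalized by the
   in-mask neighbour count), smoothed with a mask-normalized σ=2 Gaussian,
   thresholded at Q_LC,min, and reduced to its largest 6-connected
   component → m_EA.
3. **Background fit.** On m_EA the field is decomposed into (a) a
   least-squares combination of real solid spherical harmonics r^l·Y_lm up
   to order 5, orthonormalized over m_EA for conditioning, evaluated on
   m_max; and (b) the dipole field of an external pseudo-susceptibility
   χ_ext minimizing ‖m_EA(b − f0·10⁻⁶·(χ_ext*d))‖² + λ‖m_pen·χ_ext‖², with
   the penalty mask m_pen = m_max ∪ dilate(m_EA, 1) suppressing sources
   inside the support. Conjugate gradients on the normal equations with 2×
   zero-padded FFT convolutions; the resulting field is σ=1 Gaussian
   smoothed and restricted to m_max.
4. **Accumulation.** b̃_bg ← b̃_bg + b̃_SSH + b̃_DIP, and the *raw* phase is
   re-corrected with the new total. The measurement is never modified; all
   corrections are wrapped subtractions from φ̂, so no iteration can
   destroy data.

Five iterations are the default, with an optional early stop when the new
component falls below 1e-3 of the accumulated norm. The conventional
comparison pipeline is the same machinery in a single pass with
m_EA = m_max and no coherence masking.

**Susceptibility inversion.** χ minimizes
‖m_EA(b′ − χ*d)‖² + λ‖χ‖² + μ‖∇χ‖², where b′ = b/(f0·10⁻⁶) so χ is in ppm,
∇ is the forward-difference gradient with replicated-edge boundaries, and
χ is constrained to the mask support. No magnitude or spatial priors. The
defaults λ=0.03, μ=0.001 trade contrast against streaking; the
parameter-recovery checks use λ=μ=1e-4. Maps are reported mean-free over
the mask (phase carries no absolute susceptibility reference).

## Phantom

A 128³ head model at B0 = 7 T: a spherical brain support (radius 48
voxels, tissue χ = −9.0 ppm) containing three control spheres imitating
deep grey matter (R1/R2/R3 = tissue + 0.2/0.25/0.3 ppm, radius 6, near the
centre), surrounded by a tissue gap, a bone shell (radii 50–54,
χ = −0.9 ppm) and air (χ = 0.36 ppm). Two air cavities (radii 8 and 7) and
a blood bubble (radius 5, χ = −0.7 ppm) sit tangent to the brain sphere at
its inferior rim — sources *external* to m_max whose near fields corrupt
the rim phase, like sinuses and veins in vivo. Their positions (and the
background coefficients) are randomized per Monte-Carlo instance from a
recorded child seed.

The background field adds 5th-order solid harmonics with zero-mean
Gaussian coefficients (per-order standard deviations 1, 1, 2.5e-3,
1.25e-4, 1.25e-7, 1.25e-8; radial factor in voxel units, field in Hz).
The dipole field is f0·10⁻⁶·(χ*d) with f0 = 42.577 MHz/T × B0; field maps
are stored in Hz throughout. With uniform T2 = 80 ms, T2* =
1/(1/T2 + ‖∇b‖) inside the brain (central-difference gradient in Hz/voxel
read as a rate in 1/s — the natural reading for 1-voxel spacing) and 0
elsewhere, so steep gradients also dephase the magnitude. The signal
S(t) = M0·e^(−t/T2*)·e^(i·2π·b·t) is sampled at TE = 4, 16, 28, 40, 52 ms
with M0 = 1 in non-air structures and complex Gaussian noise of standard
deviation 0.01 per quadrature.

What the phantom does *not* emulate: anatomical geometry, flow and motion,
coil sensitivities, multi-channel phase combination, intra-brain
hemorrhage. Concentric spheres produce no internal field from the head
surface itself (a uniform sphere is field-free inside), so rim corruption
comes only from the explicitly placed rim structures — a cleaner, somewhat
easier setting than in vivo. Passing tests therefore demonstrate the
mechanism (restoration of externally corrupted rim phase), not performance
on anatomical data.

## Numerical choices

- Dipole kernel convention D(0) = 0: fields are mean-free over the grid;
  all comparisons are offset-corrected or contrast-based.
- FFT convolutions for *forward simulation* and the background fit are 2×
  zero-padded per axis (the r⁻³ tails otherwise wrap around). The QSM
  inversion operator is unpadded by default: its sources lie well inside
  the grid and a padded inversion changes the recovered control-region
  contrasts by under 2 percent at roughly 10× the cost; `QSMConfig.pad`
  enables it.
- Both solvers are conjugate gradients on the normal equations (symmetric
  PSD), tolerance 1e-6 on the relative residual; max 300 iterations for
  direct calls. Inside the restoration loop the external-source fit is
  capped at 150 iterations and uses single-precision FFTs: the background
  is consumed through a percent-level coherence threshold and does not
  require full convergence. Non-convergence returns the best iterate with
  a warning (suppressed where capping is deliberate).
- Unwrapping ties and exactness: the spatial unwrapper is exact up to one
  global 2πk on any field whose true neighbour differences stay below
  0.9π/voxel (property-tested); re-wrapping always reproduces the input to
  1e-9. The temporal alignment predicts each echo's reference phase by
  linear scaling of the previous echo (exact for φ = 2πbt).
- Degenerate inputs: empty masks, disconnected masks, negative echo times,
  regions overlapping the skull or leaving the grid, and thresholds that
  empty the evaluation area all raise informative errors; the restoration
  loop reports the failing iteration and threshold.
- Coherence boundary handling renormalizes by the available (in-mask)
  neighbourhood; without this, undefined exterior phase biases rim
  coherence downward and the evaluation area can never approach m_max.
- Sample (n−1) standard deviation for region statistics; 6-connectivity
  for components, erosion-based rim masks (6-connected structuring
  element, width 6 by default).

## Evaluation protocol and problem sizes

`refrase.evaluate.sweep` reproduces the study design — Monte-Carlo
instances × coherence thresholds × iterations (0 = conventional), with a
reconstruction and the metric set (n_rel = excluded fraction of m_max,
R1 mean and standard deviation, offset-corrected global and rim RMSE) per
cell — as a tidy table. The test suite runs this at the scaled-down
conditions (64³ grid, 2 instances, thresholds 0.6 and 0.9, 5 iterations);
parameter recovery through the inversion runs on the full 128³ noise-free
phantom. The scaled phantom keeps the printed susceptibilities, timing,
noise level and harmonic coefficient spreads and shrinks all radii with
the grid; because the harmonic coefficients multiply r^l, the scaled
background is smoother than at full size, while the rim dipole distortions
keep their ppm magnitude.

## Known limitations

- The external-source fit, like projection-onto-dipole-fields methods, can
  overcompensate within the last voxel or two at the mask edge; the σ=1
  smoothing and the m_EA ⊂ m_max margin mitigate but do not remove this.
- Very strict thresholds (Q_LC,min ≥ 0.9 here) permanently exclude steep-
  gradient rim regions; very loose ones admit noise-corrupted voxels that
  no physical background model can repair. 0.6–0.7 is the robust range on
  the phantom, matching the threshold guidance the method was designed
  around.
- The quantitative inversion checks need the full 128³ grid: at 64³ the
  control regions are only 3 voxels in radius and discretization fields of
  the ±9 ppm interfaces dominate their statistics.
- λ_ext = 1e-3 for the external fit is a package default chosen to
  suppress in-support sources without biasing the external fit; it is not
  taken from the method's original description, which leaves it open.
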