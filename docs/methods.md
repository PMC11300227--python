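# Methods

`hfevert` predicts the compressive strength and stiffness of metastatic
human vertebral bodies from CT-derived bone-volume-fraction (BV/TV)
fields with a damage-based homogenized finite-element (hFE) model, and
calibrates the material model against measured load–displacement
curves. This note records the model, its assumptions, the numerical
choices, and what the synthetic phantoms do and do not demonstrate.

## Constitutive model

The material point is a finite-strain rheological network. The
deformation gradient splits multiplicatively, F = F_ve · F_vp. The
viscoelastic part carries a Maxwell–Wiechert network: an equilibrium
hyperelastic branch (Saint-Venant stiffness on the Green–Lagrange
strain of F_ve, second Piola–Kirchhoff stress pushed forward to Cauchy)
in parallel with two deviatoric Maxwell branches representing low- and
high-rate viscous mechanisms (collagen-level and interstitial-fluid
effects). Branch i obeys

    eps'_dot = 3/(2 eta_i~) T_i + 3/(2 mu_i~) T_i_dot,

so its stress relaxes with time constant eta_i/mu_i under held strain.
Total Cauchy stress is the sum of the three branch stresses.

Every modulus is scaled by the tissue function

    TF(b) = b^k                                   for b <= 0.5
    TF(b) = b^k + (Emax - E0)/E0 ((b-0.5)/0.5)^2k for b  > 0.5,

the density–elasticity power law with a dense-bone correction branch
(continuous at b = 0.5), and degraded by (1 - D) where D in [0, 1] is
the scalar damage. The BV/TV factor is applied to the full isotropic
stiffness (shear and bulk); the source material typesets it on the
shear term only, but a density scaling of one Lamé constant alone has
no physical reading.

Viscoplastic flow is co-directional with the deviatoric Cauchy stress:
D_vp = (tau / (sqrt(3) S0_eff))^m N, where tau is the deviatoric stress
magnitude, N = T'/(tau sqrt 2) the unit direction (tr NᵀN = 1), m the
rate-sensitivity exponent, and S0_eff = S0 · TF · (1 - D). Two scalings
of the reference stress are deliberate model decisions:

* **TF-scaling.** Without it, a low-BV/TV element could never reach the
  flow regime (tau << sqrt(3) S0 at any attainable strain) and damage
  would be unreachable in trabecular bone; yield and flow must scale
  with density together.
* **(1 - D)-scaling (effective-stress concept).** Damage degrades the
  flow stress along with the stiffness. This is what makes the material
  genuinely soften — a stress–strain curve that peaks and descends —
  rather than merely plateau; it follows the strain-equivalence
  principle standard in continuum damage mechanics.

Flow is gated by a halfspacewise Hill criterion
Y = sqrt(S:F±:S)/(1 - D) - r(D), with the compression tensor selected
for tr S <= 0, axial terms 1/sigma0±², interaction terms -chi0±/sigma0±²,
shear terms 1/(2 tau0²), a leading 1/TF² factor, and isotropic fabric
(identity fabric tensors). The criterion is evaluated on the *corotated*
stress Rᵀ T R (R from the polar decomposition of F_ve): the surface is
anchored to material fabric axes, so frame indifference requires
removing the rigid rotation first. The division by (1 - D) places the
criterion in effective-stress space — without it, the hardening radius
r(D) = 1 - (1 - alpha) e^(-k_hard D) (starting at the yield-to-ultimate
ratio alpha and saturating at 1) would combine with stiffness
degradation to shut the gate exactly when damage accelerates. Below
yield the power-law flow is numerically negligible anyway (m ≈ 18), so
the gate's practical role is to guarantee an exactly rate-independent
elastic domain: kappa stays at the numerical floor (1e-12) for any time
step while Y < 0.

Damage is coupled to accumulated plastic strain kappa
(kappa_dot = sqrt(2/3) ||D_vp||) through a saturating law the source
family implies but does not print:

    D = 1 - exp(-zeta kappa),  zeta = 10 by default.

zeta = 10 gives gradual accumulation (D ≈ 0.5 near 7 % plastic strain),
appropriate for trabecular bone which fails progressively; much larger
values concentrate failure so sharply that the quasi-static solver
localizes immediately past the peak. D is non-decreasing by
construction and capped at 1.

### Integration scheme

* Maxwell branches: exact exponential integrator for a constant strain
  rate over the step. It agrees with the central-difference
  (Crank–Nicolson) update to second order for steps below the branch
  time constant and, unlike Crank–Nicolson, is free of ringing in the
  stiff limit dt >> eta/mu that quasi-static loading produces
  (relaxation times are sub-millisecond; solver steps are ~0.2 s).
* Plasticity: elastic predictor, then an implicit scalar return on the
  deviatoric stress magnitude (vectorized bisection, 64 halvings) with
  the flow direction frozen at the trial state; F_vp advances by a
  truncated-series exponential map, which preserves det F_vp to
  round-off for traceless flow. The update sub-steps automatically when
  the plastic increment exceeds 0.02 (capped at 25 sub-steps; points
  beyond D = 0.95 carry near-zero stress and are excluded from the
  refinement criterion).
* A corrector pass re-evaluates all stresses at the updated internal
  state; predictor-only results are returned in the purely elastic case.

Units are mm–N–s–MPa internally; moduli enter in GPa (eta02 in kPa·s)
and are converted once at the parameter boundary.

### Default parameters

The packaged reference set (data/default_params.toml) carries the
cortical-bone viscoelastic/viscoplastic constants E00 = 2.9, E01 = 0.78,
E02 = 4.18 GPa, eta01 = 0.24 MPa·s, eta02 = 0.40 kPa·s, S0 = 140 MPa,
m = 18.24. Constants the source does not tabulate are calibration
starting points, exposed in the file: nu = 0.3 (standard for
homogenized bone), k = 2 (elasticity–density power law), Emax = 10 GPa,
alpha = 0.78, sigma0⁻ = 140 MPa, sigma0⁺ = 0.62 sigma0⁻,
tau0 = 0.35 sigma0⁻, chi0± = 0.5, k_hard = 2, zeta = 10. The
calibration machinery — not these defaults — is what fixes material
behavior for a given specimen. eta_D is reserved for a viscous damage
regularization; only the rate-independent damage path is validated.

## Image-to-model pipeline

A density volume (HU or calibrated BMD in mgHA/cm³, voxel-center
convention, z craniocaudal) passes through: trilinear resampling to the
working resolution (0.3185 mm for clinical-resolution inputs; phantoms
are generated at their working resolution directly) → affine HU→BMD
conversion → inclusive threshold segmentation (390 mgHA/cm³ for
µCT-derived inputs; homogenized phantoms use a geometry threshold of
30 mgHA/cm³ since their trabecular mean BMD is ~120) → BV/TV =
clamp(BMD/1200, 0, 1) inside the mask → structured tetrahedral meshing
→ per-element BV/TV mapping.

The mesher covers the mask with cubic cells of the requested element
size (default 1 mm), keeps cells with voxel occupancy >= 0.5, and
splits each cube into six tetrahedra along its main diagonal (Kuhn
subdivision — conforming across cells and volume-exact). This replaces
unstructured meshing with topological optimization: it is
deterministic, dependency-free, and supports the element-size study;
externally produced meshes can be imported through the VTK reader.

Element BV/TV is the mean of five trilinear probes per tet (centroid
and centroid–vertex midpoints), restricted to probes that land on bone
(BV/TV > 0), floored at 0.01 so no element is void of stiffness. The
mask restriction mirrors interpolation of a segmented-and-masked image:
a coarse boundary element draws its density from the bone it overlaps —
including a thin cortical shell — instead of being diluted by
background. For a spatially linear field the probe mean equals the
centroid value exactly.

## Quasi-static FE solution

Linear tetrahedra with one quadrature point; total-Lagrangian internal
force f = V0 P ∇N with P = J sigma F⁻ᵀ, so the residual is
geometrically nonlinear. Boundary conditions reproduce a
plane-parallel-section compression test: caudal surface encastre,
cranial surface given a monotonically increasing axial displacement at
5 mm/min (in-plane cranial motion free by default, mirroring a
ball-jointed platen; 'clamped' is available and makes a single-cube
mesh an exact uniaxial-strain patch test). The reaction is the sum of
internal-force residuals over the cranial nodes, reported in kN.

The nonlinear solve is a modified Newton iteration: the tangent is a
per-element isotropic secant stiffness E00 · TF · (1-D) · phi, where
phi is the scalar return-map derivative (1 in the elastic domain),
refreshed at a fixed iteration schedule and factorized sparsely.
Geometric stiffness is omitted from the tangent — convergence is judged
on the residual (relative infinity-norm <= 1e-5 of the reaction scale),
so the equilibrium path is unaffected by the tangent approximation.
Aitken relaxation accelerates the linearly convergent iteration, and a
residual watchdog damps it when successive iterates flip between
plastic/elastic trial sets near the force peak. Increments halve
adaptively on failure (growing back only after three clean successes)
and the run ends in one of three ways: the displacement protocol is
exhausted; a quadrature point reaches the full-damage threshold
(1 - 1e-9 by default — under the saturating damage law this is
asymptotic and reached only under extreme localized flow, so the
threshold is configurable); or no equilibrium exists within tolerance
at the minimum increment. The last case is structural failure under
displacement control (snap-back after damage localization): the solver
reports the partial curve, whose final point is the failure
displacement. Strength is the maximum force on the curve; stiffness is
the regression slope over the 20–80 % force sub-window of the elastic
region, with the region's end detected where the local tangent first
drops below half its running peak.

## Calibration

**Specimen-specific.** Two proportional families follow the study's
protocol: s_E multiplies all branch moduli (and the branch viscosities,
with an extra fixed 1/100 to suppress rate effects in quasi-static
runs); s_S multiplies the strength family sigma0±, tau0 — and S0. The
inclusion of S0 in the strength family is a deliberate deviation from
treating it as untouched: with power-law flow the stress plateau (hence
strength) is set by S0, so a strength-driven calibration that cannot
move S0 would be inoperable. Non-dimensional constants (m, chi0±,
alpha, zeta) stay fixed. Iteration: stiffness mismatch drives s_E,
strength mismatch drives s_S, multiplicatively, with step damping on
RMSE overshoot; termination at curve RMSE <= 5 % of the reference peak
force (the study's own stopping rule) or 50 forward evaluations.

**Global.** One parameter set across specimens. The objective is
Obj = λ·RMS(e) + (1-λ)·SD(e) with λ = 0.5, where e_i is the
trapezoid-rule integral of |F_sim - F_ref|/F_ref up to the reference
failure displacement (the integrand is taken in absolute value: an
error functional must be non-negative; "RMSE" in the combination is
read as the root mean square of the per-specimen errors, and SD is the
sample standard deviation). The optimizer Latin-hypercube samples the
scale box spanned by the per-specimen calibrations, scores each sample
with the true objective, trains a feed-forward surrogate network
(hidden layers of 20 and 10 units, tanh activations, L-BFGS,
standardized inputs/outputs, 80/20 train/validation split,
deterministic under a fixed seed), runs projected gradient descent on
the surrogate from the best samples (three restarts;
finite-difference input gradients — the surrogate is smooth and cheap,
so this is as accurate as analytic differentiation at these step
sizes), and accepts a proposal only if its true objective improves on
the best sample. The surrogate is implemented with scikit-learn's
MLPRegressor; it only ever interpolates the objective landscape — every
reported number comes from true forward evaluations.

## Synthetic phantoms

A phantom is an elliptic-cylindrical vertebral-body section
(plane-parallel faces, as in cadaver tests): a cortical shell
(thickness 0.8 mm, BV/TV 0.8) around a trabecular interior whose BV/TV
is a correlated Gaussian random field (correlation length 2 mm),
standardized over the trabecular compartment so the target mean and SD
are met exactly there, then clipped to [0.005, 0.95]. Default
trabecular BV/TV is 0.10 ± 0.03, matching the osteolytic-to-
osteosclerotic range of the study population (9–13 %). Lesions carve
the interior: osteolytic (L) sets connected "moth-eaten" blobs — the
top fraction of a second correlated field — to BV/TV 0.02 (below the
meshing threshold, so lytic voids also remove geometry); osteosclerotic
(S) raises blobs to BV/TV 0.85 (near-solid plates); mixed (M) applies L
anteriorly and S posteriorly. BMD = BV/TV × 1200 mgHA/cm³ plus Gaussian
noise (default SD 5 mgHA/cm³). Everything is deterministic per seed.

The default *mini vertebra* is 8.4 × 6.0 × 10 mm at 0.5 mm voxels,
meshed at 1 mm into ~2.6 k tetrahedra — a desk-scale stand-in sized so
a forward solve takes tens of seconds and the full calibration
demonstration minutes. Phantoms emulate the statistical structure of
homogenized vertebral sections (density distribution, shell, lesion
connectivity); they do not emulate anatomical shape (endplate
curvature, posterior elements), real trabecular architecture or
anisotropy, scanner noise spectra, or the size of real vertebrae.
Passing phantom tests therefore demonstrates correctness of the
pipeline and the model mechanics, not clinical accuracy on real scans —
the study's cadaver-validation statistics (R² against measured strength
and stiffness) require the original scans and are out of reach here.

### Known limitation: the coarse half of the mesh-size study

On real vertebrae the study found 2 mm meshes to overestimate strength
and stiffness (conforming meshes thicken the cortex at coarse
resolution) and 0.5 mm meshes to underestimate them (fine meshes
resolve weak pockets, localize damage and soften). The fine half
reproduces on the seeded phantom (1 mm predicts higher strength than
0.5 mm). The coarse half does not: with a structured voxel-occupancy
mesher on a body only ~8 mm wide, 2 mm cells quantize the cross-section
and drop partial boundary cells, under-representing the thin shell
instead of thickening it. Reproducing the coarse-mesh bias requires
element size << body width — a body of tens of millimetres — whose
0.5 mm mesh (>100 k elements) is beyond the intended desk-scale test
sizes. The corresponding regression test asserts the full published
ordering and is expected to fail on the 2 mm vs 1 mm comparison; the
generator was not adjusted to mask this.

## Problem sizes used in tests and the acceptance script

Chosen as the package's own desk-scale conditions: mini-vertebra
calibration (t-style acceptance) — ~2.6 k elements, 1 mm mesh,
1 mm total compression in 0.03 mm increments, reference at scales
(s_E, s_S) = (1.3, 0.8), calibration from (1, 1); lesion-type ensembles
— five seeds per type on 6 × 4.4 × 7 mm phantoms; mesh-size study —
2/1/0.5 mm on the seeded mini vertebra to 0.5 mm compression. The
calibration demonstration converges in 2–3 forward evaluations at a
final RMSE well under the 5 % stopping rule, recovering the generating
scales to within ~7 %.

## Degenerate inputs and tie-breaks

Hydrostatic stress has no deviatoric direction: N is the zero tensor
when tau is at round-off level. Thresholding uses the inclusive
convention (>= threshold). Single-record statistical groups report
SD = 0 with a flag. Zero-variance predictors, empty masks, disjoint
curve ranges, non-positive element volumes and inverted deformation
gradients raise typed errors. The stiffness window requires at least
two samples and a nonzero force signal. RMSE normalization uses the
reference peak, so the metric is asymmetric under operand exchange by
the ratio of peaks (documented behavior, not a bug).
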