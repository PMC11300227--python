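# hfevert

Damage-based homogenized finite-element (hFE) prediction of the
compressive strength and stiffness of metastatic human vertebral
bodies from CT-derived bone-volume-fraction fields.

Spinal metastases remodel vertebral bone into osteolytic (rarefied,
"moth-eaten"), osteosclerotic (densified, plate-like) or mixed
patterns, and with them the risk of pathologic vertebral fracture.
`hfevert` is for biomechanics researchers who want to simulate the
quasi-static compression of such vertebrae from calibrated density
images: it converts a voxel volume into a tetrahedral mesh whose
elements carry a local bone volume fraction (BV/TV), runs a
displacement-controlled nonlinear FE compression with an
elastic–viscoplastic–damage material at every quadrature point, and
extracts strength and stiffness the way a mechanical test would.
Because real specimen scans are rarely shareable, the package ships a
synthetic vertebra generator with known ground truth so the entire
pipeline — including both calibration modes — is exercisable end to
end.

## Model

At each material point the deformation gradient splits into
viscoelastic and viscoplastic parts, **F** = **F**ᵥₑ·**F**ᵥₚ. The
viscoelastic part is a Maxwell–Wiechert network: an equilibrium
hyperelastic branch (modulus E₀⁰) in parallel with two deviatoric
Maxwell branches (E₀¹/η₀¹ low-rate, E₀²/η₀² high-rate); the total
Cauchy stress is the sum of the branch stresses, T = Tᴱ⁰ + Tᴱ¹ + Tᴱ².
All moduli scale with the tissue function
TF(ρ) = ρᵏ (+ dense-bone correction above ρ = 0.5), ρ = BV/TV, and
degrade with the scalar damage D ∈ [0, 1].

Viscoplastic flow is co-directional with the deviatoric stress,
**D**ᵥₚ = (τ/(√3·S₀·TF·(1−D)))ᵐ **N**, gated by a halfspacewise Hill
criterion Y = √(S:𝔽±:S)/(1−D) − r(D) with damage hardening
r(D) = 1 − (1−α)e^(−kD). Damage grows with accumulated plastic strain
κ as D = 1 − e^(−ζκ), so the material yields, softens and eventually
fails. Strength is the maximum force on the simulated
load–displacement curve; stiffness is the regression slope over the
20–80 % force window of its elastic region.

Material constants are calibrated per specimen by proportionally
adjusting an elastic family (s_E) and a strength family (s_S) until
the simulated curve matches a measured one within 5 % normalized RMSE,
or globally across specimens by surrogate optimization (a small
feed-forward network over the scale space, minimizing
Obj = λ·RMS(e) + (1−λ)·SD(e) with λ = 0.5 over per-specimen
trapezoid-rule curve errors).

See `docs/methods.md` for the full formulation, numerical choices and
known limitations.

## Worked example

Simulate the seeded osteosclerotic mini-vertebra phantom (≈2.6 k
tetrahedra, 1 mm elements) under compression at 5 mm/min:

```python
import hfevert as hv
from hfevert.phantom import fixture_suite, make_phantom, phantom_to_mesh
from hfevert.solver import LoadProtocol, solve_quasi_static

spec = fixture_suite()["mini_vertebra_S"]      # seeded osteosclerotic phantom
mesh = phantom_to_mesh(make_phantom(spec), element_size=1.0)
params = hv.default_parameters()
protocol = LoadProtocol(max_displacement=1.0, displacement_rate=5.0,
                        increment=0.03)
result = solve_quasi_static(mesh, params, protocol)

print(f"elements: {mesh.n_elements}")
print(f"stop reason: {result.stop_reason}")
print(f"strength:  {result.strength_kN:.3f} kN")
print(f"stiffness: {result.stiffness_kN_per_mm:.3f} kN/mm")
print(f"final max damage: {result.damage[-1].max():.3f}")
```

prints

```
elements: 2580
stop reason: non_convergence
strength:  2.912 kN
stiffness: 3.538 kN/mm
final max damage: 0.862
```

The phantom supports 2.9 kN before failing: damage accumulates in its
weakest elements until no equilibrium exists under further imposed
displacement (`non_convergence` is the displacement-control signature
of structural failure; the curve up to that point is returned). The
stiffness, 3.5 kN/mm, is the slope of the curve's elastic region. A
specimen-specific calibration against a measured (or synthetic
reference) curve then looks like:

```python
from hfevert.calibrate import specimen_calibrate

def forward(p):
    return solve_quasi_static(mesh, p, protocol, record_fields=False).curve

calib = specimen_calibrate(forward, reference_curve, params, tol=5.0)
# calib.scales.s_E, calib.scales.s_S, calib.rmse (percent of ref peak)
```

A thin CLI wraps the same functionality:

```sh
hfevert phantom --type S --seed 3 --out vol.nii.gz --mesh-out mesh.vtk
hfevert simulate --mesh mesh.vtk --rate 5 --max-disp 1.0 --out out/
hfevert evaluate --sim out/curve.csv --ref measured.csv
hfevert calibrate-specimen --ref measured.csv --mesh mesh.vtk --out scales.json
```

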