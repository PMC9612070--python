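# Methods

## Physical model

The package computes the free-energy trajectory of stalk formation between a
lipid-droplet **monolayer** and a peroxisome **bilayer**, and of the
subsequent radial expansion of the fused contact into a π-shaped structure
(pexopodium precursor). Three energy contributions are kept:

1. **Elastic deformation** of the monolayer in the Hamm–Kozlov tilt/bending
   framework. The state is two axisymmetric fields, director projection
   n(r) and neutral-surface height h(r); to quadratic order the density is

       w_e = 2πr [ B/2 (n' + n/r + J_s)² − B/2 J_s²
                   + K/2 (n − h')² + σ̃/2 h'² ].

   Lateral stretching, Gaussian-curvature and bilayer-midplane coupling
   terms are excluded by construction — the model deliberately keeps only
   bending and tilt.

2. **Hydration repulsion** between the dimple and the facing membrane,
   exponential in the local water gap with decay ξ_h and zero-separation
   pressure P₀, integrated over the dimple footprint with the membrane
   shape replaced by a plane. The energy is referenced to the initial flat
   state at separation H₀ (it vanishes there by construction).

3. **Hydrophobic attraction** between facing tail-exposed defects of radius
   ρ, rising from zero at contact to the bare cost 2πρ²σ₀ of two exposed
   patches over the decay length ξ_f.

The bilayer partner is treated as rigid in monolayer–bilayer mode; the
symmetric bilayer–bilayer reference case reuses the same monolayer energies
with weights 4·W_e (dimple stage) and 2·W_e + 2·W_e2 (defect stage), gap
H₀ − 2H and stalk contact at H = H₀/2.

## Closed-form elastic energies

The Euler–Lagrange equations of the functional admit, in each force-free
region, solutions built from first-order modified Bessel functions of the
scaled radius r/λ, λ = l√((1+σ)/σ), l = √(B/K). Two configurations are
solved:

* **Dimple** (radius R, apex height H): regular interior solution on
  [0, R] stitched continuously (in n and h) to a decaying exterior solution
  on [R, ∞) with the apex held at height H. Eliminating the constants gives

      W_e = πK H² (R/l) σ^{3/2} √(1+σ)
            · I₁K₁ (I₁K₀ + I₀K₁) / [I₁K₀ + (I₀−1)K₁]²,

  all Bessel functions at R_σ = (R/l)√(σ/(1+σ)). W_e ∝ H² exactly, and the
  J_s-linear boundary terms of the two regions cancel because n is
  continuous at the stitch — the dimple energy is independent of
  spontaneous curvature.

* **Defect rim** (radius ρ, rim height H): only the decaying exterior
  solution exists; the rim is held at h(ρ) = H with a free director. The
  J_s rim term survives:

      W_e2 = πK H (ρ/l) √(σ(1+σ)) (2 J_s l² + Hσ) · K₁(ρ_σ)/K₀(ρ_σ).

  For J_s < 0 this is negative — the rim relaxes curvature frustration —
  which is what allows the defect branch to undercut the dimple branch and
  makes the monolayer–bilayer stalk metastable (W_e2 at contact ≈ −4 k_BT
  for the DOPC parameter set at H₀ = 3 nm).

Both expressions are evaluated with exponentially scaled Bessel functions
(`i0e/k0e` families), so they remain finite at arbitrarily large radii.

## The numeric oracle (and why it is a BVP solve, not a free minimisation)

`numeric_shape_solver` and `numeric_defect_solver` validate the closed forms
independently: they solve the reduced Euler–Lagrange system per region,

    n'' = −n'/r + n/r² + σ/((1+σ)l²) n,    h' = n/(1+σ),

with a generic collocation method (`scipy.integrate.solve_bvp`; no Bessel
functions anywhere on this path), stitch the regions by linearity, and
integrate the full energy density by quadrature. Agreement with the closed
forms is ~0.2%, dominated by domain truncation.

A free minimisation of the discretised functional subject only to the apex
constraint h(0) = H would *not* reproduce the model: in that problem the
stationarity conditions force zero vertical ring force everywhere and the
minimiser's energy decouples from H entirely. The stitched construction
instead carries a concentrated force and torque at the dimple edge r = R
(physically: the lumped hydration push), which is not a stationarity
condition — so the correct numeric counterpart is the boundary-value
problem with the construction's own matching conditions, solved exactly as
the closed form was derived.

Numerical choices: interior grid geometric from r_min = 10⁻³ nm (the
regular solution behaves as n ∝ r there; the boundary condition
n'(r_min) = n(r_min)/r_min selects it); exterior domain to
r_max = max(50 l, 6 λ) (λ ≈ 31.6 nm at σ = 0.001, so truncation error
~e^{−12}); collocation tolerance 10⁻¹⁰; Simpson quadrature on 6000 points.
Doubling r_max moves the energy by < 0.5%.

## Trajectory assembly and barrier location

* At each H on a uniform grid (default 400 points) the dimple branch
  minimises W_e-weighted elastic plus hydration energy over R with a
  bounded scalar minimiser (tolerance 10⁻⁴ nm) on R ∈ [10⁻³, 15] nm.
  The lower edge is a *numerical floor*, not a physical bound: the model's
  optimal radius genuinely → 0 as H → 0, because hydration grows as H·R²
  while the elastic cost falls as H²; energies there are ≈ 0 and the
  floor has no effect on the barrier. The upper edge is physical (dimples
  are nanometric) and reaching it raises an error rather than silently
  clamping, since ρ = R_min feeds the defect branch.
* The defect branch reuses ρ = R_min(H) ("the defect replaces the dimple").
* The crossing is the smallest H with W₂ ≤ W₁, refined by bisection on the
  exactly recomputed branch difference to 10⁻⁴ nm; the barrier is E = W₁(H*).
  Doubling the H grid moves E by < 0.1 k_BT.
* H = 0 is special-cased: W₁ = 0 exactly (no deformation, no excess
  hydration) and the reported radius is the small-H continuation.
* Everything is deterministic; identical inputs give bit-identical profiles.

## Parameters

| symbol | meaning | unit | DOPC | DOPC:DOPE 1:1 |
|---|---|---|---|---|
| B | monolayer bending modulus | k_BT | 10 | 10 |
| K | tilt modulus | k_BT/nm² | 10 | 10 |
| J_s | spontaneous curvature | nm⁻¹ | −0.1 | −0.25 |
| σ | dimensionless tension σ̃/K | — | 0.001 | 0.001 |
| P₀ | hydration pressure at contact | k_BT/nm³ | 800 | 60 |
| ξ_h | hydration decay length | nm | 0.235 | 0.37 |
| σ₀ | hydrophobic patch energy | k_BT/nm² | 12.5 | 12.5 |
| ξ_f | hydrophobic decay length | nm | 1 | 1 |
| H₀ | initial separation | nm | 2–4 (default 3) | — |

All energies are k_BT and all lengths nm throughout; σ̃ = 0.01 k_BT/nm²
corresponds to ≈ 0.04 mN/m at 300 K (explicit converters are provided,
nothing converts implicitly). σ below 10⁻⁶ raises: the closed forms
degenerate in the tension-free limit and the working value is 10⁻³.
Composition interpolation between the two presets is linear in DOPE mole
fraction in (J_s, P₀, ξ_h) — a convenience anchored at exactly two points,
not a claim; extrapolation above 0.5 warns and raises once P₀ would turn
negative (at fraction ≈ 0.54).

## π-structure expansion

The transition zone between the fused membranes is approximated as a
cylinder of height H₀ whose mean curvature combines ~1/R (equatorial) and
−1/H₀ (meridional); only bending is kept (tilt is negligible in this
regime). The energy is linear at large R with slope πB(2H₀J_s + 1)/H₀, so
expansion is favorable iff J_s < −1/(2H₀) — at H₀ = 2.5 nm the threshold
is −0.2 nm⁻¹, between pure DOPC (−0.1) and a 1:1 DOPC:oleic-acid mixture
(−0.4). The domain of validity is R > H₀; the stalk-to-π transition at
small radii and its modest barrier are outside the model, as are
pexopodium shape, tubular "gnarl" morphology and fatty-acid partitioning
kinetics.

## Chain coordinate

ξ_ch is the fraction of 0.1 nm axial slices of a user-specified cylinder
that contain at least one bead. Slice intervals are half-open
[sΔ, (s+1)Δ) from the base, points exactly on the far cap excluded, so
counting is deterministic. Inputs are assumed unwrapped point sets (no
periodic boundaries): this is a reference implementation for testing and
teaching, not a trajectory-analysis engine, and the cylinder radius is a
required input. The smooth indicator n/(n + w) is provided because biased
dynamics needs a differentiable switch; it recovers the hard indicator as
w → 0 but reaches 1 only asymptotically in the bead count.

## Synthetic fixtures and what passing tests show

The fixture generators place random bead slabs (seeded PCG64) with an
exactly known number of empty slices, optionally bridged by an on-axis
column, so the chain coordinate of every fixture is known by construction
arithmetic. They emulate only the *geometry* of a membrane gap — two
occupied regions and a void — not bead chemistry, lipid packing, density
profiles or thermal disorder. Tests passing on these fixtures therefore
establish the correctness of the slice bookkeeping and invariances, not
the behaviour of ξ_ch on real coarse-grained trajectories.

## Known limitations

* The two-stage decomposition assigns hydration only to the dimple stage
  and hydrophobic attraction only to the defect stage, by construction.
* The DOPC:DOPE barrier reduction shrinks with H₀ and inverts by ~0.2 k_BT
  (well below the model's meaningful resolution) for monolayer–bilayer
  fusion at H₀ ≤ 2.1 nm: the mixture's weaker hydration also weakens the
  push that lets the defect open early. Quoted barrier differences should
  be read at the integer-k_BT level.
* Barriers are continuum estimates with integer-k_BT reliability at best;
  molecular detail (stalk hydration structure, tail protrusions) is outside
  the theory.
* No hemifusion-diaphragm or fusion-pore stages: the trajectory ends at the
  stalk, and the π-structure module takes over only at R > H₀.
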