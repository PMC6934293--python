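# Methods

## Scope and model overview

`coildeploy` simulates endovascular coil embolization of intracranial
aneurysms. An embolic coil is a multiscale device: a platinum-alloy stock
wire of diameter D1 wound tightly into a helical "secondary" tube of outer
diameter D2, which is heat-set on a shaped mandrel into a 3D "tertiary"
pre-shape of envelope diameter D3. Treatment has three mechanical steps —
packaging (the coil is pulled from its pre-shape into a delivery catheter),
advancement (it is pushed along the catheter placed on the parent-artery
centerline), and deployment (it is pushed out into the aneurysm sac, where
it tries to recover its pre-shape). The package models each stage
explicitly and quantifies the resulting intra-aneurysmal coil distribution
on cross-sections.

Two modelling pathways are configurable: the *spring-calibrated* pathway
(mandrel-wound pre-shape, equivalent spring moduli, explicit advancement)
and a *stiff baseline* pathway (parametric spherical-spiral pre-shape,
platinum wire moduli E = 230 GPa / G = 82 GPa, a straight catheter placed
perpendicular to the neck, no advancement) for A/B comparison.

## Spring-equivalent beam properties

The secondary structure is geometrically a helical spring, so beam elements
representing the coil receive elastic moduli obtained by equating beam
rigidity to helical-spring rigidity. With tight winding (pitch = D1, coil
length l = n·D1 for n wire loops):

    D_compressive = Gw D1^4 l / (8 n D2^3)          [N]
    D_shearing    = Ew D1^4 l / (8 n D2^3)          [N]
    D_flexural    = Ew Gw D1^4 l / (16 n D2 (2Gw + Ew))   [N mm^2]

and `Eb·Ab = D_compressive`, `λ·Gb·Ab = D_shearing`, `Eb·Ib = D_flexural`.
The axial and flexural equations overdetermine Eb for any fixed beam
section, and no single section convention reproduces both published example
moduli of the bare platinum coil simultaneously, so section conventions are
explicit configuration (`ANNULUS_OUTER_D2`, `ANNULUS_AROUND_D2`,
`SOLID_D2`). The default calibration takes Eb from the flexural equation
with the annulus laid *around* D2 (coil looping is bending-dominated),
giving Eb = 1.506e-3 GPa (0.9 % from the published 1.52e-3 GPa), and Gb
from the shear equation with a solid-D2 disc and shape factor λ = 0.75,
giving Gb = 1.843e-3 GPa (0.4 % from 1.85e-3 GPa). Both Eb candidates are
recorded on every `EquivalentMaterial` for transparency. The equivalent
moduli are about five orders of magnitude below platinum — the essential
physical difference from the stiff baseline.

Mass: the effective beam density makes beam mass per unit length equal the
physical coil's, `ρ_w (π/4 D1²) π(D2−D1)/D1 / Ab` ≈ 0.512 mg/mm for the
bare platinum dimensions.

## Virtual manufacturing of the pre-shape

The mandrel is a main cylinder of diameter D3 − 1.5 mm carrying cross-axis
cylinders of diameter D3; cross-cylinder count, spacing, and azimuths are
free parameters because real designs are proprietary. The default mandrel
uses two cross cylinders spaced 1.2·D3 apart with azimuths 90° apart.

Winding is computed analytically rather than by CAD spline projection.
Every segment lies exactly on a cylinder surface: main-axis helices, and
one half-turn pass over each cross cylinder that runs from the *bottom
junction point* (where the main and cross surfaces meet) over the pin to
the *top junction point*, with a radial excursion amplitude above the coil
diameter. Because consecutive segments hand over at junction points with
azimuthal tangents on both sides, the curve is position-continuous exactly
and tangent-continuous to within a few degrees (asserted < 10° in tests);
exact C¹ joins across two intersecting cylinders have no closed form, and
the physical coil tolerates curvature jumps. The winding handedness
alternates after each pass — a property of junction-connected half-turn
passes, not a free choice. The approach helix before each cross cylinder is
re-solved (fractional turns, pitch never below D2) to land on the junction.
Self-intersection of the inflated tube (minimum distance between
non-adjacent centerline segments ≥ D2) is checked for every shipped
pattern; a 1.5-turn out-and-back wrap provably must self-intersect, which
is why the default is a half-turn pass.

The parametric baseline pre-shape is a spherical spiral on a sphere of
diameter D3 whose winding number is solved (Brent root find) so the arc
length equals the coil length; it is a documented stand-in family, not a
reproduction of any published parametric coil equations.

Discretization samples the curve at equal arc-length intervals h (default
h = D2 ≈ 0.29 mm; the reduced test protocol uses h = 0.5 mm for speed).

## Synthetic vascular geometry

Idealized cases avoid any dependence on patient data: a spherical sac of
diameter Ds on a tubular parent artery of diameter Dv.

* *Sidewall*: the sac centre sits above the vessel so the sphere dips a
  configurable fraction (default 0.3·Rs) into the tube surface. The orifice
  contour is the exact sphere ∩ tube-surface curve (per-azimuth Brent root
  solve), the sac mesh is a UV sphere trimmed exactly along that curve, and
  the neck cover is a centroid fan across the (non-planar) contour. Sac
  surface + neck cover form a watertight closed region.
* *Terminal*: the sac caps the vessel end; the orifice is a planar circle
  of radius Rv and the cover is a flat disc.

No mesh boolean engine is used; containment queries are analytic for
synthetic cases (sphere interior), with mesh ray-parity (vectorized
Möller–Trumbore over all faces) as an independent cross-check. The
catheter is a swept tube of inner radius D2 (twice the coil radius) along
the truncated centerline, proximally extended by one coil length; the
centerline is truncated so the upstream length is at least the longest
coil. For sidewall cases the distal few millimetres of the catheter path
bend smoothly (quadratic Bézier) through the orifice so the tip points into
the sac, the usual clinical microcatheter position; the curvature radius is
checked against the tube radius.

## Explicit rod dynamics

The coil is a discrete shear-deformable (Timoshenko/Cosserat) rod: node
positions plus per-element unit-quaternion material frames. Strains are
`Γ = Rᵀ(x_{j+1}−x_j)/h − e₃` (stretch/shear, stiffness
diag(λGbAb, λGbAb, EbAb)) and `Δκ = log(r₀⁻¹ q_{j−1}⁻¹ q_j)/ĥ`
(bending/twist, stiffness diag(EbIb, EbIb, GbJ)) measured against the
pre-shape rest state — the shape memory that drives deployment. Bending
torques apply the exact transposed inverse right-Jacobian of SO(3) so they
are exact gradients of the strain energy (the first-order approximation
measurably pumps energy), with the upstream edge receiving the exact
world-frame opposite. Clamped ends add a ghost-frame bending site at half
element weight, which restores second-order accuracy of cantilever
deflections.

Integration is the central-difference rule with lumped masses. Rotary
inertias are uniformly inflated (×3 by default), a routine explicit-code
conditioning that leaves the quasi-static response unchanged. Rayleigh
damping uses the mass (α) and stiffness (β) terms, defaults α = 1 s⁻¹,
β = 1e-6 s; stiffness damping is applied at element level on strain rates
so no stiffness matrix is ever assembled. The stable time increment follows
the per-element highest-frequency estimate
`Δt = safety · min_e (2/ω_e)(√(1+ξ_e²) − ξ_e)` over axial/shear wave,
rotational, and contact-penalty frequencies, with ξ_e the damping fraction
at ω_e.

Contact is penalty-based: normal force k_n·δ at tube penetration δ with
k_n = 10·EbAb/D2 per node (tangential stiffness a tenth of that), a hard
one-sided law with zero force at zero gap, plus a normal dashpot (0.3 of
critical, included in the stable-step estimate) that absorbs impact energy
so fast nodes cannot tunnel through the thin contact band. Rigid-surface
penalties are unsaturated during drives — the wall must always beat
transient fold pressure — while coil self-contact saturates at half the
coil radius, and a gentler saturated law is used only while the posed
pre-shape settles into the loading funnel. Friction is an anchor-spring
clamped at μ|N| (stick–slip), with μ = 0 for coil–catheter (lubricated),
0.2 coil–coil, 0.6 coil–sac. Rigid surfaces are analytic
where possible (swept-tube interior by point-to-polyline projection with a
conical entry funnel, spherical sac cavity, neck-cover band) — far cheaper
and more robust than mesh contact at these scales — and triangulated
barriers (vectorized node-vs-triangle closest point) support imported STL
geometry. Coil self-contact tests all non-adjacent segment pairs (O(n²),
fine at protocol sizes). Tube contact only acts on nodes actually inside
the tube: nodes radially beyond the wall (a released tip curling back
alongside the catheter) and nodes past the distal tip are free.

### Energy ledger

The ledger is an exact discrete audit: the work of every force group is
integrated over the actual displacement increments, conservative
(beam + penalty) contributions are reconciled lazily against the stored
energy change, and the central-difference velocity-form loss
½m|Δv|² is tracked explicitly. The balance
`W_ext = Δ(K+U+P) + D_damping + D_other` then closes to a fraction of a
percent through packaging; `D_other` carries stiffness-viscous, friction,
and discrete contact-switching losses. Dissipated damping work is monotone;
an instability detector aborts on explosive kinetic-energy growth.

### Scaled quasi-static runs

Tests and the reduced protocol scale the density uniformly (×50) to
enlarge Δt and damp with α = 30 s⁻¹ so the added inertia dissipates within
each drive ramp; only energy ratios and containment are asserted in scaled
runs, never absolute dynamics. Driving speeds are set to a few percent of
the (scaled) shear wave speed, keeping kinetic energy far below strain
energy. With unscaled platinum moduli the same solver runs but needs far
smaller steps — the stiff baseline pathway is exposed for configuration
and geometric checks rather than routine dynamic tests.

## The three mechanical steps

*Packaging* pre-settles the posed pre-shape against the loading funnel
(a 40° conical chute before the tube mouth, with the tip held), resets the
energy ledger to a clean baseline, then pulls the distal node along the
catheter path by a smooth-step (quintic, C²) displacement of amplitude
equal to the coil length; simultaneously the trailing end is fed along a
straight line to the mouth, arriving as packaging completes, which keeps
the coil taut and single-file (unguided feeds let loops cross inside the
2×-clearance tube and lock). A backstop plane at the mouth — the pusher
wire — keeps the tail from relaxing back out during the final settle.
Packaged node centers stay within the tube's inner radius (2 % slack), the
protocol's containment bound. *Advancement* pushes
the proximal node by the catheter centerline arc length; the amplitude is
corrected by the discrete coil tip's actual arc position so the tip lands
at the orifice end of the catheter within one element. A pushed coil
partially relieves its straightening energy by spiralling against the tube
wall — real pushed coils do the same — and a settled bend configuration can
even undercut the straight one when the bend curvature part-matches the
coil's natural curl. Bend loading is therefore quantified by the *peak*
strain during the advancement drive, which is robustly larger through a
curved artery than a straight one (asserted in the tests). *Deployment*
pushes until the coil is fully released, at half the packaging speed (a
faster push kinks the emerging coil against the already-deployed loops),
with the pusher guiding the coil end a short way (0.3·Rs) past the
catheter tip into the sac so release does not occur right at the mouth.
Release sheds strain: deployed strain is below the strain at the onset of
release (end of advancement) as the coil recovers its pre-shape.
The neck cover acts as a one-sided barrier for released nodes only (the
balloon/stent surrogate is active during deployment, and the catheter
crossing the orifice must not fight it); after release a free settle phase
runs until kinetic energy is below 10⁻³ of strain energy.

Ensembles rotate the pre-shape coaxially about the catheter axis in 40°
increments (9 runs); full rotations are exact identities so θ = 0 and
θ = 360° reproduce bit-identical runs. Multi-coil plans run the three steps
sequentially per coil with earlier coils frozen as rigid capsule-chain
contact bodies — the cheaper of the two readings of "left in place as
contact bodies"; fully deformable earlier coils would require simultaneous
multi-chain integration.

## Cross-section metrics

Five section planes 1 mm apart are placed perpendicular to the dome→neck
axis starting one spacing below the dome apex. Rasterization marks a pixel
black when its 3D centre lies within D2/2 of any deployed centerline
segment — exactly the swept-tube/plane intersection — at default
resolution D2/8 ≈ 0.037 mm/px, masked by the sac outline of the *first*
section. Coil density CD is the black fraction inside the mask. Lacunarity
uses the gliding-box statistic: for each box size r the r×r window slides
over every position inside the mask bounding box, Λ(r) = σ²/μ² + 1 over
window masses, and L is the arithmetic mean over a power-of-two size
series up to 45 % of the bounding box (single top-left anchored grid; an
all-empty image has L = 1 by convention). Aneurysm-averaged (CD, L) points
are standardized per coordinate (z-scores over the pooled set), and
simulated ensembles are compared to a reference point by dMin/dMax over the
individual distances and dAvg to the ensemble centroid (which may undercut
dMin); group comparisons run Shapiro-Wilk, Levene, and Student's t-test
with equal variances assumed when Levene does not reject, at α = 0.05.

## What the synthetic conditions do and do not show

The synthetic generator reproduces the protocol's geometry and mechanics at
reduced scale (5 mm spherical sac, straight 3 mm parent vessel, one
5 mm × 20 mm coil, h = 0.5 mm elements), which keeps the full 9-rotation
ensemble within minutes on one core. It does not reproduce patient-specific
lumen shapes, vessel compliance, blood–coil interaction, gravity, coil
detachment mechanics, or the photographic sectioning of physical phantoms;
passing tests demonstrate the mechanics and metrics pipeline is correct and
self-consistent under the stated model, not that any specific clinical
deployment is predicted.

## Known limitations

* Equivalent-moduli calibration cannot match both published example moduli
  exactly under any single section convention (documented 0.9 % / 0.4 %
  residuals); conventions are configuration, not inference.
* Penalty contact admits penetrations up to the saturation band during
  transients; the maximum penetration is reported per run.
* The O(n²) self-contact and brute-force mesh queries are sized for
  protocol-scale models (tens to hundreds of elements), not for very long
  multi-coil treatments.
* Earlier coils in multi-coil plans are rigid during later deployments.
* The stiff baseline pathway is validated geometrically; its explicit
  dynamics at unscaled moduli are impractically slow at desk scale, which
  mirrors the large runtime gap between the two pathways.
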