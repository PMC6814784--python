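# Methods

`aortasph` simulates an idealized cross-section of the murine descending
thoracic aorta as a two-dimensional total-Lagrangian smoothed-particle
(SPH) solid, resolving the medial lamellar architecture particle by
particle.  This note records the model, its numerical treatment, and the
design choices made where more than one reasonable option existed.

## Model overview

The wall is an annular sector (default 90°, rotationally periodic) with
inner radius 646.8 µm and thickness 40.2 µm in the *in vivo* homeostatic
configuration (luminal pressure 102 mmHg, axial stretch 1.62).  The
homeostatic state is the kinematic reference: `F = I` there, and each
constituent is loaded through a deposition prestretch in the
constrained-mixture sense (elastin `G^e = diag(0.32, 1.90, 1.62)` in the
radial/circumferential/axial frame; collagen-family stretches 1.20-1.25).
The media (inner two thirds) contains six elastic lamellae — 2 µm
elastin-only bands — delimiting five intra-lamellar layers of smooth
muscle cells (SMCs), collagen and diffuse glycosaminoglycans (GAGs); the
outer third is a collagen-dominated adventitia.

Per-particle strain energy is a mass-fraction-weighted mixture:

    W = phi_e [ mu/2 (I1_e - 3) - mu ln J + lambda_hat/2 (ln J)^2 ]
      + sum_k phi_ck c1k/(4 c2k) ( exp(c2k (I4k - 1)^2) - 1 )

with an anisotropically prestretched neo-Hookean elastin matrix and four
exponential fiber families (axial, circumferential, two symmetric
diagonals at 29.91° from the axial direction).  Fibers switch between
tension and compression constants at `I4 = 1`; the switch is
stress-continuous because the fiber stress carries an `(I4 - 1)` factor.
SMC passive response is folded into the circumferential family.  Active
tone adds a parabolic circumferential Cauchy stress
`sigma_act = phi_c2 T_max lam [1 - ((lam_max - lam)/(lam_max - lam_min))^2]`,
zero at `lam_min = 0.6`, maximal at `lam_max = 1.1`, `T_max = 500` kPa.
GAG pools replace the mixture by a soft isotropic solid
`sigma = mu_GAG/J (B - I) - p_swell I` with `mu_GAG = 0.1` kPa; the
Gibbs-Donnan swelling pressure `p_swell = RT(sqrt(c_FC^2 + c*^2) - c*)`
is 156 kPa for 200 vs 300 mEq/l at 310 K, deformation-independent and
purely isotropic.

The motion is in-plane at fixed axial stretch `lambda_z = 1` relative to
the prestretched reference (the in vivo 1.62 lives inside the axial
prestretches); `J = det(F_2D) * lambda_z`.  The axial stress component is
evaluated for reporting but never enters in-plane force balance.

## Discretisation

Particles sit on concentric rings with arc spacing ≈ radial spacing
(nominally `1/sqrt(density)`, ~2 µm at the reference density of
0.24/µm²).  Every material band — each 2 µm lamella, each intra-lamellar
gap, the adventitia — is subdivided into however many rings its thickness
affords, so constituent *volume fractions are density-invariant*; that is
what makes transmural stress fields comparable across particle densities.
Particle volume is the exact annular Voronoi cell, so volumes tile the
sector area identically.  Lattice generation is deterministic; there is
no random number generator anywhere in the package.

The Spiky kernel (cubic, 2D-normalised, non-vanishing gradient at the
origin) has support `h = 3 x` nominal spacing by default (~28 in-plane
neighbours).  `h` is a purely numerical parameter; the density-robustness
tests therefore hold `h` at its physical (reference-density) value while
the lattice is refined.  Discrete gradients use per-particle correction
matrices, which makes affine deformations exact everywhere including free
boundaries, and makes severing *reference* connectivity a faithful model
of rupture.  Neighbour sets are built once on the reference lattice;
rotational sector periodicity enters through per-edge image rotations.
The correction matrix is rejected as boundary-deficient above condition
number 1e8.  One known wart: the discrete partition of unity of the
peaked Spiky kernel overshoots by ~8% at `h = 3x` spacing (the self term
over-counts its Voronoi cell); this affects only smoothed *field*
reports, never forces, and shrinks with larger support.

## Quasi-static solution

Equilibria are found by damped explicit dynamics (leapfrog) under
fictitious masses scaled per particle from a local stiffness bound
(tangent moduli with headroom, current stress magnitude as a geometric
term, viscosity, hourglass penalty), so the stable step is uniform and
fixed at `dt = 1`.  Damping is adaptive near-critical: each step the
dominant frequency is estimated from a Rayleigh quotient of the stiffness
sampled along the current velocity, and the velocity-scaling factor set
to its critical value (clamped to [0.7, 0.999]).  Fixed velocity scaling
and kinetic damping are available but were found to over/under-damp
state-dependently.  Two stabilizers act throughout: an hourglass penalty
on deviations from locally affine motion (`alpha = 25`, penalty stiffness
following the local material modulus as in FEM hourglass control, down to
the swelling-pressure scale inside GAG pools), and an artificial
viscosity `P_visc = 2 eta J d F^{-T}` (`eta = 30`).  Neither affects
converged stresses (regression-tested at ±2x viscosity, <0.5% change).

Convergence requires the residual force below `1e-4` of the mean internal
force scale *and* either kinetic energy below `1e-6` of its peak or a
displacement rate below 1e-6 µm/step ("nothing moves"); absolute floors
handle stress-free states.  A relaxation that exhausts its step budget
restarts with masses refreshed from the current state (large deformations
outgrow the initial stiffness bound); repeated stalls escalate the mass
safety factor.

Loading is displacement-controlled (semi-inverse): inner-rim particles
ramp radially (smoothstep over 400 steps) and hold; the outer rim is
traction-free.  Pressure is an *output* via the Laplace relation
`P = sigma_theta h / r_in` from the volume-weighted mean circumferential
Cauchy stress and the current surface radii (rim particles sit half a
radial cell inside the surfaces).  Pressure targets are met by secant
iteration on the rim radius, each iterate a fully relaxed equilibrium.
An independent check: the net radial rim reaction equals
`P x r_in x sector` within 5%.

## Damage protocols

Lamellar disruption is topological, with no damage constitutive law:
(i) zero the neo-Hookean constants of the chosen segment, (ii) detach the
ruptured particles from every neighbour list, (iii) disconnect intact
same-lamella particles across the gap, then relax.  Pool (SMC-loss)
steps run strictly in order — I loss of contractility, II replacement by
the soft GAG solid, III osmotic swelling — each followed by relaxation;
step IV ruptures the lamellae bounding the pool.  After the severe
step-IV states the severed-tip region can retain slow localised residual
motion; scenario execution records a per-event converged flag instead of
failing, because the midline observables (below) are stationary there.
Tip fields themselves are not trusted at this resolution.

Read-outs: stress concentrations are read along the radial line through
the defect *midpoint* (window ±1° or one particle arc), explicitly not at
the severed tips; `regional_max_stress` additionally excludes particles
within one kernel support of any recorded tip.  Scenario defaults: defect
centred on the sector midline; single pool in the band between the middle
and next-outer lamellae (band 3); two unmerged pools in bands 2 and 4, so
the "interior" lamellae between them are exactly the lamellae bounding
the single-pool band and the two studies read off identical material
regions; merged pools occupy bands 2-3 with the shared lamella removed
before baseline, at twice the angular extent.  Pool scenarios run with
tone on (loss of contractility is meaningless without baseline tone);
the lamellar-rupture study is passive.  During damage events the rim
displacement is held, so the reported pressure drifts slightly (<2% for
the defect sizes studied) — pressure is re-targeted only between
scenarios, not within an event sequence.

## Thin-wall oracle

Bulk behaviour is validated against a homogenised incompressible membrane
solution: thickness-weighted mixture of the three layer types, membrane
kinematics `lambda_r = 1/lambda_theta`, and the plane-stress correction
`sigma_theta - sigma_rr` (the through-thickness reaction enforcing
`sigma_rr ≈ 0`; with a radial elastin prestretch of 0.32 this correction
is ~28 kPa and not optional).  The particle model's passive
pressure-diameter curve agrees with the oracle within ~3% over
80-184 mmHg; the oracle's active form reproduces the ~23% constriction at
102 mmHg.

## Desk-scale configurations

The sector angle only sets the domain size: the lamellar structure is
radial, so axisymmetric experiments (pressure sweeps, constriction) use a
15° periodic sector (~1.9k particles) and defect studies a 30° sector
(~3.8k particles) at the reference density 0.24/µm², with 8° the default
defect extent for quantitative read-outs (≥3 particle arcs at every
tested density, yet far from the distributed-defect regime).  The
density-robustness study uses 15° sectors at 0.24-0.62/µm².  Full-circle,
full-density runs are a straightforward (if slow) configuration change.

## Known limitations

- Tip stress fields of severed lamellae are not resolution-independent
  and are excluded from all read-outs; the lamellar *bending* response
  over a swollen pool becomes resolution-dependent once lamellae carry
  two particle rings (the bending moment is unresolved below that).
- The thin lamellae carry no explicit bending stiffness beyond the
  hourglass penalty.
- No fluid, no growth/remodelling, no mechanosensing; the viscosity is a
  numerical stabilizer, not tissue viscoelasticity.
- Sector periodicity means a defect implicitly repeats every sector
  angle; defect extents are kept well below the sector so interactions
  through the periodic images are negligible.
- The partition-of-unity and step-IV convergence caveats noted above.
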