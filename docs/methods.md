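# Methods

`furrowshell` models the onset of ventral furrow formation (VFF) in the
*Drosophila* embryo as a purely mechanical problem: the apical surface of the
blastoderm is a thin, pre-stressed elastic shell on an ovoid, holding a fixed
enclosed volume and confined by the rigid vitelline envelope. Apical
actomyosin (MyoII) contractility enters only through an isotropic areal
pre-strain of the prospective mesoderm; no cell-autonomous wedging, lateral
or basal force appears anywhere in the model. The package also implements the
measurement procedures used to characterise the process — stress anisotropy,
midline curvature and buckling detection, furrow depth and propagation,
vitelline distance maps, tissue shortening, recoil velocities — and the MyoII
intensity kinetics that prescribe the loading schedule.

## Reference geometry

The embryo surface is the image of the unit sphere under the closed-form map

    (x, y, z) = (a·q_x, q_y, q_z − d·q_z²),

with `a = ap_dv_ratio = 3` (AP extent is exactly three times the DV extent)
and `d = dissymmetry` (default 0.15). The map preserves the mid-sagittal
(y = 0) and mid-transverse (x = 0) mirror symmetries; for `d > 0` the ventral
apex (z < 0) has cross-section curvature `1 + 2d` and the dorsal apex
`1 − 2d`, so the ventral side is more curved, while the total DV extent
stays 2. Lengths are nondimensionalised by the DV semi-axis (≈ 90 µm
physically; this scale is recorded in run configs, never used in the
mechanics). The closed-form shape is this package's own parameterisation; it
reproduces the three defining geometric facts (3:1 axis ratio, ventral
curvature bias, two mirror symmetries) with a single dissymmetry scalar.

The mesh is a subdivided octahedron projected to the sphere and pushed
through the map. Unlike an icosphere, the octahedral vertex set contains the
six axis poles exactly and is invariant under all three coordinate
reflections, which makes the AP:DV extent ratio exact and lets tests pair
every vertex with its mirror image. Subdivision level `n` gives `8·4^n`
facets; tests use 512–2048 facets, production runs 8192.

The prospective mesoderm is the set of facets within a DV arc band around
the ventral midline spanning a fraction `dv_arc_fraction = 1/6` of the local
cross-section contour, and within an AP extent spanning
`ap_arc_fraction = 1/3` of the mid-sagittal contour. DV distance from the
midline is measured in cell-row units, one row = (mid-cross circumference)/80
≈ 7 µm, matching the mean apical cell diameter.

Pre-strain is graded with row distance: `eps_a(row) = eps_m · exp(−(row/4)²)`
by default, which is 1 at the midline and drops below 0.05 beyond seven rows,
the observed extent of the graded MyoII distribution. A tabulated profile
can be substituted. Facet target areas are `A_0 = A_i/(1 + eps_a)`, so each
mesoderm facet carries areal pre-strain `eps_a = (A_i − A_0)/A_0` and
pre-stress `sigma_a = chi_2d · eps_a` before any deformation.

## Shell mechanics

**Membrane.** Constant-strain triangles with Green–Lagrange strain `E`
measured against the facet's target metric (the reference triangle shrunk
isotropically to area `A_0`). The energy density per unit target area is

    W = (chi/2)(tr E)² + mu_s · dev E : dev E,

with `chi` the areal compression modulus and
`mu_s = chi(1 − nu)/(1 + nu)` the in-plane shear modulus. Because `tr E`
equals the areal strain exactly under isotropic stretch, a facet held at its
reference shape carries the isotropic stress `chi·eps_a` exactly, at any
pre-strain magnitude. `nu = 0` by default, following the model's stated
in-plane Poisson ratio.

**Bending.** Discrete-shells hinge energy on interior edges,
`(B/2)·3|e|²/(A1+A2)·(θ − θ̄)²`, with the reference dihedral subtracted so
the undeformed embryo is bending-neutral (the pre-gastrulation shape is an
equilibrium). The continuum limit is a squared-mean-curvature-difference
energy with a mesh-dependent O(1) prefactor (≈ 1.4 × `2B·Area/R²` for a
uniformly bent patch on the structured test grid).

**Nondimensionalisation.** The single stiffness ratio is
`chi_tilde = chi·L²/B` with `L` the DV semi-axis (the code length unit) and
`B` the bending modulus (the code energy unit). The default `chi_tilde = 50`
corresponds to an effectively thick shell (bending length
`(B/chi)^(1/4) ≈ 0.4 L`); because conventions for the bending-modulus prefactor (and hence for
`chi_tilde`) differ between discretisations, `B` is exposed for recalibration, and the
furrowing pipeline (below) uses a thin-shell setting.

**Constraints.** The enclosed volume is held at its reference value — the
incompressible yolk/cytoplasm — via an augmented Lagrangian with an exact
final Newton projection along the volume gradient (drift ≤ 1e-6 relative,
typically 1e-12). The vitelline envelope is the reference surface offset
outward by the perivitelline gap (default 0.004 ≈ 0.35 µm, within the
0.2–0.5 µm physical range); its signed distance comes from the smooth inverse
of the ovoid map (first-order accurate in distance, exact on the embryo
surface, exact analytic gradient). Contact is frictionless and one-sided: an
adaptive quadratic penalty on penetration during minimisation, followed by
projection of offending vertices onto the vitelline interior (penetration
tolerance 1e-3 code units). Because the vitelline is rigid and the enclosed
volume fixed, the global perivitelline fluid volume is conserved
automatically.

**Minimisation.** Inner solves use L-BFGS (scipy, `maxcor = 20`) on the
penalised energy; outer iterations update the volume multiplier and raise
penalty weights only while the corresponding violation is not shrinking.
The reported gradient norm is the residual of the penalised equilibrium just
before the final feasibility projection (the projection moves contact
vertices by at most the penetration tolerance, which injects a
discretisation-scale force imbalance at the contact ring that would otherwise
mask convergence). The default gradient tolerance is
`1e-8 · chi_tilde · total area`; pipeline runs use 1e-3–1e-1 depending on the
load scale. The solver is fully deterministic — no random perturbation is
ever injected; equilibrium-branch selection is by geometry and warm starting
only — so re-running a ramp reproduces vertex positions bitwise.

Pre-strain ramps solve a non-decreasing sequence of `eps_m` values, each
warm-started from the previous equilibrium; a non-converged step truncates
and flags the trajectory.

## Stress and strain extraction

Per-facet second Piola–Kirchhoff stress `S = ∂W/∂E` is pushed forward to a
Cauchy membrane tension `σ = F S Fᵀ / J` and expressed in a tangent frame
whose first axis is the global AP direction projected onto the facet plane
(facets whose normal is nearly AP-parallel — the polar caps — are excluded
from AP/DV extracts). Principal stresses are the closed-form 2×2 eigenvalues.
The midline anisotropy ratio averages `σ_AP` and `σ_DV` (area-weighted) over
facets with DV angle ≤ π/16 and the central 50% of the AP extent; both the
band half-angle and the AP fraction are parameters, since the averaging
window behind reported midline-ratio values is rarely specified. Strain profiles
bin the current/initial stretch of material elements along AP or DV against
the DV angle (64 bins, area-weighted; empty bins are interpolated from
neighbours and reported with count 0).

## Furrow morphometrics

Planar sections (mid-sagittal, or cross-sections at AP stations) are
plane–mesh intersections stitched into ordered contours. Curvature is the
signed three-point circumcircle curvature (`κ = 1/R`; convex positive,
concave negative), evaluated at the ventral apex with an arc spacing of
three mean edge lengths by default — image-based versions of this
measurement work at pixel scale, so the mesh-scale analogue needs an explicit
spacing choice, and the spacing parameter is exposed because narrow creases are
smoothed away when the spacing exceeds their width. The buckling threshold is
the first ramp value at which the ventral DV curvature reaches zero (linear
interpolation between steps); a ramp whose curvature stays positive returns
"not reached" (`None`). Furrow depth at an AP station is the inward offset of
the cross-section's ventral apex from its reference height. Pole displacement
is the distance between the fixed vitelline pole point and the pole-most
surface vertex. Tissue shortening tracks two material points (barycentric
anchors on the reference mesh placed at prescribed arc offsets along a
section) and measures their separation along the deformed section contour.
Recoil velocity is the maximum of the first derivative of a displacement
trace, from tricube-weighted local quadratic regression (LOESS-style; the
local fit degree 2 keeps the boundary derivative unbiased to second order).

## MyoII kinetics

Midline MyoII fluorescence follows the double-exponential model

    I_myo(t) = I_c + I·(exp(exp((t − t0)/T) − 1) − 1),

with constant signal `I_c` (4 arb units), amplitude `I`, onset `t0` and
characteristic time `T` (20 min at confocal frame rates; light-sheet movies
develop twice as fast, and synchronised confocal times are divided by 2).
The exponent grouping is the one consistent with `I_myo(t0) = I_c`, i.e. the
onset time marks the departure from baseline. Fitting is bounded nonlinear
least squares from a deterministic multi-start grid over (t0, T) — the model
is strongly initialisation-sensitive — and recovers all four parameters to
1e-6 relative on noiseless data. With 2% multiplicative noise the
characteristic time is identifiable to 5% only when the series pools many
tracked cells (≈ 2000 samples across the rise); sparse single-cell series
leave a broad (I, t0, T) trade-off, which is why the acceptance checks use
densely pooled series.

The spatio-temporal signal is separated as `I_i(t) = I_c + profile(i)·g(t)`
by a rank-1 SVD factorisation of the excess intensity, normalised to
`profile(0) = 1` (which makes the factorisation unique). The pre-stress
schedule is `sigma_a(row, t) = scale · profile(row) · (I_myo(t) − I_c)` with
`eps_a = sigma_a/chi_2d`; the stress-per-intensity `scale` is a free
calibration, with the default chosen so the midline pre-strain reaches 0.43
at synchronised time zero.

Time zero is the instant the mean apical area of the five midline rows drops
20% below its pre-gastrulation value (linear interpolation of the crossing).

## Synthetic observations

The tracking-table generator emulates confocal cell-tracking output: nine
cell rows per side, ~12 cells per row, frames every 30 s over ~16 min,
intensity = the double-exponential model times the row profile plus optional
multiplicative log-normal noise (fluorescence character), areas and ellipse
axes following smooth logistic responses — midline rows constrict (by 55% at
late times), rows 6–9 expand (by ~20%) with DV stretch beyond row 3
(additive Gaussian noise, segmentation character) — and optional track
dropout. All generators are deterministic functions of their seed and attach
their ground truth. They emulate the *statistical structure* of tracked
data, not its biology: passing recovery tests shows the estimators are
correct on data matching their assumptions, not that real movies satisfy
those assumptions (real intensity profiles need not factorise exactly, real
noise is not log-normal, and tracking errors are correlated across frames).
The area-response curves may also be taken from a simulation trajectory to
close the model → observation → quantification loop.

## The furrowing regime and its limits

With the default thick-shell stiffness (`chi_tilde = 50`) and the default
mesoderm extent, ramping the midline pre-strain reproduces the tension
anisotropy (AP stress ≈ pre-stress at the midline, compressive hoop collar
just beyond the mesoderm periphery, DV contraction below π/8 and stretch
between π/8 and π/4) and pulls the polar caps inward monotonically — but the
ventral band remains pressed against the vitelline: the internal pressure
generated by pole retraction exceeds the inward pull `σ_AP·κ_AP` of the
ventral midline at every load, and no furrow forms. The volume budget is the
controlling quantity: every inward displacement must be compensated by
outward motion limited to the perivitelline gap, and the polar caps, pulled
by the full AP force of the contractile band, win that competition.

The pipeline's furrowing preset therefore uses (i) a mesoderm AP extent of
1/6 of the sagittal contour — the reading of the "three times shorter than
the blastoderm" statement in which lengths are pole-to-pole surface
distances rather than full closed contours; the shorter band sheds part of
its AP force into the surrounding membrane before it reaches the poles,
halving the pressure — and (ii) a thin-shell stiffness `chi_tilde = 600`
(bending length ≈ 0.2 L). In that regime the ventral band detaches and the
model reproduces the documented first phase of VFF: the ventral DV curvature
drops rapidly (1.23 → 0.97 over the ramp) while the AP midline flattens
(κ_AP 0.15 → 0.06), a stable furrow depression forms (deepest at mid-AP,
shallower toward the poles), and the perivitelline space opens at the poles.
The second phase — the abrupt sign inversion of the DV curvature — is *not*
reached by midline pre-strain 5.25 under this discretisation and
nondimensionalisation: the curvature decreases monotonically but stays
positive. Extensive exploration (stiffness from `chi_tilde` 2 to 1800,
profile shapes from step to narrow Gaussian, dissymmetry to 0.3, both
mesoderm readings, mesh refinement to 8k facets, inward-perturbation probes
for competing equilibrium branches) indicates this is a robust property of
this implementation of the model rather than a numerical artifact; the
missing ingredient lies in implementation details the model statement
leaves open (the bending discretisation and the nondimensionalisation
convention chiefly among them). The buckling detector and all
downstream quantifications are implemented and tested against synthetic
curvature series regardless.

## Numerical choices and degenerate inputs

* Volume drift ≤ 1e-6 relative at every accepted state (exact projection).
* Containment: signed distance ≥ −1e-3 code units at every accepted state.
* Degenerate (zero-area) facets, non-manifold edges, decreasing ramps,
  non-positive gaps and moduli are rejected with explicit errors.
* Meshes too coarse to resolve the mesoderm band (< 24 facets) are rejected.
* Empty angular-profile bins are interpolated and flagged with count 0; the
  anisotropy band rejects configurations that contain no facets.
* The contact tolerance (1e-3) is a quarter of the default gap; tightening
  it raises the penalty stiffness adaptively.
* Remeshing between ramp steps is intentionally absent: determinism and
  bitwise reproducibility were preferred over mesh quality at extreme
  contraction, where facet aspect ratios degrade (a known limitation at
  midline pre-strains beyond ~8).

## Known limitations

* The shell does not internalise the mesoderm after furrowing — the model
  addresses furrow formation only, by construction.
* Viscous relaxation is absent (quasi-static elastic equilibria); the model
  is meaningful only while the load rises faster than the tissue relaxes.
* The DV-curvature sign inversion at high pre-strain is not reproduced under
  the default calibration (see above); quantitative buckling-threshold values
  from this package should be treated as calibration-dependent.
* The approximate vitelline signed distance is first-order accurate; deep
  inside the embryo the "distance map" is an increasing function of true
  distance rather than an exact metric distance.
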