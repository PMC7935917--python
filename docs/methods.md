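# Methods

## The model

`corollafold` simulates the mechanics of a growing petal (corolla tube)
cross-section to test whether friction against the surrounding perianth
organ is sufficient to fold it.  The cross-section is a two-dimensional
linearly elastic sheet in plane stress; growth is driven by turgor pressure
and proceeds by the incremental (morphoelastic) scheme:

1. **Inflate**: the current rest shape is loaded by a per-element isotropic
   eigenstress, so the element stress is `sigma = C eps(u) - p I` with
   turgor pressure `p`; the linear elastic equilibrium is solved.
2. **Release**: the deformed configuration is adopted as the rest shape of
   the next step, discarding the elastic stress.  This is the incremental
   analogue of viscous stress relaxation in growing tissue.

Iterating inflate/release for `n_steps = 200` steps compounds the
per-step elastic strain into finite growth.  The pre-release equilibrium
stress of each step is retained as that step's record of the stress the
tissue experienced while developing.

### Constitutive law

In the material frame (axis 1 = principal stiffness direction,
proximodistal by default) the stress–strain relation is

    (s11, s22, s12)^T = E/(1-nu^2) *
        [[1+a,                 nu*sqrt((1+a)(1-a)),  0        ],
         [nu*sqrt((1+a)(1-a)), 1-a,                  0        ],
         [0,                   0,                    b/(1+nu) ]] (e11, e22, e12)^T

with geometric-mean Young's modulus `E = 3e6 Pa`, Poisson ratio
`nu = 0.4`, anisotropy index `a = alpha = 0.1` and shear factor
`b = beta = 0.9`.  Two deliberate fidelity choices:

* The shear entry `beta/(1+nu)` sits inside the `E/(1-nu^2)` prefactor and
  does **not** reduce to the textbook isotropic shear term at `beta = 1`.
  The law is implemented in this exact form because it is the operative
  model; `beta = 1 - nu^2` recovers exact isotropy and is what the
  manufactured-solution convergence test uses.
* The matrix places the stiffer modulus `E(1+alpha)` on the `s11`
  (principal-axis) row.  A documented switch `swap_anisotropy_axes`
  exchanges the two diagonal entries for users who prefer the opposite
  convention; it is off by default.

The scalar stress readout is the von Mises-type intensity
`MS = sqrt((s11 - s22)^2 / 2)` computed per triangle from the
material-frame normal stresses.  The shear component deliberately does not
enter this readout; the intensity is invariant under hydrostatic shifts and
under exchanging the two normal components.

### Discretization and solver

Linear (P1) triangles with single-point quadrature: strain and stress are
constant per element.  The stiffness is assembled per element with the
constitutive matrix rotated into the global frame through each element's
material axis; the linear system is symmetric positive definite once
Dirichlet constraints remove the rigid-body modes and is solved by a sparse
direct factorization (deterministic — no iterative tolerance, no seed).
The solve is verified to a relative residual of 1e-10 and aborts on any
non-finite solution or inverted element (with the element index and growth
step in the error).  Verification: a patch test is exact to 1e-10, the
single-element free-expansion strain `P(1-nu)/E = 0.008` is exact to
1e-10, and a manufactured smooth solution converges at second order under
uniform refinement.

Material axes are convected: after each step the per-element deformation
gradient maps the axis vector forward (renormalized), so proximodistal
stiffness follows the tissue when it folds.

### Geometry and boundary conditions

The initial shape is a 0.1 mm x 0.8 mm rectangle with the base at `y = 0`
(x horizontal, y proximodistal, mm throughout).  The default structured
mesh is `nx = 4` by `ny = 32` quads split into 256 triangles, with the quad
diagonals mirrored about the vertical midline so that the triangulation —
not just the node set — is exactly mirror-symmetric; a single diagonal
direction would itself bias the buckling direction.  Conclusions are
checked at doubled resolution (8 x 64).

The base is supported vertically (`uy = 0` on all basal nodes, with the
basal midpoint also fixed horizontally to anchor the column).  The
receptacle prevents the corolla base from moving down or sliding as a
whole, but grows with the corolla, so the base must remain free to widen.
This choice makes the friction-free control run exactly stress-free
uniform growth, the clean baseline the friction response is measured
against; a full clamp (available as `base_bc="clamp"`) instead imprints a
corner stress concentration that grows with the accumulated widening and
swamps the friction-induced stress field.

### Friction

Friction with the outer organ is a growth-inhibition proxy: inside the
contact band the turgor is reduced to `P_red = (1 - eta) P`, with
`eta = 0` free growth and `eta = 1` no growth in the band.  The band is
material (Lagrangian): selected once on the initial rectangle — by default
the right side, heights 0.70–1.00 of the column, outer half of the width —
and carried with the tissue for the whole run.  The distal contact region
of a petal pressed against a sepal extends to the tip, hence the band's
upper bound at 1.0; ending the band below the tip leaves a free lip that
develops its own kink at the band's upper edge and confounds the fold
localization.  The band depth is a width fraction rather than an element
count so the physical problem does not change with mesh resolution.

An optional bilateral horizontal pin of the band's boundary nodes
(`pin_friction_boundary`) models the petal being unable to slide sideways
at the contact.  It is **off** by default: the contact is unilateral — the
organ can only push, and the buckling deflection moves the petal away from
the contact surface — so a bilateral pin spuriously holds the column
straight (measured: deflection ratios drop from 0.12/0.16 to 0.04/0.02 at
eta 0.4/0.7 and lose their monotonicity in eta).

No symmetry-breaking noise is required: the one-sided band itself breaks
the mirror symmetry, so the buckling direction is deterministic.  The
`seed` only drives optional interior-node jitter used in robustness
checks; the default runs have none.

### Buckling diagnostics

The midline is the node column that started at `x = width/2`, tracked by
index (connectivity never changes).  Reported measures:

* **deflection profile**: signed horizontal deviation of the midline nodes
  from the vertical through the base midpoint, against arclength;
* **column length**: the midline polyline arclength — used as the "height"
  in the buckling ratio because it is stable under bending, unlike the
  vertical extent of a folded column;
* **bend angle**: the maximum angle any midline segment makes with the
  basal segment direction (a robust monotone summary of total turning);
* **buckled**: max |deflection| / length > 0.1 (threshold configurable);
* **fold location**: arclength fraction of the vertex of maximum discrete
  turning angle of the final midline.

Because the band grows more slowly than the tissue below it, the band's
lower edge sits at a final arclength fraction larger than its initial 0.70.
`band_edge_fractions` maps the material band edges onto the final midline
so that "fold below the band" can be asked of the grown shape; at the
default conditions the fold lands just below the band's lower edge
(e.g. 0.734 vs 0.748 at eta = 0.4).

## Residual-stress mapping on traced outlines

A folded cross-section outline — traced from an image (CSV of `x_mm,y_mm`
vertices) or generated synthetically — is triangulated and loaded with a
downward traction of magnitude `4P` (the rough scale of the residual
stress accumulated during development; `force_multiple` is free) on its
distal boundary segment (topmost 5% of the height, configurable), with the
basal 5% clamped.  The traction is weighted by each boundary edge's
horizontal projection, so the total equals traction x projected width and
side edges carry none.  A body-force variant (`as_body_force=True`)
distributes the same total over the section.  The solution is linear in
the load; a straight column reproduces the uniaxial closed form
`MS = 4P/sqrt(2)` away from the clamp, and a doubly folded outline
concentrates von Mises stress at the fold troughs (about 3x the straight
control at the default geometry).

Polygon triangulation is done in-house: the outline is resampled at the
target edge length (sharp corners preserved, smooth chains resampled
uniformly so densely traced outlines do not force slivers), the interior
is seeded with a staggered triangular lattice kept clear of the boundary,
Delaunay-triangulated, filtered by centroid containment, and improved by a
few Laplacian smoothing passes with re-triangulation.  Measured quality on
the shipped geometries: minimum interior angle above 15 degrees, maximum
edge below twice the target, area error below 0.5%.

## Synthetic folded outlines

The stand-in for image-traced outlines is a constant-width column whose
midline deviates sinusoidally: `n_folds` excursions of amplitude
`fold_depth * height`, offset by half the width on each side along the
local normal.  `n_folds = 2` emulates the doubly folded "cup" phenotype;
`n_folds = 0` degenerates to a rectangle (exact to 1e-12).  Offsets
self-intersect when midline curvature exceeds `2/width`; this is detected
analytically and reported with the offending fold index.  Optional seeded
vertex jitter (off by default) emulates tracing noise.  What the generator
does **not** emulate: variable wall thickness, open or touching contact
surfaces, and the asymmetric fold shapes of real cross-sections — so
passing stress-mapping tests demonstrates the method's behavior on
idealized folds, not agreement with any particular specimen.

## Phenotype statistics

The F2 segregation test is the plain Pearson chi-square against a 3:1
Mendelian ratio, df = 1, upper-tail p, **no** Yates continuity correction:
the observed 33:8 counts give chi2 = 0.6585, p = 0.4171 (the corrected
statistic would give a different value).  The asymptotic p approximates
the exact multinomial tail (0.4759 by enumeration at n = 41) only to
within count discreteness; the test suite checks the Monte-Carlo null
against the exact enumeration at MC precision and the asymptotic p against
the exact tail within a 0.08 discreteness bound.  Folding-class tables
report per-line proportions over the four severity classes (normal,
traced, half, cup) in input order, summing to 1 per line.

## Problem sizes and numerical choices

Default growth runs use the 4 x 32 mesh for 200 steps (a solve per step on
~330 unknowns); robustness checks double both subdivisions.  Outline
meshes use a 0.08 mm target edge (~400–1400 elements), halved for
refinement checks.  Per-step strains are ≲ 0.01, so the small-strain
assumption holds within each increment; finite rotations are captured by
compounding across steps.  Ties in arg-max diagnostics (stress peaks on
symmetric geometries) are resolved by first index; the peak location test
therefore asks that the refined peak lands at one of the coarse
concentration sites rather than that the tie resolves identically.

## Known limitations

* Friction is a growth-inhibition proxy plus an optional kinematic pin —
  not Coulomb contact against a meshed sepal; `eta` has no calibration to
  a physical friction coefficient.
* Single petal cross-section in 2D: no tube curvature, no interaction
  between the five fused petals, no out-of-plane buckling.
* Each increment is geometrically linear; very large per-step strains
  (P approaching E) would need a finite-strain kernel.
* The residual-stress map is a static estimate under an assumed load, not
  a reconstruction of the developmental stress history.
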