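# Methods

`carpalfem` implements a reduced biomechanical model of the proximal carpal
row: distal radius, scaphoid, lunate and capitate, their articular
cartilage, a 3D block for the scapholunate interosseous ligament (SLIL) and
1D springs for the remaining ligaments, loaded by wrist motions applied to
the capitate. This note records the model, its assumptions, the numerical
choices, and what the synthetic surrogate does and does not establish.

## Units and frame

All computations use a consistent mm-N-MPa system; pressures are converted
to Pa once, at the reporting layer. The model frame is
x: radial(-)/ulnar(+), y: dorsal(-)/volar(+), z: proximal(-)/distal(+).
The uniformly negative z of the published capitate-displacement table is
reproduced by this convention (all motions draw the capitate proximally);
the convention is ours, chosen to match that sign pattern.

## Surrogate anatomy

The original model is segmented from one subject's CT scan; those scans are
not bundled here. `anatomy.generate_reduced_wrist` builds a parametric
stand-in: every part is a star-shaped superellipsoid-like solid (icosphere
directions radially mapped, exponent 2.2-3.0) with a small smooth random
perturbation (default 1.5% of the local radius; the analytically smooth
cartilage lenses and the SLIL block carry a 0.4% perturbation, which also
breaks the exact symmetry planes that produce degenerate Delaunay
configurations). Default dimensions are wrist-scale: distal radius
semi-axes 13 x 11 x 14 mm with a cancellous core at 72% scale, carpal bones
~5-6.5 mm semi-axes, cartilage layers 1.2 mm thick, articular clearances
0.3 mm, and a scaphoid-lunate gap of 2 mm bridged by the SLIL block.
A single `scale` factor multiplies every length (geometry is homogeneous in
it). Every part is watertight by construction; generation is bit-exact
reproducible from `(seed, config)`.

Ligament attachment landmarks are placed by anatomical direction (dorsal /
volar / radial combinations per ligament name) and snapped to the part
surface. The published ligament table is implemented verbatim, including
its two oddities — "Short radiolunate" connecting radius-scaphoid, and the
volar radioscapholunate row attaching to scaphoid *and* lunate at
50.75 N/mm each — with an override hook rather than a silent correction.

Because the geometry is a surrogate, all downstream field magnitudes
(pressures, displacements) are geometry-specific. The pipeline reproduces
the published *procedure* and its qualitative findings; it does not claim
the published pressure numbers, which depend on the subject's articular
congruence.

## Meshing

Surfaces become 4-node tetrahedra via a deterministic Delaunay procedure:
boundary vertices (subdivided to the target edge length) plus a jittered
interior grid are triangulated and tets whose centroid falls outside the
surface are discarded; orientation is repaired by vertex swap and
zero-volume slivers are removed. Point containment uses generalized
winding numbers (robust where ray-parity grazes edges of structured
meshes). Each bone and its cartilage are meshed as one body: the union
envelope (star-shaped, obtained by ray casting against both part surfaces)
is triangulated once and tets are region-tagged by centroid containment,
giving conforming bone-cartilage interfaces with shared nodes — no tied
contact search, and no spurious interface stiffness. The radius
additionally carries its cancellous core as a nested region. On exactly
symmetric inputs (e.g. an axis-aligned cube) lattice degeneracies can
leave isolated zero-volume internal slits after sliver removal; organic
geometry with the default perturbations is unaffected beyond ~1 node per
mesh, and the mesher verifies its boundary stays within one target edge of
the input surface.

Quality control follows the usual hygiene rules: triangle aspect ratio
`2 r_in / R_circ` (equilateral = 1), tet quality `3 r_in / R_circ`
(regular = 1), slenderness = longest/shortest edge, and an
adjacent-element size-ratio (gradation) check. Default thresholds
(quality 0.1, slenderness 10, gradation 2) are engineering choices; the
source states the rules but no numbers. Default target edges (radius
2.8 mm, carpals 1.8-2.0 mm, SLIL 0.9 mm) are desk-scale choices balancing
resolution against the direct sparse solver.

## Materials

Bone is linear elastic isotropic; cartilage and the SLIL are compressible
two-parameter Mooney-Rivlin solids,

    W = C1 (I1b - 3) + C2 (I2b - 3) + D1 (J - 1)^2 ,

with deviatoric invariants I1b = J^(-2/3) I1, I2b = J^(-4/3) I2 and
D1 = K/2 so the small-strain volumetric response equals the bulk modulus K
(the source never states D1; K/2 is the standard identification). Library
defaults, as published: cortical E = 18 MPa, nu = 0.2; cancellous
E = 100 MPa, nu = 0.25; cartilage C1 = 4.1, C2 = 0.41, K = 19.3 MPa (from
E = 11.6 MPa, nu = 0.4 via K = E/(3(1-2nu))); SLIL C1 = 832.4e-6,
C2 = 11.05e-6, K = 9.19802 MPa. Two published values deserve comment:
cortical bone at 18 MPa is ~1000x below common literature values (likely a
units slip for 18 GPa) and is used as printed with an override hook; the
SLIL bulk modulus 9.19802 MPa is stored as printed because the quoted
derivation ("bulk/shear ratio 1000" with "mu = C1*C2") is dimensionally
inconsistent — the printed value is reproduced only by the chain
1000 x 832.4e-6 x 11.05e-6 x 1e6.

In the assembled wrist model the carpal bones use the cortical material as
a single piece — the conclusion of the cancellous-influence study below.

First Piola-Kirchhoff stress is coded analytically; Cauchy stress follows
as J^-1 P F^T. Element tangents for the hyperelastic elements are obtained
by complex-step differentiation of the analytic P (machine-precision
derivatives, so Newton keeps its quadratic rate); linear-elastic element
matrices are precomputed.

## Ligament springs and part coupling

Each non-SLIL ligament is one linear spring between single mesh nodes
(nearest boundary node to each landmark), stiffness from the published
table, rest length equal to the as-built distance (no pre-tension is
published, so springs are unstressed at reference). Single-node attachment
reproduces a known artifact of the source model: concentrated forces at
attachment nodes. A `tension_only` flag exists (real ligaments slack in
compression) but defaults to off, matching the published "linear spring"
wording. Spring tangents carry both material and geometric parts.

The SLIL block is tied to the scaphoid and lunate by node-pair penalties on
the displacement difference (default 1e3 N/mm per pair, pairs within
1.5 mm). Node-pair ties penalize relative rotation over the pair offset;
for the thin SLIL gap this parasitic moment stiffness is small and only
*adds* to the constraint the tie is meant to impose. (Bone-cartilage
interfaces deliberately do not use ties — conforming meshing avoids the
artifact entirely, which matters for the mechanism analysis below.)

Articulations (radiocarpal and midcarpal) are frictionless compression-only
"gap springs": each slave boundary node pairs with its nearest opposing
node, and engages when their separation along the initial pair direction
drops below `s0 - g0`, where g0 is the node's initial clearance to the
opposing *surface* — i.e. contact starts when the slave would cross the
master surface. The force law is C1-smoothed over a 0.05 mm band at
engagement; the hard kink otherwise makes Newton chatter on the active set.
A node-to-triangle penalty mode is also implemented; its tangent omits the
closest-point motion (geometric) terms, so it converges to ~1e-3-1e-4
relative residuals and is not the default. Contact penalty defaults to
150 N/mm, roughly 10x the cartilage bulk modulus divided by the contact
element size.

## Boundary conditions

The proximal radius face (nodes within 1 mm of the minimum z) is fully
fixed. Wrist motion is applied to every capitate node as a uniform
translation — the distal row is taken to move as a rigid solid with the
capitate — linearly ramped over the load steps (default 10). The published
rotation-to-displacement conversion is reconstructed as

    tangential = r sin(theta),  axial = -r (1 - cos(theta)),

with extension -> -y, flexion -> +y, radial -> -x, ulnar -> +x, theta at
the midpoint of the published range of motion, and lever arm r = 19.40 mm
(least-squares fit over the eight published displacement components;
residual < 0.02 mm). r and the angle policy are configuration parameters.
Pronation-supination is stored in the ROM table but never converted: it
does not involve the scapholunate joint.

## Solver

Total-Lagrangian tet4 statics, Newton-Raphson with a backtracking line
search on the residual norm, adaptive load substepping (an increment halves
on failure down to 1/2^3 of the step and regrows on success), and an
escalating Levenberg-style diagonal damping fallback when the line search
stalls (the near-floating carpals make the early tangents badly
conditioned before contact engages). Linear solves use direct sparse
factorization; the tangent is symmetric for this conservative system.
Convergence: relative residual 1e-6 (to the step's initial residual) with
a 1e-9 N absolute floor, max 25 iterations per substep. Element inversion
is detected (det F <= 0) and handled by the line search / substepping; a
step that still fails produces a structured divergence record — by design
non-convergence is an observable result, not a crash.

Mechanism detection assembles the tangent at the constrained reference
state and counts eigenvalues below 1e-12 of the largest (shift-invert
Lanczos; dense below 600 dofs). The threshold sits between genuinely rank-
deficient modes (~1e-19 relative, from assembly roundoff) and the softest
physical modes of the intact model (~4e-9 relative, the SLIL-resisted
relative scaphoid-lunate motions), five orders from either side. On the
default surrogate: with SLIL 0 modes; without SLIL exactly 3 — twelve
rigid freedoms of scaphoid+lunate minus nine independent axial spring
constraints.

The eigen count, not the solve outcome, is the reliable instability
diagnosis: an unregularized Newton iteration on the singular no-SLIL
tangent diverges (matching the source solver's behaviour), but the damped
fallback here can also "converge" by simply leaving the unloaded mechanism
modes wherever they drift. Both outcomes are reported; the mode count is
what distinguishes the intact from the SLIL-deficient wrist.

## Cancellous-influence study

`run_reduced_radius_study` loads the radius-only model (cortical shell,
cancellous core, cartilage layer; proximal face fixed) with unit-magnitude
pressure (1 MPa) on two fossa patches of the distal cartilage where
scaphoid and lunate seat, ramped with the steps. The published load is
"unity"; we read it as unit pressure on the articular patches. The
observable is the strain-energy partition: on the surrogate the cancellous
core stores a several-fold smaller fraction than the cortical shell and
displacement maxima sit on the loaded cartilage, supporting the published
simplification of treating each bone as a single cortical piece.

## Pressure reporting

"Pressure" is the hydrostatic part of the Cauchy stress,
p = -tr(sigma)/3, with compression positive (matching the separate
max-compression / max-traction reporting convention; the opposite sign
convention is common, and a contact-pressure reading of the published
figures is also conceivable — hydrostatic stress is what is implemented).
Per-region envelope curves report min/max over elements and the
volume-weighted mean per step, in Pa.

## Stiffness experiment

The cadaveric SLIL validation is reproduced statistically: linear stiffness
is the ordinary least-squares slope of force vs displacement over a window
(default: the upper 60% of the displacement range, skipping the toe
region); summaries use the sample (n-1) standard deviation, which is what
reproduces the published 71.50/39.00 N/mm from the six published samples
(the n denominator gives 35.6). The pooled literature value 65.50/34.70 is
a stored constant: its mean matches the midpoint-of-ranges reading but its
std does so only approximately, so it is never used as a computed check.
The synthetic curve generator produces a C1 cubic toe blending into an
exactly linear branch plus Gaussian force noise (default sd 1 N over 50
samples to 2 mm — a realistic bench-test noise floor); parameter-recovery
bias of the fit is below 1% over 200 replicates.

## Problem sizes

Default meshes run ~4.5k nodes / ~17k tets for the assembled wrist. The
verification and demonstration runs use deliberately coarse desk-scale
settings: the radius study at 2.5 mm edges and 2 load steps, the full
extension solve at {radius 3.2, carpals 2.2-2.4, SLIL 1.1} mm edges and 10
steps (~4k nodes), and the CLI smoke run at a 5 degree explicit angle.
These sizes are the package's own choices for quick, reproducible runs;
all of them are configuration parameters.

## Known limitations

* Surrogate geometry: convex-ish star-shaped solids cannot reproduce
  articular congruence, so absolute pressures and the detailed load paths
  differ from the CT-based original; only qualitative patterns (dorsal
  compression in extension, the mechanism diagnosis, energy partitions)
  transfer.
* Under the published pure-translation boundary conditions, flat-ish
  surrogate articular surfaces wedge the carpal stack harder than curved
  congruent ones would; the gap-spring articulation tolerates this
  (penetration is penalized, not forbidden), which is the main reason it
  is the default contact mode.
* Bones use small-strain linear elasticity inside a large-displacement
  solve; rigid translations are exact, but large rigid rotations of a bone
  would generate spurious strain. Carpal rotations here are moderate.
* Ligament springs attach at single nodes; attachment-region averaging and
  ligament-bone contact are not modelled.
* No dynamics, friction, viscoelasticity, anisotropy or damage.
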