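# Methods

## Model overview

The simulator treats peri-implant bone healing as two sequential
processes on one finite-element model of a bone–implant cross-section:
a short-term mechano-regulation stage that differentiates the soft callus
into tissue phenotypes day by day, and a long-term remodeling stage that
adapts bone apparent density toward a homeostatic stimulus.  The final
state of the first stage is the initial state of the second ("hybrid"
protocol); the "conventional" protocol starts remodeling directly from a
uniform 2 GPa bone-graft callus.  Both stages are deterministic: no
operation anywhere consumes randomness, so identical configurations give
byte-identical outputs.

## Geometry

The study geometry is a parametric 2D plane-strain cross-section in the
buccal–lingual plane: a cortical shell (default 1.5 mm) around a
cancellous core (14 × 12 mm), an extraction socket holding a
5.0 × 5.1 mm implant with rectangular thread notches, a callus annulus
(default gap 0.5 mm) between implant and bone, and a prosthesis crown on
top.  A bone–tooth twin replaces implant + callus + crown by a natural
tooth *on the identical grid*, so the healthy-state attractor stimulus
transfers element-for-element.  Meshes are structured rectilinear quad
grids, optionally refined in a band around the socket
(`refinement_factor`); the callus annulus must span at least two element
layers.  A 2D section stands in for a patient-specific extruded 3D model:
the algorithmic behavior (stress concentration at threads, marginal
region, oblique-load asymmetry) survives in 2D, but absolute stimulus
magnitudes differ, so no quantitative claims about any particular
3D anatomy should be read off these meshes.

Boundary conditions: the mesial side is a symmetry plane (normal
displacement fixed), the distal side is fully fixed, and the load is a
10.5 µm displacement (equivalent to a ~100 N bite) applied to the crown
top nodes.  The load angle from vertical is not standardized; the
default is 15° toward the lingual side and is configurable — treat it as
a modeling choice, not a measured value.

## Mechanics core

Plane-strain linear elasticity and quasi-static Biot consolidation on
bilinear quadrilaterals (2×2 Gauss stiffness) and linear triangles.
Displacements and pore pressure share the bilinear basis; because the
equal-order pair is not inf–sup stable in the undrained limit, the
storage block carries a Brezzi–Pitkäranta pressure-Laplacian
stabilization with τₑ = hₑ²/(4(λ+2µ)), which suppresses checkerboard
pressure modes and is consistent to O(h²).  Verified against the
classical consolidation-column series solution: mid-depth excess pore
pressure within 2% at Tv ∈ {0.05, 0.1, 0.5}, error halving under mesh
refinement.

Poroelastic constants not fixed by the material table: Biot coefficient
α = 1, pore-fluid bulk modulus 2.3 GPa, porosity 0.8 for soft tissues
and 0.3 for bone.  Non-porous materials (implant, tooth, prosthesis,
bone graft) are purely elastic inside the coupled solve — their nodes
carry no active pressure unknowns, which also makes the implant
interface impermeable by construction.  The exterior bone surface
(bottom and crest outside the socket) is the drainage boundary (p = 0).

Each daily solve is one backward-Euler ramp-and-hold consolidation step
of `load_duration` (default 1 s) from the instantaneous undrained state;
γ and ν are evaluated at the end of the step at element centroids
(single-point stimulus extraction even where stiffness uses full
quadrature).  The remodeling stage uses the drained elastic solve, which
is all the strain-energy-density stimulus needs.  The bone–implant
interface is bonded (merged nodes); frictional sliding is not modeled,
which shifts absolute stimulus magnitudes near the interface.

Units: the model stores mm, GPa, g/cm³ and m⁴/(N·s); conversion to SI
happens only inside the mechanics module.

## Short-term stage

One loop iteration is one day, 70 days by default (a typical implant
healing period), one mechanics solve per day.  Per day and per callus
element: classify the phenotype from S_TD = γ/a + ν/b (a = 0.0375,
b = 3 µm/s) using lower-exclusive/upper-inclusive intervals; advance the
stem-cell concentration by one implicit diffusion step
(D = 8.85×10⁻¹⁴ m²/s, dt = 86 400 s, lumped mass so the discrete maximum
principle holds on these meshes; concentration lives on nodes, averaged
to centroids); blend granulation and freshly classified tissue
properties with the rule of mixtures; and smooth by averaging the most
recent min(10, available) daily mixtures.  The smoothing is a moving
average over the raw mixture history (the common reading of the
Prendergast-school smoothing rule); an alternative recursive form that
averages previously smoothed values coincides with it at steady state.

Two deliberate consequences of this contract are worth knowing:

* Classification is immediate — every callus element carries a
  stimulus-derived phenotype from day 1, so "granulation" leaves the
  phenotype-fraction
  series at once.  The *material* story is unchanged: where the cell
  concentration is still ~0 the rule of mixtures keeps the effective
  properties at granulation values, so early-day mechanics behaves as a
  granulation-filled socket regardless of labels.
* "Resorbed" elements have no tabulated material; they keep
  granulation-tissue properties and remain classifiable on later days.

The stimulus classification and effective-property update use the
previous day's smoothed properties for the mechanics solve (solve →
classify → diffuse → mix → smooth), so the loop is an explicit
day-to-day recurrence.

## Long-term stage

S_BR = u/ρ with u the strain energy density (J/m³) and ρ the apparent
density.  ρ is stored in g/cm³ — the units in which the Carter–Hayes
constant C = 3.79 with E in GPa is a conventional fit (cortical bone at
13.7 GPa ↔ 1.53 g/cm³) — and converted to kg/m³ inside the stimulus so
S_BR is in J/kg.  The attractor K(r) is the element-wise S_BR of the
solved bone–tooth twin (twin densities from the inverse law on the
table moduli); former-callus elements get the constant K = 5 J/kg.

Density update per iteration (integrated forward Euler):

* formation, S ≥ (1+s)K: ρ += Af·Δt·[S − (1+s)K]²
* lazy zone, (1−s)K < S ≤ (1+s)K: ρ unchanged
* resorption, S ≤ (1−s)K: ρ += Ar·Δt·[S − (1−s)K]³ (the bracket is
  negative, so a positive Ar decreases ρ; the cubic makes resorption
  outpace formation at equal distance from the zone)

with s = 0.75, Af·Δt = Ar·Δt = 10⁻¹¹, ρ clamped to
[0.01, 1.74] g/cm³ (the ceiling is the inverse law at E = 20 GPa; the
floor prevents division by zero in the stimulus).  The lazy-zone branch
is homeostasis — density is *unchanged*, not zeroed.  After each update
E = Cρ³ restores modulus–density consistency; elements pinned at the
floor are flagged resorbed.  Cortical, cancellous and former-callus
elements all remodel; implant and crown never do.  The run stops at
`max_iterations` (100) or when the relative change of S_ave (the mean
stimulus over remodelable bone) drops below 10⁻⁴; setting the tolerance
to 0 forces the full run.

Note on rates: with integration coefficients of 10⁻¹¹ and stimuli of
order K ≈ 5 J/kg, per-iteration density increments are ~10⁻¹¹ g/cm³ —
the density field is effectively stationary and S_ave settles
immediately.  The coefficients are configuration parameters; studies of
the transient dynamics (resorption fronts reaching the floor, formation
bands growing) should raise them (e.g. 10⁻⁴–10⁻⁵), which the density-
update tests do explicitly.

Summary metrics: resorption volume fraction (area of floor-flagged
elements over remodelable bone area), area-weighted mean bone modulus,
and bone–implant contact fraction — the share of implant-interface edge
length whose adjacent tissue element exceeds 2 GPa.  The 2 GPa threshold
is used as stated even though the tabulated immature-bone modulus it is
nominally tied to is 1 GPa (cancellous bone is the 2 GPa entry); the
label discrepancy is inherited from the remodeling literature this
follows.

## Synthetic data: what it does and does not show

The generated cross-sections emulate the *topology* of a molar implant
site — cortical shell, cancellous core, threaded implant, callus
annulus, oblique load — and produce realistic stimulus distributions
(soft tissue at thread tips and the apex, bone elsewhere; healed-callus
mean modulus near 2 GPa).  They do not emulate patient-specific anatomy,
3D thread helices, CT-calibrated density fields, frictional interfaces,
or the periodontal ligament.  Passing tests therefore demonstrate the
correctness and qualitative behavior of the algorithms, not clinical
accuracy for any real implant case.

## Numerical choices and degenerate inputs

* Backward Euler everywhere (consolidation, diffusion): unconditionally
  stable; accuracy needs come from the test-driven step counts, not
  stability.
* Stimulus extraction at element centroids; SED floored at 0 against
  round-off.
* Zero load is a valid degenerate input: all fields vanish and the whole
  callus classifies as resorption.
* Singular systems (no displacement constraints) raise a solver error
  naming the unconstrained rigid-body mode.
* Symmetry constraints support axis-aligned planes (the generated
  geometries use a vertical mesial plane).
* Classifications at interval boundaries are upper-inclusive
  exactly as tabulated; ties at the lazy-zone boundaries produce zero
  increment on both branches, so the update is continuous in S.

## Known limitations

2D plane strain only (the data model permits 3D connectivity but no 3D
solver ships); bonded bone–implant interface; pure diffusion for cell
transport (no proliferation source, no vascular random walk); no
periodontal ligament; continuum-density remodeling without surface
remodeling or osteocyte signaling.
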