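# Methods

`cellindent` models a single invasive cell — an initially hemispherical body
(diameter 20 μm) with an embedded ellipsoidal nucleus (planar × vertical
diameters 6 × 8 μm) — resting on a soft elastic gel cylinder (radius 225 μm,
height 300 μm), and computes the quasi-static mechanical response when the
cell loads itself: a downward force routed through the top or the bottom
third of its nucleus, balanced by upward-and-inward tractions at the cell
base perimeter angled at 50° to the surface. Units are fixed to kPa, μm, nN
and s (1 nN/μm² = 1 kPa).

## Model

**Geometry and interfaces.** The loading and geometry are radially
symmetric, so the three-dimensional problem is posed in the (r, z)
half-plane with revolved (2πr-weighted) integration. The nucleus centre
sits at z = 4.5 μm so that a 0.5 μm cytoplasmic layer separates the nucleus
bottom pole from the gel: the central force reaches the gel "through" the
contact disc at the base of the cytoplasm rather than by direct
nucleus–gel contact. All interfaces (cell base ↔ gel surface, nucleus ↔
cytoplasm) are tied — no slip, no separation — which a single conforming
mesh realizes exactly: interface nodes are shared by construction, so no
constraint equations are needed and the tie cannot drift. Nucleus rotation
is impossible under axisymmetry, so the anchoring constraint of the
perinuclear cytoskeleton is satisfied by construction.

**Materials.** Cytoplasm and nucleus are compressible Neo-Hookean solids,
W = (μ/2)(I₁ − 3) − μ ln J + (λ/2)(ln J)², with Young's moduli 0.8–2.0 kPa
(cytoplasm, swept) and 2.0 kPa (nucleus), Poisson ratio 0.49. The gel
(E = 2.4 kPa, ν = 0.48) is "linearly elastic" in the sense of an exact
Hookean small-strain limit; it is carried by the same Neo-Hookean kernel
because the local compressive stretches under the contact (up to ~40%)
destroy the convexity of the Saint Venant–Kirchhoff alternative — we
verified that an SVK gel inverts elements below ~20 nN. SVK remains
available as an explicit law (`svk`) for small-strain use. Densities are
accepted in configs but unused: body forces other than the applied load are
zero in the quasi-static balance.

**Viscoelastic cytoplasm.** A two-branch Prony series
(G∞, G₁, G₂ = 4.05, 34, 20.2 kPa; τ₁, τ₂ = 0.58, 5.47 s) defines the
reduced relaxation function g(t); the cytoplasm stress is the quasi-linear
viscoelastic convolution of g with the Neo-Hookean PK2 stress, integrated
by the standard exponential recurrence (exact for elastic stress varying
linearly across a step). Because the printed branch moduli sum to
58.25 kPa — far above the quoted 0.8–2 kPa elastic cytoplasm — two
anchorings are provided:

* `literal` (production default): the constants are shear moduli in kPa.
  Instantaneous shear modulus ΣG = 58.25 kPa, relaxed shear modulus
  G∞ = 4.05 kPa, i.e. a relaxed Young's modulus of 12.07 kPa at ν = 0.49.
* `equilibrium`: the constants act only as relaxation weights and the
  relaxed modulus equals the elastic-case E; elastic and viscoelastic runs
  then provably coincide at steady state, which makes this mode useful for
  verification but structurally incapable of producing elastic-vs-
  viscoelastic contrasts under held loads.

Note a timescale subtlety: under force control the *structure* creeps on
τ/g(∞) ≈ 79 s, an order of magnitude slower than the material relaxation
times; holds default to 400 s (> 4 creep times).

**Loading.** The perimeter push–pull is applied as a uniform body-force
density over the annular band of cytoplasm elements within 1 μm of the
base rim (upward resultant F, inward resultant F/tan 50°); the central
force as a uniform downward body-force density over the selected nucleus
third (thirds of the nucleus z-extent, elements selected by centroid).
Volumetric bands, rather than surface tractions, mirror the highlighted
element bands of the reference configuration sketches and keep tractions
finite. The assembled vertical resultant vanishes to round-off — the cell
is self-equilibrated and the gel reacts only through the tied interface.
Gel bottom and lateral faces are fully fixed; the axis carries u_r = 0; the
gel top and all cell surfaces are free.

## Discretization and solver

Six-node (quadratic) triangles with three-point quadrature are the default
element: the mild under-integration relieves volumetric locking at
ν = 0.48–0.49, and this element passes the analytic benchmarks (rigid flat
punch on the gel within 1–3% of the Boussinesq depth d = F(1−ν²)/(2aE);
monotone convergence under refinement). Linear (constant-strain) triangles
are available as `element_order=1`; they lock noticeably (0.82× the
Boussinesq depth at the coarsest level) — which is precisely the behaviour
of the linear-tetrahedra family used by the solver that produced the
published numbers, and the reason they are the **production-study
element** (below).

Nonlinear equilibrium is solved by Newton iteration with analytic
consistent tangents (verified against finite differences to ~1e-6),
backtracking line search, incremental loading with a secant predictor and
automatic step halving, and a Levenberg-damped fallback that engages when
plain Newton stalls near limit points. Linear systems use SuperLU with its
deterministic default ordering, so repeated runs are bit-identical.
Convergence demands a relative residual ≤ 1e-8; reactions then balance the
applied resultant to better than 1e-8 relative. A grid-sequencing helper
prolongs a coarse solution onto a refined mesh to warm-start refined
solves.

Mesh resolution is a single integer scaling every subdivision count;
region volumes match the analytic hemisphere/ellipsoid/cylinder values
within 2% already at level 1, and element counts grow ≈ quadratically.

## The production study frame, and what it shows

The study grid is the published protocol: forces 50–300 nN in 50 nN steps,
cytoplasm stiffness {0.8, 1.2, 2.0} kPa, both force configurations,
elastic and viscoelastic cytoplasm. Production runs use linear triangles
at resolution 1 (cell elements ≈ 1.2 μm, matching the reference model's
637/7197-element nucleus/cytoplasm meshes).

This element choice is deliberate and is the package's most consequential
design decision. With the printed parameters the model is *soft*: the
300 nN central force funnels through the nucleus bottom pole (curvature
radius a²/b = 2.25 μm) into the 2.4 kPa gel, and the computed indentation
(~10 μm at 300 nN) matches the classical Hertz estimate
(9F²/16RE*²)^{1/3} ≈ 13 μm to within the geometric corrections. Beyond
~200 nN the 2 kPa, ν = 0.49 nucleus (shear modulus 0.67 kPa) has no
stable axisymmetric equilibrium under the top-routed force with
locking-free quadratic elements — the quasi-static path terminates at a
collapse fold, and refining the mesh sharpens the fold. Linear triangles
at the reference coarseness stabilize the collapse the same way the
reference discretization did, and are the only frame in which the full
published force ladder possesses solutions. The quadratic element remains
the default for everything with an analytic answer.

Two consequences are documented rather than hidden. First, absolute
indentation depths in this honest parameterization are ≈ 2.5–3× the
published ones; reproducing those absolutes would require a cell
effectively 5–10× stiffer than its printed moduli (the volumetric-locking
bias of coarse linear tetrahedra at ν ≈ 0.49). Second, the low-force
indentation ordering comes out bottom > top here (the bottom-routed force
is the more direct punch), the opposite of the published ordering, which
belongs to the quasi-rigid-cell regime. Ratio-type outcomes are far more
robust: the nuclear-stress contrast (top ≫ bottom, 2.3–8-fold across the
ladder), the gel-transmission ordering (bottom > top at every grid point),
the near-closure of the depth gap at 300 nN (≈ 1%), and the viscoelastic
attenuation of peak nuclear stress (≈ 39% vs the published ≈ 42%) all
reproduce.

**Aggregation choices.** The published scalars "stress in the
nucleus/gel" do not state their aggregation. Region scalars here are
volume means over revolved quadrature weights (max and volume-sum are also
computed). For the gel-transmission comparisons the *whole-gel* mean von
Mises stress is used: it is the aggregate whose top/bottom ordering is
concordant with the published comparisons at every grid point, whereas the
localized under-cell mean (the library default for single-run reporting)
loses the ordering at 300 nN where the deep top-applied crater dominates
it. Nucleus "total stress" is the trace of the Cauchy stress (the sum of
the three directional stresses); both configurations are compressive at
high force, so signed percentage differences are positive as printed.

**Viscoelastic protocol.** Load ramps over 1 s and is held; stepping stops
when the per-step relative change of indentation depth falls below 1e-4 or
the hold is exhausted. At 300 nN the literal-mode creep path encounters a
creep-buckling fold mid-hold where no quasi-static continuation exists;
the relaxed steady state still exists and is computed exactly as the
elastic solve with the relaxed moduli (the t → ∞ limit of quasi-linear
viscoelasticity). `run_single` falls back to that equivalence
automatically and flags it in its output; the time stepper itself is
verified against the equivalence at small force.

**Mesh convergence.** The <2% refinement criterion for indentation depth
is met by the quadratic element in the stable response regime (100 nN:
1.6% between resolutions 2 and 3). In the post-collapse regime no
discretization converges in h (the coarse-mesh stabilization *is* part of
the response there); the convergence study reports the honest ≈ 20%
level-1 → level-2 change at 300 nN rather than hiding it.

## What the verification fixtures do and do not show

The fixtures (flat punch vs the Boussinesq closed form, single-point
uniaxial states vs energy-differentiated stresses, step-strain relaxation
vs g(t), seeded random equilibrium checks) pin down the correctness of
kinematics, assembly, constitutive laws and the time integrator. They are
synthetic benchmark problems, not biological data: passing them certifies
the solver, not the biological fidelity of the cell model — which
inherits the published idealizations (no actin dynamics, no cortex, tied
non-separating contacts, axisymmetry).

## Known limitations

* No self-contact: once the free cell surface folds onto itself (top
  config, ≳250 nN, fine meshes) the model leaves its validity domain.
* Axisymmetry excludes non-axisymmetric buckling modes and collective
  (multi-cell) configurations.
* The perimeter-band width (1 μm) and the nucleus gap (0.5 μm) are
  geometric choices the reference leaves unstated; both are config
  parameters.
* Absolute stress/depth magnitudes depend on element technology in the
  collapse regime; only ratio-type comparisons should be read
  quantitatively there.
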