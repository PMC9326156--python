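# Methods

This note documents the models, parameters and numerical choices behind
`gopharm`, and what the synthetic test harness does and does not
establish.

## Scoring models

### Gaussian shape overlap

Atoms are soft Gaussians g(r) = p·exp(−α|r − r₀|²) with
α = (3p√π / 4σ³)^{2/3}, so that the Gaussian integrates to the
hard-sphere volume 4πσ³/3.  The molecular overlap is the weighted
first-order pair sum V_AB = Σ wᵢwⱼvᵢⱼ, where vᵢⱼ is the closed-form
product-Gaussian integral and the weights
wᵢ = vᵢ/(vᵢ + k·Σ_{j≠i} vᵢⱼ), k = 0.8665, damp the over-counting that a
first-order sum incurs inside dense molecules.  Higher-order
inclusion–exclusion terms are deliberately absent: the weighting is the
correction.  Key properties relied on throughout:

- weights depend only on *intra*-molecular distances → rigid-motion
  invariant → computed once per molecule, never per pose;
- V_AB(A, A at identity) = V_AA, so Tc_S = V_AB/(V_AA+V_BB−V_AB) is
  exactly 1 for self-comparison and bounded in [0, 1].

Parameters: softness p = 2.7 (the conventional value at which one
Gaussian reproduces its hard sphere), vdW radii from the bundled Bondi
table (user-overridable TSV), pair cutoff d > 4.5(σᵢ+σⱼ) discarding
terms below ~10⁻¹² of their d = 0 value (pure speed; documented bound).

### Grid electrostatics

The potential is evaluated on a regular grid of spacing h covering the
molecule plus a margin.  The physically complete route would solve a
Poisson problem with a spatially varying dielectric; that solver is out
of scope here, so φ comes from a pluggable potential model whose default
is the uniform-dielectric Coulomb sum φ(r) = Σ qₐ/(4πε|r − rₐ|).  The
similarity machinery — masked product integral and Tanimoto ratio — is
independent of how φ is produced, and a finite-difference solver can be
supplied as `ElectroParams.potential_model`.

Numerical choices:

- mask Θ = 0 strictly inside the unscaled vdW envelope, 1 elsewhere; no
  outer cutoff (the grid extent bounds the integral);
- the target's φ and Θ are re-evaluated on the query's fixed grid from
  the transformed atom positions at every pose — rotating a precomputed
  grid would introduce interpolation error and break the exact
  self-similarity identity;
- self energies E_AA are computed once per molecule on its own grid
  (rigid-motion invariant) and cached;
- defaults h = 0.5 Å, margin = 5 Å, ε = 4: chosen for desk-scale
  runtime; the Tanimoto identities (self = 1, charge-negated = −1/3) are
  algebraic on any shared grid and do not depend on them.  Off-identity
  Tc_E values do depend on h; halving h moves a typical toy-pair score
  by < 0.02.

## Pose space and search domain

A pose is (α, θ, φ, Δx, Δy, Δz).  The rotation axis is the unit vector
(cosθ·sinφ, sinθ·sinφ, cosφ) with φ ∈ [0, π/2]: restricting to the upper
hemisphere gives every axis a unique code and removes the redundant
proportional-vector representations a 3-vector axis would have.  The
rotation (Rodrigues) is about the origin of the query frame — both
molecules are pre-centered by the canonical orientation step — followed
by the translation.  Translation bounds are half the summed bounding-box
extents per axis (the displacement at which the boxes can just
separate), floored at 1 Å for degenerate point-like inputs.

Projection keeps candidates in the domain: α and θ wrap circularly via
the double modulus mod(mod(x, U) + U, U) into [0, 2π) — preserving
search continuity across the 0/2π seam — while φ and the translations
clamp.  At φ = 0 the axis is the pole (0, 0, 1) and θ is inert; no
special-casing is needed elsewhere.

Canonical orientation centers the molecule and aligns principal axes
(largest variance → X, smallest → Z).  Axis signs for X and Y follow the
largest-|projection| atom convention; Z is X × Y so the rotation is
always proper (det = +1).  Fixing all three signs independently could
produce an improper rotation, which is why the Z sign is derived.

## The optimizer

Cost convention: the optimizer *minimizes* cost = −Tc, because the
algorithm's selection and acceptance rules are written as a minimizer;
similarity is recovered as −cost.

Each iteration applies three phases; every phase builds one candidate
per individual, projects it, evaluates it, and accepts it only on
*strict* improvement (ties keep the incumbent — deterministic).

- **Leader**: move toward the population argmin T with
  X̃ = X + rt·(T − TF·X̄ + (TF−1)·R), TF ∈ {1, 2} per individual, and a
  polynomial-mutation reference point R around T (distribution index
  n_m = 20).  The exponent in the reference-point formula is read as
  (r^{1/(n_m+1)}) − 1, i.e. the standard bounded polynomial-mutation
  delta in [−1, 0]; the literal reading r^{1/(n_m+1)−1} would produce
  unbounded offspring and is available behind
  `GOPharmConfig.literal_exponent` for auditing only.
- **Collaborative**: move toward (away from) a random partner when the
  partner is better (worse); zero step on exact cost ties.
- **Self-guiding**: standard bounded polynomial mutation of each
  variable around the incumbent; r₃ = 0.5 leaves a variable unchanged.

Random draws subscripted ij in the formulas (rt, rl, r₁, r₂, r₃) are
fresh per individual *and* per variable; TF and the partner index are
per individual.

**Axis lock / convergence test.**  The axis variables (θ, φ) are frozen
until the best cost stagnates: at iteration k ≥ 5 the current best is
compared with the best five iterations earlier and the axis is freed iff
the absolute difference is below δ = 10⁻⁴.  The recorded history starts
with the initialization best; for k = 5 the lookback clamps to that
initialization value so the test first fires at k = 5 (a strict
six-entry window would delay it to k = 6; the off-by-one is documented
here and has no qualitative effect).  The test is re-evaluated every
iteration, never latched.

**Duplicates.**  After the third phase, individuals equal in all six
variables (relative tolerance 10⁻⁹ of each range) are perturbed by up to
±1% of each range on a random nonempty coordinate subset, projected and
re-evaluated.  Two subtleties: the scan keeps the *best* member of each
duplicate cluster (otherwise near-duplicates could evict the incumbent
best and break the monotone best-cost history), and the perturbable
subset excludes θ/φ while the axis is locked (otherwise the lock
invariant would be violated).

**Accounting.**  Phase evaluations are exactly 3·N·M_iter per run —
30,000 at the defaults — because every phase evaluates every individual
once regardless of acceptance.  Initialization evaluations (N per run)
and duplicate re-evaluations are counted in separate fields so the
headline 10×3×1000×5 = 150,000 arithmetic of a full two-layer pair is
reproduced exactly.

## Two-layer strategy

Layer 1: four independent runs, each seeded with one problem-knowledge
pose — identity, and half-turns about OX, OY, OZ — plus N−1 random
individuals.  Layer 2: one run seeded with the four optima, four
axis-flipped variants (θ̃ = θ − π/2 circularly, φ̃ = π/2 − φ, everything
else redrawn), and random fill; requires N ≥ 8.  Elitist seeding
guarantees the final similarity is at least the best first-layer one.
The five runs use independent substreams spawned from one master
generator, so a single seed reproduces the whole procedure.  The
second-layer random fill is plain uniform (no reuse of first-layer
knowledge beyond the eight seeds).

## Screening and statistics

One two-layer run per query–target pair; the self-pair (same id) is
skipped.  Per-pair seeds are derived by hashing (master seed, query id,
target id, run index) — a determinism contract that also makes screens
embarrassingly parallelizable.  ROC-AUC uses the Mann–Whitney midrank
form (ties get half credit); repeated-run summaries use the sample
(n−1) standard deviation.  The reference protocol repeats each instance
50 times.

## Synthetic data

The generator emulates a drug-like small molecule only geometrically:
~20 atoms uniform in an 8 Å cube, vdW radii in [1.2, 1.8] Å, partial
charges in [−0.4, 0.4] e shifted to net neutrality (so electrostatic
similarity exercises sign structure, not monopole dominance).  Clouds
with principal-moment ratio λ₁/λ₃ < 1.5 are rejected so pose-recovery
tests have a unique optimum basin.  It does *not* produce bonds,
valences, realistic charge distributions or conformers — a green
synthetic test establishes the machinery (scoring identities, optimizer
behavior, recovery of a known rigid pose), not agreement with any
published per-compound similarity value, which additionally depends on
unpublished radius/charge/softness/grid choices.

Pose-recovery experiments canonicalize both the query and the posed
copy before optimizing, exactly as every molecule entering the real
pipeline is preprocessed.  Without that centering (targets displaced by
most of the translation range) the landscape is dominated by flat
zero-overlap regions and the optimizer recovers only about half of such
instances — a known limitation of the guided search on unnormalized
inputs, which the pipeline never presents to it.

## Known limitations

- Rigid-body poses only; no conformer flexibility.
- The Coulomb default ignores dielectric boundaries and solvent
  screening; plug in a Poisson solver for physically faithful fields.
- First-order weighted Gaussian overlap; no pharmacophore/color terms.
- Reproducing published per-compound DrugBank/DUD scores requires the
  original structure files and parameter choices not shipped here.
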