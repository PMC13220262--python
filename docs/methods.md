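# Methods

This note documents the models, numerical choices and limitations of
`cgpathway`.  Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Coarse-grained representation

Each residue is reduced to two beads: its Cα and the unweighted
centroid of the resolved side-chain heavy atoms (all heavy atoms past
Cα, excluding backbone N/C/O).  Glycine, and residues with no
resolved side-chain atoms, carry no centroid; wherever a side-chain
bead is needed (burial, pair terms) their Cα stands in.  Hetero groups
(ligands, sterols) are opt-in by residue name and become one rigid
bead per heavy atom with a user-supplied partial charge and radius;
they are held fixed in every stage, mirroring positional restraints
on a bound ligand.  Structures are taken as pre-oriented with the
membrane normal along +z (OPM-style); the package never re-orients
them.

This two-bead representation is the smallest one that can express the
two motion classes the pipeline analyses — a collective backbone hinge
and a discrete side-chain rotamer switch.

## Surrogate membrane energy function

The energy of a frame is a sum of five terms, every constant of which
lives in `EnergyParams` (defaults in parentheses):

* **Membrane burial** `Σ h(res)·f(z)` — h is a per-residue transfer
  free energy (Wimley–White water→octanol scale, kcal/mol; replaceable
  wholesale) evaluated at the side-chain bead; f(z) is 1 inside the
  slab (z ∈ [−15, +15] Å), falls as cos² over a 6 Å taper, and is 0
  beyond it.
* **Screened Coulomb** `332.0637·q_iq_j/(ε(r)·r)` over formally charged
  side-chain beads (Asp/Glu −1, Lys/Arg +1, His 0; fixed protonation),
  with a distance-dependent dielectric ε(r) = ε₀ + m·r (ε₀ = 1,
  m = 3.9 Å⁻¹, i.e. ε ≈ 40 at 10 Å).  Below `elec_r_min` (2 Å) the
  interaction is held at its value there (zero force): the bare form
  diverges as r → 0 and would otherwise let oppositely charged beads
  collapse during long relaxations.
* **Contact** — an attractive 8-6 well
  `ε_c[(σ/r)⁸ − 2(σ/r)⁶]` (ε_c = 0.3 kcal/mol, σ = 6 Å) between
  side-chain beads, clamped to ≤ 0 so that short-range repulsion is
  handled by one term only.
* **Excluded volume** — harmonic overlap `k(r₀ − r)²` (k = 10
  kcal/mol/Å², r₀ = 4 Å) between Cα pairs *and* between side-chain
  bead pairs.  The latter is required for boundedness: with the
  contact term clamped, nothing else prevents side-chain bead overlap.
* **Ligand interaction** — the electrostatic and contact terms between
  hetero beads and residue beads, with a per-bead contact radius
  σ_b = bead radius + σ/2.

Pair terms act between residues with sequence separation ≥ 3 within a
chain (inter-chain pairs always qualify; separation is measured on
author numbering) and are cut off at 12 Å with a cos² switching
function over the last 2 Å, so the energy is continuous in the
coordinates.  The evaluator is vectorised with analytic gradients;
the test suite checks it against an independently written double-loop
oracle to 1e-9 relative and against finite differences.

"Free energy" here is the CG potential of a relaxed single frame —
there is no entropy estimator and no ensemble averaging per
intermediate.  Profiles are therefore conformational *energy*
profiles of relaxed frames; this is a deliberate simplification and
the central caveat when reading barrier magnitudes.

## Targeted morphing

The pathway generator is a desk-scale surrogate for targeted MD.  The
target is Kabsch-superposed onto the start; all paired beads are then
steered by a harmonic restraint ½·k(R − ρ)² on the direct RMSD R to
the target, with the restraint centre ρ scheduled linearly from the
initial RMSD to 0 over `n_steps` (120) steps.  Each step applies
`relax_iters` (40) moves of gradient descent on E_CG + restraint, with
the per-move displacement capped at `step_size` (0.02 Å) for the
worst bead; optional Gaussian coordinate noise (seeded, default 0)
makes the relaxation stochastic but bit-reproducible.  A harmonic
tether (k = 100 kcal/mol/Å²) keeps each side-chain bead at its native
distance from its Cα during relaxation — in a two-bead model nothing
else bonds a side chain to its residue.  Frozen selections
(hetero beads by default, plus optional residues) never move and are
excluded from steering.

Frame 0 is the start structure bit-for-bit.  After the last step the
achieved RMSD must be ≤ `convergence_tol` (0.15 Å) or the morph fails
with a convergence error; on success the terminal frame is set to the
target exactly, so the path is anchored at both endpoints.

Both endpoints are settled by 200 iterations of unrestrained energy
descent before morphing (configurable).  Without this, the first morph
step mixes steering with a large relaxation jump and the early path is
sparse in progress; with it, frames are close to uniformly spaced.
Intermediates along a morph accumulate more relaxation than the
endpoints, so profiles can dip below zero mid-path — scores compare
similarly relaxed frames, not variationally minimised ones.

## Progress coordinate and intermediate extraction

Progress is s = d₀/(d₀ + d₁), where d₀/d₁ are the RMSDs of a frame to
start/target over Cα *and* side-chain beads after a Cα fit.  The
side-chain beads are included deliberately: steering distributes the
restraint over all beads while the energy acts mostly on side chains,
so a Cα-only metric saturates near 1 once the backbone has converged
and would bunch all late frames together.  s is 0 at the start, 1 at
the target, symmetric, and dimensionless.

"Uniform extraction" of n intermediates (default 30, endpoints
included) picks the frames nearest to the grid {0, 1/(n−1), …, 1} in
s; duplicates collapse with a warning.  Uniformity is in conformational
progress, not in simulation time.

## Profile analysis

G[i] = E(frame_i) − E(frame_0), so G[0] = 0 at the inactive state by
construction.  An optional centred moving average (odd window,
shrinking symmetrically at the edges, re-anchored at 0) smooths
sampling noise.  Stationary points are discrete extrema by sign change
of finite differences; exact plateaus collapse to their midpoint;
endpoints are candidate minima only.  A maximum whose barrier over the
preceding minimum is below the prominence threshold (default 0.5
kcal/mol) is merged away together with the shallower neighbouring
minimum, so minima/maxima strictly alternate and every reported
barrier clears the threshold.  Barriers are ΔG‡ = G(TS) − G(preceding
minimum); the rate-limiting TS is the argmax, ties resolved toward the
lower index.  TS positions are reported at sample resolution — no
spline interpolation.

The 0.5 kcal/mol default suppresses jitter without hiding barriers on
the few-kcal/mol scale of receptor activation profiles; for noisy
profiles (σ ≈ 0.1 kcal/mol) a window-7 moving average plus this
threshold recovers all three barriers of the default triple-well in
≥ 95 of 100 seeds with errors below 0.3 kcal/mol (computed by the
acceptance script, not assumed).

## Perturbation experiments

*Alanine truncation* renames the residue to ALA and moves its
side-chain bead to 1.52 Å from the Cα along the original direction;
glycine sites are rejected (no direction), alanine sites are warned
no-ops.  *Rotamer transfer* superposes the reference's local backbone
window (site ± 2 residues, Cα only) onto the target structure and
transplants the transformed side-chain bead.

ΔΔG‡ scans mutate BOTH endpoints identically and re-run the full
pipeline with the same seed and configuration — each mutant owns its
pathway; mutants are never single-frame rescorings.  Transition states
are matched between wild type and mutant by rank order along s; count
mismatches are flagged and unmatched TS reported as missing rather
than imputed.  Classification uses a neutrality band τ (default 0.25
kcal/mol): ΔΔG‡ > τ "inhibits", < −τ "facilitates", else "neutral".
Identity mutations give exactly zero because the pipeline is
bit-deterministic at fixed seed.

`ddg_scan` accepts an alternative pathway generator (`morph_fn`).
The synthetic module provides a deterministic straight-line
interpolator with optional planted side-chain excursions
(`height·sin²(πt)` along +z), which is how the test suite constructs
pathways whose transition-region energetics are known exactly — a
mid-path membrane exit of a chosen residue cannot be produced by
steering between any two endpoint geometries, so it is planted by
construction.  The same hook supports averaging profiles over
multiple start frames.

## Synthetic ground truth

The toy two-state protein is an ideal antiparallel two-helix hairpin
(rise 1.5 Å/residue, 100° twist, radius 2.3 Å, Cβ-like beads at
1.53 Å), centred on the membrane mid-plane; activation is a hinge
rotation of helix 2 about an in-plane axis through the loop midpoint
plus a rotamer flip of one tryptophan from radial ("flattened") to
axial ("vertical").  Sequences are drawn per-seed from a 15-residue
palette (no glycine/proline, so every residue has a side-chain bead).
The generator book-keeps exactly which residues differ between states,
and the bookkeeping is asserted in tests.

Analytic landscapes are sums of Gaussian wells and bumps on s ∈ [0,1];
stationary points are located at construction by a 10⁵-point grid
search refined by bounded scalar minimisation (≈1e-10), giving
closed-form-grade ground truth.  The default triple-well's barriers
are on the scale seen for chemokine-receptor activation (≈13, 5, 7
kcal/mol); sampled profiles add i.i.d. Gaussian noise — the simplest
model under which the prominence threshold can be calibrated.

What the toys do **not** emulate: real sequence statistics, loop
flexibility, lipid or cholesterol particles, G-protein coupling, and
any entropic contribution.  A test passing on them validates the
pipeline's logic and numerics, not the energetics of any real
receptor.

## Problem sizes and determinism

Default study sizes: 60-residue toys for morph/profile experiments,
120 morph steps × 40 relaxation moves, 30 extracted intermediates,
301-point landscape sampling, and 100-seed Monte-Carlo checks.  All
randomness flows from one master seed (config `seed`); with zero
noise the morph is deterministic regardless of seed, and identical
configurations reproduce outputs byte-for-byte.

## Known limitations

* The energy function is a documented surrogate, not a published
  membrane CG parametrisation; absolute barrier heights are not
  comparable to experiment or to all-atom MD.
* Single-frame scoring (no ensemble averages, no entropy).
* Chord-space steering cannot discover detours: if the physical
  pathway leaves the direct conformational corridor, the morph will
  not find it.
* Discrete TS positions (sample resolution); 1D profiles only.
* Fixed protonation; no titratable residues; His is treated as
  neutral.
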