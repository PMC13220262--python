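# cgpathway

Coarse-grained activation-pathway analysis for membrane proteins.

Class-A G-protein-coupled receptors (GPCRs) such as the chemokine
receptor CXCR4 switch between an inactive and an active conformation
over a rugged free-energy landscape: activation proceeds through
intermediate states (Int1, Int2, …) separated by transition states
(TS1, TS2, …), and the largest barrier ΔG‡ sets the rate-limiting
step.  Which residues pay for those barriers — hinge residues in
intracellular loop 3, rotamer "microswitches" like a tryptophan that
flips from a flattened to a vertical orientation, cholesterol-pocket
side chains — is exactly the information an agonist designer wants.

`cgpathway` is a desk-scale pipeline for that analysis.  Given two
endpoint structures (PDB or mmCIF, pre-oriented with the membrane
normal along +z):

1. **Coarse-graining** — two beads per residue: the Cα and the
   unweighted centroid of the side-chain heavy atoms; ligands/sterols
   optionally carried as rigid hetero beads.
2. **Targeted morphing** — a surrogate for targeted molecular dynamics:
   gradient descent on the CG energy under a harmonic RMSD-to-target
   restraint ½·k(R − ρ)² whose centre ρ is scheduled linearly from the
   initial RMSD to 0.
3. **Energy scoring** — a transparent surrogate membrane energy
   E = Σ h(res)·f(z) (Wimley–White burial) + screened Coulomb
   332.0637·q_iq_j/(ε(r)·r) with ε(r) = ε₀ + m·r + an 8-6 contact
   well + harmonic excluded volume (+ rigid-ligand interaction terms).
4. **Profile analysis** — the conformational free-energy profile
   G(s) along the progress coordinate s = d₀/(d₀+d₁), zeroed at the
   inactive state; 30 uniformly spaced intermediates by default;
   alternating Int/TS detection with a prominence threshold, per-TS
   barriers ΔG‡ = G(TS) − G(preceding Int), and the rate-limiting TS.
5. **Perturbation** — side-chain rotamer switches transferred from a
   reference state, and alanine scanning with
   ΔΔG‡ = ΔG‡_mutant − ΔG‡_WT per transition state
   (ΔΔG‡ > 0 inhibits activation, ΔΔG‡ < 0 facilitates).

A first-class synthetic-data module supplies two-state toy membrane
proteins (hinge motion + rotamer switch) and analytic multi-well
landscapes with exact ground truth, so the whole pipeline is testable
without downloading any structures.

## Worked example

`examples/` holds one short script per capability.  Alanine scanning
on a pathway with a planted transition-region contribution
(`python examples/03_alanine_scan.py`) prints:

```
wild-type barriers: {'TS1': 3.34}
site A:7   TS1: dG_wt= 3.340  dG_mut= 1.250  ddG=-2.090 kcal/mol  -> facilitates
site A:9   TS1: dG_wt= 3.340  dG_mut= 3.340  ddG=+0.000 kcal/mol  -> neutral
site A:12  TS1: dG_wt= 3.340  dG_mut= 3.340  ddG=+0.000 kcal/mol  -> neutral
```

Residue A:7 is a tryptophan that exits the membrane slab only in
transition-region frames, contributing its transfer free energy
(+2.09 kcal/mol) to the barrier by construction; truncating it to
alanine removes exactly that work (ΔΔG‡ = −2.09, "facilitates").
A:9 is already alanine (a no-op control, exactly 0) and A:12 never
contributes burial work (neutral).

Barrier detection against exact ground truth
(`python examples/04_analytic_landscape.py`):

```
ground-truth barriers : [12.88   4.887  7.41 ] kcal/mol
recovered states      : ['Int1', 'Int2', 'Int3', 'Int4'] ['TS1', 'TS2', 'TS3']
TS1: true 12.880  recovered 12.791  error 0.089 kcal/mol
TS2: true  4.887  recovered  4.766  error 0.120 kcal/mol
TS3: true  7.410  recovered  7.357  error 0.053 kcal/mol
rate-limiting step    : TS1
```

## Command line

A thin CLI wraps the library for shell use:

```sh
cgpathway synth --n-res 60 --hinge-angle 15 --out toy/        # toy endpoints
cgpathway profile --config run.json                           # activation profile
cgpathway switch  --config run.json --sites sites.tsv         # rotamer switch
cgpathway alascan --config run.json --sites sites.tsv         # ΔΔG‡ scan
cgpathway superpose mobile.pdb reference.pdb                  # Kabsch fit
```

A single JSON/TOML config file carries every parameter (energy
constants, morph schedule, analysis knobs, master seed) and is echoed
into the output directory, so every run is self-describing and
bit-reproducible.

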