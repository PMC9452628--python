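# hcnflex

Rigidity-theory stability mapping, conformational-ensemble geometry and
gating-curve analysis for HCN-channel glycine-insertion constructs.

HCN channels are tetrameric, hyperpolarization-activated cation channels
whose opening is enhanced by cAMP binding to the intracellular
cyclic-nucleotide-binding domain (CNBD).  A classic way to probe how the
cAMP signal reaches the pore is to uncouple the C-linker (CL) from the
S6 gate helix by inserting glycines between them and then ask what
changed — in the channel's function (activation curves, kinetics, ligand
binding) and in its structural ensemble (mobility, inter-domain
geometry, local mechanical stability).  `hcnflex` implements that
computational analysis chain as a reusable, tested Python library for
structural bioinformaticians and channel physiologists:

* **Constraint networks & rigidity.**  Structure snapshots become
  body-bar networks: atoms are rigid bodies; covalent bonds contribute
  5 bars (6 when non-rotatable), hydrogen bonds and salt bridges 5 bars
  with a Mayo-type energy
  `E_HB = V₀ [5(d₀/d)¹² − 6(d₀/d)¹⁰]·F(θ,φ,γ)` (V₀ = 8 kcal/mol,
  d₀ = 2.8 Å), and hydrophobic tethers between apolar C/S atoms
  (cutoff = Σ vdW radii + 0.25 Å) 2 bars.  A (6,6) pebble game
  decomposes each network into rigid clusters and floppy modes; diluting
  hydrogen bonds in order of increasing strength yields neighbor
  stability maps
  `rc_ij = min{E_cut | ∃ c ∈ C^Ecut : R_i, R_j ∈ c}`
  over residue pairs in ≤ 4.5 Å heavy-atom contact, per-residue
  chemical potential energies `E_i = ½ Σ_{j≠i} rc_ij`, their total
  `E_CNA = Σ_{i<j} rc_ij`, and construct-vs-wildtype difference maps
  `ΔE_i = E_i(ref) − E_i(construct)` with per-residue Welch tests
  (negative ΔE_i = destabilized construct).
* **Ensemble geometry.**  Pore-superposed residue-wise RMSF, the
  vertical displacement `d_z` between the S6 C-terminus and the
  C-linker of the counter-clockwise preceding subunit, the S6–A′ helix
  kink angle, S4–CL contact counts, and Kabsch–Sander secondary
  structure with per-region content.
* **Electrophysiology & fluorometry fits.**  Boltzmann steady-state
  activation `I/I_max = I/I_max,satV / (1 + e^{zδF(V−V_1/2)/RT})`,
  single-exponential activation kinetics (τ after an initial delay),
  the Hill binding relation `F/F_max = 1/(1 + (BC₅₀/x)^{H_b})`, the
  dual-dye bound-fluorescence correction for confocal patch-clamp
  fluorometry, and the grand-mean ± SEM convention (subunits → runs).
* **Synthetic ground truth.**  Generators build C₄-symmetric
  poly-alanine two-segment helices whose S6/CL junction is a tunable
  hinge, with optional planted downward CL shifts, plus noisy
  forward-simulated recordings — so every stage runs end-to-end with
  known answers and no external data.

## Worked example

`examples/hinged_construct_comparison.py` compares a near-rigid
"wildtype" tetramer against a flexibly hinged "construct" (the in-silico
analogue of a glycine insertion) through the full pipeline:

```
grand-mean d_z (Å):
  0G: 9.34 ± 0.01
  4G: 9.15 ± 0.02
grand-mean S6-A' kink angle (deg):
  0G: 1.4 ± 0.1
  4G: 12.6 ± 0.2

significantly destabilized residues (ΔE_i = E_i,ref − E_i,con < 0):
 residue  dE_kcal_mol        p
       7    -0.856944 0.022646
       8    -0.586250 0.011998
       9    -0.891875 0.003200
```

The hinged construct kinks at the S6–A′ junction (12.6° vs 1.4°), and
the dilution analysis flags exactly the hinge-flanking residues (the
junction lies between local residues 8 and 9) as significantly
destabilized — the same signature, in direction and location, that
glycine insertions produce in the real channel.  The other examples
(`rigidity_dilution.py`, `gating_fits.py`,
`binding_image_correction.py`) each exercise one capability and print
what the numbers mean.

A thin CLI mirrors the library: `hcnflex run -c config.yaml` drives the
comparison from a YAML config, `hcnflex generate-ensemble` writes
synthetic multi-model PDB fixtures, `hcnflex fit
boltzmann|exponential|hill table.tsv` fits a delimited data table.

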