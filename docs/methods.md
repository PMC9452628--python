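# Methods

This note records the models implemented in `hcnflex`, the defaults and
why they were chosen, what the synthetic generators do and do not
emulate, and the numerical choices a user should know about.

## Constraint networks

A snapshot is converted to a body-bar framework in which every atom is
a rigid body with 6 degrees of freedom and every interaction removes
degrees of freedom through bars:

| interaction | bars | rationale |
|---|---|---|
| covalent bond, rotatable | 5 | leaves the dihedral spin free |
| covalent bond, non-rotatable | 6 | peptide bonds, double/aromatic bonds, ring bonds |
| hydrogen bond / salt bridge | 5 | locked except for the bond-axis spin |
| hydrophobic tether | 2 | weak, slippery contact |

Covalent topology comes from the Chemical Component Dictionary residue
templates shipped with biotite, plus peptide links between consecutive
residues of a chain and disulfides detected as SG–SG pairs within
2.3 Å.  Ring membership is computed per residue with a cycle basis.
No bond perception from coordinates is attempted; a residue whose atoms
do not match any template is a hard error naming the residue.

**Hydrogen bonds.**  Donors are N/O/S atoms with a covalently bound
hydrogen (structures are expected to be protonated, as MD-derived
snapshots are; a nitrogen that could donate but has no hydrogen is
skipped with a warning).  Acceptors are O and S atoms plus bare ring
nitrogens (no H, heavy degree ≤ 2).  Geometric screens before scoring:
H···A ≤ 2.6 Å, D–A ≤ 3.6 Å (3.8 Å for salt bridges), D–H···A ≥ 100°;
all configurable through `HBondParams`.  Accepted triples are scored
with the Mayo 12-10 form `E_HB = V₀[5(d₀/d)¹² − 6(d₀/d)¹⁰]·F` with
V₀ = 8 kcal/mol, d₀ = 2.8 Å and d the donor–acceptor distance, so the
radial term bottoms out at −V₀.  The angular factor F implements the
standard hybridization cases (sp3–sp3: cos²θ·cos²(φ−109.5°); sp3–sp2:
cos²θ·cos²φ; sp2–sp3: cos⁴θ; sp2–sp2: cos²θ times the worse of the
in-plane and out-of-plane acceptor angles).  The exact angular
treatment used for salt bridges in the original rigidity codes is not
fully documented; here salt bridges between charged side-chain groups
(Arg/Lys/His donors, Asp/Glu carboxylates) are scored with the radial
term only at a shifted equilibrium distance d₀ = 3.287 Å.  Only bonds
with E_HB < 0 are kept.

**Hydrophobic tethers.**  C/S atom pairs from different residues whose
distance is at most the sum of their van der Waals radii (C 1.7 Å,
S 1.8 Å) plus an offset of 0.25 Å, boundary inclusive.  By default only
*apolar* C/S atoms participate: a carbon or sulfur covalently bonded to
N or O (backbone Cα, carbonyl C) forms no tether.  This follows the
convention of the rigidity-analysis lineage the network model
reproduces; without it, backbone–backbone carbon contacts rigidify a
helix so strongly that hydrogen-bond dilution has no effect at all,
which defeats the purpose of the dilution analysis.  The literal
all-C/S variant is available via `apolar_only=False`.

## Pebble game and dilution

Rigidity is decided by a (6,6) pebble game: each body holds 6 pebbles;
a bar copy is accepted as an independent constraint if 7 pebbles can be
gathered on its endpoints; a bar of multiplicity m is inserted as m
copies.  Rigid clusters are maintained online: when, after an accepted
insertion on (u, v), only 6 pebbles can be gathered on the pair, the
bodies that cannot reach any free pebble outside the pair's directed
reach form a new rigid cluster.  Because bodies carry full 6-DOF
frames, mutual rigidity is an equivalence relation and the clusters
partition the atoms; cluster ids are canonicalized by lowest atom index
so results are independent of bar insertion order (the underlying
independence system is a matroid).  Floppy modes are
`6·N − 6·(connected components) − rank`; the suite cross-checks both
the partition and the floppy count against the numeric rank of an
explicitly constructed generic rigidity matrix.

Dilution walks a strictly decreasing cutoff grid; the state at E_cut
retains hydrogen bonds with E_HB ≤ E_cut.  Since raising the cutoff
only adds bonds, a single incremental game run from the most negative
grid value upward produces the decomposition at every grid point; the
suite verifies it against independent per-cutoff recomputation.  The
default grid is −0.1 to −6.0 kcal/mol in 0.1 steps, the convention of
constraint-network-analysis workflows; it is configurable everywhere.

**Stability maps and energies.**  Residue pairs are "in contact" when
at least one heavy-atom pair is within 4.5 Å (inclusive).  A residue
belongs to a cluster when at least one of its heavy atoms does (the
permissive standard).  `rc_ij` is the most negative grid cutoff at
which the two residues still share a cluster; contacts that are never
co-rigid receive a sentinel one grid step above the weakest cutoff
(0.0 kcal/mol for the default grid), so they contribute the weakest
possible stability rather than dropping out of the sums — users who
prefer to exclude them can filter on the sentinel.  Per-residue
energies are `E_i = ½ Σ_{j≠i} rc_ij` and satisfy `Σ_i E_i = E_CNA`
exactly (checked to 1e-9).  For ensembles, rc maps are computed per
snapshot and averaged over the snapshots in which the pair is in
contact, *before* forming energies; computing per-snapshot energies and
averaging afterwards is also supported.

**Differences.**  `ΔE_i = mean_ref(E_i) − mean_construct(E_i)` with a
per-residue Welch (unequal-variance) t-test across subunit × run
replicates at α = 0.05, no multiple-testing correction; non-significant
residues are zeroed in the reported map and the raw values retained.
Negative ΔE_i means the construct is destabilized.

## Ensemble geometry

* **RMSF** per residue (Cα representative; atom-level averaging
  optional) after least-squares superposition; the default
  superposition selection is the backbone (N, Cα, C, O) of the pore
  region, the structurally most invariant part of the channel.
* **d_z** per subunit: mass-weighted heavy-atom z-centers of the four
  C-terminal S6 residues minus the C-linker of the counter-clockwise
  preceding subunit.  Subunit adjacency is declared explicitly in the
  domain annotation as an ordered chain cycle rather than inferred from
  geometry, which is fragile for toy systems.  The z-axis convention is
  that ensembles are superposed onto a reference whose pore axis is
  aligned with z; the synthetic fixtures are built axis-aligned.
* **Kink angle** between the N→C axes of two helix ranges.  The axis
  estimator uses the fact that Cα bisectors of a helix are radial: the
  axis is the null direction of the bisector set, refined by a full
  parametric helix fit (axis, anchor, radius, rise, twist, phase) to
  the Cα coordinates.  This is exact for ideal helices of any length
  and recovers constructed 0°/30°/90° geometries within 2° under 0.1 Å
  coordinate noise; near-collinear traces fall back to a principal
  component.
* **Contacts**: residue pairs with ≥ 1 heavy-atom pair within 4.5 Å
  (inclusive), the same rule as the stability-map contacts; the report
  metadata records this definition.
* **Secondary structure**: Kabsch–Sander backbone H-bond energies
  `E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)` kcal/mol with a
  −0.5 kcal/mol threshold, amide hydrogens taken from the structure or
  placed opposite the preceding carbonyl; n-turns (i→i+3/4/5), minimal
  helices from consecutive turns, strands from bridge patterns
  (inter-chain bonds included); precedence H > E > G > I > T.
  Per-region content counts helix/strand (H/G/I/E) cells only — turns
  and bends are not structure.  π-helix detection is retained for
  completeness.

## Parametric fits

Boltzmann: `I/I_max = I/I_max,satV / (1 + exp(zδ·F·(V − V_1/2)/RT))`
with F = 96485 C/mol, R = 8.314 J/(mol·K) and T = 295 K by default
(room temperature; configurable), V in mV.  Initial guesses: V_half at
the half-range voltage, zδ = 4, plateau at the curve maximum.  Fits are
per recording, then summarized.  The printed form of the kinetic model
is a decaying exponential; activation currents grow toward a steady
state, so the implemented model is the equivalent relaxation
`I(t) = I_∞ − A·e^{−(t−delay)/τ}` for t ≥ delay — τ is identical in
both readings.  The delay is user-fixed or estimated as the last time
before the absolute slope first exceeds 10 % of its maximum.  Hill:
`F/F_max = 1/(1 + (BC₅₀/x)^{H_b})`, fitted to mean data, initialized at
the interpolated half-maximum and H_b = 1.5.  All fits are unweighted
nonlinear least squares (scipy `curve_fit`); standard errors come from
the Jacobian covariance; degenerate inputs (flat curves, saturated
binding, steady-state traces) raise a `FitError` carrying the last
iterate.

The cPCF correction estimates channel offsets from a signal-free border
region when given, scales the red (free-dye) channel to the green
channel in the bath, and takes the mean of the per-pixel difference
inside the patch mask; normalization by F_max requires the caller to
designate the saturating reference because the recording protocol, not
the data, defines it.

Summary statistics follow the two-level convention: per-subunit time
averages → run means → grand mean, with the SEM across run means; a
single run yields an undefined SEM, reported as missing.  The unpaired
t-test is the Welch variant (the equal-variance assumption is not
testable with n = 4 subunits); two zero-variance groups with equal
means return p = 1 by convention.

## Synthetic data: what it does and does not show

The structural generator builds C_n-symmetric (default C₄) poly-alanine
chains, each one continuous ideal α-helix (φ = −57°, ψ = −47°, standard
bond geometry, backbone + Cβ + ideal amide hydrogens) whose S6-like and
CL-like segments meet at a hinge: the junction peptide bond's midpoint.
Frames sample a bending angle from a normal distribution
(SD = `hinge_flexibility`) about a uniformly random azimuth, and the
post-hinge segment can additionally be translated down the pore axis by
`planted_dz_shift`.  Every generator is a pure function of its spec
including the seed.

Defaults are the package's study conditions: 4 chains, 10+10 residues
per chain, 50 frames; the hinged-vs-rigid contrast uses bending SDs of
15° vs 2° (a clearly flexible hinge against thermal jitter), and the
planted displacement of 2.61 Å mirrors the magnitude reported for the
strongest insertion construct.  Two runs of four subunits give eight
replicates per group for the significance tests, a deliberately
desk-scale stand-in for the five 1-µs trajectories of a production
study; the acceptance script states the sizes it uses in its output.

What passing tests show: the pipeline recovers planted flexibility,
displacement and destabilization signatures in direction, location and
(for d_z) magnitude.  What they do not show: force-field realism,
solvent/lipid effects, side-chain chemistry (glycine insertions are
emulated by hinge flexibility, not sequence), sampling convergence of
real MD ensembles, or experimental noise structure beyond additive
i.i.d. Gaussian.

## Numerical choices and limitations

* Boundary rules are inclusive (≤) for both the tether cutoff and the
  4.5 Å contact rule; distances are exact Euclidean norms, so ties are
  measure-zero in practice.
* The pebble game is pure Python; a 670-atom tetramer snapshot with a
  60-point grid dilutes in ~0.1 s, which covers the intended desk-scale
  use.  Very large systems would want a compiled engine.
* `delta_stability` requires ≥ 2 replicates per group; comparisons of
  single runs are refused rather than silently unpowered.
* Ensembles are exchanged as multi-model PDB only, keeping fixtures
  text-based and diffable; binary trajectory formats are out of scope.
* Ligands (cAMP) are not parameterized in the constraint network; the
  rigidity analysis operates on the protein.
* The t-test applies no multiple-testing correction across residues;
  the per-residue maps are descriptive, as is standard for this kind of
  stability mapping.
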