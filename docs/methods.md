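# Methods

This note documents the models, numerical choices and limitations behind
`metalswitch`. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The scientific model

The Sonic Hedgehog N-terminal domain (ShhN) carries a LAS-type zinc
center: the zinc is tetrahedrally coordinated by two histidine ring
nitrogens (H141, H183), an aspartate carboxylate (D148) and a water
molecule; E177 is the putative catalytic base, H135 the substrate clamp,
E127 the residue that couples the center to the adjacent double-calcium
site. The package quantifies a *switch* hypothesis: the buried,
high-affinity calcium (Ca1) rigidifies the fold, while the solvent-exposed,
weakly bound calcium (Ca2) drags E127 — and through it H135 — away from
the catalytic machinery, widens the H135–E177 clamp, twists the G128
carbonyl off H141, destabilizes the zinc-coordinating water, and flips the
electrostatics of the substrate groove. Autodegradation at conserved
glycines (the C-terminal G197–G198 GG, the G58/G94 GA motifs) is the
proposed function; the ShhN_AAA (E90A/E91A/E127A, calcium-blind) versus
ShhN_AAAA (+E177A, catalytic knockout) decay contrast is its experimental
readout.

## Structure handling (structio)

Coordinates are internal in Å (PDB convention); ensemble statistics
(RMSF/RMSD) are converted to nm at the reporting layer only. Residue
numbering is the author (PDB) numbering in the mouse ShhN convention.
Altlocs resolve to the highest-occupancy conformer, ties alphabetical.
Hydrogens absent from X-ray inputs are tolerated everywhere; operations
that prefer protons (H-bond series) fall back to donor heavy atoms and
flag the series. Symmetry expansion applies all crystallographic operators
combined with lattice translations in [−1, 1]³ — sufficient for
nearest-neighbor contacts — and keeps copies with any atom within the
cutoff of the original. Range clipping (L40–E189) applies to ShhN-like
inputs; comparison structures are not clipped unless requested, since the
analysis range for them is a user decision, not a structural fact.

## Constellation matching (match)

Matching is order-free: template functional groups (carboxylate C/O for
D/E, the two ring N for H, the metal by element) are paired with
chemically compatible target groups, identical residue class by default or
physico-chemical classes ({D,E}, {N,Q}, {S,T}, {K,R}, {I,L,V,M}, {F,Y,W};
metals by element) in conservative mode. Partial assignments are pruned
when any pairwise centroid distance disagrees by more than
`2·max_rmsd + 0.2 Å` — a bound loose enough that the optimal full solution
can never be pruned for centers of this size. Carboxylate oxygens and the
two imidazole nitrogens are crystallographically interchangeable, so both
pairings are enumerated exactly at each leaf (≤2⁷ Kabsch fits per
candidate assignment). Ranking is coverage (descending) then RMSD
(ascending) with the target id as final tie-break, so repeated runs are
byte-identical. The combinatorial budget defaults to 10⁶ visited nodes;
exceeding it raises an error carrying the partial hit list. The exact
similarity index that production screening tools combine from several
quantities is not reimplemented; coverage + RMSD ranking is the contract.
A separate ICP-style Cα aligner (greedy one-to-one nearest pairing within
5 Å, refit, iterate) serves global-fold comparisons such as ShhN vs the
VanX dipeptidase; it needs a sensible initial transform, for which a
conservative center match is used.

## Ensemble geometry (geometry)

RMSF superposes every frame onto the iteratively refined ensemble average
(three refinement passes) using the analysis selection (backbone of the
modelled range by default), then averages per-atom mean-square
fluctuations within residues. RMSD is per-frame Kabsch against a
reference. Clustering is greedy leader-style on mutual superposed RMSD
(largest neighborhood becomes a center; default cutoff 0.1 nm, which
reproduces single-dominant-cluster behaviour on calcium-bound synthetic
ensembles). Water tracking reports, per frame, the water oxygen nearest
the zinc within `d_max` (default 3 Å): distance, angle α = O–Zn–N(H141)
and a second pose angle β = O–Zn–C(D148 carboxylate). The H141 reference
atom defaults to the zinc-coordinating Nδ1 and is configurable, as is the
β reference — both choices are conventions, not measurements. The
rank-sum test uses the exact null distribution when both samples have
n ≤ 12 and no ties, otherwise the normal approximation with tie
correction; two identical constant samples short-circuit to p = 1 with a
degeneracy flag. RMSF distributions across calcium states are compared
unpaired (they are per-residue samples from independent simulations); a
paired comparison can be run by the caller on matched residue indices.

SASA is Shrake–Rupley with 960 sphere points (Biopython's implementation
behind this module's interface), Bondi/Mantina van der Waals radii, and
ionic radii for bare metal cations (Zn²⁺ 0.74 Å, Ca²⁺ 1.00 Å) — desolvated
ions probed at 0.5 Å are the input of the affinity model below, and a vdW
radius would be the wrong physical picture for them.

## Energetics

**Calcium affinity from exposure.** The empirical model is linear and
monotone: ΔG = a + b·A_SAS with b > 0 (the more exposed the ion, the
weaker the affinity), A_SAS computed with a 0.5 Å probe in the context of
the full structure. The defaults (a = −58 kJ/mol, b = 1 kJ/(mol·Å²)) are
package defaults for a configurable coefficient pair; because the model
ignores ion–ion interaction and the conformational entropy spent on
binding the first ion, *only the difference* ΔΔG(Ca2 − Ca1) is treated as
meaningful, and all tests enforce sign and monotonicity rather than
absolute values. Site labels follow exposure: Ca1 is the buried ion.

**Poisson–Boltzmann.** The solver is a finite-difference *linearized* PB
on a uniform grid: seven-point stencil, face dielectrics assigned by
whether the face midpoint lies inside the probe-inflated (1.4 Å) atom
volume, Debye screening (κ from the ionic strength, zero inside the
molecule), trilinear charge spreading, Debye–Hückel boundary values, and
red–black successive over-relaxation (ω = 1.9) to a relative residual of
10⁻⁶ (non-convergence raises, with the residual history attached).
Defaults: spacing 0.6 Å, padding 10 Å, ε_in = 2, ε_out = 79, 0.1 mol/l
1:1 salt, 298.15 K. The linearization is a deliberate reduction: every
conclusion consumed here is a sign or ordering claim, and those are stable
under it; a Boltzmann-term iteration could be added behind the same
interface. Validation is against closed forms: Coulomb (within 3%) and
Born solvation (within 5%).

**Water-binding cycle.** ΔG = G(protein·water) − G(protein) − G(water),
all three legs solved on one grid *and one dielectric/salt map built from
the complex*, with identical charge discretization. With shared maps, grid
self-energies and cavity terms cancel exactly: discharging the water gives
ΔG ≡ 0, and the three-state cycle ΔΔG(Ca2−Ca0) = ΔΔG(Ca2−Ca1) +
ΔΔG(Ca1−Ca0) closes algebraically. What remains is the screened
electrostatic interaction of the water charges with the protein charges —
precisely the quantity whose sign is compared across calcium states.
States must differ only by calcium content (checked), with the water
placed identically.

**Charges.** The bundled charge set is compact and self-authored: integer
formal charges localized on ionizable groups (Asp/Glu −1 across the
carboxylate, Lys/Arg +1, charged termini when OXT is present), balanced
backbone and side-chain dipoles that sum to zero per residue, a neutral
histidine ring dipole across the two nitrogens (so reduced ring fragments
still balance), SPC/E 3-point water, and +2/+1 monatomic ions. Every
standard residue sums to its formal charge exactly (test-enforced).
Waters lacking hydrogens are assigned zero charge and flagged rather than
given an unbalanced oxygen monopole. A user-supplied force-field table
(mapping (residue, atom) → charge) overrides the bundled set; the
provenance string records which was used. Histidine tautomer assignment
affects only proton placement, which heavy-atom inputs lack, so the
bundled set is tautomer-neutral.

## Conservation and phylogeny (seqcons)

Alignments are consumed pre-aligned (aligned FASTA); building them is out
of scope. Positions map through the reference (mouse ShhN) gap structure.
The conservative-exchange classes here include {H,K,R} so that the rat
H181R exchange is annotated conservative. Cleavage candidates are
reference glycines conserved in a configurable fraction (default 100%) of
a labelled subset (default the vertebrate sequences; "vertebrate" is an
input label, never inferred), typed GG/GA/G by the next reference residue,
with mean Kyte–Doolittle hydropathy over a ±2-residue context. Distances
are p-distances over mutually ungapped columns (Poisson correction
optional); the tree is BioNJ (variance-weighted neighbor joining) with
label-order tie-breaks for determinism and negative branch lengths clamped
to zero. Bootstrap support resamples columns with one seeded stream
(replicate r consumes draw r) and counts canonical unrooted splits of the
full-alignment tree. Branch lengths of published Hedgehog trees are not
claimed to be reproduced — the distance model and gap handling of the
original runs are not recoverable from the text.

## Decay kinetics (decayfit)

The fit is ordinary least squares on log intensity versus time — the
straight-line form of the published presentation — with k = −slope,
t½ = ln2/k, half-life bounds ln2/(k ± SE), and a 95% confidence band for
the linear model. The t = 0 normalization anchor is included by default
(option to exclude); intensities below a detection floor (default 0.01)
are censored and counted, since near-vanished bands carry no reliable log
signal. Non-positive rates flag `no_decay` with infinite half-life. The
half-life ratio between variants propagates relative slope errors to
first order. The Monte-Carlo calibration checks three things over 200
seeded simulations at the generator's conditions (σ_log = 0.1, 3
replicates, k = 0.2/h): the estimator is unbiased, it lands within two
standard errors of the truth in ≥95% of runs, and the per-fit SE tracks
the true (empirical) sampling SE. The coverage statement uses the
estimator's sampling SE; at 12 points the per-fit SE has visible
t-distribution tails, and ±2·(per-fit SE) covers slightly less by
construction.

## The synthetic-data generators (synthdata)

The generators encode the qualitative contrasts of the switch model, not
molecular-dynamics physics. What they emulate — and what they do not:

* **Zinc center.** An idealized constellation with exact tetrahedral
  ligand directions, crystallographic bond lengths (Zn–N 2.05 Å, Zn–O 2.0
  Å, H-bonds 2.7–2.9 Å) and the H135/E177 clamp at 4.5 Å. Both calcium
  sites sit on the water's H–H bisector flank, so the ions face the
  positive end of the water dipole — the construction that makes each
  added calcium destabilize the zinc-coordinating water, as in the
  modelled pocket. Ca1 is caged by six acidic oxygens (buried at probe
  0.5 Å); Ca2 has three (exposed). Real centers have thermal disorder,
  second-shell effects and anisotropic environments that these constructs
  do not.
* **Ensembles.** Frames are the base structure plus Gaussian displacements
  correlated along the chain (Gaussian kernel, width 3 residues,
  row-normalized so per-residue marginal variance is exact). The Ca0
  regime boosts backbone amplitudes in the calcium-binding loops (66–72,
  88–94, 128–139) from 0.5 Å to 1.55 Å — values chosen so the
  residue-averaged synthetic RMSF lands near the ~0.12/0.09 nm contrast
  between calcium-free and calcium-bound states; the Ca2 regime shifts
  the E177 side chain by the 1 Å clamp offset and twists the G128
  carbonyl 1.2 Å away from H141. Site side chains keep background
  amplitude in all states (loops flap; the H-bonded machinery does not),
  which is why the clamp offset is recoverable to ±10% from medians.
  There is no physical force field, no solvent, no kinetics — passing
  tests show the *statistics pipeline* recovers designed contrasts, not
  that MD would produce them.
* **Water regimes.** Fixed: one water jittered about the tetrahedral
  site. Bimodal: two angular basins 40° apart with Markov switching
  (p = 0.05) and occasional identity exchange with an outer water
  (p = 0.03). The scaffold backbone is a smooth helical curve carrying
  residue identity for per-residue statistics; it is a geometric scaffold,
  not a protein fold.
* **Families.** 17 vertebrate-like and 13 fly-like sequences over
  reference positions 40–198; motif, calcium-site and glycine columns are
  pinned (vertebrates EHHDEHH with the rat H181R exception; flies
  EHHTVHY, no C-terminal GG, no G58-A59 GA; one fly E90D), background
  columns diverge by seeded substitution (3%/8% within clades, 35% shared
  fly divergence) drawn from an alphabet without G/A so conserved glycine
  candidates are exactly the designed ones.
* **Decay.** exp(−kt) with multiplicative lognormal noise, normalized per
  replicate to the maximum observed content; defaults k = 0.20/h
  (ShhN_AAA, low pH: effectively vanished by 18 h), 0.04/h (ShhN_AAAA,
  low pH: about half left at 18 h) and ~0 at neutral pH (stable for many
  hours), σ_log = 0.1, 3 replicates, time points 0/3/6/18 h. The exact
  published half-lives and pH values are not encoded; the defaults encode
  the qualitative contrast.

Determinism: one global seed; each generator draws from a substream keyed
by the stable CRC-32 of its name, so outputs are byte-identical per
configuration and independent across generators.

## Problem sizes

Default test and acceptance scales: 500-frame ensembles (the scale at
which loop-flexibility rank-sum contrasts are decisive at α = 0.01 while
the shared-amplitude states remain indistinguishable), 300-frame water
runs, PB grids at 0.8 Å spacing with 8 Å padding for the synthetic-center
cycle (0.4–0.5 Å for the closed-form validations), 100 bootstrap
replicates, 200 calibration simulations. The exhaustive matcher oracle
runs on instances with ≤12 candidate residues, where enumeration over all
correspondences and atom pairings is exact and affordable.

## Known limitations

* The PB solver is linearized and desk-scale; it validates against
  Coulomb/Born closed forms, not against production nonlinear solvers'
  absolute energies. The cycle is rigid — no conformational relaxation
  between calcium states.
* The charge set is a dipole/formal-charge reduction, adequate for the
  sign and ordering claims made here, not for absolute energetics; supply
  a force-field table for anything finer.
* Real-structure checks (the 1vhh lattice-neighbor triangle, the Hedgehog
  matcher benchmark, the VanX Cα comparison) require user-supplied PDB
  files; without them those two acceptance tests fail with a pointer to
  the expected path.
* MD-derived absolute magnitudes (residue-averaged RMSF values of real
  trajectories, zinc-center RMSD distributions against LAS enzymes) need a
  physics engine; the desk-scale suite asserts the orderings and contrasts
  they imply on synthetic regimes instead.
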