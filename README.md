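# metalswitch

Analysis toolkit for **calcium-regulated zinc-peptidase centers**, built
around the Sonic Hedgehog N-terminal domain (ShhN). ShhN carries a
LAS-type tetrahedral zinc center (LAS: Lysostaphin-type peptidases,
D-Ala-D-Ala metallopeptidases, Sonic hedgehog) — yet it is the only LAS
member without proven peptidase activity, and uniquely binds two calcium
ions next to that center. `metalswitch` implements the computational chain
used to argue that ShhN is an autodegrading zinc peptidase switched *off*
by the second calcium ion:

1. **structio** — PDB parsing (altloc resolution, author numbering),
   residue-range clipping (L40–E189), crystal-symmetry expansion for
   lattice-neighbor contacts, and extraction of the eight-group center
   template (Zn, E127, H135, H141, D148, E177, H181, H183).
2. **match** — sequence-order-free superposition of metal-center
   constellations: correspondence enumeration between chemically compatible
   groups (identical or conservative substitution classes), distance
   pruning, Kabsch superposition with symmetry-equivalent carboxylate-O and
   imidazole-N pairings, ranking by coverage then RMSD; plus an ICP-style
   Cα alignment for global-fold comparisons (ShhN vs VanX).
3. **geometry** — Shrake–Rupley SASA, distance/angle measurement, H-bond
   switch series (E127–H135, H135–E177, G128–H141, E54–H183), RMSF/RMSD
   after least-squares superposition, greedy RMSD clustering,
   catalytic-water tracking at the zinc (distance, O–Zn–N(H141) angle,
   exchange events), and Wilcoxon–Mann–Whitney rank-sum tests (exact for
   small samples).
4. **energetics** — the empirical calcium-affinity estimate
   ΔG = a + b·A_SAS (ion exposure at probe 0.5 Å; more exposed, weaker
   binding), and the electrostatic water-binding free energy
   ΔG = G(protein·water) − G(protein) − G(water) from a finite-difference
   linearized Poisson–Boltzmann solver (ε_in = 2, ε_out = 79, 0.1 mol/l
   salt), differenced between calcium states Ca0/Ca1/Ca2; surface-potential
   maps on the solvent-accessible surface.
5. **seqcons** — catalytic-motif conservation (EHHDEHH vs the fly
   EHHTVHY), calcium-site acid conservation (E90, E91, D96, E127, D130,
   D132), conserved-glycine cleavage candidates (GG/GA with Kyte–Doolittle
   context), p-distance matrices, a BioNJ tree and column-resampling
   bootstrap.
6. **decayfit** — log-linear least-squares exponential-decay fits of
   band-intensity time series (half-life with slope-SE bounds, 95%
   confidence bands), rank-sum comparisons between the calcium-blind
   ShhN_AAA (E90A/E91A/E127A) and catalytic-knockout ShhN_AAAA (+E177A)
   variants.
7. **synthdata** — deterministic generators for all of the above:
   idealized zinc-center constellations with decoys, state-labelled
   Gaussian ensembles with loop-specific amplitudes, fixed vs bimodal
   catalytic-water regimes, Hedgehog-like sequence families, and noisy
   decay assays. Every generator emits ground truth for recovery tests.

## Worked example

```python
from metalswitch import (GeneratorConfig, gen_ensemble, gen_decay,
                         rmsf_profile, hbond_series, fit_decay,
                         rank_sum_test)

# state-labelled ensembles: no calcium (Ca0) vs both calciums (Ca2)
ca0 = gen_ensemble(GeneratorConfig(seed=10, state_label="Ca0"), n_frames=500)
ca2 = gen_ensemble(GeneratorConfig(seed=12, state_label="Ca2"), n_frames=500)
p0, p2 = rmsf_profile(ca0), rmsf_profile(ca2)
print(f"mean backbone RMSF: Ca0 {p0.mean():.3f} nm, Ca2 {p2.mean():.3f} nm")

pair = [(("A", 135, "NE2"), ("A", 177, "OE1"))]
d0 = hbond_series(ca0, pair)[0]
d2 = hbond_series(ca2, pair)[0]
print(f"H135-E177 clamp: Ca0 {d0.median:.2f} A -> Ca2 {d2.median:.2f} A")

decay = gen_decay(GeneratorConfig(seed=3))
for variant in ("AAA", "AAAA"):
    fit = fit_decay(decay[(variant, "low")])
    print(f"ShhN_{variant} at low pH: t1/2 = {fit.half_life:.1f} h "
          f"(k = {fit.rate:.3f} /h)")
```

prints

```
mean backbone RMSF: Ca0 0.113 nm, Ca2 0.081 nm
H135-E177 clamp: Ca0 4.57 A -> Ca2 5.55 A
ShhN_AAA at low pH: t1/2 = 3.5 h (k = 0.197 /h)
ShhN_AAAA at low pH: t1/2 = 18.8 h (k = 0.037 /h)
```

That is the switch in miniature: removing calcium raises backbone
flexibility (the calcium-binding loops most of all), binding the second
calcium widens the H135–E177 substrate clamp by about 1 Å, and at low pH
the calcium-blind putative peptidase (ShhN_AAA) decays several-fold faster
than the additional E177A catalytic knockout.

A CLI mirrors the library (`metalswitch parse|match|ion-affinity|pb-ddg|
ensemble-report|water-track|motif-scan|tree|decay-fit|simulate`).

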