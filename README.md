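# confe — conformational free energies of structural ensembles

`confe` estimates the relative free energy of protein conformational
states from ensembles of structure snapshots, for structural biologists
and molecular modellers who want to ask "which of these two experimentally
determined conformations is dominant in solution?" without trusting the
enthalpy alone.

The free energy of a conformational form *a*, observed as an ensemble of
snapshots, is decomposed as

```
G1_a = ⟨E_a^MM⟩ + ⟨E_a^ASA⟩ − T·S_a          (with conformational entropy)
G2_a = ⟨E_a^MM⟩ + ⟨E_a^ASA⟩                  (without)
```

* **⟨E^MM⟩** — ensemble-averaged molecular-mechanics + implicit-solvent
  enthalpy: harmonic bonds/angles, cosine torsions, 12-6 Lennard-Jones,
  Coulomb, and a generalized-Born polar solvation term with effective
  radii from Hawkins pairwise descreening (HCT).
* **⟨E^ASA⟩** — nonpolar solvation, γ·SASA + b, with the solvent-accessible
  surface area from a deterministic Shrake–Rupley construction
  (probe radius 1.4 Å).
* **S_a** — conformational entropy from the distribution of the protein's
  dihedral angles: each torsion is histogrammed on the circle over the
  ensemble and `S_a = −Σ_i Σ_θ P_a(θ_i) ln P_a(θ_i)` is summed over the
  `Nd` torsions (discrete and differential readings both supported);
  `TS = k_B·T·S` with `k_B = 0.0019872041 kcal/mol/K`.

Around that core the package provides trajectory geometry (Kabsch
superposition, global and per-region RMSD, metal–water contact counting),
PCA of conformational ensembles with equal-arc-length waypoint selection
for pathway free-energy profiles, a replicate-run statistics layer
(mean ± σ tables, one-σ significance flags), and a synthetic-data
generator whose per-torsion distributions (uniform / von Mises / fixed)
have closed-form entropies — so every stage can be validated against
analytic ground truth.

## Worked example

Two states of the same chain differing only in how concentrated their
torsion distributions are (state A uniform, state B von Mises κ=8, 20
torsions, 20 000 snapshots each; closed-form ΔTS = 16.976 kcal/mol):

```python
from confe import synthetic, EnsembleFreeEnergy

ens_a, ens_b, truth = synthetic.make_two_state_system(
    kappa_a=0.0, kappa_b=8.0, n_torsions=20, n_frames=20_000, seed=42)

res = EnsembleFreeEnergy(ens_a, bin_width=12.0, energy_stride=200,
                         label="loose").fit()
print(res.summary())
```

```
Ensemble free energy
==============================================
label                 loose
frames (entropy)      20000
frames (energy)       100
torsions Nd           20
entropy mode          differential
bin width (deg)       12
temperature (K)       300
----------------------------------------------
<E_MM>  (kcal/mol)            0.0000
<E_ASA> (kcal/mol)            2.7532
S (nats)                     36.7429
TS (kcal/mol)                21.9047
G2 = <E> (kcal/mol)           2.7532
G1 = G2 - TS                -19.1515
==============================================
```

The loose state's 20 uniform torsions carry 36.74 nats of entropy
(analytically 20·ln 2π = 36.76), worth 21.90 kcal/mol at 300 K; its G1 is
lowered accordingly while G2 contains only the (here deliberately inert)
enthalpy and surface term.  Fitting state B the same way and differencing
gives an estimated ΔTS of 16.80 kcal/mol against the analytic 16.98 —
the high-entropy state is the G1-favored one even when its enthalpy is
slightly worse, which is exactly the entropic-stabilization pattern seen
when comparing solution (NMR) and crystal conformations of a protein.

The same analysis runs from the command line over YAML configurations:
`confe compare`, `confe pathway`, `confe entropy`, `confe energy`,
`confe synth`.

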