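# Methods

## The model

A conformational state ("form") is represented by an ensemble of
coordinate snapshots over one parameterized topology.  Its free energy is
estimated as

    G1 = ⟨E_MM⟩ + ⟨E_ASA⟩ − T·S,     G2 = ⟨E_MM⟩ + ⟨E_ASA⟩,

an enthalpy-like implicit-solvent average plus a conformational-entropy
term computed from the ensemble's dihedral-angle distributions.  The two
are reported side by side because their difference — the TS term — is
precisely what distinguishes an entropically stabilized conformation
(favored in G1) from an enthalpically stabilized one (favored in G2).
The estimator makes no claim to absolute populations; only relative
stabilities of states evaluated with identical settings are meaningful.

### Enthalpy: GBSA snapshot energies

Each snapshot (solvent stripped; stripping is explicit and the removed
atom count is reported, never silent) is evaluated with:

* bonded terms Σk_b(b−b₀)², Σk_θ(θ−θ₀)², Σ(V_n/2)(1+cos(nφ−γ));
* 12-6 Lennard-Jones (Rmin/2 addition, geometric-mean ε) and Coulomb
  k_e q_iq_j/r with k_e = 332.06 kcal·Å/mol/e²; 1-2/1-3 pairs excluded,
  1-4 pairs scaled (defaults 1/1.2 electrostatic, 1/2 LJ, configurable);
  no distance cutoffs — snapshot re-evaluation at this scale does not
  need them and their omission removes a convergence parameter;
* generalized-Born polar solvation in the Hawkins–Cramer–Truhlar (HCT)
  pairwise-descreening flavor: inverse effective radius = inverse reduced
  intrinsic radius (intrinsic − 0.09 Å offset) minus the analytic
  Coulomb-field integral of each neighbor's screened sphere, then the
  Still pairwise energy −(k_e/2)(1/ε_in − 1/ε_out)Σ q_iq_j/f_GB with
  f_GB = √(r² + R_iR_j e^{−r²/4R_iR_j}) including self terms.  Interior
  dielectric 1, solvent 78.5.  Intrinsic radii and screening factors come
  from the topology (mbondi-like values in the toy generator).
  Non-positive inverse radii (possible in HCT for pathological overlaps)
  are clamped, warned about, and counted in the per-frame output;
* nonpolar solvation E_ASA = γ·SASA + b with γ = 0.005 kcal/mol/Å²,
  b = 0 by default, SASA from Shrake–Rupley with a deterministic
  Fibonacci sphere of 960 points per atom (radius = Rmin/2 + 1.4 Å
  probe).  Determinism was chosen over random point sets so energies are
  exactly reproducible; the price is that areas are rotation-invariant
  only to the quadrature resolution (≈0.3% against analytic two-sphere
  overlaps, worth a few hundredths of kcal/mol through γ).

The HCT radii were validated against direct numerical quadrature of the
descreening integral (1-D shell reduction, agreement to ≪1%), the GB
energy against the analytic Born formula and the distant-ion
Born-plus-screened-Coulomb limit, and the surface areas against exact
one- and two-sphere formulas.

### Entropy: dihedral-angle histograms

Bond lengths and bond angles are effectively rigid in constrained-MD
ensembles; the conformational entropy is carried by torsions.  Each
torsion of the enumerated set is histogrammed over the ensemble on bins
of width w anchored at −180° (half-open, +180 identified with −180) and

    discrete:       S_i = −Σ_b P_b ln P_b
    differential:   S_i = −Σ_b P_b ln(P_b / w_rad)

is summed over torsions; TS = k_B T S.  0·ln 0 ≡ 0.  Torsions are
treated as independent — no mutual-information correction — which is the
assumption that makes the synthetic ground truth exact.  Default mode is
**differential**: it approximates the continuous entropy of the angle
density and is bin-width independent for smooth distributions, which
matches the observed behavior that TS is stable across 12°–60° bins and
drifts at 120°.  The discrete reading is first-class and reported on
request (it shifts by ln(nbins) under uniformity).  An optional
Miller–Madow bias correction exists but is off by default.

The torsion set defaults to *all rotatable heavy-atom bonds* (one
quadruple per non-terminal bond, flanking atoms chosen by lowest index
for determinism); Nd is always reported, since results are only
comparable at equal Nd.

**Bin width.** The default is 30°, appropriate for comparing states of
similar smoothness.  For recovery of closed-form entropies the package's
validation runs use 12°: the discretization bias of a histogram entropy
grows quadratically with w for smooth densities, and exact quadrature of
the binned von Mises(κ=8) density (circular σ ≈ 20°) shows a +0.079
nats/torsion bias at 30° that no sample size removes, versus +0.013 at
12°.  A bin-sensitivity report (12/30/60/120°) is part of the API so this
choice can be checked per data set.

### Replicates, comparisons, profiles

Replicate runs (independent seeds) are summarized as mean and sample
standard deviation (n−1 denominator, stated in the output header).
Tables print a "−TS" column — the quantity added to G2 to give G1 — to
match the common published layout; internally TS ≥ 0 whenever S ≥ 0 and
G1 = G2 − TS holds identically.  Two states are compared by difference
of replicate means with quadrature-propagated σ and a deliberately loose
significance flag: |Δ| greater than the larger of the two state σ's.
Pathway profiles evaluate the same machinery at ordered waypoints.

### Geometry

Superposition is Kabsch least squares (SVD with reflection correction);
it was cross-checked against an independent quaternion (Horn) method.
RMSD superposes on a *fit* selection then measures over a *measure*
selection; with fit = measure this is the standard global RMSD, and
per-region values (loops, single residues) are measured after a global
main-chain fit — the convention under which region RMSDs can exceed the
global value, as published per-residue tables require.  Main chain means
atoms named N, CA, C, O.  Dihedrals follow the IUPAC sign convention
(cis = 0°, trans = 180°, range (−180°, 180°]), verified against an
independent triple-product oracle and RDKit during development.
Metal–water contacts count water atoms within a cutoff of any center
atom; the cutoff default is 3.0 Å — a typical Zn²⁺–O first-shell
distance; it is configurable because published contact counts rarely
state theirs.

### Pathways: PCA, waypoints, morphing

Ensembles are aligned (to the first frame, or iteratively to the
converged mean) before PCA of the flattened selected coordinates; the
mean structure is the origin of the component axes, eigenvalues use the
sample (n−1) convention, and eigenvector signs are fixed by making each
axis's largest-magnitude component positive.  Waypoints along a
projected path are selected at equal cumulative arc length in the first
two components (endpoints always included, ties toward the smaller
index) — arc length rather than frame index, so dense dwelling regions
do not attract all waypoints.  The transition path itself is a **linear
Cartesian morph** between superposed endpoints, labeled "interpolated"
in frame metadata: it is a geometric stand-in that exercises the
profile machinery and makes no claim to resemble a physical transition
ensemble.  Per-waypoint replicate ensembles are generated by von Mises
torsion resampling centered on the waypoint's torsions (concentration
configurable), a documented stand-in for position-restrained sampling.

## Synthetic data and what passing tests show

The generator builds toy chains — either a plain CA chain or an
N-CA-C(=O) backbone pattern — with fixed bond lengths (1.5 Å) and angles
(111°), full force-field parameters, and charges summing to zero.
Cartesian coordinates are constructed from torsion values by sequential
internal-coordinate placement, built so that re-measuring the enumerated
torsions returns the inputs exactly; sampling is i.i.d. per frame with
per-torsion distributions (fixed / uniform / von Mises) whose
differential entropies are known in closed form (uniform: ln 2π; von
Mises: ln(2π I₀(κ)) − κI₁(κ)/I₀(κ), validated against independent
quadrature).  A metal-site generator places a Zn ion and waters so the
expected in-cutoff count equals a prescribed mean; a two-state generator
produces two ensembles differing only in torsion concentration, with
analytic ΔS (state A minus state B) and ΔTS = k_BTΔS.

Two-state systems use a **non-interacting** chain (zero charges and LJ
well depths; radii kept so surface terms remain defined): with
interacting nonbonded terms a uniform-torsion chain self-overlaps and
its clash energies would swamp any constructed signal.  Enthalpy
differences are instead injected as an exact constant per-state energy
offset carried on the topology, so ΔG2 is controlled independently of
ΔTS.  Consequently the synthetic benchmark validates the *estimator
chain* — sampling → geometry → histograms → entropy → free-energy
assembly — under the estimator's own independence assumption.  It does
not emulate correlated torsions, rugged enthalpy landscapes, solvent
structure, or force-field error; agreement on synthetic data bounds
estimator bias, not model error on real proteins.

Enthalpy averages in pipeline runs may be computed on an evenly strided
subset of frames (`energy_stride`) while entropy always uses every
frame: the energy mean of an i.i.d. ensemble converges with O(10²)
frames, whereas the histogram entropy needs O(10⁵) samples for
tenth-of-a-nat accuracy.  Validation runs use 10⁵ frames per state with
energies on every 400th frame.

## Reference data

Small published summary tables for the A3Gctd test system (ten-replicate
20-ns MD of the NMR 2KEM and crystal 3IR2 forms: per-run G2/−TS/G1,
main-chain RMSDs, Zn-contacting water counts) are embedded as constants
in `confe.datasets`.  The absolute energies depend on that study's
trajectories and force-field variant and are not recomputable at desk
scale; the package reproduces the *arithmetic* over them — per-run
recombination G1 = G2 + (−TS), Average and σ rows, state differences and
the one-σ significance call — which validates the replicate-statistics
layer against an external calculation.

## Numerical choices and degenerate inputs

* Superposition requires ≥3 non-collinear fit atoms; collinear sets are
  rejected rather than silently returning an arbitrary rotation.
* Dihedrals with collinear consecutive atoms raise; histogram binning
  maps exactly ±180° to the first bin.
* Single-frame ensembles have no entropy; G2-only evaluation requires an
  explicit flag.
* Zero-length PCA paths (identical endpoints) fall back to equal index
  spacing for waypoints.
* PDB I/O keeps author residue numbering verbatim, keeps the highest-
  occupancy alternate location, writes coordinates at the format's 3
  decimals, and rejects multi-model files with inconsistent atom counts.
* All generators take explicit seeds and are bit-reproducible; pipeline
  outputs carry a configuration hash and a log of every default used.

## Known limitations

No forces, minimization or dynamics; no salt dependence in GB; no
mmCIF; no torsion-correlation entropy corrections; toy energetics are
not physical and the morph path is not a transition mechanism.  GB/SASA
parameters not fixed by the science (γ, radii set, 1-4 scaling) are
configuration, and conclusions should be checked for robustness against
them.
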