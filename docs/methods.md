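# Methods

`mdfingerprint` re-implements, as a tested library, the comparative
analysis workflow used to characterise temperature adaptation in membrane
transporters from molecular-dynamics trajectories: every analysis is run at
a cold and a hot temperature and the difference is the fingerprint.  This
note records the models, conventions, numerical choices and limitations.

## Coordinate and residue conventions

Systems are a static atom table (`Topology`) plus frames × atoms × 3
coordinates with per-frame orthorhombic box edges (`Trajectory`).  Units
are Å, ns, amu, elementary charges, kcal/mol.  Residue identity is
`(chain_id, residue_seq_id)` in author numbering, preserved verbatim from
the source PDB, so residue ranges quoted in the structural literature
(e.g. a C-terminal segment 660–670) can be addressed directly.  Triclinic
boxes are rejected explicitly; all minimum-image arithmetic assumes an
orthorhombic cell.  Contact analyses use minimum-image distances on the
coordinates as stored (wrapped or not); the domain–membrane distance is the
one operation that re-images coordinates itself (below).

Per-atom nonbonded parameters (charge, Lennard-Jones ε and r_min/2,
intrinsic Born radius, optional GB screening factor) come from a plain TSV
keyed by (residue name, atom name), keeping the package self-contained
rather than parsing force-field binaries.

## Flexibility

RMSD and RMSF use a least-squares rigid superposition (Kabsch, via SVD,
reflections suppressed).  RMSF follows the two-pass convention: fit all
frames to frame 0 on the fitting selection (default Cα), compute the mean
structure, re-fit to the mean, then per-atom RMSF = √⟨|r − ⟨r⟩|²⟩.
Per-residue values average all atoms of the residue, unweighted; mass
weighting of the fit is optional and off by default.  ΔRMSF is defined
hot − cold.

Two numerical facts matter for interpretation:

* For isotropic per-coordinate jitter σ, RMSF → σ√3 (χ-distribution
  mean-square identity).  Superposing onto pure noise removes six rigid
  degrees of freedom and biases RMSF low by roughly √(1 − 6/(3N)); the
  closed-form checks therefore use ≥100 residues, where the bias is under
  1%.
* RMSD of a frame against a reference is invariant to any rigid transform
  of that frame, which the property tests assert.

## MM/GBSA binding energetics

Single-trajectory end-state protocol: for each snapshot every component is
computed for the complex and for the isolated receptor and ligand at the
identical geometry, and differenced.  The internal (bonded) term cancels
exactly and is reported as 0.

* **Electrostatics**: pairwise Coulomb with k_e = 332.0636 kcal·Å/(mol·e²),
  interior dielectric 1.0, no cutoff (implicit-solvent convention — the
  cutoffs belong to trajectory generation, which is out of scope).
* **van der Waals**: 12-6 Lennard-Jones, Lorentz–Berthelot combining.
* **Polar solvation**: Still-style generalized Born,
  ΔG = −k_e/2 Σ_ij (1/ε_in − e^{−κ f_ij}/ε_out) q_i q_j / f_ij with
  f_ij = √(r² + R_i R_j e^{−r²/(4 R_i R_j)}), self-terms included.
  Effective radii are OBC-II: pairwise HCT descreening integrals with
  scaled reduced radii (offset 0.09 Å, default screen 0.8), rescaled by
  tanh(αΨ − βΨ² + γΨ³) with (α, β, γ) = (1.0, 0.8, 4.85).  OBC-II was
  chosen as the most common MM-GBSA default; the variant is isolated behind
  `born_radii` so an HCT flavour can be swapped in.  An isolated atom's
  effective radius is its intrinsic radius minus the offset; burial only
  increases it.  Salt enters as Debye–Hückel screening, κ computed from
  physical constants for a 1:1 electrolyte (default 0.4 M at 298.15 K,
  ε_out 80).  The single-ion limit reproduces the Born equation.
* **Nonpolar solvation**: γ·SASA with γ = 0.0072 kcal/(mol·Å²), probe
  1.4 Å, heavy atoms only.  SASA is the LCPO analytic form
  A_i = P1·S1 + P2·ΣA_ij + P3·ΣA_jk + P4·Σ A_ij·ΣA_jk over probe-augmented
  spheres, negative per-atom areas clamped to zero.  Published per-type
  coefficients are included for common carbon/oxygen types; atoms without
  covalent context (all synthetic atoms) use the `sphere` set (1, −1, 0, 0),
  which is the exact truncated inclusion–exclusion limit — exact for
  isolated and pairwise-overlapping spheres, degrading when three spheres
  overlap mutually.  The surface-area validation clusters are therefore
  generated in the shallow-pairwise-overlap regime (every pairwise distance
  ≥ 0.88 × the sum of augmented radii), where the point-sampling oracle
  agrees to well under 1%; deep covalent-packing accuracy requires fitted
  per-type coefficients and is not claimed for synthetic atoms.
* **Entropy** is omitted by construction.

Ensembles average the decomposition over snapshots picked from the
trajectory tail — by default the final 100 ns at 2 ns spacing, each target
time mapped to the nearest frame (500 ns at 1 ns/frame → exactly 50
snapshots) — and report per-component SEM = s/√n.  The identity
g_total = Σ components holds to 1e−6 per snapshot and, means being linear,
for ensembles.

**Hydrogen bonds**: a donor–acceptor pair is bonded in a frame when the
minimum-image D–A distance ≤ 3.5 Å and the D–H–A angle ≥ 150° for any
hydrogen attached to the donor (same residue, ≤ 1.3 Å in frame 0).  Both
thresholds are configurable since geometric conventions vary.  Occupancy is
the percentage of frames bonded; Δ-occupancy is cold − hot.

## Lipid interface

Two deliberately different per-residue contact statistics:

* **Minimum distance**: per frame, the minimum-image distance from the
  residue's Cα to any lipid atom; profile value is the time average.
* **Occupancy**: a frame counts when *any* atom of the residue is within
  the cutoff (default 5.0 Å) of any lipid atom; profile value is the
  percentage of frames.  Occupancy is monotone non-decreasing in the
  cutoff.  Δ-occupancy is cold − hot.

**Order parameters**: S_CD(k) = ⟨(3cos²θ − 1)/2⟩ where θ is the angle
between a chain vector and the membrane normal (z).  The default
per-carbon convention uses the C_{k−1} → C_{k+1} vector (reported for
k = 2..n−1), the standard united-atom surrogate that matches per-carbon
profile plots; a whole-chain-axis mode (mean of all C–C bond vectors) is
also provided.  cos² is insensitive to sign, so both leaflets pool without
reflection.  S_CD ∈ [−0.5, 1] always: +1 fully extended along the normal,
0 isotropic, −0.5 in-plane.  Chain membership uses CHARMM POPC atom-name
prefixes (sn-1 = C3x, sn-2 = C2x), overridable.  "Lipids near the protein"
is a per-frame filter: a lipid contributes when any of its chain atoms is
within a shell (default 6.0 Å — the contact cutoff plus one bond length;
the literature rarely states this radius) of any protein atom.
ΔS_CD is hot − cold, so heating-induced disorder is negative.

## Cross-correlated dynamics

C_ij = ⟨Δr_i·Δr_j⟩ / √(⟨|Δr_i|²⟩⟨|Δr_j|²⟩) over Cα displacements from the
trajectory mean, 3D dot products, diagonal set to exactly 1.  The root in
the denominator is the standard Pearson normalization (required for
|C_ij| ≤ 1).  By default frames are superposed on the mean Cα structure
(two-pass, Bio3D-style) before the covariances are taken; the fit is
exposed as a flag because superposing onto a trajectory with *no* real
rigid-body motion (e.g. the Gaussian-network generator) redistributes
noise through the six fitted degrees of freedom and visibly distorts
correlations — the planted-recovery validations therefore run with the fit
disabled, which is the correct estimator for that data-generating process.
Zero-variance residues yield NaN rows/columns with a warning.

ΔCC defaults to cold − hot; because the opposite convention also appears
in the literature the sign is an explicit flag, never silent.
`region_coupling` reports, for each residue outside a residue range, the
mean coupling to the range (self-block excluded).  `threshold_report`
groups cells with |ΔCC| beyond ±0.5 (configurable) into 4-connected blocks
on the matrix grid and reports bounding residue ranges with block means.

## CTD conformational tracking

Secondary structure is assigned from backbone dihedrals alone: a residue
is helical when (φ, ψ) lies within ±30° of (−57°, −47°) *and* belongs to a
run of ≥ 4 consecutive in-window residues; termini and residues with
missing backbone atoms are coil.  This binary, deterministic, rigid-motion
invariant assignment is sufficient to track a helix↔coil transition; it is
not a DSSP/STRIDE replacement (no H-bond patterns, no β or 3₁₀ classes),
and the window and run length are configurable.

Domain–membrane displacement is |z_COM(domain) − z_COM(membrane)| per
frame, mass-weighted, the membrane COM taken over all lipid atoms (not
phosphates only).  Domain atoms are imaged along z to the periodic copy
nearest the membrane COM before averaging, so a genuinely drifting domain
is not folded back into the cell.  The detachment frame is located by a
two-segment least-squares fit (constant before, straight line after,
minimized over the split), which recovers a planted change point to a few
frames at the default noise level.

## Synthetic data: what it emulates and what it does not

Every generator returns (topology, trajectory, ground truth); the truth
travels as a JSON sidecar when written to disk, so recovery tests never
re-derive it from the data they are checking.  All generators are
bit-reproducible under a fixed seed.

* **Gaussian network**: frames drawn from a 3N-dimensional normal around a
  helical mean CA trace.  `covariance_from_residue_correlation` expands an
  n×n residue correlation into isotropic 3×3 blocks, making the planted
  matrix the exact expectation of the DCCM.  Emulates the second-moment
  structure of Cα fluctuations; has no time correlation, anharmonicity or
  rigid-body diffusion.
* **Bilayer**: rigid-rod acyl chains (P bead + two chains of point
  carbons), tilt redrawn per chain per frame from a fixed, isotropic
  (cos θ ~ U(0,1)) or wrapped-Gaussian distribution; leaflets mirrored in
  z.  Rigid rods make ⟨cos²θ⟩ — hence S_CD — analytic while exercising the
  per-carbon vector extraction.  No gauche defects, no per-carbon order
  gradient, no lipid diffusion.
* **H-bond triplets**: donor/H/acceptor placed in an exactly-bonded or
  exactly-broken geometry by an independent Bernoulli(p) draw per frame.
  Occupancy estimators are frame-count fractions, insensitive to dwell
  times, so the absence of temporal autocorrelation is immaterial.
* **Domain drift**: a lipid-bead slab at z = 0 plus a 27-atom pseudo-domain
  whose z-COM is flat until the detachment frame and then linear, plus
  Gaussian jitter (default σ 0.2 Å).
* **Toy complex**: explicit atoms with user-supplied charges/LJ/Born
  parameters whose Coulomb/LJ/GB energies are hand-computable.
* **Sphere clusters**: growth process with every pairwise distance
  ≥ 0.88 × the sum of probe-augmented radii (see LCPO above).

Passing recovery tests on these systems validates the estimators and their
conventions, not the biology: real trajectories add autocorrelation,
anisotropy, conformational substates and force-field physics that no
generator here produces.

The packaged comparative bundle (`make_comparative_bundle`) plants
qualitative cold-vs-hot contrasts chosen once as representative of a
cold-adapted transporter scenario: smaller fluctuations (σ 0.5 vs 0.8 Å)
with an extra correlated residue block when cold; more ordered lipid tilt
(15° ± 8° vs 35° ± 20°); stronger toy-complex binding (ligand 1.2 Å
further out when hot); higher planted H-bond occupancy (0.9 vs 0.35, with
a 0.6 control pair); and membrane detachment only in the hot run.  The
default bundle length is 200 frames at 1 ns/frame so the snapshot picker
yields its standard 50 snapshots.

## Pipeline

`run_pipeline` executes the enabled stages from a validated YAML config
(all validation errors collected before reporting), differences cold and
hot with each stage's documented sign convention, and writes one tidy CSV
per stage (columns: metric, chain, key, value_cold, value_hot, delta,
delta_convention) plus correlation matrices as TSV and a JSON report with
the package version, canonical config hash and seed.  Output formatting is
fixed (`%.6f`), so identical config + inputs give byte-identical outputs.
A stage failure aborts with a stage-named error unless `--keep-going`.

## Problem sizes

Validation sizes were chosen so each check is statistically decisive at
its tolerance: 5000 frames for DCCM/RMSF recovery (sampling error ≪ the
0.05 / 3% bands), 200 lipids × 500 frames for the isotropic S_CD average
(±0.01), 2000 frames for occupancy recovery (99% binomial band), 20 seeds
for the surface-area oracle, and a 120–200-frame bundle for end-to-end
determinism.

## Known limitations

* GB radii/variant are one published choice among several; absolute
  solvation magnitudes depend on it.
* LCPO accuracy for covalently packed heavy atoms depends on fitted
  per-type coefficients; only C/O types ship, others raise.
* The dihedral SS assignment cannot see 3₁₀/π helices or sheets.
* Orthorhombic boxes only; no velocities; no PSF/PRMTOP parsing.
* Analyses assume molecules are whole across the boundary except where
  noted (domain–membrane distance re-images along z).
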