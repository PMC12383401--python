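# mdfingerprint

Comparative fingerprinting of membrane-protein molecular-dynamics
trajectories across temperatures.

Cold-adapted membrane transporters differ from their temperate orthologs
not in one number but in a *profile* of differences between simulations run
cold and hot: per-residue flexibility (ΔRMSF), substrate binding energetics
(MM/GBSA), hydrogen-bond occupancies, protein–lipid contacts and acyl-chain
order (ΔS_CD), cross-correlated residue dynamics (ΔCC), and the
conformation and membrane association of regulatory domains.
`mdfingerprint` implements this whole comparative workflow as a tested
Python library with a thin `fingerprint` CLI, for structural biologists and
simulators who have a topology (PDB) and trajectory pair (DCD/XTC) per
temperature and want the differential profiles with explicit, documented
sign conventions.

Because production trajectories are rarely shareable, the package also
ships generators for synthetic trajectories with *planted* ground truth
(Gaussian fluctuation networks, tilted-rod bilayers, Bernoulli-toggled
hydrogen bonds, drifting domains, hand-computable toy complexes); every
analysis is validated by recovering what was planted.

## The quantities

* **RMSF** (per residue, Å): √⟨|r − ⟨r⟩|²⟩ after two-pass rigid
  superposition; ΔRMSF = RMSF_hot − RMSF_cold.
* **MM/GBSA**: ΔG_bind = ΔE_MM + ΔG_solv per snapshot, averaged over the
  trajectory tail (default: final 100 ns every 2 ns → 50 snapshots), with
  ΔE_MM = ΔE_elec + ΔE_vdW (Coulomb + Lennard-Jones, no cutoff) and
  ΔG_solv = ΔG_GB + γ·ΔSASA (OBC-II generalized Born with Debye–Hückel
  salt screening; LCPO surface area, γ = 0.0072 kcal/(mol·Å²)).  Entropy
  omitted.  The internal term cancels exactly in the single-trajectory
  protocol.
* **H-bond occupancy** (%): fraction of frames with D–A ≤ 3.5 Å and
  D–H–A ≥ 150° (configurable); Δ = cold − hot.
* **Lipid contacts**: Cα–lipid minimum distance (time-averaged) and
  any-atom contact occupancy within 5.0 Å; Δ-occupancy = cold − hot.
* **S_CD** (per acyl carbon): ⟨(3cos²θ − 1)/2⟩ with θ the angle between
  the C_{k−1}→C_{k+1} vector and the bilayer normal; ΔS_CD = hot − cold.
* **DCCM**: C_ij = ⟨Δr_i·Δr_j⟩/√(⟨|Δr_i|²⟩⟨|Δr_j|²⟩) over Cα
  displacements; ΔCC = CC_cold − CC_hot (sign flag available), with
  region-coupling summaries and ±0.5 threshold block reports.
* **CTD tracking**: dihedral-window helix/coil timeline and the
  domain–membrane z-COM distance, with change-point detection.

See `docs/methods.md` for conventions, defaults and limitations.

## Worked example

Generate the self-contained synthetic comparative bundle (five stages,
cold/hot pairs with planted contrasts) and run the full pipeline:

```sh
fingerprint synth bundle --seed 1 --out demo
fingerprint run demo/config.yaml
```

This writes one tidy CSV per stage under `demo/results/`.  The binding
stage (`gbsa.csv`) reports, for the breathing toy complex whose ligand
sits 1.2 Å further out in the hot run:

```
metric           key       value_cold  value_hot  delta
e_electrostatic  kcal/mol   -3.235820  -2.345399   0.890421
e_vdw            kcal/mol   -0.207503  -0.093344   0.114159
g_polar_solv     kcal/mol    3.801996   2.553913  -1.248083
g_nonpolar_solv  kcal/mol   -0.672280  -0.359830   0.312450
g_total          kcal/mol   -0.313608  -0.244660   0.068948
hbond_occupancy_pct N11-O11  88.000000  30.500000  57.500000
```

Binding is stronger cold (g_total more negative), the loss on heating is
electrostatic/vdW partially compensated by cheaper desolvation, and the
planted strong hydrogen bond (occupancy 0.9 cold vs 0.35 hot) shows a
+57.5 point cold−hot occupancy difference.  The lipid stage recovers the
planted tilt ordering — S_CD ≈ 0.87 cold vs 0.44 hot (ΔS_CD ≈ −0.43,
order lost on heating) — and the CTD stage shows the pseudo-domain
detaching from the membrane slab only in the hot trajectory.

Single-stage commands (`fingerprint flex|gbsa|lipids|dccm|ctd`) run one
analysis on explicit topology/trajectory inputs; `fingerprint synth ...`
generates individual ground-truth systems; `fingerprint validate` checks a
config and reports every problem at once.

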