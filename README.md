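# csprobe

Detect subtle protein conformational change upon fragment binding from
solution NMR observables.

## The problem

In fragment-based drug discovery, weakly binding aromatic fragments are
screened against a protein by ¹⁵N-HSQC titration.  Ligand binding perturbs
amide chemical shifts for two reasons: the direct magnetic effect of the
ligand (dominated, for aromatic fragments, by the ring-current field of its
aromatic rings) and any rearrangement of the protein itself.  Crystallography
can resolve the rearrangement, but fragment complexes often refuse to
crystallise.  `csprobe` separates the two contributions computationally: it
simulates the ring-current chemical shift perturbation (CSP) every docked
pose of the fragment would induce at every backbone amide proton, and any
residue whose *experimental* CSP exceeds what the best pose can produce is
evidence that the protein moved.  Residual dipolar couplings (RDCs) provide
an independent, orientation-based cross-check.

The intended users are NMR spectroscopists and structure-based drug
designers with an assigned HSQC, an apo structure, and a set of docked
fragment poses.

## The model

**Ring-current shift (Haigh–Mallion).**  For one aromatic ring and one amide
proton,

```
δ_rc = i · B · Σ_{bonds (j,k)} S_jk · (1/r_j³ + 1/r_k³)
```

where `i` is the ring-type intensity factor (1.00 for a benzene-type
carbocycle), `B` the amide-proton target factor (ppm·Å³), `r_j`, `r_k` the
3D distances from the bond's ring atoms to the proton, and `S_jk` the signed
area of the triangle (proton, atom j, atom k) after projection onto the ring
plane.  The sum runs over the bonds of the ring.  Simulated per-residue CSPs
are the magnitude of the signed sum over all rings of the pose, matching the
magnitude definition of experimental CSPs,

```
CSP_H = |δH_bound − δH_free|,
CSP_combined = sqrt(CSP_H² + (0.14·CSP_N)²).
```

**Pose agreement (P factor).**  For pose *k*, over the residues observed in
both experiment and simulation,

```
P_k = (1/N) Σ_res |CSP_H_exp − CSP_H_sim,k|
```

with `N` the fixed residue count of the protein (an RMSD-style variant is
selectable).  Low `P` means the pose's ring-current field alone explains the
spectrum.  Residues where `CSP_H_exp − max_k CSP_H_sim,k` exceeds 0.2 ppm
(strong) or 0.06 ppm (moderate) are flagged: no candidate binding mode can
explain them, so the protein must have rearranged there.

**RDC cross-check.**  One-bond N–H RDCs obey `D = vᵀ S v` with `S` the
traceless symmetric alignment tensor (5 parameters, fitted by SVD from ≥ 5
couplings).  Agreement between observed and back-calculated couplings is
scored by the Pearson correlation r and the quality factor
`Q = rms(D_exp − D_calc)/rms(D_exp)`; residues deviating by more than
6.5 Hz are flagged, and several candidate structures can be ranked by
refitting the tensor against each.

## Worked example

```sh
python examples/flag_conformational_change.py
```

builds a 20-residue ideal helix, places a benzene fragment 4 Å from the
amide proton of residue 11, forward-models free/bound peak lists from its
ring-current field, injects an extra 0.3 ppm on residues 5 and 9 (a
synthetic "conformational change"), and analyses the result:

```
P factor of the pose: 0.0316 ppm (over 19 residues)
flagged residues (exp CSP exceeds best simulated CSP):
  A5    delta=+0.300 ppm  [strong]
  A9    delta=+0.300 ppm  [strong]
```

The P factor is nonzero only because of the injected perturbation, and
exactly the two injected residues are flagged at the default 0.2 ppm tier —
their CSPs cannot arise from any ring-current effect of the fragment.
Other examples: `simulate_pose_csp.py` (per-residue simulated CSPs),
`fit_rdc_tensor.py` (tensor recovery and structure ranking),
`isoshielding_map.py` (shielding-cone/deshielding-belt map of benzene).

The same pipeline is scriptable from the shell:

```sh
csprobe make-fixtures --out-dir fx --seed 7 --perturb 5,9 --injected-ppm 0.3
csprobe flag --protein fx/protein.pdb --poses fx/poses.pdb \
        --free-peaks fx/peaks_free.tsv --bound-peaks fx/peaks_bound.tsv \
        --out-dir out
csprobe fit-rdc --rdc-table fx/rdcs.tsv --structure fx/protein.pdb --out-dir out
```

Real data enter through the same readers: a PDB protein structure (amide
protons are built onto X-ray coordinates automatically), docked poses as
multi-MODEL PDB or AutoDock pdbqt, peak lists and RDC tables as delimited
text with headers `residue_number [chain] delta_h delta_n` / `rdc_hz`.

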