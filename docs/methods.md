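# Methods

## Scope and model

`csprobe` implements a comparison between experimental amide-proton chemical
shift perturbations (CSPs) and CSPs simulated from the ring-current fields
of docked ligand poses, plus an SVD-based residual dipolar coupling (RDC)
analysis.  The underlying physical assumption is that, in the absence of
protein rearrangement, the dominant contribution of an aromatic fragment to
amide-proton CSPs is the ring-current effect of its aromatic rings.
Contributions the model deliberately omits:

* hydrogen-bond and electric-field shift contributions (hard to simulate
  reliably, and typically localised to few residues);
* nitrogen chemical shifts (not interpretable by a ring-current model;
  the combined CSP is provided for binding-site mapping only);
* protein-side aromatic rings (Phe/Tyr/Trp/His).  Their reorientation is
  precisely the conformational-change signal the comparison is designed to
  expose, so including them would mask the effect being sought.

Consequently a residue whose experimental CSP exceeds the largest simulated
CSP over every candidate pose is evidence of conformational change; the
converse (simulation exceeding experiment) is expected and tolerated, since
docking can place ligands unphysically close to the protein and experimental
CSPs saturate below the simulated maximum when binding is not saturated.

## Ring-current evaluation

The Haigh–Mallion form is used: the shift of a proton due to one ring is
`i·B·Σ_bonds S_jk (1/r_j³ + 1/r_k³)` where `S_jk` is the signed area of the
triangle (proton, ring atom j, ring atom k) with all three vertices
projected onto the ring's least-squares plane, and `r_j`, `r_k` are
*unprojected* 3D distances from the ring atoms to the proton.  The ring
plane normal is oriented by the right-hand rule over the ring's atom
ordering; the result is invariant under reversal of that ordering because
the normal and every bond traversal flip together.  The overall sign is
chosen so the axial shielding cone is negative ppm (upfield) and the
in-plane belt positive.  Per-residue simulated CSPs sum the *signed*
contributions of all rings of a pose first, then take the magnitude — two
rings can partially cancel, as they do physically.

Numerical constants (all configurable through `RingCurrentConstants` and
the CLI config; defaults in `constants.py`):

| constant | default | unit | role |
|---|---|---|---|
| `target_factor_b` | 5.4566 | ppm·Å³ | amide-proton target factor (SHIFTX-lineage calibration) |
| intensity `i` (benzene) | 1.00 | – | reference ring type |
| intensity `i` (other ring classes) | 1.00 | – | placeholder; calibrations vary, override per run |
| clash distance | 0.5 | Å | proton–ring-atom contacts below this are flagged, values retained |
| N–H build length | 1.02 | Å | amide proton construction on X-ray coordinates |

The correctness of the evaluator is established structurally (all invariant
tests are independent of `B`): agreement with an independently coded
brute-force oracle to 1e-12 relative near the ring, the shoelace closure
(per-bond projected triangle areas sum exactly to the ring polygon's area,
wherever the proton sits), mirror symmetry, joint rigid-motion invariance,
and 1/r³ far-field scaling.  Far from the ring the evaluation is a heavy
cancellation of large signed areas, so relative (not absolute) precision
degrades harmlessly at shifts below ~1e-6 ppm.

## Geometry handling

* **Amide protons.**  X-ray inputs lack protons; H is placed in the
  C(i−1)–N–CA plane opposing the bisector of the two N bonds at 1.02 Å.
  Prolines and chain N-termini are never protonated; residues with missing
  geometry are skipped with a warning, not fatally.
* **Ring perception.**  Docking outputs rarely carry connectivity, so bonds
  are inferred from non-hydrogen interatomic distances (≤ 1.8 Å), the
  smallest-cycle basis of that graph is taken, and cycles of size 5–6 made
  of C/N/O/S passing an out-of-plane RMS test (≤ 0.1 Å) become ring-current
  sources.  Larger rings are reported but never scored.  Perception is
  invariant under rigid motion and atom-order permutation.

## CSP analysis

Experimental CSPs are magnitudes; the combined CSP uses the conventional
nitrogen weight 0.14 (configurable) and is intended for binding-site
mapping, not for pose scoring.  The P factor defaults to the mean absolute
deviation normalised by a caller-supplied residue count `N` (the full
protein length, so that sparse experimental coverage is diluted rather than
ignored); an RMSD variant is selectable and recorded in output metadata.
Disagreement tiers default to 0.2 ppm (strong) and 0.06 ppm (moderate) on
`delta = CSP_exp − max_poses CSP_sim`, with the max taken over all poses or
over one cluster (`scope`).  Ties at exactly a threshold fall to the lower
tier; `delta < 0` is reported as `sim_exceeds_exp` and never flagged.

## RDC analysis

Couplings are fitted in Hz with the dipolar prefactor absorbed into the
Saupe tensor, so no gyromagnetic constants enter.  The design matrix uses
direction cosines of unit N–H vectors; plain (unweighted) least squares via
SVD, with an explicit rank check that turns orientationally degenerate
vector sets into a structured error.  The quality factor is
`Q = rms(D_exp − D_calc)/rms(D_exp)` — the simpler of the conventions in
use; a Da-normalised Q is out of scope.  `compare_structures` refits the
tensor independently per candidate structure so each row is self-contained,
and ranks rows by Pearson r.  The outlier threshold defaults to 6.5 Hz.

## Synthetic fixtures

The generators emulate the shape of the real inputs with exactly known
ground truth:

* **Helix.**  An ideal helical backbone parameterised by rise (1.5 Å) and
  twist (100°) per residue; N and C positions are solved numerically from
  ideal backbone bond lengths/angles on helices of the same pitch (residual
  misfit ~0.01 Å — the imposed rise/twist slightly over-constrain the ideal
  internal coordinates).  All residues are alanine-like; amide protons come
  from the same builder used for real structures.
* **Ligand.**  An ideal benzene hexagon (C–C 1.39 Å), optionally a coplanar
  coaxial second ring linked at 1.48 Å (biphenyl-like).  The default
  placement puts the ring on the radial axis through a target residue's
  amide proton at 4 Å, normal pointing at the proton.
* **Peak lists.**  A fixed deterministic baseline plus the signed simulated
  ring-current shift, seeded Gaussian noise, and optional injected
  perturbations on chosen residues (co-signed with the ring shift so the
  CSP magnitude grows by exactly the injected amount).  Nitrogen shifts are
  copied unchanged, mirroring the proton-only simulation scope; combined-CSP
  code paths are tested with hand-set nitrogen deltas instead.
* **RDCs.**  Back-calculated from a known traceless symmetric tensor plus
  seeded Gaussian noise.

What the fixtures do **not** emulate: a real protein fold (packing,
side-chain rings, chemical-shift dispersion from structure), docking
energetics, titration kinetics/partial saturation, peak overlap, or
assignment errors.  Passing tests therefore demonstrate the correctness of
the computation and the internal consistency of the pipeline — not that the
physical model captures every contribution in real spectra (hydrogen-bond
terms and protein-ring currents are known omissions, discussed above).

Every generator is a pure function of its spec: fixed seed ⇒ byte-identical
output files.

## Numerical choices and edge cases

* Degenerate (collinear) rings and zero-variance RDC sets raise structured
  errors rather than returning NaN.
* Protons inside 0.5 Å of a ring atom are flagged but their (large) shifts
  are retained — close contacts produced by rigid-body docking are a
  finding, not an invalid input.
* Problem sizes used by the test-suite and the verification script (helices
  of 12–25 residues, 100 oracle configurations, 80 noise replicates at
  n ∈ {10, 20, 40}) were chosen as the smallest sizes at which every
  property is sharply testable; all scale linearly if enlarged.
* The P-factor normalisation `N` must be supplied by the caller (protein
  length convention); the CLI defaults it to the number of simulated
  residues when unspecified.

## Known limitations

* Only 5- and 6-membered rings are scored; macrocycles are ignored with a
  notice.
* Intensity factors for non-benzene ring classes default to 1.00 and should
  be overridden when a specific calibration is required.
* No Johnson–Bovey or point-dipole alternatives; no error-weighted RDC
  fitting; no prediction of alignment from molecular shape.
* Saturation of the binding site is assumed; no Kd extrapolation of CSPs.
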