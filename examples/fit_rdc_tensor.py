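"""Fit an alignment tensor to RDCs and rank candidate structures.

Generates couplings from a known tensor on a helix, fits them back by SVD
(perfect recovery), then compares the generating structure against a decoy
whose N-H vectors were rotated by 30 degrees on residues 5-14.  The Pearson
r and quality factor Q per structure show which backbone matches the
couplings measured in solution.
"""

import dataclasses

import numpy as np
from scipy.spatial.transform import Rotation

from csprobe import back_calculate_rdc, compare_structures, fit_alignment_tensor, nh_vectors
from csprobe.structio import RDCSet
from csprobe.synthfix import FixtureSpec, make_helix_protein, random_alignment_tensor

rng = np.random.default_rng(1)
protein = make_helix_protein(FixtureSpec(n_residues=20))
tensor = random_alignment_tensor(rng)
rdcs = RDCSet("bound", back_calculate_rdc(tensor, nh_vectors(protein)))

fit = fit_alignment_tensor(rdcs, nh_vectors(protein))
print(f"tensor recovery: r = {fit.pearson_r:.4f}, Q = {fit.q_factor:.2e}, "
      f"Da = {fit.tensor.axial:.2f} Hz, R = {fit.tensor.rhombicity:.3f}")

rot = Rotation.from_euler("x", 30.0, degrees=True)
decoy_amides = []
for a in protein.amides:
    if a.h_coord is not None and 5 <= a.residue_number <= 14:
        nh = a.h_coord - a.n_coord
        a = dataclasses.replace(a, h_coord=a.n_coord + rot.apply(nh))
    decoy_amides.append(a)
decoy = dataclasses.replace(protein, source_id="decoy", amides=decoy_amides)

print("\nstructure ranking against the same couplings:")
for row in compare_structures(rdcs, [decoy, protein]):
    print(f"  {row.structure_id:<8s} r={row.pearson_r:.4f} Q={row.q_factor:.4f} "
          f"n={row.n_used} outliers={len(row.outliers)}")
print(
    "\nThe generating structure fits exactly (r = 1); the decoy's rotated\n"
    "N-H vectors degrade the correlation — how RDCs expose a backbone whose\n"
    "solution conformation differs from the model."
)
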