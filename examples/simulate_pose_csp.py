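"""Simulate ring-current CSPs of a docked aromatic fragment on a helix.

Builds a 20-residue ideal helix, places a benzene ring 4 A from the amide
proton of residue 11, and prints the largest simulated amide-proton CSPs.
The values are the magnitude of the Haigh-Mallion ring-current shift each
amide proton would experience if the fragment bound at that pose: residues
facing the ring's shielding cone shift the most.
"""

from csprobe import perceive_aromatic_rings, simulate_pose_csp
from csprobe.synthfix import FixtureSpec, make_helix_protein, make_ring_pose

spec = FixtureSpec(n_residues=20)
protein = make_helix_protein(spec)
pose = perceive_aromatic_rings(make_ring_pose(spec, protein))

csp = simulate_pose_csp(protein, pose)
print("residue   simulated CSP_H (ppm)")
for key, value in sorted(csp.items(), key=lambda kv: -kv[1])[:5]:
    print(f"  {key[0]}{key[1]:<4d}   {value:8.4f}")
print(
    "\nThe target residue (A11) sits on the ring axis and shows the largest\n"
    "shift; its helical neighbours feel the decaying 1/r^3 fringe field."
)
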