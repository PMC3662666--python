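"""Detect residues whose CSP no docked pose can explain.

Forward-models free/bound peak lists from a single pose, injects an extra
0.3 ppm perturbation on residues 5 and 9 (emulating a local conformational
change), and runs the disagreement analysis.  Exactly the injected residues
are recovered as "strong" flags; the P factor quantifies how well the pose
explains everything else.
"""

from csprobe import (
    compute_experimental_csp,
    flag_disagreement,
    p_factor,
    perceive_aromatic_rings,
    simulate_ensemble,
)
from csprobe.synthfix import (
    FixtureSpec,
    make_helix_protein,
    make_ring_pose,
    make_synthetic_peaklists,
)

spec = FixtureSpec(
    n_residues=20, perturbed_residues=frozenset({5, 9}), injected_ppm=0.3, seed=1
)
protein = make_helix_protein(spec)
pose = perceive_aromatic_rings(make_ring_pose(spec, protein))
free, bound = make_synthetic_peaklists(protein, pose, spec)

table = compute_experimental_csp(free, bound)
matrix = simulate_ensemble(protein, [pose])
(score,) = p_factor(table, matrix, n_residues=len(matrix.residues))
report = flag_disagreement(table, matrix)   # defaults: 0.2 / 0.06 ppm tiers

print(f"P factor of the pose: {score.p_value:.4f} ppm "
      f"(over {score.n_residues_used} residues)")
print("flagged residues (exp CSP exceeds best simulated CSP):")
for e in report.flagged:
    print(f"  {e.key[0]}{e.key[1]:<4d} delta={e.delta:+.3f} ppm  [{e.tier}]")
print(
    "\nOnly the residues carrying the injected perturbation are flagged:\n"
    "their experimental CSP cannot arise from the fragment's ring current,\n"
    "so the protein itself must have rearranged there."
)
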