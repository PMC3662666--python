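"""Map the ring-current field of a benzene ring (iso-shielding sections).

Samples the Haigh-Mallion shift on the plane perpendicular to an ideal
benzene ring and prints a coarse character map: '-' marks the shielding
cone above/below the ring (upfield, negative ppm), '+' the in-plane
deshielding belt (downfield, positive ppm).  The full numeric grid is
written as a delimited matrix.
"""

import numpy as np

from csprobe import isoshielding_grid, perceive_aromatic_rings
from csprobe.synthfix import FixtureSpec, make_ring_pose

pose = perceive_aromatic_rings(
    make_ring_pose(FixtureSpec(ligand_position=(0.0, 0.0, 0.0)))
)
grid = isoshielding_grid(
    pose.rings[0], plane_spec="perpendicular", extent=6.0, resolution=0.5
)
grid.write("isoshielding_perpendicular.tsv")

print("perpendicular section through the ring centre (x: in-plane, y: axis):")
for y, row in zip(grid.coords2[::-1], grid.values[::-1]):
    chars = "".join(
        "x" if np.isnan(v) else ("-" if v < -0.01 else "+" if v > 0.01 else ".")
        for v in row
    )
    print(f"  {y:+5.1f} A  {chars}")
axial = grid.values[np.argmin(np.abs(grid.coords2 - 3.0)),
                    np.argmin(np.abs(grid.coords1))]
print(f"\nshift 3 A above the ring centre: {axial:+.3f} ppm (shielding cone)")
print("wrote full grid to isoshielding_perpendicular.tsv")
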