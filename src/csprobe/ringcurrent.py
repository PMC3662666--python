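"""Haigh-Mallion ring-current shifts for amide protons.

The semi-classical Haigh-Mallion model writes the ring-current contribution
of one aromatic ring to the shift of a proton as

    delta = i * B * sum over ring bonds (j,k) of S_jk * (1/r_j^3 + 1/r_k^3)

where ``i`` is the ring-type intensity factor, ``B`` the target-nucleus
factor (ppm * A^3, calibrated for amide protons), ``r_j``/``r_k`` the full 3D
distances from the bond's two ring atoms to the proton, and ``S_jk`` the
signed area of the triangle formed by the proton and the two ring atoms after
projection onto the ring plane.  The sign convention used here reports the
axial shielding cone as negative ppm (upfield) and the in-plane deshielding
belt as positive ppm; it is independent of the arbitrary choice of ring
normal, because reversing the atom order flips both the normal and every
bond traversal.

Per-residue simulated CSPs are the magnitude of the signed sum over all
ligand rings, matching how experimental CSPs are defined as magnitudes.
Protein-side aromatic rings (Phe/Tyr/Trp/His) are deliberately not part of
the simulation: their reorientation is precisely the conformational-change
signal the comparison is designed to expose.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .constants import RingCurrentConstants
from .structio import AromaticRing, LigandPose, ProteinStructure, ResidueKey

logger = logging.getLogger(__name__)


@dataclass
class SimulatedCSPMatrix:
    """Simulated amide-proton CSPs: rows = residues, columns = poses."""

    residues: list[ResidueKey]
    pose_ids: list[int]
    values: np.ndarray                       # (n_residues, n_poses), ppm >= 0
    cluster_ids: list[int | None] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.residues), len(self.pose_ids)):
            raise ValueError("CSP matrix shape inconsistent with labels")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("CSP matrix contains non-finite values")

    def column(self, pose_id: int) -> dict[ResidueKey, float]:
        j = self.pose_ids.index(pose_id)
        return {res: float(self.values[i, j]) for i, res in enumerate(self.residues)}

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.values,
            index=[f"{c}{n}" for c, n in self.residues],
            columns=[f"pose_{p}" for p in self.pose_ids],
        )
        df.index.name = "residue"
        return df

    def write(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", float_format="%.8f")


def ring_plane(ring: AromaticRing) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares plane of a ring: (centroid, unit normal).

    The normal orientation follows the right-hand rule over the ring's atom
    ordering.  Degenerate (collinear) rings raise ``ValueError``.
    """
    coords = ring.coords
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < 1e-9 * max(s[0], 1.0):
        raise ValueError(f"ring {ring.ring_label}: atoms are collinear")
    normal = vt[2]
    # orient by the polygon's circulation
    circulation = np.zeros(3)
    n = len(coords)
    for i in range(n):
        circulation += np.cross(centered[i], centered[(i + 1) % n])
    if np.dot(normal, circulation) < 0:
        normal = -normal
    return centroid, normal / np.linalg.norm(normal)


def signed_projected_area(
    a: np.ndarray,
    b: np.ndarray,
    p: np.ndarray,
    plane: tuple[np.ndarray, np.ndarray],
) -> float:
    """Signed area (A^2) of triangle (p', a', b') projected onto the ring plane.

    Positive when the traversal p' -> a' -> b' runs counter-clockwise about
    the plane normal.  Degenerate triangles return 0.
    """
    centroid, normal = plane

    def proj(x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return x - np.dot(x - centroid, normal) * normal

    ap = proj(a) - proj(p)
    bp = proj(b) - proj(p)
    return 0.5 * float(np.dot(normal, np.cross(ap, bp)))


def ring_current_shift(
    proton: np.ndarray,
    ring: AromaticRing,
    constants: RingCurrentConstants | None = None,
) -> float:
    """Signed Haigh-Mallion ring-current shift (ppm) of one ring at a proton.

    Negative in the axial shielding cone, positive in the in-plane
    deshielding belt.  Protons inside the clash distance of any ring atom are
    flagged via the logger but the value is still returned (close contacts
    produced by rigid docking are a finding, not an error).
    """
    constants = constants or RingCurrentConstants()
    proton = np.asarray(proton, dtype=float)
    plane = ring_plane(ring)
    coords = ring.coords
    dists = np.linalg.norm(coords - proton, axis=1)
    if float(dists.min()) <= constants.clash_distance:
        logger.warning(
            "proton within clash distance (%.2f A) of ring %s",
            float(dists.min()), ring.ring_label,
        )
    inv3 = 1.0 / dists**3
    n = len(coords)
    total = 0.0
    for i in range(n):
        j = (i + 1) % n
        s_ij = signed_projected_area(coords[i], coords[j], proton, plane)
        total += s_ij * (inv3[i] + inv3[j])
    return -ring.intensity_factor * constants.target_factor_b * total


def signed_pose_shift(
    protein: ProteinStructure,
    pose: LigandPose,
    constants: RingCurrentConstants | None = None,
) -> dict[ResidueKey, float]:
    """Signed summed ring-current shift per amide proton (used by fixtures/maps)."""
    constants = constants or RingCurrentConstants()
    if not pose.rings:
        logger.warning(
            "pose %d has no aromatic rings: ring-current model has no signal",
            pose.pose_id,
        )
    out: dict[ResidueKey, float] = {}
    for amide in protein.amides:
        if amide.h_coord is None:
            continue
        out[amide.key] = sum(
            ring_current_shift(amide.h_coord, ring, constants) for ring in pose.rings
        )
    return out


def simulate_pose_csp(
    protein: ProteinStructure,
    pose: LigandPose,
    constants: RingCurrentConstants | None = None,
) -> dict[ResidueKey, float]:
    """Simulated amide-proton CSP (ppm, >= 0) for one ligand pose.

    Signed ring contributions are summed first, then the magnitude is taken,
    mirroring the magnitude definition of experimental CSPs.  Residues
    without an amide proton are absent from the map.
    """
    return {k: abs(v) for k, v in signed_pose_shift(protein, pose, constants).items()}


def simulate_ensemble(
    protein: ProteinStructure,
    poses: Sequence[LigandPose],
    constants: RingCurrentConstants | None = None,
) -> SimulatedCSPMatrix:
    """Simulated CSP matrix over a pose ensemble (column per pose, in order)."""
    if not poses:
        raise ValueError("simulate_ensemble requires at least one pose")
    constants = constants or RingCurrentConstants()
    residues = [a.key for a in protein.amides if a.h_coord is not None]
    values = np.zeros((len(residues), len(poses)))
    for j, pose in enumerate(poses):
        col = simulate_pose_csp(protein, pose, constants)
        values[:, j] = [col[r] for r in residues]
    return SimulatedCSPMatrix(
        residues=residues,
        pose_ids=[p.pose_id for p in poses],
        values=values,
        cluster_ids=[p.cluster_id for p in poses],
    )


@dataclass
class IsoshieldingGrid:
    """Regular 2D grid of ring-current shifts around a ring centroid."""

    plane_spec: str                  # "in-plane" | "perpendicular"
    axis1: np.ndarray                # unit vector of the grid x axis
    axis2: np.ndarray                # unit vector of the grid y axis
    coords1: np.ndarray              # (n,) offsets along axis1, Angstrom
    coords2: np.ndarray              # (m,) offsets along axis2
    values: np.ndarray               # (m, n) ppm, NaN where clashing
    ring_label: str = "ring"

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# ring: {self.ring_label}\n")
            fh.write(f"# plane: {self.plane_spec}\n")
            fh.write(
                f"# extent: {self.coords1.max():.3f} A, "
                f"resolution: {self.coords1[1] - self.coords1[0]:.3f} A\n"
            )
            fh.write("# rows: axis2 offsets; columns: axis1 offsets (ppm values)\n")
            header = "\t".join(f"{x:.3f}" for x in self.coords1)
            fh.write(f"offset\t{header}\n")
            for y, row in zip(self.coords2, self.values):
                cells = "\t".join("nan" if np.isnan(v) else f"{v:.6f}" for v in row)
                fh.write(f"{y:.3f}\t{cells}\n")


def isoshielding_grid(
    ring: AromaticRing,
    plane_spec: str = "perpendicular",
    extent: float = 8.0,
    resolution: float = 0.25,
    constants: RingCurrentConstants | None = None,
) -> IsoshieldingGrid:
    """Map the ring-current shift on a plane through the ring centroid.

    ``plane_spec='in-plane'`` samples the ring plane itself;
    ``'perpendicular'`` samples the plane spanned by one in-plane axis and
    the ring normal (the classic shielding-cone section).  Grid points within
    the clash distance of a ring atom are masked as NaN.
    """
    if extent <= 0 or resolution <= 0:
        raise ValueError("extent and resolution must be positive")
    constants = constants or RingCurrentConstants()
    centroid, normal = ring_plane(ring)
    e1 = ring.coords[0] - centroid
    e1 = e1 - np.dot(e1, normal) * normal
    e1 /= np.linalg.norm(e1)
    if plane_spec == "in-plane":
        e2 = np.cross(normal, e1)
    elif plane_spec == "perpendicular":
        e2 = normal
    else:
        raise ValueError("plane_spec must be 'in-plane' or 'perpendicular'")

    offsets = np.arange(-extent, extent + 0.5 * resolution, resolution)
    values = np.zeros((len(offsets), len(offsets)))
    for iy, y in enumerate(offsets):
        for ix, x in enumerate(offsets):
            p = centroid + x * e1 + y * e2
            if np.linalg.norm(ring.coords - p, axis=1).min() <= constants.clash_distance:
                values[iy, ix] = np.nan
            else:
                values[iy, ix] = ring_current_shift(p, ring, constants)
    return IsoshieldingGrid(
        plane_spec=plane_spec,
        axis1=e1,
        axis2=e2,
        coords1=offsets,
        coords2=offsets,
        values=values,
        ring_label=ring.ring_label,
    )
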