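"""Synthetic inputs with known ground truth for testing and demonstration.

The generators stand in for the real experimental system (a helical protein,
an aromatic fragment docked nearby, HSQC peak lists, phage-aligned RDCs):

* an ideal alpha-helix backbone, parameterised by rise and twist, with
  correct bond geometry solved numerically;
* benzene / biphenyl-like ring poses placed at known positions;
* peak lists forward-modelled from a pose's ring-current field, optionally
  with injected "conformational change" perturbations on chosen residues;
* RDC sets generated from a known alignment tensor.

Every generator is a pure, seeded function of its spec: a fixed seed yields
byte-identical outputs.  Realism is deliberately limited — see the methods
note for what these fixtures do and do not emulate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

from .rdcfit import AlignmentTensor, back_calculate_rdc, nh_vectors
from .ringcurrent import signed_pose_shift
from .structio import (
    Atom,
    LigandPose,
    PeakList,
    ProteinStructure,
    RDCSet,
    ResidueKey,
    build_amide_protons,
    perceive_aromatic_rings,
    write_ligand_poses,
    write_peaklist,
    write_protein_structure,
    write_rdc_table,
)

# ideal backbone internal coordinates (Angstrom / degrees)
_N_CA = 1.458
_CA_C = 1.525
_C_N = 1.329
_C_O = 1.231
_ANG_N_CA_C = 111.2
_ANG_CA_C_N = 116.2
_ANG_C_N_CA = 121.7
_CA_RADIUS = 2.30          # Angstrom, CA helix radius of an ideal alpha-helix
_BENZENE_CC = 1.39         # Angstrom, aromatic C-C bond
_RING_LINK = 1.48          # Angstrom, biphenyl inter-ring single bond


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic protein/ligand/peak-list/RDC scenario.

    ``rise``/``twist`` set the helix geometry (defaults: ideal alpha-helix,
    1.5 A rise and 100 deg twist per residue).  The ligand ring is placed at
    ``ligand_position`` (or, when that is None, on the amide-proton axis of
    ``target_residue`` at ``ligand_distance`` A — the ring's shielding cone
    then points at that residue, which therefore shows the largest simulated
    CSP).  ``perturbed_residues`` receive an extra ``injected_ppm`` on the
    bound-state proton shift, emulating a conformational change the ring
    currents cannot explain.
    """

    n_residues: int = 30
    rise: float = 1.5
    twist: float = 100.0
    chain_id: str = "A"
    ring_count: int = 1
    ligand_position: tuple[float, float, float] | None = None
    ligand_euler: tuple[float, float, float] = (0.0, 0.0, 0.0)
    target_residue: int | None = None
    ligand_distance: float = 4.0
    perturbed_residues: frozenset[int] = frozenset()
    injected_ppm: float = 0.0
    noise_ppm: float = 0.0
    noise_hz: float = 0.0
    tensor_params: tuple[float, float, float, float, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_residues < 5:
            raise ValueError("n_residues must be >= 5")
        if self.ring_count not in (1, 2):
            raise ValueError("ring_count must be 1 or 2")
        if self.injected_ppm < 0:
            raise ValueError("injected_ppm must be >= 0")


def _cyl(radius: float, phi_deg: float, z: float) -> np.ndarray:
    phi = math.radians(phi_deg)
    return np.array([radius * math.cos(phi), radius * math.sin(phi), z])


def _helix_offsets(rise: float, twist: float) -> tuple[np.ndarray, np.ndarray]:
    """Solve cylindrical offsets of N and C relative to CA on an ideal helix.

    CA_i sits at (radius ``_CA_RADIUS``, angle i*twist, height i*rise); N and
    C travel helices of the same pitch with six unknown offsets (radius, phase,
    height each), determined in least squares from the six ideal bond
    lengths / angles of the backbone.  For helix parameters near the ideal
    alpha-helix the residual misfit is ~0.01 A / 0.01 deg (the imposed
    rise/twist slightly over-constrain the ideal internal coordinates).
    Returns the two offset triples (r, phi_deg, dz).
    """

    def angle(p, q, r):
        u = p - q
        v = r - q
        cosa = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
        return math.degrees(math.acos(np.clip(cosa, -1.0, 1.0)))

    def residuals(x):
        rn, pn, zn, rc, pc, zc = x
        ca0 = _cyl(_CA_RADIUS, 0.0, 0.0)
        ca1 = _cyl(_CA_RADIUS, twist, rise)
        n0 = _cyl(rn, pn, zn)
        n1 = _cyl(rn, twist + pn, rise + zn)
        c0 = _cyl(rc, pc, zc)
        return [
            np.linalg.norm(n0 - ca0) - _N_CA,
            np.linalg.norm(c0 - ca0) - _CA_C,
            np.linalg.norm(n1 - c0) - _C_N,
            angle(n0, ca0, c0) - _ANG_N_CA_C,
            angle(ca0, c0, n1) - _ANG_CA_C_N,
            angle(c0, n1, ca1) - _ANG_C_N_CA,
        ]

    guess = [1.60, -26.0, -0.85, 2.00, 27.0, 0.44]
    sol = least_squares(residuals, guess, xtol=1e-14, ftol=1e-14, gtol=1e-14)
    if not sol.success or np.abs(sol.fun).max() > 0.05:
        raise RuntimeError(
            f"helix geometry solve failed for rise={rise}, twist={twist}"
        )
    rn, pn, zn, rc, pc, zc = sol.x
    return np.array([rn, pn, zn]), np.array([rc, pc, zc])


def make_helix_protein(spec: FixtureSpec) -> ProteinStructure:
    """Ideal helical backbone (N, CA, C, O + built amide H), residues 1..n."""
    n_off, c_off = _helix_offsets(spec.rise, spec.twist)
    atoms: list[Atom] = []
    n = spec.n_residues
    for i in range(n):
        key: ResidueKey = (spec.chain_id, i + 1)
        phi = i * spec.twist
        z = i * spec.rise
        n_pos = _cyl(n_off[0], phi + n_off[1], z + n_off[2])
        ca_pos = _cyl(_CA_RADIUS, phi, z)
        c_pos = _cyl(c_off[0], phi + c_off[1], z + c_off[2])
        # carbonyl O in the peptide plane, opposite the bisector at C
        n_next = _cyl(n_off[0], (i + 1) * spec.twist + n_off[1],
                      (i + 1) * spec.rise + n_off[2])
        u1 = ca_pos - c_pos
        u1 /= np.linalg.norm(u1)
        u2 = n_next - c_pos
        u2 /= np.linalg.norm(u2)
        o_dir = -(u1 + u2)
        o_pos = c_pos + _C_O * o_dir / np.linalg.norm(o_dir)
        atoms.extend(
            [
                Atom("N", "N", n_pos, key, "ALA"),
                Atom("CA", "C", ca_pos, key, "ALA"),
                Atom("C", "C", c_pos, key, "ALA"),
                Atom("O", "O", o_pos, key, "ALA"),
            ]
        )
    from .structio import AmideGroup

    amides = [
        AmideGroup(spec.chain_id, i + 1, "ALA", atoms[4 * i].coord) for i in range(n)
    ]
    structure = ProteinStructure(
        source_id=f"helix{n}", model_index=0, amides=amides, all_atoms=atoms
    )
    return build_amide_protons(structure)


def _benzene_ring(center: np.ndarray, first_index: int) -> list[Atom]:
    atoms = []
    for k in range(6):
        ang = math.radians(60.0 * k)
        pos = center + _BENZENE_CC * np.array([math.cos(ang), math.sin(ang), 0.0])
        atoms.append(
            Atom(f"C{first_index + k}", "C", pos, ("L", 1), "LIG")
        )
    return atoms


def make_ring_pose(spec: FixtureSpec, protein: ProteinStructure | None = None) -> LigandPose:
    """Benzene (or coaxial biphenyl-like two-ring) pose at a known placement.

    The ring template lies in the local xy-plane (normal +z) centred at the
    origin; it is rotated by ``ligand_euler`` (xyz, degrees) and translated
    to ``ligand_position``.  When ``ligand_position`` is None a protein must
    be supplied: the ring is centred ``ligand_distance`` A radially outward
    from the amide proton of ``target_residue`` (default: the middle
    residue), ring normal pointing back at that proton, so the target sits
    on the shielding-cone axis and is the closest amide to the ring.  Rings
    are left empty for :func:`perceive_aromatic_rings`.
    """
    atoms = _benzene_ring(np.zeros(3), 1)
    if spec.ring_count == 2:
        atoms += _benzene_ring(
            np.array([2 * _BENZENE_CC + _RING_LINK, 0.0, 0.0]), 7
        )

    rot = Rotation.from_euler("xyz", spec.ligand_euler, degrees=True)
    if spec.ligand_position is not None:
        position = np.asarray(spec.ligand_position, dtype=float)
    else:
        if protein is None:
            raise ValueError(
                "make_ring_pose needs a protein when ligand_position is None"
            )
        target = spec.target_residue or (spec.n_residues // 2 + 1)
        amide = protein.amide_map().get((spec.chain_id, target))
        if amide is None or amide.h_coord is None:
            raise ValueError(f"target residue {target} has no amide proton")
        radial = amide.h_coord.copy()
        radial[2] = 0.0            # helix axis is z for fixture helices
        radial /= np.linalg.norm(radial)
        position = amide.h_coord + spec.ligand_distance * radial
        # align ring normal (+z of the template) with the outward radial axis
        rot = Rotation.align_vectors([radial], [[0.0, 0.0, 1.0]])[0]

    placed = [
        Atom(a.name, a.element, rot.apply(a.coord) + position, a.residue_key, a.residue_name)
        for a in atoms
    ]
    return LigandPose(pose_id=1, atoms=placed, rings=[])


def make_synthetic_peaklists(
    protein: ProteinStructure, pose: LigandPose, spec: FixtureSpec
) -> tuple[PeakList, PeakList]:
    """Forward-model free/bound peak lists from one pose's ring-current field.

    The free list carries an arbitrary fixed baseline; the bound list adds
    the signed ring-current shift, seeded Gaussian noise (sigma =
    ``noise_ppm``) and, on ``perturbed_residues``, an ``injected_ppm``
    perturbation co-signed with the ring shift so the experimental CSP
    magnitude grows by exactly the injected amount (noise apart).  Nitrogen
    shifts are copied unchanged: the ring-current model predicts protons
    only.
    """
    if not pose.rings:
        raise ValueError("pose rings must be perceived before forward-modelling")
    rng = np.random.default_rng([spec.seed, 1])
    shifts = signed_pose_shift(protein, pose)
    free: dict[ResidueKey, tuple[float, float]] = {}
    bound: dict[ResidueKey, tuple[float, float]] = {}
    for amide in protein.amides:
        if amide.h_coord is None:
            continue
        key = amide.key
        dh = 8.2 + 0.3 * math.sin(0.7 * key[1])
        dn = 118.0 + 5.0 * math.sin(0.3 * key[1])
        s = shifts[key]
        bh = dh + s
        if key[1] in spec.perturbed_residues:
            bh += spec.injected_ppm * (1.0 if s >= 0 else -1.0)
        if spec.noise_ppm > 0:
            bh += rng.normal(0.0, spec.noise_ppm)
        free[key] = (dh, dn)
        bound[key] = (bh, dn)
    names = {a.key: a.residue_name for a in protein.amides}
    return (
        PeakList("free", free, names),
        PeakList("bound", bound, names),
    )


def make_synthetic_rdcs(
    protein: ProteinStructure,
    tensor: AlignmentTensor,
    spec: FixtureSpec,
    state_label: str = "synthetic",
) -> RDCSet:
    """RDC set back-calculated from a known tensor plus seeded Gaussian noise."""
    rng = np.random.default_rng([spec.seed, 2])
    vectors = nh_vectors(protein)
    couplings = back_calculate_rdc(tensor, vectors)
    if spec.noise_hz > 0:
        couplings = {
            k: d + rng.normal(0.0, spec.noise_hz) for k, d in couplings.items()
        }
    return RDCSet(state_label, couplings)


def random_alignment_tensor(rng: np.random.Generator, scale: float = 10.0) -> AlignmentTensor:
    """Random traceless symmetric tensor with elements on the given Hz scale."""
    return AlignmentTensor.from_params(rng.normal(0.0, scale, size=5))


def random_unit_vectors(rng: np.random.Generator, n: int) -> np.ndarray:
    """n unit vectors drawn uniformly on the sphere."""
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def write_fixture_set(spec: FixtureSpec, out_dir: str | Path) -> dict[str, Path]:
    """Emit a complete worked example (PDB, poses, peak lists, RDCs) to disk.

    Returns the mapping of logical names to file paths.  All files are in the
    structio dialects and re-ingest cleanly; output is byte-identical for a
    fixed spec.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    protein = make_helix_protein(spec)
    pose = perceive_aromatic_rings(make_ring_pose(spec, protein))
    free, bound = make_synthetic_peaklists(protein, pose, spec)
    tensor = (
        AlignmentTensor.from_params(spec.tensor_params)
        if spec.tensor_params is not None
        else random_alignment_tensor(np.random.default_rng([spec.seed, 3]))
    )
    rdcs = make_synthetic_rdcs(protein, tensor, spec)

    paths = {
        "protein": out / "protein.pdb",
        "poses": out / "poses.pdb",
        "free_peaks": out / "peaks_free.tsv",
        "bound_peaks": out / "peaks_bound.tsv",
        "rdcs": out / "rdcs.tsv",
    }
    write_protein_structure(protein, paths["protein"])
    write_ligand_poses([pose], paths["poses"])
    write_peaklist(free, paths["free_peaks"])
    write_peaklist(bound, paths["bound_peaks"])
    write_rdc_table(rdcs, paths["rdcs"])
    return paths
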