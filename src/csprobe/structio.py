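"""Structure and table I/O: proteins, ligand pose ensembles, peak lists, RDC tables.

Conventions
-----------
* Residues are keyed by ``(chain_id, residue_number)`` using the numbering of
  the input file; numbering is never renormalised.
* PDB is the pose interchange format; AutoDock ``.pdbqt`` is accepted
  read-only.  Covalent bonds of ligands are inferred from interatomic
  distances (docking outputs rarely carry CONECT records).
* Peak lists and RDC tables are comma- or tab-delimited text with a header;
  writers emit the same dialect the readers consume.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import networkx as nx
import numpy as np
import pandas as pd

from .constants import DEFAULT_NH_LENGTH

logger = logging.getLogger(__name__)

ResidueKey = tuple[str, int]

DEFAULT_BOND_CUTOFF = 1.8     # Angstrom, non-hydrogen covalent cutoff
DEFAULT_PLANARITY_TOL = 0.1   # Angstrom, RMS out-of-plane tolerance for rings
RING_CAPABLE_ELEMENTS = {"C", "N", "O", "S"}

#: AutoDock atom types -> chemical element (pdbqt files carry AD types, not
#: element symbols, in the last column).
_PDBQT_ELEMENTS = {
    "A": "C", "C": "C", "N": "N", "NA": "N", "NS": "N", "OA": "O", "OS": "O",
    "O": "O", "S": "S", "SA": "S", "H": "H", "HD": "H", "HS": "H", "F": "F",
    "CL": "Cl", "BR": "Br", "I": "I", "P": "P",
}


class StructureError(ValueError):
    """Raised for unreadable or inconsistent structural input."""


class TableError(ValueError):
    """Raised for unreadable peak-list / RDC tables."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class AmideGroup:
    """One backbone amide observation site (the N-H of a residue)."""

    chain_id: str
    residue_number: int
    residue_name: str
    n_coord: np.ndarray
    h_coord: np.ndarray | None = None
    h_built: bool = False

    @property
    def key(self) -> ResidueKey:
        return (self.chain_id, self.residue_number)

    def __post_init__(self) -> None:
        self.n_coord = np.asarray(self.n_coord, dtype=float)
        if self.h_coord is not None:
            self.h_coord = np.asarray(self.h_coord, dtype=float)
            d = float(np.linalg.norm(self.h_coord - self.n_coord))
            if not 0.8 <= d <= 1.2:
                raise StructureError(
                    f"amide H of {self.chain_id}{self.residue_number} is {d:.2f} A "
                    "from N (expected 0.8-1.2 A)"
                )


@dataclass
class Atom:
    name: str
    element: str
    coord: np.ndarray
    residue_key: ResidueKey
    residue_name: str = ""

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)


@dataclass
class ProteinStructure:
    """Protein atoms of one model, plus the derived list of amide groups."""

    source_id: str
    model_index: int
    amides: list[AmideGroup]
    all_atoms: list[Atom]

    def amide_map(self) -> dict[ResidueKey, AmideGroup]:
        return {a.key: a for a in self.amides}

    def atom(self, key: ResidueKey, name: str) -> Atom | None:
        for at in self.all_atoms:
            if at.residue_key == key and at.name == name:
                return at
        return None

    def _atom_index(self) -> dict[tuple[ResidueKey, str], Atom]:
        return {(a.residue_key, a.name): a for a in self.all_atoms}


@dataclass
class AromaticRing:
    """An ordered cycle of ligand atoms acting as a ring-current source."""

    atom_indices: list[int]
    coords: np.ndarray            # (n_ring, 3)
    intensity_factor: float = 1.0
    ring_label: str = "ring"
    ring_type: str = "benzene"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if len(self.atom_indices) not in (5, 6):
            raise StructureError(
                f"ring {self.ring_label}: cycle length must be 5 or 6, "
                f"got {len(self.atom_indices)}"
            )
        if self.coords.shape != (len(self.atom_indices), 3):
            raise StructureError(f"ring {self.ring_label}: coords shape mismatch")

    def reversed(self) -> "AromaticRing":
        return AromaticRing(
            atom_indices=list(reversed(self.atom_indices)),
            coords=self.coords[::-1].copy(),
            intensity_factor=self.intensity_factor,
            ring_label=self.ring_label,
            ring_type=self.ring_type,
        )


@dataclass
class LigandPose:
    """One docked ligand conformation."""

    pose_id: int
    atoms: list[Atom]
    rings: list[AromaticRing] = field(default_factory=list)
    cluster_id: int | None = None
    binding_energy: float | None = None

    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms], dtype=float)


@dataclass
class PeakList:
    """Per-residue amide chemical shifts for one titration state."""

    state_label: str
    entries: dict[ResidueKey, tuple[float, float]]   # (delta_h ppm, delta_n ppm)
    residue_names: dict[ResidueKey, str] = field(default_factory=dict)
    ligand_concentration: float | None = None

    def __post_init__(self) -> None:
        for key, (dh, dn) in self.entries.items():
            if not (math.isfinite(dh) and math.isfinite(dn)):
                raise TableError(f"non-finite shift for residue {key}")


@dataclass
class RDCSet:
    """Per-residue one-bond N-H residual dipolar couplings (Hz)."""

    state_label: str
    entries: dict[ResidueKey, float]

    def __post_init__(self) -> None:
        for key, d in self.entries.items():
            if not math.isfinite(d):
                raise TableError(f"non-finite RDC for residue {key}")


# ---------------------------------------------------------------------------
# protein structures
# ---------------------------------------------------------------------------

def read_protein_structure(path: str | Path, model_index: int = 0) -> ProteinStructure:
    """Read one model of a PDB file into a :class:`ProteinStructure`.

    HETATM ligands and waters are excluded from the amide list (and from
    ``all_atoms``, which carries protein atoms only).  Every residue with a
    backbone N atom contributes an amide group; amide protons are taken from
    the file when present (``H``/``HN``) and can otherwise be built with
    :func:`build_amide_protons`.
    """
    path = Path(path)
    if not path.exists():
        raise StructureError(f"structure file not found: {path}")
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"cannot parse PDB file {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureError(f"no models in {path}")
    if not 0 <= model_index < len(st):
        raise StructureError(
            f"model_index {model_index} out of range for {path} "
            f"({len(st)} model(s))"
        )
    model = st[model_index]

    amides: list[AmideGroup] = []
    atoms: list[Atom] = []
    for chain in model:
        chain_has_n = False
        chain_has_protein_atom = False
        for res in chain:
            if res.het_flag != "A":       # skip HETATM (ligands, waters)
                continue
            chain_has_protein_atom = True
            key = (chain.name, res.seqid.num)
            n_coord = None
            h_coord = None
            for at in res:
                pos = np.array([at.pos.x, at.pos.y, at.pos.z])
                atoms.append(Atom(at.name, at.element.name, pos, key, res.name))
                if at.name == "N":
                    n_coord = pos
                elif at.name in ("H", "HN") and res.name != "PRO":
                    h_coord = pos
            if n_coord is not None:
                chain_has_n = True
                amides.append(
                    AmideGroup(chain.name, res.seqid.num, res.name, n_coord, h_coord)
                )
        if chain_has_protein_atom and not chain_has_n:
            raise StructureError(
                f"chain {chain.name!r} in {path} has no backbone N atoms"
            )
    amides.sort(key=lambda a: (a.chain_id, a.residue_number))
    return ProteinStructure(
        source_id=path.stem, model_index=model_index, amides=amides, all_atoms=atoms
    )


def write_protein_structure(structure: ProteinStructure, path: str | Path) -> None:
    """Write a structure as a single-model PDB file (fixed-width ATOM records)."""
    path = Path(path)
    lines: list[str] = []
    serial = 0
    for at in structure.all_atoms:
        serial += 1
        chain, resnum = at.residue_key
        name = at.name if len(at.name) >= 4 else f" {at.name:<3s}"
        lines.append(
            f"ATOM  {serial:5d} {name:<4s} {at.residue_name:<3s} {chain:1s}"
            f"{resnum:4d}    {at.coord[0]:8.3f}{at.coord[1]:8.3f}{at.coord[2]:8.3f}"
            f"{1.0:6.2f}{0.0:6.2f}          {at.element:>2s}"
        )
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def build_amide_protons(
    structure: ProteinStructure, nh_length: float = DEFAULT_NH_LENGTH
) -> ProteinStructure:
    """Place missing backbone amide protons by the in-plane bisector rule.

    For every non-proline, non-N-terminal residue lacking an amide H, the
    proton is placed in the plane of C(i-1), N, CA along the direction
    opposing the bisector of the N->C(i-1) and N->CA bonds, at ``nh_length``
    Angstrom from N.  Residues whose preceding C or own CA is missing are
    skipped with a warning.  Existing protons are left untouched; the
    operation is idempotent.
    """
    index = structure._atom_index()
    chains: dict[str, list[AmideGroup]] = {}
    for am in structure.amides:
        chains.setdefault(am.chain_id, []).append(am)

    new_amides: list[AmideGroup] = []
    for chain_id, chain_amides in chains.items():
        first_resnum = min(a.residue_number for a in chain_amides)
        for am in chain_amides:
            if (
                am.h_coord is not None
                or am.residue_name == "PRO"
                or am.residue_number == first_resnum
            ):
                new_amides.append(am)
                continue
            ca = index.get((am.key, "CA"))
            c_prev = index.get(((chain_id, am.residue_number - 1), "C"))
            if ca is None or c_prev is None:
                logger.warning(
                    "cannot build amide H for %s%d: missing %s",
                    chain_id, am.residue_number,
                    "CA" if ca is None else "preceding C",
                )
                new_amides.append(am)
                continue
            u1 = c_prev.coord - am.n_coord
            u1 /= np.linalg.norm(u1)
            u2 = ca.coord - am.n_coord
            u2 /= np.linalg.norm(u2)
            direction = -(u1 + u2)
            direction /= np.linalg.norm(direction)
            h = am.n_coord + nh_length * direction
            new_amides.append(replace(am, h_coord=h, h_built=True))
    new_amides.sort(key=lambda a: (a.chain_id, a.residue_number))

    new_atoms = list(structure.all_atoms)
    for am in new_amides:
        if am.h_built and structure.amide_map()[am.key].h_coord is None:
            new_atoms.append(Atom("H", "H", am.h_coord, am.key, am.residue_name))
    return ProteinStructure(
        source_id=structure.source_id,
        model_index=structure.model_index,
        amides=new_amides,
        all_atoms=new_atoms,
    )


# ---------------------------------------------------------------------------
# ligand poses
# ---------------------------------------------------------------------------

_CLUSTER_RE = re.compile(r"cluster\s*[=:#]?\s*(\d+)", re.IGNORECASE)
_ENERGY_RE = re.compile(
    r"(?:free energy of binding|binding energy|energy binding|energy)\s*[=:]?\s*"
    r"(-?\d+(?:\.\d+)?)",
    re.IGNORECASE,
)


def _pose_line_atom(line: str, lineno: int, pdbqt: bool) -> Atom:
    try:
        name = line[12:16].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except (ValueError, IndexError) as exc:
        raise StructureError(f"malformed coordinate line {lineno}: {line!r}") from exc
    if pdbqt:
        # AutoDock type is the last field (fixed columns drift between tools)
        ad_type = line.split()[-1] if line.split() else name[:1]
        element = _PDBQT_ELEMENTS.get(ad_type.upper(), ad_type.capitalize())
    else:
        element = line[76:78].strip().capitalize()
        if not element:
            element = re.sub(r"[^A-Za-z]", "", name)[:1].upper()
    return Atom(name, element, np.array([x, y, z]), ("L", 1))


def read_ligand_poses(path: str | Path, format_hint: str | None = None) -> list[LigandPose]:
    """Read a ligand pose ensemble from a PDB multi-MODEL or pdbqt file.

    One :class:`LigandPose` is returned per MODEL block (a file without MODEL
    records yields a single pose).  AutoDock cluster ids and binding energies
    are parsed from REMARK/USER lines when present.  Rings are left empty;
    call :func:`perceive_aromatic_rings` to fill them.
    """
    path = Path(path)
    if not path.exists():
        raise StructureError(f"pose file not found: {path}")
    fmt = (format_hint or path.suffix.lstrip(".")).lower()
    pdbqt = fmt == "pdbqt"

    poses: list[LigandPose] = []
    atoms: list[Atom] = []
    cluster_id: int | None = None
    energy: float | None = None
    in_model = False
    next_id = 1

    def flush(pose_id: int) -> None:
        nonlocal atoms, cluster_id, energy
        if atoms:
            poses.append(LigandPose(pose_id, atoms, [], cluster_id, energy))
        atoms, cluster_id, energy = [], None, None

    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "MODEL":
                flush(next_id)
                next_id = len(poses) + 1
                in_model = True
            elif rec == "ENDMDL":
                flush(next_id)
                next_id = len(poses) + 1
                in_model = False
            elif rec in ("ATOM", "HETATM"):
                atoms.append(_pose_line_atom(line.rstrip("\n"), lineno, pdbqt))
            elif rec in ("REMARK", "USER"):
                m = _CLUSTER_RE.search(line)
                if m:
                    cluster_id = int(m.group(1))
                m = _ENERGY_RE.search(line)
                if m:
                    energy = float(m.group(1))
    flush(next_id)
    del in_model
    if not poses:
        raise StructureError(f"no ligand poses found in {path}")
    return poses


def write_ligand_poses(poses: Sequence[LigandPose], path: str | Path) -> None:
    """Write poses as a multi-MODEL PDB file (cluster/energy as REMARK lines)."""
    path = Path(path)
    lines: list[str] = []
    for pose in poses:
        lines.append(f"MODEL     {pose.pose_id:4d}")
        if pose.cluster_id is not None:
            lines.append(f"REMARK  cluster = {pose.cluster_id}")
        if pose.binding_energy is not None:
            lines.append(f"REMARK  binding energy = {pose.binding_energy:.3f} kcal/mol")
        for i, at in enumerate(pose.atoms, start=1):
            name = at.name if len(at.name) >= 4 else f" {at.name:<3s}"
            lines.append(
                f"HETATM{i:5d} {name:<4s} LIG L   1    "
                f"{at.coord[0]:8.3f}{at.coord[1]:8.3f}{at.coord[2]:8.3f}"
                f"{1.0:6.2f}{0.0:6.2f}          {at.element:>2s}"
            )
        lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def _ring_type(elements: Sequence[str], size: int) -> str:
    all_carbon = all(e == "C" for e in elements)
    if size == 6:
        return "benzene" if all_carbon else "six-heterocycle"
    return "five-carbocycle" if all_carbon else "five-heterocycle"


def _order_cycle(graph: nx.Graph, nodes: set[int]) -> list[int]:
    """Order a set of cycle nodes by walking the induced cycle subgraph."""
    sub = graph.subgraph(nodes)
    start = min(nodes)
    order = [start]
    prev = None
    current = start
    while len(order) < len(nodes):
        nbrs = [n for n in sub.neighbors(current) if n != prev]
        if not nbrs:
            raise StructureError("cycle nodes do not form a simple cycle")
        prev, current = current, min(nbrs) if len(order) == 1 else nbrs[0]
        order.append(current)
    return order


def perceive_aromatic_rings(
    pose: LigandPose,
    planarity_tol: float = DEFAULT_PLANARITY_TOL,
    bond_cutoff: float = DEFAULT_BOND_CUTOFF,
) -> LigandPose:
    """Detect planar 5- and 6-membered rings of a pose from geometry alone.

    The covalent graph is inferred from non-hydrogen interatomic distances
    (<= ``bond_cutoff`` Angstrom); the smallest-cycle basis is extracted and
    cycles of size 5-6 built from ring-capable elements (C/N/O/S) that pass
    the out-of-plane RMS test are kept as :class:`AromaticRing` sources.
    Larger rings are reported (log) but never scored.  Returns a new pose;
    the input is not modified.
    """
    heavy = [(i, a) for i, a in enumerate(pose.atoms) if a.element != "H"]
    rings: list[AromaticRing] = []
    if len(heavy) >= 3:
        coords = np.array([a.coord for _, a in heavy])
        dists = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
        graph = nx.Graph()
        graph.add_nodes_from(idx for idx, _ in heavy)
        n = len(heavy)
        for i in range(n):
            for j in range(i + 1, n):
                if 0.4 < dists[i, j] <= bond_cutoff:
                    graph.add_edge(heavy[i][0], heavy[j][0])
        for cycle_nodes in nx.minimum_cycle_basis(graph):
            size = len(cycle_nodes)
            if size not in (5, 6):
                if size > 6:
                    logger.info(
                        "pose %d: %d-membered ring ignored (only 5/6 scored)",
                        pose.pose_id, size,
                    )
                continue
            order = _order_cycle(graph, set(cycle_nodes))
            elements = [pose.atoms[i].element for i in order]
            if any(e not in RING_CAPABLE_ELEMENTS for e in elements):
                continue
            ring_coords = np.array([pose.atoms[i].coord for i in order])
            centered = ring_coords - ring_coords.mean(axis=0)
            _, s, vt = np.linalg.svd(centered, full_matrices=False)
            rms_out = float(np.sqrt(np.mean((centered @ vt[2]) ** 2)))
            if rms_out > planarity_tol:
                continue
            rtype = _ring_type(elements, size)
            rings.append(
                AromaticRing(
                    atom_indices=order,
                    coords=ring_coords,
                    intensity_factor=1.0,
                    ring_label=f"pose{pose.pose_id}_ring{len(rings) + 1}",
                    ring_type=rtype,
                )
            )
    return LigandPose(
        pose_id=pose.pose_id,
        atoms=list(pose.atoms),
        rings=rings,
        cluster_id=pose.cluster_id,
        binding_energy=pose.binding_energy,
    )


# ---------------------------------------------------------------------------
# tabular formats
# ---------------------------------------------------------------------------

def _read_table(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise TableError(f"table not found: {path}")
    try:
        df = pd.read_csv(path, sep=None, engine="python", comment="#")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise TableError(f"cannot parse table {path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableError(f"{path}: missing required column(s) {missing}")
    return df


def _residue_keys(df: pd.DataFrame, path: Path) -> list[ResidueKey]:
    chains = df["chain"] if "chain" in df.columns else ["A"] * len(df)
    try:
        numbers = [int(n) for n in df["residue_number"]]
    except (TypeError, ValueError) as exc:
        raise TableError(f"{path}: non-integer residue_number") from exc
    return [(str(c), n) for c, n in zip(chains, numbers)]


def read_peaklist(path: str | Path, state_label: str | None = None) -> PeakList:
    """Read a peak list (columns: residue_number [chain] [residue_name] delta_h delta_n)."""
    path = Path(path)
    df = _read_table(path, ["residue_number", "delta_h", "delta_n"])
    keys = _residue_keys(df, path)
    entries: dict[ResidueKey, tuple[float, float]] = {}
    names: dict[ResidueKey, str] = {}
    for i, key in enumerate(keys):
        if key in entries:
            raise TableError(f"{path}: duplicate residue {key[0]}{key[1]}")
        try:
            dh = float(df["delta_h"].iloc[i])
            dn = float(df["delta_n"].iloc[i])
        except (TypeError, ValueError) as exc:
            raise TableError(f"{path}: non-numeric shift for residue {key}") from exc
        entries[key] = (dh, dn)
        if "residue_name" in df.columns:
            names[key] = str(df["residue_name"].iloc[i])
    if not entries:
        raise TableError(f"{path}: no peak entries")
    return PeakList(state_label or path.stem, entries, names)


def write_peaklist(peaks: PeakList, path: str | Path) -> None:
    rows = [
        {
            "chain": key[0],
            "residue_number": key[1],
            "residue_name": peaks.residue_names.get(key, "UNK"),
            "delta_h": dh,
            "delta_n": dn,
        }
        for key, (dh, dn) in sorted(peaks.entries.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_rdc_table(path: str | Path, state_label: str | None = None) -> RDCSet:
    """Read an RDC table (columns: residue_number [chain] rdc_hz)."""
    path = Path(path)
    df = _read_table(path, ["residue_number", "rdc_hz"])
    keys = _residue_keys(df, path)
    entries: dict[ResidueKey, float] = {}
    for i, key in enumerate(keys):
        if key in entries:
            raise TableError(f"{path}: duplicate residue {key[0]}{key[1]}")
        try:
            entries[key] = float(df["rdc_hz"].iloc[i])
        except (TypeError, ValueError) as exc:
            raise TableError(f"{path}: non-numeric RDC for residue {key}") from exc
    if not entries:
        raise TableError(f"{path}: no RDC entries")
    return RDCSet(state_label or path.stem, entries)


def write_rdc_table(rdcs: RDCSet, path: str | Path) -> None:
    rows = [
        {"chain": key[0], "residue_number": key[1], "rdc_hz": d}
        for key, d in sorted(rdcs.entries.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6f")
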