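"""Alignment-tensor fitting and RDC back-calculation by SVD.

A one-bond N-H residual dipolar coupling reports the orientation of the N-H
bond unit vector v relative to the molecular alignment (Saupe) tensor S,

    D = v^T S v,   S symmetric and traceless (5 independent elements).

With the dipolar prefactor absorbed into S, couplings are fitted in Hz
directly: each residue contributes one row of the design matrix

    [vx^2 - vz^2,  vy^2 - vz^2,  2 vx vy,  2 vx vz,  2 vy vz]

acting on (Sxx, Syy, Sxy, Sxz, Syz), solved by singular-value decomposition
(plain least squares; the source experiments carry no per-residue weights).
Back-calculated couplings from the fitted tensor are compared to experiment
through the Pearson correlation r and the quality factor

    Q = rms(D_exp - D_calc) / rms(D_exp),

and residues deviating by more than a threshold (default 6.5 Hz) are flagged
as outliers — the residues whose N-H orientation in solution disagrees with
the model structure.  ``compare_structures`` runs the whole fit independently
per candidate structure and ranks them by r.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .constants import DEFAULT_RDC_OUTLIER_HZ
from .structio import ProteinStructure, RDCSet, ResidueKey, build_amide_protons

logger = logging.getLogger(__name__)


class FitError(ValueError):
    """Raised when an alignment-tensor fit is impossible or degenerate."""


@dataclass
class AlignmentTensor:
    """Traceless symmetric order tensor, scaled into Hz.

    ``saupe`` holds the full 3x3 matrix; ``from_params``/``params`` map to
    the 5 independent elements (Sxx, Syy, Sxy, Sxz, Syz) with
    Szz = -Sxx - Syy.
    """

    saupe: np.ndarray

    def __post_init__(self) -> None:
        self.saupe = np.asarray(self.saupe, dtype=float)
        if self.saupe.shape != (3, 3):
            raise FitError("Saupe matrix must be 3x3")
        if abs(np.trace(self.saupe)) > 1e-9 * max(1.0, np.abs(self.saupe).max()):
            raise FitError("Saupe matrix must be traceless")
        if np.abs(self.saupe - self.saupe.T).max() > 1e-9 * max(
            1.0, np.abs(self.saupe).max()
        ):
            raise FitError("Saupe matrix must be symmetric")

    @classmethod
    def from_params(cls, params: Sequence[float]) -> "AlignmentTensor":
        sxx, syy, sxy, sxz, syz = (float(p) for p in params)
        szz = -sxx - syy
        return cls(np.array([[sxx, sxy, sxz], [sxy, syy, syz], [sxz, syz, szz]]))

    @property
    def params(self) -> np.ndarray:
        s = self.saupe
        return np.array([s[0, 0], s[1, 1], s[0, 1], s[0, 2], s[1, 2]])

    @property
    def eigenvalues(self) -> np.ndarray:
        """Principal values ordered by increasing magnitude (|Sxx'| <= |Syy'| <= |Szz'|)."""
        w = np.linalg.eigvalsh(self.saupe)
        return w[np.argsort(np.abs(w))]

    @property
    def axial(self) -> float:
        """Axial component Da = Szz'/2 in the principal frame."""
        return float(self.eigenvalues[2] / 2.0)

    @property
    def rhombicity(self) -> float:
        """R = (Sxx' - Syy') / Szz' (0 for axially symmetric alignment)."""
        w = self.eigenvalues
        return float((w[0] - w[1]) / w[2])


@dataclass
class FitResult:
    """One SVD alignment fit: tensor, per-residue couplings, r and Q."""

    tensor: AlignmentTensor
    d_exp: dict[ResidueKey, float]
    d_calc: dict[ResidueKey, float]
    pearson_r: float
    q_factor: float
    residues_used: list[ResidueKey]

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.pearson_r <= 1.0 + 1e-12:
            raise FitError("Pearson r out of range")
        if self.q_factor < 0:
            raise FitError("Q factor cannot be negative")


def nh_vectors(structure: ProteinStructure) -> dict[ResidueKey, np.ndarray]:
    """Unit N->H bond vectors per residue (protons built if absent).

    Prolines and the N-terminal residue carry no amide proton and are absent
    from the map; any other residue still lacking H after building is
    reported via the logger and skipped.
    """
    if any(a.h_coord is None and a.residue_name != "PRO" for a in structure.amides):
        structure = build_amide_protons(structure)
    first_per_chain: dict[str, int] = {}
    for a in structure.amides:
        first_per_chain[a.chain_id] = min(
            first_per_chain.get(a.chain_id, a.residue_number), a.residue_number
        )
    out: dict[ResidueKey, np.ndarray] = {}
    for amide in structure.amides:
        if amide.h_coord is None:
            if (
                amide.residue_name != "PRO"
                and amide.residue_number != first_per_chain[amide.chain_id]
            ):
                logger.warning(
                    "residue %s%d lacks an amide H even after building; skipped",
                    amide.chain_id, amide.residue_number,
                )
            continue
        v = amide.h_coord - amide.n_coord
        out[amide.key] = v / np.linalg.norm(v)
    return out


def _design_row(v: np.ndarray) -> np.ndarray:
    x, y, z = v
    return np.array([x * x - z * z, y * y - z * z, 2 * x * y, 2 * x * z, 2 * y * z])


def back_calculate_rdc(
    tensor: AlignmentTensor, vectors: Mapping[ResidueKey, np.ndarray]
) -> dict[ResidueKey, float]:
    """Couplings (Hz) predicted by a tensor for a set of unit N-H vectors."""
    out: dict[ResidueKey, float] = {}
    for key, v in vectors.items():
        v = np.asarray(v, dtype=float)
        out[key] = float(v @ tensor.saupe @ v)
    return out


def fit_quality(
    d_exp: Mapping[ResidueKey, float], d_calc: Mapping[ResidueKey, float]
) -> tuple[float, float]:
    """Pearson r and quality factor Q = rms(exp - calc)/rms(exp) on shared keys."""
    shared = sorted(set(d_exp) & set(d_calc))
    if len(shared) < 2:
        raise FitError("fit_quality needs at least 2 shared residues")
    e = np.array([d_exp[k] for k in shared])
    c = np.array([d_calc[k] for k in shared])
    if np.allclose(e, e[0]):
        raise FitError("experimental RDCs have zero variance; correlation undefined")
    rms_exp = float(np.sqrt(np.mean(e**2)))
    if rms_exp == 0.0:
        raise FitError("rms of experimental RDCs is zero; Q undefined")
    r = float(stats.pearsonr(e, c).statistic)
    q = float(np.sqrt(np.mean((e - c) ** 2)) / rms_exp)
    return r, q


def fit_alignment_tensor(
    rdcs: RDCSet, vectors: Mapping[ResidueKey, np.ndarray]
) -> FitResult:
    """Least-squares (SVD) fit of the 5 Saupe elements to observed couplings.

    Requires >= 5 residues shared between the RDC set and the vector map with
    non-degenerate orientations; a rank-deficient design matrix (e.g. all
    N-H vectors parallel) raises :class:`FitError`.
    """
    shared = sorted(set(rdcs.entries) & set(vectors))
    if len(shared) < 5:
        raise FitError(
            f"alignment fit needs >= 5 shared residues, got {len(shared)}"
        )
    a = np.array([_design_row(np.asarray(vectors[k], dtype=float)) for k in shared])
    b = np.array([rdcs.entries[k] for k in shared])
    rank = np.linalg.matrix_rank(a, tol=1e-8 * max(1.0, float(np.abs(a).max())))
    if rank < 5:
        raise FitError(
            f"design matrix rank {rank} < 5: N-H vector set is orientationally degenerate"
        )
    params, *_ = np.linalg.lstsq(a, b, rcond=None)
    tensor = AlignmentTensor.from_params(params)
    d_calc = back_calculate_rdc(tensor, {k: vectors[k] for k in shared})
    d_exp = {k: rdcs.entries[k] for k in shared}
    r, q = fit_quality(d_exp, d_calc)
    return FitResult(
        tensor=tensor,
        d_exp=d_exp,
        d_calc=d_calc,
        pearson_r=r,
        q_factor=q,
        residues_used=shared,
    )


def flag_rdc_outliers(
    d_exp: Mapping[ResidueKey, float],
    d_calc: Mapping[ResidueKey, float],
    threshold: float = DEFAULT_RDC_OUTLIER_HZ,
) -> list[ResidueKey]:
    """Residues with |D_exp - D_calc| above threshold, largest deviation first."""
    if threshold <= 0:
        raise FitError("outlier threshold must be positive")
    shared = set(d_exp) & set(d_calc)
    devs = {k: abs(d_exp[k] - d_calc[k]) for k in shared}
    flagged = [k for k, d in devs.items() if d > threshold]
    return sorted(flagged, key=lambda k: -devs[k])


@dataclass
class StructureComparison:
    structure_id: str
    pearson_r: float | None
    q_factor: float | None
    n_used: int
    outliers: list[ResidueKey] = field(default_factory=list)
    error: str | None = None


def compare_structures(
    rdcs: RDCSet,
    structures: Sequence[ProteinStructure],
    residue_subset: Sequence[ResidueKey] | None = None,
    outlier_threshold: float = DEFAULT_RDC_OUTLIER_HZ,
) -> list[StructureComparison]:
    """Fit the same RDC set against several candidate structures.

    The tensor is refitted independently per structure (each row is a
    self-contained SVD fit); ``residue_subset`` optionally restricts the
    analysis, e.g. to the helices near a binding site.  Structures whose fit
    fails yield a row carrying the error instead of aborting the comparison.
    Rows are ranked by Pearson r descending (failed fits last).
    """
    if not structures:
        raise FitError("compare_structures needs at least one structure")
    rows: list[StructureComparison] = []
    for structure in structures:
        try:
            vectors = nh_vectors(structure)
            if residue_subset is not None:
                vectors = {k: v for k, v in vectors.items() if k in set(residue_subset)}
            result = fit_alignment_tensor(rdcs, vectors)
            outliers = flag_rdc_outliers(
                result.d_exp, result.d_calc, threshold=outlier_threshold
            )
            rows.append(
                StructureComparison(
                    structure_id=structure.source_id,
                    pearson_r=result.pearson_r,
                    q_factor=result.q_factor,
                    n_used=len(result.residues_used),
                    outliers=outliers,
                )
            )
        except FitError as exc:
            logger.warning("fit failed for %s: %s", structure.source_id, exc)
            rows.append(
                StructureComparison(
                    structure_id=structure.source_id,
                    pearson_r=None,
                    q_factor=None,
                    n_used=0,
                    error=str(exc),
                )
            )
    rows.sort(key=lambda r: (-(r.pearson_r if r.pearson_r is not None else -np.inf)))
    return rows


def comparison_table(rows: Sequence[StructureComparison]):
    """Comparison rows as a DataFrame with stable column order."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "structure": r.structure_id,
                "pearson_r": r.pearson_r,
                "q_factor": r.q_factor,
                "n_used": r.n_used,
                "outliers": ";".join(f"{c}{n}" for c, n in r.outliers),
                "error": r.error or "",
            }
            for r in rows
        ]
    )
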