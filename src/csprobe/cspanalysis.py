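"""Experimental CSPs, pose agreement (P factor), and conformational-change flags.

Experimental chemical shift perturbations are magnitudes of the free-to-bound
shift difference per residue:

    CSP_H = |dH_bound - dH_free|,  CSP_N = |dN_bound - dN_free|,
    CSP_combined = sqrt(CSP_H^2 + (w * CSP_N)^2)   (w = 0.14 by default)

The per-pose agreement factor P compares experimental proton CSPs to the
CSPs simulated from a docked pose's ring currents, normalised by a
caller-supplied residue count N (conventionally the full protein length),
so that proteins of different sizes score on the same scale:

    P_k = (1/N) * sum_res |CSP_H_exp - CSP_H_sim,k|        (mad mode)
    P_k = sqrt((1/N) * sum_res (CSP_H_exp - CSP_H_sim,k)^2) (rmsd mode)

Low P means the pose's ring-current field alone explains the observed
perturbations.  Residues whose experimental CSP exceeds the *maximum*
simulated CSP over every candidate pose cannot be explained by any binding
mode and are flagged as evidence of protein conformational change, in two
tiers (defaults 0.2 ppm strong / 0.06 ppm moderate).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .constants import (
    DEFAULT_MODERATE_THRESHOLD,
    DEFAULT_NITROGEN_WEIGHT,
    DEFAULT_STRONG_THRESHOLD,
)
from .ringcurrent import SimulatedCSPMatrix
from .structio import PeakList, ResidueKey

#: Sentinel cluster id for poses that carry no cluster label.
UNCLUSTERED = -1


class AnalysisError(ValueError):
    """Raised for inconsistent CSP-analysis inputs."""


@dataclass
class CSPEntry:
    csp_h: float
    csp_n: float | None = None
    csp_combined: float | None = None


@dataclass
class CSPTable:
    """Per-residue experimental chemical shift perturbations (ppm, >= 0)."""

    entries: dict[ResidueKey, CSPEntry]
    unmatched_free: list[ResidueKey] = field(default_factory=list)
    unmatched_bound: list[ResidueKey] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "chain": key[0],
                "residue_number": key[1],
                "csp_h": e.csp_h,
                "csp_n": e.csp_n,
                "csp_combined": e.csp_combined,
            }
            for key, e in sorted(self.entries.items())
        ]
        return pd.DataFrame(rows)


@dataclass
class PoseScore:
    """Agreement of one pose's simulated CSPs with experiment (lower = better)."""

    pose_id: int
    p_value: float
    n_residues_used: int
    cluster_id: int | None = None
    mode: str = "mad"

    def __post_init__(self) -> None:
        if self.p_value < 0:
            raise AnalysisError("P factor cannot be negative")


@dataclass
class ResidueDisagreement:
    key: ResidueKey
    csp_h_exp: float
    max_csp_h_sim: float
    delta: float                       # exp - max(sim); > 0 means unexplained
    tier: Literal["strong", "moderate", "none", "sim_exceeds_exp"]


@dataclass
class DisagreementReport:
    """Residues whose experimental CSP cannot be explained by any pose."""

    entries: list[ResidueDisagreement]
    strong_threshold: float
    moderate_threshold: float
    scope: str = "all"

    @property
    def flagged(self) -> list[ResidueDisagreement]:
        """Strong + moderate residues, sorted by delta descending."""
        out = [e for e in self.entries if e.tier in ("strong", "moderate")]
        return sorted(out, key=lambda e: -e.delta)

    def residues(self, tier: str) -> list[ResidueKey]:
        return [e.key for e in self.entries if e.tier == tier]

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "chain": e.key[0],
                "residue_number": e.key[1],
                "csp_h_exp": e.csp_h_exp,
                "max_csp_h_sim": e.max_csp_h_sim,
                "delta": e.delta,
                "tier": e.tier,
            }
            for e in sorted(self.entries, key=lambda e: -e.delta)
        ]
        return pd.DataFrame(rows)


def compute_experimental_csp(
    free: PeakList,
    bound: PeakList,
    n_weight: float = DEFAULT_NITROGEN_WEIGHT,
) -> CSPTable:
    """Per-residue CSPs between a free and a ligand-bound peak list.

    Only residues present in both lists are scored; keys found in a single
    list are recorded as unmatched.  Raises if the lists share no residue.
    """
    shared = sorted(set(free.entries) & set(bound.entries))
    if not shared:
        raise AnalysisError(
            f"peak lists {free.state_label!r} and {bound.state_label!r} share no residues"
        )
    entries: dict[ResidueKey, CSPEntry] = {}
    for key in shared:
        fh, fn = free.entries[key]
        bh, bn = bound.entries[key]
        csp_h = abs(bh - fh)
        csp_n = abs(bn - fn)
        combined = math.sqrt(csp_h**2 + (n_weight * csp_n) ** 2)
        entries[key] = CSPEntry(csp_h=csp_h, csp_n=csp_n, csp_combined=combined)
    return CSPTable(
        entries=entries,
        unmatched_free=sorted(set(free.entries) - set(bound.entries)),
        unmatched_bound=sorted(set(bound.entries) - set(free.entries)),
    )


def p_factor(
    exp: CSPTable,
    sim: SimulatedCSPMatrix,
    n_residues: int,
    mode: Literal["mad", "rmsd"] = "mad",
) -> list[PoseScore]:
    """P agreement factor for every pose of a simulated CSP matrix.

    Residues present in only one of experiment/simulation contribute zero to
    the sum, but the normalisation N stays the caller-supplied total residue
    count, so sparse experimental coverage does not inflate agreement.
    """
    if n_residues <= 0:
        raise AnalysisError("n_residues must be positive")
    if mode not in ("mad", "rmsd"):
        raise AnalysisError(f"unknown P-factor mode {mode!r}")
    shared = [r for r in sim.residues if r in exp.entries]
    if not shared:
        raise AnalysisError("experiment and simulation share no residues")
    if n_residues < len(shared):
        raise AnalysisError(
            f"n_residues={n_residues} smaller than shared residue count {len(shared)}"
        )
    rows = [sim.residues.index(r) for r in shared]
    exp_vec = np.array([exp.entries[r].csp_h for r in shared])
    diffs = np.abs(sim.values[rows, :] - exp_vec[:, None])   # (shared, poses)

    scores: list[PoseScore] = []
    clusters = sim.cluster_ids or [None] * len(sim.pose_ids)
    for j, pose_id in enumerate(sim.pose_ids):
        if mode == "mad":
            p = float(diffs[:, j].sum() / n_residues)
        else:
            p = float(np.sqrt((diffs[:, j] ** 2).sum() / n_residues))
        scores.append(
            PoseScore(
                pose_id=pose_id,
                p_value=p,
                n_residues_used=len(shared),
                cluster_id=clusters[j],
                mode=mode,
            )
        )
    return scores


@dataclass
class ClusterSummary:
    """Per-cluster P statistics plus the global P range."""

    clusters: dict[int, tuple[float, float, float, int]]  # mean, min, max, count
    global_min: float
    global_max: float

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "cluster_id": cid,
                "mean_p": stats[0],
                "min_p": stats[1],
                "max_p": stats[2],
                "count": stats[3],
            }
            for cid, stats in sorted(self.clusters.items())
        ]
        return pd.DataFrame(rows)


def aggregate_clusters(scores: Sequence[PoseScore]) -> ClusterSummary:
    """Mean/min/max P per pose cluster (unlabelled poses grouped as UNCLUSTERED)."""
    if not scores:
        raise AnalysisError("no pose scores to aggregate")
    groups: dict[int, list[float]] = {}
    for s in scores:
        cid = s.cluster_id if s.cluster_id is not None else UNCLUSTERED
        groups.setdefault(cid, []).append(s.p_value)
    clusters = {
        cid: (float(np.mean(v)), float(min(v)), float(max(v)), len(v))
        for cid, v in groups.items()
    }
    all_p = [s.p_value for s in scores]
    return ClusterSummary(clusters, float(min(all_p)), float(max(all_p)))


def flag_disagreement(
    exp: CSPTable,
    sim: SimulatedCSPMatrix,
    strong_threshold: float = DEFAULT_STRONG_THRESHOLD,
    moderate_threshold: float = DEFAULT_MODERATE_THRESHOLD,
    scope: int | None = None,
) -> DisagreementReport:
    """Tier residues by how far experiment exceeds the best simulated CSP.

    For each residue shared between experiment and simulation,
    ``delta = CSP_H_exp - max over in-scope poses of CSP_H_sim``.  A positive
    delta means no candidate pose's ring-current field can account for the
    observed perturbation — the signature of a protein rearrangement.
    ``scope`` restricts the pose set to one cluster id (default: all poses).
    """
    if not (strong_threshold > moderate_threshold > 0):
        raise AnalysisError(
            "thresholds must satisfy strong > moderate > 0, got "
            f"{strong_threshold} / {moderate_threshold}"
        )
    if scope is None:
        cols = list(range(len(sim.pose_ids)))
        scope_label = "all"
    else:
        clusters = sim.cluster_ids or [None] * len(sim.pose_ids)
        cols = [j for j, c in enumerate(clusters) if c == scope]
        scope_label = f"cluster {scope}"
    if not cols:
        raise AnalysisError(f"no poses in scope ({scope_label})")

    shared = [r for r in sim.residues if r in exp.entries]
    if not shared:
        raise AnalysisError("experiment and simulation share no residues")

    entries: list[ResidueDisagreement] = []
    for res in shared:
        i = sim.residues.index(res)
        max_sim = float(sim.values[i, cols].max())
        exp_h = exp.entries[res].csp_h
        delta = exp_h - max_sim
        if delta > strong_threshold:
            tier = "strong"
        elif delta > moderate_threshold:
            tier = "moderate"
        elif delta < 0:
            tier = "sim_exceeds_exp"
        else:
            tier = "none"
        entries.append(ResidueDisagreement(res, exp_h, max_sim, delta, tier))
    return DisagreementReport(
        entries=entries,
        strong_threshold=strong_threshold,
        moderate_threshold=moderate_threshold,
        scope=scope_label,
    )


def write_attribute_file(report: DisagreementReport, path) -> None:
    """Per-residue delta attribute table for structure-viewer colouring."""
    with open(path, "w") as fh:
        fh.write("# per-residue delta = experimental CSP_H - max simulated CSP_H (ppm)\n")
        fh.write(f"# scope: {report.scope}\n")
        fh.write("chain\tresidue_number\tdelta\ttier\n")
        for e in sorted(report.entries, key=lambda e: (e.key[0], e.key[1])):
            fh.write(f"{e.key[0]}\t{e.key[1]}\t{e.delta:.6f}\t{e.tier}\n")
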