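"""Docked-pose triage.

Docking produces tens of thousands of raw nanobody placements on the
antigen.  This stage keeps only "compatible" poses: those that overlap the
competitor GTPase binding site substantially (so the design can compete with
the natural partner), avoid the bulky scaffold domain, touch the epitope with
all three CDR loops, and satisfy the CDR1/CDR2 anchor-distance constraint
used during docking.

Overlap and hindrance are both measured as a clashscore (clash count per
1000 pose atoms); the defaults require clashscore ≥ 30 against the
competitor and < 10 against the scaffold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .mdrmsd import LoopDefinition
from .structio import AtomRecord, ChainModel, clash_metrics

__all__ = [
    "DockedPose",
    "TriageThresholds",
    "competitor_overlap_score",
    "scaffold_clash_score",
    "cdr_contact_check",
    "anchor_constraint_check",
    "triage_poses",
]


@dataclass
class DockedPose:
    """One nanobody placement in the antigen frame, with engine provenance."""

    pose_id: str
    nanobody: ChainModel
    complementarity_score: float = float("nan")
    engine_rank: int = -1
    source_chain: str = ""


@dataclass
class TriageThresholds:
    competitor_overlap_min: float = 30.0  # clashscore, keep requires >=
    scaffold_clash_max: float = 10.0  # clashscore, keep requires <
    contact_cutoff: float = 5.0  # Å, heavy-atom CDR-epitope contact
    anchor_residues: tuple[int, int] = (38, 60)
    anchor_distance_max: float = 12.0  # Å

    def __post_init__(self) -> None:
        for name in (
            "competitor_overlap_min",
            "scaffold_clash_max",
            "contact_cutoff",
            "anchor_distance_max",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def competitor_overlap_score(
    pose: DockedPose, competitor_atoms: Sequence[AtomRecord]
) -> float:
    """Clashscore of the pose against the competitor (spatial-overlap proxy)."""
    if not competitor_atoms:
        raise ValueError("empty competitor atom set")
    _, score = clash_metrics(pose.nanobody.atoms, competitor_atoms)
    return score


def scaffold_clash_score(pose: DockedPose, scaffold_atoms: Sequence[AtomRecord]) -> float:
    """Clashscore of the pose against the scaffold domain (steric hindrance)."""
    if not scaffold_atoms:
        raise ValueError("empty scaffold atom set")
    _, score = clash_metrics(pose.nanobody.atoms, scaffold_atoms)
    return score


def _heavy_coords(atoms: Sequence[AtomRecord]) -> np.ndarray:
    return np.array(
        [a.xyz for a in atoms if a.element.upper() not in {"H", "D"}], dtype=float
    )


def cdr_contact_check(
    pose: DockedPose,
    antigen_atoms: Sequence[AtomRecord],
    loopdef: LoopDefinition,
    cutoff: float = 5.0,
) -> tuple[dict[str, bool], bool]:
    """Does each CDR place at least one heavy atom within ``cutoff`` of the antigen?"""
    ag = _heavy_coords(antigen_atoms)
    if ag.size == 0:
        raise ValueError("empty antigen atom set")
    tree = cKDTree(ag)
    verdict: dict[str, bool] = {}
    for loop, (lo, hi) in loopdef.loops.items():
        loop_atoms = [
            a
            for res in pose.nanobody.residues
            if lo <= res.res_seq <= hi
            for a in res.atoms
            if a.element.upper() not in {"H", "D"}
        ]
        if not loop_atoms:
            raise ValueError(f"{loop} range {lo}-{hi} resolves to no residues")
        d, _ = tree.query(np.array([a.xyz for a in loop_atoms]))
        verdict[loop] = bool(np.min(d) <= cutoff)
    return verdict, all(verdict.values())


def anchor_constraint_check(
    pose: DockedPose,
    epitope_atoms: Sequence[AtomRecord],
    anchors: tuple[int, int] = (38, 60),
    dmax: float = 12.0,
) -> bool:
    """Are both anchor residues' Cα within ``dmax`` of the nearest epitope atom?

    This is a post-hoc geometric surrogate for the two-point distance
    constraint (CDR1 residue 38, CDR2 residue 60) imposed during docking.
    """
    ep = _heavy_coords(epitope_atoms)
    if ep.size == 0:
        raise ValueError("empty epitope atom set")
    tree = cKDTree(ep)
    for res_seq in anchors:
        res = pose.nanobody.get_residue(res_seq)  # KeyError if absent
        ca = [a for a in res.atoms if a.atom_name == "CA"]
        if not ca:
            raise KeyError(f"residue {res_seq} has no CA atom")
        d, _ = tree.query(ca[0].xyz)
        if d > dmax:
            return False
    return True


def triage_poses(
    poses: Sequence[DockedPose],
    competitor_atoms: Sequence[AtomRecord],
    scaffold_atoms: Sequence[AtomRecord],
    thresholds: TriageThresholds | None = None,
    loopdef: LoopDefinition | None = None,
    antigen_atoms: Sequence[AtomRecord] | None = None,
) -> tuple[list[DockedPose], pd.DataFrame]:
    """Keep compatible poses; report every score for every input pose.

    A pose is retained iff its competitor overlap clashscore is ≥
    ``competitor_overlap_min`` AND its scaffold clashscore is <
    ``scaffold_clash_max`` AND (when ``loopdef`` and ``antigen_atoms`` are
    given) all three CDRs contact the antigen within ``contact_cutoff``.
    """
    thresholds = thresholds or TriageThresholds()
    rows = []
    retained: list[DockedPose] = []
    for pose in poses:
        overlap = competitor_overlap_score(pose, competitor_atoms)
        scaffold = scaffold_clash_score(pose, scaffold_atoms)
        row: dict = {
            "pose_id": pose.pose_id,
            "overlap_score": overlap,
            "scaffold_score": scaffold,
        }
        keep = (
            overlap >= thresholds.competitor_overlap_min
            and scaffold < thresholds.scaffold_clash_max
        )
        if loopdef is not None and antigen_atoms is not None:
            contacts, all_three = cdr_contact_check(
                pose, antigen_atoms, loopdef, thresholds.contact_cutoff
            )
            row.update(
                cdr1_contact=contacts["CDR1"],
                cdr2_contact=contacts["CDR2"],
                cdr3_contact=contacts["CDR3"],
            )
            keep = keep and all_three
        row["retained"] = keep
        rows.append(row)
        if keep:
            retained.append(pose)
    report = pd.DataFrame(rows)
    return retained, report
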