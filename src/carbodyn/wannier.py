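"""Assignment of precomputed Wannier centers to oxygens and R_O-MLWF stats.

Maximally localized Wannier-function centers are a proxy for electron-pair
positions: each is attached to its nearest oxygen (within 0.8 A) and
classified *bonding* when it lies close to a covalent-bond segment (O-H or
O-C), else *lone*.  The O-to-center distance R_O-MLWF is histogrammed per
oxygen role (hydroxyl vs carbonyl; for the CT conformer the trans-oriented
hydroxyl O2 is tracked separately from the cis-oriented O1) and conformer.
This module only consumes center coordinates supplied alongside the
trajectory; it performs no electronic-structure computation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from carbodyn.io import Frame, Trajectory, WannierStream, match_stride, min_image_vec
from carbodyn.topology import (
    BondMap,
    StateSequence,
    acid_dihedrals,
    assign_hydrogens,
    carboxyl_oxygens,
)

logger = logging.getLogger(__name__)

R_ASSIGN = 0.8  # max center-to-O distance, Angstrom
SEG_CUT = 0.45  # max center-to-bond-segment distance for "bonding"
H_BOND_CUT = 1.2  # covalent O-H neighbor cutoff
C_BOND_CUT = 1.6  # covalent O-C neighbor cutoff


@dataclass
class WannierAssignment:
    """Per-center attachment for one frame."""

    center_to_o: dict[int, int]
    pair_class: dict[int, str]  # lone / bonding
    r_o_mlwf: dict[int, float]
    unassigned: list[int] = field(default_factory=list)


def _near_bond_axis(p: np.ndarray, b: np.ndarray, seg_cut: float) -> bool:
    """True when p (relative to the O) sits alongside the bond vector b:
    positive projection within the bond length and perpendicular distance
    within ``seg_cut``.  A center perpendicular to every bond (zero or
    negative projection) is a lone pair however close to the nucleus."""
    blen = float(np.linalg.norm(b))
    if blen == 0:
        return False
    t = float(np.dot(p, b)) / blen
    if t <= 0 or t > blen:
        return False
    perp = float(np.linalg.norm(p - (t / blen) * b))
    return perp <= seg_cut


def assign_centers(
    frame: Frame,
    centers: np.ndarray,
    r_assign: float = R_ASSIGN,
    seg_cut: float = SEG_CUT,
) -> WannierAssignment:
    """Attach each center to its nearest oxygen and classify the pair.

    A center within ``seg_cut`` of the segment from its oxygen to a
    covalently bound neighbor (H within 1.2 A or C within 1.6 A) is a
    bonding pair, otherwise a lone pair.
    """
    centers = np.asarray(centers, dtype=float)
    o_idx = frame.indices_of("O")
    h_idx = frame.indices_of("H")
    c_idx = frame.indices_of("C")
    out = WannierAssignment(center_to_o={}, pair_class={}, r_o_mlwf={})
    for ci, center in enumerate(centers):
        d = np.array(
            [np.linalg.norm(min_image_vec(frame.coords[o], center, frame.cell))
             for o in o_idx]
        )
        j = int(np.argmin(d))
        if d[j] > r_assign:
            out.unassigned.append(ci)
            continue
        o = int(o_idx[j])
        rel_c = min_image_vec(frame.coords[o], center, frame.cell)
        bonding = False
        for n_idx, cut in ((h_idx, H_BOND_CUT), (c_idx, C_BOND_CUT)):
            for nb in n_idx:
                rel_n = min_image_vec(frame.coords[o], frame.coords[nb], frame.cell)
                if np.linalg.norm(rel_n) <= cut:
                    if _near_bond_axis(rel_c, rel_n, seg_cut):
                        bonding = True
                        break
            if bonding:
                break
        out.center_to_o[ci] = o
        out.pair_class[ci] = "bonding" if bonding else "lone"
        out.r_o_mlwf[ci] = float(d[j])
    return out


@dataclass
class RoleHistograms:
    """Raw R_O-MLWF values keyed by (conformer, oxygen_role, pair_class)."""

    values: dict[tuple[str, str, str], list[float]] = field(default_factory=dict)
    skipped_frames: int = 0

    def add(self, conformer: str, role: str, pair_class: str, r: float) -> None:
        self.values.setdefault((conformer, role, pair_class), []).append(r)

    def histogram(
        self, key: tuple[str, str, str], bins: int = 40,
        value_range: tuple[float, float] = (0.0, 0.8),
    ) -> tuple[np.ndarray, np.ndarray]:
        counts, edges = np.histogram(self.values[key], bins=bins, range=value_range)
        return (edges[:-1] + edges[1:]) / 2, counts

    def means(self) -> dict[tuple[str, str, str], float]:
        return {k: float(np.mean(v)) for k, v in sorted(self.values.items())}

    def to_tsv(self, path: str | Path, bins: int = 40,
               value_range: tuple[float, float] = (0.0, 0.8)) -> None:
        import pandas as pd

        rows = []
        for key in sorted(self.values):
            centers, counts = self.histogram(key, bins, value_range)
            for r, c in zip(centers, counts):
                rows.append(
                    {"conformer": key[0], "oxygen_role": key[1], "pair_class": key[2],
                     "r_bin": r, "count": int(c)}
                )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def r_distributions(
    traj: Trajectory,
    centers_stream: WannierStream,
    stateseq: StateSequence,
    bondmaps: Sequence[BondMap] | None = None,
    r_assign: float = R_ASSIGN,
    seg_cut: float = SEG_CUT,
) -> RoleHistograms:
    """R_O-MLWF distributions per oxygen role, pair class and conformer.

    Roles: ``carbonyl`` for the bare carboxyl oxygen; for CT frames the
    hydroxyl whose dihedral is trans is ``hydroxyl_O2`` and the cis one
    ``hydroxyl_O1``; CC (and TT) hydroxyls are pooled as ``hydroxyl``.
    Bicarbonate/carbonate frames carry no conformer role and are skipped.
    """
    stride = match_stride(centers_stream, traj)
    if stateseq.carbon is None:
        raise ValueError("state sequence carries no carbon index")
    out = RoleHistograms()
    for k, centers in enumerate(centers_stream.frames):
        i = k * stride
        frame = traj.frame(i)
        lab = stateseq.labels[i]
        if not lab.startswith("H2CO3"):
            out.skipped_frames += 1
            continue
        conformer = lab.split("_")[-1]
        bm = bondmaps[i] if bondmaps is not None else assign_hydrogens(frame)
        members = carboxyl_oxygens(frame, stateseq.carbon)
        carbonyl = [int(o) for o in members if bm.o_h_count[int(o)] == 0]
        alpha, beta, hydroxyls = acid_dihedrals(frame, bm, stateseq.carbon)
        roles: dict[int, str] = {carbonyl[0]: "carbonyl"}
        if conformer == "CT":
            angles = {hydroxyls[0]: alpha, hydroxyls[1]: beta}
            for o, ang in angles.items():
                roles[o] = "hydroxyl_O2" if abs(ang) >= np.pi / 2 else "hydroxyl_O1"
        else:
            roles[hydroxyls[0]] = "hydroxyl"
            roles[hydroxyls[1]] = "hydroxyl"
        assignment = assign_centers(frame, centers, r_assign, seg_cut)
        for ci, o in assignment.center_to_o.items():
            if o in roles:
                out.add(conformer, roles[o], assignment.pair_class[ci],
                        assignment.r_o_mlwf[ci])
    if out.skipped_frames:
        logger.info("skipped %d frames without a defined conformer", out.skipped_frames)
    return out
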