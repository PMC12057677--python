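"""Instantaneous chemical topology: O-H bonding, species and conformers.

Molecular identity in a reactive trajectory is defined frame by frame by
assigning each hydrogen to its minimum-image nearest oxygen (the standard
reactive-MD convention; a hard cutoff would leave protons unassigned
mid-hop).  The carbon species follows from the hydrogen count on the three
carboxyl oxygens, and the H2CO3 conformer (CC / CT / TT) from the two
carbonyl-C-hydroxyl-H dihedral angles alpha and beta: an angle is cis when
|angle| < pi/2, trans otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from carbodyn.io import (
    CellSpec,
    Frame,
    Trajectory,
    min_image_displacements,
    min_image_distance_matrix,
    min_image_vec,
)

logger = logging.getLogger(__name__)

# species labels
H2CO3_CC = "H2CO3_CC"
H2CO3_CT = "H2CO3_CT"
H2CO3_TT = "H2CO3_TT"
HCO3 = "HCO3"
CO3 = "CO3"
UNASSIGNED = "UNASSIGNED"

CONFORMER_LABELS = (H2CO3_CC, H2CO3_CT, H2CO3_TT)

#: O-H host distance (Angstrom) beyond which an assignment is flagged stretched.
OH_WARN = 1.30
#: carboxyl-O membership cutoff around C (covers C-OH ~1.34 and C=O ~1.21).
CO_CUT = 1.60


class TopologyError(ValueError):
    """Chemically inconsistent frame (e.g. carbon without 3 oxygens)."""


@dataclass
class BondMap:
    """Instantaneous H -> host-O assignment for one frame."""

    h_to_o: dict[int, int]
    o_h_count: dict[int, int]
    stretched: set[int] = field(default_factory=set)

    def hosts_of(self, o_index: int) -> list[int]:
        return [h for h, o in self.h_to_o.items() if o == o_index]


def assign_hydrogens(frame: Frame, oh_warn: float = OH_WARN) -> BondMap:
    """Map every H to its minimum-image nearest O.

    Ties within 1e-9 Angstrom resolve to the lower oxygen atom index and are
    logged.  Hosts farther than ``oh_warn`` are flagged ``stretched``.
    """
    o_idx = frame.indices_of("O")
    h_idx = frame.indices_of("H")
    if len(o_idx) == 0:
        raise TopologyError(f"frame {frame.index}: no oxygen atoms")
    h_to_o: dict[int, int] = {}
    stretched: set[int] = set()
    o_h_count = {int(o): 0 for o in o_idx}
    if len(h_idx):
        dist = min_image_distance_matrix(frame.coords[h_idx], frame.coords[o_idx], frame.cell)
        best = np.argmin(dist, axis=1)
        for row, h in enumerate(h_idx):
            d0 = dist[row, best[row]]
            ties = np.flatnonzero(dist[row] <= d0 + 1e-9)
            if len(ties) > 1:
                logger.debug(
                    "frame %d: H %d equidistant from O %s; lower index wins",
                    frame.index, h, [int(o_idx[t]) for t in ties],
                )
            host = int(o_idx[ties[0]])
            h_to_o[int(h)] = host
            o_h_count[host] += 1
            if d0 > oh_warn:
                stretched.add(int(h))
    return BondMap(h_to_o=h_to_o, o_h_count=o_h_count, stretched=stretched)


def carboxyl_oxygens(frame: Frame, carbon: int, co_cut: float = CO_CUT) -> np.ndarray:
    """The three oxygens covalently bound to a carbon, by distance cutoff."""
    o_idx = frame.indices_of("O")
    d = np.linalg.norm(
        min_image_displacements(frame.coords[carbon], frame.coords[o_idx], frame.cell), axis=-1
    )
    members = o_idx[d <= co_cut]
    if len(members) != 3:
        raise TopologyError(
            f"frame {frame.index}: carbon {carbon} has {len(members)} oxygens "
            f"within {co_cut} A (need 3)"
        )
    return members


def identify_carbon_species(
    frame: Frame, bondmap: BondMap, co_cut: float = CO_CUT
) -> dict[int, str]:
    """Raw species per carbon from the H count on its carboxyl oxygens."""
    out: dict[int, str] = {}
    for c in frame.indices_of("C"):
        members = carboxyl_oxygens(frame, int(c), co_cut)
        n_h = sum(bondmap.o_h_count[int(o)] for o in members)
        if n_h == 2:
            out[int(c)] = "H2CO3"
        elif n_h == 1:
            out[int(c)] = HCO3
        elif n_h == 0:
            out[int(c)] = CO3
        else:
            logger.warning(
                "frame %d: carbon %d carries %d hydrogens; leaving unassigned",
                frame.index, c, n_h,
            )
            out[int(c)] = UNASSIGNED
    return out


def dihedral(p1, p2, p3, p4, cell: CellSpec) -> float:
    """Signed dihedral of the p1-p2-p3-p4 chain in radians, in [-pi, pi).

    Bond vectors are minimum-image; the sign follows the IUPAC convention
    (positive for a clockwise rotation of the far bond viewed along p2->p3).
    """
    b1 = min_image_vec(p1, p2, cell)
    b2 = min_image_vec(p2, p3, cell)
    b3 = min_image_vec(p3, p4, cell)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise ValueError("collinear points: dihedral undefined")
    b2n = b2 / np.linalg.norm(b2)
    angle = float(np.arctan2(np.dot(np.cross(n1, n2), b2n), np.dot(n1, n2)))
    if angle >= np.pi:  # fold +pi onto the -pi side of the half-open interval
        angle -= 2 * np.pi
    if np.isclose(angle, np.pi):
        angle = -np.pi
    return angle


def classify_conformer(alpha: float, beta: float) -> str:
    """CC / CT / TT from the two (=O, C, O_OH, H) dihedrals.

    cis iff |angle| < pi/2 (the separatrix between the basins at 0 and pi).
    """
    cis_a = abs(alpha) < np.pi / 2
    cis_b = abs(beta) < np.pi / 2
    if cis_a and cis_b:
        return H2CO3_CC
    if cis_a or cis_b:
        return H2CO3_CT
    return H2CO3_TT


def acid_dihedrals(
    frame: Frame, bondmap: BondMap, carbon: int, co_cut: float = CO_CUT
) -> tuple[float, float, tuple[int, int]]:
    """(alpha, beta) for a doubly protonated acid, plus the hydroxyl O pair.

    The carbonyl O is the carboxyl oxygen hosting zero hydrogens; alpha
    belongs to the lower-index hydroxyl oxygen, beta to the higher.
    """
    members = carboxyl_oxygens(frame, carbon, co_cut)
    hydroxyl = sorted(int(o) for o in members if bondmap.o_h_count[int(o)] == 1)
    carbonyl = [int(o) for o in members if bondmap.o_h_count[int(o)] == 0]
    if len(hydroxyl) != 2 or len(carbonyl) != 1:
        raise TopologyError(
            f"frame {frame.index}: expected 2 hydroxyl + 1 carbonyl oxygens, "
            f"got {len(hydroxyl)} + {len(carbonyl)}"
        )
    angles = []
    for o in hydroxyl:
        h = bondmap.hosts_of(o)[0]
        angles.append(
            dihedral(
                frame.coords[carbonyl[0]],
                frame.coords[carbon],
                frame.coords[o],
                frame.coords[h],
                frame.cell,
            )
        )
    return angles[0], angles[1], (hydroxyl[0], hydroxyl[1])


@dataclass
class StateSequence:
    """Per-frame species/conformer labels with dihedrals and times."""

    labels: list[str]
    dihedrals: np.ndarray  # (n, 2), nan where undefined
    times: np.ndarray  # ps
    acid_oxygens: tuple[int, ...] = ()  # carboxyl O indices (constant ordering)
    carbon: int | None = None

    def __post_init__(self) -> None:
        self.dihedrals = np.asarray(self.dihedrals, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if len(self.labels) != len(self.times):
            raise ValueError("labels and times length mismatch")

    def __len__(self) -> int:
        return len(self.labels)

    def to_tsv(self, path: str | Path) -> None:
        import pandas as pd

        df = pd.DataFrame(
            {
                "frame": np.arange(len(self)),
                "time_ps": self.times,
                "label": self.labels,
                "alpha_rad": self.dihedrals[:, 0],
                "beta_rad": self.dihedrals[:, 1],
            }
        )
        df.to_csv(path, sep="\t", index=False)


def smooth_labels(labels: Sequence[str], window: int) -> list[str]:
    """Minimum-persistence label smoothing: runs shorter than ``window``
    frames are absorbed into the preceding accepted label."""
    if window <= 1 or not labels:
        return list(labels)
    out: list[str] = []
    runs: list[tuple[str, int]] = []
    for lab in labels:
        if runs and runs[-1][0] == lab:
            runs[-1] = (lab, runs[-1][1] + 1)
        else:
            runs.append((lab, 1))
    accepted: str | None = None
    for lab, n in runs:
        if n >= window or accepted is None:
            accepted = lab
        out.extend([accepted] * n)
    return out


def label_trajectory(
    traj: Trajectory,
    bondmaps: Sequence[BondMap] | None = None,
    co_cut: float = CO_CUT,
    oh_warn: float = OH_WARN,
    smooth_frames: int = 1,
) -> StateSequence:
    """Per-frame species + conformer labels for a single-solute trajectory."""
    carbons = np.flatnonzero(traj.species == "C")
    if len(carbons) != 1:
        raise TopologyError(f"expected exactly one carbon, found {len(carbons)}")
    carbon = int(carbons[0])
    labels: list[str] = []
    dihedrals = np.full((len(traj), 2), np.nan)
    acid_o: tuple[int, ...] = ()
    for i, frame in enumerate(traj):
        bm = bondmaps[i] if bondmaps is not None else assign_hydrogens(frame, oh_warn)
        try:
            members = carboxyl_oxygens(frame, carbon, co_cut)
        except TopologyError:
            raise
        if not acid_o:
            acid_o = tuple(int(o) for o in members)
        raw = identify_carbon_species(frame, bm, co_cut)[carbon]
        if raw == "H2CO3":
            alpha, beta, _ = acid_dihedrals(frame, bm, carbon, co_cut)
            dihedrals[i] = (alpha, beta)
            labels.append(classify_conformer(alpha, beta))
        else:
            labels.append(raw)
    if smooth_frames > 1:
        labels = smooth_labels(labels, smooth_frames)
    return StateSequence(
        labels=labels, dihedrals=dihedrals, times=traj.times.copy(),
        acid_oxygens=acid_o, carbon=carbon,
    )


def mole_percent(seq: StateSequence | Sequence[str]) -> dict[str, float]:
    """Species abundances x_i = n_i / N as percentages (sum to 100)."""
    labels = seq.labels if isinstance(seq, StateSequence) else list(seq)
    if not labels:
        raise ValueError("empty state sequence")
    n = len(labels)
    out: dict[str, float] = {}
    for lab in labels:
        out[lab] = out.get(lab, 0) + 1
    return {lab: 100.0 * c / n for lab, c in sorted(out.items())}
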