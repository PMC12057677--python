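"""Geometric hydrogen-bond detection and solute ring statistics.

A hydrogen bond is declared when the donor-acceptor O...O distance is within
``r_cut`` (default 3.5 A) and the H-O_donor...O_acceptor angle within
``ang_cut`` (default 30 deg) — the standard water criterion.  Bonds build an
undirected molecule graph in which the whole solute is contracted to a
single node; ring sizes therefore count molecules.  Ring statistics use the
primitive-ring criterion: a cycle counts only if no pair of its nodes is
connected by a graph path shorter than along the cycle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np

from carbodyn.io import Frame, Trajectory, min_image_vec
from carbodyn.topology import (
    CONFORMER_LABELS,
    BondMap,
    StateSequence,
    assign_hydrogens,
    carboxyl_oxygens,
)

logger = logging.getLogger(__name__)

R_CUT = 3.5  # O...O distance cutoff, Angstrom
ANG_CUT = 30.0  # H-O_d...O_a angle cutoff, degrees
MAX_RING_SIZE = 8
SOLUTE_NODE = 0  # molecule id of the contracted solute by convention


@dataclass(frozen=True)
class HBond:
    donor_o: int
    h: int
    acceptor_o: int
    r_oo: float
    angle: float  # degrees


def detect_hbonds(
    frame: Frame,
    bondmap: BondMap,
    r_cut: float = R_CUT,
    ang_cut: float = ANG_CUT,
) -> list[HBond]:
    """All donor-H/acceptor pairs meeting both geometric criteria.

    An oxygen may donate once per hosted hydrogen and accept any number of
    bonds.  Distances and angles use minimum-image vectors.
    """
    o_idx = frame.indices_of("O")
    bonds: list[HBond] = []
    for h, donor in bondmap.h_to_o.items():
        v_dh = min_image_vec(frame.coords[donor], frame.coords[h], frame.cell)
        for acceptor in o_idx:
            a = int(acceptor)
            if a == donor:
                continue
            v_da = min_image_vec(frame.coords[donor], frame.coords[a], frame.cell)
            r_oo = float(np.linalg.norm(v_da))
            if r_oo > r_cut:
                continue
            cosang = np.dot(v_dh, v_da) / (np.linalg.norm(v_dh) * r_oo)
            angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
            if angle <= ang_cut:
                bonds.append(HBond(donor_o=int(donor), h=int(h), acceptor_o=a,
                                   r_oo=r_oo, angle=angle))
    return bonds


def molecule_map(frame: Frame, bondmap: BondMap, carbon: int | None = None) -> dict[int, int]:
    """Assign each oxygen a molecule id; the three carboxyl O share id 0.

    Water oxygens get consecutive ids 1, 2, ... in atom-index order.
    """
    if carbon is None:
        carbons = frame.indices_of("C")
        if len(carbons) != 1:
            raise ValueError(f"expected one carbon, found {len(carbons)}")
        carbon = int(carbons[0])
    solute_o = {int(o) for o in carboxyl_oxygens(frame, carbon)}
    mapping: dict[int, int] = {}
    next_id = 1
    for o in frame.indices_of("O"):
        o = int(o)
        if o in solute_o:
            mapping[o] = SOLUTE_NODE
        else:
            mapping[o] = next_id
            next_id += 1
    return mapping


def build_graph(hbonds: Sequence[HBond], molecule_map: dict[int, int]) -> nx.Graph:
    """Undirected molecule-level H-bond graph.

    Parallel bonds between the same molecule pair collapse to one edge with
    a ``multiplicity`` attribute; intramolecular bonds (same molecule id)
    are dropped so the contracted solute carries no self-loop.
    """
    g = nx.Graph()
    g.add_nodes_from(sorted(set(molecule_map.values())))
    for b in hbonds:
        u, v = molecule_map[b.donor_o], molecule_map[b.acceptor_o]
        if u == v:
            continue
        if g.has_edge(u, v):
            g[u][v]["multiplicity"] += 1
        else:
            g.add_edge(u, v, multiplicity=1)
    return g


def count_solute_rings(
    graph: nx.Graph,
    max_size: int = MAX_RING_SIZE,
    solute: int = SOLUTE_NODE,
) -> dict[int, int]:
    """Primitive cycles through the solute node, keyed by ring size.

    A cycle is primitive when for every pair of its nodes the shortest path
    in the full graph is as long as the shorter arc along the cycle — i.e.
    the ring admits no chord-path shortcut.
    """
    if max_size < 3:
        raise ValueError("max_size must be >= 3")
    counts: dict[int, int] = {}
    if solute not in graph:
        return counts
    for cycle in nx.simple_cycles(graph, length_bound=max_size):
        if solute not in cycle:
            continue
        if _is_primitive(graph, cycle):
            k = len(cycle)
            counts[k] = counts.get(k, 0) + 1
    return dict(sorted(counts.items()))


def _is_primitive(graph: nx.Graph, cycle: Sequence[int]) -> bool:
    k = len(cycle)
    pos = {node: i for i, node in enumerate(cycle)}
    for i, u in enumerate(cycle):
        lengths = nx.single_source_shortest_path_length(graph, u, cutoff=k // 2)
        for j in range(i + 1, k):
            v = cycle[j]
            arc = min(j - i, k - (j - i))
            d = lengths.get(v)
            if d is not None and d < arc:
                return False
    return True


@dataclass
class RingHistogram:
    """Mean number of solute rings per frame, by size, for one conformer."""

    conformer: str
    counts: dict[int, float]
    n_frames: int

    @property
    def total_mean(self) -> float:
        return float(sum(self.counts.values()))


def rings_by_conformer(
    traj: Trajectory,
    stateseq: StateSequence,
    bondmaps: Sequence[BondMap] | None = None,
    r_cut: float = R_CUT,
    ang_cut: float = ANG_CUT,
    max_size: int = MAX_RING_SIZE,
    contract_solute: bool = True,
) -> dict[str, RingHistogram]:
    """Per-frame solute ring counts averaged within each conformer label.

    With ``contract_solute`` false each carboxyl oxygen is its own node
    (atomic-O sensitivity mode); ring sizes then count oxygens.
    """
    if stateseq.carbon is None:
        raise ValueError("state sequence carries no carbon index")
    sums: dict[str, dict[int, float]] = {}
    frames_per: dict[str, int] = {}
    for i, frame in enumerate(traj):
        lab = stateseq.labels[i]
        if lab not in CONFORMER_LABELS:
            continue
        bm = bondmaps[i] if bondmaps is not None else assign_hydrogens(frame)
        bonds = detect_hbonds(frame, bm, r_cut, ang_cut)
        mmap = molecule_map(frame, bm, stateseq.carbon)
        if contract_solute:
            g = build_graph(bonds, mmap)
            counts = count_solute_rings(g, max_size)
        else:
            solute_o = sorted(o for o, m in mmap.items() if m == SOLUTE_NODE)
            base = max(mmap.values()) + 1
            atomic_nodes = {solute_o[0]: SOLUTE_NODE}
            for extra, o in enumerate(solute_o[1:]):
                mmap[o] = base + extra
                atomic_nodes[o] = base + extra
            g = build_graph(bonds, mmap)
            counts = _rings_through(g, set(atomic_nodes.values()), max_size)
        frames_per[lab] = frames_per.get(lab, 0) + 1
        acc = sums.setdefault(lab, {})
        for k, v in counts.items():
            acc[k] = acc.get(k, 0.0) + v
    out: dict[str, RingHistogram] = {}
    for lab, acc in sums.items():
        n = frames_per[lab]
        out[lab] = RingHistogram(
            conformer=lab,
            counts={k: v / n for k, v in sorted(acc.items())},
            n_frames=n,
        )
    missing = set(CONFORMER_LABELS) - set(out)
    if missing:
        logger.info("conformers never visited: %s", sorted(missing))
    return out


def _rings_through(graph: nx.Graph, nodes: set[int], max_size: int) -> dict[int, int]:
    """Primitive-ring counts through any of the given nodes."""
    counts: dict[int, int] = {}
    for cycle in nx.simple_cycles(graph, length_bound=max_size):
        if not nodes.intersection(cycle):
            continue
        if _is_primitive(graph, cycle):
            k = len(cycle)
            counts[k] = counts.get(k, 0) + 1
    return dict(sorted(counts.items()))


def ring_histograms_to_tsv(hists: dict[str, RingHistogram], path: str | Path) -> None:
    import pandas as pd

    rows = []
    for lab, h in sorted(hists.items()):
        for size, mean in h.counts.items():
            rows.append(
                {"conformer": lab, "ring_size": size, "mean_count": mean,
                 "n_frames": h.n_frames}
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
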